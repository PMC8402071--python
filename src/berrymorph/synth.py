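"""Synthetic berry silhouettes with known ground truth.

Real berry panels are rarely redistributable, so every downstream stage of
the pipeline (trait measurement, elliptic Fourier analysis, discriminant
statistics) is exercised on generated silhouettes whose true dimensions are
recorded at draw time.  Outlines come in three families that cover the shape
vocabulary of table grapes — near-spherical, ellipsoidal and drop-like
(tapered toward one end) — and each variety is parameterized by normal
distributions of its length L, width W and thickness T in millimetres.

Conventions fixed here and relied on elsewhere:

* outline polygons are counter-clockwise in a y-up millimetre frame;
* the horizontal view of a berry is its L x W silhouette, the vertical view
  is the W x T cross-section (the section perpendicular to the length axis,
  which is elliptical for every family, taper included);
* rasterization flips y so that image row 0 is the top of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.measure import label as _label

__all__ = [
    "OutlineSpec",
    "VarietyConfig",
    "SilhouetteMask",
    "make_outline",
    "rasterize",
    "generate_dataset",
    "default_varieties",
    "load_variety_configs",
    "save_masks",
    "load_masks",
]

FAMILIES = ("ellipse", "circle", "drop")
#: family labels at the variety level; "sphere" shares the ellipse geometry
#: (its drawn L and W are nearly equal) but is kept distinct as ground truth
VARIETY_FAMILIES = ("ellipse", "sphere", "drop")

DEFAULT_SCALE = 0.05  # mm per pixel; a 30 mm berry spans ~600 px
DEFAULT_N_POINTS = 256


@dataclass(frozen=True)
class OutlineSpec:
    """Parameters of a single closed outline.

    ``length`` and ``width`` are the bounding-box extents in mm along x and
    y; ``asym`` in [0, 0.6] tapers the drop family toward +x (0 degenerates
    to the ellipse); ``n_points`` is the polygon vertex count.
    """

    family: str
    length: float
    width: float
    asym: float = 0.0
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown outline family {self.family!r}")
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"require L >= W > 0, got L={self.length}, W={self.width}"
            )
        if self.family == "circle" and abs(self.length - self.width) > 1e-12:
            raise ValueError("circle family requires L == W")
        if not (0.0 <= self.asym <= 0.6):
            raise ValueError(f"asym must lie in [0, 0.6], got {self.asym}")
        if self.family != "drop" and self.asym != 0.0:
            raise ValueError("asym is only meaningful for the drop family")
        if self.n_points < 16:
            raise ValueError("n_points must be at least 16")


@dataclass(frozen=True)
class VarietyConfig:
    """Dimension distributions of one variety group.

    ``family`` is the planted shape family ('ellipse', 'sphere' or 'drop');
    means and SDs are in mm.  Sampling is truncated at +/-3 SD and redrawn
    for nonpositive values or draws with W > L.
    """

    name: str
    family: str
    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float
    thickness_mean: float
    thickness_sd: float
    asym: float = 0.0
    n_berries: int = 40

    def __post_init__(self) -> None:
        if self.family not in VARIETY_FAMILIES:
            raise ValueError(f"unknown variety family {self.family!r}")
        for sd in (self.length_sd, self.width_sd, self.thickness_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.n_berries < 1:
            raise ValueError("n_berries must be >= 1")
        if self.length_mean < self.width_mean:
            raise ValueError("mean length must be >= mean width")

    @property
    def outline_family(self) -> str:
        """Geometric family used to draw outlines ('sphere' -> 'ellipse')."""
        return "drop" if self.family == "drop" else "ellipse"


@dataclass
class SilhouetteMask:
    """Binary raster of one berry in one orientation.

    ``pixels`` is a boolean array (row 0 = top); ``scale`` is mm per pixel;
    ``orientation`` is 'horizontal' (L along columns, W along rows) or
    'vertical' (W along columns, T along rows).
    """

    pixels: np.ndarray
    scale: float
    orientation: str
    variety: str = ""
    berry_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive (mm per pixel)")


def _shoelace_centroid(xy: np.ndarray) -> tuple[float, float, float]:
    """Signed area and area centroid of a closed polygon (last!=first)."""
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return area, cx, cy


def make_outline(spec: OutlineSpec) -> np.ndarray:
    """Build the closed polygon (mm) for an outline spec.

    Returns an ``(n_points, 2)`` array of (x, y) vertices, counter-clockwise,
    with the area centroid at the origin and the axis-aligned bounding box
    equal to ``(length, width)`` to within 1e-6 mm.  The ellipse/circle
    family is the parametric ellipse ``x = (L/2) cos t, y = (W/2) sin t``;
    the drop family multiplies the half-width by ``1 + asym * sin(t/2)``
    (widest near the -x end, tapering to +x) and is rescaled so the
    bounding box is preserved.
    """
    t = 2.0 * np.pi * np.arange(spec.n_points) / spec.n_points
    x = 0.5 * spec.length * np.cos(t)
    y = 0.5 * spec.width * np.sin(t)
    if spec.family == "drop" and spec.asym > 0.0:
        y = y * (1.0 + spec.asym * np.sin(0.5 * t))
    # pin the bounding box exactly, then recentre on the area centroid
    x *= spec.length / (x.max() - x.min())
    y *= spec.width / (y.max() - y.min())
    x -= 0.5 * (x.max() + x.min())
    y -= 0.5 * (y.max() + y.min())
    xy = np.column_stack([x, y])
    _, cx, cy = _shoelace_centroid(xy)
    xy[:, 0] -= cx
    xy[:, 1] -= cy
    return xy


def _scanline_fill(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of a closed polygon over integer pixel centres.

    ``rows``/``cols`` are float vertex coordinates; a pixel is foreground
    when its centre lies inside the polygon.  Vectorized over edges, so it
    is fast for large rasters.
    """
    out = np.zeros(shape, dtype=bool)
    r1, c1 = rows, cols
    r2, c2 = np.roll(rows, -1), np.roll(cols, -1)
    y = np.arange(shape[0], dtype=float)[:, None]          # scanlines
    crossing = (r1[None, :] <= y) != (r2[None, :] <= y)     # half-open rule
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = c1 + (y - r1) * (c2 - c1) / (r2 - r1)
    xs = np.where(crossing, xs, np.nan)
    counts = crossing.sum(axis=1)
    if (counts <= 2).all():
        idx = np.nonzero(counts == 2)[0]
        lo = np.ceil(np.nanmin(xs[idx], axis=1))
        hi = np.floor(np.nanmax(xs[idx], axis=1))
        for k, i in enumerate(idx):
            if lo[k] <= hi[k]:
                out[i, int(lo[k]) : int(hi[k]) + 1] = True
    else:
        for i in np.nonzero(counts > 0)[0]:
            xr = np.sort(xs[i][~np.isnan(xs[i])])
            for a, b in xr.reshape(-1, 2):
                ja, jb = int(np.ceil(a)), int(np.floor(b))
                if ja <= jb:
                    out[i, ja : jb + 1] = True
    return out


def _rotate90(xy: np.ndarray) -> np.ndarray:
    """Rotate a polygon 90 degrees counter-clockwise (keeps orientation)."""
    return np.column_stack([-xy[:, 1], xy[:, 0]])


def rasterize(
    polygon: np.ndarray,
    scale: float = DEFAULT_SCALE,
    margin: int = 8,
    *,
    orientation: str = "horizontal",
    variety: str = "",
    berry_id: int = 0,
) -> SilhouetteMask:
    """Rasterize a closed polygon (mm, y up) into a binary mask.

    A pixel is foreground when its centre falls inside the polygon.  The
    grid is sized to the polygon's bounding box plus ``margin`` background
    pixels on every side, so the foreground never touches the border.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if margin < 1:
        raise ValueError("margin must be >= 1")
    xy = np.asarray(polygon, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    w_px = (x.max() - x.min()) / scale
    h_px = (y.max() - y.min()) / scale
    if w_px * h_px > 4e8:
        raise ValueError(
            f"polygon of {w_px:.0f} x {h_px:.0f} px exceeds the representable grid"
        )
    cols = (x - x.min()) / scale + margin
    rows = (y.max() - y) / scale + margin  # y flip: row 0 on top
    shape = (int(np.ceil(h_px)) + 2 * margin + 1, int(np.ceil(w_px)) + 2 * margin + 1)
    pixels = _scanline_fill(rows, cols, shape)
    if not pixels.any():
        raise ValueError("polygon rasterized to an empty mask; check scale")
    if _label(pixels, connectivity=2).max() != 1:
        raise ValueError("rasterization produced multiple components")
    return SilhouetteMask(pixels, scale, orientation, variety, berry_id)


def _draw_dimensions(cfg: VarietyConfig, rng: np.random.Generator) -> tuple[float, float, float]:
    """One (L, W, T) draw: truncated at 3 SD, positive, and L >= W."""
    for _ in range(10_000):
        z = rng.standard_normal(3)
        if np.any(np.abs(z) > 3.0):
            continue
        L = cfg.length_mean + cfg.length_sd * z[0]
        W = cfg.width_mean + cfg.width_sd * z[1]
        T = cfg.thickness_mean + cfg.thickness_sd * z[2]
        if min(L, W, T) > 0 and L >= W:
            return float(L), float(W), float(T)
    raise RuntimeError(
        f"could not draw admissible dimensions for {cfg.name!r}; "
        "check that the configured means and SDs are physical"
    )


def generate_dataset(
    configs: list[VarietyConfig],
    master_seed: int,
    *,
    scale: float = DEFAULT_SCALE,
    n_points: int = DEFAULT_N_POINTS,
    margin: int = 8,
) -> tuple[list[SilhouetteMask], pd.DataFrame]:
    """Generate masks for every berry of every variety plus the truth table.

    Each berry contributes a horizontal (L x W) and a vertical (W x T) mask.
    The vertical view is the cross-section perpendicular to the length axis,
    which is elliptical for all families.  Reproducible: the per-variety
    random streams are spawned from ``master_seed``.
    """
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("variety names must be distinct")
    streams = np.random.SeedSequence(master_seed).spawn(len(configs))
    masks: list[SilhouetteMask] = []
    rows = []
    for cfg, ss in zip(configs, streams):
        rng = np.random.default_rng(ss)
        for b in range(cfg.n_berries):
            L, W, T = _draw_dimensions(cfg, rng)
            h_spec = OutlineSpec(
                cfg.outline_family, L, W,
                asym=cfg.asym if cfg.outline_family == "drop" else 0.0,
                n_points=n_points,
            )
            h_poly = make_outline(h_spec)
            # vertical view: ellipse with x extent W, y extent T
            v_spec = OutlineSpec("ellipse", max(W, T), min(W, T), n_points=n_points)
            v_poly = make_outline(v_spec)
            if T > W:
                v_poly = _rotate90(v_poly)
            masks.append(
                rasterize(h_poly, scale, margin, orientation="horizontal",
                          variety=cfg.name, berry_id=b)
            )
            masks.append(
                rasterize(v_poly, scale, margin, orientation="vertical",
                          variety=cfg.name, berry_id=b)
            )
            rows.append(
                dict(variety=cfg.name, berry_id=b, family=cfg.family,
                     asym=cfg.asym, L=L, W=W, T=T)
            )
    truth = pd.DataFrame(rows)
    return masks, truth


def default_varieties(n_berries: int = 40) -> list[VarietyConfig]:
    """Reference panel of ten table-grape variety groups.

    Dimension means/SDs (mm) follow published per-variety berry statistics
    for ten Anatolian table grapes; families are assigned from the reported
    shape descriptions: near-spherical varieties ('sphere'), elongated ones
    ('ellipse') and one drop-shaped variety.
    """
    rowspec = [
        # name,            family,    L mean, L sd,  W mean, W sd,  T mean, T sd, asym
        ("Ata Sarisi",     "ellipse", 30.87, 1.78, 25.21, 1.36, 25.60, 1.25, 0.0),
        ("Baris",          "sphere",  24.96, 1.81, 21.94, 1.38, 21.96, 1.36, 0.0),
        ("Dimiski",        "drop",    30.83, 1.64, 21.98, 0.86, 22.70, 0.80, 0.3),
        ("Hatun Parmagi",  "ellipse", 29.28, 1.81, 19.66, 0.82, 19.98, 1.05, 0.0),
        ("Helvani",        "sphere",  25.94, 1.04, 24.67, 0.99, 24.65, 1.06, 0.0),
        ("Horoz Karasi",   "ellipse", 33.77, 1.55, 22.00, 1.02, 22.70, 1.35, 0.0),
        ("Honusu",         "ellipse", 28.61, 1.41, 21.19, 0.81, 21.41, 0.80, 0.0),
        ("Italia",         "sphere",  26.11, 1.39, 23.45, 1.32, 23.58, 1.23, 0.0),
        ("Mevlana Sarisi", "ellipse", 33.77, 2.20, 20.17, 1.10, 20.92, 1.16, 0.0),
        ("Red Globe",      "sphere",  29.29, 1.59, 27.08, 1.61, 27.22, 1.97, 0.0),
    ]
    return [
        VarietyConfig(name, fam, lm, ls, wm, ws, tm, ts, asym=a, n_berries=n_berries)
        for name, fam, lm, ls, wm, ws, tm, ts, a in rowspec
    ]


def load_variety_configs(path: str | Path) -> list[VarietyConfig]:
    """Read variety configs from a YAML file (list of mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [VarietyConfig(**entry) for entry in raw]


def save_masks(masks: list[SilhouetteMask], out_dir: str | Path) -> list[Path]:
    """Write masks as 8-bit PNGs named ``<variety>_<id>_<orientation>.png``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in masks:
        safe = m.variety.replace(" ", "-") or "berry"
        p = out / f"{safe}_{m.berry_id:03d}_{m.orientation}.png"
        iio.imwrite(p, (m.pixels.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def load_masks(
    in_dir: str | Path, scale: float, threshold: int = 128
) -> list[SilhouetteMask]:
    """Read PNG/TIFF silhouettes written by :func:`save_masks`.

    Grayscale values are binarized at ``threshold``; metadata is recovered
    from the ``<variety>_<id>_<orientation>`` filename pattern.
    """
    masks = []
    for p in sorted(Path(in_dir).glob("*")):
        if p.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img[..., 0]
        stem = p.stem.rsplit("_", 2)
        if len(stem) == 3:
            variety, bid, orient = stem[0].replace("-", " "), int(stem[1]), stem[2]
        else:
            variety, bid, orient = p.stem, 0, "horizontal"
        masks.append(
            SilhouetteMask(img >= threshold, scale, orient, variety, bid)
        )
    return masks
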