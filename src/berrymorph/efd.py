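"""Elliptic Fourier analysis of closed raster contours.

The classic outline-morphometrics chain: the single foreground blob of a
silhouette is traced into a Freeman chain code; the chain's x- and
y-projections are expanded into elliptic Fourier harmonics (Kuhl &
Giardina's piecewise-linear arc-length integrals); the coefficients are
normalized for size, rotation, translation and starting point using the
first-harmonic ellipse; and principal components of the normalized
coefficients summarize shape variation across a collection of outlines,
which can be visualized by reconstructing outlines at mean +/- k SD along
a component.

Coefficient layout: harmonic n contributes (a_n, b_n) for x(t) and
(c_n, d_n) for y(t),

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)

and likewise y(t) with (c_n, d_n).  After normalization a1 = 1 and
b1 = c1 = 0; d1 is the first-harmonic aspect ratio (positive for
counter-clockwise contours).  The 180-degree start-point ambiguity of the
first-harmonic normalization (both ends of the major axis are admissible
start points; the two solutions differ by negating every even harmonic) is
pinned by requiring the largest-magnitude even-harmonic coefficient to be
positive.  Mirror images are deliberately not identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import SilhouetteMask

__all__ = [
    "ChainOutline",
    "EFDSet",
    "ShapePCA",
    "trace_contour",
    "chain_length",
    "chain_to_efd",
    "normalize",
    "reconstruct",
    "efd_matrix",
    "fit_pca",
    "pc_shape",
    "analyze_masks",
]

DEFAULT_HARMONICS = 20

# Freeman code k -> displacement, in a y-up frame: angle 45 k degrees
_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1])
_DY = np.array([0, 1, 1, 1, 0, -1, -1, -1])

# neighbour scan order in image coords (row down): E, SE, S, SW, W, NW, N, NE
_NBR = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


@dataclass
class ChainOutline:
    """Closed 8-connected boundary as start pixel + Freeman chain code.

    ``start`` is (row, col) of the first boundary pixel; ``code`` holds
    Freeman directions 0-7 (0 = +x, increasing counter-clockwise in the
    y-up mm frame); ``scale`` converts pixel steps to mm.
    """

    start: tuple[int, int]
    code: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.code = np.asarray(self.code, dtype=np.int8)
        if len(self.code) < 8:
            raise ValueError("chain code shorter than 8 steps is degenerate")
        if not self.closed:
            raise ValueError("chain code does not return to its start pixel")

    @property
    def closed(self) -> bool:
        return bool(_DX[self.code].sum() == 0 and _DY[self.code].sum() == 0)

    def points(self) -> np.ndarray:
        """Vertex coordinates in mm, y up: ``(len(code)+1, 2)``, closed."""
        r0, c0 = self.start
        x = (c0 + np.concatenate([[0], np.cumsum(_DX[self.code])])) * self.scale
        y = (-r0 + np.concatenate([[0], np.cumsum(_DY[self.code])])) * self.scale
        return np.column_stack([x, y])


@dataclass
class EFDSet:
    """Harmonic coefficients of one outline.

    ``coeffs`` has shape (n_harmonics, 4) with columns (a, b, c, d);
    ``dc`` is the (A0, C0) centroid offset of the raw expansion (zeroed by
    normalization).
    """

    coeffs: np.ndarray
    dc: tuple[float, float] = (0.0, 0.0)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape[1] != 4:
            raise ValueError("coeffs must have 4 columns (a, b, c, d)")

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major coefficient vector [a1, b1, c1, d1, a2, ...]."""
        return self.coeffs.ravel()


@dataclass
class ShapePCA:
    """Principal components of normalized coefficient vectors.

    The three constant columns of normalized sets (a1, b1, c1) are dropped
    before the eigendecomposition; ``free_idx`` records which flattened
    columns were retained.  ``loadings`` holds one unit eigenvector per
    column, eigenvalues are nonincreasing, and the loading element of
    largest magnitude is forced positive so scores are reproducible.
    """

    mean: np.ndarray          # full flattened mean vector (4 N)
    free_idx: np.ndarray      # indices of the analyzed columns
    eigenvalues: np.ndarray   # nonincreasing, >= 0
    proportions: np.ndarray   # fraction of total variance per component
    loadings: np.ndarray      # (n_free, n_components)
    scores: np.ndarray        # (n_outlines, n_components), centered

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _first_pixel(px: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(px)
    r0 = rows.min()
    return int(r0), int(cols[rows == r0].min())


def trace_contour(mask: SilhouetteMask) -> ChainOutline:
    """Freeman chain code of the single foreground component.

    Moore border following from the topmost-leftmost foreground pixel; the
    chain is returned counter-clockwise in the y-up mm frame (reversed if
    the raw trace came out clockwise).
    """
    px = mask.pixels
    if not px.any():
        raise ValueError("empty mask: nothing to trace")
    pad = np.pad(px, 1)
    r0, c0 = _first_pixel(px)
    start = (r0 + 1, c0 + 1)

    def scan(p, from_dir):
        for j in range(1, 9):
            d = (from_dir + j) % 8
            q = (p[0] + _NBR[d][0], p[1] + _NBR[d][1])
            if pad[q]:
                return d, q
        raise ValueError("isolated pixel: contour is degenerate")

    d0, q = scan(start, 4)  # initial backtrack: the (background) west cell
    moves = [d0]
    p, back = q, (d0 + 4) % 8
    limit = 4 * px.size
    while True:
        d, q = scan(p, back)
        if p == start and d == d0:
            break  # about to repeat the first directed edge: cycle closed
        moves.append(d)
        p, back = q, (d + 4) % 8
        if len(moves) > limit:
            raise RuntimeError("contour tracing failed to terminate")

    # image-frame scan direction d corresponds to Freeman code (8 - d) % 8
    code = (8 - np.asarray(moves)) % 8
    chain = ChainOutline((r0, c0), code, mask.scale)
    # enforce counter-clockwise orientation in mm space
    pts = chain.points()
    x, y = pts[:-1, 0], pts[:-1, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        rev = (code[::-1] + 4) % 8
        chain = ChainOutline((r0, c0), rev, mask.scale)
    return chain


def chain_length(outline: ChainOutline, corrected: bool = True) -> float:
    """Contour length (mm) of a Freeman chain.

    With ``corrected=True`` (default) straight and diagonal steps weigh
    0.948 and 1.340 (Kulpa's weights), which is close to unbiased for
    smooth contours; the naive 1 / sqrt(2) weighting overestimates the
    length of a digitized disk by ~5%.
    """
    diag = (outline.code % 2 == 1).sum()
    straight = len(outline.code) - diag
    if corrected:
        w_s, w_d = 0.948, 1.340
    else:
        w_s, w_d = 1.0, float(np.sqrt(2.0))
    return float((w_s * straight + w_d * diag) * outline.scale)


def chain_to_efd(outline: ChainOutline, n_harmonics: int = DEFAULT_HARMONICS) -> EFDSet:
    """Raw elliptic Fourier coefficients of a closed chain.

    Piecewise-linear arc-length integrals over the chain vertices; diagonal
    steps weigh sqrt(2).  The dc term is the exact centroid of the
    piecewise-linear curve.
    """
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    pts = outline.points()
    return _points_to_efd(pts, n_harmonics)


def _points_to_efd(pts: np.ndarray, n_harmonics: int) -> EFDSet:
    """EFD of any closed polyline (first point repeated at the end)."""
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if len(dt) < 3:
        raise ValueError("contour has fewer than 3 distinct vertices")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :] / T           # (N, K+1)
    dcos = np.diff(np.cos(phi), axis=1)
    dsin = np.diff(np.sin(phi), axis=1)
    const = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    dd = const * (dsin @ vy)
    # centroid of the piecewise-linear curve (exact segment midpoint rule)
    x_mid = pts[:-1][keep] + 0.5 * d
    dc = tuple((x_mid * dt[:, None]).sum(axis=0) / T)
    return EFDSet(np.column_stack([a, b, c, dd]), dc=(float(dc[0]), float(dc[1])))


def _param_rotate(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Shift the curve parameter start by ``theta`` (first-harmonic phase)."""
    out = np.empty_like(coeffs)
    n = np.arange(1, coeffs.shape[0] + 1)
    cos_t, sin_t = np.cos(n * theta), np.sin(n * theta)
    a, b, c, d = coeffs.T
    out[:, 0] = a * cos_t + b * sin_t
    out[:, 1] = -a * sin_t + b * cos_t
    out[:, 2] = c * cos_t + d * sin_t
    out[:, 3] = -c * sin_t + d * cos_t
    return out


def _space_rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the curve in the plane by ``-psi``."""
    out = np.empty_like(coeffs)
    a, b, c, d = coeffs.T
    out[:, 0] = np.cos(psi) * a + np.sin(psi) * c
    out[:, 1] = np.cos(psi) * b + np.sin(psi) * d
    out[:, 2] = -np.sin(psi) * a + np.cos(psi) * c
    out[:, 3] = -np.sin(psi) * b + np.cos(psi) * d
    return out


def normalize(e: EFDSet) -> EFDSet:
    """Size/rotation/translation/start-point normalization.

    Standardizes on the first-harmonic ellipse: the parameter origin is
    moved to the semi-major axis, the ellipse is rotated onto the x-axis
    and all coefficients are divided by the semi-major amplitude, giving
    a1 = 1, b1 = c1 = 0.  The residual two-fold start ambiguity is resolved
    by making the largest even-harmonic coefficient positive.  Idempotent.
    """
    C = e.coeffs.copy()
    a1, b1, c1, d1 = C[0]
    power = a1 * a1 + b1 * b1 + c1 * c1 + d1 * d1
    if power < 1e-30:
        raise ValueError("degenerate first harmonic: contour is point-like")
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1
    )
    C = _param_rotate(C, theta)
    psi = np.arctan2(C[0, 2], C[0, 0])
    C = _space_rotate(C, psi)
    scale = C[0, 0]
    if scale <= 0:  # numerically impossible after the rotations, but be safe
        raise ValueError("nonpositive first-harmonic amplitude")
    C /= scale
    # pin the 180-degree branch: negating the start point of the parameter
    # negates exactly the even harmonics
    if C.shape[0] >= 2:
        even = C[1::2]
        if even.size:
            k = np.argmax(np.abs(even))
            if even.ravel()[k] < 0:
                C[1::2] *= -1.0
    C[0, 1] = 0.0
    C[0, 2] = 0.0
    return EFDSet(C, dc=(0.0, 0.0), normalized=True)


def reconstruct(e: EFDSet, n_points: int = 256) -> np.ndarray:
    """Inverse truncated Fourier sum: closed polygon ``(n_points, 2)``."""
    th = 2.0 * np.pi * np.arange(n_points) / n_points
    n = np.arange(1, e.n_harmonics + 1)[:, None]
    cos_m = np.cos(n * th[None, :])
    sin_m = np.sin(n * th[None, :])
    a, b, c, d = e.coeffs.T
    x = e.dc[0] + a @ cos_m + b @ sin_m
    y = e.dc[1] + c @ cos_m + d @ sin_m
    return np.column_stack([x, y])


def efd_matrix(efds: list[EFDSet]) -> np.ndarray:
    """Stack flattened coefficient vectors into an (outlines, 4 N) matrix."""
    n = {e.n_harmonics for e in efds}
    if len(n) != 1:
        raise ValueError("all EFD sets must share the harmonic count")
    return np.vstack([e.flatten() for e in efds])


def fit_pca(X: np.ndarray, normalized: bool = True) -> ShapePCA:
    """Covariance-matrix PCA of coefficient vectors.

    For normalized sets the constant columns (a1, b1, c1) are excluded.
    Eigenvector signs are pinned (largest-magnitude element positive) and
    the number of retained components is ``min(n_outlines - 1, n_free)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 outlines to fit a PCA")
    free = np.arange(X.shape[1])
    if normalized:
        free = free[3:]
    Xf = X[:, free]
    mean = X.mean(axis=0)
    Xc = Xf - Xf.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    r = min(X.shape[0] - 1, len(free))
    vals, vecs = vals[:r], vecs[:, :r]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] *= -1.0
    total = vals.sum()
    props = vals / total if total > 0 else np.zeros_like(vals)
    scores = Xc @ vecs
    return ShapePCA(
        mean=mean,
        free_idx=free,
        eigenvalues=vals,
        proportions=props,
        loadings=vecs,
        scores=scores,
    )


def pc_shape(p: ShapePCA, pc: int, k: float, n_points: int = 256) -> np.ndarray:
    """Outline reconstructed at mean + k * SD along component ``pc``.

    ``k`` is in SD units (the usual panels use -2, 0, +2).
    """
    if not 0 <= pc < p.n_components:
        raise IndexError(f"component {pc} out of range (0..{p.n_components - 1})")
    vec = p.mean.copy()
    vec[p.free_idx] = (
        p.mean[p.free_idx]
        + k * np.sqrt(p.eigenvalues[pc]) * p.loadings[:, pc]
    )
    coeffs = vec.reshape(-1, 4)
    return reconstruct(EFDSet(coeffs, normalized=True), n_points=n_points)


def analyze_masks(
    masks: list[SilhouetteMask],
    n_harmonics: int = DEFAULT_HARMONICS,
    orientation: str = "horizontal",
) -> tuple[pd.DataFrame, list[EFDSet]]:
    """Chain-code, expand and normalize every mask of one orientation.

    Returns an id table (variety, berry_id) aligned with the list of
    normalized EFD sets.
    """
    ids, efds = [], []
    for m in masks:
        if m.orientation != orientation:
            continue
        e = normalize(chain_to_efd(trace_contour(m), n_harmonics))
        ids.append((m.variety, m.berry_id))
        efds.append(e)
    if not efds:
        raise ValueError(f"no masks with orientation {orientation!r}")
    return pd.DataFrame(ids, columns=["variety", "berry_id"]), efds
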