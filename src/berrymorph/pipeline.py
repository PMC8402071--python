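"""End-to-end analysis runs: generate, measure, EFA, discriminate, cluster.

A run is described by a :class:`RunConfig` and produces, under the output
directory:

* ``tables/`` — per-berry trait table, per-variety summary (mean +/- SD
  with Duncan letters), normalized EFD coefficients, shape-PC scores,
  discriminant eigenvalue tables, structure matrix, MANOVA blocks,
  pairwise Hotelling/Mahalanobis triangles and confusion matrices, for
  both the size/shape-trait block and the shape-PC block;
* ``figures/`` — discriminant biplots, shape variation panels
  (mean -2 SD / mean / mean +2 SD per component) and the centroid
  dendrogram;
* ``tree.nwk`` and ``manifest.json`` (config, seed, versions, row counts).

All interchange is CSV so every stage's output can be re-read by the
module that consumes it.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy as _hier

from . import efd as _efd
from . import morpho as _morpho
from . import mvstats as _mv
from . import synth as _synth

__all__ = ["RunConfig", "run_all", "DISCRIMINANT_TRAITS"]

log = logging.getLogger("berrymorph")

#: trait block used for the size/shape discriminant step.  The remaining
#: traits (ED, Dg, V, SA, Ev, PA_v) are deterministic functions of these
#: and would make the pooled within-group covariance singular.
DISCRIMINANT_TRAITS = [
    "phi", "Eh", "P_h", "PA_h", "L", "P_v", "T", "W", "C_h", "C_v",
]


@dataclass
class RunConfig:
    """Settings of one pipeline run (defaults follow the standard protocol:
    20 harmonics, alpha = 0.05, 0.05 mm/px, 40 berries per variety)."""

    out_dir: str = "berrymorph_run"
    seed: int = 0
    scale: float = _synth.DEFAULT_SCALE        # mm per pixel
    harmonics: int = _efd.DEFAULT_HARMONICS
    alpha: float = 0.05
    orientation: str = "horizontal"            # which view feeds the EFA
    n_berries: int = 40
    n_shape_pcs: int = 2                       # PCs fed to the shape CDA
    varieties_file: str | None = None          # YAML; None = built-in panel
    masks_dir: str | None = None               # load instead of generate
    save_masks: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **kw)


def _summary_table(traits: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Per-variety mean +/- SD with Duncan letters for every trait."""
    num_cols = [c for c in traits.columns if c not in ("variety", "berry_id")]
    rows = {}
    for col in num_cols:
        dres = _mv.anova_duncan(traits[col], traits["variety"], alpha=alpha)
        g = traits.groupby("variety")[col]
        mean, sd = g.mean(), g.std(ddof=1)
        rows[col] = {
            v: f"{mean[v]:.3f} +/- {sd[v]:.3f} {dres.letters[v]}"
            for v in mean.index
        }
    return pd.DataFrame(rows)


def _eigen_table(fit: _mv.DiscriminantResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "eigenvalue": fit.eigenvalues,
            "percent_variance": fit.percent_variance,
            "cumulative_percent": np.cumsum(fit.percent_variance),
            "canonical_correlation": fit.canonical_correlations,
        },
        index=pd.Index(range(1, len(fit.eigenvalues) + 1), name="function"),
    )


def _manova_table(m: _mv.ManovaResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("wilks_lambda", m.wilks_lambda, m.df_hypothesis, m.df_error_wilks,
             m.f_wilks, m.p_wilks),
            ("pillai_trace", m.pillai_trace, m.df_hypothesis, m.df_error_pillai,
             m.f_pillai, m.p_pillai),
        ],
        columns=["statistic", "value", "df_hypothesis", "df_error", "F", "p"],
    ).set_index("statistic")


def _pairwise_table(pw: _mv.PairwiseResult) -> pd.DataFrame:
    """Square table: D^2 in the lower triangle, corrected p above."""
    out = pw.p_corrected.copy()
    low = np.tril_indices(len(out), k=-1)
    out.values[low] = pw.d2.values[low]
    np.fill_diagonal(out.values, 0.0)
    return out


def _biplot(fit: _mv.DiscriminantResult, title: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 6))

    def pad2(a):  # single-function fits plot against zero on the y axis
        return a if a.shape[1] >= 2 else np.column_stack([a, np.zeros(len(a))])

    for gname in fit.groups:
        sel = fit.sample_groups == gname
        pts = pad2(fit.scores[sel][:, :2])
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.5, label=gname)
    cent = pad2(fit.centroids.to_numpy())
    ax.scatter(cent[:, 0], cent[:, 1], c="k", marker="x", s=60)
    ax.set_xlabel(f"Function 1 ({fit.percent_variance[0]:.1f}%)")
    if fit.scores.shape[1] > 1:
        ax.set_ylabel(f"Function 2 ({fit.percent_variance[1]:.1f}%)")
    ax.legend(fontsize=7, ncol=2)
    ax.set_title(title)
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _shape_panels(pca: _efd.ShapePCA, n_pcs: int, path: Path) -> None:
    n_pcs = min(n_pcs, pca.n_components)
    fig, axes = plt.subplots(n_pcs, 3, figsize=(6, 2 * n_pcs), squeeze=False)
    for i in range(n_pcs):
        for j, k in enumerate((-2.0, 0.0, 2.0)):
            poly = _efd.pc_shape(pca, i, k)
            ax = axes[i][j]
            ax.fill(poly[:, 0], poly[:, 1], color="0.6")
            ax.set_aspect("equal")
            ax.set_axis_off()
            if i == 0:
                ax.set_title(["mean - 2 SD", "mean", "mean + 2 SD"][j], fontsize=8)
        axes[i][0].set_axis_on()
        axes[i][0].set_ylabel(
            f"PC{i + 1} ({100 * pca.proportions[i]:.2f}%)", fontsize=8
        )
        axes[i][0].set_xticks([])
        axes[i][0].set_yticks([])
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _dendrogram(tree: _mv.ClusterTree, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    _hier.dendrogram(tree.linkage, labels=tree.labels, ax=ax, leaf_rotation=60)
    ax.set_ylabel("Euclidean distance (between-group linkage)")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of in-memory results.

    Any stage failure raises with the stage name in the message.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    tables, figures = out / "tables", out / "figures"
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        # ---- generate ----------------------------------------------------
        stage = "generate"
        t0 = time.time()
        if config.masks_dir:
            masks = _synth.load_masks(config.masks_dir, config.scale)
            truth = None
        else:
            if config.varieties_file:
                configs = _synth.load_variety_configs(config.varieties_file)
            else:
                configs = _synth.default_varieties(n_berries=config.n_berries)
            masks, truth = _synth.generate_dataset(
                configs, config.seed, scale=config.scale
            )
            _write(truth, tables / "ground_truth.csv", index=False)
            if config.save_masks:
                _synth.save_masks(masks, out / "masks")
        timings[stage] = time.time() - t0
        log.info("generate: %d masks", len(masks))

        # ---- measure -----------------------------------------------------
        stage = "measure"
        t0 = time.time()
        traits = _morpho.measure_dataset(masks)
        _write(traits, tables / "traits.csv", index=False)
        _write(_summary_table(traits, config.alpha), tables / "trait_summary.csv")
        timings[stage] = time.time() - t0
        log.info("measure: %d berries", len(traits))

        # ---- elliptic Fourier -------------------------------------------
        stage = "efd"
        t0 = time.time()
        ids, efds = _efd.analyze_masks(
            masks, n_harmonics=config.harmonics, orientation=config.orientation
        )
        coeff = _efd.efd_matrix(efds)
        long = []
        for (row, e) in zip(ids.itertuples(index=False), efds):
            for h in range(e.n_harmonics):
                long.append((row.variety, row.berry_id, h + 1, *e.coeffs[h]))
        _write(
            pd.DataFrame(long, columns=["variety", "berry_id", "harmonic",
                                        "a", "b", "c", "d"]),
            tables / "efd_coefficients.csv", index=False,
        )
        pca = _efd.fit_pca(coeff, normalized=True)
        n_pcs = min(config.n_shape_pcs, pca.n_components)
        pc_scores = ids.copy()
        for j in range(n_pcs):
            pc_scores[f"PC{j + 1}"] = pca.scores[:, j]
        _write(pc_scores, tables / "shape_pc_scores.csv", index=False)
        _write(
            pd.DataFrame(
                {"eigenvalue": pca.eigenvalues,
                 "proportion": pca.proportions},
                index=pd.Index(range(1, pca.n_components + 1), name="pc"),
            ),
            tables / "shape_pca_summary.csv",
        )
        _shape_panels(pca, n_pcs, figures / "shape_pc_panels.png")
        timings[stage] = time.time() - t0
        log.info("efd: %d outlines, PC1 %.2f%%", len(efds),
                 100 * pca.proportions[0])

        # ---- discriminate: size/shape traits ----------------------------
        stage = "discriminate_traits"
        t0 = time.time()
        fit_tr = _mv.cda_fit(traits[DISCRIMINANT_TRAITS], traits["variety"])
        man_tr = _mv.manova_from_eigenvalues(
            fit_tr.eigenvalues, len(traits), len(fit_tr.groups),
            len(DISCRIMINANT_TRAITS),
        )
        pw_tr = _mv.hotelling_pairwise(
            traits[DISCRIMINANT_TRAITS], traits["variety"]
        )
        _write(_eigen_table(fit_tr), tables / "traits_discriminant.csv")
        _write(fit_tr.structure, tables / "traits_structure_matrix.csv")
        _write(_manova_table(man_tr), tables / "traits_manova.csv")
        _write(_pairwise_table(pw_tr), tables / "traits_pairwise.csv")
        _write(fit_tr.confusion, tables / "traits_confusion.csv")
        _biplot(fit_tr, "Discriminant functions: size and shape traits",
                figures / "traits_biplot.png")
        timings[stage] = time.time() - t0
        log.info("traits CDA: %.1f%% correct", fit_tr.percent_correct)

        # ---- discriminate: shape PC scores -------------------------------
        stage = "discriminate_shape"
        t0 = time.time()
        pc_cols = [f"PC{j + 1}" for j in range(n_pcs)]
        fit_pc = _mv.cda_fit(pc_scores[pc_cols], pc_scores["variety"])
        man_pc = _mv.manova_from_eigenvalues(
            fit_pc.eigenvalues, len(pc_scores), len(fit_pc.groups), n_pcs
        )
        pw_pc = _mv.hotelling_pairwise(pc_scores[pc_cols], pc_scores["variety"])
        _write(_eigen_table(fit_pc), tables / "shape_discriminant.csv")
        _write(_manova_table(man_pc), tables / "shape_manova.csv")
        _write(_pairwise_table(pw_pc), tables / "shape_pairwise.csv")
        _write(fit_pc.confusion, tables / "shape_confusion.csv")
        _biplot(fit_pc, "Discriminant functions: shape PC scores",
                figures / "shape_biplot.png")
        timings[stage] = time.time() - t0
        log.info("shape CDA: %.1f%% correct", fit_pc.percent_correct)

        # ---- cluster ------------------------------------------------------
        stage = "cluster"
        t0 = time.time()
        feats = pd.concat(
            [
                fit_tr.centroids.add_prefix("traits_"),
                fit_pc.centroids.reindex(fit_tr.centroids.index).add_prefix("shape_"),
            ],
            axis=1,
        )
        _write(feats, tables / "cluster_features.csv")
        tree = _mv.cluster_centroids(feats)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        _dendrogram(tree, figures / "dendrogram.png")
        timings[stage] = time.time() - t0

        # ---- manifest -----------------------------------------------------
        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "counts": {
                "masks": len(masks),
                "berries": int(len(traits)),
                "outlines": len(efds),
            },
            "results": {
                "traits_percent_correct": fit_tr.percent_correct,
                "shape_percent_correct": fit_pc.percent_correct,
                "shape_pc1_proportion": float(pca.proportions[0]),
                "wilks_lambda_traits": man_tr.wilks_lambda,
                "wilks_lambda_shape": man_pc.wilks_lambda,
            },
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "total_s": round(time.time() - t_start, 3),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return {
        "truth": truth,
        "traits": traits,
        "shape_pca": pca,
        "pc_scores": pc_scores,
        "fit_traits": fit_tr,
        "fit_shape": fit_pc,
        "manova_traits": man_tr,
        "manova_shape": man_pc,
        "pairwise_traits": pw_tr,
        "pairwise_shape": pw_pc,
        "tree": tree,
        "manifest": manifest,
    }
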