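"""Synthetic multi-atlas rs-fMRI cohorts with planted connectivity effects.

Each subject's ROI time series under a view is drawn i.i.d. from a zero-mean
multivariate normal whose correlation matrix is a shared per-view base matrix
plus (a) a class-specific shift of magnitude ``effect_size`` on a designated
set of edges — informative views only — and (b) a per-site random symmetric
perturbation emulating scanner/site batch effects.  Any target matrix that
loses positive definiteness is repaired by eigenvalue clipping and
re-normalised to unit diagonal; repairs are logged.

The generator writes exactly the plain-text formats the feature extractor
reads (whitespace-delimited ``.1D`` time-series files plus a phenotype CSV),
and is bit-reproducible for a fixed seed.  Time series are temporally white:
the downstream pipeline consumes only pairwise correlations, so autocorrelation
is deliberately not modelled (see docs/methods.md for the consequences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasSpec, ROITimeSeries, build_view_features, lower_triangle_indices

__all__ = ["CohortSpec", "Cohort", "make_cohort", "verify_cohort",
           "preset_spec", "PRESETS"]

logger = logging.getLogger(__name__)

PRESETS = ("null", "separable", "complementary-views", "noise-view")

_MIN_EIGENVALUE = 1e-3
_MAX_ABS_CORR = 0.98


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_per_class: tuple[int, int] = (40, 40)
    atlases: tuple[AtlasSpec, ...] = (
        AtlasSpec("synA", 10), AtlasSpec("synB", 12), AtlasSpec("synC", 14))
    n_timepoints: int = 120
    n_affected_edges: int = 8
    effect_size: float = 0.6
    informative_views: tuple[str, ...] | None = None  # None -> all views
    n_sites: int = 2
    site_scale: float = 0.02
    base_corr_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.informative_views is None:
            self.informative_views = tuple(a.name for a in self.atlases)
        min_dim = min(a.feature_dim for a in self.atlases
                      if a.name in self.informative_views) if self.informative_views else 0
        if self.informative_views and self.n_affected_edges > min_dim:
            raise ValueError(
                f"n_affected_edges {self.n_affected_edges} exceeds the smallest "
                f"informative view's feature dimension {min_dim}")


@dataclass
class Cohort:
    spec: CohortSpec
    phenotypes: pd.DataFrame  # subject_id, label, site
    timeseries: dict[str, list[ROITimeSeries]]  # view name -> per-subject series
    affected_edges: dict[str, list[tuple[int, int]]]  # informative views only
    generating_corr: dict[str, np.ndarray]  # view -> (N, n, n) target matrices

    @property
    def labels(self) -> np.ndarray:
        return self.phenotypes["label"].to_numpy()

    def view_features(self) -> dict[str, pd.DataFrame]:
        """Per-view FC feature tables (subject x S) via the feature extractor."""
        return {a.name: build_view_features(self.timeseries[a.name], a)
                for a in self.spec.atlases}

    def write(self, out_dir: str | Path) -> Path:
        """Write `.1D` files (one per subject per view) and phenotype.csv."""
        out = Path(out_dir)
        for atlas in self.spec.atlases:
            view_dir = out / atlas.name
            view_dir.mkdir(parents=True, exist_ok=True)
            for ts in self.timeseries[atlas.name]:
                header = f"# {ts.subject_id} {atlas.name} {atlas.n_rois} ROIs\n"
                body = "\n".join(
                    "\t".join(f"{v:.10f}" for v in row) for row in ts.data)
                (view_dir / f"rois_{ts.subject_id}.1D").write_text(header + body + "\n")
        self.phenotypes.to_csv(out / "phenotype.csv", index=False)
        return out


def _repair_correlation(sigma: np.ndarray, context: str = "") -> np.ndarray:
    """Clip eigenvalues to keep the matrix PD, renormalise to unit diagonal."""
    sigma = (sigma + sigma.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sigma)
    if eigval.min() < _MIN_EIGENVALUE:
        logger.debug("repairing non-PD correlation matrix %s (min eig %.3g)",
                     context, eigval.min())
        sigma = (eigvec * np.clip(eigval, _MIN_EIGENVALUE, None)) @ eigvec.T
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _base_correlation(n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    off = rng.normal(0.0, scale, size=(n, n))
    base = np.eye(n) + np.tril(off, -1) + np.tril(off, -1).T
    return _repair_correlation(base, "base")


def make_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate a cohort; optionally write it to ``out_dir``."""
    ss = np.random.SeedSequence(spec.seed)
    view_seeds = ss.spawn(len(spec.atlases))
    n0, n1 = spec.n_per_class
    n_subjects = n0 + n1
    labels = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    sites = np.arange(n_subjects) % spec.n_sites  # balanced within class order
    subject_ids = [f"sub-{k:04d}" for k in range(n_subjects)]
    phenotypes = pd.DataFrame({
        "subject_id": subject_ids,
        "label": labels,
        "site": [f"site{s}" for s in sites],
    })

    timeseries: dict[str, list[ROITimeSeries]] = {}
    affected: dict[str, list[tuple[int, int]]] = {}
    generating: dict[str, np.ndarray] = {}

    for atlas, vseed in zip(spec.atlases, view_seeds):
        rng = np.random.default_rng(vseed)
        n = atlas.n_rois
        base = _base_correlation(n, spec.base_corr_scale, rng)
        class_corr = [base, base.copy()]
        informative = atlas.name in spec.informative_views
        edges: list[tuple[int, int]] = []
        if informative and spec.n_affected_edges > 0 and spec.effect_size != 0.0:
            i_all, j_all = lower_triangle_indices(n)
            pick = rng.choice(len(i_all), size=spec.n_affected_edges, replace=False)
            edges = [(int(i_all[k]), int(j_all[k])) for k in pick]
            shifted = base.copy()
            for (i, j) in edges:
                target = np.clip(base[i, j] + spec.effect_size,
                                 -_MAX_ABS_CORR, _MAX_ABS_CORR)
                if abs(target - base[i, j]) < abs(spec.effect_size) / 2.0:
                    raise ValueError(
                        f"effect_size {spec.effect_size} cannot be planted on edge "
                        f"({i},{j}) of view {atlas.name}: base correlation "
                        f"{base[i, j]:.3f} leaves headroom only "
                        f"{_MAX_ABS_CORR - base[i, j]:.3f}")
                shifted[i, j] = shifted[j, i] = target
            class_corr[1] = _repair_correlation(shifted, f"{atlas.name}/class1")
        affected[atlas.name] = edges

        # per-site perturbations shared by both classes
        site_corr = np.empty((spec.n_sites, 2, n, n))
        for s in range(spec.n_sites):
            e = rng.normal(0.0, spec.site_scale, size=(n, n))
            e = np.tril(e, -1)
            e = e + e.T
            for c in (0, 1):
                site_corr[s, c] = _repair_correlation(
                    class_corr[c] + e, f"{atlas.name}/site{s}/class{c}")

        chol = {(s, c): np.linalg.cholesky(site_corr[s, c])
                for s in range(spec.n_sites) for c in (0, 1)}
        subj_seeds = np.random.SeedSequence(
            entropy=vseed.entropy, spawn_key=vseed.spawn_key + (1,)).spawn(n_subjects)
        series = []
        gen = np.empty((n_subjects, n, n))
        for k in range(n_subjects):
            s, c = int(sites[k]), int(labels[k])
            z = np.random.default_rng(subj_seeds[k]).standard_normal(
                (spec.n_timepoints, n))
            series.append(ROITimeSeries(subject_ids[k], atlas, z @ chol[(s, c)].T))
            gen[k] = site_corr[s, c]
        timeseries[atlas.name] = series
        generating[atlas.name] = gen

    cohort = Cohort(spec=spec, phenotypes=phenotypes, timeseries=timeseries,
                    affected_edges=affected, generating_corr=generating)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def verify_cohort(cohort: Cohort, alpha: float = 0.01) -> dict:
    """Recompute FC through the feature extractor and test the planted structure.

    For every edge of every view, a two-sample t-test compares the two
    classes' sample correlations.  The report gives, per view, the fraction
    of planted edges flagged at ``alpha``, the total flagged fraction, and a
    site-effect summary; plus cohort-level class balance.  Report-only: never
    raises on a failed check.
    """
    features = cohort.view_features()
    y = cohort.labels
    sites = cohort.phenotypes["site"].to_numpy()
    report: dict = {
        "alpha": alpha,
        "n_subjects": int(len(y)),
        "class_counts": {"HC": int((y == 0).sum()), "ASD": int((y == 1).sum())},
        "views": {},
    }
    for atlas in cohort.spec.atlases:
        x = features[atlas.name].to_numpy()
        _, pvals = stats.ttest_ind(x[y == 1], x[y == 0], axis=0)
        flagged = pvals < alpha
        i_idx, j_idx = lower_triangle_indices(atlas.n_rois)
        edge_pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(i_idx, j_idx))}
        planted = [edge_pos[e] for e in cohort.affected_edges[atlas.name]]
        site_means = np.array([x[sites == s].mean() for s in np.unique(sites)])
        report["views"][atlas.name] = {
            "n_edges": int(x.shape[1]),
            "n_planted": len(planted),
            "planted_flagged_frac":
                float(flagged[planted].mean()) if planted else None,
            "total_flagged_frac": float(flagged.mean()),
            "site_mean_fc_variance": float(site_means.var()),
        }
    return report


def preset_spec(name: str, seed: int = 0, scale: str = "test") -> CohortSpec:
    """Named study conditions used by the tests, CLI and acceptance runs.

    * ``null``: no class effect anywhere — downstream accuracy should sit at
      chance.
    * ``separable``: strong effects (delta 0.6 on 8 edges) planted in all
      three views.
    * ``complementary-views``: moderate effects (delta 0.45 on 4 edges) with
      each view drawing its own edge set, so views carry complementary signal.
    * ``noise-view``: two views, only the first informative — attention should
      learn to favour it.

    Only the desk-scale ``scale="test"`` conditions (10/12/14-ROI atlases,
    T=120, 40+40 subjects, 2 sites) are defined; they keep the full pipeline
    runnable in minutes on one CPU.
    """
    if scale != "test":
        raise ValueError(f"unknown scale {scale!r}")
    three = (AtlasSpec("synA", 10), AtlasSpec("synB", 12), AtlasSpec("synC", 14))
    if name == "null":
        return CohortSpec(atlases=three, effect_size=0.0, n_affected_edges=0,
                          seed=seed)
    if name == "separable":
        return CohortSpec(atlases=three, effect_size=0.6, n_affected_edges=8,
                          seed=seed)
    if name == "complementary-views":
        return CohortSpec(atlases=three, effect_size=0.45, n_affected_edges=4,
                          seed=seed)
    if name == "noise-view":
        two = (AtlasSpec("synA", 10), AtlasSpec("synB", 12))
        return CohortSpec(atlases=two, effect_size=0.6, n_affected_edges=8,
                          informative_views=("synA",), seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose one of {PRESETS}")
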