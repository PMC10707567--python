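"""Readers, writers, run configuration and the end-to-end pipeline driver.

Time-series input follows the preprocessed-connectomes ``rois_*.1D`` dialect:
a whitespace-delimited numeric matrix of T rows x n ROI columns, optionally
preceded by one ``#`` header line.  Column order is trusted to match the
atlas's ROI order (the files carry no usable ROI names).  Phenotypes are CSV
with at least ``subject_id`` and ``label`` (ASD/HC strings or 1/0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import AtlasSpec, ROITimeSeries, build_view_features
from .config import ModelConfig
from .evaluation import EvalReport, train_maacnn, loocv

__all__ = [
    "ConfigError", "DataError",
    "read_roi_timeseries", "read_phenotypes", "read_view_dir",
    "write_features", "read_features", "RunConfig", "run_pipeline",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or missing input data (CLI exit code 3)."""


def read_roi_timeseries(path: str | Path, atlas: AtlasSpec,
                        subject_id: str | None = None) -> ROITimeSeries:
    """Parse one ``.1D`` file, validating the column count against the atlas."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if rows:
                    raise DataError(f"{path}:{lineno}: comment after data")
                continue
            try:
                rows.append([float(tok) for tok in stripped.split()])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric token ({exc})") from None
    if not rows:
        raise DataError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise DataError(f"{path}: ragged rows with widths {sorted(widths)}")
    n_cols = widths.pop()
    if n_cols != atlas.n_rois:
        raise DataError(
            f"{path}: expected {atlas.n_rois} ROI columns for atlas "
            f"{atlas.name}, found {n_cols}")
    if subject_id is None:
        stem = path.stem
        subject_id = stem[5:] if stem.startswith("rois_") else stem
    return ROITimeSeries(subject_id=subject_id, atlas=atlas,
                         data=np.asarray(rows, dtype=np.float64))


def read_phenotypes(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Load the phenotype CSV.

    Returns (table, excluded_subject_ids).  Labels are normalised to
    0 = HC, 1 = ASD; rows with a missing/unknown label are excluded and
    reported rather than silently dropped.  Duplicate ids are an error.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = {"subject_id", "label"} - set(df.columns)
    if missing_cols:
        raise DataError(f"{path}: missing required column(s) {sorted(missing_cols)}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise DataError(f"{path}: duplicate subject_id(s) {dupes}")
    mapping = {"ASD": 1, "HC": 0, "1": 1, "0": 0, 1: 1, 0: 0}
    raw = df["label"]
    norm = raw.map(lambda v: mapping.get(v if pd.isna(v) else
                                         (v.strip() if isinstance(v, str) else v)))
    excluded = df.loc[norm.isna(), "subject_id"].tolist()
    if excluded:
        logger.warning("excluding %d subject(s) with missing/unknown labels: %s",
                       len(excluded), excluded)
    out = df.loc[norm.notna()].copy()
    out["label"] = norm[norm.notna()].astype(int)
    return out.reset_index(drop=True), excluded


def read_view_dir(view_dir: str | Path, atlas: AtlasSpec,
                  subject_ids: list[str]) -> tuple[list[ROITimeSeries], list[str]]:
    """Load ``rois_<subject>.1D`` for each subject; missing files are returned
    in an exclusion report, not silently dropped."""
    view_dir = Path(view_dir)
    series, missing = [], []
    for sid in subject_ids:
        p = view_dir / f"rois_{sid}.1D"
        if not p.exists():
            missing.append(sid)
            continue
        series.append(read_roi_timeseries(p, atlas, subject_id=sid))
    if missing:
        logger.warning("view %s: %d subject file(s) missing: %s",
                       view_dir, len(missing), missing)
    return series, missing


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    """Per-view subject x feature table as CSV with a feature-index header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    views: dict[str, str]  # view name -> directory of .1D files
    atlases: dict[str, int]  # view name -> ROI count
    phenotypes: str
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    out_dir: str = "maacnn-out"
    protocol: str = "kfold"  # kfold | loocv

    def __post_init__(self) -> None:
        for name in self.views:
            if name not in self.atlases:
                raise ConfigError(f"view {name!r} has no atlas entry")
        if self.protocol not in ("kfold", "loocv"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")

    def atlas_spec(self, name: str) -> AtlasSpec:
        return AtlasSpec(name, self.atlases[name])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            model = ModelConfig.from_dict(raw.get("model", {}))
            return cls(views=dict(raw["views"]),
                       atlases={k: int(v) for k, v in raw["atlases"].items()},
                       phenotypes=raw["phenotypes"], model=model,
                       seed=int(raw.get("seed", 0)),
                       out_dir=raw.get("out_dir", "maacnn-out"),
                       protocol=raw.get("protocol", "kfold"))
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "views": self.views, "atlases": self.atlases,
            "phenotypes": self.phenotypes, "model": self.model.to_dict(),
            "seed": self.seed, "out_dir": self.out_dir, "protocol": self.protocol,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _provenance(config: RunConfig) -> dict:
    from . import __version__
    return {"package": "maacnn", "version": __version__,
            "config_digest": config.model.digest(), "seed": config.seed}


def run_pipeline(config: RunConfig) -> EvalReport:
    """features -> (per-fold SDA pretraining) -> train/evaluate, with artifacts
    and provenance written under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, path in config.views.items():
        if not Path(path).is_dir():
            raise DataError(f"view {name!r}: directory {path} does not exist")
    if not Path(config.phenotypes).exists():
        raise DataError(f"phenotype file {config.phenotypes} does not exist")

    pheno, _excluded = read_phenotypes(config.phenotypes)
    subject_ids = pheno["subject_id"].tolist()
    feature_tables: dict[str, pd.DataFrame] = {}
    keep = set(subject_ids)
    for name, path in config.views.items():
        atlas = config.atlas_spec(name)
        series, missing = read_view_dir(path, atlas, subject_ids)
        keep -= set(missing)
        feature_tables[name] = build_view_features(series, atlas)
    # drop subjects missing from any view so all views stay aligned
    kept_ids = [sid for sid in subject_ids if sid in keep]
    if not kept_ids:
        raise DataError("no subject present in every view")
    pheno = pheno[pheno["subject_id"].isin(keep)]
    views = {name: tbl.loc[kept_ids] for name, tbl in feature_tables.items()}
    for name, tbl in views.items():
        write_features(tbl, out / "features" / f"{name}.csv")

    y = pheno.set_index("subject_id").loc[kept_ids, "label"].to_numpy()
    runner = loocv if config.protocol == "loocv" else train_maacnn
    report = runner(views, y, config.model, seed=config.seed)

    payload = json.loads(report.to_json())
    payload["provenance"] = _provenance(config)
    (out / "eval_report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "eval_report.txt").write_text(report.table() + "\n")
    if report.attention_weights:
        pd.DataFrame([report.attention_weights]).to_csv(
            out / "attention_weights.csv", index=False)
    return report
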