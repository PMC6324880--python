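"""Tabular readers/writers and run manifests.

All tabular artifacts are tab-separated UTF-8 text with a header row and '.'
decimals; models and reports are JSON.  See docs/SCHEMAS.md for the column
contracts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruth, SubjectRecord

COHORT_COLUMNS = [
    "subject_id",
    "diagnosis",
    "site",
    "age",
    "sex",
    "wma_true",
    "score_3back",
    "score_nback",
    "score_digit",
    "fluid_iq",
    "composite_cog",
    "mean_fd",
]


def records_to_frames(
    records: list[SubjectRecord], feature_labels: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split subject records into a cohort table and an FC matrix."""
    cohort = pd.DataFrame(
        [{c: getattr(r, c) for c in COHORT_COLUMNS} for r in records]
    )
    fc = pd.DataFrame(
        np.vstack([r.fc for r in records]),
        columns=feature_labels,
        index=[r.subject_id for r in records],
    )
    fc.index.name = "subject_id"
    return cohort, fc


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id: {dup}")
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id: {dup}")
    return df


def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    row_ids: list[str],
    col_labels: list[str],
    index_name: str = "subject_id",
) -> None:
    """Write a labelled matrix as TSV (rows = subjects, header = features)."""
    df = pd.DataFrame(np.asarray(matrix), index=row_ids, columns=col_labels)
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "schema": "wmconn-ground-truth-1",
        "w_true": gt.w_true.tolist(),
        "support": gt.support.tolist(),
        "intercept_true": gt.intercept_true,
        "noise_sd": gt.noise_sd,
        "fc_mean": gt.fc_mean.tolist(),
        "fc_subject_sd": gt.fc_subject_sd,
        "delta": {k: v.tolist() for k, v in gt.delta.items()},
        "confound_coupling": gt.confound_coupling,
        "seed": gt.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    gt = GroundTruth(
        w_true=np.asarray(d["w_true"], dtype=float),
        intercept_true=float(d["intercept_true"]),
        noise_sd=float(d["noise_sd"]),
        fc_mean=np.asarray(d["fc_mean"], dtype=float),
        fc_subject_sd=float(d["fc_subject_sd"]),
        confound_coupling=d["confound_coupling"],
        seed=int(d["seed"]),
    )
    gt.delta = {k: np.asarray(v, dtype=float) for k, v in d["delta"].items()}
    return gt


def read_timeseries(path: str | Path) -> np.ndarray:
    """Voxels x frames plain-text matrix (whitespace or tab separated)."""
    return np.loadtxt(path)


def read_motion(path: str | Path) -> np.ndarray:
    """Frames x 6 realignment parameters."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion file {path} must have 6 columns")
    return m


def read_meta_intervals(path: str | Path) -> dict[str, dict[str, tuple[float, float]]]:
    """Meta-analytic effect-size confidence intervals from YAML or JSON.

    Layout: diagnosis -> measure -> [low, high].  These external constants
    are consumed as configuration (for effect-size containment checks) and
    never recomputed.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for diag, measures in raw.items():
        out[diag] = {}
        for measure, bounds in measures.items():
            lo, hi = (float(b) for b in bounds)
            if lo > hi:
                raise ValueError(
                    f"inverted interval for {diag}/{measure}: ({lo}, {hi})"
                )
            out[diag][measure] = (lo, hi)
    return out


def write_manifest(path: str | Path, config: dict, seeds: dict) -> None:
    """Record what produced a run: config hash, seeds, library versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True).encode()
    manifest = {
        "schema": "wmconn-manifest-1",
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seeds": seeds,
        "versions": {
            "wmconn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
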