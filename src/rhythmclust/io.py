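"""CSV reading/writing and configuration files.

The long-format sequence CSV has one row per sampled frame:

    sequence_id, subject_id, trial_id, side, task, score, frame, value

3-axis accelerometer files replace ``value`` with ``value_x, value_y,
value_z``.  Floats are written with 12 significant digits so that a
write/read round trip is the identity at that precision; all tables are
written in a deterministic row order so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .core import (
    AnalysisConfig,
    LabeledDataset,
    Sequence,
    SequenceMeta,
    TriaxialSequence,
    WindowSpec,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"

META_COLS = ["sequence_id", "subject_id", "trial_id", "side", "task", "score"]
SEQ_COLS = META_COLS + ["frame", "value"]
TRIAX_COLS = META_COLS + ["frame", "value_x", "value_y", "value_z"]

GRID_COLS = [
    "representation",
    "distance",
    "linkage",
    "auc",
    "auc_oriented",
    "n_cluster1",
    "n_cluster2",
    "delong_variance",
]
COMPARISON_COLS = [
    "pair",
    "representation_a",
    "representation_b",
    "auc_a",
    "auc_b",
    "z",
    "p",
    "p_fdr",
]


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: non-numeric {col!r} cell at data row {row} "
            f"(value {raw.loc[row]!r})"
        )
    return num


def _meta_from_group(sid: str, g: pd.DataFrame) -> SequenceMeta:
    first = g.iloc[0]
    score = first["score"]
    score = None if pd.isna(score) else float(score)
    return SequenceMeta(
        sequence_id=str(sid),
        subject_id=str(first.get("subject_id", "NA")),
        trial_id=str(first.get("trial_id", "NA")),
        side=str(first.get("side", "NA")),
        task=str(first.get("task", "")),
        score=score,
    )


def _read_long(path, value_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    # keep literal "NA" side/id strings; only truly empty cells are missing
    df = pd.read_csv(
        path,
        dtype={c: str for c in ["sequence_id", "subject_id", "trial_id", "side", "task"]},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in ["sequence_id", "frame"] + value_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in ["subject_id", "trial_id", "side"]:
        if c not in df.columns:
            df[c] = "NA"
        else:
            df[c] = df[c].fillna("NA")
    if "task" not in df.columns:
        df["task"] = ""
    else:
        df["task"] = df["task"].fillna("")
    if "score" not in df.columns:
        df["score"] = np.nan
    df["frame"] = _check_numeric(df, "frame", path).astype(int)
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    for c in value_cols:
        df[c] = _check_numeric(df, c, path)
    dup = df.duplicated(subset=["sequence_id", "frame"], keep=False)
    if dup.any():
        first = df.loc[dup, ["sequence_id", "frame"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate frame {int(first['frame'])} for sequence "
            f"{first['sequence_id']!r}"
        )
    return df


def read_sequences_csv(
    path, fps: float, kind: str = "position"
) -> LabeledDataset:
    """Read a long-format 1-D sequence CSV into a :class:`LabeledDataset`.

    Sequences with a missing score are retained (and flagged in the log);
    the evaluation stage drops them.
    """
    df = _read_long(path, ["value"])
    seqs = []
    for sid, g in df.groupby("sequence_id", sort=True):
        g = g.sort_values("frame")
        meta = _meta_from_group(sid, g)
        if meta.score is None:
            logger.info("sequence %r has no score; retained but unscored", sid)
        seqs.append(Sequence(g["value"].to_numpy(float), fps=fps, kind=kind, meta=meta))
    return LabeledDataset(seqs)


def read_triaxial_csv(path, fps: float) -> list[TriaxialSequence]:
    """Read a 3-axis accelerometer CSV (``value_x/value_y/value_z``)."""
    df = _read_long(path, ["value_x", "value_y", "value_z"])
    out = []
    for sid, g in df.groupby("sequence_id", sort=True):
        g = g.sort_values("frame")
        out.append(
            TriaxialSequence(
                g["value_x"].to_numpy(float),
                g["value_y"].to_numpy(float),
                g["value_z"].to_numpy(float),
                fps=fps,
                meta=_meta_from_group(sid, g),
            )
        )
    return out


def _meta_frame(meta: SequenceMeta, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": meta.sequence_id,
            "subject_id": meta.subject_id,
            "trial_id": meta.trial_id,
            "side": meta.side,
            "task": meta.task,
            "score": np.nan if meta.score is None else meta.score,
            "frame": np.arange(n),
        }
    )


def write_sequences_csv(ds: LabeledDataset, path) -> None:
    frames = []
    for s in sorted(ds, key=lambda s: s.meta.sequence_id):
        f = _meta_frame(s.meta, len(s))
        f["value"] = s.values
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEQ_COLS)
    out.to_csv(path, index=False, float_format=FLOAT_FMT, columns=SEQ_COLS)


def write_triaxial_csv(seqs: list[TriaxialSequence], path) -> None:
    frames = []
    for s in sorted(seqs, key=lambda s: s.meta.sequence_id):
        f = _meta_frame(s.meta, len(s))
        f["value_x"], f["value_y"], f["value_z"] = s.x, s.y, s.z
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRIAX_COLS)
    out.to_csv(path, index=False, float_format=FLOAT_FMT, columns=TRIAX_COLS)


def grid_to_frame(grid) -> pd.DataFrame:
    """Flatten a :class:`~rhythmclust.evaluation.GridResult` to a tidy table.

    One row per (representation, distance, linkage) condition, sorted
    lexicographically; conditions that failed (degenerate clustering etc.)
    appear with empty numeric cells.
    """
    rows = []
    for (rep, dist, link) in sorted(set(grid.results) | set(grid.errors)):
        r = grid.results.get((rep, dist, link))
        rows.append(
            {
                "representation": rep,
                "distance": dist,
                "linkage": link,
                "auc": np.nan if r is None else r.auc_raw,
                "auc_oriented": np.nan if r is None else r.auc_oriented,
                "n_cluster1": np.nan if r is None else r.n1,
                "n_cluster2": np.nan if r is None else r.n2,
                "delong_variance": np.nan if r is None else r.variance,
            }
        )
    return pd.DataFrame(rows, columns=GRID_COLS)


def write_grid_csv(grid, path) -> None:
    grid_to_frame(grid).to_csv(path, index=False, float_format=FLOAT_FMT)


def comparison_to_frame(result) -> pd.DataFrame:
    rows = [
        {
            "pair": row.pair,
            "representation_a": row.representation_a,
            "representation_b": row.representation_b,
            "auc_a": row.auc_a,
            "auc_b": row.auc_b,
            "z": row.z,
            "p": row.p,
            "p_fdr": row.p_fdr,
        }
        for row in result.rows
    ]
    return pd.DataFrame(rows, columns=COMPARISON_COLS)


def write_comparison_csv(result, path) -> None:
    comparison_to_frame(result).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_matrix_csv(matrix, path) -> None:
    """Export a ShortTimeMatrix as CSV with lag_k / freq_k row labels."""
    prefix = "lag" if matrix.transform == "ACF" else "freq"
    offset = 0 if matrix.transform == "ACF" else 1
    labels = [f"{prefix}_{i + offset}" for i in range(matrix.entries.shape[0])]
    pd.DataFrame(matrix.entries, index=labels).to_csv(
        path, float_format=FLOAT_FMT, header=[f"win_{j}" for j in range(matrix.entries.shape[1])]
    )


def config_to_dict(cfg: AnalysisConfig) -> dict:
    return {
        "window": {"width": cfg.window.width, "shift": cfg.window.shift},
        "representation": cfg.representation,
        "distance": cfg.distance,
        "linkage": cfg.linkage,
        "n_clusters": cfg.n_clusters,
        "seed": cfg.seed,
    }


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    window = d.get("window", {})
    return AnalysisConfig(
        window=WindowSpec(int(window.get("width", 45)), int(window.get("shift", 5))),
        representation=d.get("representation", "stacf_raw"),
        distance=d.get("distance", "dtw"),
        linkage=d.get("linkage", "ward_d"),
        n_clusters=int(d.get("n_clusters", 2)),
        seed=int(d.get("seed", 0)),
    )


def save_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
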