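"""Per-iteration trajectory records and their TSV serialization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TrajectoryRecord:
    """Snapshot of one iteration of an iterative reweighter.

    ``active_n`` is the number of nonzero-weight rows (hard removal) or the
    full cohort size (soft reweighting).  Optional fields are filled only
    when the corresponding quantity was monitored.
    """

    iteration: int
    active_n: int
    auroc: float | None = None
    mmd: float | None = None
    relative_bias: float | None = None
    best_mmd: float | None = None
    candidate_mmds: list = field(default_factory=list)
    dropped_ids: list = field(default_factory=list)
    oof_scores: np.ndarray | None = None
    weights: np.ndarray | None = None


_TSV_COLUMNS = ("iteration", "active_n", "auroc", "mmd", "relative_bias", "best_mmd")


def trajectory_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in _TSV_COLUMNS})
    return pd.DataFrame(rows, columns=list(_TSV_COLUMNS))


def write_trajectory(records, path) -> None:
    trajectory_frame(records).to_csv(path, sep="\t", index=False)
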