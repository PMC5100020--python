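"""Relative movement (RM) of the labeled S cohort.

RM normalizes the labeled cohort's mean DNA-stain fluorescence between the
unlabeled G1 and G2/M means:

    RM = (F_L - F_G1) / (F_G2/M - F_G1)

Under constant-rate synthesis and a cohort initially uniform across S, RM
is 0.5 immediately after the pulse and reaches 1.0 when every labeled
nucleus has finished replication.  RM is invariant to any linear gain
change of the DNA-stain channel.  Per-sample values across biological
replicates are pooled (not averaged) into one series for regression, so
replicate scatter propagates into the fitted slope confidence intervals;
per-time averaging across replicates is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DegeneratePopulationError, FittingInsufficiencyError
from .gating import GateSet, PopulationStats, gated_stats
from .io import TimeCourse

logger = logging.getLogger("sphase")

_COLUMNS = ("time_h", "rm", "replicate", "n_labeled", "n_g1", "n_g2m")


@dataclass
class RMSeries:
    """Pooled (time, RM) observations across replicates."""

    points: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(_COLUMNS)))

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.points.columns)
        if missing:
            raise ValueError(f"RMSeries missing columns {sorted(missing)}")
        self.points = self.points.sort_values(
            ["time_h", "replicate"], kind="stable").reset_index(drop=True)
        if (self.points["time_h"] < 0).any():
            raise ValueError("chase times must be >= 0")
        if not np.isfinite(self.points["rm"].to_numpy(float)).all():
            raise ValueError("RM values must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def t(self) -> np.ndarray:
        return self.points["time_h"].to_numpy(float)

    @property
    def rm(self) -> np.ndarray:
        return self.points["rm"].to_numpy(float)

    def require_fittable(self, min_points: int = 4) -> None:
        n_times = len(np.unique(self.t))
        if len(self) < min_points or n_times < 2:
            raise FittingInsufficiencyError(
                f"{len(self)} RM points over {n_times} distinct times; "
                f"need >= {min_points} points over >= 2 times")

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RMSeries":
        return cls(pd.read_csv(path, sep="\t"))


def relative_movement(stats: PopulationStats) -> float:
    """RM = (F_L - F_G1) / (F_G2/M - F_G1); unclamped, may leave [0, 1] under noise."""
    if not stats.f_g2m > stats.f_g1:
        raise DegeneratePopulationError(
            f"F_G2/M ({stats.f_g2m}) must exceed F_G1 ({stats.f_g1})")
    return (stats.f_l - stats.f_g1) / (stats.f_g2m - stats.f_g1)


def assemble_series(time_course: TimeCourse,
                    gates: Mapping[str, GateSet] | GateSet,
                    pooling: str = "pooled",
                    min_labeled: int = 50) -> RMSeries:
    """One RM point per (time, replicate) sample.

    ``gates`` maps replicate id to the gate set derived from that
    replicate's 0 h sample (a single :class:`GateSet` is applied to all
    replicates).  Samples whose labeled gate is empty or holds fewer than
    ``min_labeled`` events (a cohort-mean on a noise tail is meaningless,
    e.g. after the whole cohort has divided) are omitted with a warning.
    ``pooling="averaged"`` collapses replicates to one mean RM per time
    point.
    """
    if pooling not in ("pooled", "averaged"):
        raise ValueError(f"unknown pooling {pooling!r}")
    rows = []
    for table in time_course:
        rep = str(table.replicate)
        gate = gates if isinstance(gates, GateSet) else gates[rep]
        stats = gated_stats(table, gate, is_t0=(table.time_h == 0))
        if stats.labeled_missing or stats.n_labeled < min_labeled:
            logger.warning("only %d labeled events at t=%g h replicate %s "
                           "(minimum %d); RM point omitted",
                           stats.n_labeled, table.time_h, rep, min_labeled)
            continue
        rows.append({
            "time_h": table.time_h, "rm": relative_movement(stats),
            "replicate": rep, "n_labeled": stats.n_labeled,
            "n_g1": stats.n_g1, "n_g2m": stats.n_g2m,
        })
    df = pd.DataFrame(rows, columns=list(_COLUMNS))
    if pooling == "averaged" and len(df):
        df = (df.groupby("time_h", as_index=False)
                .agg(rm=("rm", "mean"), n_labeled=("n_labeled", "sum"),
                     n_g1=("n_g1", "sum"), n_g2m=("n_g2m", "sum"))
                .assign(replicate="mean"))[list(_COLUMNS)]
    return RMSeries(df)
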