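"""Synthetic EdU pulse-chase bivariate cytometry time courses.

The generator emulates a proliferating plant-cell population measured by
bivariate flow cytometry after a brief EdU pulse: unlabeled G1 (2C) and
G2/M (4C) clusters, a labeled S cohort initially spread uniformly between
2C and 4C, constant-rate DNA synthesis during the chase, division of cells
that finish G2/M into two 2C daughter nuclei (each carrying half the parent
label), optional residual low-level incorporation producing a dim "arm" of
weakly labeled nuclei, an optional slow or arrested subpopulation, sub-2C
debris, and multiplicative measurement noise on both channels.

All stochasticity flows from one ``numpy`` Generator keyed by
``SimConfig.seed``; the chase is a single simulated trajectory of one
population, sampled (not re-simulated) at each chase time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import EventTable, TimeCourse, write_events_csv, write_events_fcs, write_manifest

_G1, _S, _G2M, _PARKED, _STATIC_G1 = 0, 1, 2, 3, 4


@dataclass
class SimConfig:
    """Ground-truth cell-cycle and measurement parameters.

    Durations are hours.  ``label_gain`` is in arbitrary units per
    full-genome equivalent of DNA synthesized while labeled precursor is
    available (a cell traversing all of S during the pulse scores 1.0).
    ``residual_rate`` is the fraction of the pulse incorporation rate still
    active at chase start, decaying as ``exp(-t/residual_decay)``.
    Slow cells traverse S at ``1/slow_factor`` of the normal rate during
    the chase (the brief pulse labels them normally); ``slow_factor=inf``
    encodes arrest, freezing them at their current replicated fraction.
    ``noncycling_fraction`` of nuclei
    are static (differentiated tissue), split between 2C and 4C by
    ``noncycling_g2_fraction``; they keep the unlabeled G1 and G2/M anchor
    peaks occupied while the cycling pool turns over during the chase.
    """

    t_g1: float = 1.0
    t_s: float = 2.7
    t_g2m: float = 3.5
    pulse_len: float = 0.5
    chase_times: Sequence[float] = field(default_factory=lambda: tuple(float(t) for t in range(8)))
    n_cells: int = 20_000
    dapi_cv: float = 0.04
    label_cv: float = 0.10
    dapi_gain: float = 100.0
    label_gain: float = 1000.0
    label_background: float = 2.0
    residual_rate: float = 0.0
    residual_decay: float = 1.0
    slow_fraction: float = 0.0
    slow_factor: float = 1.0
    noncycling_fraction: float = 0.5
    noncycling_g2_fraction: float = 0.2
    debris_fraction: float = 0.05
    age_distribution: str = "uniform"
    divide_labeled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.chase_times = tuple(float(t) for t in self.chase_times)
        for name in ("t_g1", "t_s", "t_g2m"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be finite and > 0, got {v}")
        if not (math.isfinite(self.pulse_len) and self.pulse_len >= 0):
            raise ConfigurationError(f"pulse_len must be >= 0, got {self.pulse_len}")
        for name in ("slow_fraction", "debris_fraction", "noncycling_fraction",
                     "noncycling_g2_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        for name in ("dapi_cv", "label_cv", "residual_rate", "residual_decay",
                     "dapi_gain", "label_gain", "label_background"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        if not (self.slow_factor >= 1.0):  # inf allowed
            raise ConfigurationError(f"slow_factor must be >= 1, got {self.slow_factor}")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if len(self.chase_times) == 0 or list(self.chase_times) != sorted(self.chase_times):
            raise ConfigurationError("chase_times must be sorted ascending")
        if self.chase_times[0] != 0.0:
            raise ConfigurationError("first chase time must be 0")
        if self.age_distribution not in ("uniform", "exponential_growth"):
            raise ConfigurationError(
                f"unknown age_distribution {self.age_distribution!r}")

    @property
    def t_cycle(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2m

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chase_times"] = list(self.chase_times)
        return d


def closed_form_rm(u):
    """Noise-free relative movement of an ideal uniform S cohort.

    For a cohort with replicated fractions uniform on (0, 1) at pulse end,
    advancing at constant rate and truncated at completion, the mean
    position after a scaled chase time ``u = t / t_s`` in [0, 1] is
    ``0.5 + u - u**2 / 2``: 0.5 at u=0 and 1.0 when the whole cohort has
    finished replication.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or not np.all(np.isfinite(u)):
        raise ValueError("scaled chase time u must lie in [0, 1]")
    out = 0.5 + u - 0.5 * u * u
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population state and kinetics
# ---------------------------------------------------------------------------

class _Population:
    """Vectorized deterministic-kinetics population.

    ``frac`` is the fraction of the current phase elapsed; in S it equals
    the replicated fraction (DNA = 2C * (1 + frac)).  ``mult`` counts the
    nuclei represented by each lineage row (doubles at division).
    """

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        n = cfg.n_cells
        self.cfg = cfg
        # non-cycling nuclei (differentiated cells of the sampled tissue)
        # keep the unlabeled 2C and 4C anchor populations occupied while
        # the cycling pool turns over during the chase
        n_static = int(round(n * cfg.noncycling_fraction))
        n_static4 = int(round(n_static * cfg.noncycling_g2_fraction))
        n_cyc = n - n_static

        if cfg.age_distribution == "uniform":
            age = rng.random(n_cyc) * cfg.t_cycle
        else:  # density proportional to 2**(-a/T_C) on [0, T_C)
            u = rng.random(n_cyc)
            age = -cfg.t_cycle * np.log2(1.0 - 0.5 * u)
        slow = rng.random(n_cyc) < cfg.slow_fraction
        self.t_s_eff = np.concatenate([
            np.where(slow, cfg.t_s * cfg.slow_factor, cfg.t_s),
            np.full(n_static, cfg.t_s),
        ])

        self.phase = np.full(n, _G1, dtype=np.int8)
        self.frac = np.zeros(n)
        cyc = np.arange(n) < n_cyc
        in_s = np.zeros(n, dtype=bool)
        in_g2 = np.zeros(n, dtype=bool)
        in_s[:n_cyc] = (age >= cfg.t_g1) & (age < cfg.t_g1 + cfg.t_s)
        in_g2[:n_cyc] = age >= cfg.t_g1 + cfg.t_s
        in_g1 = cyc & ~in_s & ~in_g2
        self.phase[in_s] = _S
        self.phase[in_g2] = _G2M
        self.frac[in_g1] = age[in_g1[:n_cyc]] / cfg.t_g1
        self.frac[in_s] = (age[in_s[:n_cyc]] - cfg.t_g1) / cfg.t_s
        self.frac[in_g2] = (age[in_g2[:n_cyc]] - cfg.t_g1 - cfg.t_s) / cfg.t_g2m
        self.phase[n_cyc:n - n_static4] = _STATIC_G1
        self.phase[n - n_static4:] = _PARKED

        self.label = np.zeros(n)
        self.mult = np.ones(n, dtype=np.int64)
        self.divided = np.zeros(n, dtype=bool)
        self.pulse_labeled = np.zeros(n, dtype=bool)

    # -- label-incorporation efficiency integrals ---------------------------

    def _pulse_integral(self, a, b):
        return b - a  # full efficiency during the pulse

    def _chase_integral(self, a, b):
        cfg = self.cfg
        if cfg.residual_rate == 0.0:
            return np.zeros_like(a)
        rd = cfg.residual_decay
        if rd == 0.0:
            return np.zeros_like(a)
        return cfg.residual_rate * rd * (np.exp(-a / rd) - np.exp(-b / rd))

    # -- kinetics ------------------------------------------------------------

    def advance(self, t_start: float, t_end: float, during_pulse: bool) -> None:
        """Advance every lineage from absolute time t_start to t_end.

        The slow/arrest phenotype acts during the chase only: slow cells
        incorporate label normally during the brief pulse and then stall
        (or crawl) part way through S, which is what produces the stalled
        labeled subpopulation seen in arrested cultures.
        """
        cfg = self.cfg
        integral = self._pulse_integral if during_pulse else self._chase_integral
        t_s_eff = (np.full_like(self.t_s_eff, cfg.t_s) if during_pulse
                   else self.t_s_eff)
        remaining = np.full(len(self.frac), float(t_end - t_start))
        for _ in range(10_000):
            active = remaining > 1e-12
            if not active.any():
                break
            # phase transitions for cells sitting at a boundary with time left
            at_end = active & (self.frac >= 1.0 - 1e-12) & (self.phase < _PARKED)
            if at_end.any():
                g1_done = at_end & (self.phase == _G1)
                s_done = at_end & (self.phase == _S)
                g2_done = at_end & (self.phase == _G2M)
                self.phase[g1_done] = _S
                self.frac[g1_done] = 0.0
                self.phase[s_done] = _G2M
                self.frac[s_done] = 0.0
                if g2_done.any():
                    if cfg.divide_labeled:
                        self.phase[g2_done] = _G1
                        self.frac[g2_done] = 0.0
                        self.label[g2_done] *= 0.5
                        self.mult[g2_done] *= 2
                        self.divided[g2_done] = True
                    else:
                        self.phase[g2_done] = _PARKED

            dur = np.select(
                [self.phase == _G1, self.phase == _S, self.phase == _G2M],
                [np.full_like(self.frac, cfg.t_g1), t_s_eff,
                 np.full_like(self.frac, cfg.t_g2m)],
                default=np.inf,
            )
            finite = np.isfinite(dur)
            tte = np.where(finite, (1.0 - self.frac) * np.where(finite, dur, 1.0),
                           np.inf)
            step = np.where(active, np.minimum(remaining, tte), 0.0)

            syn = active & (self.phase == _S) & np.isfinite(t_s_eff) & (step > 0)
            if syn.any():
                a = t_end - remaining
                self.label[syn] += integral(a[syn], a[syn] + step[syn]) / t_s_eff[syn]

            self.frac = np.where(finite & active,
                                 self.frac + step / np.where(finite, dur, 1.0),
                                 self.frac)
            remaining -= step
        else:  # pragma: no cover - defensive
            raise RuntimeError("population kinetics failed to terminate")

    # -- measurement ---------------------------------------------------------

    def dna_content(self) -> np.ndarray:
        """DNA content in C units per lineage (2C in G1, 4C in G2/M)."""
        return np.select(
            [(self.phase == _G1) | (self.phase == _STATIC_G1), self.phase == _S],
            [np.full_like(self.frac, 2.0), 2.0 * (1.0 + np.minimum(self.frac, 1.0))],
            default=4.0,
        )

    def snapshot(self, time_h: float, rng: np.random.Generator,
                 replicate: str = "1") -> EventTable:
        cfg = self.cfg
        idx = np.repeat(np.arange(len(self.frac)), self.mult)
        dna = self.dna_content()[idx]
        amount = self.label[idx]
        truth_labeled = self.pulse_labeled[idx]
        truth_divided = self.divided[idx]
        truth_s_fraction = np.where(self.phase == _S, self.frac, np.nan)[idx]

        n_live = len(idx)
        d = cfg.debris_fraction
        n_debris = int(round(n_live * d / (1.0 - d))) if d > 0 else 0
        if n_debris:
            dna = np.concatenate([dna, rng.uniform(0.2, 1.8, n_debris)])
            amount = np.concatenate([amount, np.zeros(n_debris)])
            truth_labeled = np.concatenate([truth_labeled, np.zeros(n_debris, bool)])
            truth_divided = np.concatenate([truth_divided, np.zeros(n_debris, bool)])
            truth_s_fraction = np.concatenate([truth_s_fraction,
                                               np.full(n_debris, np.nan)])

        n_ev = len(dna)
        eps_d = rng.normal(0.0, cfg.dapi_cv, n_ev) if cfg.dapi_cv > 0 else 0.0
        eps_l = rng.normal(0.0, cfg.label_cv, n_ev) if cfg.label_cv > 0 else 0.0
        eps_s = rng.normal(0.0, 0.25, n_ev)
        dapi = cfg.dapi_gain * dna * (1.0 + eps_d)
        label = cfg.label_background + cfg.label_gain * amount * (1.0 + eps_l)
        ssc = 30.0 * dna * np.clip(1.0 + eps_s, 0.05, None)

        df = pd.DataFrame({
            "dapi": dapi, "label": label, "ssc": ssc,
            "truth_labeled": truth_labeled,
            "truth_divided": truth_divided,
            "truth_s_fraction": truth_s_fraction,
            "truth_debris": np.arange(n_ev) >= n_live,
        })
        return EventTable(df, sample=f"t{time_h:g}h_r{replicate}",
                          time_h=time_h, replicate=replicate)


def simulate_time_course(config: SimConfig, replicate: str = "1") -> TimeCourse:
    """Simulate one labeled cohort chased through the cell cycle.

    Returns one :class:`EventTable` per chase time.  The pulse window is
    ``[-pulse_len, 0]``; cells in S during any part of it incorporate label
    in proportion to the DNA synthesized in the overlap.  ``pulse_len=0`` is
    the idealized limit: cells in S at t=0 receive a unit saturating label
    so the cohort remains classifiable while carrying zero synthesis time.
    """
    rng = np.random.default_rng(config.seed)
    pop = _Population(config, rng)

    if config.pulse_len > 0:
        pop.advance(-config.pulse_len, 0.0, during_pulse=True)
    else:
        in_s = (pop.phase == _S) & (pop.frac > 0) & (pop.frac < 1)
        pop.label[in_s] = 1.0
    pop.pulse_labeled = pop.label > 0

    tables: list[EventTable] = []
    t_prev = 0.0
    for t in config.chase_times:
        if t > t_prev:
            pop.advance(t_prev, t, during_pulse=False)
            t_prev = t
        tables.append(pop.snapshot(t, rng, replicate=replicate))
    return TimeCourse(tables)


def simulate_to_dir(config: SimConfig, out_dir, fmt: str = "csv",
                    replicate: str = "1", include_truth: bool = False) -> Path:
    """Write a simulated time course plus manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    course = simulate_time_course(config, replicate=replicate)
    records = []
    for table in course:
        name = f"events_t{table.time_h:g}h_r{table.replicate}.{fmt}"
        path = out_dir / name
        if fmt == "csv":
            write_events_csv(table, path, include_truth=include_truth)
        elif fmt == "fcs":
            write_events_fcs(table, path)
        else:
            raise ConfigurationError(f"unknown output format {fmt!r}")
        records.append({"time_h": table.time_h, "replicate": table.replicate,
                        "path": name})
    manifest = out_dir / "manifest.yaml"
    write_manifest(records, manifest)
    return manifest
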