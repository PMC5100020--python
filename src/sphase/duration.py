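"""S-phase duration estimates and the end-to-end pipeline.

A converged broken-line fit of the RM time series yields two duration
estimates: the breakpoint ``psi`` itself (lower estimate: the time at
which the main labeled cohort has essentially completed replication) and
the extrapolation of the first segment to the theoretical ceiling RM = 1.0
(upper estimate, ``(1 - b0) / b1``), together with the fitted RM value at
the breakpoint (``b0 + b1 * psi``).  Both estimates are always reported:
they bracket the population's S-phase duration rather than compete.

Durations are reported half-up rounded to one decimal hour and RM values
to two decimals (the precision at which such estimates are conventionally
tabulated), alongside full-precision values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import NoProgressionError
from .gating import auto_gates, GateSet
from .io import TimeCourse, load_manifest
from .kinetics import RMSeries, assemble_series
from .segreg import SegmentedFit, fit_segmented, series_digest

logger = logging.getLogger("sphase")

REPORT_SCHEMA_VERSION = 1


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (0.85 stays 0.85, 0.845 -> 0.85)."""
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass
class DurationEstimate:
    """Breakpoint (lower) and extrapolation (upper) S-phase durations, hours."""

    t_lower: float
    t_upper: float
    rm_at_breakpoint: float
    provenance: dict = field(default_factory=dict)

    @property
    def t_lower_rounded(self) -> float:
        return round_half_up(self.t_lower, 1)

    @property
    def t_upper_rounded(self) -> float:
        return round_half_up(self.t_upper, 1)

    @property
    def rm_at_breakpoint_rounded(self) -> float:
        return round_half_up(self.rm_at_breakpoint, 2)

    def to_dict(self) -> dict:
        return {
            "t_lower_h": self.t_lower, "t_upper_h": self.t_upper,
            "rm_at_breakpoint": self.rm_at_breakpoint,
            "t_lower_h_rounded": self.t_lower_rounded,
            "t_upper_h_rounded": self.t_upper_rounded,
            "rm_at_breakpoint_rounded": self.rm_at_breakpoint_rounded,
            "provenance": self.provenance,
        }


def estimate_duration(fit: SegmentedFit) -> DurationEstimate:
    """Convert a broken-line fit into the two S-phase duration estimates."""
    if not fit.beta1 > 0:
        raise NoProgressionError(
            f"first-segment slope {fit.beta1} is not positive; the labeled "
            f"cohort is not advancing")
    t_lower = fit.psi
    t_upper = (1.0 - fit.beta0) / fit.beta1
    rm_bp = fit.beta0 + fit.beta1 * fit.psi
    return DurationEstimate(
        t_lower=float(t_lower), t_upper=float(t_upper),
        rm_at_breakpoint=float(rm_bp),
        provenance={"converged": fit.converged, "rss": fit.rss, "n": fit.n},
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    gates: dict
    series: RMSeries
    fit: SegmentedFit
    estimate: DurationEstimate
    report: dict


def analyze_time_course(course: TimeCourse, pooling: str = "pooled",
                        weights: str = "none",
                        gates: GateSet | dict | None = None) -> PipelineResult:
    """Gate, compute the RM series, fit the broken line, estimate durations.

    Gates are derived from each replicate's 0 h sample unless supplied.
    """
    if gates is None:
        gates = {}
        for rep in course.replicates:
            t0 = course.at(0.0, rep)
            gates[rep] = auto_gates(t0)
            logger.info("replicate %s gates: %s", rep, gates[rep])
    series = assemble_series(course, gates, pooling=pooling)
    series.require_fittable()
    w = series.points["n_labeled"].to_numpy(float) if weights == "counts" else None
    fit = fit_segmented(series, weights=w)
    est = estimate_duration(fit)

    gates_doc = (
        {rep: json.loads(g.to_json()) for rep, g in gates.items()}
        if isinstance(gates, dict) else {"all": json.loads(gates.to_json())}
    )
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "input_digest": series_digest(series.t, series.rm),
        "options": {"pooling": pooling, "weights": weights},
        "gates": gates_doc,
        "rm_series": series.points.to_dict(orient="records"),
        "segmented_fit": json.loads(fit.to_json()),
        "duration": est.to_dict(),
    }
    est.provenance["input_digest"] = report["input_digest"]
    return PipelineResult(gates=gates_doc, series=series, fit=fit,
                          estimate=est, report=report)


def run_pipeline(manifest, out_dir=None, pooling: str = "pooled",
                 weights: str = "none", channel_map=None,
                 allow_missing_t0: bool = False,
                 make_plot: bool = True) -> PipelineResult:
    """Execute ingest -> gate -> stats -> RM series -> fit -> duration.

    When ``out_dir`` is given, writes ``report.json`` (deterministic byte
    layout for identical inputs), ``rm_series.tsv`` and ``rm_fit.png``.
    """
    course = load_manifest(manifest, channel_map=channel_map,
                           allow_missing_t0=allow_missing_t0)
    result = analyze_time_course(course, pooling=pooling, weights=weights)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(result.report, indent=2, sort_keys=True) + "\n")
        result.series.to_tsv(out_dir / "rm_series.tsv")
        if make_plot:
            plot_rm_fit(result.series, result.fit, result.estimate,
                        out_dir / "rm_fit.png")
    return result


def plot_rm_fit(series: RMSeries, fit: SegmentedFit, est: DurationEstimate,
                path) -> None:
    """RM plot with both fitted segments, the dashed extrapolation of the
    first segment to the dotted RM = 1.0 reference, and the breakpoint arrow."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    markers = ["o", "s", "^", "D", "v", "P", "X"]
    for i, (rep, grp) in enumerate(series.points.groupby("replicate")):
        ax.scatter(grp["time_h"], grp["rm"], s=28,
                   marker=markers[i % len(markers)],
                   facecolors="none", edgecolors="k", label=f"replicate {rep}")
    t_lo, t_hi = float(series.t.min()), float(series.t.max())
    seg1 = np.linspace(t_lo, fit.psi, 50)
    seg2 = np.linspace(fit.psi, t_hi, 50)
    ax.plot(seg1, fit.predict(seg1), "k-", lw=1.5)
    ax.plot(seg2, fit.predict(seg2), "k-", lw=1.5)
    ext = np.linspace(fit.psi, est.t_upper, 50)
    ax.plot(ext, fit.beta0 + fit.beta1 * ext, "k--", lw=1.0)
    ax.axhline(1.0, color="gray", ls=":", lw=1.0)
    ax.annotate("", xy=(fit.psi, fit.beta0 + fit.beta1 * fit.psi),
                xytext=(fit.psi, fit.beta0 + fit.beta1 * fit.psi + 0.12),
                arrowprops=dict(arrowstyle="->", color="k"))
    ax.set_xlabel("Chase time (h)")
    ax.set_ylabel("Relative movement (RM)")
    ax.set_title(
        f"t_lower = {est.t_lower_rounded:g} h, t_upper = {est.t_upper_rounded:g} h, "
        f"RM at breakpoint = {est.rm_at_breakpoint_rounded:.2f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
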