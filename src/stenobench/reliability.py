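"""Test-retest reliability and agreement statistics for pressure-drop metrics.

Implements the 4-condition x 2-session x 8-regimen experiment harness
(64 flow runs), ordinary-least-squares agreement regression with r^2 and a
t-based 95% slope interval, and Bland-Altman bias / limits-of-agreement
statistics, pooled across conditions and flow rates the way test-retest
studies report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phantom import (
    FlowCondition,
    PerturbationScales,
    PhantomConfig,
    apply_condition_perturbation,
    simulate_recording,
)
from .pipeline import analyze_recording

HARNESS_COLUMNS = [
    "condition", "session", "mode", "peak_flow_ml_s",
    "peak_drop_mmhg", "net_drop_mmhg", "peak_to_peak_drop_mmhg",
    "peak_instant_s", "peak_location_mm",
    "true_peak_drop_mmhg", "true_net_drop_mmhg",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """The full reproducibility protocol.

    Four handling conditions x two sessions, each exposing the valve to
    four constant-flow and four pulsatile-flow regimens: 8
    condition-session combinations, 64 flow experiments in total under the
    defaults.
    """

    base_config: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0
    conditions: Tuple[int, ...] = (1, 2, 3, 4)
    sessions: Tuple[str, ...] = ("A", "B")
    pulsatile_flows_ml_s: Tuple[float, ...] = (100.0, 150.0, 200.0, 250.0)
    constant_flows_ml_s: Tuple[float, ...] = (100.0, 150.0, 200.0, 250.0)
    heart_rate_bpm: float = 75.0
    perturbation_scales: PerturbationScales = field(
        default_factory=PerturbationScales
    )

    @property
    def n_runs(self) -> int:
        per_combo = len(self.pulsatile_flows_ml_s) + len(self.constant_flows_ml_s)
        return len(self.conditions) * len(self.sessions) * per_combo


@dataclass
class AgreementResult:
    """Regression and/or Bland-Altman agreement between paired measurements."""

    n: int
    r_squared: Optional[float] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None
    slope_ci: Optional[Tuple[float, float]] = None
    bias: Optional[float] = None
    bias_sd: Optional[float] = None
    loa: Optional[Tuple[float, float]] = None
    percent_bias: Optional[float] = None


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------

def run_harness(design: ExperimentDesign) -> pd.DataFrame:
    """Simulate and analyse every run of the design; one tidy row per run.

    Deterministic under ``design.seed``: a seed tree assigns one
    independent stream per run for the handling perturbation and one for
    the measurement noise, in a fixed (condition, session, mode, flow)
    order.  Perturbations are redrawn per run — every regimen change
    involves operator interaction with the loop — on top of the systematic
    session-B day effect.
    """
    root = np.random.SeedSequence(design.seed)
    rows = []
    regimens = [("constant", f) for f in design.constant_flows_ml_s] + [
        ("pulsatile", f) for f in design.pulsatile_flows_ml_s
    ]
    children = iter(root.spawn(
        len(design.conditions) * len(design.sessions) * len(regimens) * 2
    ))
    for condition_label in design.conditions:
        for session in design.sessions:
            for mode, flow in regimens:
                pert_rng = np.random.default_rng(next(children))
                noise_seed = int(
                    next(children).generate_state(1, np.uint32)[0] % (2**31)
                )
                cfg = apply_condition_perturbation(
                    design.base_config, condition_label, session, pert_rng,
                    design.perturbation_scales,
                )
                cfg = replace(cfg, rng_seed=noise_seed)
                flow_condition = FlowCondition(
                    mode=mode,
                    peak_flow_ml_s=flow,
                    heart_rate_bpm=design.heart_rate_bpm,
                )
                rec = simulate_recording(
                    cfg, flow_condition,
                    provenance={"condition": condition_label,
                                "session": session},
                )
                m = analyze_recording(rec)
                rows.append({
                    "condition": condition_label,
                    "session": session,
                    "mode": mode,
                    "peak_flow_ml_s": flow,
                    "peak_drop_mmhg": m.peak_drop_mmhg,
                    "net_drop_mmhg": m.net_drop_mmhg,
                    "peak_to_peak_drop_mmhg": (
                        np.nan if m.peak_to_peak_drop_mmhg is None
                        else m.peak_to_peak_drop_mmhg
                    ),
                    "peak_instant_s": (
                        np.nan if m.peak_instant_s is None else m.peak_instant_s
                    ),
                    "peak_location_mm": m.peak_location_mm,
                    "true_peak_drop_mmhg": rec.ground_truth.true_peak_drop_mmhg,
                    "true_net_drop_mmhg": rec.ground_truth.true_net_drop_mmhg,
                })
    return pd.DataFrame(rows, columns=HARNESS_COLUMNS)


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def regress_agreement(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Ordinary least squares of y on x: r^2, slope, intercept, 95% slope CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("regression requires at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression slope is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return AgreementResult(
        n=int(x.size),
        r_squared=float(res.rsquared),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Bland-Altman bias, SD of differences and 1.96-SD limits of agreement.

    Differences are d = y - x; ``percent_bias`` is 100 x bias over the
    grand mean of the pairwise means (x + y)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("Bland-Altman requires at least 2 paired points")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    grand_mean = float(np.mean((x + y) / 2.0))
    return AgreementResult(
        n=int(x.size),
        bias=bias,
        bias_sd=sd,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        percent_bias=(
            100.0 * bias / grand_mean if grand_mean != 0 else float("nan")
        ),
    )


def _merge(reg: AgreementResult, ba: AgreementResult) -> AgreementResult:
    return AgreementResult(
        n=reg.n, r_squared=reg.r_squared, slope=reg.slope,
        intercept=reg.intercept, slope_ci=reg.slope_ci,
        bias=ba.bias, bias_sd=ba.bias_sd, loa=ba.loa,
        percent_bias=ba.percent_bias,
    )


def session_comparison(
    table: pd.DataFrame,
    metric: str,
    mode: str = "pulsatile",
) -> AgreementResult:
    """Session A vs session B agreement of one metric, pooled over
    conditions and flow rates within one flow mode.

    Every (condition, peak flow) run must be present in both sessions;
    missing pairs are reported explicitly.
    """
    sub = table[table["mode"] == mode]
    if sub.empty:
        raise ValueError(f"no {mode!r} runs in the table")
    pivot = sub.pivot_table(
        index=["condition", "peak_flow_ml_s"],
        columns="session",
        values=metric,
        aggfunc="mean",
    )
    for session in ("A", "B"):
        if session not in pivot.columns:
            raise ValueError(f"table holds no session {session} runs")
    missing = pivot[pivot.isna().any(axis=1)].index.tolist()
    if missing:
        raise ValueError(f"unmatched session pairs for runs: {missing}")
    x = pivot["A"].to_numpy()
    y = pivot["B"].to_numpy()
    return _merge(regress_agreement(x, y), bland_altman(x, y))


def metric_relation(
    table: pd.DataFrame,
    metric_x: str,
    metric_y: str,
    mode: str = "pulsatile",
) -> AgreementResult:
    """Regression of one metric on another, pooled across runs of one mode."""
    columns = [metric_x] if metric_x == metric_y else [metric_x, metric_y]
    sub = table[table["mode"] == mode][columns].dropna()
    if sub.empty:
        raise ValueError(
            f"no {mode!r} runs with both {metric_x} and {metric_y}"
        )
    return regress_agreement(
        sub[metric_x].to_numpy(), sub[metric_y].to_numpy()
    )
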