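"""Monte Carlo probabilistic sensitivity analysis over the economic model.

Each iteration draws one independent realization of every triangular
parameter, evaluates the funnel-adjusted cost-consequence model for every
fund, and sums the nets; summaries (mean, median, 2.5th/97.5th percentiles,
probability of any net savings) are computed over the iteration totals.
Triangular draws use the explicit inverse-CDF transform of a uniform variate
so that results are reproducible across platforms given the same uniform
stream. Percentiles are computed by linear interpolation between order
statistics (the numpy default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .admin_data import FundYearRecord, TherapyClass, substream_rng
from .economic import (
    DrawnParams,
    EconomicParams,
    FunnelParams,
    TriangularSpec,
    evaluate_fund,
)


class PsaError(Exception):
    pass


@dataclass
class PsaConfig:
    """Monte Carlo settings. ``draw_sharing="shared"`` applies one parameter
    draw per iteration to every fund (parameters are system-wide properties
    of the therapeutic, not fund-specific); ``"independent"`` redraws per
    fund for the stratified analysis."""

    n_iterations: int = 10_000
    seed: int = 0
    stratify_by_fund: bool = False
    draw_sharing: str = "shared"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise PsaError("n_iterations must be >= 1")
        if self.draw_sharing not in ("shared", "independent"):
            raise PsaError(f"unknown draw_sharing policy: {self.draw_sharing!r}")


@dataclass
class PsaSummary:
    mean: float
    median: float
    lower_2_5: float
    upper_97_5: float
    prob_positive: float
    n_iterations: int
    per_fund: dict[str, "PsaSummary"] | None = None

    def to_dict(self) -> dict:
        d = {
            "mean": self.mean,
            "median": self.median,
            "lower_2_5": self.lower_2_5,
            "upper_97_5": self.upper_97_5,
            "prob_positive": self.prob_positive,
            "n_iterations": self.n_iterations,
        }
        if self.per_fund is not None:
            d["per_fund"] = {k: v.to_dict() for k, v in self.per_fund.items()}
        return d


# ---------------------------------------------------------------------------
# Triangular sampling
# ---------------------------------------------------------------------------


def triangular_ppf(u: float, spec: TriangularSpec) -> float:
    """Inverse CDF of the triangular law on [low, high] with the given mode."""
    a, c, b = spec.low, spec.mode, spec.high
    if a == b:
        return a
    fc = (c - a) / (b - a)
    if u < fc:
        return a + np.sqrt(u * (b - a) * (c - a))
    return b - np.sqrt((1.0 - u) * (b - a) * (b - c))


def sample_triangular(spec: TriangularSpec, rng: np.random.Generator) -> float:
    """One triangular draw; always inside [low, high]."""
    return float(triangular_ppf(rng.random(), spec))


def draw_params(econ: EconomicParams, rng: np.random.Generator) -> DrawnParams:
    """One independent draw per parameter, in a fixed documented order
    (c_diga, r_sub per class, e_gain, r_comp per class)."""
    return DrawnParams(
        c_diga=sample_triangular(econ.c_diga, rng),
        r_sub={cls: sample_triangular(econ.r_sub[cls], rng) for cls in TherapyClass},
        e_gain=sample_triangular(econ.e_gain, rng),
        r_comp={cls: sample_triangular(econ.r_comp[cls], rng) for cls in TherapyClass},
    )


# ---------------------------------------------------------------------------
# PSA runs
# ---------------------------------------------------------------------------


def _summarize(totals: np.ndarray) -> PsaSummary:
    lo, hi = np.percentile(totals, [2.5, 97.5])
    return PsaSummary(
        mean=float(np.mean(totals)),
        median=float(np.median(totals)),
        lower_2_5=float(lo),
        upper_97_5=float(hi),
        # exact count fraction, no smoothing
        prob_positive=float(np.count_nonzero(totals > 0) / totals.size),
        n_iterations=int(totals.size),
    )


def _usable(records: Sequence[FundYearRecord]) -> list[FundYearRecord]:
    usable = [
        r
        for r in records
        if any(
            r.case_count[c] is not None and r.spend_per_case()[c] is not None
            for c in TherapyClass
        )
    ]
    if not usable:
        raise PsaError("no usable fund records (all strata missing)")
    return usable


def _net_matrix(
    records: Sequence[FundYearRecord],
    econ: EconomicParams,
    funnel: FunnelParams,
    config: PsaConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """(n_iterations x n_funds) net savings plus the raw parameter draws."""
    funds = _usable(records)
    nets = np.empty((config.n_iterations, len(funds)))
    draw_rows = []
    if config.draw_sharing == "shared":
        rng = substream_rng(config.seed, "psa")
        for i in range(config.n_iterations):
            drawn = draw_params(econ, rng)
            for j, rec in enumerate(funds):
                nets[i, j] = evaluate_fund(rec, drawn, funnel).net
            draw_rows.append(_draw_row(i, drawn))
    else:
        for j, rec in enumerate(funds):
            rng = substream_rng(config.seed, f"psa:{rec.fund_id}")
            for i in range(config.n_iterations):
                drawn = draw_params(econ, rng)
                nets[i, j] = evaluate_fund(rec, drawn, funnel).net
    draws = pd.DataFrame(draw_rows)
    return nets, draws


def _draw_row(i: int, drawn: DrawnParams) -> dict:
    return {
        "iteration": i,
        "c_diga": drawn.c_diga,
        "r_sub_physiotherapy": drawn.r_sub[TherapyClass.PHYSIOTHERAPY],
        "r_sub_eap": drawn.r_sub[TherapyClass.EAP],
        "e_gain": drawn.e_gain,
        "r_comp_physiotherapy": drawn.r_comp[TherapyClass.PHYSIOTHERAPY],
        "r_comp_eap": drawn.r_comp[TherapyClass.EAP],
    }


def run_psa(
    records: Sequence[FundYearRecord],
    econ: EconomicParams,
    funnel: FunnelParams,
    config: PsaConfig,
    return_draws: bool = False,
):
    """Pooled PSA over all funds; optionally also return the audit table of
    raw draws with per-fund and total nets."""
    funds = _usable(records)
    nets, draws = _net_matrix(records, econ, funnel, config)
    totals = nets.sum(axis=1)
    summary = _summarize(totals)
    if config.stratify_by_fund:
        summary.per_fund = {
            rec.fund_id: _summarize(nets[:, j]) for j, rec in enumerate(funds)
        }
    if return_draws:
        if not draws.empty:
            for j, rec in enumerate(funds):
                draws[f"net_{rec.fund_id}"] = nets[:, j]
            draws["net_total"] = totals
        return summary, draws
    return summary


def stratify_psa(
    records: Sequence[FundYearRecord],
    econ: EconomicParams,
    funnel: FunnelParams,
    config: PsaConfig,
) -> dict[str, PsaSummary]:
    """Per-fund PSA summaries. Under shared draws the per-fund nets of each
    iteration sum exactly to the pooled net of that iteration."""
    funds = _usable(records)
    nets, _ = _net_matrix(records, econ, funnel, config)
    return {rec.fund_id: _summarize(nets[:, j]) for j, rec in enumerate(funds)}
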