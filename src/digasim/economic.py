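"""Deterministic cost-consequence model for DiGA integration.

Two mutually exclusive savings mechanisms operate on disjoint case
partitions: direct substitution (a share R_Sub of conventional cases is fully
replaced by a digital therapeutic, avoiding the conventional cost) and
complementary efficiency (among the remaining 1 - R_Sub cases, a share R_Comp
uses a DiGA add-on that reduces standard-care cost by a fraction E_Gain).

A three-stage eligibility/adherence funnel precedes both mechanisms: only a
fraction of candidates is eligible and willing (default 70%); the prescribed
cohort splits into engaged users (default 15%), the only ones who realize
substitution and efficiency effects, and short-term users (85%), who are
credited a partial benefit worth a fixed number of avoided physiotherapy
sessions. The prescription cost C_DiGA is charged once per prescribed case
regardless of adherence.

Break-even solvers find the DiGA price and the engaged-adherence share at
which aggregate net savings cross zero; the adherence threshold is searched
on an extended domain because it can exceed 100% (a structurally loss-making
configuration without short-term partial benefit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

from .admin_data import FundYearRecord, TherapyClass


class EconomicModelError(Exception):
    """Base class for economic-model errors."""


class ConfigurationError(EconomicModelError):
    """A required configuration value (e.g. session cost) is unset."""


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangularSpec:
    """Minimum / mode / maximum of a triangular distribution.

    Degenerate specs (low == mode == high) are allowed and represent a fixed
    parameter.
    """

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.mode <= self.high:
            raise EconomicModelError(
                f"triangular spec must satisfy low <= mode <= high, got "
                f"({self.low}, {self.mode}, {self.high})"
            )

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0

    @property
    def is_degenerate(self) -> bool:
        return self.low == self.high

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


def _rate_spec(low: float, mode: float, high: float) -> TriangularSpec:
    spec = TriangularSpec(low, mode, high)
    if not (0.0 <= low and high <= 1.0):
        raise EconomicModelError(f"rate spec must lie in [0, 1], got {spec}")
    return spec


@dataclass
class EconomicParams:
    """Triangular specifications for all model parameters.

    Defaults are the base analysis set: C_DiGA (250, 450, 600) euros per
    prescription; substitution rates (0.05, 0.10, 0.25) for physiotherapy and
    (0.01, 0.03, 0.08) for EAP; efficiency gain (0.10, 0.20, 0.30);
    complementary use rates (0.20, 0.35, 0.50) and (0.15, 0.25, 0.40).
    """

    c_diga: TriangularSpec = field(
        default_factory=lambda: TriangularSpec(250.0, 450.0, 600.0)
    )
    r_sub: dict[TherapyClass, TriangularSpec] = field(
        default_factory=lambda: {
            TherapyClass.PHYSIOTHERAPY: _rate_spec(0.05, 0.10, 0.25),
            TherapyClass.EAP: _rate_spec(0.01, 0.03, 0.08),
        }
    )
    e_gain: TriangularSpec = field(
        default_factory=lambda: _rate_spec(0.10, 0.20, 0.30)
    )
    r_comp: dict[TherapyClass, TriangularSpec] = field(
        default_factory=lambda: {
            TherapyClass.PHYSIOTHERAPY: _rate_spec(0.20, 0.35, 0.50),
            TherapyClass.EAP: _rate_spec(0.15, 0.25, 0.40),
        }
    )

    def __post_init__(self) -> None:
        if self.c_diga.low <= 0:
            raise EconomicModelError("c_diga spec must be > 0")
        for cls in TherapyClass:
            for spec in (self.r_sub[cls], self.r_comp[cls]):
                if spec.low < 0 or spec.high > 1:
                    raise EconomicModelError("rate specs must lie in [0, 1]")

    def at_mode(self) -> "DrawnParams":
        """Base case: every parameter fixed at its mode."""
        return DrawnParams(
            c_diga=self.c_diga.mode,
            r_sub={cls: self.r_sub[cls].mode for cls in TherapyClass},
            e_gain=self.e_gain.mode,
            r_comp={cls: self.r_comp[cls].mode for cls in TherapyClass},
        )


@dataclass
class DrawnParams:
    """One realization (scalar per parameter) of :class:`EconomicParams`."""

    c_diga: float
    r_sub: dict[TherapyClass, float]
    e_gain: float
    r_comp: dict[TherapyClass, float]


@dataclass
class FunnelParams:
    """Eligibility and adherence shares of the three-stage funnel.

    ``session_cost`` is the euro value of one avoided physiotherapy session
    used to price the short-term users' partial benefit; when left ``None`` it
    is derived at evaluation time as the physiotherapy spend per case divided
    by ``mean_sessions_per_case``. ``session_cost_by_class`` optionally
    overrides the session value per therapy class.
    """

    eligibility_rate: float = 0.70
    engaged_share: float = 0.15
    partial_benefit_sessions: float = 3.0
    session_cost: float | None = None
    mean_sessions_per_case: float = 6.0
    session_cost_by_class: dict[TherapyClass, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.eligibility_rate <= 1.0:
            raise EconomicModelError("eligibility_rate must be in [0, 1]")
        if not 0.0 <= self.engaged_share <= 1.0:
            raise EconomicModelError("engaged_share must be in [0, 1]")
        if self.partial_benefit_sessions < 0:
            raise EconomicModelError("partial_benefit_sessions must be >= 0")
        if self.mean_sessions_per_case <= 0:
            raise EconomicModelError("mean_sessions_per_case must be > 0")


@dataclass
class FunnelCohorts:
    """Cohort sizes after the funnel; real-valued expected counts."""

    n_candidates: float
    n_prescribed: float
    n_engaged: float
    n_short_term: float


@dataclass
class ClassBreakdown:
    """Savings decomposition for a single therapy class."""

    substitution_savings: float
    complementary_savings: float
    partial_benefit_value: float
    diga_cost_total: float

    @property
    def net(self) -> float:
        return (
            self.substitution_savings
            + self.complementary_savings
            + self.partial_benefit_value
            - self.diga_cost_total
        )


@dataclass
class NetSavingsBreakdown:
    """Fund-year savings decomposition, aggregated over therapy classes."""

    substitution_savings: float
    complementary_savings: float
    partial_benefit_value: float
    diga_cost_total: float
    net: float
    per_class: dict[TherapyClass, ClassBreakdown]
    skipped: list[TherapyClass]


@dataclass
class ThresholdResult:
    """Outcome of a break-even search.

    ``status`` is ``"ok"`` (feasible root), ``"infeasible"`` (a root exists
    but lies outside the admissible range — e.g. an adherence share above
    100%), or ``"no_root"`` (net savings never cross zero on the search
    domain).
    """

    value: float | None
    feasible: bool
    status: str
    net_at_value: float | None = None


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def apply_funnel(n_candidates: float, funnel: FunnelParams) -> FunnelCohorts:
    """Stage the candidate pool through eligibility and adherence splits."""
    if n_candidates < 0:
        raise EconomicModelError("n_candidates must be >= 0")
    prescribed = funnel.eligibility_rate * n_candidates
    engaged = funnel.engaged_share * prescribed
    return FunnelCohorts(
        n_candidates=n_candidates,
        n_prescribed=prescribed,
        n_engaged=engaged,
        n_short_term=prescribed - engaged,
    )


def substitution_savings(
    n_cases: float, spend_per_case: float, r_sub: float, c_diga: float
) -> float:
    """Model 1 (direct substitution): a share r_sub of cases is fully
    replaced; each replaced case avoids the conventional cost and incurs the
    DiGA price. May be negative when the DiGA costs more than the case it
    replaces."""
    if n_cases < 0 or spend_per_case < 0:
        raise EconomicModelError("n_cases and spend_per_case must be >= 0")
    return n_cases * r_sub * (spend_per_case - c_diga)


def complementary_savings(
    n_cases: float,
    spend_per_case: float,
    r_sub: float,
    r_comp: float,
    e_gain: float,
    c_diga: float,
) -> float:
    """Model 2 (complementary efficiency): among the non-substituted
    (1 - r_sub) cases, a share r_comp adds a DiGA that reduces standard-care
    cost by the fraction e_gain; net per case is e_gain * cost - c_diga."""
    if n_cases < 0 or spend_per_case < 0:
        raise EconomicModelError("n_cases and spend_per_case must be >= 0")
    return n_cases * (1.0 - r_sub) * r_comp * (e_gain * spend_per_case - c_diga)


def partial_benefit_value(n_short_term: float, funnel: FunnelParams) -> float:
    """Euro value of short-term users' partial benefit: a fixed number of
    avoided physiotherapy sessions per short-term user."""
    if funnel.partial_benefit_sessions > 0 and funnel.session_cost is None:
        raise ConfigurationError(
            "session_cost is unset; configure it or use evaluate_fund, which "
            "derives it from physiotherapy spend per case"
        )
    if n_short_term < 0:
        raise EconomicModelError("n_short_term must be >= 0")
    if funnel.partial_benefit_sessions == 0:
        return 0.0
    return n_short_term * funnel.partial_benefit_sessions * funnel.session_cost


def _resolve_session_cost(
    funnel: FunnelParams,
    cls: TherapyClass,
    spend_per_case: dict[TherapyClass, float],
) -> float:
    if funnel.session_cost_by_class and cls in funnel.session_cost_by_class:
        return funnel.session_cost_by_class[cls]
    if funnel.session_cost is not None:
        return funnel.session_cost
    phys = spend_per_case.get(TherapyClass.PHYSIOTHERAPY)
    if phys is None:
        raise ConfigurationError(
            "session_cost unset and physiotherapy spend per case unavailable"
        )
    return phys / funnel.mean_sessions_per_case


def _class_breakdown(
    n_cases: float,
    spc: float,
    params: DrawnParams,
    cls: TherapyClass,
    eligibility: float,
    engaged_share: float,
    sessions: float,
    session_cost: float,
) -> ClassBreakdown:
    """Funnel + both mechanisms for one therapy class.

    Engaged users realize gross substitution and efficiency savings; the
    prescription cost is charged once per prescribed case regardless of
    adherence; short-term users contribute the partial benefit.
    ``engaged_share`` may exceed 1 here: the break-even solver extrapolates
    the affine model beyond the admissible range to locate infeasible roots.
    """
    prescribed = eligibility * n_cases
    engaged = engaged_share * prescribed
    short_term = prescribed - engaged
    r_sub = params.r_sub[cls]
    r_comp = params.r_comp[cls]
    sub = substitution_savings(engaged, spc, r_sub, c_diga=0.0)
    comp = complementary_savings(
        engaged, spc, r_sub, r_comp, params.e_gain, c_diga=0.0
    )
    partial = short_term * sessions * session_cost
    cost = prescribed * params.c_diga
    return ClassBreakdown(
        substitution_savings=sub,
        complementary_savings=comp,
        partial_benefit_value=partial,
        diga_cost_total=cost,
    )


def evaluate_fund(
    record: FundYearRecord,
    params: DrawnParams,
    funnel: FunnelParams,
    spend_per_case: dict[TherapyClass, float] | None = None,
    engaged_share_override: float | None = None,
) -> NetSavingsBreakdown:
    """Evaluate the funnel-adjusted cost-consequence model for one fund-year.

    Therapy classes are modeled separately and then aggregated. A class with
    a missing case count or spend per case is skipped and flagged rather than
    imputed. ``spend_per_case`` defaults to the record's own expenditure /
    case ratio.
    """
    spc_map = dict(record.spend_per_case()) if spend_per_case is None else dict(
        spend_per_case
    )
    engaged_share = (
        funnel.engaged_share
        if engaged_share_override is None
        else engaged_share_override
    )
    per_class: dict[TherapyClass, ClassBreakdown] = {}
    skipped: list[TherapyClass] = []
    for cls in TherapyClass:
        n_cases = record.case_count[cls]
        spc = spc_map.get(cls)
        if n_cases is None or spc is None:
            skipped.append(cls)
            continue
        session_cost = (
            _resolve_session_cost(
                funnel, cls, {k: v for k, v in spc_map.items() if v is not None}
            )
            if funnel.partial_benefit_sessions > 0
            else 0.0
        )
        per_class[cls] = _class_breakdown(
            n_cases,
            spc,
            params,
            cls,
            funnel.eligibility_rate,
            engaged_share,
            funnel.partial_benefit_sessions,
            session_cost,
        )
    total = lambda attr: sum(getattr(b, attr) for b in per_class.values())
    return NetSavingsBreakdown(
        substitution_savings=total("substitution_savings"),
        complementary_savings=total("complementary_savings"),
        partial_benefit_value=total("partial_benefit_value"),
        diga_cost_total=total("diga_cost_total"),
        net=sum(b.net for b in per_class.values()),
        per_class=per_class,
        skipped=skipped,
    )


def aggregate_net(
    records: Sequence[FundYearRecord],
    params: DrawnParams,
    funnel: FunnelParams,
    engaged_share_override: float | None = None,
) -> float:
    """Total net savings over a set of fund-year records."""
    return sum(
        evaluate_fund(
            rec, params, funnel, engaged_share_override=engaged_share_override
        ).net
        for rec in records
    )


def latest_year_records(records: Sequence[FundYearRecord]) -> list[FundYearRecord]:
    """The evaluation-year slice: for each fund, its most recent record."""
    latest: dict[str, FundYearRecord] = {}
    for rec in records:
        if rec.fund_id not in latest or rec.year > latest[rec.fund_id].year:
            latest[rec.fund_id] = rec
    return sorted(latest.values(), key=lambda r: r.fund_id)


# ---------------------------------------------------------------------------
# Demand reduction (economics -> queue coupling)
# ---------------------------------------------------------------------------

FIXED_REDUCTION_PRESET = 0.15  # the documented fixed-demand-reduction scenario


def demand_reduction(
    params: DrawnParams,
    funnel: FunnelParams,
    mode: str = "funnel",
    fixed_value: float = FIXED_REDUCTION_PRESET,
    scaling: float = 1.0,
) -> float:
    """Fraction by which EAP arrivals fall under DiGA integration.

    ``mode="funnel"``: fully substituted engaged EAP cases leave the queue,
    i.e. eligibility_rate x engaged_share x r_sub(EAP) — one documented
    interpretation of how the adherence funnel translates into demand.
    ``mode="fixed"``: a user-supplied fraction (preset 0.15).
    ``scaling`` multiplies the effect for conservative (0.5) / realistic
    (1.0) / ambitious (1.5) scenarios.
    """
    if mode == "funnel":
        base = (
            funnel.eligibility_rate
            * funnel.engaged_share
            * params.r_sub[TherapyClass.EAP]
        )
    elif mode == "fixed":
        base = fixed_value
    else:
        raise EconomicModelError(f"unknown demand-reduction policy: {mode!r}")
    return scaling * base


# ---------------------------------------------------------------------------
# Break-even thresholds and one-way curves
# ---------------------------------------------------------------------------

# Reported price precision is one cent; the bisection runs well past it so
# that the plugged-back net is within one euro even for large case volumes.
PRICE_TOL = 1e-7
ADHERENCE_DOMAIN = (0.0, 5.0)


def _bisect(
    f: Callable[[float], float], lo: float, hi: float, xtol: float
) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise EconomicModelError("no sign change on bracket")
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if fmid == 0.0:
            return mid
        if flo * fmid < 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    return 0.5 * (lo + hi)


def breakeven_price(
    records: Sequence[FundYearRecord],
    econ: EconomicParams,
    funnel: FunnelParams,
) -> ThresholdResult:
    """Maximum DiGA price that keeps aggregate net savings nonnegative, with
    all other parameters at their modes. Net savings are affine and strictly
    decreasing in the price, so bisection to EUR 0.01 locates the unique root.
    """
    base = econ.at_mode()

    def net_at(price: float) -> float:
        p = replace(base, c_diga=price)
        return aggregate_net(records, p, funnel)

    lo = econ.c_diga.low
    if net_at(lo) <= 0:
        return ThresholdResult(
            value=None, feasible=False, status="infeasible",
            net_at_value=net_at(lo),
        )
    hi = max(2.0 * lo, lo + 100.0)
    while net_at(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            return ThresholdResult(value=None, feasible=False, status="no_root")
    root = _bisect(net_at, lo, hi, PRICE_TOL)
    return ThresholdResult(
        value=root, feasible=True, status="ok", net_at_value=net_at(root)
    )


def breakeven_adherence(
    records: Sequence[FundYearRecord],
    econ: EconomicParams,
    funnel: FunnelParams,
) -> ThresholdResult:
    """Engaged-adherence share at which aggregate net savings cross zero.

    Searched on the extended domain [0, 5]: a root above 1 is a mathematical
    impossibility in practice and is reported as infeasible with the solved
    value attached (the model is then structurally dependent on short-term
    users' partial benefit). If net savings never cross zero on the domain,
    the threshold is unbounded (``status="no_root"``).
    """
    base = econ.at_mode()

    def net_at(share: float) -> float:
        return aggregate_net(records, base, funnel, engaged_share_override=share)

    lo, hi = ADHERENCE_DOMAIN
    if net_at(lo) * net_at(hi) > 0:
        return ThresholdResult(
            value=None, feasible=False, status="no_root",
            net_at_value=net_at(funnel.engaged_share),
        )
    root = _bisect(net_at, lo, hi, 1e-9)
    feasible = root <= 1.0
    return ThresholdResult(
        value=root,
        feasible=feasible,
        status="ok" if feasible else "infeasible",
        net_at_value=net_at(root),
    )


def one_way_curve(
    param_name: str,
    grid: Iterable[float],
    records: Sequence[FundYearRecord],
    econ: EconomicParams,
    funnel: FunnelParams,
) -> list[tuple[float, float]]:
    """One-way sensitivity curve: net savings over a grid of one parameter
    (``c_diga`` or ``engaged_share``), all other parameters at their modes."""
    base = econ.at_mode()
    if param_name == "c_diga":
        return [
            (v, aggregate_net(records, replace(base, c_diga=v), funnel))
            for v in grid
        ]
    if param_name == "engaged_share":
        return [
            (v, aggregate_net(records, base, funnel, engaged_share_override=v))
            for v in grid
        ]
    raise EconomicModelError(f"unknown parameter name: {param_name!r}")
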