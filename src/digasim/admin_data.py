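"""Fund-year administrative aggregates: I/O, validation, derived indicators,
and synthetic data generation.

The unit of input is one fund-year of aggregated expenditure and case counts
for two therapy classes (conventional physiotherapy and extended outpatient
physiotherapy, EAP) reported by German statutory accident insurance funds
(Berufsgenossenschaften). Because the real fund-level summaries are nonpublic,
this module also provides a synthetic generator that reproduces the published
system-level marginals (total expenditure, year-over-year growth, insured
population, annual EAP case volume) while leaving the unpublished per-fund and
per-class decomposition as explicit free parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants and defaults
# ---------------------------------------------------------------------------

DEFAULT_BUSINESS_DAYS = 250
DEFAULT_YEAR_RANGE = (2000, 2100)
DEFAULT_SPEND_PER_CASE_RANGE = (10.0, 50_000.0)

CSV_COLUMNS = [
    "fund_id",
    "sector_label",
    "year",
    "insured_count",
    "therapy_class",
    "expenditure_eur",
    "case_count",
    "stated_total_eur",
]


class TherapyClass(str, Enum):
    """The two reimbursed therapy classes carried by every record."""

    PHYSIOTHERAPY = "physiotherapy"
    EAP = "eap"


class AdminDataError(Exception):
    """Base class for administrative-data errors."""


class ParseError(AdminDataError):
    """A CSV row could not be parsed; the message names the row number."""


class DuplicateRecordError(AdminDataError):
    """The same (fund, year, therapy class) appears more than once."""


class InfeasibleConfigError(AdminDataError):
    """A synthetic configuration cannot be realized exactly."""


def _round_cents(x: float) -> float:
    return float(np.round(x, 2))


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from a master seed.

    Each consumer of randomness (generator, PSA, DES, ...) draws from its own
    stream so that modules never silently share a generator state.
    """
    key = int.from_bytes(
        hashlib.blake2s(name.encode("utf-8"), digest_size=4).digest(), "little"
    )
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FundYearRecord:
    """One fund-year of aggregated administrative data.

    ``expenditure`` and ``case_count`` always carry both therapy classes as
    keys; a missing cell is an explicit ``None``, never a silently absent key.
    Monetary values are nominal euros at cent precision in I/O.
    """

    fund_id: str
    sector_label: str
    year: int
    insured_count: int
    expenditure: dict[TherapyClass, float | None]
    case_count: dict[TherapyClass, float | None]
    stated_total_eur: float | None = None

    def __post_init__(self) -> None:
        for cls in TherapyClass:
            self.expenditure.setdefault(cls, None)
            self.case_count.setdefault(cls, None)

    def spend_per_case(self) -> dict[TherapyClass, float | None]:
        """Expenditure per case; ``None`` (flagged, not imputed) when the
        case count is zero or either field is missing."""
        out: dict[TherapyClass, float | None] = {}
        for cls in TherapyClass:
            exp, n = self.expenditure[cls], self.case_count[cls]
            out[cls] = None if exp is None or not n else exp / n
        return out


@dataclass
class SyntheticConfig:
    """Targets and free parameters for the synthetic administrative dataset.

    The defaults encode the published system-level marginals of the five-fund
    sample: combined 2024 expenditure of EUR 404.0 million growing 10.1%
    year-over-year, case volume growing 1.2%, 25.9 million insured, and
    26,705 annual EAP patients. The split of spending between therapy classes
    and across funds is not public; ``eap_share_of_spend``,
    ``physio_mean_spend_per_case`` and ``fund_weights`` are therefore free
    parameters, not facts.
    """

    n_funds: int = 5
    total_expenditure_target: float = 404.0e6
    cost_growth_target: float = 0.101
    volume_growth_target: float = 0.012
    insured_total: int = 25_900_000
    eap_cases_total: int = 26_705
    eap_share_of_spend: float = 0.25
    physio_mean_spend_per_case: float = 800.0
    fund_weights: tuple[float, ...] = (0.12, 0.20, 0.17, 0.33, 0.18)
    fund_ids: tuple[str, ...] = ("BGBAU", "BGHM", "BGHW", "VBG", "BGW")
    sector_labels: tuple[str, ...] = (
        "construction",
        "wood and metal",
        "trade and logistics",
        "administration",
        "health and welfare",
    )
    years: tuple[int, int] = (2023, 2024)
    jitter_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "total_expenditure_target",
            "insured_total",
            "eap_cases_total",
            "physio_mean_spend_per_case",
        ):
            if getattr(self, name) <= 0:
                raise InfeasibleConfigError(f"{name} must be > 0")
        if not 0 < self.eap_share_of_spend < 1:
            raise InfeasibleConfigError("eap_share_of_spend must be in (0, 1)")
        if len(self.fund_weights) != self.n_funds:
            raise InfeasibleConfigError(
                f"fund_weights has {len(self.fund_weights)} entries for "
                f"{self.n_funds} funds"
            )
        if any(w <= 0 for w in self.fund_weights):
            raise InfeasibleConfigError("fund_weights must be positive")
        if abs(sum(self.fund_weights) - 1.0) > 1e-9:
            raise InfeasibleConfigError("fund_weights must sum to 1 (tol 1e-9)")
        if len(self.fund_ids) != self.n_funds:
            self.fund_ids = tuple(f"F{i + 1:02d}" for i in range(self.n_funds))
        if len(self.sector_labels) != self.n_funds:
            self.sector_labels = tuple("unspecified" for _ in range(self.n_funds))
        if self.eap_cases_total < self.n_funds:
            raise InfeasibleConfigError(
                "eap_cases_total too small to allocate across funds"
            )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _parse_money(cell: str | None, row_no: int, col: str) -> float | None:
    if cell is None or str(cell).strip() == "":
        return None
    try:
        return _round_cents(float(cell))
    except ValueError as exc:
        raise ParseError(f"row {row_no}: cannot parse {col}={cell!r}") from exc


def load_fund_records(path: str | Path) -> list[FundYearRecord]:
    """Read the long-format fund-year-therapy CSV into records.

    One row per (fund, year, therapy class); empty cells become explicit
    missing markers. Raises :class:`ParseError` naming the offending row and
    :class:`DuplicateRecordError` on repeated (fund, year, therapy) keys.
    """
    path = Path(path)
    if not path.exists():
        raise AdminDataError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing required columns: {missing_cols}")

    records: dict[tuple[str, int], FundYearRecord] = {}
    seen: set[tuple[str, int, str]] = set()
    for idx, row in df.iterrows():
        row_no = int(idx) + 2  # 1-based, after header
        fund = str(row["fund_id"]).strip()
        if not fund:
            raise ParseError(f"row {row_no}: empty fund_id")
        try:
            year = int(row["year"])
        except ValueError as exc:
            raise ParseError(f"row {row_no}: cannot parse year={row['year']!r}") from exc
        try:
            cls = TherapyClass(str(row["therapy_class"]).strip().lower())
        except ValueError as exc:
            raise ParseError(
                f"row {row_no}: unknown therapy_class={row['therapy_class']!r}"
            ) from exc
        key = (fund, year, cls.value)
        if key in seen:
            raise DuplicateRecordError(
                f"row {row_no}: duplicate entry for fund={fund}, year={year}, "
                f"therapy_class={cls.value}"
            )
        seen.add(key)
        try:
            insured = int(float(row["insured_count"]))
        except ValueError as exc:
            raise ParseError(
                f"row {row_no}: cannot parse insured_count={row['insured_count']!r}"
            ) from exc
        expenditure = _parse_money(row["expenditure_eur"], row_no, "expenditure_eur")
        case_cell = str(row["case_count"]).strip()
        if case_cell == "":
            cases: float | None = None
        else:
            try:
                cases = float(case_cell)
            except ValueError as exc:
                raise ParseError(
                    f"row {row_no}: cannot parse case_count={case_cell!r}"
                ) from exc
        stated = None
        if "stated_total_eur" in df.columns:
            stated = _parse_money(row["stated_total_eur"], row_no, "stated_total_eur")

        rec = records.get((fund, year))
        if rec is None:
            rec = FundYearRecord(
                fund_id=fund,
                sector_label=str(row["sector_label"]),
                year=year,
                insured_count=insured,
                expenditure={},
                case_count={},
                stated_total_eur=stated,
            )
            records[(fund, year)] = rec
        rec.expenditure[cls] = expenditure
        rec.case_count[cls] = cases
        if stated is not None:
            rec.stated_total_eur = stated
    return sorted(records.values(), key=lambda r: (r.fund_id, r.year))


def _format_cases(v: float | None) -> str:
    if v is None:
        return ""
    return repr(v) if v != int(v) else str(int(v))


def write_fund_records(records: Sequence[FundYearRecord], path: str | Path) -> None:
    """Write records back to the long-format CSV (round-trip safe)."""
    rows = []
    for rec in records:
        for cls in TherapyClass:
            rows.append(
                {
                    "fund_id": rec.fund_id,
                    "sector_label": rec.sector_label,
                    "year": rec.year,
                    "insured_count": rec.insured_count,
                    "therapy_class": cls.value,
                    "expenditure_eur": (
                        "" if rec.expenditure[cls] is None
                        else f"{rec.expenditure[cls]:.2f}"
                    ),
                    "case_count": _format_cases(rec.case_count[cls]),
                    "stated_total_eur": (
                        "" if rec.stated_total_eur is None
                        else f"{rec.stated_total_eur:.2f}"
                    ),
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_records(
    records: Sequence[FundYearRecord],
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
    spend_per_case_range: tuple[float, float] = DEFAULT_SPEND_PER_CASE_RANGE,
    reconciliation_tol: float = 0.01,
) -> list[dict]:
    """Report-style quality checks; returns a list of violations (empty when
    clean). Checks nonnegativity, plausible ranges, reconciliation of the two
    therapy-class subtotals against a stated aggregate when one is present,
    and cross-year consistency (every fund observed in every year).
    """

    def violation(rule: str, rec: FundYearRecord, cls, message: str) -> dict:
        return {
            "rule": rule,
            "fund_id": rec.fund_id,
            "year": rec.year,
            "therapy_class": None if cls is None else cls.value,
            "message": message,
        }

    report: list[dict] = []
    for rec in records:
        if rec.insured_count < 0:
            report.append(
                violation("nonnegativity", rec, None,
                          f"insured_count={rec.insured_count} < 0")
            )
        if not year_range[0] <= rec.year <= year_range[1]:
            report.append(
                violation("plausible_range", rec, None,
                          f"year {rec.year} outside {year_range}")
            )
        for cls in TherapyClass:
            exp, n = rec.expenditure[cls], rec.case_count[cls]
            if exp is not None and exp < 0:
                report.append(
                    violation("nonnegativity", rec, cls, f"expenditure={exp} < 0")
                )
            if n is not None and n < 0:
                report.append(
                    violation("nonnegativity", rec, cls, f"case_count={n} < 0")
                )
            if exp is not None and n is not None and n > 0 and exp >= 0:
                spc = exp / n
                if not spend_per_case_range[0] <= spc <= spend_per_case_range[1]:
                    report.append(
                        violation(
                            "plausible_range", rec, cls,
                            f"spend_per_case={spc:.2f} outside "
                            f"{spend_per_case_range}",
                        )
                    )
        if rec.stated_total_eur is not None:
            parts = [rec.expenditure[c] for c in TherapyClass]
            if all(p is not None for p in parts):
                subtotal = sum(parts)  # type: ignore[arg-type]
                if abs(subtotal - rec.stated_total_eur) > reconciliation_tol:
                    report.append(
                        violation(
                            "reconciliation", rec, None,
                            f"subtotals {subtotal:.2f} != stated aggregate "
                            f"{rec.stated_total_eur:.2f}",
                        )
                    )
    all_years = sorted({r.year for r in records})
    by_fund: dict[str, set[int]] = {}
    for rec in records:
        by_fund.setdefault(rec.fund_id, set()).add(rec.year)
    for fund, years in sorted(by_fund.items()):
        missing = set(all_years) - years
        if missing:
            rec = next(r for r in records if r.fund_id == fund)
            report.append(
                violation(
                    "cross_year", rec, None,
                    f"fund {fund} missing years {sorted(missing)}",
                )
            )
    return report


def violations_to_jsonl(report: Iterable[Mapping]) -> str:
    """Serialize a validation report as JSON lines."""
    return "\n".join(json.dumps(v, sort_keys=True) for v in report)


# ---------------------------------------------------------------------------
# Derived indicators
# ---------------------------------------------------------------------------


def derive_indicators(
    records: Sequence[FundYearRecord],
    business_days: int = DEFAULT_BUSINESS_DAYS,
) -> pd.DataFrame:
    """Per fund-year-therapy indicators.

    Columns: spend_per_case, cases_per_1000_insured, yoy_cost_growth,
    yoy_volume_growth (defined only when the previous year is present),
    arrival_rate_proxy (annual cases / business days). Undefined indicators
    (zero or missing denominators) are NaN — flagged, never imputed — and the
    underlying totals remain available in the records.
    """
    if business_days <= 0:
        raise AdminDataError("business_days must be > 0")
    prev: dict[tuple[str, TherapyClass, int], FundYearRecord] = {
        (r.fund_id, cls, r.year): r for r in records for cls in TherapyClass
    }
    rows = []
    for rec in records:
        for cls in TherapyClass:
            exp, n = rec.expenditure[cls], rec.case_count[cls]
            spc = exp / n if exp is not None and n else np.nan
            per_1000 = (
                1000.0 * n / rec.insured_count
                if n is not None and rec.insured_count > 0
                else np.nan
            )
            arrival = n / business_days if n is not None else np.nan
            prev_rec = prev.get((rec.fund_id, cls, rec.year - 1))
            cost_growth = np.nan
            vol_growth = np.nan
            if prev_rec is not None:
                pexp, pn = prev_rec.expenditure[cls], prev_rec.case_count[cls]
                if exp is not None and pexp:
                    cost_growth = exp / pexp - 1.0
                if n is not None and pn:
                    vol_growth = n / pn - 1.0
            rows.append(
                {
                    "fund_id": rec.fund_id,
                    "year": rec.year,
                    "therapy_class": cls.value,
                    "spend_per_case": spc,
                    "cases_per_1000_insured": per_1000,
                    "yoy_cost_growth": cost_growth,
                    "yoy_volume_growth": vol_growth,
                    "arrival_rate_proxy": arrival,
                }
            )
    return pd.DataFrame(rows)


def aggregate_growth(records: Sequence[FundYearRecord]) -> dict[str, float]:
    """System-level year-over-year cost and volume growth over all funds and
    therapy classes (latest year vs the year before)."""
    years = sorted({r.year for r in records})
    if len(years) < 2:
        raise AdminDataError("need at least two years for growth")
    y1, y0 = years[-1], years[-2]

    def totals(year: int) -> tuple[float, float]:
        exp = sum(
            r.expenditure[c] or 0.0
            for r in records if r.year == year for c in TherapyClass
        )
        cases = sum(
            r.case_count[c] or 0.0
            for r in records if r.year == year for c in TherapyClass
        )
        return exp, cases

    e1, c1 = totals(y1)
    e0, c0 = totals(y0)
    if e0 <= 0 or c0 <= 0:
        raise AdminDataError("base-year totals must be positive")
    return {
        "year": y1,
        "base_year": y0,
        "total_expenditure": e1,
        "total_cases": c1,
        "cost_growth": e1 / e0 - 1.0,
        "volume_growth": c1 / c0 - 1.0,
    }


# ---------------------------------------------------------------------------
# Synthetic data generation
# ---------------------------------------------------------------------------


def _integer_allocation(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of an integer total."""
    raw = np.asarray(weights, dtype=float) * total
    base = np.floor(raw).astype(np.int64)
    remainder = int(total - base.sum())
    order = np.argsort(-(raw - base))
    base[order[:remainder]] += 1
    return base


def _cents_allocation(total_eur: float, weights: np.ndarray) -> np.ndarray:
    """Allocate a euro amount across weights exactly, at cent precision."""
    total_cents = int(np.round(total_eur * 100))
    cents = _integer_allocation(total_cents, np.asarray(weights) / np.sum(weights))
    return cents / 100.0


def generate_synthetic_records(config: SyntheticConfig) -> list[FundYearRecord]:
    """Generate a two-year, multi-fund dataset satisfying the configured
    marginals exactly (to documented rounding).

    Guarantees: latest-year expenditure sums to ``total_expenditure_target``
    at cent precision; aggregate cost growth equals ``cost_growth_target`` up
    to cent rounding of the base year; aggregate volume growth equals
    ``volume_growth_target`` exactly (base-year case counts are real-valued
    expected counts); insured counts sum to ``insured_total``; latest-year EAP
    cases sum to ``eap_cases_total``. Identical seeds give identical output.
    """
    cfg = config
    w = np.asarray(cfg.fund_weights, dtype=float)
    rng = substream_rng(cfg.seed, "synthetic-records")
    year0, year1 = cfg.years

    insured = _integer_allocation(cfg.insured_total, w)

    def jittered(weights: np.ndarray) -> np.ndarray:
        s = weights * np.exp(cfg.jitter_sigma * rng.standard_normal(len(weights)))
        return s / s.sum()

    total = _round_cents(cfg.total_expenditure_target)
    eap_total = _round_cents(total * cfg.eap_share_of_spend)
    phys_total = _round_cents(total - eap_total)

    exp1 = {
        TherapyClass.PHYSIOTHERAPY: _cents_allocation(phys_total, jittered(w)),
        TherapyClass.EAP: _cents_allocation(eap_total, jittered(w)),
    }
    eap_cases1 = _integer_allocation(cfg.eap_cases_total, jittered(w))
    phys_cases_total = int(round(phys_total / cfg.physio_mean_spend_per_case))
    if phys_cases_total < cfg.n_funds:
        raise InfeasibleConfigError(
            "physio_mean_spend_per_case too large: fewer cases than funds"
        )
    phys_cases1 = _integer_allocation(phys_cases_total, jittered(w))
    cases1 = {TherapyClass.PHYSIOTHERAPY: phys_cases1, TherapyClass.EAP: eap_cases1}

    # Base year: expenditure cells proportional to latest-year cells, summing
    # exactly (at cent precision) to total / (1 + cost growth); case counts
    # divided uniformly so the aggregate volume-growth marginal is exact.
    base_total = total / (1.0 + cfg.cost_growth_target)
    flat1 = np.concatenate([exp1[c] for c in TherapyClass])
    flat0 = _cents_allocation(base_total, flat1)
    exp0 = {
        cls: flat0[i * cfg.n_funds:(i + 1) * cfg.n_funds]
        for i, cls in enumerate(TherapyClass)
    }
    cases0 = {
        cls: cases1[cls] / (1.0 + cfg.volume_growth_target) for cls in TherapyClass
    }

    records = []
    for i in range(cfg.n_funds):
        for year, exp, cas in ((year0, exp0, cases0), (year1, exp1, cases1)):
            records.append(
                FundYearRecord(
                    fund_id=cfg.fund_ids[i],
                    sector_label=cfg.sector_labels[i],
                    year=year,
                    insured_count=int(insured[i]),
                    expenditure={cls: float(exp[cls][i]) for cls in TherapyClass},
                    case_count={cls: float(cas[cls][i]) for cls in TherapyClass},
                )
            )
    return sorted(records, key=lambda r: (r.fund_id, r.year))


def generate_waiting_sample(
    n: int = 31,
    target_mean: float = 17.3,
    share_gt_3d: float = 0.968,
    seed: int = 0,
    threshold: float = 3.0,
) -> np.ndarray:
    """Synthetic empirical waiting-time sample (days) for queue calibration.

    Emulates a small single-center sample: exactly ``round(share_gt_3d * n)``
    of the ``n`` waits exceed the clinical ``threshold`` (3 days by default)
    and the sample mean equals ``target_mean`` exactly (within float
    arithmetic). With the defaults this yields 30 of 31 waits above 3 days —
    an exceedance share of 96.8% — and a mean of 17.3 days.
    """
    if n < 1:
        raise InfeasibleConfigError("n must be >= 1")
    if not 0 < share_gt_3d <= 1:
        raise InfeasibleConfigError("share_gt_3d must be in (0, 1]")
    if target_mean <= 0:
        raise InfeasibleConfigError("target_mean must be > 0")
    k = int(round(share_gt_3d * n))  # number of waits above the threshold
    m = n - k
    rng = substream_rng(seed, "waiting-sample")
    low = rng.uniform(0.25 * threshold, threshold, size=m)
    if k == 0:
        if target_mean > threshold:
            raise InfeasibleConfigError(
                f"mean {target_mean} unattainable with no waits above "
                f"{threshold} days"
            )
        low *= target_mean * n / low.sum()
        return np.sort(low)
    slack = n * target_mean - low.sum() - k * threshold
    if slack <= 0:
        raise InfeasibleConfigError(
            f"mean {target_mean} too small for {k}/{n} waits above "
            f"{threshold} days"
        )
    tails = rng.exponential(1.0, size=k)
    high = threshold + tails * (slack / tails.sum())
    sample = np.concatenate([low, high])
    rng.shuffle(sample)
    return sample
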