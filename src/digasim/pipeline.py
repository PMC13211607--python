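"""End-to-end orchestration: data -> validation -> indicators -> base case ->
PSA -> break-even -> queuing -> DES -> report bundle.

A single :class:`RunConfig` (built in code or parsed from YAML/JSON) drives
every stage; one master seed expands into named substreams for the synthetic
generator, the PSA, and the DES, so a re-run with the same configuration
reproduces the bundle exactly. The demand reduction predicted by the
adherence funnel (or the fixed preset) is propagated from the economic model
into the queuing scenarios.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import __version__
from .admin_data import (
    FundYearRecord,
    SyntheticConfig,
    TherapyClass,
    aggregate_growth,
    derive_indicators,
    generate_synthetic_records,
    load_fund_records,
    validate_records,
    violations_to_jsonl,
    write_fund_records,
)
from .des import DesConfig, compare_scenarios
from .economic import (
    EconomicParams,
    FunnelParams,
    TriangularSpec,
    breakeven_adherence,
    breakeven_price,
    demand_reduction,
    evaluate_fund,
    latest_year_records,
)
from .psa import PsaConfig, run_psa, stratify_psa
from .queueing import (
    QueueModel,
    arrival_rate,
    calibrate_mu_from_exceedance,
    calibrate_mu_from_mean_wait,
    scenario_table,
)

logger = logging.getLogger("digasim")


class PipelineError(Exception):
    """A stage failed; the message names the stage."""


@dataclass
class QueueBlock:
    """Queuing-stage configuration.

    ``annual_cases`` is the single-center annual EAP start count from which
    the arrival rate is derived (default 27 over 250 business days, i.e.
    lambda = 0.108/day). Calibration is ``"mean_wait"`` (primary; inverts the
    Wq formula at ``observed_mean_wait``) or ``"exceedance-rho"`` /
    ``"exceedance-tail"`` (from ``exceedance_share`` at ``threshold_days``).
    """

    annual_cases: float = 27.0
    business_days: int = 250
    calibration: str = "mean_wait"
    observed_mean_wait: float = 17.28
    exceedance_share: float = 0.968
    threshold_days: float = 3.0
    annual_population: float = 26_705.0
    wage_per_day: float = 180.0
    replacement_low: float = 0.68
    replacement_high: float = 0.80


@dataclass
class RunConfig:
    """Full-run configuration with exactly one data source."""

    seed: int
    data_path: str | None = None
    synthetic: SyntheticConfig | None = None
    econ: EconomicParams = field(default_factory=EconomicParams)
    funnel: FunnelParams = field(default_factory=FunnelParams)
    psa: PsaConfig | None = field(default_factory=PsaConfig)
    queue: QueueBlock = field(default_factory=QueueBlock)
    # (name, scaling of the demand-reduction effect)
    scenario_scalings: tuple[tuple[str, float], ...] = (
        ("conservative", 0.5),
        ("realistic", 1.0),
        ("ambitious", 1.5),
    )
    demand_policy: str = "fixed"  # "fixed" (preset 0.15) or "funnel"
    fixed_reduction: float = 0.15
    des: DesConfig | None = field(default_factory=DesConfig)
    output_dir: str = "digasim_output"

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.synthetic is None):
            raise PipelineError(
                "exactly one data source required: data_path or synthetic"
            )


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------


def _triangular_from(obj: Any) -> TriangularSpec:
    if isinstance(obj, (list, tuple)):
        return TriangularSpec(*map(float, obj))
    return TriangularSpec(float(obj["min"]), float(obj["mode"]), float(obj["max"]))


def _econ_from(d: dict) -> EconomicParams:
    kwargs: dict[str, Any] = {}
    if "c_diga" in d:
        kwargs["c_diga"] = _triangular_from(d["c_diga"])
    if "e_gain" in d:
        kwargs["e_gain"] = _triangular_from(d["e_gain"])
    for name in ("r_sub", "r_comp"):
        if name in d:
            kwargs[name] = {
                TherapyClass(k.lower()): _triangular_from(v)
                for k, v in d[name].items()
            }
    return EconomicParams(**kwargs)


def config_from_dict(d: dict) -> RunConfig:
    data = d.get("data", {})
    synthetic = None
    data_path = data.get("path")
    if "synthetic" in data:
        synthetic = SyntheticConfig(**data["synthetic"])
    elif data_path is None:
        synthetic = SyntheticConfig(seed=int(d["seed"]))
    kwargs: dict[str, Any] = {
        "seed": int(d["seed"]),
        "data_path": data_path,
        "synthetic": synthetic,
    }
    if "econ" in d:
        kwargs["econ"] = _econ_from(d["econ"])
    if "funnel" in d:
        f = dict(d["funnel"])
        if "session_cost_by_class" in f and f["session_cost_by_class"]:
            f["session_cost_by_class"] = {
                TherapyClass(k.lower()): float(v)
                for k, v in f["session_cost_by_class"].items()
            }
        kwargs["funnel"] = FunnelParams(**f)
    if "psa" in d:
        kwargs["psa"] = None if d["psa"] is None else PsaConfig(
            seed=int(d["seed"]), **d["psa"]
        )
    if "queue" in d:
        kwargs["queue"] = QueueBlock(**d["queue"])
    if "des" in d:
        kwargs["des"] = None if d["des"] is None else DesConfig(
            seed=int(d["seed"]), **d["des"]
        )
    for key in ("demand_policy", "fixed_reduction", "output_dir"):
        if key in d:
            kwargs[key] = d[key]
    if "scenario_scalings" in d:
        kwargs["scenario_scalings"] = tuple(
            (str(name), float(s)) for name, s in d["scenario_scalings"]
        )
    return RunConfig(**kwargs)


def config_from_yaml(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def _config_echo(obj: Any) -> Any:
    """JSON-serializable echo of a (nested) config dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_echo(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {
            (k.value if isinstance(k, TherapyClass) else k): _config_echo(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_config_echo(v) for v in obj]
    if isinstance(obj, TherapyClass):
        return obj.value
    return obj


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


def _breakdown_dict(b) -> dict:
    return {
        "substitution_savings": b.substitution_savings,
        "complementary_savings": b.complementary_savings,
        "partial_benefit_value": b.partial_benefit_value,
        "diga_cost_total": b.diga_cost_total,
        "net": b.net,
    }


def run_full_analysis(config: RunConfig, write: bool = True) -> dict:
    """Execute every stage in dependency order and return the report bundle.

    With ``write=True`` the bundle (JSON), the dataset, the validation report
    (JSON lines), the indicator table and the scenario tables (CSV) are
    written into ``config.output_dir``.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {
        "metadata": {
            "package_version": __version__,
            "master_seed": config.seed,
            "config": _config_echo(config),
        }
    }

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("data")
        if config.synthetic is not None:
            synth = dataclasses.replace(config.synthetic, seed=config.synthetic.seed)
            records = generate_synthetic_records(synth)
            if write:
                write_fund_records(records, out / "fund_records.csv")
        else:
            records = load_fund_records(config.data_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'data' failed: {exc}") from exc

    try:
        stage("validate")
        report = validate_records(records)
        bundle["validation"] = {"n_violations": len(report), "violations": report}
        if write:
            (out / "validation_report.jsonl").write_text(
                violations_to_jsonl(report) + ("\n" if report else ""),
                encoding="utf-8",
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'validate' failed: {exc}") from exc

    try:
        stage("indicators")
        indicators = derive_indicators(records)
        bundle["aggregates"] = aggregate_growth(records)
        if write:
            indicators.to_csv(out / "indicators.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'indicators' failed: {exc}") from exc

    eval_records = latest_year_records(records)

    try:
        stage("base_case")
        base = config.econ.at_mode()
        bundle["base_case"] = {
            rec.fund_id: _breakdown_dict(
                evaluate_fund(rec, base, config.funnel)
            )
            for rec in eval_records
        }
        bundle["base_case_total_net"] = sum(
            v["net"] for v in bundle["base_case"].values()
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'base_case' failed: {exc}") from exc

    if config.psa is not None:
        try:
            stage("psa")
            pooled = run_psa(eval_records, config.econ, config.funnel, config.psa)
            per_fund = stratify_psa(
                eval_records, config.econ, config.funnel, config.psa
            )
            bundle["psa"] = {
                "pooled": pooled.to_dict(),
                "per_fund": {k: v.to_dict() for k, v in per_fund.items()},
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'psa' failed: {exc}") from exc

    try:
        stage("breakeven")
        price = breakeven_price(eval_records, config.econ, config.funnel)
        adherence = breakeven_adherence(eval_records, config.econ, config.funnel)
        bundle["breakeven"] = {
            "price": dataclasses.asdict(price),
            "adherence": dataclasses.asdict(adherence),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'breakeven' failed: {exc}") from exc

    try:
        stage("queue")
        q = config.queue
        lam = arrival_rate(q.annual_cases, q.business_days)
        if q.calibration == "mean_wait":
            mu = calibrate_mu_from_mean_wait(lam, q.observed_mean_wait)
        elif q.calibration == "exceedance-rho":
            mu = calibrate_mu_from_exceedance(
                lam, q.threshold_days, q.exceedance_share, mode="rho-direct"
            )
        elif q.calibration == "exceedance-tail":
            mu = calibrate_mu_from_exceedance(
                lam, q.threshold_days, q.exceedance_share, mode="tail-consistent"
            )
        else:
            raise PipelineError(f"unknown calibration: {q.calibration!r}")
        model = QueueModel(lambda_=lam, mu=mu)
        model.require_stable()
        effect = demand_reduction(
            config.econ.at_mode(),
            config.funnel,
            mode=config.demand_policy,
            fixed_value=config.fixed_reduction,
        )
        scenarios = [
            (name, scaling * effect) for name, scaling in config.scenario_scalings
        ]
        table = scenario_table(
            model,
            scenarios,
            annual_population=q.annual_population,
            threshold=q.threshold_days,
            wage_per_day=q.wage_per_day,
            replacement=(q.replacement_low, q.replacement_high),
        )
        bundle["queue"] = {
            "lambda": lam,
            "mu": mu,
            "rho": model.rho,
            "calibration": q.calibration,
            "demand_reduction_effect": effect,
            "scenarios": table.to_dict(orient="records"),
        }
        if write:
            table.to_csv(out / "queue_scenarios.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'queue' failed: {exc}") from exc

    if config.des is not None:
        try:
            stage("des")
            des_cfg = dataclasses.replace(config.des, seed=config.seed)
            des_table = compare_scenarios(model, scenarios, des_cfg)
            bundle["des"] = des_table.to_dict(orient="records")
            if write:
                des_table.to_csv(out / "des_scenarios.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'des' failed: {exc}") from exc

    if write:
        stage("report")
        (out / "bundle.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True, default=str),
            encoding="utf-8",
        )
    return bundle
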