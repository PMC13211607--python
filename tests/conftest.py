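import pytest

from digasim import (
    EconomicParams,
    FundYearRecord,
    FunnelParams,
    SyntheticConfig,
    TherapyClass,
    generate_synthetic_records,
    latest_year_records,
)


@pytest.fixture
def toy_record() -> FundYearRecord:
    """One fund with 1000 physiotherapy cases at EUR 1500/case and 500 EAP
    cases at EUR 4000/case."""
    return FundYearRecord(
        fund_id="TOY",
        sector_label="toy sector",
        year=2024,
        insured_count=100_000,
        expenditure={
            TherapyClass.PHYSIOTHERAPY: 1500.0 * 1000,
            TherapyClass.EAP: 4000.0 * 500,
        },
        case_count={TherapyClass.PHYSIOTHERAPY: 1000.0, TherapyClass.EAP: 500.0},
    )


@pytest.fixture
def econ() -> EconomicParams:
    return EconomicParams()


@pytest.fixture
def funnel() -> FunnelParams:
    return FunnelParams(session_cost=25.0)


@pytest.fixture(scope="session")
def synthetic_records():
    return generate_synthetic_records(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_latest(synthetic_records):
    return latest_year_records(synthetic_records)
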