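from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def worked_example_table():
    """The adjuvant-chemotherapy teaching example: 25% vs 35% recurrence
    in arms of 100."""
    from nntbench import from_counts

    return from_counts(25, 75, 35, 65)


@pytest.fixture
def endpoint_csv(tmp_path):
    """A small endpoint CSV in the standard schema (percent dialect)."""
    p = tmp_path / "endpoints.csv"
    p.write_text(
        "trial,endpoint,endpoint_class,exp_rate_pct,ctrl_rate_pct,exp_n,ctrl_n,printed_value\n"
        "breast,Any SRE,efficacy,30.7,36.5,1026,1020,18\n"
        "breast,Hypocalcemia,harm,5.5,3.4,1020,1013,48\n"
        "synthetic,Made up,efficacy,10.0,12.0,500,500,\n"
    )
    return p
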