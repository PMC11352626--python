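import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlstrat.cohort import CensoringSpec, CohortSpec, GroupSpec, simulate_cohort
from hlstrat.survival import SurvivalRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(i, time, os_event=False, pfs_time=None, pfs_event=None,
                satb1=False, p16=False, **covariates):
    """One survival record with sensible defaults for unit tests."""
    if pfs_time is None:
        pfs_time = time
    if pfs_event is None:
        pfs_event = os_event
    return SurvivalRecord(
        sample_id=f"S{i:04d}",
        time=float(time),
        os_event=bool(os_event),
        pfs_time=float(pfs_time),
        pfs_event=bool(pfs_event),
        satb1_positive=satb1,
        p16_positive=p16,
        covariates=covariates,
    )


def two_group_spec(plateau_a, hl_a, plateau_b, hl_b, frac_a, n=86, exact=True):
    """Cohort spec with two marker-defined groups (SATB1+ vs SATB1-)."""
    return CohortSpec(
        n=n,
        groups=[
            GroupSpec("A", ("S+P-",), plateau_a, hl_a, plateau_a, hl_a),
            GroupSpec("B", ("S-P-",), plateau_b, hl_b, plateau_b, hl_b),
        ],
        marker_joint={"S+P-": frac_a, "S-P-": 1.0 - frac_a},
        censoring=CensoringSpec(admin_max_months=197.0, min_months=1.0),
        seed=0,
        exact_cells=exact,
    )


@pytest.fixture(scope="session")
def paper_cohort():
    """A paper-like synthetic cohort: 86 patients, marker table 12/8/4/62."""
    from hlstrat.cohort import paper_like_spec

    return simulate_cohort(paper_like_spec(), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
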