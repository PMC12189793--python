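import numpy as np
import pytest

from toiseg import ChangepointSet, PerfusionRecord, SimulationDesign


@pytest.fixture
def trace_record():
    """30-sample record with marker blocks basal 1-10, cold 11-20, warm 21-30."""
    markers = np.array(["basal"] * 10 + ["cold"] * 10 + ["warm"] * 10, dtype=object)
    return PerfusionRecord(
        subject_index=1,
        internal_code="WT14D4",
        group="control",
        sex="male",
        times=np.arange(1.0, 31.0),
        markers=markers,
        values=np.linspace(100.0, 129.0, 30),
    )


@pytest.fixture
def trace_cpts():
    """Interior changepoints {4, 12, 22} over 30 samples."""
    return ChangepointSet(positions=np.array([0, 4, 12, 22, 30]), total_cost=0.0)


@pytest.fixture
def small_design():
    """Fast cohort design: 8 subjects, 60-sample TOIs."""
    return SimulationDesign(
        n_per_group={
            ("control", "female"): 2,
            ("control", "male"): 2,
            ("experimental", "female"): 2,
            ("experimental", "male"): 2,
        },
        toi_lengths=(60, 60, 60),
        artifact_halfwidth=3,
        seed=11,
    )
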