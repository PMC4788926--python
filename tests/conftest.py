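import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fflscreen.qpcr import CONTROL, CtTable, PhaseSchedule, SampleMeta

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_ct_table(
    genes,
    conditions=(CONTROL, "P1"),
    times=(0.0, 2.0, 8.0, 12.0),
    K=2,
    housekeeping=(),
    fill=None,
    rng=None,
):
    """Small CT table with one column per (condition, time, replicate)."""
    schedule = PhaseSchedule(8.0)
    samples, cols = [], {}
    for cond in conditions:
        for t in times:
            for r in range(1, K + 1):
                sid = f"{cond}_t{t:g}_r{r}"
                samples.append(SampleMeta(sid, cond, t, schedule.phase_of(t), r))
                if fill is not None:
                    cols[sid] = [fill(g, cond, t, r) for g in genes]
                else:
                    base = rng or np.random.default_rng(0)
                    cols[sid] = base.uniform(18, 30, size=len(genes))
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"), dtype=float)
    return CtTable(values=values, samples=samples,
                   housekeeping_candidates=list(housekeeping), schedule=schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example_calls():
    from fflscreen.examples import example_calls as _ec

    return _ec()
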