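import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import semseason as ss

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete simulated study shared across tests."""
    cfg = ss.SimulationConfig(seed=11, n_sequences=2, seq_length=50_000,
                              n_genes=8, spike_in_length=3_000)
    genome, annotation = ss.simulate_genome(cfg)
    reports, truth = ss.simulate_methylome(cfg, genome, annotation)
    series = ss.truth_series(truth, reports)
    expression = ss.simulate_expression(cfg, annotation, truth)
    return {
        "cfg": cfg, "genome": genome, "annotation": annotation,
        "reports": reports, "truth": truth, "series": series,
        "expression": expression,
    }


def make_series(meth, total, context="CG", dates=None) -> ss.MethylomeSeries:
    """Hand-built series: one dummy contig, sites 10 bp apart."""
    meth = np.asarray(meth, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    n, t = meth.shape
    if dates is None:
        dates = list(ss.STUDY_DATES)[:t]
    sites = pd.DataFrame({
        "seq_id": "chr_test", "pos": np.arange(n) * 10, "strand": "+",
        "context": context,
    })
    return ss.MethylomeSeries(sites, meth, total, list(dates))


@pytest.fixture
def series_factory():
    return make_series
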