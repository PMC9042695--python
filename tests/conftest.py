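import pandas as pd
import pytest

from trideg import classify, simdata


@pytest.fixture(scope="session")
def reference_fixture() -> pd.DataFrame:
    """The canonical worked-example fixture table (both cell types)."""
    return simdata.build_fixture(simdata.reference_region_counts())


@pytest.fixture(scope="session")
def reference_summary(reference_fixture) -> classify.ClassificationSummary:
    by_ct = {
        ct: classify.classify_table(sub.drop(columns="cell_type"))
        for ct, sub in reference_fixture.groupby("cell_type")
    }
    return classify.summarize(by_ct)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study with planted effects, shared across tests."""
    cfg = simdata.SimConfig(n_genes=400, seed=7)
    counts, design, truth = simdata.simulate_counts(cfg)
    return cfg, counts, design, truth
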