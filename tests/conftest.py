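import numpy as np
import pandas as pd
import pytest

import trapmeta as tm


@pytest.fixture(scope="session")
def sim_config():
    return tm.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def taxonomy(sim_config):
    return tm.make_taxonomy(sim_config)


@pytest.fixture(scope="session")
def community(sim_config, taxonomy):
    """(AbundanceTable, GroundTruth) for the default planted fixture."""
    return tm.simulate_community_counts(sim_config, taxonomy)


@pytest.fixture(scope="session")
def metadata():
    return tm.default_metadata()


@pytest.fixture
def small_table(metadata):
    """Hand-built 4-genus table over the 8-sample design."""
    samples = list(metadata.index)
    counts = pd.DataFrame(
        {s: [0, 0, 0, 0] for s in samples},
        index=pd.Index(["gA", "gB", "gC", "gD"], name="genus"))
    # gA: enriched in traps; gB: flat; gC: trap-exclusive; gD: rare
    for s in samples:
        organ = metadata.at[s, "organ"]
        counts.at["gA", s] = 400 if organ == "trap" else 100
        counts.at["gB", s] = 500
        counts.at["gC", s] = 50 if organ == "trap" else 0
        counts.at["gD", s] = 2
    cats = pd.Series({"gA": "Bacteria", "gB": "Bacteria",
                      "gC": "Metazoa", "gD": "Bacteria"})
    return tm.AbundanceTable(counts=counts, categories=cats, metadata=metadata)
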