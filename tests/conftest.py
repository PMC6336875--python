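import numpy as np
import pytest

import dipscan as d


@pytest.fixture(scope="session")
def small_reference():
    return d.make_reference(60, seed=1)


@pytest.fixture(scope="session")
def reference_435():
    return d.make_reference(435, seed=1)


@pytest.fixture(scope="session")
def domains():
    return d.default_domains()


@pytest.fixture(scope="session")
def cassette(domains):
    return domains[0]


@pytest.fixture(scope="session")
def small_config(domains):
    return d.SimulationConfig(seed=3, n_variants=5000, depth_per_pool=20_000,
                              domains=domains)


def simulate_mean_profiles(reference, domains, config, truth,
                           domain_names=("PDZ", "Cib81")):
    """Full SE/NSE simulation -> replicate-mean profiles per domain."""
    library = d.simulate_library(reference, config)
    out = {}
    for dom in domain_names:
        profiles = []
        for rep in range(1, config.n_replicates + 1):
            se, nse = d.simulate_sort_counts(library, truth, dom, config, rep)
            profiles.append(d.enrichment(se, nse))
        out[dom] = d.mean_profile(profiles)
    return out


@pytest.fixture(scope="session")
def full_study(reference_435, domains):
    """One default-scale study shared by the slower statistical tests."""
    config = d.SimulationConfig(seed=11, domains=domains)
    truth = d.simulate_truth(reference_435, domains, seed=11)
    means = simulate_mean_profiles(reference_435, domains, config, truth)
    return {"reference": reference_435, "config": config, "truth": truth,
            "means": means}
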