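import numpy as np
import pytest

from melasig.nmf import identify_uv_signature, kmeans_exposures, nmf_multistart
from melasig.simulate import (
    CohortSpec,
    GeneratorSignatures,
    make_toy_genome,
    simulate_catalog,
    simulate_panel,
)

N_COHORTS = 20


@pytest.fixture(scope="session")
def generator_signatures():
    return GeneratorSignatures.default()


@pytest.fixture(scope="session")
def toy_genome():
    return make_toy_genome(1_000_000, seed=99)


@pytest.fixture(scope="session")
def small_genome():
    return make_toy_genome(120_000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_genome, generator_signatures):
    """One cheap cohort (n=30) for unit tests."""
    spec = CohortSpec(n_samples=30, genome_length=120_000, seed=5)
    catalog, truth, tally = simulate_catalog(spec, generator_signatures, small_genome)
    return {"spec": spec, "catalog": catalog, "truth": truth, "tally": tally}


@pytest.fixture(scope="session")
def cohorts(toy_genome, generator_signatures):
    """Twenty seeded default cohorts (n=200 each) with full ground truth."""
    out = []
    for seed in range(N_COHORTS):
        spec = CohortSpec(n_samples=200, seed=seed)
        catalog, truth, tally = simulate_catalog(spec, generator_signatures, toy_genome)
        panel = simulate_panel(toy_genome, seed=seed + 500)
        out.append(
            {"spec": spec, "catalog": catalog, "truth": truth, "tally": tally, "panel": panel}
        )
    return out


@pytest.fixture(scope="session")
def fitted_cohorts(cohorts):
    """The same cohorts with rank-2 multistart NMF fits and k-means clusters."""
    fitted = []
    for c in cohorts:
        res = nmf_multistart(c["tally"], 2, 10, seed=c["spec"].seed)
        uv = identify_uv_signature(res)
        clusters = kmeans_exposures(res, seed=0, uv_index=uv)
        fitted.append({**c, "nmf": res, "uv_index": uv, "clusters": clusters})
    return fitted
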