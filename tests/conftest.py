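import numpy as np
import pandas as pd
import pytest

from djsplice.junctions import annotate_junctions
from djsplice.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def cassette_cohort():
    """Seeded two-group cohort: gene_1 carries a hidden cassette exon with
    inclusion 0.7 in group A vs 0.05 in group B (60 samples per group)."""
    spec = CohortSpec(n_genes=10, n_samples_per_group=(60, 60),
                      cassette_genes=[("gene_1", 0.7, 0.05)], seed=11)
    table, annotation, truth = simulate_cohort(spec)
    return table, annotation, truth


@pytest.fixture(scope="session")
def cassette_statuses(cassette_cohort):
    table, annotation, _ = cassette_cohort
    return annotate_junctions(table, annotation)


@pytest.fixture(scope="session")
def cohort_groups(cassette_cohort):
    _, _, truth = cassette_cohort
    return pd.Series(truth["groups"], index=truth["samples"])


@pytest.fixture(scope="session")
def anticoupled_cohort():
    """Two cassette genes whose per-sample inclusion fractions are exact
    complements (psi_B = 1 - psi_A), programming trans-mutual exclusivity."""
    rng = np.random.default_rng(202)
    n = 80
    psi_a = rng.uniform(0.05, 0.95, n)
    spec = CohortSpec(
        n_genes=6, n_samples_per_group=(40, 40),
        cassette_genes=[("gene_1", 0.5, 0.5), ("gene_3", 0.5, 0.5)],
        psi_profiles={"gene_1": psi_a, "gene_3": 1.0 - psi_a},
        gene_abundance=150.0, seed=77)
    table, annotation, truth = simulate_cohort(spec)
    return table, annotation, truth
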