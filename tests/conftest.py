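import numpy as np
import pytest

from dysbiosis.data import SampleMeta, TaxonCountTable
from dysbiosis.simulate import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 0)."""
    return simulate_cohort(SyntheticConfig(seed=0))


@pytest.fixture()
def tiny_table():
    """3 samples x 2 taxa with genus-resolved lineages."""
    return TaxonCountTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["otuA", "otuB"],
        counts=np.array([[3, 0], [1, 5], [2, 2]]),
        lineages={
            "otuA": "k__Bacteria;p__Firmicutes;g__Staphylococcus",
            "otuB": "k__Bacteria;p__Actinobacteria;g__Cutibacterium",
        },
    )


@pytest.fixture()
def paired_meta():
    return [
        SampleMeta("s1L", "sub1", "lesion"),
        SampleMeta("s1P", "sub1", "peri_lesion"),
        SampleMeta("s2L", "sub2", "lesion"),
        SampleMeta("s2P", "sub2", "peri_lesion"),
    ]


def random_table(rng, n_samples=6, n_taxa=8):
    counts = rng.integers(0, 50, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # keep totals positive
    taxa = [f"t{j}" for j in range(n_taxa)]
    return TaxonCountTable(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        taxon_ids=taxa,
        counts=counts,
        lineages={t: f"k__Bacteria;g__G{j}" for j, t in enumerate(taxa)},
    )
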