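import numpy as np
import pytest
from hypothesis import settings

from co1bayes import (
    DEFAULT_LADDER,
    Lineage,
    ReferenceSequence,
    ReferenceSet,
    SyntheticConfig,
    TaxonomyTree,
    generate_reference_set,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

UPPER = ("Root", "Eukaryota", "Metazoa", "Arthropoda", "Insecta", "Diptera")


def toy_lineage(family: str, genus: str) -> Lineage:
    """Full genus-rank lineage under a fixed upper hierarchy."""
    return Lineage(tuple(zip(UPPER + (family, genus), DEFAULT_LADDER)))


def make_refset(entries) -> ReferenceSet:
    """Build a validated genus-trained ReferenceSet from (id, seq, family, genus)."""
    sequences = [
        ReferenceSequence(seq_id, seq, toy_lineage(family, genus))
        for seq_id, seq, family, genus in entries
    ]
    tree = TaxonomyTree.from_lineages(s.lineage for s in sequences)
    refset = ReferenceSet(sequences, tree, "genus", DEFAULT_LADDER)
    refset.validate()
    return refset


@pytest.fixture(scope="session")
def default_refset() -> ReferenceSet:
    """The default well-separated synthetic reference set (48 sequences)."""
    refset, _ = generate_reference_set(SyntheticConfig(seed=11))
    return refset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
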