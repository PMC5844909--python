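"""Hierarchical synthetic reference sets with known truth.

The generator emulates the nested similarity structure of a barcode
reference database: a single random ancestral sequence is mutated down a
star tree at each taxonomic level (family, genus, species, individual),
with per-level substitution rates ordered so that within-species
divergence < within-genus < within-family.  Ranks above family share one
fixed lineage.  A configurable fraction of leaf taxa is truncated to a
single sequence after generation, to emulate singleton genera/species —
taxa whose leave-one-out assignment cannot possibly be correct at the
leaf rank.

Everything is reproducible from one seed, and the emitted set passes
reference-set validation by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .taxonomy import (
    DEFAULT_LADDER,
    SPECIES_LADDER,
    Lineage,
    ReferenceSequence,
    ReferenceSet,
    TaxonomyTree,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: single upper lineage shared by every generated family
UPPER_LINEAGE = (
    ("Root", "rootrank"),
    ("Eukaryota", "superkingdom"),
    ("Animalia", "kingdom"),
    ("Arthropoda", "phylum"),
    ("Insecta", "class"),
    ("Diptera", "order"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and divergence of the generated reference set.

    Counts give the star-tree branching per level; substitution rates are
    the per-site probabilities applied on the branch leading into each
    level (defaults 0.15 / 0.05 / 0.02 / 0.005 create well-separated
    genera with realistic within-taxon noise for a ~650 bp barcode).
    ``singleton_fraction`` truncates that fraction of leaf taxa to one
    sequence (0.23 mimics the genus-level singleton share of public CO1
    data, 0.33 the species-level share).
    """

    families: int = 4
    genera_per_family: int = 3
    species_per_genus: int = 2
    seqs_per_species: int = 2
    sequence_length: int = 650
    d_family: float = 0.15
    d_genus: float = 0.05
    d_species: float = 0.02
    d_within: float = 0.005
    singleton_fraction: float = 0.0
    training_rank: str = "genus"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("families", "genera_per_family", "species_per_genus", "seqs_per_species"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("d_family", "d_genus", "d_species", "d_within"):
            rate = getattr(self, name)
            if not 0 <= rate < 0.75:
                raise ValueError(f"{name} must be in [0, 0.75)")
        if not 0 <= self.singleton_fraction <= 1:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if self.training_rank not in ("genus", "species"):
            raise ValueError("training_rank must be genus or species")


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted base becomes one of the three *other* bases, uniformly.
    """
    if not 0 <= rate < 0.75:
        raise ValueError("rate must be in [0, 0.75)")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        codes = np.searchsorted(_BASES, arr[hit])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, size=hit.sum())
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_reference_set(
    config: Optional[SyntheticConfig] = None,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Generate a reference set plus its truth table.

    Returns the validated :class:`ReferenceSet` and a DataFrame with one
    row per sequence: ``seq_id``, the full ``lineage`` string, and the
    ``singleton`` flag (leaf taxon truncated to a single sequence).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ladder = SPECIES_LADDER if config.training_rank == "species" else DEFAULT_LADDER

    root_seq = random_sequence(config.sequence_length, rng)

    sequences: list[ReferenceSequence] = []
    leaf_members: dict[str, list[ReferenceSequence]] = {}
    for f in range(1, config.families + 1):
        fam_name = f"Fam{f:02d}"
        fam_seq = mutate_sequence(root_seq, config.d_family, rng)
        for g in range(1, config.genera_per_family + 1):
            gen_name = f"{fam_name}Gen{g:02d}"
            gen_seq = mutate_sequence(fam_seq, config.d_genus, rng)
            for s in range(1, config.species_per_genus + 1):
                sp_name = f"{gen_name}Sp{s:02d}"
                sp_seq = mutate_sequence(gen_seq, config.d_species, rng)
                nodes = UPPER_LINEAGE + ((fam_name, "family"), (gen_name, "genus"))
                if config.training_rank == "species":
                    nodes = nodes + ((sp_name, "species"),)
                lineage = Lineage(nodes)
                for i in range(1, config.seqs_per_species + 1):
                    seq = mutate_sequence(sp_seq, config.d_within, rng)
                    ref = ReferenceSequence(f"{sp_name}_{i}", seq, lineage)
                    sequences.append(ref)
                    leaf_members.setdefault(str(lineage), []).append(ref)

    # truncate a seeded choice of leaf taxa to one sequence each
    leaf_keys = sorted(leaf_members)
    n_single = int(len(leaf_keys) * config.singleton_fraction + 0.5)
    singled: set[str] = set()
    if n_single:
        chosen = rng.choice(len(leaf_keys), size=n_single, replace=False)
        singled = {leaf_keys[i] for i in sorted(chosen)}
        keep: list[ReferenceSequence] = []
        for ref in sequences:
            key = str(ref.lineage)
            if key in singled and ref is not leaf_members[key][0]:
                continue
            keep.append(ref)
        sequences = keep

    tree = TaxonomyTree.from_lineages(seq.lineage for seq in sequences)
    refset = ReferenceSet(sequences, tree, config.training_rank, ladder)
    refset.validate()

    truth = pd.DataFrame(
        {
            "seq_id": [s.seq_id for s in sequences],
            "lineage": [str(s.lineage) for s in sequences],
            "singleton": [str(s.lineage) in singled for s in sequences],
        }
    )
    logger.info(
        "generated %d sequences in %d leaf taxa (%d singleton)",
        len(sequences), len(leaf_keys), len(singled),
    )
    return refset, truth
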