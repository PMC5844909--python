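"""Reference-set input/output in the RDP training dialect.

A reference set is a pair of plain-text files:

* a FASTA file whose headers carry the full taxonomic lineage after a
  single tab, semicolon-delimited from root to leaf, e.g.::

      >AB123456\tRoot;Eukaryota;Metazoa;Arthropoda;Insecta;Diptera;Culicidae;Aedes

* a taxonomy file of asterisk-delimited records
  ``taxid*name*parent_taxid*depth*rank`` with the fixed root line
  ``0*Root*-1*0*rootrank``.

Lineage ranks are assigned positionally from a rank ladder
(rootrank, superkingdom, kingdom, phylum, class, order, family, genus,
optionally species).  The module validates every lineage against the
taxonomy tree, applies the minimum-length filter used when compiling
barcode training sets (>= 500 bp by default), and round-trips sets
byte-faithfully.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ROOT_RANK = "rootrank"
#: names conventionally used for the root field of a lineage
ROOT_NAMES = frozenset({"Root", "cellularOrganisms"})

#: rank ladder for a genus-trained reference set (v1-style)
DEFAULT_LADDER: tuple[str, ...] = (
    ROOT_RANK,
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
)
#: rank ladder for a species-trained reference set (v2-style)
SPECIES_LADDER: tuple[str, ...] = DEFAULT_LADDER + ("species",)

#: minimum training-sequence length (full-length barcode filter)
DEFAULT_MIN_TRAIN_LENGTH = 500

_COMPLEMENTABLE = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """A line of input does not follow the expected dialect."""


class ConsistencyError(ValueError):
    """Sequences and taxonomy disagree (lineage absent from the tree, ...)."""


def rank_ladder(training_rank: str = "genus") -> tuple[str, ...]:
    """Return the standard rank ladder ending at ``training_rank``."""
    for ladder in (DEFAULT_LADDER, SPECIES_LADDER):
        if training_rank in ladder:
            return ladder[: ladder.index(training_rank) + 1]
    raise ValueError(f"unknown training rank: {training_rank!r}")


@dataclass(frozen=True)
class Lineage:
    """An ordered root-to-leaf path of ``(name, rank)`` nodes."""

    nodes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("lineage must have at least one node")
        for name, rank in self.nodes:
            if not name or not rank:
                raise ValueError("lineage nodes must have non-empty name and rank")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.nodes)

    @property
    def ranks(self) -> tuple[str, ...]:
        return tuple(rank for _, rank in self.nodes)

    @property
    def leaf_name(self) -> str:
        return self.nodes[-1][0]

    @property
    def leaf_rank(self) -> str:
        return self.nodes[-1][1]

    def name_at(self, rank: str) -> Optional[str]:
        """Name of the ancestor at ``rank``, or None if absent."""
        for name, r in self.nodes:
            if r == rank:
                return name
        return None

    def prefix_at(self, rank: str) -> Optional[tuple[str, ...]]:
        """Names from the root down to ``rank`` inclusive, or None."""
        for i, (_, r) in enumerate(self.nodes):
            if r == rank:
                return tuple(name for name, _ in self.nodes[: i + 1])
        return None

    def __str__(self) -> str:
        return ";".join(self.names)

    def __len__(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_names(cls, names: Sequence[str], ladder: Sequence[str]) -> "Lineage":
        if len(names) > len(ladder):
            raise FormatError(
                f"lineage has {len(names)} fields but the rank ladder has "
                f"only {len(ladder)} entries: {';'.join(names)}"
            )
        return cls(tuple(zip(names, ladder)))


def parse_lineage(header_line: str, ladder: Sequence[str] = DEFAULT_LADDER) -> Lineage:
    """Parse the lineage from a ``>id<TAB>name;name;...`` FASTA header.

    Ranks are assigned positionally from ``ladder``; the leading
    ``Root``/``cellularOrganisms`` field maps to the root rank.
    """
    _, lineage = parse_header(header_line, ladder)
    return lineage


def parse_header(header_line: str, ladder: Sequence[str] = DEFAULT_LADDER) -> tuple[str, Lineage]:
    """Parse a lineage-bearing FASTA header into ``(seq_id, Lineage)``."""
    line = header_line.rstrip("\r\n")
    if line.startswith(">"):
        line = line[1:]
    if "\t" not in line:
        raise FormatError(f"missing tab separator in header: {header_line!r}")
    seq_id, rest = line.split("\t", 1)
    seq_id = seq_id.strip()
    if not seq_id:
        raise FormatError(f"empty sequence id in header: {header_line!r}")
    fields = [f.strip() for f in rest.split(";")]
    if any(not f for f in fields):
        raise FormatError(f"empty lineage field in header: {header_line!r}")
    return seq_id, Lineage.from_names(fields, ladder)


@dataclass(frozen=True)
class TaxonRecord:
    taxid: int
    name: str
    parent_taxid: int
    depth: int
    rank: str


class TaxonomyTree:
    """The assignment hierarchy, stored RDP-training-file style.

    Each node is ``(taxid, name, parent_taxid, depth, rank)``; the single
    root has parent −1 and depth 0.  Nodes are addressed by the
    ``(parent_taxid, name, rank)`` triple, which is unique.
    """

    def __init__(self) -> None:
        self._records: dict[int, TaxonRecord] = {}
        self._by_key: dict[tuple[int, str, str], int] = {}
        self._next_id = 0

    # -- construction ------------------------------------------------------

    @classmethod
    def with_root(cls, name: str = "Root", rank: str = ROOT_RANK) -> "TaxonomyTree":
        tree = cls()
        tree._insert(name, -1, 0, rank)
        return tree

    def _insert(self, name: str, parent: int, depth: int, rank: str) -> int:
        taxid = self._next_id
        self._next_id += 1
        self._records[taxid] = TaxonRecord(taxid, name, parent, depth, rank)
        self._by_key[(parent, name, rank)] = taxid
        return taxid

    def add_lineage(self, lineage: Lineage) -> int:
        """Insert any missing nodes along ``lineage``; return the leaf taxid."""
        if not self._records:
            root_name, root_rank = lineage.nodes[0]
            self._insert(root_name, -1, 0, root_rank)
        taxid = self.root.taxid
        root_name, root_rank = lineage.nodes[0]
        if (self.root.name, self.root.rank) != (root_name, root_rank):
            raise ConsistencyError(
                f"lineage root {root_name!r} does not match tree root {self.root.name!r}"
            )
        for depth, (name, rank) in enumerate(lineage.nodes[1:], start=1):
            key = (taxid, name, rank)
            if key in self._by_key:
                taxid = self._by_key[key]
            else:
                taxid = self._insert(name, taxid, depth, rank)
        return taxid

    @classmethod
    def from_lineages(cls, lineages: Iterable[Lineage]) -> "TaxonomyTree":
        tree = cls()
        for lineage in lineages:
            tree.add_lineage(lineage)
        return tree

    # -- queries -----------------------------------------------------------

    @property
    def root(self) -> TaxonRecord:
        for rec in self._records.values():
            if rec.parent_taxid == -1:
                return rec
        raise ConsistencyError("taxonomy tree has no root")

    @property
    def records(self) -> tuple[TaxonRecord, ...]:
        return tuple(self._records[t] for t in sorted(self._records))

    def __len__(self) -> int:
        return len(self._records)

    def max_depth(self) -> int:
        return max(rec.depth for rec in self._records.values())

    def resolve(self, lineage: Lineage) -> int:
        """Return the taxid of the lineage's leaf, or raise KeyError."""
        root = self.root
        name, rank = lineage.nodes[0]
        if (root.name, root.rank) != (name, rank):
            raise KeyError(f"root {name!r} ({rank}) not in tree")
        taxid = root.taxid
        for name, rank in lineage.nodes[1:]:
            key = (taxid, name, rank)
            if key not in self._by_key:
                raise KeyError(f"taxon {name!r} ({rank}) not in tree")
            taxid = self._by_key[key]
        return taxid

    def contains(self, lineage: Lineage) -> bool:
        try:
            self.resolve(lineage)
            return True
        except KeyError:
            return False

    def validate(self) -> None:
        """Check the structural invariants; raise ConsistencyError on failure."""
        roots = [r for r in self._records.values() if r.parent_taxid == -1]
        if len(roots) != 1:
            raise ConsistencyError(f"expected exactly one root, found {len(roots)}")
        if roots[0].depth != 0:
            raise ConsistencyError("root depth must be 0")
        for rec in self._records.values():
            if rec.parent_taxid == -1:
                continue
            parent = self._records.get(rec.parent_taxid)
            if parent is None:
                raise ConsistencyError(f"taxid {rec.taxid} has unknown parent {rec.parent_taxid}")
            if rec.depth != parent.depth + 1:
                raise ConsistencyError(
                    f"taxid {rec.taxid} depth {rec.depth} != parent depth {parent.depth} + 1"
                )
        if len(self._by_key) != len(self._records):
            raise ConsistencyError("(name, rank, parent) triples are not unique")

    # -- file dialect ------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "TaxonomyTree":
        tree = cls()
        max_id = -1
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("*")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 asterisk-delimited fields")
            try:
                taxid, name, parent, depth, rank = (
                    int(parts[0]), parts[1], int(parts[2]), int(parts[3]), parts[4],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if taxid in tree._records:
                raise FormatError(f"{path}:{lineno}: duplicate taxid {taxid}")
            tree._records[taxid] = TaxonRecord(taxid, name, parent, depth, rank)
            tree._by_key[(parent, name, rank)] = taxid
            max_id = max(max_id, taxid)
        tree._next_id = max_id + 1
        tree.validate()
        return tree

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            for rec in self.records:
                fh.write(f"{rec.taxid}*{rec.name}*{rec.parent_taxid}*{rec.depth}*{rec.rank}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTree):
            return NotImplemented
        return set(self._records.values()) == set(other._records.values())


@dataclass
class ReferenceSequence:
    """A single reference barcode with its known lineage."""

    seq_id: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.seq_id}: empty sequence")


@dataclass
class ReferenceSet:
    """A lineage-annotated sequence collection plus its taxonomy tree."""

    sequences: list[ReferenceSequence]
    tree: TaxonomyTree
    training_rank: str
    ladder: tuple[str, ...] = DEFAULT_LADDER

    def __len__(self) -> int:
        return len(self.sequences)

    def leaf_counts(self) -> Counter:
        """Sequence count per leaf taxon, keyed by the full lineage string."""
        return Counter(str(seq.lineage) for seq in self.sequences)

    def singleton_taxa(self) -> set[str]:
        """Leaf taxa represented by exactly one sequence."""
        return {taxon for taxon, n in self.leaf_counts().items() if n == 1}

    def validate(self) -> None:
        self.tree.validate()
        seen: set[str] = set()
        bad: list[str] = []
        for seq in self.sequences:
            if seq.seq_id in seen:
                raise ConsistencyError(f"duplicate seq_id {seq.seq_id!r}")
            seen.add(seq.seq_id)
            if seq.lineage.leaf_rank != self.training_rank:
                raise ConsistencyError(
                    f"{seq.seq_id}: leaf rank {seq.lineage.leaf_rank!r} != "
                    f"training rank {self.training_rank!r}"
                )
            if not self.tree.contains(seq.lineage):
                bad.append(seq.seq_id)
        if bad:
            raise ConsistencyError(f"lineages absent from taxonomy tree: {', '.join(bad)}")


def _clean_sequence(raw: str) -> str:
    # tolerant ingestion: uppercase, RNA U -> T
    return raw.upper().replace("U", "T")


def read_reference_set(
    fasta_path: str | Path,
    taxonomy_path: str | Path,
    min_length: int = DEFAULT_MIN_TRAIN_LENGTH,
    training_rank: Optional[str] = None,
    ladder: Optional[Sequence[str]] = None,
) -> ReferenceSet:
    """Load and validate a reference set from its FASTA + taxonomy files.

    Sequences shorter than ``min_length`` are dropped (the count is logged).
    ``training_rank`` defaults to the leaf rank of the first retained
    lineage; the ladder is inferred from the tree when not given (species
    ladder if any node carries the species rank).
    """
    tree = TaxonomyTree.from_file(taxonomy_path)
    if ladder is None:
        ranks_present = {rec.rank for rec in tree.records}
        ladder = SPECIES_LADDER if "species" in ranks_present else DEFAULT_LADDER
    ladder = tuple(ladder)

    sequences: list[ReferenceSequence] = []
    seen: set[str] = set()
    dropped = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq_id, lineage = parse_header(record.description, ladder)
        if seq_id in seen:
            raise ConsistencyError(f"duplicate seq_id {seq_id!r} in {fasta_path}")
        seen.add(seq_id)
        sequence = _clean_sequence(str(record.seq))
        if len(sequence) < min_length:
            dropped += 1
            continue
        sequences.append(ReferenceSequence(seq_id, sequence, lineage))
    if dropped:
        logger.info("dropped %d sequence(s) shorter than %d bp", dropped, min_length)

    if training_rank is None:
        if not sequences:
            raise ConsistencyError(f"no sequences >= {min_length} bp in {fasta_path}")
        training_rank = sequences[0].lineage.leaf_rank
    refset = ReferenceSet(sequences, tree, training_rank, ladder)
    refset.validate()
    return refset


def write_reference_set(
    refset: ReferenceSet, fasta_path: str | Path, taxonomy_path: str | Path
) -> None:
    """Write a reference set in the same dialect :func:`read_reference_set` reads."""
    records = []
    for seq in refset.sequences:
        description = f"{seq.seq_id}\t{seq.lineage}"
        records.append(SeqRecord(Seq(seq.sequence), id=seq.seq_id, description=description))
    with open(fasta_path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")
    tree = refset.tree
    if not len(tree):
        tree = TaxonomyTree.with_root()
    tree.to_file(taxonomy_path)


def read_query_fasta(path: str | Path, min_length: int = 1) -> list[tuple[str, str]]:
    """Read plain query FASTA as ``(seq_id, sequence)`` pairs (no lineage)."""
    out = []
    dropped = 0
    for record in SeqIO.parse(str(path), "fasta"):
        sequence = _clean_sequence(str(record.seq))
        if len(sequence) < min_length:
            dropped += 1
            continue
        out.append((record.id, sequence))
    if dropped:
        logger.info("dropped %d query sequence(s) shorter than %d bp", dropped, min_length)
    return out
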