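"""IUPAC-aware primer location, trimming and anchored-fragment extraction.

Amplicon reads start where a PCR primer sat, so benchmark fragments are
anchored at primer sites rather than sampled at random: the 200 bp
immediately 3' of a located forward primer, or the 200 bp immediately 5'
of a located reverse primer site (returned reverse-complemented into
read orientation).  Primer location is an ungapped scan with degenerate
IUPAC bases on the primer side and a substitution budget of
``floor(primer length x 0.10)`` mismatches by default; the best match is
the one with the fewest mismatches, ties going to the 5'-most position.
All coordinates are 0-based half-open on the plus strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .taxonomy import ReferenceSet

logger = logging.getLogger(__name__)

#: IUPAC degenerate codes expanded to the plain bases they stand for
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

FORWARD = "forward"
REVERSE = "reverse"
DEFAULT_MAX_MISMATCH_FRACTION = 0.10
DEFAULT_ANCHOR_LENGTH = 200


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement."""
    try:
        return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(sequence))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from exc


def iupac_match(primer_base: str, seq_base: str) -> bool:
    """Whether a sequence base satisfies a (possibly degenerate) primer base.

    Degeneracy is honoured on the primer side only: an N in the sequence
    matches nothing unless the primer base itself is N.
    """
    if primer_base not in IUPAC:
        raise ValueError(f"invalid primer base {primer_base!r}")
    if seq_base not in IUPAC:
        raise ValueError(f"invalid sequence base {seq_base!r}")
    if primer_base == "N":
        return True
    return seq_base in IUPAC[primer_base]


@dataclass(frozen=True)
class PrimerDef:
    """A named primer, its direction, and its tolerated mismatch fraction."""

    name: str
    sequence: str
    direction: str  # forward | reverse
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: invalid IUPAC base(s) {sorted(bad)}")
        if self.direction not in (FORWARD, REVERSE):
            raise ValueError(f"primer {self.name}: direction must be forward or reverse")
        if not 0 <= self.max_mismatch_fraction < 1:
            raise ValueError("max_mismatch_fraction must be in [0, 1)")

    @property
    def mismatch_budget(self) -> int:
        return math.floor(len(self.sequence) * self.max_mismatch_fraction)

    @property
    def scan_pattern(self) -> str:
        """The plus-strand pattern actually scanned for.

        Reverse primers anneal to the plus strand as their reverse
        complement.
        """
        if self.direction == REVERSE:
            return reverse_complement(self.sequence)
        return self.sequence


@dataclass(frozen=True)
class PrimerMatch:
    """Best primer placement: 0-based half-open plus-strand interval."""

    start: int
    end: int
    mismatches: int
    direction: str


def locate_primer(sequence: str, primer: PrimerDef) -> Optional[PrimerMatch]:
    """Best ungapped placement of ``primer`` on the plus strand, or None.

    Best means fewest mismatches; ties go to the smallest start.  No
    match is reported when even the best placement exceeds the primer's
    mismatch budget, or the primer is longer than the sequence.
    """
    pattern = primer.scan_pattern
    plen = len(pattern)
    if plen > len(sequence):
        return None
    budget = primer.mismatch_budget
    best_start = -1
    best_mm = plen + 1
    for start in range(len(sequence) - plen + 1):
        mm = 0
        for pb, sb in zip(pattern, sequence[start : start + plen]):
            if not iupac_match(pb, sb):
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_mm = mm
            best_start = start
            if mm == 0:
                break
    if best_mm > budget:
        return None
    return PrimerMatch(best_start, best_start + plen, best_mm, primer.direction)


def primer_anchored_fragment(
    sequence: str, primer: PrimerDef, L: int = DEFAULT_ANCHOR_LENGTH
) -> Optional[str]:
    """The ``L`` bases adjacent to the primer site, in read orientation.

    Forward primer: bases immediately 3' of the match on the plus
    strand.  Reverse primer: bases immediately 5' of the reverse-
    complement match, reverse-complemented.  None when there is no match
    or fewer than ``L`` bases remain on the relevant side.
    """
    match = locate_primer(sequence, primer)
    if match is None:
        return None
    if primer.direction == FORWARD:
        fragment = sequence[match.end : match.end + L]
        return fragment if len(fragment) == L else None
    fragment = sequence[max(0, match.start - L) : match.start]
    if len(fragment) != L:
        return None
    return reverse_complement(fragment)


def primer_coverage(
    refset: ReferenceSet,
    primer: PrimerDef,
    L: int = DEFAULT_ANCHOR_LENGTH,
    per_rank: Optional[str] = None,
) -> tuple[float, Optional[pd.DataFrame]]:
    """Fraction of reference sequences yielding an anchored fragment.

    A located primer with fewer than ``L`` flanking bases does not count
    as covered.  With ``per_rank`` a per-taxon breakdown at that rank is
    returned as well.
    """
    if not refset.sequences:
        raise ValueError("empty reference set")
    covered = []
    groups: dict[str, list[bool]] = {}
    for seq in refset.sequences:
        ok = primer_anchored_fragment(seq.sequence, primer, L) is not None
        covered.append(ok)
        if per_rank is not None:
            name = seq.lineage.name_at(per_rank) or "unresolved"
            groups.setdefault(name, []).append(ok)
    fraction = sum(covered) / len(covered)
    breakdown = None
    if per_rank is not None:
        breakdown = pd.DataFrame(
            [
                {"taxon": name, "n": len(flags), "coverage": sum(flags) / len(flags)}
                for name, flags in sorted(groups.items())
            ]
        )
    return fraction, breakdown


def read_primer_tsv(path: str | Path) -> list[PrimerDef]:
    """Read primer definitions from TSV (name, sequence, direction[, max_mismatch_fraction])."""
    frame = pd.read_csv(path, sep="\t")
    required = {"name", "sequence", "direction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing primer column(s) {sorted(missing)}")
    primers = []
    for _, row in frame.iterrows():
        kwargs = {}
        if "max_mismatch_fraction" in frame.columns and not pd.isna(
            row.get("max_mismatch_fraction")
        ):
            kwargs["max_mismatch_fraction"] = float(row["max_mismatch_fraction"])
        primers.append(
            PrimerDef(str(row["name"]), str(row["sequence"]).upper(), str(row["direction"]), **kwargs)
        )
    return primers


def primer_benchmark(
    refset: ReferenceSet,
    primers: Sequence[PrimerDef],
    model=None,
    boot_config=None,
    rank: str = "genus",
    cutoff: int = 60,
    L: int = DEFAULT_ANCHOR_LENGTH,
    include_singletons: bool = False,
) -> pd.DataFrame:
    """Leave-one-out evaluation of primer-anchored fragments per primer.

    For each primer: the anchored-fragment coverage of the reference
    set, then — classifying each covered, held-out sequence's fragment —
    the proportion of correct assignments at ``rank`` before and after
    applying the bootstrap support ``cutoff``, mirroring how trimmed
    amplicon reads would be scored.
    """
    from .bootstrap import BootstrapConfig, bootstrap_classify
    from .classifier import train, word_codes
    from .evaluation import LOORecord, classify_outcomes, outcome_rates

    boot_config = boot_config or BootstrapConfig()
    if model is None:
        model = train(refset)
    singletons = refset.singleton_taxa()

    rows = []
    for primer in primers:
        coverage, _ = primer_coverage(refset, primer, L)
        records = []
        for seq in refset.sequences:
            singleton = str(seq.lineage) in singletons
            if singleton and not include_singletons:
                continue
            fragment = primer_anchored_fragment(seq.sequence, primer, L)
            if fragment is None:
                continue
            taxon_idx = model.taxon_index(str(seq.lineage))
            codes = word_codes(seq.sequence, model.config.word_size, distinct=True)
            model.remove_sequence_counts(codes, taxon_idx)
            try:
                result = bootstrap_classify(model, fragment, boot_config, seq_id=seq.seq_id)
            finally:
                model.add_sequence_counts(codes, taxon_idx)
            records.append(
                LOORecord(
                    seq.seq_id, L, seq.lineage, result.lineage, result.support,
                    singleton, result.unclassifiable,
                )
            )
        no_cut = classify_outcomes(records, rank, 0)
        with_cut = classify_outcomes(records, rank, cutoff)
        passing = with_cut.tp + with_cut.fp
        rows.append(
            {
                "primer": primer.name,
                "direction": primer.direction,
                "coverage": coverage,
                "n_classified": no_cut.classified,
                "prop_correct": outcome_rates(no_cut).accuracy,
                "prop_correct_cutoff": (with_cut.tp / passing) if passing else float("nan"),
                "prop_passing_cutoff": (passing / with_cut.classified)
                if with_cut.classified else float("nan"),
            }
        )
    return pd.DataFrame(rows)
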