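"""Per-rank bootstrap confidence for naive Bayes assignments.

The assignment itself is made from the query's full word set.  Confidence
is then estimated by repeatedly (100 times by default) drawing a random
subsample of the query's words — one eighth of them, without replacement,
clamped to at least one word — classifying the subsample, and recording
the winning leaf's full lineage.  The support reported at a rank is the
percentage of trials whose winner agrees with the full-set assignment
along the whole root-to-rank path, which makes support monotone
non-decreasing from the leaf toward the root by construction.

Each query gets its own random stream derived from ``(seed, seq_id)``, so
results do not depend on batch order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classifier import TrainedModel, UnclassifiableError, word_codes
from .taxonomy import Lineage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: trial count, subsample fraction, replacement, seed."""

    trials: int = 100
    subsample_fraction: float = 0.125  # 1/8 of the query's words
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")

    def subsample_size(self, word_count: int) -> int:
        """s = max(1, floor(W * f))."""
        return max(1, int(word_count * self.subsample_fraction))


@dataclass
class ClassificationResult:
    """A leaf assignment with integer percent support at every rank."""

    seq_id: str
    lineage: Optional[Lineage]
    support: dict[str, int] = field(default_factory=dict)
    unclassifiable: bool = False

    def __post_init__(self) -> None:
        assert all(0 <= v <= 100 for v in self.support.values())


def query_rng(seed: int, seq_id: str, *extra: int) -> np.random.Generator:
    """Independent, reproducible random stream for one query."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(seq_id.encode("utf-8")), *extra])
    )


def subsample_words(
    words: np.ndarray | Sequence,
    s: int,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> np.ndarray:
    """Uniform draw of ``s`` words; without replacement by default."""
    words = np.asarray(words)
    if not with_replacement and s > len(words):
        raise ValueError(f"cannot draw {s} of {len(words)} words without replacement")
    idx = rng.choice(len(words), size=s, replace=with_replacement)
    return words[idx]


def support_from_trials(
    full_lineage: Lineage,
    trial_lineages: Sequence[Lineage],
    ladder: Sequence[str],
) -> dict[str, int]:
    """Percent of trials recovering the full-set assignment at each rank.

    Agreement at a rank means the whole root-to-rank name path matches,
    so the returned map is monotone non-decreasing toward the root.
    """
    trials = len(trial_lineages)
    support: dict[str, int] = {}
    for rank in ladder:
        target = full_lineage.prefix_at(rank)
        if target is None:
            continue
        hits = sum(1 for lin in trial_lineages if lin.prefix_at(rank) == target)
        support[rank] = int(100 * hits / trials + 0.5)  # round half up
    return support


def bootstrap_classify(
    model: TrainedModel,
    sequence: str,
    config: BootstrapConfig,
    seq_id: str = "query",
) -> ClassificationResult:
    """Classify a query and attach per-rank bootstrap support.

    The full word set decides the assignment; trials vote on whether
    subsampled word sets recover it rank by rank.  A query yielding no
    valid words is returned as an unclassifiable record rather than
    raising, so batch runs keep going.
    """
    codes = word_codes(sequence, model.config.word_size, model.config.use_distinct_words)
    if codes.size == 0:
        return ClassificationResult(seq_id, None, {}, unclassifiable=True)

    cols = model._cols(codes)
    winner = model.classify_cols(cols)
    full_lineage = model.lineages[model.taxa[winner]]

    rng = query_rng(config.seed, seq_id)
    s = config.subsample_size(len(cols))
    trial_lineages = []
    for _ in range(config.trials):
        sub = subsample_words(cols, s, rng, config.with_replacement)
        t = model.classify_cols(sub)
        trial_lineages.append(model.lineages[model.taxa[t]])

    support = support_from_trials(full_lineage, trial_lineages, model.ladder)
    return ClassificationResult(seq_id, full_lineage, support)


def write_fixrank(
    results: Sequence[ClassificationResult],
    ladder: Sequence[str],
    path,
) -> None:
    """Write a classification batch as fixed-rank TSV.

    One row per query: seq_id then a (name, rank, support) triple for
    every ladder rank.  Unclassifiable queries get empty names and zero
    support.
    """
    with open(path, "w", newline="\n") as fh:
        header = ["seq_id"]
        for rank in ladder:
            header += [f"name_{rank}", "rank", f"support_{rank}"]
        fh.write("\t".join(header) + "\n")
        for res in results:
            row = [res.seq_id]
            for rank in ladder:
                name = res.lineage.name_at(rank) if res.lineage else ""
                row += [name or "", rank, str(res.support.get(rank, 0))]
            fh.write("\t".join(row) + "\n")


def apply_rank_cutoffs(
    result: ClassificationResult, cutoffs: dict[str, int]
) -> Optional[Lineage]:
    """Truncate an assignment to the deepest rank meeting its support cutoff.

    Walks from the leaf toward the root; the first rank whose support is
    at or above its cutoff (ranks without a cutoff always pass) ends the
    reported lineage.  Returns None when even the root fails.
    """
    if result.lineage is None:
        return None
    nodes = result.lineage.nodes
    for i in range(len(nodes) - 1, -1, -1):
        rank = nodes[i][1]
        needed = cutoffs.get(rank)
        if needed is None or result.support.get(rank, 0) >= needed:
            return Lineage(nodes[: i + 1])
    return None
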