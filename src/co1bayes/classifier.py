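"""Naive Bayesian word-frequency classifier for DNA barcodes.

The classifier follows the canonical RDP formulation.  Training records,
for words of fixed size *k* (default 8 bp), per-sequence word *presence*:

* ``N``      — total number of training sequences,
* ``n(w)``   — number of training sequences containing word *w*,
* ``M_G``    — number of sequences in leaf taxon *G*,
* ``m_G(w)`` — number of *G*'s sequences containing *w*.

From these, the word prior is ``P_w = (n(w) + 0.5) / (N + 1)`` and the
per-taxon conditional is ``P(w | G) = (m_G(w) + P_w) / (M_G + 1)``; a
query's score for *G* is the naive-Bayes sum of log conditionals over the
query's (by default distinct) words, and the assignment is the leaf taxon
with the maximum score, ties broken by lexicographically smallest taxon
name.  Words containing any non-ACGT character are skipped entirely.

Counts are plain integers, so a sequence can be removed from and restored
to a trained model exactly — the basis of leave-one-out testing.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .taxonomy import DEFAULT_LADDER, Lineage, ReferenceSet

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# byte-level lookup: ACGT -> 0..3, everything else -> -1
_CODE_TABLE = np.full(256, -1, dtype=np.int64)
for _b, _c in _BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _c


class UnclassifiableError(ValueError):
    """The query yields no valid words and cannot be scored."""


def encode_word(word: str) -> int:
    """2-bit encode an ACGT word to an integer."""
    code = 0
    for base in word:
        code = (code << 2) | _BASE_CODE[base]
    return code


def decode_word(code: int, k: int) -> str:
    bases = []
    for _ in range(k):
        bases.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(bases))


def word_codes(sequence: str, k: int, distinct: bool = True) -> np.ndarray:
    """Integer codes of all valid length-``k`` windows of ``sequence``.

    Windows containing any non-ACGT character are skipped.  With
    ``distinct`` the codes are deduplicated (sorted); otherwise one code
    per window position is returned, in order.
    """
    if k < 1:
        raise ValueError("word size must be >= 1")
    n = len(sequence)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = _CODE_TABLE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    values = windows[valid] @ powers
    if distinct:
        return np.unique(values)
    return values


def extract_words(sequence: str, k: int, distinct: bool = True) -> list[str]:
    """All valid length-``k`` words of ``sequence`` as strings.

    Returned in order of first occurrence; duplicates collapsed when
    ``distinct`` is true.  A sequence shorter than ``k`` yields an empty
    list (the caller decides whether that is fatal).
    """
    codes = word_codes(sequence, k, distinct=False)
    words = [decode_word(int(c), k) for c in codes]
    if distinct:
        return list(dict.fromkeys(words))
    return words


@dataclass(frozen=True)
class ModelConfig:
    """Classifier configuration.

    ``word_size``
        length of the k-mer feature, default 8 bp.
    ``training_rank``
        rank of the leaf taxa the model assigns (genus or species).
    ``use_distinct_words``
        score each distinct query word once (presence semantics, the
        default) or once per occurrence.
    """

    word_size: int = 8
    training_rank: str = "genus"
    use_distinct_words: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.word_size <= 16:
            raise ValueError("word_size must be in [1, 16]")


class TrainedModel:
    """Word-presence counts for a reference set, ready for classification.

    The per-taxon count matrix ``m`` has one column per training-vocabulary
    word plus a trailing all-zero sentinel column onto which unseen query
    words are mapped (so their conditional reduces to the prior term).
    """

    def __init__(
        self,
        config: ModelConfig,
        ladder: tuple[str, ...],
        taxa: list[str],
        lineages: dict[str, Lineage],
        M: np.ndarray,
        m: np.ndarray,
        word_col: dict[int, int],
        N: int,
    ) -> None:
        self.config = config
        self.ladder = ladder
        self.taxa = taxa
        self.lineages = lineages
        self.M = M
        self.m = m
        self.word_col = word_col
        self.N = N
        self._taxon_index = {t: i for i, t in enumerate(taxa)}

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_index(self, taxon: str) -> int:
        """Index of a taxon given its full lineage string or leaf name."""
        if taxon in self._taxon_index:
            return self._taxon_index[taxon]
        hits = [i for i, t in enumerate(self.taxa) if self.lineages[t].leaf_name == taxon]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise KeyError(f"unknown taxon {taxon!r}")
        raise KeyError(f"ambiguous leaf name {taxon!r}; use the full lineage string")

    def word_count(self, word: str | int) -> int:
        """n(w): number of training sequences containing ``word``."""
        code = encode_word(word) if isinstance(word, str) else word
        col = self.word_col.get(code)
        if col is None:
            return 0
        return int(self.m[:, col].sum())

    def check_invariants(self) -> None:
        assert self.N == int(self.M.sum()), "sum of M_G must equal N"
        assert (self.m >= 0).all() and (self.M >= 0).all()
        assert (self.m <= self.M[:, None]).all(), "m_G(w) must not exceed M_G"

    # -- probabilities -----------------------------------------------------

    def word_prior(self, word: str | int) -> float:
        """P_w = (n(w) + 0.5) / (N + 1); strictly inside (0, 1)."""
        return (self.word_count(word) + 0.5) / (self.N + 1)

    def taxon_conditional(self, word: str | int, taxon: str) -> float:
        """P(w | G) = (m_G(w) + P_w) / (M_G + 1); strictly inside (0, 1)."""
        t = self.taxon_index(taxon)
        code = encode_word(word) if isinstance(word, str) else word
        col = self.word_col.get(code)
        m_gw = int(self.m[t, col]) if col is not None else 0
        return (m_gw + self.word_prior(code)) / (int(self.M[t]) + 1)

    def _cols(self, codes: np.ndarray) -> np.ndarray:
        sentinel = self.m.shape[1] - 1
        return np.fromiter(
            (self.word_col.get(int(c), sentinel) for c in codes),
            dtype=np.int64,
            count=len(codes),
        )

    def _scores_for_cols(self, cols: np.ndarray) -> np.ndarray:
        """Log-posterior score of every taxon for the given word columns."""
        sub = self.m[:, cols]  # (T, W)
        priors = (sub.sum(axis=0) + 0.5) / (self.N + 1)  # P_w per word
        cond = (sub + priors[None, :]) / (self.M[:, None] + 1)
        return np.log(cond).sum(axis=1)

    def score(self, words: Iterable[str | int] | np.ndarray, taxon: str) -> float:
        """Sum of log conditionals of ``words`` for ``taxon``."""
        if isinstance(words, np.ndarray):
            codes = words
        else:
            codes = np.array(
                [encode_word(w) if isinstance(w, str) else w for w in words], dtype=np.int64
            )
        if codes.size == 0:
            raise UnclassifiableError("unclassifiable: no valid words")
        t = self.taxon_index(taxon)
        cols = self._cols(codes)
        return float(self._scores_for_cols(cols)[t])

    # -- classification ----------------------------------------------------

    def classify_cols(self, cols: np.ndarray) -> int:
        """Index of the best-scoring candidatable taxon for word columns.

        Taxa with no remaining training sequences (M == 0) are excluded
        from candidacy.  ``self.taxa`` is sorted by (leaf name, lineage),
        so ``argmax``'s first-maximum rule implements the lexicographic
        tie-break.
        """
        scores = self._scores_for_cols(cols)
        scores[self.M == 0] = -np.inf
        if not np.isfinite(scores).any():
            raise UnclassifiableError("no candidatable taxa (all emptied)")
        return int(np.argmax(scores))

    def classify_codes(self, codes: np.ndarray) -> int:
        if codes.size == 0:
            raise UnclassifiableError("unclassifiable: no valid words")
        return self.classify_cols(self._cols(codes))

    def classify_leaf(self, sequence: str) -> tuple[str, Lineage]:
        """Maximum-posterior leaf assignment of a query sequence."""
        codes = word_codes(sequence, self.config.word_size, self.config.use_distinct_words)
        t = self.classify_codes(codes)
        lineage = self.lineages[self.taxa[t]]
        return lineage.leaf_name, lineage

    # -- incremental updates (leave-one-out) -------------------------------

    def remove_sequence_counts(self, distinct_codes: np.ndarray, taxon_idx: int) -> None:
        """Subtract one sequence's presence counts (exact inverse of add)."""
        cols = self._cols(distinct_codes)
        sentinel = self.m.shape[1] - 1
        if (cols == sentinel).any():
            raise KeyError("sequence contains words absent from the model vocabulary")
        self.m[taxon_idx, cols] -= 1
        self.M[taxon_idx] -= 1
        self.N -= 1
        if self.m[taxon_idx].min() < 0 or self.M[taxon_idx] < 0:
            raise ValueError("count underflow: sequence was not part of this taxon")

    def add_sequence_counts(self, distinct_codes: np.ndarray, taxon_idx: int) -> None:
        """Add one sequence's presence counts, growing the vocabulary if needed."""
        new = [int(c) for c in distinct_codes if int(c) not in self.word_col]
        if new:
            sentinel = self.m.shape[1] - 1
            grown = np.zeros((self.n_taxa, self.m.shape[1] + len(new)), dtype=np.int64)
            grown[:, :sentinel] = self.m[:, :sentinel]
            self.m = grown
            for code in new:
                self.word_col[code] = sentinel
                sentinel += 1
        cols = self._cols(distinct_codes)
        self.m[taxon_idx, cols] += 1
        self.M[taxon_idx] += 1
        self.N += 1

    def add_sequence(self, sequence: str, lineage: Lineage) -> None:
        """Incrementally train on one more sequence (new taxa allowed)."""
        key = str(lineage)
        if key not in self._taxon_index:
            self.taxa.append(key)
            self.lineages[key] = lineage
            order = sorted(
                range(len(self.taxa)),
                key=lambda i: (self.lineages[self.taxa[i]].leaf_name, self.taxa[i]),
            )
            taxa = [self.taxa[i] for i in order]
            self.M = np.append(self.M, 0)[order]
            self.m = np.vstack([self.m, np.zeros((1, self.m.shape[1]), dtype=np.int64)])[order]
            self.taxa = taxa
            self._taxon_index = {t: i for i, t in enumerate(taxa)}
        codes = word_codes(sequence, self.config.word_size, distinct=True)
        self.add_sequence_counts(codes, self._taxon_index[key])

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to a single self-describing JSON file."""
        k = self.config.word_size
        sentinel = self.m.shape[1] - 1
        words = {}
        for code, col in sorted(self.word_col.items()):
            counts = self.m[:, col]
            nz = np.nonzero(counts)[0]
            words[decode_word(code, k)] = {int(i): int(counts[i]) for i in nz}
        payload = {
            "format": "co1bayes-model",
            "version": MODEL_FORMAT_VERSION,
            "config": {
                "word_size": k,
                "training_rank": self.config.training_rank,
                "use_distinct_words": self.config.use_distinct_words,
            },
            "ladder": list(self.ladder),
            "taxa": self.taxa,
            "lineages": {t: [list(node) for node in self.lineages[t].nodes] for t in self.taxa},
            "M": [int(x) for x in self.M],
            "N": self.N,
            "words": words,
            "_sentinel_note": f"vocabulary size {sentinel}",
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "co1bayes-model":
            raise ValueError(f"{path}: not a co1bayes model file")
        if payload["version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported model version {payload['version']}")
        config = ModelConfig(**payload["config"])
        taxa = payload["taxa"]
        lineages = {
            t: Lineage(tuple((n, r) for n, r in payload["lineages"][t])) for t in taxa
        }
        M = np.array(payload["M"], dtype=np.int64)
        words = payload["words"]
        word_col = {encode_word(w): i for i, w in enumerate(sorted(words))}
        m = np.zeros((len(taxa), len(words) + 1), dtype=np.int64)
        for w, counts in words.items():
            col = word_col[encode_word(w)]
            for t_idx, c in counts.items():
                m[int(t_idx), col] = c
        model = cls(
            config, tuple(payload["ladder"]), taxa, lineages, M, m, word_col, payload["N"]
        )
        model.check_invariants()
        return model


def train(refset: ReferenceSet, config: Optional[ModelConfig] = None) -> TrainedModel:
    """Train a naive Bayes word model on a reference set.

    Word presence is counted at most once per sequence, whatever the
    number of occurrences.
    """
    if config is None:
        config = ModelConfig(training_rank=refset.training_rank)
    if not refset.sequences:
        raise ValueError("cannot train on an empty reference set")
    if refset.training_rank != config.training_rank:
        raise ValueError(
            f"reference set trained to {refset.training_rank!r} but config expects "
            f"{config.training_rank!r}"
        )

    lineages: dict[str, Lineage] = {}
    members: dict[str, list[np.ndarray]] = {}
    vocab: set[int] = set()
    for seq in refset.sequences:
        key = str(seq.lineage)
        lineages.setdefault(key, seq.lineage)
        codes = word_codes(seq.sequence, config.word_size, distinct=True)
        members.setdefault(key, []).append(codes)
        vocab.update(int(c) for c in codes)

    taxa = sorted(members, key=lambda t: (lineages[t].leaf_name, t))
    word_col = {code: i for i, code in enumerate(sorted(vocab))}
    m = np.zeros((len(taxa), len(vocab) + 1), dtype=np.int64)  # +1 sentinel column
    M = np.zeros(len(taxa), dtype=np.int64)
    for t_idx, taxon in enumerate(taxa):
        for codes in members[taxon]:
            cols = [word_col[int(c)] for c in codes]
            m[t_idx, cols] += 1
            M[t_idx] += 1

    model = TrainedModel(
        config, tuple(refset.ladder), taxa, lineages, M, m, word_col, int(M.sum())
    )
    model.check_invariants()
    logger.info(
        "trained model: %d sequences, %d leaf taxa, %d distinct %d-mers",
        model.N, model.n_taxa, len(vocab), config.word_size,
    )
    return model
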