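"""Leave-one-out benchmarking, outcome accounting, ROC and calibration.

Leave-one-out (LOO) testing removes each reference sequence from the
trained model in turn (its counts are decremented exactly, and leaf taxa
emptied by the removal drop out of candidacy), classifies a fragment of
it with bootstrap support, restores the counts, and moves on.  Fragments
are either the full sequence or a random contiguous substring of fixed
length (400, 200, 100 or 50 bp), drawn once per (sequence, length).

From the resulting records, assignments at a chosen rank and bootstrap
cutoff are sorted into the four outcome classes:

* TP — correct assignment with support at or above the cutoff,
* FN — correct assignment below the cutoff,
* FP — incorrect assignment at or above the cutoff,
* TN — incorrect assignment below the cutoff,

with TPR = TP/(TP+FN), FPR = FP/(FP+TN) and accuracy = (TP+TN)/total.
Sweeping the cutoff from 0 to 100 traces a ROC curve; calibration finds,
per (rank, fragment length), the smallest cutoff at which the passing
assignments are at least 99% correct, together with the resulting
reduction in the proportion of sequences still classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, bootstrap_classify, query_rng
from .classifier import ModelConfig, TrainedModel, train, word_codes
from .taxonomy import DEFAULT_LADDER, Lineage, ReferenceSet

logger = logging.getLogger(__name__)

#: marker for the untrimmed full-length fragment
FULL = "full"
#: the standard benchmark fragment series
DEFAULT_LENGTHS: tuple[Union[str, int], ...] = (FULL, 400, 200, 100, 50)
#: bootstrap-cutoff grid in percent
DEFAULT_GRID: tuple[int, ...] = tuple(range(0, 101, 10))

FragmentLength = Union[str, int]


@dataclass(frozen=True)
class FragmentSpec:
    """Which fragment lengths to test and the seed for fragment placement."""

    lengths: tuple[FragmentLength, ...] = DEFAULT_LENGTHS
    seed: int = 0

    def __post_init__(self) -> None:
        for L in self.lengths:
            if L != FULL and (not isinstance(L, int) or L < 1):
                raise ValueError(f"invalid fragment length {L!r}")


def sample_fragment(sequence: str, L: int, rng: np.random.Generator) -> Optional[str]:
    """A length-``L`` contiguous substring at a uniform random start.

    Returns None when the sequence is shorter than ``L`` (the caller
    logs and skips the record).
    """
    n = len(sequence)
    if n < L:
        return None
    start = int(rng.integers(0, n - L + 1))
    return sequence[start : start + L]


@dataclass
class LOORecord:
    """One leave-one-out trial: truth, prediction, support, context flags."""

    seq_id: str
    fragment_length: FragmentLength
    truth: Lineage
    predicted: Optional[Lineage]
    support: dict[str, int]
    singleton: bool
    unclassifiable: bool = False

    def correct_at(self, rank: str) -> Optional[bool]:
        """Whether prediction and truth agree on the root-to-rank path.

        None when the record is unclassifiable or the truth lineage does
        not reach ``rank``.
        """
        target = self.truth.prefix_at(rank)
        if target is None:
            return None
        if self.unclassifiable or self.predicted is None:
            return None
        return self.predicted.prefix_at(rank) == target


def loo_classify(
    model: TrainedModel,
    refset: ReferenceSet,
    seq_id: str,
    L: FragmentLength,
    boot_config: BootstrapConfig,
    fragment_seed: int = 0,
) -> LOORecord:
    """Leave one sequence out, classify one fragment of it, restore.

    The model's counts are decremented for the held-out sequence (taxa
    emptied by the removal lose candidacy), the fragment is classified
    with bootstrap support, and the counts are restored exactly.
    """
    by_id = {s.seq_id: s for s in refset.sequences}
    if seq_id not in by_id:
        raise KeyError(f"unknown seq_id {seq_id!r}")
    seq = by_id[seq_id]
    singletons = refset.singleton_taxa()
    taxon_idx = model.taxon_index(str(seq.lineage))
    codes = word_codes(seq.sequence, model.config.word_size, distinct=True)
    model.remove_sequence_counts(codes, taxon_idx)
    try:
        (record,) = _classify_held_out(
            model, seq, [L], boot_config, fragment_seed, str(seq.lineage) in singletons
        )
    finally:
        model.add_sequence_counts(codes, taxon_idx)
    return record


def _classify_held_out(
    model: TrainedModel,
    seq,
    lengths: Sequence[FragmentLength],
    boot_config: BootstrapConfig,
    fragment_seed: int,
    singleton: bool,
) -> list[LOORecord]:
    records = []
    for L in lengths:
        if L == FULL:
            fragment = seq.sequence
        else:
            rng = query_rng(fragment_seed, seq.seq_id, int(L))
            fragment = sample_fragment(seq.sequence, int(L), rng)
        if fragment is None:
            logger.debug("%s: shorter than %s bp, fragment skipped", seq.seq_id, L)
            records.append(
                LOORecord(seq.seq_id, L, seq.lineage, None, {}, singleton, unclassifiable=True)
            )
            continue
        result = bootstrap_classify(model, fragment, boot_config, seq_id=seq.seq_id)
        records.append(
            LOORecord(
                seq.seq_id, L, seq.lineage, result.lineage, result.support,
                singleton, result.unclassifiable,
            )
        )
    return records


def run_loo(
    refset: ReferenceSet,
    model_config: Optional[ModelConfig] = None,
    boot_config: Optional[BootstrapConfig] = None,
    fragment_spec: Optional[FragmentSpec] = None,
    include_singletons: bool = True,
    model: Optional[TrainedModel] = None,
) -> list[LOORecord]:
    """Leave-one-out test every sequence at every fragment length.

    Returns one record per (sequence, length).  Singleton records (leaf
    taxon represented once, so the correct leaf answer is impossible once
    held out) are flagged, and dropped entirely when
    ``include_singletons`` is false.
    """
    boot_config = boot_config or BootstrapConfig()
    fragment_spec = fragment_spec or FragmentSpec()
    if model is None:
        model = train(refset, model_config)
    singletons = refset.singleton_taxa()

    records: list[LOORecord] = []
    for i, seq in enumerate(refset.sequences):
        singleton = str(seq.lineage) in singletons
        if singleton and not include_singletons:
            continue
        taxon_idx = model.taxon_index(str(seq.lineage))
        codes = word_codes(seq.sequence, model.config.word_size, distinct=True)
        model.remove_sequence_counts(codes, taxon_idx)
        try:
            records.extend(
                _classify_held_out(
                    model, seq, fragment_spec.lengths, boot_config,
                    fragment_spec.seed, singleton,
                )
            )
        finally:
            model.add_sequence_counts(codes, taxon_idx)
        if (i + 1) % 50 == 0:
            logger.info("leave-one-out: %d/%d sequences done", i + 1, len(refset))
    return records


# -- outcome accounting ----------------------------------------------------


@dataclass(frozen=True)
class OutcomeCounts:
    """TP/FN/TN/FP tallies at one (rank, cutoff); unclassifiable kept apart."""

    rank: str
    cutoff: int
    tp: int
    fn: int
    tn: int
    fp: int
    unclassified: int = 0

    @property
    def classified(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class OutcomeRates:
    """TPR, FPR and accuracy; a zero denominator yields rate 0 plus a flag."""

    tpr: float
    fpr: float
    accuracy: float
    undefined: frozenset = frozenset()


def classify_outcomes(
    records: Sequence[LOORecord],
    rank: str,
    cutoff: int,
    strict: bool = False,
) -> OutcomeCounts:
    """Sort records into TP/FN/TN/FP at ``rank`` for a support ``cutoff``.

    An assignment passes the cutoff when its support is >= cutoff
    (``strict`` switches to >).  Unclassifiable records are counted
    separately and excluded from the four cells.
    """
    tp = fn = tn = fp = unclassified = 0
    for rec in records:
        correct = rec.correct_at(rank)
        if correct is None:
            unclassified += 1
            continue
        support = rec.support.get(rank, 0)
        passes = support > cutoff if strict else support >= cutoff
        if correct:
            tp, fn = (tp + 1, fn) if passes else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if passes else (fp, tn + 1)
    return OutcomeCounts(rank, cutoff, tp, fn, tn, fp, unclassified)


def outcome_rates(counts: OutcomeCounts) -> OutcomeRates:
    """TPR = TP/(TP+FN), FPR = FP/(FP+TN), accuracy = (TP+TN)/all."""
    undefined = set()
    tpr = fpr = accuracy = 0.0
    if counts.tp + counts.fn:
        tpr = counts.tp / (counts.tp + counts.fn)
    else:
        undefined.add("tpr")
    if counts.fp + counts.tn:
        fpr = counts.fp / (counts.fp + counts.tn)
    else:
        undefined.add("fpr")
    if counts.classified:
        accuracy = (counts.tp + counts.tn) / counts.classified
    else:
        undefined.add("accuracy")
    return OutcomeRates(tpr, fpr, accuracy, frozenset(undefined))


@dataclass
class ROCCurve:
    """(cutoff, FPR, TPR) points and the trapezoidal AUC for one rank."""

    rank: str
    points: list[tuple[int, float, float]]
    auc: float
    degenerate: bool = False


def roc_curve(
    records: Sequence[LOORecord],
    rank: str,
    grid: Sequence[int] = DEFAULT_GRID,
    strict: bool = False,
) -> ROCCurve:
    """ROC traced by tuning the bootstrap cutoff across ``grid``.

    The AUC is the trapezoid rule over FPR-sorted points anchored at
    (0,0) and (1,1).  With no correct or no incorrect records the curve
    is flagged degenerate (one of the rates is identically 0).
    """
    if not records:
        raise ValueError("no records to build a ROC curve from")
    points = []
    for cutoff in grid:
        counts = classify_outcomes(records, rank, cutoff, strict=strict)
        rates = outcome_rates(counts)
        points.append((int(cutoff), rates.fpr, rates.tpr))
    base = classify_outcomes(records, rank, 0, strict=strict)
    degenerate = (base.tp + base.fn == 0) or (base.fp + base.tn == 0)

    xy = sorted([(fpr, tpr) for _, fpr, tpr in points] + [(0.0, 0.0), (1.0, 1.0)])
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    auc = float(np.trapezoid(ys, xs))
    return ROCCurve(rank, points, auc, degenerate)


def plot_roc(curves: Sequence[ROCCurve], path, title: str = "ROC") -> None:
    """Optional matplotlib rendering of one or more ROC curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for curve in curves:
        xy = sorted([(f, t) for _, f, t in curve.points] + [(0, 0), (1, 1)])
        ax.plot([p[0] for p in xy], [p[1] for p in xy], marker="o",
                label=f"{curve.rank} (AUC {curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=1)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -- cutoff calibration ----------------------------------------------------


@dataclass
class CutoffMatrix:
    """Per (rank, length): minimum calibrated cutoff and classified reduction.

    ``cutoffs`` holds the smallest grid cutoff at which at least
    ``target`` of the passing assignments are correct (NaN = not
    attainable); ``reduction`` the corresponding fraction of classified
    sequences lost to the cutoff.
    """

    target: float
    cutoffs: pd.DataFrame   # rank x length, float with NaN for N/A
    reduction: pd.DataFrame


def calibrate_cell(
    records: Sequence[LOORecord],
    rank: str,
    target: float = 0.99,
    grid: Sequence[int] = DEFAULT_GRID,
    strict: bool = False,
) -> tuple[Optional[int], Optional[float]]:
    """Smallest grid cutoff with TP/(TP+FP) >= target, and its reduction.

    Returns (None, None) when no grid cutoff attains the target or there
    are no classifiable records.
    """
    total = classify_outcomes(records, rank, 0, strict=strict).classified
    if total == 0:
        return None, None
    for cutoff in grid:
        counts = classify_outcomes(records, rank, cutoff, strict=strict)
        passing = counts.tp + counts.fp
        if passing and counts.tp / passing >= target:
            return int(cutoff), 1.0 - passing / total
    return None, None


def calibrate_cutoffs(
    records: Sequence[LOORecord],
    ranks: Sequence[str],
    lengths: Sequence[FragmentLength] = DEFAULT_LENGTHS,
    target: float = 0.99,
    grid: Sequence[int] = DEFAULT_GRID,
    strict: bool = False,
) -> CutoffMatrix:
    """Calibrate minimum bootstrap cutoffs per (rank, fragment length).

    Callers wanting the benchmark convention of excluding singleton
    leaf taxa must filter the records first.
    """
    cut = pd.DataFrame(index=list(ranks), columns=[str(L) for L in lengths], dtype=float)
    red = pd.DataFrame(index=list(ranks), columns=[str(L) for L in lengths], dtype=float)
    by_length: dict[str, list[LOORecord]] = {}
    for rec in records:
        by_length.setdefault(str(rec.fragment_length), []).append(rec)
    for rank in ranks:
        for L in lengths:
            subset = by_length.get(str(L), [])
            cutoff, reduction = calibrate_cell(subset, rank, target, grid, strict)
            cut.loc[rank, str(L)] = np.nan if cutoff is None else float(cutoff)
            red.loc[rank, str(L)] = np.nan if reduction is None else reduction
    return CutoffMatrix(target, cut, red)


def accuracy_by_rank(
    records: Sequence[LOORecord], ranks: Sequence[str]
) -> dict[str, float]:
    """Proportion of correct assignments per rank (no cutoff applied)."""
    out = {}
    for rank in ranks:
        counts = classify_outcomes(records, rank, 0)
        out[rank] = outcome_rates(counts).accuracy
    return out


# -- TSV round trip --------------------------------------------------------


def records_to_frame(records: Sequence[LOORecord], ladder: Sequence[str]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "seq_id": rec.seq_id,
            "fragment_length": str(rec.fragment_length),
            "singleton": rec.singleton,
            "unclassifiable": rec.unclassifiable,
            "truth": str(rec.truth),
            "predicted": "" if rec.predicted is None else str(rec.predicted),
        }
        for rank in ladder:
            row[f"support_{rank}"] = rec.support.get(rank, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() == "true"
    return bool(value)


def frame_to_records(frame: pd.DataFrame, ladder: Sequence[str]) -> list[LOORecord]:
    records = []
    support_cols = [rank for rank in ladder if f"support_{rank}" in frame.columns]
    for _, row in frame.iterrows():
        truth = Lineage.from_names(str(row["truth"]).split(";"), ladder)
        predicted = None
        if isinstance(row["predicted"], str) and row["predicted"]:
            predicted = Lineage.from_names(row["predicted"].split(";"), ladder)
        length = row["fragment_length"]
        length = length if length == FULL else int(length)
        records.append(
            LOORecord(
                str(row["seq_id"]), length, truth, predicted,
                {rank: int(row[f"support_{rank}"]) for rank in support_cols},
                _as_bool(row["singleton"]), _as_bool(row["unclassifiable"]),
            )
        )
    return records


def write_loo_tsv(records: Sequence[LOORecord], ladder: Sequence[str], path) -> None:
    records_to_frame(records, ladder).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_loo_tsv(path, ladder: Sequence[str] = DEFAULT_LADDER) -> list[LOORecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"predicted": str})
    return frame_to_records(frame, ladder)
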