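"""Fragment sampling, leave-one-out mechanics, outcome rates, ROC, calibration."""

import math

import numpy as np
import pytest

from co1bayes import (
    DEFAULT_GRID,
    DEFAULT_LADDER,
    FULL,
    BootstrapConfig,
    FragmentSpec,
    LOORecord,
    ModelConfig,
    OutcomeCounts,
    SyntheticConfig,
    accuracy_by_rank,
    calibrate_cutoffs,
    classify_outcomes,
    extract_words,
    generate_reference_set,
    loo_classify,
    outcome_rates,
    read_loo_tsv,
    roc_curve,
    run_loo,
    sample_fragment,
    train,
    write_loo_tsv,
)
from co1bayes.evaluation import calibrate_cell, records_to_frame, frame_to_records
from conftest import make_refset, toy_lineage


class TestSampleFragment:
    def test_full_length_request_is_identity(self, rng):
        seq = "ACGT" * 40
        assert sample_fragment(seq, len(seq), rng) == seq

    def test_too_short_sequence_is_skipped(self, rng):
        assert sample_fragment("A" * 120, 200, rng) is None

    def test_start_positions_cover_the_range_uniformly(self, rng):
        L = 200
        # recover each draw's start by lookup in a sequence whose 200-mers are unique
        marked = "".join(np.random.default_rng(1).choice(list("ACGT"), size=658))
        starts = []
        for _ in range(10_000):
            frag = sample_fragment(marked, L, rng)
            assert len(frag) == L
            starts.append(marked.index(frag))
        starts = np.array(starts)
        assert starts.min() == 0 and starts.max() == 458
        # coarse uniformity: each quarter of the range gets ~25% of draws
        hist, _ = np.histogram(starts, bins=4, range=(0, 459))
        assert np.abs(hist / 10_000 - 0.25).max() < 0.03


def _fake_record(correct, support, seq_id="r", length=FULL, singleton=False,
                 family_correct=True):
    truth = toy_lineage("Culicidae", "Aedes")
    if correct:
        predicted = truth
    elif family_correct:
        predicted = toy_lineage("Culicidae", "Culex")
    else:
        predicted = toy_lineage("Tipulidae", "Tipula")
    support_map = {rank: 100 for rank in DEFAULT_LADDER}
    support_map["genus"] = support
    support_map["family"] = max(support, support_map["genus"])
    return LOORecord(seq_id, length, truth, predicted, support_map, singleton)


FOUR_RECORDS = [
    _fake_record(True, 90, "a"),
    _fake_record(True, 40, "b"),
    _fake_record(False, 70, "c"),
    _fake_record(False, 10, "d"),
]


class TestOutcomeAccounting:
    def test_four_hand_records_at_cutoff_50(self):
        counts = classify_outcomes(FOUR_RECORDS, "genus", 50)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)

    def test_cutoff_zero_has_no_below_cutoff_cells(self):
        counts = classify_outcomes(FOUR_RECORDS, "genus", 0)
        assert counts.fn == 0 and counts.tn == 0

    def test_cutoff_above_grid_passes_nothing(self):
        counts = classify_outcomes(FOUR_RECORDS, "genus", 101)
        assert counts.tp == 0 and counts.fp == 0

    def test_strict_mode_uses_greater_than(self):
        counts = classify_outcomes(FOUR_RECORDS, "genus", 70, strict=True)
        assert counts.fp == 0  # support 70 no longer passes a 70 cutoff
        assert classify_outcomes(FOUR_RECORDS, "genus", 70).fp == 1

    def test_unclassifiable_records_counted_apart(self):
        records = FOUR_RECORDS + [
            LOORecord("u", FULL, toy_lineage("Culicidae", "Aedes"), None, {}, False, True)
        ]
        counts = classify_outcomes(records, "genus", 50)
        assert counts.unclassified == 1 and counts.classified == 4


class TestOutcomeRates:
    def test_published_rdp_confusion_counts(self):
        counts = OutcomeCounts("genus", 60, tp=16_887_619, fn=727_269,
                               tn=230_262, fp=117_457)
        rates = outcome_rates(counts)
        assert round(100 * rates.fpr) == 34
        assert round(100 * rates.tpr) == 96
        assert round(100 * rates.accuracy) == 95
        assert counts.classified == 17_962_607

    def test_published_top_blast_confusion_counts(self):
        counts = OutcomeCounts("genus", 0, tp=17_559_411, fn=3_350,
                               tn=384, fp=397_820)
        assert round(100 * outcome_rates(counts).accuracy) == 98

    def test_balanced_counts_give_half_everywhere(self):
        rates = outcome_rates(OutcomeCounts("genus", 50, 1, 1, 1, 1))
        assert rates.tpr == rates.fpr == rates.accuracy == 0.5

    def test_zero_denominators_flagged(self):
        rates = outcome_rates(OutcomeCounts("genus", 50, 0, 0, 0, 0))
        assert rates.undefined == {"tpr", "fpr", "accuracy"}
        assert rates.tpr == rates.fpr == rates.accuracy == 0.0


class TestROC:
    def test_four_record_toy_curve_points(self):
        curve = roc_curve(FOUR_RECORDS, "genus")
        points = {c: (f, t) for c, f, t in curve.points}
        assert points[50] == (0.5, 0.5)
        assert points[80] == (0.0, 0.5)
        assert not curve.degenerate

    def test_rates_non_increasing_in_cutoff(self):
        curve = roc_curve(FOUR_RECORDS, "genus")
        fprs = [f for _, f, _ in curve.points]
        tprs = [t for _, _, t in curve.points]
        assert fprs == sorted(fprs, reverse=True)
        assert tprs == sorted(tprs, reverse=True)

    def test_all_correct_records_are_degenerate(self):
        records = [_fake_record(True, s, str(s)) for s in (10, 50, 90)]
        curve = roc_curve(records, "genus")
        assert curve.degenerate
        assert all(f == 0.0 for _, f, _ in curve.points)

    def test_null_records_give_chance_auc(self):
        rng = np.random.default_rng(404)
        records = [
            _fake_record(bool(rng.integers(0, 2)), int(rng.integers(0, 101)), str(i))
            for i in range(2000)
        ]
        curve = roc_curve(records, "genus")
        assert abs(curve.auc - 0.5) < 0.05

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            roc_curve([], "genus")


class TestCalibration:
    def test_cutoff_raised_until_target_met(self):
        records = [_fake_record(True, 100, f"c{i}") for i in range(97)] + [
            _fake_record(False, 50, f"i{i}") for i in range(3)
        ]
        cutoff, reduction = calibrate_cell(records, "genus")
        assert cutoff == 60
        assert reduction == pytest.approx(0.03)

    def test_cutoff_zero_when_target_already_met(self):
        records = [_fake_record(True, 100, f"c{i}") for i in range(100)] + [
            _fake_record(False, 100, "i")
        ]
        cutoff, reduction = calibrate_cell(records, "genus")
        assert cutoff == 0 and reduction == 0.0

    def test_unattainable_target_is_not_applicable(self):
        records = [_fake_record(True, 100, f"c{i}") for i in range(10)] + [
            _fake_record(False, 100, f"i{i}") for i in range(10)
        ]
        assert calibrate_cell(records, "genus") == (None, None)

    def test_matrix_guarantee_and_na_cells(self):
        mixed = (
            [_fake_record(True, 100, f"c{i}") for i in range(97)]
            + [_fake_record(False, 50, f"i{i}") for i in range(3)]
            + [_fake_record(True, 100, f"n{i}", length=50) for i in range(10)]
            + [_fake_record(False, 100, f"m{i}", length=50) for i in range(10)]
        )
        matrix = calibrate_cutoffs(mixed, ["genus"], [FULL, 50])
        assert matrix.cutoffs.loc["genus", "full"] == 60
        assert math.isnan(matrix.cutoffs.loc["genus", "50"])
        # wherever a cutoff is reported, the passing fraction meets the target
        by_len = {"full": [r for r in mixed if r.fragment_length == FULL]}
        counts = classify_outcomes(by_len["full"], "genus", 60)
        assert counts.tp / (counts.tp + counts.fp) >= matrix.target


@pytest.fixture(scope="module")
def small_refset():
    config = SyntheticConfig(
        families=2, genera_per_family=3, species_per_genus=2,
        seqs_per_species=1, sequence_length=300, seed=5,
    )
    refset, _ = generate_reference_set(config)  # 12 sequences, 6 genera
    return refset


class TestLeaveOneOut:
    def test_record_cardinality(self, small_refset):
        records = run_loo(
            small_refset,
            boot_config=BootstrapConfig(trials=10, seed=1),
            fragment_spec=FragmentSpec(lengths=(FULL, 200), seed=1),
        )
        assert len(records) == 2 * len(small_refset)

    def test_exclude_singletons_drops_flagged_records(self):
        config = SyntheticConfig(
            families=2, genera_per_family=2, species_per_genus=1,
            seqs_per_species=3, sequence_length=200, singleton_fraction=0.5, seed=9,
        )
        refset, truth = generate_reference_set(config)
        spec = FragmentSpec(lengths=(FULL,), seed=1)
        boot = BootstrapConfig(trials=5, seed=1)
        all_records = run_loo(refset, boot_config=boot, fragment_spec=spec)
        kept = run_loo(refset, boot_config=boot, fragment_spec=spec,
                       include_singletons=False)
        flagged = {r.seq_id for r in all_records if r.singleton}
        assert flagged == set(truth[truth.singleton].seq_id)
        assert {r.seq_id for r in kept} == {r.seq_id for r in all_records} - flagged

    def test_decremental_model_matches_full_retrain(self):
        # 10-sequence toy: scores after removal equal scores of a model
        # retrained from scratch without the sequence
        rng = np.random.default_rng(77)
        entries = [
            (f"s{i}", "".join(rng.choice(list("ACGT"), size=60)),
             "Fam", f"Gen{chr(65 + i % 3)}")
            for i in range(10)
        ]
        config = ModelConfig(word_size=4)
        model = train(make_refset(entries), config)
        held = entries[0]
        from co1bayes import word_codes

        codes = word_codes(held[1], 4)
        idx = model.taxon_index(str(toy_lineage(held[2], held[3])))
        model.remove_sequence_counts(codes, idx)
        try:
            retrained = train(make_refset(entries[1:]), config)
            query_words = extract_words("".join(rng.choice(list("ACGT"), size=50)), 4)
            for taxon in retrained.taxa:
                assert model.score(query_words, taxon) == pytest.approx(
                    retrained.score(query_words, taxon), rel=1e-9, abs=1e-9
                )
        finally:
            model.add_sequence_counts(codes, idx)
        # restoration is exact
        full = train(make_refset(entries), config)
        for taxon in full.taxa:
            q = extract_words(held[1], 4)
            assert model.score(q, taxon) == full.score(q, taxon)

    def test_held_out_congeneric_recovers_its_genus(self, small_refset):
        model = train(small_refset)
        record = loo_classify(
            model, small_refset, small_refset.sequences[0].seq_id, FULL,
            BootstrapConfig(trials=10, seed=2),
        )
        assert record.correct_at("genus") is True

    def test_held_out_singleton_cannot_be_correct_at_leaf(self):
        config = SyntheticConfig(
            families=2, genera_per_family=2, species_per_genus=1,
            seqs_per_species=2, sequence_length=250, singleton_fraction=0.5, seed=3,
        )
        refset, _ = generate_reference_set(config)
        records = run_loo(refset, boot_config=BootstrapConfig(trials=5, seed=3),
                          fragment_spec=FragmentSpec(lengths=(FULL,), seed=3))
        singles = [r for r in records if r.singleton]
        assert singles  # the fraction produced some
        assert all(r.correct_at("genus") is False for r in singles if not r.unclassifiable)

    def test_accuracy_monotone_over_ranks(self, small_refset):
        records = run_loo(small_refset, boot_config=BootstrapConfig(trials=5, seed=4),
                          fragment_spec=FragmentSpec(lengths=(FULL, 100), seed=4))
        acc = accuracy_by_rank(records, ["genus", "family", "order", "phylum"])
        assert acc["genus"] <= acc["family"] <= acc["order"] <= acc["phylum"]


class TestTsvRoundTrip:
    def test_records_survive_frame_round_trip(self, tmp_path):
        records = FOUR_RECORDS + [
            LOORecord("u", 50, toy_lineage("Culicidae", "Aedes"), None, {}, True, True)
        ]
        path = tmp_path / "loo.tsv"
        write_loo_tsv(records, DEFAULT_LADDER, path)
        back = read_loo_tsv(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert (a.seq_id, str(a.fragment_length), a.singleton, a.unclassifiable) == (
                b.seq_id, str(b.fragment_length), b.singleton, b.unclassifiable
            )
            assert str(a.truth) == str(b.truth)
            assert (str(a.predicted) if a.predicted else "") == (
                str(b.predicted) if b.predicted else ""
            )
            assert all(a.support.get(r, 0) == b.support.get(r, 0) for r in DEFAULT_LADDER)
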