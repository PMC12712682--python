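import json

import numpy as np
import pytest

import enzadapt as ez
from enzadapt.binding import (
    AttentionRecord,
    BindingAnnotation,
    Segment,
    SegmentSet,
    extract_cls_attention,
    false_positive_rate,
    load_annotations,
    overlap_score,
    rank_heads,
    select_budgeted_residues,
)


# --- residue-set oracle -----------------------------------------------------

def os_oracle(pred: SegmentSet, truth: SegmentSet) -> float:
    return len(pred.residues() & truth.residues()) / len(truth.residues())


def fpr_oracle_width1(pred_residues, truth: SegmentSet) -> float:
    t = truth.residues()
    return sum(1 for r in pred_residues if r not in t) / len(pred_residues)


def random_segment_set(rng, n_max=5, span=60) -> SegmentSet:
    residues = set()
    for _ in range(rng.integers(1, n_max + 1)):
        start = int(rng.integers(0, span - 5))
        residues |= set(range(start, start + int(rng.integers(1, 6))))
    return SegmentSet.from_residues(residues)


class TestSegments:
    def test_invalid_segment_rejected(self):
        with pytest.raises(ValueError):
            Segment(4, 4)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            SegmentSet((Segment(0, 5), Segment(3, 8)))

    def test_one_based_inclusive_conversion(self):
        seg = Segment.from_one_based_inclusive(1, 5)
        assert (seg.start, seg.end) == (0, 5)
        assert seg.length == 5

    def test_from_residues_merges_contiguous_runs(self):
        ss = SegmentSet.from_residues({1, 2, 3, 7, 9, 10})
        assert ss.segments == (Segment(1, 4), Segment(7, 8), Segment(9, 11))
        assert ss.total_length == 6


class TestOverlapScore:
    def test_perfect_prediction(self):
        truth = SegmentSet((Segment(2, 6), Segment(10, 12)))
        assert overlap_score(truth, truth) == 1.0

    def test_partial_overlap_fraction(self):
        pred = SegmentSet((Segment(2, 5),))
        truth = SegmentSet((Segment(4, 8),))
        assert overlap_score(pred, truth) == pytest.approx(0.25)

    def test_disjoint_gives_zero(self):
        assert overlap_score(
            SegmentSet((Segment(0, 3),)), SegmentSet((Segment(10, 14),))
        ) == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            overlap_score(SegmentSet((Segment(0, 2),)), SegmentSet(()))

    def test_monotone_in_growing_predictions(self):
        rng = np.random.default_rng(5)
        truth = random_segment_set(rng)
        residues: set[int] = set()
        last = 0.0
        for r in rng.permutation(60):
            residues.add(int(r))
            score = overlap_score(SegmentSet.from_residues(residues), truth)
            assert score >= last - 1e-15
            last = score


class TestFalsePositiveRate:
    def test_perfect_prediction_zero(self):
        truth = SegmentSet((Segment(2, 6),))
        assert false_positive_rate(truth, truth) == 0.0

    def test_segment_level_indicator(self):
        pred = SegmentSet((Segment(0, 2), Segment(4, 6)))
        truth = SegmentSet((Segment(4, 8),))
        assert false_positive_rate(pred, truth) == pytest.approx(0.5)

    def test_entirely_outside_truth_is_one(self):
        pred = SegmentSet((Segment(0, 4),))
        truth = SegmentSet((Segment(20, 25),))
        assert false_positive_rate(pred, truth) == 1.0

    def test_empty_pred_rejected(self):
        with pytest.raises(ValueError):
            false_positive_rate(SegmentSet(()), SegmentSet((Segment(0, 2),)))

    def test_partially_overlapping_segment_counts_fully_true(self):
        # a segment with any truth overlap contributes nothing to the FPR,
        # even if most of its residues are outside the truth
        pred = SegmentSet((Segment(0, 10),))
        truth = SegmentSet((Segment(9, 12),))
        assert false_positive_rate(pred, truth) == 0.0


class TestOracleAgreement:
    def test_os_matches_residue_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            pred, truth = random_segment_set(rng), random_segment_set(rng)
            assert abs(overlap_score(pred, truth) - os_oracle(pred, truth)) < 1e-12

    def test_width1_fpr_matches_residue_oracle(self):
        rng = np.random.default_rng(321)
        for _ in range(1000):
            truth = random_segment_set(rng)
            residues = [int(r) for r in rng.choice(60, size=8, replace=False)]
            width1 = [Segment(r, r + 1) for r in residues]
            fp = sum(
                s.length for s in width1
                if all(s.overlap(t) == 0 for t in truth.segments)
            )
            assert fp / len(width1) == pytest.approx(
                fpr_oracle_width1(residues, truth), abs=1e-12
            )


class TestBudgetedSelection:
    def test_budget_equals_length_covers_everything(self):
        rec = AttentionRecord("s", 0, 0, np.linspace(0, 1, 10))
        ss = select_budgeted_residues(rec, budget=10)
        assert ss.segments == (Segment(0, 10),)

    def test_ties_break_toward_smaller_index(self):
        rec = AttentionRecord("s", 0, 0, [0.1, 0.4, 0.4, 0.05])
        ss = select_budgeted_residues(rec, budget=2)
        assert ss.segments == (Segment(1, 3),)

    def test_budget_one_is_argmax(self):
        rec = AttentionRecord("s", 0, 0, [0.1, 0.05, 0.9, 0.2])
        ss = select_budgeted_residues(rec, budget=1)
        assert ss.segments == (Segment(2, 3),)

    def test_total_length_equals_budget(self):
        rng = np.random.default_rng(0)
        rec = AttentionRecord("s", 0, 0, rng.random(50))
        for budget in (1, 7, 23, 50):
            assert select_budgeted_residues(rec, budget).total_length == budget

    def test_out_of_range_budget_rejected(self):
        rec = AttentionRecord("s", 0, 0, [0.1, 0.2])
        with pytest.raises(ValueError):
            select_budgeted_residues(rec, 0)
        with pytest.raises(ValueError):
            select_budgeted_residues(rec, 3)


class TestAttentionExtraction:
    def test_identical_sequences_identical_records(self, tiny_model, small_corpus):
        enc = tiny_model.protein_encoder
        seq = small_corpus[0].sequence
        a = extract_cls_attention(enc, seq)
        b = extract_cls_attention(enc, seq)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.weights, rb.weights)

    def test_one_record_per_final_layer_head(self, tiny_model, small_corpus):
        enc = tiny_model.protein_encoder
        records = extract_cls_attention(enc, small_corpus[0].sequence)
        assert len(records) == 2  # tiny config heads
        assert all(r.layer == len(enc.layers) - 1 for r in records)

    def test_residue_weights_sum_at_most_one(self, tiny_model, small_corpus):
        enc = tiny_model.protein_encoder
        for rec in extract_cls_attention(enc, small_corpus[0].sequence):
            assert len(rec.weights) == len(small_corpus[0].sequence)
            assert rec.weights.sum() <= 1.0 + 1e-12
            assert (rec.weights >= 0).all()


class TestRankHeads:
    def _annotations(self, sequence):
        truth = SegmentSet((Segment(3, 8),))
        return [BindingAnnotation("s1", sequence, truth, budget=5)]

    def test_single_pair_single_head_table(self, small_corpus):
        class OneHeadEncoder(ez.TinyProteinEncoder):
            pass

        enc = ez.TinyProteinEncoder(hidden=16, layers=1, heads=1, ffn=32,
                                    max_positions=128, seed=0)
        anns = self._annotations(small_corpus[0].sequence)
        table = rank_heads(enc, anns)
        assert len(table) == 1
        rec = extract_cls_attention(enc, anns[0].sequence)[0]
        pred = select_budgeted_residues(rec, 5)
        assert table.iloc[0].mean_overlap_score == pytest.approx(
            overlap_score(pred, anns[0].truth)
        )
        assert table.iloc[0].mean_false_positive_rate == pytest.approx(
            false_positive_rate(pred, anns[0].truth)
        )

    def test_oracle_head_reaches_budget_limited_maximum(self):
        """A head whose weights equal the truth indicator recovers the truth."""

        class OracleEncoder:
            layers = [None]

            def tokenize(self, seqs):
                raise NotImplementedError

        truth = SegmentSet((Segment(3, 8), Segment(12, 15)))
        weights = np.zeros(30)
        for r in truth.residues():
            weights[r] = 1.0
        rec = AttentionRecord("s", 0, 0, weights)
        pred = select_budgeted_residues(rec, budget=truth.total_length)
        assert overlap_score(pred, truth) == 1.0
        assert false_positive_rate(pred, truth) == 0.0

    def test_averaging_is_unweighted_over_pairs(self, tiny_model, small_corpus):
        enc = tiny_model.protein_encoder
        anns = [
            BindingAnnotation(f"s{i}", p.sequence,
                              SegmentSet((Segment(2, 7),)), budget=4)
            for i, p in enumerate(small_corpus[:3])
        ]
        table = rank_heads(enc, anns)
        per_pair = []
        for ann in anns:
            rec = extract_cls_attention(enc, ann.sequence)[0]
            pred = select_budgeted_residues(rec, ann.budget)
            per_pair.append(overlap_score(pred, ann.truth))
        head0 = table[table["head"] == 0].iloc[0]
        assert head0.mean_overlap_score == pytest.approx(np.mean(per_pair))

    def test_empty_set_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            rank_heads(tiny_model.protein_encoder, [])

    def test_annotation_file_round_trip(self, tmp_path):
        payload = [{"id": "s1", "sequence": "MKLVAADSTW",
                    "segments": [[4, 8]], "budget": 3}]
        path = tmp_path / "sites.json"
        path.write_text(json.dumps(payload))
        (ann,) = load_annotations(path)
        assert ann.truth.segments == (Segment(3, 8),)
        assert ann.budget == 3
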