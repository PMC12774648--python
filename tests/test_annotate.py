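"""Annotation transfer, confidence tiers, and whole-genome annotation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structannot import (
    AnnotationLabel,
    DualSequence,
    FixtureSpec,
    SearchParams,
    StructannotError,
    annotate_genome,
    classify_tier,
    generate_database,
    generate_genome,
    transfer_annotation,
)
from structannot.search import Alignment


def _hit(target, ev, bits=100.0, qcov=0.9, tcov=0.9, fident=0.5):
    return Alignment(
        query_id="q", target_id=target, score=100, bits=bits, evalue=ev,
        fident=fident, qcov=qcov, tcov=tcov, alnlen=100,
        qstart=0, qend=90, tstart=0, tend=90,
    )


LABELS = {
    "unk": AnnotationLabel("phrog_8", "hypothetical protein", "unknown function"),
    "tail": AnnotationLabel("phrog_5", "tail fiber protein", "tail"),
    "portal": AnnotationLabel("phrog_6", "portal protein", "head and packaging"),
}


class TestTransfer:
    def test_known_function_overrides_rank(self):
        hits = [_hit("unk", 1e-20), _hit("tail", 1e-8)]
        ann = transfer_annotation(hits, LABELS, 1e-3)
        assert ann.label.product == "tail fiber protein"
        assert ann.functional_hit and ann.any_hit_count == 2
        assert ann.best_hit.target_id == "tail"

    def test_no_hits(self):
        ann = transfer_annotation([], LABELS, 1e-3)
        assert ann.label is None and ann.tier == "none" and ann.any_hit_count == 0

    def test_only_unknown_hits_keep_group(self):
        ann = transfer_annotation([_hit("unk", 1e-20)], LABELS, 1e-3)
        assert ann.label.group_id == "phrog_8"
        assert ann.label.category == "unknown function"
        assert not ann.functional_hit and ann.tier == "none"

    def test_hits_above_threshold_ignored(self):
        ann = transfer_annotation([_hit("tail", 0.5)], LABELS, 1e-3)
        assert ann.label is None and ann.any_hit_count == 0

    def test_tied_evalues_resolve_deterministically(self):
        a = _hit("tail", 1e-8, bits=50.0)
        b = _hit("portal", 1e-8, bits=50.0)
        ranked = sorted([a, b], key=Alignment.sort_key)
        winner = transfer_annotation(ranked, LABELS, 1e-3).label.group_id
        for perm in ([a, b], [b, a]):
            again = sorted(perm, key=Alignment.sort_key)
            assert transfer_annotation(again, LABELS, 1e-3).label.group_id == winner

    def test_missing_target_rejected(self):
        with pytest.raises(StructannotError, match="absent"):
            transfer_annotation([_hit("ghost", 1e-8)], LABELS, 1e-3)


# (qcov, tcov, fident, conf, evalue) -> expected tier in prostt5 mode.
# Rows sweep every clause combination: reciprocal vs one-sided vs no
# coverage, identity above/below 30%, confidence <45 / [45,60) / >=60,
# and E-value <1e-10 / <1e-5 / >=1e-5.
TIER_TABLE = [
    ((0.90, 0.85, 0.35, 50.0, 1e-04), "high"),    # reciprocal cov + identity
    ((0.90, 0.50, 0.35, 50.0, 1e-06), "medium"),  # one-sided cov + identity
    ((0.50, 0.50, 0.50, 80.0, 1e-30), "low"),     # low coverage overrides all
    ((0.90, 0.90, 0.10, 62.0, 1e-04), "high"),    # confidence >= 60
    ((0.90, 0.90, 0.10, 30.0, 1e-12), "high"),    # E < 1e-10
    ((0.90, 0.90, 0.10, 30.0, 1e-04), "low"),     # no high clause, no medium clause
    ((0.90, 0.70, 0.10, 50.0, 1e-06), "medium"),  # confidence in [45,60)
    ((0.90, 0.70, 0.10, 50.0, 1e-04), "low"),     # medium E-bound mandatory
    ((0.90, 0.70, 0.10, 62.0, 1e-06), "low"),     # conf >= 60 only helps high
    ((0.90, 0.70, 0.40, 10.0, 1e-06), "medium"),  # identity route to medium
    ((0.79, 0.79, 0.40, 70.0, 1e-20), "low"),     # both coverages just under
    ((0.80, 0.80, 0.31, 0.0, 1e-03), "high"),     # inclusive 80% boundary
    ((0.80, 0.80, 0.30, 44.0, 1e-04), "low"),     # identity must exceed 30%
    ((0.80, 0.80, 0.30, 45.0, 1e-06), "medium"),  # conf boundary 45 inclusive
    ((0.85, 0.90, 0.20, 59.9, 1e-11), "high"),    # E boundary strict
    ((0.70, 0.90, 0.20, 59.9, 1e-11), "medium"),  # one-sided + conf + E
]


class TestTiers:
    @pytest.mark.parametrize("row, expected", TIER_TABLE)
    def test_prostt5_truth_table(self, row, expected):
        qcov, tcov, fident, conf, ev = row
        hit = _hit("tail", ev, qcov=qcov, tcov=tcov, fident=fident)
        assert classify_tier(hit, conf, "prostt5", 1e-3) == expected

    @pytest.mark.parametrize(
        "row, expected",
        [
            ((0.90, 0.90, 0.10, 1e-04), "low"),     # conf clause dropped
            ((0.90, 0.90, 0.35, 1e-04), "high"),
            ((0.90, 0.50, 0.10, 1e-06), "low"),
            ((0.90, 0.50, 0.35, 1e-06), "medium"),
        ],
    )
    def test_structures_mode_drops_confidence(self, row, expected):
        qcov, tcov, fident, ev = row
        hit = _hit("tail", ev, qcov=qcov, tcov=tcov, fident=fident)
        assert classify_tier(hit, None, "structures", 1e-3) == expected

    def test_prostt5_requires_confidence(self):
        with pytest.raises(StructannotError):
            classify_tier(_hit("tail", 1e-8), None, "prostt5", 1e-3)

    def test_hit_above_threshold_rejected(self):
        with pytest.raises(StructannotError):
            classify_tier(_hit("tail", 0.5), 50.0, "prostt5", 1e-3)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 100),
        st.floats(1e-30, 1e-3),
        st.floats(0.0, 0.3), st.floats(0.0, 0.2),
    )
    @settings(deadline=None, max_examples=100)
    def test_improving_hit_never_demotes(self, qc, tc, fi, conf, ev, dcov, dfi):
        order = {"low": 0, "medium": 1, "high": 2}
        base = classify_tier(_hit("t", ev, qcov=qc, tcov=tc, fident=fi), conf, "prostt5", 1e-3)
        better = classify_tier(
            _hit("t", ev, qcov=min(1, qc + dcov), tcov=min(1, tc + dcov),
                 fident=min(1, fi + dfi)),
            conf, "prostt5", 1e-3,
        )
        assert order[better] >= order[base]


@pytest.fixture(scope="module")
def known_only_db():
    mix = {
        "head and packaging": 0.3, "tail": 0.3, "lysis": 0.2,
        "DNA, RNA and nucleotide metabolism": 0.2,
    }
    spec = FixtureSpec(seed=17, db_size=25, category_mix=mix)
    return (spec, *generate_database(spec))


class TestAnnotateGenome:
    def test_exact_copies_all_high(self, known_only_db, params):
        spec, db, labels = known_only_db
        queries = [DualSequence(f"q{i}", db[i].aa, db[i].tdi) for i in range(8)]
        anns, summary = annotate_genome(queries, db, labels, params, mode="structures", seed=4)
        assert summary["functional_rate"] == 1.0
        assert all(a.tier == "high" for a in anns)

    def test_decoy_genome_rate_zero(self, known_only_db, params):
        spec, db, labels = known_only_db
        fx = generate_genome(spec, db, labels, n_cds=6, planted_fraction=0.0)
        anns, summary = annotate_genome(fx.queries, db, labels, params, seed=4)
        assert summary["functional_rate"] == 0.0

    def test_output_order_invariant(self, known_only_db, params):
        spec, db, labels = known_only_db
        fx = generate_genome(spec, db, labels, n_cds=8, planted_fraction=0.5)
        queries = list(fx.queries)
        a1, s1 = annotate_genome(queries, db, labels, params, seed=4)
        random.Random(0).shuffle(queries)
        a2, s2 = annotate_genome(queries, db, labels, params, seed=4)
        assert [(a.cds_id, a.tier, a.any_hit_count) for a in a1] == [
            (a.cds_id, a.tier, a.any_hit_count) for a in a2
        ]
        assert s1 == s2

    def test_functional_rate_bounded_by_any_hit_rate(self, known_only_db, params):
        spec, db, labels = known_only_db
        fx = generate_genome(spec, db, labels, n_cds=10, planted_fraction=0.5)
        _, summary = annotate_genome(fx.queries, db, labels, params, seed=4)
        assert summary["functional_rate"] <= summary["any_hit_rate"]
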