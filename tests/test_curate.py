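"""Database-curation rules: fragmentation, model selection, hit
acceptance, dual-evidence reconciliation, annotation propagation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from structannot import (
    AnnotationLabel,
    CurationHit,
    StructannotError,
    StructureModel,
    accept_structural_hit,
    fragment_protein,
    propagate_unknown_phrog,
    resolve_dual_evidence,
    select_best_model,
)
from structannot.curate import hmm_hit_passes


class TestFragmentation:
    def test_five_thousand_splits_in_two(self):
        parts = fragment_protein("A" * 5000)
        assert [len(p) for p in parts] == [2500, 2500]

    def test_eight_thousand_one_hundred_splits_in_three(self):
        parts = fragment_protein("A" * 8100)
        assert [len(p) for p in parts] == [2700, 2700, 2700]

    def test_at_limit_unsplit(self):
        assert len(fragment_protein("A" * 3000)) == 1

    def test_empty_rejected(self):
        with pytest.raises(StructannotError):
            fragment_protein("")

    @given(st.integers(1, 20000), st.integers(1, 5000))
    @settings(deadline=None, max_examples=200)
    def test_fragmentation_invariants(self, length, limit):
        seq = "".join(chr(65 + i % 20) for i in range(length))
        parts = fragment_protein(seq, limit)
        n = -(-length // limit)
        assert len(parts) == n
        assert "".join(parts) == seq
        assert max(len(p) for p in parts) <= -(-length // n)
        assert max(len(p) for p in parts) - min(len(p) for p in parts) <= 1
        if length > limit:
            assert all(len(p) < limit + 1 for p in parts)


class TestModelSelection:
    def test_highest_plddt_wins(self):
        models = [
            StructureModel("p1", "colabfold", 74.8),
            StructureModel("p1", "esmfold", 61.2),
        ]
        assert select_best_model(models).predictor == "colabfold"

    def test_single_candidate(self):
        m = StructureModel("p1", "esmfold", 50.0)
        assert select_best_model([m]) is m

    def test_exact_tie_prefers_colabfold(self):
        models = [
            StructureModel("p1", "esmfold", 70.0),
            StructureModel("p1", "colabfold", 70.0),
        ]
        assert select_best_model(models).predictor == "colabfold"

    def test_mixed_proteins_rejected(self):
        models = [
            StructureModel("p1", "colabfold", 70.0),
            StructureModel("p2", "esmfold", 60.0),
        ]
        with pytest.raises(StructannotError, match="mixed"):
            select_best_model(models)


def _fs_hit(evalue=1e-8, tm=0.8, qcov=0.9, tcov=0.9, alnlen=200,
            product="portal protein", category="head and packaging",
            group="phrog_1"):
    return CurationHit(
        query_id="q", target_id=group, evalue=evalue, qcov=qcov, tcov=tcov,
        alnlen=alnlen, source="foldseek", tmscore=tm,
        target_label=AnnotationLabel(group, product, category),
    )


def _hmm_hit(evalue=1e-6, qcov=0.9, tcov=0.9, product="portal protein",
             category="head and packaging", group="phrog_2"):
    return CurationHit(
        query_id="q", target_id=group, evalue=evalue, qcov=qcov, tcov=tcov,
        alnlen=150, source="hmm",
        target_label=AnnotationLabel(group, product, category),
    )


class TestStructuralAcceptance:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(qcov=0.9, tcov=0.8, tm=0.65, alnlen=200, evalue=0.5), True),
            (dict(qcov=0.9, tcov=0.8, tm=0.65, alnlen=60, evalue=0.02), False),
            (dict(qcov=0.9, tcov=0.8, tm=0.65, alnlen=60, evalue=0.01), True),
            (dict(tm=0.59), False),
            (dict(tm=0.6, qcov=0.7, tcov=0.7), True),
            (dict(qcov=0.69), False),
            (dict(tcov=0.69), False),
            (dict(alnlen=74, evalue=0.01), True),
            (dict(alnlen=74, evalue=0.02), False),
            (dict(alnlen=75, evalue=0.02), True),
        ],
    )
    def test_threshold_boundaries(self, kw, expected):
        assert accept_structural_hit(_fs_hit(**kw)) is expected

    def test_missing_tmscore_rejected(self):
        hit = _fs_hit()
        hit.tmscore = None
        with pytest.raises(StructannotError):
            accept_structural_hit(hit)

    @given(
        st.floats(0.7, 1.0), st.floats(0.7, 1.0), st.floats(0.6, 1.0),
        st.floats(0, 0.5), st.floats(0, 0.5), st.floats(0, 0.4),
        st.integers(20, 300),
    )
    @settings(deadline=None, max_examples=100)
    def test_improvement_never_flips_accept(self, qc, tc, tm, dq, dt, dm, alnlen):
        base = _fs_hit(qcov=qc - dq, tcov=tc - dt, tm=max(0, tm - dm), alnlen=alnlen)
        better = _fs_hit(qcov=qc, tcov=tc, tm=tm, alnlen=alnlen)
        if accept_structural_hit(base):
            assert accept_structural_hit(better)

    def test_hmm_prefilter(self):
        assert hmm_hit_passes(_hmm_hit(evalue=1e-3, qcov=0.7, tcov=0.7))
        assert not hmm_hit_passes(_hmm_hit(evalue=2e-3))
        assert not hmm_hit_passes(_hmm_hit(qcov=0.69))


class TestDualEvidence:
    def test_identical_phrog(self):
        fs = _fs_hit(evalue=1e-8, group="phrog_10")
        hm = _hmm_hit(evalue=1e-12, group="phrog_10")
        winner, cls = resolve_dual_evidence(fs, hm)
        assert cls == "identical_phrog" and winner is hm  # lower E-value

    def test_known_beats_unknown_despite_evalue(self):
        fs = _fs_hit(evalue=1e-20, product="hypothetical protein",
                     category="unknown function", group="phrog_A")
        hm = _hmm_hit(evalue=1e-4, product="portal protein", group="phrog_B")
        winner, cls = resolve_dual_evidence(fs, hm)
        assert cls == "one_unknown" and winner is hm

    def test_conflicting_categories_lowest_evalue(self):
        fs = _fs_hit(evalue=1e-9, product="tail fiber protein", category="tail")
        hm = _hmm_hit(evalue=1e-6, product="portal protein",
                      category="head and packaging")
        winner, cls = resolve_dual_evidence(fs, hm)
        assert cls == "conflicting_categories" and winner is fs

    def test_same_annotation_different_group(self):
        fs = _fs_hit(group="phrog_1")
        hm = _hmm_hit(group="phrog_2")
        _, cls = resolve_dual_evidence(fs, hm)
        assert cls == "same_annotation"

    def test_same_category_different_product(self):
        fs = _fs_hit(product="portal protein")
        hm = _hmm_hit(product="terminase large subunit")
        _, cls = resolve_dual_evidence(fs, hm)
        assert cls == "same_category"

    def test_single_source_classes(self):
        assert resolve_dual_evidence(_fs_hit(), None)[1] == "foldseek_only"
        assert resolve_dual_evidence(None, _hmm_hit())[1] == "hmm_only"
        with pytest.raises(StructannotError):
            resolve_dual_evidence(None, None)


class TestPropagation:
    def test_ten_percent_rule(self):
        hits = ["terminase"] * 3 + [None] * 7
        v = propagate_unknown_phrog("phrog_x", hits)
        assert v.decision == "propagate" and v.proposed_label == "terminase"
        assert v.support_fraction == pytest.approx(0.3)

    def test_small_family_needs_unanimity(self):
        v = propagate_unknown_phrog("phrog_x", ["portal", None])
        assert v.decision == "reject"
        assert propagate_unknown_phrog("phrog_x", ["portal", "portal"]).decision == "propagate"

    def test_three_members_two_thirds(self):
        assert propagate_unknown_phrog("p", ["integrase", "integrase", None]).decision == "propagate"
        assert propagate_unknown_phrog("p", ["integrase", None, None]).decision == "reject"

    def test_vague_annotations_excluded(self):
        hits = ["DUF1234 domain protein"] * 4 + [None] * 6
        v = propagate_unknown_phrog("phrog_x", hits)
        assert v.decision == "reject" and "only_vague_annotations" in v.reasons

    def test_divergent_annotations_rejected(self):
        hits = ["integrase"] * 3 + ["capsid"] * 3 + [None] * 4
        v = propagate_unknown_phrog("phrog_x", hits)
        assert v.decision == "reject" and "divergent_annotations" in v.reasons

    def test_vague_not_counted_as_divergent(self):
        hits = ["integrase"] * 3 + ["Putative membrane protein"] * 3 + [None] * 4
        assert propagate_unknown_phrog("phrog_x", hits).decision == "propagate"

    def test_synonym_table_merges_support(self):
        hits = ["terminase", "terminase large subunit"] + [None] * 18
        syn = {"terminase large subunit": "terminase"}
        v = propagate_unknown_phrog("p", hits, synonyms=syn)
        assert v.decision == "propagate" and v.support_fraction == pytest.approx(0.1)

    @given(st.permutations(["integrase"] * 3 + ["Integrase!"] * 2 + ["capsid"] + [None] * 6))
    @settings(deadline=None, max_examples=30)
    def test_order_invariance(self, hits):
        v = propagate_unknown_phrog("p", list(hits))
        ref = propagate_unknown_phrog(
            "p", ["integrase"] * 3 + ["Integrase!"] * 2 + ["capsid"] + [None] * 6
        )
        assert (v.decision, v.proposed_label, v.support_fraction) == (
            ref.decision, ref.proposed_label, ref.support_fraction
        )
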