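import dataclasses

import pytest

from cd4lag3 import classifier as cl, synthetic_data as sd


CD41_VECTOR = cl.FeatureVector(
    clasp="CxC",
    inhibitory="none",
    cd41_cterm_motif=True,
    d1_intron_phase=1,
    tail_exon_count=2,
    architecture="V-C2-V-C2",
    linker_cxxc=False,
    head_to_tail_role="downstream",
    thymus_dominant=True,
    ep_repeat_n=0,
    acidic_fraction=0.1,
)

LAG3_VECTOR = cl.FeatureVector(
    clasp="none",
    inhibitory="ITIM_like",
    cd41_cterm_motif=False,
    d1_intron_phase=2,
    tail_exon_count=1,
    architecture="V-C2-V-C2",
    linker_cxxc=False,
    head_to_tail_role="upstream",
    thymus_dominant=False,
    ep_repeat_n=7,
    acidic_fraction=8 / 17,
)

SHARK_VECTOR = cl.FeatureVector(
    clasp="CxH",
    inhibitory="none",
    d1_intron_phase="absent",
    tail_exon_count=3,
    architecture="V-C2-V-C2",
    head_to_tail_role="downstream",
    thymus_dominant=True,
)

HYBRID_VECTOR = cl.FeatureVector(
    clasp="none",
    inhibitory="ITIM_like",
    cd41_cterm_motif=False,
    d1_intron_phase=1,
    tail_exon_count=1,
    architecture="V-C2-V-C2",
    head_to_tail_role="none",
)

FROG_VECTOR = cl.FeatureVector(
    clasp="none",
    inhibitory="none",
    d1_intron_phase=2,
    tail_exon_count=1,
    architecture="V-C2-V-C2",
    head_to_tail_role="upstream",
)


class TestScore:
    def test_all_unknown_scores_zero(self):
        cd4, lag3, contributions = cl.score(cl.FeatureVector())
        assert (cd4, lag3) == (0, 0)
        assert contributions == []

    def test_canonical_cd41_vector(self):
        cd4, lag3, _ = cl.score(CD41_VECTOR)
        assert 9 <= cd4 <= 10
        assert lag3 == 0

    def test_canonical_lag3_vector(self):
        cd4, lag3, _ = cl.score(LAG3_VECTOR)
        assert lag3 >= 8
        assert cd4 == 0

    def test_non_dominance_is_not_lag3_evidence(self):
        base = cl.score(cl.FeatureVector(inhibitory="ITIM_like"))
        with_info = cl.score(
            cl.FeatureVector(inhibitory="ITIM_like", thymus_dominant=False)
        )
        assert with_info[:2] == base[:2]

    def test_cxf_clasp_weaker_than_cxc(self):
        cxc = cl.score(cl.FeatureVector(clasp="CxC"))[0]
        cxf = cl.score(cl.FeatureVector(clasp="CxF"))[0]
        assert cxc == 3 and cxf == 2


class TestLabel:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            (CD41_VECTOR, "CD4-1"),
            (LAG3_VECTOR, "LAG-3"),
            (SHARK_VECTOR, "CD4"),
            (HYBRID_VECTOR, "HYBRID"),
            (FROG_VECTOR, "LAG-3"),
            (cl.FeatureVector(), "AMBIGUOUS"),
        ],
    )
    def test_reference_vectors(self, vector, expected):
        assert cl.classify(vector).label == expected

    def test_cd42_split_requires_ray_finned_cue(self):
        plain = dataclasses.replace(CD41_VECTOR, cd41_cterm_motif=False)
        assert cl.classify(plain).label == "CD4"
        reduced = dataclasses.replace(plain, architecture="V-C2")
        assert cl.classify(reduced).label == "CD4-2"
        linkered = dataclasses.replace(plain, linker_cxxc=True)
        assert cl.classify(linkered).label == "CD4-2"

    def test_weak_evidence_is_ambiguous(self):
        weak = cl.FeatureVector(clasp="CxC")  # 3 points: below the minimum
        assert cl.classify(weak).label == "AMBIGUOUS"

    def test_label_reproducible_from_scores(self):
        for vec in (CD41_VECTOR, LAG3_VECTOR, SHARK_VECTOR, FROG_VECTOR):
            rep = cl.classify(vec)
            assert rep.label == cl.label(rep.cd4_score, rep.lag3_score, vec)
            assert rep.cd4_score == sum(
                c.points for c in rep.contributions if c.lineage == "CD4"
            )
            assert rep.lag3_score == sum(
                c.points for c in rep.contributions if c.lineage == "LAG-3"
            )


class TestMonotonicity:
    def test_adding_concordant_cd4_features_never_hurts(self):
        base = cl.FeatureVector(clasp="CxC", tail_exon_count=2, d1_intron_phase=1)
        base_rep = cl.classify(base)
        assert base_rep.label == "CD4"
        additions = {
            "cd41_cterm_motif": True,
            "thymus_dominant": True,
            "head_to_tail_role": "downstream",
        }
        for field, value in additions.items():
            richer = dataclasses.replace(base, **{field: value})
            rep = cl.classify(richer)
            assert rep.cd4_score >= base_rep.cd4_score
            assert rep.label in ("CD4", "CD4-1", "CD4-2")

    def test_adding_concordant_lag3_features_never_hurts(self):
        base = cl.FeatureVector(inhibitory="ITIM_like", tail_exon_count=1,
                                d1_intron_phase=2)
        base_rep = cl.classify(base)
        assert base_rep.label == "LAG-3"
        additions = {"ep_repeat_n": 7, "head_to_tail_role": "upstream"}
        for field, value in additions.items():
            rep = cl.classify(dataclasses.replace(base, **{field: value}))
            assert rep.lag3_score >= base_rep.lag3_score
            assert rep.label == "LAG-3"


class TestPipeline:
    def test_full_cohort_recovery_and_determinism(self, cohort_dir):
        import pandas as pd

        args = (
            cohort_dir / "cohort.fasta",
            cohort_dir / "cohort.gff3",
            cohort_dir / "synteny.tsv",
            cohort_dir / "expression.tsv",
        )
        reports = cl.classify_pipeline(*args)
        truth = pd.read_csv(cohort_dir / "truth.tsv", sep="\t").set_index(
            "gene_id"
        )["true_label"]
        assert all(r.label == truth[r.gene_id] for r in reports)
        again = cl.classify_pipeline(*args)
        assert [r.to_dict() for r in again] == [r.to_dict() for r in reports]

    def test_fasta_only_degraded_input(self, cohort_dir):
        """Sequence-only classification: structural features stay unknown."""
        reports = cl.classify_pipeline(cohort_dir / "cohort.fasta")
        assert len(reports) == 100
        for r in reports:
            assert r.features["d1_intron_phase"] is None
            assert r.features["tail_exon_count"] is None
            assert r.features["clasp"] is not None

    def test_shark_cd4_argument_recapitulated(self):
        """CxH clasp + extra tail exon + no D1 intron + locus + expression
        resolve the shark gene as CD4."""
        rep = cl.classify(SHARK_VECTOR)
        assert rep.label == "CD4"
        assert rep.cd4_score >= 5 and rep.lag3_score == 0

    def test_unclassifiable_record_reported_inline(self, tmp_path):
        from cd4lag3 import seq_io

        p = tmp_path / "short.fasta"
        p.write_text(">tiny\nMKK\n>ok\n" + "D" * 30 + "L" * 19 + "RK" * 10 + "\n")
        reports = cl.classify_pipeline(p)
        assert len(reports) == 2
        tiny = reports[0]
        assert tiny.label == "AMBIGUOUS"
        assert any("TM" in n for n in tiny.notes)
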