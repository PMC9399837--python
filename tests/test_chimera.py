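"""Chimeric frame arithmetic and protein-domain retention."""

import itertools

import pytest

from fusiontriage.chimera import (
    FRAME_IN,
    FRAME_NONCODING,
    FRAME_OUT,
    FRAME_PROMOTER_SWAP,
    DomainStatus,
    _interval_status,
    build_junction,
    domain_retention,
    frame_status,
    functional_pass,
    junction_offsets,
)
from fusiontriage.io import FusionCall, SupportEvidence
from fusiontriage.simulate import fixture_breakpoints

from oracles import codon_walk_in_frame


def fixture_call(gene5, gene3, structures, sample_id="T1", split=50, disc=2):
    chrom5, pos5, chrom3, pos3 = fixture_breakpoints(gene5, gene3, structures)
    return FusionCall(
        sample_id=sample_id, gene5=gene5, gene3=gene3,
        chrom5=chrom5, pos5=pos5, chrom3=chrom3, pos3=pos3,
        support=SupportEvidence(split_reads=split, discordant_mates=disc),
    )


class _Off:
    """Minimal CodingOffset stand-in for pure frame-rule tests."""

    def __init__(self, noncoding=False, in_utr=False):
        self.noncoding = noncoding
        self.in_utr = in_utr


CODING = _Off()


class TestFrameRule:
    def test_multiple_of_three_difference_is_in_frame(self):
        assert frame_status(300, 0, CODING, CODING) == FRAME_IN
        assert frame_status(300, 123, CODING, CODING) == FRAME_IN

    def test_off_by_one_is_out_of_frame(self):
        assert frame_status(301, 0, CODING, CODING) == FRAME_OUT
        assert frame_status(300, 1, CODING, CODING) == FRAME_OUT

    def test_noncoding_three_prime_dominates(self):
        assert frame_status(300, 0, CODING, _Off(noncoding=True)) == FRAME_NONCODING

    def test_promoter_swap_requires_both_utr_breakpoints(self):
        assert frame_status(0, 0, _Off(in_utr=True), CODING) == FRAME_PROMOTER_SWAP
        # 5' breakpoint inside CDS with c5 = 0 is impossible; a coding
        # breakpoint at the CDS start (c5 = 3, say) is ordinary arithmetic
        assert frame_status(3, 0, CODING, CODING) == FRAME_IN

    def test_noncoding_five_prime_into_mid_cds(self):
        assert frame_status(0, 120, _Off(noncoding=True), CODING) == FRAME_NONCODING


class TestFixtureJunctions:
    def test_ptprg_raf1_offsets_and_frame(self, annotation, structures):
        call = fixture_call("PTPRG", "RAF1", structures)
        offs = junction_offsets(call, annotation)
        assert offs.c5 == 13 * 120  # PTPRG exons 1-13 retained
        assert offs.c3 == 6 * 120  # RAF1 exons 1-6 excluded
        j = build_junction(call, annotation)
        assert j.frame == FRAME_IN

    def test_out_of_frame_cases(self, annotation, structures):
        for g5, g3 in (("KIF13A", "PIK3CA"), ("PDZD2", "AKT2")):
            j = build_junction(fixture_call(g5, g3, structures), annotation)
            assert j.frame == FRAME_OUT, (g5, g3)

    def test_promoter_swap_case(self, annotation, structures):
        j = build_junction(fixture_call("ZNF462", "MUSK", structures), annotation)
        assert j.frame == FRAME_PROMOTER_SWAP
        assert j.retained3 == (1, annotation.protein_length("MUSK"))

    def test_frame_agrees_with_codon_walk_oracle(self, annotation, structures):
        """Oracle equivalence over a grid of exon-boundary junctions."""
        genes5 = ("PTPRG", "SS18", "EWSR1", "KIF13A")
        genes3 = ("RAF1", "PIK3CA", "GREB1", "NTRK1")
        checked = 0
        for g5, g3 in itertools.product(genes5, genes3):
            tx5 = annotation.canonical_transcript(g5)
            tx3 = annotation.canonical_transcript(g3)
            for k5 in range(1, len(structures[g5].exons) + 1, 3):
                for k3 in range(1, len(structures[g3].exons) + 1, 3):
                    pos5 = structures[g5].exon_end_tx(k5)
                    pos3 = structures[g3].exon_start_tx(k3)
                    call = FusionCall(
                        sample_id="T", gene5=g5, gene3=g3,
                        chrom5=structures[g5].spec.chrom, pos5=pos5,
                        chrom3=structures[g3].spec.chrom, pos3=pos3,
                        support=SupportEvidence(split_reads=50, discordant_mates=2),
                    )
                    j = build_junction(call, annotation)
                    if j.frame not in (FRAME_IN, FRAME_OUT):
                        continue
                    oracle = codon_walk_in_frame(tx5, pos5, tx3, pos3)
                    assert (j.frame == FRAME_IN) == oracle, (g5, k5, g3, k3)
                    checked += 1
        assert checked >= 40


class TestDomainRetention:
    def test_interval_trichotomy_is_total(self):
        """Every (domain, retained-interval) pair over a small grid gets
        exactly one status, and boundary equality counts as intact."""
        from fusiontriage.annotation import ProteinDomain

        for ds, de in itertools.combinations(range(1, 9), 2):
            dom = ProteinDomain(gene_symbol="G", name="d", category="kinase",
                                aa_start=ds, aa_end=de)
            for lo in range(1, 9):
                for hi in range(lo - 1, 9):
                    s = _interval_status(dom, (lo, hi))
                    assert s in {"intact", "lost", "truncated"}
                    if (lo, hi) == (ds, de):
                        assert s == "intact"

    def test_ss18_greb1_qpgy_lost(self, annotation, structures):
        j = build_junction(fixture_call("SS18", "GREB1", structures), annotation)
        statuses = {
            d.domain.name: d.status
            for d in domain_retention(j, annotation)
            if d.partner == "five_prime"
        }
        assert statuses["QPGY"] == "lost"

    def test_raf1_kinase_intact(self, annotation, structures):
        j = build_junction(fixture_call("PTPRG", "RAF1", structures), annotation)
        kinase = [
            d for d in domain_retention(j, annotation)
            if d.partner == "three_prime" and d.domain.category == "kinase"
        ]
        assert kinase and all(d.status == "intact" for d in kinase)

    def test_retention_monotone_in_breakpoint(self, annotation, structures):
        """Moving the 5' breakpoint downstream never demotes a 5' domain."""
        rank = {"lost": 0, "truncated": 1, "intact": 2}
        st5 = structures["SS18"]
        prev: dict[str, int] = {}
        _, _, chrom3f, pos3f = fixture_breakpoints("SS18", "GREB1", structures)
        for k in range(1, len(st5.exons) + 1):
            call = FusionCall(
                sample_id="T", gene5="SS18", gene3="GREB1",
                chrom5=st5.spec.chrom, pos5=st5.exon_end_tx(k),
                chrom3=chrom3f, pos3=pos3f,
                support=SupportEvidence(split_reads=50, discordant_mates=2),
            )
            j = build_junction(call, annotation)
            cur = {
                d.domain.name: rank[d.status]
                for d in domain_retention(j, annotation)
                if d.partner == "five_prime"
            }
            for name, r in cur.items():
                assert r >= prev.get(name, 0), (name, k)
            prev = cur


class TestFunctionalPass:
    def test_kinase_fusion_passes(self, annotation, structures):
        j = build_junction(fixture_call("PTPRG", "RAF1", structures), annotation)
        verdict, _ = functional_pass(
            j, domain_retention(j, annotation), "other", "protein_kinase"
        )
        assert verdict == "pass"

    def test_domain_loss_fails(self, annotation, structures):
        j = build_junction(fixture_call("SS18", "GREB1", structures), annotation)
        verdict, reason = functional_pass(
            j, domain_retention(j, annotation), "transcription_factor", "other"
        )
        assert verdict == "fail"
        assert "QPGY" in reason

    def test_no_driver_annotation_is_indeterminate(self, annotation, structures):
        j = build_junction(fixture_call("MAZ", "NCOA2", structures), annotation)
        verdict, _ = functional_pass(j, domain_retention(j, annotation), "other", "other")
        assert verdict == "indeterminate_pass"

    def test_promoter_swap_always_passes(self, annotation, structures):
        j = build_junction(fixture_call("ZNF462", "MUSK", structures), annotation)
        verdict, reason = functional_pass(
            j, domain_retention(j, annotation), "other", "protein_kinase"
        )
        assert verdict == "pass"
        assert "promoter swap" in reason

    def test_driver_without_annotated_domain_is_indeterminate(self):
        # a kinase-class partner with no kinase domain annotated
        from fusiontriage.chimera import ChimericJunction

        call = FusionCall(
            sample_id="T", gene5="A", gene3="B", chrom5="chr1", pos5=1,
            chrom3="chr3", pos3=1,
            support=SupportEvidence(split_reads=50, discordant_mates=2),
        )
        junction = ChimericJunction(
            call=call, c5=300, c3=0, frame=FRAME_IN,
            retained5=(1, 100), retained3=(1, 200), off5=CODING, off3=CODING,
        )
        verdict, _ = functional_pass(junction, [], "protein_kinase", "other")
        assert verdict == "indeterminate_pass"
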