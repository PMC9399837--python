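"""The filter cascade: QC, artifact screen, support screen, classification."""

import dataclasses
import itertools
import random

import pytest

from fusiontriage.io import FusionCall, SupportEvidence
from fusiontriage.simulate import fixture_breakpoints
from fusiontriage.triage import (
    CLASS_ARTIFACT,
    CLASS_KNOWN,
    CLASS_NOVEL,
    CLASS_PASSENGER,
    ONCOGENIC_CLASSES,
    TriageConfig,
    ValidationError,
    artifact_screen,
    classify_call,
    classify_cohort,
    sample_qc,
    support_screen,
)


def fixture_call(gene5, gene3, structures, sample_id="T1", split=50, disc=2,
                 flags=frozenset()):
    chrom5, pos5, chrom3, pos3 = fixture_breakpoints(gene5, gene3, structures)
    return FusionCall(
        sample_id=sample_id, gene5=gene5, gene3=gene3,
        chrom5=chrom5, pos5=pos5, chrom3=chrom3, pos3=pos3,
        support=SupportEvidence(split_reads=split, discordant_mates=disc),
        flags=flags,
    )


class TestConfig:
    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            TriageConfig(min_split_reads=-1)

    def test_yaml_round_trip_and_unknown_key(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("min_split_reads: 5\nrequire_dual_caller: false\n")
        cfg = TriageConfig.from_yaml(p)
        assert cfg.min_split_reads == 5 and not cfg.require_dual_caller
        bad = tmp_path / "bad.yaml"
        bad.write_text("min_split: 5\n")
        with pytest.raises(ValidationError, match="min_split"):
            TriageConfig.from_yaml(bad)


class TestSampleQC:
    @pytest.mark.parametrize(
        "reads,expected",
        [(0, "indeterminate"), (9, "indeterminate"), (10, "pass"), (5000, "pass")],
    )
    def test_unique_read_floor(self, reads, expected, cfg):
        assert sample_qc(reads, cfg) == expected

    def test_negative_count_rejected(self, cfg):
        with pytest.raises(ValidationError):
            sample_qc(-1, cfg)


class TestArtifactScreen:
    def test_mispriming_flag(self, structures, cfg, annotation):
        call = fixture_call("TPM3", "AKT2", structures, flags=frozenset({"mispriming"}))
        hit, reasons = artifact_screen(call, cfg, annotation)
        assert hit and "mispriming" in reasons

    def test_readthrough_geometry_adjacent_collinear(self, structures, cfg, annotation):
        call = fixture_call("AZGP1", "GJC3", structures)
        hit, reasons = artifact_screen(call, cfg, annotation)
        assert hit and reasons == ["readthrough"]

    def test_readthrough_requires_upstream_to_downstream(self, structures, cfg,
                                                         annotation):
        fwd = fixture_call("AZGP1", "GJC3", structures)
        rev = FusionCall(
            sample_id="T1", gene5="GJC3", gene3="AZGP1",
            chrom5=fwd.chrom3, pos5=fwd.pos3, chrom3=fwd.chrom5, pos3=fwd.pos5,
            support=fwd.support,
        )
        hit, reasons = artifact_screen(rev, cfg, annotation)
        assert "readthrough" not in reasons

    def test_interchromosomal_never_readthrough_or_proximal(self, structures, cfg,
                                                            annotation):
        call = fixture_call("PTPRG", "RAF1", structures)
        hit, reasons = artifact_screen(call, cfg, annotation)
        assert not hit and reasons == []

    def test_proximity_threshold_is_strict(self, cfg, annotation):
        def call_at(pos3):
            return FusionCall(
                sample_id="T1", gene5="PEX26", gene3="TUBA8",
                chrom5="chr2", pos5=1_000_000, chrom3="chr2", pos3=pos3,
                support=SupportEvidence(split_reads=50, discordant_mates=2),
            )

        # distance exactly at the threshold is kept; one base closer is not
        hit, reasons = artifact_screen(call_at(2_000_000), cfg, annotation=None)
        assert "proximity_lt_1mbp" not in reasons
        hit, reasons = artifact_screen(call_at(1_999_999), cfg, annotation=None)
        assert hit and "proximity_lt_1mbp" in reasons

    def test_proximal_decoy_pair(self, structures, cfg, annotation):
        call = fixture_call("PEX26", "TUBA8", structures)
        hit, reasons = artifact_screen(call, cfg, annotation)
        assert hit and reasons == ["proximity_lt_1mbp"]


class TestSupportScreen:
    @pytest.mark.parametrize(
        "split,disc,low",
        [
            (87, 5, False),   # well supported
            (9, 0, True),     # below floor, no mates
            (9, 1, False),    # a discordant mate rescues
            (10, 0, False),   # floor is inclusive
            (0, 0, True),
            (11, 0, False),
        ],
    )
    def test_conjunction_rule(self, split, disc, low, cfg):
        ev = SupportEvidence(split_reads=split, discordant_mates=disc)
        assert support_screen(ev, cfg) is low


class TestClassifyCall:
    def test_artifact_exits_without_junction(self, structures, annotation, cohort, cfg):
        call = fixture_call("TPM3", "AKT2", structures,
                            flags=frozenset({"mispriming"}))
        cc = classify_call(call, annotation, cohort.db, cfg)
        assert cc.classification == CLASS_ARTIFACT
        assert cc.junction is None and cc.domain_statuses == []

    def test_passenger_accumulates_all_reasons(self, structures, annotation, cohort,
                                               cfg):
        call = fixture_call("PDZD2", "AKT2", structures, split=4, disc=0)
        cc = classify_call(call, annotation, cohort.db, cfg)
        assert cc.classification == CLASS_PASSENGER
        assert set(cc.reasons) == {"low_support", "out_of_frame"}

    def test_domain_loss_passenger(self, structures, annotation, cohort, cfg):
        call = fixture_call("SS18", "GREB1", structures, split=45, disc=2)
        cc = classify_call(call, annotation, cohort.db, cfg)
        assert cc.classification == CLASS_PASSENGER
        assert cc.reasons == ["domain_lost"]

    def test_literature_only_pair_is_still_known(self, structures, annotation, cohort,
                                                 cfg):
        call = fixture_call("ESR1", "NCOA3", structures, split=60, disc=4)
        cc = classify_call(call, annotation, cohort.db, cfg)
        assert cc.classification == CLASS_KNOWN

    def test_novel_candidate(self, structures, annotation, cohort, cfg):
        call = fixture_call("APPL2", "RAF1", structures, split=87, disc=5)
        cc = classify_call(call, annotation, cohort.db, cfg)
        assert cc.classification == CLASS_NOVEL

    def test_truth_table_oracle(self, structures, annotation, cohort, cfg):
        """Exhaustive cascade check: every combination of artifact flag,
        support level, frame outcome and database membership must land in
        the class an independent truth table predicts."""
        frame_pairs = {
            "in": ("APPL2", "RAF1"),       # in-frame, kinase intact, not in DB
            "in_db": ("TPM3", "NTRK1"),    # in-frame, in curated DB
            "out": ("KIF13A", "PIK3CA"),   # out-of-frame
        }
        for flagged, lowsup, frame_key in itertools.product(
            (False, True), (False, True), frame_pairs
        ):
            g5, g3 = frame_pairs[frame_key]
            call = fixture_call(
                g5, g3, structures,
                split=4 if lowsup else 80, disc=0 if lowsup else 3,
                flags=frozenset({"mispriming"}) if flagged else frozenset(),
            )
            cc = classify_call(call, annotation, cohort.db, cfg)
            if flagged:
                expected = CLASS_ARTIFACT
            elif lowsup or frame_key == "out":
                expected = CLASS_PASSENGER
            elif frame_key == "in_db":
                expected = CLASS_KNOWN
            else:
                expected = CLASS_NOVEL
            assert cc.classification == expected, (flagged, lowsup, frame_key)

    def test_dual_caller_unconfirmed_is_artifact(self, structures, annotation, cohort,
                                                 cfg):
        call = fixture_call("APPL2", "RAF1", structures, split=87, disc=5)
        cc = classify_call(call, annotation, cohort.db, cfg, dual_confirmed=False)
        assert cc.classification == CLASS_ARTIFACT
        assert cc.reasons == ["not_dual_called"]
        relaxed = dataclasses.replace(cfg, require_dual_caller=False)
        cc2 = classify_call(call, annotation, cohort.db, relaxed,
                            dual_confirmed=False)
        assert cc2.classification == CLASS_NOVEL


class TestClassifyCohort:
    def test_orphan_call_rejected(self, cohort, annotation, cfg):
        orphan = dataclasses.replace(cohort.calls[0], sample_id="NO_SUCH")
        with pytest.raises(ValidationError, match="NO_SUCH"):
            classify_cohort(cohort.samples, [orphan], annotation, cohort.db, cfg)

    def test_qc_failed_samples_report_no_calls(self, results, cohort):
        failed = [r for r in results if r.qc == "indeterminate"]
        assert len(failed) == 5
        assert all(r.calls == [] and not r.fusion_positive for r in failed)

    def test_input_order_invariance(self, cohort, annotation, cfg, results):
        shuffled_calls = list(cohort.calls)
        shuffled_samples = list(cohort.samples)
        random.Random(11).shuffle(shuffled_calls)
        random.Random(12).shuffle(shuffled_samples)
        again = classify_cohort(
            shuffled_samples, shuffled_calls, annotation, cohort.db, cfg
        )
        assert [r.sample_id for r in again] == [r.sample_id for r in results]
        for a, b in zip(again, results):
            assert [(c.call, c.classification, c.reasons) for c in a.calls] == [
                (c.call, c.classification, c.reasons) for c in b.calls
            ]

    def test_positive_set_shrinks_as_support_floor_rises(self, cohort, annotation,
                                                         cfg):
        prev = None
        for floor in (0, 10, 50, 120, 10_000):
            c = dataclasses.replace(cfg, min_split_reads=floor)
            res = classify_cohort(cohort.samples, cohort.calls, annotation,
                                  cohort.db, c)
            positives = {r.sample_id for r in res if r.fusion_positive}
            if prev is not None:
                assert positives <= prev, floor
            prev = positives
        # the conjunction rule means discordant mates can rescue a call at
        # any split floor; raising both thresholds excludes everything
        strict = dataclasses.replace(
            cfg, min_split_reads=10_000, max_discordant_for_low_support=10_000
        )
        res = classify_cohort(cohort.samples, cohort.calls, annotation,
                              cohort.db, strict)
        assert not any(r.fusion_positive for r in res)

    def test_every_call_has_exactly_one_class(self, results):
        valid = {CLASS_ARTIFACT, CLASS_PASSENGER, *ONCOGENIC_CLASSES}
        for r in results:
            for cc in r.calls:
                assert cc.classification in valid
                assert cc.reasons
                assert (cc.junction is None) == (cc.classification == CLASS_ARTIFACT)

    def test_dual_caller_stream_filters_unconfirmed(self, cohort, annotation, cfg):
        # second stream that confirms every call except one novel candidate
        dropped = next(
            c for c in cohort.calls if (c.gene5, c.gene3) == ("APPL2", "RAF1")
        )
        stream2 = [c for c in cohort.calls if c is not dropped]
        res = classify_cohort(cohort.samples, cohort.calls, annotation, cohort.db,
                              cfg, calls2=stream2)
        by_id = {r.sample_id: r for r in res}
        cc = next(
            c for c in by_id[dropped.sample_id].calls
            if (c.call.gene5, c.call.gene3) == ("APPL2", "RAF1")
        )
        assert cc.classification == CLASS_ARTIFACT
        assert "not_dual_called" in cc.reasons
        # all other samples keep their single-stream classes
        base = classify_cohort(cohort.samples, cohort.calls, annotation, cohort.db,
                               cfg)
        base_by_id = {r.sample_id: r for r in base}
        for sid, r in by_id.items():
            if sid == dropped.sample_id:
                continue
            assert [c.classification for c in r.calls] == [
                c.classification for c in base_by_id[sid].calls
            ]
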