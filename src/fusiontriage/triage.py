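"""The filter cascade: artifact screen, support screen, frame and domain
criteria, known-fusion lookup — applied per call and per sample.

Cascade order: artifact geometry/flags first (such calls never receive
frame or domain labels), then the three passenger criteria (support,
frame, functional-domain retention), then the database lookup.  All
failed passenger criteria are accumulated as reason codes, so a call
excluded for several reasons reports all of them.  Order affects only
reason codes, never membership of the oncogenic classes.

Default thresholds mirror targeted-panel practice: a call is low-support
when fewer than 10 unique (post-dedup) split fragments coincide with
exactly 0 discordant mates; same-chromosome breakpoints closer than
1 Mbp are excluded as likely local artifacts; samples with fewer than
10 unique RNA reads are indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .annotation import GenomeAnnotation
from .chimera import (
    FRAME_NONCODING,
    FRAME_OUT,
    ChimericJunction,
    DomainStatus,
    build_junction,
    domain_retention,
    functional_pass,
)
from .io import FusionCall, KnownFusionDB, SupportEvidence, concordant_calls

CLASS_ARTIFACT = "artifact"
CLASS_PASSENGER = "passenger"
CLASS_KNOWN = "known_oncogenic"
CLASS_NOVEL = "novel_candidate"
ONCOGENIC_CLASSES = (CLASS_KNOWN, CLASS_NOVEL)

ARTIFACT_REASONS = ("mispriming", "readthrough", "proximity_lt_1mbp", "not_dual_called")
PASSENGER_REASONS = ("low_support", "out_of_frame", "domain_lost")


class ValidationError(ValueError):
    """Inputs are inconsistent (orphan calls, negative counts, ...)."""


@dataclass
class TriageConfig:
    """Tunable thresholds of the cascade (all ≥ 0)."""

    min_split_reads: int = 10
    max_discordant_for_low_support: int = 0
    min_breakpoint_distance: int = 1_000_000
    min_sample_unique_reads: int = 10
    bp_tolerance: int = 10
    require_dual_caller: bool = True

    def __post_init__(self) -> None:
        for name in (
            "min_split_reads", "max_discordant_for_low_support",
            "min_breakpoint_distance", "min_sample_unique_reads", "bp_tolerance",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "TriageConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClassifiedCall:
    """Final class of one call plus machine-readable reasons.

    ``junction`` is absent for artifact-class exits (frame arithmetic is
    never run on artifacts).
    """

    call: FusionCall
    classification: str
    reasons: list[str]
    junction: ChimericJunction | None = None
    domain_statuses: list[DomainStatus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.classification == CLASS_ARTIFACT:
            assert set(self.reasons) & set(ARTIFACT_REASONS)
        if self.classification == CLASS_PASSENGER:
            assert set(self.reasons) & set(PASSENGER_REASONS)


@dataclass
class SampleResult:
    sample_id: str
    qc: str  # pass | indeterminate
    calls: list[ClassifiedCall] = field(default_factory=list)

    @property
    def fusion_positive(self) -> bool:
        return any(c.classification in ONCOGENIC_CLASSES for c in self.calls)

    @property
    def detected_prefilter(self) -> bool:
        """At least one call survived QC and the artifact screen."""
        return any(c.classification != CLASS_ARTIFACT for c in self.calls)


def sample_qc(sample_unique_reads: int, cfg: TriageConfig) -> str:
    """Per-sample QC: indeterminate below the unique-read floor."""
    if sample_unique_reads < 0:
        raise ValidationError("sample unique-read count must be >= 0")
    return (
        "indeterminate"
        if sample_unique_reads < cfg.min_sample_unique_reads
        else "pass"
    )


def _is_readthrough_geometry(
    call: FusionCall, annotation: GenomeAnnotation
) -> bool:
    """Collinear, same-strand, adjacent partner genes.

    Read-through transcription runs off the end of one gene into its
    downstream neighbour, so both genes must sit on one strand of one
    chromosome with the 5' partner transcriptionally upstream and no
    gene between them.
    """
    if call.gene5 not in annotation.genes or call.gene3 not in annotation.genes:
        return False
    g5 = annotation.genes[call.gene5]
    g3 = annotation.genes[call.gene3]
    if g5.chrom != g3.chrom or g5.strand != g3.strand:
        return False
    if g5.strand == "+":
        if g5.end >= g3.start:
            return False
        gap = (g5.end, g3.start)
    else:
        if g3.end >= g5.start:
            return False
        gap = (g3.end, g5.start)
    for other in annotation.genes.values():
        if other.symbol in (g5.symbol, g3.symbol) or other.chrom != g5.chrom:
            continue
        if gap[0] < other.start and other.end < gap[1]:
            return False  # an intervening gene: not adjacent
    return True


def artifact_screen(
    call: FusionCall,
    cfg: TriageConfig,
    annotation: GenomeAnnotation | None = None,
) -> tuple[bool, list[str]]:
    """Mispriming / read-through / breakpoint-proximity screen.

    Flags set by the upstream caller are honoured as-is; the geometric
    read-through rule additionally fires when an annotation is supplied.
    The proximity rule is strict ``<``: same-chromosome breakpoints
    exactly at the threshold distance are kept.
    """
    reasons: list[str] = []
    if "mispriming" in call.flags:
        reasons.append("mispriming")
    if "readthrough" in call.flags or (
        annotation is not None and _is_readthrough_geometry(call, annotation)
    ):
        reasons.append("readthrough")
    if (
        call.chrom5 == call.chrom3
        and abs(call.pos5 - call.pos3) < cfg.min_breakpoint_distance
    ):
        reasons.append("proximity_lt_1mbp")
    return bool(reasons), reasons


def support_screen(support: SupportEvidence, cfg: TriageConfig) -> bool:
    """Low support: both few split fragments *and* no discordant mates.

    The conjunction is deliberate — either ≥ ``min_split_reads`` unique
    junction fragments or any discordant mate rescues the call.
    """
    return (
        support.split_reads < cfg.min_split_reads
        and support.discordant_mates <= cfg.max_discordant_for_low_support
    )


def classify_call(
    call: FusionCall,
    annotation: GenomeAnnotation,
    db: KnownFusionDB,
    cfg: TriageConfig,
    dual_confirmed: bool | None = None,
) -> ClassifiedCall:
    """Run one call through the full cascade.

    ``dual_confirmed`` is the per-call outcome of the second-caller
    concordance check; ``None`` means a single caller stream was
    supplied, in which case the dual-caller requirement is skipped.
    """
    is_artifact, reasons = artifact_screen(call, cfg, annotation)
    if cfg.require_dual_caller and dual_confirmed is False:
        is_artifact = True
        reasons.append("not_dual_called")
    if is_artifact:
        return ClassifiedCall(call=call, classification=CLASS_ARTIFACT, reasons=reasons)

    junction = build_junction(call, annotation)
    statuses = domain_retention(junction, annotation)
    verdict, _domain_reason = functional_pass(
        junction,
        statuses,
        annotation.gene(call.gene5).gene_class,
        annotation.gene(call.gene3).gene_class,
    )

    if support_screen(call.support, cfg):
        reasons.append("low_support")
    if junction.frame in (FRAME_OUT, FRAME_NONCODING):
        reasons.append("out_of_frame")
    if verdict == "fail":
        reasons.append("domain_lost")

    if reasons:
        classification = CLASS_PASSENGER
    elif db.lookup(call.gene5, call.gene3):
        classification = CLASS_KNOWN
        reasons = ["in_known_db"]
    else:
        classification = CLASS_NOVEL
        reasons = ["passes_all"]
    return ClassifiedCall(
        call=call,
        classification=classification,
        reasons=reasons,
        junction=junction,
        domain_statuses=statuses,
    )


def write_classified_calls(results: list[SampleResult], path) -> None:
    """TSV of every classified call with its reason codes."""
    import pandas as pd

    rows = []
    for res in results:
        for cc in res.calls:
            rows.append({
                "sample_id": cc.call.sample_id,
                "gene5": cc.call.gene5,
                "gene3": cc.call.gene3,
                "chrom5": cc.call.chrom5,
                "pos5": cc.call.pos5,
                "chrom3": cc.call.chrom3,
                "pos3": cc.call.pos3,
                "split_reads": cc.call.support.split_reads,
                "discordant_mates": cc.call.support.discordant_mates,
                "frame": cc.junction.frame if cc.junction else "",
                "class": cc.classification,
                "reasons": ",".join(cc.reasons),
            })
    columns = ["sample_id", "gene5", "gene3", "chrom5", "pos5", "chrom3",
               "pos3", "split_reads", "discordant_mates", "frame", "class",
               "reasons"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_sample_results(results: list[SampleResult], path) -> None:
    """Per-sample TSV: QC status and fusion-positivity."""
    import pandas as pd

    rows = [{
        "sample_id": r.sample_id,
        "qc": r.qc,
        "n_calls": len(r.calls),
        "detected_prefilter": r.detected_prefilter,
        "fusion_positive": r.fusion_positive,
    } for r in results]
    pd.DataFrame(
        rows,
        columns=["sample_id", "qc", "n_calls", "detected_prefilter",
                 "fusion_positive"],
    ).to_csv(path, sep="\t", index=False)


def _call_sort_key(call: FusionCall):
    return (call.sample_id, call.gene5, call.gene3, call.chrom5, call.pos5,
            call.chrom3, call.pos3)


def classify_cohort(
    samples,
    calls: list[FusionCall],
    annotation: GenomeAnnotation,
    db: KnownFusionDB,
    cfg: TriageConfig,
    calls2: list[FusionCall] | None = None,
) -> list[SampleResult]:
    """Per-sample QC then per-call classification for a whole cohort.

    ``samples`` is a sequence of objects with ``sample_id`` and
    ``unique_reads`` attributes (see ``report.SampleMeta``).  When a
    second caller stream ``calls2`` is given, calls from ``calls`` not
    confirmed by a concordant partner call are artifacts
    (``not_dual_called``).  Output is deterministic and independent of
    input row order.
    """
    meta_by_id = {s.sample_id: s for s in samples}
    for call in calls:
        if call.sample_id not in meta_by_id:
            raise ValidationError(
                f"call {call.name} references unknown sample {call.sample_id}"
            )

    calls = sorted(calls, key=_call_sort_key)
    by_sample: dict[str, list[FusionCall]] = {}
    for call in calls:
        by_sample.setdefault(call.sample_id, []).append(call)

    calls2_by_sample: dict[str, list[FusionCall]] = {}
    if calls2 is not None:
        for call in sorted(calls2, key=_call_sort_key):
            calls2_by_sample.setdefault(call.sample_id, []).append(call)

    results: list[SampleResult] = []
    for sample_id in sorted(meta_by_id):
        meta = meta_by_id[sample_id]
        qc = sample_qc(getattr(meta, "unique_reads", cfg.min_sample_unique_reads), cfg)
        if qc == "indeterminate":
            results.append(SampleResult(sample_id=sample_id, qc=qc, calls=[]))
            continue
        sample_calls = by_sample.get(sample_id, [])
        confirmed: dict[int, bool] = {}
        if calls2 is not None:
            matches = concordant_calls(
                sample_calls, calls2_by_sample.get(sample_id, []), cfg.bp_tolerance
            )
            hit = {i for i, _ in matches}
            confirmed = {i: (i in hit) for i in range(len(sample_calls))}
        classified = [
            classify_call(call, annotation, db, cfg, dual_confirmed=confirmed.get(i))
            for i, call in enumerate(sample_calls)
        ]
        results.append(SampleResult(sample_id=sample_id, qc=qc, calls=classified))
    return results
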