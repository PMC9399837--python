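"""Chimeric transcript construction: reading frame and domain retention.

Given a fusion call and a transcript annotation, this module computes

* ``c5`` — coding nucleotides of the 5' partner retained in the chimera
  (CDS start through the 5' breakpoint), and
* ``c3`` — coding nucleotides of the 3' partner excluded upstream of the
  junction,

and from them the frame of the chimeric ORF:  the 3' partner is
translated in its native frame iff ``(c5 - c3) ≡ 0 (mod 3)``.  A fusion
whose 5' breakpoint precedes its partner's CDS while the full 3' CDS is
retained is a *promoter swap* (enhancer hijacking): the 3' protein is
produced intact from its own start codon, so frame is irrelevant.

Retained protein intervals use residue counts ``floor(c/3)``; the codon
split across the junction is attributed to neither partner.  Each
annotated domain is then intact (interval fully retained), lost
(disjoint from the retained interval) or truncated (partial overlap) —
a total trichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import CodingOffset, GenomeAnnotation, ProteinDomain, coding_offset
from .io import FusionCall

FRAME_IN = "in_frame"
FRAME_OUT = "out_of_frame"
FRAME_PROMOTER_SWAP = "promoter_swap"
FRAME_NONCODING = "noncoding"

# domain categories a driver gene class must retain intact
REQUIRED_CATEGORIES = {
    "protein_kinase": {"kinase"},
    "transcription_factor": {"transactivation", "dna_binding"},
}


@dataclass(frozen=True)
class JunctionOffsets:
    c5: int
    c3: int
    off5: CodingOffset
    off3: CodingOffset


@dataclass(frozen=True)
class ChimericJunction:
    """Computed junction arithmetic for one fusion call.

    ``retained5``/``retained3`` are 1-based inclusive residue intervals
    on each partner's native protein; an interval with start > end is
    empty.
    """

    call: FusionCall
    c5: int
    c3: int
    frame: str
    retained5: tuple[int, int]
    retained3: tuple[int, int]
    off5: CodingOffset
    off3: CodingOffset


@dataclass(frozen=True)
class DomainStatus:
    domain: ProteinDomain
    partner: str  # five_prime | three_prime
    status: str  # intact | truncated | lost


def junction_offsets(call: FusionCall, annotation: GenomeAnnotation) -> JunctionOffsets:
    """Coding offsets of both breakpoints on their canonical transcripts."""
    off5 = coding_offset(annotation, call.gene5, call.pos5, "five_prime")
    off3 = coding_offset(annotation, call.gene3, call.pos3, "three_prime")
    return JunctionOffsets(c5=off5.n_coding_nt, c3=off3.n_coding_nt, off5=off5, off3=off3)


def frame_status(c5: int, c3: int, off5: CodingOffset, off3: CodingOffset) -> str:
    """Frame of the chimeric ORF from the two coding offsets.

    * 3' partner non-coding → ``noncoding`` (no chimeric protein).
    * both breakpoints precede their CDS (5' retains no coding sequence,
      3' retains its full CDS) → ``promoter_swap``.
    * otherwise in-frame iff ``(c5 - c3) % 3 == 0``.

    A coding-less 5' partner joined into the middle of the 3' CDS also
    yields ``noncoding``: with no upstream ORF there is nothing to set
    the reading frame of the truncated 3' protein.
    """
    if off3.noncoding:
        return FRAME_NONCODING
    if c5 == 0 and (off5.in_utr or off5.noncoding) and c3 == 0:
        return FRAME_PROMOTER_SWAP
    if off5.noncoding and c3 > 0:
        return FRAME_NONCODING
    return FRAME_IN if (c5 - c3) % 3 == 0 else FRAME_OUT


def build_junction(call: FusionCall, annotation: GenomeAnnotation) -> ChimericJunction:
    """Full junction arithmetic: offsets, frame, retained residue intervals."""
    offs = junction_offsets(call, annotation)
    frame = frame_status(offs.c5, offs.c3, offs.off5, offs.off3)
    length3 = (
        annotation.protein_length(call.gene3) if not offs.off3.noncoding else 0
    )
    retained5 = (1, offs.c5 // 3)
    retained3 = (offs.c3 // 3 + 1, length3)
    return ChimericJunction(
        call=call,
        c5=offs.c5,
        c3=offs.c3,
        frame=frame,
        retained5=retained5,
        retained3=retained3,
        off5=offs.off5,
        off3=offs.off3,
    )


def _interval_status(domain: ProteinDomain, retained: tuple[int, int]) -> str:
    lo, hi = retained
    if lo > hi:  # empty retained interval
        return "lost"
    if lo <= domain.aa_start and domain.aa_end <= hi:
        return "intact"
    if domain.aa_end < lo or domain.aa_start > hi:
        return "lost"
    return "truncated"


_RANK = {"lost": 0, "truncated": 1, "intact": 2}


def domain_retention(
    junction: ChimericJunction, annotation: GenomeAnnotation
) -> list[DomainStatus]:
    """Status of every annotated domain of both partners.

    Promoter-swap junctions treat the full 3' protein as retained
    (already encoded in ``retained3`` since ``c3 = 0``).  For an
    intragenic whole-exon deletion (gene5 == gene3) a domain survives if
    it survives on either flank, so the more favourable side is
    reported.
    """
    call = junction.call
    statuses: list[DomainStatus] = []
    if call.gene5 == call.gene3:
        for dom in annotation.domains_for(call.gene5):
            s5 = _interval_status(dom, junction.retained5)
            s3 = _interval_status(dom, junction.retained3)
            best = s5 if _RANK[s5] >= _RANK[s3] else s3
            statuses.append(DomainStatus(domain=dom, partner="three_prime", status=best))
        return statuses
    for dom in annotation.domains_for(call.gene5):
        statuses.append(
            DomainStatus(
                domain=dom,
                partner="five_prime",
                status=_interval_status(dom, junction.retained5),
            )
        )
    for dom in annotation.domains_for(call.gene3):
        statuses.append(
            DomainStatus(
                domain=dom,
                partner="three_prime",
                status=_interval_status(dom, junction.retained3),
            )
        )
    return statuses


def functional_pass(
    junction: ChimericJunction,
    domain_statuses: list[DomainStatus],
    gene5_class: str,
    gene3_class: str,
) -> tuple[str, str]:
    """Does the chimera retain the functional domain its driver needs?

    A partner annotated as a protein kinase must keep a ``kinase``
    domain intact; a transcription factor must keep a ``transactivation``
    or ``dna_binding`` domain intact.  The fusion passes when at least
    one driver-class partner retains its required category; it fails
    when driver-class partners are annotated and none does.  When the
    required domains are simply not annotated, the result is
    ``indeterminate_pass`` — absence of annotation is not evidence of
    domain loss, so the criterion cannot exclude.

    Returns ``(verdict, reason)`` with verdict in
    {"pass", "fail", "indeterminate_pass"}.
    """
    if junction.frame == FRAME_PROMOTER_SWAP:
        return "pass", "full 3' protein retained (promoter swap)"

    classes = {"five_prime": gene5_class, "three_prime": gene3_class}
    driver_sides = [s for s, c in classes.items() if c in REQUIRED_CATEGORIES]
    if not driver_sides:
        return "indeterminate_pass", "no kinase or transcription-factor partner"

    failures: list[str] = []
    any_annotated = False
    for side in driver_sides:
        required = REQUIRED_CATEGORIES[classes[side]]
        relevant = [
            ds for ds in domain_statuses
            if ds.partner == side and ds.domain.category in required
        ]
        if not relevant:
            continue
        any_annotated = True
        if any(ds.status == "intact" for ds in relevant):
            return "pass", f"{relevant[0].domain.gene_symbol} required domain intact"
        worst = relevant[0]
        failures.append(
            f"{worst.domain.gene_symbol} {worst.domain.name} domain {worst.status}"
        )
    if not any_annotated:
        return "indeterminate_pass", "required domains not annotated for either partner"
    return "fail", "; ".join(failures)


def write_junction_report(
    junctions: list[tuple[ChimericJunction, list[DomainStatus]]], path
) -> None:
    """TSV report: one row per (junction, domain) pair."""
    import pandas as pd

    rows = []
    for junction, statuses in junctions:
        call = junction.call
        base = {
            "sample_id": call.sample_id,
            "gene5": call.gene5,
            "gene3": call.gene3,
            "c5": junction.c5,
            "c3": junction.c3,
            "frame": junction.frame,
        }
        if not statuses:
            rows.append({**base, "domain": "", "domain_status": ""})
        for ds in statuses:
            rows.append(
                {**base, "domain": ds.domain.name, "domain_status": ds.status}
            )
    pd.DataFrame(
        rows,
        columns=["sample_id", "gene5", "gene3", "c5", "c3", "frame", "domain",
                 "domain_status"],
    ).to_csv(path, sep="\t", index=False)
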