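"""Cohort-level summaries: per-diagnostic-group detection frequency,
fusion recurrence, and the unknown/novel fusion inventory.

Group frequencies use all enrolled patients as denominators (sequencing
failures included) and are rounded half-up to integer percent.  The
novelty inventory distinguishes two tiers of prior knowledge: curated
fusion databases (the first lookup a pipeline performs) and literature
reports (a second, manual tier) — a pair absent from the databases is
*unknown*; an unknown pair also absent from the literature is a *novel*
candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import KnownFusionDB
from .triage import CLASS_ARTIFACT, CLASS_NOVEL, ONCOGENIC_CLASSES, SampleResult


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMeta:
    """One enrolled patient sample with its diagnostic-group label."""

    sample_id: str
    group_id: int
    group_label: str = ""
    diagnosis: str = ""
    unique_reads: int = 10**6  # per-sample unique RNA reads for QC

    def __post_init__(self) -> None:
        if self.group_id < 1:
            raise ReportError(f"sample {self.sample_id}: group_id must be >= 1")


def read_samples(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise ReportError(f"{path}: missing columns {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=row["sample_id"],
            group_id=int(row["group_id"]),
            group_label=row.get("group_label", ""),
            diagnosis=row.get("diagnosis", ""),
            unique_reads=int(row.get("unique_reads") or 10**6),
        )
        for row in df.to_dict("records")
    ]


def write_samples(samples: list[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group_id": s.group_id,
            "group_label": s.group_label,
            "diagnosis": s.diagnosis,
            "unique_reads": s.unique_reads,
        }
        for s in samples
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "group_id", "group_label", "diagnosis", "unique_reads"],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class NovelInventory:
    unknown_pairs: list[tuple[str, str]]
    n_samples_unknown: int
    novel_prefilter_pairs: list[tuple[str, str]]
    novel_candidate_pairs: list[tuple[str, str]]

    @property
    def n_unknown_fusions(self) -> int:
        return len(self.unknown_pairs)


@dataclass
class CohortReport:
    per_group: pd.DataFrame
    recurrence: pd.DataFrame
    novel: NovelInventory
    counts: dict = field(default_factory=dict)

    @property
    def distinct_fusion_count(self) -> int:
        return len(self.recurrence)


def _percent_half_up(numerator: int, denominator: int) -> int:
    if denominator == 0:
        return 0
    return (200 * numerator + denominator) // (2 * denominator)


def group_frequency(
    results: list[SampleResult], meta: list[SampleMeta]
) -> pd.DataFrame:
    """Per-group rows: patients, fusion-positive samples, integer percent.

    Denominators are all enrolled patients in the group, including
    samples that failed sequencing QC.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    for res in results:
        if res.sample_id not in meta_by_id:
            raise ReportError(f"result sample {res.sample_id} not in sample metadata")
    positive = {r.sample_id for r in results if r.fusion_positive}
    rows = []
    groups = sorted({m.group_id for m in meta})
    for gid in groups:
        members = [m for m in meta if m.group_id == gid]
        n_pos = sum(1 for m in members if m.sample_id in positive)
        rows.append(
            {
                "group_id": gid,
                "group_label": members[0].group_label,
                "n_patients": len(members),
                "n_fusion_positive": n_pos,
                "frequency_pct": _percent_half_up(n_pos, len(members)),
            }
        )
    return pd.DataFrame(rows)


def recurrence_table(results: list[SampleResult]) -> pd.DataFrame:
    """One row per distinct ordered gene pair among oncogenic-class calls.

    ``n_samples`` counts distinct samples carrying the pair; rows sort
    by descending count with the fusion name as the deterministic
    tie-break.
    """
    seen: dict[str, set[str]] = {}
    for res in results:
        for cc in res.calls:
            if cc.classification in ONCOGENIC_CLASSES:
                seen.setdefault(cc.call.name, set()).add(res.sample_id)
    rows = [
        {"fusion_name": name, "n_samples": len(samples)}
        for name, samples in seen.items()
    ]
    rows.sort(key=lambda r: (-r["n_samples"], r["fusion_name"]))
    return pd.DataFrame(rows, columns=["fusion_name", "n_samples"])


def novel_inventory(
    results: list[SampleResult],
    db: KnownFusionDB,
    literature_sources: tuple[str, ...] = ("literature",),
) -> NovelInventory:
    """Unknown and novel fusion pairs among non-artifact calls.

    * *unknown*: distinct pairs with no entry in a curated fusion
      database (entries from ``literature_sources`` do not count as
      database hits), taken before the passenger filters.
    * *novel pre-filter*: unknown pairs that are also absent from the
      literature tier, i.e. absent from the database entirely.
    * *novel candidates*: distinct pairs classified ``novel_candidate``
      after the full cascade.
    """
    unknown: dict[tuple[str, str], set[str]] = {}
    novel_prefilter: set[tuple[str, str]] = set()
    novel_candidates: set[tuple[str, str]] = set()
    for res in results:
        for cc in res.calls:
            if cc.classification == CLASS_ARTIFACT:
                continue
            pair = cc.call.pair
            sources = db.sources_for(*pair)
            if not (sources - set(literature_sources)):
                unknown.setdefault(pair, set()).add(res.sample_id)
                if not sources:
                    novel_prefilter.add(pair)
            if cc.classification == CLASS_NOVEL:
                novel_candidates.add(pair)
    samples_unknown = set().union(*unknown.values()) if unknown else set()
    return NovelInventory(
        unknown_pairs=sorted(unknown),
        n_samples_unknown=len(samples_unknown),
        novel_prefilter_pairs=sorted(novel_prefilter),
        novel_candidate_pairs=sorted(novel_candidates),
    )


def build_report(
    results: list[SampleResult], meta: list[SampleMeta], db: KnownFusionDB
) -> CohortReport:
    per_group = group_frequency(results, meta)
    recurrence = recurrence_table(results)
    novel = novel_inventory(results, db)
    counts = {
        "n_enrolled": len(meta),
        "n_sequenced": sum(1 for r in results if r.qc == "pass"),
        "n_detected_prefilter": sum(1 for r in results if r.detected_prefilter),
        "n_positive_postfilter": sum(1 for r in results if r.fusion_positive),
    }
    return CohortReport(
        per_group=per_group, recurrence=recurrence, novel=novel, counts=counts
    )


def write_report(report: CohortReport, outdir) -> list[Path]:
    """Write per_group.tsv, recurrence.tsv, novel.tsv and summary.json.

    Output is byte-stable for identical inputs: rows are fully ordered
    and JSON keys are sorted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = outdir / "per_group.tsv"
    report.per_group.to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = outdir / "recurrence.tsv"
    report.recurrence.to_csv(p, sep="\t", index=False)
    paths.append(p)

    p = outdir / "novel.tsv"
    rows = [
        {"gene5": g5, "gene3": g3, "tier": tier}
        for tier, pairs in (
            ("unknown", report.novel.unknown_pairs),
            ("novel_prefilter", report.novel.novel_prefilter_pairs),
            ("novel_candidate", report.novel.novel_candidate_pairs),
        )
        for g5, g3 in pairs
    ]
    pd.DataFrame(rows, columns=["gene5", "gene3", "tier"]).to_csv(
        p, sep="\t", index=False
    )
    paths.append(p)

    p = outdir / "summary.json"
    summary = {
        **report.counts,
        "distinct_fusion_count": report.distinct_fusion_count,
        "n_unknown_fusions": report.novel.n_unknown_fusions,
        "n_samples_unknown": report.novel.n_samples_unknown,
        "n_novel_prefilter": len(report.novel.novel_prefilter_pairs),
        "n_novel_candidates": len(report.novel.novel_candidate_pairs),
    }
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(p)
    return paths
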