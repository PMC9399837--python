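"""Reading and writing fusion call tables, known-fusion databases, sample
sheets and raw junction reads; UMI deduplication; dual-caller concordance.

Two call-table dialects are supported:

* ``generic`` — the tab-separated layout this package writes, one call
  per row with post-dedup support counts.
* ``arriba`` — the subset of Arriba's ``fusions.tsv`` columns needed
  here (``#gene1, gene2, breakpoint1, breakpoint2, split_reads1,
  split_reads2, discordant_mates, reading_frame``); split support is
  the sum of the two directional split-read columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

GENERIC_COLUMNS = [
    "sample_id", "gene5", "gene3", "chrom5", "pos5", "chrom3", "pos3",
    "split_reads", "discordant_mates", "flags", "caller",
]

ARRIBA_COLUMNS = [
    "#gene1", "gene2", "breakpoint1", "breakpoint2",
    "split_reads1", "split_reads2", "discordant_mates", "reading_frame",
]

VALID_FLAGS = {"mispriming", "readthrough"}


class SchemaError(ValueError):
    """A call table or database file is missing required columns."""


class RowError(ValueError):
    """A specific row could not be parsed; message names the row number."""


@dataclass(frozen=True)
class ReadRecord:
    """One raw junction read carrying a molecular barcode (UMI)."""

    read_id: str
    umi: str
    junction_spanning: bool = True

    def __post_init__(self) -> None:
        if not self.umi:
            raise ValueError(f"read {self.read_id}: empty UMI")


@dataclass(frozen=True)
class SupportEvidence:
    """Junction support: unique fragments post-dedup plus discordant pairs."""

    split_reads: int
    discordant_mates: int
    raw_reads: tuple[ReadRecord, ...] | None = None

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.discordant_mates < 0:
            raise ValueError("support counts must be non-negative")
        if self.raw_reads is not None and self.split_reads > len(self.raw_reads):
            raise ValueError("split_reads exceeds number of raw reads")


@dataclass(frozen=True)
class FusionCall:
    """One candidate fusion junction from one sample.

    Breakpoints follow the annotation convention: ``pos5`` is the last
    retained base of the 5' partner, ``pos3`` the first retained base of
    the 3' partner.  ``flags`` carries upstream artifact annotations.
    """

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    pos5: int
    chrom3: str
    pos3: int
    support: SupportEvidence
    caller: str = "archer"
    flags: frozenset[str] = frozenset()
    frame_hint: str | None = None

    def __post_init__(self) -> None:
        if self.pos5 < 1 or self.pos3 < 1:
            raise ValueError("breakpoint positions must be >= 1")
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags {sorted(bad)}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)

    @property
    def name(self) -> str:
        return f"{self.gene5}-{self.gene3}"


@dataclass
class KnownFusionDB:
    """Ordered 5'→3' gene-pair lookup with a provenance label per entry.

    Sources distinguish curated fusion databases (e.g. quiver, chimerdb,
    oncokb) from literature reports; the novelty inventory treats the
    two tiers differently, mirroring the two-step novelty review
    (database search, then literature check).
    """

    entries: set[tuple[str, str, str]] = field(default_factory=set)

    def lookup(self, gene5: str, gene3: str, sources: set[str] | None = None) -> bool:
        """True if the ordered pair is present (optionally restricted to sources)."""
        for g5, g3, src in self.entries:
            if (g5, g3) == (gene5, gene3) and (sources is None or src in sources):
                return True
        return False

    def sources_for(self, gene5: str, gene3: str) -> set[str]:
        return {src for g5, g3, src in self.entries if (g5, g3) == (gene5, gene3)}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _parse_flags(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw in ("", "."):
        return frozenset()
    return frozenset(str(raw).split(","))


def read_calls(path, dialect: str = "generic") -> list[FusionCall]:
    """Read a fusion call TSV; rows are preserved in input order."""
    if dialect not in ("generic", "arriba"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "generic":
        _require_columns(df, [c for c in GENERIC_COLUMNS if c != "flags"], path)
        return [_generic_row(row, i, path) for i, row in enumerate(df.to_dict("records"))]
    _require_columns(df, ARRIBA_COLUMNS, path)
    return [_arriba_row(row, i, path) for i, row in enumerate(df.to_dict("records"))]


def _generic_row(row, i, path) -> FusionCall:
    try:
        return FusionCall(
            sample_id=row["sample_id"],
            gene5=row["gene5"],
            gene3=row["gene3"],
            chrom5=row["chrom5"],
            pos5=int(row["pos5"]),
            chrom3=row["chrom3"],
            pos3=int(row["pos3"]),
            support=SupportEvidence(
                split_reads=int(row["split_reads"]),
                discordant_mates=int(row["discordant_mates"]),
            ),
            caller=row.get("caller") or "archer",
            flags=_parse_flags(row.get("flags")),
        )
    except (ValueError, KeyError) as exc:
        raise RowError(f"{path}: row {i + 2}: {exc}") from exc


def _split_breakpoint(text: str) -> tuple[str, int]:
    chrom, _, pos = str(text).rpartition(":")
    if not chrom:
        raise ValueError(f"unparsable breakpoint {text!r} (expected chrom:pos)")
    return chrom, int(pos)


def _arriba_row(row, i, path) -> FusionCall:
    try:
        chrom5, pos5 = _split_breakpoint(row["breakpoint1"])
        chrom3, pos3 = _split_breakpoint(row["breakpoint2"])
        frame = row.get("reading_frame") or None
        hint = {"in-frame": "in_frame", "out-of-frame": "out_of_frame"}.get(frame)
        return FusionCall(
            sample_id=row.get("sample_id", ""),
            gene5=row["#gene1"],
            gene3=row["gene2"],
            chrom5=chrom5,
            pos5=pos5,
            chrom3=chrom3,
            pos3=pos3,
            support=SupportEvidence(
                split_reads=int(row["split_reads1"]) + int(row["split_reads2"]),
                discordant_mates=int(row["discordant_mates"]),
            ),
            caller="arriba",
            frame_hint=hint,
        )
    except (ValueError, KeyError) as exc:
        raise RowError(f"{path}: row {i + 2}: {exc}") from exc


def write_calls(calls: list[FusionCall], path) -> None:
    """Write calls in the generic dialect (lossless round-trip)."""
    rows = [
        {
            "sample_id": c.sample_id,
            "gene5": c.gene5,
            "gene3": c.gene3,
            "chrom5": c.chrom5,
            "pos5": c.pos5,
            "chrom3": c.chrom3,
            "pos3": c.pos3,
            "split_reads": c.support.split_reads,
            "discordant_mates": c.support.discordant_mates,
            "flags": ",".join(sorted(c.flags)),
            "caller": c.caller,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=GENERIC_COLUMNS).to_csv(path, sep="\t", index=False)


def unique_fragment_count(reads: list[ReadRecord]) -> int:
    """Unique junction-spanning fragments after molecular-barcode dedup.

    Reads sharing a UMI derive from one original fragment, so the count
    is the number of distinct UMIs among junction-spanning reads.
    """
    return len({r.umi for r in reads if r.junction_spanning})


def dedup_support(call: FusionCall) -> FusionCall:
    """Recompute split support from raw reads when they are attached."""
    if call.support.raw_reads is None:
        return call
    n = unique_fragment_count(list(call.support.raw_reads))
    return replace(call, support=replace(call.support, split_reads=n))


def concordant_calls(
    a: list[FusionCall], b: list[FusionCall], bp_tolerance: int = 10
) -> set[tuple[int, int]]:
    """Index pairs (i, j) where a[i] matches b[j].

    A match requires the same ordered (gene5, gene3) pair and both
    breakpoints within ``bp_tolerance``; orientation-swapped pairs never
    match because the 5'/3' roles determine oncogenicity.
    """
    matched = set()
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            if (
                ca.pair == cb.pair
                and ca.chrom5 == cb.chrom5
                and ca.chrom3 == cb.chrom3
                and abs(ca.pos5 - cb.pos5) <= bp_tolerance
                and abs(ca.pos3 - cb.pos3) <= bp_tolerance
            ):
                matched.add((i, j))
    return matched


def read_known_db(path) -> KnownFusionDB:
    """Read a known-fusion TSV (``gene5, gene3, source``); set semantics."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["gene5", "gene3", "source"], path)
    entries = set()
    for i, row in enumerate(df.to_dict("records")):
        if not row["gene5"] or not row["gene3"]:
            raise RowError(f"{path}: row {i + 2}: empty gene symbol")
        entries.add((row["gene5"], row["gene3"], row["source"]))
    return KnownFusionDB(entries=entries)


def write_known_db(db: KnownFusionDB, path) -> None:
    rows = sorted(db.entries)
    pd.DataFrame(rows, columns=["gene5", "gene3", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_raw_reads(path) -> dict[tuple[str, str], list[ReadRecord]]:
    """Read the optional raw-read TSV, grouped by (sample_id, call_key)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ["sample_id", "call_key", "read_id", "umi", "junction_spanning"], path
    )
    groups: dict[tuple[str, str], list[ReadRecord]] = {}
    for row in df.to_dict("records"):
        rec = ReadRecord(
            read_id=row["read_id"],
            umi=row["umi"],
            junction_spanning=row["junction_spanning"].lower() in ("1", "true", "yes"),
        )
        groups.setdefault((row["sample_id"], row["call_key"]), []).append(rec)
    return groups
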