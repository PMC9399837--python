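"""Synthetic test data: a mini transcript annotation, a deterministic
reference cohort, raw barcoded junction reads, and randomized cohorts
with planted ground truth.

The reference cohort emulates a published 165-sample targeted RNA-seq
panel study at the *call* level: 165 samples across 14 diagnostic
groups, 5 sequencing failures, 68 fusion-positive samples carrying 34
distinct fusions (8 of them novel, with their reported split/discordant
read supports), three passenger cases (a domain-loss fusion, an
out-of-frame low-support fusion, and an out-of-frame fusion), and decoy
artifact calls (read-through, breakpoint proximity, mispriming).

The mini annotation is synthetic: real gene symbols are used so the
fixture reads naturally, but exon counts, coordinates and domain
intervals are toy values constructed so that each fusion's documented
frame and domain-retention outcome holds (e.g. the PTPRG-RAF1 chimera
joining PTPRG exons 1-13 to RAF1 exons 7-18 is in-frame with the RAF1
kinase domain intact, while the SS18-GREB1 breakpoint falls upstream of
the SS18 QPGY transactivation domain).  It encodes the study's
qualitative claims, not real genomic coordinates.

Layout: every coding exon carries 120 coding nt (40 residues) unless
overridden; introns are 5 kb; 5' partner genes live on chr1, 3' partner
genes on chr3, so every real fusion is inter-chromosomal; chr2 hosts
the artifact-decoy geometry.  Two deliberate exceptions to the
120-nt rule (a 121/119-nt exon pair in KIF13A and in PDZD2) produce the
two out-of-frame junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, load_annotation
from .io import (
    FusionCall,
    KnownFusionDB,
    ReadRecord,
    SupportEvidence,
    write_calls,
    write_known_db,
)
from .report import SampleMeta, write_samples

DEFAULT_EXON_LEN = 120  # coding nt per exon unless overridden
DEFAULT_INTRON_LEN = 5_000
DEFAULT_SPACING = 2_000_000  # gap between consecutive genes on a chromosome
ORIGIN = 1_000_000


@dataclass(frozen=True)
class GeneSpec:
    """Declarative description of one fixture gene."""

    symbol: str
    chrom: str
    strand: str
    n_exons: int
    gene_class: str = "other"
    # (name, category, aa_start, aa_end)
    domains: tuple[tuple[str, str, int, int], ...] = ()
    # exon number -> coding nt (default DEFAULT_EXON_LEN)
    coding_overrides: dict[int, int] = field(default_factory=dict, hash=False)
    utr5_nt: int = 0  # non-coding nt at the transcript 5' end (within exon 1)
    gap_before: int | None = None  # overrides DEFAULT_SPACING


def _coding_len(spec: GeneSpec, exon_number: int) -> int:
    return spec.coding_overrides.get(exon_number, DEFAULT_EXON_LEN)


# --------------------------------------------------------------------------
# The fixture gene table.  k5/k3 breakpoint exons live in REFERENCE_BREAKPOINTS.
# --------------------------------------------------------------------------

DEFAULT_GENES: tuple[GeneSpec, ...] = (
    # 5' partners (chr1)
    GeneSpec("TPM3", "chr1", "+", 10),
    GeneSpec("EML4", "chr1", "-", 23),
    GeneSpec("KIF5B", "chr1", "+", 26),
    GeneSpec("SLC34A2", "chr1", "-", 13),
    GeneSpec("BRD4", "chr1", "+", 20),
    GeneSpec("WHSC1L1", "chr1", "-", 24),
    GeneSpec("ESR1", "chr1", "+", 8, "transcription_factor",
             (("DBD", "dna_binding", 100, 160),)),
    GeneSpec("COL1A1", "chr1", "-", 20),
    GeneSpec("EWSR1", "chr1", "+", 17, "transcription_factor",
             (("EAD", "transactivation", 1, 200),)),
    GeneSpec("JAZF1", "chr1", "-", 5),
    GeneSpec("ZNF462", "chr1", "+", 8, coding_overrides={1: 0}, utr5_nt=200),
    GeneSpec("LSM1", "chr1", "-", 6),
    GeneSpec("SS18", "chr1", "+", 11, "transcription_factor",
             (("QPGY", "transactivation", 180, 380),)),
    GeneSpec("APPL2", "chr1", "-", 22),
    GeneSpec("FUS", "chr1", "+", 15, "transcription_factor",
             (("EAD", "transactivation", 1, 150),)),
    GeneSpec("MAZ", "chr1", "-", 5, "transcription_factor",
             (("DBD", "dna_binding", 80, 160),)),
    GeneSpec("NAB2", "chr1", "+", 7),
    GeneSpec("HEY1", "chr1", "-", 5, "transcription_factor",
             (("bHLH", "dna_binding", 50, 100),)),
    GeneSpec("PAX3", "chr1", "+", 8, "transcription_factor",
             (("paired_box", "dna_binding", 34, 130),)),
    GeneSpec("CAPZA2", "chr1", "-", 10),
    GeneSpec("CIC", "chr1", "+", 20, "transcription_factor",
             (("HMG", "dna_binding", 200, 270),)),
    GeneSpec("TAF15", "chr1", "-", 15, "transcription_factor",
             (("EAD", "transactivation", 1, 150),)),
    GeneSpec("TFE3", "chr1", "+", 10, "transcription_factor",
             (("bHLH", "dna_binding", 190, 260),)),
    GeneSpec("PTPRG", "chr1", "-", 30),
    GeneSpec("PLAGL1", "chr1", "+", 6, "transcription_factor",
             (("DBD", "dna_binding", 10, 180),)),
    GeneSpec("FOS", "chr1", "-", 4, "transcription_factor",
             (("bZIP", "dna_binding", 20, 100),)),
    GeneSpec("PDZD2", "chr1", "+", 12, coding_overrides={5: 121, 6: 119}),
    GeneSpec("KIF13A", "chr1", "-", 20, coding_overrides={10: 121, 11: 119}),
    # 3' partners (chr3)
    GeneSpec("NTRK1", "chr3", "+", 17, "protein_kinase",
             (("kinase", "kinase", 510, 660),)),
    GeneSpec("ALK", "chr3", "-", 29, "protein_kinase",
             (("kinase", "kinase", 900, 1120),)),
    GeneSpec("RET", "chr3", "+", 20, "protein_kinase",
             (("kinase", "kinase", 620, 780),)),
    GeneSpec("ROS1", "chr3", "-", 35, "protein_kinase",
             (("kinase", "kinase", 1250, 1390),)),
    GeneSpec("NUTM1", "chr3", "+", 7),
    GeneSpec("NCOA3", "chr3", "-", 20, "transcription_factor",
             (("AD", "transactivation", 600, 760),)),
    GeneSpec("PDGFB", "chr3", "+", 7),
    GeneSpec("FLI1", "chr3", "-", 9, "transcription_factor",
             (("ETS", "dna_binding", 280, 360),)),
    GeneSpec("PHF1", "chr3", "+", 10),
    GeneSpec("MUSK", "chr3", "-", 14, "protein_kinase",
             (("kinase", "kinase", 420, 540),), utr5_nt=60),
    GeneSpec("WT1", "chr3", "+", 10, "transcription_factor",
             (("ZF", "dna_binding", 320, 400),)),
    GeneSpec("NRG1", "chr3", "-", 10),
    GeneSpec("SSX1", "chr3", "+", 5),
    GeneSpec("SSX2", "chr3", "-", 5),
    GeneSpec("RAF1", "chr3", "-", 18, "protein_kinase",
             (("kinase", "kinase", 349, 609),)),
    GeneSpec("NFATC2", "chr3", "+", 10, "transcription_factor",
             (("RHD", "dna_binding", 250, 350),)),
    GeneSpec("NCOA2", "chr3", "-", 20, "transcription_factor",
             (("AD", "transactivation", 600, 760),)),
    GeneSpec("STAT6", "chr3", "+", 16, "transcription_factor",
             (("DBD", "dna_binding", 270, 390),)),
    GeneSpec("FEV", "chr3", "-", 3, "transcription_factor",
             (("ETS", "dna_binding", 45, 110),)),
    GeneSpec("CREB3L2", "chr3", "+", 12, "transcription_factor",
             (("bZIP", "dna_binding", 290, 350),)),
    GeneSpec("FOXO1", "chr3", "-", 5, "transcription_factor",
             (("AD", "transactivation", 120, 190),)),
    GeneSpec("MET", "chr3", "+", 21, "protein_kinase",
             (("kinase", "kinase", 680, 810),)),
    GeneSpec("DUX4", "chr3", "-", 3),
    GeneSpec("CREM", "chr3", "+", 8),
    GeneSpec("NR4A3", "chr3", "-", 8, "transcription_factor",
             (("DBD", "dna_binding", 180, 260),)),
    GeneSpec("ERG", "chr3", "+", 11, "transcription_factor",
             (("ETS", "dna_binding", 290, 370),)),
    GeneSpec("KLF14", "chr3", "-", 3, "transcription_factor",
             (("ZF", "dna_binding", 70, 110),)),
    GeneSpec("ASPSCR1", "chr3", "+", 13),
    GeneSpec("GLI1", "chr3", "-", 12, "transcription_factor",
             (("ZF", "dna_binding", 240, 360),)),
    GeneSpec("GREB1", "chr3", "+", 20),
    GeneSpec("AKT2", "chr3", "-", 13, "protein_kinase",
             (("kinase", "kinase", 152, 409),)),
    GeneSpec("PIK3CA", "chr3", "+", 21, "protein_kinase",
             (("kinase", "kinase", 700, 830),)),
    # artifact-decoy geometry (chr2): AZGP1/GJC3 are collinear adjacent
    # same-strand genes (read-through); PEX26/TUBA8 sit < 1 Mbp apart on
    # opposite strands (breakpoint proximity).
    GeneSpec("AZGP1", "chr2", "+", 4),
    GeneSpec("GJC3", "chr2", "+", 2),
    GeneSpec("PEX26", "chr2", "+", 6),
    GeneSpec("TUBA8", "chr2", "-", 4, gap_before=300_000),
)


@dataclass
class FixtureSpec:
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES
    exon_len: int = DEFAULT_EXON_LEN
    intron_len: int = DEFAULT_INTRON_LEN
    spacing: int = DEFAULT_SPACING


@dataclass
class GeneStructure:
    """Resolved genomic layout of one fixture gene."""

    spec: GeneSpec
    start: int
    end: int
    # (g_start, g_end) per exon, transcription order
    exons: list[tuple[int, int]]
    # (g_start, g_end) per coding exon, transcription order
    cds: list[tuple[int, int]]

    def exon_end_tx(self, k: int) -> int:
        """Genomic coordinate of the transcription-order end of exon k."""
        s, e = self.exons[k - 1]
        return e if self.spec.strand == "+" else s

    def exon_start_tx(self, k: int) -> int:
        s, e = self.exons[k - 1]
        return s if self.spec.strand == "+" else e

    def intron_mid_after(self, k: int) -> int:
        """A genomic position in the middle of the intron after exon k."""
        if self.spec.strand == "+":
            return self.exons[k - 1][1] + (self.exons[k][0] - self.exons[k - 1][1]) // 2
        return self.exons[k - 1][0] - (self.exons[k - 1][0] - self.exons[k][1]) // 2


def build_gene_structures(spec: FixtureSpec | None = None) -> dict[str, GeneStructure]:
    spec = spec or FixtureSpec()
    cursors: dict[str, int] = {}
    structures: dict[str, GeneStructure] = {}
    for gs in spec.genes:
        if gs.symbol in structures:
            raise ValueError(f"duplicate fixture gene {gs.symbol}")
        exon_lens = []
        for i in range(1, gs.n_exons + 1):
            length = gs.coding_overrides.get(i, spec.exon_len)
            if i == 1:
                length += gs.utr5_nt
            if length < 1:
                raise ValueError(f"{gs.symbol}: exon {i} has length < 1")
            exon_lens.append(length)
        span = sum(exon_lens) + (gs.n_exons - 1) * spec.intron_len
        if gs.chrom not in cursors:
            gstart = ORIGIN
        else:
            gstart = cursors[gs.chrom] + (
                gs.gap_before if gs.gap_before is not None else spec.spacing
            )
        gend = gstart + span - 1
        cursors[gs.chrom] = gend

        # genomic left-to-right exon layout; transcription order depends on strand
        genomic = []
        pos = gstart
        lens_lr = exon_lens if gs.strand == "+" else exon_lens[::-1]
        for length in lens_lr:
            genomic.append((pos, pos + length - 1))
            pos += length + spec.intron_len
        exons_tx = genomic if gs.strand == "+" else genomic[::-1]

        cds = []
        for i, (s, e) in enumerate(exons_tx, start=1):
            coding = gs.coding_overrides.get(i, spec.exon_len)
            if coding == 0:
                continue
            utr = gs.utr5_nt if i == 1 else 0
            if gs.strand == "+":
                cds.append((s + utr, e))
            else:
                cds.append((s, e - utr))
        structures[gs.symbol] = GeneStructure(
            spec=gs, start=gstart, end=gend, exons=exons_tx, cds=cds
        )
    return structures


def _gtf_attrs(**kv) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def build_fixture_annotation(
    outdir, spec: FixtureSpec | None = None, verify: bool = True
) -> tuple[Path, Path]:
    """Write the fixture GTF + domain table; returns their paths.

    With ``verify=True`` (default) the written annotation is re-loaded
    and the documented frame/domain outcomes of the reference fusions
    are re-derived from it; a construction error raises instead of
    silently producing a fixture that contradicts its own documentation.
    """
    spec = spec or FixtureSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structures = build_gene_structures(spec)

    gtf_path = outdir / "fixture_annotation.gtf"
    lines = ["##description: synthetic mini-annotation for fusion-triage fixtures"]
    for sym in sorted(structures, key=lambda s: (structures[s].spec.chrom,
                                                 structures[s].start)):
        st = structures[sym]
        gs = st.spec
        tid = f"{sym}-201"
        base = [gs.chrom, "fixture"]
        lines.append("\t".join(
            base + ["gene", str(st.start), str(st.end), ".", gs.strand, ".",
                    _gtf_attrs(gene_id=sym, gene_name=sym, gene_class=gs.gene_class)]
        ))
        lines.append("\t".join(
            base + ["transcript", str(st.start), str(st.end), ".", gs.strand, ".",
                    _gtf_attrs(gene_id=sym, transcript_id=tid, gene_name=sym)]
        ))
        for i, (s, e) in enumerate(st.exons, start=1):
            lines.append("\t".join(
                base + ["exon", str(s), str(e), ".", gs.strand, ".",
                        _gtf_attrs(gene_id=sym, transcript_id=tid,
                                   exon_number=i)]
            ))
        for s, e in st.cds:
            lines.append("\t".join(
                base + ["CDS", str(s), str(e), ".", gs.strand, "0",
                        _gtf_attrs(gene_id=sym, transcript_id=tid)]
            ))
    gtf_path.write_text("\n".join(lines) + "\n")

    domain_path = outdir / "fixture_domains.tsv"
    rows = [
        {"gene": gs.symbol, "name": name, "category": cat,
         "aa_start": a, "aa_end": b}
        for gs in spec.genes
        for name, cat, a, b in gs.domains
    ]
    pd.DataFrame(
        rows, columns=["gene", "name", "category", "aa_start", "aa_end"]
    ).to_csv(domain_path, sep="\t", index=False)

    if verify and spec.genes is DEFAULT_GENES:
        _verify_reference_outcomes(load_annotation(gtf_path, domain_path))
    return gtf_path, domain_path


# --------------------------------------------------------------------------
# Reference cohort
# --------------------------------------------------------------------------

# Per-pair breakpoint exons: (k5, k3, mode5) where the 5' breakpoint is the
# transcription-order end of exon k5 ("exon_end") or the middle of the
# intron after exon k5 ("intron_mid"); the 3' breakpoint is the start of
# exon k3.
REFERENCE_BREAKPOINTS: dict[tuple[str, str], tuple[int, int, str]] = {
    ("TPM3", "NTRK1"): (7, 9, "exon_end"),
    ("EML4", "ALK"): (13, 20, "exon_end"),
    ("KIF5B", "RET"): (15, 12, "exon_end"),
    ("SLC34A2", "ROS1"): (4, 32, "exon_end"),
    ("BRD4", "NUTM1"): (11, 2, "exon_end"),
    ("WHSC1L1", "NUTM1"): (7, 2, "exon_end"),
    ("ESR1", "NCOA3"): (4, 10, "exon_end"),
    ("COL1A1", "PDGFB"): (7, 2, "exon_end"),
    ("EWSR1", "FLI1"): (7, 6, "exon_end"),
    ("JAZF1", "PHF1"): (3, 2, "exon_end"),
    ("ZNF462", "MUSK"): (1, 1, "exon_end"),  # UTR-to-UTR: promoter swap
    ("EWSR1", "WT1"): (7, 8, "exon_end"),
    ("LSM1", "NRG1"): (4, 3, "exon_end"),
    ("SS18", "SSX2"): (10, 2, "exon_end"),
    ("APPL2", "RAF1"): (15, 7, "exon_end"),
    ("FUS", "NFATC2"): (6, 3, "exon_end"),
    ("MAZ", "NCOA2"): (4, 10, "exon_end"),
    ("SS18", "SSX1"): (10, 2, "exon_end"),
    ("NAB2", "STAT6"): (6, 2, "exon_end"),
    ("HEY1", "NCOA2"): (3, 10, "exon_end"),
    ("EWSR1", "FEV"): (7, 1, "exon_end"),
    ("FUS", "CREB3L2"): (6, 5, "exon_end"),
    ("PAX3", "FOXO1"): (7, 2, "exon_end"),
    ("CAPZA2", "MET"): (5, 14, "exon_end"),
    ("CIC", "DUX4"): (15, 1, "exon_end"),
    ("EWSR1", "CREM"): (7, 2, "exon_end"),
    ("EWSR1", "NR4A3"): (7, 3, "exon_end"),
    ("FUS", "ERG"): (6, 6, "exon_end"),
    ("SS18", "KLF14"): (10, 1, "exon_end"),
    ("TAF15", "NR4A3"): (6, 3, "exon_end"),
    ("TFE3", "ASPSCR1"): (8, 6, "exon_end"),
    ("PTPRG", "RAF1"): (13, 7, "exon_end"),
    ("PLAGL1", "FOXO1"): (5, 2, "exon_end"),
    ("FOS", "GLI1"): (3, 6, "exon_end"),
    # passenger cases
    ("SS18", "GREB1"): (2, 3, "exon_end"),     # QPGY domain lost
    ("PDZD2", "AKT2"): (5, 2, "intron_mid"),   # intronic, out-of-frame
    ("KIF13A", "PIK3CA"): (10, 3, "exon_end"),  # out-of-frame
    # artifact decoys
    ("AZGP1", "GJC3"): (2, 1, "exon_end"),
    ("PEX26", "TUBA8"): (3, 2, "exon_end"),
    ("TPM3", "AKT2"): (7, 2, "exon_end"),      # mispriming-flagged decoy
}

# Novel fusions with their reported unique split-fragment / discordant-mate
# counts, in sample order.
NOVEL_FUSIONS: tuple[tuple[str, str, str, int, int], ...] = (
    ("AF0033", "PLAGL1", "FOXO1", 175, 0),
    ("AF0062", "PTPRG", "RAF1", 87, 5),
    ("AF0111", "FOS", "GLI1", 110, 0),
    ("AF0112", "MAZ", "NCOA2", 97, 0),
    ("AF0140", "SS18", "KLF14", 151, 21),
    ("AF0171", "ZNF462", "MUSK", 37, 3),
    ("AF0197", "LSM1", "NRG1", 11, 0),
    ("AF0216", "APPL2", "RAF1", 87, 5),
)

NOVEL_PAIRS = {(g5, g3) for _, g5, g3, _, _ in NOVEL_FUSIONS}

# Previously reported pairs (curated-database tier); ESR1-NCOA3 is known
# only from the literature tier, so the database lookup misses it.
KNOWN_DB_PAIRS: tuple[tuple[str, str], ...] = (
    ("TPM3", "NTRK1"), ("EML4", "ALK"), ("KIF5B", "RET"), ("SLC34A2", "ROS1"),
    ("BRD4", "NUTM1"), ("WHSC1L1", "NUTM1"), ("COL1A1", "PDGFB"),
    ("EWSR1", "FLI1"), ("JAZF1", "PHF1"), ("EWSR1", "WT1"), ("SS18", "SSX2"),
    ("FUS", "NFATC2"), ("SS18", "SSX1"), ("NAB2", "STAT6"), ("HEY1", "NCOA2"),
    ("EWSR1", "FEV"), ("FUS", "CREB3L2"), ("PAX3", "FOXO1"), ("CAPZA2", "MET"),
    ("CIC", "DUX4"), ("EWSR1", "CREM"), ("EWSR1", "NR4A3"), ("FUS", "ERG"),
    ("TAF15", "NR4A3"), ("TFE3", "ASPSCR1"),
)

LITERATURE_PAIRS: tuple[tuple[str, str], ...] = (("ESR1", "NCOA3"),)

# Table-1 structure: group -> (n_patients, [(gene5, gene3, n_samples), ...])
GROUP_SIZES = {1: 9, 2: 3, 3: 4, 4: 3, 5: 13, 6: 56, 7: 42, 8: 9, 9: 11,
               10: 5, 11: 4, 12: 1, 13: 1, 14: 4}

GROUP_LABELS = {
    1: "Adenocarcinoma",
    2: "Carcinoma, a known lineage",
    3: "Carcinoma, a known fusion",
    4: "Carcinoma, unknown lineage; undifferentiated carcinoma",
    5: "Uterine malignancy",
    6: "Sarcoma, unknown lineage; undifferentiated sarcoma",
    7: "Sarcoma, known fusion",
    8: "Sarcoma, myogenic lineage without known fusion",
    9: "Sarcoma, fibroblastic lineage without known fusion",
    10: "Sarcoma, neurogenic lineage without known fusion",
    11: "Sarcoma, chondroid or bone lineage without known fusion",
    12: "Sarcoma, lipogenic lineage without known fusion",
    13: "Sarcoma, vascular or perivascular lineage without known fusion",
    14: "Other malignancy",
}

# Positive samples per group; named samples keep their study identifiers,
# the rest receive deterministic AF5xx identifiers at build time.
GROUP_FUSIONS: dict[int, list[tuple[str, str, int]]] = {
    1: [("TPM3", "NTRK1", 2), ("EML4", "ALK", 1), ("KIF5B", "RET", 1),
        ("SLC34A2", "ROS1", 1)],
    3: [("BRD4", "NUTM1", 2), ("WHSC1L1", "NUTM1", 1)],
    5: [("ESR1", "NCOA3", 2)],
    6: [("COL1A1", "PDGFB", 2), ("EWSR1", "FLI1", 2), ("JAZF1", "PHF1", 1),
        ("BRD4", "NUTM1", 1), ("ZNF462", "MUSK", 1), ("EWSR1", "WT1", 1),
        ("LSM1", "NRG1", 1), ("SS18", "SSX2", 1), ("APPL2", "RAF1", 1),
        ("FUS", "NFATC2", 1), ("MAZ", "NCOA2", 1)],
    7: [("SS18", "SSX1", 6), ("COL1A1", "PDGFB", 4), ("NAB2", "STAT6", 4),
        ("EWSR1", "FLI1", 3), ("HEY1", "NCOA2", 3), ("EWSR1", "FEV", 2),
        ("FUS", "CREB3L2", 2), ("PAX3", "FOXO1", 2), ("SS18", "SSX2", 2),
        ("CAPZA2", "MET", 1), ("CIC", "DUX4", 1), ("EWSR1", "CREM", 1),
        ("EWSR1", "NR4A3", 1), ("EWSR1", "WT1", 1), ("FUS", "ERG", 1),
        ("SS18", "KLF14", 1), ("TAF15", "NR4A3", 1), ("TFE3", "ASPSCR1", 1)],
    9: [("COL1A1", "PDGFB", 2), ("BRD4", "NUTM1", 1)],
    10: [("PTPRG", "RAF1", 1), ("SS18", "SSX2", 1), ("FOS", "GLI1", 1)],
    11: [("HEY1", "NCOA2", 1)],
    14: [("PLAGL1", "FOXO1", 1)],
}

# study identifiers for the narratively described samples
NAMED_SAMPLES: dict[tuple[str, str], list[tuple[str, int]]] = {
    ("PLAGL1", "FOXO1"): [("AF0033", 14)],
    ("PTPRG", "RAF1"): [("AF0062", 10)],
    ("FOS", "GLI1"): [("AF0111", 10)],
    ("MAZ", "NCOA2"): [("AF0112", 6)],
    ("SS18", "KLF14"): [("AF0140", 7)],
    ("ZNF462", "MUSK"): [("AF0171", 6)],
    ("LSM1", "NRG1"): [("AF0197", 6)],
    ("APPL2", "RAF1"): [("AF0216", 6)],
    ("SS18", "SSX1"): [("AF0052", 7)],
    ("BRD4", "NUTM1"): [("AF0065", 3)],
    ("CIC", "DUX4"): [("AF0154", 7)],
}

# passenger cases: (sample_id, group, gene5, gene3, split, discordant)
PASSENGER_CASES = (
    ("AF0050", 5, "SS18", "GREB1", 45, 2),
    ("AF0162", 5, "PDZD2", "AKT2", 4, 0),
    ("AF0201", 2, "KIF13A", "PIK3CA", 30, 1),
)

# sequencing failures: (group, unique_reads)
QC_FAILURES = ((1, 3), (6, 0), (6, 7), (8, 9), (9, 5))

_SUPPORT_SEED = 220810  # fixed: the reference cohort is fully deterministic


@dataclass
class ReferenceCohort:
    calls: list[FusionCall]
    samples: list[SampleMeta]
    db: KnownFusionDB


def fixture_breakpoints(
    gene5: str, gene3: str, structures: dict[str, GeneStructure] | None = None
) -> tuple[str, int, str, int]:
    """(chrom5, pos5, chrom3, pos3) for a fixture gene pair."""
    structures = structures or build_gene_structures()
    k5, k3, mode5 = REFERENCE_BREAKPOINTS[(gene5, gene3)]
    st5, st3 = structures[gene5], structures[gene3]
    pos5 = st5.intron_mid_after(k5) if mode5 == "intron_mid" else st5.exon_end_tx(k5)
    pos3 = st3.exon_start_tx(k3)
    return st5.spec.chrom, pos5, st3.spec.chrom, pos3


def build_reference_cohort() -> ReferenceCohort:
    """Deterministic reference cohort: calls, sample sheet and known DB.

    Support counts for the novel fusions and the passenger cases are the
    reported values; recurrent known fusions draw their support from a
    fixed-seed uniform [20, 200] split / [0, 30] discordant distribution
    (any value clearing the support screen is equivalent).
    """
    structures = build_gene_structures()
    rng = np.random.default_rng(_SUPPORT_SEED)

    novel_support = {(g5, g3): (s, d) for _, g5, g3, s, d in NOVEL_FUSIONS}
    named = {pair: list(ids) for pair, ids in NAMED_SAMPLES.items()}

    calls: list[FusionCall] = []
    samples: list[SampleMeta] = []
    filler = iter(f"AF5{i:02d}" for i in range(100))

    def add_call(sample_id, gene5, gene3, split, disc, flags=frozenset()):
        chrom5, pos5, chrom3, pos3 = fixture_breakpoints(gene5, gene3, structures)
        calls.append(FusionCall(
            sample_id=sample_id, gene5=gene5, gene3=gene3,
            chrom5=chrom5, pos5=pos5, chrom3=chrom3, pos3=pos3,
            support=SupportEvidence(split_reads=split, discordant_mates=disc),
            caller="archer", flags=flags,
        ))

    # fusion-positive samples, in table order
    for group in sorted(GROUP_FUSIONS):
        for gene5, gene3, n in GROUP_FUSIONS[group]:
            for _ in range(n):
                pool = named.get((gene5, gene3), [])
                use_named = next(
                    (i for i, (_, g) in enumerate(pool) if g == group), None
                )
                if use_named is not None:
                    sample_id = pool.pop(use_named)[0]
                else:
                    sample_id = next(filler)
                if (gene5, gene3) in novel_support:
                    split, disc = novel_support[(gene5, gene3)]
                else:
                    split = int(rng.integers(20, 201))
                    disc = int(rng.integers(0, 31))
                add_call(sample_id, gene5, gene3, split, disc)
                samples.append(SampleMeta(
                    sample_id=sample_id, group_id=group,
                    group_label=GROUP_LABELS[group],
                    diagnosis=GROUP_LABELS[group], unique_reads=5000,
                ))

    # passenger-only samples (detected pre-filter, excluded post-filter)
    for sample_id, group, gene5, gene3, split, disc in PASSENGER_CASES:
        add_call(sample_id, gene5, gene3, split, disc)
        samples.append(SampleMeta(
            sample_id=sample_id, group_id=group, group_label=GROUP_LABELS[group],
            diagnosis=GROUP_LABELS[group], unique_reads=5000,
        ))

    # sequencing failures
    for i, (group, unique_reads) in enumerate(QC_FAILURES):
        samples.append(SampleMeta(
            sample_id=f"AF9{i:02d}", group_id=group,
            group_label=GROUP_LABELS[group], diagnosis=GROUP_LABELS[group],
            unique_reads=unique_reads,
        ))

    # fusion-negative filler samples up to the per-group patient counts
    neg = iter(f"AF8{i:02d}" for i in range(120))
    negatives: list[str] = []
    for group in sorted(GROUP_SIZES):
        have = sum(1 for s in samples if s.group_id == group)
        for _ in range(GROUP_SIZES[group] - have):
            sample_id = next(neg)
            negatives.append(sample_id)
            samples.append(SampleMeta(
                sample_id=sample_id, group_id=group,
                group_label=GROUP_LABELS[group], diagnosis=GROUP_LABELS[group],
                unique_reads=5000,
            ))

    # artifact decoys in three fusion-negative samples: the screen must
    # remove them without making their samples count as detections
    add_call(negatives[0], "AZGP1", "GJC3", 28, 2)              # read-through
    add_call(negatives[1], "PEX26", "TUBA8", 55, 4)             # proximity
    add_call(negatives[2], "TPM3", "AKT2", 35, 1,
             flags=frozenset({"mispriming"}))                   # mispriming

    db_entries = set()
    db_sources = ("quiver", "chimerdb", "oncokb")
    for i, (g5, g3) in enumerate(KNOWN_DB_PAIRS):
        db_entries.add((g5, g3, db_sources[i % 3]))
    for g5, g3 in LITERATURE_PAIRS:
        db_entries.add((g5, g3, "literature"))
    # a couple of curated pairs the cohort never shows, as in any real DB
    db_entries.update({("ETV6", "NTRK3", "quiver"), ("CD74", "ROS1", "oncokb")})

    assert len(samples) == sum(GROUP_SIZES.values())
    return ReferenceCohort(calls=calls, samples=samples, db=KnownFusionDB(db_entries))


def write_reference_cohort(outdir) -> dict[str, Path]:
    """Write the full reference fixture (annotation + cohort) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf, domains = build_fixture_annotation(outdir)
    cohort = build_reference_cohort()
    paths = {
        "gtf": gtf,
        "domains": domains,
        "calls": outdir / "calls.tsv",
        "samples": outdir / "samples.tsv",
        "known_db": outdir / "known_db.tsv",
    }
    write_calls(cohort.calls, paths["calls"])
    write_samples(cohort.samples, paths["samples"])
    write_known_db(cohort.db, paths["known_db"])
    return paths


def _verify_reference_outcomes(annotation: GenomeAnnotation) -> None:
    """Assert the documented frame/domain outcomes hold in the built fixture."""
    from .chimera import build_junction, domain_retention

    def junction(gene5, gene3):
        chrom5, pos5, chrom3, pos3 = fixture_breakpoints(gene5, gene3)
        call = FusionCall(
            sample_id="check", gene5=gene5, gene3=gene3, chrom5=chrom5,
            pos5=pos5, chrom3=chrom3, pos3=pos3,
            support=SupportEvidence(split_reads=50, discordant_mates=5),
        )
        return build_junction(call, annotation)

    j = junction("PTPRG", "RAF1")
    assert j.frame == "in_frame", "PTPRG-RAF1 must be in-frame"
    kinase = [d for d in domain_retention(j, annotation)
              if d.domain.gene_symbol == "RAF1"]
    assert kinase and all(d.status == "intact" for d in kinase), \
        "RAF1 kinase domain must be intact"
    assert junction("KIF13A", "PIK3CA").frame == "out_of_frame"
    assert junction("PDZD2", "AKT2").frame == "out_of_frame"
    assert junction("ZNF462", "MUSK").frame == "promoter_swap"
    j = junction("SS18", "GREB1")
    assert j.frame == "in_frame"
    qpgy = [d for d in domain_retention(j, annotation) if d.domain.name == "QPGY"]
    assert qpgy and qpgy[0].status == "lost", "SS18 QPGY domain must be lost"


# --------------------------------------------------------------------------
# Randomized cohorts with planted ground truth
# --------------------------------------------------------------------------

PLANTED_CLASSES = (
    "artifact_readthrough", "artifact_proximity", "passenger_low_support",
    "passenger_frame", "passenger_domain", "known", "novel",
)

# planted class -> expected cascade class
EXPECTED_CLASS = {
    "artifact_readthrough": "artifact",
    "artifact_proximity": "artifact",
    "passenger_low_support": "passenger",
    "passenger_frame": "passenger",
    "passenger_domain": "passenger",
    "known": "known_oncogenic",
    "novel": "novel_candidate",
}


@dataclass
class CohortSpec:
    n_calls: int = 500
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "artifact_readthrough": 0.1, "artifact_proximity": 0.1,
        "passenger_low_support": 0.15, "passenger_frame": 0.15,
        "passenger_domain": 0.1, "known": 0.25, "novel": 0.15,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("n_calls must be >= 1")
        unknown = set(self.class_mix) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class-mix proportions sum to {total}, expected 1")


@dataclass
class SimulatedCohort:
    calls: list[FusionCall]
    samples: list[SampleMeta]
    truth: pd.DataFrame  # columns: sample_id, gene5, gene3, planted_class


def simulate_cohort(spec: CohortSpec | None = None) -> SimulatedCohort:
    """One call per synthetic sample, each realizing its planted class.

    Identical specs (including seed) produce byte-identical TSVs when
    written with the ``write_*`` helpers.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    structures = build_gene_structures()

    known_pairs = list(KNOWN_DB_PAIRS)
    novel_pairs = sorted(NOVEL_PAIRS)

    def high_support():
        return int(rng.integers(20, 201)), int(rng.integers(0, 31))

    calls, samples, truth_rows = [], [], []
    labels = rng.choice(
        list(spec.class_mix), size=spec.n_calls, p=list(spec.class_mix.values())
    )
    for i, label in enumerate(labels):
        sample_id = f"S{i:04d}"
        flags = frozenset()
        if label == "artifact_readthrough":
            gene5, gene3 = "AZGP1", "GJC3"
            split, disc = high_support()
        elif label == "artifact_proximity":
            gene5, gene3 = "PEX26", "TUBA8"
            split, disc = high_support()
        elif label == "passenger_low_support":
            gene5, gene3 = known_pairs[int(rng.integers(len(known_pairs)))]
            split, disc = int(rng.integers(0, 10)), 0
        elif label == "passenger_frame":
            gene5, gene3 = "KIF13A", "PIK3CA"
            split, disc = high_support()
        elif label == "passenger_domain":
            gene5, gene3 = "SS18", "GREB1"
            split, disc = high_support()
        elif label == "known":
            gene5, gene3 = known_pairs[int(rng.integers(len(known_pairs)))]
            split, disc = high_support()
        else:  # novel
            gene5, gene3 = novel_pairs[int(rng.integers(len(novel_pairs)))]
            split, disc = high_support()
        chrom5, pos5, chrom3, pos3 = fixture_breakpoints(gene5, gene3, structures)
        calls.append(FusionCall(
            sample_id=sample_id, gene5=gene5, gene3=gene3,
            chrom5=chrom5, pos5=pos5, chrom3=chrom3, pos3=pos3,
            support=SupportEvidence(split_reads=split, discordant_mates=disc),
            flags=flags,
        ))
        samples.append(SampleMeta(
            sample_id=sample_id, group_id=int(rng.integers(1, 15)),
            unique_reads=5000,
        ))
        truth_rows.append({"sample_id": sample_id, "gene5": gene5,
                           "gene3": gene3, "planted_class": label})
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "gene5", "gene3", "planted_class"]
    )
    return SimulatedCohort(calls=calls, samples=samples, truth=truth)


def write_simulated_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / "calls.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_calls(cohort.calls, paths["calls"])
    write_samples(cohort.samples, paths["samples"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_reads(n_raw: int, n_unique: int, seed: int = 0) -> list[ReadRecord]:
    """``n_raw`` junction-spanning reads over exactly ``n_unique`` UMIs.

    Deduplication by molecular barcode recovers ``n_unique`` exactly:
    each UMI tags at least one read, and reads sharing a UMI are PCR
    duplicates of one fragment.
    """
    if not 1 <= n_unique <= n_raw:
        raise ValueError("need 1 <= n_unique <= n_raw")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    umis: set[str] = set()
    while len(umis) < n_unique:
        umis.add("".join(rng.choice(alphabet, size=10)))
    umi_list = sorted(umis)
    assignments = umi_list + [
        umi_list[int(rng.integers(n_unique))] for _ in range(n_raw - n_unique)
    ]
    return [
        ReadRecord(read_id=f"read{i:05d}", umi=umi, junction_spanning=True)
        for i, umi in enumerate(assignments)
    ]
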