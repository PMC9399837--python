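"""Transcript annotation model and strand-aware coordinate arithmetic.

Loads a GTF (gene/transcript/exon/CDS features, Ensembl-style attributes)
plus a protein-domain table, and answers the one question the downstream
frame logic needs: *how many coding nucleotides of a gene lie on the
retained side of a genomic breakpoint?*

Coordinate conventions
----------------------
* GTF convention throughout: 1-based, inclusive on both ends.
* A 5'-partner breakpoint is the **last retained base** of the upstream
  gene; a 3'-partner breakpoint is the **first retained base** of the
  downstream gene.  These match how exon-junction fusion calls are
  reported by Archer-style pipelines and make exon-boundary arithmetic
  exact.
* Intronic breakpoints snap to the nearest retained exon boundary (end
  of the preceding exon on the 5' side, start of the following exon on
  the 3' side), mirroring the spliced fusion transcript; the
  ``in_intron`` flag is preserved for reporting.
* One canonical transcript per gene (longest CDS, transcript_id as the
  deterministic tie-break).  CDS features are taken to exclude the stop
  codon (Ensembl convention), so protein length = CDS length / 3 and
  ``floor(coding_nt / 3)`` is a residue count.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import gffutils
import pandas as pd

GENE_CLASSES = ("protein_kinase", "transcription_factor", "other")
DOMAIN_CATEGORIES = ("kinase", "transactivation", "dna_binding", "other")


class AnnotationError(Exception):
    """Base class for annotation loading/validation failures."""


class GTFParseError(AnnotationError):
    """A GTF line could not be parsed; message names the line number."""


class PositionError(AnnotationError):
    """A genomic position falls outside the queried gene's span."""


class UnknownGeneError(AnnotationError, KeyError):
    """A gene symbol does not resolve in the annotation."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return Exception.__str__(self)


@dataclass(frozen=True)
class Exon:
    """One exon; ``number`` is the 1-based ordinal in transcription order."""

    number: int
    g_start: int
    g_end: int

    @property
    def length(self) -> int:
        return self.g_end - self.g_start + 1


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_class: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.symbol}: strand must be + or -")
        if self.start > self.end:
            raise AnnotationError(f"gene {self.symbol}: start > end")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(
                f"gene {self.symbol}: gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )


@dataclass
class Transcript:
    """A transcript with exons in transcription (5'→3') order.

    ``cds_segments`` are genomic (start, end) intervals, also in
    transcription order; empty when the transcript is non-coding.
    """

    transcript_id: str
    gene: Gene
    exons: list[Exon]
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    # Derived, filled by _finalize()
    _cum: list[int] = field(default_factory=list, repr=False)
    cds_tx_start: int = -1
    cds_len: int = 0

    @property
    def cds_present(self) -> bool:
        return bool(self.cds_segments)

    @property
    def cds_start_offset(self) -> int:
        """0-based transcript offset of the first coding base (−1 if non-coding)."""
        return self.cds_tx_start

    def _finalize(self) -> None:
        self._validate_exons()
        # cumulative exon lengths: _cum[i] = transcript offset of exon i's first base
        self._cum = [0]
        for ex in self.exons:
            self._cum.append(self._cum[-1] + ex.length)
        if self.cds_segments:
            tx_positions = sorted(
                self.tx_coord(s) for seg in self.cds_segments for s in seg
            )
            self.cds_len = sum(e - s + 1 for s, e in self.cds_segments)
            self.cds_tx_start = tx_positions[0]
            if tx_positions[-1] - tx_positions[0] + 1 != self.cds_len:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS is not contiguous "
                    "in transcript coordinates"
                )

    def _validate_exons(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        for i, ex in enumerate(self.exons, start=1):
            if ex.number != i:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon ordinals not consecutive"
                )
        # non-overlapping and 5'→3' (genomically descending on the - strand)
        for a, b in zip(self.exons, self.exons[1:]):
            ok = b.g_start > a.g_end if self.gene.strand == "+" else b.g_end < a.g_start
            if not ok:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are not "
                    "in transcription order"
                )

    @property
    def length(self) -> int:
        return self._cum[-1]

    def exon_index_at(self, gpos: int) -> int | None:
        """0-based index of the exon containing gpos, or None if intronic."""
        for i, ex in enumerate(self.exons):
            if ex.g_start <= gpos <= ex.g_end:
                return i
        return None

    def tx_coord(self, gpos: int) -> int:
        """0-based transcript coordinate of an exonic genomic position."""
        i = self.exon_index_at(gpos)
        if i is None:
            raise PositionError(
                f"position {gpos} is not exonic in transcript {self.transcript_id}"
            )
        ex = self.exons[i]
        within = gpos - ex.g_start if self.gene.strand == "+" else ex.g_end - gpos
        return self._cum[i] + within


@dataclass(frozen=True)
class ProteinDomain:
    gene_symbol: str
    name: str
    category: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise AnnotationError(
                f"domain {self.name} ({self.gene_symbol}): need 1 <= aa_start <= aa_end"
            )
        if self.category not in DOMAIN_CATEGORIES:
            raise AnnotationError(
                f"domain {self.name} ({self.gene_symbol}): category "
                f"{self.category!r} not in {DOMAIN_CATEGORIES}"
            )


@dataclass(frozen=True)
class CodingOffset:
    """Result of :func:`coding_offset`.

    ``n_coding_nt`` counts coding nucleotides on the retained side of the
    breakpoint (see module docstring for the side-specific semantics).
    """

    n_coding_nt: int
    in_utr: bool = False
    in_intron: bool = False
    noncoding: bool = False


@dataclass
class GenomeAnnotation:
    """Genes indexed by symbol, transcripts by id, one canonical transcript per gene."""

    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]
    domains: list[ProteinDomain]
    canonical: dict[str, str]

    def __post_init__(self) -> None:
        for dom in self.domains:
            if dom.gene_symbol not in self.genes:
                raise AnnotationError(
                    f"domain {dom.name} references unknown gene {dom.gene_symbol}"
                )
        for sym, tid in self.canonical.items():
            if tid not in self.transcripts:
                raise AnnotationError(
                    f"canonical transcript {tid} for {sym} does not exist"
                )

    def gene(self, symbol: str) -> Gene:
        try:
            return self.genes[symbol]
        except KeyError:
            raise UnknownGeneError(f"unknown gene symbol {symbol!r}") from None

    def canonical_transcript(self, symbol: str) -> Transcript:
        self.gene(symbol)
        return self.transcripts[self.canonical[symbol]]

    def domains_for(self, symbol: str) -> list[ProteinDomain]:
        return [d for d in self.domains if d.gene_symbol == symbol]

    def protein_length(self, symbol: str) -> int:
        """Residues of the canonical protein (CDS excludes the stop codon)."""
        tx = self.canonical_transcript(symbol)
        return tx.cds_len // 3


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _prevalidate_gtf(gtf_path) -> None:
    with _open_text(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise GTFParseError(
                    f"{gtf_path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields"
                )


def load_annotation(gtf_path, domain_table_path=None) -> GenomeAnnotation:
    """Load a GTF plus an optional protein-domain TSV into a validated model.

    The GTF must carry gene/transcript/exon features (CDS optional) with
    ``gene_id``/``transcript_id`` attributes; ``gene_name`` falls back to
    ``gene_id`` and an optional ``gene_class`` attribute records the
    panel role (protein_kinase / transcription_factor / other).  Feature
    order in the file is irrelevant.  The domain table is a TSV with
    header ``gene, name, category, aa_start, aa_end``.
    """
    _prevalidate_gtf(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: dict[str, Gene] = {}
    gene_by_id: dict[str, Gene] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes["gene_id"][0]
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        gene_class = feat.attributes.get("gene_class", ["other"])[0]
        gene = Gene(
            gene_id=gene_id,
            symbol=symbol,
            chrom=feat.seqid,
            strand=feat.strand,
            start=feat.start,
            end=feat.end,
            gene_class=gene_class,
        )
        if symbol in genes:
            raise AnnotationError(f"duplicate gene symbol {symbol}")
        genes[symbol] = gene
        gene_by_id[gene_id] = gene

    transcripts: dict[str, Transcript] = {}
    for feat in db.features_of_type("transcript"):
        tid = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        if gene_id not in gene_by_id:
            raise AnnotationError(f"transcript {tid} references unknown gene {gene_id}")
        gene = gene_by_id[gene_id]

        exon_feats = sorted(
            db.children(feat, featuretype="exon"),
            key=lambda f: f.start,
            reverse=(gene.strand == "-"),
        )
        exons = [
            Exon(number=i, g_start=f.start, g_end=f.end)
            for i, f in enumerate(exon_feats, start=1)
        ]
        cds_feats = sorted(
            db.children(feat, featuretype="CDS"),
            key=lambda f: f.start,
            reverse=(gene.strand == "-"),
        )
        tx = Transcript(
            transcript_id=tid,
            gene=gene,
            exons=exons,
            cds_segments=[(f.start, f.end) for f in cds_feats],
        )
        tx._finalize()
        transcripts[tid] = tx

    canonical: dict[str, str] = {}
    for sym, gene in genes.items():
        txs = [t for t in transcripts.values() if t.gene.symbol == sym]
        if not txs:
            raise AnnotationError(f"gene {sym} has no transcript")
        best = max(txs, key=lambda t: (t.cds_len, t.length, t.transcript_id))
        canonical[sym] = best.transcript_id

    domains: list[ProteinDomain] = []
    if domain_table_path is not None:
        domains = _read_domain_table(domain_table_path)

    return GenomeAnnotation(
        genes=genes, transcripts=transcripts, domains=domains, canonical=canonical
    )


def _read_domain_table(path) -> list[ProteinDomain]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "name", "category", "aa_start", "aa_end"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(
            f"{path}: domain table missing columns {sorted(missing)}"
        )
    return [
        ProteinDomain(
            gene_symbol=row.gene,
            name=row.name_,
            category=row.category,
            aa_start=int(row.aa_start),
            aa_end=int(row.aa_end),
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def coding_offset(
    annotation: GenomeAnnotation, symbol: str, genomic_pos: int, side: str
) -> CodingOffset:
    """Coding nucleotides retained by a breakpoint at ``genomic_pos``.

    side="five_prime": the breakpoint is the last retained base of the
    gene; returns the number of coding nucleotides from the CDS start
    through the breakpoint, inclusive.

    side="three_prime": the breakpoint is the first retained base;
    returns the number of coding nucleotides strictly upstream of it
    (i.e. excluded from the chimera).

    Intronic positions snap to the nearest retained exon boundary and
    set ``in_intron``.  Positions in a UTR set ``in_utr``; a breakpoint
    upstream of the CDS yields 0 for either side.  Non-coding
    transcripts yield 0 with ``noncoding`` set.
    """
    if side not in ("five_prime", "three_prime"):
        raise ValueError(f"side must be five_prime or three_prime, got {side!r}")
    gene = annotation.gene(symbol)
    if not gene.start <= genomic_pos <= gene.end:
        raise PositionError(
            f"position {gene.chrom}:{genomic_pos} outside span of {symbol} "
            f"({gene.start}-{gene.end})"
        )
    tx = annotation.canonical_transcript(symbol)

    in_intron = False
    pos = genomic_pos
    if tx.exon_index_at(pos) is None:
        pos = _snap_intronic(tx, pos, side)
        in_intron = True
        if pos is None:
            # intronic before the first / after the last exon with nothing
            # retained on this side
            n = 0 if side == "five_prime" else 0
            return CodingOffset(n, in_utr=True, in_intron=True,
                                noncoding=not tx.cds_present)

    if not tx.cds_present:
        return CodingOffset(0, in_utr=True, in_intron=in_intron, noncoding=True)

    t = tx.tx_coord(pos)
    rel = t - tx.cds_tx_start  # 0-based offset of pos within the CDS
    if side == "five_prime":
        n = min(max(rel + 1, 0), tx.cds_len)
    else:
        n = min(max(rel, 0), tx.cds_len)
    in_utr = rel < 0 or rel >= tx.cds_len
    return CodingOffset(n, in_utr=in_utr, in_intron=in_intron)


def _snap_intronic(tx: Transcript, gpos: int, side: str) -> int | None:
    """Snap an intronic position to the retained exon boundary.

    5' side keeps the end (transcript orientation) of the preceding
    exon; 3' side keeps the start of the following exon.  Returns None
    when no exon exists on the retained side.
    """
    strand = tx.gene.strand
    # exons upstream of gpos in transcription order
    if strand == "+":
        preceding = [ex for ex in tx.exons if ex.g_end < gpos]
        following = [ex for ex in tx.exons if ex.g_start > gpos]
        if side == "five_prime":
            return preceding[-1].g_end if preceding else None
        return following[0].g_start if following else None
    preceding = [ex for ex in tx.exons if ex.g_start > gpos]
    following = [ex for ex in tx.exons if ex.g_end < gpos]
    if side == "five_prime":
        return preceding[-1].g_start if preceding else None
    return following[0].g_end if following else None
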