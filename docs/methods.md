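# Methods

This note records the model behind `fusion-triage`, the default
parameters and why they have the values they do, what the synthetic
reference cohort emulates (and deliberately does not), and the design
decisions that were genuinely open.

## Transcript model and coordinate arithmetic

The annotation layer (`fusiontriage.annotation`) loads a GTF into an
in-memory transcript model (via gffutils) plus an optional
protein-domain table (`gene, name, category, aa_start, aa_end`, 1-based
inclusive residue coordinates on the native protein).

* **Canonical transcript.** One transcript represents each gene: the
  one with the longest total CDS, tie-broken by transcript length and
  then transcript ID. All breakpoint arithmetic uses this transcript.
* **Breakpoint convention.** A 5' breakpoint is the *last retained
  base* of the 5' partner; a 3' breakpoint is the *first retained
  base* of the 3' partner. Hence the two offsets the frame rule needs:
  * `c5` — coding bases from the CDS start through the 5' breakpoint,
    inclusive;
  * `c3` — coding bases strictly upstream of the 3' breakpoint
    (i.e. excluded from the chimera).
* **Intronic breakpoints** snap to the nearest retained exon boundary:
  on the 5' side, the end of the preceding exon; on the 3' side, the
  start of the following exon. This models splicing of the chimeric
  pre-mRNA and is flagged (`in_intron`) rather than hidden.
* **CDS convention.** The CDS excludes the stop codon, so the protein
  length is `cds_len / 3`.

## Chimeric reading frame

The 3' partner is translated in its native frame iff
`(c5 − c3) ≡ 0 (mod 3)`. Special cases, in precedence order:

1. 3' partner has no CDS → `noncoding` (no chimeric protein).
2. Both breakpoints precede their CDS (`c5 = 0` in the 5' UTR, full 3'
   CDS retained) → `promoter_swap`: the intact 3' protein is produced
   from its own start codon under the 5' partner's promoter/enhancers,
   so frame is irrelevant.
3. A coding-less 5' partner joined into the middle of the 3' CDS →
   `noncoding`: with no upstream ORF there is nothing to set the frame
   of the truncated 3' protein.
4. Otherwise `in_frame` / `out_of_frame` by the congruence.

The test suite checks the congruence against a brute-force oracle that
walks both transcripts base by base and compares codon phases at the
junction, over every exon-boundary pair of the fixture annotation.

## Domain retention and the functional criterion

Retained residue intervals are `[1, ⌊c5/3⌋]` (5' protein) and
`[⌊c3/3⌋+1, L3]` (3' protein); the codon split by the junction is
attributed to neither partner. Each domain is **intact** (contained in
the retained interval), **lost** (disjoint from it), or **truncated**
(partial overlap) — a total trichotomy, with boundary equality counting
as intact.

The functional criterion asks whether the chimera keeps the domain its
driver class requires: `protein_kinase` → an intact `kinase` domain;
`transcription_factor` → an intact `transactivation` or `dna_binding`
domain. The fusion **passes** if any driver-class partner retains its
required category, **fails** if driver-class partners are annotated and
none does, and is **indeterminate_pass** when no driver-class partner
exists or the required domains are simply not annotated — absence of
annotation is not evidence of loss, so the criterion cannot exclude.
Promoter swaps always pass (the full 3' protein is retained).

## The triage cascade

Per sample: fewer than `min_sample_unique_reads` unique RNA reads →
QC `indeterminate`; such samples contribute no calls.

Per call, in order:

1. **Artifact screen** — any of: a `mispriming` flag from the upstream
   caller; a `readthrough` flag *or* read-through geometry (same
   chromosome and strand, 5' partner transcriptionally upstream,
   no intervening gene — i.e. adjacent collinear neighbours);
   same-chromosome breakpoints closer than `min_breakpoint_distance`
   (strict `<`); or, when a second caller stream is supplied and
   `require_dual_caller` is set, no concordant partner call (same
   ordered gene pair, both breakpoints within `bp_tolerance`).
   Artifacts exit immediately and never receive frame or domain labels.
2. **Passenger criteria**, all evaluated and all failures recorded:
   * `low_support` — fewer than `min_split_reads` unique split
     fragments **and** no more than `max_discordant_for_low_support`
     discordant mates. The conjunction is deliberate: either evidence
     type alone rescues a call.
   * `out_of_frame` — frame is `out_of_frame` or `noncoding`.
   * `domain_lost` — the functional criterion fails.
3. **Novelty** — surviving calls are `known_oncogenic` if the ordered
   gene pair is in the known-fusion database (any source tier),
   otherwise `novel_candidate`.

A sample is **fusion-positive** if any call is oncogenic-class;
**detected pre-filter** if any call survives QC and the artifact screen.

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| `min_split_reads` | 10 | standard targeted-panel floor for unique (UMI-deduplicated) junction fragments |
| `max_discordant_for_low_support` | 0 | any discordant mate is independent evidence; only the conjunction of few split reads *and* zero mates is "low support" |
| `min_breakpoint_distance` | 1 Mbp | same-chromosome events closer than this are overwhelmingly local artifacts or small-scale rearrangements a panel cannot adjudicate |
| `min_sample_unique_reads` | 10 | a library yielding fewer unique RNA reads cannot support a negative call |
| `bp_tolerance` | 10 | callers may place the same junction a few bases apart |
| `require_dual_caller` | true | applies only when a second stream is supplied |

### Two-tier novelty

The known-fusion database distinguishes curated database sources
(`quiver`, `chimerdb`, `oncokb`, …) from a `literature` tier of
individually reported pairs. The *unknown* inventory (pairs absent
from curated databases, taken pre-passenger-filter among non-artifact
calls) is what an automated lookup yields; removing pairs also present
in the literature tier gives the *novel pre-filter* set, and the calls
surviving the whole cascade give the *novel candidates*. Call
classification itself treats any tier as "known": a literature-reported
pair is not a novel discovery.

## Cohort summaries

Per-group detection frequency uses **all enrolled patients** as the
denominator — including samples that failed sequencing QC — and rounds
half-up to integer percent (`(200·n + d) // (2·d)`). Recurrence counts
distinct samples per ordered gene pair, sorted by descending count with
the fusion name as the deterministic tie-break. All writers produce
byte-stable output for identical inputs (fully ordered rows, sorted
JSON keys).

## The synthetic reference cohort

`fusiontriage.simulate` builds, programmatically and deterministically,
a complete desk-scale cohort: a GTF of ~60 genes with per-gene domain
tables, a 165-sample sheet across 14 diagnostic groups, a call table,
and a two-tier known-fusion database.

What it emulates:

* exon/intron structures sized so that specific, documented fusions
  realize each frame and domain outcome (in-frame kinase fusions,
  out-of-frame passengers, a UTR-to-UTR promoter swap, a
  transactivation-domain loss);
* adjacent collinear gene pairs and proximal same-chromosome pairs as
  artifact decoys, with real fusions placed on different chromosomes
  so no genuine event can trip a geometric artifact rule;
* sequencing failures (5 samples below the unique-read floor),
  passenger-only samples, and recurrent known fusions with support
  drawn from a fixed-seed distribution (any value clearing the support
  screen is equivalent).

What it does not emulate: real genomic coordinates or sequence content,
alignment-level noise, subclonal support distributions, or multiple
transcript isoforms per gene — the triage logic under test consumes
none of these.

`simulate_cohort` additionally generates randomized cohorts with a
**planted ground-truth class per call** (artifact, each passenger mode,
known, novel); the suite requires the cascade to recover the planted
class for 100% of 500 calls. `simulate_reads` generates
junction-spanning reads over an exact number of unique molecular
barcodes for dedup testing.

## Numerical and determinism choices

* All counts are integer arithmetic; the only division is the half-up
  percentage, implemented in integers to avoid float rounding.
* All randomness flows through `numpy.random.default_rng` with
  explicit seeds; the reference cohort uses one fixed seed and is
  byte-identical across rebuilds.
* `classify_cohort` sorts calls and samples internally, so results are
  independent of input row order.

## Open design decisions

* **Canonical transcript = longest CDS.** Without expression data this
  is the least surprising deterministic choice; real deployments may
  want caller-reported transcripts instead.
* **Intron snapping** to the retained-side exon boundary assumes the
  chimeric pre-mRNA splices around the breakpoint; genomic breakpoints
  that disrupt splice sites are not modelled.
* **Reason accumulation.** All passenger criteria are evaluated for
  every non-artifact call, so a call failing several is reported with
  all reasons; the cascade order affects reason codes only, never
  class membership.
* **Read-through geometry requires adjacency.** Flagging every
  collinear same-chromosome pair would swallow genuine intra-
  chromosomal fusions; the geometric rule therefore requires that no
  annotated gene lie between the partners, and flag-based exclusion
  from the upstream caller is honoured regardless.
* **`indeterminate_pass`.** The domain criterion only excludes when a
  required domain is demonstrably lost or truncated; unannotated
  domains cannot fail a call.
* **Per-sample (not per-region) QC.** The unique-read floor is applied
  per sample; per-target-region coverage is out of scope.

## Limitations

The pipeline reasons purely at the transcript-model level: it does not
re-align reads, re-assemble junction sequences, or verify breakpoint
base accuracy; it trusts the upstream caller's gene assignments and
support counts (after UMI dedup); and it classifies at the level of
ordered gene pairs, so distinct isoform-level junctions of one pair are
aggregated in the recurrence and novelty summaries.
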