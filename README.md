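# fusion-triage

Triage of gene-fusion calls from targeted RNA-seq panels: annotate
fusion breakpoints against a transcript model, decide whether the
chimeric transcript keeps a productive reading frame and the protein
domains its driver needs, screen out common panel artifacts, and roll
the per-call verdicts up into per-sample classifications and
cohort-level summaries.

## The problem

Anchored multiplex PCR panels detect gene fusions without prior
knowledge of the partner gene, which makes them attractive for tumors
of uncertain lineage — but the raw caller output mixes genuine
oncogenic drivers with read-through transcripts, mispriming artifacts,
and passenger rearrangements that cannot produce a functional fusion
protein. Telling these apart is a sequence-arithmetic problem, not a
wet-lab problem:

1. **Reading frame.** Let `c5` be the number of coding nucleotides of
   the 5' partner retained up to the breakpoint, and `c3` the number of
   coding nucleotides of the 3' partner excluded upstream of its
   breakpoint. The 3' partner is translated in its native frame iff
   `(c5 − c3) ≡ 0 (mod 3)`. A fusion whose 5' breakpoint lies upstream
   of any coding sequence while the full 3' ORF is retained is a
   *promoter swap* (enhancer hijacking) and needs no frame.
2. **Domain retention.** The retained residue intervals are
   `[1, ⌊c5/3⌋]` on the 5' protein and `[⌊c3/3⌋+1, L]` on the 3'
   protein (the codon split by the junction counts for neither).
   Each annotated domain is then *intact*, *truncated*, or *lost* — and
   a kinase-class partner must keep its kinase domain intact, a
   transcription factor its transactivation or DNA-binding domain.
3. **Artifact and support screens.** Mispriming and read-through
   events, same-chromosome breakpoints closer than 1 Mbp, calls not
   confirmed by a second caller, and calls with fewer than 10 unique
   split fragments and zero discordant mates are excluded.
4. **Novelty.** Surviving oncogenic-class calls are split into
   previously reported fusions (curated database hit) and novel
   candidates.

## Quick start

The package ships a deterministic synthetic reference cohort
(165 samples across 14 diagnostic groups, with a matching GTF,
protein-domain table and known-fusion database) so the whole pipeline
can be exercised without any external data:

```console
$ fusion-triage fixture --out fixture/
$ fusion-triage run \
    --calls fixture/calls.tsv \
    --gtf fixture/fixture_annotation.gtf \
    --domains fixture/fixture_domains.tsv \
    --db fixture/known_db.tsv \
    --samples fixture/samples.tsv \
    --out results/
INFO 165 samples (160 sequenced); 71 with detections pre-filter; 68 fusion-positive; 34 distinct fusions
```

`results/summary.json` after that run:

```json
{
  "distinct_fusion_count": 34,
  "n_detected_prefilter": 71,
  "n_enrolled": 165,
  "n_novel_candidates": 8,
  "n_novel_prefilter": 11,
  "n_positive_postfilter": 68,
  "n_samples_unknown": 13,
  "n_sequenced": 160,
  "n_unknown_fusions": 12
}
```

and the head of `results/recurrence.tsv`:

```
fusion_name     n_samples
COL1A1-PDGFB    8
SS18-SSX1       6
EWSR1-FLI1      5
BRD4-NUTM1      4
```

The same machinery is available as a library:

```python
from fusiontriage import (
    TriageConfig, build_junction, classify_call, load_annotation,
)
from fusiontriage.io import read_calls, read_known_db

annotation = load_annotation("fixture/fixture_annotation.gtf",
                             "fixture/fixture_domains.tsv")
db = read_known_db("fixture/known_db.tsv")
call = read_calls("fixture/calls.tsv")[0]

junction = build_junction(call, annotation)
print(call.name, junction.frame)          # TPM3-NTRK1 in_frame
verdict = classify_call(call, annotation, db, TriageConfig())
print(verdict.classification)             # known_oncogenic
```

Arriba `fusions.tsv` output is read directly with
`read_calls(path, dialect="arriba")`; supplying a second caller stream
to `fusion-triage run --calls2 ...` (or `classify_cohort(...,
calls2=...)`) enables the dual-caller concordance requirement.

## Testing

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracles (base-by-base codon walks for
the frame rule, exhaustive truth tables for the cascade), planted-truth
recovery on randomized cohorts, and byte-stability checks on all
written outputs. See `docs/methods.md` for the underlying model and
the rationale for every default threshold.
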