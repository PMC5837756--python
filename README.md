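# cnarec

Recurrent somatic copy-number-alteration (CNA) discovery for paired
discovery/validation tumour cohorts, built around interval-graph maximal
cliques, with downstream gene annotation, CNA–expression (eQTL)
association and disease-specific survival analysis. Because the real
cohorts such analyses run on are controlled-access, the package ships a
first-class synthetic-cohort simulator that generates every input the
pipeline consumes, so the whole method is testable end to end offline.

## Method overview

1. **Segment I/O and filtering** (`cnarec.segment_io`) — read SEG-like
   per-patient CNA calls (as produced by circular binary segmentation),
   keep segments supported by ≥ 10 probes and ≥ 1 kb, and partition them
   into young (< 45 y) / old (≥ 45 y) × gain / loss buckets.
2. **Interval-graph clique calling** (`cnarec.interval_clique`) — per
   chromosome, segments are vertices and edges connect intersecting
   intervals; all maximal cliques are enumerated with an O(n log n)
   endpoint sweep (end events before start events at equal coordinates,
   half-open semantics). A Bron–Kerbosch enumeration is kept as an
   independent oracle for testing.
3. **Recurrent regions** (`cnarec.recurrent_caller`) — each clique with
   ≥ 2 members, ≥ 5 distinct patients and a minimal common region (MCR,
   the intersection of all member intervals) of ≥ 1 kb becomes a
   recurrent region with inner (MCR) and outer (union-extent)
   coordinates. Young-specific regions are those whose inner MCR does
   not overlap any same-type old-group region; discovery regions are
   validated when their inner MCR overlaps a same-type validation-cohort
   region.
4. **Annotation** (`cnarec.gene_annotation`) — BED/GTF gene models are
   intersected with inner MCRs; regions are classed coding/non-coding,
   and a gene × patient mutation matrix ({G, L, .}) is exported for
   oncoprint-style plotting.
5. **Association** (`cnarec.association`) — per gene: logistic
   regression of binarized-by-mean expression on CNA carrier status
   (odds ratio + Wald CI + BH-adjusted q), Kaplan–Meier curves with a
   log-rank test by carrier status, and a Cox proportional-hazards fit
   on (z-scored) expression.
6. **Simulation** (`cnarec.synthetic_cohort`) — paired cohorts with
   planted recurrent regions (configurable penetrance, breakpoint
   jitter, expression shift and survival hazard), background noise
   segments, and deterministic seeded streams.

`cnarec.pipeline.run_pipeline` orchestrates all stages and logs a
machine-readable count of segments/regions surviving each step.

## Command-line usage

```bash
# simulate a paired experiment described by a flat key=value config
cnarec simulate --config examples/synthetic.cfg --out sim/

# run every stage end to end (simulated or file inputs, per config)
cnarec run-all --config examples/synthetic.cfg --out results/

# stage-by-stage on files
cnarec call --segments sim/discovery/segments.seg \
            --clinical sim/discovery/clinical.tsv --out called/
cnarec annotate --regions called/young_specific_gain.tsv \
                --genes sim/discovery/genes.bed --out annotated.tsv
cnarec eqtl     --regions annotated.tsv --segments sim/discovery/segments.seg \
                --clinical sim/discovery/clinical.tsv \
                --expression sim/discovery/expression.tsv --out eqtl.tsv
cnarec survival --regions annotated.tsv --segments sim/discovery/segments.seg \
                --clinical sim/discovery/clinical.tsv \
                --expression sim/discovery/expression.tsv --out survival.tsv
```

A config file is flat `key = value` text. Example:

```
simulate = true
seed = 1
n_young = 120
n_old = 300
noise_rate = 0.2
min_patients = 5
# chrom:start:end:type:group:penetrance:jitter[:beta[:gamma]]
planted_region = 1:50000000:50250000:gain:young:0.45:300:1.0:0.7
planted_region = 2:100000000:100300000:loss:young:0.4:300
```

Replace the simulate block with `discovery_segments = …`,
`validation_segments = …`, `discovery_clinical = …`, etc. to run on real
files (SEG-like segments, clinical TSV, expression TSV, BED/GTF genes).

## Coordinate conventions

Intervals are 0-based half-open `[start, end)` internally, so
`size == end − start`; this is the only convention consistent with the
inner/outer size columns of the published region tables the package
mirrors. SEG inputs using 1-based fully-closed coordinates are converted
on load via `SegDialect(coords="one-based-inclusive")`. Touching
intervals do not overlap.
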