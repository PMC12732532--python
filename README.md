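# pbscout

Mining, annotation and evolutionary profiling of **piggyBac (PB) DNA
transposons** in genome assemblies.

PB elements are "cut-and-paste" transposons that insert at TTAA
tetranucleotides, duplicating the target site on both flanks, and are
bounded by short terminal inverted repeats (TIRs). Because recently
mobilised copies are near-identical to their family consensus while old
copies accumulate substitutions, the distribution of per-copy divergence
doubles as a relative-time profile of transposition activity — and
families with many intact, near-zero-divergence copies are prime
candidates for new genetic-engineering tools.

`pbscout` turns the manual mining workflow into a reproducible pipeline:

1. **Translated homology search** — a seed-and-extend tBLASTN-style scan
   of all six reading frames with a transposase DDE-domain protein query;
   hits are retained when identity > 80% and query coverage > 30%
   (strict inequalities), then extracted with ±4 kb flanks.
2. **Family clustering** — greedy centroid clustering (UCLUST-style,
   decreasing-length order, both orientations) at identity 0.5.
3. **Structural annotation** — TIR-pair detection anchored on TTAA
   target-site duplications, TSD reading, six-frame ORF scan, and
   intactness classification: a copy is *intact* iff it has a TIR pair, a
   duplicated target site, and a transposase ORF **exceeding** 500 aa.
4. **Divergence landscape** — per-copy Kimura 2-parameter distance to the
   family consensus,

   K = −½ · ln((1 − 2P − Q) · √(1 − 2Q)),

   with P/Q the transition/transversion proportions; copy base pairs are
   binned by K (width 0.01) into a genome-coverage landscape, and
   families are tiered: *currently_active_candidate* (100% intact,
   median K ≤ 0.01), *putatively_active* (intact fraction > 0.5 and
   > 10 intact copies), *long_term_resident* (median K ≥ 0.10), else
   *inactive*.
5. **Conservation summaries** — TIR sequence-logo information content
   (R = 2 − H bits over the first 24 bp), per-domain
   (NTD/DDBD1/DDD/DDBD2/CRD) pairwise-identity matrices between clades,
   a neighbor-joining tree, and FASTA/relaxed-PHYLIP export for external
   ML phylogenetics.

A **synthetic-genome simulator** plants PB-like elements (TIRs 6–46 bp,
TTAA TSDs, a single 500–725 aa transposase ORF, element lengths
2074–3465 bp, per-family mutational ages, decayed copies with premature
stops / truncations / scrambled TIRs) and emits a truth table, so every
stage is verifiable without downloading genomes.

## Worked example

```bash
pbscout simulate --out-dir demo/sim --seed 1
# wrote 5 contigs (2161346 bp), 60 planted copies to demo/sim

pbscout run-all --genome demo/sim/genome.fasta --query demo/sim/query.faa \
        --out-dir demo/run --seed 1
```

The run report (also written as `report.tsv` / `report.json`):

```
family_id  n_PB  n_intact  length_min  length_max  tpase_aa_min  tpase_aa_max  tir_bp_min  tir_bp_max  median_K              activity_tier
cluster_1     9         8        3400        3400           690           690          19          20    0.0518                   inactive
cluster_2    10         9        3100        3100           640           640          17          17    0.0330                   inactive
cluster_3    10        10        2800        2800           600           600          16          16    0.0190                   inactive
cluster_4    11        11        2500        2500           560           560          15          15    0.0113          putatively_active
cluster_5    12        12        2200        2200           520           520          13          13    0.0000 currently_active_candidate
```

Each row is one recovered element family: copy counts (all elements vs
intact ones), element-length / transposase-length / TIR-length ranges,
the median Kimura divergence to the family consensus, and the activity
tier. Here the fully intact, zero-divergence family (cluster_5) is
flagged as a currently active candidate, and the 11-intact-copy family
at median K ≈ 0.01 as putatively active — the signature used to
shortlist elements for tool development.

Scoring the run against the planted truth:

```bash
pbscout validate --elements demo/run/elements.gff3 --truth demo/sim/truth.tsv
# intact_recall              1.0
# boundary_exact_fraction    1.0
# decayed_classified_intact  0
```

All 50 planted intact copies were recovered with base-exact TTAA/TIR
boundaries, and none of the 10 decayed copies was misclassified as
intact.

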