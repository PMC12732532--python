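# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `pbscout`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The mining model

PB-superfamily elements have a stereotyped architecture: a short terminal
inverted repeat (TIR) at each end, a TTAA target-site duplication (TSD)
immediately outside both TIRs, and a single transposase ORF occupying
most of the element. Mining proceeds from protein homology (the
transposase DDE domain is the most conserved part) and only then resolves
element boundaries from the TIR/TSD structure, because the nucleotide
sequence outside the catalytic domain diverges quickly between families.

### Translated homology search

The genome is translated in six frames; exact 4-aa word matches against
the query seed ungapped X-drop extensions (BLOSUM62, X-drop 20, ungapped
score threshold 40), and surviving regions are re-scored by affine-gap
local alignment (gap open 11, extend 1) in a window padded by one query
length. Identity is matches / alignment columns with gaps counted;
coverage is aligned query residues / query length — the BLAST
conventions, since the mining thresholds are quoted without definitions.
Retention requires identity **strictly** above 0.8 and coverage
**strictly** above 0.3 (both exposed as parameters). Overlapping hits in
a frame keep the best score; hits within 2 kb on the same contig and
strand merge into one candidate locus (frameshifted, decayed copies
produce split hits that must become one candidate), extracted with
±4 kb flanks and reverse-complemented to transposase sense for minus
loci.

A single query at >80% identity can only find families at least that
similar to it. The search therefore accepts a multi-record query FASTA
and pools hits across queries; the simulator emits one DDE-domain query
per planted family (the central 60% of each transposase). On real data a
user would supply one or several known PB transposase domains and,
optionally, lower the identity threshold.

### Family clustering

Greedy centroid (star) clustering in decreasing-length order, both
orientations tested, joining the first centroid at identity ≥ threshold
(default 0.5) — the documented behaviour of `cluster_fast`-style tools.
An 8-mer Jaccard prefilter (≥ 0.05 in the better orientation) skips
hopeless comparisons.

Identity is matches / columns of a global affine-gap alignment after
stripping terminal-gap columns, with scoring match +1 / mismatch −3 /
gap open −16 / extend −4. The stiff penalties are deliberate: with soft
BLAST-like scoring the optimal global alignment of *unrelated* random
DNA chases spurious matches and scores ≈ 0.52 identity — above the 0.5
clustering threshold — whereas under the stiff scheme unrelated pairs
measure ≈ 0.37, same-family copies (a few percent divergence) ≈ 0.86+,
and pairs differing at half their sites ≈ 0.50, giving clean separation
around every operating point the pipeline uses.

Clustering operates by default on the **core hit spans** (the homologous
transposase region), not the full ±4 kb loci. With 4 kb of unrelated
flank on each side of a 2–3.4 kb element, full-locus identity of
same-family copies is dragged toward the random-pair baseline and the
0.5 threshold becomes a coin flip; core spans carry the actual homology
signal. `--cluster-on locus` restores full-locus clustering for data
where flanks are informative.

Consensus building star-aligns members to the centroid; per centroid
column the most frequent residue wins (ties broken A<C<G<T), columns
gapped in more than half the members are dropped, and member insertions
relative to the centroid are ignored — adequate because the simulator is
substitution-only by default; with indel-rich real data a proper MSA
(exported via `conservation_summary.export_alignment`) should replace
the star consensus.

### TIR / TSD detection and intactness

Boundary detection runs two channels sharing one scoring rule
(score = matches − mismatches over the TIR comparison, + 8 per flank
reading TTAA immediately outside; extension halts at 2 consecutive
mismatches; TIR length 6–50 bp, pair identity ≥ 0.8):

* **TSD-anchored**: every TTAA in a 3 kb window left of the homology
  core is paired with every TTAA right of it that brackets the core, and
  the terminal sequences inside the anchors are compared to each other's
  reverse complement. This channel pins boundaries base-exactly.
* **Seed-based**: exact reverse-complement 6-mers between the windows
  are extended outward, for elements whose TSD decayed.

The acceptance threshold 28 comes from a false-call analysis: 3 kb
windows contain ~12 TTAA each (~144 anchor pairs per locus), and the
net-12 requirement inside canonical TSDs pushes chance anchored inverted
repeats below ~1e-5 per locus; one step looser admits roughly one
spurious element per few dozen loci, which in simulation was enough to
dress a truncated copy up as a 4.5 kb "intact" element via a chance
11-mer. The cost is a sensitivity floor of a 12 bp exact TIR (14 bp
with one mismatch) when TSDs are present; TIRs shorter than 12 bp are
only detectable with perfect TSD anchoring and longer self-complementary
runs, a documented limitation.

Intactness is the census definition: TIR pair **and** duplicated target
site (both 4-mers equal, not necessarily TTAA) **and** an ORF strictly
exceeding 500 aa (`--min-orf-aa`; the strict inequality follows the
"exceeding 500 amino acids" wording). Elements with a TIR pair that fail
intactness are retained as non-intact PB copies; TSD presence is not
required to *call* an element, only for intact status. No hard element-
length filter is applied: the 2074–3465 bp band is an observed range,
not a criterion.

### Divergence and activity

Per-copy divergence is copy-vs-family-consensus (the RepeatMasker
`calcDivergenceFromAlign` convention, not all-pairs). Copies are
globally aligned to the consensus, terminal gaps stripped, and the
Kimura 2-parameter distance computed over ungapped ACGT columns:
K = −½·ln((1−2P−Q)·√(1−2Q)). Saturated estimates (non-positive log
arguments) are flagged undefined and excluded from landscapes; copies
aligning over fewer than 100 sites are dropped with a warning. No
CpG-adjusted variant is applied (none is claimed for the source
workflow).

The landscape bins copy base pairs by K (width 0.01, the RepeatMasker
landscape convention) as percent genome coverage; per-family coverage
sums exactly to family bp / genome bp.

Activity tiers, evaluated in order: *currently_active_candidate* if
intact fraction = 1.0 and median K ≤ `young_K` (default 0.01 — "K ≈ 0"
is not quantified in the literature; 0.01 ≈ one substitution per 100 bp
is the configurable operationalisation); *putatively_active* if intact
fraction > 0.5 **and** intact copies > 10 (both strict);
*long_term_resident* if median K ≥ `old_K` (default 0.10); else
*inactive*.

### Conservation summaries

TIR logos use plain per-position frequencies over the first L = 24
positions counted from the element-outer end, information
R = 2 − H bits, no pseudocount or small-sample correction by default;
TIRs shorter than a position simply do not contribute there (`pad=skip`).
Domain identity matrices take domain coordinates from an input TSV
(protein_id, domain, start, end; domains NTD, DDBD1, DDD, DDBD2, CRD)
and report mean pairwise percent identity per clade pair; singleton
clades have an unavailable diagonal. Neighbor joining is the classical
algorithm with a deterministic tie-break (minimal Q, then the
lexicographically smallest leaf-label pair) and branch lengths clamped
at zero; it is exact on additive matrices and intended as a quick
distance-based approximation — publication phylogenetics should use the
exported alignments with external MSA/ML tools.

## The synthetic study

The simulator emulates the structure of the real substrate, not its
full complexity. Background contigs are i.i.d. nucleotides at GC 0.35
(insect-like; no background model is claimed by the source workflow).
Master elements are built per family with exact TIRs (prefixed CCCT,
the motif observed at PB TIR 5′ ends), a single ATG→stop ORF in the
standard nuclear code, an in-frame guard stop before the ATG (so the
planted ORF cannot extend upstream) and two guard bases inside each TIR
chosen to break reverse-complement extension (so TIR length is
unambiguous).

Copies are mutated by drawing each site from the closed-form K2P
transition matrix at the requested divergence K with rate ratio
κ = α/β (default 2): P(transition) = ¼ + ¼e^{−4βt} − ½e^{−2(α+β)t},
P(each transversion) = ¼ − ¼e^{−4βt}, with βt = K/(κ+2). Multiple hits
are therefore implicit and the K2P *estimator* applied to a copy is
centred on the requested K; the recorded `realized_K` is that estimate,
computed per copy. Indels are off by default (the divergence convention
scores substitutions).

Copies designated intact are mutated under functional constraints:
substitutions that would destroy the start codon, create an in-frame
stop, remove the terminal stop, or fall inside a TIR are reverted or
redirected to a neutral base. This mirrors selection — the copies that
remain transposition-competent are exactly those whose functional sites
survived — and is what makes a "50 intact copies at K ≤ 0.05" study
constructible at all: unconstrained mutation at K = 0.05 introduces ~3
premature stops per 1.7 kb ORF, leaving essentially no intact copies.
Decayed copies instead receive an explicit lesion (premature stop at 40%
of the ORF, a 30–50% 5′ or 3′ truncation, or a scrambled right TIR),
cycled so all lesion types occur across families. The handful of
redirected sites biases realized divergence negligibly (they remain
substitutions; only the target base changes).

Insertions are non-overlapping (≥ 5 kb apart) and non-nested, with the
TSD written as TTAA-element-TTAA; truth coordinates cover the element
excluding TSDs, 0-based half-open. The truth `is_intact` flag is set by
running the package's own structural annotator on each planted copy in
situ, so the simulator/annotator round trip holds by construction and
copies whose TIRs decayed below the detection floor are honestly labelled
non-intact. Seeding fans a master seed out to per-copy child seeds via a
counter, so runs are byte-reproducible.

The **default study** is 5 contigs × 400 kb with five independent
families (TIR 13–19 bp, ORF 520–690 aa, element 2200–3400 bp, expected
K ∈ {0, 0.01, 0.02, 0.035, 0.05}), 60 copies: 50 intact, 10 decayed.
famA (12/12 intact, K = 0) exercises the currently-active regime and
famB (11 intact of 14, K = 0.01) the putatively-active regime. These
sizes keep a full pipeline run under a minute on one CPU while leaving
each stage statistically meaningful.

**What passing on synthetic data does and does not show.** The simulator
has i.i.d. background (no host genes, satellites or nested repeats), no
indels by default, exact TTAA TSDs, and families that are unrelated to
each other outside the planted homology. Perfect recall/precision here
validates the algorithms and their bookkeeping (coordinates, strands,
thresholds), not performance on real assemblies, where diverged old
copies, nested insertions and assembly artifacts will lower recall and
boundary exactness. The census figures of any real survey are outside
what desk-scale synthetic data can reproduce.

## Numerical and design choices

* TIR length range 6–50 with pair identity ≥ 0.8; the observed upper
  range conflict in the source material (≤ 26 bp vs up to 46 bp) is
  resolved in favour of the wider table range, with slack to 50.
* Strict inequalities wherever the defining wording is strict
  (identity > 0.8, coverage > 0.3, ORF > 500 aa, intact copies > 10,
  intact fraction > 0.5).
* Fig-4-style selection of families for dynamics plots (copy identity
  > 99%) is exposed as a filter on copy-to-consensus identity rather
  than hard-coded, since the original definition is ambiguous.
* Reverse-complement handling: candidate loci are sense-oriented at
  extraction; clustering still tests both orientations in case strand
  assignment failed for a decayed copy.
* Degenerate inputs: empty genomes yield an empty report with exit 0;
  unknown contigs, malformed truth tables, non-ACGTN clustering input,
  asymmetric NJ matrices and infeasible element geometries raise typed
  errors; a TIR flush against a locus edge yields an unknown TSD and
  cannot be intact.
* Determinism: all randomness flows from explicit seeds; artifacts
  contain no timestamps; a rerun with identical inputs and config is
  byte-identical (the config hash in the report is the SHA-256 of the
  resolved YAML).

## Limitations

* No E-value statistics; retention is by identity/coverage only.
* Star consensus and star MSA are approximations; indel-rich families
  need external MSA.
* TIR detection requires either TSD anchoring or ≥ 12 bp of near-exact
  inverted repeat; short-TIR elements with decayed TSDs are missed.
* No pHMM domain verification (domain coordinates are accepted as
  input); no MITE/non-autonomous derivative detection; no ML
  phylogenetics or bootstrap support in-package.
* Activity tiers are heuristics over copy counts and divergence; they
  shortlist candidates, they do not demonstrate transposition activity.
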