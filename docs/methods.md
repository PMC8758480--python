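# Methods

## The measurement

Gene-structure conservation is scored at the splice site, the most
conserved and most position-critical feature of an intron. Each site of
each multi-exonic transcript (single-exon transcripts carry no sites and
are excluded with a logged count) is located in the reference genome at
the leftmost coordinate of its intronic dinucleotide, mapped through a
reference-anchored multiple alignment into each target species, and
classified as conserved, lost, or not alignable. Coordinates are 0-based
half-open throughout; GTF input is converted on reading, so BED12 is the
native dialect and off-by-one arithmetic is confined to one reader.

Allowed dinucleotides default to the canonical `GT` (donor) / `AG`
(acceptor) on the transcript strand; the minor classes (`GC`/`AT` donors,
`AC` acceptors) can be switched on but are off by default, since canonical
introns dominate and scoring a non-canonical human intron against a
canonical target motif would conflate motif class with conservation.
For '-'-strand transcripts the aligned context is reverse-complemented
before matching, so the comparison is always on the transcript strand.

### Shift window

Multiple-alignment columns jitter by a few positions around indels, so an
exactly aligned dinucleotide is too strict a criterion. The classifier
accepts an allowed dinucleotide starting within ±s nt of the mapped
boundary (default s = 6; the tie-break is smallest |shift|, then the
negative/upstream shift, making calls deterministic). The context window
spans s + 2 alignment columns each side so that every candidate placement
is visible. s = 0 gives a strict mode used for oracle-grade comparisons
against scripted truth. Widening s can only add conserved calls, never
remove them — a monotonicity the test suite asserts.

### Ambiguity and alignability

If several blocks cover a site (duplicated or paralogous alignments), the
first block in file order containing the boundary is used and the call is
flagged `ambiguous_block`. A species absent from the block, or aligned by
gaps only, yields `not_alignable`. Two denominator policies exist:

* **strict** (default): not-alignable sites simply count as not conserved;
* **conditioned**: transcripts with < 50% alignable sites in a species are
  dropped from that species' rate denominators, separating genuine
  structure loss from assembly/alignment dropout.

## Transcript-level grading

Per transcript × species, with n sites of which c are conserved:

* present: c ≥ `min_present` (default 1 — the weakest defensible notion of
  "the locus is still detectable as an entity"; the parameter is exposed
  because stricter detectability notions are equally defensible),
* intermediate(f): c/n ≥ f for each configured f (default 0.25, 0.5, 0.75),
* complete: c = n.

With the defaults these levels nest (complete ⇒ intermediate ⇒ present),
and rates are monotone in level stringency for every species.

## Set comparison

For each species and level, transcripts attaining the level in a target
vs a background set form a 2×2 table tested with a two-sided Fisher's
exact test. The implementation enumerates hypergeometric weights
C(n₁,x)·C(n₂,k−x) as exact integers (a ratio recurrence keeps this fast
even for thousands of transcripts), sums those not exceeding the observed
weight, and converts the rational once at the end — so "as probable as
the observed table" is decided exactly, with no floating-point tie
ambiguity. Tables with an empty column margin (everything conserved, or
nothing) admit a single configuration and get p = 1.

The significance flag uses raw p < 0.05 per species; Benjamini–Hochberg
adjusted p-values across species within a level are reported in the same
table for readers who prefer a corrected view. Species are ordered by
patristic distance from the reference leaf (ties by name), and
non-monotonic wiggles across species are reported as-is — assembly and
alignment quality vary between genomes and smoothing would hide exactly
the artefacts the conditioned mode is meant to expose.

No phylogenetic correction (independent contrasts etc.) is applied across
species: the per-species tests are deliberately marginal and their
non-independence across species is why conclusions should rest on the
pattern over many species, not on any single filled circle.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real sequence evolution:

* **Tree**: any newick with branch lengths and the reference as a leaf;
  the built-in default has 18 non-reference species with human-patristic
  distances from ~0.013 (chimp-like) to ~2.5 (teleost-like).
* **Transcripts**: exon counts uniform on [2, 15]; exon/intron lengths
  shifted-geometric with means 150/400 nt and a 50 nt floor — the
  right order of magnitude for vertebrate genes while keeping files small.
* **Turnover**: each site survives each branch of length d with
  probability exp(−λ·d), independently per site and branch, loss being
  permanent along a lineage; branches shared by several species are drawn
  once, so sister species are correlated as they would be in reality.
  The memoryless exponential is the simplest model consistent with the
  monotone decay of conservation with distance. Defaults: λ = 0.15 per
  unit branch length for the background and λ = 0.30 for the target set —
  chosen, via the closed-form expectations below, so that complete-level
  background rates span ~0.95 (great apes) down to < 0.1 (fish) across
  the default tree, and the target deficit is detectable at n = 150
  against n = 2000 over most of the distance range.
* **Dropout**: with probability m per (block, species) the species row is
  omitted, the only source of not_alignable truth (a transcript whose
  sites were all lost but whose row aligns is "structure lost", not
  unalignable).
* **Noise and guards**: every site dinucleotide is flanked by an 8 nt
  guard kept free of allowed dinucleotides in every row (lost sites are
  rewritten to `CC`, never a splice motif on either strand). Substitution
  noise (default 0, 1% in the preset) is applied outside guard windows
  only. Consequently the scripted per-(site, species) status is exact for
  any shift window ≤ 6 even under noise — passing tests certify the
  mapping and classification machinery, not a lucky absence of
  coincidental motifs.
* **Fragmentation preset**: splits each locus at the midpoint of its
  middle intron into two blocks to exercise multi-block interval queries.

What the generator does **not** emulate: indels (alignment columns never
shift, so the shift window is exercised only by construction, not by
realistic jitter), site *gain*, GC content and motif composition of real
genomes, lineage-specific rate variation, and any correlation between
expression and structure. Green tests therefore certify the pipeline's
correctness and the statistics' calibration under the stated model — not
that real alignments are free of artefacts; the conditioned mode and the
ambiguity flag exist precisely because real data are not.

### Closed-form expectations

With survival p = exp(−λ·D) at patristic distance D and n = 2(k−1) sites,
the conserved count is Binomial(n, p), so

* P(complete) = pⁿ,
* P(present) = 1 − (1−p)ⁿ for min_present = 1 (generally a binomial tail),

marginalized over the exon-count distribution. `expected_rates` evaluates
these; since each transcript's exon count is drawn independently, observed
per-species rates over N transcripts are exactly Binomial(N, expected)/N,
which is what the parameter-recovery check asserts with a 99% band.

The type-I calibration experiment (equal λ in both sets, 500 replicates)
draws per-transcript level outcomes directly from these exact marginals
rather than re-emitting alignment files per replicate: the distribution
per species is identical, and the file-level path is separately certified
exact by the noiseless-recovery check. Its species sit at distances
0.5–3.0 with λ = 0.05, placing complete-level rates in the interior of
(0, 1) where the discrete Fisher null has enough support for the achieved
size to approach the nominal level; at extreme rates the exact test is
intrinsically conservative and a calibration check would measure
discreteness, not correctness.

## Numerical and degenerate-input choices

* Fisher p-values are exact rationals converted once to float; BH uses
  statsmodels.
* classify_site is total over valid inputs: empty context ⇒ not_alignable,
  never an exception.
* Duplicate annotation records: identical duplicates are dropped with a
  warning, conflicting ones are an error; malformed lines report their
  line number.
* Transcript sets: target/background overlap is removed from the
  background with a warning; an empty set after removal is an error.
* Determinism: a single integer seed drives the generator; identical
  seeds give byte-identical output files, and pipeline reruns on fixed
  inputs give byte-identical tables.

## Problem sizes in the shipped experiments

The shipped experiments use 18 species × 2 150 transcripts for the
turnover-contrast run, 1 000 transcripts for parameter recovery, 200 for
the noiseless-recovery check and 500 replicates for calibration — sizes
at which the binomial bands are tight enough to be informative while a
full run of the suite stays in the tens of seconds on one CPU.

## Known limitations

* Site conservation is scored per transcript; isoforms sharing a splice
  site are counted independently (no per-gene de-duplication).
* Homology is structural only: no synteny or sequence-similarity check
  guards against a splice motif conserved by chance in a non-homologous
  aligned region — at real phylogenetic depths the alignment itself must
  carry the homology claim.
* The presence level with min_present = 1 is permissive; conclusions
  about "evolutionary origin" should be read as alignment-detectability.
* The per-species tests share transcripts across species and are not
  independent; the BH column corrects across species only, not across
  levels.
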