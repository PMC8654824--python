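# Methods

## Distances

Both models operate under **pairwise deletion**: for each sequence pair,
alignment columns where either member is anything other than a plain
A/C/G/T (gap, N, or an IUPAC ambiguity code) are ignored. This is the most
conservative reading of "pairwise deletion" — ambiguity codes are treated as
missing rather than partially matched — and it keeps every distance a
deterministic function of integer site counts, so exact ties between
distances are meaningful and no epsilon is used anywhere in the
classification logic.

* **K2P** (used for gap analysis and BM/BCM by default):
  `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with transition (A↔G, C↔T)
  proportion P and transversion proportion Q over the comparable sites.
  A pair is **UNDEFINED** when it has zero comparable sites or when either
  log argument is ≤ 0 (saturation). UNDEFINED is carried as NaN and is
  *excluded* — never zeroed — from range summaries, gap records, BCM
  thresholds and match candidates; queries with no defined distance at all
  are dropped from the BM/BCM denominator and listed in the report.
* **p-distance** (used for NJ trees by default): mismatches / comparable
  sites; UNDEFINED iff no comparable sites.

The all-pairs matrix is computed by one-hot matrix products (site counts,
matches, transitions via BLAS), which is exactly equivalent to the per-pair
scalar routines and fast enough for alignments of a few thousand sequences.
No variance or standard error is estimated.

## Barcoding gap

Per species with ≥ 2 individuals: `max_intra` is the maximum defined
conspecific distance and `min_inter` the minimum defined distance from any
member to any heterospecific individual (all individuals, not species
centroids). The gap criterion is the **strict** inequality
`min_inter > max_intra`; a dot on the 1:1 line does not count. Singleton
species have no intraspecific distance, so they are excluded from the
records (the only non-arbitrary choice — the maximum over an empty set is
undefined); their individuals still serve as potential nearest
heterospecific neighbours of other species. Species whose intra or inter
distances are all UNDEFINED are skipped and reported as such. The histogram
view bins all defined intra- and interspecific distances on a shared grid
(default bin width 0.01, configurable); counts conserve pair totals.

## Best Match / Best Close Match

Leave-one-out: the query is never its own candidate. The best-match species
set contains the species of *all* samples attaining the minimum defined
distance; CORRECT iff the set equals the query's species, AMBIGUOUS iff it
contains it plus others, INCORRECT otherwise. The BCM threshold is the
empirical 95th percentile of all defined intraspecific distances — the
smallest observed value v with at least 95% of them ≤ v, by rank, no
interpolation — and a query whose best distance exceeds v is NO MATCH
(reported as a fourth percentage category in the denominator). Singleton
species must be deleted beforehand; the functions enforce this with a hard
error and the pipeline performs the deletion. With an infinite threshold BCM
reduces exactly to BM. Note that even on perfectly clean data BCM can emit
a few NO MATCH verdicts: by construction ~5% of intraspecific distances
exceed the threshold, so a query with an atypically divergent conspecific
neighbourhood may fall beyond it. The 100%-recovery guarantee on clean data
therefore applies to BM and to BCM at infinite threshold.

## Neighbour joining and monophyly

Standard Saitou–Nei agglomeration with the Studier–Keppler criterion
`Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`. Ties in Q are broken by
the lowest (row, column) index pair in the current label order, which makes
the output deterministic under record order. Branch lengths use the standard
allocation; negative lengths are clamped to 0 without redistribution (this
changes lengths only, never the topology, so monophyly is unaffected). The
final three clusters are joined at one internal node; the result is an
unrooted binary tree with 2n−3 edges.

`nj_build` refuses matrices containing UNDEFINED entries rather than
imputing them — a silently imputed distance could flip a monophyly verdict.
The pipeline instead greedily removes the samples with the most undefined
pairs (logged) until the matrix is complete.

A species is monophyletic iff some edge's bipartition has one side exactly
equal to its leaf set. A second, independent implementation roots the tree
at an arbitrary leaf and tests rooted clades (for the species containing the
root leaf, the complement must form a clade); the test suite asserts the two
agree on every simulated tree. Species with a single individual are
trivially monophyletic and are excluded from the discrimination denominator
(they would inflate the rate); they are listed separately. No bootstrap is
computed — the identification criterion is purely topological.

## Dataset filters and concatenation

* Minimum length: records with fewer than 300 determinate bases (gaps and N
  excluded, i.e. the pre-alignment sequence length) are removed, except for
  loci in the exemption set (default {ITS2}, whose natural length is short).
* Per-species cap: at most 20 individuals, keeping the longest ungapped
  sequences, ties broken lexicographically by sample id. The published
  practice of preferring geographically diverse, high-quality sequences is
  not computable from an alignment; the deterministic longest-first rule is
  used instead and every removal is logged with its reason.
* Concatenation joins loci on sample id and keeps the **intersection** of
  samples present in all constituent loci (missing-data-free supermatrix);
  partition ranges are recorded 0-based half-open and written as a sidecar
  table. Conflicting species labels for one sample id across loci are a hard
  error. By default trnH-psbA is excluded from combinations (its alignment
  pathologies create heavy missing data) and ITS+ITS2 are never combined
  (ITS2 is a sub-region of ITS); both defaults are overridable by passing
  explicit combinations.

## Simulator

The generator emulates species-structured barcode matrices:

* **Species tree**: pure-birth (Yule) topology with exponential waiting
  times, made ultrametric and rescaled so the root-to-tip height equals
  `inter_scale` (expected substitutions/site). Because a pure-birth process
  can place the most recent speciation arbitrarily close to the present,
  internal node times are additionally compressed by
  `1 − min_split_frac` (default 0.2), guaranteeing every species' stem is at
  least `min_split_frac × inter_scale`. This is what makes a "clean" dataset
  clean *by construction*: the interspecific floor (≥ 2 × 0.2 × inter_scale)
  sits far above the intraspecific ceiling (≤ 2 × intra_scale) plus the
  estimation noise at the default 800 bp.
* **Individuals**: each species tip becomes a star of individuals with
  pendant lengths uniform on [0, intra_scale]. A star genealogy (rather
  than a coalescent) is deliberate: it bounds and directly controls the
  maximum intraspecific distance, which is the quantity the gap statistics
  consume. It does not reproduce the correlation structure of real
  within-species genealogies.
* **Confusable pairs** (`n_confusable_pairs`): selected species pairs share
  their species-level sequence — the second member's individuals radiate
  from the first member's tip — emulating cryptic or over-split species.
  Expected consequences, used as ground truth: no barcoding gap, non-CORRECT
  BM verdicts for roughly half of their members (each query's nearest
  neighbour is equally likely from either twin), and loss of monophyly for
  both members.
* **Sequences**: root drawn uniform over ACGT; Kimura 2-parameter process
  per branch using exact transition probabilities (no site discretisation),
  with rates normalised to one expected substitution per site per unit
  branch length, so estimated K2P distances converge to path lengths.
  `kappa` is the expected transitions-per-transversion ratio R = α/2β
  (default 2.0, a typical plant value); `kappa = 0.5` gives equal rates to
  all three target bases. No indels are simulated: alignment-pathology
  effects (as seen in real trnH-psbA) are out of scope, so passing tests say
  nothing about alignment quality on real data.
* **Multi-locus suite**: three independent loci evolved on the same
  individual tree, each sample retained per locus with probability
  `1 − missing_fraction` (default dropout 0.1), for concatenation tests.

One `numpy.random.Generator` seeded from `SimulationConfig.seed` drives
everything; FASTA output is byte-identical across runs.

## Benchmark problem sizes

The verification benchmark uses 30 species × 5 individuals, 800 bp,
`inter_scale = 0.2`, `intra_scale = 0.005` (clean, and with 3 confusable
pairs), 4–8-taxon additive matrices for tree recovery, and batches of small
simulated datasets (≤ 200 sequences) for brute-force classifier
equivalence. These sizes give clear separation between signal and
Monte-Carlo noise while each full run stays within seconds.

## Known limitations

* Real-data range extrema can differ in the last digit from other software
  depending on how ambiguous bases are treated under pairwise deletion; the
  conservative all-missing rule used here is documented above but not
  universal.
* NJ tie-breaking and negative-branch handling differ between
  implementations; on real data, discrimination percentages may differ by a
  fraction of a percent from other NJ programs even at identical distances.
* The simulator's star genealogies and indel-free alignments mean tests
  demonstrate correctness of the statistics, not robustness to alignment
  error or deep coalescence.
* PCR/sequencing success rates sometimes reported alongside such evaluations
  are wet-lab outcomes; they are accepted as input metadata, never computed.
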