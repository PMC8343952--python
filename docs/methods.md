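# Methods

This note documents the models, defaults and design choices behind lineakit,
and what the synthetic study conditions do and do not establish about real
casework data.

## mtDNA profiles and coordinates

Profiles are coded as differences to the revised Cambridge Reference
Sequence: 1-based inclusive coordinates, fixed length 16,569, linear (no
circular wrap — the analyses only use the control region and linearly coded
mitogenomes).  Variant tokens follow forensic nomenclature (`73G`, `315.1C`,
`249DEL`; the `249-` deletion dialect is accepted on input, `DEL` written on
output).  Bases coded `N` are missing data: they are excluded from match
counting and distances.  Insertion tokens are treated literally; no
phylogenetic realignment of length-heteroplasmic stretches (309/315/16193
region) is attempted, so data prepared with a different insertion convention
should be normalised before loading.

Because the true rCRS sequence is licensed GenBank data, the package ships no
reference sequence.  `reference.synthetic_reference()` builds a deterministic
stand-in of the right length whose bases agree with the rCRS at every
position used by the shipped haplogroup table and are arbitrary elsewhere;
`reference.load_reference()` reads a user-supplied rCRS FASTA.  No matching
or probability statistic depends on reference content — it matters only when
profiles are expanded to nucleotides for tree building, where any fixed
reference gives the same pairwise differences.

Multiple alignments are built directly from reference-coded profiles: the
union of observed insertion slots defines extra columns, gap-filled for
samples lacking the insertion, and deletions stay as gaps.  This is exact for
reference-coded data and avoids running an aligner.

## Matching and the two-population contrast

The comparability rule is conservative: a record enters the denominator only
if it covers the whole comparison window.  The alternative — intersecting
the window per record — is available (`comparability="per-record"`) but not
the default, because it makes match counts across records incomparable.
The augmented-count estimator (x+1)/(n+1) is used as is; no confidence
intervals or substructure corrections are applied.  The winner of a contrast
is decided by exact integer arithmetic on (x+1)(n'+1) cross-products, so
float rounding can never flip a call, and exact ties are reported as `"tie"`.

## Haplogroup assignment

Unit-cost scoring (`match +1`, `expected-but-absent-within-coverage −1`) is
the simplest defensible scheme; weights are configurable.  Observed variants
not expected anywhere on the best path are reported as `private` but never
scored — private variation is ubiquitous and penalising it would punish
well-covered profiles.  Diagnostics outside the profile's coverage are
ignored entirely.  Ties break toward the deeper node (then lexicographically),
matching the forensic practice of reporting the finest defensible subclade;
one consequence is that a profile matching only a backbone motif is reported
at the deepest node whose extra diagnostics all fall outside coverage.

The shipped table `data/synthetic_haplogroups.tsv` is a deliberately small,
synthetic stand-in: 21 nodes covering the eight case subclades (K1a1b1a,
K2a2a1, H3p, HV1b2, I1c1a, J1c14, V7a, X2b7) and their ancestors, with two to
three control-region diagnostics per branch at positions whose reference
bases are well established.  It is **not** a Phylotree import and must not be
used to haplogroup real data; `HaplogroupTree.from_tsv` is the extension
point for a full table.

## Phylogeography under T92

* θ (G+C content) is estimated once from alignment-wide base composition by
  default; per-pair estimation is available by flag.  Default κ
  (transition/transversion rate ratio) starts at 4 — a typical mtDNA
  control-region order of magnitude — and is refined by bounded scalar search
  on [0.1, 100] alternating with branch sweeps.
* Distances use pairwise deletion of gaps/N; saturation (non-positive log
  argument) raises an error naming the pair rather than returning infinity.
* The candidate topology set is exactly {NJ, BioNJ}; no NNI/SPR search.
  Negative branch-length estimates are clamped to zero with a logged warning.
* Branch lengths are optimised coordinate-wise (bounded [0, 10]
  substitutions/site) until the log-likelihood gain per sweep drops below
  1e-6 or 20 sweeps; a proposed length is accepted only if it improves the
  likelihood, so the trace is non-decreasing by construction.
* Rate heterogeneity (+G) is intentionally not modelled, and no bootstrap is
  computed.
* Likelihood uses Felsenstein pruning with site-pattern compression and an
  eigendecomposed rate matrix; missing characters contribute partial
  likelihood 1 in every state, so an all-missing column contributes exactly
  zero log-likelihood.
* The clade-label report reads clades on the NJ-central rooting: walking up
  from a query leaf, the first ancestor with an informative co-member defines
  the "clustered-with" clade.  Sibling queries are excluded from the tally so
  a population call never rests on other queries.

## Synthetic study conditions

The generator emulates the statistical structure of a two-population
forensic comparison:

* **Spectra.** Two populations over one founder tree with disjoint frequency
  vectors (spectral overlap 0, within the ≤10% design bound): the
  query-source population concentrated on the eight fine subclades, the
  contrast population on ancestral/other clades.
* **Lineage pools.** Within each founder haplogroup a pool of
  `n_lineages = 6` distinct mitotypes is generated: lineage 0 is the founder
  motif, the rest add Poisson(`lambda_private = 1.0`) private substitutions
  at uniform non-diagnostic positions; individuals draw a lineage with
  geometric weights (w ∝ 2⁻ʲ).  A population is thus a finite mixture of
  recurring mitotypes — the regime in which database matching is informative.
  Modelling private variation per *individual* instead would make almost
  every haplotype unique and reduce every contrast to a comparison of panel
  sizes, which is not the phenomenon this analysis measures.
* **Queries** are drawn from the same pools as their source population's
  reference records, emulating case lineages that are present in the
  candidate population's database.
* **Y-STRs** follow a symmetric single-step stepwise mutation model with
  per-locus probability `mu_smm = 0.02` per draw around four founder
  haplotypes (the CMH for "J-P58", three synthetic founders ≥3 loci apart).
* **Sizes.** Panels of `n = 500` per population and 10 queries; all
  randomness flows from one seed through named integer substreams, so output
  is platform-independently reproducible.

What passing tests on these conditions do **not** show: robustness to
database heterogeneity (mixed coverage windows, transcription errors),
heteroplasmy, back-mutation or recurrent mutation at diagnostic sites,
realistic locus-specific Y-STR mutation rates, population substructure, or
the behaviour of the haplogroup caller on a full Phylotree.  Private
mutations never hit diagnostic positions by construction — a simplification
that keeps generating labels recoverable and haplogroup recovery near 100%.

## Numerical choices and degenerate inputs

* Augmented probabilities and contrast winners use exact integer arithmetic.
* Restricting a profile to a disjoint window yields a flagged
  empty-coverage profile (`is_empty`), never a silent empty result; using it
  downstream raises explicit errors.
* Zero comparable database records is an error naming the failing
  population, not a zero count.
* θ is clipped to (1e-6, 1−1e-6) so degenerate base compositions still
  define a model; transition-probability matrices are clipped at 0 and
  row-renormalised before simulation sampling.
* Tie-breaks are deterministic everywhere (argmin scan order in NJ,
  depth-then-name in haplogrouping, first-candidate in topology selection)
  and reruns of the pipeline with one config are byte-identical.

## Problem sizes

The shipped tests and the acceptance script run at deliberately small scale:
panels of 500 profiles over the control region, trees of ~30 taxa for the
phylogeographic stage, 5,000-site alignments for parameter-recovery checks,
and exhaustive likelihood enumeration only up to 5 taxa.  These sizes
exercise every code path; nothing in the implementation is specific to them.

## Known limitations

* The haplogroup scorer is a simplified engine, not a re-implementation of
  any curated database service; its unit costs ignore site mutability.
* The Y haplogroup scorer (`ystr_assign`) is a transparent mean
  allele-frequency ranking, not a replication of any dedicated predictor's
  model.
* Heteroplasmy codes and sequence→profile alignment are out of scope;
  profiles are the input format.
* BioNJ variance updates assume distance-proportional variances (its
  standard first-order model); for exactly additive inputs NJ and BioNJ
  coincide, which the tests exploit.
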