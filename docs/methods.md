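# Methods

This note documents the models and procedures implemented in `polysloc`,
the assumptions behind them, the numerical and design choices made where
the problem was genuinely open, and what the synthetic-data tests do and
do not demonstrate about real data.

## Distance estimation

Pairwise distances are computed on compared sites only. The default gap
and ambiguity convention is **pairwise deletion**: a column is used for a
pair when both sequences carry an unambiguous base (A, C, G or T).
Complete deletion (drop any column with a gap/ambiguity in *any* row) is
available when the full alignment is in hand. Percent identity is
(1 − p)·100; it is reported rounded to the nearest integer but threshold
comparisons use the unrounded value (rounding first would silently move
the >98% membership boundary by up to half a percentage point).

* Jukes–Cantor: d = −(3/4) ln(1 − 4p/3), defined for p < 3/4, with the
  delta-method standard error sqrt(p(1−p) / (L (1−4p/3)²)). Saturated
  pairs raise an error rather than returning NaN.
* Kimura two-parameter: d = −(1/2) ln(1−2P−Q) − (1/4) ln(1−2Q) from the
  transition proportion P and transversion proportion Q; domain
  1−2P−Q > 0 and 1−2Q > 0.
* Nei–Gojobori Ks/Ka: per codon, each position contributes one site
  split into a synonymous fraction equal to (number of one-step changes
  producing a sense codon for the same amino acid)/3 — so changes to
  stop codons count as nonsynonymous and S + N is exactly 3 per codon.
  Site counts are averaged between the two sequences. Codons differing
  at k positions are scored by averaging the synonymous/nonsynonymous
  step counts over all k! minimal substitution pathways with equal
  weights, excluding pathways through stop codons (if every pathway hits
  a stop, all are used). Ks and Ka apply the Jukes–Cantor correction to
  Sd/S and Nd/N and are flagged undefined at ≥ 3/4. Only the standard
  genetic code is supported. Note that on single codons the raw
  proportion Sd/S can exceed 1 (e.g. one synonymous difference at a
  codon with 1/3 synonymous site); this is a property of the counting
  scheme, immaterial at realistic sequence lengths.
* Group mean divergence averages all between-set pairwise distances.
  The SE is analytic for a singleton-vs-singleton comparison; otherwise
  it is a nonparametric bootstrap over alignment columns (default 1000
  replicates) — whether published error bars of this kind are analytic
  or bootstrap is generally unstated, so both routes are provided and
  agree to within sampling error on simulated data.

## Haplogroup classification and parental origin

A query belongs to a known haplogroup when its identity to the best
reference is **strictly greater than** the threshold (default 98%);
identity exactly at the threshold is called novel. Ties between
references are broken by input order and flagged. This rule rests on the
empirical bimodality of S-locus identity: same-specificity sequences are
>98% identical while different specificities share at most ~91–92%, so
the call is insensitive to the exact threshold on well-separated data.
No alignment region is hard-coded; region selection (e.g. restricting to
the S-domain) is the caller's responsibility.

Parental origin is the argmin of the corrected distances to the two
parental orthologs; distances equal within an absolute tolerance of
1e−9 give "ambiguous" (only exact ties are biologically
uninterpretable). With one ortholog missing the call is made from the
single comparison and flagged.

## Neighbor joining

Saitou–Nei NJ with Q(i,j) = (n−2) d(i,j) − Σ d(i,·) − Σ d(j,·). Ties in
the Q minimum are broken by the lowest (row, column) index pair so runs
are deterministic across platforms. Negative branch lengths are clamped
to zero with the deficit transferred to the sister branch of the same
join, preserving the joined pair's path length — a common convention for
slightly non-additive matrices. Newick output carries branch lengths at
six decimals; a round-trip parser is included. On additive matrices NJ
recovery is exact (tested to 1e−9 on random 8-leaf trees against a
graph-shortest-path oracle).

## F2 segregation under four inheritance models

An allotetraploid F1 carries two dominant markers whose joint
segregation in the F2 discriminates four hypotheses:

| model | F1 genotype | classes (both : A : B : neither) |
|---|---|---|
| disomic, allelic | one diploid-behaving locus {A,B} | 2/4 : 1/4 : 1/4 : 0 |
| disomic, nonallelic | two loci {A,−}, {B,−} | 9/16 : 3/16 : 3/16 : 1/16 |
| tetrasomic, allelic | one locus {A,A,B,B} | 34/36 : 1/36 : 1/36 : 0 |
| tetrasomic, nonallelic | two loci {A,A,−,−}, {B,B,−,−} | 1225/1296 : 35/1296 : 35/1296 : 1/1296 |

Gametes are enumerated exactly: a disomic locus transmits each of its
two copies with probability 1/2; a tetrasomic locus transmits each
unordered pair of its four copies with probability 1/6 (random
chromosome segregation; double reduction — transmission of sister
chromatid copies under chromatid segregation — is excluded, and only
this choice yields the fractions above). All probabilities are
`fractions.Fraction` rationals and sum to exactly 1; the F1 genotype
presets are the unique simple genotypes consistent with each hypothesis.

Goodness-of-fit is Pearson's χ² with expected counts N·p from the exact
fractions (never from rounded per-class values — at N = 95 the 1/4
class expects 23.75, and only that value reproduces χ² = 2.62 for the
disomic-allelic model on counts 53/25/17/0). Classes with p = 0
contribute nothing and are excluded from df = #{p>0} − 1; observing a
count in such a class rejects the model outright (χ² = ∞). No continuity
correction. Models are ranked by descending p-value (ties by ascending
χ²).

**Identifiability limit.** The two tetrasomic models differ only in the
"neither" class of probability 1/1296 — about 0.073 expected individuals
in an F2 of 95. At that sample size they are statistically
near-indistinguishable: p-value ranking never prefers the allelic
variant (the nonallelic one has an extra positive-expectation class,
hence df 3 vs 2 and a larger p at near-equal χ²), while χ²-ranking would
instead misassign much of the nonallelic data. Model-recovery
simulations therefore show ≥99% recovery for the disomic models and
tetrasomic-nonallelic, and confusion strictly within the tetrasomic pair
for tetrasomic-allelic data. Discriminating those two models requires
either far larger families (to observe the 1/1296 class) or different
marker configurations; the disomic/tetrasomic and allelic/nonallelic
contrasts that matter for the biology are recovered essentially always.

## Association statistics

Contingency tables cross queried markers with population clusters; an
accession carrying two or more of the queried markers (a heterozygote)
or none of them is excluded, and the exclusion count is reported.
Cramér's V = sqrt(χ² / (n (min(r,c)−1))) uses the Pearson χ² of
independence; all-zero rows/columns are dropped with a warning first. V
equals 1 exactly when one variable determines the other along the
smaller dimension. Significance comes from Fisher's exact test: for 2×2
tables the one-tailed p is the hypergeometric tail in the direction of
the observed deviation, and the two-tailed p is the probability-mass
method — the sum over tables whose probability does not exceed the
observed table's by more than a relative 1e−7 (the dominant software
convention). Larger tables are totally enumerated up to a 10⁷-table
guard, beyond which seeded Monte Carlo must be requested explicitly;
one-tailed p is undefined beyond 2×2.

Marker frequencies are computed over subgenome allele slots: each
accession is diploid within a subgenome (2 slots), a sole carrier is
taken as homozygous (2 slots for its marker), and a two-marker carrier
contributes 1 slot to each.

Evanno's ΔK uses L′(K) = mean L(K) − mean L(K−1),
|L″(K)| = |L′(K+1) − L′(K)| and ΔK = |L″(K)| / sd(L(K)) with the
**sample** (n−1) standard deviation across runs (the original
formulation is ambiguous on this point); ΔK is undefined at boundary K
and flagged where the sd is zero. The Bayesian clustering itself is out
of scope — cluster assignments and ln P(X|K) tables are inputs.

Pollination assays score incompatible at <20 penetrating pollen tubes
(compatible crosses typically show >100), with a stricter <10 criterion
available as a sensitivity flag; where tubes were not assessed, silique
length <5 mm marks incompatibility. Exactly 20 tubes (or 5.0 mm) falls
between the two published phrasings and is scored compatible here.

## Divergence dating

T = K/2r assumes a strict molecular clock. Two bundled rates: a
fossil-calibrated synonymous rate of 1.5×10⁻⁸ ± 0.5×10⁻⁸ per site per
year (consumes Ks, generation-time independent) and a
mutation-accumulation rate of 7.1×10⁻⁹ ± 0.7×10⁻⁹ per site per
generation (consumes total K; divided by the generation time, default 2
years, configurable because annual accessions exist). The published "±"
terms are not defined as SE or half-width; they are read here directly
as the 95% bounds — a documented interpretation, not a claim about the
original authors' intent. The CI of T pairs the upper K bound with the
lower rate bound and vice versa; lower bounds are truncated at 0. Mean K
across loci uses the among-locus sd/√n for ≥2 loci and the analytic
per-pair SE for a single locus. Feeding a Ks-calibrated rate with total
K (or vice versa) is a validation error.

## Synthetic-data generator

The generator emulates the statistical structure of the study system; it
is the fixture for every end-to-end test.

* **Sequences** evolve by a per-site independent substitution process
  with equal exchange rates (the Jukes–Cantor process) on a star
  genealogy: haplogroup founders at (between − within)/2 from a common
  ancestor, tips at within/2 from their founder, so between- and
  within-group tip paths are exactly `between_divergence` and
  `within_divergence` substitutions/site. This is the matched process
  for the JC estimator, making parameter-recovery tests exact in
  expectation. Defaults (five haplogroups, 600 sites, between 0.09 ≈
  91% identity, within 0.005 ≈ 99.5%) mirror the observed identity
  bimodality. No coalescent genealogy, recombination, indels or rate
  heterogeneity — so passing tests demonstrate estimator correctness
  under the assumed process, not robustness to model misspecification.
* **Accession panels** (default 49 accessions, two clusters) draw one
  marker per subgenome from cluster-specific frequency vectors;
  heterozygotes (default rate 0.02, roughly one per panel) carry a
  second marker on subgenome 1, mirroring the single observed
  heterozygote in the surveyed panel. Markers within a cluster are
  mutually exclusive by construction, which is what makes perfect
  cluster-partitioned specs yield Cramér's V = 1.
* **F2 populations** sample two independent gametes per locus per
  individual from the exact gamete distribution, so observed class
  frequencies converge (binomially) to the inheritance module's exact
  rationals; agreement is tested at n = 10⁵–10⁶ with 3-SE bounds.

All generators take one seed and are byte-deterministic under it.

## Problem sizes

Default test and acceptance problem sizes were chosen as the smallest
that make the statistical assertions sharp: 100 seeds at L = 10 kb for
JC parameter recovery, 20 random 8-leaf trees for NJ consistency, 1000
seeded F2 families of 95 per model for the recovery confusion matrix,
10⁵–10⁶ F2 draws for convergence checks, and 10⁴ accessions for panel
frequency convergence. The whole suite runs in well under a minute.

## Known limitations

* Distances: no maximum-likelihood or gamma-rate-heterogeneity
  corrections; no codon substitution models.
* NJ only (no ML/Bayesian trees, no bootstrap supports in v1).
* Inheritance: no double-reduction coefficient, no likelihood-based
  model selection (AIC), no linkage estimation; the tetrasomic pair is
  near-unidentifiable at small family sizes (see above).
* Identity percentages depend on the gap convention; ours (pairwise
  deletion) is documented, not claimed identical to any published
  convention.
* Dating assumes a strict clock and user-supplied divergences; no
  relaxed-clock modelling.
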