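# Methods

This note documents the models and procedures implemented in `teclass`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Evolutionary distances (module `jtt`)

Distances are estimated under the JTT-1992 empirical amino-acid model.
The generator is built from the published integer exchangeabilities and
stationary frequencies (the `jones.dat` data distributed with standard
phylogenetics tools), as Q_ab = S_ab·π_b off-diagonal, rows summing to
zero, scaled to one expected substitution per site at stationarity. The
model is time-reversible; transition matrices P(t) = exp(Qt) are computed
by eigendecomposition of the symmetrized generator (numerically exact
symmetry, entries clamped at zero against round-off).

The pairwise distance is the maximum-likelihood divergence time: only
columns where both sequences carry canonical residues enter the
likelihood (*pairwise deletion*; gaps and ambiguity codes B/Z/X/J/U/O/*
count as missing), the site patterns are collapsed to a 20×20 count
matrix, and the likelihood Σ c_ab·log(π_a·P_ab(t)) is maximized by bounded
scalar optimization on [1e-6, 10] with tolerance 1e-8. The count matrix
is symmetrized first, which is information-preserving under reversibility
and makes the estimate exactly invariant to argument order. Estimates at
the upper bound are reported as 10 substitutions/site and flagged
`saturated` (downstream matrix algebra needs finite values); pairs with
fewer than 20 shared sites are flagged `low_coverage`; zero shared sites
is an error naming the pair. Rates are uniform across sites — no gamma
heterogeneity — which matches the simulation model used for validation;
it is an extension point, not a claim about real alignments.

The estimator was cross-checked two ways: against an exhaustive
grid search of the likelihood (step 1e-4, agreement within 2e-4) and,
during development, against an independent phylogenetics package's JTT ML
distances (agreement to ~1e-7 on a simulated pair).

## Tree building (module `trees`)

The tree criterion is minimum evolution with OLS branch lengths. The
search is the standard realization: a neighbor-joining starting tree
(Q-criterion, ties broken by the smallest row/column pair so exact ties
are deterministic; negative pendant estimates clamped at zero) followed by
greedy nearest-neighbor-interchange hill climbing, accepting per sweep the
best move that strictly decreases the sum of OLS branch-length estimates
(tolerance 1e-10). OLS lengths solve the normal equations of the
path-length system; the ME criterion uses the raw estimate sum, while the
reported branch lengths are clamped at zero. On additive matrices this
recovers the generating topology and branch lengths to machine precision.

Bootstrap supports resample alignment columns with replacement (seeded),
recompute the distance matrix under each replicate's own pairwise-deletion
masks, rebuild the tree with the same NJ+NNI procedure, and score each
internal edge of the point-estimate tree by the percentage of replicates
containing its bipartition. Supports attach to the point-estimate tree; a
majority-rule consensus writer is provided separately. A replicate whose
columns leave some pair with no shared sites is redrawn (at most ten
times). Rooting places the root at the midpoint of the edge subtending a
(checked) monophyletic outgroup; per the delineation protocol, subfamily
trees are rooted with up to three sequences from the partner subfamily
with the highest z.

## Subfamily delineation (module `subfamilies`)

For two groups A and B the statistic is

z = (d̄_AB − d̄_intra) / √(σ̄²_AB/N_inter + σ̄²_intra/N_intra)

where d̄_AB averages all |A|·|B| cross distances, d̄_intra pools the two
within-group pair sets weighted by pair counts, and the variances are
population variances pooled the same way (configurable to n−1). Two count
conventions are supported because "number of taxa used" is ambiguous
between distances and sequences: `counts="pairs"` (default) divides each
variance by the number of distances entering its mean; `counts="taxa"`
divides by |A|+|B|. Both are tested; the acceptance rule z > 3.3
corresponds to a one-sided standard-normal tail of 4.8e-4 (< 0.001).
When both variances vanish (constant blocks), z is reported as +inf with a
`degenerate` flag when the means separate, and 0 on exact equality;
variances below 1e-30 are snapped to zero so this path triggers
deterministically. A valid partition requires every pairwise z above the
threshold and every group to hold ≥ 5 sequences from ≥ 5 distinct species
(the strict reading; both knobs configurable).

The initial proposal automates the qualitative "break the supported tree
into apparent subfamilies" step: an unrooted clade is identified with the
minority side of a supported internal edge (both sides when the split is
even), candidates meeting the membership rule are accepted greedily from
largest to smallest skipping overlaps — so nested qualifying clades
resolve to the outermost — and everything else starts non-grouped.

Refinement is a deterministic greedy surrogate for manual curation, and
the action order is a package choice, logged per step for audit: while
validation fails, (1) groups violating the membership rule dissolve to
non-grouped; (2) if the worst pair's union is a clade of the guide tree,
merge; (3) otherwise eject the single member of the worst pair whose
removal maximally increases the minimum z (ties to the lexicographically
smallest id). The loop is capped at 10·j iterations and either returns a
partition that validates (possibly with fewer groups, or none) or raises
carrying the best partition found.

## Specificity quantitation (module `specificity`)

The assay model: a 2 mL medium sample spiked with 10 µg heptanoic (7:0),
10 µg undecanoic (11:0) and 20 µg heptadecanoic (17:0) acid. An analyte's
concentration is (area_analyte/area_IS) × response factor × [IS], the
standard chosen by carbon number: ≤ 9 → 7:0, 10–12 → 11:0, ≥ 13 → 17:0.
C9 is unassigned by the stated C4–C8 / C10–C12 ranges; it maps to 7:0
(nearest standard below), configurable. Molar response factors default to
1.0 for every analyte — IS-relative quantitation without response curves —
and are configurable per species. Net production subtracts the
empty-plasmid control strain's concentrations per species, clamping
negatives at zero (with a log entry; compositions are non-negative by
definition). Mol% uses the fatty-acid total as denominator; methylketones
(2-ketones, quantified the same way via their carbon count) are reported
relative to that same fatty-acid total, so fatty-acid mol% alone sums to
exactly 100.

## Class clustering (module `clustering`)

Profiles are compared by Euclidean distance on mol% vectors (absent
species = 0). Ward's method is the classical minimum-variance
agglomeration, implemented as the Lance–Williams recursion on squared
distances; the reported merge height is the increase in total
within-cluster sum of squares, and ties break to the smallest cluster
indices (scipy numbering). The implementation matches both scipy's
`linkage(..., "ward")` and a brute-force greedy agglomeration oracle on
small instances.

Multiscale bootstrap resamples the composition features (species columns)
with replacement: at each scale r ∈ {0.5, 0.6, …, 1.4}, ⌈r·m⌉ of the m
columns are drawn, the profiles are reclustered, and each point-estimate
node's presence frequency BP(r) is recorded. The AU p-value per node comes
from weighted least-squares probit regression of Φ⁻¹(1−BP(r)) on
{√r, 1/√r} with binomial-variance weights: AU = 1−Φ(v̂−ĉ), and the
bias-corrected BP = 1−Φ(v̂+ĉ) is kept alongside (reports carry both, since
either may be what a reader expects as "the p-value"). BP values are
clipped to [1/(B+1), B/(B+1)] before the transform; a node at the boundary
at every scale carries no curvature information, so the boundary value is
reported directly rather than forcing the regression through clipped
constants. The small feature count typical of fatty-acid panels (~11–14
species) limits AU accuracy; treat AU on such panels as indicative.
The class cut takes k = 3 by default (the structure observed for these
enzymes) but k is a parameter, and mean silhouette widths for k = 2…6 are
emitted as a diagnostic. Classes are numbered by decreasing size.

## Synthetic data (module `synthetic`)

The sequence generator emulates subfamily structure: k clades (default 3)
of m tips (default 10), each a random nested subtree whose tip depths are
drawn U(0.5, 1)·intra_depth (default 0.1 substitutions/site) — random
depths give realistic within-clade distance variance, keeping z
denominators non-degenerate — joined by stems of stem_length (default 1.0).
Alignments (default 300 columns) evolve site-wise under the JTT process:
root states from π, branch transitions sampled from P(t). The generator
produces no indels, no rate heterogeneity and no alignment error, so
passing recovery tests show the statistical machinery is correct, not that
real alignments are this clean.

The profile generator draws mol% vectors from Dirichlet(c·archetype/100)
around three archetypes (C14/C16-dominant; bimodal C8+C14; C8-dominant)
with concentration c = 200 — tight, well-separated classes — eight
profiles per class; totals are lognormal (median 200 nmol/mL, σ = 0.8 on
the log scale, spanning the ~9–1400 nmol/mL range observed for expressed
TEs); the control background defaults to the empty-plasmid strain's
dominant products (8:0 = 2.0, 14:0 = 3.5, 16:0 = 3.1 nmol/mL). Peak tables
are emitted by inverting the internal-standard arithmetic so the entire
quantitation path is exercised; with noise disabled the pipeline output
equals the generating mol% to 1e-9 (measured: ~1e-14).

## Validation studies and problem sizes

`teclass.studies` packages the validation experiments run by the test
suite and `scripts/acceptance.py`: the z-threshold tail probability;
distance-vs-grid-oracle agreement (20 pairs, 200 sites); NJ+OLS recovery
on random additive 4–5 taxon matrices (20 cases); the 4+4 toy z against
direct arithmetic; subfamily recovery on 20 seeded three-clade simulations
(bootstrap effort 25 replicates per seed — stems of length 1.0 are
essentially unanimous, so modest replicate counts resolve the ≥ 70%
support rule cleanly); null calibration on 200 seeded splits of a
homogeneous clade; the noise-free quantitation round-trip; class recovery
with AU support on 20 seeded three-class simulations (1000 replicates ×
10 scales); and the k = 3 classification of composition vectors assembled
from published headline values (`teclass.datasets`, whose unreported
minor components are a uniform synthetic completion).

## Known limitations

- The ME search explores NNI moves only; no SPR/TBR. Adequate at the
  sizes validated here; large, noisy matrices may retain NNI-local optima.
- Uniform-rate JTT only; no among-site rate variation or alternative
  empirical matrices (WAG/LG).
- AU p-values inherit the small-m caveat above, and the refinement loop
  is a surrogate for expert curation — its audit log should be read, not
  trusted blindly.
- Molecular weight and pI depend on the chosen mass table and pKa set
  (average masses and the Bjellqvist set by default, both configurable);
  published "theoretical pI" values computed with other sets will differ
  by tenths of a pH unit.
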