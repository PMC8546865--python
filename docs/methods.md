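# Methods

This note documents the models, conventions and design choices behind
`plastimine`, in the order the pipeline runs.

## Synthetic study generator

The generator (`plastimine.synthetic`) emulates the inputs of a global
metagenome mining survey; it is first-class, tested code, and every
downstream number in the tests is checked against its ground truth.

**Sequences.** Enzyme families are built from i.i.d.-uniform ancestral
proteins (20-letter alphabet, default length 200); members substitute each
position independently at rate `within_family_divergence` (default 0.2),
always to a different residue, so expected identity to the ancestor is
`1 − d` and between two members `(1 − d)² + d²/19`. Background genes are
i.i.d. draws from a uniform residue background — the same null the scorer's
decoys assume. The control catalog is half background and half
"near-decoys": per-sequence residue shuffles of family members, i.e.
composition-matched negatives with no positional signal, which stress the
calibration filter the way shared-ancestry gut homologues do in real data.

**Geography and pollution.** Samples get uniform coordinates, depth layers
drawn as surface (5 m) / deep-chlorophyll-maximum (~71 ± 41 m) /
mesopelagic (~600 ± 220 m), habitat labels from eight ocean regions, and a
latent pollution field: a superposition of four broad Gaussian bumps over
the globe plus a small white component (so nearby samples see similar
pollution and no two samples tie). Surveys measure
`scale_k · exp(γ_k (field + ε))` at coordinates jittered ≤ 0.3° around
their samples, with per-survey scale factors (1, 10, 250, 1000) and
exponents γ — strictly monotone, survey-specific distortions, with
measurement noise sd 0.05 in field units chosen small enough that each
survey's within-survey rank order tracks the field closely (the pooling
stage is exactly rank-preserving under such distortions, so larger noise
would only blur the ground truth the recovery tests rely on).

**Count coupling.** Per-sample planted-homologue counts follow a Gaussian
copula on the field ranks: the latent count variable has Pearson
correlation `2·sin(π·ρ_s/6)` with the field's normal scores, giving
population Spearman exactly `target_rho` for any field marginal; counts are
a rounded monotone map of that latent variable (mean
`planted_fraction × genes_per_sample`, spread 8 genes — wide enough that
discretisation ties attenuate the empirical Spearman by well under the
±0.05 convergence tolerance checked at n = 500). At `target_rho = ±1` the
map switches to a strictly rank-preserving integer sequence so the
empirical Spearman is exactly ±1 (guaranteed while
`genes_per_sample` can hold the largest count, which holds at the
defaults).

**Defaults as study conditions.** 20 families × 4 curated members,
40 samples × 100 genes, planted fraction 0.2, 2000 control genes,
4 surveys, `target_rho` 0.5. These sizes keep the full pipeline under
~20 s on one CPU while leaving every separation margin (planted vs decoy
scores, per-family data points vs the 20-point gate) wide.

**What the generator does not emulate:** real protein domain structure,
indels (members are substitution-only, so alignments to the representative
are gap-free), phylogenetic correlation within families, assembly and
gene-calling artifacts, compositional bias of real metagenomes, and spatial
autocorrelation of sampling effort. Passing tests therefore demonstrate the
pipeline's logic and calibration under a clean null — not performance on
real survey data, where identity distributions and contamination structure
are harsher.

## Model library

Identity is the number of identical columns of a global alignment
(match +1 / mismatch 0 / linear gap −1) divided by the shorter sequence's
length — the common semantics of greedy clustering tools. Clustering is
exact greedy: records sorted by descending length (ties lexicographic by
id), each joining the first representative matched at ≥ cutoff. This
deliberately replaces heuristic accelerator settings of production
clustering tools with a deterministic, oracle-checkable procedure.

Homolog expansion assigns a database sequence to every identity bin whose
cutoff it meets (cumulative mode, the default: per-cutoff model counts then
grow with looser cutoffs, matching how stratified libraries are reported);
a `bracket` mode assigning each sequence only to its own identity bracket
is provided because published descriptions are compatible with either. The
representative belongs to every bin, so bins are never empty and bins are
nested (cutoff c ⊇ cutoff c′ > c).

Models are position-specific log-odds matrices over the representative's
columns with plus-one pseudocounts, `log2((count+1)/(n+20) / q)`. The
payload is an opaque, scorer-owned object so an external profile-HMM
builder can stand behind the same interface.

## Search and E-value calibration

The built-in scorer is the best ungapped window log-odds score in bits;
ungapped scanning is sufficient at the generator's divergence levels and
keeps the scorer deterministic and fast. Statistical calibration is
empirical, from seeded residue-shuffle decoys of the searched catalog
(default 10,000 decoy scores per model, one shared decoy pool per catalog):

    E(s) = N_catalog · (1 + #{decoy ≥ s}) / (1 + N_decoys)

inside the decoy score range. The plus-one numerator floors this at
`N_catalog/(1+N_decoys)` (≈ 0.2 at the defaults), which can never certify
hits at the stringent E < 1e−16 gate the filter uses; above the largest
decoy score the survival function is therefore continued with an
exponential tail, `E(s) = E(s_max) · exp(−(s − s_max)/β)`, where β is the
maximum-likelihood mean exceedance of decoy scores over their 90th
percentile. The tail matches the asymptotically exponential upper tail of
ungapped log-odds score distributions, keeps E(s) continuous, strictly
positive (floored at 1e−300) and non-increasing, and remains purely
decoy-driven. True homologues sit hundreds of bits above the decoy maximum,
so their extrapolated E-values clear 1e−16 by many orders of magnitude,
while background genes — at most a few bits above it — never do.

Deduplication keeps one hit per gene across all models: minimal E-value,
ties by maximal bit score, then lexicographic model id. Both the
environmental and control tables are deduplicated before calibration (the
symmetric choice; a per-model mode exists behind a flag).

## Calibration gates

Per model, environmental hits are positives and control hits negatives.
The PR curve uses thresholds at each distinct score (descending, ties
grouped); PR-AUC is the trapezoid over recall anchored at
(recall 0, precision of the highest-score point) — a step-wise
average-precision alternative is available behind a flag and is tested
against scikit-learn's implementation. Retention requires, in order:
≥ 20 data points (environmental + control combined; an
environmental-only counting mode exists behind a flag), AUC ≥ 0.75, and a
score threshold — the smallest distinct score whose precision reaches
0.9999, i.e. maximal recall at the precision target, with hits kept at
score ≥ threshold. Final hits additionally require E < 1e−16 (strict).
Raising the precision target can only shrink the surviving set
(monotonicity, tested). Models with no hits at all are counted as not
retained when the retained fraction is reported against the library size.

## Aggregation conventions

Percentages (e.g. additive shares) are rounded to integers and ratios to 3
significant figures, matching how survey tables are printed. The summary
table's mean row is the plain arithmetic mean of the per-dataset rows (the
packaged published counts are consistent with a plain mean); it is labeled
"mean". The packaged per-dataset counts (`data/study_counts.tsv`) and the
library-size constants (1201 built / 121 retained models) are inputs taken
from the published survey so the dataset-level arithmetic can be recomputed
exactly. Genome-bin profiles exclude hits on unbinned genes but leave them
in the overall totals.

## Statistics

Two-tailed tests are the default; one-tailed only where a directional claim
is tested (Fisher enrichment, directional habitat comparisons). Spearman
uses average ranks and the t approximation (n − 2 df). The rank-sum test
enumerates the full permutation distribution of the tie-averaged rank sum
when the combined sample is ≤ 12 (C(n, n₁) ≤ 924 subsets) and otherwise
uses the tie-corrected normal approximation; the two backends agree within
10% on n ≥ 20 (tested against a 10⁵-permutation oracle). Fisher enrichment
is the upper hypergeometric tail with fixed margins. Bray-Curtis is
`1 − 2Σmin/(Σu+Σv)` with all-zero row pairs flagged NaN. PCoA is classical
scaling (double-center −D²/2, symmetric eigendecomposition); negative
eigenvalues are dropped with no Lingoes/Cailliez correction and variance
fractions are taken over the positive eigenvalues, so reported fractions
are non-negative, non-increasing and sum to ≤ 1. The PCoA feature space is
counts per retained model per sample (finer than plastic type; a per-type
mode is a one-line change in the driver).

## Pollution linkage

Haversine distances use the IUGG mean Earth radius 6371.0088 km; the choice
of radius moves distances by < 0.3‰ and no conclusion depends on it.
Box-Cox λ is fitted by bounded profile-likelihood search on [−5, 5] to
1e−6; non-positive survey values are shifted by `1 − min` first (recorded
per survey, so the transform is reproducible). Standardization is
per-survey (Box-Cox then z-score within each survey) before pooling — a
global mode would let the survey with the widest dynamic range dominate the
pooled scale. Matching keeps the single nearest point per sample within
the radius, ties broken by (survey id, point index). The trend line is
Siegel's repeated median (50% breakdown): the median over points of the
median pairwise slope, pairs at equal abscissa excluded, intercept the
median of `y − slope·x`. Country-level linkage for soil-style data is an
exact join on a country key rather than spatial matching.

At the defaults the end-to-end recovered correlation between *final
filtered* hit counts and the pooled field sits below the generator's
`target_rho`: the coupling is defined on planted counts, and calibration
losses (families whose models miss the 20-point gate) plus n = 40 sampling
error attenuate the pipeline-level estimate. The recovery checks therefore
target the generator's own coupling (planted counts, n = 60), where the
estimate is within ±0.15 of the target across matching radii.

## Numerical and degenerate-input conventions

Zero rank variance makes Spearman undefined — flagged, not raised. Empty
groups in the habitat scan are skipped with a note; fewer than 3 matched
samples at a radius omits ρ with a note. All RNG streams are
`numpy.random.Generator` seeded via tagged `SeedSequence`s from one integer
seed; fixed seed gives byte-identical FASTA/TSV outputs (fixed float
formats, no locale-dependent formatting). Residue `X` is accepted in
curated records and scored as the first alphabet letter (a deliberate
simplification; curated inputs here never contain it).

## Known limitations

Ungapped scoring underestimates homology across indels; the exponential
E-value tail is an extrapolation — honest for ranking and thresholding at
these scales, but not a substitute for analytic profile-HMM statistics on
real data. The greedy clusterer is quadratic and meant for curated-catalog
sizes (~10²–10³ sequences), not metagenome-scale gene sets. The synthetic
generator's independence assumptions (uniform background, i.i.d.
substitutions) make separation easier than in real metagenomes; thresholds
that pass here should be re-calibrated on real negative controls before any
biological claim.
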