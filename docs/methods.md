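# Methods

## Endpoints

The classification endpoint is binary hTTR binding activity from the
ANSA-based competitive fluorescence displacement assay: a compound is
*active* (class A) when its median displacement activity is at or above 50%,
*weak/not active* (class I) below.  Replicate median activities must agree on
a side of the cutoff; straddling replicates raise an explicit conflict rather
than being silently averaged.

The regression endpoint is Log RP, the base-10 logarithm of the relative
competitive potency RP = EC50(T4) / EC50(compound), with replicate EC50s
combined as the arithmetic mean of the RP values before the log transform.
Base 10 is assumed: it is the convention under which the literature
strong-binder cutoff Log RP ≥ −1.26 is stated, and the sign convention
(positive = out-competes T4) only holds with the T4 affinity in the
numerator.  The T4 reference EC50 is a configuration value, not a constant:
it is assay-dependent and not something the package should hard-code.

## Curation

QSAR-ready structures are single-component, neutral, metal-free organics.
Operational proxies: dot-disconnected SMILES are salts (if any fragment is
charged or a lone metal atom) or mixtures; elements outside
{H, C, N, O, F, S, P, Cl, Br, I, Si, B} mark organometals; a `*` atom marks a
polymer; any formal charge marks a charged structure.  Stereochemistry is
stripped before deduplication (2D descriptors cannot see it), so
stereoisomers collapse to one non-chiral record; this is switchable.
Canonicalization uses RDKit's canonical SMILES.  The canonical *string* is an
implementation detail — all descriptor values are invariant to the input
notation, which is what the tests pin down.

## Descriptors

Seven 2D descriptors are computed natively from the molecular graph.  Two
graph conventions are used, following the reference 2D-descriptor software:
autocorrelations and information content see the hydrogen-explicit graph;
path counts and topological charge indices see the hydrogen-suppressed
heavy-atom graph.  Aromatic bonds carry conventional order 1.5.

* **ATSC_d(w)** (centered Broto–Moreau): Σ over unordered atom pairs at
  topological distance d of (w_i − w̄)(w_j − w̄); at d = 0, Σ(w_i − w̄)².
* **AATSC_d(w)**: ATSC divided by the number of contributing terms (atoms at
  lag 0, pairs at lag d).  AATSC0 is the population variance of the property.
* **GATS_d(w)** (Geary): [Σ ordered-pair (w_i − w_j)² / 2Δ_d] /
  [Σ(w_i − w̄)²/(n − 1)].  A homoatomic graph has zero denominator and
  returns a configurable degenerate value (default 0, logged); real PFAS
  never trigger it.
* **MIC_k**: atoms are partitioned by iterated neighborhood symmetry
  (radius-0 classes split by element; each refinement appends the sorted
  multiset of (bond order, neighbor class)); the information content in bits
  weights each atom's term by atomic mass: −Σ_g (M_g/M)·log2(n_g/n).
* **piPC_k**: ln(1 + Σ over simple paths of exactly k bonds of the product
  of conventional bond orders), by exhaustive DFS.
* **GGI_k** (Gálvez): M = A·D\* with A the *binary* adjacency and D\* the
  inverse-square distance matrix; GGI_k = Σ_{pairs at distance k} |M_ij − M_ji|.

Property weights (bundled, versioned element table): atomic mass, Sanderson
electronegativity, and atomic polarizability in Å³, all unscaled.  Sanderson
(rather than Pauling) electronegativity and binary (rather than bond-order)
GGI adjacency were fixed by calibration against the printed descriptor
values of reference compounds: with these conventions the engine reproduces
the published training-set extremes exactly to printed precision —
piPC5 = 2.3 for perfluorobutanoic acid, piPC5 = 4.6 and GGI9 = 0.74 for
perfluorotetradecanoic acid — and places frozen-equation Log RP predictions
for the perfluorocarboxylic homologous series in the experimentally observed
range, with the known inverted-U chain-length trend.  The alternatives
(Pauling, carbon-scaled properties, weighted adjacency) each break at least
one of these anchors.  Correctness of the implementations themselves is
established against independent brute-force enumeration oracles on every
connected graph of up to 7 nodes.

Descriptor-matrix filtering removes near-constant columns (modal value on
more than 80% of compounds), columns spanning more than two orders of
magnitude (absolute span > 10², the simple reading of an ambiguous rule;
configurable), and the alphabetically later member of any pair with
|Pearson r| > 0.95 (deterministic tie-break).

## Model development

**Splitting.**  Within each stratum (activity class for classification, the
whole set for regression) descriptors are autoscaled, compounds ranked by
first-principal-component score, and every third rank assigned to the test
set.  Systematic 1-in-3 sampling along the structural ranking keeps both
sets spanning the chemical space, which is the point of splitting "by
structure"; head/tail variants would not.

**LDA** is the canonical two-class discriminant with pooled within-class
covariance (denominator n − K, matching the reference implementations to
1e-8), empirical priors by default, autoscaled inputs (scaler stored in the
model), posteriors by softmax of the class scores, and exact score ties
resolved to class A — the precautionary choice for a hazard screen.
**OLS** is fit on raw descriptors so coefficients are directly comparable to
the published equations; the model stores coefficient standard errors, the
inverse design cross-product (for leverages and prediction intervals) and
the training response range.

**Step-up selection** keeps a population of the best 25 subsets at each
size (MR criterion for LDA, R² for OLS); size-k candidates extend each
retained size-(k−1) subset by one descriptor.  With an unbounded beam it
degenerates to exhaustive search, which is how it is tested.

**Leave-one-out bootstrap**: B = 100 resamples with replacement; each
compound's error is averaged over the resamples where it was out-of-bag
(plain OOB, not 0.632 — switchable); the reported spread is the SD over 5
repeats of the whole procedure.  Resamples missing a class are redrawn (at
most 100 retries, logged).  The suggested model size is the smallest k whose
successor improves the bootstrap error by no more than a tolerance
(default 0.005) — flattening or increase signals overfitting.

**Randomization**: the full step-up selection is rerun (default 100 times)
on columns redrawn uniformly within their ranges, or respecting each
column's detected nature (binary → Bernoulli at the observed frequency,
integer → uniform integers, continuous → uniform).  Both the empirical
exceedance fraction and a normal-tail probability fitted to the run criteria
are returned; the normal-tail value is the headline number because it
resolves probabilities below 1/runs, which the empirical fraction cannot.
**Y-scrambling** reports the mean training R² over 50 response permutations.

Metrics: ACC/MR/SN/SP/P from confusion counts with class A positive; AUC by
the rank (Mann–Whitney) statistic with tie averaging; Q²_LOO by refitting
without each compound; Q²_F3 = 1 − (PRESS_test/n_test)/(TSS_train/n_train).
Degenerate denominators yield NaN with a warning, never a crash.

## Applicability domains and uncertainty

*Classification*: a query is structurally outside when the mean cosine
similarity to its 3 nearest training compounds falls below the threshold set
at 95% training coverage (the 5th percentile of the training k-NN similarity
distribution).  Similarities use raw descriptor vectors: descriptor values
share a common orientation, which is what makes training thresholds land
close to 1; autoscaling would center the cloud and spread cosines over
[−1, 1], destroying the check's resolution (a fitted scaler can still be
supplied).  The endpoint check flags posteriors in (0.25, 0.75) as
uncertain; the entropy check compares the prediction's Shannon entropy
(nats; the rule is base-invariant) with the maximum training entropy.  For
two classes the band and entropy checks coincide when the band is symmetric;
both are computed because they generalize differently.

*Regression*: structural check h ≤ h\* = 3(p+1)/n (raw h always reported —
reliability degrades continuously beyond the cutoff); response check:
prediction inside the training response range; uncertainty check:
t-based 95% prediction-interval width (ŷ ± t·s·√(1+h)) within the training
maximum.  Standardized residuals beyond ±2.5 flag response outliers on the
training side.  A prediction is reliable only if every component check
passes.

## Frozen models and screening

The published full-dataset equations are frozen exactly as printed (rounded
coefficients and all) and kept distinct from anything refit by this package.
The prior terms use the natural log — the canonical LDA form; base 10 would
shift both scores by a near-common constant and almost never flip the
argmax.  The sequential screen classifies every compound, sends reliable
actives to the regression, and tiers results as weak/not active,
active-moderate, active-strong (Log RP ≥ −1.26, inclusive), or unreliable;
per-compound failures are logged and never abort a batch.

## Synthetic data

The generators define the test conditions.  Classification: two Gaussian
clouds with shared unit covariance, class sizes defaulting to 74/49 (the
modelled dataset's class balance) and mean separation δ along one axis, so
the Bayes accuracy Φ(δ/2) is known in closed form.  Regression: y = Xβ + ε
with n = 43, p = 3 and noise chosen from the population identity
σ = ‖β‖·√((1−R²)/R²) to target R² = 0.8, the modelled dataset's geometry.
The fluoroalkyl SMILES generator builds CF3-(CF2)k chains with carboxylic,
sulfonic, telomer-alcohol, ether-acid, amide and sulfonamide heads, drawn
without replacement so batches contain no duplicates, and every output
passes curation.  All randomness flows through numpy's PCG64 with explicit
seeds; a fixed seed regenerates bit-identical data.

What the synthetic data does not emulate: assay noise structure, the real
descriptor correlation structure of heterogeneous PFAS, or activity cliffs
between near-neighbour structures.  Passing tests therefore demonstrate the
correctness of the machinery and the statistical behaviour of the
procedures, not the biological performance of refit models on new assay
data.  Reproducing the published refit statistics (e.g. the 121-compound
classification accuracy) requires the external modelled dataset, which the
package deliberately does not bundle; the screen of the full OECD PFAS
inventory is likewise out of desk scope, and the screening logic is
exercised end-to-end on fluoroalkyl fixture batches instead.

## Numerical notes and sizes

Homoatomic property vectors short-circuit to exact zeros (avoiding 1e-30
residue from mean subtraction).  PC1 sign is fixed by making the
largest-magnitude loading positive; PC1 ties are broken by input order.
Zero response variance reports R² = 0 (with a warning) rather than NaN in
fit paths, and NaN in metric paths.  Simulation sizes in tests and the
acceptance script (50 oracle datasets, 200 prediction-interval replicates,
40 randomization runs, 36 + 20 compound screening batches) were chosen so
Monte-Carlo error sits comfortably inside the asserted tolerances while the
suite stays fast.
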