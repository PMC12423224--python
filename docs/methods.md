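# Methods

## The problem

Data-driven subtypes of type 2 diabetes (SIDD, SIRD, MOD, MARD) are
assigned by the nearest-centroid rule: an individual's clustering features
(age at diagnosis, BMI, HbA1c, HOMA2-B, HOMA2-IR) are standardised with
sex-specific means and SDs, and the individual is given the subtype whose
sex-specific centroid is closest in Euclidean distance. Hard assignment
discards how *well* the individual matches that prototype. This package
quantifies the discarded information and propagates it into downstream
outcome analyses.

## Model and procedure

**Classification probabilities.** Given distances d_1..d_K to the K
centroids, soft membership probabilities are obtained by normalising
inverted distances:

    p_k = (1/d_k) / sum_j (1/d_j)

This is the primary construction. It is scale-invariant in the distances:
multiplying every d_k by a constant leaves p unchanged, so only the
relative geometry of the centroids matters. Two alternative constructions
are available, both requiring explicit parameters (no silent defaults):
softmax, p_k ∝ exp(-d_k/T), and a Gaussian kernel, p_k ∝ exp(-d_k²/2h²).
Neither is scale-invariant. All three are monotone decreasing in each
distance, so argmax p always coincides with the nearest centroid, and the
maximum of a normalised K-vector guarantees p_assigned ≥ 1/K (0.25 for
four clusters).

**Zero distance.** When a point coincides with one or more centroids
(within 1e-12 standardised units, the double-precision floor), the
inverse-distance rule takes its continuity limit: mass is split uniformly
over the coincident centroids and is zero elsewhere.

**Normalised relative entropy.** The probability vector condenses to

    NRE = 1 + (Σ_k p_k ln p_k) / ln K,   with 0·ln 0 = 0,

the Kullback–Leibler divergence of p from the uniform distribution divided
by ln K. NRE = 0 iff p is uniform (complete uncertainty), NRE = 1 iff p is
degenerate (complete certainty). K is taken from the vector length, not
hard-coded to four, so the same code applies to other subtype systems.
Tiny negative values from floating-point underflow (≥ -1e-12) are clamped
to 0. The NRE is deliberately conservative: p_assigned = 0.97 over four
clusters yields NRE ≈ 0.87, and p_assigned = 0.51 with a spread remainder
stays below 0.3 (a 0.51/0.49 coin flip between two clusters, however,
reaches NRE ≈ 0.5 — the bound concerns spread remainders). Because the NRE
is relative, outputs also carry the minimum centroid distance as an
absolute-certainty criterion.

**Eligibility.** Before classification, records are filtered with the
standard inclusion rules: complete clustering information (including sex
and, by default, fasting glucose, C-peptide and GADA), fasting glucose in
[3.0, 25.0] mmol/l, fasting C-peptide in [0.2, 3.5] nmol/l (both ranges
inclusive — the source ranges are written as closed intervals; whether the
original endpoints were inclusive is not stated, so inclusive was chosen
and is flagged here), and GADA < 2 U/ml (GADA-positive individuals belong
to the autoimmune subtype and leave the four-cluster system). Decisions
list every violated rule; the cohort summary tallies one primary reason
per excluded record with precedence missing data > glucose > C-peptide >
GADA, so the counts partition the exclusions. An HbA1c ceiling (a
recruitment-style criterion, not part of the method) is available but off
by default.

**Weighted outcome regression.** A continuous outcome y (e.g. a predicted
10-year CVD risk in %) is regressed on subtype with a one-factor linear
model, once unweighted (OLS) and once with weights w_i = NRE_i (WLS),
both on the identical complete-case subset. In the saturated one-factor
model the fitted subtype mean is exactly the weighted mean of that
subtype's outcomes; this identity is asserted in the tests. 95% CIs for
the predicted means use t-based WLS standard errors with n−K degrees of
freedom (homoskedastic working model). R² = 1 − SSR_w/SST_w with SST_w
about the *weighted* grand mean — the standard WLS convention; the source
analyses do not define their R² formula, so this convention is a design
choice, as is the percentile bootstrap (default 2000 resamples, seeded)
used for median-NRE and R² intervals where no analytic interval is
assumed. A subtype whose total weight is zero is excluded from the design
and reported with undefined estimates rather than extrapolated.

## Reference models are configuration

The published sex-specific centroid coordinates and scaling parameters are
not shipped; they are entered through a documented YAML/JSON schema and
validated (positive SDs, complete per-sex blocks, centroid length equal to
the variable count, ≥ 2 unique clusters). The package ships a synthetic
demo reference whose geometry is a clinically plausible caricature
(centroids roughly 2–4 standardised units apart) and which is labelled
synthetic in the file itself. Per-variable transforms (identity or natural
log, applied before standardisation) are configurable because the
clustering literature varies on whether HOMA indices are log-scaled;
default identity. Sex is a categorical key with no pooled fallback —
pooled centroids require an explicit single-sex configuration.

## Synthetic-data generator

`simulate_cohort` draws each record as z ~ Normal(c_{sex,k}, σ²I) in
standardised space (spherical covariance, matching the geometry the
Euclidean nearest-centroid rule implicitly assumes), destandardises to
native units, and generates the outcome as

    y = effect_k + coupling · ‖z − c_{sex,k}‖ + Normal(0, sd²).

The linear-in-distance outcome is the simplest mechanism under which
certainty weighting provably helps: individuals far from their generating
prototype carry distance-correlated outcome distortion, have lower NRE,
and are down-weighted. This is a modelling choice of the generator, not an
empirical claim about any cohort. A contamination fraction assigns
out-of-range glucose or C-peptide values or a positive GADA titre to
random records to exercise the eligibility rules. One global seed expands
into independent substreams (cohort draw, contamination, outcome noise)
via `numpy.random.SeedSequence`, so identical scenarios and seeds give
byte-identical output files.

Default study conditions (the demo scenario): 25 individuals per sex per
cluster (n = 200), dispersion 0.6 — chosen so that the cohort-level median
NRE lands in the ~0.08–0.15 range typical of real centroid-classified
cohorts — outcome effects SIDD/SIRD/MOD/MARD = 14/12/7/9 (percent-risk
scale), proximity coupling −3 per standardised distance unit, residual SD
1.5, contamination 5%. The replication study of the weighting effect uses
the same generative settings at n = 800 over 200 replicates; the
monotonicity and exact-recovery checks use a four-centroid reference
separated by ~28 standardised units, because with inverse-distance
probabilities an NRE above 0.9 requires the competing centroids to be
roughly two orders of magnitude further away than the own-cluster
distance.

**What the generator does not emulate:** realistic marginal distributions
or correlations of the clinical features, measurement error, assay
differences in GADA units, non-spherical or cluster-specific covariance,
and any real cohort's case mix. Passing tests therefore demonstrate the
*mechanics* of the method — probability construction, entropy algebra,
weighting identities, recovery under the assumed mixture — not its
behaviour on access-restricted clinical data, whose published summary
values (median NREs, predicted risks, cohort R² values) are not
reproducible from synthetic data and are not asserted anywhere.

## Numerical choices

- Probability simplex validation tolerance: sum within 1e-9 of 1.
- Zero-distance tolerance 1e-12; NRE clamp tolerance 1e-12.
- Softmax/RBF stabilised by subtracting the minimum (squared) distance
  before exponentiation.
- Distance ties broken by the reference model's cluster order (first
  wins), with a tie flag in the output.
- Standardise/destandardise round-trip accurate to ~1e-12 relative.
- Human-readable outputs round the NRE to 3 decimals; machine outputs
  (JSONL) keep full precision.

## Known limitations

- The NRE is relative: identical distances to the assigned centroid can
  yield different NREs depending on the other centroids, which is why the
  minimum distance is reported alongside.
- The WLS CIs assume the homoskedastic working model; with strongly
  NRE-dependent residual variance a sandwich estimator would be more
  appropriate and is not implemented.
- No imputation of missing clustering variables and no GADA assay
  harmonisation.
- The bootstrap for R² resamples individuals; other resampling schemes
  (e.g. stratified by subtype) may be preferable for very small subtypes.
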