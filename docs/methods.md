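# Methods

## Problem setting

Susceptibility variants for a heterogeneous disease are assumed to act
through a small number of mechanistic pathways, and variants sharing a
pathway to show similar directional effects across intermediate traits.
Working entirely from GWAS summary statistics, the pipeline (i) clusters
variants by their trait-association profiles, (ii) scores each cluster's
aggregate (genetic-risk-score) association with traits and disease outcomes,
and (iii) estimates causal trait–disease effects with two-sample Mendelian
randomization (MR). No individual-level data are touched; the unit of
information is always a per-variant (allele, β, se, p, EAF, N) tuple.

## Harmonization

All downstream computation assumes effects expressed per copy of the
disease risk-increasing allele declared in a variant panel. For each panel
variant and each trait table the harmonizer applies exactly one action:
`kept`, `allele_flipped` (swap alleles, negate β, EAF → 1−EAF),
`strand_flipped` (complement alleles; β and EAF unchanged — the same allele
on the other strand), `proxy_substituted`, or one of three drops
(`dropped_palindromic`, `dropped_mismatch`, `dropped_missing`). The audit
trail is emitted as a flat table; action counts always sum to the panel size.

**Palindromic SNVs** (A/T, C/G) cannot be strand-resolved from labels.
Policies: `drop`; `keep` (trust labels); `infer_by_eaf` (default): records
with |EAF − 0.5| < 0.08 are dropped as ambiguous; otherwise the nominal
label alignment is used, and — only when the panel supplies a reference
risk-allele frequency (`risk_af`) — the orientation is reversed when the
record's risk-allele frequency and the reference sit on opposite sides
of 0.5. Without a reference frequency no genuine inference is possible,
so the window then acts purely as an ambiguity guard; this is stated here
because silent misorientation of palindromic variants is the classic
harmonization failure mode. Missing EAF on a palindromic variant drops it.
The 0.08 window is the common MR-practice default and is configurable.

**Proxies.** A panel variant absent from a table may be represented by a
declared LD proxy when its declared R² ≥ 0.5 (the independence threshold
used for panel construction; configurable). The proxy's statistics are
oriented to the proxy risk allele *declared in the panel* — no LD-based
phasing is attempted — and relabelled under the panel variant's identity so
downstream stages key on the panel variant; provenance is kept in the audit
detail. Indels and multi-allelic rows are rejected at read time; the panel
is biallelic SNVs only. Positions are carried but never used.

## z-score matrix

z<sub>ij</sub> = β<sub>ij</sub>/se<sub>ij</sub> over harmonized tables, rows
in panel order, one column per configured trait. Variants whose fraction of
missing traits exceeds 0.25 (configurable; the exclusion rule for variants
absent from "most" traits is inherently a judgement call) are removed;
remaining missing cells are imputed to 0 — the null-association value on the
z scale — and flagged in the missingness report. Columns are *not*
standardized by default: z is already unit-free and raw z is what is
clustered; a standardization switch exists for sensitivity analysis.

## Clustering and the choice of k

k-means is Lloyd's algorithm from k-means++ starts, best of `n_restarts`
(default 100) by total within-cluster sum of squares (WSS), deterministic
given a seed, `max_iter` 300, centroid-shift tolerance 1e-8. An empty
cluster is re-seeded at the point farthest from its assigned centroid.
Labels are 1-based and relabelled by order of first appearance so output is
stable; WSS is non-increasing across iterations and the returned solution is
the best restart.

k is chosen by a majority vote of eight internal validity indices, a
deliberately small, well-defined battery that behaves sensibly at a few
dozen rows (the classical 30-index suites include many indices that are
degenerate or unstable at n ≈ 26):

| index | value | best-k rule |
|---|---|---|
| silhouette | mean silhouette width | max |
| Calinski–Harabasz | (B/(k−1))/(W/(n−k)) | max |
| Davies–Bouldin | mean worst pairwise overlap | min |
| Dunn | min inter-cluster gap / max diameter | max |
| gap | E*[log W] − log W, uniform bounding-box refs (B = 100, seeded) | smallest k with Gap(k) ≥ Gap(k+1) − s(k+1) |
| Hartigan | (W<sub>k</sub>/W<sub>k+1</sub> − 1)(n−k−1) | smallest k with H ≤ 10 |
| Krzanowski–Lai | \|DIFF<sub>k</sub>/DIFF<sub>k+1</sub>\|, DIFF<sub>k</sub> = (k−1)^{2/p}W<sub>k−1</sub> − k^{2/p}W<sub>k</sub> | max |
| Ball–Hall | W<sub>k</sub>/k | max successive drop |

Ties break toward the smallest k (parsimony). The report is flagged
`ambiguous` when no k reaches an absolute majority of the votes cast or when
the gap statistic's one-standard-error rule applied at k = 1 prefers the
no-clustering null (`no_cluster_evidence`); an all-identical-rows matrix is
flagged `degenerate` with `chosen_k = None`. Known property: on cleanly
separated k = 3 data the Ball–Hall successive-drop rule votes k = 2 by
construction (its k = 2 drop contains the k = 1 → 2 collapse), so a 7/8
majority is the expected ceiling there.

PCA is a column-centered SVD; variant scores, trait loadings (biplot
arrows) and variance fractions are returned, with the largest-magnitude
loading per component made positive so signs are reproducible. Cluster
naming (e.g. "adiposity") is a reporting-layer annotation driven by the
dominant centroid coordinates, not a computation.

## GRS meta-analysis

The summary-form genetic risk score of a cluster on a trait is the
fixed-effect inverse-variance combination of its member variants' (β, se):
weights 1/se², pooled se (Σw)^{−1/2}, two-sided normal p, Cochran's Q with
k−1 df reported. No random-effects fallback is applied — the fixed-effect
model is the estimand here — and Q is a diagnostic only. At GWAS sample
sizes t-corrections are immaterial, hence normal p-values. Significance
uses α/(n_traits + n_outcomes) recomputed from the configuration (0.05/21 ≈
0.0024 for the canonical 16-trait + 5-outcome grid), never hard-coded.
Clusters missing a variant in a trait pool the available ones and record the
count; zero available variants yields a flagged, non-estimable row. The
two-study GWAS meta-analysis uses the same engine per shared variant after
harmonizing study B's alleles to study A (SE weighting, i.e. the STDERR
scheme of the classical meta-analysis tools); single-study variants pass
through with a source flag.

## Mendelian randomization

Instruments are supplied as exposure/outcome tables in the same dialect as
every other table; instrument selection (clumping, p thresholds) is
upstream of this package. The outcome table is harmonized to the exposure's
effect alleles with the machinery above.

* **IVW** (main analysis): weighted regression of β_Y on β_X through the
  origin, weights 1/se²_Y. `se_mode="fixed"` gives (Σβ²_X/se²_Y)^{−1/2};
  the default `multiplicative_random` multiplies by max(1, φ), φ² the
  weighted residual mean square on n−1 df — the multiplicative
  random-effects convention of the standard MR tooling. The fixed-mode
  estimate is identically the fixed-effect meta-analysis of the Wald ratios
  β_Y/β_X with first-order weights (cross-checked to 1e-10 in tests).
* **MR-Egger**: instruments oriented so β_X ≥ 0, then weighted regression
  with a free intercept; slope and intercept SEs scaled by max(1, φ) on
  n−2 df, p-values from t(n−2). The intercept estimates average directional
  pleiotropy (valid under InSIDE); a nonzero intercept is the sensitivity
  signal.
* **Weighted median**: Wald ratios sorted, weights β²_X/se²_Y (inverse
  first-order ratio variance), estimate = linear interpolation of the
  ratios at cumulative standardized weight p_j = (S_j − w_j/2)/S at 0.5.
  Consistent while ≥ 50% of weight comes from valid instruments. SE is the
  standard deviation over 1000 seeded parametric resamples (β*_X, β*_Y
  drawn normal around the observed values with their SEs). This bootstrap
  is conservative when valid instruments share a single true ratio — the
  resampling world carries the observation noise twice — so its CIs
  over-cover by design in the cleanest simulations; with real heterogeneity
  the effect shrinks. Instruments with β_X = 0 have no ratio and are
  rejected with a warning.

Reporting: OR = exp(β), CI = exp(β ∓ q·se) with q = Φ⁻¹((1+level)/2)
(= 1.959964 at 95%, not 1.96 exactly; the difference is below printed
precision except for ORs in the double digits). Confidence intervals for β
are Wald intervals with the normal quantile for all methods, matching the
OR arithmetic; only Egger's p-values use the t distribution. Second-order
ratio weights, MR-PRESSO, mode estimators, Steiger filtering and
multivariable MR are out of scope.

## Synthetic data

The generator is the test bed for every stage and defines the conditions
under which recovery claims hold.

* **Clustered summary statistics**: 26 variants, 16 traits (hormonal /
  insulin-resistance / lipid / adiposity panel with BMI-adjusted columns),
  3 clusters of sizes 4/10/12 mirroring the adiposity / insulin-resistant /
  reproductive pathway structure; per-trait N = 1e5;
  MAF ~ U(0.05, 0.5); se = (2·maf·(1−maf)·N)^{−1/2} (standardized-trait
  approximation, binary outcomes on the log-odds scale via effective sample
  size); β ~ N(μ_cluster,trait, se²); allele orientations randomly
  scrambled so harmonization is genuinely exercised (generated allele pairs
  are non-palindromic so no variants are lost to the palindrome policy).
  The planted per-cluster means give signature |z| ≈ 5–10 — a
  strong-signal recovery benchmark. Real susceptibility variants have far
  weaker, noisier cross-trait profiles: passing ARI = 1 and a ≥ 95%
  index-vote majority here demonstrates correctness of the machinery, not
  that three clusters would be recovered this cleanly from real data. The
  generator also omits LD between variants and correlation between traits.
* **MR datasets**: true instrument strengths β_X ~ U(0.05, 0.35) (wide
  strength heterogeneity, as in instrument panels drawn from real GWAS —
  narrow-strength designs make Egger fragile via errors-in-variables
  attenuation); se_X = se_Y = 0.005, the biobank-scale SE of a
  standardized trait at N ≈ 1e5 and MAF 0.25; a fraction of invalid
  instruments receives a direct outcome effect α ~ N(mean, sd²) (defaults
  0.1 and 0.05 when planted), giving a planted Egger intercept of
  invalid_frac × mean; invalid_frac ≥ 0.5 is rejected (weighted-median
  breakdown). The degenerate zero-noise mode returns θ exactly and anchors
  the estimators' correctness tests.
* **Two-study realizations**: one table's βs serve as the truth; the two
  studies get independent noise, SEs scaled by √(n_B/n_A), and
  independently scrambled orientations.

Truth (cluster labels, μ matrix, θ, invalid set, seeds) is serialized as
JSON beside the data; identical config + seed reproduces outputs
byte-identically.

## Numerical and reproducibility choices

One master seed in the run config fans out to per-stage seeds by hashing
the stage name (CRC32), so stages rerun independently and deterministically.
Restart batches in k-means are vectorized across the restart axis.
p-values are floored at the smallest positive double rather than reported
as 0. Degenerate inputs: empty effect lists, k outside [2, n−1],
all-zero exposure effects, and sub-minimum instrument counts raise typed
errors; in the reporting suite an under-instrumented method yields a
flagged non-estimable row instead of aborting the pair. The acceptance
script uses 100 clustering replicates and 1000 MR replicates per condition
(the test suite uses 2000 for the MR recovery checks), sizes chosen to make
Monte-Carlo error comfortably smaller than the tolerances being checked.

## Limitations

Hard (single-membership) clustering cannot express pleiotropic variants
that genuinely belong to several pathways. The 8-index vote is a documented
subset, not a replication of any particular 30-index battery, and which
indices voted for a given k will differ from other software. LD is consumed
as declared proxy R² values, never computed. The MR estimators use
first-order ratio weights only, and exact replication of any particular R
tooling's SEs is not attempted — the reporting arithmetic (β/SE → OR/CI) is
the validated surface.
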