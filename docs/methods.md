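# Methods

This note documents the statistical procedures, the parameter defaults and
their rationale, the synthetic-data model, and the numerical choices behind
`antagmap`. Quantitative claims here are limited to what the test suite and
`scripts/acceptance.py` actually compute.

## 1. Association scan with grid-wide FDR

Each of the eleven antagonistic target SNPs is looked up in the GWAS summary
statistics of 79 IDP columns: 34 Desikan–Killiany regional surface areas (SA),
34 regional cortical thicknesses (CT), total SA and mean CT, eight subcortical
volumes, and a dedicated hippocampal-volume GWAS column (hippocampus therefore
contributes two columns). Records are harmonized to the risk allele: if a
record's effect allele is the risk allele's complement in the pair, the
alleles are swapped and the signed effect negated; allele pairs that match
neither orientation raise an error. Strand-ambiguous pairs (A/T, C/G) are
flagged (`ambiguity_policy="warn"`, default) or dropped (`"exclude"`). A
target absent from a catalog may be substituted by a linkage-disequilibrium
proxy when r² ≥ 0.8 (default `min_proxy_r2`); the substitute is recorded in a
`used_snp` column.

Multiple testing is controlled with the Benjamini–Hochberg step-up procedure
applied once over the whole grid: adjusted p_(i) = min over j ≥ i of
min(1, m·p_(j)/j) on the sorted p-values. The denominator convention is that
**m equals the full grid size** (11 × 79 = 869), with cells whose lookup
failed padded at p = 1 rather than removed. Padding at p = 1 and counting the
cell in m are equivalent for the surviving cells (a property the test suite
checks), and this convention reproduces the published adjusted column exactly.
The implementation is a reversed cumulative minimum over the sorted array
(O(m log m)); an O(m²) literal transcription of the definition serves as the
test oracle. Significance is `p_fdr < alpha` with `alpha = 0.05`.

Reproduction tolerance: printed raw p-values carry 3 significant figures, and
multiplying by m/rank can move the third significant figure of the adjusted
value by one unit relative to the unrounded inputs. The table-reproduction
tests therefore accept a deviation of one unit in the third significant
figure; 25 of the 27 published cells match exactly at 3 digits and the other
two differ by exactly that one unit.

## 2. Bootstrap enrichment null

The observed statistic is the number of significant cells in the target grid.
The null redraws `set_size` SNPs (default: the number of targets) without
replacement from a pool — either all SNPs shared by every per-IDP table minus
the targets and their proxies (`all_snps`), or the subset with cross-disorder
association p ≤ 1×10⁻⁶ (`cross_disorder`) — rebuilds the same grid, re-runs
BH with the same m convention, and counts significant cells. The empirical
p-value uses the add-one estimator p = (1 + #{counts ≥ observed}) / (1 + B),
whose smallest attainable value is 1/(B+1); B defaults to 10,000. Replicates
draw from `numpy.random.SeedSequence(seed, spawn_key=(r,))` substreams, so
results are reproducible and independent of execution order. An optional
minor-allele-frequency-matched sampler draws nulls within MAF bins of the
target set.

Operating characteristics measured on synthetic nulls (150-SNP pool × 20
IDPs): the acceptance suite requires the rejection rate at α = 0.05 over 200
independent outer repetitions (B = 200) to stay within two binomial standard
errors of 0.05, and requires ≥ 95% power over 100 repetitions (B = 500) when
8 of 11 target SNPs carry 5-standard-error effects in three IDP columns each.
These problem sizes are the package's own choices, set to give informative
Monte-Carlo resolution within a modest CPU budget.

## 3. Effect-direction concordance

For each significant SNP–IDP association, the triplet (allele → IDP effect,
disorder → case-control Cohen's d) is classified with a symmetric rule: the
expected case-control sign for the risk disorder equals the sign of the IDP
effect, and the opposite for the protective disorder. This formulation is
invariant under re-harmonization (flipping to the other allele negates the
IDP effect and swaps the risk/protective annotation), a property the tests
check directly. Calls, in order of precedence:

- `opposed_idp` — both disorders show significant case-control effects of
  opposite sign on the same IDP;
- `consistent_mediation` / `inconsistent` — the available significant
  case-control signs all match / any contradicts the expected pattern;
- `indeterminate` — with reasons `no-case-control-data` (no meta-analysis
  exists for anorexia nervosa or Tourette's regional measures),
  `missing-data`, or `non-significant`.

Case-control tables are per-hemisphere; the default merge policy
(`both-required`) averages d and requires both hemispheres significant with
the same sign, while `either` passes a single significant hemisphere through.
Subphenotype rows (e.g. recurrent-episode subgroups) are excluded on ingest.

## 4. Annotation filters

The eQTL filter keeps records with p below the exact Bonferroni threshold
α/(n_SNPs·n_tissues) — 0.05/128 = 3.90625×10⁻⁴ for 8 SNPs × 16 tissues —
after removing genes whose locus type contains "pseudogene"
(case-insensitive). A `paper_compat` flag substitutes the rounded 4.0×10⁻⁴
cutoff for strict comparability with previously reported gene lists. The
trait filter keeps genome-wide significant associations (p < 5×10⁻⁸) and
drops traits matching any disorder synonym substring, so that the disorders
defining the SNP set do not re-enter as "further traits".

## 5. Voxel-wise analysis

The design matrix is intercept + allele dosage + covariates (categoricals
dummy-coded, drop-first); rank deficiency raises an error naming the
collinear columns. OLS is fit jointly across masked voxels via the closed
form (XᵀX)⁻¹XᵀY, and the dosage t-statistic is compared against an external
OLS implementation to 10⁻⁸ relative tolerance in the tests. Suprathreshold
voxels (one-sided p < 0.001 on the t distribution) form clusters under
6/18/26-connectivity (default 18) with a strict extent rule k > 10; cluster
membership is validated against a flood-fill oracle.

Peak-level FWE uses a Freedman–Lane max-|t| permutation scheme. The dosage
and the voxel data are residualized on the nuisance covariates
(Frisch–Waugh–Lovell, via QR); each permutation permutes the *outcome*
residuals and re-residualizes them on the nuisance before forming the t-map.
Permuting the dosage residuals instead would leave part of the permuted
vector inside the nuisance span and deflate the null maxima — an
anti-conservative error the FWER acceptance test detects. Because the dosage
residual is orthogonal to the nuisance, only the per-voxel residual sum of
squares needs correcting, keeping the per-permutation cost at a few
matrix-vector products. The identity permutation reproduces the observed
t-map exactly. p_FWE = (1 + #{max ≥ |t_peak|}) / (1 + n_perm).

Acceptance-level checks (16³ grid, n = 40, n_perm = 200, 200 repetitions):
the family-wise error rate at α = 0.05 must stay within two binomial standard
errors of 0.05 under the global null; with a planted β = 2.0 effect in a
27-voxel cube (n = 60), the mean recovered β̂ over 50 seeds must fall within
±25% of truth.

## 6. Synthetic-data generators

**Summary statistics.** z-scores are drawn as z ~ N(planted mean, 1) with
SE = 1/√n (default n = 30,000), EFFECT = z·SE, and two-sided p = 2·Φ̄(|z|).
An optional block-equicorrelation across IDP columns mimics the dependence of
neighboring regional measures. Allele pairs are drawn from the four
non-strand-ambiguous combinations. This captures the sampling distribution of
single-SNP association statistics but not linkage disequilibrium between
SNPs, genomic inflation, or MAF-dependent SE heterogeneity.

**Imaging cohorts.** Volumes are Gaussian-smoothed white noise (σ =
FWHM/2.3548 voxels, default FWHM 2.0) standardized to unit voxel SD, plus
linear covariate contributions (age, sex, diagnosis, total intracranial
volume, scanner site, three ancestry components) and a planted β·dosage
effect in chosen voxels; dosage ~ Binomial(2, allele frequency 0.3). Effect
sizes are therefore in units of noise SD. Smoothing yields realistic spatial
autocorrelation; the generator does not model tissue-class structure,
scanner-specific noise spectra, or non-linear covariate effects.

**Published fixture.** The 27-cell association table (raw p and signed
effects, with the proxy substitution), the eleven target annotations (eight
published, three synthetic placeholders completing the set), and the
case-control values for the superior-temporal worked example ship as
generator fixtures, so the headline reproduction runs without external data.

## 7. Open design decisions

- `count_missing_as_tests` (default False): whether failed lookups, beyond
  being padded at p = 1, should also be counted when m is derived from data
  rather than fixed at the full grid size.
- Hemisphere merge policy (default `both-required`), the ambiguity policy,
  and the proxy r² floor are all exposed rather than hard-coded.
- The classifier's symmetric expected-sign rule was chosen over an
  asymmetric "risk-allele lowers the measure" rule because only the
  symmetric form is invariant under re-harmonization.

## 8. Limitations

- The enrichment null resamples SNPs independently; real SNPs are correlated
  through linkage disequilibrium, so pool construction should pre-prune LD if
  calibrated p-values are needed on real data.
- The grid-wide BH procedure assumes the PRDS-type positive dependence under
  which BH is valid; strongly negatively dependent IDP columns are not
  covered.
- Permutation FWE assumes exchangeable errors after covariate removal;
  heteroscedastic site effects would require block-restricted permutations,
  which are not implemented.
- The synthetic generators are calibration instruments, not biophysical
  simulators; absolute power figures transfer to real cohorts only
  qualitatively.
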