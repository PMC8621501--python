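# Methods

## Scope and data model

`lipidmr` implements two-sample summary-data Mendelian randomization:
the exposure association β̂ₓⱼ and outcome association β̂ᵧⱼ of each
variant come from non-overlapping GWAS samples. Exposures are continuous
and standardized (effects per 1 SD); outcomes are binary with effects on
the log-odds scale, so causal estimates exponentiate to odds ratios per
SD of exposure. Matching between datasets is by variant identifier only;
coordinates are 1-based and chromosomes are strings.

## Harmonization

Both effects must refer to the same effect allele before any estimator
runs. For each shared variant the outcome record is aligned to the
exposure's alleles: a swapped allele pair negates β̂ᵧ and complements the
effect-allele frequency (EAF); a reverse-complement pair is treated as a
strand difference and aligned the same way. Palindromic variants (A/T,
C/G) are letter-ambiguous across strands, so the default
`infer_by_eaf` policy keeps them only when both EAFs fall outside
[0.42, 0.58] and aligns strand by minor/major agreement; inside that
band the variant is excluded as ambiguous. Palindromic variants with a
missing EAF are excluded; non-palindromic ones are kept. The `drop`
(exclude all palindromic) and `keep` (trust reported strands) policies
are available. Source studies rarely state how they resolved strand;
this default is standard practice, not a reconstruction of any
particular study's choice, and is therefore a documented package
decision. Harmonization is idempotent and invariant to flips of the
outcome's allele coding (property-tested).

## Synthetic GWAS generator

The generator produces the summary statistics directly — no
individual-level genotypes — under the model

- MAFⱼ ~ U(maf_range), default (0.1, 0.5);
- instrument effects γⱼ ~ N(0, σ_γ²), equicorrelated within consecutive
  LD blocks with correlation ld_rho; non-instruments have γⱼ = 0;
- a fraction of instruments is invalid with a direct outcome effect of
  magnitude N(μ_α, σ_α²) applied on the *exposure-raising* orientation
  (stored in allele coordinates as sign(γⱼ)·N(μ_α, σ_α²));
- true outcome effect bⱼ = θγⱼ + αⱼ;
- observed effects add independent noise with the standard
  summary-statistic SEs: seₓ = 1/√(2 n_exp p(1−p)) for a unit-variance
  continuous trait and se_y = 1/√(2 n_out p(1−p) φ(1−φ)) for a binary
  trait with case fraction φ (logistic approximation; rare-outcome
  default φ = 0.01);
- two-sided normal p-values; one seeded generator, draws in documented
  order, byte-reproducible.

Defaults are the regime of a large lipid GWAS against rare aneurysm-like
outcomes: n_exp = 190,000, n_out = 400,000, ~100 instruments with
σ_γ = 0.042, which puts the total exposure variance explained
(Σ 2p(1−p)γ²) near 7% — mid single digits, as typical for lipid
instrument panels — and per-variant F statistics far above the weak-
instrument bound.

**Why pleiotropy is oriented on the exposure-raising allele.** A direct
effect fixed in allele coordinates with a *symmetric* γ distribution is
annihilated by MR-Egger's bx > 0 orientation: the oriented pleiotropy
sign(γ)·α has mean zero, the intercept estimand vanishes, and
"directional" pleiotropy is undetectable by construction. The standard
directional-pleiotropy literature draws instrument effects one-signed;
with a symmetric γ the equivalent regime is pleiotropy aligned with the
exposure-raising direction (e.g. lipid-raising alleles also raising risk
through a second pathway), which is what the generator implements. Under
this model IVW bias has the sign of μ_α, and the Egger intercept
estimand equals the invalid fraction times μ_α.

**What the generator does not emulate.** No sample overlap, no
population stratification, no winner's curse beyond what significance
selection itself induces (effects are drawn before noise, so selection
bias is measurable rather than hidden), and — outside gene regions — LD
enters only through the block-correlated *true* effects and the reported
r² matrix, not through correlated estimation noise. Passing calibration
here shows the statistical machinery is correct under its stated
assumptions; it does not certify behaviour under real-data pathologies
such as stratification or overlapping samples.

Gene regions use an AR(1) LD correlation over position rank
(r = ld_rho^|i−j|), place variants uniformly in the flanked window, and
propagate n_causal causal signals into marginal effects via β = Rγ, the
standard relation between joint and marginal effects under LD.

## Instrument selection

Filters run in a fixed order: exposure p < 5×10⁻⁸ → greedy clumping →
harmonization → exclusion of variants genome-wide significant for the
outcome → per-variant F = (β̂ₓ/seₓ)² > 10. Clumping repeatedly takes the
smallest-p remaining variant and removes neighbours with r² ≥ threshold
within the distance window; ties on p break by smaller position then
lexicographic identifier, making the output deterministic. Two presets
exist because primary-analysis conventions differ from cis analyses:
strict (r² < 0.001, 10 Mb — also covering the looser r² < 0.01 variant
some analyses quote; both are plain config knobs) and cis (r² < 0.2,
250 kb). Every exclusion is logged as (variant, stage, reason), so
instrument-count accounting per filter is automatic. An empty surviving
set is a diagnosable result, not an exception.

## Estimators

- **Wald ratio**: β̂ᵧ/β̂ₓ with first-order SE se_y/|β̂ₓ| (exposure-side
  noise ignored, matching the convention of standard MR software; the
  choice matters little at F ≫ 10).
- **IVW**: weighted regression through the origin, weights 1/se_y².
  "Random effects" is the multiplicative-overdispersion model — SE
  inflated by √(Q/(n−1)) floored at 1 — which never reports more
  precision than fixed effects. Q is computed on the Wald-ratio scale,
  algebraically identical to the weighted regression residual sum.
- **MR-Egger**: variants oriented to β̂ₓ > 0, weighted regression with
  intercept; the intercept estimates mean directional pleiotropy and is
  tested against zero with a t(n−2) reference; slope and intercept SEs
  carry the same multiplicative floor, here √(RSS_w/(n−2)).
- **Weighted median**: Wald ratios sorted, cumulative standardized
  weights sⱼ = (Σ_{k≤j} w_k − w_j/2)/Σw interpolated at 0.5; weights are
  inverse-variance of the ratios. SE by seeded parametric bootstrap
  (resampling β̂ₓ, β̂ᵧ from normals at their SEs; default 1000 draws,
  bit-reproducible given the seed).
- **Weighted mode**: argmax of a weighted Gaussian kernel density over
  the ratios, bandwidth φ·0.9·min(sd, mad/0.6745)·n^(−1/5) (default
  φ = 1), evaluated on a 10,000-point grid spanning mean ± 5 SD; the
  bootstrap reuses a 1,001-point grid to keep the SE affordable (the
  discretization error is bounded by the grid step and tested). If all
  ratios coincide the common ratio is returned directly.
- **Multivariable IVW**: weighted regression of β̂ᵧ on the k exposure
  columns without intercept, weights 1/se_y²; SEs carry the
  multiplicative floor √(RSS_w/(n−k)) (reducible to the plain SEs via a
  flag, since conventions differ). The design is checked by SVD; a
  condition-number failure raises a collinearity error naming exposure
  pairs with |correlation| > 0.9999. The reference allele frame is the
  first exposure's.

P-values are two-sided normal for Wald/IVW/median/mode and t(n−2) for
both Egger coefficients. Degenerate inputs (zero exposure effect, too
few variants) raise typed errors; p-values are floored at the smallest
positive double so they stay in (0, 1].

## MR-PRESSO

The observed residual sum of squares takes each variant's residual about
its leave-one-out IVW slope (weights 1/se_y²). The null distribution is
built by simulating β̂ₓ* ~ N(β̂ₓ, seₓ) and β̂ᵧ* ~ N(b₋ⱼβ̂ₓ, se_y) and
recomputing the statistic n_sim times (default 1000; empirical p-values
use (1+count)/(1+n_sim), so they never hit zero). Per-variant outlier
p-values are Bonferroni-multiplied by n and flagged below α = 0.05 —
note the smallest attainable adjusted p is n/(n_sim+1), so n_sim must
comfortably exceed n/α for the test to have resolution. The distortion
test compares the with/without-outlier IVW difference against the same
difference over random same-size subsets (drawn without replacement).
When outliers are found both raw and corrected IVW are reported; the
pipeline never silently drops variants (which estimate is "primary" is a
config flag).

## Drug-target (cis) analysis

Instruments for a target gene are the genome-wide-significant variants
of the relevant lipid trait inside the gene ± 100 kb, clumped with the
cis preset. Each harmonized variant is re-expressed per 1-SD lipid
*reduction*: switch to the lipid-lowering allele where needed, then flip
the exposure scale (net effect β̂ₓ → |β̂ₓ|, β̂ᵧ → −sign(β̂ₓ)·β̂ᵧ). The
allele switch alone leaves the Wald ratio unchanged, so the scale flip
is what actually turns estimates into "per unit lowering" — a protective
lowering target then shows OR < 1. Estimation is random-effects IVW
(Wald ratio for a single instrument). Because r² < 0.2 leaves residual
correlation among cis instruments, the default independent-weights SE is
anti-conservative in that regime; a generalized-least-squares variant
taking a signed LD correlation matrix is provided and coincides with
fixed-effects IVW at zero LD. Gene coordinates (GRCh37) ship as an
editable TSV; no annotation service is queried.

## Meta-analysis and the significance screen

Cohort-level log-OR estimates pool with fixed-effect inverse-variance
weights; Q, I² = max(0, (Q−df)/Q)·100 and the DerSimonian–Laird
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)) are always computed, and the random-
effects model (weights 1/(se²+τ²)) is used exactly when p_Q < 0.1 *and*
I² > 50%. With two cohorts τ² is noisy; that is a property of the moment
estimator and is reported, not patched. The significance screen is
Bonferroni over the analysis grid, α/(n_exposures·n_outcomes), reported
at two significant figures; the suggestive band is
threshold ≤ p < 0.05 (the only internally consistent reading of a
"between corrected and nominal" band), and classification metadata says
so explicitly.

## Validation studies and their designs

All operating characteristics are measured by `lipidmr.validation`
(shared verbatim by the test suite and `scripts/acceptance.py`); one
sub-seed per replicate derives from a single base seed.

| Study | Design | Expected behaviour |
| --- | --- | --- |
| IVW type-I error | θ = 0, 100 valid instruments, 2000 reps | rejection at α = 0.05 within [0.03, 0.07] (the overdispersion floor makes the test mildly conservative) |
| PRESSO global null | 30 valid instruments, θ = 0.3, 300 reps | ≤ 8% rejection |
| Recovery | defaults (θ = 0.3, ~100 instruments, ~7% variance explained), 500 reps | relative bias < 5% (regression-dilution attenuation is ≈ seₓ²/σ_γ² ≈ 0.7%), coverage in [0.92, 0.97] |
| Robustness | 100 instruments, 40% invalid, μ_α = 0.05, σ_α = 0.01, 300 reps | weighted median beats IVW on \|bias\| in ≥ 90% of reps; Egger intercept power ≥ 60%. μ_α was set by an a-priori power calculation: the intercept estimand is 0.4·μ_α against an intercept SE ≈ 0.005–0.006 at this design, so μ_α = 0.05 (direct effects ≈ 2× the typical outcome SE) gives strong power where 0.02 would sit near 45% |
| Outlier injection | 25 valid instruments; the strongest gets +8×se_y; n_sim = 2000; 200 reps | flagged ≥ 90%; corrected IVW closer to θ in ≥ 90% of flagged reps. The set size balances two small-sample effects: with very few instruments the outlier contaminates the other leave-one-out slopes and inflates the simulated null residuals; with many, the Bonferroni floor n/(n_sim+1) erodes resolution |
| Drug-target recovery | 60-variant cis region, AR(1) ld_rho = 0.8, 2 causal signals, true raising effect +0.7 | lowering estimate ≈ −0.7; CI coverage ≥ 90% |

## Numerical choices

Floats are written with 12 significant digits (round-trip safe at the
10-digit requirement). The 95% quantile is 1.959964. Clumping tie-breaks
and all bootstrap/simulation draws are deterministic given seeds.
Empirical p-values use add-one smoothing. LD matrices are validated for
symmetry, unit diagonal and range on construction.

## Known limitations

Wald SEs are first-order; the weighted-mode bootstrap uses a coarser
grid than the point estimate; the distortion test's subset distribution
is a heuristic reference (as in the original procedure); cis GLS needs a
*signed* LD correlation, which an r² matrix alone cannot supply; and the
generator's idealizations listed above mean real-data failure modes
(stratification, overlap, correlated noise under LD) are out of scope of
what the passing studies demonstrate. Reproducing published lipid–
aneurysm ORs requires the original GWAS summary files and an LD
reference panel, which this package deliberately does not download; with
those inputs in the canonical format, the same pipeline runs unchanged.
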