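# lipidmr

Two-sample Mendelian randomization (MR) for continuous exposures (e.g.
blood lipid fractions, in SD units) against rare binary outcomes (e.g.
aneurysm diagnoses, on the log-odds scale), built for analyses that run
entirely on GWAS *summary statistics*.

MR uses genetic variants as instrumental variables: a variant robustly
associated with the exposure, independent of confounders, and affecting
the outcome only through the exposure yields a causal effect estimate
from observational data. `lipidmr` covers the whole chain a lipid–disease
MR study needs, plus a fully seeded synthetic GWAS generator so every
stage can be validated by parameter recovery and calibration without
downloading any real GWAS:

- **Summary-statistic I/O and harmonization** — canonical TSV layouts,
  allele alignment (swaps, strand flips, palindromic variants resolved by
  effect-allele frequency).
- **Instrument selection** — genome-wide significance (p < 5×10⁻⁸),
  greedy LD clumping (default r² < 0.001 within 10 Mb), exclusion of
  outcome-associated variants, per-variant F > 10, with a full audit log
  and variance-explained reporting.
- **Estimators** — Wald ratio; inverse-variance-weighted (IVW) with fixed
  or multiplicative random effects; MR-Egger with the intercept
  (directional-pleiotropy) test; weighted median; weighted mode;
  multivariable IVW; Cochran Q / I² heterogeneity.
- **MR-PRESSO** — simulation-based global, outlier and distortion tests
  with raw and outlier-corrected IVW estimates.
- **Cis drug-target MR** — instruments from ±100 kb gene windows
  (packaged GRCh37 coordinates for *HMGCR*, *NPC1L1*, *PCSK9*, *CETP*,
  *LDLR*, *ANGPTL3*, *LPL*), clumped at r² < 0.2 / 250 kb and oriented
  per 1-SD lipid *lowering* so estimates read as pharmacological
  inhibition proxies.
- **Meta-analysis** — fixed-effect pooling, switching to
  DerSimonian–Laird random effects when Cochran Q signals heterogeneity
  (p < 0.1 and I² > 50%), plus a Bonferroni screen over the analysis
  grid (e.g. 0.05/4 exposures/7 outcomes ≈ 0.0018) with a suggestive
  band up to p < 0.05.

## The core estimator

For harmonized variant *j* with exposure effect β̂ₓⱼ (SD units) and
outcome effect β̂ᵧⱼ (log-odds), the IVW estimate is the weighted
regression of β̂ᵧ on β̂ₓ through the origin with weights wⱼ = 1/se(β̂ᵧⱼ)²:

```
θ̂ = Σ wⱼ β̂ₓⱼ β̂ᵧⱼ / Σ wⱼ β̂ₓⱼ² ,   se_fixed = (Σ wⱼ β̂ₓⱼ²)^(-1/2)
```

with Cochran Q = Σ wⱼ(β̂ᵧⱼ − θ̂ β̂ₓⱼ)² and the multiplicative
random-effects SE `se_fixed · max(1, √(Q/(n−1)))`. Results are reported
as OR = exp(θ̂) with 95% CI exp(θ̂ ± 1.96·se) per 1-SD exposure change.

## Worked example

Simulate a study-scale dataset (200 variants, ~100 true instruments,
exposure GWAS n = 190,000, rare binary outcome GWAS n = 400,000, true
effect θ = 0.3 log-odds per SD, total exposure variance explained ≈ 7%)
and run the analysis:

```bash
lipidmr simulate --seed 2 --out-prefix sim
lipidmr select --exposure sim_exposure.tsv --outcome sim_outcome.tsv \
               --ld sim_ld.tsv --out-prefix sel
# sim_exposure: 58 instruments, variance explained 0.0697
lipidmr mr --exposure sim_exposure.tsv --outcome sim_outcome.tsv \
           --ld sim_ld.tsv --seed 2 --out mr.tsv
lipidmr presso --exposure sim_exposure.tsv --outcome sim_outcome.tsv \
               --ld sim_ld.tsv --seed 2 --out-prefix pr
# global p = 0.6653; outliers: none
```

`mr.tsv` (one row per method):

```
         method     beta       se      or_   ci_low  ci_high       pvalue  n_snps
         ivw_re 0.297961 0.060177 1.347109 1.197236 1.515743 7.368104e-07      58
          egger 0.285229 0.133243 1.330067 1.024370 1.726990 3.666869e-02      58
weighted_median 0.308079 0.091028 1.360808 1.138449 1.626597 7.132516e-04      58
  weighted_mode 0.331572 0.108888 1.393156 1.125419 1.724587 2.326247e-03      58
```

All four estimators recover the generating θ = 0.3 (OR ≈ 1.35 per SD);
the MR-PRESSO global test finds no pleiotropic outliers, as expected for
valid instruments. Other CLI verbs: `mvmr` (multivariable IVW),
`drug-target` (cis target grid), `meta` (cross-cohort pooling),
`run-grid` (full exposure × outcome × cohort grid from a YAML config)
and `render` (forest TSV + figure). Every verb is a thin wrapper over
the library API (`lipidmr.ivw`, `lipidmr.presso`, `lipidmr.meta`, ...).

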