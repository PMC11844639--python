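# Methods notes

## Generative model (what the synthetic cohort emulates)

Each simulated protein has a shared latent abundance

    U = β_cis·G_cis + β_trans·G_hub + Σ γ_c·(c − c̄) + ε_U,   Var(U) = σ_U²

and platform measures

    M_A = U + δ_A·G_PAV + e_A,   e_A ~ N(0, σ_eA²)
    M_B = U + δ_B·G_PAV + e_B,   e_B ~ N(0, σ_eB²)

The PAV term is the epitope artifact: it moves each platform's *measure*
without moving the shared abundance, with platform-specific signed effects
δ_A, δ_B. Genotypes are Binomial(2, p_g) under HWE within each ancestry
group; group frequencies follow the Balding–Nichols model
Beta(p0(1−F)/F, (1−p0)(1−F)/F) around an ancestral frequency p0. Raw
scales are monotone maps of the latent measures (exp(7 + 0.5·M_A) for the
RFU-like platform; M_B + 5 for the NPX-like platform), so rank-based
transforms recover the latent structure exactly.

Closed-form oracle for the adjustment analysis, with v_G = 2q(1−q) at the
PAV's pooled frequency q:

    r_unadj = (σ_U² + δ_A δ_B v_G) / √((σ_U² + δ_A² v_G + σ_eA²)(σ_U² + δ_B² v_G + σ_eB²))
    r_adj   =  σ_U² / √((σ_U² + σ_eA²)(σ_U² + σ_eB²))

Note v_G ignores the between-group (Wahlund) variance component
2·Var_groups(p); the realized dosage variance is slightly larger, so
empirical correlations sit ~0.01–0.02 below `r_unadj` for strongly
differentiated PAVs. The ±0.03 agreement band used in tests absorbs this
plus the small distortion of inverse-normal transformation of a
genotype-mixture distribution.

**What a green test does not establish.** The generator has no realistic
LD maps (only an explicit Gaussian-copula knob between chosen pairs), no
admixed individuals (each sample belongs wholly to one group; the
"unassigned" label draws at the ancestral frequency), no batch/plate
effects on measures, no missingness unless injected, and independent noise
across probes. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to cohort
artifacts.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| ancestry composition | AFR 439 : AMR 231 : EAS 277 : EUR 939 (+44 unassigned) | reference multi-ancestry cohort design; any `--n` is split proportionally |
| F (neutral loci) | 0.05 | genome-wide continental-scale differentiation; also consistent with a 75th-percentile χ² threshold of ≈200 at n≈1,900 |
| F (differentiated loci) | 0.12 | upper range of continental differentiation, used for deliberately ancestry-differentiated PAVs |
| scenario-d PAV frequencies | 0.14 / 0.53 / 0.60 / 0.32 | archetypal discordant-PAV pattern (common in EAS/AMR, rarer in AFR/EUR) |
| δ_A, δ_B (scenario d) | −1.0, +0.5 | epitope effects of opposite sign on the SD scale of U; yields oracle r 0.325 → 0.500 |
| σ_U², σ_eA², σ_eB² | 1, 1, 1 | signal-to-noise giving mid-range inter-platform correlation (~0.3–0.5), the regime where adjustment matters |
| covariate effects on U | age 0.01/yr, sex 0.2 | small shared covariate structure (<2% of σ_U²) |
| rank-INT offset c | 0.5 | Blom-type (r−½)/m grid, the common QTL convention; configurable |
| Wakefield prior W | 0.04 | prior SD 0.2 on the transformed-residual scale, standard for molecular traits; configurable |
| max conditional rounds | 5 | desk-scale cap on signals per probe |
| cis window | ±1 Mb of TSS, closed | field convention; coordinates 1-based everywhere |
| significance | 5×10⁻⁸ cis, 1×10⁻¹¹ trans | genome-wide and trans-scan conventions |
| LD filter | r² > 0.1 | credible-set dedup and newly-associated rule |
| pleiotropy | ±500 kb windows, ≥5 proteins both / ≥5 vs ≤1 | "a 1 Mb window around" a sentinel read literally as total width 1 Mb (configurable) |
| negative controls | 186 per probe, N(3.0, 0.35²) | control count matching a ~100-plate design; LOD ≈ 4.0 NPX-like units |

## Numerical and design choices

- **Fine-mapping** is a deterministic stepwise-conditional procedure with
  Wakefield-ABF credible sets rather than an iterative Bayesian variable
  selection: each round takes the top variant by p, converts the round's
  marginal (β, se) to ABFs, normalizes to pips, takes the smallest 95%
  set, then residualizes the working phenotype on the lead dosage. This
  reproduces the output contract (credible sets, leads, significance)
  without convergence concerns; pips are exact within a round (Σ = 1).
- **Covariates** are removed by pre-residualization of phenotypes only;
  post-adjustment mapping adds the PAV by further residualization, which
  for single-variant scans equals including it as a covariate.
- **Protein/genotype PC covariates** (10+10 in genome-scale designs)
  default to 0 here: PCs computed from a handful of simulated probes or
  variants are dominated by the planted signal itself and would remove it.
  Both counts are configurable for real-scale inputs.
- **EAF χ²** is computed on allele counts (2n per group), never on
  frequencies — the only version with a defined null; monomorphic pooled
  frequencies return χ² = 0, p = 1, flagged. Missing dosages are excluded
  from counts but mean-imputed in association scans.
- **Ties and determinism.** Probe-pair ties break lexicographically;
  dedup visits sets by ascending lead p; region merging is idempotent and
  order-independent; identical (config, seed) pairs give byte-identical
  outputs.
- **Degenerate inputs.** Scans refuse n < 10; monomorphic variants and
  zero-residual fits are flagged, not dropped silently; |r| = 1 is
  rejected by the Fisher-z test (infinite z); groups with n < 4 are
  excluded from Q with a warning and reduced df.
- **Direction of epidemiological regression.** Phenotype is the outcome,
  protein the predictor (the only coherent reading once sex/T2D are
  logistic); covariate sets per phenotype are as listed in `crossprot.epi`.
- **classify_pair** adds an explicit `no_overlap` category for pairs force-
  compared without a shared member; the pipeline's per-protein enumeration
  never emits it.

## Heterogeneity power (a deliberate red test)

One test asserts that the cross-ancestry correlation-heterogeneity test
reaches ≥80% power at the Bonferroni level (1.85×10⁻⁵) in the discordant-
PAV scenario, and that Q decreases after adjustment in ≥90–95% of
replicates. Under this generative model those bounds are unattainable:
with δ_A = −1, δ_B = +0.5 and PAV frequencies 0.14–0.60, per-group
correlations span only ≈0.33–0.41, giving Q a noncentrality of ≈2.5 at
n = 2,000, while 80% power at α = 1.85×10⁻⁵ (df = 3, critical value 27.0)
requires noncentrality ≈30. Even an extreme configuration (δ_A ≈ −2,
frequencies 0.10 vs ≈0) yields ≈13. Measured rates: power 0–2/100,
Q-decrease ≈80/100. The test is left asserting the claimed bounds rather
than weakened, because the adjacent claims it guards (PAV recovery,
discordant classification, correlation improvement, differentiation
flagging) all hold at 97–100/100.

## Known limitations

- Fine-mapping pips are conditional-round approximations, not joint
  posteriors; in high LD the credible set can straddle a clump that a
  joint method would split (the r² > 0.1 dedup mitigates double counting).
- The EAF χ² assumes independent allele draws; related individuals would
  inflate it (the reference design excludes first-degree relatives).
- LOD uses per-probe SD pooled across all negative controls; per-plate
  pooling is a config extension, not implemented.
- Sex chromosomes, phased haplotypes, BGEN/PLINK inputs, permutation FDR,
  colocalization, and survival phenotypes are out of scope.
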