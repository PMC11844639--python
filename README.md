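# crossprot

Cross-platform affinity-proteomics concordance analysis across ancestry
groups: inter-platform correlation and its heterogeneity, cis/trans pQTL
mapping with credible sets, cross-platform signal classification,
ancestry-differentiated variant detection, and protein-altering-variant
(PAV) adjustment with quantified improvement of concordance.

## The problem

Aptamer (SomaScan-style, platform **A**) and antibody/PEA (Olink-style,
platform **B**) assays often disagree when measuring the same circulating
protein. One mechanistic driver is *epitope artifacts*: a protein-altering
variant (missense, start-loss, stop-gain, stop-loss) changes the proteoform
that an affinity reagent binds, so a pQTL can reflect binding efficiency
rather than abundance — with effects of opposite sign on the two platforms.
Because PAV frequencies differ across ancestry groups, such artifacts also
make inter-platform agreement ancestry-dependent and bias any downstream
analysis (epidemiological associations, Mendelian randomization) that
assumes measures track true abundance.

`crossprot` implements the full analysis as a reusable pipeline, plus a
synthetic-cohort generator embodying the generative model the analysis
assumes, so that every stage is testable without access to cohort data.

## Model and statistics

- **Transformation.** Raw measures are rank-based inverse-normal
  transformed per probe: `Φ⁻¹((r − ½)/m)` with average ranks for ties.
- **Concordance.** Per UniProt target, Pearson r of transformed measures
  for the best probe pair; per-ancestry r with Fisher z = atanh(r),
  weights w = n − 3, Cochran's **Q = Σ w (z − z̄)²** on χ²(#groups − 1),
  Bonferroni-controlled over probe pairs (e.g. 0.05/2,708 = 1.85×10⁻⁵).
- **pQTL mapping.** Marginal regression of residualized measures on dosage
  (β = cov(g,y)/var(g), t-test with n−2 df); cis = within 1 Mb of the TSS
  (closed interval), thresholds 5×10⁻⁸ (cis) and 1×10⁻¹¹ (trans).
- **Fine-mapping.** Deterministic stepwise-conditional rounds with
  Wakefield approximate Bayes factors,
  `ABF = √(se²/(se²+W)) · exp(z²W/(2(se²+W)))` (W = 0.04); pip ∝ ABF;
  95% credible set = smallest pip-ranked set with Σpip ≥ 0.95; credible
  sets in LD (r² > 0.1) deduplicated keeping the better lead.
- **Classification.** Overlapping A/B credible-set pairs compared at a
  shared sentinel: concordant/discordant by sign of the per-platform betas.
- **Ancestry differentiation.** Pearson χ² on per-group allele counts;
  a variant is differentiated when χ² exceeds the empirical 75th
  percentile over all variants tested.
- **Pleiotropy.** ±500 kb windows around significant trans leads, merged
  transitively; shared regions need ≥ 5 proteins on both platforms.
- **Adjustment.** Measures are residualized on PAV allele copies; the
  report quantifies r before/after, cross-platform effect heterogeneity
  `Q = (β_A − β_B)²/(se_A² + se_B²)`, and strengthened / attenuated /
  newly-associated cis signals (with a residual-LD filter).
- **LOD.** Antibody-platform limit of detection = median(negative
  controls) + 3·SD, compared against raw measures only.

## Worked example

Simulate the archetypal discordant cohort (scenario `d`: a missense PAV
with per-group frequencies 0.14/0.53/0.60/0.32, δ_A = −1.0, δ_B = +0.5)
and run the pipeline:

```bash
crossprot simulate --scenario d --n 2000 --seed 1 --out cohort/
crossprot run --config run.yaml --out results/
```

or equivalently in one step from Python (this is what
`scripts/acceptance.py --seed 1` prints):

```text
proteins compared: 1
inter-platform r (overall): 0.317
credible sets: 4
pair categories: {'overlapping_discordant': 1, 'overlapping_concordant': 1}
PAV adjustment (pav1): r 0.317 -> 0.486; Q 7.78 -> 3.26
PAV ancestry-differentiation X^2: 389.5 (differentiated: True)
```

Reading: the protein carries two cis signals per platform — the true
cis-regulatory variant (classified *overlapping_concordant*) and the PAV
(*overlapping_discordant*: β has opposite signs across platforms). The PAV
is strongly ancestry-differentiated (χ² = 389.5, above the 75th-percentile
threshold). Adjusting the measures for PAV allele copies raises the
inter-platform correlation from 0.32 to 0.49 — matching the closed-form
oracle r: 0.34 → 0.50 — and reduces cross-ancestry heterogeneity Q.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full scenario-d analysis from scratch at the given seed
(simulation → transformation → concordance → fine-mapping →
classification → differentiation → adjustment), prints the summary above,
and writes the JSON target report to `--out`.

## Layout

| module | contents |
|---|---|
| `crossprot.io` | container types; VCF (cyvcf2) and TSV readers/writers |
| `crossprot.preprocess` | rank-INT, covariate residualization, PCA |
| `crossprot.concordance` | probe-pair correlation, Fisher-z/Cochran's Q |
| `crossprot.pqtl` | association scan, ABF fine-mapping, LD, dedup |
| `crossprot.crossplatform` | pair classification, EAF χ², pleiotropy, sentinels |
| `crossprot.adjustment` | PAV adjustment, effect heterogeneity, signal deltas |
| `crossprot.epi` | phenotype models (OLS/logistic), LOD |
| `crossprot.simulate` | Balding–Nichols cohort generator, scenario catalogue |
| `crossprot.pipeline` / `crossprot.cli` | orchestration, `crossprot` CLI |
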