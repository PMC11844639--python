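"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a multi-ancestry cohort measured on two affinity
platforms:

* K ancestry groups with Balding-Nichols-differentiated allele frequencies
  (group frequency ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) around an ancestral
  frequency p0, differentiation parameter F);
* genotypes drawn Binomial(2, p_group) under Hardy-Weinberg equilibrium,
  with an optional Gaussian-copula LD knob between chosen variant pairs;
* per protein, a shared latent abundance
  ``U = beta_cis * G_cis + beta_trans * G_hub + covariate terms + noise``
  with total variance ``sigma_u2``;
* platform measures ``M_A = U + delta_A * G_PAV + e_A`` and
  ``M_B = U + delta_B * G_PAV + e_B`` — a protein-altering variant (PAV)
  perturbs each platform's epitope binding by its own signed effect, of
  possibly opposite sign, on top of the common abundance;
* raw scales mimicking the platforms (log-normal RFU-like for A, shifted
  NPX-like for B; both are monotone in the latent measure, so rank-based
  transforms recover identical structure);
* covariates (age, sex, site, plate, BMI), a logistic T2D phenotype and
  negative-control measures for the antibody platform.

The closed-form inter-platform correlation implied by this model,

    r_unadj = (s_U + dA dB vG) / sqrt((s_U + dA^2 vG + s_eA)(s_U + dB^2 vG + s_eB))
    r_adj   =  s_U            / sqrt((s_U + s_eA)(s_U + s_eB))

with ``vG = 2 q (1 - q)`` at the PAV's pooled frequency q, is exposed as an
oracle for the adjustment analysis.

Default cohort sizes follow the reference multi-ancestry study design
(AFR 439, AMR 231, EAS 277, EUR 939, 44 unassigned; 1,930 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .io import GenotypeData, ProteinMatrix

DEFAULT_GROUPS = {"AFR": 439, "AMR": 231, "EAS": 277, "EUR": 939}
DEFAULT_N_UNASSIGNED = 44
#: genome-wide continental-scale differentiation for ordinary variants
DEFAULT_FST_NEUTRAL = 0.05
#: differentiation for deliberately ancestry-differentiated loci
DEFAULT_FST_DIFFERENTIATED = 0.12


@dataclass
class VariantSpec:
    variant_id: str
    chrom: str
    pos: int
    p0: float
    fst: float = DEFAULT_FST_NEUTRAL
    group_freqs: dict[str, float] | None = None  # fixed frequencies override the BN draw
    ref: str = "A"
    alt: str = "G"
    consequence_class: str = "none"
    consequence_gene: str = ""


@dataclass
class ProteinBlock:
    uniprot_id: str
    gene: str
    probe_a: str
    probe_b: str
    chrom: str
    tss: int
    cis_variant: str | None = None
    cis_beta: float = 0.0
    pav_variant: str | None = None
    delta_a: float = 0.0
    delta_b: float = 0.0
    trans_variant: str | None = None
    trans_beta: float = 0.0
    sigma_u2: float = 1.0   # total variance of the shared component U
    sigma_ea2: float = 1.0  # platform A measurement noise
    sigma_eb2: float = 1.0  # platform B measurement noise


@dataclass
class SimConfig:
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_unassigned: int = DEFAULT_N_UNASSIGNED
    variants: list[VariantSpec] = field(default_factory=list)
    proteins: list[ProteinBlock] = field(default_factory=list)
    ld_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.2})
    age_mean: float = 58.2
    age_sd: float = 8.8
    bmi_mean: float = 28.1
    bmi_sd: float = 5.0
    n_sites: int = 6
    n_plates: int = 8
    t2d_intercept: float = -2.2
    t2d_age: float = 0.04
    t2d_bmi: float = 0.08
    n_negative_controls: int = 186
    ctrl_mu: float = 3.0
    ctrl_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for blk in self.proteins:
            for v in (blk.sigma_u2, blk.sigma_ea2, blk.sigma_eb2):
                if v <= 0:
                    raise ValueError("all variances must be > 0")
        for n in self.groups.values():
            if n < 2:
                raise ValueError("group sizes must be >= 2")
        for vs in self.variants:
            if not 0 < vs.p0 < 1:
                raise ValueError("ancestral frequencies must lie in (0, 1)")


@dataclass
class SimResult:
    samples: pd.DataFrame
    genotypes: GenotypeData
    mat_a: ProteinMatrix
    mat_b: ProteinMatrix
    probe_map: pd.DataFrame
    controls: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def draw_subpop_freqs(p0: float, fst: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies (degenerate at fst = 0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if fst == 0:
        return np.full(k, p0)
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, size=k), 1e-4, 1 - 1e-4)


def _haplotypes(freqs: np.ndarray, n: int, ld_index: list[tuple[int, int, float]],
                rng: np.random.Generator) -> np.ndarray:
    """n x m dosage draws at per-variant frequencies, Gaussian-copula LD pairs."""
    m = len(freqs)
    thresh = ndtri(freqs)
    dose = np.zeros((n, m))
    for _ in range(2):  # two haplotypes per individual
        z = rng.standard_normal((n, m))
        for i, j, rho in ld_index:
            z[:, j] = rho * z[:, i] + np.sqrt(1 - rho**2) * z[:, j]
        dose += (z < thresh[None, :]).astype(float)
    return dose


def pooled_frequency(spec: VariantSpec, cfg: SimConfig,
                     realized: dict[str, float] | None = None) -> float:
    """Cohort-pooled expected frequency of a variant (unassigned at p0)."""
    freqs = realized or spec.group_freqs or {g: spec.p0 for g in cfg.groups}
    num = sum(cfg.groups[g] * freqs[g] for g in cfg.groups) + cfg.n_unassigned * spec.p0
    return num / (sum(cfg.groups.values()) + cfg.n_unassigned)


def expected_cross_platform_r(sigma_u2: float, delta_a: float, delta_b: float,
                              v_g: float, sigma_ea2: float, sigma_eb2: float,
                              adjusted: bool = False) -> float:
    """Closed-form inter-platform correlation under the generative model."""
    if adjusted:
        return sigma_u2 / np.sqrt((sigma_u2 + sigma_ea2) * (sigma_u2 + sigma_eb2))
    num = sigma_u2 + delta_a * delta_b * v_g
    den = np.sqrt((sigma_u2 + delta_a**2 * v_g + sigma_ea2)
                  * (sigma_u2 + delta_b**2 * v_g + sigma_eb2))
    return float(num / den)


def _dosage_variance(freqs: dict[str, float], cfg: SimConfig, p0: float) -> float:
    """Theoretical Var(G) in the pooled cohort: HWE within plus between-group term."""
    labels = list(cfg.groups) + ["__un__"]
    sizes = np.array([cfg.groups[g] for g in cfg.groups] + [cfg.n_unassigned], dtype=float)
    w = sizes / sizes.sum()
    p = np.array([freqs[g] for g in cfg.groups] + [p0])
    pbar = float((w * p).sum())
    var_p = float((w * (p - pbar) ** 2).sum())
    return 2 * pbar * (1 - pbar) + 2 * var_p


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Draw one cohort; identical (cfg, seed) pairs give identical output."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    group_labels = list(cfg.groups)
    sizes = [cfg.groups[g] for g in group_labels] + [cfg.n_unassigned]
    labels = np.repeat(group_labels + ["unassigned"], sizes)
    n = len(labels)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    # --- per-variant group frequencies --------------------------------------
    realized: dict[str, dict[str, float]] = {}
    for vs in cfg.variants:
        if vs.group_freqs is not None:
            realized[vs.variant_id] = dict(vs.group_freqs)
        else:
            draws = draw_subpop_freqs(vs.p0, vs.fst, len(group_labels), rng)
            realized[vs.variant_id] = dict(zip(group_labels, draws))

    # --- genotypes -----------------------------------------------------------
    vid_index = {vs.variant_id: k for k, vs in enumerate(cfg.variants)}
    ld_index = [(vid_index[a], vid_index[b], rho) for a, b, rho in cfg.ld_pairs]
    dose = np.zeros((n, len(cfg.variants)))
    offset = 0
    for g, size in zip(group_labels + ["unassigned"], sizes):
        freqs = np.array([
            vs.p0 if g == "unassigned" else realized[vs.variant_id][g]
            for vs in cfg.variants
        ])
        dose[offset:offset + size] = _haplotypes(freqs, size, ld_index, rng)
        offset += size

    variants = pd.DataFrame(
        [(vs.variant_id, vs.chrom, vs.pos, vs.ref, vs.alt,
          vs.consequence_class, vs.consequence_gene) for vs in cfg.variants],
        columns=["variant_id", "chrom", "pos", "ref", "alt",
                 "consequence_class", "consequence_gene"]).set_index("variant_id")
    genotypes = GenotypeData(pd.DataFrame(dose, index=sample_ids, columns=variants.index),
                             variants)

    # --- covariates and phenotypes ------------------------------------------
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    sex = rng.integers(0, 2, n).astype(float)
    site = rng.integers(0, cfg.n_sites, n)
    plate = rng.integers(0, cfg.n_plates, n)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, n)
    t2d_logit = (cfg.t2d_intercept + cfg.t2d_age * (age - cfg.age_mean)
                 + cfg.t2d_bmi * (bmi - cfg.bmi_mean))
    t2d = (rng.uniform(size=n) < expit(t2d_logit)).astype(int)
    samples = pd.DataFrame({
        "age": age, "sex": sex, "site": [f"site{s}" for s in site],
        "plate": [f"plate{p}" for p in plate], "ancestry": labels,
        "bmi": bmi, "t2d": t2d,
    }, index=pd.Index(sample_ids, name="sample_id"))

    cov_term = np.zeros(n)
    cov_var = 0.0
    cov_values = {"age": (age - cfg.age_mean, cfg.age_sd**2),
                  "sex": (sex - 0.5, 0.25),
                  "bmi": (bmi - cfg.bmi_mean, cfg.bmi_sd**2)}
    for name, gamma in cfg.covariate_effects.items():
        centered, var = cov_values[name]
        cov_term = cov_term + gamma * centered
        cov_var += gamma**2 * var

    # --- protein measures ----------------------------------------------------
    a_cols, b_cols, truth_rows, probe_rows = {}, {}, [], []
    spec_by_id = {vs.variant_id: vs for vs in cfg.variants}
    for blk in cfg.proteins:
        genetic = np.zeros(n)
        explained = cov_var
        for vid, beta in ((blk.cis_variant, blk.cis_beta),
                          (blk.trans_variant, blk.trans_beta)):
            if vid is not None and beta != 0.0:
                genetic = genetic + beta * (dose[:, vid_index[vid]]
                                            - 2 * pooled_frequency(spec_by_id[vid], cfg,
                                                                   realized[vid]))
                explained += beta**2 * _dosage_variance(realized[vid], cfg,
                                                        spec_by_id[vid].p0)
        resid_var = blk.sigma_u2 - explained
        if resid_var <= 0:
            raise ValueError(
                f"{blk.uniprot_id}: genetic + covariate variance ({explained:.3f}) "
                f"exceeds sigma_u2 ({blk.sigma_u2})")
        u = genetic + cov_term + rng.normal(0, np.sqrt(resid_var), n)
        pav = (dose[:, vid_index[blk.pav_variant]]
               if blk.pav_variant is not None else np.zeros(n))
        m_a = u + blk.delta_a * pav + rng.normal(0, np.sqrt(blk.sigma_ea2), n)
        m_b = u + blk.delta_b * pav + rng.normal(0, np.sqrt(blk.sigma_eb2), n)
        a_cols[blk.probe_a] = np.exp(7.0 + 0.5 * m_a)  # log-normal RFU-like scale
        b_cols[blk.probe_b] = m_b + 5.0                # NPX-like log2 scale
        probe_rows.append((blk.probe_a, "A", blk.uniprot_id, blk.gene, blk.chrom, blk.tss))
        probe_rows.append((blk.probe_b, "B", blk.uniprot_id, blk.gene, blk.chrom, blk.tss))
        if blk.pav_variant is not None:
            q = pooled_frequency(spec_by_id[blk.pav_variant], cfg,
                                 realized[blk.pav_variant])
            v_g = 2 * q * (1 - q)
        else:
            q, v_g = np.nan, 0.0
        truth_rows.append({
            "uniprot_id": blk.uniprot_id, "gene": blk.gene,
            "probe_a": blk.probe_a, "probe_b": blk.probe_b,
            "cis_variant": blk.cis_variant or "", "cis_beta": blk.cis_beta,
            "pav_variant": blk.pav_variant or "",
            "delta_a": blk.delta_a, "delta_b": blk.delta_b,
            "trans_variant": blk.trans_variant or "", "trans_beta": blk.trans_beta,
            "sigma_u2": blk.sigma_u2, "sigma_ea2": blk.sigma_ea2,
            "sigma_eb2": blk.sigma_eb2, "pav_pooled_freq": q, "pav_v_g": v_g,
            "r_expected_pre": expected_cross_platform_r(
                blk.sigma_u2, blk.delta_a, blk.delta_b, v_g,
                blk.sigma_ea2, blk.sigma_eb2),
            "r_expected_post": expected_cross_platform_r(
                blk.sigma_u2, blk.delta_a, blk.delta_b, v_g,
                blk.sigma_ea2, blk.sigma_eb2, adjusted=True),
        })

    mat_a = ProteinMatrix("A", pd.DataFrame(a_cols, index=samples.index), layer="raw")
    mat_b = ProteinMatrix("B", pd.DataFrame(b_cols, index=samples.index), layer="raw")
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "platform", "uniprot_id",
                                                  "gene_symbol", "chrom", "tss"])

    controls = pd.DataFrame({
        "probe_id": np.repeat([blk.probe_b for blk in cfg.proteins],
                              cfg.n_negative_controls),
        "value": rng.normal(cfg.ctrl_mu, cfg.ctrl_sd,
                            cfg.n_negative_controls * len(cfg.proteins)),
    })

    return SimResult(samples, genotypes, mat_a, mat_b, probe_map, controls,
                     pd.DataFrame(truth_rows), cfg)


def write_cohort(sim: SimResult, out_dir) -> dict[str, str]:
    """Write VCF + TSVs (+ truth table); returns the path map."""
    import os

    from .io import write_genotype_vcf, write_matrix_tsv, write_result_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("genotypes", "genotypes.vcf"), ("protein_a", "protein_a.tsv"),
        ("protein_b", "protein_b.tsv"), ("samples", "samples.tsv"),
        ("probe_map", "probe_map.tsv"), ("annotation", "annotation.tsv"),
        ("controls", "negative_controls.tsv"), ("truth", "truth.tsv"),
    ]}
    write_genotype_vcf(sim.genotypes, paths["genotypes"])
    write_matrix_tsv(sim.mat_a, paths["protein_a"])
    write_matrix_tsv(sim.mat_b, paths["protein_b"])
    sim.samples.to_csv(paths["samples"], sep="\t")
    sim.probe_map.to_csv(paths["probe_map"], sep="\t", index=False)
    ann = sim.genotypes.variants.reset_index()[
        ["variant_id", "consequence_class", "consequence_gene"]]
    ann.to_csv(paths["annotation"], sep="\t", index=False)
    sim.controls.to_csv(paths["controls"], sep="\t", index=False)
    write_result_table(sim.truth, paths["truth"], precision=10)
    return paths


# ---------------------------------------------------------------------------
# scenario catalogue
# ---------------------------------------------------------------------------


def scale_groups(n_total: int, groups: dict[str, int] | None = None,
                 n_unassigned: int = 0) -> dict[str, int]:
    """Scale the default ancestry composition to a target assigned-sample count."""
    groups = groups or DEFAULT_GROUPS
    total = sum(groups.values())
    scaled = {g: max(4, int(round(n_total * size / total))) for g, size in groups.items()}
    return scaled


def _cis_region_variants(chrom: str, tss: int, n_neutral: int, rng_offset: int = 0,
                         fst: float = DEFAULT_FST_NEUTRAL, prefix: str = "v"):
    """Evenly spaced neutral variants across the 1 Mb cis window."""
    positions = np.linspace(tss - 990_000, tss + 990_000, n_neutral).astype(int)
    p0s = np.linspace(0.08, 0.45, n_neutral)
    return [VariantSpec(f"{prefix}{i + rng_offset}", chrom, int(pos), float(p0), fst)
            for i, (pos, p0) in enumerate(zip(positions, p0s))]


def scenario_a(n_total: int = 1886) -> SimConfig:
    """Concordant cis-pQTL, no PAV: both platforms see the same abundance signal."""
    chrom, tss = "7", 100_000_000
    variants = _cis_region_variants(chrom, tss, 40)
    variants.append(VariantSpec("cis1", chrom, tss - 10_000, 0.30))
    proteins = [ProteinBlock("P00001", "GENE1", "seq.1001.1", "OID0001",
                             chrom, tss, cis_variant="cis1", cis_beta=0.6)]
    return SimConfig(groups=scale_groups(n_total), n_unassigned=0,
                     variants=variants, proteins=proteins)


def scenario_b(n_total: int = 1886) -> SimConfig:
    """Platform-A-only PAV: an epitope effect on the aptamer platform only."""
    cfg = scenario_a(n_total)
    cfg.variants.append(VariantSpec("pav1", "7", 100_020_000, 0.25,
                                    fst=DEFAULT_FST_DIFFERENTIATED,
                                    consequence_class="missense",
                                    consequence_gene="GENE1"))
    cfg.proteins[0] = replace(cfg.proteins[0], pav_variant="pav1",
                              delta_a=-0.8, delta_b=0.0)
    return cfg


def scenario_c(n_total: int = 1886, n_hub_proteins: int = 6) -> SimConfig:
    """Shared trans hub: one variant drives >= 5 proteins on both platforms."""
    hub = VariantSpec("hub1", "9", 136_000_000, 0.35)
    variants = [hub]
    proteins = []
    for i in range(n_hub_proteins):
        chrom, tss = str(i + 1), 50_000_000
        cis = VariantSpec(f"cis{i + 1}", chrom, tss - 5_000, 0.30)
        variants.append(cis)
        variants.extend(_cis_region_variants(chrom, tss, 6, rng_offset=100 * (i + 1)))
        proteins.append(ProteinBlock(
            f"P0000{i + 1}", f"GENE{i + 1}", f"seq.10{i + 1:02d}.1", f"OID000{i + 1}",
            chrom, tss, cis_variant=cis.variant_id, cis_beta=0.5,
            trans_variant="hub1", trans_beta=0.5))
    return SimConfig(groups=scale_groups(n_total), n_unassigned=0,
                     variants=variants, proteins=proteins)


#: group frequencies of the archetypal discordant PAV (most common in EAS/AMR,
#: rarer in AFR/EUR — the pattern seen for epitope-effect missense variants)
SCENARIO_D_PAV_FREQS = {"AFR": 0.14, "AMR": 0.53, "EAS": 0.60, "EUR": 0.32}


def scenario_d(n_total: int = 1886) -> SimConfig:
    """Discordant, ancestry-differentiated PAV (epitope-effect archetype).

    The PAV pushes the two platforms' measures in opposite directions
    (delta_A = -1.0, delta_B = +0.5 on the SD scale of the shared abundance)
    and its frequency differs strongly across ancestry groups; a separate
    cis-regulatory variant carries the true abundance signal.
    """
    chrom, tss = "7", 100_000_000
    variants = _cis_region_variants(chrom, tss, 60)
    variants += [VariantSpec(f"bg{i}", "12", 40_000_000 + 50_000 * i, float(p0))
                 for i, p0 in enumerate(np.linspace(0.1, 0.4, 20))]
    variants.append(VariantSpec("cis1", chrom, tss - 10_000, 0.30))
    variants.append(VariantSpec("pav1", chrom, tss + 20_000, 0.35,
                                fst=DEFAULT_FST_DIFFERENTIATED,
                                group_freqs=dict(SCENARIO_D_PAV_FREQS),
                                consequence_class="missense",
                                consequence_gene="GENE1"))
    proteins = [ProteinBlock("P00001", "GENE1", "seq.1001.1", "OID0001",
                             chrom, tss, cis_variant="cis1", cis_beta=0.6,
                             pav_variant="pav1", delta_a=-1.0, delta_b=0.5)]
    return SimConfig(groups=scale_groups(n_total), n_unassigned=0,
                     variants=variants, proteins=proteins)


def scenario_e(n_total: int = 1886) -> SimConfig:
    """Null protein: essentially pure platform noise, no genetic signal."""
    chrom, tss = "7", 100_000_000
    variants = _cis_region_variants(chrom, tss, 40)
    proteins = [ProteinBlock("P00001", "GENE1", "seq.1001.1", "OID0001",
                             chrom, tss, sigma_u2=0.05)]
    cfg = SimConfig(groups=scale_groups(n_total), n_unassigned=0,
                    variants=variants, proteins=proteins)
    cfg.covariate_effects = {}
    return cfg


SCENARIOS = {"a": scenario_a, "b": scenario_b, "c": scenario_c,
             "d": scenario_d, "e": scenario_e}
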