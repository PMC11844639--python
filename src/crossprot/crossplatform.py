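"""Cross-platform signal classification, ancestry-differentiated EAFs,
pleiotropic trans regions and external sentinel overlap.

A pair of credible sets for the same protein is *platform-overlapping* when
the sets share at least one member variant.  Overlapping pairs are compared
only when at least one platform's sentinel (lead) variant is a member of
the other platform's set; the pair is then *concordant* or *discordant*
according to whether the compared sentinel's marginal effects on the two
platforms share a sign.

A variant is *ancestry-differentiated* when the Pearson chi-square of its
allele counts across ancestry groups exceeds the empirical 75th percentile
of the statistic over all variants tested (strictly greater).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PAV_CLASSES, UNASSIGNED, GenotypeData
from .pqtl import CredibleSet, LD_R2_THRESHOLD

CATEGORY_A_ONLY = "A_only"
CATEGORY_B_ONLY = "B_only"
CATEGORY_CONCORDANT = "overlapping_concordant"
CATEGORY_DISCORDANT = "overlapping_discordant"
CATEGORY_UNCOMPARED = "overlapping_uncompared"
CATEGORY_NO_OVERLAP = "no_overlap"

DIFFERENTIATION_QUANTILE = 0.75
PLEIO_HALF_WINDOW = 500_000  # "a 1 Mb window around" a sentinel, read as +/- 500 kb
PLEIO_MIN_PROTEINS = 5
PLEIO_MAX_OTHER = 1


@dataclass
class SignalPairClass:
    uniprot_id: str
    set_A: CredibleSet | None
    set_B: CredibleSet | None
    category: str
    pav_in_A: bool = False
    pav_in_B: bool = False
    compared_sentinel: str | None = None
    beta_A: float = np.nan
    beta_B: float = np.nan


def classify_pair(set_a: CredibleSet | None, set_b: CredibleSet | None,
                  uniprot_id: str = "") -> SignalPairClass:
    """Classify one cross-platform credible-set pair (Figure-S4-style logic).

    Sign comparison uses the per-platform marginal betas of the compared
    sentinel (stored on the sets at fine-mapping time).  When both leads are
    shared, the sentinel of the more significant lead is compared.
    """
    if set_a is None and set_b is None:
        raise ValueError("classify_pair: both sets absent")
    if set_b is None:
        return SignalPairClass(uniprot_id, set_a, None, CATEGORY_A_ONLY)
    if set_a is None:
        return SignalPairClass(uniprot_id, None, set_b, CATEGORY_B_ONLY)

    shared = set(set_a.members) & set(set_b.members)
    if not shared:
        return SignalPairClass(uniprot_id, set_a, set_b, CATEGORY_NO_OVERLAP)

    candidates = []
    if set_a.lead in set_b.members:
        candidates.append((set_a.lead_p, set_a.lead))
    if set_b.lead in set_a.members:
        candidates.append((set_b.lead_p, set_b.lead))
    if not candidates:
        return SignalPairClass(uniprot_id, set_a, set_b, CATEGORY_UNCOMPARED)
    _, sentinel = min(candidates)
    beta_a = set_a.member_betas.get(sentinel, np.nan)
    beta_b = set_b.member_betas.get(sentinel, np.nan)
    if np.isnan(beta_a) or np.isnan(beta_b):
        return SignalPairClass(uniprot_id, set_a, set_b, CATEGORY_UNCOMPARED,
                               compared_sentinel=sentinel)
    category = CATEGORY_CONCORDANT if np.sign(beta_a) == np.sign(beta_b) else CATEGORY_DISCORDANT
    return SignalPairClass(uniprot_id, set_a, set_b, category,
                           compared_sentinel=sentinel, beta_A=beta_a, beta_B=beta_b)


def contains_pav(cset: CredibleSet, variants: pd.DataFrame, target_gene: str) -> bool:
    """True when any member is protein-altering for the encoded gene."""
    for v in cset.members:
        if v not in variants.index:
            continue
        row = variants.loc[v]
        if row["consequence_class"] in PAV_CLASSES and row["consequence_gene"] == target_gene:
            return True
    return False


def classify_protein(uniprot_id: str, sets_a: list[CredibleSet], sets_b: list[CredibleSet],
                     variants: pd.DataFrame, target_gene: str) -> list[SignalPairClass]:
    """Enumerate pair classifications for one protein's cis sets.

    Every overlapping (shared-member) A/B pair yields one row; sets with no
    cross-platform overlap are reported as single-platform rows.
    """
    out: list[SignalPairClass] = []
    used_a, used_b = set(), set()
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            if set(sa.members) & set(sb.members):
                pc = classify_pair(sa, sb, uniprot_id)
                pc.pav_in_A = contains_pav(sa, variants, target_gene)
                pc.pav_in_B = contains_pav(sb, variants, target_gene)
                out.append(pc)
                used_a.add(i)
                used_b.add(j)
    for i, sa in enumerate(sets_a):
        if i not in used_a:
            pc = classify_pair(sa, None, uniprot_id)
            pc.pav_in_A = contains_pav(sa, variants, target_gene)
            out.append(pc)
    for j, sb in enumerate(sets_b):
        if j not in used_b:
            pc = classify_pair(None, sb, uniprot_id)
            pc.pav_in_B = contains_pav(sb, variants, target_gene)
            out.append(pc)
    return out


# ---------------------------------------------------------------------------
# ancestry-differentiated allele frequencies
# ---------------------------------------------------------------------------


def eaf_by_group(genotypes: GenotypeData, labels, groups=None) -> pd.DataFrame:
    """Per-variant, per-group effect-allele frequency with allele counts.

    EAF = (sum of observed dosages) / (2 * non-missing samples); missing
    dosages are never imputed here.  Columns: eaf_<g>, alt_<g>, tot_<g>.
    """
    labels = pd.Series(np.asarray(labels), index=genotypes.dosages.index)
    if groups is None:
        groups = [g for g in pd.unique(labels) if g != UNASSIGNED]
    out = pd.DataFrame(index=genotypes.variants.index)
    for g in groups:
        sel = labels == g
        if not sel.any():
            raise ValueError(f"eaf_by_group: empty ancestry group {g!r}")
        sub = genotypes.dosages.loc[sel.to_numpy()].to_numpy(dtype=float)
        alt = np.nansum(sub, axis=0)
        tot = 2.0 * (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[f"eaf_{g}"] = np.where(tot > 0, alt / tot, np.nan)
        out[f"alt_{g}"] = alt
        out[f"tot_{g}"] = tot
    return out


def chi_square_upper_tail(x2: float, df: int) -> float:
    """Upper-tail chi-square p-value (df = number of ancestry groups - 1)."""
    return float(stats.chi2.sf(x2, df))


def eaf_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square on the groups x {alt, ref} allele-count contingency.

    ``counts`` is an iterable of (alt_count, total_alleles).  A pooled EAF of
    exactly 0 or 1 has all expected counts in one column zero; the statistic
    is then 0 with p = 1 (flagged upstream by the caller).
    """
    counts = [(float(a), float(t)) for a, t in counts]
    if len(counts) < 2:
        raise ValueError("eaf_chi_square: need >= 2 groups")
    if any(t <= 0 for _, t in counts):
        raise ValueError("eaf_chi_square: group with zero total alleles")
    df = len(counts) - 1
    alt = np.array([a for a, _ in counts])
    tot = np.array([t for _, t in counts])
    pooled = alt.sum() / tot.sum()
    if pooled <= 0 or pooled >= 1:
        return 0.0, df, 1.0
    exp_alt = tot * pooled
    exp_ref = tot * (1 - pooled)
    x2 = float((((alt - exp_alt) ** 2) / exp_alt).sum()
               + ((((tot - alt) - exp_ref) ** 2) / exp_ref).sum())
    return x2, df, chi_square_upper_tail(x2, df)


def eaf_chi_square_table(eafs: pd.DataFrame, groups) -> pd.DataFrame:
    """Apply :func:`eaf_chi_square` to every variant of an eaf_by_group table."""
    rows = []
    for vid, row in eafs.iterrows():
        counts = [(row[f"alt_{g}"], row[f"tot_{g}"]) for g in groups]
        x2, df, p = eaf_chi_square(counts)
        rec = {"variant_id": vid, "x2": x2, "df": df, "p": p,
               "monomorphic": x2 == 0.0 and p == 1.0}
        for g in groups:
            rec[f"eaf_{g}"] = row[f"eaf_{g}"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("variant_id")


def differentiation_flags(x2_values, quantile: float = DIFFERENTIATION_QUANTILE):
    """Empirical-quantile threshold (linear interpolation) and strict-> flags."""
    x2 = np.asarray(x2_values, dtype=float)
    if x2.size < 4:
        raise ValueError("differentiation_flags: need >= 4 values")
    threshold = float(np.quantile(x2, quantile))
    return threshold, x2 > threshold


# ---------------------------------------------------------------------------
# pleiotropic trans regions
# ---------------------------------------------------------------------------


def _merge_intervals(intervals):
    """Merge closed intervals that intersect by >= 1 bp; input order-free."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def trans_regions(sentinels: pd.DataFrame,
                  half_window: int = PLEIO_HALF_WINDOW,
                  min_proteins: int = PLEIO_MIN_PROTEINS,
                  max_other: int = PLEIO_MAX_OTHER) -> pd.DataFrame:
    """Region-based pleiotropy calls from per-platform significant trans leads.

    ``sentinels`` columns: platform, probe_id, chrom, pos (lead position).
    Windows [pos - hw, pos + hw] are merged transitively per platform, then
    regions overlapping across platforms are paired into one region group
    whose span is the union; protein counts are distinct probes whose lead
    lies in the group's span.  Categories: shared_pleiotropic (>= 5 on both),
    A_specific / B_specific (>= 5 on one, <= 1 on the other), else
    not_pleiotropic.  The merge is idempotent and order-independent.
    """
    if sentinels.empty:
        return pd.DataFrame(columns=["platform", "chrom", "start", "end",
                                     "protein_count_A", "protein_count_B", "category"])
    sentinels = sentinels.copy()
    sentinels["chrom"] = sentinels["chrom"].astype(str)
    rows = []
    for chrom, chrom_sent in sentinels.groupby("chrom"):
        per_platform = {}
        for plat in ("A", "B"):
            pos = chrom_sent.loc[chrom_sent["platform"] == plat, "pos"]
            per_platform[plat] = _merge_intervals(
                [(max(1, int(p) - half_window), int(p) + half_window) for p in pos])
        # connected components across both platforms' merged regions
        tagged = ([("A", s, e) for s, e in per_platform["A"]]
                  + [("B", s, e) for s, e in per_platform["B"]])
        tagged.sort(key=lambda t: (t[1], t[2]))
        groups = []
        for plat, s, e in tagged:
            if groups and s <= groups[-1]["end"]:
                groups[-1]["end"] = max(groups[-1]["end"], e)
                groups[-1]["platforms"].add(plat)
            else:
                groups.append({"start": s, "end": e, "platforms": {plat}})
        for grp in groups:
            counts = {}
            for plat in ("A", "B"):
                sel = chrom_sent[(chrom_sent["platform"] == plat)
                                 & (chrom_sent["pos"] >= grp["start"])
                                 & (chrom_sent["pos"] <= grp["end"])]
                counts[plat] = sel["probe_id"].nunique()
            ca, cb = counts["A"], counts["B"]
            if ca >= min_proteins and cb >= min_proteins:
                category = "shared_pleiotropic"
            elif ca >= min_proteins and cb <= max_other:
                category = "A_specific"
            elif cb >= min_proteins and ca <= max_other:
                category = "B_specific"
            else:
                category = "not_pleiotropic"
            rows.append({"platform": "+".join(sorted(grp["platforms"])),
                         "chrom": chrom, "start": grp["start"], "end": grp["end"],
                         "protein_count_A": ca, "protein_count_B": cb,
                         "category": category})
    out = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# external sentinel overlap
# ---------------------------------------------------------------------------


def sentinel_overlap(sets: list[CredibleSet], ext: pd.DataFrame,
                     target_gene_of_probe=None) -> pd.DataFrame:
    """Flag credible sets containing external sentinel variants.

    For eqtl / ms_pqtl rows the external target gene must match the probe's
    encoded gene.  Direction concordance requires the pQTL lead's sign to
    equal the external sign in *all* contexts; matches whose external signs
    conflict across contexts are excluded from the comparison.
    """
    target_gene_of_probe = target_gene_of_probe or {}
    rows = []
    for s in sets:
        gene = target_gene_of_probe.get(s.probe_id, "")
        match = ext[ext["variant_id"].isin(s.members)]
        gene_needed = match["source"].isin(["eqtl", "ms_pqtl"])
        match = match[~gene_needed | (match["gene"] == gene)]
        lead_sign = "+" if s.lead_beta > 0 else "-"
        if match.empty:
            rows.append({"probe_id": s.probe_id, "platform": s.platform,
                         "signal_index": s.signal_index, "matched": False,
                         "excluded": False, "concordant": False,
                         "matched_variants": ""})
            continue
        signs = set(match["sign"])
        excluded = len(signs) > 1
        concordant = (not excluded) and all(sg == lead_sign for sg in match["sign"])
        rows.append({"probe_id": s.probe_id, "platform": s.platform,
                     "signal_index": s.signal_index, "matched": True,
                     "excluded": excluded, "concordant": concordant,
                     "matched_variants": ";".join(sorted(match["variant_id"].unique()))})
    return pd.DataFrame(rows)


def pair_table(pairs: list[SignalPairClass]) -> pd.DataFrame:
    rows = []
    for pc in pairs:
        rows.append({
            "uniprot_id": pc.uniprot_id,
            "probe_id_A": pc.set_A.probe_id if pc.set_A else "",
            "signal_A": pc.set_A.signal_index if pc.set_A else -1,
            "probe_id_B": pc.set_B.probe_id if pc.set_B else "",
            "signal_B": pc.set_B.signal_index if pc.set_B else -1,
            "category": pc.category,
            "compared_sentinel": pc.compared_sentinel or "",
            "beta_A": pc.beta_A, "beta_B": pc.beta_B,
            "pav_in_A": pc.pav_in_A, "pav_in_B": pc.pav_in_B,
        })
    return pd.DataFrame(rows)
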