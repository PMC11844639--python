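"""Protein-altering-variant (PAV) adjustment and its downstream impact.

A PAV suspected of perturbing epitope binding (rather than abundance) is
removed from a platform's measure by regressing the transformed measure on
allele-dosage copies of the variant and carrying the residual forward.
The module quantifies the impact of that adjustment on inter-platform
correlation, on protein-phenotype effect-size heterogeneity across
platforms, and on cis-pQTL signals (strengthened / attenuated /
newly-associated credible sets, with an LD filter guarding against
residual-LD artifacts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pqtl import CredibleSet, LD_R2_THRESHOLD, ld_r2, max_cross_r2


def pav_adjust(measures, dosage) -> np.ndarray:
    """Residual of a measure on intercept + PAV allele dosage (0/1/2 additive).

    Missing entries in either vector are preserved as missing in the output;
    the fit uses complete cases.  A monomorphic dosage leaves the measure
    unchanged (with a warning).
    """
    y = np.asarray(measures, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if y.shape != g.shape:
        raise ValueError("pav_adjust: vectors not aligned")
    mask = ~(np.isnan(y) | np.isnan(g))
    if mask.sum() < 3:
        raise ValueError("pav_adjust: fewer than 3 complete cases")
    if g[mask].std() == 0:
        warnings.warn("pav_adjust: monomorphic dosage, returning measures unchanged")
        return y.copy()
    gm, ym = g[mask], y[mask]
    b = float(((gm - gm.mean()) * (ym - ym.mean())).sum() / ((gm - gm.mean()) ** 2).sum())
    out = np.full(y.shape, np.nan)
    out[mask] = ym - ym.mean() - b * (gm - gm.mean())
    return out


def effect_heterogeneity(beta_a: float, se_a: float,
                         beta_b: float, se_b: float) -> tuple[float, float]:
    """Two-estimate heterogeneity: Q = (bA - bB)^2 / (seA^2 + seB^2), chi-square(1)."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("effect_heterogeneity: standard errors must be positive")
    q = (beta_a - beta_b) ** 2 / (se_a**2 + se_b**2)
    return float(q), float(stats.chi2.sf(q, 1))


@dataclass
class SignalComparison:
    strengthened: list[CredibleSet] = field(default_factory=list)
    attenuated: list[CredibleSet] = field(default_factory=list)
    newly_associated: list[CredibleSet] = field(default_factory=list)
    unmatched_ld_filtered: list[CredibleSet] = field(default_factory=list)


def compare_signals_post_adjustment(pre_sets: list[CredibleSet],
                                    post_sets: list[CredibleSet],
                                    genotypes) -> SignalComparison:
    """Label post-adjustment credible sets against pre-adjustment ones.

    A post set is *matched* to a pre set sharing a member or whose lead is
    in LD (r^2 > 0.1) with the pre lead; matched sets are *strengthened*
    when the post lead p is smaller than the matched pre lead p (the most
    significant among matches), else *attenuated*.  Unmatched post sets are
    *newly_associated* only when no member is in LD (r^2 > 0.1) with any
    pre-set member (no-overlap-and-no-LD rule); otherwise they are held back
    as residual-LD artifacts.
    """
    from .io import GenotypeData

    dosage_df = genotypes.dosages if isinstance(genotypes, GenotypeData) else genotypes
    out = SignalComparison()
    for post in post_sets:
        matches = []
        for pre in pre_sets:
            share = bool(set(post.members) & set(pre.members))
            try:
                lead_ld = ld_r2(dosage_df[post.lead], dosage_df[pre.lead])
            except ValueError:
                lead_ld = 0.0
            if share or lead_ld > LD_R2_THRESHOLD:
                matches.append(pre)
        if matches:
            best_pre = min(matches, key=lambda s: s.lead_p)
            if post.lead_p < best_pre.lead_p:
                out.strengthened.append(post)
            else:
                out.attenuated.append(post)
            continue
        any_ld = any(
            max_cross_r2(post.members, pre.members, dosage_df) > LD_R2_THRESHOLD
            for pre in pre_sets
        )
        if any_ld:
            out.unmatched_ld_filtered.append(post)
        else:
            out.newly_associated.append(post)
    return out


def adjustment_report_row(uniprot_id: str, pav_id: str,
                          r_pre: float, r_post: float,
                          per_group_pre=None, per_group_post=None,
                          q_pre: float = np.nan, q_post: float = np.nan,
                          p_het_pre: float = np.nan, p_het_post: float = np.nan) -> dict:
    """Flat row for the adjustment report TSV."""
    row = {"uniprot_id": uniprot_id, "pav_id": pav_id,
           "r_pre": r_pre, "r_post": r_post, "delta": r_post - r_pre,
           "Q_pre": q_pre, "Q_post": q_post,
           "p_het_pre": p_het_pre, "p_het_post": p_het_post}
    for tag, per_group in (("pre", per_group_pre), ("post", per_group_post)):
        for g, r, n in per_group or []:
            row[f"r_{tag}_{g}"] = r
            row[f"n_{tag}_{g}"] = n
    return row
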