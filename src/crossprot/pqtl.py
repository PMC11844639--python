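"""Marginal association scans, credible-set fine-mapping and LD utilities.

Mapping model
-------------
Each variant is tested marginally by simple linear regression of the
residualized, inverse-normal-transformed protein measure on allele dosage:
``beta = cov(g, y) / var(g)`` with the usual n-2 d.f. t-test.  Signals are
then resolved into 95% credible sets by a deterministic stepwise-conditional
procedure: the top variant by p-value seeds a round; every variant's
Wakefield approximate Bayes factor

    ABF = sqrt(se^2 / (se^2 + W)) * exp(z^2 W / (2 (se^2 + W))),  z = beta/se

(prior effect variance ``W``, default 0.04) is converted to a posterior
inclusion probability (pip proportional to ABF); the credible set is the
smallest pip-ranked set of variants with cumulative pip >= 0.95.  The
phenotype is then residualized on the round's lead dosage and the scan
repeats, up to ``max_signals`` rounds or until no variant passes the
significance threshold for its kind (cis: p < 5e-8; trans: p < 1e-11; a cis
variant lies within 1 Mb of the gene's TSS, closed interval).

Credible sets for one trait whose members are in LD (r^2 > 0.1) across
participants are deduplicated, keeping the set with the more significant
lead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeData

CIS_WINDOW = 1_000_000
CIS_P_THRESHOLD = 5e-8
TRANS_P_THRESHOLD = 1e-11
LD_R2_THRESHOLD = 0.1
DEFAULT_PRIOR_VARIANCE = 0.04  # Wakefield W on the SD-scale effect
DEFAULT_MAX_SIGNALS = 5
CREDIBLE_LEVEL = 0.95


def _prepare(y, dosages):
    """Complete-case y; per-variant mean imputation of missing dosages."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    keep = ~np.isnan(y)
    y, g = y[keep], g[keep]
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = np.take(col_mean, idx[1])
    return y, g


def association_scan(y, genotypes, variant_ids=None, min_n: int = 10) -> pd.DataFrame:
    """Per-variant simple-regression scan.

    Returns a DataFrame indexed by variant_id with columns beta, se, t, p, n
    and a ``degenerate`` flag (monomorphic dosage or zero residual
    variance); degenerate rows carry NaN statistics.
    """
    if isinstance(genotypes, GenotypeData):
        dosage_df = genotypes.dosages
    else:
        dosage_df = genotypes
    if variant_ids is not None:
        dosage_df = dosage_df[list(variant_ids)]
    y_arr, g = _prepare(y, dosage_df.to_numpy(dtype=float))
    n = len(y_arr)
    if n < min_n:
        raise ValueError(f"association_scan: n={n} < {min_n}, refusing degenerate inference")
    gc = g - g.mean(axis=0)
    yc = y_arr - y_arr.mean()
    sxx = (gc**2).sum(axis=0)
    syy = float((yc**2).sum())
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = gc.T @ yc / sxx_safe
    ssr = np.maximum(syy - beta**2 * sxx_safe, 0.0)
    sigma2 = ssr / (n - 2)
    zero_resid = sigma2 <= np.finfo(float).eps * max(syy, 1.0)
    se = np.sqrt(np.where(zero_resid, np.nan, sigma2) / sxx_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = beta / se
        p = 2 * stats.t.sf(np.abs(tval), n - 2)
    degenerate = mono | zero_resid
    out = pd.DataFrame({
        "beta": np.where(degenerate, np.nan, beta),
        "se": np.where(degenerate, np.nan, se),
        "t": np.where(degenerate, np.nan, tval),
        "p": np.where(degenerate, np.nan, p),
        "n": n,
        "degenerate": degenerate,
    }, index=dosage_df.columns)
    out.index.name = "variant_id"
    return out


def cis_window_mask(tss: int, chrom: str, variants: pd.DataFrame,
                    window: int = CIS_WINDOW) -> pd.Series:
    """Boolean mask of variants within ``window`` bp of the TSS (closed), same chrom.

    The complement (same chrom beyond the window, or any other chromosome)
    is the trans universe.
    """
    if tss < 1:
        raise ValueError("tss must be >= 1")
    return (variants["chrom"] == str(chrom)) & ((variants["pos"] - tss).abs() <= window)


def cis_variants(tss: int, chrom: str, variants: pd.DataFrame,
                 window: int = CIS_WINDOW) -> list[str]:
    return list(variants.index[cis_window_mask(tss, chrom, variants, window)])


def trans_variants(tss: int, chrom: str, variants: pd.DataFrame,
                   window: int = CIS_WINDOW) -> list[str]:
    return list(variants.index[~cis_window_mask(tss, chrom, variants, window)])


def ld_r2(g_i, g_j) -> float:
    """Squared Pearson correlation of two dosage vectors over shared non-missing samples."""
    x = np.asarray(g_i, dtype=float)
    y = np.asarray(g_j, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("ld_r2: monomorphic input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def log_abf(beta, se, prior_variance: float = DEFAULT_PRIOR_VARIANCE) -> np.ndarray:
    """Natural log of the Wakefield approximate Bayes factor (log scale avoids overflow)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    se2 = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(se2 / (se2 + prior_variance)) + z2 * prior_variance / (2 * (se2 + prior_variance))


@dataclass
class CredibleSet:
    """One fine-mapped signal: members with pips, lead stats, significance."""

    probe_id: str
    platform: str
    signal_index: int
    kind: str  # cis | trans
    members: list[str]
    pips: dict[str, float]
    lead: str
    lead_beta: float
    lead_se: float
    lead_p: float
    significant: bool
    member_betas: dict[str, float] = field(default_factory=dict)
    member_ps: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.lead not in self.members:
            raise ValueError("lead variant must be a credible-set member")
        if sum(self.pips.values()) < CREDIBLE_LEVEL - 1e-9:
            raise ValueError("credible set must cover >= 95% posterior mass")


def finemap(y, genotypes, kind: str, probe_id: str = "", platform: str = "",
            variant_ids=None, threshold: float | None = None,
            prior_variance: float = DEFAULT_PRIOR_VARIANCE,
            max_signals: int = DEFAULT_MAX_SIGNALS,
            credible_level: float = CREDIBLE_LEVEL) -> list[CredibleSet]:
    """Stepwise-conditional fine-mapping into 95% credible sets.

    Returns an empty list when no variant reaches the kind's significance
    threshold.  Each returned set carries the per-round marginal (beta, p)
    of its members, used downstream for cross-platform sign comparison.
    """
    if kind not in ("cis", "trans"):
        raise ValueError("kind must be 'cis' or 'trans'")
    if threshold is None:
        threshold = CIS_P_THRESHOLD if kind == "cis" else TRANS_P_THRESHOLD
    dosage_df = genotypes.dosages if isinstance(genotypes, GenotypeData) else genotypes
    if variant_ids is not None:
        dosage_df = dosage_df[list(variant_ids)]
    if dosage_df.shape[1] == 0:
        return []

    y_work = np.asarray(y, dtype=float).copy()
    sets: list[CredibleSet] = []
    for signal_index in range(max_signals):
        scan = association_scan(y_work, dosage_df)
        usable = scan[~scan["degenerate"]]
        if usable.empty or usable["p"].min() >= threshold:
            break
        lead = usable["p"].idxmin()
        labf = log_abf(usable["beta"].to_numpy(), usable["se"].to_numpy(), prior_variance)
        labf = labf - labf.max()
        pip_arr = np.exp(labf)
        pip_arr = pip_arr / pip_arr.sum()
        pip = pd.Series(pip_arr, index=usable.index)
        order = np.argsort(-pip_arr, kind="stable")
        cum = np.cumsum(pip_arr[order])
        k = int(np.searchsorted(cum, credible_level - 1e-12) + 1)
        members = list(usable.index[order[:k]])
        pips = {v: float(pip.loc[v]) for v in members}
        sets.append(CredibleSet(
            probe_id=probe_id, platform=platform, signal_index=signal_index,
            kind=kind, members=members, pips=pips, lead=str(lead),
            lead_beta=float(usable.loc[lead, "beta"]),
            lead_se=float(usable.loc[lead, "se"]),
            lead_p=float(usable.loc[lead, "p"]),
            significant=bool(usable.loc[lead, "p"] < threshold),
            member_betas={v: float(usable.loc[v, "beta"]) for v in members},
            member_ps={v: float(usable.loc[v, "p"]) for v in members},
        ))
        # condition on the lead: residualize working phenotype on its dosage
        g_lead = dosage_df[lead].to_numpy(dtype=float)
        g_lead = np.where(np.isnan(g_lead), np.nanmean(g_lead), g_lead)
        keep = ~np.isnan(y_work)
        gl = g_lead[keep] - g_lead[keep].mean()
        yl = y_work[keep] - y_work[keep].mean()
        denom = float(gl @ gl)
        if denom == 0:
            break
        b = float(gl @ yl) / denom
        y_work = y_work.copy()
        y_work[keep] = yl - b * gl
    return sets


def max_cross_r2(members_i, members_j, dosage_df: pd.DataFrame) -> float:
    """Largest r^2 over all cross-pair member combinations (incl. shared members)."""
    best = 0.0
    for a in members_i:
        for b in members_j:
            if a == b:
                return 1.0
            try:
                best = max(best, ld_r2(dosage_df[a], dosage_df[b]))
            except ValueError:
                continue
    return best


def dedup_credible_sets(sets: list[CredibleSet], genotypes) -> list[CredibleSet]:
    """Keep, among LD-linked (r^2 > 0.1) sets for one trait, the best-lead set.

    Sets are visited by ascending lead p; a set is dropped when any already
    retained set shares a member or has a cross-pair r^2 above threshold.
    """
    dosage_df = genotypes.dosages if isinstance(genotypes, GenotypeData) else genotypes
    ordered = sorted(sets, key=lambda s: (s.lead_p, s.lead))
    kept: list[CredibleSet] = []
    for cand in ordered:
        linked = any(
            max_cross_r2(cand.members, prev.members, dosage_df) > LD_R2_THRESHOLD
            for prev in kept
        )
        if not linked:
            kept.append(cand)
    return kept


def credible_sets_table(sets: list[CredibleSet]) -> pd.DataFrame:
    """Flat TSV-ready view: members and pips semicolon-packed."""
    rows = []
    for s in sets:
        rows.append({
            "probe_id": s.probe_id, "platform": s.platform,
            "signal_index": s.signal_index, "kind": s.kind,
            "lead": s.lead, "lead_beta": s.lead_beta, "lead_se": s.lead_se,
            "lead_p": s.lead_p, "significant": s.significant,
            "members": ";".join(s.members),
            "pips": ";".join(f"{s.pips[v]:.4g}" for v in s.members),
        })
    cols = ["probe_id", "platform", "signal_index", "kind", "lead", "lead_beta",
            "lead_se", "lead_p", "significant", "members", "pips"]
    return pd.DataFrame(rows, columns=cols)
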