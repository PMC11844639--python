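"""Inter-platform correlation per protein and its cross-ancestry heterogeneity.

For each UniProt target measured on both platforms, the best probe pair (the
one with the highest all-samples Pearson correlation of transformed
measures) is carried forward.  Heterogeneity of the correlation across
ancestry groups is tested by Fisher's r-to-z transformation and Cochran's Q
with weights ``n - 3`` (the inverse variance of the z estimate), referred to
a chi-square with ``#groups - 1`` degrees of freedom, at a Bonferroni level
over the number of probe pairs tested.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import UNASSIGNED, ProteinMatrix


def pairwise_correlation(x, y) -> tuple[float, int]:
    """Pearson correlation over complete pairs; returns (r, n_used)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pairwise_correlation: vectors not aligned")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"pairwise_correlation: need >= 3 complete pairs, got {n}")
    xm, ym = x[mask], y[mask]
    sx, sy = xm.std(), ym.std()
    if sx == 0 or sy == 0:
        raise ValueError("pairwise_correlation: zero variance over complete pairs")
    r = float(((xm - xm.mean()) * (ym - ym.mean())).sum() / (n * sx * sy))
    return float(np.clip(r, -1.0, 1.0)), n


def best_probe_pair(pairs):
    """Pick the (probe_A, probe_B, r) tuple with maximal r.

    Ties break lexicographically on (probe_A, probe_B) so selection is
    deterministic.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("best_probe_pair: empty candidate list")
    return sorted(pairs, key=lambda t: (-t[2], str(t[0]), str(t[1])))[0]


def correlation_heterogeneity(groups) -> tuple[float, int, float]:
    """Cochran's Q across Fisher-z-transformed per-group correlations.

    ``groups`` is an iterable of (r_g, n_g).  Groups with n_g < 4 carry
    non-positive weight (w = n - 3) and are excluded with a warning, reducing
    the degrees of freedom.  Returns (Q, df, p).
    """
    usable = []
    for r, n in groups:
        if n < 4:
            warnings.warn(f"group with n={n} < 4 excluded from heterogeneity test")
            continue
        if abs(r) >= 1:
            raise ValueError("correlation_heterogeneity: |r| = 1 gives infinite z")
        usable.append((float(r), int(n)))
    if len(usable) < 2:
        raise ValueError("correlation_heterogeneity: need >= 2 groups with n >= 4")
    z = np.arctanh([r for r, _ in usable])
    w = np.array([n - 3 for _, n in usable], dtype=float)
    zbar = float((w * z).sum() / w.sum())
    q = float((w * (z - zbar) ** 2).sum())
    df = len(usable) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def bonferroni_threshold(alpha: float, m: int) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def per_ancestry_correlations(x, y, labels, groups) -> list[tuple[str, float, int]]:
    """Per-group (group, r, n) over complete pairs; 'unassigned' never enters."""
    labels = np.asarray(labels)
    out = []
    for g in groups:
        if g == UNASSIGNED:
            continue
        sel = labels == g
        try:
            r, n = pairwise_correlation(np.asarray(x, float)[sel], np.asarray(y, float)[sel])
        except ValueError:
            continue
        out.append((g, r, n))
    return out


def concordance_table(mat_a: ProteinMatrix, mat_b: ProteinMatrix,
                      probe_map: pd.DataFrame, samples: pd.DataFrame,
                      groups, alpha: float = 0.05) -> pd.DataFrame:
    """One row per UniProt target measured on both platforms.

    Columns: uniprot_id, probe_id_A, probe_id_B, r_overall, n_overall,
    per-group r_<g>/n_<g>, Q, df, p_het, p_het_bonferroni (the Bonferroni
    threshold over all candidate probe pairs), het_significant.
    """
    if mat_a.layer != "transformed" or mat_b.layer != "transformed":
        raise ValueError("concordance expects transformed matrices")
    for mat in (mat_a, mat_b):
        if list(mat.values.index) != list(samples.index):
            raise ValueError("concordance: matrices not aligned with sample table")

    pm_a = probe_map[probe_map["platform"] == mat_a.platform]
    pm_b = probe_map[probe_map["platform"] == mat_b.platform]
    shared = sorted(set(pm_a["uniprot_id"]) & set(pm_b["uniprot_id"]))

    n_pairs_total = 0
    chosen = []
    for uid in shared:
        probes_a = [p for p in pm_a.loc[pm_a["uniprot_id"] == uid, "probe_id"]
                    if p in mat_a.values.columns]
        probes_b = [p for p in pm_b.loc[pm_b["uniprot_id"] == uid, "probe_id"]
                    if p in mat_b.values.columns]
        candidates = []
        for pa in probes_a:
            for pb in probes_b:
                try:
                    r, n = pairwise_correlation(mat_a.values[pa], mat_b.values[pb])
                except ValueError:
                    continue
                candidates.append((pa, pb, r, n))
        n_pairs_total += len(candidates)
        if candidates:
            pa, pb, r = best_probe_pair([(c[0], c[1], c[2]) for c in candidates])
            n = next(c[3] for c in candidates if (c[0], c[1]) == (pa, pb))
            chosen.append((uid, pa, pb, r, n))

    threshold = bonferroni_threshold(alpha, max(n_pairs_total, 1))
    labels = samples["ancestry"].to_numpy()
    rows = []
    for uid, pa, pb, r, n in chosen:
        per_g = per_ancestry_correlations(mat_a.values[pa], mat_b.values[pb], labels, groups)
        row = {"uniprot_id": uid, "probe_id_A": pa, "probe_id_B": pb,
               "r_overall": r, "n_overall": n}
        for g, rg, ng in per_g:
            row[f"r_{g}"] = rg
            row[f"n_{g}"] = ng
        if len([1 for _, _, ng in per_g if ng >= 4]) >= 2:
            q, df, p = correlation_heterogeneity([(rg, ng) for _, rg, ng in per_g])
            row.update(Q=q, df=df, p_het=p, p_het_bonferroni=threshold,
                       het_significant=p < threshold)
        else:
            row.update(Q=np.nan, df=0, p_het=np.nan, p_het_bonferroni=threshold,
                       het_significant=False)
        rows.append(row)
    return pd.DataFrame(rows)
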