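"""Protein-phenotype association models and limit-of-detection (LOD).

Phenotypes are modeled as outcomes with the transformed protein measure as
predictor: linear regression for continuous outcomes (age, BMI), logistic
regression for binary ones (sex, T2D).  Covariate sets follow the cohort
convention: plate and site for age/sex models, additionally age and sex for
BMI, and age, site (and sex for T2D) in the logistic models.

The antibody platform's LOD per probe is the median of its negative-control
measures plus three sample standard deviations; it is compared against
*raw* (untransformed) measures only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ProteinMatrix

#: default covariate columns per phenotype (phenotype itself excluded)
DEFAULT_COVARIATES = {
    "age": ["plate", "site"],
    "sex": ["plate", "site"],
    "bmi": ["plate", "site", "age", "sex"],
    "t2d": ["age", "site", "sex"],
}
PHENOTYPE_FAMILY = {"age": "linear", "bmi": "linear", "sex": "logistic", "t2d": "logistic"}


@dataclass
class PhenoAssoc:
    probe_id: str
    platform: str
    phenotype: str
    model: str
    beta: float
    se: float
    p: float
    n: int
    covariates: str
    flagged: bool = False


def _design(samples: pd.DataFrame, covariates, protein: np.ndarray) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=samples.index, name="intercept"),
             pd.Series(protein, index=samples.index, name="protein")]
    for c in covariates:
        if samples[c].dtype == object or str(samples[c].dtype) == "category":
            parts.append(pd.get_dummies(samples[c], prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(samples[c].astype(float))
    return pd.concat(parts, axis=1)


def phenotype_association(protein, phenotype_name: str, samples: pd.DataFrame,
                          probe_id: str = "", platform: str = "",
                          family: str | None = None,
                          covariates=None) -> PhenoAssoc:
    """Fit one protein-phenotype model and return the protein coefficient."""
    family = family or PHENOTYPE_FAMILY[phenotype_name]
    covariates = DEFAULT_COVARIATES[phenotype_name] if covariates is None else covariates
    protein = np.asarray(protein, dtype=float)
    outcome = samples[phenotype_name].astype(float).to_numpy()
    mask = ~(np.isnan(protein) | np.isnan(outcome))
    x = _design(samples, covariates, protein).iloc[np.flatnonzero(mask)]
    y = outcome[mask]
    n = int(mask.sum())
    cov_str = ",".join(covariates)
    if family == "linear":
        fit = sm.OLS(y, x.to_numpy(dtype=float)).fit()
        j = list(x.columns).index("protein")
        flagged = bool(fit.ssr <= np.finfo(float).eps * max(float((y - y.mean()) @ (y - y.mean())), 1.0))
        return PhenoAssoc(probe_id, platform, phenotype_name, "linear",
                          float(fit.params[j]), float(fit.bse[j]),
                          float(fit.pvalues[j]) if not flagged else 0.0,
                          n, cov_str, flagged)
    if family == "logistic":
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("logistic outcome must have both classes present")
        j = list(x.columns).index("protein")
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, x.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
            separated = (not fit.mle_retvals.get("converged", True)) or abs(fit.params[j]) > 20
        except Exception:
            separated = True
            fit = None
        if separated:
            return PhenoAssoc(probe_id, platform, phenotype_name, "logistic",
                              np.nan, np.nan, np.nan, n, cov_str, flagged=True)
        return PhenoAssoc(probe_id, platform, phenotype_name, "logistic",
                          float(fit.params[j]), float(fit.bse[j]),
                          float(fit.pvalues[j]), n, cov_str)
    raise ValueError(f"unknown family {family!r}")


def olink_lod(control_values) -> float:
    """LOD = median(negative controls) + 3 * sample SD (n-1 denominator)."""
    vals = np.asarray(control_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("olink_lod: need >= 2 control values")
    return float(np.median(vals) + 3.0 * np.std(vals, ddof=1))


def frac_above_lod(measures, lod: float) -> float:
    """Fraction of non-missing raw measures strictly above the LOD."""
    vals = np.asarray(measures, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("frac_above_lod: all measures missing")
    return float((vals > lod).sum() / vals.size)


def lod_table(matrix: ProteinMatrix, controls: pd.DataFrame) -> pd.DataFrame:
    """Per-probe LOD and fraction-above from a raw matrix and long-format controls.

    Refuses transformed input: LOD is only meaningful on the raw scale.
    """
    if matrix.layer != "raw":
        raise ValueError(f"LOD requires the raw layer, got {matrix.layer!r}")
    rows = []
    for probe_id, grp in controls.groupby("probe_id"):
        if probe_id not in matrix.values.columns:
            continue
        lod = olink_lod(grp["value"].to_numpy())
        frac = frac_above_lod(matrix.values[probe_id].to_numpy(), lod)
        rows.append({"probe_id": probe_id, "platform": matrix.platform,
                     "lod": lod, "frac_above": frac})
    return pd.DataFrame(rows)


def association_table(assocs: list[PhenoAssoc]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in assocs])
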