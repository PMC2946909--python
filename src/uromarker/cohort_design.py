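"""Clinical-side utilities: GFR estimation, renal-status classification,
discovery/validation splitting and logistic assessment of clinical
confounders.

Renal status follows the explicit rule used to isolate the diabetes-type
signal from kidney-disease signal: a subject has chronic renal impairment
when the urinary albumin/creatinine ratio exceeds 30 µg/mg or the estimated
GFR falls below 60 mL/min; both boundaries are strict, so ACR = 30 and
GFR = 60 still count as normoalbuminuric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import CohortTable

__all__ = [
    "RenalStatus",
    "estimate_gfr_cockcroft_gault",
    "classify_renal_status",
    "split_discovery_validation",
    "fit_logistic_confounders",
]

NORMO = "normoalbuminuric"
CKD = "chronic_renal_impairment"


@dataclass
class RenalStatus:
    status: str
    acr: float
    gfr: float


def estimate_gfr_cockcroft_gault(
    age: float, weight: float, sex: str, creatinine: float
) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    (140 - age) * weight / (72 * serum creatinine), times 0.85 for women.
    Creatinine in mg/dL, weight in kg. Ages of 140+ clamp the estimate to 0
    with a warning. Note this is a creatinine-clearance estimate used as a
    GFR proxy; no body-surface-area renormalization is applied.
    """
    if creatinine <= 0:
        raise ValueError("serum creatinine must be positive")
    if weight <= 0 or age < 0:
        raise ValueError("age and weight must be positive")
    gfr = (140.0 - age) * weight / (72.0 * creatinine)
    if sex.lower().startswith("f"):
        gfr *= 0.85
    if gfr < 0:
        warnings.warn(f"age {age} exceeds 140; clamping GFR estimate to 0")
        gfr = 0.0
    return gfr


def classify_renal_status(acr: float, gfr: float) -> RenalStatus:
    """Chronic renal impairment iff ACR > 30 µg/mg or GFR < 60 (strict)."""
    if acr < 0 or gfr < 0:
        raise ValueError("acr and gfr must be non-negative")
    status = CKD if (acr > 30.0 or gfr < 60.0) else NORMO
    return RenalStatus(status=status, acr=acr, gfr=gfr)


def split_discovery_validation(
    cohort: CohortTable,
    fractions: dict[str, float],
    stratify_by: str = "diagnosis",
    seed: int = 0,
) -> pd.Series:
    """Random stratified partition of subjects into named parts.

    ``fractions`` maps part name -> fraction (summing to 1). Within each
    stratum of ``stratify_by``, part sizes follow largest-remainder rounding,
    so stratum proportions are preserved to rounding. Reproducible under
    ``seed``; returns a Series subject_id -> part name.
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    parts = sorted(fractions)
    rng = np.random.default_rng(seed)
    labels = pd.Series(index=cohort.data.index, dtype=object, name="part")
    for stratum, sub in cohort.data.groupby(cohort.data[stratify_by].astype(str)):
        ids = np.array(sub.index)
        if len(ids) == 0:
            raise ValueError(f"empty stratum {stratum!r}")
        rng.shuffle(ids)
        n = len(ids)
        exact = np.array([fractions[p] * n for p in parts])
        sizes = np.floor(exact).astype(int)
        rem = exact - sizes
        for j in np.argsort(-rem, kind="mergesort")[: n - sizes.sum()]:
            sizes[j] += 1
        start = 0
        for p, size in zip(parts, sizes):
            labels.loc[ids[start : start + size]] = p
            start += size
    return labels


def fit_logistic_confounders(
    cohort: CohortTable,
    outcome: str,
    covariates: list[str],
    joint: bool = True,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression of a binary outcome on
    clinical covariates.

    ``joint=True`` fits all covariates simultaneously; ``joint=False`` fits
    one single-covariate model per covariate. Rows with missing values in
    the used columns are excluded (count reported via the ``n_used``
    column). Returns a coefficient table with Wald SE and p per covariate
    and explicit ``converged`` / ``separation`` flags rather than silent
    divergence.
    """
    df = cohort.data.copy()
    y_raw = df[outcome]
    levels = sorted(y_raw.dropna().astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary, has levels {levels}")
    y = (y_raw.astype(str) == levels[1]).astype(float)

    def _encode(col: str) -> pd.Series:
        v = df[col]
        if v.dtype == object:
            lv = sorted(v.dropna().astype(str).unique())
            if len(lv) > 2:
                raise ValueError(f"covariate {col!r} has >2 levels")
            return (v.astype(str) == lv[-1]).astype(float)
        return pd.to_numeric(v, errors="coerce")

    def _fit(cols: list[str]) -> list[dict]:
        X = pd.DataFrame({c: _encode(c) for c in cols})
        mask = X.notna().all(axis=1) & y.notna()
        Xu, yu = X[mask], y[mask]
        if len(Xu) <= len(cols) + 1:
            raise ValueError("too few complete rows for the logistic fit")
        Xd = sm.add_constant(Xu, has_constant="add")
        separation = False
        converged = True
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(yu, Xd).fit(disp=0, maxiter=100, method="newton")
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception:
                separation = True
                try:
                    res = sm.Logit(yu, Xd).fit_regularized(
                        disp=0, alpha=1e-6, maxiter=200
                    )
                except Exception:
                    res = None
        if res is None:
            params = pd.Series(np.nan, index=Xd.columns)
            bse = params.copy()
            pvals = params.copy()
        else:
            params = res.params
            try:
                bse = res.bse
                pvals = res.pvalues
            except Exception:
                bse = pd.Series(np.nan, index=params.index)
                pvals = pd.Series(np.nan, index=params.index)
        if not separation:
            # flag quasi-separation via exploding coefficients / SEs
            if (np.abs(params.drop("const")) > 50).any() or bse.isna().any():
                separation = True
        return [
            {
                "covariate": c,
                "estimate": float(params[c]),
                "se": float(bse[c]),
                "p": float(pvals[c]),
                "n_used": int(len(Xu)),
                "converged": converged,
                "separation": separation,
            }
            for c in cols
        ]

    rows: list[dict] = []
    if joint:
        rows.extend(_fit(list(covariates)))
    else:
        for c in covariates:
            rows.extend(_fit([c]))
    return pd.DataFrame(rows).set_index("covariate")
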