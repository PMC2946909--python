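"""Statistical core: frequency-gated differential testing with BH-FDR
control, covariate-association exclusion, independent-cohort Mann-Whitney
validation, and the signed regulation factor.

Discovery testing uses a Welch two-sample z statistic on base-10 log
transformed intensities of *detected* samples only (the normal reference in
place of the t reference), restricted to peptides detected in at least half
the samples of a diagnostic group; p-values are corrected by the
Benjamini-Hochberg step-up procedure with the FDR controlled at 0.05.
Candidates whose abundance depends on a clinical covariate (age, diabetes
duration) are removed via a Kruskal-Wallis test across covariate quantile
bins. Validation in independent cohorts re-tests panel peptides with a
two-sided Mann-Whitney U test in which non-detected samples enter as zeros
(ties at the bottom rank).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import PeptideMatrix, PanelDefinition

__all__ = [
    "test_peptide_discovery",
    "adjust_bh",
    "discover_biomarkers",
    "exclude_covariate_associated",
    "validate_mann_whitney",
    "mann_whitney_p",
    "regulation_factor",
]

#: combined sample size up to which exact Mann-Whitney p-values are used
EXACT_MW_MAX_N = 25
#: combined size up to which tied inputs get exact enumeration instead of
#: the tie-corrected normal approximation
EXACT_MW_TIES_MAX_N = 14


def _two_group_masks(matrix: PeptideMatrix, groups: pd.Series):
    groups = groups.reindex(matrix.sample_ids).astype(str)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    g = groups.to_numpy()
    return labels, (g == labels[0]), (g == labels[1])


def regulation_factor(mean_a: float, mean_b: float) -> float:
    """Signed fold change of group B relative to group A.

    mean_b/mean_a when B is up, -mean_a/mean_b when B is down, 1 when equal.
    Returns NaN (flagged missing) when either mean is zero or undefined.
    """
    if not (mean_a > 0) or not (mean_b > 0):
        return float("nan")
    if mean_b > mean_a:
        return mean_b / mean_a
    if mean_b < mean_a:
        return -mean_a / mean_b
    return 1.0


def test_peptide_discovery(
    matrix: PeptideMatrix,
    groups: pd.Series,
    min_group_freq: float = 0.5,
    scope: str = "any_group",
    reference: str = "normal",
) -> pd.DataFrame:
    """Welch two-sample test on log10 intensities of detected samples.

    ``groups`` maps sample_id -> one of two labels (sorted alphabetically
    into group A and group B). Peptides pass the frequency gate when
    detected in >= ``min_group_freq`` of samples of at least one group
    (``scope="any_group"``) or of both (``scope="both_groups"``). A gated
    peptide with fewer than 3 detected values in either group is marked
    untestable rather than raising.

    ``reference="normal"`` (default) reads the Welch statistic against the
    standard normal — the Gaussian approximation to the t reference, which
    is mildly anti-conservative at double-digit group sizes;
    ``reference="t"`` uses the Welch-Satterthwaite t reference and yields
    exactly calibrated p-values under the log-normal model.

    Returns a DataFrame indexed by peptide_id with columns ``tested``,
    ``p_raw``, ``freq_a``/``freq_b``, ``n_det_a``/``n_det_b``,
    ``mean_log10_a``/``mean_log10_b``, ``mean_linear_a``/``mean_linear_b``
    and the signed ``regulation_factor`` of B vs A.
    """
    if scope not in ("any_group", "both_groups"):
        raise ValueError(f"unknown scope {scope!r}")
    if reference not in ("normal", "t"):
        raise ValueError(f"unknown reference {reference!r}")
    labels, mask_a, mask_b = _two_group_masks(matrix, groups)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs >= 3 samples")
    A = matrix.amplitudes.to_numpy(float)
    det = A > 0
    L = np.zeros_like(A)
    np.log10(A, out=L, where=det)

    def _stats(mask):
        d = det[:, mask]
        n = d.sum(axis=1)
        s = (L[:, mask] * d).sum(axis=1)
        ss = (L[:, mask] ** 2 * d).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
            var = np.where(n > 1, (ss - n * mean**2) / np.maximum(n - 1, 1), np.nan)
        var = np.clip(var, 0.0, None)
        lin_sum = (A[:, mask] * d).sum(axis=1)
        lin_mean = np.where(n > 0, lin_sum / np.maximum(n, 1), np.nan)
        freq = n / mask.sum()
        return n, mean, var, lin_mean, freq

    n1, m1, v1, lin1, f1 = _stats(mask_a)
    n2, m2, v2, lin2, f2 = _stats(mask_b)
    if scope == "any_group":
        gate = (f1 >= min_group_freq) | (f2 >= min_group_freq)
    else:
        gate = (f1 >= min_group_freq) & (f2 >= min_group_freq)
    testable = gate & (n1 >= 3) & (n2 >= 3)

    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = v1 / n1 + v2 / n2
        z = np.where(se2 > 0, (m1 - m2) / np.sqrt(np.where(se2 > 0, se2, 1)), 0.0)
        z = np.where((se2 == 0) & (m1 != m2), np.inf * np.sign(m1 - m2), z)
    if reference == "normal":
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            df_w = se2**2 / (
                (v1 / n1) ** 2 / np.maximum(n1 - 1, 1)
                + (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
            )
        df_w = np.where(np.isfinite(df_w) & (df_w > 0), df_w, 1.0)
        p = 2.0 * stats.t.sf(np.abs(z), df_w)
    p = np.where(testable, p, np.nan)

    F = np.array([regulation_factor(a, b) for a, b in zip(lin1, lin2)])
    out = pd.DataFrame(
        {
            "tested": testable,
            "p_raw": p,
            "freq_a": f1,
            "freq_b": f2,
            "n_det_a": n1,
            "n_det_b": n2,
            "mean_log10_a": m1,
            "mean_log10_b": m2,
            "mean_linear_a": lin1,
            "mean_linear_b": lin2,
            "regulation_factor": F,
        },
        index=matrix.peptides.index,
    )
    out.attrs["group_a"], out.attrs["group_b"] = labels
    return out


def adjust_bh(
    p_values, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (monotone adjusted q-values, boolean significance at
    ``q_level``). Empty input yields empty outputs.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def discover_biomarkers(
    matrix: PeptideMatrix,
    groups: pd.Series,
    min_group_freq: float = 0.5,
    q_level: float = 0.05,
    scope: str = "any_group",
    reference: str = "normal",
) -> pd.DataFrame:
    """Full discovery pass: frequency-gated z-tests + BH correction.

    Returns the per-peptide record table with ``q_bh`` and ``significant``
    columns, ordered by ascending q, then p, then peptide_id (untested
    peptides sort last).
    """
    rec = test_peptide_discovery(matrix, groups, min_group_freq, scope, reference)
    rec["q_bh"] = np.nan
    rec["significant"] = False
    tested = rec.index[rec["tested"]]
    if len(tested):
        q, sig = adjust_bh(rec.loc[tested, "p_raw"].to_numpy(), q_level)
        rec.loc[tested, "q_bh"] = q
        rec.loc[tested, "significant"] = sig
    rec = rec.sort_values(
        ["q_bh", "p_raw"], kind="mergesort", na_position="last"
    )
    return rec


def exclude_covariate_associated(
    matrix: PeptideMatrix,
    candidates,
    covariate: pd.Series,
    n_bins: int = 4,
    alpha: float = 0.05,
) -> tuple[list[str], list[str], pd.Series]:
    """Kruskal-Wallis screen of candidates against a clinical covariate.

    The covariate is quantile-binned into ``n_bins`` groups; each
    candidate's amplitudes over *detected* samples (the same convention as
    the discovery test; detection frequency is modeled separately) are
    compared across bins and the candidate is excluded when p < ``alpha``
    (strict). Returns (excluded ids, retained ids, per-candidate
    p-values). A covariate that cannot form >= 2 bins raises ValueError.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    covariate = covariate.reindex(matrix.sample_ids).astype(float)
    if covariate.isna().any():
        raise ValueError("covariate missing for some samples")
    try:
        bins = pd.qcut(covariate, n_bins, labels=False, duplicates="drop")
    except ValueError as exc:
        raise ValueError(f"cannot bin covariate: {exc}") from exc
    if bins.nunique() < 2:
        raise ValueError("covariate is (near-)constant; cannot form bins")
    bin_masks = [bins.to_numpy() == b for b in sorted(bins.unique())]
    cand = [str(c) for c in candidates]
    pvals = {}
    A = matrix.amplitudes
    for pid in cand:
        vals = A.loc[pid].to_numpy(float)
        groups_vals = [vals[m][vals[m] > 0] for m in bin_masks]
        groups_vals = [g for g in groups_vals if len(g)]
        if len(groups_vals) < 2:
            pvals[pid] = 1.0
            continue
        pooled = np.concatenate(groups_vals)
        if np.all(pooled == pooled[0]):
            pvals[pid] = 1.0
            continue
        h, p = stats.kruskal(*groups_vals)
        pvals[pid] = float(p)
    pser = pd.Series(pvals, name="kw_p")
    excluded = sorted(pser.index[pser < alpha])
    retained = sorted(set(cand) - set(excluded))
    return excluded, retained, pser


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value (shared test engine).

    Exact for combined n <= 25 without ties; exact enumeration for small
    tied inputs (combined n <= 14, U measured with ties counted half);
    otherwise the normal approximation with tie correction. Degenerate
    inputs where every value is equal return p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = len(pooled)
    has_ties = len(np.unique(pooled)) < n
    if not has_ties and n <= EXACT_MW_MAX_N:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    if has_ties and n <= EXACT_MW_TIES_MAX_N:
        return _exact_mw_with_ties(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y with ties counted half (pairwise definition)."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_mw_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation two-sided p for tied data via full enumeration of
    group assignments; extremeness measured by |U - mn/2|."""
    m, nn = len(x), len(y)
    pooled = np.concatenate([x, y])
    center = m * nn / 2.0
    u_obs = abs(_u_statistic(x, y) - center)
    count = 0
    total = 0
    idx = np.arange(m + nn)
    for comb in combinations(idx, m):
        sel = np.zeros(m + nn, dtype=bool)
        sel[list(comb)] = True
        u = abs(_u_statistic(pooled[sel], pooled[~sel]) - center)
        total += 1
        if u >= u_obs - 1e-12:
            count += 1
    return count / total


def validate_mann_whitney(
    matrix: PeptideMatrix,
    panel: PanelDefinition,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Re-test panel peptides in an independent cohort.

    Two-sided Mann-Whitney U per panel peptide on amplitudes with
    non-detected samples entering as zeros. Peptides absent from the matrix
    are recorded with ``missing=True`` rather than raising. Significance is
    p <= ``alpha``.
    """
    labels, mask_a, mask_b = _two_group_masks(matrix, groups)
    rows = []
    for pid in panel.peptide_ids:
        if pid not in matrix.amplitudes.index:
            rows.append({"peptide_id": pid, "p": np.nan, "significant": False, "missing": True})
            continue
        vals = matrix.amplitudes.loc[pid].to_numpy(float)
        p = mann_whitney_p(vals[mask_a], vals[mask_b])
        rows.append(
            {"peptide_id": pid, "p": p, "significant": bool(p <= alpha), "missing": False}
        )
    out = pd.DataFrame(rows).set_index("peptide_id")
    out.attrs["group_a"], out.attrs["group_b"] = labels
    out.attrs["n_significant"] = int(out["significant"].sum())
    return out
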