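"""End-to-end study workflows on synthetic cohorts.

These functions wire the pipeline stages together the way the study design
uses them — replicate discovery cohorts for false-discovery calibration,
discovery plus covariate exclusion against ground truth, and train/test
panel evaluation on a stratified cohort split — and are shared by the test
suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .biomarker_discovery import discover_biomarkers, exclude_covariate_associated
from .cohort_design import split_discovery_validation
from .evaluation import auc_confidence_interval, roc_curve
from .io_formats import PanelDefinition
from .panel_classifier import score_matrix, train_panel
from .synthetic_cohort import SimConfig, generate_cohort

__all__ = [
    "empirical_bh_fdr",
    "discovery_exclusion_recovery",
    "train_test_panel_auc",
]

MAX_SEED = 2**31 - 1


def normalize_matrix_against_housekeeping(matrix, truth):
    """Per-sample global median-ratio normalization of a generated matrix.

    The matrix from :func:`generate_cohort` still carries each sample's
    urine-dilution factor; the real pipeline removes it before any testing
    by rescaling against the housekeeping reference amplitudes. With no
    housekeeping peptides configured the matrix is returned unchanged.
    """
    hk = truth.peptides.index[truth.peptides["is_housekeeping"]]
    if not len(hk):
        return matrix
    canonical = 10.0 ** truth.peptides.loc[hk, "baseline_log10"]
    observed = matrix.amplitudes.loc[hk]
    ratio = canonical.to_numpy()[:, None] / observed.where(observed > 0)
    scale = ratio.median(axis=0).fillna(1.0)
    out = matrix.amplitudes * scale
    from .io_formats import PeptideMatrix

    return PeptideMatrix(matrix.peptides.copy(), out)


def _contrast_groups(cohort, truth_col: str):
    diag = cohort.diagnosis()
    if truth_col == "is_differential_dm":
        return diag.map(lambda d: "control" if d == "control" else "dm")
    return diag  # t1d vs t2d when no controls are simulated


def empirical_bh_fdr(
    config: SimConfig,
    n_replicates: int = 200,
    q_level: float = 0.05,
    base_seed: int = 0,
    truth_col: str = "is_differential_type",
    reference: str = "normal",
) -> pd.DataFrame:
    """Replicate the discovery procedure and record its false discoveries.

    For each replicate a fresh cohort is generated (seed = base_seed + i),
    the frequency-gated z-test + BH procedure runs at ``q_level``, and the
    false-discovery proportion among declared discoveries is recorded
    against the generator's ground truth. Returns one row per replicate
    with ``n_significant``, ``n_false``, ``fdp``.
    """
    rows = []
    for i in range(n_replicates):
        cfg = dataclasses.replace(config, seed=int((base_seed + i) % MAX_SEED))
        cohort, matrix, truth = generate_cohort(cfg)
        groups = _contrast_groups(cohort, truth_col)
        rec = discover_biomarkers(matrix, groups, q_level=q_level, reference=reference)
        sig = rec.index[rec["significant"]]
        is_true = truth.peptides.loc[sig, truth_col]
        n_sig = len(sig)
        n_false = int((~is_true).sum())
        rows.append(
            {
                "replicate": i,
                "n_significant": n_sig,
                "n_false": n_false,
                "fdp": n_false / n_sig if n_sig else np.nan,
            }
        )
    return pd.DataFrame(rows)


def discovery_exclusion_recovery(config: SimConfig) -> dict:
    """Run discovery + age/duration exclusion once against ground truth.

    Returns recovery of designed differential peptides among BH discoveries,
    the fraction of truly age-correlated candidates excluded by the
    Kruskal-Wallis screen, and the retained candidate list.
    """
    cohort, matrix, truth = generate_cohort(config)
    matrix = normalize_matrix_against_housekeeping(matrix, truth)
    groups = _contrast_groups(cohort, "is_differential_type")
    rec = discover_biomarkers(matrix, groups)
    sig = list(rec.index[rec["significant"]])
    truth_pep = truth.peptides
    n_true = int(truth_pep["is_differential_type"].sum())
    recovered = int(truth_pep.loc[sig, "is_differential_type"].sum()) if sig else 0

    age = cohort.data["age"].astype(float)
    age.index = matrix.sample_ids  # subject ids are the sample ids
    excluded, retained, _ = exclude_covariate_associated(matrix, sig, age)
    age_flag = truth_pep["is_age_correlated"]
    n_age_candidates = int(age_flag.loc[sig].sum()) if sig else 0
    n_age_excluded = int(age_flag.loc[excluded].sum()) if excluded else 0
    return {
        "n_significant": len(sig),
        "n_true_differential": n_true,
        "n_recovered": recovered,
        "recovery": recovered / n_true if n_true else np.nan,
        "n_age_candidates": n_age_candidates,
        "n_age_excluded": n_age_excluded,
        "age_exclusion_rate": (
            n_age_excluded / n_age_candidates if n_age_candidates else np.nan
        ),
        "retained": retained,
        "excluded": excluded,
    }


def train_test_panel_auc(
    config: SimConfig,
    panel: PanelDefinition | None = None,
    split_seed: int = 0,
    discovery_fraction: float = 0.5,
) -> dict:
    """Train the SVM panel on a stratified discovery split, evaluate on the
    held-out validation split by ROC.

    When ``panel`` is omitted, the discovery split first runs biomarker
    discovery + age exclusion and the retained candidates form the panel.
    """
    cohort, matrix, truth = generate_cohort(config)
    matrix = normalize_matrix_against_housekeeping(matrix, truth)
    groups = _contrast_groups(cohort, "is_differential_type")
    parts = split_discovery_validation(
        cohort,
        {"discovery": discovery_fraction, "validation": 1 - discovery_fraction},
        stratify_by="diagnosis",
        seed=split_seed,
    )
    disc_ids = list(parts.index[parts == "discovery"])
    val_ids = list(parts.index[parts == "validation"])
    disc = matrix.subset_samples(disc_ids)
    val = matrix.subset_samples(val_ids)
    if panel is None:
        rec = discover_biomarkers(disc, groups.loc[disc_ids])
        sig = list(rec.index[rec["significant"]])
        age = cohort.data.loc[disc_ids, "age"].astype(float)
        _, retained, _ = exclude_covariate_associated(disc, sig, age)
        if len(retained) < 2:
            raise RuntimeError("too few retained candidates to form a panel")
        panel = PanelDefinition(retained)
    model = train_panel(disc, panel, groups.loc[disc_ids])
    scores = score_matrix(model, val)
    roc = roc_curve(scores.to_numpy(), groups.loc[val_ids].to_numpy())
    lo, hi = auc_confidence_interval(roc)
    return {
        "auc": roc.auc,
        "ci_low": lo,
        "ci_high": hi,
        "n_discovery": len(disc_ids),
        "n_validation": len(val_ids),
        "panel_size": len(panel),
        "scores": scores,
        "roc": roc,
    }
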