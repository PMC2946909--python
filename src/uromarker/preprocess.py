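"""Per-sample signal processing: noise filtering, charge deconvolution,
migration-time calibration, housekeeping normalization and QC gating.

A raw *signal* is one (m/z, charge, intensity) observation in one spectrum;
signals are kept only when multiply charged (z >= 2), above a signal-to-noise
ratio of 4, and observed in at least 3 consecutive spectra at matching m/z.
Surviving signals are deconvoluted to neutral monoisotopic masses
(M = z * (m/z - 1.00728)) and conjugate charge states of the same compound
are merged. Migration times are then mapped onto a canonical time axis by
tricube-weighted local regression against calibrant peptides, amplitudes are
rescaled against low-variance housekeeping peptides to cancel urine dilution,
and the sample passes QC only if enough peptides were seen over a wide enough
migration window with a small enough calibration residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import PROTON_MASS

__all__ = [
    "CalibrationError",
    "NormalizationError",
    "ReferenceSet",
    "QCReport",
    "filter_signals",
    "deconvolute_charges",
    "calibrate_migration_time",
    "normalize_amplitudes",
    "qc_sample",
    "loess_fit",
]

SIGNAL_COLS = ["mz", "z", "intensity", "spectrum_index", "noise_level"]
PEAK_COLS = ["mass_da", "cetime_min", "amplitude"]


class CalibrationError(RuntimeError):
    """Migration-time calibration could not be anchored (too few calibrants)."""


class NormalizationError(RuntimeError):
    """No housekeeping peptide found in the sample."""


@dataclass
class ReferenceSet:
    """Calibrant and housekeeping reference peptides.

    ``calibrants``: DataFrame with ``mass_da`` and canonical ``cetime_min``.
    ``housekeeping``: DataFrame with ``mass_da``, ``cetime_min`` and canonical
    ``amplitude``.
    """

    calibrants: pd.DataFrame
    housekeeping: pd.DataFrame

    def validate(self, min_calibrants: int = 5) -> None:
        if len(self.calibrants) < min_calibrants:
            raise CalibrationError(
                f"need >= {min_calibrants} calibrants, have {len(self.calibrants)}"
            )
        if len(self.housekeeping) < 1:
            raise NormalizationError("need >= 1 housekeeping peptide")


@dataclass
class QCReport:
    n_peptides_detected: int
    migration_span: float
    mean_time_residual: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def filter_signals(
    signals: pd.DataFrame,
    min_consecutive: int = 3,
    min_snr: float = 4.0,
    min_z: int = 2,
    trace_tol_ppm: float = 20.0,
) -> pd.DataFrame:
    """Noise-filter raw signals.

    Keeps signals with charge >= ``min_z`` and S/N >= ``min_snr`` that belong
    to a trace of >= ``min_consecutive`` consecutive spectrum indices at
    matching m/z (within ``trace_tol_ppm``) and equal charge.
    """
    if not len(signals):
        return signals.copy()
    df = signals.copy()
    snr = df["intensity"] / df["noise_level"]
    df = df[(df["z"] >= min_z) & (snr >= min_snr)]
    if not len(df):
        return df
    keep = np.zeros(len(df), dtype=bool)
    df = df.sort_values(["z", "mz", "spectrum_index"], kind="mergesort")
    mz = df["mz"].to_numpy()
    z = df["z"].to_numpy()
    # group rows into m/z traces per charge: break where charge changes or
    # consecutive sorted m/z differ by more than the trace tolerance
    new_trace = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        dmz = np.diff(mz)
        same = (np.diff(z) == 0) & (dmz <= mz[:-1] * trace_tol_ppm * 1e-6)
        new_trace[1:] = ~same
    trace_id = np.cumsum(new_trace)
    idx = df["spectrum_index"].to_numpy()
    for _, rows in pd.Series(np.arange(len(df))).groupby(trace_id):
        pos = rows.to_numpy()
        order = np.argsort(idx[pos], kind="mergesort")
        pos = pos[order]
        spec = idx[pos]
        # runs of consecutive spectrum indices (duplicates stay in the run)
        run_start = 0
        for i in range(1, len(spec) + 1):
            if i == len(spec) or spec[i] - spec[i - 1] > 1:
                run = pos[run_start:i]
                n_distinct = len(np.unique(spec[run_start:i]))
                if n_distinct >= min_consecutive:
                    keep[run] = True
                run_start = i
    return df.iloc[keep].sort_index()


def deconvolute_charges(
    signals: pd.DataFrame,
    mono_tol_ppm: float = 25.0,
    unresolved_tol_ppm: float = 100.0,
    max_resolved_z: int = 6,
    time_tol_min: float = 0.5,
    spectra_per_min: float = 20.0,
) -> pd.DataFrame:
    """Collapse charge states into neutral monoisotopic peaks.

    Neutral mass M = z * (m/z - 1.00728). Signals agreeing in M within
    ``mono_tol_ppm`` (z <= ``max_resolved_z``; ``unresolved_tol_ppm`` above)
    and in migration time within ``time_tol_min`` merge into one peak whose
    amplitude is the sum of merged intensities and whose mass and time are
    intensity-weighted means.
    """
    if not len(signals):
        return pd.DataFrame(columns=PEAK_COLS)
    mass = signals["z"].to_numpy() * (signals["mz"].to_numpy() - PROTON_MASS)
    cetime = signals["spectrum_index"].to_numpy() / spectra_per_min
    inten = signals["intensity"].to_numpy(float)
    tol_ppm = np.where(
        signals["z"].to_numpy() <= max_resolved_z, mono_tol_ppm, unresolved_tol_ppm
    )
    order = np.argsort(mass, kind="mergesort")
    mass, cetime, inten, tol_ppm = mass[order], cetime[order], inten[order], tol_ppm[order]

    out_mass: list[float] = []
    out_time: list[float] = []
    out_amp: list[float] = []
    # sweep in mass order, merging into the running consensus of open clusters
    open_clusters: list[dict] = []
    for i in range(len(mass)):
        m, t, a, tol = mass[i], cetime[i], inten[i], tol_ppm[i]
        still_open = []
        for c in open_clusters:
            if m - c["mass"] > c["mass"] * unresolved_tol_ppm * 1e-6:
                out_mass.append(c["mass"])
                out_time.append(c["time"])
                out_amp.append(c["amp"])
            else:
                still_open.append(c)
        open_clusters = still_open
        best = None
        best_d = np.inf
        for c in open_clusters:
            tol_da = c["mass"] * min(tol, c["tol"]) * 1e-6
            if abs(m - c["mass"]) <= tol_da and abs(t - c["time"]) <= time_tol_min:
                d = (abs(m - c["mass"]) / tol_da) ** 2 + (
                    (t - c["time"]) / time_tol_min
                ) ** 2
                if d < best_d:
                    best, best_d = c, d
        if best is None:
            open_clusters.append({"mass": m, "time": t, "amp": a, "tol": tol})
        else:
            w = best["amp"] + a
            best["mass"] = (best["mass"] * best["amp"] + m * a) / w
            best["time"] = (best["time"] * best["amp"] + t * a) / w
            best["amp"] = w
            best["tol"] = min(best["tol"], tol)
    for c in open_clusters:
        out_mass.append(c["mass"])
        out_time.append(c["time"])
        out_amp.append(c["amp"])
    peaks = pd.DataFrame(
        {"mass_da": out_mass, "cetime_min": out_time, "amplitude": out_amp}
    )
    return peaks.sort_values("mass_da", ignore_index=True)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    xnew: np.ndarray,
    frac: float = 0.3,
    iters: int = 2,
) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated at ``xnew``.

    ``frac`` is the neighborhood span as a fraction of the anchor points
    (at least 2 points per local fit); ``iters`` bisquare robustness
    iterations downweight outlying anchors. Exactly reproduces any globally
    affine relation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xnew = np.atleast_1d(np.asarray(xnew, float))
    n = len(x)
    if n == 0:
        raise ValueError("no anchor points")
    if n == 1:
        return np.full(len(xnew), y[0])
    k = max(2, int(np.ceil(frac * n)))
    robust = np.ones(n)

    def predict(at: np.ndarray) -> np.ndarray:
        out = np.empty(len(at))
        for j, x0 in enumerate(at):
            d = np.abs(x - x0)
            h = np.sort(d)[min(k, n) - 1]
            if h == 0:
                h = max(d.max(), 1.0) * 1e-12 if d.max() > 0 else 1.0
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3 * robust
            if w.sum() == 0:
                w = robust.copy()
            sw = w.sum()
            xm = (w * x).sum() / sw
            ym = (w * y).sum() / sw
            sxx = (w * (x - xm) ** 2).sum()
            slope = 0.0 if sxx == 0 else (w * (x - xm) * (y - ym)).sum() / sxx
            out[j] = ym + slope * (x0 - xm)
        return out

    scale_floor = 1e-9 * (np.abs(y).max() + 1.0)
    for _ in range(max(0, iters)):
        resid = y - predict(x)
        s = np.median(np.abs(resid))
        if s <= scale_floor:  # numerically perfect fit; bisquare would misfire
            break
        robust = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return predict(xnew)


def _match_refs(
    peaks: pd.DataFrame, refs: pd.DataFrame, match_tol_ppm: float
) -> pd.DataFrame:
    """Match reference peptides to sample peaks by mass (nearest-time
    tie-break). Returns one row per matched reference."""
    rows = []
    pmass = peaks["mass_da"].to_numpy()
    ptime = peaks["cetime_min"].to_numpy()
    for _, ref in refs.iterrows():
        tol = ref["mass_da"] * match_tol_ppm * 1e-6
        cand = np.flatnonzero(np.abs(pmass - ref["mass_da"]) <= tol)
        if not len(cand):
            continue
        best = cand[np.argmin(np.abs(ptime[cand] - ref["cetime_min"]))]
        row = {"peak_index": int(best), "observed_time": ptime[best],
               "observed_amplitude": float(peaks["amplitude"].iloc[best])}
        for c in refs.columns:
            row[f"ref_{c}"] = ref[c]
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_migration_time(
    peaks: pd.DataFrame,
    refs: ReferenceSet,
    match_tol_ppm: float = 50.0,
    bandwidth: float = 0.3,
    min_calibrants: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Map observed migration times onto the canonical axis.

    Calibrants are located by mass; a tricube local regression of canonical
    on observed time is fitted and applied to every peak. Returns the
    calibrated peaks and the mean absolute residual over calibrants (the QC
    quantity that must stay below 0.35 min). Raises
    :class:`CalibrationError` when fewer than ``min_calibrants`` match.
    """
    matched = _match_refs(peaks, refs.calibrants, match_tol_ppm)
    if len(matched) < min_calibrants:
        raise CalibrationError(
            f"only {len(matched)} calibrant(s) matched; need {min_calibrants}"
        )
    obs = matched["observed_time"].to_numpy()
    canon = matched["ref_cetime_min"].to_numpy()
    new_times = loess_fit(obs, canon, peaks["cetime_min"].to_numpy(), frac=bandwidth)
    fitted_at_cal = loess_fit(obs, canon, obs, frac=bandwidth)
    mean_residual = float(np.mean(np.abs(fitted_at_cal - canon)))
    out = peaks.copy()
    out["cetime_min"] = new_times
    return out, mean_residual


def normalize_amplitudes(
    peaks: pd.DataFrame,
    refs: ReferenceSet,
    mode: str = "global_median_ratio",
    match_tol_ppm: float = 50.0,
    bandwidth: float = 0.3,
) -> pd.DataFrame:
    """Rescale amplitudes against housekeeping peptides.

    ``global_median_ratio``: every amplitude is multiplied by the median of
    canonical/observed over matched housekeeping peptides (cancels a
    per-sample dilution factor exactly). ``lowess``: the log10 ratio is
    smoothed against migration time by local regression and applied
    pointwise; with fewer than 3 matches this degrades to the global mode.
    """
    if mode not in ("global_median_ratio", "lowess"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    matched = _match_refs(peaks, refs.housekeeping, match_tol_ppm)
    if not len(matched):
        raise NormalizationError("no housekeeping peptide detected in sample")
    obs_amp = matched["observed_amplitude"].to_numpy(float)
    canon_amp = matched["ref_amplitude"].to_numpy(float)
    out = peaks.copy()
    if mode == "global_median_ratio" or len(matched) < 3:
        s = float(np.median(canon_amp / obs_amp))
        out["amplitude"] = out["amplitude"] * s
        return out
    log_ratio = np.log10(canon_amp / obs_amp)
    t_hk = matched["observed_time"].to_numpy(float)
    correction = loess_fit(
        t_hk, log_ratio, peaks["cetime_min"].to_numpy(), frac=bandwidth
    )
    out["amplitude"] = out["amplitude"] * 10.0 ** correction
    return out


def qc_sample(
    peaks: pd.DataFrame,
    mean_residual: float,
    min_peptides: int = 950,
    min_span: float = 10.0,
    max_residual: float = 0.35,
) -> QCReport:
    """Sample-level QC gate.

    Passes only if >= ``min_peptides`` peaks were detected over a migration
    window of >= ``min_span`` minutes with a mean calibration residual
    strictly below ``max_residual`` minutes.
    """
    n = len(peaks)
    span = float(peaks["cetime_min"].max() - peaks["cetime_min"].min()) if n else 0.0
    reasons = []
    if n < min_peptides:
        reasons.append(f"peptide count {n} < {min_peptides}")
    if span < min_span:
        reasons.append(f"migration span {span:.2f} min < {min_span}")
    if not (mean_residual < max_residual):
        reasons.append(
            f"mean time residual {mean_residual:.3f} min not < {max_residual}"
        )
    return QCReport(
        n_peptides_detected=n,
        migration_span=span,
        mean_time_residual=float(mean_residual),
        passed=not reasons,
        reasons=reasons,
    )
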