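"""Synthetic CE-MS cohort generator.

Emulates the statistical structure the downstream analysis assumes: three
diagnostic groups (control / T1D / T2D) with Table-2-like covariate contrasts
(T1D younger with longer diabetes duration), log10-normal peptide amplitudes
with per-peptide detection frequencies, designated truly differential peptides
with stated effect sizes and signs, age-correlated peptides, low-variance
housekeeping peptides, calibrant peptides with known migration times,
per-sample urine-dilution factors, and ppm-scale mass / minute-scale
migration-time measurement noise.

Everything is driven by a single integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import CohortTable, PeptideMatrix

__all__ = [
    "ConfigError",
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_peaklists",
    "generate_raw_signals",
    "PROTON_MASS",
]

#: Mass of a proton in Da, used for charge-state arithmetic.
PROTON_MASS = 1.00728


class ConfigError(ValueError):
    """Impossible simulation configuration."""


@dataclass
class SimConfig:
    """Simulation parameters.

    Group sizes default to the normoalbuminuric discovery design (68 T1D vs
    42 T2D, no controls); effect sizes are log10 mean shifts. Peptide roles
    (DM-differential, type-differential, age-correlated, housekeeping,
    calibrant) are disjoint.
    """

    n_control: int = 0
    n_t1d: int = 68
    n_t2d: int = 42
    n_peptides: int = 1500
    n_differential_dm: int = 0
    n_differential_type: int = 100
    effect_size_dm: float = 0.5
    effect_size_type: float = 0.5
    frac_down: float = 0.5
    n_age_correlated: int = 91
    age_slope: float = 0.02
    n_housekeeping: int = 29
    housekeeping_cv: float = 0.05
    n_calibrants: int = 10
    detection_freq_range: tuple[float, float] = (0.5, 1.0)
    dilution_sd: float = 0.3
    mass_noise_ppm: float = 10.0
    time_noise_min: float = 0.1
    mass_range: tuple[float, float] = (800.0, 20000.0)
    time_range: tuple[float, float] = (19.0, 45.0)
    amplitude_sd_log10: float = 0.4
    baseline_range_log10: tuple[float, float] = (2.0, 5.0)
    # Table-2-like covariate means/SDs (age years, DM duration years)
    age_control: tuple[float, float] = (40.0, 10.0)
    age_t1d: tuple[float, float] = (43.0, 11.0)
    age_t2d: tuple[float, float] = (63.0, 9.0)
    duration_t1d: tuple[float, float] = (27.0, 10.0)
    duration_t2d: tuple[float, float] = (11.0, 8.0)
    time_offset_sd: float = 0.5
    spectra_per_min: int = 20
    n_noise_signals: int = 200
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_control": self.n_control,
            "n_t1d": self.n_t1d,
            "n_t2d": self.n_t2d,
            "n_peptides": self.n_peptides,
            "n_differential_dm": self.n_differential_dm,
            "n_differential_type": self.n_differential_type,
            "n_age_correlated": self.n_age_correlated,
            "n_housekeeping": self.n_housekeeping,
            "n_calibrants": self.n_calibrants,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        special = (
            self.n_differential_dm
            + self.n_differential_type
            + self.n_age_correlated
            + self.n_housekeeping
            + self.n_calibrants
        )
        if special > self.n_peptides:
            raise ConfigError(
                f"role counts sum to {special} > n_peptides={self.n_peptides}"
            )
        lo, hi = self.detection_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("detection_freq_range must be ordered within [0, 1]")
        for rng_name in ("mass_range", "time_range", "baseline_range_log10"):
            lo, hi = getattr(self, rng_name)
            if not lo < hi:
                raise ConfigError(f"{rng_name} must be ordered")
        if not 0 <= self.frac_down <= 1:
            raise ConfigError("frac_down must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Per-peptide role flags / true effects and per-sample nuisance factors.

    ``peptides`` is indexed by peptide_id with boolean columns
    ``is_differential_dm``, ``is_differential_type``, ``is_age_correlated``,
    ``is_housekeeping``, ``is_calibrant``, numeric ``effect_dm`` /
    ``effect_type`` (signed log10 shifts), ``detection_freq`` and
    ``baseline_log10``. ``samples`` is indexed by sample_id with
    ``dilution_log10`` and ``time_offset_min``.
    """

    peptides: pd.DataFrame
    samples: pd.DataFrame


def _draw_clipped_normal(rng, mean, sd, n, low=0.0):
    x = rng.normal(mean, sd, n)
    return np.clip(x, low, None)


def generate_cohort(config: SimConfig) -> tuple[CohortTable, PeptideMatrix, GroundTruth]:
    """Generate (metadata, ground-truth peptide matrix, ground truth).

    The matrix holds each peptide's true consensus mass/time and, per sample,
    the dilution-scaled linear amplitude (0 where detection thinning removed
    it). Housekeeping and calibrant peptides are detected in every sample;
    housekeeping amplitudes have relative SD ``housekeeping_cv`` before
    dilution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_c, n_1, n_2 = config.n_control, config.n_t1d, config.n_t2d
    n_samples = n_c + n_1 + n_2
    if n_samples == 0:
        raise ConfigError("no samples requested")
    P = config.n_peptides

    # --- subjects -------------------------------------------------------
    diagnosis = np.array(["control"] * n_c + ["t1d"] * n_1 + ["t2d"] * n_2)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    age = np.concatenate(
        [
            _draw_clipped_normal(rng, *config.age_control, n_c, low=18.0),
            _draw_clipped_normal(rng, *config.age_t1d, n_1, low=18.0),
            _draw_clipped_normal(rng, *config.age_t2d, n_2, low=18.0),
        ]
    )
    duration = np.concatenate(
        [
            np.zeros(n_c),
            _draw_clipped_normal(rng, *config.duration_t1d, n_1),
            _draw_clipped_normal(rng, *config.duration_t2d, n_2),
        ]
    )
    duration = np.minimum(duration, np.maximum(age - 10.0, 0.0))
    sex = rng.choice(["m", "f"], n_samples)
    weight = _draw_clipped_normal(rng, 78, 14, n_samples, low=40)
    creatinine = _draw_clipped_normal(rng, 0.95, 0.2, n_samples, low=0.4)
    # normoalbuminuric cohorts: ACR around the Table-2 discovery values
    acr = np.exp(rng.normal(np.log(9), 0.5, n_samples))
    urinary_albumin = acr * 0.9
    gfr = (140 - age) * weight / (72 * creatinine)
    gfr = np.where(sex == "f", gfr * 0.85, gfr)
    sbp = _draw_clipped_normal(rng, 130, 16, n_samples, low=80)
    dbp = _draw_clipped_normal(rng, 75, 10, n_samples, low=40)
    bmi = np.where(
        diagnosis == "t2d",
        _draw_clipped_normal(rng, 30, 5, n_samples, low=16),
        _draw_clipped_normal(rng, 27, 5, n_samples, low=16),
    )
    meta = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "cohort_role": "discovery",
            "age": age,
            "dm_duration": duration,
            "sex": sex,
            "weight": weight,
            "serum_creatinine": creatinine,
            "urinary_albumin": urinary_albumin,
            "acr": acr,
            "gfr": gfr,
            "sbp": sbp,
            "dbp": dbp,
            "bmi": bmi,
            "smoking": rng.choice(["yes", "no"], n_samples, p=[0.2, 0.8]),
            "tc": _draw_clipped_normal(rng, 4.7, 1.0, n_samples, low=2),
            "hdl": _draw_clipped_normal(rng, 1.4, 0.5, n_samples, low=0.5),
            "ldl": _draw_clipped_normal(rng, 2.5, 0.8, n_samples, low=0.5),
            "tg": _draw_clipped_normal(rng, 1.5, 1.0, n_samples, low=0.3),
            "med_insulin": np.where(diagnosis == "t1d", "yes", "no"),
            "med_oral_hypoglycemics": np.where(
                (diagnosis == "t2d") & (rng.random(n_samples) < 0.6), "yes", "no"
            ),
        },
        index=pd.Index(sample_ids, name="subject_id"),
    )

    # --- peptide roles --------------------------------------------------
    pep_ids = [f"{100000 + i}" for i in range(P)]
    roles = pd.DataFrame(
        False,
        index=pd.Index(pep_ids, name="peptide_id"),
        columns=[
            "is_differential_dm",
            "is_differential_type",
            "is_age_correlated",
            "is_housekeeping",
            "is_calibrant",
        ],
    )
    order = rng.permutation(P)
    cursor = 0

    def take(n):
        nonlocal cursor
        idx = order[cursor : cursor + n]
        cursor += n
        return idx

    i_dm = take(config.n_differential_dm)
    i_type = take(config.n_differential_type)
    i_age = take(config.n_age_correlated)
    i_hk = take(config.n_housekeeping)
    i_cal = take(config.n_calibrants)
    roles.iloc[i_dm, 0] = True
    roles.iloc[i_type, 1] = True
    roles.iloc[i_age, 2] = True
    roles.iloc[i_hk, 3] = True
    roles.iloc[i_cal, 4] = True

    mass = np.exp(rng.uniform(*np.log(config.mass_range), P))
    cetime = rng.uniform(*config.time_range, P)
    baseline = rng.uniform(*config.baseline_range_log10, P)

    signs = np.where(rng.random(P) < config.frac_down, -1.0, 1.0)
    effect_dm = np.zeros(P)
    effect_dm[i_dm] = signs[i_dm] * config.effect_size_dm
    effect_type = np.zeros(P)
    effect_type[i_type] = signs[i_type] * config.effect_size_type

    det_freq = rng.uniform(*config.detection_freq_range, P)
    det_freq[i_hk] = 1.0
    det_freq[i_cal] = 1.0

    # --- amplitudes (log10 scale) --------------------------------------
    is_dm_sample = (diagnosis != "control").astype(float)  # (S,)
    is_t2d_sample = (diagnosis == "t2d").astype(float)
    mean_log = (
        baseline[:, None]
        + effect_dm[:, None] * is_dm_sample[None, :]
        + effect_type[:, None] * is_t2d_sample[None, :]
    )
    age_centered = age - age.mean()
    age_flag = roles["is_age_correlated"].to_numpy()
    mean_log[age_flag] += config.age_slope * age_centered[None, :]

    sd = np.full(P, config.amplitude_sd_log10)
    sd[i_hk] = config.housekeeping_cv / np.log(10)  # linear CV -> log10 SD
    log_amp = mean_log + rng.normal(0.0, 1.0, (P, n_samples)) * sd[:, None]

    dilution = rng.normal(0.0, config.dilution_sd, n_samples)
    log_amp += dilution[None, :]

    detected = rng.random((P, n_samples)) < det_freq[:, None]
    amplitudes = np.where(detected, 10.0 ** log_amp, 0.0)

    time_offset = rng.normal(0.0, config.time_offset_sd, n_samples)

    peptides = pd.DataFrame(
        {"mass_da": mass, "cetime_min": cetime},
        index=pd.Index(pep_ids, name="peptide_id"),
    )
    amp_df = pd.DataFrame(amplitudes, index=peptides.index, columns=sample_ids)
    matrix = PeptideMatrix(peptides, amp_df)

    truth_pep = roles.copy()
    truth_pep["effect_dm"] = effect_dm
    truth_pep["effect_type"] = effect_type
    truth_pep["detection_freq"] = det_freq
    truth_pep["baseline_log10"] = baseline
    truth_samples = pd.DataFrame(
        {"dilution_log10": dilution, "time_offset_min": time_offset},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CohortTable(meta), matrix, GroundTruth(truth_pep, truth_samples)


def generate_peaklists(
    matrix: PeptideMatrix,
    truth: GroundTruth,
    config: SimConfig,
    apply_time_offset: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-sample peak lists with measurement noise.

    Each detected matrix cell becomes one peak whose mass carries Gaussian
    ppm jitter (``mass_noise_ppm``) and whose migration time carries Gaussian
    minute jitter (``time_noise_min``) plus, optionally, the sample's constant
    migration-time offset from the ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mass = matrix.peptides["mass_da"].to_numpy()
    cetime = matrix.peptides["cetime_min"].to_numpy()
    out: dict[str, pd.DataFrame] = {}
    for s in matrix.sample_ids:
        amp = matrix.amplitudes[s].to_numpy()
        det = amp > 0
        n = int(det.sum())
        m = mass[det] * (1.0 + rng.normal(0.0, config.mass_noise_ppm * 1e-6, n))
        t = cetime[det] + rng.normal(0.0, config.time_noise_min, n)
        if apply_time_offset:
            t = t + truth.samples.loc[s, "time_offset_min"]
        out[s] = pd.DataFrame(
            {
                "mass_da": m,
                "cetime_min": t,
                "amplitude": amp[det],
                "true_peptide_id": matrix.peptides.index.to_numpy()[det],
            }
        )
    return out


def generate_raw_signals(
    matrix: PeptideMatrix,
    truth: GroundTruth,
    config: SimConfig,
    samples: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample raw signal tables for the preprocessing stage.

    Each detected peptide is emitted as 1-3 charge states z in {2..6} at
    m/z = (mass + z * 1.00728) / z, each charge-state trace replicated over 3
    consecutive spectrum indices with the charge's amplitude share split
    across them (total intensity equals the matrix amplitude). Injected noise
    comprises sub-threshold signals (S/N < 4) and singly charged (z = 1)
    contaminants. Spectrum indices encode migration time at
    ``spectra_per_min`` spectra per minute, shifted by the sample's constant
    migration-time offset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mass = matrix.peptides["mass_da"].to_numpy()
    cetime = matrix.peptides["cetime_min"].to_numpy()
    rate = config.spectra_per_min
    out: dict[str, pd.DataFrame] = {}
    sample_ids = samples if samples is not None else matrix.sample_ids
    for s in sample_ids:
        amp = matrix.amplitudes[s].to_numpy()
        det = np.flatnonzero(amp > 0)
        offset = float(truth.samples.loc[s, "time_offset_min"])
        rows_mz, rows_z, rows_int, rows_idx = [], [], [], []
        for p in det:
            m_obs = mass[p] * (1.0 + rng.normal(0.0, config.mass_noise_ppm * 1e-6))
            t_obs = cetime[p] + offset + rng.normal(0.0, config.time_noise_min)
            base_idx = int(round(t_obs * rate))
            n_z = rng.integers(1, 4)
            zs = rng.choice(np.arange(2, 7), size=n_z, replace=False)
            # concentrated Dirichlet: charge-state envelopes are peaked, no
            # vanishing shares that would fall under the S/N threshold
            shares = rng.dirichlet(np.full(n_z, 5.0)) * amp[p]
            for z, share in zip(zs, shares):
                mz = (m_obs + z * PROTON_MASS) / z
                for k, frac in enumerate((0.25, 0.5, 0.25)):  # triangular trace
                    rows_mz.append(mz)
                    rows_z.append(int(z))
                    rows_int.append(share * frac)
                    rows_idx.append(base_idx + k)
        # injected noise: low S/N and z=1 contaminants, half of each
        n_noise = config.n_noise_signals
        for _ in range(n_noise // 2):
            rows_mz.append(rng.uniform(300, 2000))
            rows_z.append(int(rng.integers(2, 7)))
            rows_int.append(rng.uniform(0.1, 3.9))  # S/N < 4 at noise_level 1
            rows_idx.append(int(rng.integers(int(19 * rate), int(45 * rate))))
        for _ in range(n_noise - n_noise // 2):
            rows_mz.append(rng.uniform(300, 2000))
            rows_z.append(1)
            rows_int.append(rng.uniform(5, 500))
            rows_idx.append(int(rng.integers(int(19 * rate), int(45 * rate))))
        out[s] = pd.DataFrame(
            {
                "mz": rows_mz,
                "z": rows_z,
                "intensity": rows_int,
                "spectrum_index": rows_idx,
                "noise_level": 1.0,
            }
        )
    return out


def reference_set_from_truth(matrix: PeptideMatrix, truth: GroundTruth):
    """Build the calibrant/housekeeping reference set the preprocessing stage
    consumes, from the generator's ground truth (synthetic analogue of the
    curated urinary reference peptide database)."""
    from .preprocess import ReferenceSet  # local import to avoid a cycle

    cal = truth.peptides["is_calibrant"]
    hk = truth.peptides["is_housekeeping"]
    calibrants = matrix.peptides.loc[cal[cal].index, ["mass_da", "cetime_min"]].copy()
    housekeeping = matrix.peptides.loc[hk[hk].index, ["mass_da", "cetime_min"]].copy()
    # canonical amplitude: undiluted expected linear amplitude
    housekeeping["amplitude"] = 10.0 ** truth.peptides.loc[hk[hk].index, "baseline_log10"]
    return ReferenceSet(calibrants=calibrants, housekeeping=housekeeping)
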