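"""Cross-sample peptide clustering and the deposit-frequency filter.

Peaks from different samples are considered the same peptide when their
neutral masses agree within 50 ppm (small peptides) or 75 ppm (larger
peptides) and their migration times agree within a relative window that
widens linearly from 2% of the migration time at 19 min to 5% at 45 min
(capillary-electrophoresis peaks broaden with migration time through analyte
diffusion). Clustering sweeps the pooled, mass-sorted peaks once, comparing
each peak against the amplitude-weighted running consensus of open clusters;
a sample may contribute at most one peak per cluster (largest amplitude
wins). Peptides detected in too small a fraction of samples are then dropped
(strict > threshold) to keep individual-specific artifacts out of the
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PeptideMatrix

__all__ = [
    "MatchWindow",
    "match_window",
    "cluster_peaks",
    "apply_frequency_filter",
    "ClusterStats",
]


@dataclass
class MatchWindow:
    """Mass/time tolerance model for cross-sample matching.

    ``small_mass_cutoff`` splits the 50 ppm vs 75 ppm regimes; the relative
    time half-width interpolates linearly between ``time_width_lo`` at
    ``time_lo`` min and ``time_width_hi`` at ``time_hi`` min, clamped outside.
    """

    mass_tol_small_ppm: float = 50.0
    mass_tol_large_ppm: float = 75.0
    small_mass_cutoff: float = 4000.0
    time_lo: float = 19.0
    time_hi: float = 45.0
    time_width_lo: float = 0.02
    time_width_hi: float = 0.05

    def mass_tol_ppm(self, mass: float) -> float:
        return (
            self.mass_tol_small_ppm
            if mass <= self.small_mass_cutoff
            else self.mass_tol_large_ppm
        )

    def time_halfwidth_frac(self, cetime: float) -> float:
        t = np.clip(cetime, self.time_lo, self.time_hi)
        frac = self.time_width_lo + (self.time_width_hi - self.time_width_lo) * (
            t - self.time_lo
        ) / (self.time_hi - self.time_lo)
        return float(frac)


def match_window(mass: float, cetime: float, params: MatchWindow | None = None):
    """Absolute (mass_tol_da, time_tol_min) half-windows at a given position."""
    params = params or MatchWindow()
    if mass <= 0 or cetime <= 0:
        raise ValueError("mass and cetime must be positive")
    mass_tol_da = mass * params.mass_tol_ppm(mass) * 1e-6
    time_tol_min = cetime * params.time_halfwidth_frac(cetime)
    return mass_tol_da, time_tol_min


@dataclass
class ClusterStats:
    n_input_peaks: int
    n_assigned: int
    n_dropped_duplicates: int
    n_clusters: int


def cluster_peaks(
    peaklists: dict[str, pd.DataFrame],
    params: MatchWindow | None = None,
) -> tuple[PeptideMatrix, ClusterStats]:
    """Cluster calibrated per-sample peak lists into a peptide matrix.

    Deterministic and invariant to the ordering of ``peaklists``: all peaks
    are pooled, sorted by (mass, time, -amplitude, sample), and swept once.
    A peak joins the nearest open cluster (normalized mass/time Euclidean
    distance) whose consensus window contains it, else founds a new cluster.
    Cluster consensus mass/time is the amplitude-weighted mean of members.
    If a sample contributes several peaks to one cluster only the largest
    amplitude is kept; drops are counted in the returned stats.
    """
    params = params or MatchWindow()
    frames = []
    for sid in peaklists:
        df = peaklists[sid]
        if not len(df):
            continue
        frames.append(
            pd.DataFrame(
                {
                    "mass_da": df["mass_da"].to_numpy(float),
                    "cetime_min": df["cetime_min"].to_numpy(float),
                    "amplitude": df["amplitude"].to_numpy(float),
                    "sample_id": str(sid),
                }
            )
        )
    sample_ids = sorted(str(s) for s in peaklists)
    if not frames:
        empty = pd.DataFrame(columns=["mass_da", "cetime_min"]).rename_axis("peptide_id")
        amps = pd.DataFrame(columns=sample_ids).rename_axis("peptide_id")
        return PeptideMatrix(empty, amps), ClusterStats(0, 0, 0, 0)
    pool = pd.concat(frames, ignore_index=True)
    pool = pool.sort_values(
        ["mass_da", "cetime_min", "amplitude", "sample_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
        ignore_index=True,
    )
    mass = pool["mass_da"].to_numpy()
    time = pool["cetime_min"].to_numpy()
    amp = pool["amplitude"].to_numpy()
    max_rel = params.mass_tol_large_ppm * 1e-6

    clusters: list[dict] = []  # closed
    open_clusters: list[dict] = []
    for i in range(len(pool)):
        m, t, a = mass[i], time[i], amp[i]
        still = []
        for c in open_clusters:
            if m - c["mass"] > c["mass"] * max_rel:
                clusters.append(c)
            else:
                still.append(c)
        open_clusters = still
        best, best_d = None, np.inf
        for c in open_clusters:
            mtol, ttol = match_window(c["mass"], c["time"], params)
            dm, dt = abs(m - c["mass"]), abs(t - c["time"])
            if dm <= mtol and dt <= ttol:
                d = (dm / mtol) ** 2 + (dt / ttol) ** 2
                if d < best_d:
                    best, best_d = c, d
        if best is None:
            open_clusters.append({"mass": m, "time": t, "amp": a, "members": [i]})
        else:
            w = best["amp"] + a
            best["mass"] = (best["mass"] * best["amp"] + m * a) / w
            best["time"] = (best["time"] * best["amp"] + t * a) / w
            best["amp"] = w
            best["members"].append(i)
    clusters.extend(open_clusters)
    clusters.sort(key=lambda c: (c["mass"], c["time"]))

    sample_arr = pool["sample_id"].to_numpy()
    n_assigned = 0
    n_dropped = 0
    pep_ids, masses, times = [], [], []
    amp_matrix = np.zeros((len(clusters), len(sample_ids)))
    col_of = {s: j for j, s in enumerate(sample_ids)}
    for ci, c in enumerate(clusters):
        pep_ids.append(f"P{ci + 1:06d}")
        masses.append(c["mass"])
        times.append(c["time"])
        best_per_sample: dict[str, int] = {}
        for i in c["members"]:
            s = sample_arr[i]
            if s not in best_per_sample or amp[i] > amp[best_per_sample[s]]:
                if s in best_per_sample:
                    n_dropped += 1
                best_per_sample[s] = i
            else:
                n_dropped += 1
        for s, i in best_per_sample.items():
            amp_matrix[ci, col_of[s]] = amp[i]
            n_assigned += 1
    peptides = pd.DataFrame(
        {"mass_da": masses, "cetime_min": times},
        index=pd.Index(pep_ids, name="peptide_id"),
    )
    amps = pd.DataFrame(amp_matrix, index=peptides.index, columns=sample_ids)
    stats = ClusterStats(
        n_input_peaks=len(pool),
        n_assigned=n_assigned,
        n_dropped_duplicates=n_dropped,
        n_clusters=len(clusters),
    )
    return PeptideMatrix(peptides, amps), stats


def apply_frequency_filter(
    matrix: PeptideMatrix,
    min_frequency: float = 0.20,
    scope: str = "all_samples",
    groups: pd.Series | None = None,
) -> tuple[PeptideMatrix, int]:
    """Drop peptides not detected often enough (strictly > ``min_frequency``).

    ``scope="all_samples"`` gates on the overall detection frequency;
    ``scope="any_group"`` keeps a peptide if any group (per ``groups``,
    sample_id -> label) exceeds the threshold. Returns the filtered matrix
    and the number of peptides removed.
    """
    if scope not in ("all_samples", "any_group"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "any_group" and groups is None:
        raise ValueError("scope='any_group' requires group labels")
    freq = matrix.frequencies(groups if scope == "any_group" else None)
    keep = (freq > min_frequency).any(axis=1)
    kept = matrix.subset_peptides(freq.index[keep])
    return kept, int((~keep).sum())
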