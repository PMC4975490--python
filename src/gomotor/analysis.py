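"""Distributional observables from trajectories.

These are the quantities the powerstroke study is read through: fitted-
subset RMSD distributions (small subunit after fitting the big subunit,
converter after fitting the motor head), centre-of-geometry distances
between nucleotide-pocket motifs or subunits, kernel-density mode
estimates, and the pre/post basin populations of a bimodal RMSD
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .dynamics import Trajectory
from .structure import fitted_rmsd

#: default histogram bin widths, nm
RMSD_BIN_NM = 0.01
DISTANCE_BIN_NM = 0.05


@dataclass
class DistributionSummary:
    """Samples of a scalar observable with histogram, KDE modes and an
    optional two-basin population split."""

    samples: np.ndarray
    bin_width: float
    edges: np.ndarray = field(default=None)
    counts: np.ndarray = field(default=None)
    modes: np.ndarray = field(default=None)
    population_split: tuple | None = None   # (threshold, frac_below, frac_above)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empty sample set")
        if self.edges is None:
            lo = np.floor(self.samples.min() / self.bin_width) * self.bin_width
            hi = np.ceil(self.samples.max() / self.bin_width) * self.bin_width
            hi = max(hi, lo + self.bin_width)
            nbins = max(1, int(round((hi - lo) / self.bin_width)))
            self.counts, self.edges = np.histogram(self.samples,
                                                   bins=nbins, range=(lo, hi))

    def to_dict(self) -> dict:
        return {
            "n_samples": int(self.samples.size),
            "mean": float(self.samples.mean()),
            "bin_width": self.bin_width,
            "modes": None if self.modes is None else np.asarray(self.modes).tolist(),
            "population_split": self.population_split,
        }


def _per_frame_rmsd(traj: Trajectory, reference, fit_group, measure_group):
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    return np.array([fitted_rmsd(f, reference, fit_group, measure_group)
                     for f in traj.frames])


def rmsd_distribution(traj: Trajectory, reference, fit_group, measure_group,
                      bin_width: float = RMSD_BIN_NM) -> DistributionSummary:
    """P(RMSD) of ``measure_group`` after per-frame least-squares fitting of
    ``fit_group`` onto the reference."""
    samples = _per_frame_rmsd(traj, reference, fit_group, measure_group)
    summary = DistributionSummary(samples, bin_width)
    summary.modes = estimate_modes(summary, 1) if len(samples) >= 100 else None
    return summary


def motif_rmsd_distribution(traj: Trajectory, reference, fit_group, motif,
                            bin_width: float = RMSD_BIN_NM) -> DistributionSummary:
    """P(RMSD) of one nucleotide-pocket motif (P-loop / switch I / switch II)
    after fitting ``fit_group`` (conventionally the big subunit) onto the
    pre-powerstroke reference."""
    return rmsd_distribution(traj, reference, fit_group, motif, bin_width)


def group_distance_series(traj: Trajectory, groupA, groupB,
                          bin_width: float = DISTANCE_BIN_NM) -> DistributionSummary:
    """Per-frame distance between the centres of geometry of two bead groups."""
    groupA = np.asarray(groupA, dtype=int)
    groupB = np.asarray(groupB, dtype=int)
    if groupA.size == 0 or groupB.size == 0:
        raise ValueError("empty group")
    if np.intersect1d(groupA, groupB).size:
        raise ValueError("groups must be disjoint")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    ca = traj.frames[:, groupA - 1, :].mean(axis=1)
    cb = traj.frames[:, groupB - 1, :].mean(axis=1)
    samples = np.linalg.norm(ca - cb, axis=1)
    summary = DistributionSummary(samples, bin_width)
    summary.modes = estimate_modes(summary, 1) if len(samples) >= 100 else None
    return summary


def estimate_modes(summary: DistributionSummary, expected_modes: int = 1,
                   prominence_frac: float = 0.05, grid_size: int = 512) -> np.ndarray:
    """Peak positions of a Gaussian-KDE (Silverman bandwidth) density.

    For ``expected_modes == 2`` the two highest-prominence peaks are
    returned in ascending order (fewer if the density has fewer peaks).
    Requires at least 100 samples.
    """
    x = summary.samples
    if x.size < 100:
        raise ValueError("need >= 100 samples for mode estimation")
    if expected_modes not in (1, 2):
        raise ValueError("expected_modes must be 1 or 2")
    if np.ptp(x) < 1e-12:
        return np.array([float(x[0])] if expected_modes == 1 else [float(x[0])])
    kde = gaussian_kde(x, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])
        props = {"prominences": np.array([dens.max()])}
    if expected_modes == 1:
        best = peaks[np.argmax(dens[peaks])]
        return np.array([grid[best]])
    order = np.argsort(props["prominences"])[::-1][:2]
    chosen = np.sort(peaks[order])
    return grid[chosen]


def basin_populations(summary: DistributionSummary, threshold: float):
    """Fractions of samples below/above a threshold placed between the two
    modes of a bimodal distribution: (fraction_pre, fraction_post)."""
    x = summary.samples
    if not (x.min() <= threshold <= x.max()):
        raise ValueError(
            f"threshold {threshold:.4g} outside sample range "
            f"[{x.min():.4g}, {x.max():.4g}]")
    below = float((x < threshold).mean())
    summary.population_split = (float(threshold), below, 1.0 - below)
    return below, 1.0 - below


def plot_summary(summary: DistributionSummary, path, xlabel: str = "") -> None:
    """Optional quick-look plot (histogram + KDE + modes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    centres = 0.5 * (summary.edges[:-1] + summary.edges[1:])
    width = summary.edges[1] - summary.edges[0]
    ax.bar(centres, summary.counts / summary.counts.sum() / width,
           width=width, alpha=0.4)
    if np.ptp(summary.samples) > 1e-12:
        kde = gaussian_kde(summary.samples, bw_method="silverman")
        grid = np.linspace(summary.samples.min(), summary.samples.max(), 400)
        ax.plot(grid, kde(grid), lw=1.5)
    if summary.modes is not None:
        for m in np.atleast_1d(summary.modes):
            ax.axvline(m, color="k", ls="--", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("probability density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
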