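"""Intensity-dependent replicate-noise model.

Replicate SD is estimated per (probe set, time point), binned by mean
intensity, summarized by a bias-corrected median per bin, and constrained to
be monotone non-increasing in intensity by isotonic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .signal_qc import SampleSheet, SignalMatrix

SD_FLOOR = 1e-3


@dataclass
class NoiseModel:
    """Monotone non-increasing mapping from mean log2 intensity to SD.

    Evaluated by linear interpolation on the bin grid with flat
    extrapolation; SD is floored at ``SD_FLOOR``.
    """

    grid_intensity: np.ndarray
    grid_sd: np.ndarray

    def __post_init__(self) -> None:
        self.grid_intensity = np.asarray(self.grid_intensity, dtype=float)
        self.grid_sd = np.maximum(np.asarray(self.grid_sd, dtype=float), SD_FLOOR)
        if self.grid_intensity.ndim != 1 or self.grid_intensity.size == 0:
            raise ValueError("empty noise grid")
        if not np.all(np.diff(self.grid_intensity) > 0):
            raise ValueError("grid intensities must be strictly increasing")
        if np.any(np.diff(self.grid_sd) > 1e-9):
            raise ValueError("SD grid must be monotone non-increasing")

    def sd(self, intensity) -> np.ndarray:
        out = np.interp(np.asarray(intensity, dtype=float),
                        self.grid_intensity, self.grid_sd)
        return np.maximum(out, SD_FLOOR)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {"bin_center": self.grid_intensity, "sd": self.grid_sd}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "NoiseModel":
        df = pd.read_csv(path, sep="\t")
        return cls(df["bin_center"].to_numpy(), df["sd"].to_numpy())


def _median_sd_correction(n_replicates: int) -> float:
    """Median of the sample SD of n iid N(0, 1) draws.

    (n-1) s^2 ~ chi2(n-1), so median(s) = sqrt(median(chi2_{n-1})/(n-1));
    dividing binned medians by this recovers sigma under Gaussian noise.
    """
    df = n_replicates - 1
    return float(np.sqrt(stats.chi2.median(df) / df))


def fit_noise(
    matrix: SignalMatrix, samplesheet: SampleSheet, n_bins: int = 50
) -> NoiseModel:
    """Fit the intensity -> SD curve from replicate groups.

    For each (PS, time) the replicate mean and SD are computed; pairs are
    binned into equal-count intensity bins; the per-bin summary is the
    median SD, corrected for the finite-replicate bias of the median under
    Gaussian noise; a decreasing isotonic regression enforces monotonicity.
    """
    R = samplesheet.n_replicates
    if R < 2:
        raise ValueError("need >= 2 replicates per time point to estimate noise")
    means, sds = [], []
    for t in samplesheet.times:
        sub = matrix.values[samplesheet.samples_at(t)]
        means.append(sub.mean(axis=1).to_numpy())
        sds.append(sub.std(axis=1, ddof=1).to_numpy())
    mean_arr = np.concatenate(means)
    sd_arr = np.concatenate(sds)

    edges = np.quantile(mean_arr, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        # Degenerate intensity distribution: single flat bin.
        center = np.array([float(np.median(mean_arr))])
        sd = np.array([float(np.median(sd_arr)) / _median_sd_correction(R)])
        return NoiseModel(center, np.maximum(sd, SD_FLOOR))
    which = np.clip(np.searchsorted(edges, mean_arr, side="right") - 1,
                    0, edges.size - 2)
    centers, med_sd, weights = [], [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.sum() < 2:
            continue
        centers.append(np.median(mean_arr[mask]))
        med_sd.append(np.median(sd_arr[mask]))
        weights.append(mask.sum())
    centers = np.asarray(centers)
    med_sd = np.asarray(med_sd) / _median_sd_correction(R)
    order = np.argsort(centers)
    centers, med_sd = centers[order], med_sd[order]
    weights = np.asarray(weights, dtype=float)[order]

    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = iso.fit_transform(centers, med_sd, sample_weight=weights)
    return NoiseModel(centers, np.maximum(fitted, SD_FLOOR))


def fc_variance(model: NoiseModel, intensity_t, intensity_0, n_replicates: int):
    """Variance of a log2 fold change between two replicate means.

    var = SD^2(I_t)/R + SD^2(I_0)/R.
    """
    sd_t = model.sd(intensity_t)
    sd_0 = model.sd(intensity_0)
    return (sd_t**2 + sd_0**2) / n_replicates
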