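"""4C-seq viewpoint profiles: normalization, smoothing, domainograms.

A 4C profile is one viewpoint's contact coverage along the chromosome.
Coverage is scaled to reads-per-million over bins outside the viewpoint
exclusion zone, smoothed with a sliding median for display-scale tracks,
and expanded into a multi-scale domainogram (mean coverage in windows of
geometrically increasing size, quantile-rank scaled per window so scales
are comparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class FourCProfile:
    """RPM-normalized per-bin 4C coverage for one viewpoint."""

    viewpoint: int  # bp
    exclusion: int  # bp
    bin_size: int
    coverage: np.ndarray  # RPM, zero inside the exclusion zone
    condition: str = ""

    @property
    def n_bins(self) -> int:
        return self.coverage.size

    def excluded_bins(self) -> np.ndarray:
        centers = np.arange(self.n_bins) * self.bin_size + self.bin_size // 2
        return np.abs(centers - self.viewpoint) <= self.exclusion


def normalize_fourc(
    raw: np.ndarray,
    viewpoint: int,
    exclusion: int = 10_000,
    bin_size: int = 2_000,
    condition: str = "",
) -> FourCProfile:
    """Zero the viewpoint's exclusion zone and scale to reads per million
    over the remaining bins."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw coverage must be non-negative")
    prof = FourCProfile(
        viewpoint=viewpoint,
        exclusion=exclusion,
        bin_size=bin_size,
        coverage=raw.copy(),
        condition=condition,
    )
    excl = prof.excluded_bins()
    cov = np.where(excl, 0.0, raw)
    total = cov.sum()
    if total == 0:
        raise ValueError("no coverage outside the exclusion zone")
    prof.coverage = cov * (1e6 / total)
    return prof


def sliding_median_track(profile: FourCProfile, window: int = 5_000) -> np.ndarray:
    """Per-bin median of coverage over bins whose centers fall within
    +/- window/2 of each bin center."""
    if window < profile.bin_size:
        raise ValueError("window must be at least one bin")
    half_bins = int(window / 2 // profile.bin_size)
    n = 2 * half_bins + 1
    return (
        pd.Series(profile.coverage)
        .rolling(n, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


@dataclass
class Domainogram:
    """Multi-scale 4C summary: rows are window sizes, values are
    per-window quantile ranks of the windowed mean coverage, in [0, 1]."""

    windows: np.ndarray  # bp
    values: np.ndarray  # (n_windows, n_bins)
    bin_size: int


def build_domainogram(
    profile: FourCProfile,
    min_w: int = 2_000,
    max_w: int = 50_000,
    n_scales: int = 20,
) -> Domainogram:
    """Mean coverage in centered windows of geometrically spaced sizes,
    quantile-rank scaled to [0, 1] per window (midrank convention)."""
    if max_w <= min_w:
        raise ValueError("max_w must exceed min_w")
    windows = np.unique(
        np.round(
            np.geomspace(min_w, max_w, n_scales) / profile.bin_size
        ).astype(int)
        * profile.bin_size
    )
    windows = windows[windows >= profile.bin_size]
    vals = np.empty((windows.size, profile.n_bins))
    cov = pd.Series(profile.coverage)
    for r, w in enumerate(windows):
        nb = max(1, int(round(w / profile.bin_size)))
        mean = cov.rolling(nb, center=True, min_periods=1).mean().to_numpy()
        ranks = rankdata(mean, method="average")
        vals[r] = (ranks - 0.5) / mean.size
    return Domainogram(windows=windows, values=vals, bin_size=profile.bin_size)


def compare_fourc_conditions(
    profiles: list[FourCProfile],
    region: tuple[int, int],
) -> tuple[np.ndarray, bool]:
    """Mean RPM per condition over ``region`` (bp, half-open), in the
    given order, plus a flag for whether the means are monotone
    (non-increasing or non-decreasing) along that order."""
    if len(profiles) < 2:
        raise ValueError("need at least two conditions")
    n = profiles[0].n_bins
    bs = profiles[0].bin_size
    for p in profiles[1:]:
        if p.n_bins != n or p.bin_size != bs:
            raise ValueError("profiles are not on a common grid")
    lo, hi = region
    if lo < 0 or hi > n * bs or hi <= lo:
        raise ValueError("region outside chromosome")
    b0, b1 = lo // bs, max(lo // bs + 1, -(-hi // bs))
    means = np.array([p.coverage[b0:b1].mean() for p in profiles])
    diffs = np.diff(means)
    monotone = bool((diffs <= 0).all() or (diffs >= 0).all())
    return means, monotone
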