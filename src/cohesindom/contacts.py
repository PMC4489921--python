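"""Sparse symmetric contact counts stored in banded (diagonal) form.

A cis contact map only needs entries up to the largest analyzed
separation, so the upper triangle is held as a dense array ``data[i, k]``
= value at bin pair ``(i, i + k)`` for diagonal offsets ``k = 0..K``.
Cells with ``i + k >= n_bins`` fall off the chromosome and are kept at
zero (or NaN for float matrices).  This layout makes per-distance
statistics (decay curves, band insulation) simple vectorized slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def power_law_pair_sum(
    alpha: float, n_bins: int, k_lo: int, k_hi: int
) -> float:
    """Sum of (n - k) * k**alpha over diagonal offsets k in [k_lo, k_hi]:
    the expected relative count mass of that separation range under a
    power-law decay with exponent alpha."""
    k = np.arange(max(1, k_lo), min(k_hi, n_bins - 1) + 1, dtype=float)
    if k.size == 0:
        return 0.0
    return float(((n_bins - k) * k**alpha).sum())


def band_share(alpha: float, n_bins: int, max_offset: int) -> float:
    """Fraction of a chromosome's cis contacts expected to fall within
    ``max_offset`` diagonals under a power-law decay with exponent alpha."""
    band = power_law_pair_sum(alpha, n_bins, 1, max_offset)
    full = power_law_pair_sum(alpha, n_bins, 1, n_bins - 1)
    return band / full


def band_valid_mask(n_bins: int, max_offset: int) -> np.ndarray:
    """Boolean mask of in-chromosome cells for a banded array."""
    i = np.arange(n_bins)[:, None]
    k = np.arange(max_offset + 1)[None, :]
    return i + k < n_bins


@dataclass
class ContactMatrix:
    """Binned symmetric cis contact counts, upper triangle, banded."""

    bin_size: int
    data: np.ndarray  # (n_bins, max_offset + 1), counts; [i, k] = c(i, i+k)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("banded data must be 2-D")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def max_offset(self) -> int:
        return self.data.shape[1] - 1

    @property
    def total(self) -> int:
        return int(self.data.sum(dtype=np.float64))

    def diagonal_sums(self) -> np.ndarray:
        """Sum of counts per diagonal offset."""
        return self.data.sum(axis=0, dtype=np.float64)

    def pairs_per_offset(self) -> np.ndarray:
        """Number of in-chromosome bin pairs per diagonal offset."""
        return (self.n_bins - np.arange(self.max_offset + 1)).astype(np.int64)

    def marginals(self) -> np.ndarray:
        """Per-bin total contact count (both orientations, k >= 1)."""
        upper = self.data[:, 1:].sum(axis=1, dtype=np.float64)
        lower = np.zeros(self.n_bins)
        for k in range(1, self.max_offset + 1):
            lower[k:] += self.data[: self.n_bins - k, k]
        return upper + lower

    # ------------------------------------------------------------------ io
    def to_triplets(self) -> pd.DataFrame:
        """Nonzero entries as (bin_i, bin_j, count), i <= j."""
        i, k = np.nonzero(self.data)
        return pd.DataFrame(
            {"bin_i": i, "bin_j": i + k, "count": self.data[i, k]}
        )

    @classmethod
    def from_triplets(
        cls,
        triplets: pd.DataFrame,
        bin_size: int,
        n_bins: int,
        max_offset: int,
    ) -> "ContactMatrix":
        i = triplets["bin_i"].to_numpy()
        j = triplets["bin_j"].to_numpy()
        c = triplets["count"].to_numpy()
        if (j < i).any():
            i, j = np.minimum(i, j), np.maximum(i, j)
        k = j - i
        keep = k <= max_offset
        data = np.zeros((n_bins, max_offset + 1), dtype=np.int64)
        np.add.at(data, (i[keep], k[keep]), c[keep])
        return cls(bin_size=bin_size, data=data)
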