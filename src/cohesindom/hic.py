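"""Distance decay, per-bin bias correction and observed/expected maps.

The normalization chain is the standard one for binned cis contact data:

1. ``estimate_distance_decay`` — the mean count per bin pair f(d) in
   log-spaced distance shells (ratio 2**0.25), capturing the power-law
   drop of contact probability with genomic separation.
2. ``estimate_bin_biases`` — multiplicative per-bin factors b_i fitted by
   iterative proportional fitting of the marginals against the
   decay-based expectation, with low-coverage bins masked.
3. ``compute_enrichment`` — e_ij = log2((c_ij + psi) / (b_i b_j f(d_ij) + psi)).
4. ``delta_matrix`` — knockout-vs-control difference of enrichment
   computed against the control's decay curve, so that a global change
   in decay shows up as signal rather than being absorbed into the
   expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .contacts import ContactMatrix, band_share


class GridMismatchError(ValueError):
    """Raised when two matrices do not share a bin grid."""


def _check_same_grid(a, b) -> None:
    if a.bin_size != b.bin_size or a.data.shape != b.data.shape:
        raise GridMismatchError("bin grids do not match")


# --------------------------------------------------------------------------
# distance decay
# --------------------------------------------------------------------------


@dataclass
class DecayCurve:
    """Mean count per bin pair in log-spaced distance shells."""

    bin_size: int
    edges: np.ndarray  # shell edges in bp, len = n_shells + 1
    f: np.ndarray  # mean count per pair, len = n_shells
    shell_of_offset: np.ndarray  # diagonal offset k -> shell index (k=0 -> -1)

    def f_of_offset(self) -> np.ndarray:
        """Expected count per pair for each diagonal offset (NaN at k=0)."""
        out = np.full(self.shell_of_offset.size, np.nan)
        ok = self.shell_of_offset >= 0
        out[ok] = self.f[self.shell_of_offset[ok]]
        return out

    def fit_exponent(
        self, d_min: float | None = None, d_max: float | None = None
    ) -> float:
        """Log-log regression slope of f(d) over [d_min, d_max]."""
        mids = np.sqrt(self.edges[:-1] * self.edges[1:])
        lo = d_min if d_min is not None else self.edges[0]
        hi = d_max if d_max is not None else self.edges[-1]
        sel = (mids >= lo) & (mids <= hi) & (self.f > 0)
        if sel.sum() < 3:
            raise ValueError("too few shells for an exponent fit")
        slope, _ = np.polyfit(np.log(mids[sel]), np.log(self.f[sel]), 1)
        return float(slope)


SHELL_RATIO = 2.0**0.25


def estimate_distance_decay(counts: ContactMatrix) -> DecayCurve:
    """Shell-averaged decay f(d) from banded counts (diagonal 0 excluded)."""
    if counts.data[:, 1:].sum() == 0:
        raise ValueError("empty contact matrix")
    K = counts.max_offset
    bs = counts.bin_size
    max_d = K * bs
    edges = [float(bs)]
    while edges[-1] < max_d:
        edges.append(edges[-1] * SHELL_RATIO)
    edges = np.asarray(edges)
    # offset k has distance k * bs; shell index via right-open edges
    k = np.arange(K + 1)
    shell = np.searchsorted(edges, k * bs, side="right") - 1
    shell = np.minimum(shell, len(edges) - 2)
    shell[0] = -1
    sums = counts.diagonal_sums().astype(float)
    pairs = counts.pairs_per_offset().astype(float)
    n_shells = len(edges) - 1
    f = np.zeros(n_shells)
    csum = np.bincount(shell[1:], weights=sums[1:], minlength=n_shells)
    cpair = np.bincount(shell[1:], weights=pairs[1:], minlength=n_shells)
    nz = cpair > 0
    f[nz] = csum[nz] / cpair[nz]
    return DecayCurve(bin_size=bs, edges=edges, f=f, shell_of_offset=shell)


# --------------------------------------------------------------------------
# per-bin biases
# --------------------------------------------------------------------------


@dataclass
class BiasVector:
    """Multiplicative per-bin factors; masked bins are NaN."""

    b: np.ndarray
    mask: np.ndarray  # True where the bin is excluded
    converged: bool = True
    n_iter: int = 0


def _expected_marginals(b: np.ndarray, fk: np.ndarray) -> np.ndarray:
    """E_i = b_i * sum_j b_j f(|i-j|) via FFT convolution (masked b = 0)."""
    K = fk.size - 1
    kern = np.zeros(2 * K + 1)
    kern[K + 1 :] = fk[1:]
    kern[:K] = fk[1:][::-1]
    conv = fftconvolve(b, kern, mode="same")
    return b * conv


def estimate_bin_biases(
    counts: ContactMatrix,
    decay: DecayCurve,
    mask_fraction: float = 0.2,
    tol: float = 1e-4,
    max_iter: int = 200,
    damping: float = 0.5,
    detrend_window: int | None = 300_000,
) -> BiasVector:
    """Iterative proportional fitting of per-bin technical biases.

    Bins whose marginal count falls below ``mask_fraction`` times the
    median marginal are masked and excluded from the fit.  Updates are
    damped (``b <- b * ratio**damping``) for stable convergence;
    non-convergence within ``max_iter`` sets ``converged=False`` rather
    than raising.

    Because marginal matching alone would also absorb broad biological
    structure (an active domain's uniformly elevated contact intensity
    inflates all its marginals), the fitted log-biases are high-pass
    filtered by subtracting a centered rolling median over
    ``detrend_window`` bp.  Technical biases are bin-scale and
    independent while compartment signal is domain-scale, so the rolling
    median isolates the structural component and leaves it in the map,
    where it belongs.  Pass ``detrend_window=None`` for plain IPF.
    """
    m = counts.marginals().astype(float)
    mask = m < mask_fraction * np.median(m)
    fk = decay.f_of_offset()
    fk = np.where(np.isnan(fk), 0.0, fk)
    b = np.where(mask, 0.0, 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        E = _expected_marginals(b, fk)
        ratio = np.ones_like(b)
        ok = ~mask & (E > 0)
        ratio[ok] = m[ok] / E[ok]
        b_new = b * ratio**damping
        gm = np.exp(np.mean(np.log(b_new[~mask]))) if (~mask).any() else 1.0
        b_new = np.where(mask, 0.0, b_new / gm)
        change = np.max(np.abs(b_new[~mask] - b[~mask]) / b[~mask]) if (~mask).any() else 0.0
        b = b_new
        if change < tol:
            converged = True
            break
    out = np.where(mask, np.nan, b)
    if detrend_window is not None and (~mask).any():
        import pandas as pd

        win = max(3, int(detrend_window // counts.bin_size) | 1)
        logb = pd.Series(np.log(out))
        trend = logb.rolling(win, center=True, min_periods=max(1, win // 4)).median()
        trend = trend.fillna(0.0).to_numpy()
        out = np.exp(np.log(out) - trend)
        gm = np.exp(np.nanmean(np.log(out)))
        out = out / gm
    return BiasVector(b=out, mask=mask, converged=converged, n_iter=it)


# --------------------------------------------------------------------------
# enrichment and delta maps
# --------------------------------------------------------------------------


@dataclass
class EnrichmentMatrix:
    """Banded log2 observed/expected contact enrichment.

    ``data[i, k]`` is e at bin pair (i, i+k); NaN where either bin is
    masked, off the chromosome, or on the main diagonal.  The observed
    counts and the expectation factors are retained so downstream
    aggregation (insulation, pair pooling) can work on count sums rather
    than per-cell log values, which matters at realistic sequencing depth.
    """

    bin_size: int
    data: np.ndarray
    pseudocount: float = 1.0
    obs: np.ndarray | None = None  # banded counts (same shape)
    expected: np.ndarray | None = None  # banded b_i b_j f(d), NaN like data
    mask: np.ndarray | None = None  # per-bin exclusion

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def max_offset(self) -> int:
        return self.data.shape[1] - 1

    @property
    def has_counts(self) -> bool:
        return self.obs is not None and self.expected is not None


# above this many cells the banded arrays are held in float32; the exact
# float64 path is kept for small (toy/oracle) matrices
_F32_THRESHOLD = 20_000_000


def _band_dtype(shape: tuple[int, int]):
    return np.float32 if shape[0] * shape[1] > _F32_THRESHOLD else np.float64


def _expected_band(
    counts_shape: tuple[int, int], b: np.ndarray, fk: np.ndarray
) -> np.ndarray:
    n, K1 = counts_shape
    exp = np.empty((n, K1), dtype=_band_dtype(counts_shape))
    exp[:, 0] = np.nan
    for k in range(1, K1):
        exp[: n - k, k] = b[: n - k] * b[k:] * fk[k]
        exp[n - k :, k] = np.nan
    return exp


def compute_enrichment(
    counts: ContactMatrix,
    decay: DecayCurve,
    biases: BiasVector,
    pseudocount: float = 1.0,
) -> EnrichmentMatrix:
    """e_ij = log2((c + psi) / (b_i b_j f(d) + psi)) on unmasked bin pairs."""
    if biases.b.size != counts.n_bins:
        raise GridMismatchError("bias vector does not match the bin grid")
    if decay.shell_of_offset.size != counts.max_offset + 1:
        raise GridMismatchError("decay curve does not match the offset range")
    fk = decay.f_of_offset()
    exp = _expected_band(counts.data.shape, biases.b, np.nan_to_num(fk))
    obs = counts.data
    with np.errstate(invalid="ignore", divide="ignore"):
        e = obs.astype(exp.dtype)
        e += exp.dtype.type(pseudocount)
        e /= exp + exp.dtype.type(pseudocount)
        np.log2(e, out=e)
    e[:, 0] = np.nan
    exp[:, 0] = np.nan
    return EnrichmentMatrix(
        bin_size=counts.bin_size,
        data=e,
        pseudocount=pseudocount,
        obs=obs,
        expected=exp,
        mask=biases.mask,
    )


@dataclass
class DeltaMatrix:
    """Banded difference of enrichment, condition B minus condition A,
    both normalized against condition A's decay curve."""

    bin_size: int
    data: np.ndarray
    enrich_a: EnrichmentMatrix | None = None
    enrich_b: EnrichmentMatrix | None = None

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]


def delta_matrix(
    counts_a: ContactMatrix,
    counts_b: ContactMatrix,
    pseudocount: float = 1.0,
    mask_fraction: float = 0.2,
    match: str = "library",
) -> DeltaMatrix:
    """Difference map e_B - e_A against the control's (A's) expectation.

    Each condition gets its own bias vector but the decay curve is
    estimated from A only, so global decay changes appear in the
    difference.  Scale matching between the conditions:

    ``match="library"`` (default) equalizes *estimated chromosome-wide*
    totals: each condition's banded total is extrapolated beyond the
    stored separation range with its own fitted decay exponent before B
    is rescaled.  A condition with a sharper decay then correctly shows
    a net gain of short-range contacts inside the band.  ``match="band"``
    equalizes the in-band totals directly, which forces the banded means
    to agree and hides part of a global decay change.
    """
    _check_same_grid(counts_a, counts_b)
    decay = estimate_distance_decay(counts_a)
    bias_a = estimate_bin_biases(counts_a, decay, mask_fraction=mask_fraction)
    e_a = compute_enrichment(counts_a, decay, bias_a, pseudocount)

    tot_a = counts_a.data[:, 1:].sum()
    tot_b = counts_b.data[:, 1:].sum()
    if tot_b == 0:
        raise ValueError("condition B has no contacts")
    if match == "library":
        n, K = counts_a.n_bins, counts_a.max_offset
        alpha_a = decay.fit_exponent()
        alpha_b = estimate_distance_decay(counts_b).fit_exponent()
        lib_a = tot_a / band_share(alpha_a, n, K)
        lib_b = tot_b / band_share(alpha_b, n, K)
        factor = lib_a / lib_b
    elif match == "band":
        factor = tot_a / tot_b
    else:
        raise ValueError(f"unknown match {match!r}")
    scaled = ContactMatrix(
        bin_size=counts_b.bin_size,
        data=(counts_b.data * factor).astype(_band_dtype(counts_b.data.shape)),
    )
    bias_b = estimate_bin_biases(scaled, decay, mask_fraction=mask_fraction)
    e_b = compute_enrichment(scaled, decay, bias_b, pseudocount)
    delta = e_b.data - e_a.data
    return DeltaMatrix(
        bin_size=counts_a.bin_size, data=delta, enrich_a=e_a, enrich_b=e_b
    )
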