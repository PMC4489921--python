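"""Forward simulation of Hi-C, 4C and expression data from a GenomeModel.

The contact intensity between bins i < j separated by k = j - i diagonals
is

    lambda_ij = s * b_i * b_j * k**alpha * S_ij

where alpha is the condition's distance-decay exponent, b are per-bin
log-normal technical biases and the structure factor S_ij multiplies

  * the active-intensity ratio when both bins lie in the same active
    domain,
  * the border attenuation once per domain border crossed,
  * a per-crossed-COH-site attenuation (class-rescaled, capped at
    ``site_attenuation_max`` effective crossings, acting only on pairs
    closer than ``site_insulation_range`` — site insulation is local,
    border insulation is not),
  * the anchor enrichment when (i, j) is within one bin of a planted
    loop-anchor pair.

The structure factor is renormalized to unit mean on every diagonal, so
structure redistributes contacts *within* each genomic separation and
the marginal contact probability follows the configured power law
exactly.  This keeps the decay exponent an honest knob: the observed
distance decay of the map is alpha by construction, and condition
differences in insulation strength do not leak into the global decay.

The overall scale s is set so the expected count total matches
``config.depth``; counts are independent Poisson draws.  Each simulated
product (wild-type map, knockout map, every 4C viewpoint, expression)
uses its own child RNG stream of the config seed so they are
independently reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .contacts import ContactMatrix, power_law_pair_sum
from .genome import GenomeModel

_STREAM_BIAS = 303
_STREAM_HIC = 202
_STREAM_4C = 404
_STREAM_EXPR = 505


def _condition_index(label: str) -> int:
    return {"wt": 0, "ko": 1}[label]


def planted_biases(config: SimConfig, condition: str) -> np.ndarray:
    """The per-bin multiplicative technical biases used by the simulator.

    Deterministic in (seed, condition); geometric mean 1.  Exposed so
    recovery analyses can compare estimates against the planted truth.
    """
    idx = _condition_index(config.condition(condition).label)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAM_BIAS, idx])
    )
    b = rng.lognormal(mean=0.0, sigma=config.bias_sd, size=config.n_bins)
    return b / np.exp(np.mean(np.log(b)))


def _site_attenuation_by_class(genome: GenomeModel, site_attenuation: float):
    """Per-site attenuation, rescaled so the per-bp insulation rate
    (1 - a)/spacing is the same in active and passive domains."""
    cfg = genome.config
    a_passive = site_attenuation
    a_active = 1.0 - (cfg.site_spacing_active / cfg.site_spacing_passive) * (
        1.0 - a_passive
    )
    return a_active, a_passive


def _crossing_cumulants(genome: GenomeModel, site_attenuation: float):
    """Cumulative (count, log-attenuation) of COH sites per bin.

    ``cum[i]`` sums over sites located in bins <= i; a pair (i, j) then
    crosses ``cum[j-1] - cum[i]`` sites (sites in the end bins are the
    pair's own anchors, not intervening material).
    """
    a_active, a_passive = _site_attenuation_by_class(genome, site_attenuation)
    dom_class_active = genome.active_domain_mask()
    coh = genome.sites[genome.sites["class"] == "COH"]
    bins = coh["position"].to_numpy() // genome.bin_size
    in_active = dom_class_active[coh["domain"].to_numpy()]
    ln_a = np.where(in_active, np.log(a_active), np.log(a_passive))
    n = genome.n_bins
    cnt = np.zeros(n)
    lna = np.zeros(n)
    np.add.at(cnt, bins, 1.0)
    np.add.at(lna, bins, ln_a)
    return np.cumsum(cnt), np.cumsum(lna)


def _anchor_cells(genome: GenomeModel) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Map diagonal offset k -> (row indices, log multiplier exponents)
    of cells within one bin of a planted anchor pair."""
    bs = genome.bin_size
    n = genome.n_bins
    cells: dict[tuple[int, int], float] = {}
    for a, b, _, strength in genome.anchor_pairs[
        ["a", "b", "domain", "strength"]
    ].itertuples(index=False):
        ab, bb = int(a) // bs, int(b) // bs
        for i in range(ab - 1, ab + 2):
            for j in range(bb - 1, bb + 2):
                if 0 <= i < n and 0 <= j < n and j > i:
                    key = (i, j - i)
                    cells[key] = max(cells.get(key, 0.0), float(strength))
    by_k: dict[int, tuple[list, list]] = {}
    for (i, k), s in cells.items():
        by_k.setdefault(k, ([], []))
        by_k[k][0].append(i)
        by_k[k][1].append(s)
    return {
        k: (np.asarray(ii, dtype=np.int64), np.asarray(ss))
        for k, (ii, ss) in by_k.items()
    }


def _structure_log(
    genome: GenomeModel,
    cfg: SimConfig,
    condition: str,
    k: int,
    dom: np.ndarray,
    bin_active: np.ndarray,
    cum_cnt: np.ndarray,
    cum_lna: np.ndarray,
    anchors: dict,
) -> np.ndarray:
    """log structure factor S_ij along diagonal k (i = 0..n-1-k)."""
    cond = cfg.condition(condition)
    n = genome.n_bins
    i = np.arange(n - k)
    j = i + k
    out = np.zeros(n - k)
    same_active = (dom[i] == dom[j]) & bin_active[i]
    out[same_active] += np.log(cfg.active_intensity_ratio)
    if 2 <= k <= cfg.site_insulation_range // cfg.bin_size:
        n_cross = cum_cnt[j - 1] - cum_cnt[i]
        ln_cross = cum_lna[j - 1] - cum_lna[i]
        scale = np.ones_like(ln_cross)
        over = n_cross > cfg.site_attenuation_max
        scale[over] = cfg.site_attenuation_max / n_cross[over]
        out += ln_cross * scale
    if k in anchors and cond.anchor_enrichment != 1.0:
        ii, ss = anchors[k]
        out[ii] += ss * np.log(cond.anchor_enrichment)
    return out


def _expected_band(
    genome: GenomeModel, condition: str, biases: np.ndarray,
    config: SimConfig | None = None,
) -> np.ndarray:
    """Unscaled expected intensity, banded float32 (diagonal 0 left at 0)."""
    cfg = config or genome.config
    cond = cfg.condition(condition)
    n, K = genome.n_bins, cfg.max_offset
    dom = genome.domain_of_bin()
    bin_active = genome.active_domain_mask()[dom]
    cum_cnt, cum_lna = _crossing_cumulants(genome, cond.site_attenuation)
    anchors = _anchor_cells(genome)
    lam = np.zeros((n, K + 1), dtype=np.float32)
    ln_border = np.log(cond.border_attenuation)
    for k in range(1, K + 1):
        s_log = _structure_log(
            genome, cfg, condition, k, dom, bin_active, cum_cnt, cum_lna, anchors
        )
        # local structure (activity, site insulation, loops) redistributes
        # contacts within a genomic separation: unit mean per diagonal.
        struct = np.exp(s_log)
        struct /= struct.mean()
        # border attenuation removes cross-border contacts outright:
        # domain demarcation genuinely depletes the library of them.
        border = np.exp((dom[k:] - dom[: n - k]) * ln_border)
        lam[: n - k, k] = (
            biases[: n - k]
            * biases[k:]
            * float(k) ** cond.decay_exponent
            * struct
            * border
        )
    return lam


def _band_and_tail(
    lam: np.ndarray, biases: np.ndarray, cfg: SimConfig, alpha: float
) -> tuple[float, float]:
    """In-band expected mass and the analytic long-range tail beyond it.

    ``depth`` counts the library's chromosome-wide cis pairs; the stored
    band only holds the share falling within max_distance.  A sharper
    decay (knockout) concentrates more of the same library inside the
    band — a real, analyzable global difference between conditions."""
    n, K = lam.shape[0], lam.shape[1] - 1
    band = float(lam.sum())
    mean_b = float(biases.mean())
    tail = mean_b**2 * power_law_pair_sum(alpha, n, K + 1, n - 1)
    return band, tail


def expected_band_total(
    genome: GenomeModel, condition: str, config: SimConfig | None = None
) -> float:
    """Expected number of simulated contacts inside the stored band."""
    cfg = config or genome.config
    cond = cfg.condition(condition)
    biases = planted_biases(cfg, condition)
    lam = _expected_band(genome, condition, biases, config=cfg)
    band, tail = _band_and_tail(lam, biases, cfg, cond.decay_exponent)
    if band + tail == 0:
        return 0.0
    return cfg.depth * band / (band + tail)


def simulate_contacts(
    genome: GenomeModel, condition: str, config: SimConfig | None = None
) -> ContactMatrix:
    """Poisson contact counts for one condition, banded up to max_distance.

    ``config.depth`` is the library's expected chromosome-wide cis pair
    count; the banded matrix receives the share of it that the
    condition's distance decay places within ``max_distance``."""
    cfg = config or genome.config
    cond = cfg.condition(condition)  # validates the label
    biases = planted_biases(cfg, condition)
    lam = _expected_band(genome, condition, biases, config=cfg)
    band, tail = _band_and_tail(lam, biases, cfg, cond.decay_exponent)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _STREAM_HIC, _condition_index(cond.label)])
    )
    n, K = lam.shape[0], lam.shape[1] - 1
    counts = np.zeros((n, K + 1), dtype=np.int32)
    if cfg.depth > 0 and band > 0:
        s = cfg.depth / (band + tail)
        for k in range(1, K + 1):
            counts[: n - k, k] = rng.poisson(s * lam[: n - k, k].astype(np.float64))
    return ContactMatrix(bin_size=cfg.bin_size, data=counts)


def simulate_fourc(
    genome: GenomeModel,
    viewpoint: int,
    condition: str,
    config: SimConfig | None = None,
) -> np.ndarray:
    """Per-bin 4C coverage for one viewpoint: Poisson draws of the
    viewpoint's row of the contact intensity, zeroed in the exclusion zone.
    """
    cfg = config or genome.config
    cond = cfg.condition(condition)
    if not 0 <= viewpoint < cfg.chromosome_length:
        raise ValueError(f"viewpoint {viewpoint} outside chromosome")
    n = cfg.n_bins
    vbin = viewpoint // cfg.bin_size
    biases = planted_biases(cfg, condition)
    dom = genome.domain_of_bin()
    bin_active = genome.active_domain_mask()[dom]
    cum_cnt, cum_lna = _crossing_cumulants(genome, cond.site_attenuation)

    j = np.arange(n)
    lo, hi = np.minimum(vbin, j), np.maximum(vbin, j)
    k = hi - lo
    lam = np.zeros(n)
    nz = k > 0
    lam[nz] = biases[vbin] * biases[j[nz]] * k[nz].astype(float) ** cond.decay_exponent
    same_active = (dom[lo] == dom[hi]) & bin_active[lo]
    lam[same_active & nz] *= cfg.active_intensity_ratio
    lam[nz] *= cond.border_attenuation ** (dom[hi[nz]] - dom[lo[nz]])
    far = (k >= 2) & (k <= cfg.site_insulation_range // cfg.bin_size)
    n_cross = np.zeros(n)
    ln_cross = np.zeros(n)
    n_cross[far] = cum_cnt[hi[far] - 1] - cum_cnt[lo[far]]
    ln_cross[far] = cum_lna[hi[far] - 1] - cum_lna[lo[far]]
    scale = np.ones(n)
    over = n_cross > cfg.site_attenuation_max
    scale[over] = cfg.site_attenuation_max / n_cross[over]
    lam *= np.exp(ln_cross * scale)
    if cond.anchor_enrichment != 1.0:
        bs = cfg.bin_size
        for a, b, _, strength in genome.anchor_pairs[
            ["a", "b", "domain", "strength"]
        ].itertuples(index=False):
            ab, bb = int(a) // bs, int(b) // bs
            if abs(vbin - ab) <= 1:
                sel = np.abs(j - bb) <= 1
            elif abs(vbin - bb) <= 1:
                sel = np.abs(j - ab) <= 1
            else:
                continue
            lam[sel] *= cond.anchor_enrichment ** float(strength)

    excl = np.abs(j * cfg.bin_size + cfg.bin_size // 2 - viewpoint) <= cfg.fourc_exclusion
    lam[excl] = 0.0
    total = lam.sum()
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [cfg.seed, _STREAM_4C, _condition_index(cond.label), int(vbin)]
        )
    )
    if cfg.fourc_depth <= 0 or total == 0:
        return np.zeros(n, dtype=np.int64)
    return rng.poisson(cfg.fourc_depth / total * lam)


def simulate_expression(
    genome: GenomeModel, config: SimConfig | None = None
) -> pd.DataFrame:
    """Replicate expression table (linear scale, expected counts).

    Columns ``wt_1..wt_R`` and ``ko_1..ko_R``; log-normal replicate noise
    around the planted baseline, with the planted knockout response added
    to the ko replicates.
    """
    cfg = config or genome.config
    if len(genome.genes) == 0:
        raise ValueError("genome has no genes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_EXPR]))
    base = genome.genes["baseline"].to_numpy()
    shift = genome.genes["planted_response"].to_numpy()
    ng, R = base.size, cfg.n_replicates
    cols = {}
    for r in range(R):
        cols[f"wt_{r + 1}"] = 2.0 ** (
            base + cfg.replicate_noise_sd * rng.normal(size=ng)
        )
    for r in range(R):
        cols[f"ko_{r + 1}"] = 2.0 ** (
            base + shift + cfg.replicate_noise_sd * rng.normal(size=ng)
        )
    return pd.DataFrame(cols, index=genome.genes.index.rename("gene"))
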