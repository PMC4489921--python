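"""Contact insulation, domain calling and domain/site statistics.

The central statistic is the band insulation I(x, w): the contact
enrichment of bin pairs that cross locus x at separations up to the band
scale w — pairs (i, j) with i in [x-w, x) and j in [x, x+w).  Because
every contributing pair straddles x, a locus that blocks contacts (a
domain border, a cohesin/CTCF site) shows up as a local trough at the
band scales it acts on.  Aggregating the track around a site class gives
the meta-insulation profile and its peak-to-trough ratio; minima of the
large-band track are domain borders; intra-domain intensity plus TSS
density classifies domains into active and passive.

By default window statistics aggregate observed and expected counts
separately and report log2(sum(obs)/sum(exp)); the per-cell mean of
log2 enrichment is available as ``mode="mean"`` (it is noisier and
biased toward zero where per-cell counts are sparse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans

from .hic import EnrichmentMatrix


@dataclass
class InsulationTrack:
    """Per-bin crossing-contact statistic at one band scale."""

    band: int  # w, bp
    bin_size: int
    values: np.ndarray  # log2 enrichment of crossing contacts; NaN undefined
    n_pairs: np.ndarray  # contributing bin pairs per locus
    min_pairs: int = 10
    mode: str = "ratio"


@dataclass
class MetaProfile:
    """Site-aligned average insulation at one band."""

    band: int
    bin_size: int
    offsets: np.ndarray  # bp, -2w..+2w
    values: np.ndarray  # mean I(site + o, w)
    n_sites: int
    peak_to_trough: float


@dataclass
class DomainSet:
    """Ordered borders and the domains between them."""

    bin_size: int
    borders: np.ndarray  # strictly increasing bin indices
    domains: pd.DataFrame  # start_bin, end_bin, class (may be None)
    degenerate: bool = False


@dataclass
class SpacingComparison:
    """Adjacent COH spacing distributions by domain class, with KS test."""

    spacings: dict[str, np.ndarray]
    D: float
    pvalue: float


# --------------------------------------------------------------------------
# band insulation
# --------------------------------------------------------------------------


def _window_sums(values: np.ndarray, wb: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of ``values`` and count of finite cells over the crossing square
    {i in [x-wb, x), j in [x, x+wb)} for every locus x (banded input)."""
    n, K1 = values.shape
    if 2 * wb - 1 > K1 - 1:
        raise ValueError("band exceeds the stored diagonal range")
    finite = np.isfinite(values)
    acc = np.float64 if values.dtype == np.float64 else np.float32
    V = np.where(finite, values, values.dtype.type(0.0))
    S = np.cumsum(V, axis=1, dtype=acc)
    C = np.cumsum(finite, axis=1, dtype=np.int32)
    total = np.zeros(n)
    count = np.zeros(n)
    for d in range(1, wb + 1):
        hi = d + wb - 1
        rows = np.arange(d, n) - d  # locus x = rows + d
        seg = S[rows, hi] - S[rows, d - 1]
        cnt = C[rows, hi] - C[rows, d - 1]
        total[d:] += seg
        count[d:] += cnt
    return total, count


def band_insulation_track(
    enrich: EnrichmentMatrix,
    w: int,
    min_pairs: int = 10,
    mode: str = "ratio",
) -> InsulationTrack:
    """Insulation track at band w (bp); w must be a multiple of the bin
    size and at least 5 bins wide."""
    bs = enrich.bin_size
    if w % bs != 0 or w < 5 * bs:
        raise ValueError("band must be a multiple of bin_size and >= 5 bins")
    wb = w // bs
    if mode == "ratio" and enrich.has_counts:
        obs = np.where(np.isfinite(enrich.expected), enrich.obs, np.nan)
        o_sum, n_cells = _window_sums(obs, wb)
        e_sum, _ = _window_sums(enrich.expected, wb)
        psi = enrich.pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.log2((o_sum + psi) / (e_sum + psi))
    else:
        e_sum, n_cells = _window_sums(enrich.data, wb)
        with np.errstate(invalid="ignore"):
            vals = e_sum / n_cells
        mode = "mean"
    vals = np.where(n_cells >= min_pairs, vals, np.nan)
    return InsulationTrack(
        band=w,
        bin_size=bs,
        values=vals,
        n_pairs=n_cells.astype(np.int64),
        min_pairs=min_pairs,
        mode=mode,
    )


def meta_insulation_profile(
    enrich: EnrichmentMatrix,
    sites: np.ndarray,
    bands: list[int],
    min_sites: int = 50,
    min_pairs: int = 10,
    mode: str = "ratio",
    trough_frac: float = 0.5,
    peak_hi_frac: float = 2.0,
) -> dict[int, MetaProfile]:
    """Site-aligned insulation profiles for several bands.

    The profile P(o) averages I(s + o, w) over sites s at offsets
    o in [-2w, 2w].  peak_to_trough = 2**(max P on the flank window
    (w*trough_frac, w*peak_hi_frac] minus min P on |o| <= w*trough_frac).
    """
    sites = np.asarray(sites)
    out: dict[int, MetaProfile] = {}
    for w in bands:
        track = band_insulation_track(enrich, w, min_pairs=min_pairs, mode=mode)
        wb = w // enrich.bin_size
        site_bins = sites // enrich.bin_size
        usable = site_bins[
            (site_bins >= 0)
            & (site_bins < enrich.n_bins)
            & np.isfinite(track.values[np.clip(site_bins, 0, enrich.n_bins - 1)])
        ]
        if usable.size < min_sites:
            raise ValueError(
                f"band {w}: only {usable.size} usable sites (need {min_sites})"
            )
        offsets = np.arange(-2 * wb, 2 * wb + 1)
        grid = usable[:, None] + offsets[None, :]
        ok = (grid >= 0) & (grid < enrich.n_bins)
        tv = np.full(grid.shape, np.nan)
        tv[ok] = track.values[grid[ok]]
        with np.errstate(invalid="ignore"):
            P = np.nanmean(tv, axis=0)
        absoff = np.abs(offsets)
        trough_w = absoff <= wb * trough_frac
        peak_w = (absoff > wb * trough_frac) & (absoff <= wb * peak_hi_frac)
        ptt = float(2.0 ** (np.nanmax(P[peak_w]) - np.nanmin(P[trough_w])))
        out[w] = MetaProfile(
            band=w,
            bin_size=enrich.bin_size,
            offsets=offsets * enrich.bin_size,
            values=P,
            n_sites=int(usable.size),
            peak_to_trough=ptt,
        )
    return out


def group_sites_by_insulation(
    track: InsulationTrack, sites: np.ndarray, min_defined: float = 0.8
) -> dict[str, np.ndarray]:
    """Split sites into bottom-quartile (most insulating, lowest I),
    middle-half and top-quartile groups by I at the site.  Ties are broken
    by genomic coordinate."""
    sites = np.asarray(sites)
    bins = sites // track.bin_size
    inside = (bins >= 0) & (bins < track.values.size)
    vals = np.full(sites.size, np.nan)
    vals[inside] = track.values[bins[inside]]
    defined = np.isfinite(vals)
    if defined.mean() < min_defined:
        raise ValueError("track undefined at too many sites")
    pos = sites[defined]
    v = vals[defined]
    order = np.lexsort((pos, v))
    n = pos.size
    nb = int(round(n / 4))
    nt = int(round(n / 4))
    ranked = pos[order]
    return {
        "bottom": np.sort(ranked[:nb]),
        "middle": np.sort(ranked[nb : n - nt]),
        "top": np.sort(ranked[n - nt :]),
    }


# --------------------------------------------------------------------------
# domain calling and classification
# --------------------------------------------------------------------------


def call_domains(
    track: InsulationTrack,
    min_domain: int = 400_000,
    percentile: float | None = None,
    min_prominence: float = 0.5,
    refine_track: InsulationTrack | None = None,
    refine_window: int = 100_000,
) -> DomainSet:
    """Borders as prominent local minima of the large-band insulation.

    A border is a local minimum of I with prominence at least
    ``min_prominence`` (log2 units); borders are at least ``min_domain``
    apart (deeper minima win).  Prominence, being relative to the local
    level, stays calibrated across activity compartments whose baseline
    insulation differs; an optional global ``percentile`` filter
    additionally requires minima below that percentile of the track, at
    the cost of discarding borders inside high-intensity regions.

    A large band localizes coarsely (its trough is a wide V whose bottom
    flattens over tens of bins); passing a small-band ``refine_track``
    snaps each coarse border to the fine-band minimum within
    ``refine_window`` bp, giving bin-level localization.
    """
    v = track.values
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("insulation track has no defined values")
    fill = np.nanmax(v) + 1.0
    vf = np.where(finite, v, fill)
    distance = max(1, min_domain // track.bin_size)
    idx, _ = find_peaks(-vf, prominence=min_prominence, distance=distance)
    borders = idx
    if percentile is not None:
        thresh = np.nanpercentile(v, percentile)
        borders = idx[v[idx] <= thresh]
    n = v.size
    if refine_track is not None and borders.size:
        rw = max(1, refine_window // track.bin_size)
        rv = refine_track.values
        refined = []
        for b in borders:
            lo, hi = max(0, b - rw), min(n, b + rw + 1)
            seg = rv[lo:hi]
            if np.isfinite(seg).any():
                refined.append(lo + int(np.nanargmin(seg)))
            else:
                refined.append(int(b))
        borders = np.unique(refined)
    edges = np.concatenate([[0], borders, [n]])
    domains = pd.DataFrame(
        {
            "start_bin": edges[:-1],
            "end_bin": edges[1:],
            "class": [None] * (edges.size - 1),
        }
    )
    return DomainSet(bin_size=track.bin_size, borders=borders, domains=domains)


def domain_intensity(
    enrich: EnrichmentMatrix,
    domains: pd.DataFrame,
    sep_range: tuple[int, int] = (60_000, 180_000),
) -> np.ndarray:
    """Per-domain log2(sum obs / sum exp) over intra-domain bin pairs at
    the given separation range (bp, half-open)."""
    bs = enrich.bin_size
    k_lo = max(1, sep_range[0] // bs)
    k_hi = max(k_lo + 1, sep_range[1] // bs)
    k_hi = min(k_hi, enrich.max_offset + 1)
    out = np.empty(len(domains))
    psi = enrich.pseudocount
    if enrich.has_counts:
        obs = np.where(np.isfinite(enrich.expected), enrich.obs, np.nan)
    for row_idx, (s, t) in enumerate(
        domains[["start_bin", "end_bin"]].itertuples(index=False)
    ):
        if not enrich.has_counts:  # fall back to the mean log2 enrichment
            vals = [
                enrich.data[s : t - k, k]
                for k in range(k_lo, k_hi)
                if t - s > k
            ]
            allv = np.concatenate(vals) if vals else np.array([np.nan])
            out[row_idx] = float(np.nanmean(allv)) if np.isfinite(allv).any() else np.nan
            continue
        o_tot = e_tot = 0.0
        for k in range(k_lo, k_hi):
            if t - s <= k:
                continue
            seg_o = obs[s : t - k, k]
            seg_e = enrich.expected[s : t - k, k]
            ok = np.isfinite(seg_e)
            o_tot += np.nansum(seg_o[ok])
            e_tot += seg_e[ok].sum()
        out[row_idx] = np.log2((o_tot + psi) / (e_tot + psi)) if e_tot > 0 else np.nan
    return out


def class_intensity_ratio(
    enrich: EnrichmentMatrix,
    domains: pd.DataFrame,
    sep_range: tuple[int, int] = (60_000, 180_000),
) -> float:
    """Pooled linear-scale active/passive intra-domain intensity ratio.

    Observed and expected counts are summed over intra-domain bin pairs at
    the separation range, separately for active- and passive-class
    domains; the ratio of the two obs/exp quotients is returned.
    """
    bs = enrich.bin_size
    k_lo = max(1, sep_range[0] // bs)
    k_hi = min(max(k_lo + 1, sep_range[1] // bs), enrich.max_offset + 1)
    obs = np.where(np.isfinite(enrich.expected), enrich.obs, np.nan)
    sums = {"active": [0.0, 0.0], "passive": [0.0, 0.0]}
    for s, t, cls in domains[["start_bin", "end_bin", "class"]].itertuples(
        index=False
    ):
        if cls not in sums:
            continue
        for k in range(k_lo, k_hi):
            if t - s <= k:
                continue
            seg_e = enrich.expected[s : t - k, k]
            ok = np.isfinite(seg_e)
            sums[cls][0] += np.nansum(obs[s : t - k, k][ok])
            sums[cls][1] += seg_e[ok].sum()
    (oa, ea), (op_, ep) = sums["active"], sums["passive"]
    if ea == 0 or ep == 0 or op_ == 0:
        raise ValueError("insufficient coverage to form the class ratio")
    return (oa / ea) / (op_ / ep)


def classify_domain_activity(
    enrich: EnrichmentMatrix,
    domains: DomainSet | pd.DataFrame,
    tss: np.ndarray,
    sep_range: tuple[int, int] = (60_000, 180_000),
) -> DomainSet:
    """Two-cluster (k-means) grouping of domains on intra-domain contact
    intensity and TSS density; the TSS-dense cluster is labelled active."""
    df = domains.domains if isinstance(domains, DomainSet) else domains
    df = df.sort_values("start_bin").reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("need at least 4 domains to classify")
    bs = enrich.bin_size
    tss = np.asarray(tss)
    tss_bins = tss // bs
    intensity = domain_intensity(enrich, df, sep_range)
    density = np.array(
        [
            ((tss_bins >= s) & (tss_bins < t)).sum() / (t - s)
            for s, t in df[["start_bin", "end_bin"]].itertuples(index=False)
        ]
    )
    feats = np.column_stack([intensity, density])
    feats = np.where(np.isfinite(feats), feats, np.nanmean(feats, axis=0))
    sd = feats.std(axis=0)
    degenerate = bool(np.all(sd < 1e-12))
    if degenerate:
        classes = ["passive"] * len(df)
    else:
        z = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        km = KMeans(n_clusters=2, n_init=10, random_state=0)
        labels = km.fit_predict(z)
        dens_by = [density[labels == g].mean() for g in (0, 1)]
        active_label = int(np.argmax(dens_by))
        classes = [
            "active" if l == active_label else "passive" for l in labels
        ]
    out = df.copy()
    out["class"] = classes
    borders = out["start_bin"].to_numpy()[1:]
    return DomainSet(
        bin_size=bs, borders=borders, domains=out, degenerate=degenerate
    )


# --------------------------------------------------------------------------
# site statistics
# --------------------------------------------------------------------------


def adjacent_spacing_ks(
    sites: np.ndarray,
    domains: pd.DataFrame,
    bin_size: int,
    min_per_class: int = 20,
) -> SpacingComparison:
    """KS comparison of adjacent same-domain COH spacings in active vs
    passive domains."""
    sites = np.sort(np.asarray(sites))
    starts = domains["start_bin"].to_numpy() * bin_size
    dom_idx = np.searchsorted(starts, sites, side="right") - 1
    classes = domains["class"].to_numpy()
    spac: dict[str, list] = {"active": [], "passive": []}
    for a, b, da, db in zip(sites[:-1], sites[1:], dom_idx[:-1], dom_idx[1:]):
        if da == db and classes[da] in spac:
            spac[classes[da]].append(b - a)
    arrs = {c: np.asarray(v, dtype=float) for c, v in spac.items()}
    for c, v in arrs.items():
        if v.size < min_per_class:
            raise ValueError(f"only {v.size} spacings in {c} domains")
    res = ks_2samp(arrs["active"], arrs["passive"], method="asymp")
    return SpacingComparison(
        spacings=arrs, D=float(res.statistic), pvalue=float(res.pvalue)
    )


def intervening_site_curve(
    enrich: EnrichmentMatrix,
    sites: np.ndarray,
    distance_strata: list[tuple[int, int]],
    max_count: int = 6,
) -> pd.DataFrame:
    """Mean enrichment by number of intervening COH sites, per distance
    stratum, relative to the stratum-wide mean (counts capped at 6+)."""
    bs = enrich.bin_size
    n = enrich.n_bins
    site_bins = np.sort(np.asarray(sites)) // bs
    cum = np.zeros(n)
    inside = (site_bins >= 0) & (site_bins < n)
    np.add.at(cum, site_bins[inside], 1.0)
    cum = np.cumsum(cum)
    cols = {}
    for lo, hi in distance_strata:
        k_lo = max(1, lo // bs)
        k_hi = min(max(k_lo + 1, hi // bs), enrich.max_offset + 1)
        sums = np.zeros(max_count + 1)
        cnts = np.zeros(max_count + 1)
        for k in range(k_lo, k_hi):
            e = enrich.data[: n - k, k]
            ok = np.isfinite(e)
            if not ok.any():
                continue
            i = np.nonzero(ok)[0]
            if k >= 2:
                crossed = (cum[i + k - 1] - cum[i]).astype(int)
            else:
                crossed = np.zeros(i.size, dtype=int)
            crossed = np.minimum(crossed, max_count)
            sums += np.bincount(crossed, weights=e[i], minlength=max_count + 1)
            cnts += np.bincount(crossed, minlength=max_count + 1)
        with np.errstate(invalid="ignore"):
            means = sums / cnts
        overall = sums.sum() / cnts.sum() if cnts.sum() else np.nan
        cols[f"{lo}-{hi}"] = means - overall
    idx = [str(c) for c in range(max_count)] + [f"{max_count}+"]
    return pd.DataFrame(cols, index=pd.Index(idx, name="intervening_sites"))
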