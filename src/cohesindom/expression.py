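"""Transcriptional response to cohesin loss.

Per-gene responses are log2 fold changes of mean expression between
knockout and control, standardized robustly (median / 1.4826 * MAD) into
z-scores; genes beyond |z| > 2 are called deregulated.  Downstream
statistics relate the calls to cohesin/CTCF occupancy: enrichment of
deregulated genes by TSS-to-site distance, correlation of responses for
gene pairs sharing a cohesin-delimited interval versus pairs separated
by at least one site, and the trend of response against baseline
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr


@dataclass
class ProximityEnrichment:
    """Deregulated-vs-all composition by TSS distance to the nearest COH
    site; enrichment is 100 * (fraction ratio - 1) per category."""

    categories: list[str]
    frac_deregulated: np.ndarray
    frac_all: np.ndarray
    enrichment_pct: np.ndarray


@dataclass
class PairCorrelationResult:
    r_same_interval: float
    r_separated: float
    n_same: int
    n_separated: int
    difference_ci: tuple[float, float] | None = None


def response_zscores(
    expr_wt: pd.DataFrame,
    expr_ko: pd.DataFrame,
    z_threshold: float = 2.0,
    min_expression: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene knockout response table.

    Columns: ``wt_mean``, ``ko_mean``, ``delta`` = log2((ko + 1)/(wt + 1)),
    ``z`` (robust standardization of delta over included genes) and
    ``label`` in {up, down, minimal, excluded}; genes with both means
    below ``min_expression`` are excluded from standardization and calls.
    """
    if not expr_wt.index.equals(expr_ko.index):
        raise ValueError("wt and ko tables must index the same genes")
    if expr_wt.shape[1] < 1 or expr_ko.shape[1] < 1:
        raise ValueError("need at least one replicate per condition")
    wt_mean = expr_wt.mean(axis=1).to_numpy()
    ko_mean = expr_ko.mean(axis=1).to_numpy()
    delta = np.log2((ko_mean + pseudocount) / (wt_mean + pseudocount))
    included = (wt_mean >= min_expression) | (ko_mean >= min_expression)
    z = np.full(delta.size, np.nan)
    if included.sum() >= 2:
        med = np.median(delta[included])
        mad = np.median(np.abs(delta[included] - med))
        scale = 1.4826 * mad
        if scale > 0:
            z[included] = (delta[included] - med) / scale
        else:
            z[included] = 0.0
    label = np.where(
        ~included,
        "excluded",
        np.where(z > z_threshold, "up", np.where(z < -z_threshold, "down", "minimal")),
    )
    return pd.DataFrame(
        {
            "wt_mean": wt_mean,
            "ko_mean": ko_mean,
            "delta": delta,
            "z": z,
            "label": label,
        },
        index=expr_wt.index,
    )


def tss_proximity_enrichment(
    response: pd.DataFrame,
    tss: np.ndarray,
    sites: np.ndarray,
    cutoffs: tuple[int, int] = (1_000, 10_000),
) -> ProximityEnrichment:
    """Composition of deregulated genes by TSS-to-COH distance category
    (< 1 Kb, < 10 Kb, > 10 Kb by default), against the all-genes
    background (strand-independent distances)."""
    tss = np.asarray(tss)
    sites = np.sort(np.asarray(sites))
    if sites.size == 0:
        raise ValueError("no sites given")
    j = np.clip(np.searchsorted(sites, tss), 0, sites.size - 1)
    d = np.minimum(np.abs(sites[j] - tss), np.abs(tss - sites[np.maximum(j - 1, 0)]))
    cat = np.where(d < cutoffs[0], 0, np.where(d < cutoffs[1], 1, 2))
    included = (response["label"] != "excluded").to_numpy()
    dereg = response["label"].isin(["up", "down"]).to_numpy()
    if not dereg.any():
        raise ValueError("no deregulated genes")
    frac_all = np.bincount(cat[included], minlength=3) / included.sum()
    frac_der = np.bincount(cat[dereg], minlength=3) / dereg.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        enr = 100.0 * (frac_der / frac_all - 1.0)
    labels = [
        f"<{cutoffs[0] // 1000} Kb",
        f"<{cutoffs[1] // 1000} Kb",
        f">{cutoffs[1] // 1000} Kb",
    ]
    return ProximityEnrichment(
        categories=labels,
        frac_deregulated=frac_der,
        frac_all=frac_all,
        enrichment_pct=enr,
    )


def _gene_pairs(
    tss: np.ndarray, sep_range: tuple[int, int]
) -> np.ndarray:
    order = np.argsort(tss)
    pos = tss[order]
    lo, hi = sep_range
    out = []
    for a_idx in range(pos.size):
        j0 = np.searchsorted(pos, pos[a_idx] + lo, side="left")
        j1 = np.searchsorted(pos, pos[a_idx] + hi, side="left")
        for b_idx in range(j0, j1):
            out.append((order[a_idx], order[b_idx]))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def pair_response_correlation(
    response: pd.DataFrame,
    tss: np.ndarray,
    sites: np.ndarray,
    sep_range: tuple[int, int] = (100_000, 200_000),
    min_pairs: int = 30,
    n_boot: int = 1_000,
    seed: int = 0,
) -> PairCorrelationResult:
    """Pearson correlation of knockout-response z-scores for gene pairs
    with TSS separation in ``sep_range``, split by whether at least one
    COH site lies strictly between the TSSs.

    A bootstrap confidence interval (95%) for r(same) - r(separated) is
    attached; pairs are resampled independently within each set.
    """
    tss = np.asarray(tss)
    sites = np.sort(np.asarray(sites))
    z = response["z"].to_numpy()
    usable = np.isfinite(z)
    pairs = _gene_pairs(tss, sep_range)
    if pairs.size:
        pairs = pairs[usable[pairs[:, 0]] & usable[pairs[:, 1]]]
    left = np.minimum(tss[pairs[:, 0]], tss[pairs[:, 1]])
    right = np.maximum(tss[pairs[:, 0]], tss[pairs[:, 1]])
    n_between = np.searchsorted(sites, right, side="left") - np.searchsorted(
        sites, left, side="right"
    )
    same = n_between == 0
    groups = {}
    for name, sel in (("same", same), ("separated", ~same)):
        sub = pairs[sel]
        if sub.shape[0] < min_pairs:
            raise ValueError(
                f"only {sub.shape[0]} {name}-interval pairs (need {min_pairs})"
            )
        # left gene = smaller coordinate
        flip = tss[sub[:, 0]] > tss[sub[:, 1]]
        sub = np.where(flip[:, None], sub[:, ::-1], sub)
        groups[name] = (z[sub[:, 0]], z[sub[:, 1]])
    r_same = float(pearsonr(*groups["same"])[0])
    r_sep = float(pearsonr(*groups["separated"])[0])
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        diffs = np.empty(n_boot)
        xs, ys = groups["same"]
        xp, yp = groups["separated"]
        for b in range(n_boot):
            i = rng.integers(xs.size, size=xs.size)
            jj = rng.integers(xp.size, size=xp.size)
            with np.errstate(invalid="ignore"):
                rs = np.corrcoef(xs[i], ys[i])[0, 1]
                rp = np.corrcoef(xp[jj], yp[jj])[0, 1]
            diffs[b] = rs - rp
        ci = (
            float(np.nanpercentile(diffs, 2.5)),
            float(np.nanpercentile(diffs, 97.5)),
        )
    return PairCorrelationResult(
        r_same_interval=r_same,
        r_separated=r_sep,
        n_same=groups["same"][0].size,
        n_separated=groups["separated"][0].size,
        difference_ci=ci,
    )


def baseline_response_trend(response: pd.DataFrame, min_genes: int = 100):
    """Spearman correlation between baseline (wt mean) expression and the
    knockout log2 fold change.  Negative rho means highly expressed genes
    tend to be downregulated."""
    ok = (response["label"] != "excluded").to_numpy()
    if ok.sum() < min_genes:
        raise ValueError("too few expressed genes for a trend estimate")
    rho, p = spearmanr(
        response.loc[ok, "wt_mean"], response.loc[ok, "delta"]
    )
    return float(rho), float(p)
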