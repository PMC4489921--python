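"""Synthetic genome annotation: domains, binding sites, genes, loop anchors.

The genome is a single chromosome partitioned into megabase-scale
topological domains of two activity classes.  Cohesin/CTCF (COH) sites are
laid down with exponential spacing, denser in active domains; consecutive
intra-domain COH pairs (plus each domain's border-most pair) are designated
loop anchors.  Accessory site classes (CTCF without cohesin, cohesin
without CTCF, putative enhancers) are placed with no structural role so
that class-selectivity analyses have a matched negative control.  Genes
carry a baseline expression level and a planted knockout response that is
partially shared within each inter-COH-site interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig

SITE_CLASSES = ("COH", "CTCF_only", "COH_only", "ENH")


@dataclass
class GenomeModel:
    """Annotation of one synthetic chromosome.

    domains: per-domain ``start_bin``, ``end_bin`` (half-open), ``class``.
    sites:   per-site ``position`` (bp, strictly increasing), ``class``,
             ``domain`` (index, -1 for accessory classes outside the COH
             bookkeeping), sorted by position.
    genes:   per-gene ``tss``, ``strand``, ``baseline`` (log2 expected
             counts), ``planted_response`` (log2 ko-vs-wt shift),
             ``interval`` (index of the inter-COH interval).
    anchor_pairs: intra-domain COH pairs ``(a, b)`` in bp with ``domain``
             and a relative loop ``strength`` multiplying the condition's
             anchor enrichment.
    """

    config: SimConfig
    domains: pd.DataFrame
    sites: pd.DataFrame
    genes: pd.DataFrame
    anchor_pairs: pd.DataFrame

    # --- convenience accessors -------------------------------------------
    @property
    def bin_size(self) -> int:
        return self.config.bin_size

    @property
    def n_bins(self) -> int:
        return self.config.n_bins

    def domain_of_bin(self) -> np.ndarray:
        """Domain index for every bin."""
        out = np.empty(self.n_bins, dtype=np.int32)
        for idx, row in self.domains.iterrows():
            out[row.start_bin : row.end_bin] = idx
        return out

    def active_domain_mask(self) -> np.ndarray:
        return (self.domains["class"] == "active").to_numpy()

    @property
    def borders(self) -> np.ndarray:
        """Internal domain borders as bin indices (starts of domains 1..)."""
        return self.domains["start_bin"].to_numpy()[1:]

    def site_positions(self, cls: str = "COH") -> np.ndarray:
        return self.sites.loc[self.sites["class"] == cls, "position"].to_numpy()

    def coh_bins(self) -> np.ndarray:
        return self.site_positions("COH") // self.bin_size


def _draw_domains(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Partition the bin range into n_domains intervals, mean size L/n."""
    n = cfg.n_domains
    n_bins = cfg.n_bins
    min_bins = cfg.min_domain_size // cfg.bin_size
    if n == 1:
        sizes = np.array([n_bins])
    else:
        # gamma weights give realistic size dispersion around the mean
        w = rng.gamma(4.0, 1.0, size=n)
        free = n_bins - n * min_bins
        extra = np.floor(free * w / w.sum()).astype(int)
        extra[: free - extra.sum()] += 1
        sizes = min_bins + extra
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    classes = np.where(rng.random(n) < cfg.active_fraction, "active", "passive")
    if n >= 2:  # guarantee both classes exist so class contrasts are defined
        if (classes == "active").all():
            classes[rng.integers(n)] = "passive"
        elif (classes == "passive").all():
            classes[rng.integers(n)] = "active"
    return pd.DataFrame(
        {"start_bin": starts, "end_bin": starts + sizes, "class": classes}
    )


def _place_exponential(
    start: float, end: float, mean_gap: float, rng: np.random.Generator
) -> np.ndarray:
    """Positions of a Poisson point process on [start, end)."""
    pos = []
    x = start + rng.exponential(mean_gap)
    while x < end:
        pos.append(x)
        x += rng.exponential(mean_gap)
    return np.asarray(pos)


def build_genome(config: SimConfig) -> GenomeModel:
    """Draw a deterministic synthetic annotation from the config's seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    domains = _draw_domains(config, rng)
    bs = config.bin_size

    # COH sites, per domain, denser in active domains.  Every internal
    # domain border additionally carries a COH site: binding sites are
    # enriched at domain borders, and these border-most sites anchor the
    # domain-spanning ("skipping") loops.
    recs: list[tuple[int, str, int]] = []
    for idx, row in domains.iterrows():
        spacing = (
            config.site_spacing_active
            if row["class"] == "active"
            else config.site_spacing_passive
        )
        pos = _place_exponential(
            row.start_bin * bs, row.end_bin * bs, spacing, rng
        )
        recs += [(int(p), "COH", idx) for p in pos]
        if idx > 0:  # site at the domain's left border
            recs.append((int(row.start_bin * bs), "COH", idx))

    # accessory classes, genome-wide, kept clear of COH sites
    coh_pos = np.array(sorted(p for p, _, _ in recs))
    for cls, spacing in (
        ("CTCF_only", config.ctcf_only_spacing),
        ("COH_only", config.coh_only_spacing),
        ("ENH", config.enh_spacing),
    ):
        pos = _place_exponential(0, config.chromosome_length, spacing, rng)
        if coh_pos.size:
            near = np.searchsorted(coh_pos, pos)
            d_right = np.where(
                near < coh_pos.size, coh_pos[np.minimum(near, coh_pos.size - 1)] - pos, np.inf
            )
            d_left = np.where(near > 0, pos - coh_pos[np.maximum(near - 1, 0)], np.inf)
            pos = pos[np.minimum(d_left, d_right) > 2 * bs]
        recs += [(int(p), cls, -1) for p in pos]

    sites = pd.DataFrame(recs, columns=["position", "class", "domain"])
    sites = sites.sort_values("position", kind="mergesort").reset_index(drop=True)
    # enforce strictly increasing positions (collisions are ~impossible at
    # bp resolution but the invariant is cheap to guarantee)
    dup = sites["position"].diff().fillna(1) <= 0
    while dup.any():
        sites.loc[dup, "position"] += 1
        sites = sites.sort_values("position", kind="mergesort").reset_index(drop=True)
        dup = sites["position"].diff().fillna(1) <= 0

    anchor_pairs = _enumerate_anchor_pairs(sites, domains, config.loop_max_skip)
    genes = _plant_genes(config, sites, domains, rng)
    return GenomeModel(
        config=config,
        domains=domains,
        sites=sites,
        genes=genes,
        anchor_pairs=anchor_pairs,
    )


def _enumerate_anchor_pairs(
    sites: pd.DataFrame, domains: pd.DataFrame, max_skip: int
) -> pd.DataFrame:
    """Intra-domain COH pairs with at most ``max_skip`` intervening sites
    (consecutive and nested/skipping loops), plus each domain's
    border-most pair, all with unit relative strength."""
    rows = []
    coh = sites[sites["class"] == "COH"]
    for idx in domains.index:
        pos = coh.loc[coh["domain"] == idx, "position"].to_numpy()
        m = pos.size
        for ai in range(m):
            for bi in range(ai + 1, min(ai + max_skip + 2, m)):
                kind = "consecutive" if bi == ai + 1 else "nested"
                rows.append((int(pos[ai]), int(pos[bi]), idx, 1.0, kind))
        if m >= 3 and m - 1 > max_skip + 1:
            rows.append((int(pos[0]), int(pos[-1]), idx, 1.0, "border_skip"))
    return pd.DataFrame(rows, columns=["a", "b", "domain", "strength", "kind"])


def _plant_genes(
    config: SimConfig,
    sites: pd.DataFrame,
    domains: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Genes with TSS density elevated in active domains, baseline
    log-expression, and a planted knockout response."""
    n_genes = int(round(config.gene_density * config.chromosome_length / 1e6))
    bs = config.bin_size
    lengths = (domains["end_bin"] - domains["start_bin"]).to_numpy() * bs
    wts = lengths * np.where(
        domains["class"].to_numpy() == "active",
        config.active_gene_density_ratio,
        1.0,
    )
    dom_idx = rng.choice(len(domains), size=n_genes, p=wts / wts.sum())
    starts = domains["start_bin"].to_numpy() * bs
    tss = np.sort(
        (starts[dom_idx] + rng.random(n_genes) * lengths[dom_idx]).astype(np.int64)
    )
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)

    coh = sites.loc[sites["class"] == "COH", "position"].to_numpy()
    interval = np.searchsorted(coh, tss).astype(np.int32)
    if coh.size:
        j = np.clip(np.searchsorted(coh, tss), 0, coh.size - 1)
        d_right = np.abs(coh[j] - tss)
        d_left = np.abs(tss - coh[np.maximum(j - 1, 0)])
        nearest = np.minimum(d_left, d_right)
    else:
        nearest = np.full(n_genes, np.inf)

    # planted knockout response: shared latent effect per inter-COH interval
    # plus an independent part; direct large effects concentrated on
    # COH-proximal genes.  The shared weight is set analytically so the
    # same-interval response correlation hits the configured target after
    # accounting for the direct-effect variance.
    c = config.response_within_interval_corr
    sigma2 = config.interval_effect_sd**2
    proximal = nearest < config.proximal_distance
    p_direct = np.where(
        proximal, config.direct_fraction_proximal, config.direct_fraction_background
    )
    v_direct = float(np.mean(p_direct)) * config.direct_effect_size**2
    w2 = min(1.0, c * (sigma2 + v_direct) / sigma2) if sigma2 > 0 else 0.0
    w = math.sqrt(w2)

    latent = rng.normal(size=int(interval.max(initial=0)) + 1)
    eps = rng.normal(size=n_genes)
    shift = config.interval_effect_sd * (
        w * latent[interval] + math.sqrt(max(0.0, 1 - w2)) * eps
    )
    is_direct = rng.random(n_genes) < p_direct
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    shift = shift + np.where(is_direct, sign * config.direct_effect_size, 0.0)
    if config.baseline_coupling != 0.0:
        z_base = (baseline - config.baseline_mean) / max(config.baseline_sd, 1e-12)
        shift = shift - config.baseline_coupling * config.interval_effect_sd * z_base

    return pd.DataFrame(
        {
            "tss": tss,
            "strand": strand,
            "baseline": baseline,
            "planted_response": shift,
            "interval": interval,
            "coh_proximal": proximal,
            "direct": is_direct,
        }
    )
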