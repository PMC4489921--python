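"""Shared fixtures: one default-scale simulated study (wild type and
knockout), a structureless null map, and a small toy map for exact
brute-force comparisons.  Session scope keeps the expensive simulations
to a single run each."""

from __future__ import annotations

import numpy as np
import pytest

import cohesindom as cd


@pytest.fixture(scope="session")
def cfg() -> cd.SimConfig:
    """The default study configuration (seed 1)."""
    return cd.SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome(cfg):
    return cd.build_genome(cfg)


@pytest.fixture(scope="session")
def wt_counts(genome):
    return cd.simulate_contacts(genome, "wt")


@pytest.fixture(scope="session")
def ko_counts(genome):
    return cd.simulate_contacts(genome, "ko")


def _normalize(counts):
    decay = cd.estimate_distance_decay(counts)
    biases = cd.estimate_bin_biases(counts, decay)
    enrich = cd.compute_enrichment(counts, decay, biases)
    return {"decay": decay, "biases": biases, "enrich": enrich}


@pytest.fixture(scope="session")
def wt_norm(wt_counts):
    return _normalize(wt_counts)


@pytest.fixture(scope="session")
def ko_norm(ko_counts):
    return _normalize(ko_counts)


# --- structureless (null) map at full scale -------------------------------


@pytest.fixture(scope="session")
def null_cfg() -> cd.SimConfig:
    """Default geometry with every structural effect switched off."""
    return cd.SimConfig(
        seed=7,
        active_intensity_ratio=1.0,
        anchor_enrichment_wt=1.0,
        border_attenuation_wt=1.0,
        site_attenuation_wt=1.0,
    )


@pytest.fixture(scope="session")
def null_genome(null_cfg):
    return cd.build_genome(null_cfg)


@pytest.fixture(scope="session")
def null_norm(null_genome):
    counts = cd.simulate_contacts(null_genome, "wt")
    out = _normalize(counts)
    out["counts"] = counts
    return out


# --- toy map for exact oracle comparisons ---------------------------------


@pytest.fixture(scope="session")
def toy_cfg() -> cd.SimConfig:
    """200 bins at 10 Kb, small enough for dense brute-force loops."""
    return cd.SimConfig(
        seed=3,
        chromosome_length=2_000_000,
        bin_size=10_000,
        n_domains=3,
        max_distance=1_000_000,
        depth=300_000,
        site_spacing_active=80_000,
        site_spacing_passive=120_000,
        gene_density=30.0,
    )


@pytest.fixture(scope="session")
def toy_counts(toy_cfg):
    genome = cd.build_genome(toy_cfg)
    return cd.simulate_contacts(genome, "wt")


@pytest.fixture(scope="session")
def toy_norm(toy_counts):
    return _normalize(toy_counts)


def constant_enrichment(value: float, n_bins: int = 40, max_offset: int = 30,
                        bin_size: int = 2_000) -> cd.EnrichmentMatrix:
    """An EnrichmentMatrix holding a constant everywhere defined (no
    counts attached, so consumers fall back to mean-of-e aggregation)."""
    data = np.full((n_bins, max_offset + 1), np.nan)
    for k in range(1, max_offset + 1):
        data[: n_bins - k, k] = value
    return cd.EnrichmentMatrix(bin_size=bin_size, data=data)
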