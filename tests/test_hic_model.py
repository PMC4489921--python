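"""Decay estimation, bias correction, enrichment and difference maps."""

from __future__ import annotations

import numpy as np
import pytest

import cohesindom as cd
from cohesindom.contacts import ContactMatrix
from cohesindom.hic import GridMismatchError

from _oracles import (
    oracle_biases,
    oracle_decay,
    oracle_enrichment,
)


# --------------------------------------------------------------------------
# distance decay
# --------------------------------------------------------------------------


def test_decay_matches_dense_oracle(toy_counts, toy_norm):
    edges, f, f_of_k = oracle_decay(toy_counts.data, toy_counts.bin_size)
    decay = toy_norm["decay"]
    assert np.allclose(decay.edges, edges, rtol=0, atol=1e-9)
    assert np.allclose(decay.f, f, rtol=0, atol=1e-9)
    got = decay.f_of_offset()
    assert np.allclose(got[1:], f_of_k[1:], rtol=0, atol=1e-9)


def test_decay_linear_in_counts(toy_counts):
    doubled = ContactMatrix(toy_counts.bin_size, toy_counts.data * 2)
    f1 = cd.estimate_distance_decay(toy_counts).f
    f2 = cd.estimate_distance_decay(doubled).f
    assert np.allclose(f2, 2 * f1, rtol=1e-12)


def test_empty_counts_rejected():
    empty = ContactMatrix(2_000, np.zeros((50, 11), dtype=np.int64))
    with pytest.raises(ValueError, match="empty"):
        cd.estimate_distance_decay(empty)


def test_flat_intensity_gives_flat_curve():
    """Counts drawn with no distance dependence produce a flat f(d)."""
    rng = np.random.default_rng(0)
    n, K = 400, 120
    data = np.zeros((n, K + 1), dtype=np.int64)
    for k in range(1, K + 1):
        data[: n - k, k] = rng.poisson(30.0, n - k)
    fk = cd.estimate_distance_decay(ContactMatrix(2_000, data)).f_of_offset()[1:]
    assert fk.max() / fk.min() < 1.2


def test_decay_exponent_recovery_structure_off():
    """Log-log slope of f(d) recovers the planted exponent within 0.05,
    and the knockout estimate is the more negative one."""
    base = cd.SimConfig(
        seed=13,
        chromosome_length=20_000_000,
        n_domains=20,
        depth=7_000_000,
        active_intensity_ratio=1.0,
        anchor_enrichment_wt=1.0,
        anchor_enrichment_ko=1.0,
        border_attenuation_wt=1.0,
        border_attenuation_ko=1.0,
        site_attenuation_wt=1.0,
        site_attenuation_ko=1.0,
    )
    g = cd.build_genome(base)
    slope_wt = cd.estimate_distance_decay(
        cd.simulate_contacts(g, "wt")
    ).fit_exponent()
    slope_ko = cd.estimate_distance_decay(
        cd.simulate_contacts(g, "ko")
    ).fit_exponent()
    assert abs(slope_wt - base.decay_exponent_wt) < 0.05
    assert abs(slope_ko - base.decay_exponent_ko) < 0.05
    assert slope_ko < slope_wt


def test_ko_decay_sharper_on_default_maps(wt_counts, ko_counts):
    """On the full structured simulations the fitted knockout exponent is
    more negative than the wild-type one."""
    s_wt = cd.estimate_distance_decay(wt_counts).fit_exponent()
    s_ko = cd.estimate_distance_decay(ko_counts).fit_exponent()
    assert s_ko < s_wt


# --------------------------------------------------------------------------
# biases
# --------------------------------------------------------------------------


def test_biases_match_dense_oracle(toy_counts, toy_norm):
    b_ref, mask_ref = oracle_biases(
        toy_counts.data,
        np.nan_to_num(toy_norm["decay"].f_of_offset()),
        toy_counts.bin_size,
    )
    bias = toy_norm["biases"]
    assert np.array_equal(bias.mask, mask_ref)
    ok = ~bias.mask
    assert np.allclose(bias.b[ok], b_ref[ok], rtol=0, atol=1e-9)


def test_unbiased_input_yields_unit_biases():
    cfg = cd.SimConfig(
        seed=19,
        chromosome_length=10_000_000,
        n_domains=10,
        depth=8_000_000,
        max_distance=1_000_000,
        bias_sd=0.0,
        active_intensity_ratio=1.0,
        anchor_enrichment_wt=1.0,
        border_attenuation_wt=1.0,
        site_attenuation_wt=1.0,
    )
    counts = cd.simulate_contacts(cd.build_genome(cfg), "wt")
    decay = cd.estimate_distance_decay(counts)
    bias = cd.estimate_bin_biases(counts, decay)
    b = bias.b[~bias.mask]
    assert b.min() > 0.9 and b.max() < 1.1


def test_planted_bias_recovery(cfg, wt_norm):
    """log-biases recovered by IPF correlate with the planted truth at
    r > 0.9 (default depth)."""
    bias = wt_norm["biases"]
    truth = cd.planted_biases(cfg, "wt")
    ok = ~bias.mask
    r = np.corrcoef(np.log(bias.b[ok]), np.log(truth[ok]))[0, 1]
    assert r > 0.9
    assert bias.converged


def test_bias_equivariance_under_bin_reversal(toy_counts, toy_norm):
    """Reversing the chromosome (a relabelling that preserves bandedness)
    reverses the fitted biases; checked on the plain-IPF path."""
    n, K1 = toy_counts.data.shape
    rev = np.zeros_like(toy_counts.data)
    for k in range(K1):
        for i in range(n - k):
            rev[n - 1 - i - k, k] = toy_counts.data[i, k]
    fwd = cd.estimate_bin_biases(
        toy_counts, toy_norm["decay"], detrend_window=None
    )
    bwd = cd.estimate_bin_biases(
        ContactMatrix(toy_counts.bin_size, rev),
        cd.estimate_distance_decay(ContactMatrix(toy_counts.bin_size, rev)),
        detrend_window=None,
    )
    ok = ~fwd.mask
    assert np.array_equal(fwd.mask, bwd.mask[::-1])
    assert np.allclose(fwd.b[ok], bwd.b[::-1][ok], rtol=1e-9)


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------


def test_enrichment_matches_dense_oracle(toy_counts, toy_norm):
    e_ref, exp_ref = oracle_enrichment(
        toy_counts.data,
        toy_norm["biases"].b,
        np.nan_to_num(toy_norm["decay"].f_of_offset()),
    )
    e = toy_norm["enrich"]
    both = np.isfinite(e.data) & np.isfinite(e_ref)
    assert np.array_equal(np.isfinite(e.data), np.isfinite(e_ref))
    assert np.allclose(e.data[both], e_ref[both], rtol=0, atol=1e-9)


def test_counts_equal_to_expectation_give_zero_enrichment(toy_counts, toy_norm):
    """If observed counts exactly equal b_i b_j f(d), e vanishes."""
    decay, bias = toy_norm["decay"], toy_norm["biases"]
    fk = np.nan_to_num(decay.f_of_offset())
    n, K1 = toy_counts.data.shape
    exact = np.zeros((n, K1))
    b = np.nan_to_num(bias.b)
    for k in range(1, K1):
        exact[: n - k, k] = b[: n - k] * b[k:] * fk[k]
    e = cd.compute_enrichment(
        ContactMatrix(toy_counts.bin_size, exact), decay, bias
    )
    finite = np.isfinite(e.data)
    assert np.abs(e.data[finite]).max() < 1e-12


def test_enrichment_scale_invariance(toy_counts, toy_norm):
    """Multiplying all counts by k leaves e nearly unchanged (only the
    pseudocount breaks exact invariance) on well-covered cells."""
    scaled = ContactMatrix(toy_counts.bin_size, toy_counts.data * 4)
    decay = cd.estimate_distance_decay(scaled)
    bias = cd.estimate_bin_biases(scaled, decay)
    e2 = cd.compute_enrichment(scaled, decay, bias)
    e1 = toy_norm["enrich"]
    dense = (
        np.isfinite(e1.data)
        & np.isfinite(e2.data)
        & (np.nan_to_num(e1.expected) > 5)
        & (toy_counts.data > 5)
    )
    assert np.nanmax(np.abs(e1.data[dense] - e2.data[dense])) < 0.25
    assert np.nanmean(np.abs(e1.data[dense] - e2.data[dense])) < 0.05


def test_grid_mismatch_rejected(toy_counts, wt_norm):
    with pytest.raises(GridMismatchError):
        cd.compute_enrichment(
            toy_counts, wt_norm["decay"], wt_norm["biases"]
        )


def test_anchor_enrichment_beats_matched_background(genome, wt_norm):
    """Mean e at planted anchor cells exceeds mean e over distance-matched
    non-anchor cells."""
    e = wt_norm["enrich"].data
    bs = genome.bin_size
    n = e.shape[0]
    pairs = genome.anchor_pairs
    pairs = pairs[(pairs.b - pairs.a).between(100_000, 300_000)]
    diffs = []
    for a, b in pairs[["a", "b"]].itertuples(index=False):
        i, k = a // bs, (b - a) // bs
        if np.isfinite(e[i, k]):
            diffs.append(e[i, k] - np.nanmean(e[: n - k, k]))
    assert np.mean(diffs) > 0


# --------------------------------------------------------------------------
# delta maps
# --------------------------------------------------------------------------


def test_delta_identity_is_zero(toy_counts):
    dm = cd.delta_matrix(toy_counts, toy_counts)
    finite = np.isfinite(dm.data)
    assert np.abs(dm.data[finite]).max() < 1e-12


def test_delta_approximately_antisymmetric(toy_cfg):
    g = cd.build_genome(toy_cfg)
    a = cd.simulate_contacts(g, "wt")
    b = cd.simulate_contacts(g, "wt", toy_cfg.with_(seed=toy_cfg.seed + 1))
    d_ab = cd.delta_matrix(a, b).data
    d_ba = cd.delta_matrix(b, a).data
    both = np.isfinite(d_ab) & np.isfinite(d_ba)
    r = np.corrcoef(d_ab[both], -d_ba[both])[0, 1]
    assert r > 0.98
    assert abs(np.mean(d_ab[both] + d_ba[both])) < 0.02


def test_delta_grid_mismatch_rejected(toy_counts, wt_counts):
    with pytest.raises(GridMismatchError):
        cd.delta_matrix(wt_counts, toy_counts)


def test_ko_delta_redistribution(genome, wt_counts, ko_counts):
    """Cohesin loss depletes intra-domain contacts and gains
    adjacent-domain inter-domain contacts (< 2 Mb)."""
    dm = cd.delta_matrix(wt_counts, ko_counts)
    dom = genome.domain_of_bin()
    n, K1 = dm.data.shape
    intra_sum = intra_n = inter_sum = inter_n = 0.0
    for k in range(1, K1):
        d = dm.data[: n - k, k]
        ok = np.isfinite(d)
        same = dom[: n - k] == dom[k:]
        adjacent = (dom[k:] - dom[: n - k]) >= 1
        within = k * dm.bin_size < 2_000_000
        s1 = ok & same
        s2 = ok & adjacent & within
        intra_sum += d[s1].sum()
        intra_n += s1.sum()
        inter_sum += d[s2].sum()
        inter_n += s2.sum()
    assert intra_sum / intra_n < 0
    assert inter_sum / inter_n > 0
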