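"""Band insulation, meta-profiles, domain calling and site statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cohesindom as cd

from _oracles import oracle_insulation
from conftest import constant_enrichment


def _track80(norm):
    return cd.band_insulation_track(norm["enrich"], 80_000)


# --------------------------------------------------------------------------
# band insulation
# --------------------------------------------------------------------------


def test_constant_matrix_gives_constant_track():
    e = constant_enrichment(0.7, n_bins=60, max_offset=40)
    track = cd.band_insulation_track(e, 5 * e.bin_size, min_pairs=1)
    defined = np.isfinite(track.values)
    assert defined.any()
    assert np.allclose(track.values[defined], 0.7, atol=1e-12)


def test_band_must_be_wide_enough(toy_norm):
    with pytest.raises(ValueError):
        cd.band_insulation_track(toy_norm["enrich"], 2 * 10_000)


def test_insulation_matches_double_loop_oracle(toy_norm):
    """Both aggregation modes agree with an explicit double loop over the
    crossing square, cell for cell."""
    e = toy_norm["enrich"]
    wb = 6
    for mode in ("mean", "ratio"):
        track = cd.band_insulation_track(e, wb * e.bin_size, mode=mode)
        ref = oracle_insulation(
            e.data,
            wb,
            mode=mode,
            obs_banded=e.obs,
            exp_banded=e.expected,
            pseudocount=e.pseudocount,
        )
        both = np.isfinite(track.values) & np.isfinite(ref)
        assert np.array_equal(np.isfinite(track.values), np.isfinite(ref))
        assert np.allclose(track.values[both], ref[both], rtol=0, atol=1e-12)


def test_affine_shift_moves_mean_track_by_constant(toy_norm):
    e = toy_norm["enrich"]
    shifted = cd.EnrichmentMatrix(bin_size=e.bin_size, data=e.data + 0.5)
    t0 = cd.band_insulation_track(e, 60_000, mode="mean")
    t1 = cd.band_insulation_track(shifted, 60_000, mode="mean")
    both = np.isfinite(t0.values) & np.isfinite(t1.values)
    assert np.allclose(t1.values[both] - t0.values[both], 0.5, atol=1e-9)


def test_borders_are_insulation_minima(genome, wt_norm):
    """Mean insulation at planted borders sits below the domain-interior
    mean (80-Kb band)."""
    track = _track80(wt_norm)
    v = track.values
    borders = genome.borders
    interior = np.ones(v.size, bool)
    for b in borders:
        interior[max(0, b - 25) : b + 25] = False
    assert np.nanmean(v[borders]) < np.nanmean(v[interior])


# --------------------------------------------------------------------------
# meta-profiles
# --------------------------------------------------------------------------


def test_null_sites_show_no_insulation(null_genome, null_norm):
    """Uniformly placed sites on a structureless map give a flat profile."""
    rng = np.random.default_rng(2)
    sites = np.sort(rng.integers(0, null_genome.config.chromosome_length, 400))
    prof = cd.meta_insulation_profile(null_norm["enrich"], sites, [80_000])
    assert prof[80_000].peak_to_trough < 1.15


def test_coh_insulation_exceeds_threshold(genome, wt_norm):
    """Cohesin/CTCF anchors insulate at the 80-Kb band with a
    peak-to-trough ratio of at least 1.5."""
    prof = cd.meta_insulation_profile(
        wt_norm["enrich"], genome.site_positions("COH"), [80_000]
    )
    assert prof[80_000].peak_to_trough >= 1.5


def test_profile_equals_mean_of_per_site_tracks(genome, wt_norm):
    """P(o) equals the straightforward average of per-site track windows."""
    sites = genome.site_positions("COH")[:120]
    prof = cd.meta_insulation_profile(
        wt_norm["enrich"], sites, [40_000], min_sites=50
    )[40_000]
    track = cd.band_insulation_track(wt_norm["enrich"], 40_000)
    wb = 40_000 // track.bin_size
    bins = sites // track.bin_size
    bins = bins[np.isfinite(track.values[bins])]
    rows = []
    for s in bins:
        row = [
            track.values[s + o] if 0 <= s + o < track.values.size else np.nan
            for o in range(-2 * wb, 2 * wb + 1)
        ]
        rows.append(row)
    ref = np.nanmean(np.asarray(rows), axis=0)
    both = np.isfinite(prof.values) & np.isfinite(ref)
    assert np.allclose(prof.values[both], ref[both], atol=1e-12)


def test_too_few_sites_names_the_band(wt_norm):
    with pytest.raises(ValueError, match="80000"):
        cd.meta_insulation_profile(
            wt_norm["enrich"], np.array([1_000_000, 2_000_000]), [80_000]
        )


def test_accessory_site_classes_show_minimal_insulation(genome, wt_norm):
    """CTCF without cohesin and cohesin without CTCF lack the insulation
    signature that co-occupied sites carry."""
    coh = cd.meta_insulation_profile(
        wt_norm["enrich"], genome.site_positions("COH"), [80_000]
    )[80_000]
    assert coh.peak_to_trough > 1.5
    for cls in ("CTCF_only", "COH_only"):
        prof = cd.meta_insulation_profile(
            wt_norm["enrich"], genome.site_positions(cls), [80_000]
        )[80_000]
        assert prof.peak_to_trough < 1.15


def test_insulation_lost_after_knockout(genome, wt_norm, ko_norm):
    """COH-site peak-to-trough collapses in the knockout while randomly
    chosen non-site loci barely change."""
    coh = genome.site_positions("COH")
    wt = cd.meta_insulation_profile(wt_norm["enrich"], coh, [80_000])[80_000]
    ko = cd.meta_insulation_profile(ko_norm["enrich"], coh, [80_000])[80_000]
    assert ko.peak_to_trough < wt.peak_to_trough

    rng = np.random.default_rng(5)
    chrom_len = genome.config.chromosome_length
    rand = np.sort(rng.integers(0, chrom_len, 500))
    keep = np.min(
        np.abs(rand[:, None] - coh[None, :]), axis=1
    ) > 20_000
    rand = rand[keep]
    r_wt = cd.meta_insulation_profile(wt_norm["enrich"], rand, [80_000])[80_000]
    r_ko = cd.meta_insulation_profile(ko_norm["enrich"], rand, [80_000])[80_000]
    assert abs(r_ko.peak_to_trough - r_wt.peak_to_trough) / r_wt.peak_to_trough < 0.10


# --------------------------------------------------------------------------
# quartile grouping
# --------------------------------------------------------------------------


def test_tiny_ranking_partitions_one_two_one():
    track = cd.InsulationTrack(
        band=10_000,
        bin_size=2_000,
        values=np.array([0.4, np.nan, 0.1, np.nan, 0.3, np.nan, 0.2]),
        n_pairs=np.ones(7, dtype=np.int64),
    )
    groups = cd.group_sites_by_insulation(
        track, np.array([0, 4_000, 8_000, 12_000]) + 1_000
    )
    assert [len(groups[g]) for g in ("bottom", "middle", "top")] == [1, 2, 1]
    assert groups["bottom"][0] == 5_000  # lowest I = most insulating


def test_group_sizes_partition_n(genome, wt_norm):
    track = _track80(wt_norm)
    sites = genome.site_positions("COH")
    groups = cd.group_sites_by_insulation(track, sites)
    n = sum(len(g) for g in groups.values())
    assert abs(len(groups["bottom"]) - n / 4) <= 1
    assert abs(len(groups["top"]) - n / 4) <= 1
    assert abs(len(groups["middle"]) - n / 2) <= 1


def test_most_insulating_quartile_has_strongest_profile(genome, wt_norm):
    track = _track80(wt_norm)
    groups = cd.group_sites_by_insulation(track, genome.site_positions("COH"))
    ptt = {
        name: cd.meta_insulation_profile(
            wt_norm["enrich"], pos, [80_000]
        )[80_000].peak_to_trough
        for name, pos in groups.items()
    }
    assert ptt["bottom"] > ptt["top"]


# --------------------------------------------------------------------------
# domain calling and classification
# --------------------------------------------------------------------------


def _call(norm):
    coarse = cd.band_insulation_track(norm["enrich"], 640_000)
    fine = cd.band_insulation_track(norm["enrich"], 80_000)
    return cd.call_domains(coarse, refine_track=fine)


def test_monotone_track_has_no_borders():
    track = cd.InsulationTrack(
        band=640_000,
        bin_size=2_000,
        values=np.linspace(0, 1, 3_000),
        n_pairs=np.full(3_000, 100, dtype=np.int64),
    )
    ds = cd.call_domains(track)
    assert ds.borders.size == 0
    assert len(ds.domains) == 1


def test_structureless_map_yields_almost_no_borders(null_norm):
    ds = _call(null_norm)
    assert ds.borders.size <= 2  # per 60 Mb


def test_planted_borders_recovered(genome, wt_norm):
    """At least 80% of planted borders found within +/-2 bins; border-set
    Jaccard (at that tolerance) at least 0.8."""
    ds = _call(wt_norm)
    planted = genome.borders
    called = ds.borders
    dist = np.abs(planted[:, None] - called[None, :])
    matched = (dist.min(axis=1) <= 2).sum()
    assert matched / planted.size >= 0.8
    jaccard = matched / (planted.size + called.size - matched)
    assert jaccard >= 0.8


def test_domain_classes_recovered(genome, wt_norm):
    """Two-feature k-means recovers at least 90% of planted activity
    classes, labelling the TSS-dense cluster active."""
    unlabelled = genome.domains.assign(**{"class": None})
    ds = cd.classify_domain_activity(
        wt_norm["enrich"], unlabelled, genome.genes["tss"].to_numpy()
    )
    agree = (
        ds.domains["class"].to_numpy() == genome.domains["class"].to_numpy()
    ).mean()
    assert agree >= 0.9
    assert not ds.degenerate


def test_classification_order_invariant(genome, wt_norm):
    tss = genome.genes["tss"].to_numpy()
    base = cd.classify_domain_activity(
        wt_norm["enrich"], genome.domains, tss
    ).domains
    shuffled = genome.domains.sample(frac=1.0, random_state=4)
    perm = cd.classify_domain_activity(
        wt_norm["enrich"], shuffled, tss
    ).domains
    pd.testing.assert_series_equal(base["class"], perm["class"])


def test_identical_domains_flagged_degenerate():
    e = constant_enrichment(0.0, n_bins=400, max_offset=100)
    domains = pd.DataFrame(
        {
            "start_bin": np.arange(0, 400, 100),
            "end_bin": np.arange(100, 500, 100),
            "class": [None] * 4,
        }
    )
    ds = cd.classify_domain_activity(e, domains, np.array([], dtype=int))
    assert ds.degenerate


def test_activity_intensity_ratio_near_two(genome, wt_norm):
    """Pooled intra-domain intensity at 60-180 Kb separations is about
    two-fold higher in active than passive domains."""
    ratio = cd.class_intensity_ratio(wt_norm["enrich"], genome.domains)
    assert 1.6 < ratio < 2.4


# --------------------------------------------------------------------------
# spacing statistics
# --------------------------------------------------------------------------


def _two_domain_frame(split_bin: int, end_bin: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_bin": [0, split_bin],
            "end_bin": [split_bin, end_bin],
            "class": ["active", "passive"],
        }
    )


def test_identical_spacings_give_zero_D():
    spacing = np.array([5_000, 7_000, 9_000] * 10)
    active = np.cumsum(np.concatenate([[10_000], spacing]))
    passive = np.cumsum(np.concatenate([[1_010_000], spacing]))
    domains = _two_domain_frame(500, 1_500)
    sites = np.concatenate([active, passive])
    sc = cd.adjacent_spacing_ks(sites, domains, 2_000, min_per_class=5)
    assert sc.D == pytest.approx(0.0, abs=1e-12)


def test_disjoint_spacings_give_unit_D():
    active = np.cumsum([10_000] + [1_000] * 30)
    passive = np.cumsum([1_010_000] + [30_000] * 30)
    domains = _two_domain_frame(500, 1_500)
    sc = cd.adjacent_spacing_ks(
        np.concatenate([active, passive]), domains, 2_000, min_per_class=5
    )
    assert sc.D == pytest.approx(1.0)


def test_spacing_distributions_differ_by_class(genome):
    """Active-domain spacings are stochastically shorter; the KS test
    rejects equality decisively on the default genome."""
    sc = cd.adjacent_spacing_ks(
        genome.site_positions("COH"), genome.domains, genome.bin_size
    )
    assert sc.D > 0
    assert sc.pvalue < 0.01


# --------------------------------------------------------------------------
# intervening-site curve
# --------------------------------------------------------------------------


def test_no_sites_collapses_to_centered_zero(toy_norm):
    curve = cd.intervening_site_curve(
        toy_norm["enrich"], np.array([], dtype=int), [(100_000, 300_000)]
    )
    col = curve.iloc[:, 0]
    assert col.iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert col.iloc[1:].isna().all()


def test_intervening_curve_matches_brute_force(toy_norm, toy_cfg):
    e = toy_norm["enrich"]
    rng = np.random.default_rng(8)
    sites = np.sort(rng.integers(0, toy_cfg.chromosome_length, 25))
    stratum = (100_000, 400_000)
    curve = cd.intervening_site_curve(e, sites, [stratum], max_count=4)
    bs = e.bin_size
    site_bins = np.sort(sites // bs)
    n, K1 = e.data.shape
    sums = np.zeros(5)
    cnts = np.zeros(5)
    for k in range(stratum[0] // bs, min(stratum[1] // bs, K1 - 1)):
        for i in range(n - k):
            v = e.data[i, k]
            if not np.isfinite(v):
                continue
            crossed = int(((site_bins > i) & (site_bins <= i + k - 1)).sum())
            crossed = min(crossed, 4)
            sums[crossed] += v
            cnts[crossed] += 1
    means = sums / np.where(cnts > 0, cnts, np.nan)
    ref = means - sums.sum() / cnts.sum()
    got = curve.iloc[:, 0].to_numpy()
    both = np.isfinite(got) & np.isfinite(ref)
    assert np.allclose(got[both], ref[both], atol=1e-12)


def test_enrichment_decreases_with_intervening_sites(genome, wt_norm):
    """Within each distance stratum, mean relative enrichment falls
    monotonically with the number of intervening COH sites."""
    from scipy.stats import spearmanr

    curve = cd.intervening_site_curve(
        wt_norm["enrich"],
        genome.site_positions("COH"),
        [(50_000, 100_000), (100_000, 200_000)],
    )
    for col in curve.columns:
        v = curve[col].to_numpy()[:6]
        rho = spearmanr(np.arange(v.size), v).statistic
        assert rho < 0
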