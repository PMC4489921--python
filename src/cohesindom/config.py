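"""Simulation configuration.

The defaults define a single 60-Mb chromosome partitioned into ~1-Mb
topological domains of two activity classes, decorated with cohesin/CTCF
(COH) sites that anchor intra-domain loops and insulate crossing contacts.
They encode the effect sizes the analysis is designed to recover: a
two-fold active/passive intra-domain intensity ratio, a two-fold
cohesin-dependent anchor-pair enrichment that vanishes in the knockout,
partial domain-border attenuation that relaxes after cohesin loss, and a
sharper knockout distance decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    # genome geometry
    chromosome_length: int = 60_000_000  # bp
    bin_size: int = 2_000  # bp; the finest analysis scale
    n_domains: int = 60
    active_fraction: float = 0.5
    min_domain_size: int = 400_000  # bp

    # cohesin/CTCF site placement (mean spacing of exponential gaps, bp)
    site_spacing_active: int = 60_000
    site_spacing_passive: int = 90_000
    # accessory site classes (no structural effect on contacts)
    ctcf_only_spacing: int = 250_000
    coh_only_spacing: int = 350_000
    enh_spacing: int = 200_000

    # contact-structure multipliers, per condition
    decay_exponent_wt: float = -1.0
    decay_exponent_ko: float = -1.15
    anchor_enrichment_wt: float = 2.0
    anchor_enrichment_ko: float = 1.0
    border_attenuation_wt: float = 0.5
    border_attenuation_ko: float = 0.75
    # multiplicative attenuation of contacts per crossed COH site, quoted
    # for sites in passive domains; active-domain sites are rescaled so the
    # per-bp insulation rate (1 - a) / spacing matches across classes and
    # the planted activity ratio stays unconfounded.
    site_attenuation_wt: float = 0.4
    site_attenuation_ko: float = 0.85
    site_attenuation_max: int = 6  # cap on effective crossed-site count
    # COH-site insulation is a local effect: it attenuates crossing
    # contacts only up to this separation, while domain borders act at
    # all scales (sites shape their local contact environment; borders
    # demarcate domains).
    site_insulation_range: int = 300_000  # bp
    # loops are planted between intra-domain COH pairs separated by at
    # most this many intervening sites (0 = consecutive only), plus each
    # domain's border-most pair; nested/skipping loops are what loop
    # extrusion between flanking sites produces.
    loop_max_skip: int = 3
    active_intensity_ratio: float = 2.0

    # technical model
    bias_sd: float = 0.3  # sd of log-normal per-bin bias
    depth: int = 20_000_000  # expected read pairs within the band
    max_distance: int = 3_000_000  # bp; contacts stored up to this separation

    # 4C
    fourc_depth: int = 1_000_000
    fourc_exclusion: int = 10_000  # bp around the viewpoint

    # expression
    gene_density: float = 20.0  # genes per Mb, chromosome-wide
    active_gene_density_ratio: float = 3.0  # active/passive TSS density
    n_replicates: int = 3
    replicate_noise_sd: float = 0.25  # log2 units
    interval_effect_sd: float = 0.5  # log2 units, sd of planted ko shifts
    response_within_interval_corr: float = 0.4
    direct_effect_size: float = 3.0  # |log2 shift| of direct responders
    direct_fraction_proximal: float = 0.25
    direct_fraction_background: float = 0.01
    proximal_distance: int = 1_000  # bp, TSS-to-COH "at the TSS" cutoff
    baseline_mean: float = 5.0  # log2 expected counts
    baseline_sd: float = 2.0
    baseline_coupling: float = 0.0  # >0 plants mean-reverting responses

    seed: int = 0

    def __post_init__(self) -> None:
        if self.chromosome_length % self.bin_size != 0:
            raise ConfigurationError("bin_size must divide chromosome_length")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ConfigurationError("active_fraction must lie in [0, 1]")
        for name in (
            "anchor_enrichment_wt",
            "anchor_enrichment_ko",
            "active_intensity_ratio",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in (
            "border_attenuation_wt",
            "border_attenuation_ko",
            "site_attenuation_wt",
            "site_attenuation_ko",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        if self.n_domains < 1:
            raise ConfigurationError("n_domains must be >= 1")
        if self.chromosome_length < self.n_domains * self.min_domain_size:
            raise ConfigurationError(
                "chromosome too short for n_domains at min_domain_size"
            )
        if self.max_distance < 10 * self.bin_size:
            raise ConfigurationError("max_distance too small")

    @property
    def n_bins(self) -> int:
        return self.chromosome_length // self.bin_size

    @property
    def max_offset(self) -> int:
        """Largest stored diagonal offset, in bins."""
        return min(self.max_distance // self.bin_size, self.n_bins - 1)

    def condition(self, label: str) -> "ConditionParams":
        """Resolve the structural parameters for a condition label."""
        if label == "wt":
            return ConditionParams(
                label="wt",
                decay_exponent=self.decay_exponent_wt,
                anchor_enrichment=self.anchor_enrichment_wt,
                border_attenuation=self.border_attenuation_wt,
                site_attenuation=self.site_attenuation_wt,
            )
        if label == "ko":
            return ConditionParams(
                label="ko",
                decay_exponent=self.decay_exponent_ko,
                anchor_enrichment=self.anchor_enrichment_ko,
                border_attenuation=self.border_attenuation_ko,
                site_attenuation=self.site_attenuation_ko,
            )
        raise ValueError(f"unknown condition {label!r}; expected 'wt' or 'ko'")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with fields replaced (invariants re-checked)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConditionParams:
    """Structural multipliers of one experimental condition."""

    label: str
    decay_exponent: float
    anchor_enrichment: float
    border_attenuation: float
    site_attenuation: float
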