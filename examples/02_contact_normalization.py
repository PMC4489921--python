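"""Normalize a contact map: distance decay, per-bin biases, enrichment.

Shows that the estimated decay exponent, the fitted technical biases and
the observed/expected enrichment recover what the simulation planted.
"""

import numpy as np

import cohesindom as cd

cfg = cd.SimConfig(chromosome_length=20_000_000, n_domains=20, depth=7_000_000, seed=0)
genome = cd.build_genome(cfg)
counts = cd.simulate_contacts(genome, "wt")

decay = cd.estimate_distance_decay(counts)
biases = cd.estimate_bin_biases(counts, decay)
enrich = cd.compute_enrichment(counts, decay, biases)

slope = decay.fit_exponent()
truth = cd.planted_biases(cfg, "wt")
ok = ~biases.mask
r = np.corrcoef(np.log(biases.b[ok]), np.log(truth[ok]))[0, 1]

print(f"fitted decay exponent: {slope:.3f} "
      f"(planted marginal exponent {cfg.decay_exponent_wt}; border attenuation"
      " steepens the fit slightly)")
print(f"bias recovery: r(log b_est, log b_true) = {r:.3f} over {ok.sum()} bins"
      f" ({biases.mask.sum()} low-coverage bins masked)")
ratio = cd.class_intensity_ratio(enrich, genome.domains)
print(f"active/passive intra-domain intensity at 60-180 Kb: {ratio:.2f}-fold")
print("The two-fold activity contrast survives bias correction because the")
print("correction removes bin-scale technical factors, not domain structure.")
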