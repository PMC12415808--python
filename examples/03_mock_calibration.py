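"""Estimate amplification efficiencies from a mock community and calibrate.

Simulates triplicate sequencing of a 26-species mock community, estimates
per-cycle log-ratio efficiencies (alpha) against the reference species
under both concentration bases, and uses the template-basis estimates to
correct a sample's composition back to its pre-PCR proportions.
"""

import numpy as np

from ampbias import (
    calibrate_sample,
    estimate_efficiencies,
    load_primer_panel,
    summarize_bias,
)
from ampbias.synthetic_data import SimulationConfig, generate_community, generate_experiment

cfg = SimulationConfig(seed=42)
_, truth = generate_community(cfg)
panel = load_primer_panel()
reads, truth = generate_experiment(truth, panel, taqs=["NPHF"], markers=["MarVer1"])

for basis in ("template", "gDNA"):
    ests = estimate_efficiencies(
        truth.mock(basis), reads, n_cycles=cfg.n_cycles,
        reference_species=cfg.reference_species,
    )
    bias = summarize_bias(ests)
    print(f"{basis:>8} basis: mean |alpha| = {bias['mean_abs_alpha'].iloc[0]:.4f} "
          f"+/- {bias['sd_abs_alpha'].iloc[0]:.4f}  ({bias['n_species'].iloc[0]} species)")
# The template (ddPCR) basis yields smaller |alpha| for this perfect-match
# marker: apparent "bias" under the gDNA basis is mostly the species-varying
# mtDNA share of each extract, not PCR.

ests = estimate_efficiencies(
    truth.mock("template"), reads, n_cycles=cfg.n_cycles,
    reference_species=cfg.reference_species,
)
sample = reads.counts.iloc[:, 0].values
res = calibrate_sample(sample, reads.species, ests, n_cycles=cfg.n_cycles, seed=1)
true_p = truth.mock("template").expected_proportions
print(f"max |calibrated - true| proportion: {np.max(np.abs(res.proportions - true_p)):.4f}")
print(f"max |raw        - true| proportion: {np.max(np.abs(sample / sample.sum() - true_p)):.4f}")
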