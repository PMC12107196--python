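#!/usr/bin/env python
"""Generate the synthetic ED presentation registry.

Draws the 510-code universe (four admission-risk tiers, Zipf-like
frequencies) and 200,000 ambulatory presentations with calibrated
covariates, then writes the registry to scratch/registry.csv (it is large
and fully reproducible from the seed, so it lives outside results/).
"""

from pathlib import Path

import numpy as np

from edrisk import simulate

SEED = 1
ROOT = Path(__file__).resolve().parents[1]

cfg = simulate.SimulationConfig(seed=SEED)
universe = simulate.generate_code_universe(cfg)
records = simulate.generate_presentations(universe, cfg)

out = ROOT / "scratch" / "registry.csv"
out.parent.mkdir(exist_ok=True)
simulate.write_registry(records, out)

tier_sizes = np.bincount(universe.tier)[1:]
print(f"registry: {len(records):,} presentations over {len(universe)} codes -> {out}")
print(f"tier sizes (codes):        {tier_sizes.tolist()}")
print(f"tier mean baseline risks:  "
      f"{[round(float(universe.true_risk[universe.tier == t].mean()), 3) for t in range(1, 5)]}")
print(f"marginal admission rate:   {records['admitted'].mean():.3f}")
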