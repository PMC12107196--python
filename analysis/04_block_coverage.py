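#!/usr/bin/env python
"""Reduce clustered codes to WHO ICD-10 blocks and rank by coverage.

Maps every presentation to its block, computes the cumulative-coverage
curve (how many top-frequency blocks account for 60-100% of presentations),
identifies blocks with >= 75% of presentations in a single cluster, and
exports the block-by-cluster heatmap matrix. Outputs under results/.
"""

import json
from pathlib import Path

import pandas as pd

from edrisk import blocks, cluster

ROOT = Path(__file__).resolve().parents[1]
THRESHOLDS = (0.6, 0.7, 0.8, 0.9, 1.0)

clean = pd.read_csv(ROOT / "scratch" / "registry_clean.csv")
risks = pd.read_csv(ROOT / "results" / "code_risks.csv")
clean["cluster"] = clean["icd10"].map(dict(zip(risks["code"], risks["cluster"])))

defs = blocks.parse_block_table()
mapped = blocks.assign_blocks(clean, defs)
summaries = blocks.summarize_blocks(mapped, defs)
print(f"{len(summaries)} nonempty ICD-10 blocks cover {len(mapped):,} presentations")

curve = blocks.cumulative_coverage(summaries, THRESHOLDS)
curve.to_frame().to_csv(ROOT / "results" / "coverage.csv", index=False)
for t in THRESHOLDS:
    print(f"  {int(t * 100):>3}% coverage: {curve.blocks_at_threshold[t]:>3} blocks")

dom, info = blocks.dominant_blocks(summaries, 0.75, registry_total=len(mapped))
with open(ROOT / "results" / "dominant_blocks.json", "w") as fh:
    json.dump({"summary": info, "blocks": dom.to_dict(orient="records")}, fh, indent=2)
print(f"\nblocks with >=75% of presentations in one cluster: {info['n_blocks']} "
      f"({info['n_presentations']:,} presentations, {info['share_percent']}% of sample)")
for lab in sorted(dom["dominant_cluster"].unique()):
    sub, sub_info = blocks.dominant_blocks(summaries, 0.75, cluster=lab,
                                           registry_total=len(mapped))
    print(f"  cluster {lab}: {sub_info['n_blocks']:>3} blocks, "
          f"{sub_info['share_percent']}% of sample")

heat = blocks.heatmap_matrix(summaries, 0.8, defs)
heat.to_csv(ROOT / "results" / "heatmap_matrix.csv")
print(f"\nheatmap matrix: {heat.shape[0]} top-80% blocks x "
      f"{heat.shape[1] - 1} clusters -> results/heatmap_matrix.csv")
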