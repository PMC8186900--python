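#!/usr/bin/env python
"""PERMANOVA on a simulated four-gene expression panel (5 vs 13 samples).

Emulates a small qPCR panel of pathway target genes where single-gene tests
are underpowered but the joint multivariate shift is clear: group B carries
a 2-SD downshift on every feature.  Also reports the null rejection rate of
the permutation test.  Writes permanova.tsv under results/.
"""

import sys
from pathlib import Path

from panelburden.config import load_config
from panelburden.io import write_results
from panelburden.pipeline import permanova_table
from panelburden.simulate import simulate_expression_panel
from panelburden.validation import permanova_null_rejection

ROOT = Path(__file__).resolve().parent.parent / "results"

panel = simulate_expression_panel(
    (5, 13), [-2.0, -2.0, -2.0, -2.0], noise_sd=1.0, seed=2026,
    feature_names=["Hey1", "Heyl", "Ptch1", "Gli1"],
)
cfg = load_config(None, seed=2026)
table = permanova_table(cfg, panel=panel)
write_results(table, ROOT / "permanova.tsv", provenance=cfg.provenance("permanova"))
row = table.iloc[0]
print(f"Joint shift detected: pseudo-F={row['pseudo_F']:.2f}, "
      f"p={row['p_value']:.4f} over {row['n_permutations']} permutations", file=sys.stderr)

rate = permanova_null_rejection(n_replicates=200, seed=2026)
print(f"Null rejection rate at alpha=0.05 over 200 replicates: {rate:.3f}", file=sys.stderr)
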