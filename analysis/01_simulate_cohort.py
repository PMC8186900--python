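#!/usr/bin/env python
"""Generate the synthetic case-control panel cohort used by the later steps.

The default world mirrors the motivating cohort's scale — 298 cases, 220
controls, 104 panel genes, ~1560 exonic variants — with one gene (GENE001)
planted at 10% case vs 1% control carrier rates of rare damaging variants,
plus planted QC violations of every kind so step 02 has something to catch.
Writes the VCF, annotation, phenotype and truth tables under results/cohort/.
"""

import sys
from pathlib import Path

from panelburden.simulate import CohortSimConfig, PlantedGene, simulate_cohort_files

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

cfg = CohortSimConfig(
    planted=(PlantedGene("GENE001", case_carrier_rate=0.10, control_carrier_rate=0.01),),
    n_low_call_sites=5,
    n_hwe_violating_sites=3,
    n_diff_missing_sites=3,
    n_multiallelic_sites=3,
    seed=2026,
)

paths = simulate_cohort_files(cfg, OUT)
for name, path in paths.items():
    print(f"{name}\t{path}", file=sys.stderr)
print(f"Simulated {cfg.n_cases}+{cfg.n_controls} samples over {cfg.n_genes} genes "
      f"with planted enrichment in GENE001 and 14 planted QC violations.", file=sys.stderr)
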