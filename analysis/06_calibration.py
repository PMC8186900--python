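#!/usr/bin/env python
"""Operating characteristics of the burden test: null calibration and power.

Runs 200 replicated null cohorts (298/220 samples, 57 testable genes) and
200 replicates with one gene planted at 10% vs 1% carrier rates, reporting
FDR control, per-gene type-I error, power and ranking.  Writes
burden_calibration.tsv under results/.  Takes ~30 s.
"""

import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from panelburden.io import write_results
from panelburden.validation import null_burden_calibration, planted_burden_power

ROOT = Path(__file__).resolve().parent.parent / "results"

cal = null_burden_calibration(n_replicates=200, seed=2026)
power = planted_burden_power(n_replicates=200, seed=2027)

table = pd.DataFrame([{**asdict(cal), "experiment": "null"},
                      {**asdict(power), "experiment": "planted_10x"}])
write_results(table, ROOT / "burden_calibration.tsv")

print(f"Null ({cal.n_replicates} cohorts): any q<0.20 in {cal.any_q_discovery_rate:.1%} of "
      f"replicates (BH target <=20%); per-gene p<0.05 rate "
      f"{cal.per_gene_rejection_rate:.2%} (discrete Fisher is conservative)", file=sys.stderr)
print(f"Planted 10x gene: q<0.20 in {power.q_discovery_rate:.1%} of replicates; "
      f"ranks first in {power.rank_first_rate:.1%}", file=sys.stderr)
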