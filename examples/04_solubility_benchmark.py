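"""Full cycle on the three benchmark compounds from published table values.

Runs the pipeline on the table-replay inputs (sublimation enthalpies and
entropies; four hydration models per compound) and prints the resulting
log10 S0 (mol/L) next to experiment.
"""

from solcycle import run_pipeline
from solcycle.fixtures import TABLE_REPLAY, table_replay_config

for compound in TABLE_REPLAY:
    cfg = table_replay_config(compound)
    expt = cfg.experimental["logS0"]
    print(f"{compound}  (expt logS0 = {expt})")
    for r in run_pipeline(cfg):
        print(f"  {r.hydration_method:<30s} logS0 = {r.logS0:7.2f}"
              f"   (expt - calcd = {expt - r.logS0:+.2f})")
    print()

print("A +1 error in logS0 is a 10-fold overestimate of solubility; the")
print("hydration model dominates the spread within each compound block.")
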