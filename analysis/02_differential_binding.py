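"""Spike-in normalized differential CTCF binding, MUT vs WT.

Runs the pipeline's ChIP stage and reports the global binding shift
(median log2FC across all peaks) next to what naive total-count
normalization would have concluded, plus recovery of the planted
enhanced-peak subset. Table: results/02_differential_binding.tsv.
"""

from pathlib import Path

import numpy as np

from loopshift import counts as cs
from loopshift.pipeline import load_config, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

if __name__ == "__main__":
    res = run_pipeline(load_config(overrides={"seed": SEED}))
    table = res["chip"]["table"]
    table.to_csv(OUT / "02_differential_binding.tsv", sep="\t", index=False)

    cm = res["bundle"]["chip"]
    disp = table["dispersion"].to_numpy()
    naive = cs.nb_wald_test(cm, cs.total_count_factors(cm.counts), disp)
    truth = set(res["bundle"]["truth"]["enhanced_peak_ids"])
    planted = table["feature"].isin(truth)

    print(f"peaks tested: {len(table)}")
    print(f"spike-in normalized median log2FC (global shift): "
          f"{table['log2FC'].median():.3f}")
    print(f"total-count normalized median log2FC (shift erased): "
          f"{naive['log2FC'].median():.3f}")
    print(f"enhanced at FDR<0.05: {res['chip']['n_enhanced']}, "
          f"weakened: {res['chip']['n_weakened']}")
    rec = (table.loc[planted, 'label'] == 'enhanced').mean()
    print(f"planted enhanced-peak recovery: {rec:.2%} of {planted.sum()}")
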