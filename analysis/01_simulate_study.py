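"""Generate the synthetic two-condition study and write it to disk.

Produces the full text-format study under results/01_simulation/: gene
models, enhancers, cohesin anchors, CTCF peaks, spike-in ChIP counts,
replicate Hi-C contact matrices for both conditions, RNA counts, and the
planted ground truth (ground_truth.json).
"""

from pathlib import Path

from loopshift.simulate import SimulationConfig, simulate_all, write_simulation

OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulation"
SEED = 1

if __name__ == "__main__":
    bundle = simulate_all(SimulationConfig(), seed=SEED)
    write_simulation(bundle, OUT)
    truth = bundle["truth"]
    print(f"wrote study (seed={SEED}) to {OUT}")
    print(f"  genes: {len(bundle['annotation']['genes'])}, "
          f"peaks: {len(bundle['peaks'])}, "
          f"loops: {len(bundle['annotation']['loops'])} "
          f"({len(truth['strengthened_loop_ids'])} strengthened, "
          f"{len(truth['weakened_loop_ids'])} weakened)")
    print(f"  planted enhanced peaks: {len(truth['enhanced_peak_ids'])}, "
          f"coupled target genes: {len(truth['target_gene_ids'])} "
          f"({len(truth['up_gene_ids'])} up-regulated)")
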