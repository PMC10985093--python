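"""Seeded synthetic two-condition study with planted ground truth.

Generates a toy genome (two chromosomes) carrying gene models, enhancers,
and cohesin anchors; two-condition × two-replicate ChIP peak counts with
exogenous spike-in totals and a planted global binding shift; replicate
Hi-C contact matrices with distance decay, checkerboard A/B compartments,
block contact domains, and focal loops whose strengths differ between
conditions; and gene expression counts coupled to strengthened-loop
anchors. Every planted feature is recorded in a ground-truth bundle so the
analysis modules can be scored for recovery.

Counts are hierarchical gamma–Poisson: a per-feature latent level with
gamma (negative-binomial) feature-to-feature variation, then Poisson
sampling per replicate at its configured depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .counts import CountMatrix
from .hic import ContactMatrix

__all__ = ["SimulationConfig", "simulate_annotation", "simulate_chip",
           "simulate_hic", "simulate_expression", "simulate_all",
           "write_simulation"]

CHIP_SAMPLES = ["WT_1", "WT_2", "MUT_1", "MUT_2"]
CONDITIONS = pd.Series(["WT", "WT", "MUT", "MUT"], index=CHIP_SAMPLES)


@dataclass
class SimulationConfig:
    """Defaults define the simulated study conditions; see docs/methods.md."""

    genome: tuple[tuple[str, int], ...] = (("chr1", 20_000_000), ("chr2", 10_000_000))
    hic_resolution: int = 50_000
    comp_resolution: int = 250_000
    n_genes: int = 1000
    n_peaks: int = 2000
    n_enhancers: int = 600
    n_loops: int = 60
    loop_strength: float = 3.0
    frac_strengthened: float = 0.15
    frac_weakened: float = 0.15
    strengthen_ratio: float = 2.0
    weaken_ratio: float = 0.5
    frac_enhanced_peaks: float = 0.15
    enhanced_peak_fold: float = 2.0
    global_binding_factor: float = 1.3
    chip_mean: float = 200.0
    chip_dispersion: float = 0.05
    chip_depths: tuple[float, ...] = (1.0, 1.1, 0.95, 1.05)
    spike_truth: float = 100_000.0
    rna_mean: float = 500.0
    rna_dispersion: float = 0.02
    rna_depths: tuple[float, ...] = (1.0, 1.05, 0.95, 1.0)
    concordance: float = 0.65
    up_gene_fold: float = 3.0
    comp_a: float = 0.3
    tad_boost: float = 0.5
    decay_scale: float = 100_000.0
    hic_base: float = 150.0
    hic_depths: tuple[float, ...] = (1.0, 0.9, 1.0, 1.1)
    promoter_upstream: int = 3000
    genes_per_strengthened_anchor: int = 12
    anchor_enhanced_prob: float = 1.0
    anchor_cohesin_prob: float = 0.6

    def genome_spec(self) -> iv.GenomeSpec:
        return iv.GenomeSpec(chroms=tuple((c, int(l)) for c, l in self.genome))

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome_spec().length(chrom) // self.hic_resolution)


def _chrom_quota(cfg: SimulationConfig, total: int) -> dict[str, int]:
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    quota = np.floor(total * lengths / lengths.sum()).astype(int)
    quota[0] += total - quota.sum()
    return {c: int(q) for (c, _), q in zip(cfg.genome, quota)}


def simulate_annotation(cfg: SimulationConfig, seed: int) -> dict:
    """Toy genome annotation plus the planted-structure skeleton.

    Places compartment blocks, contact domains, loops (a subset of which sit
    exactly on domain boundaries), gene models (with promoter clusters on
    the left anchors of strengthened loops), enhancers (forced onto the
    right anchors of strengthened loops, never overlapping promoters), and
    cohesin anchors marking insulator candidates.
    """
    rng = np.random.default_rng(seed)
    genome = cfg.genome_spec()
    res = cfg.hic_resolution
    comp_factor = cfg.comp_resolution // res

    ab_labels: dict[str, np.ndarray] = {}
    domains: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in cfg.genome:
        n_comp = -(-length // cfg.comp_resolution)
        labels = np.empty(n_comp, dtype="U1")
        pos, lab = 0, rng.choice(["A", "B"])
        while pos < n_comp:
            block = int(rng.integers(4, 9))
            labels[pos:pos + block] = lab
            pos += block
            lab = "A" if lab == "B" else "B"
        ab_labels[chrom] = labels
        n = cfg.n_bins(chrom)
        edges = [0]
        while edges[-1] < n:
            edges.append(min(n, edges[-1] + int(rng.integers(6, 17))))
        domains[chrom] = list(zip(edges[:-1], edges[1:]))

    # loops: ~2/3 on domain boundaries (loop-domain substrate), rest free pairs
    quota = _chrom_quota(cfg, cfg.n_loops)
    margin = 12  # keep anchors clear of chromosome edges (APA window)
    loop_rows: list[tuple[str, int, int, bool]] = []
    for chrom, _ in cfg.genome:
        n = cfg.n_bins(chrom)
        placed: list[tuple[int, int]] = []

        def free(b1: int, b2: int) -> bool:
            return all(max(abs(b1 - x1), abs(b2 - x2)) >= 5 for x1, x2 in placed)

        eligible = [(a, b) for a, b in domains[chrom]
                    if b - a >= 12 and a >= margin and b <= n - margin]
        rng.shuffle(eligible)
        q = quota[chrom]
        n_dom = min(len(eligible), (2 * q) // 3)
        for a, b in eligible[:n_dom]:
            if free(a, b):
                loop_rows.append((chrom, a, b, True))
                placed.append((a, b))
        attempts = 0
        while len(placed) < q:
            attempts += 1
            if attempts > 200 * max(q, 1):
                raise ValueError(f"cannot place {q} loops on {chrom}: "
                                 "requested density is infeasible")
            b1 = int(rng.integers(margin, n - margin - 12))
            gap = int(rng.integers(12, 61))
            b2 = b1 + gap
            if b2 > n - margin or not free(b1, b2):
                continue
            loop_rows.append((chrom, b1, b2, False))
            placed.append((b1, b2))
    loops = pd.DataFrame(loop_rows, columns=["chrom", "bin1", "bin2", "on_domain"])
    loops["loop_id"] = [f"L{k:03d}" for k in range(len(loops))]

    n_str = int(round(cfg.frac_strengthened * len(loops)))
    n_wk = int(round(cfg.frac_weakened * len(loops)))
    order = rng.permutation(len(loops))
    labels = np.array(["stable"] * len(loops), dtype=object)
    labels[order[:n_str]] = "strengthened"
    labels[order[n_str:n_str + n_wk]] = "weakened"
    loops["truth_label"] = labels

    # genes: promoter clusters on strengthened-loop left anchors, rest uniform
    gene_rows = []
    cluster_genes: dict[str, list[str]] = {}
    gid = 0
    # keep strengthened anchor bins free of random genes: the right anchor
    # must stay promoter-free (enhancer side), the left holds only the cluster
    forbidden_bins: set[tuple[str, int]] = set()
    for _, lp in loops[loops["truth_label"] == "strengthened"].iterrows():
        forbidden_bins.add((lp["chrom"], int(lp["bin2"])))
        forbidden_bins.add((lp["chrom"], int(lp["bin1"])))
        anchor_start = int(lp["bin1"]) * res
        ids = []
        for k in range(cfg.genes_per_strengthened_anchor):
            tss = anchor_start + 3500 + 4000 * k
            gene_rows.append((lp["chrom"], tss, tss + 2000, "+", f"gene_{gid:04d}"))
            ids.append(f"gene_{gid:04d}")
            gid += 1
        cluster_genes[lp["loop_id"]] = ids
    attempts = 0
    while gid < cfg.n_genes:
        attempts += 1
        if attempts > 100 * cfg.n_genes:
            raise ValueError("cannot place requested genes: density infeasible")
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        glen = int(rng.integers(2000, 20000))
        start = int(rng.integers(cfg.promoter_upstream, length - glen))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + glen
        if (chrom, tss // res) in forbidden_bins:
            continue
        gene_rows.append((chrom, start, start + glen, strand, f"gene_{gid:04d}"))
        gid += 1
    genes = pd.DataFrame(gene_rows, columns=iv.GENE_COLUMNS)
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    promoters = iv.promoters_from_genes(genes, upstream=cfg.promoter_upstream,
                                        genome=genome)

    # enhancers: forced onto strengthened right anchors, rest random non-promoter
    enh_rows = []
    for _, lp in loops[loops["truth_label"] == "strengthened"].iterrows():
        a2 = int(lp["bin2"]) * res
        enh_rows.append((lp["chrom"], a2 + 20_000, a2 + 21_500))
    n_random_enh = cfg.n_enhancers - len(enh_rows)
    attempts = 0
    prom_trees = promoters
    while n_random_enh > 0 and attempts < 50 * cfg.n_enhancers:
        attempts += 1
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        width = int(rng.integers(800, 2000))
        start = int(rng.integers(0, length - width))
        enh_rows.append((chrom, start, start + width))
        n_random_enh -= 1
    enh = iv.make_intervals(*zip(*enh_rows))
    enhancers = iv.define_enhancers(enh, prom_trees).reset_index(drop=True)
    enhancers["name"] = [f"enh_{k:04d}" for k in range(len(enhancers))]

    # cohesin anchors over a subset of loop anchors plus random sites
    coh_rows = []
    for _, lp in loops.iterrows():
        for bcol in ("bin1", "bin2"):
            if rng.random() < cfg.anchor_cohesin_prob:
                s = int(lp[bcol]) * res + 24_000
                coh_rows.append((lp["chrom"], s, s + 2_500))
    for _ in range(200):
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        start = int(rng.integers(0, length - 2_000))
        coh_rows.append((chrom, start, start + 2_000))
    cohesin = iv.make_intervals(*zip(*coh_rows))
    cohesin["name"] = [f"coh_{k:04d}" for k in range(len(cohesin))]

    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "promoters": promoters,
        "enhancers": enhancers,
        "cohesin": cohesin,
        "loops": loops,
        "ab_labels": ab_labels,
        "domains": domains,
        "cluster_genes": cluster_genes,
    }


def simulate_chip(cfg: SimulationConfig, ann: dict, seed: int
                  ) -> tuple[pd.DataFrame, CountMatrix, dict]:
    """ChIP peaks with two-condition × two-replicate counts and spike totals.

    Peaks sit on every loop anchor, on a subset of promoters, and at random
    sites. MUT multiplies a planted subset of peaks by the enhanced fold and
    every peak by the global binding factor; spike totals are exactly
    proportional to the configured depths (equal spike truth across
    conditions), so spike normalization exposes the global shift.
    """
    rng = np.random.default_rng(seed)
    res = cfg.hic_resolution
    loops = ann["loops"]
    genes = ann["genes"]

    rows = []
    anchor_peaks: dict[tuple[str, str], int] = {}  # (loop_id, side) -> peak index
    for _, lp in loops.iterrows():
        for side, bcol in (("left", "bin1"), ("right", "bin2")):
            center = int(lp[bcol]) * res + 25_000 + int(rng.integers(-5000, 5001))
            anchor_peaks[(lp["loop_id"], side)] = len(rows)
            rows.append((lp["chrom"], center - 200, center + 200))
    n_prom_peaks = min(len(genes), int(0.3 * cfg.n_peaks))
    prom_genes = genes.iloc[rng.choice(len(genes), n_prom_peaks, replace=False)]
    for _, g in prom_genes.iterrows():
        if g["strand"] == "+":
            c = int(g["tss"]) - 1500
        else:
            c = int(g["tss"]) + 1500
        rows.append((g["chrom"], max(0, c - 200), c + 200))
    genome = ann["genome"]
    while len(rows) < cfg.n_peaks:
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        start = int(rng.integers(0, length - 400))
        rows.append((chrom, start, start + 400))
    peaks = iv.make_intervals(*zip(*rows))
    peaks["name"] = [f"peak_{k:04d}" for k in range(len(peaks))]

    # planted enhanced subset: strengthened-loop anchor peaks w.h.p., then random fill
    n_enh = int(round(cfg.frac_enhanced_peaks * cfg.n_peaks))
    enhanced = np.zeros(len(peaks), dtype=bool)
    enhanced_anchor_loops: set[str] = set()
    for (loop_id, side), pk in anchor_peaks.items():
        row = loops.loc[loops["loop_id"] == loop_id].iloc[0]
        if row["truth_label"] == "strengthened" and rng.random() < cfg.anchor_enhanced_prob:
            enhanced[pk] = True
            enhanced_anchor_loops.add(loop_id)
    remaining = n_enh - int(enhanced.sum())
    pool = np.nonzero(~enhanced)[0]
    if remaining > 0:
        enhanced[rng.choice(pool, remaining, replace=False)] = True

    alpha = cfg.chip_dispersion
    mu = np.exp(rng.normal(np.log(cfg.chip_mean), 0.5, len(peaks)))
    level_wt = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    level_mut = level_wt * cfg.global_binding_factor
    level_mut = level_mut * np.where(enhanced, cfg.enhanced_peak_fold, 1.0)

    counts = {}
    for s, depth in zip(CHIP_SAMPLES, cfg.chip_depths):
        lvl = level_wt if s.startswith("WT") else level_mut
        counts[s] = rng.poisson(lvl * depth)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=peaks["name"].to_numpy()),
        conditions=CONDITIONS.copy(),
        spike_totals=pd.Series(
            [cfg.spike_truth * d for d in cfg.chip_depths], index=CHIP_SAMPLES),
    )
    truth = {
        "enhanced_peak_ids": sorted(peaks["name"][enhanced]),
        "anchor_peaks": {f"{lid}:{side}": peaks["name"].iloc[pk]
                         for (lid, side), pk in anchor_peaks.items()},
        "enhanced_anchor_loops": sorted(enhanced_anchor_loops),
        "global_binding_factor": cfg.global_binding_factor,
    }
    return peaks, cm, truth


def _loop_kernel(strength: float) -> np.ndarray:
    """3×3 multiplicative focal-loop kernel with the given center height."""
    off = np.arange(-1, 2)
    g = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2 * 0.7 ** 2))
    return 1.0 + (strength - 1.0) * g


def hic_truth_intensity(cfg: SimulationConfig, ann: dict, chrom: str,
                        condition: str) -> np.ndarray:
    """Noise-free contact intensity for one chromosome and condition."""
    res = cfg.hic_resolution
    n = cfg.n_bins(chrom)
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    lam = cfg.hic_base / (1.0 + d * res / cfg.decay_scale)

    comp_factor = cfg.comp_resolution // res
    labels = np.repeat(ann["ab_labels"][chrom], comp_factor)[:n]
    same = labels[:, None] == labels[None, :]
    lam *= np.where(same, 1.0 + cfg.comp_a, 1.0 - cfg.comp_a)

    dom_id = np.zeros(n, dtype=int)
    for k, (a, b) in enumerate(ann["domains"][chrom]):
        dom_id[a:b] = k
    lam *= np.where(dom_id[:, None] == dom_id[None, :], 1.0 + cfg.tad_boost, 1.0)

    for _, lp in ann["loops"][ann["loops"]["chrom"] == chrom].iterrows():
        strength = cfg.loop_strength
        if condition == "MUT":
            if lp["truth_label"] == "strengthened":
                strength *= cfg.strengthen_ratio
            elif lp["truth_label"] == "weakened":
                strength *= cfg.weaken_ratio
        K = _loop_kernel(strength)
        b1, b2 = int(lp["bin1"]), int(lp["bin2"])
        lam[b1 - 1:b1 + 2, b2 - 1:b2 + 2] *= K
        lam[b2 - 1:b2 + 2, b1 - 1:b1 + 2] *= K.T
    return lam


def simulate_hic(cfg: SimulationConfig, ann: dict, seed: int
                 ) -> dict[str, dict[str, ContactMatrix]]:
    """Per-sample, per-chromosome Poisson contact matrices around the truth."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, ContactMatrix]] = {}
    for s, depth in zip(CHIP_SAMPLES, cfg.hic_depths):
        cond = "WT" if s.startswith("WT") else "MUT"
        out[s] = {}
        for chrom, _ in cfg.genome:
            lam = hic_truth_intensity(cfg, ann, chrom, cond)
            n = lam.shape[0]
            upper = rng.poisson(np.triu(lam) * depth)
            mat = upper + np.triu(upper, 1).T
            out[s][chrom] = ContactMatrix(chrom=chrom, resolution=cfg.hic_resolution,
                                          counts=mat.astype(float))
    return out


def simulate_expression(cfg: SimulationConfig, ann: dict, chip_truth: dict,
                        seed: int) -> tuple[CountMatrix, dict]:
    """Gene counts with up-regulation coupled to strengthened-loop anchors.

    Genes in the promoter clusters of strengthened loops that carry an
    enhanced anchor peak are up-regulated (fold ``up_gene_fold``) with
    probability ``concordance``; every other gene is null.
    """
    rng = np.random.default_rng(seed)
    genes = ann["genes"]
    target_ids: list[str] = []
    for lid in chip_truth["enhanced_anchor_loops"]:
        target_ids.extend(ann["cluster_genes"].get(lid, []))
    target_ids = sorted(set(target_ids))
    up = [g for g in target_ids if rng.random() < cfg.concordance]

    alpha = cfg.rna_dispersion
    mu = np.exp(rng.normal(np.log(cfg.rna_mean), 1.0, len(genes)))
    level_wt = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    fold = np.where(genes["gene_id"].isin(up), cfg.up_gene_fold, 1.0)
    level_mut = level_wt * fold

    counts = {}
    for s, depth in zip(CHIP_SAMPLES, cfg.rna_depths):
        lvl = level_wt if s.startswith("WT") else level_mut
        counts[s] = rng.poisson(lvl * depth)
    cm = CountMatrix(counts=pd.DataFrame(counts, index=genes["gene_id"].to_numpy()),
                     conditions=CONDITIONS.copy())
    truth = {"target_gene_ids": target_ids, "up_gene_ids": sorted(up),
             "concordance": cfg.concordance}
    return cm, truth


def simulate_all(cfg: SimulationConfig | None = None, seed: int = 0) -> dict:
    """Run all four generator stages with decoupled per-stage seeds."""
    cfg = cfg or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    s_ann, s_chip, s_hic, s_expr = [int(c.generate_state(1)[0] % (2 ** 31))
                                    for c in ss.spawn(4)]
    ann = simulate_annotation(cfg, s_ann)
    peaks, chip, chip_truth = simulate_chip(cfg, ann, s_chip)
    hic = simulate_hic(cfg, ann, s_hic)
    expr, expr_truth = simulate_expression(cfg, ann, chip_truth, s_expr)

    loops = ann["loops"]
    truth = {
        "seed": seed,
        "strengthened_loop_ids": sorted(loops.loc[loops["truth_label"] == "strengthened", "loop_id"]),
        "weakened_loop_ids": sorted(loops.loc[loops["truth_label"] == "weakened", "loop_id"]),
        "loops": loops[["loop_id", "chrom", "bin1", "bin2", "truth_label", "on_domain"]]
        .to_dict(orient="records"),
        "ab_labels": {c: "".join(v) for c, v in ann["ab_labels"].items()},
        "domain_boundaries": {c: [int(b) for _, b in doms[:-1]]
                              for c, doms in ann["domains"].items()},
        **chip_truth,
        **expr_truth,
    }
    return {"config": cfg, "annotation": ann, "peaks": peaks, "chip": chip,
            "hic": hic, "expression": expr, "truth": truth}


def write_simulation(bundle: dict, outdir: str | Path) -> None:
    """Write the generated study in the text formats the analysis reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ann = bundle["annotation"]
    iv.write_genes(ann["genes"], out / "genes.tsv")
    iv.write_bed(ann["enhancers"], out / "enhancers.bed")
    iv.write_bed(ann["cohesin"], out / "cohesin_anchors.bed")
    iv.write_bed(bundle["peaks"], out / "ctcf_peaks.bed")
    bundle["chip"].to_tsv(out / "chip_counts.tsv", out / "chip_samples.tsv")
    bundle["expression"].to_tsv(out / "rna_counts.tsv", out / "rna_samples.tsv")
    genome = ann["genome"]
    for sample, per_chrom in bundle["hic"].items():
        for chrom, m in per_chrom.items():
            m.write_coo(out / f"hic_{sample}_{chrom}.coo",
                        length=genome.length(chrom))
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle["truth"], fh, indent=1, sort_keys=True)
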