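"""End-to-end orchestration: simulate → ChIP differential → Hi-C core →
loops/domains/APA → integrative statistics → JSON report.

Every stage is a plain function over the in-memory bundle so drivers, the
CLI, and tests can run any prefix of the pipeline; `run_pipeline` chains
them and emits a versioned, byte-deterministic `report.json` plus per-table
TSVs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import intervals as iv
from . import hic as hx
from . import loops as lp
from . import integrate as ig
from .counts import CountMatrix, differential_analysis
from .simulate import SimulationConfig, simulate_all, write_simulation

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline",
           "stage_chip", "stage_hic", "stage_loops", "stage_integrate"]

REPORT_VERSION = 1

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {},
    "chip": {"q_max": 0.05, "min_fold": 1.0},
    "rna": {"p_max": 0.05, "min_fold": 2.0},
    "hic": {"scc_smooth_h": 1, "scc_max_dist": 5_000_000},
    "loops": {
        "fdr": 0.1, "peak_width": 1, "donut_width": 5, "max_dist": 5_000_000,
        "pad": 1, "q_max": 0.05, "apa_window": 5, "insulation_window": 4,
        "domain_min_depth": 0.3, "slack": 1, "dedup_bins": 2,
    },
    "integration": {"n_perm": 1000, "overlap_mode": "anchors"},
}


# minimal structural schema for report.json: section -> required keys
REPORT_SCHEMA = {
    "version": int,
    "seed": int,
    "chip": {"n_peaks": int, "n_enhanced": int, "n_weakened": int},
    "hic": {"compartment_r_wt_vs_mut": dict, "scc_replicate": float,
            "scc_cross_condition": float},
    "loops": {"n_called_wt": int, "n_called_mut": int, "n_union": int,
              "n_strengthened": int, "n_weakened": int,
              "n_merged_loop_domains": int},
    "integration": {"n_ctcf_related": int},
    "recovery": dict,
}


def validate_report(report: dict) -> None:
    """Raise ValueError if the report lacks required sections/keys/types."""

    def check(schema, obj, path):
        if isinstance(schema, dict):
            if not isinstance(obj, dict):
                raise ValueError(f"report[{path}] should be a mapping")
            for key, sub in schema.items():
                if key not in obj:
                    raise ValueError(f"report missing {path}.{key}")
                check(sub, obj[key], f"{path}.{key}")
        elif schema is float:
            if not isinstance(obj, (int, float)):
                raise ValueError(f"report[{path}] should be numeric")
        elif not isinstance(obj, schema):
            raise ValueError(f"report[{path}] should be {schema.__name__}")

    check(REPORT_SCHEMA, report, "$")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override dict."""
    import copy
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def deep_update(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                deep_update(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        import yaml
        with open(path) as fh:
            deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        deep_update(cfg, overrides)
    return cfg


def stage_chip(bundle: dict, cfg: dict) -> dict:
    """Spike-in normalized differential binding over all peaks."""
    table = differential_analysis(bundle["chip"], normalization="spike",
                                  q_max=cfg["chip"]["q_max"],
                                  min_fold=cfg["chip"]["min_fold"])
    peaks = bundle["peaks"]
    enhanced = peaks[table["label"].to_numpy() == "enhanced"].reset_index(drop=True)
    return {"table": table, "enhanced_peaks": enhanced,
            "n_enhanced": int((table["label"] == "enhanced").sum()),
            "n_weakened": int((table["label"] == "weakened").sum())}


def _pooled_matrices(bundle: dict) -> dict[str, dict[str, hx.ContactMatrix]]:
    """Sum replicate matrices per condition; balance each pooled matrix."""
    pooled: dict[str, dict[str, hx.ContactMatrix]] = {}
    samples = list(bundle["hic"])
    for cond in ("WT", "MUT"):
        pooled[cond] = {}
        members = [s for s in samples if s.startswith(cond)]
        for chrom in bundle["hic"][members[0]]:
            total = sum(bundle["hic"][s][chrom].counts for s in members)
            m = hx.ContactMatrix(chrom=chrom,
                                 resolution=bundle["hic"][members[0]][chrom].resolution,
                                 counts=total)
            hx.ice_balance(m)
            pooled[cond][chrom] = m
    return pooled


def _promoter_density(promoters: pd.DataFrame, genome: iv.GenomeSpec,
                      comp_resolution: int, chrom: str) -> np.ndarray:
    n = -(-genome.length(chrom) // comp_resolution)
    dens = np.zeros(n)
    sub = promoters[promoters["chrom"] == chrom]
    mids = ((sub["start"] + sub["end"]) // 2) // comp_resolution
    np.add.at(dens, mids.to_numpy().astype(int), 1.0)
    return dens


def stage_hic(bundle: dict, cfg: dict) -> dict:
    """Pooled matrices, contact probability, compartments, reproducibility."""
    sim_cfg: SimulationConfig = bundle["config"]
    genome = bundle["annotation"]["genome"]
    promoters = bundle["annotation"]["promoters"]
    pooled = _pooled_matrices(bundle)

    rcp = {cond: {c: hx.relative_contact_probability(m)
                  for c, m in per.items()} for cond, per in pooled.items()}
    comp: dict[str, dict[str, np.ndarray]] = {"WT": {}, "MUT": {}}
    comp_r: dict[str, float] = {}
    for chrom, _ in sim_cfg.genome:
        ref = _promoter_density(promoters, genome, sim_cfg.comp_resolution, chrom)
        for cond in ("WT", "MUT"):
            comp[cond][chrom] = hx.compartment_score(
                pooled[cond][chrom], sim_cfg.comp_resolution, reference=ref)
        comp_r[chrom] = hx.compare_compartments(comp["WT"][chrom], comp["MUT"][chrom])

    samples = list(bundle["hic"])
    chrom0 = sim_cfg.genome[0][0]
    h, md = cfg["hic"]["scc_smooth_h"], cfg["hic"]["scc_max_dist"]
    wt = [s for s in samples if s.startswith("WT")]
    mut = [s for s in samples if s.startswith("MUT")]
    scc_rep = hx.scc(bundle["hic"][wt[0]][chrom0], bundle["hic"][wt[1]][chrom0],
                     smooth_h=h, max_dist=md)["scc"]
    scc_cross = hx.scc(bundle["hic"][wt[0]][chrom0], bundle["hic"][mut[0]][chrom0],
                       smooth_h=h, max_dist=md)["scc"]
    return {"pooled": pooled, "rcp": rcp, "compartments": comp,
            "compartment_r": comp_r, "scc_replicate": float(scc_rep),
            "scc_cross": float(scc_cross)}


def _dedup_loops(frames: list[pd.DataFrame], dedup_bins: int) -> pd.DataFrame:
    """Union of per-condition calls: same-anchor loops (within tolerance)
    collapse to the strongest pixel."""
    allloops = pd.concat(frames, ignore_index=True)
    out_rows = []
    for chrom, sub in allloops.groupby("chrom"):
        sub = sub.reset_index(drop=True)
        n = len(sub)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        b1 = sub["bin1"].to_numpy()
        b2 = sub["bin2"].to_numpy()
        for i in range(n):
            for j in range(i + 1, n):
                if abs(b1[i] - b1[j]) <= dedup_bins and abs(b2[i] - b2[j]) <= dedup_bins:
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            best = max(members, key=lambda k: sub.loc[k, "observed"])
            row = sub.loc[best].copy()
            row["provenance"] = ",".join(sorted(set(sub.loc[members, "condition"])))
            out_rows.append(row)
    out = pd.DataFrame(out_rows).sort_values(["chrom", "bin1", "bin2"])
    return out.reset_index(drop=True)


def stage_loops(bundle: dict, cfg: dict, hic_stage: dict) -> dict:
    """Loop calls per condition, union set, domains, loop domains, APA,
    and the differential loop table."""
    sim_cfg: SimulationConfig = bundle["config"]
    L = cfg["loops"]
    pooled = hic_stage["pooled"]

    calls = {}
    for cond in ("WT", "MUT"):
        per = []
        for chrom, m in pooled[cond].items():
            c = lp.call_loops(m, fdr=L["fdr"], peak_width=L["peak_width"],
                              donut_width=L["donut_width"], max_dist=L["max_dist"])
            per.append(c)
        calls[cond] = pd.concat(per, ignore_index=True)
        calls[cond]["condition"] = cond
    union = _dedup_loops([calls["WT"], calls["MUT"]], L["dedup_bins"])

    # insulation domains and loop domains per condition, then merge
    loop_domains = {}
    domains = {}
    for cond in ("WT", "MUT"):
        per_ld = []
        per_dom = {}
        for chrom, m in pooled[cond].items():
            ins = lp.insulation_scores(m, window=L["insulation_window"])
            dom = lp.call_domains(ins, min_depth=L["domain_min_depth"])
            per_dom[chrom] = dom
            ld = lp.identify_loop_domains(
                dom, calls[cond][calls[cond]["chrom"] == chrom], slack=L["slack"])
            ld["chrom"] = chrom
            per_ld.append(ld)
        domains[cond] = per_dom
        loop_domains[cond] = pd.concat(per_ld, ignore_index=True)
    merged_parts = []
    for chrom, _ in sim_cfg.genome:
        a = loop_domains["WT"][loop_domains["WT"]["chrom"] == chrom]
        b = loop_domains["MUT"][loop_domains["MUT"]["chrom"] == chrom]
        mg = lp.merge_loop_domains(a, b, slack=L["slack"], provenance=("WT", "MUT"))
        mg["chrom"] = chrom
        merged_parts.append(mg)
    merged_domains = pd.concat(merged_parts, ignore_index=True)

    # per-sample pixel counts on the union loop set -> differential loops
    diff_parts = []
    offset = 0
    per_chrom_tables = []
    for chrom, _ in sim_cfg.genome:
        sub = union[union["chrom"] == chrom].reset_index(drop=True)
        if len(sub) == 0:
            continue
        mats = {s: bundle["hic"][s][chrom] for s in bundle["hic"]}
        cm = lp.loop_pixel_counts(mats, sub, bundle["chip"].conditions, pad=L["pad"])
        cm.counts.index = [f"{chrom}:{b1}-{b2}" for b1, b2 in zip(sub["bin1"], sub["bin2"])]
        table = lp.differential_loops(cm, q_max=L["q_max"])
        per_chrom_tables.append(table)
    diff_table = pd.concat(per_chrom_tables, ignore_index=True)
    union = union.reset_index(drop=True)
    union["diff_label"] = diff_table["label"].to_numpy()
    union["log2FC"] = diff_table["log2FC"].to_numpy()
    union["diff_qvalue"] = diff_table["qvalue"].to_numpy()

    # label merged loop domains by their supporting loops' differential labels
    dom_labels = []
    for _, d in merged_domains.iterrows():
        sub = union[(union["chrom"] == d["chrom"])
                    & (np.abs(union["bin1"] - d["start_bin"]) <= L["slack"] + L["dedup_bins"])
                    & (np.abs(union["bin2"] - d["end_bin"]) <= L["slack"] + L["dedup_bins"])]
        labels = set(sub["diff_label"]) - {"ns"}
        dom_labels.append(sorted(labels)[0] if labels else "ns")
    merged_domains["diff_label"] = dom_labels

    # APA of strengthened union loops: WT vs MUT pooled matrices
    apa_res = {}
    strengthened = union[union["diff_label"] == "strengthened"]
    if len(strengthened) >= 3:
        scores = {"WT": [], "MUT": []}
        agg = {}
        for cond in ("WT", "MUT"):
            per_scores = []
            mats_sum = 0.0
            n_used = 0
            for chrom, _ in sim_cfg.genome:
                sub = strengthened[strengthened["chrom"] == chrom]
                if len(sub) == 0:
                    continue
                res = lp.apa(pooled[cond][chrom], sub, window=L["apa_window"])
                per_scores.append(res["per_loop_scores"])
                mats_sum = mats_sum + res["matrix"] * res["n_used"]
                n_used += res["n_used"]
            scores[cond] = pd.concat(per_scores).to_numpy()
            w = L["apa_window"]
            c = -(-w // 2)
            aggm = mats_sum / n_used
            agg[cond] = float(aggm[w, w] / np.nanmean(aggm[2 * w + 1 - c:, :c]))
        comparison = lp.compare_apa(scores["WT"], scores["MUT"])
        apa_res = {"score_wt": agg["WT"], "score_mut": agg["MUT"],
                   "comparison": comparison}

    return {"calls": calls, "union": union, "domains": domains,
            "loop_domains": loop_domains, "merged_domains": merged_domains,
            "diff_table": diff_table, "apa": apa_res}


def stage_integrate(bundle: dict, cfg: dict, chip_stage: dict,
                    loop_stage: dict, seed: int) -> dict:
    """CTCF-related loop typing, permutation enrichment, overlap fraction,
    gene targeting, and expression concordance."""
    sim_cfg: SimulationConfig = bundle["config"]
    genome = bundle["annotation"]["genome"]
    peaks = bundle["peaks"]
    promoters = bundle["annotation"]["promoters"]
    ann_set = ig.AnnotationSet(
        promoters=promoters,
        enhancers=bundle["annotation"]["enhancers"],
        insulators=iv.define_insulators(peaks, bundle["annotation"]["cohesin"]),
    )

    union_bedpe = lp.loops_to_bedpe_frame(loop_stage["union"], sim_cfg.hic_resolution)
    union_bedpe["diff_label"] = loop_stage["union"]["diff_label"].to_numpy()
    related = ig.ctcf_related_loops(union_bedpe, peaks)
    typed = ig.classify_loop_types(related, ann_set)
    type_counts = ig.loop_type_counts(typed, label_col="diff_label")

    ep = typed[typed["loop_class"] == "E-P"]
    ep_str = ep[ep["diff_label"] == "strengthened"].reset_index(drop=True)
    ep_wk = ep[ep["diff_label"] == "weakened"].reset_index(drop=True)

    out: dict[str, Any] = {
        "typed_loops": typed, "type_counts": type_counts,
        "n_ctcf_related": int(len(related)),
        "n_ep_strengthened": int(len(ep_str)), "n_ep_weakened": int(len(ep_wk)),
    }
    if len(ep_str) == 0:
        return out

    anchors = pd.concat([ig.anchors_frame(ep_str, "left"),
                         ig.anchors_frame(ep_str, "right")], ignore_index=True)
    signal = chip_stage["table"]["baseMean"].to_numpy()
    out["permutation"] = ig.permutation_binding_enrichment(
        anchors, peaks, signal, genome,
        n_perm=cfg["integration"]["n_perm"], seed=seed)

    out["overlap"] = ig.overlap_fraction(ep_str, chip_stage["enhanced_peaks"],
                                         mode=cfg["integration"]["overlap_mode"])

    flagged = ep_str[out["overlap"]["flagged"]]
    target_genes = ig.genes_targeted_by_loops(flagged, bundle["annotation"]["genes"],
                                              promoters)
    out["target_genes"] = target_genes
    rna_table = differential_analysis(bundle["expression"],
                                      normalization="median_of_ratios",
                                      q_max=cfg["rna"]["p_max"],
                                      min_fold=cfg["rna"]["min_fold"],
                                      use_raw_p=True)
    rna_table["label"] = rna_table["label"].to_numpy()
    out["rna_table"] = rna_table
    if target_genes:
        out["concordance"] = ig.expression_concordance(target_genes, rna_table)
    return out


def _recovery(bundle: dict, chip_stage: dict, loop_stage: dict,
              hic_stage: dict, integ: dict, tol: int = 2) -> dict:
    """Score pipeline output against the planted ground truth."""
    truth = bundle["truth"]
    sim_cfg: SimulationConfig = bundle["config"]

    chip_table = chip_stage["table"].set_index("feature")
    planted = truth["enhanced_peak_ids"]
    rec_peaks = float(np.mean([chip_table.loc[p, "label"] == "enhanced"
                               for p in planted])) if planted else np.nan

    union = loop_stage["union"]
    tl = pd.DataFrame(truth["loops"])

    def matched(sub: pd.DataFrame, label: str | None) -> float:
        hits = 0
        for _, t in sub.iterrows():
            cand = union[(union["chrom"] == t["chrom"])
                         & (np.abs(union["bin1"] - t["bin1"]) <= tol)
                         & (np.abs(union["bin2"] - t["bin2"]) <= tol)]
            if label is not None:
                cand = cand[cand["diff_label"] == label]
            hits += int(len(cand) > 0)
        return hits / len(sub) if len(sub) else np.nan

    rec_loops = matched(tl, None)
    rec_str = matched(tl[tl["truth_label"] == "strengthened"], "strengthened")

    comp_rs = {}
    for chrom, labels in truth["ab_labels"].items():
        ref = np.array([1.0 if ch == "A" else -1.0 for ch in labels])
        score = hic_stage["compartments"]["WT"][chrom]
        good = score != 0
        comp_rs[chrom] = float(abs(np.corrcoef(score[good], ref[:len(score)][good])[0, 1]))

    out = {"enhanced_peak_recall": rec_peaks, "loop_recall": rec_loops,
           "strengthened_loop_recall": rec_str,
           "compartment_truth_abs_r": comp_rs}
    if "concordance" in integ:
        out["recovered_concordance"] = integ["concordance"]["fraction_up_de"]
        out["configured_concordance"] = sim_cfg.concordance
    return out


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(x)] if isinstance(x, set) \
            else [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Run the full synthetic study and return (and optionally write) the report.

    Deterministic: identical config + seed produce a byte-identical
    ``report.json``.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg = dict(cfg, seed=int(seed))
    seed = int(cfg["seed"])

    sim_cfg = SimulationConfig(**cfg.get("simulate", {}))
    bundle = simulate_all(sim_cfg, seed=seed)
    chip_stage = stage_chip(bundle, cfg)
    hic_stage = stage_hic(bundle, cfg)
    loop_stage = stage_loops(bundle, cfg, hic_stage)
    integ = stage_integrate(bundle, cfg, chip_stage, loop_stage, seed=seed)
    recovery = _recovery(bundle, chip_stage, loop_stage, hic_stage, integ)

    ld = loop_stage
    report = {
        "version": REPORT_VERSION,
        "seed": seed,
        "chip": {
            "n_peaks": int(len(bundle["peaks"])),
            "n_enhanced": chip_stage["n_enhanced"],
            "n_weakened": chip_stage["n_weakened"],
        },
        "hic": {
            "compartment_r_wt_vs_mut": {k: round(v, 6) for k, v in
                                        hic_stage["compartment_r"].items()},
            "scc_replicate": round(hic_stage["scc_replicate"], 6),
            "scc_cross_condition": round(hic_stage["scc_cross"], 6),
        },
        "loops": {
            "n_called_wt": int(len(ld["calls"]["WT"])),
            "n_called_mut": int(len(ld["calls"]["MUT"])),
            "n_union": int(len(ld["union"])),
            "n_strengthened": int((ld["union"]["diff_label"] == "strengthened").sum()),
            "n_weakened": int((ld["union"]["diff_label"] == "weakened").sum()),
            "n_loop_domains_wt": int(len(ld["loop_domains"]["WT"])),
            "n_loop_domains_mut": int(len(ld["loop_domains"]["MUT"])),
            "n_merged_loop_domains": int(len(ld["merged_domains"])),
            "n_enhanced_domains": int((ld["merged_domains"]["diff_label"]
                                       == "strengthened").sum()),
            "n_weakened_domains": int((ld["merged_domains"]["diff_label"]
                                       == "weakened").sum()),
        },
        "integration": {
            "n_ctcf_related": integ.get("n_ctcf_related", 0),
            "type_counts": _jsonable(integ["type_counts"].to_dict()) if
            "type_counts" in integ else {},
            "n_ep_strengthened": integ.get("n_ep_strengthened", 0),
            "n_ep_weakened": integ.get("n_ep_weakened", 0),
        },
        "recovery": _jsonable(recovery),
    }
    if ld["apa"]:
        report["loops"]["apa_score_wt"] = round(ld["apa"]["score_wt"], 6)
        report["loops"]["apa_score_mut"] = round(ld["apa"]["score_mut"], 6)
        report["loops"]["apa_t"] = round(ld["apa"]["comparison"]["t"], 6)
        report["loops"]["apa_pvalue"] = float(f'{ld["apa"]["comparison"]["pvalue"]:.6g}')
    if "permutation" in integ:
        perm = integ["permutation"]
        report["integration"]["permutation"] = {
            "z": round(perm["z"], 6), "pvalue": float(f'{perm["pvalue"]:.6g}'),
            "pvalue_empirical": round(perm["pvalue_empirical"], 6),
            "n_perm": perm["n_perm"],
        }
    if "overlap" in integ:
        report["integration"]["overlap_fraction"] = round(
            integ["overlap"]["fraction"], 6)
        report["integration"]["n_flagged"] = integ["overlap"]["n_flagged"]
    if "concordance" in integ:
        conc = integ["concordance"]
        report["integration"]["concordance"] = {
            "fraction_increased": round(conc["fraction_increased"], 6),
            "fraction_up_de": round(conc["fraction_up_de"], 6),
            "chisq": round(conc["chisq"], 6),
            "pvalue": float(f'{conc["pvalue"]:.6g}'),
            "n_targets": conc["n_targets"],
        }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        chip_stage["table"].to_csv(out / "chip_differential.tsv", sep="\t", index=False)
        ld["union"].to_csv(out / "loops_union.tsv", sep="\t", index=False)
        ld["merged_domains"].to_csv(out / "merged_loop_domains.tsv", sep="\t", index=False)
        if "rna_table" in integ:
            integ["rna_table"].to_csv(out / "rna_differential.tsv", sep="\t", index=False)
        if "typed_loops" in integ:
            integ["typed_loops"].to_csv(out / "ctcf_related_typed_loops.tsv",
                                        sep="\t", index=False)
    return {"report": report, "bundle": bundle, "chip": chip_stage,
            "hic": hic_stage, "loops": loop_stage, "integration": integ,
            "recovery": recovery}
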