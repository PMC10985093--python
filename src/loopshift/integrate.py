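"""Integrative statistics linking binding, loops, and expression.

CTCF-related loop selection, anchor-based loop typing (E-E/E-P/P-P/I-I),
permutation enrichment of binding signal on target intervals, overlap
fractions with a one-tailed chi-square, loop-to-gene targeting, expression
concordance, and XIC stoichiometry of a post-translational modification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv

__all__ = [
    "AnnotationSet",
    "anchors_frame",
    "ctcf_related_loops",
    "classify_loop_types",
    "permutation_binding_enrichment",
    "overlap_fraction",
    "genes_targeted_by_loops",
    "expression_concordance",
    "one_tailed_chisq",
    "ptm_stoichiometry",
]

LOOP_CLASSES = ["E-E", "E-P", "P-P", "I-I", "other"]


@dataclass
class AnnotationSet:
    """Promoter / enhancer / insulator interval tracks.

    By construction enhancers exclude promoter-overlapping peaks (see
    :func:`loopshift.intervals.define_enhancers`).
    """

    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    insulators: pd.DataFrame


def anchors_frame(loops: pd.DataFrame, which: str) -> pd.DataFrame:
    """One anchor of a BEDPE-style loop frame as an interval frame."""
    k = "1" if which == "left" else "2"
    return iv.make_intervals(loops[f"chrom{k}"].to_numpy(),
                             loops[f"start{k}"].to_numpy(),
                             loops[f"end{k}"].to_numpy())


def ctcf_related_loops(loops: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Loops with a CTCF peak on both anchors."""
    if len(loops) == 0 or len(peaks) == 0:
        return loops.iloc[0:0].copy()
    a1 = iv.overlaps_any(anchors_frame(loops, "left"), peaks)
    a2 = iv.overlaps_any(anchors_frame(loops, "right"), peaks)
    return loops[a1 & a2].reset_index(drop=True)


def _anchor_labels(anchors: pd.DataFrame, ann: AnnotationSet) -> np.ndarray:
    """Label anchors by precedence promoter > enhancer > insulator > none."""
    n = len(anchors)
    is_p = iv.overlaps_any(anchors, ann.promoters) if len(ann.promoters) else np.zeros(n, bool)
    is_e = iv.overlaps_any(anchors, ann.enhancers) if len(ann.enhancers) else np.zeros(n, bool)
    is_i = iv.overlaps_any(anchors, ann.insulators) if len(ann.insulators) else np.zeros(n, bool)
    return np.where(is_p, "P", np.where(is_e, "E", np.where(is_i, "I", "-")))


def classify_loop_types(loops: pd.DataFrame, ann: AnnotationSet) -> pd.DataFrame:
    """Assign each loop a class from its unordered anchor-label pair.

    Anchors touching a promoter are P, else enhancer E, else insulator I,
    else unlabeled; pairs involving an unlabeled anchor are "other".
    """
    out = loops.copy()
    if len(loops) == 0:
        out["loop_class"] = pd.Series(dtype=str)
        return out
    l1 = _anchor_labels(anchors_frame(loops, "left"), ann)
    l2 = _anchor_labels(anchors_frame(loops, "right"), ann)
    classes = []
    for a, b in zip(l1, l2):
        if "-" in (a, b):
            classes.append("other")
        else:
            classes.append("-".join(sorted((a, b))))
    out["loop_class"] = classes
    return out


def loop_type_counts(typed_loops: pd.DataFrame,
                     label_col: str | None = None) -> pd.DataFrame:
    """Class counts, optionally split by a differential-label column."""
    if label_col and label_col in typed_loops:
        tab = typed_loops.groupby([label_col, "loop_class"]).size().unstack(fill_value=0)
    else:
        tab = typed_loops["loop_class"].value_counts().to_frame().T
    return tab.reindex(columns=LOOP_CLASSES, fill_value=0)


def _overlap_lookup(targets: pd.DataFrame):
    """Per-chrom merged target intervals with cumulative-max ends, for a
    vectorized any-overlap test (the permutation null evaluates thousands
    of shuffles; IntervalTree queries would dominate the runtime)."""
    merged = iv.merge_overlapping(targets) if len(targets) else targets
    lut = {}
    for chrom, sub in merged.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        lut[str(chrom)] = (starts, ends)
    return lut


def _fast_overlaps_any(peaks: pd.DataFrame, lut) -> np.ndarray:
    out = np.zeros(len(peaks), dtype=bool)
    for chrom, sub_idx in peaks.groupby("chrom").indices.items():
        entry = lut.get(str(chrom))
        if entry is None:
            continue
        starts, cmax_ends = entry
        qs = peaks["start"].to_numpy()[sub_idx]
        qe = peaks["end"].to_numpy()[sub_idx]
        i = np.searchsorted(starts, qe, side="left")
        hit = (i > 0) & (np.where(i > 0, cmax_ends[np.maximum(i - 1, 0)], 0) > qs)
        out[sub_idx] = hit
    return out


def permutation_binding_enrichment(targets: pd.DataFrame, peaks: pd.DataFrame,
                                   signal: np.ndarray, genome: iv.GenomeSpec,
                                   n_perm: int = 1000, seed: int = 0) -> dict:
    """Is summed peak signal on target intervals higher than for shuffled peaks?

    The observed statistic is the total signal of peaks overlapping any
    target; the null re-places peaks uniformly within their chromosomes,
    carrying their signals. Reports the z-score, the one-tailed normal
    p-value (per the normality assumption), and an empirical rank p.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    signal = np.asarray(signal, dtype=float)
    rng = np.random.default_rng(seed)
    lut = _overlap_lookup(targets)

    def stat(pk: pd.DataFrame) -> float:
        return float(signal[_fast_overlaps_any(pk, lut)].sum())

    observed = stat(peaks)
    null = np.array([stat(iv.shuffle_intervals(peaks, genome, rng))
                     for _ in range(n_perm)])
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in the permutation null")
    z = (observed - null.mean()) / sd
    p_normal = float(stats.norm.sf(z))
    p_emp = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return {"observed": observed, "null_mean": float(null.mean()),
            "null_sd": float(sd), "z": float(z), "pvalue": p_normal,
            "pvalue_empirical": p_emp, "n_perm": n_perm, "seed": seed}


def overlap_fraction(loops: pd.DataFrame, enhanced_peaks: pd.DataFrame,
                     mode: str = "anchors") -> dict:
    """Fraction of loops carrying an enhanced peak.

    ``mode='anchors'`` flags a loop when either anchor overlaps an enhanced
    peak (default: anchors are where CTCF acts); ``mode='span'`` uses the
    full anchor1-start to anchor2-end span.
    """
    if len(loops) == 0:
        raise ValueError("empty loop set")
    if len(enhanced_peaks) == 0:
        flagged = np.zeros(len(loops), bool)
    elif mode == "anchors":
        flagged = iv.overlaps_any(anchors_frame(loops, "left"), enhanced_peaks) | \
            iv.overlaps_any(anchors_frame(loops, "right"), enhanced_peaks)
    elif mode == "span":
        span = iv.make_intervals(loops["chrom1"].to_numpy(),
                                 loops["start1"].to_numpy(),
                                 loops["end2"].to_numpy())
        flagged = iv.overlaps_any(span, enhanced_peaks)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"fraction": float(flagged.mean()), "flagged": flagged,
            "n_flagged": int(flagged.sum()), "n_total": int(len(loops))}


def genes_targeted_by_loops(loops: pd.DataFrame, genes: pd.DataFrame,
                            promoters: pd.DataFrame) -> set[str]:
    """Gene ids whose promoter overlaps either anchor of any input loop."""
    if len(loops) == 0 or len(promoters) == 0:
        return set()
    anchors = pd.concat([anchors_frame(loops, "left"),
                         anchors_frame(loops, "right")], ignore_index=True)
    hits = iv.intersect(promoters, anchors)
    return set(promoters.loc[hits["index_a"].unique(), "name"])


def expression_concordance(target_genes: set[str], de_table: pd.DataFrame,
                           background_genes: set[str] | None = None,
                           direction: str = "up") -> dict:
    """Expression concordance of loop-targeted genes.

    Reports the fraction of target genes with positive log2 fold change,
    the fraction classified up by the DE rule (label column), and a 2×2
    one-tailed chi-square of (target vs background) × (up vs not up) with
    the alternative that targets are more often up.
    """
    if not target_genes:
        raise ValueError("empty target gene set")
    table = de_table.set_index("feature")
    missing = set(target_genes) - set(table.index)
    if missing:
        raise ValueError(f"target genes absent from the DE table: {sorted(missing)[:5]}")
    if background_genes is None:
        background_genes = set(table.index) - set(target_genes)
    tgt = table.loc[sorted(target_genes)]
    bg = table.loc[sorted(set(background_genes) - set(target_genes))]
    up_t = int((tgt["log2FC"] > 0).sum())
    up_b = int((bg["log2FC"] > 0).sum())
    contingency = np.array([[up_t, len(tgt) - up_t], [up_b, len(bg) - up_b]])
    chisq = one_tailed_chisq(contingency, direction=direction)
    frac_up_de = float((tgt["label"] == "enhanced").mean()) if "label" in tgt else np.nan
    return {
        "fraction_increased": float(up_t / len(tgt)),
        "fraction_up_de": frac_up_de,
        "table": contingency,
        "chisq": chisq["statistic"],
        "pvalue": chisq["pvalue"],
        "n_targets": int(len(tgt)),
        "n_background": int(len(bg)),
    }


def one_tailed_chisq(table: np.ndarray, direction: str = "up") -> dict:
    """One-tailed 2×2 chi-square test (df = 1, no continuity correction).

    chi² = n(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)). The one-tailed p is half the
    two-tailed p when the sample association matches the alternative
    (``direction='up'``: row 1 enriched in column 1), else 1 − p_two/2.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("degenerate table margins")
    statistic = n * (a * d - b * c) ** 2 / margins
    p_two = float(stats.chi2.sf(statistic, df=1))
    assoc = a * d - b * c  # >0: row 1 enriched in column 1
    matches = assoc > 0 if direction == "up" else assoc < 0
    p_one = p_two / 2 if matches else 1 - p_two / 2
    if assoc == 0:
        p_one = 0.5
    return {"statistic": float(statistic), "pvalue": float(p_one),
            "pvalue_two_tailed": p_two}


def ptm_stoichiometry(area_modified: float, area_unmodified: float) -> dict:
    """Modification occupancy from XIC peak areas of the modified and
    unmodified peptide forms, as a percentage rounded to 2 decimals."""
    if area_modified < 0 or area_unmodified < 0:
        raise ValueError("peak areas must be non-negative")
    total = area_modified + area_unmodified
    if total == 0:
        raise ValueError("both peak areas are zero")
    fraction = area_modified / total
    return {"area_modified": float(area_modified),
            "area_unmodified": float(area_unmodified),
            "fraction": float(fraction),
            "percent": round(100.0 * fraction, 2)}
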