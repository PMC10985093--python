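"""Intra-chromosomal Hi-C contact matrices.

Construction from pair records, iterative correction (ICE), distance-decay
expected models, relative contact probability, A/B compartment scoring by
the leading eigenvector of the O/E correlation matrix, and
stratum-adjusted correlation (SCC) for reproducibility.

Matrices are held dense (the package targets chromosomes of a few hundred
bins); the on-disk interchange format is sparse upper-triangle COO text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .intervals import GenomeSpec, SignalTrack

__all__ = [
    "ContactMatrix",
    "bin_pairs",
    "ice_balance",
    "expected_by_distance",
    "oe_matrix",
    "relative_contact_probability",
    "rebin",
    "compartment_score",
    "compare_compartments",
    "scc",
]


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact counts.

    ``bias`` (per-bin positive factors, NaN on masked bins) and ``mask``
    (True = excluded low-coverage bin) are populated by :func:`ice_balance`.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    bias: np.ndarray | None = None
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = c
        if self.mask is None:
            self.mask = np.zeros(len(c), dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def balanced(self, fill: float = np.nan) -> np.ndarray:
        """Bias-corrected matrix; masked rows/columns set to ``fill``."""
        if self.bias is None:
            raise ValueError("matrix is not balanced; run ice_balance first")
        b = np.where(self.mask, np.nan, self.bias)
        out = self.counts / np.outer(b, b)
        bad = self.mask[:, None] | self.mask[None, :]
        out[bad] = fill
        return out

    def valid_pairs(self) -> np.ndarray:
        good = ~self.mask
        return good[:, None] & good[None, :]

    def write_coo(self, path: str | Path, length: int | None = None) -> None:
        n = self.n_bins
        length = length if length is not None else n * self.resolution
        iu, ju = np.triu_indices(n)
        vals = self.counts[iu, ju]
        nz = vals != 0
        with open(path, "w") as fh:
            fh.write(f"#chrom {self.chrom} {length} {self.resolution}\n")
            for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{v:g}\n")

    @classmethod
    def read_coo(cls, path: str | Path) -> "ContactMatrix":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 4 or header[0] != "#chrom":
                raise ValueError("expected header '#chrom <name> <length> <resolution>'")
            chrom, length, res = header[1], int(header[2]), int(header[3])
            n = -(-length // res)
            mat = np.zeros((n, n))
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                i, j, v = line.split()
                i, j, v = int(i), int(j), float(v)
                if not (0 <= i <= j < n):
                    raise ValueError(f"line {lineno}: bin out of range")
                mat[i, j] += v
                if i != j:
                    mat[j, i] += v
        return cls(chrom=chrom, resolution=res, counts=mat)


def bin_pairs(pairs: pd.DataFrame, genome: GenomeSpec, resolution: int,
              chrom: str) -> ContactMatrix:
    """Bin intra-chromosomal position pairs into a symmetric matrix.

    ``pairs`` needs columns ``chrom1 pos1 chrom2 pos2``; only rows where both
    sides are on *chrom* are used.
    """
    length = genome.length(chrom)
    n = -(-length // resolution)
    sub = pairs[(pairs["chrom1"] == chrom) & (pairs["chrom2"] == chrom)]
    p1 = sub["pos1"].to_numpy()
    p2 = sub["pos2"].to_numpy()
    if ((p1 < 0) | (p1 >= length) | (p2 < 0) | (p2 >= length)).any():
        raise ValueError("position outside chromosome")
    i = np.minimum(p1 // resolution, p2 // resolution)
    j = np.maximum(p1 // resolution, p2 // resolution)
    mat = np.zeros((n, n))
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T - np.diag(np.diag(mat))
    return ContactMatrix(chrom=chrom, resolution=resolution, counts=mat)


def ice_balance(m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200,
                mad_cutoff: float = 3.0) -> np.ndarray:
    """Iterative correction: find per-bin biases equalising row sums.

    Bins whose raw coverage falls more than ``mad_cutoff`` MADs below the
    median coverage (or with zero coverage) are masked and excluded.
    Returns the bias vector and stores bias/mask on the matrix.
    """
    cov = m.counts.sum(axis=1)
    mask = cov <= 0
    if (~mask).any() and mad_cutoff is not None:
        nz = cov[~mask]
        med = np.median(nz)
        mad = stats.median_abs_deviation(nz)
        if mad > 0:
            mask |= cov < med - mad_cutoff * mad
    if mask.all():
        raise ValueError("all bins masked; cannot balance")

    good = ~mask
    w = m.counts.copy()
    w[mask, :] = 0.0
    w[:, mask] = 0.0
    bias = np.ones(m.n_bins)
    for _ in range(max_iter):
        s = (w / np.outer(bias, bias)).sum(axis=1)
        s_good = s[good]
        s_rel = s_good / s_good.mean()
        if np.max(np.abs(s_rel - 1.0)) < tol:
            break
        update = np.ones_like(bias)
        update[good] = s_rel
        bias *= np.sqrt(update)
    bias[good] /= np.exp(np.mean(np.log(bias[good])))  # fix gauge: geometric mean 1
    bias[mask] = np.nan
    m.bias = bias
    m.mask = mask
    return bias


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean balanced contact per diagonal distance, over unmasked bin pairs."""
    bal = m.balanced(fill=np.nan)
    n = m.n_bins
    out = np.zeros(n)
    for d in range(n):
        diag = np.diagonal(bal, offset=d)
        out[d] = np.nanmean(diag) if np.isfinite(diag).any() else 0.0
    return out


def oe_matrix(m: ContactMatrix, expected: np.ndarray | None = None,
              fill: float = np.nan) -> np.ndarray:
    """Observed/expected balanced matrix (masked or zero-expected → fill)."""
    if expected is None:
        expected = expected_by_distance(m)
    bal = m.balanced(fill=np.nan)
    n = m.n_bins
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    emat = expected[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = bal / emat
    oe[~np.isfinite(oe)] = fill
    return oe


def relative_contact_probability(m: ContactMatrix,
                                 strata: np.ndarray | None = None
                                 ) -> pd.DataFrame:
    """Mean balanced contact per log-spaced distance stratum, summing to 1."""
    n = m.n_bins
    if strata is None:
        strata = np.unique(np.geomspace(1, n - 1, 20).astype(int))
    strata = np.asarray(strata)
    if len(strata) < 2:
        raise ValueError("need at least two distance strata")
    exp = expected_by_distance(m)
    edges = list(strata) + [n]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        vals = exp[lo:hi]
        vals = vals[vals > 0]
        if len(vals):
            rows.append((lo * m.resolution, float(np.mean(vals))))
    df = pd.DataFrame(rows, columns=["distance", "probability"])
    df["probability"] /= df["probability"].sum()
    return df


def rebin(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Block-sum aggregation by an integer factor; total count conserved."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ContactMatrix(chrom=m.chrom, resolution=m.resolution,
                             counts=m.counts.copy())
    n = m.n_bins
    n_new = -(-n // factor)
    padded = np.zeros((n_new * factor, n_new * factor))
    padded[:n, :n] = m.counts
    coarse = padded.reshape(n_new, factor, n_new, factor).sum(axis=(1, 3))
    return ContactMatrix(chrom=m.chrom, resolution=m.resolution * factor,
                         counts=coarse)


def compartment_score(m: ContactMatrix, comp_resolution: int,
                      reference: np.ndarray | None = None) -> np.ndarray:
    """A/B compartment score: leading eigenvector of the O/E correlation matrix.

    The matrix is rebinned to ``comp_resolution``, balanced, converted to
    observed/expected, correlated bin-against-bin, and decomposed. The sign
    is oriented so the score correlates positively with ``reference``
    (a per-compartment-bin activity density, e.g. promoter counts); A is
    positive. Masked bins score 0. Invariant to positive scaling of counts.
    """
    if comp_resolution % m.resolution != 0:
        raise ValueError("comp_resolution must be a multiple of the matrix resolution")
    coarse = rebin(m, comp_resolution // m.resolution)
    ice_balance(coarse)
    oe = oe_matrix(coarse, fill=np.nan)
    good = ~coarse.mask
    sub = oe[np.ix_(good, good)]
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if sub.shape[0] < 3:
        raise ValueError("too few unmasked bins for compartment analysis")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    if not np.any(corr):
        raise ValueError("degenerate correlation matrix")
    vals, vecs = np.linalg.eigh(corr)
    lead = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    score = np.zeros(coarse.n_bins)
    score[good] = lead
    if reference is not None:
        ref = np.asarray(reference, dtype=float)[:coarse.n_bins]
        r = np.corrcoef(score[good], ref[good])[0, 1]
        if np.isfinite(r) and r < 0:
            score = -score
    return score


def compare_compartments(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two compartment tracks over jointly nonzero bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share binning")
    good = (a != 0) & (b != 0) & np.isfinite(a) & np.isfinite(b)
    if good.sum() < 3:
        raise ValueError("fewer than 3 shared scored bins")
    return float(np.corrcoef(a[good], b[good])[0, 1])


def scc(a: ContactMatrix, b: ContactMatrix, smooth_h: int = 1,
        max_dist: int = 5_000_000) -> dict:
    """Stratum-adjusted correlation coefficient between two matrices.

    Both raw matrices are 2D mean-filtered with half-width ``smooth_h``;
    per distance stratum k the Pearson correlation r_k is computed and
    aggregated with weights N_k * sigma_ak * sigma_bk.
    """
    if a.chrom != b.chrom or a.resolution != b.resolution or a.n_bins != b.n_bins:
        raise ValueError("matrices must share chromosome, resolution, and size")
    size = 2 * smooth_h + 1
    # nearest-padding plus trimming the smoothed diagonal ends: zero padding
    # would imprint the same edge dip on both matrices and bias r upward
    sa = ndimage.uniform_filter(a.counts, size=size, mode="nearest")
    sb = ndimage.uniform_filter(b.counts, size=size, mode="nearest")
    n = a.n_bins
    kmax = min(n - 1, max_dist // a.resolution)
    rows = []
    for k in range(1, kmax + 1):
        xa = np.diagonal(sa, offset=k)
        xb = np.diagonal(sb, offset=k)
        if smooth_h > 0 and len(xa) > 2 * smooth_h + 2:
            xa = xa[smooth_h:-smooth_h]
            xb = xb[smooth_h:-smooth_h]
        if len(xa) < 3 or xa.std() == 0 or xb.std() == 0:
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        w = len(xa) * xa.std() * xb.std()
        rows.append((k, r, w))
    if not rows:
        raise ValueError("no valid distance strata")
    strata = pd.DataFrame(rows, columns=["distance_bins", "r", "weight"])
    agg = float((strata["r"] * strata["weight"]).sum() / strata["weight"].sum())
    return {"scc": agg, "strata": strata}
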