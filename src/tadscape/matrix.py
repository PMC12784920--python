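"""Binned Hi-C contact matrices: I/O, ICE balancing, decay curves, correlation.

A :class:`ContactMatrix` holds one chromosome's cis contacts at a fixed bin
size.  Matrices are kept dense (the pipeline works per chromosome at 40 kb,
where a mammalian chromosome is a few thousand bins at most).  Bins are
0-based half-open ``[k*bin_size, (k+1)*bin_size)``; the HiC-Pro triplet
dialect uses 1-based global bin IDs and is converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    counts: np.ndarray                      # (n, n) symmetric, non-negative
    weights: Optional[np.ndarray] = None    # per-bin balancing multipliers
    mask: Optional[np.ndarray] = None       # True = usable bin
    balanced: bool = False
    merged: bool = False                    # group-merged, visualization only

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.counts.shape[0] < 2:
            raise ValueError("chromosome shorter than 2 bins")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(self.n_bins, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# HiC-Pro sparse-triplet dialect and dense TSV

def read_hicpro(matrix_path, bed_path, chrom: str) -> ContactMatrix:
    """Assemble one chromosome's matrix from HiC-Pro ``.matrix`` + ``.bed`` files.

    The bed file maps 1-based global bin IDs to intervals; the matrix file
    holds ``binA  binB  count`` triplets in either triangle (or both, as long
    as mirrored entries agree).  Triplet order is irrelevant.
    """
    bins = pd.read_csv(bed_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "bin_id"])
    sub = bins[bins["chrom"] == chrom].sort_values("start")
    if len(sub) == 0:
        raise ValueError(f"chromosome {chrom!r} not in bin table")
    sizes = (sub["end"] - sub["start"]).to_numpy()
    bin_size = int(sizes[0])
    if np.any(sizes[:-1] != bin_size):  # terminal bin may be short
        raise ValueError("bin size inconsistent within bed bin table")
    ids = sub["bin_id"].to_numpy()
    id_min, id_max = int(ids.min()), int(ids.max())
    n = len(sub)
    trip = pd.read_csv(matrix_path, sep="\t", header=None,
                       names=["a", "b", "count"])
    all_ids = set(bins["bin_id"])
    bad = set(trip["a"]).union(trip["b"]) - all_ids
    if bad:
        raise ValueError(f"bin IDs out of range: {sorted(bad)[:5]}")
    m = np.zeros((n, n))
    keep = trip["a"].between(id_min, id_max) & trip["b"].between(id_min, id_max)
    for a, b, c in trip[keep].itertuples(index=False):
        i, j = sorted((int(a) - id_min, int(b) - id_min))
        m[i, j] += float(c)
    m = m + np.triu(m, 1).T
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=m)


def write_hicpro(m: ContactMatrix, matrix_path, bed_path, chrom_length: Optional[int] = None,
                 id_offset: int = 0) -> None:
    """Write the upper triangle of a matrix in HiC-Pro triplet dialect (1-based IDs)."""
    n = m.n_bins
    length = chrom_length if chrom_length is not None else n * m.bin_size
    with open(bed_path, "w") as fh:
        for k in range(n):
            end = min((k + 1) * m.bin_size, length)
            fh.write(f"{m.chrom}\t{k * m.bin_size}\t{end}\t{id_offset + k + 1}\n")
    iu = np.triu_indices(n)
    vals = m.counts[iu]
    nz = vals != 0
    with open(matrix_path, "w") as fh:
        for i, j, c in zip(iu[0][nz], iu[1][nz], vals[nz]):
            c = int(c) if float(c).is_integer() else c
            fh.write(f"{id_offset + i + 1}\t{id_offset + j + 1}\t{c}\n")


def read_dense(path, chrom: str, bin_size: int) -> ContactMatrix:
    m = np.loadtxt(path)
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=m)


def write_dense(m: ContactMatrix, path) -> None:
    np.savetxt(path, m.counts, fmt="%.6g", delimiter="\t")


# ---------------------------------------------------------------------------
# ICE balancing

class AllBinsMaskedError(ValueError):
    pass


def ice_balance(m: ContactMatrix, mask_low: float = -1.5, mask_high: float = 5.0,
                max_iter: int = 200, tol: float = 1e-5) -> ContactMatrix:
    """Iterative correction: equalize matrix marginals over unmasked bins.

    Bins are masked before iteration when their log10 coverage z-score falls
    outside ``[mask_low, mask_high]`` (zero-coverage bins are always masked).
    Iteration stops when the maximum relative deviation of unmasked marginals
    from their mean drops below ``tol``; failing that after ``max_iter``
    rounds, a warning is issued and the best iterate returned.  Total matrix
    mass over unmasked bins is preserved, so the per-bin ``weights`` satisfy
    ``balanced[i, j] = raw[i, j] / (weights[i] * weights[j])``.
    """
    C = m.counts
    n = m.n_bins
    cov = C.sum(axis=1)
    keep = cov > 0
    if keep.sum() >= 2:
        logc = np.log10(cov[keep])
        sd = logc.std()
        z = (logc - logc.mean()) / sd if sd > 0 else np.zeros_like(logc)
        ok = (z >= mask_low) & (z <= mask_high)
        idx = np.flatnonzero(keep)
        keep = np.zeros(n, dtype=bool)
        keep[idx[ok]] = True
    if keep.sum() == 0:
        raise AllBinsMaskedError(f"{m.chrom}: every bin masked before balancing")

    W = C.copy()
    W[~keep, :] = 0.0
    W[:, ~keep] = 0.0
    raw_mass = W.sum()
    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=1)
        mean_s = s[keep].mean()
        if mean_s == 0:
            raise AllBinsMaskedError(f"{m.chrom}: zero total signal on unmasked bins")
        dev = np.abs(s[keep] / mean_s - 1.0).max()
        if dev < tol:
            converged = True
            break
        db = np.where(keep, s / mean_s, 1.0)
        db[db == 0] = 1.0
        W /= np.outer(db, db)
        bias *= db
    if not converged:
        warnings.warn(f"{m.chrom}: ICE did not reach tol={tol} in {max_iter} iterations "
                      f"(max marginal deviation {dev:.2e}); returning best iterate")
    # preserve total mass; fold the global rescale into the weights
    bal_mass = W.sum()
    scale = raw_mass / bal_mass if bal_mass > 0 else 1.0
    W *= scale
    weights = bias / np.sqrt(scale)
    return ContactMatrix(chrom=m.chrom, bin_size=m.bin_size, counts=W,
                         weights=weights, mask=keep, balanced=True)


# ---------------------------------------------------------------------------
# distance decay, replicate correlation, group merging

def distance_decay(m: ContactMatrix) -> pd.DataFrame:
    """Mean contact per genomic separation over unmasked bin pairs.

    Returns a frame with strictly increasing ``distance_bp`` and
    ``mean_contact``; distances with no usable pair are dropped.
    """
    n = m.n_bins
    mask = m.mask
    rows = []
    for d in range(n):
        vals = np.diagonal(m.counts, offset=d)
        ok = mask[: n - d] & mask[d:]
        if ok.any():
            rows.append((d * m.bin_size, float(vals[ok].mean())))
    return pd.DataFrame(rows, columns=["distance_bp", "mean_contact"])


def replicate_correlation(a: ContactMatrix, b: ContactMatrix, method: str = "pearson",
                          stratified: bool = False, pool_above_bp: int = 5_000_000):
    """Correlation between two replicate matrices on their common unmasked pairs.

    Pearson is computed on log1p counts, Spearman on raw values.  In
    stratified mode, per-distance coefficients are returned, with strata
    beyond ``pool_above_bp`` pooled into one.
    """
    if (a.chrom, a.bin_size, a.n_bins) != (b.chrom, b.bin_size, b.n_bins):
        raise ValueError("matrices are on different grids")
    n = a.n_bins
    common = a.mask & b.mask
    iu = np.triu_indices(n, k=1)
    ok = common[iu[0]] & common[iu[1]]
    x, y = a.counts[iu][ok], b.counts[iu][ok]
    d = (iu[1] - iu[0])[ok] * a.bin_size

    def _corr(u, v):
        if len(u) < 2 or np.std(u) == 0 or np.std(v) == 0:
            return np.nan
        if method == "pearson":
            return float(np.corrcoef(np.log1p(u), np.log1p(v))[0, 1])
        if method == "spearman":
            return float(_sps.spearmanr(u, v).statistic)
        raise ValueError(f"unknown method {method!r}")

    if not stratified:
        return _corr(x, y)
    strata = np.where(d > pool_above_bp, pool_above_bp + a.bin_size, d)
    rows = []
    for s in np.unique(strata):
        sel = strata == s
        rows.append((int(s), bool(s > pool_above_bp), _corr(x[sel], y[sel])))
    return pd.DataFrame(rows, columns=["distance_bp", "pooled", "correlation"])


def merge_group(matrices: Sequence[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of raw replicate matrices (descriptive use only).

    Inference stays per replicate; the merged matrix is flagged and intended
    for visualization.
    """
    if len(matrices) == 0:
        raise ValueError("nothing to merge")
    first = matrices[0]
    total = np.zeros_like(first.counts)
    for m in matrices:
        if (m.chrom, m.bin_size, m.n_bins) != (first.chrom, first.bin_size, first.n_bins):
            raise ValueError("matrices are on different grids")
        if m.balanced:
            raise ValueError("merge raw matrices before balancing")
        total += m.counts
    return ContactMatrix(chrom=first.chrom, bin_size=first.bin_size, counts=total,
                         merged=True)
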