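"""Binned contact-matrix and genomic-track containers and I/O.

Contact maps are intra-chromosomal, symmetric, dense ``numpy`` arrays with an
explicit per-bin validity mask.  Missing data travel as the mask, never as
zeros.  Supported on-disk formats are deliberately plain text:

* COO triplets ``bin_i bin_j score`` (whitespace separated, 0-based bin
  indices within the chromosome; upper or lower triangle accepted, duplicate
  ``(i, j)``/``(j, i)`` entries summed),
* dense whitespace-separated matrices,
* 4-column BED-like bin tables (``chrom  start  end  index``) and bedGraph
  tracks, both 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "ContactMatrix",
    "GenomicTrack",
    "ContactParseError",
    "BalanceConvergenceError",
    "read_bins",
    "write_bins",
    "read_contacts",
    "write_contacts",
    "read_bedgraph",
    "write_bedgraph",
    "balance_kr",
    "expected_by_distance",
    "observed_over_expected",
    "coarsen",
]


class ContactParseError(ValueError):
    """Raised when a contact or track file does not parse."""


class BalanceConvergenceError(RuntimeError):
    """Raised when matrix balancing fails to reach tolerance."""

    def __init__(self, deviation: float, max_iter: int):
        self.deviation = deviation
        self.max_iter = max_iter
        super().__init__(
            f"balancing did not converge within {max_iter} iterations "
            f"(final relative row-sum deviation {deviation:.3e})"
        )


@dataclass(frozen=True)
class BinTable:
    """Genomic bins tiling one or more chromosomes at fixed resolution.

    Bins are contiguous and non-overlapping within each chromosome;
    ``end - start == resolution`` except possibly at a chromosome's last bin.
    """

    chroms: tuple[str, ...]
    starts: np.ndarray
    ends: np.ndarray
    chrom_of: np.ndarray  # per-bin chromosome index into ``chroms``
    resolution: int

    @classmethod
    def from_chrom_sizes(cls, sizes: dict[str, int], resolution: int) -> "BinTable":
        chroms, starts, ends, chrom_of = [], [], [], []
        for ci, (chrom, length) in enumerate(sizes.items()):
            chroms.append(chrom)
            edges = np.arange(0, length, resolution)
            starts.append(edges)
            ends.append(np.minimum(edges + resolution, length))
            chrom_of.append(np.full(len(edges), ci, dtype=np.int64))
        return cls(
            chroms=tuple(chroms),
            starts=np.concatenate(starts),
            ends=np.concatenate(ends),
            chrom_of=np.concatenate(chrom_of),
            resolution=int(resolution),
        )

    def n_bins(self, chrom: str) -> int:
        ci = self.chroms.index(chrom)
        return int(np.sum(self.chrom_of == ci))

    def chrom_length(self, chrom: str) -> int:
        ci = self.chroms.index(chrom)
        return int(self.ends[self.chrom_of == ci].max())

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal contact matrix with per-bin validity mask.

    ``values[i, j]`` is the (raw or balanced) Hi-C score between bin ``i`` and
    bin ``j`` of ``chrom``.  Invalid bins carry no score; their rows/columns
    are zero and must be ignored through ``valid_mask``.
    """

    chrom: str
    resolution: int
    values: np.ndarray
    valid_mask: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        self.values = v
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (v.shape[0],):
            raise ValueError("valid_mask length must equal matrix dimension")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def check_symmetric(self, tol: float = 0.0) -> None:
        dev = np.abs(self.values - self.values.T).max() if self.n_bins else 0.0
        if dev > tol:
            raise ValueError(f"matrix not symmetric (max deviation {dev:.3e})")

    def scaled(self, factor: float) -> "ContactMatrix":
        return replace(self, values=self.values * factor)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            chrom=self.chrom,
            resolution=self.resolution,
            values=self.values.copy(),
            valid_mask=self.valid_mask.copy(),
            weights=None if self.weights is None else self.weights.copy(),
        )


@dataclass
class GenomicTrack:
    """Per-interval real-valued signal (DamID log-ratio, GC fraction, ...).

    Intervals are sorted and non-overlapping per chromosome; ``value`` may be
    NaN for explicitly missing records.
    """

    df: pd.DataFrame  # columns: chrom, start, end, value
    resolution: int | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "value"]
        if list(self.df.columns[:4]) != required:
            self.df = self.df.rename(
                columns=dict(zip(self.df.columns[:4], required))
            )
        self.df = self.df.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def to_bins(self, chrom: str, n_bins: int, resolution: int) -> np.ndarray:
        """Average the track onto a uniform bin grid (NaN where uncovered).

        Overlap-weighted mean of record values per target bin.
        """
        out = np.full(n_bins, np.nan)
        weight = np.zeros(n_bins)
        acc = np.zeros(n_bins)
        sub = self.for_chrom(chrom)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            if not np.isfinite(value):
                continue
            b0 = int(start) // resolution
            b1 = min((int(end) - 1) // resolution, n_bins - 1)
            for b in range(b0, b1 + 1):
                if b < 0 or b >= n_bins:
                    continue
                ov = min(end, (b + 1) * resolution) - max(start, b * resolution)
                if ov > 0:
                    acc[b] += ov * value
                    weight[b] += ov
        covered = weight > 0
        out[covered] = acc[covered] / weight[covered]
        return out


# ---------------------------------------------------------------------------
# text I/O


def read_bins(path: str | Path) -> BinTable:
    """Read a 4-column bin table (chrom, start, end, index), 0-based half-open."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "index"],
        comment="#",
    )
    if df.empty:
        raise ContactParseError(f"{path}: empty bin table")
    resolution = int((df["end"] - df["start"]).max())
    chroms = tuple(dict.fromkeys(df["chrom"]))
    cmap = {c: i for i, c in enumerate(chroms)}
    return BinTable(
        chroms=chroms,
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        chrom_of=df["chrom"].map(cmap).to_numpy(np.int64),
        resolution=resolution,
    )


def write_bins(bins: BinTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        idx_within: dict[int, int] = {}
        for i in range(len(bins)):
            ci = int(bins.chrom_of[i])
            k = idx_within.get(ci, 0)
            idx_within[ci] = k + 1
            fh.write(
                f"{bins.chroms[ci]}\t{bins.starts[i]}\t{bins.ends[i]}\t{k}\n"
            )


def read_contacts(
    path: str | Path,
    format: str,
    bins: BinTable,
    chrom: str | None = None,
) -> ContactMatrix:
    """Read a contact matrix from COO-triplet or dense text.

    COO dialect: whitespace-separated ``bin_i bin_j score`` with 0-based bin
    indices *within the chromosome*; either triangle accepted; duplicate
    (i,j)/(j,i) entries summed.  Unlisted pairs are zero.  An empty file yields
    an all-zero matrix with every bin masked invalid.
    """
    if chrom is None:
        if len(bins.chroms) != 1:
            raise ValueError("chrom must be given for a multi-chromosome bin table")
        chrom = bins.chroms[0]
    n = bins.n_bins(chrom)
    if format == "coo":
        mat = np.zeros((n, n))
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                try:
                    i, j = int(parts[0]), int(parts[1])
                    score = float(parts[2])
                except (IndexError, ValueError) as exc:
                    raise ContactParseError(
                        f"{path}: malformed COO line {lineno}: {line!r}"
                    ) from exc
                if not (0 <= i < n and 0 <= j < n):
                    raise ContactParseError(
                        f"{path}: line {lineno}: bin index out of range "
                        f"({i}, {j}) for {n} bins"
                    )
                mat[i, j] += score
                if i != j:
                    mat[j, i] += score
    elif format == "dense":
        try:
            mat = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ContactParseError(f"{path}: malformed dense matrix") from exc
        if mat.size == 0:
            mat = np.zeros((n, n))
        if mat.shape != (n, n):
            raise ContactParseError(
                f"{path}: dense matrix shape {mat.shape} does not match {n} bins"
            )
        mat = 0.5 * (mat + mat.T)
    else:
        raise ValueError(f"unknown contact format {format!r}")
    valid = mat.any(axis=0) | mat.any(axis=1)
    return ContactMatrix(
        chrom=chrom, resolution=bins.resolution, values=mat, valid_mask=valid
    )


def write_contacts(m: ContactMatrix, path: str | Path, format: str = "coo") -> None:
    """Write the upper triangle (COO) or full dense text matrix."""
    if format == "coo":
        iu, ju = np.triu_indices(m.n_bins)
        vals = m.values[iu, ju]
        nz = vals != 0
        with open(path, "w") as fh:
            for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")
    elif format == "dense":
        np.savetxt(path, m.values)
    else:
        raise ValueError(f"unknown contact format {format!r}")


def read_bedgraph(path: str | Path, resolution: int | None = None) -> GenomicTrack:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    return GenomicTrack(df=df, resolution=resolution)


def write_bedgraph(track: GenomicTrack, path: str | Path) -> None:
    track.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# balancing and distance normalisation


def balance_kr(
    m: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 1000,
    min_nnz: int = 10,
    mask_percentile: float = 2.0,
) -> ContactMatrix:
    """Balance a symmetric contact matrix to the Knight–Ruiz fixed point.

    Finds per-bin weights ``w`` such that ``w_i * x_ij * w_j`` has equal row
    sums over valid bins, by symmetric Sinkhorn–Knopp iteration (for a
    symmetric non-negative matrix this converges to the same doubly-stochastic
    scaling as Knight–Ruiz, up to a global factor).  The output is rescaled so
    the mean valid row sum is 1.

    Bins with fewer than ``min_nnz`` off-mask nonzero entries, or raw marginal
    below the ``mask_percentile``-th percentile of nonzero marginals, are
    masked before iterating (near-empty rows make the scaling diverge).

    Convergence is declared when the coefficient of variation of valid row
    sums drops below ``tol``; otherwise :class:`BalanceConvergenceError`.
    """
    m.check_symmetric(tol=1e-9)
    x = np.array(m.values, dtype=float)
    valid = m.valid_mask.copy()

    nnz = (x > 0).sum(axis=1)
    valid &= nnz >= min_nnz
    marg = x.sum(axis=1)
    pos = marg[valid & (marg > 0)]
    if pos.size:
        cutoff = np.percentile(pos, mask_percentile)
        valid &= marg >= cutoff
    x[~valid, :] = 0.0
    x[:, ~valid] = 0.0

    n = x.shape[0]
    w = np.ones(n)
    w[~valid] = 0.0
    if not valid.any():
        return ContactMatrix(
            chrom=m.chrom,
            resolution=m.resolution,
            values=np.zeros_like(x),
            valid_mask=valid,
            weights=w,
        )

    deviation = np.inf
    for _ in range(max_iter):
        s = w * (x @ w)
        sv = s[valid]
        mean = sv.mean()
        deviation = sv.std() / mean if mean > 0 else np.inf
        if deviation <= tol:
            break
        upd = np.ones(n)
        upd[valid] = np.sqrt(sv / mean)
        w /= upd
    else:
        raise BalanceConvergenceError(deviation, max_iter)

    balanced = (w[:, None] * x) * w[None, :]
    balanced = np.triu(balanced) + np.triu(balanced, k=1).T  # exact symmetry
    # normalise mean valid row sum to 1
    rs = balanced[valid].sum(axis=1).mean()
    if rs > 0:
        balanced /= rs
        w /= np.sqrt(rs)
    return ContactMatrix(
        chrom=m.chrom,
        resolution=m.resolution,
        values=balanced,
        valid_mask=valid,
        weights=w,
    )


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean score per genomic separation ``d`` over valid bin pairs.

    Returns an array of length ``n_bins`` where entry ``d`` is the average of
    ``values[i, i+d]`` over pairs with both bins valid.  Separations with no
    valid pair are filled by linear interpolation between neighbouring
    observed separations (constant extrapolation at the ends).
    """
    if not m.valid_mask.any():
        raise ValueError("all bins masked: expected profile undefined")
    n = m.n_bins
    v = np.where(
        m.valid_mask[:, None] & m.valid_mask[None, :], m.values, np.nan
    )
    expected = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(v, offset=d)
        good = np.isfinite(diag)
        if good.any():
            expected[d] = diag[good].mean()
    obs = np.flatnonzero(np.isfinite(expected))
    if obs.size == 0:
        raise ValueError("no valid pair at any separation")
    missing = np.flatnonzero(~np.isfinite(expected))
    if missing.size:
        expected[missing] = np.interp(missing, obs, expected[obs])
    return expected


def observed_over_expected(m: ContactMatrix) -> ContactMatrix:
    """Divide each score by the expected value at its separation.

    Pairs whose expected value is zero become NaN (missing).
    """
    expected = expected_by_distance(m)
    n = m.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp_mat = expected[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp_mat > 0, m.values / exp_mat, np.nan)
    oe[~m.valid_mask, :] = np.nan
    oe[:, ~m.valid_mask] = np.nan
    return ContactMatrix(
        chrom=m.chrom,
        resolution=m.resolution,
        values=oe,
        valid_mask=m.valid_mask.copy(),
        weights=None if m.weights is None else m.weights.copy(),
    )


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate a contact matrix to ``factor``-times coarser bins by summation.

    A coarse bin is valid if at least half of its fine bins are valid.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = m.n_bins
    nc = -(-n // factor)
    pad = nc * factor - n
    v = np.pad(m.values, ((0, pad), (0, pad)))
    mask = np.pad(m.valid_mask, (0, pad))
    coarse = v.reshape(nc, factor, nc, factor).sum(axis=(1, 3))
    coarse = np.triu(coarse) + np.triu(coarse, k=1).T  # exact symmetry
    frac_valid = mask.reshape(nc, factor).mean(axis=1)
    cmask = frac_valid >= 0.5
    return ContactMatrix(
        chrom=m.chrom,
        resolution=m.resolution * factor,
        values=coarse,
        valid_mask=cmask,
    )
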