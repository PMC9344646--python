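"""Insulation-score TAD boundary calling and boundary-centred profiles.

The insulation score of bin ``i`` is the mean balanced contact score over the
``w × w`` square of bin pairs immediately flanking ``i`` (rows ``i-w .. i-1``,
columns ``i+1 .. i+w``), i.e. the contacts that *cross* the bin.  Reported
values are log2-normalised to the chromosome mean, so TAD boundaries appear as
local minima around 0.  Boundaries are called from the delta vector — the
difference between the mean insulation over a short flank to the left and to
the right of each bin — at downward zero crossings that coincide with a local
insulation minimum, filtered by a strength threshold.

TADs are the genomic regions between two consecutive kept boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_io import ContactMatrix, GenomicTrack

__all__ = [
    "InsulationProfile",
    "TadSegmentation",
    "BoundaryMatchReport",
    "EnrichmentProfile",
    "insulation_score",
    "call_boundaries",
    "match_boundaries",
    "boundary_enrichment",
]


@dataclass
class InsulationProfile:
    """Per-bin insulation values for one chromosome.

    ``log2_insulation`` is log2(raw / chromosome mean of raw); ``delta`` is the
    left-minus-right flank mean of the log2 insulation.  ``valid`` flags bins
    where the full window fits in the chromosome and at least half the window
    pairs are unmasked.
    """

    chrom: str
    resolution: int
    window: int
    raw: np.ndarray
    log2_insulation: np.ndarray
    delta: np.ndarray
    valid: np.ndarray


@dataclass
class TadSegmentation:
    """Ordered boundary bins with strengths, and the TADs between them.

    ``boundaries`` are bin indices (strictly increasing); ``tads`` is an array
    of (start_bin, end_bin) half-open intervals, one per consecutive boundary
    pair.
    """

    chrom: str
    resolution: int
    boundaries: np.ndarray
    strengths: np.ndarray
    n_bins: int
    explicit_tads: np.ndarray | None = None  # set by the permutation control

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.strengths = np.asarray(self.strengths, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def tads(self) -> np.ndarray:
        """(n_tads, 2) half-open bin intervals between consecutive boundaries.

        A permuted segmentation may carry explicit intervals instead (its TAD
        layout can have a gap where the rotated layout wraps the chromosome).
        """
        if self.explicit_tads is not None:
            return self.explicit_tads
        b = self.boundaries
        if len(b) < 2:
            return np.empty((0, 2), dtype=np.int64)
        return np.column_stack([b[:-1], b[1:]])

    @property
    def tad_sizes_bp(self) -> np.ndarray:
        t = self.tads
        return (t[:, 1] - t[:, 0]) * self.resolution

    def positions_bp(self) -> np.ndarray:
        """Boundary positions as bin-midpoint genomic coordinates."""
        return (self.boundaries + 0.5) * self.resolution


@dataclass
class BoundaryMatchReport:
    matches: list[tuple[int, int]]
    fraction_a: float
    fraction_b: float

    @property
    def mean_fraction(self) -> float:
        return 0.5 * (self.fraction_a + self.fraction_b)


@dataclass
class EnrichmentProfile:
    """Mean signal around boundaries at fixed offsets.

    ``sem`` is sample SD / sqrt(n) across the aggregated boundary set.
    """

    offsets_bp: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_boundaries: int
    n_dropped: int = 0


def insulation_score(m: ContactMatrix, window: int = 500_000) -> InsulationProfile:
    """Windowed cross-bin contact average, log2-normalised to chromosome mean.

    ``window`` (bp) must be an integer multiple of the matrix resolution and
    smaller than the chromosome.  A bin is scored only if the full square fits
    within the chromosome and >= 50% of its pairs involve valid bins.
    """
    if window % m.resolution != 0:
        raise ValueError("window must be an integer multiple of the resolution")
    w = window // m.resolution
    n = m.n_bins
    if w < 1 or 2 * w + 1 > n:
        raise ValueError(
            f"window of {w} bins does not fit a chromosome of {n} bins"
        )

    vals = np.where(
        m.valid_mask[:, None] & m.valid_mask[None, :], m.values, 0.0
    )
    pair_ok = (m.valid_mask[:, None] & m.valid_mask[None, :]).astype(float)
    # summed-area tables for O(1) rectangle sums
    sat_v = np.zeros((n + 1, n + 1))
    sat_v[1:, 1:] = vals.cumsum(0).cumsum(1)
    sat_c = np.zeros((n + 1, n + 1))
    sat_c[1:, 1:] = pair_ok.cumsum(0).cumsum(1)

    def rect(sat: np.ndarray, r0: np.ndarray, r1: np.ndarray, c0: np.ndarray, c1: np.ndarray) -> np.ndarray:
        # half-open [r0, r1) x [c0, c1)
        return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]

    idx = np.arange(n)
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    inside = (idx >= w) & (idx + w < n)
    ii = idx[inside]
    s = rect(sat_v, ii - w, ii, ii + 1, ii + 1 + w)
    c = rect(sat_c, ii - w, ii, ii + 1, ii + 1 + w)
    ok = (c >= 0.5 * w * w) & m.valid_mask[ii]
    raw_in = np.where(c > 0, s / np.maximum(c, 1.0), np.nan)
    raw[ii[ok]] = raw_in[ok]
    valid[ii[ok]] = True

    log2_ins = np.full(n, np.nan)
    mean_raw = np.nanmean(raw[valid]) if valid.any() else np.nan
    if valid.any() and mean_raw > 0:
        with np.errstate(divide="ignore"):
            log2_ins[valid] = np.log2(raw[valid] / mean_raw)
        valid &= np.isfinite(log2_ins)

    delta = _delta_vector(log2_ins, valid, flank=max(2, w // 5))
    return InsulationProfile(
        chrom=m.chrom,
        resolution=m.resolution,
        window=window,
        raw=raw,
        log2_insulation=log2_ins,
        delta=delta,
        valid=valid,
    )


def _delta_vector(ins: np.ndarray, valid: np.ndarray, flank: int) -> np.ndarray:
    """Left-flank mean minus right-flank mean of the insulation profile.

    Positive upstream of a minimum, negative downstream, so boundaries are
    downward zero crossings.
    """
    n = len(ins)
    delta = np.full(n, np.nan)
    for i in range(n):
        if not valid[i]:
            continue
        lo = max(0, i - flank)
        hi = min(n, i + flank + 1)
        left = ins[lo:i][valid[lo:i]]
        right = ins[i + 1 : hi][valid[i + 1 : hi]]
        if left.size and right.size:
            delta[i] = left.mean() - right.mean()
    return delta


def call_boundaries(
    p: InsulationProfile, strength_min: float = 0.1
) -> TadSegmentation:
    """Call TAD boundaries at downward zero crossings of the delta vector.

    A candidate crossing between bins ``k`` and ``k+1`` (delta changing sign
    from >= 0 to < 0) is placed at the local insulation minimum within one bin
    of the crossing; its strength is the delta swing across the crossing
    (local delta maximum on the left flank minus local delta minimum on the
    right flank).  Candidates with strength below ``strength_min`` or that are
    not local insulation minima are discarded.
    """
    ins, delta, valid = p.log2_insulation, p.delta, p.valid
    n = len(ins)
    flank = max(2, (p.window // p.resolution) // 5)
    boundaries: list[int] = []
    strengths: list[float] = []
    scored = np.flatnonzero(valid & np.isfinite(delta))
    for a, b in zip(scored[:-1], scored[1:]):
        if b - a > flank:  # crossing across a gap is unreliable
            continue
        if not (delta[a] >= 0 and delta[b] < 0):
            continue
        # boundary bin: insulation minimum near the crossing
        cand = [k for k in range(max(0, a - 1), min(n, b + 2)) if valid[k]]
        bin_ = min(cand, key=lambda k: ins[k])
        lo = max(0, a - flank)
        hi = min(n, b + flank + 1)
        left = delta[lo : a + 1][np.isfinite(delta[lo : a + 1])]
        right = delta[b:hi][np.isfinite(delta[b:hi])]
        strength = float(left.max() - right.min()) if left.size and right.size else 0.0
        # require a genuine local minimum of insulation
        neigh = [k for k in (bin_ - 1, bin_ + 1) if 0 <= k < n and valid[k]]
        if neigh and any(ins[k] < ins[bin_] for k in neigh):
            continue
        if strength < strength_min:
            continue
        if boundaries and bin_ - boundaries[-1] <= 1:
            # merge twin calls, keep the stronger
            if strength > strengths[-1]:
                boundaries[-1], strengths[-1] = bin_, strength
            continue
        boundaries.append(int(bin_))
        strengths.append(strength)
    return TadSegmentation(
        chrom=p.chrom,
        resolution=p.resolution,
        boundaries=np.array(boundaries, dtype=np.int64),
        strengths=np.array(strengths),
        n_bins=n,
    )


def match_boundaries(
    a: TadSegmentation, b: TadSegmentation, tol_bins: int = 3
) -> BoundaryMatchReport:
    """Greedy nearest-first one-to-one boundary matching within a tolerance.

    A pair matches iff the distance between boundary positions (bin-midpoint
    coordinates) is at most ``tol_bins * resolution``.  Ties are broken by
    the leftmost genomic coordinate of the pair.
    """
    if a.resolution != b.resolution:
        raise ValueError("segmentations must share a resolution")
    if a.chrom != b.chrom:
        raise ValueError("segmentations must be on the same chromosome")
    pa, pb = a.positions_bp(), b.positions_bp()
    tol = tol_bins * a.resolution
    cand = [
        (abs(pa[i] - pb[j]), min(pa[i], pb[j]), i, j)
        for i in range(len(pa))
        for j in range(len(pb))
        if abs(pa[i] - pb[j]) <= tol
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    fa = len(matches) / len(pa) if len(pa) else 0.0
    fb = len(matches) / len(pb) if len(pb) else 0.0
    return BoundaryMatchReport(matches=matches, fraction_a=fa, fraction_b=fb)


def boundary_enrichment(
    track: GenomicTrack,
    seg: TadSegmentation,
    flank: int = 150_000,
) -> EnrichmentProfile:
    """Aggregate a signal track around boundary centres.

    The track is resampled to the segmentation's resolution; for each offset
    in ``-flank .. +flank`` (steps of one bin) the mean and standard error of
    the signal across the boundary set are reported.  Boundaries whose window
    leaves the chromosome are dropped and counted.
    """
    if len(seg.boundaries) == 0:
        raise ValueError("empty boundary set")
    res = seg.resolution
    fb = flank // res
    binned = track.to_bins(seg.chrom, seg.n_bins, res)
    rows = []
    dropped = 0
    for b in seg.boundaries:
        if b - fb < 0 or b + fb >= seg.n_bins:
            dropped += 1
            continue
        rows.append(binned[b - fb : b + fb + 1])
    if not rows:
        raise ValueError("no boundary window fits inside the chromosome")
    data = np.vstack(rows)
    nb = data.shape[0]
    mean = np.nanmean(data, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(data, axis=0, ddof=1) if nb > 1 else np.zeros(data.shape[1])
    sem = sd / np.sqrt(nb)
    offsets = (np.arange(-fb, fb + 1)) * res
    return EnrichmentProfile(
        offsets_bp=offsets, mean=mean, sem=sem, n_boundaries=nb, n_dropped=dropped
    )
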