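"""Synthetic Hi-C contact maps with planted TADs, compartments and LADs.

The generator emulates the statistical structure the downstream analyses
assume: a power-law distance decay ``(1+d)^alpha``, a multiplicative
intra-TAD contact boost ``beta``, a compartment checkerboard (``gamma`` for
same-compartment bin pairs, ``1/gamma`` for opposite), Poisson counting noise
at a configurable sequencing depth, and a KO condition in which selected
inter-TAD rectangles are multiplied by a planted factor ``f = 2^{±delta}``.

Design notes:

* TADs tile each chromosome; planted boundaries are the internal cuts.
* Compartment blocks are unions of consecutive whole TADs, so compartment
  edges coincide with TAD boundaries.  Without this, checkerboard edges would
  plant unlabeled insulation dips indistinguishable from TAD boundaries.
* LAD status is assigned per TAD, enriched in B compartments; the emitted
  DamID lamin log-ratio track (100 kb bins) is positive over LAD bins.
* Weakened KO pairs are drawn preferentially from mixed LAD/non-LAD pairs
  (default 75%), the asymmetry the lamina analysis is designed to detect;
  strengthened pairs are drawn uniformly from the remaining eligible pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .contact_io import (
    BinTable,
    ContactMatrix,
    GenomicTrack,
    write_bedgraph,
    write_bins,
    write_contacts,
)
from .tad_calling import TadSegmentation

__all__ = [
    "GenomeSpec",
    "SyntheticTruth",
    "generate_truth",
    "render_contact_map",
    "write_fixture_bundle",
    "evaluate_boundaries",
    "planted_compartment_at",
]

TRACK_RESOLUTION = 100_000  # DamID and GC tracks are emitted at 100 kb


@dataclass
class GenomeSpec:
    """Parameters of the planted genome and of the contact-map noise model.

    Defaults describe one 10 Mb chromosome binned at 25 kb with 5 million
    expected contacts: log-normal TAD sizes (median ~800 kb, clipped to
    [200 kb, 3 Mb]), distance-decay exponent -1, a 3x intra-TAD boost and a
    1.6x compartment checkerboard.  ``depth`` is the expected total contact
    count per chromosome; when None it scales as 5e5 per Mb.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    resolution: int = 25_000
    tad_size_median: int = 800_000
    tad_size_sigma: float = 0.35
    tad_size_min: int = 200_000
    tad_size_max: int = 3_000_000
    compartment_block_tads: float = 2.5  # mean block length in TADs (geometric)
    lad_prob_b: float = 0.70  # P(TAD is LAD | B compartment)
    lad_prob_a: float = 0.25  # P(TAD is LAD | A compartment)
    alpha: float = -1.0
    beta: float = 3.0
    gamma: float = 1.6
    depth: float | None = None
    delta_log2: float = 1.25  # planted |log2 factor| of perturbed pairs
    weakened_fraction: float = 0.24  # of eligible (both TADs > min_tad_bp) pairs
    strengthened_fraction: float = 0.18
    mixed_weakened_prop: float = 0.75
    min_tad_bp: int = 500_000
    seed: int = 7

    def __post_init__(self) -> None:
        if self.alpha >= 0:
            raise ValueError("distance-decay exponent alpha must be negative")
        if self.beta <= 1 or self.gamma <= 1:
            raise ValueError("beta and gamma must exceed 1")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length % self.resolution != 0:
                raise ValueError(
                    f"{chrom}: length must be a multiple of the resolution"
                )
            if self.tad_size_min >= length:
                raise ValueError(f"{chrom}: minimum TAD size exceeds chromosome")

    def depth_for(self, chrom: str) -> float:
        if self.depth is not None:
            return self.depth
        return 0.5 * self.chrom_lengths[chrom] / 1e6 * 1e6  # 5e5 per Mb


@dataclass
class SyntheticTruth:
    """Planted structure underlying a WT/KO contact-map pair."""

    spec: GenomeSpec
    boundaries: dict[str, np.ndarray]  # internal cut bins per chromosome
    tads: dict[str, np.ndarray]  # (n_tads, 2) half-open bin intervals
    compartment: dict[str, np.ndarray]  # per-bin sign (+1 = A, -1 = B)
    tad_lad: dict[str, np.ndarray]  # per-TAD lamina association
    ko_factors: dict[str, dict[tuple[int, int], float]]  # (tad_i, tad_j) -> f
    damid: GenomicTrack
    gc: GenomicTrack

    def segmentation(self, chrom: str) -> TadSegmentation:
        """Planted segmentation including the chromosome-end cuts."""
        n = self.spec.chrom_lengths[chrom] // self.spec.resolution
        bounds = np.concatenate([[0], self.boundaries[chrom], [n]])
        return TadSegmentation(
            chrom=chrom,
            resolution=self.spec.resolution,
            boundaries=bounds,
            strengths=np.zeros(len(bounds)),
            n_bins=n,
        )

    def planted_logfc(self, chrom: str) -> dict[tuple[int, int], float]:
        """log2(X_wt / X_ko) implied by the planted factor of each pair."""
        return {k: -np.log2(f) for k, f in self.ko_factors[chrom].items()}


def generate_truth(spec: GenomeSpec) -> SyntheticTruth:
    """Draw the planted boundaries, compartments, LADs and KO factors."""
    rng = np.random.default_rng(spec.seed)
    boundaries: dict[str, np.ndarray] = {}
    tads: dict[str, np.ndarray] = {}
    compartment: dict[str, np.ndarray] = {}
    tad_lad: dict[str, np.ndarray] = {}
    ko_factors: dict[str, dict[tuple[int, int], float]] = {}
    damid_rows = []
    gc_rows = []

    for chrom, length in spec.chrom_lengths.items():
        n = length // spec.resolution
        t = _draw_tads(spec, n, rng)
        tads[chrom] = t
        boundaries[chrom] = t[1:, 0].copy()

        comp_tad = _draw_compartment_blocks(len(t), spec.compartment_block_tads, rng)
        comp = np.empty(n, dtype=np.int8)
        for (s, e), c in zip(t, comp_tad):
            comp[s:e] = c
        compartment[chrom] = comp

        lad_p = np.where(comp_tad < 0, spec.lad_prob_b, spec.lad_prob_a)
        lad = rng.random(len(t)) < lad_p
        tad_lad[chrom] = lad

        ko_factors[chrom] = _draw_ko_factors(spec, t, lad, rng)

        dam, gc = _tracks_for_chrom(spec, chrom, t, lad, comp, rng)
        damid_rows.append(dam)
        gc_rows.append(gc)

    damid = GenomicTrack(pd.concat(damid_rows, ignore_index=True), TRACK_RESOLUTION)
    gc = GenomicTrack(pd.concat(gc_rows, ignore_index=True), TRACK_RESOLUTION)
    return SyntheticTruth(
        spec=spec,
        boundaries=boundaries,
        tads=tads,
        compartment=compartment,
        tad_lad=tad_lad,
        ko_factors=ko_factors,
        damid=damid,
        gc=gc,
    )


def _draw_tads(spec: GenomeSpec, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Tile the chromosome with log-normal TAD sizes (bins)."""
    res = spec.resolution
    mu = np.log(spec.tad_size_median)
    edges = [0]
    while edges[-1] < n_bins:
        size_bp = float(np.exp(rng.normal(mu, spec.tad_size_sigma)))
        size_bp = min(max(size_bp, spec.tad_size_min), spec.tad_size_max)
        size = max(1, int(round(size_bp / res)))
        edges.append(min(edges[-1] + size, n_bins))
    # keep the terminal TAD within the size bounds: merge a short sliver into
    # its neighbour, or split the union in half if merging would overshoot
    min_bins = max(1, spec.tad_size_min // res)
    max_bins = spec.tad_size_max // res
    if len(edges) > 2 and edges[-1] - edges[-2] < min_bins:
        union = edges[-1] - edges[-3]
        if union <= max_bins:
            edges.pop(-2)
        else:
            edges[-2] = edges[-3] + union // 2
    return np.column_stack([edges[:-1], edges[1:]]).astype(np.int64)


def _draw_compartment_blocks(
    n_tads: int, mean_block: float, rng: np.random.Generator
) -> np.ndarray:
    """Alternating A/B signs over blocks of consecutive TADs."""
    sign = int(rng.choice([-1, 1]))
    out = np.empty(n_tads, dtype=np.int8)
    i = 0
    p = 1.0 / max(mean_block, 1.0)
    while i < n_tads:
        block = int(rng.geometric(p))
        out[i : i + block] = sign
        sign = -sign
        i += block
    return out


def _draw_ko_factors(
    spec: GenomeSpec,
    tads: np.ndarray,
    lad: np.ndarray,
    rng: np.random.Generator,
) -> dict[tuple[int, int], float]:
    """Assign perturbation factors to eligible TAD pairs.

    Weakened pairs (f = 2^-delta) are drawn preferentially from mixed
    LAD/non-LAD pairs; strengthened pairs (f = 2^+delta) uniformly from the
    remaining eligible pairs.
    """
    sizes_bp = (tads[:, 1] - tads[:, 0]) * spec.resolution
    big = np.flatnonzero(sizes_bp > spec.min_tad_bp)
    pairs = [
        (int(big[a]), int(big[b]))
        for a in range(len(big))
        for b in range(a + 1, len(big))
    ]
    if not pairs:
        return {}
    mixed = [p for p in pairs if lad[p[0]] != lad[p[1]]]
    concordant = [p for p in pairs if lad[p[0]] == lad[p[1]]]
    n_weak = int(round(spec.weakened_fraction * len(pairs)))
    n_weak_mixed = min(int(round(spec.mixed_weakened_prop * n_weak)), len(mixed))
    n_weak_conc = min(n_weak - n_weak_mixed, len(concordant))

    def sample(pool: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
        idx = rng.choice(len(pool), size=k, replace=False) if k else []
        return [pool[i] for i in np.atleast_1d(idx)]

    weakened = sample(mixed, n_weak_mixed) + sample(concordant, n_weak_conc)
    taken = set(weakened)
    rest = [p for p in pairs if p not in taken]
    n_str = min(int(round(spec.strengthened_fraction * len(pairs))), len(rest))
    strengthened = sample(rest, n_str)

    factors: dict[tuple[int, int], float] = {}
    for p in weakened:
        factors[p] = float(2.0 ** (-spec.delta_log2))
    for p in strengthened:
        factors[p] = float(2.0 ** (+spec.delta_log2))
    return factors


def _tracks_for_chrom(
    spec: GenomeSpec,
    chrom: str,
    tads: np.ndarray,
    lad: np.ndarray,
    comp: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DamID lamin log-ratio and GC-fraction tracks on the 100 kb grid."""
    length = spec.chrom_lengths[chrom]
    res = spec.resolution
    lad_bins = np.zeros(length // res, dtype=bool)
    for (s, e), is_lad in zip(tads, lad):
        if is_lad:
            lad_bins[s:e] = True
    factor = TRACK_RESOLUTION // res
    n_track = -(-len(lad_bins) // factor)
    pad = n_track * factor - len(lad_bins)
    lad_frac = np.pad(lad_bins.astype(float), (0, pad)).reshape(n_track, factor).mean(1)
    comp_mean = np.pad(comp.astype(float), (0, pad)).reshape(n_track, factor).mean(1)
    starts = np.arange(n_track) * TRACK_RESOLUTION
    ends = np.minimum(starts + TRACK_RESOLUTION, length)
    damid_values = 0.8 * (2.0 * lad_frac - 1.0) + rng.normal(0, 0.3, n_track)
    gc_values = 0.42 + 0.04 * comp_mean + rng.normal(0, 0.005, n_track)
    dam = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "value": damid_values}
    )
    gc = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "value": gc_values}
    )
    return dam, gc


def render_contact_map(
    truth: SyntheticTruth,
    condition: str = "wt",
    noiseless: bool = False,
    noise_seed: int | None = None,
) -> dict[str, ContactMatrix]:
    """Sample Poisson contact maps (or return the expectation directly).

    ``condition`` is ``"wt"`` or ``"ko"``; in the KO the planted rectangles
    between perturbed TAD pairs are multiplied by their factor.  The Poisson
    draw is seeded independently of the truth (``noise_seed``), so WT
    replicates are obtained by re-rendering with a different noise seed.
    """
    if condition not in ("wt", "ko"):
        raise ValueError("condition must be 'wt' or 'ko'")
    spec = truth.spec
    if noise_seed is None:
        noise_seed = spec.seed + (1 if condition == "wt" else 2)
    rng = np.random.default_rng(noise_seed)
    out: dict[str, ContactMatrix] = {}
    for chrom in spec.chrom_lengths:
        lam = _expected_matrix(truth, chrom, condition)
        if noiseless:
            values = lam
        else:
            iu, ju = np.triu_indices(lam.shape[0])
            counts = rng.poisson(lam[iu, ju])
            values = np.zeros_like(lam)
            values[iu, ju] = counts
            values[ju, iu] = counts
        out[chrom] = ContactMatrix(
            chrom=chrom,
            resolution=spec.resolution,
            values=values.astype(float),
            valid_mask=np.ones(lam.shape[0], dtype=bool),
        )
    return out


def _expected_matrix(truth: SyntheticTruth, chrom: str, condition: str) -> np.ndarray:
    spec = truth.spec
    n = spec.chrom_lengths[chrom] // spec.resolution
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    lam = (1.0 + d).astype(float) ** spec.alpha

    tad_id = np.empty(n, dtype=np.int64)
    for k, (s, e) in enumerate(truth.tads[chrom]):
        tad_id[s:e] = k
    lam *= np.where(tad_id[:, None] == tad_id[None, :], spec.beta, 1.0)

    comp = truth.compartment[chrom].astype(float)
    lam *= spec.gamma ** (comp[:, None] * comp[None, :])

    # depth scale fixed from the unperturbed expectation, so planted KO
    # factors translate exactly into inter-TAD ratios (global depth
    # imbalance is what the LogFC median-centering absorbs downstream)
    iu, ju = np.triu_indices(n)
    lam *= spec.depth_for(chrom) / lam[iu, ju].sum()

    if condition == "ko":
        for (i1, i2), f in truth.ko_factors[chrom].items():
            s1, e1 = truth.tads[chrom][i1]
            s2, e2 = truth.tads[chrom][i2]
            lam[s1:e1, s2:e2] *= f
            lam[s2:e2, s1:e1] *= f
    return lam


def write_fixture_bundle(
    truth: SyntheticTruth,
    maps: dict[str, dict[str, ContactMatrix]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write COO matrices, bin table, tracks, boundary BED and truth JSON.

    ``maps`` maps condition name -> chromosome -> matrix.  Everything is
    plain text and loadable back through :mod:`tadlamina.contact_io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = truth.spec
    paths: dict[str, Path] = {}

    bins = BinTable.from_chrom_sizes(spec.chrom_lengths, spec.resolution)
    paths["bins"] = outdir / "bins.bed"
    write_bins(bins, paths["bins"])

    for cond, per_chrom in maps.items():
        for chrom, m in per_chrom.items():
            key = f"matrix_{cond}_{chrom}"
            paths[key] = outdir / f"{cond}.{chrom}.coo.txt"
            write_contacts(m, paths[key], format="coo")

    paths["damid"] = outdir / "damid.bedgraph"
    write_bedgraph(truth.damid, paths["damid"])
    paths["gc"] = outdir / "gc.bedgraph"
    write_bedgraph(truth.gc, paths["gc"])

    paths["boundaries"] = outdir / "planted_boundaries.bed"
    with open(paths["boundaries"], "w") as fh:
        for chrom, bnds in truth.boundaries.items():
            for b in bnds:
                fh.write(
                    f"{chrom}\t{b * spec.resolution}\t{(b + 1) * spec.resolution}\t"
                    f"planted\n"
                )

    paths["truth"] = outdir / "truth.json"
    blob = {
        "spec": {
            **{k: v for k, v in asdict(spec).items() if k != "chrom_lengths"},
            "chrom_lengths": dict(spec.chrom_lengths),
        },
        "boundaries": {c: v.tolist() for c, v in truth.boundaries.items()},
        "tads": {c: v.tolist() for c, v in truth.tads.items()},
        "compartment": {c: v.tolist() for c, v in truth.compartment.items()},
        "tad_lad": {c: v.astype(int).tolist() for c, v in truth.tad_lad.items()},
        "ko_factors": {
            c: [[int(i), int(j), f] for (i, j), f in fac.items()]
            for c, fac in truth.ko_factors.items()
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(blob, fh, indent=1)
    return paths


def decoupled_track(track: GenomicTrack, seed: int) -> GenomicTrack:
    """Shuffle a track's values within each chromosome (null construction).

    Keeps the per-chromosome value distribution but destroys any positional
    linkage with the contact structure — the no-association null for the
    lamina classification and its permutation control.
    """
    rng = np.random.default_rng(seed)
    df = track.df.copy()
    for chrom in df["chrom"].unique():
        sel = df["chrom"] == chrom
        vals = df.loc[sel, "value"].to_numpy().copy()
        rng.shuffle(vals)
        df.loc[sel, "value"] = vals
    return GenomicTrack(df=df, resolution=track.resolution)


# ---------------------------------------------------------------------------
# truth-evaluation helpers


def evaluate_boundaries(
    called: TadSegmentation, planted: np.ndarray, tol_bins: int = 1
) -> tuple[float, float]:
    """(recall, precision) of called boundary bins against planted cut bins.

    One-to-one greedy matching within ``tol_bins``; the planted cut bin ``b``
    is taken to match a call at ``b`` or ``b - 1`` (both bins flank the cut),
    extended by the tolerance.
    """
    calls = list(called.boundaries)
    planted = list(planted)
    cand = sorted(
        (min(abs(c - p), abs(c - (p - 1))), p, c)
        for p in planted
        for c in calls
        if min(abs(c - p), abs(c - (p - 1))) <= tol_bins
    )
    used_p: set[int] = set()
    used_c: set[int] = set()
    n_match = 0
    for _, p, c in cand:
        if p in used_p or c in used_c:
            continue
        used_p.add(p)
        used_c.add(c)
        n_match += 1
    recall = n_match / len(planted) if planted else 1.0
    precision = n_match / len(calls) if calls else 1.0
    return recall, precision


def planted_compartment_at(
    truth: SyntheticTruth, chrom: str, resolution: int
) -> np.ndarray:
    """Planted compartment sign averaged onto a coarser bin grid."""
    comp = truth.compartment[chrom].astype(float)
    factor = resolution // truth.spec.resolution
    n = -(-len(comp) // factor)
    pad = n * factor - len(comp)
    return np.pad(comp, (0, pad)).reshape(n, factor).mean(1)
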