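"""A/B compartment calling from the contact-correlation leading eigenvector.

Per chromosome, the balanced matrix is distance-normalised (observed over
expected), the Pearson correlation matrix of the valid bins is formed, and the
eigenvector of its largest eigenvalue is taken.  The sign is oriented so the
eigenvector correlates non-negatively with GC content; positive bins are the
active, GC-rich A compartment, negative bins are B.  Bins with |EV| below a
small cutoff stay unlabeled — compartment identity near zero is noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact_io import ContactMatrix, GenomicTrack, observed_over_expected

__all__ = [
    "CompartmentProfile",
    "CompartmentChangeSet",
    "compartment_eigenvector",
    "compare_compartments",
    "call_compartment_changes",
]

UNDEFINED_EV = 1e-3  # |eigenvector| below this -> label undefined


@dataclass
class CompartmentProfile:
    """Oriented per-bin leading eigenvector and A/B labels for one chromosome."""

    chrom: str
    resolution: int
    eigenvector: np.ndarray  # oriented; NaN on invalid bins
    labels: np.ndarray  # 'A', 'B', or '' (undefined)
    orientation_sign: int
    variance_explained: tuple[float, float]  # leading, second
    gc_degenerate: bool = False

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.eigenvector)


@dataclass
class CompartmentChangeSet:
    """Maximal runs of bins whose A/B label flips between two conditions."""

    chrom: str
    resolution: int
    regions: pd.DataFrame  # columns: chrom, start, end, direction ('A->B'/'B->A')

    def __len__(self) -> int:
        return len(self.regions)


def compartment_eigenvector(
    m: ContactMatrix, gc: GenomicTrack
) -> CompartmentProfile:
    """Leading eigenvector of the O/E Pearson-correlation matrix, GC-oriented.

    ``m`` must be a balanced matrix (conventionally at 100 kb).  The
    correlation matrix is computed over valid bins only; the eigenvector is
    embedded back onto the full grid with NaN at invalid bins.  If the Pearson
    correlation between eigenvector and GC is exactly zero the solver's sign
    is kept and the profile flagged degenerate.
    """
    valid = m.valid_mask.copy()
    if valid.sum() < 10:
        raise ValueError(
            f"only {int(valid.sum())} valid bins on {m.chrom}: too few for "
            "compartment calling"
        )
    oe = observed_over_expected(m)
    sub = oe.values[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 0.0)
    sd = sub.std(axis=1)
    keep = sd > 0
    if keep.sum() < 10:
        raise ValueError(f"degenerate O/E matrix on {m.chrom}")
    idx = np.flatnonzero(valid)[keep]
    corr = np.corrcoef(sub[np.ix_(keep, keep)])
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    lead = evecs[:, order[0]]
    var1 = float(abs(evals[order[0]]))
    var2 = float(abs(evals[order[1]])) if len(evals) > 1 else 0.0
    if var2 > 0 and var1 < 2 * var2:
        warnings.warn(
            f"{m.chrom}: leading eigenvalue {var1:.3g} < 2x second "
            f"{var2:.3g}; possible chromosome-arm artifact",
            stacklevel=2,
        )

    ev = np.full(m.n_bins, np.nan)
    ev[idx] = lead

    gc_bins = gc.to_bins(m.chrom, m.n_bins, m.resolution)
    both = np.isfinite(ev) & np.isfinite(gc_bins)
    sign = 1
    degenerate = False
    gc_sd = np.std(gc_bins[both]) if both.any() else 0.0
    gc_scale = max(np.abs(gc_bins[both]).max(), 1.0) if both.any() else 1.0
    if both.sum() >= 3 and np.std(ev[both]) > 0 and gc_sd > 1e-12 * gc_scale:
        r = float(np.corrcoef(ev[both], gc_bins[both])[0, 1])
        if r < 0:
            sign = -1
        elif r == 0:
            degenerate = True
    else:
        degenerate = True
    ev *= sign

    labels = np.full(m.n_bins, "", dtype=object)
    defined = np.isfinite(ev) & (np.abs(ev) >= UNDEFINED_EV)
    labels[defined & (ev > 0)] = "A"
    labels[defined & (ev < 0)] = "B"
    return CompartmentProfile(
        chrom=m.chrom,
        resolution=m.resolution,
        eigenvector=ev,
        labels=labels,
        orientation_sign=sign,
        variance_explained=(var1, var2),
        gc_degenerate=degenerate,
    )


def compare_compartments(
    profiles_a: list[CompartmentProfile], profiles_b: list[CompartmentProfile]
) -> tuple[dict[str, float], float]:
    """Per-chromosome Pearson r between oriented eigenvectors, and their mean.

    The genome-wide value is the unweighted mean of per-chromosome r.
    Chromosomes with fewer than 3 shared valid bins are skipped with a
    warning.
    """
    by_chrom_b = {p.chrom: p for p in profiles_b}
    per_chrom: dict[str, float] = {}
    for pa in profiles_a:
        pb = by_chrom_b.get(pa.chrom)
        if pb is None:
            continue
        both = pa.valid & pb.valid
        if both.sum() < 3:
            warnings.warn(
                f"{pa.chrom}: fewer than 3 shared valid bins, skipped",
                stacklevel=2,
            )
            continue
        a, b = pa.eigenvector[both], pb.eigenvector[both]
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"{pa.chrom}: constant eigenvector, skipped", stacklevel=2)
            continue
        if np.array_equal(a, b):
            per_chrom[pa.chrom] = 1.0  # exact, not up to rounding
        else:
            per_chrom[pa.chrom] = float(np.corrcoef(a, b)[0, 1])
    genome_wide = float(np.mean(list(per_chrom.values()))) if per_chrom else np.nan
    return per_chrom, genome_wide


def call_compartment_changes(
    a: CompartmentProfile, b: CompartmentProfile
) -> CompartmentChangeSet:
    """Maximal runs of bins labelled A in one condition and B in the other.

    Undefined bins break runs.  Each region reports its direction (the label
    change from condition ``a`` to condition ``b``) on the profile's bin grid.
    """
    if a.chrom != b.chrom or a.resolution != b.resolution:
        raise ValueError("profiles must share chromosome and grid")
    la, lb = a.labels, b.labels
    n = len(la)
    state = np.full(n, "", dtype=object)
    ab = (la == "A") & (lb == "B")
    ba = (la == "B") & (lb == "A")
    state[ab] = "A->B"
    state[ba] = "B->A"
    rows = []
    i = 0
    while i < n:
        if state[i] == "":
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        rows.append(
            {
                "chrom": a.chrom,
                "start": i * a.resolution,
                "end": (j + 1) * a.resolution,
                "direction": state[i],
            }
        )
        i = j + 1
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    return CompartmentChangeSet(chrom=a.chrom, resolution=a.resolution, regions=regions)
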