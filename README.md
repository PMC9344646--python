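# tadlamina

Downstream analysis of binned Hi-C contact maps for comparing chromatin 3D
organisation between two conditions (e.g. a wild-type and a knock-out cell
line): insulation-score TAD boundary calling, A/B compartment eigenvectors,
and — the centrepiece — a differential **inter-TAD interaction** analysis that
asks whether the TAD pairs whose long-range contacts change most are
preferentially anchored at the nuclear lamina.  A first-class synthetic-data
module generates contact maps with *planted* TADs, compartments,
lamina-associated domains (LADs) and per-pair perturbations, so every stage of
the pipeline can be scored against known truth.

Intended users: computational genomicists who already have binned,
intra-chromosomal contact matrices (any text COO/dense export) and genomic
signal tracks (DamID lamin log-ratio, GC content) and want a small,
transparent, fully testable implementation of this analysis chain.

## The analysis

**Balancing.** Matrices are scaled to the Knight–Ruiz fixed point
`w_i x_ij w_j` with equal row sums over valid bins (low-coverage bins are
masked first).

**TAD boundaries.** The insulation score of bin *i* is the mean balanced
contact over the `w × w` square of bin pairs crossing *i* (default window
500 kb at 25 kb resolution), reported as log2 ratio to the chromosome mean.
Boundaries are downward zero crossings of the delta vector (left-flank minus
right-flank mean insulation) that are local insulation minima, filtered by a
strength threshold.  TADs are the regions between consecutive boundaries.
Boundary sets from two conditions are overlapped with a 3-bin tolerance,
greedy nearest-first, one-to-one.

**Compartments.** Per chromosome at 100 kb, the leading eigenvector of the
Pearson-correlation matrix of the observed/expected map; the sign is oriented
so the eigenvector correlates positively with GC content (A = positive =
active/GC-rich, B = negative).  Conditions are compared by per-chromosome
Pearson *r*, and A↔B label flips are emitted as compartment-change regions.

**Inter-TAD fold change and lamina association.** For two TADs with sizes
`a1`, `a2` (bins), the interaction is the average score over their rectangle

```
X12 = Σ_{i∈TAD1, j∈TAD2} x_ij / (a1·a2)
```

Per pair, `FC = X_wt / X_ko` and `LogFC = log2(FC)` median-centered
genome-wide (so 0 = no relative change and global depth differences cancel).
TADs larger than 500 kb are retained; pairs with `LogFC > 1` (interaction
halved in KO) form the *decreased* set, `LogFC < −1` the *increased* set — a
per-distance top-*k* selection is available as an alternative.  Each TAD's
lamina association is its mean DamID log-ratio (100 kb bins); a pair is
**mixed** when exactly one TAD is lamina-associated.  A permutation control
re-lays shuffled TAD sizes at a random circular offset per chromosome and
repeats the identical selection and classification, and TAD size
distributions of the two selected sets are compared with a two-sample
Kolmogorov–Smirnov test.

## Worked example

Run the whole pipeline on the default synthetic genome (one 10 Mb chromosome
at 25 kb, 5×10⁶ contacts, seed 7):

```
tadlamina run --out runs/demo
```

Abridged summary (the full JSON is printed and written to
`runs/demo/summary.json`):

```json
{
 "boundaries": {"n_planted": 12, "n_called_wt": 11,
                "recall": 0.917, "precision": 1.0,
                "overlap_wt_ko": {"mean": 1.0},
                "overlap_wt_rep": {"mean": 1.0}},
 "compartments": {"mean_abs_r_vs_planted": 0.987, "n_change_regions": 2},
 "intertad": {"n_pairs": 45, "median_logfc": 0.0,
              "n_decreased": 9, "n_increased": 7,
              "lad_percentages": {"decreased": {"mixed": 77.8},
                                  "increased": {"mixed": 57.1}},
              "logfc_vs_planted_r": 0.992,
              "ks": {"d": 0.262, "p": 0.557}}
}
```

Reading this: 11 of the 12 planted boundaries are recalled with no false
calls (the twelfth sits inside the unscored 500 kb chromosome edge); the
compartment eigenvector tracks the planted compartment vector at r = 0.99;
the recovered LogFC correlates with the planted per-pair log2 factors at
r = 0.99 with an exactly null median; and the decreased set is dominated by
mixed LAD/non-LAD pairs (77.8%), the asymmetry the generator planted.  On a
single 10 Mb chromosome the selected sets are small — the genome-scale run
below is the statistically meaningful version.

Individual stages are also exposed (`tadlamina simulate | boundaries |
match | enrich | compartments | compartment-diff | intertad`), all reading
plain-text COO/dense matrices, BED and bedGraph; `--help` documents each.

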