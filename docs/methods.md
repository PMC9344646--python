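# Methods

This note records the models, numerical choices and known limitations behind
`tadlamina`.  Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs measure.

## Contact-matrix model and balancing

Contact maps are dense, symmetric, intra-chromosomal matrices with an
explicit per-bin validity mask; missing data never travel as zeros.  All
declared file formats are plain text: COO triplets (`bin_i bin_j score`,
0-based within-chromosome indices, either triangle, duplicates summed),
dense whitespace matrices, BED-like bin tables and bedGraph tracks, all
0-based half-open.  Trans-chromosomal contacts are out of scope — every
downstream statistic here is cis.

Balancing finds weights `w` with `w_i x_ij w_j` having equal row sums over
valid bins.  For a symmetric non-negative matrix the symmetric
Sinkhorn–Knopp iteration used here converges to the Knight–Ruiz fixed point
(unique up to a global factor); we declare convergence when the coefficient
of variation of valid row sums falls below `tol = 1e-5` (`max_iter = 1000`)
and rescale so the mean valid row sum is 1.  Near-empty rows make the
scaling diverge, so bins with fewer than `min_nnz = 10` nonzero entries or
with raw marginal below the 2nd percentile are masked first.  The output is
re-symmetrised exactly (upper triangle mirrored) so symmetry holds at the
representation level, not merely to rounding.

The distance-expected profile is the mean score per separation over valid
pairs, linearly interpolated across separations with no valid pair;
observed/expected divides by it (expected 0 ⇒ missing).  O/E is invariant to
positive rescaling of the input — asserted as a property test.

## Insulation score and boundary calling

The insulation score of bin *i* is the mean balanced score over the
`w × w` bin-pair square immediately flanking *i* (rows `i−w … i−1`, columns
`i+1 … i+w`), with `w` = window / resolution (default 500 kb / 25 kb = 20
bins).  A bin is scored only when the full square fits inside the chromosome
— the first and last window-widths are unscored, not extrapolated — and at
least 50% of the square's pairs involve valid bins (bounding bias near
gaps).  Reported values are log2 ratios to the chromosome mean of the raw
score.

The delta vector is the left-flank minus right-flank mean of the log2
insulation (flank = `max(2, w/5)` bins).  With this sign convention an
insulation minimum is a *downward* zero crossing of delta.  A candidate
boundary is placed at the insulation minimum within one bin of the crossing;
its strength is the delta swing across the crossing (local delta maximum on
the left minus local minimum on the right, searched within one flank);
candidates below `strength_min = 0.1`, or that are not local insulation
minima, are discarded, and twin calls on adjacent bins are merged keeping
the stronger.  Crossings that span a masked gap wider than the flank are
skipped rather than interpolated.

Boundary positions are bin midpoints, which makes cross-resolution
comparisons well defined; matching between two boundary sets is greedy by
increasing distance (ties to the leftmost coordinate), one-to-one, with a
3-bin tolerance by default.  The overlap report returns the matched
fraction of either set; where one number is needed the mean of the two
directional fractions is used.

## Compartments

Per chromosome at 100 kb: O/E → Pearson correlation matrix over valid bins
→ leading eigenvector (dense symmetric solver).  The correlation matrix, not
the raw map, is decomposed, following standard first-eigenvector compartment
practice.  The sign is flipped so the correlation with GC content is
non-negative; if that correlation is numerically zero (below 1e-12 relative)
the solver's sign is kept and the profile flagged degenerate.  |EV| < 1e-3
leaves the bin unlabeled rather than forcing A/B — compartment identity near
zero is noise.  A warning (not an error) is raised when the leading
eigenvalue is less than twice the second, a situation typical of
chromosome-arm artifacts; no arm splitting is attempted.  Condition
comparison is the unweighted mean of per-chromosome Pearson r (a bin-weighted
average would be the alternative; on the synthetic fixtures the two differ
negligibly because chromosomes are equal-sized).  Change regions are maximal
runs of A↔B label flips; unlabeled bins break runs.

## Inter-TAD fold change and lamina association

`X12 = Σ x_ij / (a1·a2)` over the TAD1×TAD2 rectangle of the balanced map,
with sizes in bins.  Masked pairs contribute zero to the numerator but stay
in the denominator — the definition divides by the full rectangle area — and
pairs with more than 50% masked area are excluded and counted.  Fold changes
are log2 with the genome-wide median subtracted, so the null is exactly 0
and any global depth mismatch between conditions cancels; `median(LogFC) = 0`
is asserted on every run.  No additional depth scaling is applied.  The
reference segmentation is always the WT one; TADs above 500 kb are retained.

Two selection modes exist because both are natural: a global cut
(`|LogFC| > 1`, i.e. a factor-2 change; the default) and a per-distance
top-/bottom-k (k = 2) that equalises genomic distances.  TAD distance is the
number of intervening *retained* TADs by default (a flag switches to all
called TADs).  Lamina association per TAD is the mean DamID lamin log-ratio
over the 100 kb track bins whose centres fall inside the TAD; positive mean
⇒ lamina-associated (log-ratio tracks are signed; no better-motivated cutoff
exists).  A pair is *mixed* when exactly one TAD is associated.

**Permutation control.**  TAD sizes are shuffled per chromosome and re-laid
end-to-end — but from a uniformly random circular offset, with the single
TAD straddling the wrap cut dropped into the margin.  Plain shuffling from
the chromosome start conserves the size multiset exactly but pins early
boundaries near their true positions (cumulative sums are anchored), which
we measured to retain most of the planted lamina/fold-change association —
an under-dispersed null.  The rotation makes the null position-free at the
cost of one TAD per permutation.  Selection and classification are repeated
identically per permutation and the mixed-percentage distributions returned.

Because the generator plants the lamina/fold-change association as a
*positional field* (perturbation factors constant over whole TAD-pair
rectangles, LAD status constant over TADs), any size-conserving permutation
on the same chromosome still samples nearly the same fields, and the control
retains the association on planted fixtures — honestly reported in the run
summary.  The control's null behaviour is therefore verified separately with
a lamina track value-shuffled within each chromosome (same marginal
distribution, no positional linkage): there the permutation distribution
shows no decreased/increased separation beyond 2 SD.  Both controls are in
the summary (`permutation` and `permutation_null_damid`).

## Synthetic-data generator

The generator emulates what the analyses assume about real maps:

- **Distance decay** `(1+d)^α`, α = −1 (canonical contact decay).
- **TADs**: log-normal sizes, median 800 kb, σ(log) = 0.35, clipped to
  [200 kb, 3 Mb], tiling each chromosome; a terminal sliver is merged into
  its neighbour, or the union split in half if merging would exceed 3 Mb, so
  planted sizes always respect the bounds.  Intra-TAD contacts are boosted
  by β = 3.
- **Compartments**: blocks of consecutive whole TADs (geometric block length,
  mean 2.5 TADs) labeled A/B alternately; same-compartment pairs ×γ,
  opposite ×1/γ, γ = 1.6.  Aligning block edges to TAD boundaries is
  deliberate: a checkerboard edge inside a TAD would plant an insulation dip
  indistinguishable from an unlabeled boundary, corrupting the ground truth
  the boundary tests score against.  GC is emitted at 100 kb as
  0.42 + 0.04·(A-ness) + N(0, 0.005).
- **LADs**: per-TAD lamina status with P(LAD|B) = 0.70, P(LAD|A) = 0.25
  (odds ratio ≈ 7, overall LAD fraction ≈ 0.5); DamID at 100 kb is
  0.8·(2·LAD-fraction − 1) + N(0, 0.3), so a >500 kb TAD's mean is reliably
  signed.
- **KO perturbation**: among pairs of retained (>500 kb) TADs, 24% are
  weakened (factor 2^−δ) and 18% strengthened (2^+δ), δ = 1.25; weakened
  pairs are drawn 75% from mixed LAD/non-LAD pairs (the asymmetry the
  analysis is built to detect), strengthened pairs uniformly.  The fractions
  keep unperturbed pairs the majority, so the LogFC median stays anchored at
  the null.
- **Noise**: Poisson counts on the upper triangle at a depth of 5×10⁵
  contacts per Mb per chromosome (5×10⁶ on the default 10 Mb chromosome).
  The intensity scale is fixed from the *unperturbed* expectation, so
  planted factors translate exactly into noiseless inter-TAD ratios.
  Overdispersion (negative binomial) is not modeled; a dispersion hook would
  slot into the intensity construction.  WT replicates re-draw only the
  Poisson noise.

What the generator does **not** emulate: restriction-fragment structure,
trans contacts, copy-number variation, mappability-driven coverage bias
along the genome, sub-compartments, and TAD nesting.  Passing tests
therefore demonstrate correctness and statistical power of the *analysis
chain* under a clean generative model, not robustness to every artifact of
real libraries.

## Fixture sizes

The default fixture is one 10 Mb chromosome at 25 kb (400 bins, ~12 TADs) —
large enough for boundary/compartment/fold-change recovery with margin.
Lamina-class percentages need hundreds of selected pairs, so the
genome-scale fixture used by the acceptance run is 6 × 40 Mb (≈4800 retained
pairs, ≈900 decreased), where the planted 75% mixed proportion is read back
within binomial error.  Both complete in well under a minute on one CPU.

## Reproducibility

Every stochastic step takes an explicit integer seed; the pipeline derives
stage seeds by fixed offsets from the run seed, and a rerun with the same
configuration is byte-identical (asserted for summaries and fixture files).
The run manifest records the configuration snapshot, seed, package versions
and SHA-256 of every output.
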