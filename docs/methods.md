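# Methods

## Model and assumptions

`taxalist` scores missense variants from a query-anchored MSA: every homolog
is stored as one contiguously aligned section in the coordinates of the query
protein, tagged with an NCBI-style taxonomy id.  The method assumes that
(i) the best local match around a position comes from a functionally related
homolog, and (ii) the phenotypic effect of an amino acid at a position
depends on how much taxonomy lineage the carrying species shares with the
reference species.  Conservation is therefore summarized not by residue
frequencies but by where in the taxonomy tree matching residues occur.

Coordinates are 1-based and inclusive everywhere a user can see them.
Multiple aligned sections of the same subject protein are independent
segments; no attempt is made to stitch them.  Query-side gaps (subject
insertions) consume no query position but are recorded as events so that the
two aligned residues flanking every gap — on either side, in query
coordinates — can be flagged as boundary (BND) residues.  BND residues count
as mismatches in all identity measures, and a BND residue at the scored
position forces LI = 0.

Sections are filtered before scoring: percent identity must exceed 40%
(identical residues over aligned, non-gap columns, BND as mismatch) and the
aligned length must reach min(70, ceil(0.7 × query length)).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window | 9 | LI window (position itself excluded), so LI ∈ [0, 8] |
| α | 4 | minimum LI_max for a VST match to be trusted (guard is ≥ α) |
| MAX_ST | 32 | edges of the packaged reference lineage; same-species ST |
| C | 0.2 | clip margin of the rescaled pseudo-probabilities |
| depth fallback | 3 | below this alignment depth, median module scores are used |
| ω grid | 0.1…1.0 | per-module weight range of the fusion |

Window size and α are fixed constants of the method (originally obtained by
grid search on large variant sets); they are exposed as configuration only.

The packaged human lineage has exactly 32 edges: the NCBI lineage plus one
synthetic tribe-level node below Homininae, inserted so that the reference
depth matches a 31-element shared-taxa profile (indices 1..31 for other
species, 32 reserved for same-species matches) while every clade split that
anchors the scale (goldfish 13, rodents 22) is preserved.  This packaged
lineage is normative for the package.  Same-species segments are excluded
from STP by default; `include_max_st` counts them at element 31 instead.
Inside PVM the VST is clamped to 31 so same-species matches score 0 rather
than negative.

## Training

* **PM2 profiles** use only positions carrying variants of a single class;
  positions with both classes are excluded.  Center and span are element-wise
  mean-midpoint and mean-difference of the per-position `log10(1 + STP)`
  vectors.
* **AM** counts rare (deleterious-labeled) and common (benign-labeled)
  substitutions per (ref, alt) cell and row-normalizes.  +1 Laplace smoothing
  is on by default because 380 cells are easily undersampled; it is disabled
  for the exact-formula unit tests.
* **Depth compensation** bins alignment depth geometrically
  ({3, 10, 32, 100, 316, 1000, ∞} above the [0, 3) fallback bin); bins with
  fewer than 200 calibration points merge rightward.  The per-bin PM2
  "range" is read robustly as the 5th–95th percentile band (`range_mode=
  "minmax"` restores the literal min–max, which a single outlier can
  dominate).  Per-bin deleterious probabilities are Laplace-smoothed
  (k+1)/(n+2).  Depth < 3 variants first take the global median PVM/PM1/PM2
  and then pass through the same two compensation steps; a degenerate
  (constant) bin range maps onto the midpoint of the global range.
* **Weights ω** are searched per module on the 0.1-step grid by coordinate
  ascent (two sweeps), maximizing the AUC of the fused root score on the
  calibration labels with the redistribution maps refit per candidate.  On a
  separable objective this finds the same optimum as the full 10⁴-point grid
  (available via `full_grid`) at a fraction of the cost.  Ties prefer the
  smaller ω, so an uninformative module sinks to the 0.1 floor; when every
  module is individually near-perfect the AUC ties everywhere and all ω
  settle at the floor, which is harmless because fusion of tied modules
  preserves the ordering.
* **Redistribution maps** are monotone piecewise-linear quantile maps with
  1,001 knots (out-of-range inputs clamped; exact knot ties broken by an
  infinitesimal ramp).  Internal fusion nodes map onto the normal
  N(0.5, 0.01) truncated to [C, 1−C]; the root maps onto the uniform
  distribution, making the final score a rank score.
* The fusion formula is the independent naive-Bayes odds product
  Πp / (Πp + Π(1−p)); 0.5 is its identity element.  The default tree fuses
  PM1 with PM2 (position-level signal), then PVM, then AM, with
  redistribution after each internal node; the topology is stored in the
  model JSON and can be reconfigured there.
* Training is deterministic: no randomness enters after the input data.

When one labeled set is supplied, it calibrates both the module training and
the fusion structure; a second set can be passed to mirror a two-stage
optimization with disjoint data.

## Synthetic benchmark generator

The generator emulates the statistical structure the scorer consumes, not
sequence evolution.  Each protein gets a random query and full-length,
gapless segments covering every ST in 1..31 (plus extras); a depth profile
assigns 90% of proteins 32–64 segments and 10% only 3–20, exercising the
depth-compensation path.  Labeled positions are spaced 10 residues apart so
their LI windows never interact.  At each labeled position, per-ST carrier
segments receive a non-reference residue with probability
0.1 + 0.6·c·σ(±(st−18)/3) (rising with ST for benign, falling for
deleterious) and a planted LI drawn uniformly from {5..8} (benign) or {1..5}
(deleterious) at full contrast c = 1; the variant's own matching segment is
drawn with ST weights ∝ exp(±c·st/4), and no match is planted at all with
probability 0.434 (deleterious) / 0.151 (benign) — the no-match rates
observed for real variant classes.  Alternate residues are drawn from two
seeded Dirichlet substitution tables, giving a recoverable ground-truth
swap-ability matrix.  `planted_profiles` and `planted_am` return the
closed-form expectations implied by these rules, which the recovery tests
compare against trained parameters.

With c = 0 and equal no-match rates the generator is label-free by
construction: the null benchmark on which trained models must score at
chance.

What passing these tests shows — and does not show: recovery and AUC results
demonstrate that the estimators and the fusion machinery are correct and
well-calibrated on data satisfying the generator's assumptions (clean
windows, independent positions, exhaustive ST coverage, no gaps at scored
columns).  They do not certify performance on real alignments, where depth,
gap structure, and phylogenetic correlation between segments are far less
tidy.

## Numerical choices and degenerate inputs

* VST ties are broken LI → SI → ST → subject id, making selection a total
  order independent of segment input order.
* LI windows truncate at query and segment termini (positions near an end
  can never reach LI 8); a gap at the scored position never matches any
  variant.
* AM cells with zero probability in both classes score 0.5 (uninformative);
  the diagonal is undefined (NaN).
* `bayes_combine` requires inputs strictly inside (0, 1); the C-clipping of
  the rescale step guarantees this upstream.
* Degenerate rescale ranges and single-class calibration sets raise errors
  rather than producing silent constants.

## Problem sizes used in the shipped checks

The acceptance-scale benchmark uses 264 proteins of length 200 (≈5,000
labeled positions, ≈48 segments each); the null benchmark uses 212 proteins
with a 50/50 split (≈2,000 held-out variants).  The distributional contracts
(uniform final score, truncated-normal node scores) are checked on 10⁴-point
calibration samples.  These sizes give stable recovery statistics while
keeping a full run on a single CPU in the tens of seconds.

## Known limitations

* The aligned-FASTA input dialect cannot represent multiple aligned sections
  of one subject; use the segment TSV for that.
* Depth compensation assumes the calibration set covers the depth range of
  the scored proteins; unseen depths fall into the nearest bin.
* The generator plants at most one carrier segment per ST at a position, so
  planted STP values are exact but per-ST multiplicity is not modeled.
* Scores are protein-independent: no protein-level deleteriousness prior is
  used or intended.
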