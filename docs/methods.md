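# Methods

## Model

A single-valued neutrosophic set (SVNS) over a universe X = {x₁,…,xₙ}
assigns each element a triple (T, I, F) of truth, indeterminacy and
falsity degrees, each in [0, 1], with T + I + F ≤ 3; an interval-valued
neutrosophic set (IVNS) replaces each degree with a closed subinterval
of [0, 1], constraining the upper bounds' sum by 3.  The three degrees
are deliberately independent — no complementarity is imposed — which is
what lets a symptom be simultaneously somewhat indicative, somewhat
uncertain and somewhat contraindicated.

Containment is componentwise (T no larger, I and F no smaller, at every
criterion; all six bounds for intervals) and equality is mutual
containment.  An IVNS whose intervals are all degenerate (lo = hi)
reduces to an SVNS; `to_svns`/`to_ivns` implement the reduction and its
section, and every interval-valued measure in the package agrees with
its single-valued counterpart on degenerate data to machine precision
(tested).

## Distances and the pooling convention

The normalized Euclidean distance squares the componentwise differences,
averages and takes a square root.  There are two defensible places to
put the square root:

* **pooled** — one global root: √(Σᵢ Σ_c Δ²ᵢ_c /(3n)) (3 → 6 for
  intervals);
* **per_item** — root per criterion, then the mean:
  (1/n)·Σᵢ √(Σ_c Δ²ᵢ_c /3).

Both are in [0, 1], symmetric, zero exactly on equal profiles, and they
coincide at n = 1.  They are *not* equal in general (root of a mean vs
mean of roots).  The reference score tables bundled with the package are
reproducible cell-for-cell only under the per-item reading — the
distance complement row, the reciprocal row and the hybrid rows all
imply per-criterion-averaged distances wherever they are internally
consistent at all — so **per_item is the package default**, and the
pooled form is exposed as an explicit option for users who want the
formula as classically printed.  The min/max overlap ratio gets the same
treatment: grand ratio (pooled) vs mean of per-criterion ratios
(per_item).

## Similarity measures and their axioms

A genuine similarity measure satisfies (1) range [0, 1], (2) S = 1 iff
the sets are equal, (3) symmetry.  The per-criterion cosine measure
violates the "only if" half of (2): cosines are scale-blind, so
proportional unequal membership vectors score exactly 1.  The hybrid
measures S* = ½·(S + 1 − D) repair this because D = 0 forces equality;
they are strictly decreasing in D with the other term held fixed.  The
improved cosines (cos of a scaled absolute difference) and the
distance-derived measures SM, SD, SY are also genuine.

The axiom engine (`check_axioms`) verifies range/symmetry on independent
random pairs, identity on self-pairs, and genuineness by flagging any
unequal pair scoring within 10⁻⁹ of 1.  The 10⁻⁹ tolerance is
deliberate: the double-precision cosine of exactly proportional vectors
can land a few ulps from 1, and a strict equality test would mask the
pathology.  For the measures known to be non-genuine a constructed
proportional pair (base vector uniform on [0.3, 1]³, scale factor
uniform on [0.4, 0.8], single criterion — the pathology is per-element,
so the minimal witness is the most readable) is injected into the
sample, making the violation deterministic rather than a matter of
sampling luck.  Reports are fully replayable from (measure, seed,
samples).

## Numerical choices

* Everything is double precision; π at machine precision; all angles in
  radians.  The reference data are 1-decimal inputs and 4-decimal
  outputs, far from any precision limit.
* Cosine zero-vector policy: both vectors zero → the criterion
  contributes 1 (limit of identical inputs); exactly one zero → 0
  (maximal disagreement); a warning is emitted either way since the
  cosine itself is 0/0 there.
* Min/max ratio with a zero denominator (both elements identically
  zero at a criterion) contributes 1, by the same limit argument.
* `sy` returns 1 exactly when D = 0, avoiding 1/(1+0⁻)-style edge
  cases; its improved-cosine term defaults to the max-difference
  variant (`sc1`), which is the pairing under which the reference
  table's SY row is consistent where it is consistent at all; the
  sum-difference variant is a parameter.
* Ties in the diagnosis ranking are never broken arbitrarily: all
  co-winners are reported with a `ties` flag, and the stable sort keeps
  knowledge-base row order among equal scores.
* Rounding for table comparison is half-away-from-zero to 4 decimals
  (via `decimal`), not banker's rounding, matching how the reference
  values were printed.

## Table reproduction and source errata

`reproduce_tables` recomputes all 90 cells of the four reference tables
from the bundled fixtures under per_item pooling and classifies each
cell: **exact** (equal after 4-dp rounding), **truncated** (off by
exactly one unit in the 4th decimal — the reference mixes rounding and
truncation, e.g. the single-element hybrid value 0.81857 printed as
0.8185), or **erratum** (anything larger).  The errata are stable and
systematic: the distance-based rows of both comparison tables at the
columns whose implied distances contradict other rows of the same
source, and almost all of the interval hybrid table.  Recomputed values
are authoritative in this package; the published cells are retained
only for the delta report.  A pinned 4-dp baseline of the recomputation
distinguishes *regressions* (the code disagreeing with its own frozen
recomputation — exit code 2 in the CLI) from source errata (exit 0).

## Random-profile generator

`random_profile` draws components i.i.d. uniform on [0, 1] (interval
endpoints drawn in pairs and sorted), which makes every draw valid by
construction and covers the whole constraint polytope of the element
invariants.  It emulates nothing about clinical data — real relation
tables are expert-elicited, sparse in high indeterminacy, and
correlated across symptoms — so axiom sweeps over these draws establish
the algebraic properties of the measures everywhere on the domain, not
the measures' clinical discrimination, which is what the bundled
benchmark fixtures probe instead.  Sweep sizes used by the test suite
(10³ pairs per measure/kind for the axiom battery, 40-pair spot checks
in the unit tests, 5 criteria per profile) were chosen to exercise the
checks densely while keeping the whole suite in the tens of seconds.

## Scope and limitations

* No criterion weights: all sums are unweighted, matching how the
  measures are defined; weighting is a deliberate non-goal.
* No neutrosophic algebra (union/intersection/complement/aggregation):
  only containment and equality are needed by the measures.
* Only Euclidean distances; Hamming/Hausdorff families are out of
  scope.
* The argmax decision rule has no probabilistic calibration; scores are
  similarities, not posteriors.  An optional minimum-similarity warning
  threshold can flag low-confidence classifications but never alters
  the ranking.
* The scikit-learn estimator accepts flattened numeric profile
  matrices for pipeline compatibility; validation of the neutrosophic
  invariants still applies row by row, so arbitrary real matrices are
  rejected, which limits use of transformers that could push values
  outside [0, 1].
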