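# Methods

## Problem and model

`chromo3d` reconstructs a preferred 3D conformation of a single chromosome
from a Hi-C interaction-frequency (IF) matrix. The chromosome is divided
into fixed-size bins (1 MB or 200 KB); each bin is represented by the 3D
position of its midpoint, and the chromosome is the piece-wise linear curve
through those midpoints in genomic order. Centromere and unmappable bins
are recorded in the region table with `modeled = false` and dropped before
modeling; consecutive modeled bins flanking such a gap receive no adjacency
constraint, since the physical linker through the gap is not represented.

Rather than converting IFs into target distances, the method classifies
bin pairs and satisfies the classes directly:

1. **Normalization.** With row marginals `m_i` and grand total `T`
   (computed over the matrix as given), the normalized IF is the
   observed/expected likelihood ratio `N_ij = C_ij * T / (m_i * m_j)`.
   Bins with zero marginals are masked. Normalization is invariant to
   rescaling all counts; on a uniform matrix (identical entries including
   the diagonal) it returns exactly 1 everywhere.
2. **Filtering.** A pair (i, j) with `i + 1 < j` is a *contact* iff
   `N_ij > cutoff` (strict), otherwise a *non-contact*. Consecutive pairs
   (i, i+1) form the *adjacent* class regardless of IF, because a separate
   objective term governs them. Default cutoffs: 0.66 for 1 MB normal-cell
   maps, 2.0 for 200 KB, 0.5 for the leukemia-cell maps. Cutoff *selection*
   against an external feature (chromosome-territory contact percentages)
   is supported as a reporting aid (`contact_percentages`), not automated.
3. **Objective.** With squared pair distances `d2_ij` and thresholds in the
   squared convention,

   ```
   F =   sum_contacts    w_ij*W1*tanh(dc2 - d2_ij) + W2*tanh(d2_ij - dmin2)
       + sum_noncontacts W3*tanh(d2_ij - dc2)      + W3*tanh(dmax2 - d2_ij)
       + sum_adjacent    W4*tanh(dmaxadj2 - d2_ij) + W4*tanh(d2_ij - dmin2)
   ```

   Every constraint is a smooth tanh step, so F is differentiable and each
   pair contributes at most ±2 to its term. `w_ij` divides `N_ij` by the
   chromosome maximum IF (bounded in (0, 1]; `weight_denominator="total"`
   switches to the total-IF convention), so strong contacts pull harder.
4. **Optimization.** Coordinates start i.i.d. uniform on (−0.5, 0.5) and
   follow steepest gradient ascent with a backtracking (Armijo) line
   search. An ensemble is built from consecutive seeds; the representative
   model is the exact medoid under the distance 1/GDT-HA.

## Parameters

| name | meaning | default (1 MB) | default (200 KB) |
|------|---------|----------------|------------------|
| dc2 | squared contact distance threshold | 7.0 | 4.5 |
| dmin2 | squared excluded-volume floor | 0.04 | 0.02 |
| dmax2 | squared territory diameter bound | 20 | 20 |
| dmaxadj2 | squared adjacent-bin bound | 2.25 | 1.0 |
| W1..W4 | term weights | 1.0 | 1.0 |

Distances are in model units nominally calibrated to micrometers through
FISH measurements at the matching genomic separation. All thresholds are
applied to *squared* distances: the 1 MB squared contact threshold of 7.0
is the calibrated published convention (violation statistics near 10 for
unsatisfied contacts and near 5 for unsatisfied non-contacts are consistent
only with the squared reading), and the same convention holds the 200 KB
values. The 1 MB excluded-volume and adjacency bounds (0.04, 2.25) are
package defaults chosen inside the required ordering
`dmin2 < dmaxadj2` and `dmin2 < dc2 < dmax2`; the source calibration for
these two numbers is not available.

Term weights are chromosome-dependent in practice. `balanced_parameters`
implements the standard balancing heuristic: because the effective contact
pull is `w_ij * W1` with `w_ij` max-normalized, heavy-tailed IF
distributions collapse the typical pull, so W1 is set to `1 / mean(w_ij)`
(a value "around the average IF"), making the average contact force
comparable to the unit non-contact force. Raising W3 relative to W1 favors
non-contact satisfaction and vice versa; the robustness fixture uses
`W3 = 0.25` to emphasise contacts.

## Optimizer numerics

The line search walks along the *unit* gradient direction, so the step
size is a displacement in model units: initial step 0.1, shrink 0.5,
sufficient-increase constant 1e−4, at most 50 backtracks. This bounded
displacement matters: tanh constraints saturate a few squared-distance
units past their threshold, so an unbounded first step can inflate the
tiny random initial structure straight into the flat region where violated
contacts exert almost no force and the run stalls at a poor optimum.
Bounded steps let the structure expand quasi-statically, with each
constraint activating while its gradient is still informative. The run
stops when the relative improvement stays below 1e−7 for 10 consecutive
iterations, when the line search underflows (reported, not raised), or at
10 000 iterations. Accepted steps never decrease the objective, so the
trace is monotone by construction. Structures are centered at the origin
on output; no re-centering happens during optimization because the
objective depends only on pairwise distances.

## Model assessment

* A contact is satisfied iff `d2 < dc2` (strict); a non-contact iff
  `d2 >= dc2`. Reports carry the two satisfaction fractions, the
  IF-weighted satisfied percentage, and violation statistics (mean squared
  distance and mean IF of unsatisfied pairs); averages over empty sets are
  reported as absent, never zero.
* GDT-HA uses thresholds 2.0/1.5/1.0/0.5 after one global least-squares
  superposition (proper rotation via the Kabsch solution; no fragment
  search, for determinism). Contact data cannot distinguish a structure
  from its mirror image, so scores are mirror-aware by default: the
  reflected partner is also superposed and the larger score kept.
* The representative model of an ensemble is the exact K = 1 medoid under
  `1/GDT-HA` (floored at 1e−6; `1 − GDT-HA` available), ties to the lowest
  index — no iterative PAM is needed for a single cluster.
* Compartments: the first principal component of the Pearson-correlation
  matrix of the normalized map (PCA on the map itself is available) splits
  bins into two classes by sign. The self-contact diagonal is replaced by
  each bin's off-diagonal mean first; left at zero it injects artifact
  variance that can dominate small matrices. The sign convention anchors
  the largest-magnitude loading positive; labels are the neutral {1, 2},
  since naming which class is euchromatin needs external annotation.

## Synthetic data

The generator produces ground-truth structures and derived contact maps so
every stage is testable without external data:

* `random_walk` — unit-step chain confined to a sphere, resampling steps
  that leave the sphere or come within 0.5 units of an earlier point. The
  default confinement radius 2.2 is half the territory diameter `sqrt(20)`
  implied by `dmax2`, so a simulated truth satisfies every model constraint
  (a wider walk would violate the territory bound and make the truth
  infeasible under its own parameters). With `dc2 = 7` this yields dense
  maps (~75% of pairs in contact), matching small-chromosome 1 MB maps.
* `helix` — deterministic, equal consecutive spacing; `two_blob` — two
  Gaussian clusters for compartment tests.
* IF models: `binary` (count 1 iff `d2 < dc2`; exact round trips) and
  `inverse_distance` (expected count ∝ 1/d², floored at d² = 0.25, scale
  100 at unit distance). The `noise` parameter scales the Poisson mean
  down (`counts ~ Poisson(lambda/noise)`), so larger values mean sparser,
  noisier maps and `noise = 0` returns exact expectations. For graded IF
  fixtures, `matched_cutoff` picks the normalized-IF quantile whose
  exceedance fraction equals the truth's short-distance fraction — the
  fixture analogue of calibrating the cutoff against independent knowledge.

The robustness study uses a sparse regime — n = 60, confinement radius
4.5 with `dmax2 = 81`, graded IFs, balanced W1, W3 = 0.25 — emulating a
large, spread-out chromosome. In dense maps the optimizer can genuinely
satisfy the withheld-as-non-contact training constraints, so withheld
recovery falls below a random-placement baseline; in the sparse regime
withheld contacts are geometrically implied by the retained ones and
recovery (~60%) clearly exceeds the territory-random baseline (~13%),
with recovery increasing in IF quartile. The "random placement" baseline
is drawn uniformly in the territory ball of radius `sqrt(dmax2)/2`; a
structure drawn from the optimizer's initial range would trivially satisfy
every contact and is not a meaningful reference.

What the generator does **not** emulate: restriction-site, GC and
mappability biases; polymer persistence length and excluded-volume physics
beyond a minimum-spacing heuristic; inter-chromosomal contacts;
translocations. Passing tests therefore demonstrate the machinery is
correct and self-consistent, not that real chromatin follows the model.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale configurations chosen to
exercise the full pipeline: 30-bin dense instances with ensembles of 5–20,
a 60-bin robustness fixture with 5–20 replicates, 200-bin compartment
matrices. All randomness flows through explicit integer seeds (ensemble
member k uses `base_seed + k`), making every pipeline output a pure
function of its inputs; re-running a config reproduces outputs
bit-for-bit.

## Known limitations

* Per-chromosome weight tables must be supplied by the user; the package
  ships only the balancing heuristic, not an automatic score-balancing
  search.
* The gradient ascent finds local optima; mirror-image substructures are
  inherent to distance-only data and are handled at scoring time, not
  prevented.
* The FISH calibration procedure behind the distance thresholds is out of
  scope; its resulting values are configuration defaults.
* Only intra-chromosomal modeling is supported; whole-genome assembly of
  per-chromosome models is not attempted.
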