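# Methods

## DTW engine

The local cost between two M-dimensional elements is the squared Euclidean
norm and the reported distance is the accumulated cost at the end cell —
no final square root. This convention matters: the acceptance bounds
(r1·d̃ₖ and T) are compared against distances on this same scale, so all
DTW calls in the package share it. Warping paths satisfy the boundary,
monotonicity and continuity conditions; an optional Sakoe–Chiba window ξ
constrains |i−j| ≤ ξ.

Numerical choices:

* **Tie-breaking.** The recurrence minimum prefers the diagonal
  predecessor, then the vertical, then the horizontal. Returned paths are
  therefore pure functions of the inputs, which the generator relies on
  for bit-reproducibility.
* **Infeasible bands.** When ξ < |L1−L2| the end cell is unreachable. The
  generator's narrow sub-windows (⌈0.1·…⌉) frequently trigger this on
  unequal-length halves, so the default policy widens ξ to |L1−L2| and
  warns; a hard-error policy is available (`on_infeasible="error"`).
  Silent failure was not an option.
* **Accumulation** is in float64; the inner loop is numba-compiled, with
  the local-cost matrix vectorised through `scipy.cdist`.

The test oracle (`dtw_bruteforce`) enumerates every admissible path
explicitly (with cost-bound pruning) and never touches the recurrence; it
is guarded to ≤ 100 grid cells.

## Suboptimal-path generation

`split_point` redraws r whenever ⌈rL⌉ hits 0 or L on either series (the
sub-alignments need non-empty inputs); 128 draws before erroring. The two
half-paths are concatenated; because the second half is aligned on the
sub-grid starting at (R1+1, R2+1), the junction step is always the
diagonal. A subtle consequence, worth stating because it trips up naive
re-derivations: the construction's result is *not* in general the cheapest
full-grid path containing (R1, R2) — paths that pass through (R1, R2) and
then step horizontally or vertically are not producible. The constrained
enumeration oracle in the tests forces the diagonal junction accordingly.

Merging extends the scalar sampling law element-wise: per time step and
per dimension an independent draw from N(μ, σ²) with μ the midpoint and
σ = 0.05 of the gap. Identical aligned elements pass through exactly
(σ = 0), so identical parents reproduce themselves bit-for-bit.

## Class statistics and the DBA representative

Statistics are computed over all unordered distinct within-class training
pairs; the standard deviation uses the population convention (divide by
the number of pairs). Classes with one member, or with all members
identical (d̃ₖ = 0, which would divide by zero in T), are skipped by the
augmentation driver with a warning.

The representative is a DTW barycenter: initialised at the class medoid
(deterministic), then refined — align every member to the current
barycenter, replace each barycenter element by the mean of all member
elements aligned to it. The recorded objective is the sum over members of
the *squared* accumulated cost by default (`squared=True`); since the
accumulated cost is itself already a sum of squared differences, the
alternative reading (`squared=False`, treating the accumulated cost as the
squared dissimilarity) is available and is the quantity for which the
EM-style argument guarantees monotone decrease. Under the default the
trace still decreases in practice; to keep the non-increasing-trace
invariant exact, the loop stops and keeps the previous barycenter if an
update would raise the recorded objective. Defaults: 10 iterations,
relative tolerance 1e-5.

## Acceptance constraints

All four comparisons are strict, exactly as the formulas read. d1 is
computed against the first parent of the pair only (a symmetric min-over-
both-parents variant exists behind `symmetric_d1`, off by default). d1/d2
and the class statistics use unbanded DTW unless a global window is set in
the configuration — the generation-time sub-windows are part of the
generator and are always applied.

One property worth documenting because it is easy to get wrong: the
acceptance interval (r1·d̃ₖ, r1·d̃ₖ + d̂ₖ(r2 + d̂ₖ/d̃ₖ)) has constant
width in r1 — raising r1 *translates* the interval rather than shrinking
it, so the accepted count is not monotone in r1 (candidates enter and
leave the window as it slides). The genuine relaxation axis is r2: on a
fixed candidate stream, growing r2 only raises the upper bound, so the
accepted sets are nested. The tests assert exactly these two facts.

Ablation modes (`both`, `lower-only`, `upper-only`, `no-d1`, `no-d2`)
deactivate the named comparisons, supporting condition-importance
experiments.

## Descriptors

* DD distance ties are broken by subset order via a stable sort — needed
  for determinism; note this makes tied configurations (e.g. perfectly
  symmetric poses) sensitive to coordinate perturbations, which is
  inherent to rank features.
* Bone vectors point from the first-listed joint to the second; the
  central bone runs Spine→Head and the Darboux frame's origin Pc is the
  Spine joint. All frame vectors are unit-normalised before dot products
  and acos arguments are clamped to [−1, 1].
* θ uses the two-argument arctangent mapped to [0, 2π) (a one-argument
  atan would lose the quadrant), then normalises by 2π. θ is excluded from
  the default feature set; `include_theta=True` restores it.
* The kard15 bone subset uses Hand/Foot end effectors (that layout has no
  Wrist/Ankle joints); the 20-joint and florence15 subsets use
  Wrist/Ankle as listed.

## Synthetic data

The generators emulate the structure the method assumes: 8-ish similar
classes, few subjects, lengths 13–76, smooth class-specific motion,
per-subject constant offsets, monotone piecewise-linear time-warp jitter
(4 Dirichlet-weighted segments; jitter 0 = identity) and i.i.d. Gaussian
noise. Class templates are a shared base curve plus a class deviation
scaled by `separation`, so separation 0 collapses all classes (chance
accuracy) and the within/between distance ratio falls monotonically as
separation grows.

What they do not emulate: bone-length constancy under noise, joint-angle
limits, occlusion/tracking failures, or label noise. Passing tests
therefore demonstrate correctness of the algorithms and the direction of
the scarce-data effect on data with the assumed statistical structure,
not performance on any real motion-capture benchmark.

## Problem sizes and the scarce-data experiment

The shipped scarce-data experiment uses 8 classes × 12 series of 4-dim
feature curves from 6 subjects (separation 0.35, noise 0.45, subject scale
0.25, lengths 13–76), chosen so that raw full-training-set 1-NN DTW
accuracy lands near 0.74 — the difficulty band typical of small skeletal
action benchmarks — with training budgets of 3–5 series per class and 10
random subject-disjoint draws per budget. At these sizes the full suite
runs in well under a minute of DTW time while leaving the effect visible.

## Known limitations

* DBA barycenter length is fixed to the medoid's length; no length search.
* Whether statistics/DBA should share the generator's bands is an open
  modelling choice; the default (unbanded) avoids inventing a band, and a
  global window option covers the alternative.
* Rejected pairs are not retried with a fresh split; one candidate per
  pair per pass by default.
* The augmentation benefit on synthetic data is small (fractions of a
  percentage point at the smallest budgets); the filter's main observable
  effect is pruning redundant or out-of-territory candidates, visible in
  the acceptance reports.
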