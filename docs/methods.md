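# Methods

This note records how helixkink measures kink angles, how the confidence
intervals are calibrated, how conservation classes are assigned, what the
synthetic-helix generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Angle measurement

A kink angle is defined between the axes of two cylinders fitted to the
disjoint six-residue backbone segments flanking a site: residues `s−5…s`
(N-terminal) and `s+1…s+6` (C-terminal), the angle being assigned to the
final residue of the first segment. Each fit minimises

    r = sqrt( (1/m) Σᵢ (dᵢ − d̄)² ),  m = 24,

over the axis line, where `dᵢ` is the distance of backbone atom `i`
(N, CA, C, O of the six residues) from the axis and `d̄` their mean. The
mean radius is free per segment — the objective subtracts the segment's own
mean — so `r` penalises only spread, not absolute radius. Sites exist at
0-based indices `5 … L−7`; a 12-residue helix has exactly one site
(index 5) and shorter helices are rejected.

**Optimiser.** The axis is parameterised by four numbers: a direction tilt
`(a, b)` about the principal axis `u₀` of the 24 atoms
(`u = normalize(u₀ + a·e₁ + b·e₂)`) and an in-plane offset `(ox, oy)` of a
point the axis passes through. This chart is smooth near the optimum and
free of gimbal problems because the solution is always close to `u₀`.
Residuals `dᵢ − d̄` are minimised with a Levenberg–Marquardt least-squares
solver (tolerances 1e-12). Tests certify the optimum against a brute-force
2°-spaced direction grid with per-direction optimal positioning: the
optimiser is never worse, and the reported `r` is reproduced by an
independent plain-loop evaluation. Degenerate input (collinear or
coincident atoms, detected via the second singular value) raises rather
than returning a meaningless axis.

**Orientation.** An axis direction is a line, so its sign is fixed by
requiring a positive dot product with the first-to-last-residue centroid
displacement (N→C). Angles are then `arccos(u_n · u_c)` in degrees,
range [0, 180]; no swivel direction is measured. Angles are invariant
under rigid motions and reflections (tested to 1e-6°), and reversing the
residue order mirrors the profile.

## Confidence intervals

The half-width of the 95% confidence interval on a measured angle is
predicted from the summed flanking fit residuals:

    ε(x) = a·ln(x − c) + b,  x = r_n + r_c,

with published defaults a = 6.349°, b = 13.15°, c = 0.2937 Å (the
`published-default` model; the package never recomputes these silently).
Because the log diverges as `x → c⁺`, and a near-perfect helix can have
`x < c` (the ideal-helix floor is 0.27 Å < 0.2937 Å), ε is clamped at
`x = c + 0.01 Å`, making the map total and monotone non-decreasing.

**Recalibration.** `helixkink calibrate` rebuilds the curve from scratch:
for each of five synthetic kinks at 15°, 20°, 30°, 40°, 50° (all above the
10° exclusion below which the angle deviation stops depending only on
`r_n + r_c`), both optimal cylinder axes are rotated about the midpoints of
their atom spans by random rotations — rotation axis uniform on the sphere,
rotation angle uniform in (0°, 15°] — and each draw records the perturbed
angle deviation `α = θ' − θ_true` and the degraded `r_n + r_c` (mean radius
re-estimated per rotated axis, so the perturbed objective is exactly the
fit objective at a non-optimal axis). Draws are binned by `r_n + r_c` in
0.05 Å bins; bins under 100 samples are merged left-to-right; ε per bin is
the 95th percentile of |α| (linear interpolation between order statistics);
`(a, b, c)` come from a bounded least-squares fit of `a·ln(x − c) + b`
through the bin midpoints, initialised from a log-linear fit with `c`
bounded below the smallest midpoint. Parameter recovery from a known
generating curve is tested to 5%.

The synthetic calibration kinks are a stand-in for the well-fitted real
kinks the published curve was built from; their `r_n + r_c` range starts at
the synthetic ideal-helix floor (≈ 0.556 Å), so a recalibrated model's
coefficients differ from the published ones and the published model remains
the default.

**A deliberate asymmetry note.** The calibration assumes α is symmetric
about zero. In the simulation this holds only approximately: the measured
angle is a nonlinear function of the axis perturbation, convex near the
optimum, so random rotations bias α upward — about +1.7° at a 15° kink,
shrinking to +0.4° at 50°, small against the 5–8° error scale. The
percentile construction does not depend on symmetry: on independently
seeded fresh samples each bin's interval covers 95% ± 2% (the acceptance
script reports ~94.9–95.3% across seeds).

## Conservation classes

**Pairs.** The most disrupted site is the largest angle in either helix;
the partner angle is the largest in the other helix within ±4 alignment
columns (a window because both the kink position and the alignment carry
error); pairs with an all-gap window are removed, with a WARN naming the
rule. With `Δθ = θ_max − θ_min`:

| class | condition |
|---|---|
| ConservedStraight | θ_max < 20° |
| ConservedKinked | θ_min > 20° and Δθ < ε₁ + ε₂ |
| NotConserved | θ_max > 20° and Δθ > ε₁ + ε₂ |
| Other | everything else |

The rules partition the domain and are symmetric under swapping the
helices (property-tested). The 20° threshold is the conventional kink
cutoff and is configurable (`kink_threshold_deg`). A proline flag (proline
at the site residue or the four following residues of that helix, gaps
skipped) is emitted per helix.

**Families** (≥ 5 members). Each member's angles are mapped to alignment
columns and smoothed by a three-column window maximum, which absorbs
one-column alignment errors and therefore also extends one column past
isolated angles. The most disrupted column is the eligible column
(≥ 5 smoothed angles) with the highest mean, ties to the smallest index.
At that column the family statistics are the median angle, the sample
standard deviation σ_θ (n−1 denominator) and the mean error μ_ε; the class
rules mirror the pair rules with σ_θ vs μ_ε playing the role of Δθ vs
ε₁+ε₂, and ties (σ_θ = μ_ε) fall on the conserved side. μ_ε for a member
is the ε of the raw angle its smoothed value came from. The branch
conditions beyond "σ_θ is compared to μ_ε" were an open design point; the
mirror of the pair rules was chosen because it reproduces the intended
qualitative outcomes (a tight 40° family is ConservedKinked; a family
mixing straight and 35–45° members is NotConserved).

**Membership.** Candidate homologous pairs are screened by: longer chain
≤ 1.5× the shorter, TM-score > 0.5 (strict), alignment sequence identity
≥ 10%, both helix-end offsets ≤ 4 residues. Community detection on the
pair graph is external; the package implements only the pruning loop:
while any member is connected to ≤ 90% of the others, remove the
lowest-connectivity member (ties: lexicographically smallest id — making
the result order-independent, which is tested), then discard communities
under five members.

**Sequence statistics.** Pairwise identity = matches / columns where
neither sequence is gapped (optionally over a column subset); family
identity = mean over member pairs. Neighbouring sequence identity uses a
k-d tree to find residues outside the helix with any atom within 4 Å of
any helix atom, takes the union of both structures' neighbour columns, and
reports identity over the non-gap ones — or a missing value (never 0) when
there are no contacts. Per-site correlation across a family is Spearman's
rank correlation with average-rank ties, requiring ≥ 5 paired members.

## Synthetic helices

The generator is the package's ground truth. The canonical straight helix
advances 1.5 Å and 100° per residue about +z, with each backbone atom type
at a fixed cylindrical position relative to its residue's CA — N (1.5514 Å,
−26.77°, −0.92 Å), CA (2.2759, 0, 0), C (1.6661, +26.74°, +1.07 Å),
O (1.9208, +20.34°, +2.26 Å) — constants derived once from a helix built
with standard internal coordinates (φ = −57°, ψ = −47°, ω = 180°) and
frozen in the source. Consequences by construction: CA–CA distances
3.80 Å, and a per-segment fit residual of ≈ 0.278 Å (the spread of the four
atom-type radii), so `r_n + r_c ≈ 0.556 Å ≥ 0.27 Å`, consistent with the
ideal-helix floor.

A kinked helix rotates all residues after the junction rigidly by the
requested angle about an in-plane axis through the N-arm axis at the
junction; the junction residue stays with the N-arm and nothing is
deleted, so the construction angle is the oracle for the measured maximum
(recovered within 3° for 10–60° kinks). Optional isotropic Gaussian
coordinate noise is seeded and deterministic. The family fixture writes
coordinate files, annotations and an aligned FASTA whose gap pattern stays
consistent with the generated helices.

What the generator does *not* emulate: real helices curve smoothly, unwind
into π/3₁₀ geometry, carry sidechains, sit in anisotropic density, and
have correlated (not isotropic) coordinate error; synthetic arms are
perfectly ideal on either side of a single sharp kink. Passing tests
therefore certify the measurement and classification machinery, not the
biological error model of any particular crystal structure.

## Numerical choices and degenerate inputs

- Cylinder fit convergence 1e-12 on the residual vector; LM from a
  principal-axis start (no restarts needed in testing: the grid oracle
  never finds a better optimum over random noisy segments).
- Perturbation magnitude: rotation angle uniform in (0°, 15°]; bounded so
  the degraded `r_n + r_c` stays in the range where the log curve is
  calibrated. The number of draws (10,000 per kink) and the 0.05 Å bin
  width balance percentile stability against runtime (~2 s for the full
  calibration-plus-coverage run).
- Percentiles use linear interpolation between order statistics throughout.
- Altloc handling: highest occupancy wins, ties to the smallest altloc
  identifier; multi-model files contribute model 1 only.
- Annotation merging joins same-chain helix segments separated by ≤ 2
  residues, iterated to a fixpoint.
- Helix ranges for measurement are trusted as given; the package does not
  re-derive helical-seed trimming from any external annotator's criteria.
- The pair ±4 window and the smoothing window operate on alignment
  columns, not author residue numbers (robust to insertion codes and
  gaps); internal residue indices are 0-based and contiguous, with author
  numbers carried through all outputs.

## Known limitations

- Kink angle magnitude only: no swivel/wobble direction, no bulge or
  π-turn detection, so "conserved kinked" may hide differently-oriented
  kinks.
- The error model depends only on `r_n + r_c`; residual dependence on the
  true angle below ~10° is excluded from calibration by design.
- Recalibrated coefficients are tied to the synthetic kink set's
  `r_n + r_c` range and are not interchangeable with the published
  defaults.
- Classification uses a single most-disrupted site per pair/family; the
  per-column profile report exists precisely because that is a
  simplification.
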