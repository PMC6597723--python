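# Methods

This note documents the models, conventions and numerical choices
behind `cpranalysis`, and what the synthetic-data tests do and do not
demonstrate about real simulation data.

## Boost potential and canonical reweighting

Accelerated MD lifts the potential below a threshold:

```
V*(r) = V(r) + ΔV(r)
ΔV(r) = 0                                   V(r) ≥ E_B
        (E_B − V(r))² / (α + E_B − V(r))    V(r) < E_B
```

`E_B` (kcal/mol) sets where boosting turns on; `α > 0` (kcal/mol) sets
its depth.  Useful exact properties, all asserted in the test suite:
ΔV ≥ 0; the boosted energy `V + ΔV` stays strictly below `E_B`
wherever the boost acts; ΔV is continuous with vanishing slope at
`V = E_B`; the boosted force is the plain force times
`dV*/dV = α²/(α + E_B − V)²`, a factor in (0, 1].  When several boosts
act additively on the same energy (the dual dihedral + total boost of
practical aMD), their ΔV's add and the force factors compose as
`1 + Σ(sᵢ − 1)`; the ΔV-log reader likewise sums all boost columns.

Canonical expectations are recovered by direct exponential
reweighting: snapshot weights `wᵢ ∝ exp(ΔVᵢ/k_BT)`, computed after
subtracting `max ΔV` so the largest exponent is zero.  This makes the
weights exactly invariant under `ΔV → ΔV + c` and overflow-safe.  We
deliberately use the plain exponential estimator rather than
cumulant-expansion variants: it is the estimator the reweighting
definition states, and at the ΔV ranges of the toy problems its
variance is manageable.  Every reweighted estimate reports the Kish
effective sample size `ESS = (Σw)²/Σw²`; treat results with
ESS ≪ n as unreliable.

Constants: `k_B = 1.987204×10⁻³ kcal/mol/K`, so `k_BT ≈ 0.6160332
kcal/mol` at the default `T = 310 K`.  Units throughout: kcal/mol, Å,
ps (trajectory time stamps in ns), amu.

## Toy Langevin simulator

The simulator integrates underdamped Langevin dynamics with the BAOAB
splitting and an exact Ornstein–Uhlenbeck friction substep.  The
choice is about sampling correctness, not speed: what downstream
reweighting tests require is that the sampled configurational
distribution be the Boltzmann distribution of the (boosted) potential,
and BAOAB's configurational bias is O(dt²) and negligible at the
operating point below.  Defaults: friction 1 ps⁻¹, timestep 2 fs,
mass 12 amu, T = 310 K — the thermostat settings of the MD campaign
the package mirrors, transplanted to the toy scale.

The double-well potential is `V(x) = h (x² − a²)²/a⁴` (+ optional
linear tilt), minima near ±a, barrier h at x = 0.  The
Boltzmann-recovery check uses `h = 7 kcal/mol` (≈ 11 k_BT, so an
unbiased run of 2×10⁶ steps essentially never crosses), `a = 1 Å`,
boost `E_B = 8`, `α = 3 kcal/mol`.  These boost numbers were chosen,
once, to balance acceleration against reweighting variance: the
boosted effective barrier is ≈ 1.4 kcal/mol (many crossings per run)
while the ΔV spread keeps the reweighting ESS near half the snapshot
count.  The recovery criterion compares the reweighted histogram
against an independent quadrature oracle (Simpson's rule per bin on
the analytic potential) via `KL(estimate ‖ oracle)` on a coarse
30-bin grid — finite for empty estimate bins because the Boltzmann
density is strictly positive — and additionally requires the
*unweighted* boosted histogram to fail the same bound, so the test
cannot pass vacuously.

## Structural observables

Centers of mass are mass-weighted with standard atomic masses by
element.  Hydrogen-free structures are allowed — COMs are then over
heavy atoms — and the convention is recorded in every output manifest.
Residue ids are the as-deposited author numbering.

The flavin "alloxazine ring" defaults to the 15 fused-ring atoms
`N1 C2 O2 N3 C4 O4 C4A N5 C5A C6 C7 C8 C9 C9A N10` (PDB
chemical-component names), excluding methyls and the ribityl chain;
the set is configurable because deposition dialects differ.  The heme
selection defaults to all heavy atoms of `HEM` including Fe.  Domain
residue ranges are **mandatory configuration**: no structure file
encodes where the FMN domain ends and the connecting domain begins,
and the shipped 1AMO-numbered example is explicitly user-editable.
No test depends on particular ranges.

Superposition is the Kabsch algorithm via SVD with the reflection
correction (det = +1 enforced), unweighted over Cα atoms by default;
atom pairing between snapshot and reference is by
`(residue_id, atom_name)` intersection.  Cα-only pairing is the
default because it is robust to hetero-group and protonation
differences between a snapshot topology and a crystal-structure
reference; all-heavy-atom and mass-weighted fits are options.  The
predicted FMN–heme distance applies the snapshot→reference FAD-domain
transform to the snapshot and measures the transformed FMN-ring COM to
the reference heme COM; moving the snapshot rather than the heme is
mathematically equivalent for the distance and keeps one structure
fixed.  The prediction is invariant under any rigid transform of the
input snapshot (the superposition absorbs it), which the tests assert
at 1e-8 Å.

Degenerate fits (< 3 points, collinear sets) raise rather than return
a garbage rotation; collinearity is detected from the singular values
of the centered coordinates.

## Distributions, free-energy surfaces, windowing

Histograms are probability masses over the retained (in-range) values;
out-of-range snapshots are dropped and counted.  The 2D free energy is
`f = −k_BT ln(density)` per occupied bin — density, not mass, so the
surface is invariant under bin-size changes up to a constant — shifted
so the minimum occupied bin is exactly 0.  Empty bins are masked, not
given 0 or ∞, so minima and plots stay well-defined.  Binning defaults
to 50 bins per axis spanning the weighted 0.5–99.5 percentile range;
all binning is recorded in the output manifest.

Time windows are half-open `[t_start, t_end)` so consecutive windows
compose without double-counting.  Multi-run analyses window each run
first (the "last half" convention of equilibrated production runs),
then pool snapshots and reweight jointly.  Whether to pool runs before
or after computing correlations is a genuine ambiguity; pooling is the
default and per-run correlations are reported as a diagnostic.

## PCA

Frames are aligned by an iterative mean-structure fit: Kabsch-fit all
frames onto the current mean over the fit selection, update the mean,
repeat until the RMS mean displacement is < 1e-6 Å (max 50
iterations; non-convergence raises with diagnostics).  The output
orientation is anchored to the first frame's pose; the converged mean
is unique up to that global frame, and covariances and eigenvalue
spectra are frame-independent (asserted).  The covariance is
`C = Σₜ wₜ (xₜ−x̄)(xₜ−x̄)ᵀ` over the 3N Cα coordinates, optionally
snapshot-weighted; whether aMD reweighting belongs inside the PCA is
not settled, so weighted is the default whenever a ΔV log is present
and `--unweighted` switches it off.  Eigenpairs come from a dense
symmetric solver (3N ≲ 2000 at CPR scale); modes are sorted by
descending eigenvalue with the largest-magnitude component made
positive (a deterministic sign convention).  Mode-arrow viewer files
scale vectors by √eigenvalue; the data model keeps unit vectors.
Alignment for the covariance uses all Cα; superposing onto a complex
reference for display is a presentation choice, not part of the
covariance.

## Synthetic data: what it emulates, what it does not

*Bivariate distance ensembles* draw (d_FAD–FMN, d_FMN–heme) pairs from
a bivariate normal per redox-state preset.  Only the correlations are
anchored to reported values (−0.21 oxidized, −0.41 reduced); the
distance means and SDs — oxidized 12 ± 2 Å and 25 ± 3 Å, reduced
14 ± 2.5 Å and 22 ± 3 Å, a 2 Å open-shift — are package choices of
realistic magnitude, because no numeric distances are reported and
figure axes are not data.  The optional *tilted* draw samples from the
preset density shifted by 0.5 SD along the FAD–FMN axis and sets the
pseudo-ΔV to `k_BT` times the log density ratio (shifted non-negative,
capped so the max weight ratio is ≤ 10³): by construction,
exp(ΔV/k_BT)-weighted estimates recover the preset while unweighted
ones recover the tilt — a ground-truth test that reweighting does real
work.

*Bead-model trajectories* place two rigid Cα-bead domains (flavin-ring
pseudo-residues at their mass centers, a HEM pseudo-residue on the
partner chain of the companion complex-reference file) at separations
sampled per frame from a preset, add per-atom Gaussian jitter
(default 0.15 Å) and a random rigid pose per frame, and write standard
multi-model PDB + ΔV logs.  The bead scatter spans ±6 Å so the
FAD-domain fit is well-conditioned — with a compact scatter, jitter
noise in the fitted rotation is amplified by the ~14 Å lever arm to
the FMN unit.  Frames whose sampled (d₁, d₂) pair violates the
triangle inequality against the fixed heme position (≲ 0.1 % of
frames at the default presets) are clamped to the feasible boundary,
and the *encoded* distances are returned as ground truth.

What passing these tests shows: the IO, selection, superposition,
reweighting, windowing and correlation machinery is correct end to
end at realistic signal/noise.  What it does not show: anything about
force fields, sampling convergence of real CPR, solvent or membrane
effects, or the physical origin of the redox–structure coupling — the
generators have the statistical structure of the real ensembles, not
their physics.

## Statistical design of the recovery tests

The sampling SE of a correlation estimate at n = 10⁴ is ≈ 0.008, so a
±0.02 comparison of a single draw against the preset value fails for
roughly 8 % of seeds on draw noise alone.  The end-to-end bead test
therefore asserts that the file-based pipeline reproduces the
*realized* ensemble's correlation to ±0.02 (isolating what the
geometry/IO path can corrupt), while recovery of the preset values
−0.41/−0.21 to ±0.02 is asserted at n = 10⁵ (draw SE ≈ 0.003), both
in the test suite and in `scripts/acceptance.py`.

## Run-plan arithmetic

Plan entries are (redox state, NADP⁺ occupancy, initial structural
state, method, length per run in μs, run count); totals use exact
rational arithmetic (`fractions.Fraction`) so μs values printed to one
decimal are exact, not float-rounded.  The built-in default plan
encodes the mirrored MD campaign: per redox state, 16×(0.2 μs cMD +
1.0 μs aMD) from the closed form, 8×(0.2 + 0.4) from the open form,
and the closed-form set repeated without NADP⁺ — 86.4 μs in total,
with 4.8 μs cMD / 19.2 μs aMD per redox state in the NADP⁺-bound
subsets.

## Problem sizes and determinism

Default test and acceptance workloads: 2×10⁶ Langevin steps for the
Boltzmann-recovery check (~1 min), 10⁵-sample ensembles for
correlation recovery (seconds), 10⁴-frame bead trajectories for the
end-to-end file pipeline (~20 s), a 5° Euler-angle grid (~1.9×10⁵
rotations) for the brute-force superposition oracle.  All stochastic
components take explicit integer seeds; seeded generation is
bit-reproducible, and re-running an analysis on identical inputs
yields byte-identical numeric tables.

## Known limitations

- PDB only (no mmCIF), no bond perception, no structure repair; altloc
  policy is first/blank and insertion codes keep the first icode per
  residue with a warning.
- Free-energy surfaces are 2D only; no block-bootstrap error bars —
  the ESS is the provided reliability diagnostic.
- The toy simulator is not an MD engine: no constraints, barostat, or
  many-particle forces; it exists to give reweighting a ground truth.
- Direct exponential reweighting degrades quickly when ΔV spreads over
  many k_BT per degree of freedom; the package reports ESS rather than
  attempting variance-reduced estimators.
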