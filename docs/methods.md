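# Methods

This note documents the models, conventions and numerical choices behind
`afmsim`, and what the synthetic test structures do and do not show about
real data.

## Units and conventions

Everything internal is in nanometres (the AFM convention); PDB angstroms
are divided by 10 on read and multiplied back on write.  The substrate is
the hard plane z = 0.  Height maps are stored row 0 = smallest y (math
convention); PNG export flips to image convention.  Orientations are proper
rotations, exposed as scalar-last quaternions and intrinsic ZYZ Euler
angles in degrees.

## Structure preparation

Molecules are hard-sphere models: element-specific van der Waals radii
(Bondi-style, nm) with a carbon-like 0.170 nm fallback for unknown
elements.  The radius table is overridable per call and via the CLI config
file, since different radius sets shift absolute heights by ~0.02 nm.
Hydrogens are used when present but never reconstructed; waters are dropped
by default; only blank/'A' alternate locations are kept; multi-chain files
are one rigid body.  The rotation centre is the coordinate centroid — mass
weighting is irrelevant to a purely geometric scan.  *Grounding* translates
the rotated model so min(zᵢ − rᵢ) = 0 and centres it laterally; it is
idempotent and commutes with rotation composition up to re-grounding.

## Collision scanning

The tip is a sphere-capped cone (apex radius R > 0, half-angle
0 < θ < 90°) joined tangentially: the junction circle sits at lateral
distance R·cos θ and height h + R(1 − sin θ) above the apex height h.  The
contact-height formulas (README) follow from sphere–sphere contact in the
cap regime and point–line distance to the flank in the cone regime; they
are continuous at the regime boundary d = (R + r)·cos θ by construction,
and the pure cone is recovered as R → 0.

Defaults that matter:

* `TipParameters(radius_nm=1.0, half_angle_deg=10.0)` in the CLI — a sharp
  modern probe; blunt probes are R ≈ 2–8 nm, θ ≈ 15–25°.
* Grids are square-pixel, built from the grounded model's bounding box
  plus a 2 nm margin (1 nm during fitting), symmetric about the lateral
  centroid with an odd cell count so one cell centre coincides with the
  centroid.  This keeps sub-pixel registration consistent between maps
  scanned at the same pixel size, which matters for fitting.  At most 512
  cells per axis.
* Scanning windows each atom to the cells it can reach (near-linear in
  atom count); a plain all-atoms × all-cells path exists for testing and
  produces bit-identical maps.

A brute-force **descent oracle** validates the geometry: the apex is
stepped downward (default dz = 1e−4 nm) and every atom sphere is tested
for overlap against the tip solid via an exact point-to-surface distance
(flank patch when the perpendicular foot lies above the junction, cap
otherwise).  Analytic and oracle maps agree within 2·dz per cell on random
fixtures; this is asserted in the test suite rather than assumed.

**Zero-tip limit.**  As R → 0 and θ → 0 the scan converges to the upper
envelope of the atom spheres (`vdw_envelope`).  The convergence is
pointwise except *on sphere silhouettes* (lateral distance exactly r from
an atom centre), where the envelope is discontinuous and any finite tip
grazes the sphere's side.  Deterministic fixtures whose cell centres land
exactly on a silhouette therefore use a small positional jitter in the
limit test; this is a property of the limit statement, not of the
implementation.

**Tip dilation.**  Any scan is pointwise ≥ the envelope, and pointwise
non-decreasing in both R and θ (a larger tip solid, aligned at the apex,
contains the smaller).  This is the geometric content of the familiar
observation that simulated absolute heights exceed measured ones while
relative heights agree — and the reason the fitting score is
scale/offset-insensitive.

## Image similarity

`similarity(sim, target)` is the Pearson correlation between height
arrays, maximized over integer pixel translations (default radius: half
the target per axis).  Design points:

* **Domain.**  At every shift the comparison domain is the *full target
  image*; the simulated map is treated as substrate (0) outside its own
  grid.  Target features the candidate fails to reproduce always count
  against it.  An earlier overlap-only formulation allowed a small overlap
  of two smooth flanks to correlate spuriously near 1 on a handful of
  pixels; the zero-extension removes that failure mode without ad-hoc
  coverage thresholds.  Simulated foreground falling outside the target is
  not penalized (the target is the data; outside it nothing is known).
* **Background.**  Pixels where both surfaces are exactly 0 are excluded.
  Experimental images should be baseline-flattened before input; a
  zero-floor flag exists on read.  Exclusion is by exact zero, not by
  threshold, so simulated maps (true zero baseline) need no preprocessing.
* **Exactness.**  The translation search runs in O(N log N) via FFT
  cross-correlations of the arrays, their squares and their zero
  indicators; the score at the selected shift is then recomputed exactly
  with direct sums, so `similarity(A, A).value == 1.0` holds bitwise.
* **Alternative.**  A registered negated-RMS score (`score="rmsd"`) is
  available when absolute heights are trusted; the default correlation is
  recommended for rigid-vs-experimental comparisons.

Lateral registration is integer-cell only; sub-pixel registration is out
of scope, and the centred odd grids (above) keep the sub-pixel phase
consistent so this costs ≲0.001 in score at matched orientations.

## Two-layered orientation search

* **Global layer.**  `sample_orientations(n_dirs, n_spins)` crosses a
  spherical Fibonacci lattice of tip-approach directions (poles included,
  so (1, 1) is the identity) with equally spaced in-plane spins.  The
  library is deterministic and covers orientation space quasi-uniformly —
  its spherical-cap discrepancy is below that of random sampling of equal
  size.  Every orientation is grounded, scanned at the target's pixel size
  and scored; the full candidate table is returned for auditing.
* **Refinement layer.**  From each of the top-k candidates, hill climbing
  evaluates ±step rotations about the three axes (6 neighbours), accepts
  the best improvement, otherwise shrinks the step geometrically
  (default 10° → ×0.5 → stop below 0.1°).  The score trace is
  non-decreasing and termination is guaranteed.  Simulated annealing was
  rejected to keep fits deterministic.
* **Defaults.**  200 directions × 18 spins, top-5 refinement.  On compact
  ~10 nm models at 0.4 nm pixels the correlation basin around the true
  orientation is roughly 15–20° wide while pseudo-solutions (flipped or
  rotated views) plateau near 0.93; the default density places a sample
  inside the basin and ranks it in the top candidates with margin.  The
  coarse-plus-refine strategy reaches the same optimum as refining a 4×
  denser brute-force library (gap < 1e−3 in score, measured), which is the
  efficiency rationale for the two layers.
* **Degeneracy.**  Refined orientations scoring within 1e−3 of the best
  and mutually separated by >10° are reported as degenerate — for a
  C4-symmetric model the four equivalent poses are all found.  The angular
  error metric is the geodesic distance on SO(3).

No z-offset or z-scale is fitted: correlation already ignores affine
height changes.

## Topography analysis

Profiles sample bilinear-interpolated heights at a fixed arc-length step
along a polyline.  `estimate_pitch` autocorrelates the mean-subtracted
profile (normalized by lag 0) and takes the *first* local maximum that
clears 0.2 both in correlation value and in peak prominence, with
parabolic sub-sample refinement.  The two-sided threshold is a deliberate
calibration: the prominence requirement rejects fine monomer ripple riding
on the slowly decaying correlation of the large-scale repeat, while the
value requirement rejects the spurious prominence peaks of noise-like
profiles (a profile of pure white noise returns "aperiodic").
Autocorrelation-first-peak was chosen over a spectral argmax because AFM
profiles typically contain only a handful of repeats.  The caller should
supply ≥ 2 expected periods.  Volume and footprint use plain cell-sum
quadrature with no baseline fitting (simulated maps have a true zero
baseline).

## Movies

Every trajectory frame receives the *same* rotation (bitwise-identical),
one shared grid, and — for rendering — one shared colour range
(0, global max), so frames are directly comparable.  Each frame is
re-grounded individually, as an adsorbed molecule would rest on the
substrate; this deliberately hides rigid z-translations between frames.
Only multi-MODEL PDB input is supported; binary trajectory formats are out
of scope.

## Synthetic structures

Generators use pseudo-atoms with inflated radii (0.3–2 nm) so grids stay
small while exercising the same code paths as real structures; all are
bitwise-deterministic per seed.

* `make_helix_filament` — a *two-start* helix (actin-like): monomers
  alternate between strands 180° apart, 13 monomers per half-turn per
  strand by default, so the topographic repeat along the axis equals the
  half-pitch parameter.  Monomer corrugation is smoothed by a ≥2 nm tip,
  leaving the half-pitch as the dominant profile period.
* `make_multi_blob(asymmetric=True)` — a chiral propeller: rod-like
  domains of unequal length, radius and base height radiating at irregular
  azimuths, tilted out of the substrate plane, plus an occluding cap atom.
  The construction guarantees no approximate rotational self-similarity:
  away from the identity no orientation scores within 0.05 of the perfect
  self-match (asserted in the suite).  Near-spherical blob clusters were
  rejected — they look alike from above and below, making flipped poses
  score deceptively well.
* `make_multi_blob(asymmetric=False)` — exact Cₙ copies of one blob, for
  degeneracy tests.
* `make_open_close_trajectory` — a fixed base plus an arm hinging
  sinusoidally about an axis in the substrate plane; the per-frame envelope
  maximum is known in closed form (2r + L·sin α_t), which the scans
  reproduce to within pixel placement.

What these fixtures do **not** emulate: instrument noise and drift, scan
line artefacts, sample deformation by the tip, partial adsorption, or
crowded fields of molecules.  Passing tests therefore demonstrate the
geometric and algorithmic correctness of scanning, fitting and analysis —
not robustness to every experimental artefact.  Correlation-based scoring
is expected to transfer to baseline-flattened experimental images, but
fitting accuracy on real data is limited by the unmodelled deformation of
soft samples.

## Problem sizes

The test suite and the acceptance script run on 20-atom clouds (oracle
comparisons, ~100-cell grids at dz = 1e−4 nm descent), ~20-atom propellers
at 0.4 nm pixels (≈ 30×40-cell targets) for fitting, and 100-monomer
filaments at 1 nm pixels for pitch recovery.  These sizes were chosen so
the whole pipeline re-runs in about a minute while every claim is still
exercised end to end; the scanning and fitting code paths are identical at
larger sizes, only slower.

## Known limitations

* Rigid tip and rigid sample; no elastic deformation, tip tilt, double-tip
  artefacts or electrostatics.
* Rigid-body fitting only; no flexible fitting of conformational
  ensembles, and one molecule per fit.
* Integer-pixel registration; no sub-pixel translation search.
* One ASCII height-map dialect; proprietary AFM formats need external
  conversion.
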