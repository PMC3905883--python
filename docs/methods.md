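# Methods

## Scope and model

The package analyses ligand-unbinding metadynamics described by two
collective variables: a mass-weighted center-of-mass distance (nm)
between the ligand and the nucleobases flanking the cleavage site, and
a coordination number counting ligand–nucleobase contacts through the
rational switching function s(r) = (1 − xⁿ)/(1 − xᵐ) with
x = (r − d₀)/r₀ and s ≡ 1 for r ≤ d₀. Internal units are nm, kJ/mol,
ps and amu throughout; k_B = 0.008314463 kJ/(mol·K).

The biasing potential is a sum of Gaussian hills deposited at the
visited CV points at a fixed pace. In standard mode every hill has the
initial height w₀; in the well-tempered variant the height decays as
w = w₀ exp(−V/(k_B (γ−1) T)) with the bias V already present at the
deposition point. The FES estimate is F = −Σ hills (standard) or
F = −(γ/(γ−1)) Σ hills (well-tempered), shifted so the global minimum
is zero; only free-energy *differences* are meaningful. Hill summation
stops at the first time the distance CV reaches a reference escape
threshold (default 4.0 nm), the point where the ligand no longer
contacts the receptor.

## Switching-function parametrization

d₀ is placed at the first local maximum of the ligand–nucleobase
atom-pair distance histogram (scanning from zero, ignoring bins below
5 % of the global maximum so single-sample noise bins do not register
as peaks) and r₀ is the full width at half maximum of that peak. The
exponents default to n = 6, m = 12, the common choice for this CV
family; all four parameters are configurable. Pairs closer than d₀
contribute the limiting value 1, and the removable singularity at
x = 1 is evaluated by first-order series expansion when |x − 1| < 1e−6.
No minimum-image convention is applied: the toy systems are
non-periodic.

## Sampling engine

Because the analysis operators only see CV-space time series, the
sampler integrates Langevin dynamics *directly in CV space* on an
analytic toy potential plus the accumulated bias — BAOAB splitting,
per-CV masses, friction 1 ps⁻¹ by default, reflecting walls at the
domain edges. Forces are tabulated on an internal grid (2001 nodes in
1-D, 400×200 in 2-D) and interpolated (bi)linearly per step; each hill
is added to the tables on a ±6σ patch, and the well-tempered height
uses the same tabulated bias. This is an engine-internal
approximation; `bias_value` and `reconstruct_fes` always sum exact
Gaussians. Runs are bitwise reproducible for a fixed seed (a single
`numpy` generator drives the pre-drawn noise and all Bernoulli draws).

Validation facts the test suite verifies: an unbiased run in a
harmonic well reproduces the configurational variance k_B·T/k within
5 % at 10⁶ steps; at T = 0 with high friction the walker descends
monotonically to a minimum; with deposition every 0.5 ps, 27,644 and
33,211 hills correspond to 13.8 and 16.6 ns.

### Estimator choice for long non-tempered runs

Standard (non-tempered) metadynamics does not converge pointwise: once
the wells are filled, continued deposition makes the instantaneous
bias churn, and on a small bounded 1-D domain the end-of-run hill sum
can misestimate a 20 kJ/mol barrier by many k_B·T after ~10⁴ hills.
`reconstruct_fes(..., average_from=f)` therefore implements the
standard remedy of averaging the running FES estimate over the last
(1−f) fraction of depositions (equivalent to a weighted hill sum).
The 1-D double-well validation uses gentle hills (w₀ = 0.25 kJ/mol,
σ = 0.1, pace 0.5 ps) with `average_from = 0.3` and recovers the
barrier to a few tenths of a kJ/mol; the default estimator remains the
plain hill sum.

## Synthetic study systems

**Double well** (1-D): U = barrier·((x/a)² − 1)², minima at ±a, exact
midpoint barrier — the engine's quantitative validation system.

**Unbinding landscape** (2-D, distance ∈ [0, 4.5] nm × contacts ∈
[0, 400]): a monotone-cubic (PCHIP) spine U(d) through fixed knots
carries the basin topology — bound minimum B at d = 0.25 nm, saddle Ts
at 0.9 nm exactly `barrier_BTs` above B, intermediate I at 1.6 nm,
exit saddle `barrier_out` above I at 2.3 nm, then a flat plateau to
4.5 nm below the Ts energy. A transverse harmonic term
½k_c(c − c*(d))² (k_c = 0.002 kJ/mol per contact²) confines the
contact CV to a valley line decaying from 300 contacts at B to exactly
zero beyond d = 2.6 nm. Monotone interpolation plus a nonnegative
transverse term guarantee exactly two local minima with the designed
minimax saddle; k_c and the exact-zero tail were chosen so that grid
evaluation shows no aliasing minima, verified by enumeration.

The pipeline's default landscape uses depths B = 45, I = 40 kJ/mol and
`barrier_out` = 35 kJ/mol. Two properties force these choices. First,
basins must be deep relative to k_B·T ≈ 2.5 kJ/mol so that escape is
bias-driven, not thermal, as in the system the landscape emulates.
Second, with hill summation truncated at escape, the reconstructed
surface is capped near the *exit-saddle* fill level — so the exit
saddle must be the highest feature or the B→Ts barrier imprint is
clipped; 35 kJ/mol keeps it above Ts for test barriers up to 30.
Default engine settings for this landscape: hills w₀ = 0.25 kJ/mol
with widths (0.05 nm, 50 contacts), pace 0.5 ps, dt = 0.005 ps,
per-CV masses (1, 5·10⁻⁴) so both CVs relax on comparable timescales,
4·10⁵ steps (4,000 hills, 2 ns). Under these conditions runs at
barriers 10/20/30 kJ/mol escape through the 4.0 nm threshold and
recover ΔG‡(B→Ts) within ~1 k_B·T, monotone in the generator barrier.

**Mock ternary complex**: ~40 pseudo-atoms — a 4-atom ligand, 3-atom
nucleobases at positions ±1, ±2 on both strands, three protein-like
residues — with per-frame state labels (default 7,512 B / 22 Ts / 631
I frames at 0.5 ps stride). A specified H-bond is realized as a
colinear D–H···A triplet at 0.30 nm (present, Bernoulli with the
state's occupancy) or 0.60 nm (absent), safely inside/outside any
sensible cutoff; each donor gets an explicit hydrogen; every other
coordinate jitters isotropically (Gaussian, per-atom σ, default
0.02 nm; 0.05 nm for nick-flanking bases). The hallmark pair
LYSD→LIGO carries 49 % occupancy in B and 0 elsewhere. What the mock
does *not* emulate: real geometry, excluded volume, correlated
motions, donor competition (each atom joins at most one pair) — so
passing tests certify the estimators (counting, averaging, filtering,
clustering), not force-field realism.

## Landscape analysis

- **Minima**: grid nodes strictly lower than all available
  8-neighbors, sorted by energy.
- **Basins**: discrete steepest descent — from each node repeatedly
  step to the lowest strictly-lower neighbor (ties to the lowest flat
  index) until a minimum; implemented by pointer jumping, which cannot
  cycle under strict descent. Plateau terminals (possible only on
  degenerate flat surfaces) are left unassigned with a warning.
- **Frame assignment**: a frame belongs to the basin of its nearest
  grid node iff its bilinearly interpolated F lies within the state
  cutoff (default 20 kJ/mol) of that basin's minimum; frames outside
  the grid are unassigned, never errors.
- **Minimum-energy path**: the 8-connected path minimizing the maximum
  F en route (minimax), computed by a Dijkstra-like search with
  lexicographic cost (path maximum, cumulative F) — the second key
  breaks ties toward the lower-energy route. The saddle is the path
  argmax; ΔG‡ = F(saddle) − F(start); the profile is reported against
  a normalized arc-length coordinate s ∈ [0, 1] in grid-index space.
- **Prominence**: each minimum's escape barrier toward any lower
  minimum, computed by the standard persistence sweep (ascending
  energy + union-find). The pipeline reports as *states* only minima
  with prominence ≥ 2 kJ/mol (above the hill-noise scale, below any
  barrier of interest) and energy within the state cutoff of the
  global minimum; `find_minima` itself is unfiltered. Sub-basins of a
  broad well are reported per-minimum; no merging is performed.
  Among state minima, the smallest-distance one is named B, the next
  I (then I2, ...), and Ts is the B→I path saddle.

## Structure analysis

- **RMSF** per residue: √(Σᵢ mᵢ⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩ / Σᵢ mᵢ) over the
  frames of one state. By default each frame is first superposed
  (mass-weighted Kabsch) onto the subtrajectory's first frame, since
  without fitting rigid-body drift dominates; `fit=False` restores raw
  behavior (and is what makes the two-position-oscillator identity
  RMSF = 1 nm exact).
- **H-bonds**: geometric criterion, donor–acceptor distance ≤ 0.35 nm
  and H–D–A angle ≤ 30° (the conventional defaults; configurable).
  Percentages of existence are per state over assigned frames only;
  rows are kept iff strictly > 25 % in at least one state.
- **RMSD/clustering**: mass-weighted least-squares superposition via
  quaternion-free Kabsch (scipy rotation alignment; ≥3 non-collinear
  atoms required). gromos clustering: repeatedly take the frame with
  the most neighbors within the RMSD cutoff (ties to the lowest frame
  index) together with its neighbors as a cluster; representative =
  medoid. Cutoff default 0.1 nm. The pipeline stride-subsamples each
  state to ≤ 60 frames before the quadratic pairwise RMSD matrix.
- **Nick width**: COM distance between the pooled bases (both strands)
  at positions −1 and +1; reported per state as mean ± sd.

## Pipeline and reproducibility

`metafes run config.yaml` executes simulate/ingest → escape truncation
→ FES → minima/basins/states → MEP profile → structure tables, writing
a JSON report with stage seeds, a config hash and every output path.
All randomness derives from one top-level seed split per stage
(`numpy.random.SeedSequence`); reruns are byte-identical. In synthetic
mode the structure tables use the mock generator's own state sequence
as the assignment — the CV-space run and the mock trajectory are
independent synthetic objects with no physical frame-to-frame mapping.
Ingested runs (HILLS/COLVAR/PDB/XYZ files) use `assign_frames` instead.

## Problem sizes and numerical choices

Default grids are 500×500 (per the workflow the package follows);
tests and the acceptance script use 300×150 with ~2,000–4,000 hills,
sizes at which the reconstruction is already grid-converged (<1 % of
the FES range between 500² and 1000² grids on smooth surfaces).
Hills are summed exactly (no tail truncation), using separability
across CV axes. Degenerate inputs — empty groups, flat histograms,
single frames, non-positive cutoffs, malformed HILLS lines — raise
errors naming the problem; non-monotone hill times and out-of-grid
frames warn and continue.

## Known limitations

- No FES error bars (no block averaging over hill streams) and no
  kinetic rate estimation; barrier heights are related to unbinding
  rates only qualitatively, and nothing here estimates a dissociation
  constant (that would require sampling the unbound state).
- Standard-mode FES estimates are reliable only up to the escape
  truncation or with the time-averaged estimator; indefinite
  non-tempered deposition diverges by design of the method.
- The CV-space Langevin sampler has no notion of atomistic kinetics;
  its friction and masses are tuning knobs for sampling efficiency,
  not physical quantities.
- H-bond typing comes from topology annotations (donor/hydrogen/
  acceptor lists), not chemical perception.
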