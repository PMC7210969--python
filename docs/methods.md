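# Methods

This note documents the models behind `colmech`, the defaults and their
units, the numerical choices, and what the synthetic generators do and do
not capture about real data.

## Fibril geometry

A fibril segment is one axial D-period, the window `[0, D]` with
`D = 67 nm`. Each of the `n_helices` (default 37) triple helices is a
molecule column with a stagger class `t = helix_id % 5`; residue
`s` (1-based) of a class-`t` chain sits at

```
z = (s - 1 - t * stagger + z_offset) * axial_rise,
```

with `stagger = 234` residues per D, `axial_rise = D/234 ≈ 0.2863 nm`, and
a small global phase `z_offset = 5` residues so that chain termini that
should be interior (telopeptides) do not coincide with the segment
boundary. Residues outside the window are truncated. With the default
chain length of 1039 residues the most-staggered class is present only in
the first `107/234 ≈ 0.457` of the period — the overlap region; the
remaining `~0.54 D` holds one fewer molecule per cross-section and is the
gap region, the classic Hodge–Petruska picture. The `0.46/0.54`
overlap/gap split is a convention; the builder derives the exact fraction
from the chain length so labels and geometry agree. Telopeptide ranges
(default residues 1–16 and 1024–1039) override the gap/overlap label.

Divalent HLKNL crosslinks connect a telopeptide lysine donor (`K`) to a
helical hydroxylysine acceptor (`k`; lowercase letters denote
posttranslational modifications, `p` is hydroxyproline). The default
rules put the N-telopeptide donor at residue 9 with its acceptor at
`9 + 4·234 − 5 = 940` on a helix four stagger classes away, and the
C-telopeptide donor at 1031 with acceptor 90; the five-residue offset
(≈1.43 nm) keeps donor and acceptor within the 1.5 nm axial cutoff. The
exact residue numbers used in published atomistic models are not public;
these defaults are conventions chosen so the default segment carries the
canonical counts — 12 crosslinks, six N-terminal and six C-terminal,
across six helix pairs. Which helix pairs may crosslink ships as an
explicit six-pair fixture list (class-0 with class-4 helices) rather than
being derived from crystallographic packing.

Chain sequences are generated synthetically (Gly-X-Y repeats, telopeptide
texture, crosslink chemistry, and a planted Tyr/Phe/Met cluster around
each acceptor); they are labelled synthetic stand-ins for the rat
α1(I)/α2(I) chains and reproduce only the features the pipeline measures.

Bead coordinates wind the three chains of a helix (minor radius 0.25 nm,
pitch 3 nm) around helix axes on a triangular lattice (spacing 1.5 nm).
Crosslink donor beads — conformationally free telopeptide residues — are
placed laterally next to their acceptor so every donor–acceptor 3-D
distance respects the cutoff.

A `mini_config()` variant (stagger 50, 10 helices, ~1350 beads, same
five-class structure and crosslink recipe) exists so that
simulation-backed tests and examples run in seconds; the full 37-helix
segment (~23 000 beads) is what the topology-level numbers are computed
on.

## Pulling simulations

Dynamics are overdamped Langevin (Euler–Maruyama):

```
x <- x + (dt/γ) (F_springs + F_ext) + sqrt(2 kT dt/γ) ξ.
```

Only harmonic bonds act (backbone and crosslinks); no excluded volume,
solvent, or electrostatics. The time-averaged bond force — the observable
of interest — is integrator-independent at steady state, which is why the
inertia-free formulation was chosen over velocity-Verlet. Defaults:
spring constant 10 nN/nm for both bond kinds, rest lengths taken from the
initial coordinates (the system starts force-free), T = 300 K
(kT ≈ 0.00414 nN·nm), friction 1 per bead, dt = 0.005 friction times,
40 000 steps recording every 100 (400 frames), the first 10 % of frames
discarded as equilibration. At these defaults the single-chain oracle's
per-bond standard error is ≈0.01 nN, i.e. ~1 % of the 1 nN load. For the
fibril fixture, runs discard 40 % (the slowest chain mode relaxes in ~26
friction times; the equilibration window covers ~3× that).

External load: `per_chain_force × weight(helix)` applied axially to the
chain end beads that lie at the segment's axial boundaries (+z at the top,
−z at the bottom, tolerance half a rise). Chain termini interior to the
segment — the telopeptides — are deliberately unloaded, so the external
load must cross the segment through backbone and crosslinks; this is what
reproduces the minimal telopeptide forces and the crosslink load transfer.
"Shear" loading means user-supplied unequal per-helix weights that must
sum to `n_helices` (load conservation); published weight distributions are
not available, so the weights are parameters.

Degenerate behaviour: diverging coordinates raise a runtime error advising
a smaller timestep; any bond exceeding `rupture_check_factor × rest`
(default 5×) sets a rupture flag on the trajectory instead of silently
continuing.

Finite-temperature fine print: a 3-D harmonic bond's scalar force has a
positive thermal offset even at zero load (radial Jacobian, ≈2kT/r₀ ≈
0.03 nN at defaults), and the loaded chain's mean scalar force carries a
≈0.5 % analogue. Tests therefore check "unloaded forces negligible"
relative to the 1 nN load (and against the closed-form offset), not
literal zero.

## Force distribution analysis

`F_ij` is the per-frame signed scalar Hooke force, tension positive,
averaged over retained frames; only bonded pairs enter. Windowed
profiles: for each crosslink, the backbone bonds of the acceptor chain
are averaged in overlapping windows of `w = 10` consecutive residues
(step 1), each bond attributed to its lower residue index, with the
crosslink bond force entering at the acceptor position; profiles are
aggregated per terminal (N/C) as mean ± sem across the crosslinked pairs
(not across frames). Ties in `locate_maxima` break by ascending residue
position.

Fidelity gap to keep in mind: in a single-D-period fragment with two
crosslinks per pair, tension along a series load path is bounded by the
transmitted load, so the gap-region backbone of a through-running chain
carries the full per-chain force and no window can exceed it. The
stress-concentration signal this geometry does show — and what the tests
assert — is local: the strongest N-terminal window sits at the crosslink,
near-crosslink windows beat far windows on the same chain, the N-terminal
junctions carry markedly more tension than the C-terminal ones, and
telopeptides off the load paths are force-free. Exceeding the far-field
force would require molecules spanning several periods with distributed
loading, which is outside this model.

## Conservation mapping

Alignment columns are mapped to reference positions (reference gaps
unmapped), per-column class occurrences are summed over sequences, and
every topology site of the selected chain family deposits its position's
counts at its axial coordinate — so the three chains of each helix and
all staggered helices crossing a slice are summed, and the profile lives
on the fibril axis. Slices span ten residues of axial extent and advance
one residue (moving average); with step = length the slices are disjoint
and counts are conserved exactly (tested). Counts are reported raw (mean
per sequence), with no density correction for the gap region. Counting
is case-sensitive (`k`/`p` are modified residues, distinct from `K`/`P`).
The circular-shift permutation test behind the enrichment ratio is a
quantification aid of this package, not a published protocol; the ratio
uses an infinity sentinel when the outside mean is zero.

## Radial distribution function

`g(r) = counts / (n_frames · n_centers · shell_volume · ρ)` with ρ the
target density in the bounding box of all coordinates inflated by
`r_max`; no periodic boundary (the segment is finite). Defaults: bin
width 0.05 nm, `r_max` 3 nm. Sites are beads (residue centroid
surrogates), not side-chain atoms, and the density convention is a
choice — so only the shape and onset of g(r) are meaningful, not absolute
values. `first_shell` uses strict inequality against its threshold.

## EPR powder spectra

Resonance condition `B = hν/(gμ_B)` (CODATA constants in
`colmech.constants`). Orientation averaging uses a deterministic
equal-area grid: midpoints uniform in cos θ (2000 by default; one octant
in φ, 90 points, added for rhombic tensors). Sticks are deposited on the
field grid with linear charge assignment and convolved with a unit-area
Gaussian (σ = ΔB_pp/2) or Lorentzian (HWHM = √3 ΔB_pp/2) kernel;
derivative detection is the numerical field-gradient of the absorption,
and output is normalized to unit maximum |intensity|. Doubling the grid
changes the axial test pattern by <10⁻⁶ of peak — far inside the 1 %
convergence contract. Fields are mT internally and linewidths gauss at
the interface (1 mT = 10 G). Hyperfine structure is omitted (unresolved
in the motivating spectra) and field modulation is treated as an ideal
derivative. No default DOPA tensor ships: principal values are
user-supplied inputs. Metrics: effective g from the interpolated
zero-crossing between the derivative extrema; pp-width from the extrema
separation; signal size = max − min; spin count from double-integral
ratios against a reference of known spin count; smoothing via a cubic
smoothing spline (`scipy`'s `make_smoothing_spline`, stiffness = λ).

## FOX assay and statistics

Stress = force/area (N/mm² = MPa). Mass-to-force uses g = 9.8 m/s², which
reproduces the printed 3.43 N for a 350 g load (9.80665 gives 3.432 N and
rounds identically). The 595 nm calibration is linear (default slope
0.02 absorbance/µM, intercept 0.05 — kit-style values; the real reagent
curve is emulated, not digitized). Concentration per condition is
`(mean A − intercept)/slope`; Δ is computed per time point (no
longitudinal model), with standard errors propagated from well-level
variance in quadrature. The significance test is the pooled-variance
two-tailed t-test with star labels `**` (p<0.01) and `***` (p<0.001);
zero pooled variance returns p = 1 for equal means and the p→0 sentinel
otherwise.

## Synthetic generators: what they do and do not emulate

All generators are bit-reproducible under a fixed seed. The pulling
simulator reproduces load transfer through a crosslinked bead-spring
network, not atomistic collagen (no force-field terms beyond bonds, no
water, no torque restraints at termini, no bond scission chemistry). The
MSA generator plants class residues at chosen positions over an i.i.d.
substitution background (default 64 sequences, enrichment probability
0.9, background rate 0.3) — real vertebrate alignments have phylogenetic
correlation and indels it does not model, so passing tests demonstrate
the mapping and counting machinery, not evolutionary inference. The EPR
sweep generator adds white Gaussian noise to the ideal powder pattern
(default plate: no drift, no baseline). The FOX plate generator draws
i.i.d. absorbance noise (default 0.001 absorbance units, plate-reader
repeatability scale) around a linear response with the pulled condition
offset by the requested Δ (default 1 µM over a 2 µM baseline) at every
time point — it does not model the incubation-time kinetics of peroxide
release.

## Known limitations

* One-bead-per-residue geometry: no side chains, no atomistic distances;
  RDF and crosslink contacts are centroid-level.
* Single-period fragment: stress concentration above far-field (see the
  force-distribution section) and multi-period load sharing are out of
  reach.
* The EPR module simulates g-tensor lineshapes only — no hyperfine,
  saturation, temperature dependence or pulse-sequence physics.
* Significance machinery is deliberately minimal (per-time t-tests,
  circular-shift permutation); no multiple-testing correction is applied.
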