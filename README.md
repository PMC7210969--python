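# colmech

Mechanical stress on collagen generates mechanoradicals: homolytic scission
of backbone and crosslink bonds leaves unpaired electrons that migrate to
nearby aromatic residues, stabilize as DOPA-type radicals, and ultimately
convert into hydrogen peroxide. `colmech` is a Python library for the
computational side of that story. It is aimed at structural-bioinformatics
and biophysics researchers who want to

* build coarse-grained, D-periodic, HLKNL-crosslinked collagen-I fibril
  segments (one bead per residue),
* run constant-force bead-spring Langevin pulling simulations and recompute
  **time-averaged pairwise bond forces** F<sub>ij</sub> = k(|r<sub>i</sub> −
  r<sub>j</sub>| − r<sub>0</sub>) from the trajectories (force distribution
  analysis), with ten-residue windowed profiles along crosslink-connected
  chains,
* map multiple-sequence-alignment counts of redox-active residues
  (Tyr/Phe/Met) onto ten-residue slices along the fibril axis and test
  enrichment near crosslinks,
* compute radial distribution functions g(r) of redox-active residues
  around crosslink sites,
* simulate powder EPR spectra from g-tensors via the resonance condition
  B = hν/(gμ<sub>B</sub>) with g(θ,φ)² = g<sub>x</sub>²sin²θcos²φ +
  g<sub>y</sub>²sin²θsin²φ + g<sub>z</sub>²cos²θ, and extract effective
  g-factor, peak-to-peak width, signal size and spin counts from sweeps,
* quantify FOX-assay (ferrous oxidation–xylenol orange) hydrogen peroxide
  measurements: tensile stress arithmetic, linear 595 nm calibration,
  pulled-minus-untreated Δ[H₂O₂] with propagated errors, and the
  equal-variance two-tailed t-test with star labels.

A synthetic-data module generates every input the pipeline consumes —
pulling trajectories, vertebrate-like MSAs with planted enrichment, noisy
EPR field sweeps and FOX absorbance plates — so the full analysis runs
without any downloads.

## Worked example

Build the default fibril segment and pull a reduced-geometry fibril at
1 nN per chain:

```python
import colmech as cm

topology = cm.build_fibril()            # 37 helices, one D-period
fibril = cm.build_fibril(cm.mini_config())
traj = cm.simulate_pulling(fibril, cm.SimulationParams(
    seed=7, per_chain_force=1.0, n_steps=40_000, record_every=100,
    equilibration_fraction=0.4))
table = cm.compute_pairwise_forces(traj)
profile = cm.windowed_profile(table, w=10)
print(cm.locate_maxima(profile, "N").iloc[0])
```

Running `python examples/build_fibril.py` and
`python examples/pulling_force_analysis.py` prints:

```
sites (beads):        23298
axial span:           67.0 nm (one D-period)
HLKNL crosslinks:     12 (6 N + 6 C)
crosslinked pairs:    6

crosslink bond tensions (nN): [0.78 0.18 0.72 0.17]
strongest N-terminal window: center residue 203.5, mean force 0.44 nN,
2.5 residues from the crosslink
```

The segment spans exactly one 67 nm D-period and carries 12 HLKNL
crosslinks (six N-terminal, six C-terminal) across six overlapping helix
pairs. Under equal 1 nN-per-chain loading the crosslinks carry a large
fraction of the transmitted load (with the N-terminal junctions clearly
dominant over the C-terminal ones), and the strongest ten-residue force
window sits directly at the N-terminal crosslink — the region where
mechanically driven bond scission is expected.

The other examples (`conservation_profile.py`, `rdf_around_crosslinks.py`,
`epr_simulation.py`, `peroxide_assay.py`) each build a small input, run one
capability and print what the numbers mean; e.g. the EPR example simulates
the tendon-radical line and re-measures `g_eff = 2.0070`,
`pp-width = 10.00 G`, and the assay example recovers the planted
`Δ[H₂O₂] ≈ 1 µM` with `***` significance at every time point.

## Documentation

`docs/methods.md` describes the models, their assumptions, the default
parameters and units, what the synthetic generators do and do not emulate,
and the package's known limitations.
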