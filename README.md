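# ngvkit

Compartmental neuro-glio-vascular (NGV) brain-energy-metabolism
simulation plus geometric quantification of 3-D reconstructed neuropil.

Two halves, one package:

* **Simulation** — a glutamate-driven reaction network spanning neuron,
  astrocyte, extracellular-space and capillary compartments (glycolysis,
  lactate shuttling via MCTs, compartmentalized cytosolic/mitochondrial
  NAD(H), creatine kinase buffering, Na/K-ATPase cost of activity,
  noradrenaline-cAMP-driven glycogenolysis, CBF as an external input),
  integrable as a single unit or tiled over a grid of 50 µm cubic voxels
  driven by synaptic release events. A Hodgkin–Huxley membrane with
  concentration-updated Nernst reversal potentials supplies optional
  electrical drive.
* **Morphometrics** — operations on labeled triangle meshes: per-vertex
  granule-to-membrane absorption maps (analytic form factor or photon
  Monte Carlo, with ray-cast occlusion), nearest-element glycogen
  granule tallies, contact surface areas, exact mesh-to-mesh minimum
  distances and planar cross sections.

A synthetic-data module generates every input needed to exercise the
package — procedural watertight neuropil scenes, planted granule
distributions with known truth, Poisson event streams and named drive
protocols — so nothing external is required.

## Units and conventions

Concentrations mM (cAMP µM), time s, lengths µm, potentials mV.
Coordinates are 0-based, right-handed; voxel cells are half-open
(`floor((pos - origin)/h)`). Model parameters live in one documented
TOML file (`src/ngvkit/data/default_params.toml`, which also persists
the balance-designed resting state used to seed the steady-state
solver); every value is overridable from a user TOML.

## CLI

The `ngv` entry point exposes the pipeline; each command writes its
outputs plus a `run_manifest.json` (config snapshot, input digests,
seeds, version) to the output directory.

```bash
ngv synth --seed 7 --granules 200 --out scene/       # procedural scene
ngv tally --scene scene/ --granules scene/granules.csv --out tally/
ngv glam  --scene scene/ --granules scene/granules.csv --out glam/
ngv contact --scene scene/ --object-a 0 --object-b 8 --epsilon 1 --out c/
ngv organelles --scene scene/ --object-a 3 --object-b 6 --out org/
ngv simulate-unit --protocol stimulus --t-end 10 --out unit/
ngv simulate-grid --config grid.yaml --events events.csv --out vols/
```

Formats: OBJ/PLY meshes (+ `manifest.csv` sidecar with class labels),
CSV granules and events (JSONL accepted for events), TOML/YAML configs,
NRRD volumes with JSON sidecars, CSV trajectories.

## Layout

```
src/ngvkit/
  metabolic_core/    state/params, rate laws, ODE assembly, steady state,
                     adaptive integration, conservation + shuttle reports
  activity/          Hodgkin–Huxley membrane, Nernst potentials,
                     spike-to-release conversion
  voxel_sim/         voxel grid, event binning, per-voxel simulation,
                     field normalization, NRRD export
  glam_morphometrics/  mesh containers, exact geometry primitives,
                     absorption maps, tallies, contacts, sections
  synthetic_data/    procedural scenes, granules, events, protocols
  io_cli/            readers/writers, run manifests, `ngv` CLI
  data/              default parameter file (TOML)
```

Default model parameters are physiologically plausible placeholders
chosen so the stored resting state balances the network exactly; they
are not fitted to any dataset and are intended to be replaced per use.
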