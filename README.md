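# splitmem

Toolkit for building, restraining, reuniting and analysing **split
head/tail lipid bilayers**: each phospholipid is cut at the glycerol
backbone into an independent head and tail molecule, both capped by
massless virtual sites, with flat-bottomed layer potentials holding the
bilayer together. Because the headgroups diffuse as free molecules, lateral
mixing is enhanced by an order of magnitude; the inverse operation merges
heads and tails back into whole lipids by closest-anchor matching under
periodic boundaries.

Everything is testable at desk scale: a synthetic-fixture module generates
deterministic toy bilayers, Brownian trajectories and ideal chains, so no
molecular-dynamics engine or binary trajectory format is required.

## Modules

| module | what it does |
| --- | --- |
| `splitmem.core` | domain types (frames, trajectories, topologies), leaflet assignment, membrane COM |
| `splitmem.io` | GRO (single/multi-frame), PDB subset, GROMACS TOP/ITP subset, NDX |
| `splitmem.split` | the head/tail split transformation with virtual-site capping |
| `splitmem.restraints` | flat-bottomed layer potentials: defaults, energy/force, engine-format emission |
| `splitmem.merge` | head-tail reunification (greedy or optimal assignment), strain report |
| `splitmem.analysis` | lateral MSD and diffusion (Einstein relation, slope/4), diffusion-time and speedup arithmetic, density profiles, S_CD order parameters, P-N angle, area per lipid, thickness, RDF |
| `splitmem.fixtures` | deterministic toy bilayers, membrane-mimic compositions, Brownian walkers, ideal all-trans chains |
| `splitmem.cli` | the `splitmem` command |

## CLI

```sh
# build a deterministic 64-lipid/leaflet toy bilayer
splitmem fixtures bilayer --n 64 --apl 0.658 --seed 1 --out-prefix bilayer

# split it into head and tail molecules (+ ITPs, NDX groups, manifest)
splitmem split --coords bilayer.gro --top bilayer.top --out-prefix split_

# emit the default flat-bottomed restraint set for the split system
splitmem restraints --coords split_gro --kind mixed --out-prefix restr_

# reunite heads and tails and check junction strain
splitmem merge --coords split_gro --manifest split_manifest.json \
    --plan-strategy greedy --threshold 0.3 --out merged.gro

# analysis (multi-frame GRO trajectories)
splitmem fixtures brownian --n 500 --d 0.05 --frames 2000 --seed 42 --out brw.gro
splitmem analyze diffusion --traj brw.gro --window 5:50
splitmem analyze apl --traj bilayer.gro --n-per-leaflet 64
splitmem report --d-standard 0.0075 --d-head 0.0884 --d-tail 0.0093
```

Every subcommand writes a provenance JSON next to its outputs; logs go to
stderr, results to files.

## Conventions

Coordinates in nm, times in ns, masses in amu, charges in e, energies in
kJ/mol; z is the bilayer normal; orthorhombic boxes only. Lateral diffusion
uses the 2D Einstein relation (D = MSD slope / 4); `diffusion_time(D, L)`
returns L²/(4D) in μs.
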