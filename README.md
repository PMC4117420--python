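# hydrofilm

Coarse-grained lattice Monte Carlo model of hydrophobin film self-assembly.

Class II hydrophobins (HFBI and HFBII of *Trichoderma reesei*) are
amphiphilic fungal proteins that form 2D crystalline films at the
air–water interface — films with an elasticity orders of magnitude above
ordinary surfactant layers.  Scattering and microscopy give a hexagonal
film lattice of ~54–56 Å; on a triangular close packing of ~20 Å protein
discs that lattice parameter singles out the (2,1) superlattice vector
(length 20·√7 ≈ 53 Å), whose unit cell holds seven lattice sites and six
proteins: two trimers related by a 2-fold axis (plane group p6).  Protein
docking additionally suggests a *metastable low-density* packing of
trimers with p3 symmetry and a smaller lattice parameter.

`hydrofilm` models this film as a spin system on a periodic triangular
lattice.  Each site is vacant or carries a protein in one of six
orientations (60° steps); adjacent proteins interact through three
attractive contact classes — intra-trimer bonds (J0 = 5), trimer–trimer
contacts of the dense P6 crystal (J1 = 2) and of the low-density P3
crystal (J2 = 1) — plus an adsorption benefit Jsurf = 10 per protein; all
other contacts are forbidden.  Metropolis dynamics with protein-like
moves (adsorption/desorption, single-protein hops and rotations, rigid
trimer moves) then probes the question the model was built for: **how
does the metastable P3 ordering change the kinetics of film formation?**
The headline answer, reproduced by this package: with P6 ordering alone
the largest bonded cluster grows *linearly* in Monte Carlo time (the
model is effectively a 7-state Potts system, one ordered structure per
vacancy sublattice), while allowing P3 contacts lets bridge bonds glue
neighbouring crystal domains, each merge multiplying the cluster size —
the growth becomes *exponential* and the film-spanning elastic network
appears far earlier.

See `docs/methods.md` for the model definition, the calibrated
temperature, the analytics, and an honest account of which published
observations this implementation does and does not reproduce.

## Layout

    src/hydrofilm/       the library: geometry, spin_model, mc_engine,
                         cluster_analysis, experiments, synthetic_fixtures
    analysis/            numbered drivers, one per study step
    scripts/acceptance.py  recomputes the headline numbers from scratch
    tests/               pytest suite

## Worked example

```python
from hydrofilm.experiments import Scenario, run_scenario

for name in ("p6_only", "p6_p3"):
    sc = Scenario(name=name, cells=10, sweeps=300, seeds=(1, 2, 3))
    for s in run_scenario(sc):
        print(f"{name} seed {s.seed}: {s.label:13s} slope={s.slope:7.2f} "
              f"rate={s.rate:.4f}")
```

prints (seeds 1–3, 140×140 sites, calibrated β = 0.08):

    p6_only seed 1: linear        slope=   0.85 rate=0.0036
    p6_only seed 2: linear        slope=   0.51 rate=0.0026
    p6_only seed 3: exponential   slope=   0.55 rate=0.0039
    p6_p3 seed 1: exponential   slope=  11.50 rate=0.0112
    p6_p3 seed 2: exponential   slope=   8.32 rate=0.0067
    p6_p3 seed 3: exponential   slope=  13.77 rate=0.0128

Read: in P6-only films the largest cluster creeps up by a fraction of a
protein per sweep (an occasional seed classifies exponential when domain
coalescence happens to dominate its window); with P3 contacts enabled
the cluster size grows by ~1 % per sweep compounding — the growth-law
switch caused by metastable domain-gluing links.  The same contrast shows
in percolation: on 1000-sweep matched runs the P6+P3 film spans the box
in every seed while the P6-only film never does.

The equivalent shell commands:

```sh
hydrofilm simulate --scenario p6_p3 --cells 10 --sweeps 300 --seed 1 --out runs/
hydrofilm analyze growth runs/p6_p3_1.csv
hydrofilm geometry lattice-vectors --a 54.0   # 54.000,0.000,0.000,-27.000,46.765,0.000
```

## The analysis scripts

Run from the repository root; each writes its table under `results/`.

| script | what it does |
|---|---|
| `analysis/00_calibrate_temperature.py` | β scan fixing the fluidity/ordering balance (default β = 0.08) |
| `analysis/01_geometry_anchors.py` | film lattice vectors, superlattice lengths, 7-site/6-protein cell |
| `analysis/02_growth_laws.py` | linear vs. exponential growth, percolation-time comparison |
| `analysis/03_subsaturation.py` | the 50 %-availability experiment |
| `analysis/04_coarsening.py` | P6-only domain-coarsening exponent |

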