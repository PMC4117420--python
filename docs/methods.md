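# Methods

## The model

Class II hydrophobins (HFBI/HFBII) form 2D crystalline films at the
air–water interface.  `hydrofilm` models such a film as a lattice gas with
orientation: each site of a periodic triangular lattice is either vacant or
carries one protein in one of six orientations (60° steps).  Lattice sites
are addressed in axial coordinates `(i, j)` with basis `e1 = (1, 0)`,
`e2 = (1/2, √3/2)`; the six neighbour directions are indexed 0–5
counterclockwise from `+e1`.

Adjacent occupied sites interact according to the relative orientation of
the pair and the bond direction.  Three attractive classes exist, each a
contact of the real film:

| class    | coupling | contact                                            |
|----------|----------|----------------------------------------------------|
| `TRIMER` | J0 = 5   | bond inside one three-protein trimer               |
| `P6DOCK` | J1 = 2   | trimer–trimer contact in the dense P6 crystal      |
| `P3DOCK` | J2 = 1   | trimer–trimer contact in the low-density P3 crystal |

plus an adsorption benefit Jsurf = 10 per occupied site (the amphiphile's
surface-energy gain).  All couplings are positive magnitudes entering the
energy with a minus sign,

    E = −J0·nT − J1·nP6 − J2·nP3 − Jsurf·N ,

and **every other adjacent orientation pair is forbidden** (infinite
energy).  The couplings are stated in units of kT at β = 1; the simulation
temperature is a separate, calibrated parameter (below).

### Reference crystals and the constructive interaction table

Two reference tilings define the allowed contacts:

* **P6 crystal** — vacancies on a √7 superlattice (generators `(2,1)` and
  `(−1,3)`); each 7-site cell holds one "up" trimer (orientations 0, 2, 4)
  and one "down" trimer (3, 5, 1), i.e. six proteins per seven sites.  The
  vacancy is the structure's 6-fold axis and the midpoint between the two
  trimer centroids is a 2-fold axis (plane group p6).  Exactly seven
  distinct translates exist — a global 60° rotation about a vacancy maps
  the crystal onto itself — so the P6-only model is effectively a
  seven-state Potts system.
* **Low-density P3 crystal** — same-parity trimers on a 2×2 superlattice,
  three proteins per four sites, invariant under 120° rotations about each
  trimer centroid but under no 2-fold rotation (plane group p3).  Its
  density (3/4) is strictly below the P6 crystal's (6/7); in this lattice
  embedding the two lattice parameters are in the ratio 2 : √7.

The exact (direction, orientation-pair) interaction table is defined
*constructively*: `TRIMER` entries are the 12 ordered bonds of the
canonical trimers; `P6DOCK` entries are the inter-trimer triples realized
in the P6 tiling; `P3DOCK` entries (present only when P3 ordering is
enabled) are the inter-trimer triples of the P3 tiling not already
claimed; everything else is forbidden.  The table is closed under the
global 60° rotation (orientation +1, direction +1) and bond reciprocity.
This construction guarantees that both target structures are realizable,
that nothing else is, and that the whole model is reproducible from the
two tilings alone.  Verified consequences (tests): the P6 crystal is a
strict local energy minimum under every move class, the seven translates
are exactly degenerate, and the P3 crystal is metastable — every single
move raises its energy — while being 33 % less dense.

The smallest square box commensurate with both crystals is 14×14 sites;
all simulation boxes are multiples of this unit cell.

## Monte Carlo dynamics

Trial moves mimic protein motion: (1) adsorption of a uniformly oriented
protein at a uniform site / desorption; (2) a single protein hopping to a
vacant neighbour and/or rotating ±60°; (3) a complete trimer translating
one site and/or rigidly rotating ±60°.  One sweep is width×height
attempts; the move mix defaults to (0.4, 0.4, 0.2).

Numerical choices worth knowing:

* **Acceptance.**  Metropolis, with a Hastings factor of 6 on
  adsorption/desorption (an insertion proposes one of six orientations, a
  deletion has a unique target): insert accepts with min(1, 6·e^{−βΔE}),
  delete with min(1, e^{−βΔE}/6).  This puts the chain in detailed balance
  with respect to e^{−βE} over configurations; the non-interacting check
  (all couplings zero, all pairs allowed) reproduces the grand-canonical
  occupancy 6·e^{βJsurf}/(1 + 6·e^{βJsurf}) to < 1 %.
* **Trimer rotation.**  A ±60° rotation of a lattice triangle about its
  own centroid does not map lattice sites to lattice sites, so the rigid
  rotation pivots about one of the trimer's three vertices (pivot drawn
  uniformly); the proposal remains symmetric and accepted trimer moves
  always leave the three sites mutually trimer-bonded.
* **Subsaturation.**  `p_absent` thins insertion *proposals* only (with
  that probability an adsorption attempt finds no protein); desorption is
  untouched.  This is a kinetic, not thermodynamic, modification.
* **Determinism.**  All randomness comes from one generator seeded per
  run; identical seeds give bit-identical time series and final snapshots.
  The tracked energy is validated against full recomputation (<1e−9 over
  10⁴-move stress tests).
* **Quench.**  Zero-temperature relaxation accepts only strictly
  energy-lowering moves and stops after the first sweep with no
  acceptance; used for metastability and two-domain checks.

### Temperature calibration

The model fixes only coupling *ratios*; the temperature sets overall
mobility and is chosen to balance film fluidity against ordering.  The
scan in `analysis/00_calibrate_temperature.py` (P6-only, 140×140 sites,
3000 sweeps, three seeds per β) shows three regimes: for β ≤ 0.05 the film
never condenses (occupancy ~0.43, no lasting clusters); for β ≥ 0.2 the
film jams almost immediately into a frozen polycrystal whose largest
cluster stops growing at ~1 % of the box; between these, adsorbed proteins
still exchange with the subphase and domains anneal.  The ordered-film
size attained in fixed time is maximal at **β = 0.08**, the package
default (`hydrofilm.experiments.DEFAULT_BETA`).  At β = 1 — couplings read
directly in kT — the model is deep in the arrested regime and exhibits no
steady-state growth at all.

## Cluster analytics

Clusters are connected components of occupied sites over *attractive*
bonds (in a finite-energy configuration every adjacent occupied pair is
attractive, so clusters are bonded domains; each P6-only cluster is
automatically a fragment of one of the seven crystal translates).
Percolation is detected by winding: during the flood fill each site
carries its unwrapped displacement from the cluster root, and a cycle that
closes with a nonzero net periodic displacement marks a wrapping cluster.
The labeling is validated against an independent breadth-first-search
oracle on a thousand random configurations.

**Growth-law classification.**  The steady-state window runs from the end
of the filling phase (occupancy first exceeding 90 % of its final plateau,
plateau = mean over the trailing 10 % of records) to strictly before the
first percolating record.  Two models are fitted to largest-cluster size
vs. sweep: a straight line (Gaussian errors) and a straight line in log
size (log-normal errors, whose AICc carries the 2·Σ log y Jacobian term so
both likelihoods refer to the same variable).  Labels are decided by AICc
with a margin of 2; smaller gaps give `indeterminate`, and windows with
fewer than 10 positive records are `indeterminate` with a diagnostic.
Residual sums of squares are floored at n·1e−30, which makes an exactly
constant series decisively linear.  The classifier recovers planted
linear/exponential labels at 5 % noise with ≥ 95 % accuracy.

**Coarsening exponent.**  The log–log slope of largest-cluster size vs.
sweep.  For the dedicated coarsening experiment
(`experiments.coarsening_experiment`: P6-only, 6000 sweeps) the fit
discards the first tenth of the run: the filling phase leaves a large size
offset that would bias a power-law fit taken from time zero.

## Scenarios and problem sizes

The three experiments (`p6_only`, `p6_p3`, `subsaturated`, the last with
p_absent = 0.5) start from an empty lattice.  The published system size is
40×40 commensurate cells (560×560 sites); the desk-scale default used by
the analysis scripts, tests and the acceptance script is 10×10 cells
(140×140 sites), with 300-sweep runs for growth-law classification and
1000-sweep runs for percolation-time comparison — a percolation *time*
can only be compared between runs long enough to percolate, and P6-only
films on this horizon typically never do.  Matched seeds are compared with
a one-sided sign test (assumption-free, 5 paired seeds).

## What the simulations show (and do not)

* **Growth-law switch (reproduced).**  P6-only films grow their largest
  cluster linearly in the steady-state window; enabling the metastable P3
  interaction makes the growth exponential and the bonded network spans
  the box far earlier.  The mechanism is visible directly in the
  two-domain fixture: crystals on different vacancy sublattices separated
  by a one-site seam merge through P3 bridge bonds within a few sweeps,
  while under a P6-only table no single protein can bond to both sides
  and quenching never merges them.
* **Subsaturation (not reproduced).**  Halving protein availability slows
  filling and delays percolation markedly, but in this implementation the
  bridging mechanism itself remains active and the largest-cluster growth
  still classifies as exponential in most seeds at every temperature
  probed.  Availability thinning rescales adsorption kinetics; it does not
  remove the constant-rate domain-merging events that produce the
  exponential law, so the suppression seen in the original study is not
  recovered by proposal thinning alone.
* **Coarsening exponent (partially reproduced).**  The P6-only model is a
  seven-state Potts system by state count, and 2D Potts coarsening
  predicts domain area ~ t.  Measured on the asymptotic window at the
  calibrated temperature the largest-cluster area exponent is ≈ 0.5
  (radius ~ t^¼) with seed-to-seed spread of ±0.2.  The shortfall is
  systematic: unlike a soft-constraint Potts model, every misoriented
  contact here is strictly forbidden, so domain-boundary motion requires
  desorption/re-adsorption or multi-step hop-rotate paths and is
  activated; the growth law is sublinear on accessible timescales.

## Synthetic data

The fixture generators produce exactly the inputs the analyses consume:
empty interfaces, rejection-sampled random adsorbate gases (valid by
construction, never equilibrated — equilibrium states come from the
engine), crystal patches, site-diluted crystals, and two-domain
configurations with a vacant seam.  They emulate the *structure* of
simulation states, not real micrographs: there is no imaging noise, no
multilayer film, no protein internal degrees of freedom, and the
continuous-space geometry module reduces the three Euler angles of the
hexamer description to the single in-plane angle (the package is strictly
2D; atomistic symmetrization is out of scope).  Passing tests therefore
certify the lattice model and its analytics, not agreement with
experimental imagery.

## Known limitations

* Absolute Monte Carlo timescales are not comparable to the original
  study's step counts (the published step unit is not defined); only
  growth-law shapes and orderings are meaningful.
* The coarsening exponent and the subsaturation suppression are not
  reproduced quantitatively (see above); both are documented honestly by
  the corresponding tests and analysis scripts rather than tuned around.
* β, the move mix and the sweep convention are implementation choices;
  all are exposed as parameters and recorded in run manifests.
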