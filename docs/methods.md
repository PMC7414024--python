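# Methods

## The model

`picycle` implements a deterministic mass-action model of the
phosphoinositide (PI) cycle driving Gq-coupled GPCR → PLCβ signalling,
parameterised in absolute molecule numbers per cell.  Three well-mixed
compartments are distinguished (plasma membrane, cytosol, organelles); a
human platelet is taken as the reference geometry with 1 fl per
compartment.

State variables (33 species) cover:

* the lipid pools — plasma-membrane PI, an organelle PI reserve, PI4P,
  PI(4,5)P2, DAG and PA, the latter four split into a free pool and a
  pool reversibly sequestered by lipid-binding proteins;
* the soluble inositol moieties — IP3, a lumped removal intermediate
  (IPx, standing for the IP4/IP2 products of IP3 3-kinase B and INPP5),
  and free inositol;
* the signalling chain — active receptors (Ra), inactivated receptors,
  Gαq and active Gαq, PLCβ and active PLCβ, and a small-G-protein pool
  that participates multiplicatively in PLCβ activation;
* the standing enzyme pools (PI4K, PIP5K, OCRL1, SAC1, DGK, LPP, CDIPT,
  IP3 modifiers, cPLA2), carried as dynamic states with zero net
  stoichiometry so that catalytic conservation is a structural property
  rather than a numerical one.

Reactions (25) follow mass action; enzymes enter rate laws
multiplicatively and are conserved.  The lipid kinase/phosphatase axis is
PI →(PI4K) PI4P →(PIP5K) PI(4,5)P2 →(OCRL1) PI4P →(SAC1) PI, with active
PLCβ cleaving PI(4,5)P2 into IP3 + DAG.  IP3 is removed quickly to the
intermediate (enzymatic) and converted slowly to inositol (first order);
DAG ↔ PA interconvert via DGK/LPP; CDIPT condenses PA with inositol into
organelle PI; a slow first-order transfer returns organelle PI to the
plasma membrane; and cPLA2 recycles membrane PI to the organelle pool.
With that recycling closure the full network conserves both the total
inositol moiety and the total glycerolipid backbone exactly, so the
closed-cycle conservation tests run against the shipped model itself
rather than a modified variant.

### Units

All state is in molecules per cell.  Rate constants of kinetic order
*m* ≥ 2 are stored pre-folded with their compartment volume
(per-molecule per-second), which keeps the simulator free of unit
conversions; the volume appears explicitly only in cell-type rescaling,
where a constant of order *m* is multiplied by `(V_ref / V_new)^(m-1)`.
This choice makes the scaling-symmetry control exact: scaling volumes,
copy numbers, pools and receptor count by a common factor leaves every
concentration trajectory invariant.

### Activation and termination

Activation is a discrete event at `t_activation`: `receptor_count`
active receptors appear and catalyse Gαq activation, which (with the
small-G pool) activates PLCβ; receptors inactivate first order
(k_ri = 0.01 /s).  Simultaneously — provided at least one receptor is
present, reflecting recruitment of the membrane kinase complex by the
receptors — the constants of PI4K, PIP5K, OCRL1 and cPLA2 switch to
primed values; SAC1's constant is never switched, and the
organelle-to-membrane PI transfer rate is never modified by activation.
The default termination resets the switched constants to basal after
100 s; an "inactivation" mode leaves them primed so signalling dies
through receptor loss alone.  Events are handled by stopping the
integrator, applying the discrete changes, and restarting, so untouched
species are continuous across events.

The membrane-PI fall is carried predominantly by the primed cPLA2
recycling flux rather than by PLC throughput.  This is a deliberate
structural choice: the observed behaviours to reproduce are (i) PI
dropping to about half its resting level and staying there, and (ii) an
IP3 peak that scales close to proportionally with receptor number.  If
the whole PI drop is routed through PLCβ, the IP3 peak saturates against
the PI influx rate and the dose response flattens; an activated
deacylation/recycling shunt (cPLA2 is itself thrombin-activated)
decouples the two.

### Solver

LSODA (stiff/non-stiff switching) with analytic Jacobian, rtol 1e-8,
atol 1e-6 molecules.  The reaction network is compiled to flat index
arrays and the right-hand side and Jacobian are numba-compiled, which
keeps a 2000 s platelet solve at ~25 ms and makes the 4096-run mosaic
scan practical on one CPU.  Amounts in (−1e-9·max, 0) are clipped to
zero after integration; anything more negative raises an error.
Steady states are found by relaxation (geometrically growing horizons
until max |dX/dt|/(|X|+1) < tol), because the conservation laws make the
algebraic system dX/dt = 0 rank-deficient for root finders.

## Calibration

The rate constants shipped in `data/platelet_core_synthetic.yaml` are
this package's own calibration — synthetic stand-ins derived from the
qualitative and quantitative constraints the platelet literature states,
not transcribed laboratory values.  The basal constants are fixed
exactly by the homeostatic state: total PI4P and PI(4,5)P2 at 1.5e6
molecules per cell (free pools 4e5 after binding equilibrium), membrane
PI at 6e6, a 2000 molecule/s basal flux around the lipid axis, and a
balanced cPLA2/transfer exchange with the organelle pool.  The primed
constants were then chosen by parameter scans so that full activation
(RGq = 5000 at 100 s) produces a PI4P/PI(4,5)P2 burst peaking within
20 s and relaxing back, membrane PI halving with under 20% recovery by
30 min, and an IP3 peak ratio near 0.5 between RGq = 1650 and 5000.

The `calibrate` module exposes the machinery used: log-spaced scans
(default ±4 decades, 5 points per decade; deterministic, ties toward the
smaller value), the ≤20% max-relative-deviation acceptance rule with a
1%-of-max floor guarding near-zero baselines, a binding-protein-number
scan with a coarse secondary on/off-rate grid plus one refinement pass,
and the staged iterations 1–4 (basal axis → activated axis → PI4P/PIP2
binding pools → downstream IP3/DAG/PA rates and their pools).  Stages
freeze earlier values; multi-parameter stages scan coordinate-wise with
one refinement sweep.  The DAG and PA binding pools are fitted in stage
4 rather than stage 3 because no monitored observable depends on them
until the downstream reactions exist.

Quantified recovery replaces fit-by-eye: on noise-free data generated by
the model itself every scanned parameter must be recovered within one
grid step, which the test suite enforces.

## Cell-type rescaling

`rescale_model` swaps compartment volumes and the twelve key protein
copy numbers while freezing reaction structure and per-concentration
kinetics; lipid and binding-protein pools scale with the membrane-volume
ratio from the platelet reference.  Geometries: mouse platelet 0.25 fl,
generic nucleated cell 17 fl per compartment (from a 2000 fl cell), with
85,000 receptors matching the platelet receptor concentration.  The
platelet cytosol is set to 1.0 fl (within the literature's 1–2 fl
range) so that all three compartments share one scale factor per cell
type, which the exact pltx17 symmetry requires.

Because a rescaled model inherits platelet-proportioned lipid pools that
are generally not its own rest state, `equilibrate_model` relaxes the
basal (event-free) system to steady state and restarts from there —
the standard pre-activation steady-state adaptation step.  Reference
cell types (mouse, pltx17, HeLa, the U2OS variants) are equilibrated
before activation; mosaic mix-and-match combinations deliberately are
not (see below).

Missing proteome entries are either borrowed from a donor table
(provenance `borrowed:<donor>`) or estimated by per-gap parameter scans
against a reference behaviour (provenance `scanned`), coordinate-wise
with a refinement sweep; a flat scan objective marks the monitored
outputs as insensitive to that protein and ties break to the grid
minimum.

## Mosaic robustness and the classifier

`mix_and_match` enumerates all 2^12 assignments of the twelve key
proteins to two source tables (stable lexicographic order), simulates
each at nucleated geometry (5000 s, activation at 1000 s) starting from
the equilibrated source-A lipid state with only the protein numbers
swapped — the semantics of a parameter scan over initial concentrations —
and classifies each trajectory against the pure source-A reference.

The correct/incorrect criterion is not stated by any published source in
quantitative form, so it is defined here explicitly, per observable
(PI, PI4P, PI(4,5)P2, IP3, DAG, PA, Ins):

1. **stability** — pre-activation drift below 10% of the starting level;
2. **direction** — the dominant post-activation response (rise vs fall)
   matches the reference;
3. **magnitude** — the response extremum is within a 5-fold band of the
   reference's.

A combination is incorrect if any observable fails any rule; failed
integrations count as incorrect.  Because the headline fraction depends
on the band, the summary always reports the 3-/5-/10-fold bracket.

## Sensitivity analysis

`ip3_sensitivity` computes the scaled time-series sensitivity
(ΔIP3/IP3)/(Δp/p) of IP3 to each protein's initial copy number by
central finite differences at p(1±δ), δ = 0.2 by default, over the full
output grid plus a summary column at the baseline IP3 peak.  Entries
where baseline IP3 is at or below 1 molecule are flagged undefined
rather than propagated.  Adjoint or forward sensitivity ODEs are
unnecessary at this scale.

## Synthetic data

The `synthetic` module stands in for collated experimental inputs:

* **Time courses** — the truth model is simulated and n = 10
  multiplicative log-normal replicates are drawn per time point
  (log-mean −sd²/2, so dataset means are unbiased); mean and SEM are
  reported.  Default relative noise 0.15, chosen to resemble the size of
  typical SEM bars on platelet lipid measurements.  Identical seeds give
  bit-identical datasets.
* **Proteomes** — a template table perturbed by median-preserving
  log-normal factors.  Shipped tables: mouse platelet = human × 0.25
  volume scale × ln-sd 0.5 orthologue divergence; HeLa = human × 17 ×
  ln-sd 0.8; U2OS = HeLa × ln-sd 0.45 residual (two human cell lines
  correlate far more with each other than either does with platelets),
  with Gαq, the IP3 modifiers, OCRL1, PI4K and cPLA2 removed to emulate
  a partial dataset.  All seeds are fixed; every shipped file carries
  `synthetic` in its name.

What passing tests therefore show: that the pipeline's algorithms —
integration, scanning, rescaling, classification — behave correctly
under controlled conditions with known ground truth.  What they do not
show: agreement with any laboratory measurement; the shipped numbers are
calibrated stand-ins, and quantitative claims about real platelets or
cell lines require the corresponding measured tables.

## Numerical choices and limitations

* Deviation floor: 1% of an observable's largest mean, guarding
  near-zero baselines (pre-activation IP3).
* Scan grids are log-spaced and deterministic; no random restarts.
  Problem sizes in the tests and the acceptance script (grid spans of
  1–2 decades, 401–2001-point output grids, 5000 s mosaic horizon) were
  chosen to characterise each behaviour at the smallest size that
  exercises it fully.
* The IPx → Ins simplification is irreversible; the real inositol
  phosphatase cascade is a reversible network.
* The PI3K/PIP3 branch, the G13 branch, and calcium dynamics are out of
  scope by design.
* The mosaic fraction is meaningful only relative to the classifier
  config and the synthetic proteome scatter; both are exposed as
  parameters so the dependence can be mapped.
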