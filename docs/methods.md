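# Methods

## Model

`polyanchor` simulates cationic semiflexible polymers adsorbing
("anchoring") onto a mixed fluid lipid monolayer with Metropolis Monte
Carlo.  The monolayer is a 50 x 50 row-offset hexagonal lattice of headgroup
disks (diameter d = 8.66 Å) on an impenetrable plane at z = 0, periodic in x
and y; each site carries one lipid: neutral PC, univalent PS (charge -1) or
tetravalent PIP2 (charge -4).  Polymers are freely-jointed chains of N = 20
hard spheres of diameter d, bond length fixed at d, one +1 charge per
segment center.  Energies are measured in k_B T and lengths in d throughout.

The potential energy is

    U = U_HS + U_E + U_bend

* U_HS: hard cores between non-bonded segments (overlap = infinite energy,
  automatic rejection) plus the wall constraint z >= d/2 on segment centers
  (sphere tangent to the plane).  Headgroups are not given an explicit hard
  core against segments: the wall already keeps segment centers at least d/2
  above any headgroup center, which is the only monolayer constraint the
  model states.
* U_E: Debye-Hückel screened Coulomb between all charged species,
  u(r) = Z_m Z_n l_B exp(-kappa_D r)/r per unordered pair, with
  l_B = 7.14 Å and kappa_D from the 1:1-salt expression
  kappa_D^2 = 1000 e^2 N_A (2 C_i) / (eps_0 eps_r k_B T).  The Bjerrum
  length is the defining electrostatic input; the Debye length is evaluated
  with eps_r = 78.5 and T = 298.15 K so that 1/kappa_D = 3.04 Å / sqrt(C_i[M])
  (30.4 Å at 10 mM).  All pairs use the solution dielectric: every charge
  sits on or above the plane, so no image-charge or slab correction is
  applied; the membrane dielectric (~2) is recorded in the parameters but
  unused.  Interactions are truncated at 6 Debye lengths (tail < 0.25% of
  the contact value), capped at half the smaller box edge, and evaluated
  with minimum-image distances; the exponential screening makes Ewald
  summation unnecessary at the salt concentrations of interest
  (C_i >= 0.001 M).  Bonded neighbors are not excluded from U_E — their
  separation is fixed, so the term is a constant that cancels from every
  energy difference.
* U_bend = kappa * sum_i (alpha_i - pi)^2 over interior vertex angles
  alpha_i; kappa = 0 recovers the freely-jointed chain.

## Sampling

One MC step attempts, in freshly randomized order:

* per chain: one local move per segment (kink-jump rotation about the axis
  through the two bonded neighbors; chain ends are re-drawn uniformly on the
  sphere around their single neighbor), plus one crankshaft, one rigid
  whole-chain translation (uniform cube of half-width d/2) and one pivot
  (random axis, uniform angle, random side);
* per charged lipid: one Kawasaki exchange with a uniformly chosen nearest
  neighbor site.  Exchanges conserve composition exactly; a swap of two
  same-species sites is an accepted no-op (identical particles are not
  relabelled, so it contributes no displacement).

All proposals are self-inverse in density, satisfying detailed balance; the
stationary distribution is verified against the exact Boltzmann law on an
enumerable micro-system in the test suite.  Angular move amplitudes are
uniform on [-pi, pi] and the translation half-width is d/2; amplitudes
affect mixing only, not the stationary distribution, and are configurable.

Acceptance uses incremental energy differences (only the moved charges are
revisited); the running total is re-synchronized against a full O(n^2)
recomputation at every recorded frame and every 1000 steps, and the maximum
bookkeeping drift is reported in the run manifest (typically < 1e-12 k_B T).

The protocol has three stages: athermal relaxation (all energies off, hard
cores / wall / fixed bonds only — its sole purpose is to forget the initial
configuration of straight rods parallel to the plane at height 2d and the
random lipid placement; lipid moves stay active), equilibration (full
energy, nothing recorded), and production (one frame every
`analysis_interval` = 50 steps, the cadence at which every observable is
defined).  All randomness derives from one master seed via SeedSequence
streams — per replica, per stage — so runs are bit-reproducible and
replicas independent.

## Observables

* **Anchoring**: a chain is anchored in a frame iff any segment center lies
  below 2d (configurable).  The threshold is an operational definition; at
  the state points studied chains are either clearly adsorbed or clearly
  desorbed and the statistics are insensitive to it.
* **Interaction zones / sequestration**: zone k (k = 1..8) of an anchored
  chain is the union of lateral disks of radius k*d around its segment
  centers, recomputed each frame.  A lipid is sequestered in zone k for the
  interval between consecutive frames iff it is inside at both bounding
  frames (intermediate steps are not stored at the 50-step cadence).
  phi_s(k) is the sequestered fraction of all lipids of species s (union
  over chains); M_s(k) the sequestered count per anchored chain, with lipids
  in overlapping zones attributed to the chain with the nearest segment.
  Zones are nested, so both are non-decreasing in k by construction.
* **Lateral RDFs**: standard 2D pair correlation of like-species headgroup
  positions with minimum-image distances, bin width 0.25 d, normalized so a
  uniformly random arrangement gives 1 (the like-species ideal density uses
  N-1).  Peak positions are reported as the bin center maximizing g(r) over
  r < 10 d.
* **Segment height distribution**: histogram of segment-center heights of
  anchored chains, normalized per anchored chain (integrates to the mean
  number of segments per anchored chain).
* **Interval MSDs**: per consecutive frame pair, m_pc is the squared COM
  displacement of chains anchored at both ends of the interval (all three
  components — desorbing chains move in z; lateral parts minimum-image);
  m_d(k, s) the squared displacement of the micro-domain COM (the species-s
  lipids sequestered in zone k of one chain); m_l(k, s) the mean squared
  lateral displacement of those single lipids.  Empty micro-domains are
  skipped, not counted as zero.
* **Persistence length**: BAC(j) = <u_i . u_{i+j}> over unit bond vectors,
  bond pairs, conformations and chains.  Since BAC ~ exp(-j/L_p) is a
  proportionality, L_p comes from a weighted least-squares line (slope plus
  free amplitude) on ln BAC(j) over j = 1..j_max with BAC > 0.2, weights
  n_pairs * BAC^2 (delta-method inverse variance).  The free amplitude
  absorbs the non-exponential single-bond drop that discrete charged chains
  show at j = 1; a through-origin fit would halve L_p for flexible charged
  chains.  A non-decaying BAC (rigid rod) reports L_p = inf.  Table values
  are measured on a single chain in bulk solution (no monolayer, no wall),
  the simplest ensemble consistent with an intrinsic chain property.

## Problem sizes

The full protocol (10^6 athermal + 2x10^6 equilibration + 2x10^6 production
steps, 20 replicas per state point) is the reference configuration and the
package default.  The shipped tests, examples and the acceptance script use
desk-scale versions chosen as the package's own study conditions: the
low-concentration state points keep the full 50x50 monolayer and 98:1:1
composition (they set the physics — 25 PIP2 and 25 PS lipids) with step
counts reduced to 2x10^4 / 6x10^4 / 6x10^4 and 3 replicas; the
high-concentration points (C_p = 0.0037) use the proportional lattice
scale-down instead — 4 chains over a 34x36 monolayer at the same surface
densities, ~4x cheaper per MC step — with 10^4 / 10^5 / 5x10^4 steps and 3
replicas.  Single-chain persistence lengths use 5x10^4 equilibration +
2x10^5 production steps sampled every 100.  At these sizes the flexible
chains anchor and the PIP2 redistribution equilibrates within the
equilibration stage (the zone-3 sequestered fraction is stationary across
production quarters; lipid diffusion covers ~sqrt(steps) ~ 200 sites); the
replica scatter of phi_s and the RDF peak location is reported as
mean +/- SE.

## What the generator does and does not emulate

Inputs are generated, never read from data: random lipid placement at exact
integer composition (largest-remainder rounding — at the standard
compositions 1% of 2500 is exact), straight non-overlapping rods as initial
chains.  The model represents headgroups as fixed-lattice point charges
(no off-lattice diffusion, flip-flop, tails, curvature or area
fluctuations), ions only through linearized screening (no explicit ions,
charge regulation or counterion condensation), and chains as monodisperse
hard-sphere polymers.  Passing tests therefore demonstrate correct sampling
of *this* coarse-grained model and its documented trends (zone nesting,
PIP2-over-PS selectivity, salt weakening, rigidity effects), not
quantitative agreement with any particular experimental membrane.

## Numerical choices and degenerate inputs

* Hard-core test uses r < d - 1e-9 so exact contacts (bonded neighbors,
  touching spheres) are legal; bond lengths are preserved by construction
  (rotations about axes through the neighbors) and drift only at the
  floating-point level (~1e-13 over 10^6 moves, asserted in tests).
* A crankshaft on a perfectly straight chain has a degenerate axis and is a
  no-op; a pivot at a chain end with an empty tail is an accepted no-op.
* Zone membership at exactly k*d, like all strict inequalities here, is
  excluded; observables avoid placing fixtures exactly on thresholds.
* Zero anchored chains: phi_s = M_s = 0 with a warning; empty micro-domains
  are skipped in MSDs; an absent species yields NaN fractions rather than
  silent zeros.
* At C_i = 0 the interaction is bare Coulomb (cutoff at half box when
  periodic, none in bulk mode).

## Known limitations

* The persistence length of stiff chains (kappa >~ 20) exceeds the 20-bead
  contour, so the BAC barely decays over the available separations and the
  fitted L_p is effectively unbounded and strongly convention-dependent;
  for the harmonic bending potential used here the intrinsic persistence
  length scales as ~2 kappa d.  L_p values for flexible and mildly stiff
  chains are well defined.
* Because headgroups live on a lattice, g(r) is a shell spectrum rather
  than a smooth curve: with 0.25 d bins the occupied bins are the hexagonal
  shells (sqrt(3), 2, sqrt(7), 3, ... in units of d) and annulus
  normalization weights shells by multiplicity/annulus-area, which can
  decide which shell carries the global maximum.  Peak locations should be
  read shell-wise, not as continuum distances.
* Desorption of strongly anchored stiff chains is an activated process
  (segment-by-segment peeling against several k_B T per segment); at
  desk-scale step counts stiff chains that anchor do not detach, so
  observables that hinge on partial dissociation of rigid chains at high
  polymer concentration require near-reference-scale equilibration.
* Kawasaki dynamics on a lattice gives relative, not absolute, mobilities;
  interval MSDs are meaningful for comparisons across zones, species and
  state points only.
* The wall is the only monolayer excluded volume; segments may approach
  headgroup centers to d/2 directly overhead, a convention choice the model
  does not resolve further.
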