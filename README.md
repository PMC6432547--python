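# polyanchor

Coarse-grained Metropolis Monte Carlo of **cationic semiflexible polymers
anchoring onto a mixed anionic lipid monolayer**, with the full observable
suite for the resulting membrane heterogeneity: anionic-lipid sequestration
in nested interaction zones, lateral radial distribution functions, the
anchored-segment height profile, interval mean-square displacements of
chains / lipid micro-domains / single sequestered lipids, and chain
persistence lengths.

## Why

Peripheral cationic macromolecules (polybasic protein domains, polypeptides,
synthetic polycations) bind anionic membranes electrostatically and locally
*sequester* multivalent lipids such as PIP2 (valence −4 at pH 7), reshaping
both the lateral organization and the mobility of the membrane.  The model
is intended for studying how chain rigidity κ, polymer surface concentration
C_p, and salt C_i control that sequestration.

## Model in brief

* Monolayer: 50 × 50 hexagonally close-packed headgroup disks (diameter
  d = 8.66 Å) on an impenetrable plane at z = 0, x/y-periodic; species
  PC (0), PS (−1), PIP2 (−4) at fixed composition (e.g. PC:PS:PIP2 =
  98:1:1), moving by Kawasaki nearest-neighbor exchange.
* Polymers: N = 20 hard spheres of diameter d, fixed bond length d, one +1
  charge per segment; conformations sampled with kink-jump / crankshaft /
  whole-chain translation / pivot moves.
* Energy (units of k_B T):  U = U_HS + U_E + U_bend with hard cores + wall,
  Debye–Hückel pair electrostatics
  `u(r) = Z_m Z_n l_B exp(−κ_D r)/r` (l_B = 7.14 Å; κ_D from the 1:1-salt
  Debye length, 30.4 Å at C_i = 0.01 M), and harmonic bending
  `U_bend = κ Σ_i (α_i − π)²`.
* Protocol: athermal relaxation → equilibration → production with one frame
  per 50 MC steps; replicas with independent derived seeds; everything
  reproducible from a single master seed.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

```python
from polyanchor import (SimulationConfig, run_replicas,
                        sequestration_stats, radial_distribution)
from polyanchor.observables import aggregate_sequestration, ZoneSpec

config = SimulationConfig(
    n_chains=2, rigidity=0.0, salt_concentration=0.01,
    steps_athermal=10_000, steps_equilibration=30_000,
    steps_production=30_000, seed=2, n_replicas=2,
)
trajs, _ = run_replicas(config)
agg = aggregate_sequestration([sequestration_stats(t, ZoneSpec()) for t in trajs])
print(agg["PIP2"]["phi_mean"].round(3))
```

prints (zone 1 … 8 sequestered PIP2 fractions; scaled-down run, exact values
depend on the seed)

```
[0.221 0.267 0.291 0.311 0.332 0.356 0.379 0.404]
```

i.e. ~22% of all PIP2 lipids sit within one segment diameter of the two
anchored flexible chains and stay there over a 50-step interval, with the
fraction growing monotonically through the nested zones; the corresponding
PS fractions are an order of magnitude smaller — the tetravalent lipid is
selectively sequestered.  The `examples/` scripts cover each capability the
same way:

* `examples/persistence_length.py` — bulk-chain L_p vs κ and C_i,
* `examples/sequestration_zones.py` — φ_s(k) / M_s(k) zone statistics,
* `examples/lipid_clustering_rdf.py` — PIP2–PIP2 RDF with and without chains,
* `examples/mobility_heterogeneity.py` — m_pc, m_d, m_l interval MSDs.

A thin CLI wraps the same library calls:

```bash
polyanchor run --config run.yaml --out traj.h5
polyanchor analyze traj.h5 --out-dir results/
polyanchor sweep --config run.yaml --out-dir sweep/ --kappa 0 --kappa 10
polyanchor lp --kappa 0 --salt 0.01
```

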