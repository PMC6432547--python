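"""PIP2 clustering induced by anchored polymers, seen in the lateral RDF.

Compares the PIP2-PIP2 radial distribution function with and without anchored
chains.  A naked monolayer gives a flat g(r) ~ 1 (electrostatic repulsion
only); anchored flexible chains gather the tetravalent lipids underneath,
producing a contact peak a couple of segment diameters wide.
"""

from polyanchor import SimulationConfig, radial_distribution, run_protocol

for n_chains, label in [(0, "naked monolayer"), (2, "2 anchored chains")]:
    config = SimulationConfig(
        n_chains=n_chains, rigidity=0.0, salt_concentration=0.01,
        steps_athermal=10_000, steps_equilibration=30_000,
        steps_production=30_000, analysis_interval=50, seed=4,
    )
    traj, _ = run_protocol(config)
    rdf = radial_distribution(traj, "PIP2", "PIP2", bin_width=0.25)
    peak = rdf.peak_position(r_max=10.0)
    sel = (rdf.r_centers > 1.0) & (rdf.r_centers < 8.0)
    print(f"{label:18s}: g(r) max over r<10d at r = {peak:.2f} d "
          f"(g = {rdf.g[rdf.r_centers == peak][0]:.2f})")
print(
    "\nDistances are in units of the 8.66 A headgroup diameter; g = 1 means\n"
    "an unstructured (ideal) lateral arrangement."
)
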