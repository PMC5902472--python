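"""Run the three DLG seeding scenarios and print their spatial indices.

Each scenario grows a colony on a 200 x 200 lattice (nutrient steps s = 3,
mean initial concentration c0 = 1) until the stopping density, then
summarises the morphology with the matching index: I_theta (angular
non-uniformity, branch screening), I_c (fraction of cells between two seeds,
repulsion when below 0.5) and I_b (right-half fraction, directed growth when
above 0.5).
"""

from dlgrowth import LatticeConfig, run_until_density
from dlgrowth.indices import ColonyPointSet, compute_index
from dlgrowth.workflows import SCENARIO_INDEX

for scenario, (kind, stop) in SCENARIO_INDEX.items():
    cfg = LatticeConfig(
        L_x=200, L_y=200, s=3, c0=1.0, scenario=scenario,
        stop_density=stop, rng_seed=42,
    )
    res = run_until_density(cfg)
    pts = ColonyPointSet.from_lattice_state(res.state, cfg)
    idx = compute_index(pts, kind)
    print(
        f"{scenario:18s} rho={stop}: {res.state.nu} cells after "
        f"{res.state.t_step} steps, I_{kind} = {idx.value:.3f}"
    )

print(
    "\nI_theta well above 0 flags branched growth; I_c below 0.5 flags a "
    "depleted gap\nbetween twin colonies; I_b near 1 flags growth directed at "
    "the nutrient source."
)
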