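"""Higher-level orchestration: parameter sweeps and the DLG verdict.

``sweep_scenario_indices`` repeats seeded lattice simulations over an
(s, c0) grid and tabulates the mean index per parameter pair, mirroring the
replicate-sweep design used to map when each DLG phenomenon is induced.
``classify_dlg`` turns a measured relative spread Δ and a dimensionless
nutrient concentration N into a DLG-plausible / DLG-implausible verdict by
looking the pair up in a reaction-diffusion regime map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import continuum, lattice
from .indices import mean_index_over_realisations

#: index kind and stopping density conventionally used per scenario
SCENARIO_INDEX = {
    "uniform_single": ("theta", 0.2),
    "uniform_two_seeds": ("c", 0.2),
    "nutrient_column": ("b", 0.1),
}


def sweep_scenario_indices(
    scenario: str,
    s_values: Sequence[int],
    c0_values: Sequence[float],
    n_reps: int = 50,
    L: int = 200,
    base_seed: int = 0,
    max_steps: int = 1_000_000,
    **config_kwargs,
) -> pd.DataFrame:
    """Mean DLG index over ``n_reps`` realisations for each (s, c0) pair.

    Returns a DataFrame with columns ``s, c0, mean, stderr, n, n_excluded``.
    Replicates are independently seeded from ``base_seed`` deterministically;
    runs that never reach the stopping density are excluded and counted.
    """
    kind, stop = SCENARIO_INDEX[scenario]
    rows = []
    for i, s in enumerate(s_values):
        for j, c0 in enumerate(c0_values):
            cfg = lattice.LatticeConfig(
                L_x=L,
                L_y=L,
                s=int(s),
                c0=float(c0),
                scenario=scenario,
                stop_density=stop,
                max_steps=max_steps,
                **config_kwargs,
            )
            cell_seed = base_seed + 100_000 * (i * len(c0_values) + j)
            ens = mean_index_over_realisations(cfg, n_reps, kind, base_seed=cell_seed)
            rows.append(
                dict(
                    s=int(s),
                    c0=float(c0),
                    mean=ens.mean,
                    stderr=ens.stderr,
                    n=ens.n,
                    n_excluded=ens.n_excluded,
                )
            )
    return pd.DataFrame(rows)


@dataclass
class DLGVerdict:
    """Outcome of the regime-map lookup for a measured (Δ, N) pair."""

    plausible: bool
    max_ib: float
    threshold: float
    grid_log10D: float
    grid_log10N: float
    rationale: str

    def __str__(self) -> str:
        label = "DLG-plausible" if self.plausible else "DLG-implausible"
        return f"{label}: {self.rationale}"


def classify_dlg(
    delta: float,
    N: float,
    regime_map: Optional[continuum.RegimeMap] = None,
    threshold: float = 0.52,
) -> DLGVerdict:
    """Classify whether DLG can shape a colony with relative spread Δ.

    The measured areal spread ratio Δ stands in for the diffusivity ratio D
    (the two compare cell and nutrient spread on the same footing); the pair
    (Δ, N) is looked up at the nearest cell of a max-I_b regime map and the
    verdict is DLG-plausible iff that value exceeds ``threshold``.  The
    threshold is a package convention (the source regimes are verbal), and is
    reported with every verdict.  Out-of-map queries raise rather than clamp.
    """
    if delta <= 0 or N <= 0:
        raise ValueError("delta and N must be positive")
    if regime_map is None:
        regime_map = default_regime_map()
    value, gd, gn = regime_map.lookup(delta, N)
    plausible = bool(value > threshold)
    rationale = (
        f"max I_b = {value:.3f} at grid cell (log10 D = {gd:g}, log10 N = {gn:g}); "
        f"threshold {threshold:g}; Delta used as the diffusivity-ratio estimate"
    )
    return DLGVerdict(
        plausible=plausible,
        max_ib=value,
        threshold=threshold,
        grid_log10D=gd,
        grid_log10N=gn,
        rationale=rationale,
    )


_DEFAULT_MAP: Optional[continuum.RegimeMap] = None


def default_regime_map(resolution: float = 1.0) -> continuum.RegimeMap:
    """Shared coarse regime map over the standard parameter ranges.

    Covers 10^-6 <= D <= 10^3 and 1 <= N <= 10^5 at integer decades by
    default; computed on first use and cached for the process lifetime.
    """
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None or (
        len(_DEFAULT_MAP.log10D) > 1
        and abs(_DEFAULT_MAP.log10D[1] - _DEFAULT_MAP.log10D[0] - resolution) > 1e-9
    ):
        log10D = np.arange(-6.0, 3.0 + 1e-9, resolution)
        log10N = np.arange(0.0, 5.0 + 1e-9, resolution)
        _DEFAULT_MAP = continuum.regime_sweep(log10D, log10N)
    return _DEFAULT_MAP
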