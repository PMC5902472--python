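"""One-dimensional cell-nutrient reaction-diffusion model and its regime map.

Dimensional model on a domain of width L (mm):

    dm/dt = D_m m_xx + p m n,      dn/dt = D_n n_xx - c p m n,

with cell density m(x, t), nutrient concentration n(x, t), proliferation rate
p, nutrient-per-new-cell c.  Rescaling x by L, t by L^2/D_n, m by M0 and n by
p L^2 / D_n yields the dimensionless system

    dm/dt = D m_xx + m n,          dn/dt = n_xx - c_hat m n,

on x in [0, 1], governed by the diffusivity ratio D = D_m/D_n, the
dimensionless nutrient concentration N = p L^2 N0 / D_n (which scales the
nutrient initial condition) and c_hat = c p M0 L^2 / D_n.

Cells start concentrated at the domain centre and nutrient off-centre to the
right; the bias index I_b(t) (fraction of cell mass in the right half)
measures directed growth toward the nutrient.  The (D, N) map of the maximum
of I_b up to t = 1 delimits where diffusion-limited growth can occur.

Boundaries are zero-flux (solid walls), which makes the quantity
``c_hat * int(m) + int(n)`` exactly conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

#: default sharpness of the Gaussian initial conditions: the squared domain
#: width L^2 (L = 83 mm), which is what rescaling x by L in the dimensional
#: initial conditions exp(-(x - 0.5 L)^2) produces
DEFAULT_IC_SHARPNESS = 83.0**2


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional parameters of the reaction-diffusion model.

    Defaults are the standard estimates for a yeast biofilm in a petri dish:
    proliferation rate p (mm^2 g^-1 min^-1), nutrient per new cell c
    (g cell^-1), nutrient diffusivity D_n (mm^2/min), domain length L (mm)
    and maximum initial cell density M0 (cell mm^-2).  The cell diffusivity
    D_m (mm^2/min) and initial nutrient concentration N0 (g mm^-2) vary by
    experiment and are optional.
    """

    p: float = 15.28
    c: float = 3.473e-11
    D_n: float = 4.01e-2
    L: float = 83.0
    M0: float = 144.509
    D_m: Optional[float] = None
    N0: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("p", "c", "D_n", "L", "M0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("D_m", "N0"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless parameters (D, N, c_hat) of the rescaled system."""

    D: float
    N: float
    c_hat: float
    ic_sharpness: float = DEFAULT_IC_SHARPNESS
    #: physical duration of one dimensionless time unit, in minutes (optional)
    time_scale_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.D <= 0 or self.N < 0 or self.c_hat <= 0 or self.ic_sharpness <= 0:
            raise ValueError("D, c_hat, ic_sharpness must be positive; N >= 0")


def nondimensionalize(phys: PhysicalParams) -> DimensionlessParams:
    """Map physical parameters to (D, N, c_hat) and the time scale L^2/D_n.

    Requires ``D_m`` and ``N0`` to be present since they define D and N.
    """
    if phys.D_m is None:
        raise ValueError("D_m is required to form the diffusivity ratio D")
    if phys.N0 is None:
        raise ValueError("N0 is required to form the dimensionless N")
    D = phys.D_m / phys.D_n
    N = phys.p * phys.L**2 * phys.N0 / phys.D_n
    c_hat = phys.c * phys.p * phys.M0 * phys.L**2 / phys.D_n
    return DimensionlessParams(
        D=D,
        N=N,
        c_hat=c_hat,
        ic_sharpness=phys.L,
        time_scale_min=phys.L**2 / phys.D_n,
    )


def initial_fields(
    params: DimensionlessParams, x: np.ndarray, nutrient_centre: float = 0.75
):
    """Gaussian initial conditions: cells centred, nutrient biased right.

    ``m0(x) = exp(-a (x - 0.5)^2)`` and
    ``n0(x) = N exp(-a (x - nutrient_centre)^2)`` with sharpness
    ``a = params.ic_sharpness``.  Setting ``nutrient_centre = 0.5`` gives the
    symmetric control in which no bias can develop.
    """
    a = params.ic_sharpness
    m0 = np.exp(-a * (x - 0.5) ** 2)
    n0 = params.N * np.exp(-a * (x - nutrient_centre) ** 2)
    return m0, n0


@dataclass
class PDESolution:
    """Method-of-lines solution of the dimensionless system."""

    x: np.ndarray
    t: np.ndarray
    m: np.ndarray  # shape (len(t), len(x))
    n: np.ndarray
    params: DimensionlessParams
    meta: dict = field(default_factory=dict)

    def conserved_quantity(self) -> np.ndarray:
        """``c_hat * int(m) + int(n)`` at every stored time (trapezoid)."""
        return self.params.c_hat * np.trapezoid(self.m, self.x, axis=1) + np.trapezoid(
            self.n, self.x, axis=1
        )

    def conservation_error(self) -> float:
        q = self.conserved_quantity()
        return float(np.abs(q - q[0]).max() / np.abs(q[0]))


def _laplacian_flux(u: np.ndarray, dx: float) -> np.ndarray:
    """Second difference with mirror (zero-flux) boundaries, in flux form."""
    out = np.empty_like(u)
    out[1:-1] = (u[:-2] - 2.0 * u[1:-1] + u[2:]) / dx**2
    out[0] = 2.0 * (u[1] - u[0]) / dx**2
    out[-1] = 2.0 * (u[-2] - u[-1]) / dx**2
    return out


def solve(
    params: DimensionlessParams,
    t_end: float = 1.0,
    n_nodes: int = 501,
    n_times: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    nutrient_centre: float = 0.75,
) -> PDESolution:
    """Solve the dimensionless system on [0, 1] with zero-flux walls.

    Uses second-order central differences on a uniform grid (odd node count,
    so x = 0.5 is a grid node) and a stiff time integrator with a banded
    Jacobian.  Output is stored at ``n_times`` uniform times including 0 and
    ``t_end``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_nodes < 3:
        raise ValueError("need at least 3 grid nodes")
    x = np.linspace(0.0, 1.0, n_nodes)
    dx = x[1] - x[0]
    m0, n0 = initial_fields(params, x, nutrient_centre=nutrient_centre)
    y0 = np.empty(2 * n_nodes)
    y0[0::2] = m0  # interleaved (m_i, n_i) keeps the Jacobian pentadiagonal
    y0[1::2] = n0
    D, c_hat = params.D, params.c_hat

    def rhs(t, y):
        m = y[0::2]
        n = y[1::2]
        mn = m * n
        dy = np.empty_like(y)
        dy[0::2] = D * _laplacian_flux(m, dx) + mn
        dy[1::2] = _laplacian_flux(n, dx) - c_hat * mn
        return dy

    t_eval = np.linspace(0.0, t_end, n_times)
    kwargs = dict(rtol=rtol, atol=atol, t_eval=t_eval, method=method)
    if method == "LSODA":
        kwargs.update(lband=2, uband=2)
    sol = solve_ivp(rhs, (0.0, t_end), y0, **kwargs)
    if not sol.success:
        raise RuntimeError(
            f"PDE solve failed for (D={params.D:g}, N={params.N:g}): {sol.message}"
        )
    m = sol.y[0::2, :].T.copy()
    n = sol.y[1::2, :].T.copy()
    # tolerate tiny negative excursions from the integrator, flag real ones
    floor = -1e-6 * max(1.0, params.N)
    if m.min() < floor or n.min() < floor:
        raise RuntimeError(
            f"negative fields beyond tolerance for (D={params.D:g}, N={params.N:g})"
        )
    m[m < 0] = 0.0
    n[n < 0] = 0.0
    sol_obj = PDESolution(
        x=x,
        t=sol.t,
        m=m,
        n=n,
        params=params,
        meta={
            "method": method,
            "rtol": rtol,
            "atol": atol,
            "n_nodes": n_nodes,
            "nfev": sol.nfev,
        },
    )
    return sol_obj


def bias_trajectory(sol: PDESolution):
    """I_b(t) = right-half cell mass fraction, its maximum and argmax time.

    Computed by trapezoid quadrature; the x = 0.5 node carries half weight on
    each side so a symmetric profile scores exactly 0.5.  Returns
    ``(t, I_b(t), max_I_b, t_at_max)``.
    """
    if len(sol.t) < 2:
        raise ValueError("solution must store at least two times")
    x = sol.x
    mid = len(x) // 2
    if abs(x[mid] - 0.5) > 1e-12:
        raise ValueError("grid must contain x = 0.5 as a node")
    total = np.trapezoid(sol.m, x, axis=1)
    if (total <= 0).any():
        raise ValueError("cell mass vanished; bias undefined")
    right = np.trapezoid(sol.m[:, mid:], x[mid:], axis=1)
    ib = right / total
    k = int(np.argmax(ib))
    return sol.t, ib, float(ib[k]), float(sol.t[k])


def max_bias(
    D: float,
    N: float,
    c_hat: float = 1.32e-2,
    t_end: float = 1.0,
    **solve_kwargs,
) -> float:
    """Maximum of I_b up to ``t_end`` for a single (D, N) pair."""
    params = DimensionlessParams(D=D, N=N, c_hat=c_hat)
    sol = solve(params, t_end=t_end, **solve_kwargs)
    return bias_trajectory(sol)[2]


@dataclass
class RegimeMap:
    """Max-I_b surface over a (log10 D, log10 N) grid."""

    log10D: np.ndarray
    log10N: np.ndarray
    max_ib: np.ndarray  # shape (len(log10N), len(log10D))
    t_end: float
    failures: list = field(default_factory=list)

    def lookup(self, D: float, N: float) -> tuple[float, float, float]:
        """Max I_b at the grid cell nearest (D, N) (log-space distance).

        Raises ``ValueError`` for queries outside the map's ranges rather
        than silently clamping.
        """
        ld, ln = np.log10(D), np.log10(N)
        if not (self.log10D.min() <= ld <= self.log10D.max()):
            raise ValueError(f"log10 D = {ld:.3g} lies outside the map")
        if not (self.log10N.min() <= ln <= self.log10N.max()):
            raise ValueError(f"log10 N = {ln:.3g} lies outside the map")
        i = int(np.argmin(np.abs(self.log10N - ln)))
        j = int(np.argmin(np.abs(self.log10D - ld)))
        return float(self.max_ib[i, j]), float(self.log10D[j]), float(self.log10N[i])

    def argmax(self) -> tuple[float, float, float]:
        """(log10 D, log10 N, value) of the global maximum."""
        i, j = np.unravel_index(np.nanargmax(self.max_ib), self.max_ib.shape)
        return float(self.log10D[j]), float(self.log10N[i]), float(self.max_ib[i, j])


def regime_sweep(
    log10D: Sequence[float],
    log10N: Sequence[float],
    c_hat: float = 1.32e-2,
    t_end: float = 1.0,
    progress: bool = False,
    **solve_kwargs,
) -> RegimeMap:
    """Compute max I_b over a (log10 D, log10 N) grid.

    Individual solver failures are recorded in ``failures`` (as NaN cells)
    rather than aborting the sweep.
    """
    log10D = np.asarray(log10D, dtype=float)
    log10N = np.asarray(log10N, dtype=float)
    out = np.full((len(log10N), len(log10D)), np.nan)
    failures = []
    for i, ln in enumerate(log10N):
        for j, ld in enumerate(log10D):
            try:
                out[i, j] = max_bias(
                    10.0**ld, 10.0**ln, c_hat=c_hat, t_end=t_end, **solve_kwargs
                )
            except RuntimeError as exc:  # pragma: no cover - rare solver failure
                failures.append(((ld, ln), str(exc)))
            if progress:
                print(f"logD={ld:+.2f} logN={ln:+.2f} -> {out[i, j]:.4f}")
    return RegimeMap(
        log10D=log10D, log10N=log10N, max_ib=out, t_end=t_end, failures=failures
    )
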