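"""Time integration of the two-stage model with a delay history buffer.

The scheme is a single unsplit explicit Euler step of the method-of-lines
system: conservative first-order upwind transport in size for both stages
(zero inflow at x = 0, free outflow at x = a_max), pointwise death and
stage transfer, and the distributed-delay birth source read from a rolling
history buffer of the reproductive density.

When ``tau > 0`` the time step is locked to the delay-node spacing
``dt = tau / (n_nodes - 1)``; the history roll is then the exact lag shift
and the whole update is precisely the explicit Euler discretization of the
finite-dimensional generator assembled by
:func:`stagepop.spectral.full_generator_matrix`.  Every mass flux entering
the update is recorded in a ledger, so the discrete balance
``d(mass) = births - deaths - outflow`` closes to round-off at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fixtures import InitialData
from .model_spec import TwoPhaseModel

__all__ = [
    "PopulationState",
    "SimulationResult",
    "CFLError",
    "step",
    "simulate",
    "mass_balance_residual",
    "growth_rate_estimate",
]


class CFLError(ValueError):
    """Time step violates the positivity/stability bound."""


@dataclass
class PopulationState:
    """State at one instant: history of p over [t - tau, t] plus profiles.

    ``p_hist`` has shape ``(n_nodes, n_cells)`` with uniformly spaced slice
    times ending at ``t``; the newest slice ``p_hist[-1]`` *is* the current
    reproductive profile ``p``.
    """

    t: float
    p_hist: np.ndarray
    n: np.ndarray

    @property
    def p(self) -> np.ndarray:
        return self.p_hist[-1]

    def to_vector(self) -> np.ndarray:
        """Flatten to the generator layout (history block, then p, then n)."""
        return np.concatenate([self.p_hist.ravel(), self.p, self.n])


@dataclass
class SimulationResult:
    """Snapshots plus the per-step mass ledger of a run."""

    model: TwoPhaseModel
    dt: float
    times: np.ndarray          # snapshot times
    p_snaps: np.ndarray        # (n_snaps, n_cells)
    n_snaps: np.ndarray        # (n_snaps, n_cells)
    hist_snaps: np.ndarray     # (n_snaps, n_nodes, n_cells)
    step_times: np.ndarray     # time after each step, length n_steps
    masses: np.ndarray         # total mass after step k; masses[0] = initial
    mass_p: np.ndarray         # length n_steps + 1, index 0 = initial
    mass_n: np.ndarray
    births: np.ndarray         # per-step ledger entries, length n_steps
    deaths: np.ndarray
    transfers: np.ndarray      # net mass moved reproductive -> nonreproductive
    outflow: np.ndarray
    extras: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.step_times)

    def state_at(self, index: int) -> PopulationState:
        return PopulationState(
            t=float(self.times[index]),
            p_hist=self.hist_snaps[index].copy(),
            n=self.n_snaps[index].copy(),
        )


class _Stepper:
    """Precomputed grid operators for a fixed (model, dt)."""

    def __init__(self, model: TwoPhaseModel, dt: float):
        if dt <= 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        size, delay = model.size, model.delay
        if delay.tau > 0:
            ds = delay.dsigma
            if abs(dt - ds) > 1e-9 * ds:
                raise ValueError(
                    f"dt must equal the history spacing tau/(n_nodes-1) = {ds:g} "
                    f"(got dt = {dt:g}); choose n_nodes to set the step"
                )
        dx = size.dx
        self.dt = dt
        self.dx = dx
        self.g1e = model.gamma_edges(1)
        self.g2e = model.gamma_edges(2)
        self.mu1 = model.rate_on_centers("mu1")
        self.mu2 = model.rate_on_centers("mu2")
        self.rho1 = model.rate_on_centers("rho1")
        self.rho2 = model.rate_on_centers("rho2")

        # positivity bound of the explicit update (implies the transport CFL)
        lim1 = self.g1e[1:] / dx + self.mu1 + self.rho1
        lim2 = self.g2e[1:] / dx + self.mu2 + self.rho2
        dt_max = 1.0 / max(lim1.max(), lim2.max())
        if dt > dt_max * (1 + 1e-12):
            raise CFLError(
                f"dt = {dt:g} violates the positivity bound; require "
                f"dt <= {dt_max:g} (refine n_nodes or coarsen the size grid)"
            )
        self.dt_max = dt_max

        # birth operator: (m*nc) -> nc, trapezoid sigma weights and dx folded in
        beta = model.beta_tensor()          # (m, nc, nc)
        w = delay.weights                   # (m,)
        bw = beta * w[:, None, None] * dx   # (m, nc, nc)
        m, nc, _ = bw.shape
        self.birth_flat = np.ascontiguousarray(
            np.moveaxis(bw, 1, 0).reshape(nc, m * nc)
        )  # rows: newborn cell i, cols: (k, j) flattened

    def birth_profile(self, p_hist: np.ndarray) -> np.ndarray:
        return self.birth_flat @ p_hist.ravel()


def _get_stepper(model: TwoPhaseModel, dt: float) -> _Stepper:
    cache = model.__dict__.get("_stepper_cache")
    if cache is None:
        cache = {}
        object.__setattr__(model, "_stepper_cache", cache)
    st = cache.get(dt)
    if st is None:
        st = _Stepper(model, dt)
        cache[dt] = st
    return st


def default_dt(model: TwoPhaseModel, cfl: float = 0.9) -> float:
    """The admissible time step: the delay spacing when tau > 0, else the
    positivity bound scaled by ``cfl``."""
    if model.delay.tau > 0:
        return model.delay.dsigma
    g1e = model.gamma_edges(1)
    g2e = model.gamma_edges(2)
    dx = model.size.dx
    lim1 = g1e[1:] / dx + model.rate_on_centers("mu1") + model.rate_on_centers("rho1")
    lim2 = g2e[1:] / dx + model.rate_on_centers("mu2") + model.rate_on_centers("rho2")
    return cfl / max(lim1.max(), lim2.max())


def step(
    state: PopulationState,
    model: TwoPhaseModel,
    dt: Optional[float] = None,
    require_nonnegative: bool = True,
) -> PopulationState:
    """Advance the state by one time step (convenience wrapper)."""
    if dt is None:
        dt = default_dt(model)
    st = _get_stepper(model, dt)
    if require_nonnegative and (np.any(state.p_hist < 0) or np.any(state.n < 0)):
        raise ValueError("negative input state with require_nonnegative=True")
    p_hist_new, n_new, _ = _euler_step(st, model, state.p_hist, state.n)
    return PopulationState(t=state.t + dt, p_hist=p_hist_new, n=n_new)


def _euler_step(st: _Stepper, model: TwoPhaseModel, p_hist: np.ndarray, n: np.ndarray):
    dt, dx = st.dt, st.dx
    nu = model.kernel.nu
    p = p_hist[-1]
    b = st.birth_profile(p_hist)

    div1 = st.g1e[1:] * p
    div1[1:] -= st.g1e[1:-1] * p[:-1]
    div1 /= dx
    div2 = st.g2e[1:] * n
    div2[1:] -= st.g2e[1:-1] * n[:-1]
    div2 /= dx

    p_new = p + dt * (-div1 - (st.mu1 + st.rho1) * p + st.rho2 * n + nu * b)
    n_new = n + dt * (-div2 - (st.mu2 + st.rho2) * n + st.rho1 * p + (1.0 - nu) * b)

    ledger = dict(
        births=dt * b.sum() * dx,
        deaths=dt * ((st.mu1 * p).sum() + (st.mu2 * n).sum()) * dx,
        transfers=dt * ((st.rho1 * p).sum() - (st.rho2 * n).sum()) * dx,
        outflow=dt * (st.g1e[-1] * p[-1] + st.g2e[-1] * n[-1]),
    )

    if p_hist.shape[0] == 1:
        hist_new = p_new[None, :].copy()
    else:
        hist_new = np.empty_like(p_hist)
        hist_new[:-1] = p_hist[1:]
        hist_new[-1] = p_new
    return hist_new, n_new, ledger


def simulate(
    model: TwoPhaseModel,
    init: InitialData,
    t_end: float,
    dt: Optional[float] = None,
    n_snapshots: int = 21,
    output_times: Optional[Sequence[float]] = None,
    require_nonnegative: bool = True,
    store_history: bool = True,
) -> SimulationResult:
    """Run the model from ``init`` to ``t_end`` and record ledger + snapshots.

    Snapshots are taken at the step times nearest the requested schedule
    (``output_times`` or ``n_snapshots`` equispaced times including 0 and
    ``t_end``); each snapshot stores the full history buffer so adjoint
    pairings can be evaluated afterwards.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if dt is None:
        dt = default_dt(model)
    st = _get_stepper(model, dt)

    m, nc = model.delay.n_nodes, model.size.n_cells
    if init.p_history.shape != (m, nc) or init.n0.shape != (nc,):
        raise ValueError(
            f"initial data shape {init.p_history.shape}/{init.n0.shape} does not "
            f"match grids ({m}, {nc})"
        )
    if require_nonnegative and not init.is_nonnegative():
        raise ValueError("negative initial data with require_nonnegative=True")

    n_steps = int(round(t_end / dt)) if t_end > 0 else 0
    if t_end > 0 and n_steps == 0:
        n_steps = 1

    if output_times is None:
        output_times = np.linspace(0.0, n_steps * dt, n_snapshots)
    snap_idx = sorted(
        {min(n_steps, max(0, int(round(tt / dt)))) for tt in np.atleast_1d(output_times)}
    )
    snap_set = set(snap_idx)

    p_hist = init.p_history.astype(float).copy()
    n = init.n0.astype(float).copy()
    dx = model.size.dx

    times, p_snaps, n_snaps, hist_snaps = [], [], [], []
    step_times = np.empty(n_steps)
    mass_p = np.empty(n_steps + 1)
    mass_n = np.empty(n_steps + 1)
    births = np.empty(n_steps)
    deaths = np.empty(n_steps)
    transfers = np.empty(n_steps)
    outflow = np.empty(n_steps)
    mass_p[0] = p_hist[-1].sum() * dx
    mass_n[0] = n.sum() * dx

    def take_snap(t):
        times.append(t)
        p_snaps.append(p_hist[-1].copy())
        n_snaps.append(n.copy())
        if store_history:
            hist_snaps.append(p_hist.copy())

    if 0 in snap_set:
        take_snap(0.0)
    for k in range(1, n_steps + 1):
        p_hist, n, ledger = _euler_step(st, model, p_hist, n)
        t = k * dt
        step_times[k - 1] = t
        mass_p[k] = p_hist[-1].sum() * dx
        mass_n[k] = n.sum() * dx
        births[k - 1] = ledger["births"]
        deaths[k - 1] = ledger["deaths"]
        transfers[k - 1] = ledger["transfers"]
        outflow[k - 1] = ledger["outflow"]
        if k in snap_set:
            take_snap(t)

    return SimulationResult(
        model=model,
        dt=dt,
        times=np.asarray(times),
        p_snaps=np.asarray(p_snaps),
        n_snaps=np.asarray(n_snaps),
        hist_snaps=(
            np.asarray(hist_snaps) if store_history else np.empty((0, m, nc))
        ),
        step_times=step_times,
        masses=mass_p + mass_n,
        mass_p=mass_p,
        mass_n=mass_n,
        births=births,
        deaths=deaths,
        transfers=transfers,
        outflow=outflow,
    )


def mass_balance_residual(result: SimulationResult) -> np.ndarray:
    """Per-step relative conservation residual.

    residual_k = [ d(total mass) - (births - deaths - outflow) ]_k / mass_k,
    built from the same fluxes the update used, so it sits at round-off for
    every run.  Steps with zero mass report the absolute residual.
    """
    if result.n_steps == 0:
        return np.zeros(0)
    total = result.masses
    d_mass = np.diff(total)
    expected = result.births - result.deaths - result.outflow
    scale = np.where(total[1:] > 0, total[1:], 1.0)
    return (d_mass - expected) / scale


def growth_rate_estimate(result: SimulationResult, window: float = 0.5) -> float:
    """Least-squares slope of log total mass over the trailing time window.

    ``window`` is the trailing fraction of the recorded step series used in
    the fit (0 < window <= 1).
    """
    if not (0 < window <= 1):
        raise ValueError("window must lie in (0, 1]")
    if result.n_steps < 2:
        raise ValueError("need at least 2 steps to estimate a growth rate")
    k0 = int(np.floor(result.n_steps * (1 - window)))
    k0 = min(k0, result.n_steps - 2)
    t = result.step_times[k0:]
    msk = result.masses[1 + k0:]
    if np.any(msk <= 0):
        raise ValueError("total mass not strictly positive on the fit window")
    slope = np.polynomial.polynomial.polyfit(t, np.log(msk), 1)[1]
    return float(slope)
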