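"""Asynchronous-exponential-growth diagnostics.

The dominant eigenpair defines a rank-one spectral projection: the
population forgets everything about its initial composition except one
scalar, the adjoint pairing ``c = <init, left eigenvector>``.  This module
computes that projection, tracks the L1 distance between the rescaled
solution and its projected limit, and monitors the adjoint-paired
functional, which the exact dynamics conserve after removal of the
``e^{lam0 t}`` factor -- so its numerical drift measures pure
discretization error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .fixtures import InitialData
from .simulator import SimulationResult
from .spectral import AdjointSolution, EigenSolution

__all__ = ["AEGDiagnostics", "rank_one_projection", "aeg_diagnostics"]


class NormalizationError(RuntimeError):
    pass


def _check_biorthonormal(
    eigen: EigenSolution, adjoint: AdjointSolution, tol: float = 1e-8
) -> None:
    pair = adjoint.pairing(eigen.to_vector())
    if abs(pair - 1.0) > tol:
        raise NormalizationError(
            f"<right, left> = {pair:.12g}, expected 1 within {tol:g}; "
            "eigen and adjoint were not computed on matching grids/normalization"
        )


def rank_one_projection(
    init: InitialData, eigen: EigenSolution, adjoint: AdjointSolution
) -> Tuple[float, InitialData]:
    """Project initial data onto the dominant eigendirection.

    Returns ``(c, projected)`` with ``c`` the adjoint pairing of the data
    (history block included) and ``projected = c * right eigenvector``
    (with its exponential history extension).  Idempotent: projecting the
    projected state returns the same ``c``.
    """
    _check_biorthonormal(eigen, adjoint)
    c = adjoint.pairing(init)
    projected = InitialData(
        p_history=c * eigen.history(), n0=c * eigen.n_star
    )
    return c, projected


@dataclass
class AEGDiagnostics:
    """Per-snapshot forgetting error and conserved-functional series.

    ``aeg_error(t)`` is the L1 distance, on the (p, n) profiles only,
    between ``e^{-lam0 t} (p, n)(t)`` and the projected initial state,
    relative to the mass of the projected state.  ``functional(t)`` is the
    adjoint pairing of the full state (history included) times
    ``e^{-lam0 t}``; its drift is the discretization error of the run.
    """

    times: np.ndarray
    aeg_error: np.ndarray
    functional: np.ndarray
    c: float
    decay_rate: float
    extras: dict = field(default_factory=dict)

    @property
    def relative_drift(self) -> float:
        f0 = self.functional[0]
        if f0 == 0:
            raise ZeroDivisionError("functional vanishes at t = 0")
        return float(np.max(np.abs(self.functional - f0)) / abs(f0))


def aeg_diagnostics(
    result: SimulationResult,
    eigen: EigenSolution,
    adjoint: AdjointSolution,
) -> AEGDiagnostics:
    """Evaluate the forgetting error and the adjoint functional on a run."""
    _check_biorthonormal(eigen, adjoint)
    if result.hist_snaps.shape[0] != result.times.shape[0]:
        raise ValueError(
            "snapshots lack history buffers; rerun simulate(store_history=True)"
        )
    lam0 = eigen.lam0
    dx = result.model.size.dx
    times = result.times
    n_snap = len(times)

    functional = np.empty(n_snap)
    for i in range(n_snap):
        functional[i] = adjoint.pairing(result.state_at(i)) * np.exp(-lam0 * times[i])
    c = functional[0]

    aeg_error = np.empty(n_snap)
    denom = abs(c)  # mass of c * (p* + n*) since the eigenpair is mass-normalized
    if denom == 0:
        raise ZeroDivisionError("projection coefficient vanishes")
    for i in range(n_snap):
        s = np.exp(-lam0 * times[i])
        err = (
            np.abs(s * result.p_snaps[i] - c * eigen.p_star).sum()
            + np.abs(s * result.n_snaps[i] - c * eigen.n_star).sum()
        ) * dx
        aeg_error[i] = err / denom

    # empirical decay exponent over the trailing half (reported, not asserted)
    half = n_snap // 2
    tail_t, tail_e = times[half:], aeg_error[half:]
    pos = tail_e > 0
    if pos.sum() >= 2:
        decay = float(
            np.polynomial.polynomial.polyfit(tail_t[pos], np.log(tail_e[pos]), 1)[1]
        )
    else:
        decay = float("nan")

    return AEGDiagnostics(
        times=times,
        aeg_error=aeg_error,
        functional=functional,
        c=float(c),
        decay_rate=decay,
    )
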