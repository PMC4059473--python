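"""Model parameterization, structural hypothesis checks, discounted birth kernel.

A :class:`TwoPhaseModel` bundles the vital rates, the delayed birth kernel
and the discretization grids.  All downstream machinery (simulation,
spectral analysis, one-phase reduction) consumes this object.

The structural hypotheses checked by :func:`validate_hypotheses` are:

H1  mu1, mu2, rho1, rho2 nonnegative on [0, a_max]
H2  gamma1, gamma2 strictly positive on [0, a_max] (C^1 assumed structurally)
H3  beta nonnegative on [-tau, 0] x [0, a_max]^2
H4  if 0 <= nu < 1: rho2 > 0 everywhere; if nu == 1: rho1 > 0 and rho2 > 0
H5  beta(., x, y) > 0 whenever y > x

H1-H3 are required for well-posedness of nonnegative solutions; H4-H5 are
the irreducibility conditions under which the population exhibits
asynchronous exponential growth with a simple dominant eigenvalue.  The
checks sample the model on its own grids and are therefore necessary
conditions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

__all__ = [
    "SizeGrid",
    "DelayGrid",
    "VitalRates",
    "BirthKernel",
    "TwoPhaseModel",
    "HypothesisReport",
    "validate_hypotheses",
    "discounted_birth_kernel",
    "sigma_discount_factors",
]

RateFunc = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SizeGrid:
    """Uniform cell-centered finite-volume grid on [0, a_max]."""

    a_max: float
    n_cells: int

    def __post_init__(self) -> None:
        if not (self.a_max > 0):
            raise ValueError(f"a_max must be > 0, got {self.a_max}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")

    @property
    def dx(self) -> float:
        return self.a_max / self.n_cells

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.a_max, self.n_cells + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx


@dataclass(frozen=True)
class DelayGrid:
    """Uniform quadrature nodes on the lag interval [-tau, 0].

    ``tau == 0`` degenerates to a single node at 0 carrying unit weight, so
    the delay integral becomes a point evaluation (the undelayed model).
    """

    tau: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.tau == 0 and self.n_nodes != 1:
            raise ValueError("tau == 0 requires n_nodes == 1")
        if self.tau > 0 and self.n_nodes < 2:
            raise ValueError("tau > 0 requires n_nodes >= 2")

    @property
    def nodes(self) -> np.ndarray:
        """Nodes from -tau to 0 inclusive, increasing."""
        if self.tau == 0:
            return np.zeros(1)
        return np.linspace(-self.tau, 0.0, self.n_nodes)

    @property
    def dsigma(self) -> float:
        """Node spacing (0 for the degenerate undelayed grid)."""
        if self.tau == 0:
            return 0.0
        return self.tau / (self.n_nodes - 1)

    @property
    def weights(self) -> np.ndarray:
        """Composite-trapezoid quadrature weights on [-tau, 0]."""
        if self.tau == 0:
            return np.ones(1)
        w = np.full(self.n_nodes, self.dsigma)
        w[0] *= 0.5
        w[-1] *= 0.5
        return w


@dataclass(frozen=True)
class VitalRates:
    """Stage-specific death (mu), transfer (rho) and growth (gamma) rates.

    Each field is a vectorized callable of size ``x`` on [0, a_max].
    ``mu1, rho1, gamma1`` act on the reproductive stage, ``mu2, rho2,
    gamma2`` on the nonreproductive stage; ``rho1`` moves individuals out of
    the reproductive stage, ``rho2`` moves them back in.
    """

    mu1: RateFunc
    mu2: RateFunc
    rho1: RateFunc
    rho2: RateFunc
    gamma1: RateFunc
    gamma2: RateFunc


@dataclass(frozen=True)
class BirthKernel:
    """Distributed-delay birth kernel and newborn stage split.

    ``beta(sigma, x, y)`` is the rate density at which reproductive
    individuals of size ``y`` produce, a lag ``-sigma`` after conception
    (sigma in [-tau, 0]), newborns of size ``x``.  ``nu`` is the constant
    fraction of newborns entering the reproductive stage.
    """

    beta: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    nu: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.nu <= 1.0):
            raise ValueError(f"nu must lie in [0, 1], got {self.nu}")


class ModelEvaluationError(ValueError):
    """A rate or kernel evaluated to a non-finite value."""


@dataclass(frozen=True)
class TwoPhaseModel:
    """Complete parameterization of the two-stage delayed-birth model."""

    rates: VitalRates
    kernel: BirthKernel
    size: SizeGrid
    delay: DelayGrid

    # -- grid evaluations (cached lazily; the model is immutable) ----------

    def rate_on_centers(self, name: str) -> np.ndarray:
        vals = self._rate_cache().get(name)
        if vals is None:
            raise KeyError(name)
        return vals

    def _rate_cache(self) -> dict:
        cache = self.__dict__.get("_rates_on_grid")
        if cache is None:
            x = self.size.centers
            cache = {}
            for name in ("mu1", "mu2", "rho1", "rho2", "gamma1", "gamma2"):
                v = np.asarray(getattr(self.rates, name)(x), dtype=float)
                v = np.broadcast_to(v, x.shape).copy()
                _check_finite(v, name, x)
                cache[name] = v
            object.__setattr__(self, "_rates_on_grid", cache)
        return cache

    def gamma_edges(self, which: Literal[1, 2]) -> np.ndarray:
        """Growth speed evaluated on the cell edges (used for fluxes)."""
        key = f"_gamma{which}_edges"
        v = self.__dict__.get(key)
        if v is None:
            fn = self.rates.gamma1 if which == 1 else self.rates.gamma2
            e = self.size.edges
            v = np.broadcast_to(np.asarray(fn(e), dtype=float), e.shape).copy()
            _check_finite(v, f"gamma{which}", e)
            object.__setattr__(self, key, v)
        return v

    def beta_tensor(self) -> np.ndarray:
        """Kernel sampled on the grids, shape (n_nodes, n_cells, n_cells).

        Entry ``[k, i, j]`` is ``beta(sigma_k, x_i, y_j)`` with ``x`` the
        newborn size (row) and ``y`` the parent size (column).
        """
        t = self.__dict__.get("_beta_tensor")
        if t is None:
            s = self.delay.nodes[:, None, None]
            x = self.size.centers[None, :, None]
            y = self.size.centers[None, None, :]
            t = np.asarray(self.kernel.beta(s, x, y), dtype=float)
            t = np.broadcast_to(
                t, (self.delay.n_nodes, self.size.n_cells, self.size.n_cells)
            ).copy()
            if not np.all(np.isfinite(t)):
                k, i, j = np.unravel_index(int(np.argmin(np.isfinite(t))), t.shape)
                raise ModelEvaluationError(
                    "beta evaluated non-finite at "
                    f"(sigma={self.delay.nodes[k]:g}, x={self.size.centers[i]:g}, "
                    f"y={self.size.centers[j]:g})"
                )
            object.__setattr__(self, "_beta_tensor", t)
        return t


def _check_finite(values: np.ndarray, name: str, points: np.ndarray) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        idx = int(np.argmax(bad))
        raise ModelEvaluationError(
            f"{name} evaluated non-finite at x={points[idx]:g}"
        )


@dataclass
class HypothesisReport:
    """Per-hypothesis pass/fail flags with grid points witnessing failures."""

    h1_nonneg_rates: bool
    h2_positive_growth: bool
    h3_nonneg_kernel: bool
    h4_transfer_positivity: bool
    h5_kernel_support: bool
    witnesses: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return (
            self.h1_nonneg_rates
            and self.h2_positive_growth
            and self.h3_nonneg_kernel
            and self.h4_transfer_positivity
            and self.h5_kernel_support
        )

    def failures(self) -> list[str]:
        names = {
            "h1_nonneg_rates": "H1",
            "h2_positive_growth": "H2",
            "h3_nonneg_kernel": "H3",
            "h4_transfer_positivity": "H4",
            "h5_kernel_support": "H5",
        }
        return [tag for f, tag in names.items() if not getattr(self, f)]


def validate_hypotheses(model: TwoPhaseModel) -> HypothesisReport:
    """Check the structural hypotheses H1-H5 on the model's own grids.

    Sampled (necessary-condition) checks: continuity/smoothness is asserted
    structurally by requiring evaluable callables, positivity is checked at
    cell centers (and edges for the growth rates) with zero tolerance.
    """
    x = model.size.centers
    witnesses: dict = {}

    h1 = True
    for name in ("mu1", "mu2", "rho1", "rho2"):
        v = model.rate_on_centers(name)
        if np.any(v < 0):
            h1 = False
            i = int(np.argmax(v < 0))
            witnesses[f"H1:{name}"] = (float(x[i]), float(v[i]))

    h2 = True
    for which, name in ((1, "gamma1"), (2, "gamma2")):
        for pts, v in ((x, model.rate_on_centers(name)), (model.size.edges, model.gamma_edges(which))):
            if np.any(v <= 0):
                h2 = False
                i = int(np.argmax(v <= 0))
                witnesses[f"H2:{name}"] = (float(pts[i]), float(v[i]))
                break

    beta = model.beta_tensor()
    h3 = bool(np.all(beta >= 0))
    if not h3:
        k, i, j = np.unravel_index(int(np.argmax(beta < 0)), beta.shape)
        witnesses["H3:beta"] = (
            float(model.delay.nodes[k]),
            float(x[i]),
            float(x[j]),
            float(beta[k, i, j]),
        )

    nu = model.kernel.nu
    h4 = True
    if nu == 1.0:
        needed = ("rho1", "rho2")
    else:  # 0 <= nu < 1
        needed = ("rho2",)
    for name in needed:
        v = model.rate_on_centers(name)
        if np.any(v <= 0):
            h4 = False
            i = int(np.argmax(v <= 0))
            witnesses[f"H4:{name}"] = (float(x[i]), float(v[i]))

    # H5: beta(., x, y) > 0 for parent size y strictly above newborn size x,
    # checked at every delay node on strictly-upper-triangular center pairs.
    iu = np.triu_indices(model.size.n_cells, k=1)
    upper = beta[:, iu[0], iu[1]]
    h5 = bool(np.all(upper > 0))
    if not h5:
        k, m = np.unravel_index(int(np.argmax(upper <= 0)), upper.shape)
        witnesses["H5:beta"] = (
            float(model.delay.nodes[k]),
            float(x[iu[0][m]]),
            float(x[iu[1][m]]),
        )

    return HypothesisReport(h1, h2, h3, h4, h5, witnesses)


def sigma_discount_factors(
    delay: DelayGrid, lam: float, discount: Literal["exp", "shift"] = "exp"
) -> np.ndarray:
    """Per-node discount of the lag integral for an exponential solution.

    Inserting ``p(t + sigma) = e^{lam * sigma} p(t)`` into the delayed birth
    term weights node ``sigma_k`` by ``e^{lam * sigma_k}``.

    ``discount="exp"``    the exact exponential weight.
    ``discount="shift"``  the weight induced by the first-order upwind
        discretization of the history shift used by
        :func:`stagepop.spectral.full_generator_matrix`, namely
        ``(1 + lam * dsigma) ** -(n_nodes - 1 - k)``.  Using it makes the
        characteristic equation algebraically identical to the generator
        matrix eigenproblem on the same grids.
    """
    if not np.isfinite(lam):
        raise ValueError("lam must be finite")
    if delay.tau == 0:
        return np.ones(1)
    if discount == "exp":
        return np.exp(lam * delay.nodes)
    if discount == "shift":
        base = 1.0 + lam * delay.dsigma
        if base <= 0:
            raise ValueError(
                f"shift discount undefined for lam <= -1/dsigma = {-1.0 / delay.dsigma:g}"
            )
        k = np.arange(delay.n_nodes)
        return base ** -(delay.n_nodes - 1.0 - k)
    raise ValueError(f"unknown discount {discount!r}")


def discounted_birth_kernel(
    model: TwoPhaseModel,
    lam: float,
    discount: Literal["exp", "shift"] = "exp",
) -> np.ndarray:
    """Lag-integrated, growth-discounted birth kernel as a size matrix.

    Returns the ``(n_cells, n_cells)`` nonnegative matrix ``B`` with

        B[i, j] ~= dx * Integral_{-tau}^{0} w(lam, sigma) beta(sigma, x_i, y_j) dsigma

    (composite trapezoid in sigma; ``w`` per :func:`sigma_discount_factors`)
    so that ``B @ P`` approximates the newborn size density produced by a
    reproductive profile growing like ``e^{lam t} P``.  Entries are
    entrywise nonincreasing in ``lam``.
    """
    d = sigma_discount_factors(model.delay, lam, discount)
    w = model.delay.weights * d
    beta = model.beta_tensor()
    return np.tensordot(w, beta, axes=(0, 0)) * model.size.dx
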