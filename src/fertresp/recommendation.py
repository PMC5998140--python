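"""Fertilization recommendation by the marginal product derivative method.

Maximum-yield rates set the partial derivatives of yield with respect to
each nutrient to zero; economic rates set them to the fertilizer/grain
price ratios (alpha, beta, gamma), the dose at which marginal yield value
equals marginal fertilizer cost.

For the non-structural surface the maximum has the closed form

.. math:: N_{max} = 1/c_1 - N_0 \\quad (\\text{and analogously for P, K}),

while the economic rates satisfy

.. math:: N_{eco} = \\frac{1}{c_1 + \\alpha / Y_{eco}} - N_0,

a fixed point in the economic yield :math:`Y_{eco}`, solved by seeding
:math:`Y_{eco}` with the maximum yield and iterating; a handful of
iterations suffice in practice because Y_eco stays close to Y_max.

For the quadratic surface both problems are 3x3 linear systems in the
constant Hessian. Rates are reported un-clipped: negative or out-of-range
components are meaningful inputs to the typicality rules, not errors here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .response_models import (
    RatePoint,
    TNFMParams,
    TPFMParams,
    tnfm_predict,
    tpfm_hessian,
    tpfm_hessian_minors,
    tpfm_predict,
)

__all__ = [
    "PriceSpec",
    "Recommendation",
    "NoMaximumError",
    "tnfm_max_rates",
    "tnfm_econ_rates",
    "tpfm_max_rates",
    "tpfm_econ_rates",
    "recommend",
]

#: Componentwise rate-change tolerance (kg/hm^2) stopping the economic
#: fixed-point iteration; well below agronomic relevance.
ECON_TOL = 0.1

#: Default iteration cap for the economic fixed point.
ECON_MAX_ITER = 5


class NoMaximumError(ValueError):
    """The surface has no (finite, unique) maximum yield point."""


@dataclass(frozen=True)
class PriceSpec:
    """Market prices per kg: N, P2O5, K2O nutrient and grain.

    The derived ratios alpha = p_n/p_y, beta = p_p/p_y, gamma = p_k/p_y
    (kg grain per kg nutrient) are what the economic optimum depends on.
    Grain price must be positive; nutrient prices non-negative (zero
    ratios degenerate the economic optimum to the maximum-yield rates).
    """

    p_n: float
    p_p: float
    p_k: float
    p_y: float = 1.0

    def __post_init__(self) -> None:
        if self.p_y <= 0:
            raise ValueError("grain price p_y must be > 0")
        if min(self.p_n, self.p_p, self.p_k) < 0:
            raise ValueError("nutrient prices must be >= 0")

    @property
    def alpha(self) -> float:
        return self.p_n / self.p_y

    @property
    def beta(self) -> float:
        return self.p_p / self.p_y

    @property
    def gamma(self) -> float:
        return self.p_k / self.p_y

    @classmethod
    def from_ratios(cls, alpha: float, beta: float, gamma: float) -> "PriceSpec":
        """Build a spec directly from price ratios (grain price 1)."""
        return cls(p_n=alpha, p_p=beta, p_k=gamma, p_y=1.0)

    def ratios(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


@dataclass(frozen=True)
class Recommendation:
    """Maximum and (optional) economic fertilization rates with yields."""

    max_rates: RatePoint
    max_yield: float
    eco_rates: RatePoint | None = None
    eco_yield: float | None = None
    iterations_used: int = 0
    eco_converged: bool = True

    def rounded(self) -> dict[str, float | None]:
        """Display form: rates and yields to the nearest kg/hm^2."""
        out: dict[str, float | None] = {
            "n_max": round(self.max_rates.n),
            "p_max": round(self.max_rates.p),
            "k_max": round(self.max_rates.k),
            "yield_max": round(self.max_yield),
        }
        if self.eco_rates is not None:
            out.update(
                n_eco=round(self.eco_rates.n),
                p_eco=round(self.eco_rates.p),
                k_eco=round(self.eco_rates.k),
                yield_eco=round(self.eco_yield),  # type: ignore[arg-type]
            )
        return out


class EconResult(NamedTuple):
    rates: RatePoint
    eco_yield: float
    iterations_used: int
    converged: bool


# ---------------------------------------------------------------------------
# Non-structural surface
# ---------------------------------------------------------------------------


def tnfm_max_rates(params: TNFMParams) -> tuple[RatePoint, float]:
    """Closed-form maximum-yield rates (1/c - soil supply) and the yield there.

    Requires all three decay coefficients positive (otherwise the surface
    is unbounded along that nutrient); negative rate components are
    returned as-is for the typicality rules to judge.
    """
    if min(params.c1, params.c2, params.c3) <= 0:
        raise NoMaximumError(
            "no finite maximum: c1, c2, c3 must all be > 0, got "
            f"({params.c1:g}, {params.c2:g}, {params.c3:g})"
        )
    point = RatePoint(
        1 / params.c1 - params.n0,
        1 / params.c2 - params.p0,
        1 / params.c3 - params.k0,
    )
    return point, float(tnfm_predict(params, point))


def tnfm_econ_rates(
    params: TNFMParams,
    prices: PriceSpec,
    max_iter: int = ECON_MAX_ITER,
    tol: float = ECON_TOL,
) -> EconResult:
    """Economic rates of the non-structural surface by fixed-point iteration.

    Y_eco is seeded with the maximum yield, rates are computed from the
    closed-form economic formula, Y_eco is re-evaluated at those rates,
    and the cycle repeats until the componentwise rate change drops below
    ``tol`` kg/hm^2 or ``max_iter`` is reached (in which case the best
    iterate is returned flagged non-converged).
    """
    _, y_eco = tnfm_max_rates(params)
    ratios = prices.ratios()
    cs = np.array([params.c1, params.c2, params.c3])
    supply = np.array([params.n0, params.p0, params.k0])
    rates = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new = 1.0 / (cs + ratios / y_eco) - supply
        if rates is not None and np.all(np.abs(new - rates) < tol):
            rates = new
            converged = True
            break
        rates = new
        y_eco = float(tnfm_predict(params, rates))
    point = RatePoint(*rates)  # type: ignore[misc]
    return EconResult(point, float(tnfm_predict(params, point)), iterations, converged)


# ---------------------------------------------------------------------------
# Quadratic surface
# ---------------------------------------------------------------------------


def _tpfm_solve(params: TPFMParams, target: np.ndarray) -> RatePoint:
    """Solve grad Y = target for the quadratic surface, checking the maximum."""
    g1, g2, g3 = tpfm_hessian_minors(params)
    checks = {"G1 < 0": g1 < 0, "G2 > 0": g2 > 0, "G3 < 0": g3 < 0}
    failed = [cond for cond, ok in checks.items() if not ok]
    if failed:
        raise NoMaximumError(
            "no global maximum: Hessian not negative-definite "
            f"(failed minor condition(s): {', '.join(failed)}; "
            f"G1={g1:.4g}, G2={g2:.4g}, G3={g3:.4g})"
        )
    h = tpfm_hessian(params)
    rhs = target - np.array([params.b1, params.b2, params.b3])
    return RatePoint(*np.linalg.solve(h, rhs))


def tpfm_max_rates(params: TPFMParams) -> tuple[RatePoint, float]:
    """Critical point of the quadratic surface and its yield.

    Raises :class:`NoMaximumError`, naming the failed principal-minor
    condition, when the Hessian is not negative-definite.
    """
    point = _tpfm_solve(params, np.zeros(3))
    return point, float(tpfm_predict(params, point))


def tpfm_econ_rates(params: TPFMParams, prices: PriceSpec) -> tuple[RatePoint, float]:
    """Economic rates of the quadratic surface (marginal product = price ratio)."""
    point = _tpfm_solve(params, prices.ratios())
    return point, float(tpfm_predict(params, point))


# ---------------------------------------------------------------------------
# Unified entry point
# ---------------------------------------------------------------------------


def recommend(
    params: TNFMParams | TPFMParams,
    prices: PriceSpec | None = None,
    max_iter: int = ECON_MAX_ITER,
    tol: float = ECON_TOL,
) -> Recommendation:
    """Maximum-yield and, when prices are given, economic recommendation."""
    if isinstance(params, TNFMParams):
        max_rates, max_yield = tnfm_max_rates(params)
        if prices is None:
            return Recommendation(max_rates, max_yield)
        eco = tnfm_econ_rates(params, prices, max_iter=max_iter, tol=tol)
        return Recommendation(
            max_rates,
            max_yield,
            eco_rates=eco.rates,
            eco_yield=eco.eco_yield,
            iterations_used=eco.iterations_used,
            eco_converged=eco.converged,
        )
    max_rates, max_yield = tpfm_max_rates(params)
    if prices is None:
        return Recommendation(max_rates, max_yield)
    eco_rates, eco_yield = tpfm_econ_rates(params, prices)
    return Recommendation(
        max_rates, max_yield, eco_rates=eco_rates, eco_yield=eco_yield
    )
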