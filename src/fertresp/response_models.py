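"""Yield response surfaces: the non-structural and quadratic models.

Two ternary (N, P, K) fertilizer response surfaces are implemented:

* the ternary **non-structural** model (TNFM)

  .. math:: Y = A\\,(N_0+N)(P_0+P)(K_0+K)\\,e^{-c_1 N - c_2 P - c_3 K}

  where :math:`N_0, P_0, K_0` (kg/hm^2) are soil nutrient supply
  equivalents, :math:`c_1, c_2, c_3` ((kg/hm^2)^-1) are yield-increase
  effect coefficients, and :math:`A` converts soil fertility to yield;

* the ternary **quadratic polynomial** model (TPFM), the full second-order
  polynomial in the three application rates,

  .. math:: Y = b_0 + b_1 N + b_2 P + b_3 K + b_4 N^2 + b_5 P^2 + b_6 K^2
                + b_7 NP + b_8 NK + b_9 PK.

Truncating the exponential of the non-structural surface to first order
and dropping the pairwise/triple products of the (small) :math:`c`
coefficients and the three-way interaction yields exactly a quadratic
surface; :func:`tnfm_to_quadratic` performs that reduction, which makes
the quadratic model a simplified special case of the non-structural one.

Parameter containers impose no sign constraints: fits with negative
estimates must be representable, and agronomic plausibility is judged by
the typicality rules, not at construction.
"""

from __future__ import annotations

from dataclasses import astuple, dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "TNFMParams",
    "TPFMParams",
    "RatePoint",
    "NumericError",
    "EXPONENT_LIMIT",
    "tnfm_predict",
    "tpfm_predict",
    "tpfm_gradient",
    "tpfm_hessian",
    "tpfm_hessian_minors",
    "tpfm_critical_point",
    "tnfm_to_quadratic",
]

#: |c1*N + c2*P + c3*K| beyond which tnfm_predict refuses to exponentiate.
EXPONENT_LIMIT = 700.0

#: Relative determinant below which the critical-point system is treated
#: as structurally singular rather than merely ill-conditioned.
SINGULARITY_RTOL = 1e-12


class NumericError(ArithmeticError):
    """Evaluation would overflow (exponent outside the guarded range)."""


class RatePoint(NamedTuple):
    """An (N, P2O5, K2O) application-rate point, kg/hm^2.

    Negative components are permitted internally (critical-point algebra);
    agronomic interpretation requires all components >= 0.
    """

    n: float
    p: float
    k: float


@dataclass(frozen=True)
class TNFMParams:
    """Parameters (A, N0, P0, K0, c1, c2, c3) of the non-structural model."""

    a: float
    n0: float
    p0: float
    k0: float
    c1: float
    c2: float
    c3: float

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), float)

    @classmethod
    def from_array(cls, x) -> "TNFMParams":
        return cls(*(float(v) for v in np.asarray(x, float)))

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d) -> "TNFMParams":
        return cls(**{k: float(d[k]) for k in ("a", "n0", "p0", "k0", "c1", "c2", "c3")})

    def all_positive(self) -> bool:
        return bool(np.all(self.as_array() > 0))


@dataclass(frozen=True)
class TPFMParams:
    """Coefficients b0..b9 of the quadratic polynomial model."""

    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    b5: float
    b6: float
    b7: float
    b8: float
    b9: float

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), float)

    @classmethod
    def from_array(cls, x) -> "TPFMParams":
        return cls(*(float(v) for v in np.asarray(x, float)))

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d) -> "TPFMParams":
        return cls(**{f"b{i}": float(d[f"b{i}"]) for i in range(10)})


def _split_rates(rates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.asarray(rates, float)
    if arr.shape[-1] != 3:
        raise ValueError(f"rates must have trailing dimension 3, got {arr.shape}")
    return arr[..., 0], arr[..., 1], arr[..., 2]


def tnfm_predict(params: TNFMParams, rates) -> np.ndarray | float:
    """Evaluate the non-structural surface at one or many rate points.

    ``rates`` is an (N, P, K) triple or an (m, 3) array. Raises
    :class:`NumericError` if the exponent magnitude exceeds
    :data:`EXPONENT_LIMIT` anywhere (guard against silent overflow).
    """
    n, p, k = _split_rates(rates)
    expo = -(params.c1 * n + params.c2 * p + params.c3 * k)
    if np.any(np.abs(expo) > EXPONENT_LIMIT):
        raise NumericError(
            f"exponent magnitude exceeds {EXPONENT_LIMIT}; rates/coefficients "
            "out of the representable range"
        )
    out = (
        params.a
        * (params.n0 + n)
        * (params.p0 + p)
        * (params.k0 + k)
        * np.exp(expo)
    )
    return out if out.ndim else float(out)


def tpfm_predict(params: TPFMParams, rates) -> np.ndarray | float:
    """Evaluate the quadratic surface at one or many rate points."""
    n, p, k = _split_rates(rates)
    b = params
    out = (
        b.b0 + b.b1 * n + b.b2 * p + b.b3 * k
        + b.b4 * n * n + b.b5 * p * p + b.b6 * k * k
        + b.b7 * n * p + b.b8 * n * k + b.b9 * p * k
    )
    return out if np.ndim(out) else float(out)


def tpfm_gradient(params: TPFMParams, rates) -> np.ndarray:
    """Marginal products (dY/dN, dY/dP, dY/dK) of the quadratic surface."""
    n, p, k = _split_rates(rates)
    b = params
    return np.stack(
        [
            b.b1 + 2 * b.b4 * n + b.b7 * p + b.b8 * k,
            b.b2 + 2 * b.b5 * p + b.b7 * n + b.b9 * k,
            b.b3 + 2 * b.b6 * k + b.b8 * n + b.b9 * p,
        ],
        axis=-1,
    )


def tpfm_hessian(params: TPFMParams) -> np.ndarray:
    """The (constant) 3x3 Hessian of the quadratic surface."""
    b = params
    return np.array(
        [
            [2 * b.b4, b.b7, b.b8],
            [b.b7, 2 * b.b5, b.b9],
            [b.b8, b.b9, 2 * b.b6],
        ]
    )


def tpfm_hessian_minors(params: TPFMParams) -> tuple[float, float, float]:
    """Leading principal minors (G1, G2, G3) of the Hessian.

    Sign pattern (G1 < 0, G2 > 0, G3 < 0) is equivalent to a
    negative-definite Hessian, i.e. the surface has a global maximum at
    its critical point.
    """
    b = params
    g1 = 2 * b.b4
    g2 = 4 * b.b4 * b.b5 - b.b7**2
    g3 = 2 * (
        4 * b.b4 * b.b5 * b.b6
        + b.b7 * b.b8 * b.b9
        - b.b4 * b.b9**2
        - b.b5 * b.b8**2
        - b.b6 * b.b7**2
    )
    return float(g1), float(g2), float(g3)


def tpfm_critical_point(params: TPFMParams) -> RatePoint | None:
    """Solve grad Y = 0 for the quadratic surface.

    Returns the unique stationary point, or ``None`` when the 3x3 system
    is singular (no unique critical point). Singularity is judged by the
    determinant relative to the Hessian's scale, so structural
    singularity is distinguished from round-off.
    """
    h = tpfm_hessian(params)
    scale = np.max(np.abs(h))
    if scale == 0 or abs(np.linalg.det(h)) < SINGULARITY_RTOL * scale**3:
        return None
    rhs = -np.array([params.b1, params.b2, params.b3])
    return RatePoint(*np.linalg.solve(h, rhs))


def tnfm_to_quadratic(params: TNFMParams) -> TPFMParams:
    """Reduce the non-structural surface to its quadratic approximation.

    First-order truncation of each exponential factor (e^x = 1 + x + ...)
    followed by dropping pairwise and triple products of c1, c2, c3 and
    the three-way N*P*K interaction. With B = 1 - N0*c1, C = 1 - P0*c2,
    D = 1 - K0*c3 the resulting quadratic coefficients are as coded below.
    The truncation is exact as printed; no higher-order correction is
    applied.
    """
    a, n0, p0, k0, c1, c2, c3 = astuple(params)
    bb = 1 - n0 * c1
    cc = 1 - p0 * c2
    dd = 1 - k0 * c3
    return TPFMParams(
        b0=a * n0 * p0 * k0,
        b1=a * bb * p0 * k0,
        b2=a * cc * n0 * k0,
        b3=a * dd * n0 * p0,
        b4=-a * c1 * p0 * k0,
        b5=-a * c2 * n0 * k0,
        b6=-a * c3 * n0 * p0,
        b7=a * bb * cc * k0,
        b8=a * bb * dd * p0,
        b9=a * cc * dd * n0,
    )
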