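"""Typicality screening of fitted fertilizer response models.

A fitted surface is only safe to use for dose recommendation when it
conforms to the general fertilizer response law of plant nutrition. The
screen is a fixed sequence of gates, and the verdict class is the first
gate that fails:

NRSS
    the regression is not significant (F-test, default alpha = 0.05);
PS
    unreasonable parameter signs — for the quadratic model, any linear
    coefficient b1..b3 <= 0 or any pure quadratic b4..b6 >= 0 (interaction
    coefficients are unconstrained; they legitimately vary in sign); for
    the non-structural model, any of the seven parameters <= 0;
MAX
    no global maximum yield point — for the quadratic model, no unique
    critical point or Hessian principal minors not in the
    negative-definite pattern (G1 < 0, G2 > 0, G3 < 0); for the
    non-structural model this gate cannot fail once the signs pass, since
    all-positive parameters guarantee an interior maximum;
RF
    the recommended rates extrapolate outside the design range
    [0, 1.5 x level-2 rate] per nutrient (boundary inclusive). With
    prices, both the maximum and the economic rates are checked; without
    prices only the maximum rates are, and the verdict is marked
    price-free.

A model passing every gate is TYPICAL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fitting
from .fitting import FitResult
from .recommendation import (
    NoMaximumError,
    PriceSpec,
    tnfm_econ_rates,
    tnfm_max_rates,
    tpfm_econ_rates,
    tpfm_hessian_minors,
    tpfm_max_rates,
)
from .response_models import RatePoint, TNFMParams, TPFMParams, tpfm_critical_point
from .trial_data import DesignRates, TrialRecord

__all__ = [
    "Klass",
    "DesignRange",
    "TypicalityVerdict",
    "classify_tpfm",
    "classify_tnfm",
    "classify",
    "batch_classify",
    "BatchResult",
]

Klass = Literal["NRSS", "PS", "MAX", "RF", "TYPICAL"]

#: Default significance level for the NRSS gate.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DesignRange:
    """Per-nutrient admissible rate intervals [0, 1.5 x level-2 rate]."""

    n_upper: float
    p_upper: float
    k_upper: float

    def __post_init__(self) -> None:
        if min(self.n_upper, self.p_upper, self.k_upper) <= 0:
            raise ValueError("design-range upper bounds must be > 0")

    @classmethod
    def from_design(cls, design: DesignRates) -> "DesignRange":
        return cls(1.5 * design.n2_rate, 1.5 * design.p2_rate, 1.5 * design.k2_rate)

    def contains(self, point: RatePoint | Sequence[float]) -> bool:
        """Componentwise containment, boundary inclusive."""
        arr = np.asarray(point, float)
        upper = np.array([self.n_upper, self.p_upper, self.k_upper])
        return bool(np.all(arr >= 0) and np.all(arr <= upper))


@dataclass(frozen=True)
class TypicalityVerdict:
    """Outcome of the typicality screen for one fitted model.

    Gate flags are ``None`` when the gate was never reached (an earlier
    gate failed). ``price_free`` records that the RF gate checked the
    maximum rates only because no prices were supplied.
    """

    model_family: str
    significant: bool
    ps_ok: bool | None
    max_ok: bool | None
    rf_ok: bool | None
    klass: Klass
    price_free: bool = False


def _rf_gate_tpfm(
    params: TPFMParams, rng: DesignRange, prices: PriceSpec | None
) -> bool:
    max_rates, _ = tpfm_max_rates(params)
    if not rng.contains(max_rates):
        return False
    if prices is None:
        return True
    eco_rates, _ = tpfm_econ_rates(params, prices)
    return rng.contains(eco_rates)


def classify_tpfm(
    fit: FitResult,
    design_range: DesignRange,
    prices: PriceSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> TypicalityVerdict:
    """Run the typicality screen on a fitted quadratic model."""
    params = fit.params
    if not isinstance(params, TPFMParams):
        raise TypeError("classify_tpfm needs a TPFM fit")
    significant = fit.stats.p < alpha
    if not significant:
        return TypicalityVerdict("tpfm", False, None, None, None, "NRSS",
                                 price_free=prices is None)
    ps_ok = (
        min(params.b1, params.b2, params.b3) > 0
        and max(params.b4, params.b5, params.b6) < 0
    )
    if not ps_ok:
        return TypicalityVerdict("tpfm", True, False, None, None, "PS",
                                 price_free=prices is None)
    g1, g2, g3 = tpfm_hessian_minors(params)
    max_ok = (
        tpfm_critical_point(params) is not None and g1 < 0 and g2 > 0 and g3 < 0
    )
    if not max_ok:
        return TypicalityVerdict("tpfm", True, True, False, None, "MAX",
                                 price_free=prices is None)
    rf_ok = _rf_gate_tpfm(params, design_range, prices)
    klass: Klass = "TYPICAL" if rf_ok else "RF"
    return TypicalityVerdict("tpfm", True, True, True, rf_ok, klass,
                             price_free=prices is None)


def classify_tnfm(
    fit: FitResult,
    design_range: DesignRange,
    prices: PriceSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> TypicalityVerdict:
    """Run the typicality screen on a fitted non-structural model."""
    params = fit.params
    if not isinstance(params, TNFMParams):
        raise TypeError("classify_tnfm needs a TNFM fit")
    significant = fit.stats.p < alpha
    if not significant:
        return TypicalityVerdict("tnfm", False, None, None, None, "NRSS",
                                 price_free=prices is None)
    ps_ok = params.all_positive()
    if not ps_ok:
        return TypicalityVerdict("tnfm", True, False, None, None, "PS",
                                 price_free=prices is None)
    # all-positive parameters guarantee an interior global maximum
    max_ok = True
    max_rates, _ = tnfm_max_rates(params)
    rf_ok = design_range.contains(max_rates)
    if rf_ok and prices is not None:
        eco = tnfm_econ_rates(params, prices)
        rf_ok = design_range.contains(eco.rates)
    klass = "TYPICAL" if rf_ok else "RF"
    return TypicalityVerdict("tnfm", True, True, max_ok, rf_ok, klass,
                             price_free=prices is None)


def classify(
    fit: FitResult,
    design_range: DesignRange,
    prices: PriceSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> TypicalityVerdict:
    """Dispatch the typicality screen on the fit's model family."""
    if fit.family == "tnfm":
        return classify_tnfm(fit, design_range, prices, alpha)
    return classify_tpfm(fit, design_range, prices, alpha)


@dataclass(frozen=True)
class BatchResult:
    """Per-trial verdicts plus an aggregate count/percentage summary."""

    verdicts: pd.DataFrame
    summary: pd.DataFrame
    failures: Mapping[str, str]


def batch_classify(
    trials: Iterable[TrialRecord],
    family: str,
    prices: PriceSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_starts: int = fitting.DEFAULT_N_STARTS,
    seed: int = 0,
) -> BatchResult:
    """Fit and screen every trial; tabulate verdict classes.

    Individual trial failures (e.g. a fit that does not converge) are
    recorded in ``failures`` and excluded from the percentages rather
    than aborting the batch. The summary has one row per verdict class
    with counts and percentages of the successfully screened trials.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("batch_classify needs at least one trial")
    rows = []
    failures: dict[str, str] = {}
    for trial in trials:
        try:
            if family == "tnfm":
                fit_res = fitting.fit_tnfm(trial, n_starts=n_starts, seed=seed)
            elif family == "tpfm":
                fit_res = fitting.fit_tpfm(trial)
            else:
                raise ValueError(f"unknown model family {family!r}")
            verdict = classify(
                fit_res, DesignRange.from_design(trial.design), prices, alpha
            )
        except (fitting.FittingError, NoMaximumError) as exc:
            failures[trial.site_id] = str(exc)
            continue
        rows.append(
            {
                "site_id": trial.site_id,
                "family": family,
                "significant": verdict.significant,
                "ps_ok": verdict.ps_ok,
                "max_ok": verdict.max_ok,
                "rf_ok": verdict.rf_ok,
                "klass": verdict.klass,
                "r2": fit_res.stats.r2,
                "f": fit_res.stats.f,
                "p": fit_res.stats.p,
            }
        )
    verdicts = pd.DataFrame(rows)
    order = ["NRSS", "PS", "MAX", "RF", "TYPICAL"]
    counts = (
        verdicts["klass"].value_counts().reindex(order, fill_value=0)
        if not verdicts.empty
        else pd.Series(0, index=order)
    )
    n_ok = int(counts.sum())
    summary = pd.DataFrame(
        {
            "count": counts.astype(int),
            "percent": (100.0 * counts / n_ok).round(1) if n_ok else 0.0,
        }
    )
    summary.index.name = "klass"
    return BatchResult(verdicts=verdicts, summary=summary, failures=failures)
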