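"""Data model and CSV I/O for "3414"-design NPK fertilizer trials.

A "3414" trial tests three nutrients (N, P2O5, K2O) at four levels each —
0, 50%, 100% and 150% of a locally recommended "level-2" rate — in a fixed
subset of 14 treatment combinations. Each trial is represented by a
:class:`TrialRecord` holding the per-site design rates and the 14 treatment
yield summaries (mean, and optionally sd and replicate count).

Model fitting in this package operates on the 14 treatment yield *means*;
standard deviations and replicate counts are carried for simulation and
display only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENT_CODES",
    "LEVEL_MULTIPLIERS",
    "SchemaError",
    "ValidationError",
    "DesignRates",
    "TreatmentObservation",
    "TrialRecord",
    "parse_treatment_code",
    "treatment_rates",
    "load_trials",
    "write_trials",
    "builtin_fixtures",
]

#: The 14 treatment combinations that constitute a valid "3414" design,
#: in conventional order.
TREATMENT_CODES: tuple[str, ...] = (
    "N0P0K0", "N0P2K2", "N1P2K2", "N2P0K2", "N2P1K2", "N2P2K2", "N2P3K2",
    "N2P2K0", "N2P2K1", "N2P2K3", "N3P2K2", "N1P1K2", "N1P2K1", "N2P1K1",
)

#: Level subscript -> fraction of the level-2 (recommended) rate.
LEVEL_MULTIPLIERS: dict[int, float] = {0: 0.0, 1: 0.5, 2: 1.0, 3: 1.5}

#: Tolerance (kg/hm^2) when checking that observed rates match the design;
#: absorbs rounding in published rate tables.
RATE_TOLERANCE = 0.5

_CODE_RE = re.compile(r"^N([0-3])P([0-3])K([0-3])$")

# Default CSV column names; `load_trials(schema=...)` maps other headers
# onto these.
_COLUMNS = ("site_id", "treatment", "n_rate", "p_rate", "k_rate",
            "yield_mean", "yield_sd", "reps")


class SchemaError(ValueError):
    """The input table cannot be interpreted (missing/ambiguous columns)."""


class ValidationError(ValueError):
    """The input data violate the "3414" design invariants."""


def parse_treatment_code(label: str) -> tuple[int, int, int]:
    """Parse a treatment label like ``"N1P2K2"`` into its (i, j, k) levels."""
    m = _CODE_RE.match(str(label).strip().upper())
    if not m:
        raise ValidationError(
            f"malformed treatment code {label!r}; expected N{{i}}P{{j}}K{{k}} "
            "with levels 0-3"
        )
    return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


@dataclass(frozen=True)
class DesignRates:
    """Level-2 (recommended) application rates of a trial, kg/hm^2."""

    n2_rate: float
    p2_rate: float
    k2_rate: float

    def __post_init__(self) -> None:
        for name in ("n2_rate", "p2_rate", "k2_rate"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be finite and > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.n2_rate, self.p2_rate, self.k2_rate], float)


def treatment_rates(code: str, design: DesignRates) -> tuple[float, float, float]:
    """Application rates (N, P2O5, K2O in kg/hm^2) of a treatment.

    Level subscripts map to multiples {0: 0, 1: 0.5, 2: 1, 3: 1.5} of the
    design's level-2 rates.
    """
    i, j, k = parse_treatment_code(code)
    return (
        LEVEL_MULTIPLIERS[i] * design.n2_rate,
        LEVEL_MULTIPLIERS[j] * design.p2_rate,
        LEVEL_MULTIPLIERS[k] * design.k2_rate,
    )


@dataclass(frozen=True)
class TreatmentObservation:
    """Yield summary of one treatment: rates plus mean (+- sd over reps)."""

    code: str
    n_rate: float
    p_rate: float
    k_rate: float
    yield_mean: float
    yield_sd: float | None = None
    reps: int | None = None

    def __post_init__(self) -> None:
        parse_treatment_code(self.code)
        for name in ("n_rate", "p_rate", "k_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.code}: {name} must be >= 0")
        if not self.yield_mean > 0:
            raise ValidationError(
                f"{self.code}: yield_mean must be > 0, got {self.yield_mean}"
            )
        if self.reps is not None and self.reps < 1:
            raise ValidationError(f"{self.code}: reps must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One "3414" trial: site id, design rates and the 14 observations."""

    site_id: str
    design: DesignRates
    observations: tuple[TreatmentObservation, ...]
    soil_properties: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        codes = [o.code for o in self.observations]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValidationError(
                f"site {self.site_id!r}: duplicate treatments {sorted(dupes)}"
            )
        missing = sorted(set(TREATMENT_CODES) - set(codes))
        extra = sorted(set(codes) - set(TREATMENT_CODES))
        if missing or extra:
            raise ValidationError(
                f"site {self.site_id!r}: not a complete '3414' design"
                + (f"; missing {missing}" if missing else "")
                + (f"; unexpected {extra}" if extra else "")
            )
        for obs in self.observations:
            expected = treatment_rates(obs.code, self.design)
            actual = (obs.n_rate, obs.p_rate, obs.k_rate)
            if any(abs(a - e) > RATE_TOLERANCE for a, e in zip(actual, expected)):
                raise ValidationError(
                    f"site {self.site_id!r}, treatment {obs.code}: rates "
                    f"{actual} do not match design {expected} "
                    f"(tolerance {RATE_TOLERANCE} kg/hm^2)"
                )

    # -- convenience accessors ------------------------------------------

    def observation(self, code: str) -> TreatmentObservation:
        for obs in self.observations:
            if obs.code == code:
                return obs
        raise KeyError(code)

    def rates(self) -> np.ndarray:
        """(14, 3) array of (N, P, K) application rates, design order."""
        ordered = [self.observation(c) for c in TREATMENT_CODES]
        return np.array([[o.n_rate, o.p_rate, o.k_rate] for o in ordered])

    def yields(self) -> np.ndarray:
        """(14,) array of treatment yield means, design order."""
        return np.array(
            [self.observation(c).yield_mean for c in TREATMENT_CODES], float
        )

    def yield_sds(self) -> np.ndarray:
        """(14,) array of yield sds (NaN where absent), design order."""
        return np.array(
            [
                np.nan
                if self.observation(c).yield_sd is None
                else self.observation(c).yield_sd
                for c in TREATMENT_CODES
            ],
            float,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _resolve(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename columns per ``schema`` ({canonical: actual}) and check presence."""
    if schema:
        rename = {actual: canon for canon, actual in schema.items()}
        missing_src = [a for a in rename if a not in df.columns]
        if missing_src:
            raise SchemaError(f"schema maps absent column(s): {missing_src}")
        df = df.rename(columns=rename)
    required = ["site_id", "treatment", "yield_mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    explicit = all(c in df.columns for c in ("n_rate", "p_rate", "k_rate"))
    by_design = all(c in df.columns for c in ("n2_rate", "p2_rate", "k2_rate"))
    if not (explicit or by_design):
        raise SchemaError(
            "missing rate columns: need either explicit rates "
            "(n_rate, p_rate, k_rate) or design rates (n2_rate, p2_rate, k2_rate)"
        )
    return df


def _site_record(site_id: str, grp: pd.DataFrame) -> TrialRecord:
    explicit = all(c in grp.columns for c in ("n_rate", "p_rate", "k_rate"))
    if explicit:
        # Design is defined by the rates of the all-level-2 treatment.
        ref = grp[grp["treatment"].astype(str).str.upper() == "N2P2K2"]
        if ref.empty:
            raise ValidationError(
                f"site {site_id!r}: treatment N2P2K2 required to infer the design"
            )
        row = ref.iloc[0]
        design = DesignRates(float(row["n_rate"]), float(row["p_rate"]),
                             float(row["k_rate"]))
    else:
        row = grp.iloc[0]
        design = DesignRates(float(row["n2_rate"]), float(row["p2_rate"]),
                             float(row["k2_rate"]))

    obs = []
    for _, r in grp.iterrows():
        code = str(r["treatment"]).upper()
        if explicit:
            n, p, k = float(r["n_rate"]), float(r["p_rate"]), float(r["k_rate"])
        else:
            n, p, k = treatment_rates(code, design)
        sd = r.get("yield_sd")
        reps = r.get("reps")
        obs.append(
            TreatmentObservation(
                code=code,
                n_rate=n,
                p_rate=p,
                k_rate=k,
                yield_mean=float(r["yield_mean"]),
                yield_sd=None if pd.isna(sd) else float(sd),
                reps=None if pd.isna(reps) else int(reps),
            )
        )
    return TrialRecord(site_id=str(site_id), design=design, observations=tuple(obs))


def load_trials(
    path, schema: Mapping[str, str] | None = None
) -> list[TrialRecord]:
    """Read "3414" trials from a CSV file.

    Parameters
    ----------
    path
        CSV file with one row per (site, treatment). Two rate encodings are
        accepted: explicit per-treatment rates (columns ``n_rate``,
        ``p_rate``, ``k_rate``) or per-site design rates (columns
        ``n2_rate``, ``p2_rate``, ``k2_rate``) from which treatment rates
        are reconstructed.
    schema
        Optional mapping {canonical name: actual column name} for files
        with different headers.

    Raises
    ------
    SchemaError
        Empty file, or required columns unresolvable.
    ValidationError
        A site with duplicate or missing treatments, non-positive yields,
        or rates inconsistent with its design.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    df = _resolve(df, schema)
    return [
        _site_record(site_id, grp)
        for site_id, grp in df.groupby("site_id", sort=False)
    ]


def write_trials(trials: Iterable[TrialRecord], path) -> None:
    """Write trials to CSV in the canonical (explicit-rates) schema."""
    rows = []
    for t in trials:
        for code in TREATMENT_CODES:
            o = t.observation(code)
            rows.append(
                {
                    "site_id": t.site_id,
                    "treatment": o.code,
                    "n_rate": o.n_rate,
                    "p_rate": o.p_rate,
                    "k_rate": o.k_rate,
                    "yield_mean": o.yield_mean,
                    "yield_sd": o.yield_sd,
                    "reps": o.reps,
                }
            )
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Built-in fixtures: six early-rice trials from two Fujian counties
# ---------------------------------------------------------------------------

#: Topsoil chemistry of the six built-in trials (conventional assays):
#: pH, organic matter (g/kg), alkali-hydrolysable N, Olsen-P and available K
#: (mg/kg).
SOIL_PROPERTIES: dict[str, dict[str, float]] = {
    "Pinghe-low": {"pH": 4.90, "OM": 27.24, "alkali_N": 121.5, "Olsen_P": 28.4, "avail_K": 67.0},
    "Pinghe-medium": {"pH": 4.87, "OM": 29.75, "alkali_N": 156.0, "Olsen_P": 29.1, "avail_K": 61.3},
    "Pinghe-high": {"pH": 4.90, "OM": 32.74, "alkali_N": 188.7, "Olsen_P": 38.5, "avail_K": 85.0},
    "Xianyou-low": {"pH": 5.40, "OM": 18.62, "alkali_N": 112.0, "Olsen_P": 16.6, "avail_K": 41.9},
    "Xianyou-medium": {"pH": 5.24, "OM": 25.94, "alkali_N": 151.5, "Olsen_P": 20.8, "avail_K": 57.2},
    "Xianyou-high": {"pH": 5.46, "OM": 24.54, "alkali_N": 148.2, "Olsen_P": 24.7, "avail_K": 65.0},
}


def builtin_fixtures() -> list[TrialRecord]:
    """The six built-in early-rice trials (Pinghe and Xianyou counties,
    Fujian, at low/medium/high soil fertility), yields as published.

    Designs are per-site: 165-75-105 kg/hm^2 N-P2O5-K2O in Pinghe,
    165-56-109 for Xianyou low/medium fertility and 165-53-112 for Xianyou
    high fertility. Pinghe yields average 3 replications, Xianyou 4.
    """
    ref = resources.files("fertresp").joinpath("data/builtin_trials.csv")
    with resources.as_file(ref) as p:
        trials = load_trials(p)
    return [
        TrialRecord(
            site_id=t.site_id,
            design=t.design,
            observations=t.observations,
            soil_properties=SOIL_PROPERTIES.get(t.site_id),
        )
        for t in trials
    ]
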