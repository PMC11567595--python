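"""The two static factor-Xa-generation protocols and the measured observable.

Experiment One: factor X (170 nM) is activated by TF:VIIa at a range of
concentrations (0.032-1.024 nM, successive doublings by default) in the
presence of TFPI (2.4 nM); activated factor X is read out at twelve
non-zero time points per enzyme level.

Experiment Two: TFPI (2.4 nM) is pre-incubated with factor Xa (0-1 nM) for
two hours, letting the Xa:TFPI complex form; the mixture is then combined
with factor X (170 nM) and TF:VIIa (0.128 nM) and read out the same way.
The Xa = 0 pre-incubation condition is by construction identical to the
0.128 nM enzyme condition of Experiment One, which the package preserves
bit-for-bit (same initial state, same solver settings).

Mixing is assumed to cause no dilution: all stated concentrations are
post-mix.  The model observable mu(t) is free Xa ([P]) by default; the
alternative mapping [P] + [E:P] (total Xa including enzyme-bound) is
available for sensitivity checks and differs by at most a few percent
under these conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from . import _vectorfield as vf
from .kinetics import SpeciesState, Trajectory, simulate_static
from .rates import RateSet

__all__ = [
    "ExperimentCondition",
    "MeasurementSeries",
    "Dataset",
    "ObservableMapping",
    "experiment_one_initial",
    "preincubate",
    "experiment_two_initial",
    "initial_state",
    "predict_observable",
    "predict_condition",
    "DEFAULT_ENZYME_LEVELS",
    "DEFAULT_PREINCUBATION_XA_LEVELS",
    "default_measurement_times",
]

ObservableMapping = Literal["free_xa", "total_xa"]

#: Experiment One TF:VIIa levels (nM): six successive doublings
DEFAULT_ENZYME_LEVELS: tuple[float, ...] = (0.032, 0.064, 0.128, 0.256, 0.512, 1.024)
#: Experiment Two pre-incubated Xa levels (nM)
DEFAULT_PREINCUBATION_XA_LEVELS: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0)


def default_measurement_times(horizon_s: float = 720.0, n: int = 12) -> np.ndarray:
    """Twelve (by default) equally spaced non-zero sampling times."""
    return np.linspace(horizon_s / n, horizon_s, n)


@dataclass(frozen=True)
class ExperimentCondition:
    """One experimental condition of either protocol."""

    experiment_id: int
    enzyme_nM: float
    X_nM: float = 170.0
    TFPI_total_nM: float = 2.4
    preincubated_Xa_nM: float = 0.0
    preincubation_s: float = 0.0

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2):
            raise ValueError("experiment_id must be 1 or 2")
        for name in ("enzyme_nM", "X_nM", "TFPI_total_nM", "preincubated_Xa_nM",
                     "preincubation_s"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.preincubation_s > 0 and self.experiment_id != 2:
            raise ValueError("pre-incubation applies only to experiment 2")

    @classmethod
    def one(cls, enzyme_nM: float, X_nM: float = 170.0,
            TFPI_nM: float = 2.4) -> "ExperimentCondition":
        return cls(1, enzyme_nM, X_nM, TFPI_nM)

    @classmethod
    def two(cls, Xa_preinc_nM: float, enzyme_nM: float = 0.128,
            X_nM: float = 170.0, TFPI_nM: float = 2.4,
            preincubation_s: float = 7200.0) -> "ExperimentCondition":
        return cls(2, enzyme_nM, X_nM, TFPI_nM, Xa_preinc_nM, preincubation_s)


@dataclass(frozen=True)
class MeasurementSeries:
    """Timed activated-factor-X measurements for one condition."""

    condition: ExperimentCondition
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0) or (t.size and t[0] <= 0):
            raise ValueError("measurement times must be strictly increasing and > 0")
        if v.shape != t.shape:
            raise ValueError("times and values must have equal length")
        if np.any(v < 0):
            raise ValueError("measured concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


_CSV_COLUMNS = [
    "experiment_id", "enzyme_nM", "X_nM", "TFPI_nM",
    "preincubated_Xa_nM", "time_s", "Xa_nM",
]


@dataclass(frozen=True)
class Dataset:
    """A collection of measurement series across both experiments."""

    series: tuple[MeasurementSeries, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))

    def __len__(self) -> int:
        return len(self.series)

    def n_measurements(self, experiment_id: int | None = None) -> int:
        return sum(
            len(s)
            for s in self.series
            if experiment_id is None or s.condition.experiment_id == experiment_id
        )

    def by_experiment(self, experiment_id: int) -> list[MeasurementSeries]:
        return [s for s in self.series if s.condition.experiment_id == experiment_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            c = s.condition
            for t, v in zip(s.times, s.values):
                rows.append((c.experiment_id, c.enzyme_nM, c.X_nM, c.TFPI_total_nM,
                             c.preincubated_Xa_nM, t, v))
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing column(s): {sorted(missing)}")
        keys = ["experiment_id", "enzyme_nM", "X_nM", "TFPI_nM", "preincubated_Xa_nM"]
        series = []
        for key, grp in df.groupby(keys, sort=False):
            exp_id, enzyme, x, tfpi, xa_pre = key
            grp = grp.sort_values("time_s")
            cond = ExperimentCondition(
                int(exp_id), float(enzyme), float(x), float(tfpi),
                float(xa_pre), 7200.0 if int(exp_id) == 2 else 0.0,
            )
            series.append(MeasurementSeries(
                cond, grp["time_s"].to_numpy(), grp["Xa_nM"].to_numpy()
            ))
        return cls(tuple(series))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))


def experiment_one_initial(
    enzyme_nM: float, X_nM: float = 170.0, TFPI_nM: float = 2.4
) -> SpeciesState:
    """Initial state of Experiment One: free enzyme, substrate and TFPI only."""
    for name, v in (("enzyme_nM", enzyme_nM), ("X_nM", X_nM), ("TFPI_nM", TFPI_nM)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    return SpeciesState(E=enzyme_nM, S=X_nM, I=TFPI_nM)


def preincubate(
    Xa_nM: float,
    TFPI_nM: float = 2.4,
    duration_s: float = 7200.0,
    rates: RateSet | None = None,
) -> tuple[float, float, float]:
    """Pre-incubation of Xa with TFPI: integrate the isolated reversible
    reaction 4 (P + I <-> P:I) for ``duration_s`` and return (P, I, PI), nM.

    With the fitted rates the relaxation time ~1/(k+4*I) is far below the
    two-hour incubation, so the result sits at the binding equilibrium.
    """
    for name, v in (("Xa_nM", Xa_nM), ("TFPI_nM", TFPI_nM), ("duration_s", duration_s)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    if rates is None:
        raise ValueError("preincubate requires a RateSet (for k+4/k-4)")
    return _preincubate_scalar(
        rates.k_plus_4, rates.k_minus_4, Xa_nM, TFPI_nM, duration_s
    )


def _preincubate_scalar(
    k4: float, km4: float, Xa_nM: float, TFPI_nM: float, duration_s: float
) -> tuple[float, float, float]:
    if Xa_nM == 0.0 or TFPI_nM == 0.0 or duration_s == 0.0 or k4 == 0.0:
        return (Xa_nM, TFPI_nM, 0.0)
    y = odeint(
        vf.preincubation_rhs,
        np.array([0.0]),
        np.array([0.0, duration_s]),
        args=(k4, km4, Xa_nM, TFPI_nM),
        rtol=1e-10,
        atol=1e-14,
    )
    PI = float(min(y[-1, 0], min(Xa_nM, TFPI_nM)))
    return (Xa_nM - PI, TFPI_nM - PI, PI)


def experiment_two_initial(
    Xa_preinc_nM: float,
    rates: RateSet,
    enzyme_nM: float = 0.128,
    X_nM: float = 170.0,
    TFPI_nM: float = 2.4,
    preincubation_s: float = 7200.0,
) -> SpeciesState:
    """Initial state of Experiment Two: enzyme and substrate added to the
    pre-incubated Xa/TFPI mixture (no dilution on mixing)."""
    P, I, PI = preincubate(Xa_preinc_nM, TFPI_nM, preincubation_s, rates)
    return SpeciesState(E=enzyme_nM, S=X_nM, P=P, I=I, PI=PI)


def initial_state(condition: ExperimentCondition, rates: RateSet) -> SpeciesState:
    """Initial species state for either protocol condition."""
    if condition.experiment_id == 1:
        return experiment_one_initial(
            condition.enzyme_nM, condition.X_nM, condition.TFPI_total_nM
        )
    return experiment_two_initial(
        condition.preincubated_Xa_nM,
        rates,
        enzyme_nM=condition.enzyme_nM,
        X_nM=condition.X_nM,
        TFPI_nM=condition.TFPI_total_nM,
        preincubation_s=condition.preincubation_s,
    )


def predict_observable(
    traj: Trajectory, mapping: ObservableMapping = "free_xa"
) -> np.ndarray:
    """Map a trajectory to the measured activated-factor-X series mu(t), nM."""
    if mapping == "free_xa":
        return traj.species("P").copy()
    if mapping == "total_xa":
        return traj.species("P") + traj.species("EP")
    raise ValueError(f"unknown observable mapping {mapping!r}")


def predict_condition(
    condition: ExperimentCondition,
    rates: RateSet,
    times: Sequence[float],
    mapping: ObservableMapping = "free_xa",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Noise-free model prediction mu(t) for one condition at the given
    measurement times."""
    y0 = initial_state(condition, rates)
    traj = simulate_static(y0, rates, times, rtol=rtol, atol=atol)
    return predict_observable(traj, mapping)
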