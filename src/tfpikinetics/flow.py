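"""Flow-through (CSTR-like) generalization of the static kinetics and the
pathway / product-inhibition steady-state analyses.

A well-mixed reaction zone sits over the injury: the wall-bound enzyme
species (E, E:S, E:P, E:P:I, P:I:E) are unaffected by flow, while factor X
and TFPI are carried in at upstream concentrations S_up and I_up and X, Xa,
TFPI and the Xa:TFPI complex are washed out, all with a single mass-transfer
rate k_flow (s^-1).  k_flow can be computed from vessel geometry as

    k_flow = (3/4) * (V^2 * D / (R*L)^2)^(1/3)

with V the midstream velocity (um/s), L the injury length (um), D the
molecular diffusivity (um^2/s) and R the vessel radius (um); with
D = 50 um^2/s and L = 10 um this spans roughly 1e-3 to 1e3 s^-1 from
venous to arterial conditions.

Four inhibition-pathway variants of the scheme are studied:

    NI   no TFPI: reactions 1-3 only (4-8 nullified)
    DB   direct binding only (4 and 5 nullified)
    IB   indirect binding only (5 and 6 nullified)
    DIB  both pathways (only 5 nullified)

The inhibition metric is E_functional = [E] + [E:S], the enzyme still able
to activate factor X; E_functional = E(0) means no inhibition and 0 means
complete inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import _vectorfield as vf
from .kinetics import (
    IntegrationError,
    SpeciesState,
    Trajectory,
    _integrate,
    conserved_totals,
)
from .rates import RateSet

__all__ = [
    "FlowConfig",
    "VesselGeometry",
    "PathwayVariant",
    "ConvergenceError",
    "kflow_from_vessel",
    "apply_pathway_variant",
    "flow_rhs",
    "simulate_flow",
    "e_functional",
    "steady_state",
    "flow_sweep",
    "product_inhibition_sweep",
    "default_kflow_grid",
]

#: steady-state residual tolerance, nM/s
STEADY_STATE_TOL = 1e-10


class ConvergenceError(RuntimeError):
    """Raised when the steady-state search does not reach the residual
    tolerance within its horizon budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class FlowConfig:
    """Mass-transfer rate (s^-1) and upstream concentrations (nM)."""

    k_flow: float
    S_up: float = 170.0
    I_up: float = 2.4

    def __post_init__(self) -> None:
        for name in ("k_flow", "S_up", "I_up"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def with_k_flow(self, k_flow: float) -> "FlowConfig":
        return FlowConfig(k_flow=k_flow, S_up=self.S_up, I_up=self.I_up)


@dataclass(frozen=True)
class VesselGeometry:
    """Vessel geometry: V midstream velocity (um/s), L injury length (um),
    D molecular diffusivity (um^2/s), R vessel radius (um)."""

    V: float
    L: float
    D: float
    R: float

    def __post_init__(self) -> None:
        for name in ("V", "L", "D", "R"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")


#: reactions nullified by each inhibition-pathway label
_VARIANT_NULLIFICATIONS: dict[str, frozenset[int]] = {
    "NI": frozenset({4, 5, 6, 7, 8}),
    "DB": frozenset({4, 5}),
    "IB": frozenset({5, 6}),
    "DIB": frozenset({5}),
}


@dataclass(frozen=True)
class PathwayVariant:
    """One of the four inhibition-pathway restrictions of the scheme."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in _VARIANT_NULLIFICATIONS:
            raise ValueError(
                f"unknown pathway variant {self.label!r}; "
                f"expected one of {sorted(_VARIANT_NULLIFICATIONS)}"
            )

    @property
    def nullified_reactions(self) -> frozenset[int]:
        return _VARIANT_NULLIFICATIONS[self.label]


def kflow_from_vessel(geom: VesselGeometry) -> float:
    """Mass-transfer rate (s^-1) from vessel geometry (see module docstring).

    Note the V -> 0 limit is 0 even though VesselGeometry requires V > 0."""
    return 0.75 * (geom.V**2 * geom.D / (geom.R * geom.L) ** 2) ** (1.0 / 3.0)


def apply_pathway_variant(rates: RateSet, variant: PathwayVariant | str) -> RateSet:
    """Copy of ``rates`` with the variant's nullified reactions zeroed."""
    if isinstance(variant, str):
        variant = PathwayVariant(variant)
    return rates.nullify(*sorted(variant.nullified_reactions))


def flow_rhs(state: SpeciesState, rates: RateSet, flow: FlowConfig) -> np.ndarray:
    """Rate of change (nM/s) per species in the flow model: the static
    mass-action terms plus the exchange terms on S, P, I and P:I."""
    state.validate()
    return vf.rhs(
        state.to_array(), 0.0, rates.to_array(), flow.k_flow, flow.S_up, flow.I_up
    )


def simulate_flow(
    initial: SpeciesState,
    rates: RateSet,
    flow: FlowConfig,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the flow model from ``initial`` (at t = 0); same contract
    and error behaviour as :func:`tfpikinetics.kinetics.simulate_static`."""
    initial.validate(nonnegative=True)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("times must be strictly increasing with first entry >= 0")
    y = _integrate(
        initial.to_array(), rates.to_array(), t, flow.k_flow, flow.S_up, flow.I_up,
        rtol, atol,
    )
    return Trajectory(t, y)


def e_functional(state: SpeciesState) -> float:
    """Functional-enzyme metric [E] + [E:S], nM."""
    state.validate()
    return state.E + state.ES


def _residual(y: np.ndarray, K: np.ndarray, flow: FlowConfig) -> np.ndarray:
    return vf.rhs(y, 0.0, K, flow.k_flow, flow.S_up, flow.I_up)


#: reactions touching each species (index = canonical species order)
_REACTIONS_BY_SPECIES = (
    (1, 3, 5, 8), (1,), (1, 2), (2, 3, 6), (3, 4),
    (4, 6), (4, 5, 8), (6, 7, 8), (5, 7),
)
#: K-vector indices of each reaction's rate constants
_K_BY_REACTION = {
    1: (0, 1), 2: (2,), 3: (3, 4), 4: (5, 6),
    5: (7, 8), 6: (9, 10), 7: (11, 12), 8: (13, 14),
}
#: species with a flow exchange term (S, P, I, PI)
_FLOW_SPECIES = frozenset({1, 4, 5, 6})


def _frozen_species(K: np.ndarray, k_flow: float) -> list[int]:
    """Species whose dynamics vanish identically under the nullified rates
    (every touching reaction off, no flow term).  In pathway variants these
    are unreachable pools; fixed-point solves must pin them, otherwise the
    root-finder can park enzyme in a state the dynamics never reach."""
    out = []
    for i, rxns in enumerate(_REACTIONS_BY_SPECIES):
        if i in _FLOW_SPECIES and k_flow > 0:
            continue
        if all(K[j] == 0.0 for r in rxns for j in _K_BY_REACTION[r]):
            out.append(i)
    return out


def _polish(
    y: np.ndarray, K: np.ndarray, flow: FlowConfig, enzyme_total: float
) -> np.ndarray | None:
    """Algebraic polish of a near-steady state.

    The enzyme moiety is conserved by the flow field, so the nine equations
    flow_rhs = 0 are rank-deficient; the dE/dt row is replaced by the
    conservation constraint E+ES+EP+EPI+PIE = enzyme_total before solving.
    Returns the polished state, or None if the solve fails or leaves the
    physical region.
    """
    enzyme_idx = [0, 2, 3, 7, 8]
    frozen = [i for i in _frozen_species(K, flow.k_flow) if i != 0]

    def fun(z: np.ndarray) -> np.ndarray:
        r = _residual(z, K, flow)
        r[0] = z[enzyme_idx].sum() - enzyme_total
        for i in frozen:
            r[i] = z[i] - y[i]
        return r

    def jac(z: np.ndarray) -> np.ndarray:
        J = vf.jac(z, 0.0, K, flow.k_flow, flow.S_up, flow.I_up)
        J[0, :] = 0.0
        J[0, enzyme_idx] = 1.0
        for i in frozen:
            J[i, :] = 0.0
            J[i, i] = 1.0
        return J

    sol = root(fun, y, jac=jac, method="hybr")
    z = sol.x
    # the caller verifies the residual; reject only non-physical output
    if np.any(z < -1e-9) or np.any(~np.isfinite(z)):
        return None
    return np.clip(z, 0.0, None) if z.min() < 0 else z


def steady_state(
    rates: RateSet,
    flow: FlowConfig,
    enzyme_total: float = 1.0,
    max_horizon_s: float = 1e9,
) -> SpeciesState:
    """Steady state of the flow model reached from the standard start
    (E = enzyme_total, every other species 0).

    Found by stiff integration over geometrically expanding horizons until
    the residual is small, then polished on the algebraic system; the
    returned state satisfies max |d/dt| < 1e-10 nM/s and carries the
    requested enzyme-moiety total.  Raises :class:`ConvergenceError`
    (reporting the residual) if the budget is exhausted.
    """
    if flow.k_flow <= 0:
        raise ValueError("steady_state requires k_flow > 0")
    if enzyme_total <= 0:
        raise ValueError("enzyme_total must be > 0")
    K = rates.to_array()
    y = np.zeros(vf.N_SPECIES)
    y[0] = enzyme_total
    # horizons spanning the slowest timescales (1/k_flow, 1/k-4 ~ 1e4 s)
    t_end = 1e2
    best_res = np.inf
    while t_end <= max_horizon_s:
        y = _integrate(y, K, np.array([t_end]), flow.k_flow, flow.S_up, flow.I_up,
                       1e-8, 1e-12)[-1]
        res = float(np.max(np.abs(_residual(y, K, flow))))
        best_res = min(best_res, res)
        z = _polish(y, K, flow, enzyme_total)
        if z is not None:
            zres = float(np.max(np.abs(_residual(z, K, flow))))
            enz = z[[0, 2, 3, 7, 8]].sum()
            if zres < STEADY_STATE_TOL and abs(enz - enzyme_total) < 1e-8:
                return SpeciesState.from_array(z)
        if res < STEADY_STATE_TOL:
            return SpeciesState.from_array(y)
        t_end *= 10.0
    raise ConvergenceError(
        f"steady state not reached within {max_horizon_s:g} s "
        f"(best residual {best_res:.3e} nM/s)",
        residual=best_res,
    )


def default_kflow_grid(n: int = 25) -> np.ndarray:
    """Logarithmic k_flow grid over the physiological range 1e-3..1e3 s^-1."""
    return np.logspace(-3, 3, n)


def flow_sweep(
    rates: RateSet,
    variant: PathwayVariant | str,
    kflow_grid: Iterable[float] | None = None,
    flow: FlowConfig | None = None,
    enzyme_total: float = 1.0,
) -> pd.DataFrame:
    """Steady-state E_functional across a k_flow grid for one pathway
    variant.  Returns columns variant, phi, k_flow_per_s, E_functional_nM
    (phi = 1 here; see :func:`product_inhibition_sweep`)."""
    if isinstance(variant, str):
        variant = PathwayVariant(variant)
    if flow is None:
        flow = FlowConfig(k_flow=1.0)
    grid = default_kflow_grid() if kflow_grid is None else np.asarray(
        list(kflow_grid), dtype=float
    )
    if np.any(grid <= 0):
        raise ValueError("k_flow grid values must be > 0")
    vrates = apply_pathway_variant(rates, variant)
    rows = []
    for kf in grid:
        try:
            ss = steady_state(vrates, flow.with_k_flow(float(kf)), enzyme_total)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"k_flow={kf:g} s^-1 ({variant.label}): {err}", residual=err.residual
            ) from err
        rows.append((variant.label, 1.0, float(kf), e_functional(ss)))
    return pd.DataFrame(
        rows, columns=["variant", "phi", "k_flow_per_s", "E_functional_nM"]
    )


def product_inhibition_sweep(
    rates: RateSet,
    phi_values: Sequence[float],
    kflow_grid: Iterable[float] | None = None,
    flow: FlowConfig | None = None,
    enzyme_total: float = 1.0,
) -> pd.DataFrame:
    """No-TFPI sweeps with the product off-rate k-3 scaled down by phi.

    k+3 stays at its input value while k-3 -> k-3/phi, i.e. the product
    dissociation constant K_D,3 is scaled to K_D,3/phi; phi = 1 reproduces
    the plain NI sweep.  Returns the concatenated sweep frames with the
    ``phi`` column set accordingly.
    """
    phis = np.asarray(list(phi_values), dtype=float)
    if np.any(phis <= 0):
        raise ValueError("phi values must be > 0")
    frames = []
    for phi in phis:
        scaled = replace(rates, k_minus_3=rates.k_minus_3 / phi)
        df = flow_sweep(scaled, "NI", kflow_grid, flow, enzyme_total)
        df["phi"] = phi
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
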