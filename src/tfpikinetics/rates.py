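"""Rate-constant containers for the TF:VIIa / Xa / TFPI reaction scheme.

The scheme has eight elementary reactions (numbered 1-8 following the
convention of the underlying biochemistry literature):

    1. E + S   <->  E:S        substrate binding
    2. E:S      ->  E:P        catalysis (X -> Xa)
    3. E + P   <->  E:P        product (Xa) rebinding
    4. P + I   <->  P:I        Xa:TFPI formation in solution
    5. E + P:I <->  P:I:E      one-step quaternary formation (nullified)
    6. E:P + I <->  E:P:I      direct binding of TFPI to bound Xa
    7. E:P:I   <->  P:I:E      conformational change to the tight complex
    8. E + P:I <->  E:P:I      indirect binding of Xa:TFPI to the enzyme

Forward bimolecular constants are in nM^-1 s^-1; all unimolecular
constants (including the catalytic k+2 and conformational k+7) in s^-1.
Reaction 5 is retained in the equations but carries zero rates by default:
the two simultaneous binding events it would require make it negligible
next to the single-step reaction 8.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from ._vectorfield import RATE_ORDER

__all__ = [
    "RateSet",
    "table1_median_rates",
    "table2_median_rates",
    "load_rates",
    "save_rates",
]


@dataclass(frozen=True)
class RateSet:
    """The fifteen forward/reverse rate constants k(+/-)1 ... k(+/-)8.

    Reaction-5 rates default to zero (see module docstring).  Derived
    equilibrium quantities (K_M, the dissociation constants K_D,n and the
    reaction-7 ratio) are exposed as properties.
    """

    k_plus_1: float   # nM^-1 s^-1
    k_minus_1: float  # s^-1
    k_plus_2: float   # s^-1 (catalytic)
    k_plus_3: float   # nM^-1 s^-1
    k_minus_3: float  # s^-1
    k_plus_4: float   # nM^-1 s^-1
    k_minus_4: float  # s^-1
    k_plus_6: float   # nM^-1 s^-1
    k_minus_6: float  # s^-1
    k_plus_7: float   # s^-1 (conformational change)
    k_minus_7: float  # s^-1
    k_plus_8: float   # nM^-1 s^-1
    k_minus_8: float  # s^-1
    k_plus_5: float = 0.0   # nM^-1 s^-1, nullified by default
    k_minus_5: float = 0.0  # s^-1, nullified by default

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"rate {f.name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"rate {f.name} must be >= 0, got {v}")

    # -- derived constants -------------------------------------------------
    @property
    def K_M(self) -> float:
        """Michaelis constant (k-1 + k+2)/k+1, nM."""
        if self.k_plus_1 <= 0:
            raise ZeroDivisionError("K_M undefined when k_plus_1 = 0")
        return (self.k_minus_1 + self.k_plus_2) / self.k_plus_1

    def K_D(self, reaction: int) -> float:
        """Dissociation constant k-n/k+n (nM) for reaction n in {1,3,4,5,6,8}."""
        if reaction not in (1, 3, 4, 5, 6, 8):
            raise ValueError(f"no dissociation constant for reaction {reaction}")
        kf = getattr(self, f"k_plus_{reaction}")
        kr = getattr(self, f"k_minus_{reaction}")
        if kf <= 0:
            raise ZeroDivisionError(f"K_D,{reaction} undefined when k_plus_{reaction} = 0")
        return kr / kf

    @property
    def K_R_7(self) -> float:
        """Forward/reverse ratio k+7/k-7 of the conformational step (dimensionless)."""
        if self.k_minus_7 <= 0 or self.k_plus_7 <= 0:
            raise ZeroDivisionError("K_R,7 undefined when a reaction-7 rate is 0")
        return self.k_plus_7 / self.k_minus_7

    # -- conversions -------------------------------------------------------
    def to_array(self) -> np.ndarray:
        """Rates as a float64 vector in the canonical integrator order."""
        return np.array([getattr(self, name) for name in RATE_ORDER])

    @classmethod
    def from_array(cls, K: np.ndarray) -> "RateSet":
        return cls(**dict(zip(RATE_ORDER, (float(v) for v in K))))

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_ORDER}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        extra = set(d) - set(RATE_ORDER)
        if extra:
            raise KeyError(f"unknown rate key(s): {sorted(extra)}")
        missing = set(RATE_ORDER) - {"k_plus_5", "k_minus_5"} - set(d)
        if missing:
            raise KeyError(f"missing rate key(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def nullify(self, *reactions: int) -> "RateSet":
        """Copy with forward and reverse rates of the given reactions set to 0."""
        changes: dict[str, float] = {}
        for r in reactions:
            if r not in range(1, 9):
                raise ValueError(f"unknown reaction number {r}")
            changes[f"k_plus_{r}"] = 0.0
            if r != 2:  # reaction 2 is irreversible; it has no reverse rate
                changes[f"k_minus_{r}"] = 0.0
        return replace(self, **changes)


def table1_median_rates() -> RateSet:
    """Posterior-median rate constants of the full scheme (reaction 5 nullified)."""
    return RateSet(
        k_plus_1=0.51, k_minus_1=104.30, k_plus_2=16.23,
        k_plus_3=0.16, k_minus_3=81.18,
        k_plus_4=3.67e-3, k_minus_4=9.64e-5,
        k_plus_6=0.56, k_minus_6=25.16,
        k_plus_7=360.92, k_minus_7=7.36e-3,
        k_plus_8=0.95, k_minus_8=16.03,
    )


def table2_median_rates() -> RateSet:
    """Posterior-median rates for the alternative scheme without the
    conformational step (reactions 5 and 7 nullified)."""
    return RateSet(
        k_plus_1=0.51, k_minus_1=103.93, k_plus_2=17.33,
        k_plus_3=7.42e-2, k_minus_3=38.59,
        k_plus_4=3.40e-3, k_minus_4=8.94e-5,
        k_plus_6=0.24, k_minus_6=2.21e-4,
        k_plus_7=0.0, k_minus_7=0.0,
        k_plus_8=0.94, k_minus_8=8.19e-4,
    )


def load_rates(path: str | Path) -> RateSet:
    """Read a rate set from a flat YAML or JSON key-value file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of rate constants")
    return RateSet.from_dict(data)


def save_rates(rates: RateSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rates.to_dict(), indent=2) + "\n")
    else:
        import yaml

        path.write_text(yaml.safe_dump(rates.to_dict(), sort_keys=False))
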