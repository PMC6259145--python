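"""Single-capture activation: target burn-up and product yield closed forms.

Covers the simple scheme ``S (n,gamma) R`` with first-order target
depletion (constant ``delta_S``), product depression (``Lambda_Ri``),
time of maximum yield, and post-irradiation decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from ._kinetics import e2
from .constants import BARN_CM2, LN2
from .nuclear_data import NeutronField, ReactionChannel
from .spectrum import omega

__all__ = [
    "DepletionConstants",
    "ActivationSeries",
    "depletion_constant",
    "remaining_atoms",
    "burned_atoms",
    "half_burnup_time",
    "product_atoms",
    "product_activity",
    "time_of_max_yield",
    "max_yield",
    "max_yield_via_auxiliaries",
]

# relative rate gap below which the removable D = 1 singularity branches engage
_DEGENERATE_TOL = 1.0e-10


@dataclass(frozen=True)
class DepletionConstants:
    """Rate constants of one target/product pair (all in s^-1).

    ``delta_S``     total target burn-up constant phi_th * sum(Omega)
    ``lambda_total`` total decay constant of the product
    ``delta_Ri``    neutron destruction constant of the product (default 0)
    """

    delta_S: float
    lambda_total: float
    delta_Ri: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_S < 0 or self.lambda_total < 0 or self.delta_Ri < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def Lambda_Ri(self) -> float:
        """Product depression constant: decay plus destruction."""
        return self.lambda_total + self.delta_Ri

    @property
    def D(self) -> float:
        """Depression-to-burn-up ratio Lambda_Ri / delta_S."""
        if self.delta_S <= 0:
            raise ZeroDivisionError("D undefined for delta_S = 0")
        return self.Lambda_Ri / self.delta_S

    @property
    def is_degenerate(self) -> bool:
        scale = max(self.Lambda_Ri, self.delta_S)
        return scale == 0 or abs(self.Lambda_Ri - self.delta_S) / scale < _DEGENERATE_TOL

    # auxiliaries of the maximum-yield closed form (require D != 1)
    @property
    def f(self) -> float:
        return self.lambda_total / self.Lambda_Ri

    @property
    def p(self) -> float:
        d = self.D
        return 1.0 if self.is_degenerate else math.log(d) / (d - 1.0)

    @property
    def h(self) -> float:
        return self.D * self.p if not self.is_degenerate else 1.0

    @property
    def q(self) -> float:
        d = self.D
        if self.is_degenerate:
            raise ZeroDivisionError("q undefined at D = 1")
        return 1.0 / (1.0 - d)


def depletion_constant(channels: list[ReactionChannel], field: NeutronField) -> float:
    """Total burn-up constant phi_th * sum_i Omega_i (s^-1) of one nuclide.

    All channels must share the same parent.
    """
    if not channels:
        raise ValueError("at least one reaction channel is required")
    parents = {ch.parent.symbol for ch in channels}
    if len(parents) != 1:
        raise ValueError(f"channels mix parents: {sorted(parents)}")
    return field.phi_th * sum(omega(ch, field) for ch in channels) * BARN_CM2


def remaining_atoms(N0: float, delta_S: float, t) -> np.ndarray | float:
    """Un-burned target atoms N0 * exp(-delta_S * t)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("irradiation time must be non-negative")
    if N0 < 0:
        raise ValueError("N0 must be non-negative")
    out = N0 * np.exp(-delta_S * t_arr)
    return float(out) if t_arr.ndim == 0 else out


def burned_atoms(N0: float, delta_S: float, t) -> np.ndarray | float:
    """Burned target atoms N0 - remaining."""
    return N0 - remaining_atoms(N0, delta_S, t)


def half_burnup_time(delta_S: float) -> float:
    """Time at which half the target atoms are burned: ln2 / delta_S."""
    if delta_S <= 0:
        raise ValueError("delta_S must be positive")
    return LN2 / delta_S


def production_rate(omega_prod: float, field: NeutronField) -> float:
    """Per-atom production rate phi_th * Omega_prod (s^-1), Omega in barns."""
    if omega_prod < 0:
        raise ValueError("omega_prod must be non-negative")
    return field.phi_th * omega_prod * BARN_CM2


def product_atoms(N0: float, omega_prod: float, field: NeutronField,
                  consts: DepletionConstants, t_irr, t_c=0.0) -> np.ndarray | float:
    """Product atoms after irradiation t_irr and cooling t_c.

    N(t) = phi * Omega * N0 * (exp(-delta_S t) - exp(-Lambda t)) / (Lambda -
    delta_S), with the analytic limit at Lambda = delta_S; cooling applies
    exp(-lambda_total * t_c).
    """
    t_arr = np.asarray(t_irr, dtype=float)
    if np.any(t_arr < 0) or np.any(np.asarray(t_c) < 0):
        raise ValueError("times must be non-negative")
    rate = production_rate(omega_prod, field)
    out = rate * N0 * e2(consts.delta_S, consts.Lambda_Ri, t_arr)
    out = out * np.exp(-consts.lambda_total * np.asarray(t_c, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def product_activity(N0: float, omega_prod: float, field: NeutronField,
                     consts: DepletionConstants, t_irr, t_c=0.0) -> np.ndarray | float:
    """Product activity lambda_total * product_atoms (Bq)."""
    return consts.lambda_total * product_atoms(N0, omega_prod, field, consts, t_irr, t_c)


def time_of_max_yield(consts: DepletionConstants) -> float:
    """Irradiation time maximizing product activity:
    ln(Lambda / delta_S) / (Lambda - delta_S); 1/Lambda at D = 1."""
    lam, dlt = consts.Lambda_Ri, consts.delta_S
    if lam <= 0 or dlt <= 0:
        raise ValueError("both Lambda_Ri and delta_S must be positive")
    if consts.is_degenerate:
        return 1.0 / lam
    return math.log(lam / dlt) / (lam - dlt)


def max_yield(consts: DepletionConstants, N0: float, omega_prod: float,
              field: NeutronField) -> tuple[float, float]:
    """Maximum yield (atoms, Bq), i.e. the curve evaluated at its optimum."""
    t_star = time_of_max_yield(consts)
    n = product_atoms(N0, omega_prod, field, consts, t_star)
    return n, consts.lambda_total * n


def max_yield_via_auxiliaries(consts: DepletionConstants, N0: float,
                              omega_prod: float, field: NeutronField) -> tuple[float, float]:
    """Maximum yield through the (D, f, p, h, q) auxiliary closed form.

    Independent algebraic path used to cross-check :func:`max_yield`.
    """
    rate = production_rate(omega_prod, field)
    if consts.is_degenerate:
        n = rate * N0 * math.exp(-1.0) / consts.Lambda_Ri
        return n, consts.lambda_total * n
    d, p, h, q, f = consts.D, consts.p, consts.h, consts.q, consts.f
    n = rate * N0 * (math.exp(-p) - math.exp(-h)) / (consts.delta_S * (d - 1.0))
    a = rate * N0 * f * d * q * (math.exp(-h) - math.exp(-p))
    return n, a


@dataclass
class ActivationSeries:
    """Per-isotope atom/activity trajectories on a common time grid."""

    times: np.ndarray
    phase: np.ndarray  # "irradiation" | "cooling" per time point
    atoms: dict[str, np.ndarray] = dc_field(default_factory=dict)
    activities: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.phase) != n:
            raise ValueError("phase and times length mismatch")
        for name, arr in {**self.atoms, **self.activities}.items():
            if len(arr) != n:
                raise ValueError(f"series {name!r} length mismatch")
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"series {name!r} has negative entries")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, phase, isotope, atoms, activity_Bq."""
        rows = []
        for symbol in self.atoms:
            act = self.activities.get(symbol, np.zeros_like(self.times))
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": self.times,
                        "phase": self.phase,
                        "isotope": symbol,
                        "atoms": self.atoms[symbol],
                        "activity_Bq": act,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")
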