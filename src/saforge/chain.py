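"""Two-step production chains S (n,gamma) R_x (beta) R_i.

Closed forms for the three-state chain (carrier-free product), for the
impurity-driven in-growth of a stable carrier isotope during and after
irradiation, for the resulting SA, and for the SA of a mixture of
radioactive sources (isotopic dilution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kinetics import e2, e3, int_e2
from .constants import BARN_CM2
from .nuclear_data import Isotope, NeutronField

__all__ = [
    "ChainSystem",
    "RadioactiveSource",
    "chain_product_atoms",
    "chain_product_activity",
    "intermediate_yield",
    "branch_partial_activity",
    "stable_ingrowth",
    "sa_with_ingrowth",
    "mixture_sa",
]


@dataclass(frozen=True)
class ChainSystem:
    """One capture-then-decay chain parent -> intermediate -> product.

    ``omega_production`` (barns) is the capture channel feeding the
    intermediate; ``delta_parent`` (s^-1) the parent's total burn-up
    constant.  Neutron destruction of intermediate and product default to
    zero (settable for sensitivity studies).  ``branch_fraction`` is the
    share of intermediate decays that feed the product.
    """

    parent: Isotope
    intermediate: Isotope
    product: Isotope
    field: NeutronField
    omega_production: float
    delta_parent: float
    delta_intermediate: float = 0.0
    delta_product: float = 0.0
    branch_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.intermediate.is_stable:
            raise ValueError("chain intermediate must be radioactive")
        if self.omega_production < 0 or self.delta_parent < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.branch_fraction <= 1.0:
            raise ValueError("branch fraction out of [0, 1]")

    @property
    def production_rate(self) -> float:
        """phi_th * Omega_production in s^-1."""
        return self.field.phi_th * self.omega_production * BARN_CM2

    @property
    def Lambda_x(self) -> float:
        """Intermediate depression: decay plus neutron destruction."""
        return self.intermediate.lambda_total + self.delta_intermediate

    @property
    def Lambda_i(self) -> float:
        return self.product.lambda_total + self.delta_product

    @property
    def lambda_x_branch(self) -> float:
        """Partial decay constant of the intermediate feeding the product."""
        return self.branch_fraction * self.intermediate.lambda_total


def chain_product_atoms(system: ChainSystem, N0: float, t_irr, t_c=0.0):
    """Product atoms of the three-state chain after t_irr (+ cooling t_c).

    Three-exponential solution in (delta_parent, Lambda_x, Lambda_i);
    repeated-rate degeneracies are handled by the kernel's limit branches.
    Cooling multiplies by exp(-lambda_total_product * t_c).
    """
    t_arr = np.asarray(t_irr, dtype=float)
    if np.any(t_arr < 0) or np.any(np.asarray(t_c) < 0):
        raise ValueError("times must be non-negative")
    out = (
        system.lambda_x_branch
        * system.production_rate
        * N0
        * e3(system.delta_parent, system.Lambda_x, system.Lambda_i, t_arr)
    )
    out = out * np.exp(-system.product.lambda_total * np.asarray(t_c, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def chain_product_activity(system: ChainSystem, N0: float, t_irr, t_c=0.0):
    """Product activity lambda_total * atoms (Bq)."""
    return system.product.lambda_total * chain_product_atoms(system, N0, t_irr, t_c)


def intermediate_yield(system: ChainSystem, N0: float, t_irr):
    """Intermediate nuclide (atoms, Bq) at irradiation time t_irr."""
    t_arr = np.asarray(t_irr, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("irradiation time must be non-negative")
    atoms = system.production_rate * N0 * e2(system.delta_parent, system.Lambda_x, t_arr)
    act = system.intermediate.lambda_total * atoms
    if np.ndim(atoms) == 0:
        return float(atoms), float(act)
    return atoms, act


def branch_partial_activity(activity, branch_fraction: float):
    """Partial activity feeding one decay branch."""
    if not 0.0 <= branch_fraction <= 1.0:
        raise ValueError(f"branch fraction out of [0, 1]: {branch_fraction}")
    return activity * branch_fraction


def stable_ingrowth(system: ChainSystem, N0: float, t_irr, t_c=0.0):
    """Stable-carrier atoms grown from the chain during and after irradiation.

    In-pile part: integral of the branch decay rate of the intermediate
    over the irradiation.  Cooling part: the end-of-bombardment
    intermediate inventory decaying with its total decay constant, branch
    share collected.  Monotone non-decreasing in both times.
    """
    t_arr = np.asarray(t_irr, dtype=float)
    tc_arr = np.asarray(t_c, dtype=float)
    if np.any(t_arr < 0) or np.any(tc_arr < 0):
        raise ValueError("times must be non-negative")
    rate = system.production_rate * N0
    during = system.lambda_x_branch * rate * int_e2(system.delta_parent, system.Lambda_x, t_arr)
    n_x_eob = rate * np.asarray(e2(system.delta_parent, system.Lambda_x, t_arr))
    lam_x = system.intermediate.lambda_total
    after = system.branch_fraction * n_x_eob * (-np.expm1(-lam_x * tc_arr))
    out = during + after
    return float(out) if np.ndim(out) == 0 else out


def sa_with_ingrowth(system_main: ChainSystem, system_impurity: ChainSystem,
                     N0_main: float, N0_imp: float, t_irr, t_c=0.0):
    """SA (atom %) of the chain product diluted by in-grown stable carrier.

    Both systems must produce isotopes of the same element.  At zero
    inventory (t_irr = 0) the carrier-free limit 100 atom % is returned.
    """
    if system_main.product.element != system_impurity.product.element:
        raise ValueError("chain products belong to different elements")
    n_ri = np.asarray(chain_product_atoms(system_main, N0_main, t_irr, t_c))
    n_sg = np.asarray(stable_ingrowth(system_impurity, N0_imp, t_irr, t_c))
    total = n_ri + n_sg
    sa = np.where(total > 0, 100.0 * n_ri / np.where(total > 0, total, 1.0), 100.0)
    return float(sa) if np.ndim(sa) == 0 else sa


@dataclass(frozen=True)
class RadioactiveSource:
    """One source entering a mixture: quantity (hot atoms or Bq, one unit
    across the mixture) and its SA in atom %."""

    label: str
    quantity: float
    sa: float

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"{self.label}: quantity must be >= 0")
        if not 0.0 <= self.sa <= 100.0:
            raise ValueError(f"{self.label}: SA out of [0, 100] atom %")


def mixture_sa(sources) -> float:
    """SA (atom %) of pooled radioactive sources.

    SA_mix = sum(q_j) / sum(q_j / SA_j); the quantity unit (hot atoms or
    activity of the same radioisotope) cancels.  A source with SA = 0
    carries stable atoms but no quantity handle — fold its stable pool
    into another source first.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("mixture needs at least one source")
    for s in sources:
        if s.sa == 0.0:
            raise ValueError(
                f"source {s.label!r} has SA = 0; combine its stable atoms "
                "with a source of nonzero SA before mixing"
            )
    live = [s for s in sources if s.quantity > 0]
    if not live:
        raise ValueError("all sources have zero quantity; mixture SA undefined")
    total = sum(s.quantity for s in live)
    return total / sum(s.quantity / s.sa for s in live)
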