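"""Specific radioactivity: definitions, unit conversions, target formulas.

SA here is primarily "atom %": hot atoms of the radioisotope per hundred
atoms of its chemical element (hot atoms included in the denominator).  A
carrier-free radioisotope therefore has SA = 100 atom %.  Conversions to
Bq/mol and Bq/g follow from the decay constant and the material's mean
atomic mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import activation
from .constants import AVOGADRO, BARN_CM2
from .nuclear_data import (
    Isotope,
    NeutronField,
    ReactionChannel,
    TargetSpec,
    material_mean_mass,
)
from .spectrum import omega

__all__ = [
    "SpecificActivity",
    "sa_atom_percent",
    "convert_sa",
    "atom_percent_from_bq_per_g",
    "material_atomic_weight",
    "sa_general",
    "sa_two_isotope",
    "sa_one_isotope",
    "multi_as_two",
    "time_of_max_sa",
    "sa_at_max_yield",
    "sa_at_max_yield_via_auxiliaries",
    "MaxSaNotBracketedError",
]


class MaxSaNotBracketedError(RuntimeError):
    """Root search for the SA maximum failed after a bracket was found."""


@dataclass(frozen=True)
class SpecificActivity:
    """SA value with optional mass/mole-basis conversions."""

    atom_percent: float
    bq_per_g: float | None = None
    bq_per_mol: float | None = None
    reference_symbol: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.atom_percent <= 100.0 + 1e-9:
            raise ValueError(f"atom percent out of [0, 100]: {self.atom_percent}")


def sa_atom_percent(hot_atoms: float, element_atoms: float) -> float:
    """SA in atom %: 100 * hot / element atoms."""
    if element_atoms <= 0:
        raise ZeroDivisionError("SA undefined: no element atoms present")
    if hot_atoms < 0 or hot_atoms > element_atoms * (1 + 1e-12):
        raise ValueError("hot atoms must lie in [0, element atoms]")
    return 100.0 * hot_atoms / element_atoms


def convert_sa(atom_percent: float, material_atomic_weight: float,
               lambda_total: float, avogadro: float = AVOGADRO,
               reference_symbol: str | None = None) -> SpecificActivity:
    """Fill in Bq/mol and Bq/g for an atom-% SA value.

    Bq/mol = (atom%/100) * lambda * N_A;  Bq/g = Bq/mol / M.
    """
    if material_atomic_weight <= 0:
        raise ValueError("atomic weight must be positive")
    if lambda_total <= 0 and atom_percent > 0:
        raise ValueError("a stable reference isotope has no Bq-basis SA")
    bq_per_mol = atom_percent / 100.0 * lambda_total * avogadro
    return SpecificActivity(
        atom_percent=atom_percent,
        bq_per_mol=bq_per_mol,
        bq_per_g=bq_per_mol / material_atomic_weight,
        reference_symbol=reference_symbol,
    )


def atom_percent_from_bq_per_g(bq_per_g: float, material_atomic_weight: float,
                               lambda_total: float, avogadro: float = AVOGADRO) -> float:
    """Inverse of :func:`convert_sa` (round-trips are identity)."""
    if lambda_total <= 0:
        raise ValueError("lambda_total must be positive")
    return 100.0 * bq_per_g * material_atomic_weight / (lambda_total * avogadro)


def material_atomic_weight(isotopes) -> float:
    """Mean atomic mass from (weight %, g/mol) pairs or Isotope objects:
    (sum P) / sum(P / M)."""
    pairs = []
    for item in isotopes:
        if isinstance(item, Isotope):
            pairs.append((item.weight_percent, item.atomic_mass))
        else:
            pairs.append((float(item[0]), float(item[1])))
    total = sum(p for p, _ in pairs)
    if total <= 0:
        raise ValueError("weight percents sum to zero")
    for _, m in pairs:
        if m <= 0:
            raise ValueError("atomic masses must be positive")
    return total / sum(p / m for p, m in pairs)


# ---------------------------------------------------------------------------
# target SA closed forms


def _production_channel(target: TargetSpec, channels,
                        production_channel: ReactionChannel | None) -> ReactionChannel:
    if production_channel is not None:
        return production_channel
    symbols = {iso.symbol for iso in target.isotopes}
    for ch in channels:
        if ch.parent.symbol in symbols and not ch.product.is_stable:
            return ch
    raise ValueError("no channel with a radioactive product found; pass production_channel")


@dataclass(frozen=True)
class _TargetModel:
    """Resolved rates and initial atom numbers of a simple target."""

    primary: Isotope
    others: tuple[Isotope, ...]
    product: Isotope
    delta_primary: float          # full isotope burn-up of S1
    delta_others: tuple[float, ...]  # element-depleting burn-up per impurity
    omega_prod: float             # barns, production channel
    consts: activation.DepletionConstants
    n0_primary: float
    n0_others: tuple[float, ...]
    field: NeutronField

    def element_atoms(self, t):
        """Element pool excluding product atoms: sum of stable-isotope
        survivors (captured-but-undecayed side products are ignored)."""
        total = activation.remaining_atoms(self.n0_primary, self.delta_primary, t)
        for n0, d in zip(self.n0_others, self.delta_others):
            total = total + activation.remaining_atoms(n0, d, t)
        return total

    def d_element_atoms(self, t):
        out = -self.delta_primary * activation.remaining_atoms(
            self.n0_primary, self.delta_primary, t
        )
        for n0, d in zip(self.n0_others, self.delta_others):
            out = out - d * activation.remaining_atoms(n0, d, t)
        return out

    def product_atoms(self, t, t_c=0.0):
        return activation.product_atoms(
            self.n0_primary, self.omega_prod, self.field, self.consts, t, t_c
        )


def _build_model(target: TargetSpec, channels, field: NeutronField,
                 delta_Ri: float = 0.0,
                 production_channel: ReactionChannel | None = None,
                 avogadro: float = AVOGADRO) -> _TargetModel:
    prod_ch = _production_channel(target, channels, production_channel)
    primary = target.isotope(prod_ch.parent.symbol)
    others = tuple(i for i in target.isotopes if i.symbol != primary.symbol)

    primary_channels = [ch for ch in channels if ch.parent.symbol == primary.symbol]
    delta_primary = activation.depletion_constant(primary_channels, field)

    delta_others = []
    for iso in others:
        chs = [
            ch
            for ch in channels
            if ch.parent.symbol == iso.symbol and not ch.element_preserving
        ]
        delta_others.append(
            field.phi_th * sum(omega(ch, field) for ch in chs) * BARN_CM2 if chs else 0.0
        )

    consts = activation.DepletionConstants(
        delta_S=delta_primary,
        lambda_total=prod_ch.product.lambda_total,
        delta_Ri=delta_Ri,
    )
    return _TargetModel(
        primary=primary,
        others=others,
        product=prod_ch.product,
        delta_primary=delta_primary,
        delta_others=tuple(delta_others),
        omega_prod=omega(prod_ch, field),
        consts=consts,
        n0_primary=target.initial_atoms(primary.symbol, avogadro),
        n0_others=tuple(target.initial_atoms(i.symbol, avogadro) for i in others),
        field=field,
    )


def _sa_curve(model: _TargetModel, t, t_c=0.0):
    n_ri = model.product_atoms(t, t_c)
    n_stable = model.element_atoms(t)
    return 100.0 * n_ri / (n_stable + n_ri), n_ri, n_stable


def sa_general(target: TargetSpec, channels, field: NeutronField, t_irr,
               t_c=0.0, delta_Ri: float = 0.0,
               production_channel: ReactionChannel | None = None,
               avogadro: float = AVOGADRO):
    """SA (atom %) of the product in a simple multi-isotope target.

    Each non-primary isotope depletes only through its element-depleting
    channels (zero when it has none, per the convention that captures
    yielding stable isotopes of the target element do not remove element
    atoms).  Scalar ``t_irr`` returns a :class:`SpecificActivity` with
    Bq-basis conversions; an array returns the atom-% curve.
    """
    model = _build_model(target, channels, field, delta_Ri, production_channel, avogadro)
    scalar = np.ndim(t_irr) == 0 and np.ndim(t_c) == 0
    sa_pct, n_ri, n_stable = _sa_curve(model, t_irr, t_c)
    if not scalar:
        return np.asarray(sa_pct)
    if n_ri + n_stable <= 0:
        return SpecificActivity(0.0, reference_symbol=model.product.symbol)
    # atom-weighted mean mass of the element pool for Bq/g conversion
    per_iso = [
        (
            activation.remaining_atoms(model.n0_primary, model.delta_primary, t_irr),
            model.primary.atomic_mass,
        )
    ]
    for iso, n0, d in zip(model.others, model.n0_others, model.delta_others):
        per_iso.append((activation.remaining_atoms(n0, d, t_irr), iso.atomic_mass))
    per_iso.append((n_ri, model.product.atomic_mass))
    atoms_total = sum(n for n, _ in per_iso)
    m_bar = sum(n * m for n, m in per_iso) / atoms_total
    return convert_sa(
        float(sa_pct), m_bar, model.product.lambda_total, avogadro,
        reference_symbol=model.product.symbol,
    )


def sa_two_isotope(target: TargetSpec, channels, field: NeutronField, t_irr,
                   t_c=0.0, delta_Ri: float = 0.0,
                   production_channel: ReactionChannel | None = None,
                   avogadro: float = AVOGADRO):
    """SA of the product in a two-stable-isotope target (or one reduced via
    :func:`multi_as_two`)."""
    if len(target.isotopes) != 2:
        raise ValueError(
            f"target has {len(target.isotopes)} stable isotopes; reduce it "
            "with multi_as_two or use sa_general"
        )
    return sa_general(target, channels, field, t_irr, t_c, delta_Ri,
                      production_channel, avogadro)


def sa_one_isotope(target: TargetSpec, channels, field: NeutronField, t_irr,
                   t_c=0.0, delta_Ri: float = 0.0,
                   production_channel: ReactionChannel | None = None,
                   avogadro: float = AVOGADRO):
    """SA in a single-isotope (100% enriched) target: strictly increasing
    in irradiation time, no interior maximum."""
    if len(target.isotopes) != 1:
        raise ValueError("target must have exactly one stable isotope")
    return sa_general(target, channels, field, t_irr, t_c, delta_Ri,
                      production_channel, avogadro)


def multi_as_two(target: TargetSpec, primary: str | None = None,
                 channels=None, tolerance_barns: float = 0.01) -> TargetSpec:
    """Collapse all non-primary isotopes into one combined impurity block.

    The combined block carries the summed weight percent and the harmonic
    mean atomic mass.  Requires non-depleting impurities: if ``channels``
    are supplied, any impurity with an element-depleting cross-section above
    ``tolerance_barns`` causes a refusal (use the general formula instead).
    """
    primary_symbol = primary or target.isotopes[0].symbol
    primary_iso = target.isotope(primary_symbol)
    others = [i for i in target.isotopes if i.symbol != primary_symbol]
    if len(others) <= 1:
        return target
    if channels is not None:
        for iso in others:
            depleting = sum(
                ch.sigma0
                for ch in channels
                if ch.parent.symbol == iso.symbol and not ch.element_preserving
            )
            if depleting > tolerance_barns:
                raise ValueError(
                    f"impurity {iso.symbol} depletes the element "
                    f"(sigma0 sum {depleting} b); use sa_general"
                )
    p_imp = sum(i.weight_percent for i in others)
    m_imp = material_atomic_weight(others)
    combined = Isotope(
        symbol=f"{target.element}-imp",
        atomic_mass=m_imp,
        half_life_s=None,
        weight_percent=p_imp,
    )
    return replace(target, isotopes=(primary_iso, combined))


def time_of_max_sa(target: TargetSpec, channels, field: NeutronField,
                   delta_Ri: float = 0.0,
                   production_channel: ReactionChannel | None = None,
                   avogadro: float = AVOGADRO,
                   horizon_half_burnups: float = 20.0) -> float | None:
    """Irradiation time of the interior SA maximum, or ``None``.

    The SA derivative changes sign where N'_Ri * N_stable = N_Ri *
    N'_stable (product terms cancel).  A log-spaced sign scan over
    [0, horizon * T_half-burn-up] seeds a bracketed root refinement.
    Returns ``None`` for a one-isotope target or when no sign change
    occurs within the horizon (monotone SA).
    """
    model = _build_model(target, channels, field, delta_Ri, production_channel, avogadro)
    if not model.others or sum(model.n0_others) == 0.0:
        return None

    rate = activation.production_rate(model.omega_prod, field)

    def dsa_sign(t):
        n_ri = model.product_atoms(t)
        n_s = model.element_atoms(t)
        n_s1 = activation.remaining_atoms(model.n0_primary, model.delta_primary, t)
        d_ri = rate * n_s1 - model.consts.Lambda_Ri * n_ri
        return d_ri * n_s - n_ri * model.d_element_atoms(t)

    t_hi = horizon_half_burnups * activation.half_burnup_time(model.delta_primary)
    grid = np.geomspace(t_hi * 1e-6, t_hi, 400)
    vals = np.array([dsa_sign(t) for t in grid])
    neg = np.nonzero(vals <= 0)[0]
    if len(neg) == 0:
        return None
    i = neg[0]
    if i == 0:
        # derivative non-positive from the start: no interior maximum
        return None
    lo, hi = grid[i - 1], grid[i]
    try:
        return float(brentq(dsa_sign, lo, hi, xtol=1e-12, rtol=1e-8))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise MaxSaNotBracketedError(
            f"bracket [{lo:.6g}, {hi:.6g}] s found but refinement failed"
        ) from exc


def sa_at_max_yield(target: TargetSpec, channels, field: NeutronField,
                    delta_Ri: float = 0.0,
                    production_channel: ReactionChannel | None = None,
                    avogadro: float = AVOGADRO) -> SpecificActivity:
    """SA evaluated at the irradiation time of maximum product yield."""
    model = _build_model(target, channels, field, delta_Ri, production_channel, avogadro)
    t_star = activation.time_of_max_yield(model.consts)
    return sa_general(target, channels, field, t_star, 0.0, delta_Ri,
                      production_channel, avogadro)


def sa_at_max_yield_via_auxiliaries(target: TargetSpec, channels,
                                    field: NeutronField, delta_Ri: float = 0.0,
                                    production_channel: ReactionChannel | None = None,
                                    avogadro: float = AVOGADRO) -> float:
    """Atom-% SA at maximum yield through the (D, p, h) auxiliary form.

    At t* = ln(D)/(Lambda - delta):  exp(-delta t*) = exp(-p) and
    exp(-Lambda t*) = exp(-h), so every term of the SA quotient reduces to
    the auxiliaries.  Independent algebraic path for cross-checks.
    """
    model = _build_model(target, channels, field, delta_Ri, production_channel, avogadro)
    c = model.consts
    rate = activation.production_rate(model.omega_prod, field)
    if c.is_degenerate:
        n_ri = rate * model.n0_primary * math.exp(-1.0) / c.Lambda_Ri
        n_s1 = model.n0_primary * math.exp(-1.0)
    else:
        e_p, e_h = math.exp(-c.p), math.exp(-c.h)
        n_ri = rate * model.n0_primary * (e_p - e_h) / (c.delta_S * (c.D - 1.0))
        n_s1 = model.n0_primary * e_p
    t_star = activation.time_of_max_yield(c)
    n_others = sum(
        activation.remaining_atoms(n0, d, t_star)
        for n0, d in zip(model.n0_others, model.delta_others)
    )
    return 100.0 * n_ri / (n_s1 + n_others + n_ri)
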