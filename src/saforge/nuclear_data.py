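"""Domain types and bundled nuclear-data fixtures.

Fixtures are plain YAML files under :mod:`saforge.data`, one per target
(see that directory's ``README`` for the schema).  Each fixture bundles a
target composition with the neutron reaction channels of its nuclides.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import yaml

from .constants import LN2

__all__ = [
    "DecayBranch",
    "Isotope",
    "ReactionChannel",
    "NeutronField",
    "ElementalImpurity",
    "TargetSpec",
    "FixtureNotFoundError",
    "load_fixture",
    "fixture_names",
    "parse_half_life",
    "barns_to_cm2",
]

_TIME_UNITS = {"s": 1.0, "m": 60.0, "h": 3600.0, "d": 86400.0, "y": 365.25 * 86400.0}

#: Atomic mass of oxygen used for oxide stoichiometry (g/mol).
OXYGEN_MASS = 15.999


class FixtureNotFoundError(KeyError):
    """Raised when a named nuclear-data fixture does not exist."""


def parse_half_life(text: str | float) -> float | None:
    """Parse a half-life written as e.g. ``"6.71d"``, ``"1.9h"``, ``"32d"``.

    Returns seconds, or ``None`` for the marker ``"stable"``.  Bare numbers
    are taken as seconds.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip().lower()
    if s == "stable":
        return None
    match = re.fullmatch(r"([0-9.eE+\-]+)\s*([smhdy]?)", s)
    if not match:
        raise ValueError(f"unparseable half-life: {text!r}")
    value = float(match.group(1))
    unit = match.group(2) or "s"
    if value <= 0:
        raise ValueError(f"half-life must be positive: {text!r}")
    return value * _TIME_UNITS[unit]


def barns_to_cm2(sigma: float) -> float:
    """Convert a cross-section from barns to cm^2 (1 b = 1e-24 cm^2)."""
    if sigma < 0:
        raise ValueError(f"cross-section must be non-negative, got {sigma}")
    return sigma * 1.0e-24


@dataclass(frozen=True)
class DecayBranch:
    """One decay branch with its fractional intensity."""

    label: str
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"branch fraction out of [0, 1]: {self.fraction}")


@dataclass(frozen=True)
class Isotope:
    """A nuclide: identity, mass, decay data, and share of its target.

    ``half_life_s`` is ``None`` for stable nuclides.  ``weight_percent`` is
    the weight share of this isotope within its chemical element in the
    target (enrichment tables round, so sums are checked to 0.1).
    """

    symbol: str
    atomic_mass: float
    half_life_s: float | None = None
    branches: tuple[DecayBranch, ...] = (DecayBranch("decay"),)
    weight_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.atomic_mass <= 0:
            raise ValueError(f"{self.symbol}: atomic mass must be positive")
        if self.half_life_s is not None and self.half_life_s <= 0:
            raise ValueError(f"{self.symbol}: half-life must be positive")
        if self.weight_percent < 0:
            raise ValueError(f"{self.symbol}: weight percent must be >= 0")
        total = sum(b.fraction for b in self.branches)
        if self.branches and not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"{self.symbol}: branch fractions sum to {total}, not 1")

    @property
    def is_stable(self) -> bool:
        return self.half_life_s is None

    @property
    def lambda_total(self) -> float:
        """Total decay constant ln2 / T1/2 in s^-1 (0 for stable)."""
        if self.half_life_s is None:
            return 0.0
        return LN2 / self.half_life_s

    @property
    def decay_constants(self) -> tuple[tuple[str, float], ...]:
        """Per-branch decay constants (label, lambda_branch)."""
        lam = self.lambda_total
        return tuple((b.label, b.fraction * lam) for b in self.branches)

    @property
    def element(self) -> str:
        return self.symbol.split("-")[0]


@dataclass(frozen=True)
class ReactionChannel:
    """One neutron reaction channel of a target nuclide.

    ``element_preserving`` marks channels whose product chain stays within
    the parent's chemical element as a stable isotope (such captures do not
    deplete the element pool that enters specific-activity denominators).
    """

    parent: Isotope
    product: Isotope
    sigma0: float
    I0: float = 0.0
    sigma_fast: float = 0.0
    kind: str = "n-gamma"
    non_1v: bool = False
    k_factor: float = 1.0
    element_preserving: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.I0 < 0 or self.sigma_fast < 0:
            raise ValueError(f"{self.label or self.parent.symbol}: negative cross-section")
        if self.k_factor <= 0:
            raise ValueError("k_factor must be positive")
        if self.kind not in ("n-gamma", "n-alpha", "n-p"):
            raise ValueError(f"unknown reaction kind: {self.kind}")


@dataclass(frozen=True)
class NeutronField:
    """Reactor neutron field description.

    ``R_epi`` is the epithermal-to-thermal flux ratio (the Hogdahl f_H);
    ``alpha`` is the epithermal spectrum shape parameter.
    """

    phi_th: float
    R_epi: float = 0.0
    R_fast: float = 0.0
    alpha: float = 0.0
    E_Cd: float = 0.55
    E0: float = 0.0253

    def __post_init__(self) -> None:
        if self.phi_th <= 0:
            raise ValueError("phi_th must be positive")
        if self.R_epi < 0 or self.R_fast < 0:
            raise ValueError("flux ratios must be non-negative")
        if self.E_Cd <= 0:
            raise ValueError("E_Cd must be positive")

    @property
    def f_H(self) -> float:
        """Hogdahl epithermal/thermal flux ratio (alias of R_epi)."""
        return self.R_epi


@dataclass(frozen=True)
class ElementalImpurity:
    """Trace element in the target: ppm by mass of the target element,
    with assumed isotopic weight percents (``None`` if not modelled)."""

    element: str
    ppm: float
    abundances: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.ppm < 0:
            raise ValueError("ppm must be >= 0")


@dataclass(frozen=True)
class TargetSpec:
    """An irradiation target: mass, element, isotope set, impurities."""

    mass_g: float
    element: str
    isotopes: tuple[Isotope, ...]
    elemental_impurities: tuple[ElementalImpurity, ...] = ()
    oxide_stoichiometry: tuple[int, int] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("target mass must be positive")
        total = sum(iso.weight_percent for iso in self.isotopes)
        if abs(total - 100.0) > 0.1:
            raise ValueError(
                f"target {self.name or self.element}: isotope weight percents "
                f"sum to {total}, expected 100 +/- 0.1"
            )

    def isotope(self, symbol: str) -> Isotope:
        for iso in self.isotopes:
            if iso.symbol == symbol:
                return iso
        raise KeyError(f"no isotope {symbol} in target {self.name or self.element}")

    @property
    def element_mass_g(self) -> float:
        """Mass of the target element.

        For an oxide target (stoichiometry (n_metal, n_oxygen)) the metal
        share of the oxide mass is used; otherwise the full target mass.
        """
        if self.oxide_stoichiometry is None:
            return self.mass_g
        n_m, n_o = self.oxide_stoichiometry
        m_bar = material_mean_mass(self.isotopes)
        frac = n_m * m_bar / (n_m * m_bar + n_o * OXYGEN_MASS)
        return self.mass_g * frac

    def initial_atoms(self, symbol: str, avogadro: float) -> float:
        """N0 of one isotope: N_A * m_element * P / (100 * M)."""
        iso = self.isotope(symbol)
        return avogadro * self.element_mass_g * iso.weight_percent / (100.0 * iso.atomic_mass)

    def with_percents(self, percents: dict[str, float]) -> "TargetSpec":
        """Copy of the target with overridden isotope weight percents.

        Isotopes set to 0 are dropped.
        """
        new = []
        for iso in self.isotopes:
            p = percents.get(iso.symbol, iso.weight_percent)
            if p > 0:
                new.append(replace(iso, weight_percent=p))
        return replace(self, isotopes=tuple(new))


def material_mean_mass(isotopes: Iterable[Isotope]) -> float:
    """Mean atomic mass of an isotope mixture from weight percents:
    (sum P) / sum(P / M)."""
    isotopes = list(isotopes)
    total_p = sum(i.weight_percent for i in isotopes)
    if total_p <= 0:
        raise ValueError("weight percents sum to zero")
    return total_p / sum(i.weight_percent / i.atomic_mass for i in isotopes)


# ---------------------------------------------------------------------------
# fixture loading


def fixture_names() -> tuple[str, ...]:
    root = resources.files("saforge.data")
    return tuple(sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml")))


def _build_isotope(raw: dict) -> Isotope:
    branches = tuple(
        DecayBranch(b["label"], float(b.get("fraction", 1.0)))
        for b in raw.get("branches", [{"label": "decay", "fraction": 1.0}])
    )
    return Isotope(
        symbol=raw["symbol"],
        atomic_mass=float(raw["atomic_mass"]),
        half_life_s=parse_half_life(raw.get("half_life", "stable")),
        branches=branches,
        weight_percent=float(raw.get("weight_percent", 0.0)),
    )


def load_fixture(name: str) -> tuple[TargetSpec, list[ReactionChannel]]:
    """Load a bundled target fixture by name.

    Returns the target specification and all reaction channels of its
    nuclides.  Raises :class:`FixtureNotFoundError` for unknown names.
    """
    root = resources.files("saforge.data")
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except (FileNotFoundError, OSError) as exc:
        raise FixtureNotFoundError(
            f"no fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from exc
    raw = yaml.safe_load(text)

    registry: dict[str, Isotope] = {}
    target_isotopes = []
    for iso_raw in raw["isotopes"]:
        iso = _build_isotope(iso_raw)
        registry[iso.symbol] = iso
        target_isotopes.append(iso)
    for iso_raw in raw.get("products", []):
        iso = _build_isotope(iso_raw)
        registry.setdefault(iso.symbol, iso)

    impurities = tuple(
        ElementalImpurity(
            element=imp["element"],
            ppm=float(imp["ppm"]),
            abundances=tuple((k, float(v)) for k, v in imp["abundances"].items())
            if imp.get("abundances")
            else None,
        )
        for imp in raw.get("elemental_impurities", [])
    )

    target = TargetSpec(
        mass_g=float(raw.get("mass_g", 1.0e-3)),
        element=raw["element"],
        isotopes=tuple(target_isotopes),
        elemental_impurities=impurities,
        oxide_stoichiometry=tuple(raw["oxide_stoichiometry"])
        if raw.get("oxide_stoichiometry")
        else None,
        name=raw.get("name", name),
    )

    channels = []
    for ch in raw.get("channels", []):
        channels.append(
            ReactionChannel(
                parent=registry[ch["parent"]],
                product=registry[ch["product"]],
                sigma0=float(ch["sigma0"]),
                I0=float(ch.get("I0", 0.0)),
                sigma_fast=float(ch.get("sigma_fast", 0.0)),
                kind=ch.get("kind", "n-gamma"),
                non_1v=bool(ch.get("non_1v", False)),
                k_factor=float(ch.get("k_factor", 1.0)),
                element_preserving=bool(ch.get("element_preserving", False)),
                label=ch.get("label", ""),
            )
        )
    return target, channels
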