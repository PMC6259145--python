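"""Pre-wired Lu-177 production scenarios.

Two routes are bundled: direct activation of an enriched Lu-176 target
(Westcott k-factor 1.74, Lu-175 impurity non-depleting) and the indirect
route through an enriched Yb-176 target, where the carrier-free chain
product is diluted by Lu-175 in-growth from the Yb-174 impurity and by
direct activation of the elemental Lu contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from . import activation, specific_activity as sa_mod
from .activation import ActivationSeries, DepletionConstants
from .chain import ChainSystem, RadioactiveSource, chain_product_atoms, mixture_sa, stable_ingrowth
from .constants import BARN_CM2, avogadro as _avogadro
from .nuclear_data import NeutronField, TargetSpec, load_fixture
from .spectrum import omega

__all__ = ["ScenarioResult", "direct_route", "flux_scan", "flux_scan_argmax", "indirect_route"]

DEFAULT_R_EPI = 0.02
#: default cooling before reporting the indirect-route product (lets the
#: short-lived intermediate decay out).
DEFAULT_INDIRECT_COOLING_S = 24 * 3600.0
DEFAULT_FLUX_GRID = tuple(np.geomspace(5e13, 1e15, 12))


@dataclass
class ScenarioResult:
    """Outputs of one scenario run."""

    series: ActivationSeries | None
    sa_series: pd.DataFrame
    t_yield_max: float | None
    t_sa_max: float | None
    sources: list[RadioactiveSource] = dc_field(default_factory=list)
    extras: dict = dc_field(default_factory=dict)

    @property
    def ratio(self) -> float | None:
        """t_sa_max / t_yield_max when both are defined."""
        if self.t_sa_max is None or self.t_yield_max is None:
            return None
        return self.t_sa_max / self.t_yield_max


def _direct_target(enrichment: float, mass_g: float) -> tuple[TargetSpec, list]:
    if not 0.0 < enrichment <= 100.0:
        raise ValueError("enrichment must be in (0, 100]")
    target, channels = load_fixture("lu176_enriched")
    target = replace(target, mass_g=mass_g).with_percents(
        {"Lu-176": enrichment, "Lu-175": 100.0 - enrichment}
    )
    return target, channels


def direct_route(enrichment: float, phi_th: float, t_grid=None,
                 R_epi: float = DEFAULT_R_EPI, t_c: float = 0.0,
                 mass_g: float = 1.0e-3, replication: bool = False) -> ScenarioResult:
    """Direct-route scenario: Lu-176(n,gamma)Lu-177 in an enriched target.

    Returns target depletion, product build-up, the SA curve, and the two
    characteristic optimization times (an enrichment of 100 has no SA
    maximum).
    """
    avo = _avogadro(replication)
    target, channels = _direct_target(enrichment, mass_g)
    field = NeutronField(phi_th, R_epi=R_epi)
    prod_ch = channels[0]  # Lu-176 -> Lu-177 capture

    parent_channels = [ch for ch in channels if ch.parent.symbol == "Lu-176"]
    delta_s1 = activation.depletion_constant(parent_channels, field)
    consts = DepletionConstants(delta_s1, prod_ch.product.lambda_total)
    n0 = target.initial_atoms("Lu-176", avo)

    t_yield = activation.time_of_max_yield(consts)
    t_sa = sa_mod.time_of_max_sa(target, channels, field, avogadro=avo)

    if t_grid is None:
        t_end = 2.0 * t_sa if t_sa is not None else 6.0 * t_yield
        t_grid = np.linspace(0.0, t_end, 241)
    t_grid = np.asarray(t_grid, dtype=float)

    n_s1 = activation.remaining_atoms(n0, delta_s1, t_grid)
    n_ri = activation.product_atoms(n0, omega(prod_ch, field), field, consts, t_grid, t_c)
    a_ri = consts.lambda_total * n_ri
    series = ActivationSeries(
        times=t_grid,
        phase=np.full(t_grid.shape, "irradiation", dtype=object),
        atoms={"Lu-176": np.asarray(n_s1), "Lu-177": np.asarray(n_ri)},
        activities={"Lu-177": np.asarray(a_ri)},
    )

    sa_pct = sa_mod.sa_general(target, channels, field, t_grid, t_c, avogadro=avo)
    bq_per_g = np.array(
        [
            s.bq_per_g if s.bq_per_g is not None else 0.0
            for s in (
                sa_mod.sa_general(target, channels, field, float(t), t_c, avogadro=avo)
                for t in t_grid
            )
        ]
    )
    sa_series = pd.DataFrame(
        {"time_s": t_grid, "sa_atom_percent": sa_pct, "sa_bq_per_g": bq_per_g}
    )
    sa_max = None
    if t_sa is not None:
        sa_max = float(sa_mod.sa_general(target, channels, field, np.array([t_sa]))[0])
    return ScenarioResult(
        series=series,
        sa_series=sa_series,
        t_yield_max=t_yield,
        t_sa_max=t_sa,
        extras={
            "enrichment": enrichment,
            "phi_th": phi_th,
            "delta_S1": delta_s1,
            "Lambda_Ri": consts.Lambda_Ri,
            "sa_max_atom_percent": sa_max,
        },
    )


def flux_scan(enrichments=(60.0, 74.1, 90.0, 99.9), phi_grid=None,
              R_epi: float = DEFAULT_R_EPI, mass_g: float = 1.0e-3,
              replication: bool = False) -> pd.DataFrame:
    """Optimization-time ratio and peak SA over a (enrichment, flux) grid.

    One row per cell: t_yield_max, t_sa_max (NaN when the SA curve is
    monotone), their ratio, and the SA at its maximum.
    """
    avo = _avogadro(replication)
    if phi_grid is None:
        phi_grid = DEFAULT_FLUX_GRID
    phi_grid = list(phi_grid)
    enrichments = list(enrichments)
    if not phi_grid or not enrichments:
        raise ValueError("grids must be non-empty")

    rows = []
    for enr in enrichments:
        target, channels = _direct_target(enr, mass_g)
        for phi in phi_grid:
            field = NeutronField(phi, R_epi=R_epi)
            parent_channels = [ch for ch in channels if ch.parent.symbol == "Lu-176"]
            delta_s1 = activation.depletion_constant(parent_channels, field)
            consts = DepletionConstants(delta_s1, channels[0].product.lambda_total)
            t_yield = activation.time_of_max_yield(consts)
            t_sa = sa_mod.time_of_max_sa(target, channels, field, avogadro=avo)
            sa_max = np.nan
            if t_sa is not None:
                sa_max = float(sa_mod.sa_general(target, channels, field, np.array([t_sa]))[0])
            rows.append(
                {
                    "enrichment": enr,
                    "phi_th": phi,
                    "t_yield_max_s": t_yield,
                    "t_sa_max_s": t_sa if t_sa is not None else np.nan,
                    "ratio": (t_sa / t_yield) if t_sa is not None else np.nan,
                    "sa_max_atom_percent": sa_max,
                }
            )
    return pd.DataFrame(rows)


def flux_scan_argmax(table: pd.DataFrame) -> pd.DataFrame:
    """Per enrichment, the grid flux maximizing t_sa_max / t_yield_max."""
    rows = []
    for enr, grp in table.groupby("enrichment"):
        valid = grp.dropna(subset=["ratio"])
        if valid.empty:
            continue
        rows.append(valid.loc[valid["ratio"].idxmax()])
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# indirect route


def _indirect_systems(target: TargetSpec, yb_channels, field: NeutronField):
    """Build the main (Yb-176) and impurity (Yb-174) chain systems."""
    lu_nat, lu_channels = load_fixture("lu_natural")
    lu177 = lu_channels[0].product
    lu175 = lu_nat.isotope("Lu-175")
    ch_main = next(ch for ch in yb_channels if ch.parent.symbol == "Yb-176")
    ch_imp = next(ch for ch in yb_channels if ch.parent.symbol == "Yb-174")

    main = ChainSystem(
        parent=ch_main.parent,
        intermediate=ch_main.product,
        product=lu177,
        field=field,
        omega_production=omega(ch_main, field),
        delta_parent=field.phi_th * omega(ch_main, field) * BARN_CM2,
    )
    imp = ChainSystem(
        parent=ch_imp.parent,
        intermediate=ch_imp.product,
        product=lu175,
        field=field,
        omega_production=omega(ch_imp, field),
        delta_parent=field.phi_th * omega(ch_imp, field) * BARN_CM2,
    )
    return main, imp, (lu_nat, lu_channels)


def _lu_impurity_ppm(target: TargetSpec) -> float:
    for imp in target.elemental_impurities:
        if imp.element == "Lu":
            return imp.ppm
    return 0.0


def indirect_route(target: TargetSpec | None = None, phi_th: float = 5.0e13,
                   t_irr: float = 240 * 3600.0,
                   t_c: float = DEFAULT_INDIRECT_COOLING_S,
                   R_epi: float = DEFAULT_R_EPI,
                   lu_ppm: float | None = None,
                   yb174_percent: float | None = None,
                   t_grid=None, tc_grid=None,
                   replication: bool = False) -> ScenarioResult:
    """Indirect-route scenario: Yb-176(n,gamma)Yb-177 -> beta -> Lu-177.

    Source S1 is the chain product of the elementally pure Yb target (its
    SA degraded by Lu-175 in-growth from Yb-174); source S2 is Lu-177 from
    direct activation of the natural-abundance elemental Lu impurity.  The
    combined SA follows the mixture rule; total activity is A1 + A2.

    ``sa_series`` tabulates the combined SA against irradiation time at the
    given cooling time; ``extras["cooling_series"]`` against cooling time
    at the given irradiation time.
    """
    avo = _avogadro(replication)
    yb_channels: list
    if target is None:
        target, yb_channels = load_fixture("yb176_enriched")
    else:
        _, yb_channels = load_fixture("yb176_enriched")
    if yb174_percent is not None:
        old = target.isotope("Yb-174").weight_percent
        target = target.with_percents(
            {"Yb-174": yb174_percent,
             "Yb-176": target.isotope("Yb-176").weight_percent + (old - yb174_percent)}
        )
    if lu_ppm is None:
        lu_ppm = _lu_impurity_ppm(target)

    field = NeutronField(phi_th, R_epi=R_epi)
    main, imp, (lu_nat, lu_channels) = _indirect_systems(target, yb_channels, field)

    n0_yb176 = target.initial_atoms("Yb-176", avo)
    has_yb174 = any(i.symbol == "Yb-174" for i in target.isotopes)
    n0_yb174 = target.initial_atoms("Yb-174", avo) if has_yb174 else 0.0

    m_lu = lu_ppm * 1.0e-6 * target.element_mass_g
    lu_target = replace(lu_nat, mass_g=m_lu) if m_lu > 0 else None
    lu_prod_ch = lu_channels[0]
    lu_parent_channels = [ch for ch in lu_channels if ch.parent.symbol == "Lu-176"]

    def evaluate(t_i, t_cool):
        """Vectorized over either argument: (A1, SA1, A2, SA2, combined)."""
        n177 = np.asarray(chain_product_atoms(main, n0_yb176, t_i, t_cool))
        a1 = main.product.lambda_total * n177
        n175 = np.asarray(stable_ingrowth(imp, n0_yb174, t_i, t_cool))
        pool1 = n177 + n175
        sa1 = np.where(pool1 > 0, 100.0 * n177 / np.where(pool1 > 0, pool1, 1.0), 100.0)
        if lu_target is not None:
            delta_lu = activation.depletion_constant(lu_parent_channels, field)
            consts = DepletionConstants(delta_lu, lu_prod_ch.product.lambda_total)
            n0_lu176 = lu_target.initial_atoms("Lu-176", avo)
            a2 = np.asarray(
                activation.product_activity(
                    n0_lu176, omega(lu_prod_ch, field), field, consts, t_i, t_cool
                )
            )
            sa2 = np.asarray(
                sa_mod.sa_general(lu_target, lu_channels, field,
                                  np.atleast_1d(np.asarray(t_i, dtype=float)),
                                  t_cool, avogadro=avo)
            )
            if np.ndim(a2) == 0:
                sa2 = sa2[0]
        else:
            a2 = np.zeros_like(np.asarray(a1, dtype=float))
            sa2 = np.full_like(np.asarray(a1, dtype=float), np.nan)
        total = a1 + a2
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.where(a1 > 0, a1 / np.where(sa1 > 0, sa1, 1.0), 0.0) + np.where(
                a2 > 0, a2 / sa2, 0.0
            )
            combined = np.where(total > 0, total / np.where(denom > 0, denom, 1.0), 100.0)
        return a1, sa1, a2, sa2, combined

    # scalar result at the requested (t_irr, t_c)
    a1, sa1, a2, sa2, combined = (np.asarray(x, dtype=float) for x in evaluate(t_irr, t_c))
    sources = [RadioactiveSource("S1-chain", float(a1), float(sa1))]
    if m_lu > 0:
        sources.append(RadioactiveSource("S2-lu-impurity", float(a2), float(np.asarray(sa2).item())))

    if t_grid is None:
        t_grid = np.linspace(1.0, max(2.0 * t_irr, 400 * 3600.0), 201)
    t_grid = np.asarray(t_grid, dtype=float)
    a1_s, sa1_s, a2_s, sa2_s, comb_s = evaluate(t_grid, t_c)
    sa_series = pd.DataFrame(
        {
            "time_s": t_grid,
            "sa_atom_percent": comb_s,
            "sa1_atom_percent": sa1_s,
            "a1_Bq": a1_s,
            "a2_Bq": a2_s,
        }
    )

    if tc_grid is None:
        tc_grid = np.linspace(0.0, 10 * 86400.0, 101)
    tc_grid = np.asarray(tc_grid, dtype=float)
    _, sa1_c, _, _, comb_c = evaluate(float(t_irr), tc_grid)
    cooling = pd.DataFrame(
        {"t_c_s": tc_grid, "sa_atom_percent": comb_c, "sa1_atom_percent": sa1_c}
    )

    # interior maximum of the combined SA over irradiation time, if any
    t_sa_max = None
    idx = int(np.nanargmax(comb_s))
    if 0 < idx < len(t_grid) - 1:
        t_sa_max = float(t_grid[idx])

    return ScenarioResult(
        series=None,
        sa_series=sa_series,
        t_yield_max=None,
        t_sa_max=t_sa_max,
        sources=sources,
        extras={
            "phi_th": phi_th,
            "t_irr_s": float(t_irr),
            "t_c_s": float(t_c),
            "lu_ppm": lu_ppm,
            "A1_Bq": float(a1),
            "A2_Bq": float(a2),
            "A_total_Bq": float(a1 + a2),
            "SA1_atom_percent": float(sa1),
            "SA2_atom_percent": float(np.asarray(sa2).item()) if m_lu > 0 else None,
            "SA_combined_atom_percent": float(combined),
            "cooling_series": cooling,
        },
    )
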