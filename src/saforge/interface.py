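"""Run configuration, validation, and artifact-producing entry point.

``RunConfig`` is the schema behind both the YAML config file and the CLI
flags; :func:`run` executes one configured scenario and writes CSV/JSON
artifacts, logging every resolved rate constant for auditability.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import activation, cases_lu177, specific_activity as sa_mod
from .activation import DepletionConstants
from .constants import avogadro as _avogadro
from .nuclear_data import NeutronField, load_fixture
from .spectrum import corrections, omega

__all__ = ["RunConfig", "FieldConfig", "parse_time", "run"]

log = logging.getLogger("saforge")

_TIME_RE = re.compile(r"^\s*([0-9.eE+\-]+)\s*(s|h|d)\s*$")
_TIME_FACTORS = {"s": 1.0, "h": 3600.0, "d": 86400.0}


def parse_time(text: str) -> float:
    """Parse a duration with a mandatory unit suffix (s, h or d)."""
    m = _TIME_RE.match(str(text))
    if not m:
        raise ValueError(
            f"time {text!r} needs an explicit unit suffix: e.g. '3600s', '240h', '10d'"
        )
    value = float(m.group(1))
    if value < 0:
        raise ValueError(f"time must be non-negative: {text!r}")
    return value * _TIME_FACTORS[m.group(2)]


class FieldConfig(BaseModel):
    """Neutron field parameters."""

    phi_th: float = Field(gt=0, description="thermal flux, n cm^-2 s^-1")
    R_epi: float = Field(default=0.02, ge=0)
    R_fast: float = Field(default=0.0, ge=0)
    alpha: float = 0.0
    E_Cd: float = Field(default=0.55, gt=0)

    def build(self) -> NeutronField:
        return NeutronField(
            phi_th=self.phi_th, R_epi=self.R_epi, R_fast=self.R_fast,
            alpha=self.alpha, E_Cd=self.E_Cd,
        )


class RunConfig(BaseModel):
    """One scenario run: what to compute, on which target, over what times."""

    mode: Literal["activate", "sa", "optimize", "direct", "indirect", "flux-scan"]
    fixture: str = "lu176_enriched"
    field: FieldConfig
    t_irr: str = "240h"
    t_c: str = "0s"
    steps: int = Field(default=201, gt=1)
    enrichment: float | None = Field(default=None, gt=0, le=100)
    enrichments: list[float] = Field(default=[60.0, 74.1, 90.0, 99.9])
    flux_grid: list[float] | None = None
    lu_ppm: float | None = Field(default=None, ge=0)
    mass_g: float | None = Field(default=None, gt=0)
    replication: bool = False
    out_dir: str = "."
    plot: bool = False

    @field_validator("t_irr", "t_c")
    @classmethod
    def _check_time(cls, v: str) -> str:
        parse_time(v)
        return v

    @field_validator("flux_grid")
    @classmethod
    def _check_flux(cls, v):
        if v is not None and any(x <= 0 for x in v):
            raise ValueError("all flux grid values must be positive")
        return v


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _log_constants(channels, field) -> None:
    for ch in channels:
        c = corrections(ch, field)
        log.info(
            "channel %-6s sigma_eff=%.6g b (Q0=%.4g, xi=%.4g, flux ratio %.6g)",
            ch.label or ch.parent.symbol, c.sigma_eff, c.Q0, c.xi_alpha,
            c.flux_ratio_westcott_hogdahl,
        )


def _maybe_plot(out: Path, frame: pd.DataFrame, x: str, y: str, fname: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(frame[x], frame[y])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.savefig(out / fname, dpi=120)
    plt.close(fig)


def run(config: RunConfig) -> dict:
    """Execute one configured scenario; returns a summary dict.

    Artifacts (CSV series, JSON summary) are written under
    ``config.out_dir``.  Deterministic: identical configs produce
    identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    field = config.field.build()
    t_irr = parse_time(config.t_irr)
    t_c = parse_time(config.t_c)
    avo = _avogadro(config.replication)
    summary: dict = {"mode": config.mode, "replication": config.replication}

    if config.mode in ("activate", "sa", "optimize"):
        target, channels = load_fixture(config.fixture)
        if config.mass_g:
            from dataclasses import replace

            target = replace(target, mass_g=config.mass_g)
        _log_constants(channels, field)
        prod_ch = next(ch for ch in channels if not ch.product.is_stable)
        parent_channels = [
            ch for ch in channels if ch.parent.symbol == prod_ch.parent.symbol
        ]
        delta = activation.depletion_constant(parent_channels, field)
        consts = DepletionConstants(delta, prod_ch.product.lambda_total)
        log.info(
            "delta_S=%.6g s^-1  Lambda_Ri=%.6g s^-1  D=%.6g",
            delta, consts.Lambda_Ri, consts.D,
        )
        summary.update(
            {"delta_S_per_s": delta, "Lambda_Ri_per_s": consts.Lambda_Ri, "D": consts.D}
        )

        if config.mode == "optimize":
            t_yield = activation.time_of_max_yield(consts)
            t_sa = sa_mod.time_of_max_sa(target, channels, field, avogadro=avo)
            summary.update(
                {
                    "t_yield_max_s": t_yield,
                    "t_sa_max_s": t_sa,
                    "ratio": (t_sa / t_yield) if t_sa is not None else None,
                }
            )
            _write_json(out / "optimize.json", summary)
            return summary

        grid = np.linspace(0.0, t_irr, config.steps)
        if config.mode == "activate":
            n0 = target.initial_atoms(prod_ch.parent.symbol, avo)
            n_s = activation.remaining_atoms(n0, delta, grid)
            n_ri = activation.product_atoms(n0, omega(prod_ch, field), field, consts, grid, t_c)
            series = activation.ActivationSeries(
                times=grid,
                phase=np.full(grid.shape, "irradiation", dtype=object),
                atoms={prod_ch.parent.symbol: np.asarray(n_s),
                       prod_ch.product.symbol: np.asarray(n_ri)},
                activities={prod_ch.product.symbol: consts.lambda_total * np.asarray(n_ri)},
            )
            path = out / "activation.csv"
            series.to_csv(path)
            summary["csv"] = str(path)
            _write_json(out / "activate.json", summary)
            return summary

        # mode == "sa"
        sa_pct = sa_mod.sa_general(target, channels, field, grid, t_c, avogadro=avo)
        rows = [
            sa_mod.sa_general(target, channels, field, float(t), t_c, avogadro=avo)
            for t in grid
        ]
        frame = pd.DataFrame(
            {
                "time_s": grid,
                "sa_atom_percent": sa_pct,
                "sa_bq_per_g": [r.bq_per_g if r.bq_per_g else 0.0 for r in rows],
            }
        )
        path = out / "sa.csv"
        frame.to_csv(path, index=False, float_format="%.9g")
        if config.plot:
            _maybe_plot(out, frame, "time_s", "sa_atom_percent", "sa.png")
        summary["csv"] = str(path)
        _write_json(out / "sa.json", summary)
        return summary

    if config.mode == "direct":
        result = cases_lu177.direct_route(
            enrichment=config.enrichment or 74.1,
            phi_th=config.field.phi_th,
            R_epi=config.field.R_epi,
            t_c=t_c,
            mass_g=config.mass_g or 1.0e-3,
            replication=config.replication,
        )
        result.series.to_csv(out / "direct_series.csv")
        result.sa_series.to_csv(out / "direct_sa.csv", index=False, float_format="%.9g")
        if config.plot:
            _maybe_plot(out, result.sa_series, "time_s", "sa_atom_percent", "direct_sa.png")
        summary.update(
            {
                "t_yield_max_s": result.t_yield_max,
                "t_sa_max_s": result.t_sa_max,
                "ratio": result.ratio,
                **{k: v for k, v in result.extras.items() if not isinstance(v, pd.DataFrame)},
            }
        )
        _write_json(out / "direct.json", summary)
        return summary

    if config.mode == "indirect":
        result = cases_lu177.indirect_route(
            phi_th=config.field.phi_th,
            t_irr=t_irr,
            t_c=t_c,
            R_epi=config.field.R_epi,
            lu_ppm=config.lu_ppm,
            replication=config.replication,
        )
        result.sa_series.to_csv(out / "indirect_sa.csv", index=False, float_format="%.9g")
        result.extras["cooling_series"].to_csv(
            out / "indirect_cooling.csv", index=False, float_format="%.9g"
        )
        if config.plot:
            _maybe_plot(out, result.sa_series, "time_s", "sa_atom_percent", "indirect_sa.png")
        summary.update(
            {k: v for k, v in result.extras.items() if not isinstance(v, pd.DataFrame)}
        )
        summary["t_sa_max_s"] = result.t_sa_max
        _write_json(out / "indirect.json", summary)
        return summary

    # mode == "flux-scan"
    table = cases_lu177.flux_scan(
        enrichments=config.enrichments,
        phi_grid=config.flux_grid,
        R_epi=config.field.R_epi,
        replication=config.replication,
    )
    table.to_csv(out / "flux_scan.csv", index=False, float_format="%.9g")
    best = cases_lu177.flux_scan_argmax(table)
    best.to_csv(out / "flux_scan_argmax.csv", index=False, float_format="%.9g")
    summary["argmax"] = {
        f"{row.enrichment:g}": row.phi_th for row in best.itertuples()
    }
    _write_json(out / "flux_scan.json", summary)
    return summary
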