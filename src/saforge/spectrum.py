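"""Effective cross-sections and flux-convention conversions.

Two reaction-rate conventions are supported: the Hogdahl convention for
1/v nuclides (sigma_eff = sigma0 + f_H * I0(alpha)) and the Westcott
k-factor shortcut for non-1/v nuclides (sigma_eff = k * sigma0), with the
fast-flux term carried separately.  The epithermal spectrum shape alpha
enters through xi(alpha) and, when an effective resonance energy is
supplied, through the Q0(alpha) correction of the resonance integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .nuclear_data import NeutronField, ReactionChannel

__all__ = [
    "SpectrumCorrections",
    "xi",
    "westcott_hogdahl_flux_ratio",
    "q0_alpha",
    "i0_alpha",
    "sigma_eff_1v",
    "sigma_eff_non1v",
    "omega",
    "corrections",
]


def xi(alpha: float, E_Cd: float = 0.55) -> float:
    """Cadmium cut-off correction 0.429 / ((1 + 2 alpha) * E_Cd ** alpha)."""
    if E_Cd <= 0:
        raise ValueError("E_Cd must be positive")
    denom = 1.0 + 2.0 * alpha
    if denom == 0.0:
        raise ZeroDivisionError("xi(alpha) is singular at alpha = -0.5")
    return 0.429 / (denom * E_Cd**alpha)


def westcott_hogdahl_flux_ratio(f_H: float, alpha: float, E_Cd: float = 0.55) -> float:
    """Ratio of Westcott conventional flux to Hogdahl thermal flux,
    1 + f_H * xi(alpha)."""
    if f_H < 0:
        raise ValueError("f_H must be non-negative")
    return 1.0 + f_H * xi(alpha, E_Cd)


def q0_alpha(Q0: float, alpha: float, e_resonance: float, E_Cd: float = 0.55) -> float:
    """Shape-corrected resonance-integral ratio.

    ``e_resonance`` is the effective resonance energy (eV) of the nuclide,
    which the bundled tables do not provide; callers must supply it to
    activate the alpha correction.
    """
    if e_resonance <= 0:
        raise ValueError("effective resonance energy must be positive")
    return (Q0 - 0.429) / e_resonance**alpha + xi(alpha, E_Cd)


def i0_alpha(sigma0: float, I0: float, alpha: float, e_resonance: float | None,
             E_Cd: float = 0.55) -> float:
    """Resonance integral corrected for the spectrum shape parameter.

    With ``alpha == 0`` (or sigma0 == 0) this is I0 itself.  For a nonzero
    alpha without an effective resonance energy the uncorrected I0 is used
    and a warning is emitted.
    """
    if alpha == 0.0 or sigma0 == 0.0:
        return I0
    if e_resonance is None:
        warnings.warn(
            "alpha != 0 but no effective resonance energy supplied; "
            "using the uncorrected resonance integral I0",
            stacklevel=2,
        )
        return I0
    return q0_alpha(I0 / sigma0, alpha, e_resonance, E_Cd) * sigma0


def sigma_eff_1v(sigma0: float, I0_alpha_: float, f_H: float) -> float:
    """Hogdahl effective cross-section sigma0 + f_H * I0(alpha), barns."""
    if sigma0 < 0 or I0_alpha_ < 0 or f_H < 0:
        raise ValueError("cross-sections and flux ratio must be non-negative")
    return sigma0 + f_H * I0_alpha_


def sigma_eff_non1v(sigma0: float, k_factor: float) -> float:
    """Westcott effective cross-section k * sigma0, barns.

    The fast-flux term, if any, is added separately by the caller.
    """
    if sigma0 < 0:
        raise ValueError("sigma0 must be non-negative")
    if k_factor <= 0:
        raise ValueError("k_factor must be positive")
    return k_factor * sigma0


def omega(channel: ReactionChannel, field: NeutronField,
          e_resonance: float | None = None) -> float:
    """Per-channel reaction-rate cross-section (barns) for a neutron field.

    Non-1/v channels use the Westcott k-factor; 1/v channels use the
    Hogdahl convention with the (optionally alpha-corrected) resonance
    integral.  The fast contribution R_fast * sigma_fast is added in both
    cases (zero by default).
    """
    fast = field.R_fast * channel.sigma_fast
    if channel.non_1v:
        return sigma_eff_non1v(channel.sigma0, channel.k_factor) + fast
    ia = i0_alpha(channel.sigma0, channel.I0, field.alpha, e_resonance, field.E_Cd)
    return sigma_eff_1v(channel.sigma0, ia, field.f_H) + fast


@dataclass(frozen=True)
class SpectrumCorrections:
    """Resolved spectrum quantities for one channel in one field."""

    xi_alpha: float
    Q0: float
    Q0_alpha: float
    I0_alpha: float
    sigma_eff: float
    flux_ratio_westcott_hogdahl: float


def corrections(channel: ReactionChannel, field: NeutronField,
                e_resonance: float | None = None) -> SpectrumCorrections:
    """Compute and bundle all spectrum corrections for auditing/logging."""
    x = xi(field.alpha, field.E_Cd)
    q0 = channel.I0 / channel.sigma0 if channel.sigma0 > 0 else 0.0
    ia = i0_alpha(channel.sigma0, channel.I0, field.alpha, e_resonance, field.E_Cd)
    qa = ia / channel.sigma0 if channel.sigma0 > 0 else 0.0
    return SpectrumCorrections(
        xi_alpha=x,
        Q0=q0,
        Q0_alpha=qa,
        I0_alpha=ia,
        sigma_eff=omega(channel, field, e_resonance),
        flux_ratio_westcott_hogdahl=westcott_hogdahl_flux_ratio(field.f_H, field.alpha, field.E_Cd),
    )
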