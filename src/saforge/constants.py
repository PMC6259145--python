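"""Physical constants and unit helpers shared across the package."""

from __future__ import annotations

import math

#: CODATA 2018 Avogadro constant (mol^-1).
AVOGADRO = 6.02214076e23

#: Truncated Avogadro constant used in replication mode (mol^-1).
AVOGADRO_REPLICATION = 6.02e23

#: One barn in cm^2.
BARN_CM2 = 1.0e-24

#: Reference thermal neutron energy (eV), 2200 m/s.
E0_EV = 0.0253

#: Cadmium cut-off energy (eV).
E_CD_EV = 0.55

LN2 = math.log(2.0)

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


def avogadro(replication: bool = False) -> float:
    """Avogadro constant; ``replication=True`` selects the truncated value
    used for digit-level reproduction of legacy hand calculations."""
    return AVOGADRO_REPLICATION if replication else AVOGADRO
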