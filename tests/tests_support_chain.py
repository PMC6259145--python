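"""Shared helper for building ad-hoc chain systems in tests."""

from saforge.chain import ChainSystem
from saforge.constants import LN2
from saforge.nuclear_data import DecayBranch, Isotope


def build_system(field, omega_b, delta_parent, lam_x, lam_i):
    """Chain with given rate constants; ``lam_i=None`` makes the product
    stable (in-growth configuration)."""
    parent = Isotope("S-0", 176.0, None, weight_percent=100.0)
    inter = Isotope("X-0", 177.0, LN2 / lam_x, branches=(DecayBranch("beta", 1.0),))
    product = Isotope(
        "R-0", 177.0, None if lam_i is None else LN2 / lam_i,
        branches=(DecayBranch("beta", 1.0),),
    )
    return ChainSystem(
        parent=parent,
        intermediate=inter,
        product=product,
        field=field,
        omega_production=omega_b,
        delta_parent=delta_parent,
    )
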