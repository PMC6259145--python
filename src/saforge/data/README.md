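# Fixture schema

One YAML file per target. Fields:

```yaml
name: <fixture name>
element: <target element symbol>
mass_g: <default target mass, grams of the compound>
oxide_stoichiometry: [n_metal, n_oxygen]   # omit for elemental targets
isotopes:          # stable isotopes making up the target element
  - symbol: Xx-NNN
    atomic_mass: <g/mol>
    half_life: stable | "<value><s|m|h|d|y>"
    weight_percent: <share of the element mass>
products:          # nuclides referenced by channels but not in the target
  - symbol: ...
    atomic_mass: ...
    half_life: ...
    branches: [{label: <text>, fraction: <0..1>}, ...]
channels:          # neutron reaction channels
  - label: <short id>
    parent: <isotope symbol>
    product: <isotope symbol>
    sigma0: <barns, thermal 2200 m/s>
    I0: <barns, resonance integral>
    sigma_fast: <barns, default 0>
    kind: n-gamma | n-alpha | n-p
    non_1v: <bool, Westcott k-factor applies>
    k_factor: <dimensionless, default 1.0>
    element_preserving: <bool, capture chain ends in a stable isotope of
                         the parent's element>
elemental_impurities:
  - {element: Xx, ppm: <by mass of the target element>,
     abundances: {Xx-NNN: <weight %>, ...}}   # abundances optional
```

Quantities quoted in the source tables only as upper bounds are stored at
the bound (cross-sections) or the midpoint (isotope contents), with a
comment in the file.
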