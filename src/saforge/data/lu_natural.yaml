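# Natural-abundance elemental lutetium: 97.41% Lu-175 + 2.59% Lu-176.
# Reaction channels are identical to the enriched Lu target.  Used for the
# elemental Lu impurity in the enriched Yb target (no oxide stoichiometry:
# the impurity is accounted as elemental mass).
name: lu_natural
element: Lu
mass_g: 1.0e-3
isotopes:
  - symbol: Lu-175
    atomic_mass: 175.0
    half_life: stable
    weight_percent: 97.41
  - symbol: Lu-176
    atomic_mass: 176.0
    half_life: stable
    weight_percent: 2.59
products:
  - symbol: Lu-177
    atomic_mass: 177.0
    half_life: 6.71d
    branches: [{label: "beta to Hf-177", fraction: 1.0}]
  - symbol: Lu-177m
    atomic_mass: 177.0
    half_life: 160.7d
    branches: [{label: "IT to Lu-177", fraction: 1.0}]
  - symbol: Tm-173
    atomic_mass: 173.0
    half_life: 8.2h
    branches: [{label: "beta to Yb-173", fraction: 1.0}]
  - symbol: Lu-176m
    atomic_mass: 176.0
    half_life: 3.7h
    branches: [{label: "IT to Lu-176", fraction: 1.0}]
  - symbol: Tm-172
    atomic_mass: 172.0
    half_life: 2.6d
    branches: [{label: "beta to Yb-172", fraction: 1.0}]
channels:
  - label: Lu-1
    parent: Lu-176
    product: Lu-177
    sigma0: 2300.0
    I0: 1200.0
    kind: n-gamma
    non_1v: true
    k_factor: 1.74
    element_preserving: false
  - label: Lu-2
    parent: Lu-176
    product: Lu-177m
    sigma0: 2.0
    I0: 3.0
    kind: n-gamma
    element_preserving: false
  - label: Lu-3
    parent: Lu-176
    product: Tm-173
    sigma0: 2.0e-3
    I0: 0.0
    kind: n-alpha
    element_preserving: false
  - label: Lu-4
    parent: Lu-175
    product: Lu-176m
    sigma0: 16.0
    I0: 550.0
    kind: n-gamma
    element_preserving: true
  - label: Lu-5
    parent: Lu-175
    product: Lu-176
    sigma0: 9.0
    I0: 300.0
    kind: n-gamma
    element_preserving: true
  - label: Lu-6
    parent: Lu-175
    product: Tm-172
    sigma0: 1.0e-5
    I0: 0.0
    kind: n-alpha
    element_preserving: false
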