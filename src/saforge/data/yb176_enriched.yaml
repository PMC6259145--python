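# Enriched Yb2O3 target.  Yb-170 and Yb-168 contents are quoted only as an
# upper bound (<0.01%); the midpoint 0.005% is stored.  The elemental Lu
# impurity (50 ppm of elemental Yb mass) is assumed to have natural
# isotopic abundance: 97.41% Lu-175 + 2.59% Lu-176.
name: yb176_enriched
element: Yb
mass_g: 1.0e-3
oxide_stoichiometry: [2, 3]
isotopes:
  - symbol: Yb-176
    atomic_mass: 176.0
    half_life: stable
    weight_percent: 97.6
  - symbol: Yb-174
    atomic_mass: 174.0
    half_life: stable
    weight_percent: 1.93
  - symbol: Yb-173
    atomic_mass: 173.0
    half_life: stable
    weight_percent: 0.18
  - symbol: Yb-172
    atomic_mass: 172.0
    half_life: stable
    weight_percent: 0.22
  - symbol: Yb-171
    atomic_mass: 171.0
    half_life: stable
    weight_percent: 0.07
  - symbol: Yb-170
    atomic_mass: 170.0
    half_life: stable
    weight_percent: 0.005
  - symbol: Yb-168
    atomic_mass: 168.0
    half_life: stable
    weight_percent: 0.005
products:
  - symbol: Yb-177
    atomic_mass: 177.0
    half_life: 1.911h
    branches: [{label: "beta to Lu-177", fraction: 1.0}]
  - symbol: Lu-177
    atomic_mass: 177.0
    half_life: 6.71d
    branches: [{label: "beta to Hf-177", fraction: 1.0}]
  - symbol: Yb-175
    atomic_mass: 175.0
    half_life: 4.2d
    branches: [{label: "beta to Lu-175", fraction: 1.0}]
  - symbol: Lu-175
    atomic_mass: 175.0
    half_life: stable
  - symbol: Yb-169
    atomic_mass: 169.0
    half_life: 32d
    branches: [{label: "EC to Tm-169", fraction: 1.0}]
channels:
  - label: Yb-1
    parent: Yb-176
    product: Yb-177
    sigma0: 3.0
    I0: 8.0
    kind: n-gamma
    element_preserving: false
  - label: Yb-2
    parent: Yb-174
    product: Yb-175
    sigma0: 63.0
    I0: 60.0
    kind: n-gamma
    element_preserving: false
  - label: Yb-3
    parent: Yb-173
    product: Yb-174
    sigma0: 17.4
    I0: 400.0
    kind: n-gamma
    element_preserving: true
  - label: Yb-4
    parent: Yb-172
    product: Yb-173
    sigma0: 1.3
    I0: 25.0
    kind: n-gamma
    element_preserving: true
  - label: Yb-5
    parent: Yb-171
    product: Yb-172
    sigma0: 50.0
    I0: 320.0
    kind: n-gamma
    element_preserving: true
  - label: Yb-6
    parent: Yb-170
    product: Yb-171
    sigma0: 10.0
    I0: 300.0
    kind: n-gamma
    element_preserving: true
  - label: Yb-7
    parent: Yb-168
    product: Yb-169
    sigma0: 2300.0
    I0: 2100.0
    kind: n-gamma
    element_preserving: false
elemental_impurities:
  - {element: Er, ppm: 50}
  - {element: Tm, ppm: 50}
  - element: Lu
    ppm: 50
    abundances: {Lu-175: 97.41, Lu-176: 2.59}
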