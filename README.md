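# saforge

Reaction-yield and specific-radioactivity (SA) assessment for
reactor-produced radioisotopes: target burn-up, Bateman-type yield with
product depression, SA-maximizing irradiation times, two-step
(n,γ) + β⁻ chain production with stable-carrier in-growth, and the SA of
mixtures of radioactive sources (isotopic dilution). Two Lu-177
production case studies are bundled: the direct ¹⁷⁶Lu(n,γ)¹⁷⁷Lu route and
the indirect ¹⁷⁶Yb(n,γ)¹⁷⁷Yb → β⁻ → ¹⁷⁷Lu route.

## Layout

| module | contents |
| --- | --- |
| `saforge.nuclear_data` | domain types (`Isotope`, `ReactionChannel`, `NeutronField`, `TargetSpec`) and bundled YAML fixtures (`lu176_enriched`, `yb176_enriched`, `lu_natural`) |
| `saforge.spectrum` | effective cross-sections: Hogdahl convention for 1/v nuclides, Westcott k-factor for non-1/v, ξ(α) and flux-convention ratio |
| `saforge.activation` | single-capture closed forms: burn-up, product yield/activity, half-burn-up time, time of maximum yield |
| `saforge.specific_activity` | SA definitions and unit conversions, SA of one/two/multi-isotope targets, time of maximum SA |
| `saforge.chain` | three-state chain yield, stable-carrier in-growth during/after irradiation, SA with in-growth, mixture SA |
| `saforge.cases_lu177` | pre-wired direct/indirect route scenarios and the flux scan of the optimization-time ratio |
| `saforge.oracle` | independent matrix-exponential integrator for first-order networks (used to validate every closed form) |
| `saforge.interface` / `saforge.cli` | config schema, run orchestration, `saforge` command line |

## CLI

```sh
saforge optimize --phi 2.5e14                      # yield-max and SA-max times
saforge sa --phi 2.5e14 --t-irr 240h --out outdir  # SA time series CSV
saforge activate --phi 2.5e14 --t-irr 240h         # atom/activity series
saforge case direct --enrichment 74.1 --phi 2.5e14
saforge case indirect --phi 5e13 --t-irr 240h --t-c 24h
saforge case flux-scan --enrichments 60,74.1,90,99.9
```

Every subcommand accepts `--config FILE` (YAML mirroring
`saforge.interface.RunConfig`; flags override file values), `--out DIR`,
and `--plot` (PNG output, needs matplotlib). Times require explicit unit
suffixes (`s`, `h`, `d`). `--replication` switches to the truncated
legacy Avogadro constant for digit-level reproduction of hand
calculations.

## Conventions and caveats

- Cross-sections are stored in barns and converted to cm² at module
  boundaries; all rates are s⁻¹ internally.
- Impurity isotopes whose captures end in stable isotopes of the target
  element do not deplete the element pool (their channels are flagged
  `element_preserving` in the fixtures).
- Post-irradiation cooling of a chain product decays the end-of-bombardment
  inventory only; continued feed from the remaining intermediate is
  excluded (cool for several intermediate half-lives before reporting —
  the test suite quantifies the deficit bound).
- Fast-neutron contributions default to zero but are carried as
  parameters (`R_fast`, `sigma_fast`).
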