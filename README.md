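# washera

Bio-economic scaling model for community-based sheep breeding programs
(CBBPs), applied to the Ethiopian Washera breed. For quantitative
geneticists and livestock-development analysts who want to ask: if the
existing farmer-cooperative breeding nuclei sell their surplus improved
rams to surrounding client flocks, and fattening enterprises join the
chain, how much meat and money does the region gain, and how many new
cooperatives would population-wide coverage need?

The pipeline is deterministic and desk-scale. Its stages:

1. **Demography** — from cluster censuses (households, ewes/household,
   litter size) and management rates (25 ewes/sire, 2.5-yr ram service,
   conception 0.9, lamb survival 0.9, 8-month lambing interval) to
   ewes, sires, replacement rams and the annual cull stream.
2. **Up-/out-scaling** — above-average ram lambs (minus a 5% appearance
   cull and own replacements) serve client ewes at the standard mating
   ratio; the shortfall against the regional ewe target is expressed as
   additional average-sized cooperatives per cluster.
3. **Genetic gain** — realized gain rates (ΔSMW = 0.18 kg/yr, ΔLS =
   0.0021 lambs/lambing/yr) flow through a two-tier cohort recursion:
   client cohorts express half the merit of last year's nucleus ram
   cohort. Potential gains come from two-trait selection-index theory,
   `b = P⁻¹Ga`, response `i (b'G_j)/σ_I / L`.
4. **Production** — carcass meat under non-integrated, partially
   integrated and three fully integrated feedlot-capacity scenarios.
5. **Economics** — cash ledgers discounted at 7% over years 0–10;
   accumulated income, cost, benefit and ROI per tier, with the
   increment attributable to selection kept in its own ledger.

## Worked example

```python
from washera import washera_fixture
from washera.demography import demography_table, demography_report
from washera.scaling import upscaling_table, coverage_fraction

clusters, rates, traits, scheme = washera_fixture()
report = demography_report(demography_table(clusters, rates))
print(report.loc["Total", ["ewes", "sires", "young_sires", "culled_for_meat"]])

upscale = upscaling_table(clusters, report, rates)
print(round(upscale.loc["Total", "sire_capacity"]),
      round(100 * coverage_fraction(upscale)),
      int(upscale.loc["Total", "cbbp_gap"]))
```

prints

```
ewes               21768.0
sires                871.0
young_sires          367.0
culled_for_meat    17154.0
Name: Total, dtype: float64
8322 22 152
```

i.e. the 28 cooperatives hold 21,768 breeding ewes, need 367 young
rams a year for themselves, and cull 17,154 male lambs; up-scaled, they
can produce 8,322 breeding ram lambs a year, enough to serve 22% of the
regional ewe population — full coverage needs 152 more cooperatives.

The same chain continues into meat and money (see `analysis/01…05`,
which write the summary tables under `results/`): 152 t carcass today,
3,495 t with client integration, up to ~2,541 t of additional finished
meat at full feedlot build-out; the non-integrated breeding program
returns 55.9 USD per USD of selection cost, and genetic improvement
alone adds 146 t of carcass in year 10, scaling linearly with the
assumed gain rates.

A `washera` command exposes each stage (`washera demography`,
`washera upscale`, `washera simulate`, `washera run --out results`).

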