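"""Up-scaling ram output to client flocks and the out-scaling gap.

How many client ewes can the current cooperatives' above-average ram
lambs serve, how many meat lambs do those clients produce, and how many
additional cooperatives would full regional coverage require?
"""

from pathlib import Path

from washera import washera_fixture
from washera.demography import demography_report, demography_table
from washera.scaling import coverage_fraction, upscaling_report, upscaling_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clusters, rates, _, _ = washera_fixture()
    demog = demography_report(demography_table(clusters, rates))
    table = upscaling_table(clusters, demog, rates)
    report = upscaling_report(table)
    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "table2_upscaling.csv")

    total = report.loc["Total"]
    print(report)
    print(
        f"\n{total['sire_capacity']:,} ram lambs/yr are fit for breeding; after "
        f"{demog.loc['Total', 'young_sires']:,} own replacements, {total['rams_for_clients']:,} "
        f"go to client flocks and serve {total['client_ewes']:,} ewes "
        f"({100 * coverage_fraction(table):.0f}% of the {total['targeted_ewes']:,} targeted)."
    )
    print(
        f"Closing the gap takes {total['cbbp_gap']} additional cooperatives "
        f"(cluster 1 has a surplus: gap {report.loc['1', 'cbbp_gap']})."
    )
    print(f"wrote {OUT / 'table2_upscaling.csv'}")


if __name__ == "__main__":
    main()
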