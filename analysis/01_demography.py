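"""Current flock structure of the 28 Washera breeding cooperatives.

Reproduces the census-derived demography table: breeding ewes, sires in
service, young replacement rams and the annual cull stream per cluster.
"""

from pathlib import Path

from washera import washera_fixture
from washera.demography import demography_report, demography_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clusters, rates, _, _ = washera_fixture()
    report = demography_report(demography_table(clusters, rates))
    OUT.mkdir(exist_ok=True)
    report.to_csv(OUT / "table1_demography.csv")

    total = report.loc["Total"]
    print(report[["n_cbbps", "households", "ewes", "sires", "young_sires", "culled_for_meat"]])
    print(
        f"\nAcross {total['n_cbbps']} cooperatives in 5 clusters: "
        f"{total['ewes']:,} breeding ewes need {total['sires']:,} sires "
        f"({total['young_sires']:,} young replacement rams/yr); "
        f"{total['culled_for_meat']:,} surplus male lambs are culled for meat each year."
    )
    print(f"wrote {OUT / 'table1_demography.csv'}")


if __name__ == "__main__":
    main()
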