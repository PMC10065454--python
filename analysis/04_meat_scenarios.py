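"""Carcass-meat supply under the three chain-integration scenarios.

Non-integrated cooperatives vs partial integration with client flocks
vs full integration with fattening enterprises at three capacity
schedules (current stations, a 1,000-lambs/yr expansion, growth to the
whole above-average lamb pool).
"""

from pathlib import Path

from washera import washera_fixture
from washera.demography import demography_report, demography_table
from washera.production import production_table
from washera.scaling import upscaling_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clusters, rates, _, _ = washera_fixture()
    demog = demography_report(demography_table(clusters, rates))
    upscale = upscaling_table(clusters, demog, rates)
    table = production_table(demog, upscale, rates)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "table3_production.csv")

    print(table.round(1))
    print(
        f"\nCurrent cooperatives alone: {table.loc['total_meat_t', 'non_integrated']:.0f} t "
        f"carcass/yr. Linked to client flocks: {table.loc['total_meat_t', 'partial']:.0f} t. "
        f"With feedlots, finished meat adds "
        f"{table.loc['finished_meat_t', 'c1']:.0f} / "
        f"{table.loc['finished_meat_t', 'c2']:.0f} / "
        f"{table.loc['finished_meat_t', 'c3']:.0f} t under the three capacity cases."
    )
    print(f"wrote {OUT / 'table3_production.csv'}")


if __name__ == "__main__":
    main()
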