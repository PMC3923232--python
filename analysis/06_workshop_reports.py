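#!/usr/bin/env python
"""Produce the workshop handouts and plottable network exports.

For each sub-city: the organization directory (type, services, contact),
the complementary-services table (who offers what each organization
lacks), and the sociogram as GraphML for downstream drawing.
"""

from pathlib import Path

import pandas as pd

from orna import fixtures, reporting

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for subcity in ("kirkos", "kolfe"):
        net = fixtures.make_paper_fixture(subcity)
        reporting.directory_frame(net).to_csv(
            OUT / f"directory_{subcity}.csv", index=False
        )
        comp = reporting.complementary_table(net)
        pd.DataFrame(
            [
                {"org_id": k, "complementary_orgs": ";".join(v)}
                for k, v in comp.items()
            ]
        ).to_csv(OUT / f"complementary_{subcity}.csv", index=False)
        reporting.export_sociogram(net, OUT / f"sociogram_{subcity}.graphml")
        n_with = sum(1 for v in comp.values() if v)
        print(
            f"{net.subcity_label}: directory with {net.n} entries; "
            f"{n_with} organizations have at least one complementary partner"
        )


if __name__ == "__main__":
    main()
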