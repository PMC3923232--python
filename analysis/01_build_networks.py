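#!/usr/bin/env python
"""Generate the two sub-city referral networks and their survey-style files.

Writes, for each sub-city, the organization roster (nodes.csv), the client
referral arcs (edges.csv), the snowball nomination records
(nominations.csv) and the inter-organization distance matrix
(distances.csv) under results/fixtures/<subcity>/.
"""

from pathlib import Path

import pandas as pd

from orna import fixtures, write_network
from orna.roster import write_nominations

OUT = Path(__file__).resolve().parents[1] / "results" / "fixtures"


def main() -> None:
    for subcity in ("kirkos", "kolfe"):
        net = fixtures.make_paper_fixture(subcity)
        d = OUT / subcity
        d.mkdir(parents=True, exist_ok=True)
        write_network(net, d / "nodes.csv", d / "edges.csv")
        write_nominations(
            fixtures.nomination_fixture(net, seed=13), d / "nominations.csv"
        )
        dist = fixtures.distance_matrix(net)
        pd.DataFrame(dist, index=net.org_ids, columns=net.org_ids).to_csv(
            d / "distances.csv"
        )
        print(
            f"{net.subcity_label}: {net.n} organizations, {net.m} referral arcs "
            f"-> {d}"
        )


if __name__ == "__main__":
    main()
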