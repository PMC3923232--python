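"""Workshop artifacts and plottable exports.

Two handouts support a results-interpretation workshop with the surveyed
organizations: a directory of every organization in the network (type,
services offered, contact) and, per organization, the list of others whose
services complement its own — the candidates for new referral links.  The
sociogram itself is exported as data (GraphML or DOT) for downstream
drawing; no layout or rendering happens here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .core_model import (
    DEFAULT_CATALOGUE,
    ReferralNetwork,
    ServiceCatalogue,
)

__all__ = [
    "DirectoryEntry",
    "directory",
    "directory_frame",
    "complementary_table",
    "export_sociogram",
]


@dataclass(frozen=True)
class DirectoryEntry:
    org_id: str
    name: str
    org_type: str
    services: str
    contact: str


def directory(
    net: ReferralNetwork, catalogue: ServiceCatalogue = DEFAULT_CATALOGUE
) -> list[DirectoryEntry]:
    """One entry per organization, sorted by id, services as domain labels."""
    entries = []
    for o in sorted(net.organizations, key=lambda o: o.org_id):
        labels = catalogue.domains_of(o.services)
        entries.append(
            DirectoryEntry(
                org_id=o.org_id,
                name=o.name,
                org_type=o.org_type,
                services="+".join(labels) if labels else "none",
                contact=f"contact@{o.org_id.lower()}.example",
            )
        )
    return entries


def directory_frame(
    net: ReferralNetwork, catalogue: ServiceCatalogue = DEFAULT_CATALOGUE
) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in directory(net, catalogue)])


def complementary_table(
    net: ReferralNetwork, catalogue: ServiceCatalogue = DEFAULT_CATALOGUE
) -> dict[str, list[str]]:
    """For each organization, the others offering a service code it lacks.

    Only codes in the catalogue count.  An organization covering the full
    catalogue has an empty list.
    """
    all_codes = catalogue.all_codes
    services = {o.org_id: o.services & all_codes for o in net.organizations}
    table: dict[str, list[str]] = {}
    for org_id in net.org_ids:
        table[org_id] = sorted(
            other
            for other in net.org_ids
            if other != org_id and services[other] - services[org_id]
        )
    return table


def export_sociogram(net: ReferralNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize nodes (with attributes) and directed arcs for plotting.

    ``graphml`` round-trips through :func:`networkx.read_graphml`; ``dot``
    is a minimal Graphviz digraph.  Node and arc counts are preserved
    exactly in both formats.
    """
    path = Path(path)
    g = net.to_networkx()
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = [f'digraph "{net.subcity_label or "referrals"}" {{']
        for node, data in sorted(g.nodes(data=True)):
            attrs = ", ".join(
                f'{k}="{v}"' for k, v in sorted(data.items())
            )
            lines.append(f'  "{node}" [{attrs}];')
        for u, v in sorted(g.edges()):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
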