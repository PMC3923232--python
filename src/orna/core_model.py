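"""Domain types, validation and file I/O for organizational referral networks.

The unit of analysis is a service-providing organization (a clinic, NGO,
faith-based organization, hospital ...) and the directed relation
"organization *i* refers clients to organization *j*".  Networks are simple
directed graphs: no self-referrals, at most one arc per ordered pair.  Ties
are analyzed as binary; a surveyed referral *frequency* is carried as an
optional arc attribute but ignored by every metric.

On-disk format is plain CSV: a node table with one row per organization and
an edge table with ``source,target[,frequency]``.  Service sets are
serialized as ``;``-joined codes; coordinates as ``loc_x``/``loc_y`` columns
(blank when unknown).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ORG_TYPES",
    "MANAGEMENT_TYPES",
    "FREQUENCY_LEVELS",
    "DEFAULT_CATALOGUE",
    "NetworkValidationError",
    "ServiceCatalogue",
    "Organization",
    "ReferralArc",
    "ReferralNetwork",
    "read_network",
    "write_network",
    "adjacency",
    "load_catalogue",
]

#: Closed vocabulary of self-reported organization types.
ORG_TYPES = frozenset(
    {
        "gov_hospital",
        "gov_health_center",
        "gov_health_post",
        "ngo",
        "fbo",
        "private_clinic",
        "private_hospital",
    }
)

#: Who runs the organization (board, government office, private owner, ...).
MANAGEMENT_TYPES = frozenset({"board", "government", "owner", "religious", "other"})

#: Ordinal referral-frequency answers; kept verbatim, never used by metrics.
FREQUENCY_LEVELS = frozenset({"never", "rarely", "sometimes", "often"})


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class ServiceCatalogue:
    """Service domains mapped to the concrete service codes they contain.

    The default distinguishes a family-planning domain with a single code
    from an HIV domain split into testing, antiretroviral treatment, care
    and support, and prevention of mother-to-child transmission.  The split
    exists so that *partial* HIV coverage (an organization offering only a
    few HIV services) is expressible in the gap audit.
    """

    domains: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("catalogue must define at least one domain")
        frozen = {name: frozenset(codes) for name, codes in self.domains.items()}
        seen: set[str] = set()
        for codes in frozen.values():
            if seen & codes:
                raise ValueError(f"service codes reused across domains: {seen & codes}")
            seen |= codes
        object.__setattr__(self, "domains", frozen)

    @property
    def all_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for codes in self.domains.values():
            out |= codes
        return frozenset(out)

    def domains_of(self, services: Iterable[str]) -> list[str]:
        """Domain names touched by a service set, in sorted order."""
        s = set(services)
        return sorted(d for d, codes in self.domains.items() if s & codes)


DEFAULT_CATALOGUE = ServiceCatalogue(
    domains={
        "FP": frozenset({"fp"}),
        "HIV": frozenset({"hiv_testing", "hiv_art", "hiv_care_support", "hiv_pmtct"}),
    }
)


@dataclass(frozen=True)
class Organization:
    """One service-providing node with its surveyed attributes."""

    org_id: str
    name: str
    subcity: str
    org_type: str
    management: str
    services: frozenset[str]
    clients_per_month: int
    clinical_staff: int
    nonclinical_staff: int
    location: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.org_type not in ORG_TYPES:
            raise NetworkValidationError(
                f"unknown org_type {self.org_type!r} for {self.org_id!r}"
            )
        if self.management not in MANAGEMENT_TYPES:
            raise NetworkValidationError(
                f"unknown management {self.management!r} for {self.org_id!r}"
            )
        object.__setattr__(self, "services", frozenset(self.services))
        for fld in ("clients_per_month", "clinical_staff", "nonclinical_staff"):
            if int(getattr(self, fld)) < 0:
                raise NetworkValidationError(f"{fld} must be nonnegative ({self.org_id})")
        if self.location is not None:
            object.__setattr__(
                self, "location", (float(self.location[0]), float(self.location[1]))
            )


@dataclass(frozen=True)
class ReferralArc:
    """Directed referral tie ``source -> target`` with optional frequency."""

    source: str
    target: str
    frequency: str | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise NetworkValidationError(f"self-referral {self.source!r} rejected")
        if self.frequency is not None and self.frequency not in FREQUENCY_LEVELS:
            raise NetworkValidationError(
                f"unknown frequency {self.frequency!r} on {self.source}->{self.target}"
            )


@dataclass
class ReferralNetwork:
    """A validated directed client-referral network for one sub-city."""

    organizations: list[Organization]
    arcs: list[ReferralArc]
    subcity_label: str = ""

    def __post_init__(self) -> None:
        ids = [o.org_id for o in self.organizations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate org_id: {dupes}")
        known = set(ids)
        seen_pairs: set[tuple[str, str]] = set()
        for arc in self.arcs:
            for endpoint in (arc.source, arc.target):
                if endpoint not in known:
                    raise NetworkValidationError(f"dangling endpoint {endpoint!r}")
            pair = (arc.source, arc.target)
            if pair in seen_pairs:
                raise NetworkValidationError(f"duplicate arc {pair}")
            seen_pairs.add(pair)

    # -- basic views ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.organizations)

    @property
    def m(self) -> int:
        return len(self.arcs)

    @property
    def org_ids(self) -> list[str]:
        """Organization ids in the canonical (sorted) order."""
        return sorted(o.org_id for o in self.organizations)

    def org(self, org_id: str) -> Organization:
        for o in self.organizations:
            if o.org_id == org_id:
                return o
        raise KeyError(org_id)

    @property
    def arc_set(self) -> frozenset[tuple[str, str]]:
        return frozenset((a.source, a.target) for a in self.arcs)

    def out_neighbors(self, org_id: str) -> set[str]:
        return {a.target for a in self.arcs if a.source == org_id}

    def in_neighbors(self, org_id: str) -> set[str]:
        return {a.source for a in self.arcs if a.target == org_id}

    def to_networkx(self):
        """Export as a :class:`networkx.DiGraph` with node/edge attributes."""
        import networkx as nx

        g = nx.DiGraph(subcity=self.subcity_label)
        for o in sorted(self.organizations, key=lambda o: o.org_id):
            g.add_node(
                o.org_id,
                name=o.name,
                org_type=o.org_type,
                management=o.management,
                services=";".join(sorted(o.services)),
            )
        for a in self.arcs:
            attrs = {} if a.frequency is None else {"frequency": a.frequency}
            g.add_edge(a.source, a.target, **attrs)
        return g

    def validate_services(self, catalogue: ServiceCatalogue) -> None:
        """Check every organization's service set against a catalogue."""
        for o in self.organizations:
            extra = o.services - catalogue.all_codes
            if extra:
                raise NetworkValidationError(
                    f"{o.org_id}: services not in catalogue: {sorted(extra)}"
                )


# -- CSV I/O --------------------------------------------------------------

_NODE_COLUMNS = [
    "org_id",
    "name",
    "subcity",
    "org_type",
    "management",
    "services",
    "clients_per_month",
    "clinical_staff",
    "nonclinical_staff",
    "loc_x",
    "loc_y",
]


def read_network(
    nodes_path: str | Path, edges_path: str | Path, subcity_label: str | None = None
) -> ReferralNetwork:
    """Read and validate a network from a node CSV and an edge CSV.

    Parameters
    ----------
    nodes_path, edges_path
        Node table (one row per organization) and edge table
        (``source,target[,frequency]``).
    subcity_label
        Label for the network; defaults to the most common ``subcity``
        value in the node table.
    """
    nodes = pd.read_csv(nodes_path, dtype=str, keep_default_na=False)
    missing = set(_NODE_COLUMNS[:9]) - set(nodes.columns)
    if missing:
        raise NetworkValidationError(f"node file missing columns: {sorted(missing)}")
    orgs = []
    for row in nodes.itertuples(index=False):
        loc = None
        loc_x = getattr(row, "loc_x", "")
        loc_y = getattr(row, "loc_y", "")
        if str(loc_x) != "" and str(loc_y) != "":
            loc = (float(loc_x), float(loc_y))
        services = frozenset(c for c in str(row.services).split(";") if c)
        orgs.append(
            Organization(
                org_id=row.org_id,
                name=row.name,
                subcity=row.subcity,
                org_type=row.org_type,
                management=row.management,
                services=services,
                clients_per_month=int(row.clients_per_month),
                clinical_staff=int(row.clinical_staff),
                nonclinical_staff=int(row.nonclinical_staff),
                location=loc,
            )
        )

    edges = pd.read_csv(edges_path, dtype=str, keep_default_na=False)
    if not {"source", "target"} <= set(edges.columns):
        raise NetworkValidationError("edge file must have source,target columns")
    arcs = []
    for row in edges.itertuples(index=False):
        freq = getattr(row, "frequency", "") or None
        arcs.append(ReferralArc(source=row.source, target=row.target, frequency=freq))

    if subcity_label is None:
        subcity_label = (
            nodes["subcity"].mode().iloc[0] if len(nodes) else ""
        )
    return ReferralNetwork(organizations=orgs, arcs=arcs, subcity_label=subcity_label)


def write_network(
    net: ReferralNetwork, nodes_path: str | Path, edges_path: str | Path
) -> None:
    """Write a network to CSV such that :func:`read_network` round-trips it."""
    rows = []
    for o in sorted(net.organizations, key=lambda o: o.org_id):
        rows.append(
            {
                "org_id": o.org_id,
                "name": o.name,
                "subcity": o.subcity,
                "org_type": o.org_type,
                "management": o.management,
                "services": ";".join(sorted(o.services)),
                "clients_per_month": o.clients_per_month,
                "clinical_staff": o.clinical_staff,
                "nonclinical_staff": o.nonclinical_staff,
                "loc_x": "" if o.location is None else repr(o.location[0]),
                "loc_y": "" if o.location is None else repr(o.location[1]),
            }
        )
    pd.DataFrame(rows, columns=_NODE_COLUMNS).to_csv(nodes_path, index=False)

    erows = [
        {
            "source": a.source,
            "target": a.target,
            "frequency": a.frequency or "",
        }
        for a in sorted(net.arcs, key=lambda a: (a.source, a.target))
    ]
    pd.DataFrame(erows, columns=["source", "target", "frequency"]).to_csv(
        edges_path, index=False
    )


def adjacency(net: ReferralNetwork) -> np.ndarray:
    """Binary adjacency matrix ordered by sorted ``org_id``.

    Entry ``(i, j)`` is 1 iff the arc ``i -> j`` exists; the diagonal is
    zero and row sums equal out-degrees.
    """
    ids = net.org_ids
    index = {org_id: k for k, org_id in enumerate(ids)}
    a = np.zeros((net.n, net.n), dtype=np.int64)
    for arc in net.arcs:
        a[index[arc.source], index[arc.target]] = 1
    return a


def load_catalogue(path: str | Path) -> ServiceCatalogue:
    """Load a service catalogue from a YAML or JSON config file.

    The file maps domain names to lists of service codes, either at the top
    level or under a ``domains`` key.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if "domains" in data:
        data = data["domains"]
    return ServiceCatalogue(
        domains={name: frozenset(codes) for name, codes in data.items()}
    )
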