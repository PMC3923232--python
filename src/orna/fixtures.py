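"""Synthetic sub-city referral networks and nomination data.

The raw sociometric data behind the two sub-city analyses (Kirkos and
Kolfe Keranyo, Addis Ababa) were never deposited, so this module generates
stand-in networks that reproduce every printed marginal: organization-type
counts, service mixes, staffing and client-volume medians, arc counts,
dyad censuses (hence density and reciprocity), the four-FBO referral
clique with a single outward arc, the government-hospital referral hub,
and the planted family-planning referral gaps.  Nothing beyond those
marginals is claimed: the generated arcs are otherwise random.

Edge placement is constraint-first: planted structures (clique, hub,
coverage arcs, mutual-dyad quota) are laid down before a seeded random
fill brings the arc count to its target, with rejection and a deterministic
seed escalation if a draw paints itself into a corner.  Generation is
fully deterministic: the same code yields byte-identical CSV files on
every run and platform.

All attribute values are synthetic; names and contacts are placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from . import ergm
from .core_model import (
    DEFAULT_CATALOGUE,
    Organization,
    ReferralArc,
    ReferralNetwork,
)
from .roster import NominationRecord

__all__ = [
    "FixtureSpec",
    "make_paper_fixture",
    "random_network",
    "sample_organizations",
    "nomination_fixture",
    "nomination_seeds",
    "distance_matrix",
    "KIRKOS",
    "KOLFE",
]

_SERVICE_SETS = {
    "both_full": frozenset({"fp", "hiv_testing", "hiv_art", "hiv_care_support", "hiv_pmtct"}),
    "hiv_full": frozenset({"hiv_testing", "hiv_art", "hiv_care_support", "hiv_pmtct"}),
    "hiv_partial2": frozenset({"hiv_testing", "hiv_art", "hiv_care_support"}),
    "hiv_partial1": frozenset({"hiv_testing", "hiv_care_support"}),
    "fp_only": frozenset({"fp"}),
}

# org_id, org_type, management, service key, clients/month, clinical, nonclinical.
# Client and staffing columns are hand-placed so the sub-city medians equal the
# surveyed values exactly (clients 219, clinical 10, nonclinical 2 in Kirkos;
# 1350 / 7 / 5 in Kolfe Keranyo, hospital at 150000) and the medians of the
# per-organization client:staff ratios fall near the surveyed 29/19 and 127/203.
_KIRKOS_ORGS = [
    ("K01", "gov_health_center", "government", "both_full", 1350, 30, 60),
    ("K02", "gov_health_center", "government", "both_full", 880, 20, 40),
    ("K03", "gov_health_center", "government", "both_full", 630, 15, 28),
    ("K04", "ngo", "board", "both_full", 480, 12, 22),
    ("K05", "ngo", "board", "both_full", 420, 11, 20),
    ("K06", "ngo", "board", "both_full", 360, 10, 17),
    ("K07", "ngo", "board", "hiv_full", 340, 10, 16),
    ("K08", "ngo", "board", "hiv_full", 330, 10, 16),
    ("K09", "ngo", "other", "hiv_full", 310, 10, 14),
    ("K10", "ngo", "board", "hiv_full", 300, 10, 15),
    ("K11", "ngo", "board", "hiv_full", 219, 10, 2),
    ("K12", "ngo", "board", "hiv_partial2", 25, 1, 2),
    ("K13", "ngo", "board", "hiv_full", 26, 1, 2),
    ("K14", "ngo", "other", "hiv_full", 26, 1, 2),
    ("K15", "ngo", "board", "hiv_partial2", 27, 1, 2),
    ("K16", "ngo", "board", "hiv_full", 28, 1, 2),
    ("K17", "ngo", "board", "hiv_partial1", 29, 1, 2),
    ("K18", "fbo", "religious", "hiv_full", 30, 1, 2),
    ("K19", "fbo", "religious", "hiv_full", 30, 1, 2),
    ("K20", "fbo", "religious", "hiv_partial2", 31, 1, 2),
    ("K21", "fbo", "religious", "both_full", 290, 10, 15),
    ("K22", "fbo", "religious", "hiv_full", 32, 1, 2),
    ("K23", "fbo", "religious", "hiv_partial1", 32, 1, 2),
    ("K24", "private_clinic", "owner", "hiv_full", 270, 10, 14),
    ("K25", "private_clinic", "owner", "hiv_partial2", 33, 1, 2),
]

_KOLFE_ORGS = [
    ("L01", "gov_hospital", "government", "both_full", 150000, 400, 300),
    ("L02", "gov_health_center", "government", "both_full", 30000, 200, 140),
    ("L03", "gov_health_center", "government", "both_full", 15000, 100, 70),
    ("L04", "gov_health_center", "government", "both_full", 9000, 60, 42),
    ("L05", "gov_health_post", "government", "both_full", 300, 3, 2),
    ("L06", "gov_health_post", "government", "both_full", 350, 3, 2),
    ("L07", "gov_health_post", "government", "both_full", 400, 4, 2),
    ("L08", "ngo", "board", "hiv_full", 1350, 7, 5),
    ("L09", "ngo", "board", "hiv_partial2", 1350, 7, 5),
    ("L10", "ngo", "board", "hiv_full", 450, 4, 3),
    ("L11", "ngo", "other", "hiv_partial1", 500, 5, 3),
    ("L12", "ngo", "board", "hiv_full", 560, 5, 3),
    ("L13", "ngo", "board", "both_full", 600, 5, 3),
    ("L14", "fbo", "religious", "fp_only", 640, 6, 4),
    ("L15", "private_clinic", "owner", "both_full", 700, 6, 4),
    ("L16", "private_clinic", "owner", "both_full", 800, 7, 5),
    ("L17", "private_clinic", "owner", "both_full", 900, 7, 5),
    ("L18", "private_clinic", "owner", "both_full", 1600, 13, 8),
    ("L19", "private_clinic", "owner", "both_full", 1800, 14, 9),
    ("L20", "private_clinic", "owner", "both_full", 2000, 14, 10),
    ("L21", "private_clinic", "owner", "both_full", 2400, 16, 11),
    ("L22", "private_clinic", "owner", "both_full", 3000, 20, 14),
    ("L23", "private_clinic", "owner", "both_full", 3600, 24, 17),
    ("L24", "private_clinic", "owner", "both_full", 420, 4, 2),
    ("L25", "private_hospital", "owner", "both_full", 6000, 40, 28),
    ("L26", "private_hospital", "owner", "both_full", 4500, 30, 21),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one packaged sub-city network."""

    subcity: str
    org_table: tuple = ()
    m: int = 0
    mutual_dyads: int = 0
    clique_members: tuple[str, ...] = ()
    clique_exit: tuple[str, str] | None = None
    hub: tuple[str, int] | None = None  # (org_id, exact in-degree = global max)
    in_degree_cap: int = 10**9  # cap for non-hub organizations
    gap_orgs: tuple[str, ...] = ()  # planted FP referral gaps
    gap_domain: str = "FP"
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.mutual_dyads > self.m:
            raise ValueError("mutual-dyad quota exceeds the arc budget")
        if self.clique_members and 2 * len(self.clique_members) > len(self.org_table):
            raise ValueError("clique too large for the network")

    @property
    def n(self) -> int:
        return len(self.org_table)

    @property
    def type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for row in self.org_table:
            out[row[1]] = out.get(row[1], 0) + 1
        return out

    @property
    def service_mix(self) -> dict[str, int]:
        """Counts of HIV-only / FP-only / both organizations."""
        mix = {"hiv_only": 0, "fp_only": 0, "both": 0}
        for row in self.org_table:
            codes = _SERVICE_SETS[row[3]]
            has_fp = bool(codes & DEFAULT_CATALOGUE.domains["FP"])
            has_hiv = bool(codes & DEFAULT_CATALOGUE.domains["HIV"])
            if has_fp and has_hiv:
                mix["both"] += 1
            elif has_fp:
                mix["fp_only"] += 1
            else:
                mix["hiv_only"] += 1
        return mix


KIRKOS = FixtureSpec(
    subcity="Kirkos",
    org_table=tuple(_KIRKOS_ORGS),
    m=69,
    mutual_dyads=9,
    clique_members=("K18", "K19", "K20", "K21"),
    clique_exit=("K18", "K01"),
    hub=("K01", 7),
    in_degree_cap=6,
    gap_orgs=("K16", "K17"),
    seed=20110501,
)

KOLFE = FixtureSpec(
    subcity="Kolfe Keranyo",
    org_table=tuple(_KOLFE_ORGS),
    m=101,
    mutual_dyads=15,
    hub=("L01", 17),
    in_degree_cap=8,
    seed=20110502,
)


def _make_orgs(spec: FixtureSpec, rng: np.random.Generator) -> list[Organization]:
    orgs = []
    for org_id, org_type, management, svc_key, clients, clin, nonclin in spec.org_table:
        orgs.append(
            Organization(
                org_id=org_id,
                name=f"{spec.subcity} {org_type.replace('_', ' ')} {org_id}",
                subcity=spec.subcity,
                org_type=org_type,
                management=management,
                services=_SERVICE_SETS[svc_key],
                clients_per_month=clients,
                clinical_staff=clin,
                nonclinical_staff=nonclin,
                location=(round(rng.uniform(0, 10), 3), round(rng.uniform(0, 10), 3)),
            )
        )
    return orgs


def _fp_providers(spec: FixtureSpec) -> set[str]:
    fp_codes = DEFAULT_CATALOGUE.domains[spec.gap_domain]
    return {row[0] for row in spec.org_table if _SERVICE_SETS[row[3]] & fp_codes}


def _build_arcs(spec: FixtureSpec, rng: np.random.Generator) -> set[tuple[str, str]]:
    """One attempt at constraint-first edge placement; raises if it jams."""
    ids = sorted(row[0] for row in spec.org_table)
    providers = _fp_providers(spec)
    clique = set(spec.clique_members)
    gap = set(spec.gap_orgs)
    hub_id, hub_deg = spec.hub if spec.hub else (None, None)

    arcs: set[tuple[str, str]] = set()
    in_deg = {i: 0 for i in ids}

    def in_cap(v: str) -> int:
        return hub_deg if v == hub_id else spec.in_degree_cap

    def can_add(u: str, v: str, allow_mutual: bool = False) -> bool:
        if u == v or (u, v) in arcs:
            return False
        if u in clique:  # clique out-arcs are frozen after planting
            return False
        if u in gap and v in providers:
            return False
        if in_deg[v] >= in_cap(v):
            return False
        if not allow_mutual and (v, u) in arcs:
            return False
        return True

    def add(u: str, v: str) -> None:
        arcs.add((u, v))
        in_deg[v] += 1

    # 1. plant the clique: all arcs among members, then the single exit arc
    for u in sorted(clique):
        for v in sorted(clique):
            if u != v:
                arcs.add((u, v))
                in_deg[v] += 1
    if spec.clique_exit:
        u, v = spec.clique_exit
        arcs.add((u, v))
        in_deg[v] += 1

    # 2. coverage arcs: every org that must reach an FP provider gets one
    fp_codes = DEFAULT_CATALOGUE.domains[spec.gap_domain]
    needs_fp = [
        row[0]
        for row in spec.org_table
        if not (_SERVICE_SETS[row[3]] & fp_codes)
        and row[0] not in gap
        and row[0] not in clique  # clique members reach the in-clique provider
    ]
    for u in needs_fp:
        choices = [v for v in sorted(providers) if can_add(u, v)]
        if not choices:
            raise RuntimeError("no FP provider available for coverage arc")
        add(u, rng.choice(choices))

    # 3. fill the hub to its exact in-degree
    if hub_id is not None:
        while in_deg[hub_id] < hub_deg:
            choices = [u for u in ids if can_add(u, hub_id)]
            if not choices:
                raise RuntimeError("cannot complete hub in-degree")
            add(rng.choice(choices), hub_id)

    # 4. mutual dyads beyond those inside the clique
    def mutual_count() -> int:
        return sum(1 for (u, v) in arcs if u < v and (v, u) in arcs)

    guard = 0
    while mutual_count() < spec.mutual_dyads:
        guard += 1
        if guard > 5000:
            raise RuntimeError("cannot place mutual-dyad quota")
        u, v = rng.choice(ids, size=2, replace=False)
        if u in clique or v in clique or u in gap or v in gap:
            continue
        if can_add(u, v) and can_add(v, u):
            if len(arcs) + 2 > spec.m:
                raise RuntimeError("arc budget exhausted before mutual quota")
            add(u, v)
            add(v, u)

    # 5. random fill with asymmetric arcs up to the arc budget
    guard = 0
    while len(arcs) < spec.m:
        guard += 1
        if guard > 200000:
            raise RuntimeError("random fill stalled")
        u, v = rng.choice(ids, size=2, replace=False)
        if can_add(u, v):
            add(u, v)

    return arcs


def _verify(spec: FixtureSpec, net: ReferralNetwork) -> None:
    from . import gaps as gaps_mod
    from . import metrics

    assert net.n == spec.n and net.m == spec.m
    m_count, a_count, n_count = metrics.dyad_census(net)
    assert m_count == spec.mutual_dyads, (m_count, spec.mutual_dyads)
    arcs = net.arc_set
    clique = set(spec.clique_members)
    if clique:
        intra = {(u, v) for u in clique for v in clique if u != v}
        assert intra <= arcs
        exits = {(u, v) for (u, v) in arcs if u in clique and v not in clique}
        assert exits == {spec.clique_exit}
    if spec.hub:
        hub_id, hub_deg = spec.hub
        counts, _ = metrics.degree(net, "in")
        assert counts[hub_id] == hub_deg
        assert max(counts.values()) == hub_deg
    records = gaps_mod.detect_gaps(net, DEFAULT_CATALOGUE, mode="domain")
    flagged = gaps_mod.flagged_orgs(records, domain=spec.gap_domain)
    assert flagged == sorted(spec.gap_orgs), flagged


def make_paper_fixture(subcity: str) -> ReferralNetwork:
    """Deterministic packaged network for ``"kirkos"`` or ``"kolfe"``."""
    key = subcity.strip().lower()
    if key.startswith("kirkos"):
        spec = KIRKOS
    elif key.startswith("kolfe"):
        spec = KOLFE
    else:
        raise ValueError("subcity must be 'kirkos' or 'kolfe'")

    last_err: Exception | None = None
    for attempt in range(64):
        rng = np.random.default_rng(spec.seed + attempt)
        orgs = _make_orgs(spec, rng)
        try:
            arc_pairs = _build_arcs(spec, rng)
        except RuntimeError as err:
            last_err = err
            continue
        freq_levels = ["rarely", "sometimes", "often"]
        arcs = [
            ReferralArc(source=u, target=v, frequency=freq_levels[int(rng.integers(3))])
            for (u, v) in sorted(arc_pairs)
        ]
        net = ReferralNetwork(organizations=orgs, arcs=arcs, subcity_label=spec.subcity)
        _verify(spec, net)
        return net
    raise RuntimeError(f"fixture generation failed: {last_err}")


# -- random networks for statistical tests --------------------------------

_DEFAULT_TYPE_PROBS = {
    "gov_health_center": 0.12,
    "ngo": 0.45,
    "fbo": 0.20,
    "private_clinic": 0.15,
    "gov_hospital": 0.04,
    "private_hospital": 0.04,
}
_MANAGEMENT_BY_TYPE = {
    "gov_hospital": "government",
    "gov_health_center": "government",
    "gov_health_post": "government",
    "ngo": "board",
    "fbo": "religious",
    "private_clinic": "owner",
    "private_hospital": "owner",
}


def sample_organizations(
    n: int,
    rng: np.random.Generator,
    type_probs: Mapping[str, float] | None = None,
    p_both: float = 0.4,
    subcity: str = "simulated",
) -> list[Organization]:
    """Random organization attributes: types by frequency, a ``both`` vs
    HIV-only service mix, log-normal client volumes, Poisson-ish staffing
    and uniform coordinates on a 10 x 10 km box."""
    probs = dict(type_probs or _DEFAULT_TYPE_PROBS)
    types = sorted(probs)
    p = np.array([probs[t] for t in types], dtype=float)
    p /= p.sum()
    orgs = []
    for k in range(n):
        org_type = types[int(rng.choice(len(types), p=p))]
        both = rng.random() < p_both
        services = _SERVICE_SETS["both_full" if both else "hiv_full"]
        clients = int(np.round(np.exp(rng.normal(5.5, 1.0))))
        clin = 1 + int(rng.poisson(6))
        nonclin = 1 + int(rng.poisson(3))
        orgs.append(
            Organization(
                org_id=f"S{k:03d}",
                name=f"simulated org S{k:03d}",
                subcity=subcity,
                org_type=org_type,
                management=_MANAGEMENT_BY_TYPE[org_type],
                services=services,
                clients_per_month=clients,
                clinical_staff=clin,
                nonclinical_staff=nonclin,
                location=(float(rng.uniform(0, 10)), float(rng.uniform(0, 10))),
            )
        )
    return orgs


def random_network(
    n: int,
    theta: Sequence[float],
    seed: int,
    terms: Sequence[ergm.ErgmTerm] | None = None,
    attribute_sampler: Callable[[int, np.random.Generator], list[Organization]] | None = None,
    burn_in: int | None = None,
) -> ReferralNetwork:
    """One draw from an exponential random graph over sampled organizations.

    Default model is ``edges`` only (``theta`` of length 1); pass ``terms``
    for anything richer.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sampler = attribute_sampler or (lambda n, r: sample_organizations(n, r))
    orgs = sampler(n, rng)
    model = list(terms) if terms is not None else [ergm.edges()]
    (net,) = ergm.simulate(
        orgs,
        model,
        theta,
        burn_in=burn_in,
        thin=1,
        n_samples=1,
        seed=int(rng.integers(2**31 - 1)),
    )
    return net


def distance_matrix(net: ReferralNetwork) -> np.ndarray:
    """Euclidean driving-distance proxy (km) between organization
    coordinates, ordered by sorted org_id, zero diagonal."""
    locs = []
    for org_id in net.org_ids:
        loc = net.org(org_id).location
        if loc is None:
            raise ValueError(f"{org_id} has no location")
        locs.append(loc)
    pts = np.asarray(locs)
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


# -- nomination data -------------------------------------------------------


def nomination_seeds(net: ReferralNetwork) -> set[str]:
    """The census seed list: government organizations, else the first org."""
    gov = {o.org_id for o in net.organizations if o.org_type.startswith("gov_")}
    return gov or {net.org_ids[0]}


def nomination_fixture(
    net: ReferralNetwork, over_nominate: float = 0.2, seed: int = 0
) -> list[NominationRecord]:
    """Nomination records from which the roster rule recovers ``net`` exactly.

    The first seed names every organization (and one non-private distractor
    outside the network, which the rule must exclude); a second organization
    names every non-private organization so each has two distinct namers;
    private clinics stay named-once to exercise the exception.  A seeded
    fraction ``over_nominate`` of extra random nominations (never aimed at
    private clinics) is layered on top.
    """
    rng = np.random.default_rng(seed)
    ids = net.org_ids
    seeds = sorted(nomination_seeds(net))
    s1 = seeds[0]
    s2 = next(i for i in ids if i != s1)
    private = {o.org_id for o in net.organizations if o.org_type == "private_clinic"}

    records: list[NominationRecord] = []
    for org in ids:
        if org != s1:
            records.append(NominationRecord(nominator=s1, nominee=org))
    distractor = f"EXT_{net.subcity_label.split()[0].upper()}_CBO"
    records.append(NominationRecord(nominator=s1, nominee=distractor))
    for org in ids:
        if org not in (s1, s2) and org not in private:
            records.append(NominationRecord(nominator=s2, nominee=org))
    records.append(NominationRecord(nominator=s2, nominee=s1))
    if s2 not in seeds and s2 not in private:
        s3 = next(i for i in ids if i not in (s1, s2))
        records.append(NominationRecord(nominator=s3, nominee=s2))

    existing = {(r.nominator, r.nominee) for r in records}
    n_extra = int(over_nominate * len(ids))
    guard = 0
    while n_extra > 0 and guard < 10000:
        guard += 1
        u, v = rng.choice(ids, size=2, replace=False)
        if v in private or (u, v) in existing:
            continue
        records.append(NominationRecord(nominator=u, nominee=v))
        existing.add((u, v))
        n_extra -= 1
    return records
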