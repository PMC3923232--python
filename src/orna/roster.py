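"""Roster construction from snowball nomination data.

The analyzable set of organizations is built in two steps, mirroring how a
referral census is run in the field: starting from a seed list of
organizations known to the coordinating health authority, each interviewed
organization is asked which other organizations it knows of; newly named
organizations are asked in turn until no new names arise (the snowball
closure).  An organization then enters the roster only if it was named by
at least two *distinct* other organizations — except private clinics, which
sit apart from the free public/NGO circuit and are seldom named, and are
therefore admitted with a single nomination.  Seed organizations anchor the
census and are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

__all__ = [
    "NominationRecord",
    "read_nominations",
    "write_nominations",
    "snowball_closure",
    "apply_inclusion_rule",
    "build_roster",
]


@dataclass(frozen=True)
class NominationRecord:
    """One raw datum: ``nominator`` named ``nominee`` as a known organization."""

    nominator: str
    nominee: str

    def __post_init__(self) -> None:
        if self.nominator == self.nominee:
            raise ValueError(f"self-nomination {self.nominator!r} rejected")


def read_nominations(path: str | Path) -> list[NominationRecord]:
    df = pd.read_csv(path, dtype=str)
    return [
        NominationRecord(nominator=r.nominator, nominee=r.nominee)
        for r in df.itertuples(index=False)
    ]


def write_nominations(records: Iterable[NominationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"nominator": r.nominator, "nominee": r.nominee} for r in records],
        columns=["nominator", "nominee"],
    ).to_csv(path, index=False)


def snowball_closure(
    seeds: set[str] | frozenset[str], nominations: Iterable[NominationRecord]
) -> set[str]:
    """Transitive closure of nomination reachability from the seeds.

    Returns the candidate pool: every organization reachable from a seed by
    following nominator -> nominee links.  Deterministic and independent of
    nomination order.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set must be nonempty")
    named_by: dict[str, set[str]] = {}
    for rec in nominations:
        named_by.setdefault(rec.nominator, set()).add(rec.nominee)
    reached = set(seeds)
    frontier = set(seeds)
    while frontier:
        nxt: set[str] = set()
        for org in frontier:
            nxt |= named_by.get(org, set()) - reached
        reached |= nxt
        frontier = nxt
    return reached


def apply_inclusion_rule(
    candidates: set[str] | frozenset[str],
    nominations: Iterable[NominationRecord],
    is_private_clinic: Callable[[str], bool],
    seeds: set[str] | frozenset[str] = frozenset(),
) -> set[str]:
    """Apply the named-by-at-least-two rule with the private-clinic exception.

    An organization is included iff it was named by >= 2 distinct nominators,
    or it is a private clinic named by >= 1 nominator, or it is a seed.
    Repeated nominations from the same nominator count once; an
    organization's nomination of itself never occurs (records forbid it).
    Only nominations among candidates are considered.
    """
    candidates = set(candidates)
    nominators: dict[str, set[str]] = {c: set() for c in candidates}
    for rec in nominations:
        if rec.nominee in nominators and rec.nominator in candidates:
            nominators[rec.nominee].add(rec.nominator)
    included = set()
    for org in candidates:
        n_namers = len(nominators[org])
        if org in seeds:
            included.add(org)
        elif n_namers >= 2:
            included.add(org)
        elif n_namers >= 1 and is_private_clinic(org):
            included.add(org)
    return included


def build_roster(
    seeds: set[str] | frozenset[str],
    nominations: Iterable[NominationRecord],
    is_private_clinic: Callable[[str], bool],
) -> set[str]:
    """Snowball closure followed by the inclusion rule, in one call."""
    nominations = list(nominations)
    pool = snowball_closure(seeds, nominations)
    return apply_inclusion_rule(pool, nominations, is_private_clinic, seeds=seeds)
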