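"""Service-gap audit over a referral network.

A service gap is an organization that could have, but did not, refer
clients for services it does not itself provide: it neither covers a
service domain nor has a single out-arc to an organization that does.
Two scan modes are offered:

* ``domain`` — the organization provides *no* code of the domain (e.g. an
  HIV-only organization and the family-planning domain) and refers to no
  provider of that domain;
* ``partial`` — the organization provides a nonempty *strict subset* of the
  domain's codes (e.g. only HIV testing out of the full HIV service array)
  and refers to no *other* provider of the domain.

The audit also emits the referral-nature grid used to find gaps visually:
a square organization-by-organization table whose cell for an existing arc
``i -> j`` names the domains *i* lacks entirely that *j* can cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_model import ReferralNetwork, ServiceCatalogue, DEFAULT_CATALOGUE

__all__ = ["GapRecord", "detect_gaps", "gap_grid", "flagged_orgs"]


@dataclass(frozen=True)
class GapRecord:
    """Audit result for one (organization, service domain) pair."""

    org_id: str
    service_domain: str
    provided_codes: frozenset[str]
    n_qualifying_targets: int
    flagged: bool


def detect_gaps(
    net: ReferralNetwork,
    catalogue: ServiceCatalogue = DEFAULT_CATALOGUE,
    mode: str = "domain",
) -> list[GapRecord]:
    """Scan every (organization, domain) pair and return all records.

    A qualifying target is an out-neighbor providing at least one code of
    the domain.  In ``domain`` mode an organization is flagged iff it
    provides no code of the domain and has zero qualifying targets; in
    ``partial`` mode iff it provides a nonempty strict subset of the
    domain's codes and has zero qualifying targets (the organization itself
    never qualifies as its own target).
    """
    if mode not in ("domain", "partial"):
        raise ValueError("mode must be 'domain' or 'partial'")
    providers: dict[str, set[str]] = {
        d: {o.org_id for o in net.organizations if o.services & codes}
        for d, codes in catalogue.domains.items()
    }
    records = []
    for o in sorted(net.organizations, key=lambda o: o.org_id):
        out = net.out_neighbors(o.org_id)
        for dname in sorted(catalogue.domains):
            codes = catalogue.domains[dname]
            provided = frozenset(o.services & codes)
            n_targets = len(out & providers[dname] - {o.org_id})
            if mode == "domain":
                needs = not provided
            else:
                needs = bool(provided) and provided != codes
            records.append(
                GapRecord(
                    org_id=o.org_id,
                    service_domain=dname,
                    provided_codes=provided,
                    n_qualifying_targets=n_targets,
                    flagged=needs and n_targets == 0,
                )
            )
    return records


def flagged_orgs(records: list[GapRecord], domain: str | None = None) -> list[str]:
    """Sorted ids of flagged organizations, optionally for one domain."""
    return sorted(
        {
            r.org_id
            for r in records
            if r.flagged and (domain is None or r.service_domain == domain)
        }
    )


def gap_grid(
    net: ReferralNetwork, catalogue: ServiceCatalogue = DEFAULT_CATALOGUE
) -> pd.DataFrame:
    """Referral-nature grid: rows are senders, columns receivers.

    For an existing arc ``i -> j`` the cell lists (joined by ``+``) the
    domains that *i* provides no code of and *j* provides at least one code
    of — the needs of *i* coverable through this referral.  Cells without
    an arc are empty.  Scanning row *i* for a domain name reproduces the
    ``domain``-mode flag for *i*: the domain appears nowhere in the row iff
    *i* has no qualifying target.
    """
    ids = net.org_ids
    services = {o.org_id: o.services for o in net.organizations}
    grid = pd.DataFrame("", index=ids, columns=ids, dtype=object)
    for arc in net.arcs:
        needed = [
            d
            for d in sorted(catalogue.domains)
            if not (services[arc.source] & catalogue.domains[d])
            and (services[arc.target] & catalogue.domains[d])
        ]
        grid.loc[arc.source, arc.target] = "+".join(needed) if needed else "-"
    return grid
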