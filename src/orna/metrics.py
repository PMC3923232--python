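"""Whole-network and per-organization descriptive statistics.

All statistics treat the network as a binary simple directed graph on *n*
organizations with *m* arcs:

* density ``m / (n(n-1))`` — arcs as a share of all ordered pairs;
* in-/out-degree — referrals received / sent, with mean ``m / n``;
* dyad census ``(M, A, N)`` — unordered pairs that are mutual, asymmetric
  or null, with ``M + A + N = n(n-1)/2`` and ``m = 2M + A``;
* reciprocity — dyadic mode ``(M + N) / (M + A + N)`` (the share of dyads
  that are *symmetric*, counting null dyads; this is the convention behind
  the reported sub-city values) or arc mode ``2M / m``;
* Freeman degree centralization — concentration of degree on a hub,
  normalized so the star of the matching mode scores exactly 1;
* the mixing matrix — arc counts cross-tabulated by a categorical node
  attribute of the sender and receiver, the raw material of any
  homophily/heterophily reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .core_model import ReferralNetwork, adjacency

__all__ = [
    "NetworkSummary",
    "density",
    "degree",
    "dyad_census",
    "reciprocity",
    "centralization",
    "mixing_matrix",
    "summarize",
]


@dataclass(frozen=True)
class NetworkSummary:
    """One row of the relational-characteristics table for a sub-city."""

    subcity: str
    n: int
    m: int
    density: float
    centralization: float
    mean_out_degree: float
    mean_in_degree: float
    reciprocity_dyadic: float
    reciprocity_arc: float
    dyad_census: tuple[int, int, int]

    def as_display_row(self) -> dict[str, float | int | str]:
        """Rounded for display: 3 decimals for density, 2 elsewhere."""
        return {
            "subcity": self.subcity,
            "links": self.m,
            "density": round(self.density, 3),
            "centralization": round(self.centralization, 3),
            "out_degree": round(self.mean_out_degree, 2),
            "in_degree": round(self.mean_in_degree, 2),
            "reciprocity": round(self.reciprocity_dyadic, 2),
        }


def _require_n(net: ReferralNetwork, minimum: int) -> None:
    if net.n < minimum:
        raise ValueError(f"metric requires n >= {minimum}, got n = {net.n}")


def density(net: ReferralNetwork) -> float:
    """Arc count as a fraction of the ``n(n-1)`` possible ordered pairs."""
    _require_n(net, 2)
    return net.m / (net.n * (net.n - 1))


def degree(net: ReferralNetwork, direction: str) -> tuple[dict[str, int], float]:
    """Per-organization in- or out-degree and the mean degree ``m / n``.

    ``direction`` is ``"in"`` (referrals received) or ``"out"``
    (referrals sent).
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    counts = {org_id: 0 for org_id in net.org_ids}
    for arc in net.arcs:
        key = arc.target if direction == "in" else arc.source
        counts[key] += 1
    return counts, net.m / net.n


def dyad_census(net: ReferralNetwork) -> tuple[int, int, int]:
    """Counts ``(M, A, N)`` of mutual, asymmetric and null unordered pairs."""
    a = adjacency(net)
    upper = np.triu_indices(net.n, k=1)
    both = a[upper] + a.T[upper]  # 2 = mutual, 1 = asymmetric, 0 = null
    m_count = int(np.count_nonzero(both == 2))
    a_count = int(np.count_nonzero(both == 1))
    n_count = int(np.count_nonzero(both == 0))
    return m_count, a_count, n_count


def reciprocity(net: ReferralNetwork, mode: str = "dyadic") -> float:
    """Proportion of symmetric dyads (``dyadic``) or mutual arcs (``arc``).

    Dyadic mode counts null dyads as symmetric: ``(M + N) / (M + A + N)``.
    Arc mode is ``2M / m`` and is undefined on an arcless network.
    """
    _require_n(net, 2)
    m_count, a_count, n_count = dyad_census(net)
    if mode == "dyadic":
        return Fraction(m_count + n_count, m_count + a_count + n_count).__float__()
    if mode == "arc":
        if net.m == 0:
            raise ValueError("arc reciprocity is undefined when m = 0")
        return 2 * m_count / net.m
    raise ValueError("mode must be 'dyadic' or 'arc'")


def centralization(net: ReferralNetwork, mode: str = "in") -> float:
    """Freeman degree centralization in ``[0, 1]``.

    ``sum_i (c_max - c_i) / D`` with ``c_i`` the chosen degree and the
    denominator the maximum attainable sum: ``(n-1)^2`` for in- or
    out-degree (the inward/outward star), and ``(n-1)(2n-4)`` for total
    degree (the fully mutual star, whose center has total degree
    ``2(n-1)`` against leaves at 2).
    """
    _require_n(net, 3)
    n = net.n
    if mode in ("in", "out"):
        counts, _ = degree(net, mode)
        c = np.array([counts[i] for i in net.org_ids], dtype=float)
        denom = (n - 1) ** 2
    elif mode == "total":
        cin, _ = degree(net, "in")
        cout, _ = degree(net, "out")
        c = np.array([cin[i] + cout[i] for i in net.org_ids], dtype=float)
        denom = (n - 1) * (2 * n - 4)
    else:
        raise ValueError("mode must be 'in', 'out' or 'total'")
    return float((c.max() - c).sum() / denom)


def mixing_matrix(
    net: ReferralNetwork, attribute: str, normalize: bool = False
) -> pd.DataFrame:
    """Arc counts cross-tabulated by sender and receiver category.

    Cell ``(a, b)`` is the number of arcs from category-``a`` organizations
    to category-``b`` organizations; the grand total equals ``m``.  With
    ``normalize=True`` rows are divided by their sums (zero rows left at 0).
    """
    values = {}
    for o in net.organizations:
        v = getattr(o, attribute, None)
        if v is None:
            raise ValueError(f"attribute {attribute!r} missing for {o.org_id}")
        values[o.org_id] = v
    cats = sorted(set(values.values()))
    table = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for arc in net.arcs:
        table.loc[values[arc.source], values[arc.target]] += 1
    if normalize:
        sums = table.sum(axis=1).replace(0, 1)
        return table.div(sums, axis=0)
    return table


def summarize(net: ReferralNetwork, centralization_mode: str = "in") -> NetworkSummary:
    """All whole-network statistics in one record.

    Internal consistency (``m = 2M + A``, mean in = mean out = ``m/n``)
    holds by construction.
    """
    _require_n(net, 3)
    m_count, a_count, n_count = dyad_census(net)
    _, mean_out = degree(net, "out")
    _, mean_in = degree(net, "in")
    return NetworkSummary(
        subcity=net.subcity_label,
        n=net.n,
        m=net.m,
        density=density(net),
        centralization=centralization(net, centralization_mode),
        mean_out_degree=mean_out,
        mean_in_degree=mean_in,
        reciprocity_dyadic=reciprocity(net, "dyadic"),
        reciprocity_arc=(2 * m_count / net.m) if net.m else float("nan"),
        dyad_census=(m_count, a_count, n_count),
    )
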