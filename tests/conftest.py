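import numpy as np
import pytest

from orna import fixtures
from orna.core_model import Organization, ReferralArc, ReferralNetwork


@pytest.fixture(scope="session")
def kirkos():
    return fixtures.make_paper_fixture("kirkos")


@pytest.fixture(scope="session")
def kolfe():
    return fixtures.make_paper_fixture("kolfe")


def make_org(org_id, org_type="ngo", services=frozenset({"hiv_testing"}), **kw):
    defaults = dict(
        name=f"org {org_id}",
        subcity="toy",
        org_type=org_type,
        management={"ngo": "board", "fbo": "religious"}.get(org_type, "other"),
        services=services,
        clients_per_month=100,
        clinical_staff=2,
        nonclinical_staff=1,
    )
    defaults.update(kw)
    return Organization(org_id=org_id, **defaults)


def toy_network(arc_pairs, n=None, org_kwargs=None, label="toy"):
    """Small network over orgs A, B, C, ... with the given arcs."""
    names = sorted({x for pair in arc_pairs for x in pair})
    if n is not None:
        import string

        names = sorted(set(names) | set(string.ascii_uppercase[:n]))
    org_kwargs = org_kwargs or {}
    orgs = [make_org(name, **org_kwargs.get(name, {})) for name in names]
    arcs = [ReferralArc(source=u, target=v) for u, v in arc_pairs]
    return ReferralNetwork(organizations=orgs, arcs=arcs, subcity_label=label)


def net_from_matrix(a, orgs=None):
    """Network with org ids N00, N01, ... from a 0/1 adjacency matrix."""
    a = np.asarray(a)
    n = a.shape[0]
    if orgs is None:
        orgs = [make_org(f"N{k:02d}") for k in range(n)]
    arcs = [
        ReferralArc(source=orgs[i].org_id, target=orgs[j].org_id)
        for i in range(n)
        for j in range(n)
        if i != j and a[i, j]
    ]
    return ReferralNetwork(organizations=list(orgs), arcs=arcs, subcity_label="matrix")
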