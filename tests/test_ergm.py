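"""ERGM change statistics, pseudolikelihood fit and Metropolis simulation."""

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_org, net_from_matrix, toy_network
from orna import ergm, fixtures, metrics
from orna.core_model import ReferralArc, ReferralNetwork


def logit(p):
    return np.log(p / (1 - p))


class TestChangeStatistics:
    def test_edges_term_is_all_ones(self, kirkos):
        x = ergm.change_statistics(kirkos, [ergm.edges()])
        assert x.shape == (25 * 24, 1) and (x == 1).all()

    def test_nodematch_on_org_type(self):
        net = toy_network(
            [],
            n=3,
            org_kwargs={"C": {"org_type": "fbo", "management": "religious"}},
        )
        x = ergm.change_statistics(net, [ergm.nodematch("org_type")])
        dyads = ergm.ordered_dyads(net.org_ids)
        col = dict(zip(dyads, x[:, 0]))
        assert col[("A", "B")] == 1.0  # ngo -> ngo
        assert col[("A", "C")] == 0.0  # ngo -> fbo

    def test_edgecov_reads_matrix_entries(self):
        net = toy_network([], n=3)
        mat = np.array([[0, 5, 1], [2, 0, 9], [4, 7, 0]], dtype=float)
        x = ergm.change_statistics(net, [ergm.edgecov(mat)])
        dyads = ergm.ordered_dyads(net.org_ids)
        col = dict(zip(dyads, x[:, 0]))
        assert col[("A", "B")] == 5.0 and col[("C", "B")] == 7.0

    def test_edgecov_shape_and_diagonal_validated(self):
        with pytest.raises(ValueError):
            ergm.edgecov(np.ones((2, 3)))
        with pytest.raises(ValueError):
            ergm.edgecov(np.eye(3))

    def test_missing_attribute_rejected(self, kirkos):
        with pytest.raises(ValueError, match="no attribute"):
            ergm.change_statistics(kirkos, [ergm.nodematch("budget")])

    def test_rows_equal_bruteforce_statistic_differences(self):
        """delta(i,j) must equal s(G + ij) - s(G - ij) computed from whole
        graphs, for every dyad of random 5-node graphs."""
        rng = np.random.default_rng(42)
        n = 5
        orgs = fixtures.sample_organizations(n, rng)
        ratio = {
            o.org_id: o.clients_per_month / o.clinical_staff for o in orgs
        }
        dist = np.round(rng.uniform(0, 9, size=(n, n)), 2)
        np.fill_diagonal(dist, 0)
        terms = [
            ergm.edges(),
            ergm.nodematch("org_type"),
            ergm.nodemix("org_type", ("ngo", "fbo")),
            ergm.absdiff(ratio, label="ratio"),
            ergm.node_out_cov(ratio, label="ratio"),
            ergm.node_in_cov(ratio, label="ratio"),
            ergm.edgecov(dist, label="distance"),
        ]

        def full_statistics(arc_pairs):
            """Whole-graph statistics recomputed from first principles."""
            by_id = {o.org_id: o for o in orgs}
            ids = sorted(by_id)
            idx = {i: k for k, i in enumerate(ids)}
            s = np.zeros(len(terms))
            for u, v in arc_pairs:
                s[0] += 1
                s[1] += by_id[u].org_type == by_id[v].org_type
                s[2] += (by_id[u].org_type, by_id[v].org_type) == ("ngo", "fbo")
                s[3] += abs(ratio[u] - ratio[v])
                s[4] += ratio[u]
                s[5] += ratio[v]
                s[6] += dist[idx[u], idx[v]]
            return s

        for trial in range(5):
            a = (rng.random((n, n)) < 0.4).astype(int)
            np.fill_diagonal(a, 0)
            net = net_from_matrix(a, orgs=orgs)
            x = ergm.change_statistics(net, terms)
            dyads = ergm.ordered_dyads(net.org_ids)
            base = set(net.arc_set)
            for row, (u, v) in zip(x, dyads):
                with_arc = full_statistics(base | {(u, v)})
                without = full_statistics(base - {(u, v)})
                np.testing.assert_allclose(row, with_arc - without, atol=1e-10)


class TestFitMple:
    def test_edges_only_equals_logit_density(self, kirkos):
        fit = ergm.fit_mple(kirkos, [ergm.edges()])
        assert fit.converged
        assert fit.coef[0] == pytest.approx(logit(69 / 600), abs=1e-10)
        assert fit.n_dyads == 600

    def test_matches_statsmodels_logistic_solver(self, kirkos):
        dist = fixtures.distance_matrix(kirkos)
        terms = [ergm.edges(), ergm.nodematch("org_type"), ergm.edgecov(dist)]
        fit = ergm.fit_mple(kirkos, terms)
        x = ergm.change_statistics(kirkos, terms)
        y = ergm.arc_indicator(kirkos)
        ref = sm.Logit(y, x).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_pure_homophily_flags_separation(self):
        # all arcs within category, none across: nodematch separates
        kwargs = {k: {"org_type": "fbo", "management": "religious"} for k in "CD"}
        net = toy_network(
            [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")], org_kwargs=kwargs
        )
        fit = ergm.fit_mple(net, [ergm.edges(), ergm.nodematch("org_type")])
        assert not fit.converged

    def test_constant_extra_column_is_rank_deficient(self, kirkos):
        with pytest.raises(ValueError, match="rank deficient"):
            ergm.fit_mple(kirkos, [ergm.edges(), ergm.edges()])

    def test_single_category_nodematch_is_rank_deficient(self):
        net = toy_network([("A", "B")], n=4)  # every org the same type
        with pytest.raises(ValueError, match="rank deficient"):
            ergm.fit_mple(net, [ergm.edges(), ergm.nodematch("org_type")])


class TestSimulate:
    def test_zero_theta_gives_half_density(self):
        rng = np.random.default_rng(5)
        orgs = fixtures.sample_organizations(12, rng)
        nets = ergm.simulate(orgs, [ergm.edges()], [0.0], n_samples=200, seed=11)
        mean_density = np.mean([metrics.density(g) for g in nets])
        assert mean_density == pytest.approx(0.5, abs=0.02)

    def test_edges_theta_gives_expected_arc_count(self):
        rng = np.random.default_rng(6)
        orgs = fixtures.sample_organizations(25, rng)
        nets = ergm.simulate(
            orgs, [ergm.edges()], [logit(0.115)], n_samples=500, thin=600, seed=12
        )
        mean_m = np.mean([g.m for g in nets])
        assert mean_m == pytest.approx(600 * 0.115, abs=3)

    def test_same_seed_reproduces_edge_lists(self):
        rng = np.random.default_rng(7)
        orgs = fixtures.sample_organizations(10, rng)
        a = ergm.simulate(orgs, [ergm.edges()], [-1.0], n_samples=3, seed=99)
        b = ergm.simulate(orgs, [ergm.edges()], [-1.0], n_samples=3, seed=99)
        assert [g.arc_set for g in a] == [g.arc_set for g in b]

    def test_nonfinite_theta_rejected(self):
        rng = np.random.default_rng(8)
        orgs = fixtures.sample_organizations(5, rng)
        with pytest.raises(ValueError):
            ergm.simulate(orgs, [ergm.edges()], [np.inf])


class TestHomophilyReport:
    def test_planted_fbo_clique_pushes_nodematch_positive(self, kirkos):
        rep = ergm.homophily_report(kirkos, attrs=["org_type"])
        row = rep.iloc[0]
        assert row["term"] == "nodematch.org_type"
        assert row["estimate"] > 0

    def test_single_category_attribute_reported_degenerate(self):
        net = toy_network([("A", "B"), ("B", "C")], n=4)
        rep = ergm.homophily_report(net, attrs=["org_type"])
        assert rep.iloc[0]["note"].startswith("degenerate")
        assert not rep.iloc[0]["associated"]

    def test_numeric_attribute_enters_as_absdiff(self, kolfe):
        ratio = {
            o.org_id: o.clients_per_month / max(o.clinical_staff, 1)
            for o in kolfe.organizations
        }
        rep = ergm.homophily_report(kolfe, attrs=[ratio])
        assert rep.iloc[0]["term"].startswith("absdiff")
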