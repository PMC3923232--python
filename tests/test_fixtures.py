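"""The packaged sub-city networks reproduce every printed marginal."""

import numpy as np
import pytest

from orna import ergm, fixtures, gaps, metrics, roster
from orna.core_model import DEFAULT_CATALOGUE, write_network


def service_mix(net):
    mix = {"hiv_only": 0, "fp_only": 0, "both": 0}
    for o in net.organizations:
        has_fp = bool(o.services & DEFAULT_CATALOGUE.domains["FP"])
        has_hiv = bool(o.services & DEFAULT_CATALOGUE.domains["HIV"])
        key = "both" if (has_fp and has_hiv) else ("fp_only" if has_fp else "hiv_only")
        mix[key] += 1
    return mix


class TestKirkosMarginals:
    def test_size_and_type_counts(self, kirkos):
        assert kirkos.n == 25 and kirkos.m == 69
        types = {}
        for o in kirkos.organizations:
            types[o.org_type] = types.get(o.org_type, 0) + 1
        assert types == {
            "gov_health_center": 3,
            "ngo": 14,
            "fbo": 6,
            "private_clinic": 2,
        }

    def test_service_mix(self, kirkos):
        assert service_mix(kirkos) == {"hiv_only": 18, "fp_only": 0, "both": 7}

    def test_dyad_census(self, kirkos):
        assert metrics.dyad_census(kirkos) == (9, 51, 240)

    def test_four_fbo_clique_with_single_exit(self, kirkos):
        clique = {"K18", "K19", "K20", "K21"}
        assert all(kirkos.org(i).org_type == "fbo" for i in clique)
        arcs = kirkos.arc_set
        intra = {(u, v) for u in clique for v in clique if u != v}
        assert intra <= arcs  # all 12 within-clique arcs
        exits = [(u, v) for (u, v) in arcs if u in clique and v not in clique]
        assert len(exits) == 1

    def test_planted_fp_gap_count(self, kirkos):
        records = gaps.detect_gaps(kirkos, mode="domain")
        flagged = gaps.flagged_orgs(records, "FP")
        assert len(flagged) == 2
        hiv_only = {
            o.org_id
            for o in kirkos.organizations
            if not o.services & DEFAULT_CATALOGUE.domains["FP"]
        }
        assert set(flagged) <= hiv_only
        assert len(hiv_only - set(flagged)) == 16  # the orgs that do refer

    def test_attribute_medians(self, kirkos):
        orgs = kirkos.organizations
        assert np.median([o.clients_per_month for o in orgs]) == 219
        assert np.median([o.clinical_staff for o in orgs]) == 10
        assert np.median([o.nonclinical_staff for o in orgs]) == 2

    def test_ratio_medians_within_soft_band(self, kirkos):
        orgs = kirkos.organizations
        r_clin = np.median([o.clients_per_month / o.clinical_staff for o in orgs])
        r_non = np.median([o.clients_per_month / o.nonclinical_staff for o in orgs])
        assert r_clin == pytest.approx(29, rel=0.15)
        assert r_non == pytest.approx(19, rel=0.15)

    def test_centralization_within_soft_band(self, kirkos):
        assert metrics.centralization(kirkos, "in") == pytest.approx(0.192, abs=0.05)


class TestKolfeMarginals:
    def test_size_and_type_counts(self, kolfe):
        assert kolfe.n == 26 and kolfe.m == 101
        types = {}
        for o in kolfe.organizations:
            types[o.org_type] = types.get(o.org_type, 0) + 1
        assert types == {
            "gov_hospital": 1,
            "gov_health_center": 3,
            "gov_health_post": 3,
            "ngo": 6,
            "fbo": 1,
            "private_clinic": 10,
            "private_hospital": 2,
        }

    def test_service_mix(self, kolfe):
        assert service_mix(kolfe) == {"hiv_only": 5, "fp_only": 1, "both": 20}

    def test_dyad_census(self, kolfe):
        assert metrics.dyad_census(kolfe) == (15, 71, 239)

    def test_hospital_hub(self, kolfe):
        counts, _ = metrics.degree(kolfe, "in")
        (hospital,) = [
            o.org_id for o in kolfe.organizations if o.org_type == "gov_hospital"
        ]
        assert counts[hospital] >= 12
        assert counts[hospital] == max(counts.values())
        assert kolfe.org(hospital).clients_per_month == 150000

    def test_every_non_fp_org_reaches_an_fp_provider(self, kolfe):
        records = gaps.detect_gaps(kolfe, mode="domain")
        assert gaps.flagged_orgs(records, "FP") == []

    def test_attribute_medians(self, kolfe):
        orgs = kolfe.organizations
        assert np.median([o.clients_per_month for o in orgs]) == 1350
        assert np.median([o.clinical_staff for o in orgs]) == 7
        assert np.median([o.nonclinical_staff for o in orgs]) == 5

    def test_ratio_medians_within_soft_band(self, kolfe):
        orgs = kolfe.organizations
        r_clin = np.median([o.clients_per_month / o.clinical_staff for o in orgs])
        r_non = np.median([o.clients_per_month / o.nonclinical_staff for o in orgs])
        assert r_clin == pytest.approx(127, rel=0.15)
        assert r_non == pytest.approx(203, rel=0.15)

    def test_centralization_within_soft_band(self, kolfe):
        assert metrics.centralization(kolfe, "in") == pytest.approx(0.525, abs=0.05)


class TestDeterminism:
    def test_byte_identical_files_across_runs(self, tmp_path):
        paths = []
        for run in range(2):
            net = fixtures.make_paper_fixture("kirkos")
            nodes = tmp_path / f"nodes{run}.csv"
            edges = tmp_path / f"edges{run}.csv"
            write_network(net, nodes, edges)
            paths.append((nodes.read_bytes(), edges.read_bytes()))
        assert paths[0] == paths[1]

    def test_spec_invariant_checks(self):
        with pytest.raises(ValueError, match="mutual-dyad quota"):
            fixtures.FixtureSpec(subcity="x", org_table=(), m=3, mutual_dyads=2)

    def test_spec_summaries(self):
        assert fixtures.KIRKOS.n == 25
        assert sum(fixtures.KIRKOS.type_counts.values()) == 25
        assert fixtures.KIRKOS.service_mix == {
            "hiv_only": 18,
            "fp_only": 0,
            "both": 7,
        }


class TestRandomNetworks:
    def test_same_seed_identical_edge_lists(self):
        a = fixtures.random_network(15, [-1.5], seed=42)
        b = fixtures.random_network(15, [-1.5], seed=42)
        assert a.arc_set == b.arc_set

    def test_edges_theta_mean_density(self):
        theta = np.log(0.115 / 0.885)
        dens = [
            metrics.density(fixtures.random_network(25, [theta], seed=s))
            for s in range(60)
        ]
        assert np.mean(dens) == pytest.approx(0.115, abs=0.01)

    def test_positive_nodematch_inflates_diagonal_share(self):
        terms_theta = (-2.0, 1.2)
        hits = 0
        trials = 40
        for s in range(trials):
            rng = np.random.default_rng(1000 + s)
            orgs = fixtures.sample_organizations(25, rng)
            net = fixtures.random_network(
                25,
                terms_theta,
                seed=1000 + s,
                terms=[ergm.edges(), ergm.nodematch("org_type")],
                attribute_sampler=lambda n, r: orgs,
            )
            if net.m == 0:
                continue
            table = metrics.mixing_matrix(net, "org_type")
            diag_share = np.trace(table.values) / table.values.sum()
            # expected diagonal share with no homophily
            counts = np.array(
                [
                    sum(o.org_type == t for o in orgs)
                    for t in sorted({o.org_type for o in orgs})
                ]
            )
            n = len(orgs)
            null_share = (counts * (counts - 1)).sum() / (n * (n - 1))
            if diag_share > null_share:
                hits += 1
        assert hits >= 0.95 * trials

    def test_distance_matrix_is_euclidean_and_hollow(self, kirkos):
        d = fixtures.distance_matrix(kirkos)
        assert d.shape == (25, 25)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)
        ids = kirkos.org_ids
        a, b = kirkos.org(ids[0]).location, kirkos.org(ids[3]).location
        assert d[0, 3] == pytest.approx(np.hypot(a[0] - b[0], a[1] - b[1]))


class TestNominationFixture:
    @pytest.fixture()
    def kirkos_roster_inputs(self, kirkos):
        noms = fixtures.nomination_fixture(kirkos, seed=13)
        seeds = fixtures.nomination_seeds(kirkos)
        private = {
            o.org_id for o in kirkos.organizations if o.org_type == "private_clinic"
        }
        return kirkos, noms, seeds, private

    def test_roster_recovers_exactly_the_fixture(self, kirkos_roster_inputs):
        kirkos, noms, seeds, private = kirkos_roster_inputs
        got = roster.build_roster(seeds, noms, lambda o: o in private)
        assert got == set(kirkos.org_ids)

    def test_once_named_nonprivate_distractor_excluded(self, kirkos_roster_inputs):
        kirkos, noms, seeds, private = kirkos_roster_inputs
        distractors = {r.nominee for r in noms} - set(kirkos.org_ids)
        assert distractors  # the fixture plants at least one
        got = roster.build_roster(seeds, noms, lambda o: o in private)
        assert not distractors & got

    def test_once_named_private_clinic_distractor_included(self, kirkos_roster_inputs):
        kirkos, noms, seeds, private = kirkos_roster_inputs
        extra = roster.NominationRecord(nominator=sorted(seeds)[0], nominee="PX99")
        got = roster.build_roster(
            seeds, list(noms) + [extra], lambda o: o in private or o == "PX99"
        )
        assert "PX99" in got
        assert len(got) == 26

    def test_private_clinics_in_fixture_named_exactly_once(self, kirkos_roster_inputs):
        kirkos, noms, seeds, private = kirkos_roster_inputs
        for clinic in private:
            namers = {r.nominator for r in noms if r.nominee == clinic}
            assert len(namers) == 1
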