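"""Habitat selectivity, niche overlap, association, profile clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from camtrap_niche.niche import (
    chisq_distance,
    chisq_distance_matrix,
    dendrogram_newick,
    habitat_preference,
    hcluster,
    jacobs_index,
    pianka,
    spatial_association,
    spearman,
    temporal_association,
)
from camtrap_niche.circular import HourlyProfile
from camtrap_niche.records import habitat_use, rai_matrix
from tests.conftest import make_detections


class TestJacobs:
    @pytest.mark.parametrize(
        "r, p, expected",
        [(0.3, 0.5, -0.4), (0.5, 0.5, 0.0), (0.0, 0.4, -1.0), (1.0, 0.4, 1.0)],
    )
    def test_known_values(self, r, p, expected):
        assert jacobs_index(r, p) == pytest.approx(expected)

    def test_degenerate_returns_none(self):
        assert jacobs_index(0.0, 0.0) is None
        assert jacobs_index(1.0, 1.0) is None

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_in_use_and_availability(self, r, p):
        assert jacobs_index(r, p) == pytest.approx(-jacobs_index(p, r), abs=1e-12)

    def test_bounded(self):
        for r in np.linspace(0, 1, 21):
            for p in np.linspace(0, 1, 21):
                d = jacobs_index(r, p)
                if d is not None:
                    assert -1 <= d <= 1 + 1e-12


class TestHabitatPreference:
    def test_uniform_use_equal_effort_all_zero(self, four_stations):
        # force equal effort
        stations = [type(s)(s.station_id, s.habitat, 10.0) for s in four_stations]
        events = []
        for s in stations:
            events += make_detections([0, 120], station=s.station_id)
        prof = habitat_use(events, stations)
        for res in habitat_preference(prof, stations):
            assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_never_used_habitat_is_minus_one(self, four_stations):
        events = (make_detections([0, 120], station="ST01")
                  + make_detections([0], station="ST02")
                  + make_detections([0], station="ST03"))  # nothing in Thorn
        prof = habitat_use(events, four_stations)
        thorn = [r for r in habitat_preference(prof, four_stations)
                 if r.habitat == "Thorn"][0]
        assert thorn.D == pytest.approx(-1.0)


class TestPianka:
    def test_identical_profiles(self):
        assert pianka([0.2, 0.8], [0.2, 0.8]).O == pytest.approx(1.0)

    def test_disjoint_profiles(self):
        assert pianka([1, 0, 0], [0, 0.5, 0.5]).O == pytest.approx(0.0)

    def test_hand_value(self):
        assert pianka([0.5, 0.5], [1.0, 0.0]).O == pytest.approx(1 / np.sqrt(2))

    def test_permutation_invariance(self, rng):
        a = rng.dirichlet(np.ones(6))
        b = rng.dirichlet(np.ones(6))
        perm = rng.permutation(6)
        assert pianka(a[perm], b[perm]).O == pytest.approx(pianka(a, b).O)

    def test_proportional_profiles_give_one(self):
        assert pianka([1, 2, 3], [2, 4, 6]).O == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            pianka([0, 0], [1, 0])


def brute_force_spearman(x, y):
    """Rank-formula oracle for distinct values: 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(x)
    rx = [sum(1 for v in x if v < xi) + 1 for xi in x]
    ry = [sum(1 for v in y if v < yi) + 1 for yi in y]
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1 - 6 * d2 / (n * (n**2 - 1))


class TestSpearman:
    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3], [3, 2, 1]).r_s == pytest.approx(-1.0)

    def test_identity_is_one(self):
        assert spearman([1, 5, 2, 9], [1, 5, 2, 9]).r_s == pytest.approx(1.0)

    def test_exhaustive_permutation_oracle(self):
        x = [1, 2, 3, 4, 5]
        for perm in itertools.permutations([10.0, 3.5, 7.2, 0.1, 5.5]):
            got = spearman(x, list(perm)).r_s
            assert got == pytest.approx(brute_force_spearman(x, perm), abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        res = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_undefined(self):
        res = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert res.r_s is None and res.p is None

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])


class TestAssociations:
    def _profile(self, hot_hours):
        pct = np.zeros(24)
        pct[list(hot_hours)] = 100 / len(hot_hours)
        return HourlyProfile(percent=pct)

    def test_identical_hourly_profiles(self):
        p = self._profile(range(8, 16))
        assert temporal_association(p, p).r_s == pytest.approx(1.0)

    def test_day_vs_rotated_strongly_negative(self):
        day = self._profile(range(8, 16))
        night = self._profile([(h + 12) % 24 for h in range(8, 16)])
        res = temporal_association(day, night)
        assert res.r_s < -0.5
        assert res.n == 24

    def test_flat_profile_undefined(self):
        flat = HourlyProfile(percent=np.full(24, 100 / 24))
        assert temporal_association(flat, self._profile(range(4))).r_s is None

    def test_site_association_duplicate_and_reversed(self, four_stations):
        # equal effort so count ranks and RAI ranks coincide
        stations = [type(s)(s.station_id, s.habitat, 10.0)
                    for s in four_stations]
        ev = []
        counts = {"ST01": 1, "ST02": 2, "ST03": 3, "ST04": 4}
        for sid, k in counts.items():
            ev += make_detections(range(0, k * 60, 60), "a", sid)
            ev += make_detections(range(0, k * 60, 60), "b", sid)
            rev = 5 - k
            ev += make_detections(range(0, rev * 60, 60), "c", sid)
        rai = rai_matrix(ev, stations)
        assert spatial_association(rai, "a", "b").r_s == pytest.approx(1.0)
        assert spatial_association(rai, "a", "c").r_s == pytest.approx(-1.0)

    def test_unknown_species_rejected(self, four_stations):
        rai = rai_matrix(make_detections([0]), four_stations)
        with pytest.raises(KeyError):
            spatial_association(rai, "leopard", "ghost")


class TestChisqDistance:
    def test_identical_rows_zero(self):
        assert chisq_distance([3, 1, 2], [6, 2, 4], [0.5, 0.25, 0.25]) == 0.0

    def test_hand_value(self):
        assert chisq_distance([1, 0], [0, 1], [0.5, 0.5]) == pytest.approx(2.0)

    def test_row_scale_invariance(self, rng):
        a = rng.integers(1, 10, 4).astype(float)
        b = rng.integers(1, 10, 4).astype(float)
        m = rng.dirichlet(np.ones(4))
        assert chisq_distance(7 * a, b, m) == pytest.approx(chisq_distance(a, b, m))

    def test_metric_axioms_on_random_triples(self, rng):
        m = rng.dirichlet(np.ones(5))
        for _ in range(50):
            a, b, c = rng.integers(1, 20, (3, 5)).astype(float)
            dab = chisq_distance(a, b, m)
            dba = chisq_distance(b, a, m)
            assert dab == pytest.approx(dba)
            assert dab <= chisq_distance(a, c, m) + chisq_distance(c, b, m) + 1e-12

    def test_bad_mass_rejected(self):
        with pytest.raises(ValueError):
            chisq_distance([1, 2], [2, 1], [0.7, 0.7])


class TestHCluster:
    def test_two_species_single_merge(self):
        tbl = pd.DataFrame([[5, 1], [1, 5]], index=["a", "b"], columns=["h1", "h2"])
        link, labels = hcluster(tbl)
        mass = tbl.sum(0) / tbl.values.sum()
        expected = chisq_distance(tbl.loc["a"], tbl.loc["b"], mass.to_numpy())
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(expected)

    def test_nearest_pair_merges_first(self):
        tbl = pd.DataFrame(
            [[10, 1, 1], [9, 1, 2], [1, 1, 10]],
            index=["A", "B", "C"], columns=["h1", "h2", "h3"],
        )
        link, labels = hcluster(tbl)
        first = {labels[int(link[0, 0])], labels[int(link[0, 1])]}
        assert first == {"A", "B"}

    def test_heights_monotone(self, rng):
        tbl = pd.DataFrame(rng.integers(1, 30, (6, 4)).astype(float),
                           index=list("abcdef"))
        link, _ = hcluster(tbl)
        assert (np.diff(link[:, 2]) >= -1e-12).all()

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hcluster(pd.DataFrame([[1, 2]], index=["a"]))

    def test_newick_parses_with_all_leaves(self):
        import io

        from Bio import Phylo

        tbl = pd.DataFrame([[5, 1, 2], [1, 5, 2], [2, 2, 9], [7, 1, 1]],
                           index=["a", "b", "c", "d"])
        link, labels = hcluster(tbl)
        nwk = dendrogram_newick(link, labels)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)

    def test_distance_matrix_symmetry(self, rng):
        tbl = pd.DataFrame(rng.integers(1, 20, (4, 3)).astype(float),
                           index=list("wxyz"))
        dm = chisq_distance_matrix(tbl)
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0)
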