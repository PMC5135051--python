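"""Descriptors, Poisson GLMs, core extraction, PERMANOVA, NMDS."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from antweb.community_stats import (
    build_core_incidence,
    core_similarity_permanova,
    descriptor_table,
    extract_core,
    nmds,
    permanova,
    poisson_glm_test,
    site_descriptors,
)
from antweb.errors import DegenerateDesignError, ValidationError

from _oracles import permanova_exhaustive_oracle
from conftest import make_event, make_layer


class TestSiteDescriptors:
    def test_counts_on_small_example(self):
        events = [
            make_event("P1", "A1"),
            make_event("P1", "A1"),
            make_event("P2", "A2"),
        ]
        d = site_descriptors(events, "EFN", "S1")
        assert (d.size, d.richness, d.frequency) == (4, 2, 3)
        assert not d.empty

    def test_empty_layer_flagged(self):
        events = [make_event("P1", "A1", "EFN")]
        d = site_descriptors(events, "flower", "S1")
        assert (d.size, d.richness, d.frequency) == (0, 0, 0)
        assert d.empty

    def test_invariants_on_random_events(self, rng):
        events = [
            make_event(f"P{rng.integers(5)}", f"A{rng.integers(4)}",
                       site=f"S{rng.integers(2) + 1}")
            for _ in range(30)
        ]
        for s in ("S1", "S2"):
            d = site_descriptors(events, "EFN", s)
            assert d.frequency >= d.richness
            assert d.richness <= (d.size // 2) * (d.size - d.size // 2) or d.size == 0


class TestPoissonGlm:
    @staticmethod
    def design(values):
        rows = []
        for s, counts in values.items():
            for r, y in counts.items():
                rows.append(
                    {"site_id": s, "resource": r, "size": y, "richness": y, "frequency": y}
                )
        return pd.DataFrame(rows)

    def test_flat_design_has_zero_deviance(self):
        df = self.design({"S1": {"EFN": 5, "flower": 5}, "S2": {"EFN": 5, "flower": 5}})
        dev, ddf, p = poisson_glm_test(df, "size")
        assert dev == pytest.approx(0.0, abs=1e-9)
        assert ddf == 1 and p == pytest.approx(1.0)

    def test_two_level_deviance_matches_closed_form(self):
        # balanced two-level design; LR deviance = 2*sum y*ln(y/yhat)
        df = self.design({"S1": {"EFN": 8, "flower": 2}, "S2": {"EFN": 6, "flower": 4}})
        dev, ddf, p = poisson_glm_test(df, "frequency")
        y = np.array([8, 2, 6, 4], dtype=float)
        fitted_full = np.array([7, 3, 7, 3], dtype=float)  # group means
        fitted_null = np.full(4, 5.0)  # grand mean
        closed = 2 * np.sum(y * np.log(y / fitted_full)) - 2 * np.sum(
            y * np.log(y / fitted_null)
        )
        assert dev == pytest.approx(-closed if closed < 0 else closed, rel=1e-6)
        assert ddf == 1

    def test_non_integer_response_rejected(self):
        df = self.design({"S1": {"EFN": 1, "flower": 2}, "S2": {"EFN": 2, "flower": 1}})
        df["size"] = df["size"].astype(float)
        df.loc[0, "size"] = 1.5
        with pytest.raises(ValidationError):
            poisson_glm_test(df, "size")


class TestExtractCore:
    def test_all_equal_degrees_give_empty_core(self):
        core = extract_core(make_layer([[2, 0], [0, 1]]))
        assert not core.core_ants and not core.core_plants

    def test_star_network_core_is_the_hub(self):
        A = np.ones((5, 1), dtype=int)
        A = np.hstack([A, np.zeros((5, 1), dtype=int)])
        A[0, 1] = 1  # second ant so the matrix is 5x2
        core = extract_core(make_layer(A))
        assert core.core_ants == frozenset({"A1"})

    def test_membership_is_exactly_above_mean(self, rng):
        A = rng.integers(0, 2, size=(8, 5)) * rng.integers(1, 4, size=(8, 5))
        A[A.sum(axis=1) == 0, 0] = 1
        A[0, A.sum(axis=0) == 0] = 1
        layer = make_layer(A)
        core = extract_core(layer)
        from antweb.metrics import degree_centrality

        deg = degree_centrality(layer)
        thr = np.mean(list(deg.values()))
        expect_p = {p for p in layer.plants if deg[p] > thr}
        expect_a = {a for a in layer.ants if deg[a] > thr}
        assert core.core_plants == expect_p and core.core_ants == expect_a

    def test_idempotent_and_label_invariant(self, rng):
        A = rng.integers(0, 3, size=(5, 5)) + np.eye(5, dtype=int)
        layer = make_layer(A)
        c1 = extract_core(layer)
        c2 = extract_core(layer)
        assert c1 == c2
        perm = rng.permutation(5)
        from antweb.network_model import LayerMatrix

        relabeled = LayerMatrix(
            "EFN",
            [layer.plants[i] for i in perm],
            layer.ants,
            np.asarray(layer.A)[perm],
        )
        c3 = extract_core(relabeled)
        assert c3.core_plants == c1.core_plants and c3.core_ants == c1.core_ants


def cores_from(spec):
    """Build CoreSets from {(site, resource): (ants, plants)}."""
    from antweb.community_stats import CoreSet

    return [
        CoreSet(site, res, frozenset(a), frozenset(p), 1.0)
        for (site, res), (a, p) in spec.items()
    ]


class TestPermanova:
    def test_identical_composition_across_groups_not_significant(self):
        # composition varies by site but is the same in both resource
        # groups, so the grouping factor carries no signal
        spec = {
            (f"S{i}", r): ([f"A{i}", "A10"], ["P1"])
            for i in range(1, 5)
            for r in ("EFN", "flower")
        }
        res = core_similarity_permanova(cores_from(spec), "ants", n_perm=199, seed=0)
        assert res.p_value > 0.05

    def test_fully_identical_rows_degenerate(self):
        spec = {
            (f"S{i}", r): (["A1", "A2"], ["P1"])
            for i in range(1, 4)
            for r in ("EFN", "flower")
        }
        with pytest.raises(DegenerateDesignError):
            core_similarity_permanova(cores_from(spec), "ants", n_perm=199, seed=0)

    def test_disjoint_pools_detected(self):
        # three resource groups with disjoint pools (two groups of three
        # rows cannot beat p = 0.1 under free permutation: only the true
        # split and its mirror attain the maximal pseudo-F among C(6,3)
        # groupings)
        spec = {}
        for i in range(1, 4):
            spec[(f"S{i}", "EFN")] = ([f"A{i}", "A10", "A11"], ["P1"])
            spec[(f"S{i}", "flower")] = ([f"B{i}", "B10", "B11"], ["P1"])
            spec[(f"S{i}", "trophobiont")] = ([f"C{i}", "C10", "C11"], ["P1"])
        res = core_similarity_permanova(cores_from(spec), "ants", n_perm=999, seed=1)
        assert res.p_value <= 0.05
        assert res.R2 > 0.3

    def test_exhaustive_matches_independent_enumeration(self, rng):
        X = rng.random((4, 3))
        D = squareform(pdist(X))
        groups = np.array(["a", "a", "b", "b"])
        res = permanova(D, groups, exhaustive=True)
        f_star, p_star = permanova_exhaustive_oracle(D, groups)
        assert res.pseudo_F == pytest.approx(f_star)
        assert res.p_value == pytest.approx(p_star)

    def test_monte_carlo_converges_to_exhaustive(self, rng):
        X = rng.random((5, 2))
        D = squareform(pdist(X))
        groups = np.array(["a", "a", "b", "b", "b"])
        exact = permanova(D, groups, exhaustive=True).p_value
        mc = permanova(D, groups, n_perm=19999, seed=3).p_value
        assert mc == pytest.approx(exact, abs=0.02)

    def test_agrees_with_skbio_statistic(self, rng):
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        X = (rng.random((9, 4)) > 0.5).astype(float)
        X[:, 0] = 1  # avoid all-zero rows
        D = squareform(pdist(X, metric="jaccard"))
        groups = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        res = permanova(D, groups, n_perm=99, seed=0)
        sk = sk_permanova(DistanceMatrix(D), grouping=list(groups), permutations=99)
        assert res.pseudo_F == pytest.approx(float(sk["test statistic"]), rel=1e-9)

    def test_r2_bounds_and_f_sign(self, rng):
        X = rng.random((8, 3))
        D = squareform(pdist(X))
        groups = np.array(["a", "b"] * 4)
        res = permanova(D, groups, n_perm=49, seed=5)
        assert 0.0 <= res.R2 <= 1.0 and res.pseudo_F >= 0.0

    def test_all_zero_distances_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            permanova(np.zeros((4, 4)), ["a", "a", "b", "b"], n_perm=19)


class TestIncidence:
    def test_empty_cores_dropped(self):
        spec = {
            ("S1", "EFN"): (["A1"], ["P1"]),
            ("S2", "EFN"): ([], ["P2"]),
            ("S1", "flower"): (["A2"], []),
        }
        inc = build_core_incidence(cores_from(spec), "ants")
        assert len(inc) == 2
        assert set(inc.columns) == {"resource", "A1", "A2"}


class TestNmds:
    def test_collinear_points_fit_one_dimension(self):
        x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
        D = np.abs(x[:, None] - x[None, :])
        res = nmds(D, k=1, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_stress_non_increasing_in_k(self, rng):
        X = rng.random((8, 4))
        D = squareform(pdist(X))
        stresses = [nmds(D, k=k, n_starts=8, seed=1).stress for k in (1, 2, 3)]
        assert stresses[1] <= stresses[0] + 1e-6
        assert stresses[2] <= stresses[1] + 1e-6

    def test_more_starts_self_consistency(self, rng):
        X = rng.random((4, 2))
        D = squareform(pdist(X))
        quick = nmds(D, k=2, n_starts=10, seed=2).stress
        thorough = nmds(D, k=2, n_starts=100, seed=3).stress
        assert quick <= thorough + 0.02

    def test_coordinates_centered(self, rng):
        X = rng.random((6, 3))
        D = squareform(pdist(X))
        res = nmds(D, k=2, n_starts=5, seed=4)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_degenerate_distances_rejected(self):
        with pytest.raises(DegenerateDesignError):
            nmds(np.zeros((4, 4)), k=2)
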