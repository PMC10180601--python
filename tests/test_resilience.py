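import numpy as np
import pandas as pd
import pytest

from dendrostress import (
    StressEvent,
    TreeSeries,
    anova_tukey,
    indices_for_forest,
    kruskal_dunn,
    lloret_indices,
    percent_decline,
    species_summary,
)


def make_tree(values: dict, tree_id="T1", species="SP"):
    return TreeSeries(tree_id=tree_id, species=species,
                      widths=pd.Series(values, dtype=float).sort_index())


class TestLloretIndices:
    def test_constant_growth_gives_unity(self):
        tree = make_tree({y: 2.0 for y in range(2000, 2006)})
        r = lloret_indices(tree, StressEvent(2003, window=1))
        assert (r.resistance, r.recovery, r.resilience) == (1.0, 1.0, 1.0)

    def test_single_year_window_ratios(self):
        tree = make_tree({2002: 4.0, 2003: 2.0, 2004: 3.0})
        r = lloret_indices(tree, StressEvent(2003, window=1))
        assert r.resistance == pytest.approx(0.5)
        assert r.recovery == pytest.approx(1.5)
        assert r.resilience == pytest.approx(0.75)

    def test_two_year_window_uses_means(self):
        tree = make_tree({2001: 4.0, 2002: 2.0, 2003: 2.0, 2004: 3.0, 2005: 3.0})
        r = lloret_indices(tree, StressEvent(2003, window=2))
        assert r.resistance == pytest.approx(2.0 / 3.0)
        assert r.recovery == pytest.approx(1.5)
        assert r.resilience == pytest.approx(1.0)

    def test_identity_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        for w in (1, 2):
            for _ in range(200):
                vals = rng.lognormal(1.0, 0.4, size=7)
                tree = make_tree(dict(zip(range(2000, 2007), vals)))
                r = lloret_indices(tree, StressEvent(2003, window=w))
                assert r.resilience == pytest.approx(r.resistance * r.recovery, rel=1e-12)
                scaled = make_tree(dict(zip(range(2000, 2007), 3.7 * vals)))
                rs = lloret_indices(scaled, StressEvent(2003, window=w))
                assert rs.resistance == pytest.approx(r.resistance, rel=1e-12)
                assert rs.recovery == pytest.approx(r.recovery, rel=1e-12)
                assert rs.resilience == pytest.approx(r.resilience, rel=1e-12)

    def test_missing_post_years_raise(self):
        tree = make_tree({2016: 1.0, 2017: 1.0, 2018: 1.0, 2019: 1.0})
        with pytest.raises(ValueError, match="2020"):
            lloret_indices(tree, StressEvent(2018, window=2))

    def test_incomplete_windows_dropped_in_bulk(self):
        trees = [make_tree({y: 1.0 for y in range(2016, 2020)}, tree_id=f"T{i}")
                 for i in range(3)]
        events = [StressEvent(2018, window=1), StressEvent(2018, window=2)]
        with pytest.warns(UserWarning, match="lacked complete windows"):
            out = indices_for_forest(trees, events)
        assert {r.window for r in out} == {1}  # w=2 needs 2020 data

    def test_percent_decline(self):
        assert percent_decline(0.72) == pytest.approx(28.0)


class TestSpeciesSummary:
    def test_single_tree_equals_its_indices(self):
        tree = make_tree({2002: 4.0, 2003: 2.0, 2004: 3.0})
        summary = species_summary([lloret_indices(tree, StressEvent(2003))])
        s = summary[0]
        assert s.per_event.loc[2003, "Rs"] == pytest.approx(0.5)
        assert s.pooled_median["Rc"] == pytest.approx(1.5)

    def test_median_across_trees(self):
        indices = []
        for i, rs in enumerate([0.5, 0.7, 0.9]):
            tree = make_tree({2002: 1.0, 2003: rs, 2004: 1.0}, tree_id=f"T{i}")
            indices.append(lloret_indices(tree, StressEvent(2003)))
        s = species_summary(indices)[0]
        assert s.per_event.loc[2003, "Rs"] == pytest.approx(0.7)

    def test_two_average_conventions(self):
        # median-of-event-medians vs pooled per-tree-per-event median
        indices = []
        for event in (2003, 2010):
            for i, rs in enumerate([0.4, 0.6, 0.8] if event == 2003 else [1.0, 1.2]):
                tree = make_tree({event - 1: 1.0, event: rs, event + 1: 1.0},
                                 tree_id=f"T{event}{i}")
                indices.append(lloret_indices(tree, StressEvent(event)))
        s = species_summary(indices)[0]
        assert s.average_of_medians["Rs"] == pytest.approx(np.median([0.6, 1.1]))
        assert s.pooled_median["Rs"] == pytest.approx(np.median([0.4, 0.6, 0.8, 1.0, 1.2]))


class TestGroupTests:
    def test_kruskal_identical_groups(self):
        out = kruskal_dunn({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert out["H"] == 0.0
        assert out["pairwise"] == []

    def test_kruskal_hand_oracle(self):
        groups = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}
        out = kruskal_dunn(groups)
        assert out["H"] == pytest.approx(7.2)
        z13 = next(p["z"] for p in out["pairwise"] if p["groups"] == ("g1", "g3"))
        assert z13 == pytest.approx(-6.0 / np.sqrt(5.0))

    def test_dunn_rejection_uses_half_alpha(self):
        groups = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}
        out = kruskal_dunn(groups, alpha=0.05)
        for p in out["pairwise"]:
            assert p["reject"] == (p["p_adjusted"] <= 0.025)

    def test_anova_identical_groups(self):
        out = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert out["F"] == 0.0

    def test_anova_hand_oracle(self):
        groups = {"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [3, 4, 5]}
        out = anova_tukey(groups)
        assert out["F"] == pytest.approx(3.0)

    def test_species_separation_in_resistance(self, study_climate):
        # species with drought multiplier 0.9 must out-resist one with 0.6
        from dendrostress import build_trees, simulate_forest
        from dendrostress.synthetic import ForestGenConfig
        rng_seeds = range(5)
        wins = 0
        for s in rng_seeds:
            groups = {}
            for species, mult in (("A", 0.9), ("B", 0.6)):
                cfg = ForestGenConfig(
                    species=species, n_trees=15, seed=100 + s * 2 + (species == "B"),
                    driver=("ppt", "FEB"), drought_multipliers={2003: mult},
                    year_effect_seed=900 + s,  # same site, shared year weather
                )
                cores, _ = simulate_forest(cfg, study_climate)
                trees = build_trees(cores)[species]
                idx = indices_for_forest(trees, [StressEvent(2003, window=1)])
                groups[species] = [r.resistance for r in idx]
            if np.median(groups["A"]) > np.median(groups["B"]):
                wins += 1
        assert wins == len(list(rng_seeds))
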