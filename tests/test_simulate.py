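"""Synthetic cohort generator: determinism, design counterbalancing, and
configured-probability checks."""

import json
import math
import warnings

import numpy as np
import pandas as pd
import pytest

import lexgaze as lg
from lexgaze import gaze as G
from lexgaze.network import build_network
from lexgaze.simulate import (
    EXPERIMENTAL_ITEMS,
    GazeParams,
    NormsParams,
    SimConfig,
    VocabParams,
    draw_truth,
    gen_children,
    gen_design,
    gen_gaze,
    gen_norms,
    gen_ratings,
    make_checklist,
    simulate_cohort,
)
from lexgaze.vocab import ChecklistDefinition

NULL_GAZE = dict(
    beta={"related": {"gcc": 0.0, "degree": 0.0, "density": 0.0},
          "unrelated": {"gcc": 0.0, "degree": 0.0, "density": 0.0}},
    gamma={"related": 0.0, "unrelated": 0.0},
)


def small_checklist(per_cat=10):
    items = {}
    for cat in lg.EXPERIMENTAL_CATEGORIES:
        stem = cat.lower().replace("-", "_")
        for i in range(per_cat):
            items[f"{stem}_{i}"] = cat
    return ChecklistDefinition(items=items)


class TestChecklist:
    def test_experimental_category_sizes_match_cdi(self):
        cl = make_checklist()
        sizes = {c: cl.category_size(c) for c in lg.EXPERIMENTAL_CATEGORIES}
        assert sizes == {
            "ANIMALS": 43, "CLOTHING": 28, "VEHICLES": 14,
            "BODY-PARTS": 27, "FRUIT": 7, "DRINKS": 7,
        }

    def test_experimental_items_present_in_their_categories(self):
        cl = make_checklist()
        for word, cat in EXPERIMENTAL_ITEMS.items():
            assert cl.items[word] == cat


class TestDeterminism:
    def test_same_seed_reproduces_cohort_exactly(self, shared_norms,
                                                 shared_adjacency):
        cohorts = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cohorts.append(simulate_cohort(
                    SimConfig(seed=42, n_children=8),
                    norms=shared_norms, adjacency=shared_adjacency,
                ))
        a, b = cohorts
        assert [c.produced for c in a.children] == [c.produced for c in b.children]
        pd.testing.assert_frame_equal(a.design, b.design)
        assert a.ratings == b.ratings
        assert a.truth == b.truth
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.states, tb.states)

    def test_different_seeds_differ(self, shared_norms, shared_adjacency):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = simulate_cohort(SimConfig(seed=1, n_children=5),
                                norms=shared_norms, adjacency=shared_adjacency)
            b = simulate_cohort(SimConfig(seed=2, n_children=5),
                                norms=shared_norms, adjacency=shared_adjacency)
        assert any(
            not np.array_equal(ta.states, tb.states)
            for ta, tb in zip(a.trials, b.trials)
        )

    def test_sim_truth_round_trips_exactly(self, tmp_path):
        truth = draw_truth(SimConfig(seed=9))
        path = tmp_path / "truth.json"
        truth.to_json(path)
        assert lg.SimTruth.from_json(path) == truth


class TestDesign:
    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_trial_and_condition_counts(self, seed):
        d = gen_design(SimConfig(seed=seed), "c0", 0)
        assert len(d) == 24
        assert (d["condition"] == "related").sum() == 12
        assert (d["condition"] == "unrelated").sum() == 12
        assert sorted(d["block"].unique()) == [1, 2, 3, 4]
        assert (d["block"].value_counts() == 6).all()

    @pytest.mark.parametrize("seed", [0, 3])
    def test_each_image_fully_counterbalanced(self, seed):
        d = gen_design(SimConfig(seed=seed), "c0", 1)
        for img in EXPERIMENTAL_ITEMS:
            as_t = d[d["target"] == img]
            as_d = d[d["distractor"] == img]
            assert len(as_t) == 2 and len(as_d) == 2  # 4 appearances
            assert sorted(as_t["condition"]) == ["related", "unrelated"]
            assert sorted(as_d["condition"]) == ["related", "unrelated"]
            sides = list(as_t["target_side"]) + [
                "left" if s == "right" else "right" for s in as_d["target_side"]
            ]
            assert sorted(sides) == ["left", "left", "right", "right"]

    def test_pairings_respect_category_structure(self):
        d = gen_design(SimConfig(seed=2), "c0", 0)
        for row in d.itertuples():
            same = (EXPERIMENTAL_ITEMS[row.target]
                    == EXPERIMENTAL_ITEMS[row.distractor])
            assert same == (row.condition == "related")


class TestNorms:
    def test_zero_between_probability_blocks_cross_edges(self):
        cl = small_checklist()
        cfg = SimConfig(seed=3, norms=NormsParams(p_within=1.0, p_between=0.0))
        norms = gen_norms(cfg, cl)
        net = build_network(set(cl.items), norms)
        for e in net.edges:
            a, b = tuple(e)
            assert cl.items[a] == cl.items[b]

    def test_full_within_probability_connects_category_pairs(self):
        cl = small_checklist()
        cfg = SimConfig(seed=3, norms=NormsParams(p_within=1.0, p_between=0.0))
        net = build_network(set(cl.items), gen_norms(cfg, cl))
        for cat in lg.EXPERIMENTAL_CATEGORIES:
            members = sorted(cl.category_items(cat))
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert frozenset((a, b)) in net.edges

    def test_taxonomic_sharing_alone_creates_no_edges(self):
        cl = small_checklist()
        cfg = SimConfig(seed=3, norms=NormsParams(p_within=0.0, p_between=0.0))
        net = build_network(set(cl.items), gen_norms(cfg, cl))
        assert not net.edges  # category-wide taxonomic feature filtered out

    def test_empirical_edge_rates_match_configured(self):
        cl = small_checklist()  # 60 concepts
        p_w, p_b = 0.4, 0.1
        n_within = n_between = hit_w = hit_b = 0
        for rep in range(50):
            cfg = SimConfig(seed=100 + rep,
                            norms=NormsParams(p_within=p_w, p_between=p_b))
            net = build_network(set(cl.items), gen_norms(cfg, cl))
            words = sorted(cl.items)
            for i, a in enumerate(words):
                for b in words[i + 1:]:
                    same = cl.items[a] == cl.items[b]
                    linked = frozenset((a, b)) in net.edges
                    if same:
                        n_within += 1
                        hit_w += linked
                    else:
                        n_between += 1
                        hit_b += linked
        for hits, n, p in ((hit_w, n_within, p_w), (hit_b, n_between, p_b)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(hits / n - p) < 3 * se


class TestChildren:
    def test_degenerate_size_distribution(self):
        cfg = SimConfig(seed=4, n_children=10,
                        vocab=VocabParams(min_words=10, max_words=10))
        kids = gen_children(cfg)
        assert all(c.total_produced == 10 for c in kids)

    def test_infinite_concentration_equalizes_composition(self):
        cl = make_checklist()
        cfg = SimConfig(seed=4, n_children=30,
                        vocab=VocabParams(concentration=np.inf))
        kids = gen_children(cfg, cl)
        from lexgaze.vocab import category_proportions

        # with identical item weights, per-category production rates track
        # vocabulary size tightly: proportions normalized by size are stable
        for child in kids[:10]:
            props = category_proportions(child, cl)
            vals = np.array(list(props.values()))
            expected = child.total_produced / len(cl.items)
            assert np.allclose(vals, expected, atol=4 * math.sqrt(
                expected * (1 - expected) / 7))  # binomial noise, smallest n=7

    def test_sizes_match_calibrated_distribution(self):
        # truncated log-normal calibrated to mean 92.1 and median 61
        sizes = []
        for rep in range(50):
            cfg = SimConfig(seed=500 + rep)
            sizes.extend(c.total_produced for c in gen_children(cfg))
        sizes = np.array(sizes)
        assert sizes.min() >= 10 and sizes.max() <= 374
        se = sizes.std(ddof=1) / math.sqrt(len(sizes))
        assert abs(sizes.mean() - 92.1) < 2 * se


class TestRatings:
    def make_kids(self, cfg):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return gen_children(cfg)

    def test_zero_low_probability_keeps_every_trial(self):
        cfg = SimConfig(seed=6, n_children=10, low_rating_prob=0.0)
        ratings = gen_ratings(cfg, self.make_kids(cfg))
        assert all(r >= 2 for r in ratings.values())

    def test_unit_probability_removes_everything(self):
        cfg = SimConfig(seed=6, n_children=10, low_rating_prob=1.0)
        ratings = gen_ratings(cfg, self.make_kids(cfg))
        assert all(r == 1 for r in ratings.values())

    def test_default_rate_matches_comprehension_bookkeeping_scale(self):
        # at ~4.8% per trial, a 79-child cohort loses ~90 of ~1892 trials
        cfg = SimConfig(seed=6, low_rating_prob=0.048)
        ratings = gen_ratings(cfg, self.make_kids(cfg))
        n = len(ratings)  # 79 x 12 rated items, each appearing in 2 trials
        low = sum(1 for r in ratings.values() if r < 2)
        expected = 0.048 * n
        assert abs(low - expected) < 3 * math.sqrt(n * 0.048 * 0.952)


class TestGaze:
    def run_cohort(self, cfg, shared_norms, shared_adjacency):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return simulate_cohort(cfg, norms=shared_norms,
                                   adjacency=shared_adjacency)

    def test_null_config_is_symmetric(self, shared_norms, shared_adjacency):
        cfg = SimConfig(seed=7, n_children=30,
                        gaze=GazeParams(beta0=0.0, beta_cond=0.0,
                                        item_intercept_sd=0.0, **NULL_GAZE))
        cohort = self.run_cohort(cfg, shared_norms, shared_adjacency)
        n_t = n_d = 0
        latency = int(cfg.gaze.latency_ms)
        for t in cohort.trials:
            post = t.states[t.times >= latency]
            n_t += int((post == G.GazeState.TARGET).sum())
            n_d += int((post == G.GazeState.DISTRACTOR).sum())
        se = math.sqrt(n_t + n_d)  # conservative for a paired count contrast
        assert abs(n_t - n_d) < 3 * se

    def test_strong_preference_dominates_trials(self, shared_norms,
                                                shared_adjacency):
        cfg = SimConfig(seed=8, n_children=20,
                        gaze=GazeParams(beta0=4.0, beta_cond=0.0,
                                        item_intercept_sd=0.0,
                                        fussy_trial_prob=0.0, **NULL_GAZE))
        cohort = self.run_cohort(cfg, shared_norms, shared_adjacency)
        accs = [G.trial_log_gaze(t) for t in cohort.trials]
        pos = sum(1 for a in accs if a.log_gaze > 0)
        assert pos / len(accs) >= 0.99

    def test_high_offscreen_rate_fails_track_loss(self, shared_norms,
                                                  shared_adjacency):
        cfg = SimConfig(seed=9, n_children=20,
                        gaze=GazeParams(offscreen_rate=0.9,
                                        fussy_trial_prob=0.0))
        cohort = self.run_cohort(cfg, shared_norms, shared_adjacency)
        accs = [G.trial_log_gaze(t) for t in cohort.trials]
        failing = sum(1 for a in accs if a.onscreen_prop < 0.2)
        assert failing > len(accs) / 2

    def test_target_curve_rises_above_distractor_after_latency(
            self, small_cohort):
        accs = [G.trial_log_gaze(t) for t in small_cohort.trials]
        retained, _ = G.filter_trials(small_cohort.trials, accs)
        tc = G.grand_timecourse([t for t, _ in retained])
        post = tc[tc["bin_start_ms"] >= 800]
        assert (post["p_target"] > post["p_distractor"]).mean() > 0.95

    def test_unreachable_stationary_config_rejected(self):
        with pytest.raises(ValueError):
            GazeParams(offscreen_rate=1.0).validate()


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=13, n_children=5,
                        gaze=GazeParams(beta0=0.1, latency_ms=450.0))
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_children=1)
        with pytest.raises(ValueError):
            SimConfig(low_rating_prob=1.5)
        with pytest.raises(ValueError):
            SimConfig(gaze=GazeParams(stay_prob=1.0))
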