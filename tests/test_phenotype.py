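"""Biomass matrix normalization, filtering, variability, clustering."""

import numpy as np
import pandas as pd
import pytest

import hubnet
from hubnet import (
    SyntheticConfig,
    apply_filters,
    batch_normalize,
    detect_hyper_strains,
    hierarchical_cluster,
    variability_summary,
)

from .conftest import make_biofilm


def simple_matrix(values, envs=None, **kwargs):
    envs = envs or [f"e{j}" for j in range(len(values[0]))]
    strains = ["WT"] + [f"s{i}" for i in range(len(values) - 1)]
    df = pd.DataFrame(values, index=strains, columns=envs, dtype=float)
    return make_biofilm(df, **kwargs)


class TestBatchNormalize:
    def test_division_by_batch_wt_mean(self):
        m = simple_matrix([[0.5, 0.5], [0.25, 1.0]])
        norm = batch_normalize(m)
        assert norm.values.at["s0", "e0"] == pytest.approx(0.5)
        assert norm.values.at["s0", "e1"] == pytest.approx(2.0)

    def test_identical_to_wt_gives_ones(self):
        m = simple_matrix([[0.4, 0.6], [0.4, 0.6], [0.4, 0.6]])
        norm = batch_normalize(m)
        assert np.allclose(norm.values.values, norm.values.values[0])
        # wild-type entries average 1 within the batch
        assert norm.wt.mean() == pytest.approx(1.0)

    def test_planted_batch_multipliers_removed(self):
        """Generator batches with multipliers {1, 2}: normalization levels them."""
        rng = np.random.default_rng(0)
        envs = [f"e{j}" for j in range(40)]
        batches = {e: ("b1" if j < 20 else "b2") for j, e in enumerate(envs)}
        mult = np.array([1.0] * 20 + [2.0] * 20)
        base = 0.5 + rng.normal(0, 0.05, size=(10, 40))
        df = pd.DataFrame(base * mult, columns=envs,
                          index=["WT"] + [f"s{i}" for i in range(9)])
        norm = batch_normalize(make_biofilm(df, batches=batches))
        b1 = norm.values[envs[:20]].values.mean()
        b2 = norm.values[envs[20:]].values.mean()
        assert abs(b1 - b2) / b1 < 0.05

    def test_zero_wt_batch_named_in_error(self):
        m = simple_matrix([[0.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="batch"):
            batch_normalize(m)

    def test_second_normalization_refused(self):
        m = simple_matrix([[0.5, 0.5], [0.25, 1.0]])
        norm = batch_normalize(m)
        with pytest.raises(ValueError, match="already"):
            batch_normalize(norm)

    def test_negative_readings_floored(self):
        m = simple_matrix([[0.5, 0.5], [-0.1, 0.4]])
        norm = batch_normalize(m)
        assert norm.values.at["s0", "e0"] == 0.0

    def test_subtract_mode_centers_wt_at_zero(self):
        m = simple_matrix([[0.5, 0.5], [0.3, 0.8]])
        norm = batch_normalize(m, mode="subtract")
        assert norm.wt.mean() == pytest.approx(0.0, abs=1e-12)
        assert norm.values.at["s0", "e0"] == pytest.approx(-0.2)


class TestApplyFilters:
    def test_fixture_arithmetic_50x188_to_42x182(self, default_bundle):
        bio = default_bundle["biofilm"]
        truth = default_bundle["biofilm_truth"]
        assert bio.values.shape == (50, 188)
        norm = batch_normalize(bio)
        filtered = apply_filters(norm, truth.hyper_strains,
                                 truth.detergent_envs)
        assert filtered.values.shape == (42, 182)

    def test_empty_lists_are_identity(self, default_bundle):
        bio = default_bundle["biofilm"]
        out = apply_filters(bio, [], [])
        assert out.values.shape == bio.values.shape

    def test_removing_all_environments_errors(self):
        m = simple_matrix([[0.5, 0.5], [0.3, 0.8]])
        with pytest.raises(ValueError, match="no environments remain"):
            apply_filters(m, [], ["e0", "e1"])

    def test_unknown_identifier_errors(self):
        m = simple_matrix([[0.5, 0.5], [0.3, 0.8]])
        with pytest.raises(KeyError):
            apply_filters(m, ["nope"], [])

    def test_idempotent_with_same_lists(self, default_bundle):
        bio = default_bundle["biofilm"]
        truth = default_bundle["biofilm_truth"]
        once = apply_filters(bio, truth.hyper_strains, truth.detergent_envs)
        twice = apply_filters(once, truth.hyper_strains, truth.detergent_envs)
        assert once.values.equals(twice.values)


class TestDetectHyperStrains:
    def test_planted_constitutive_fixture_recovered_exactly(self):
        """8 strains at +3×0.09 over a homogeneous background: exact recovery."""
        rng = np.random.default_rng(2)
        envs = [f"e{j}" for j in range(100)]
        strains = ["WT"] + [f"s{i:02d}" for i in range(49)]
        hyper = [f"s{i:02d}" for i in range(8)]
        base = 1.0 + rng.normal(0, 0.03, size=(50, 100))
        df = pd.DataFrame(base, index=strains, columns=envs)
        df.loc[hyper] += 3 * 0.09
        detected = detect_hyper_strains(make_biofilm(df), quantile=0.75)
        assert detected == hyper

    def test_homogeneous_matrix_gives_empty_list(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            1.0 + rng.normal(0, 0.03, size=(20, 50)),
            index=["WT"] + [f"s{i}" for i in range(19)],
            columns=[f"e{j}" for j in range(50)],
        )
        assert detect_hyper_strains(make_biofilm(df)) == []

    def test_half_time_high_strain_not_returned(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            1.0 + rng.normal(0, 0.03, size=(20, 50)),
            index=["WT"] + [f"s{i}" for i in range(19)],
            columns=[f"e{j}" for j in range(50)],
        )
        df.loc["s0", df.columns[:25]] += 1.0  # high in only half the envs
        assert "s0" not in detect_hyper_strains(make_biofilm(df))

    def test_planted_hypers_dominate_as_a_group(self, default_bundle):
        """At generator defaults the planted hyper strains have the top group mean."""
        bio = default_bundle["biofilm"]
        truth = default_bundle["biofilm_truth"]
        norm = batch_normalize(bio)
        means = norm.mutant_values.mean(axis=1)
        hyper_mean = means[truth.hyper_strains].mean()
        others = means.drop(index=truth.hyper_strains)
        assert hyper_mean > others.mean() + 2 * others.std()


class TestVariabilitySummary:
    def test_constant_matrix_all_zero(self):
        m = simple_matrix([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        vs = variability_summary(m)
        assert vs.median_sd_across_strains == 0.0
        assert vs.median_sd_across_environments == 0.0

    def test_two_by_two_hand_computation(self):
        """Rows [0,1] twice: environment-axis SD 0.7071, strain-axis 0."""
        df = pd.DataFrame(
            [[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]],
            index=["WT", "s0", "s1"], columns=["e0", "e1"],
        )
        vs = variability_summary(make_biofilm(df))
        assert vs.median_sd_across_environments == pytest.approx(
            0.7071, abs=1e-4
        )
        assert vs.median_sd_across_strains == 0.0

    def test_invariant_under_permutation(self, default_bundle):
        bio = default_bundle["biofilm"]
        rng = np.random.default_rng(5)
        vs1 = variability_summary(bio)
        shuffled = bio.values.iloc[
            rng.permutation(len(bio.values)),
            rng.permutation(bio.values.shape[1]),
        ]
        vs2 = variability_summary(
            make_biofilm(shuffled.copy())
        )
        assert vs1.median_sd_across_strains == pytest.approx(
            vs2.median_sd_across_strains
        )
        assert vs1.median_sd_across_environments == pytest.approx(
            vs2.median_sd_across_environments
        )


class TestHierarchicalCluster:
    def test_identical_rows_adjacent_and_merged_at_zero(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 1.5], [0.1, 0.2, 0.15], [0.1, 0.2, 0.15]],
            index=["WT", "s0", "s1"], columns=["e0", "e1", "e2"],
        )
        res = hierarchical_cluster(make_biofilm(df))
        order = res.strain_order
        assert abs(order.index("s0") - order.index("s1")) == 1
        assert res.strain_linkage[0, 2] == 0.0  # first merge at height 0

    def test_block_structure_separated_at_top_split(self):
        rng = np.random.default_rng(6)
        lows = rng.normal(0.2, 0.01, size=(5, 20))
        highs = rng.normal(1.8, 0.01, size=(5, 20))
        df = pd.DataFrame(
            np.vstack([lows, highs]),
            index=["WT"] + [f"lo{i}" for i in range(4)]
            + [f"hi{i}" for i in range(5)],
            columns=[f"e{j}" for j in range(20)],
        )
        res = hierarchical_cluster(make_biofilm(df))
        order = res.strain_order
        lo_pos = [order.index(s) for s in df.index[:5]]
        hi_pos = [order.index(s) for s in df.index[5:]]
        assert max(lo_pos) < min(hi_pos) or max(hi_pos) < min(lo_pos)

    def test_single_row_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["WT"], columns=["e0", "e1"])
        with pytest.raises(ValueError):
            hierarchical_cluster(make_biofilm(df))

    def test_deterministic(self, default_bundle):
        bio = default_bundle["biofilm"]
        a = hierarchical_cluster(bio)
        b = hierarchical_cluster(bio)
        assert a.strain_order == b.strain_order
        assert a.environment_order == b.environment_order


class TestPlantedVarianceOrdering:
    def test_strain_axis_exceeds_environment_axis(self):
        """Planted strain SD 0.09 > env SD 0.07: ordering recovered in ≥18/20 seeds."""
        wins = 0
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed)
            net, nt = hubnet.generate_network(cfg)
            bio, bt = hubnet.generate_biofilm(cfg, net, nt)
            norm = batch_normalize(bio)
            filt = apply_filters(norm, bt.hyper_strains, bt.detergent_envs)
            vs = variability_summary(filt)
            if vs.median_sd_across_strains > vs.median_sd_across_environments:
                wins += 1
        assert wins >= 18
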