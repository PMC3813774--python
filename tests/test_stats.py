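"""Litter summaries, permutation inference, and step-down Šidák."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fgrtools.stats import (
    compare_groups,
    fetal_placental_ratio,
    interaction_permutation_test,
    litter_summaries,
    permutation_test,
    sequential_sidak,
    two_sample_t,
)
from fgrtools.synthetic import (
    CellMeans,
    FetusRecord,
    GeneratorConfig,
    generate_cohort,
)


def _fetus(fid, lid, genotype, treatment, fw, pw=0.09):
    return FetusRecord(fid, lid, genotype, treatment, fw, pw, 28, 25, 24)


def _null_cohort(seed, n_per_arm=8):
    m = CellMeans(1.0, 0.08, 28, 25, 24)
    gm = {(g, t): m for g in ("WT", "P0") for t in ("water", "SC")}
    cfg = GeneratorConfig(
        n_litters={"water": n_per_arm, "SC": n_per_arm},
        group_means=gm, seed=seed,
    )
    return generate_cohort(cfg)[1]


class TestLitterSummaries:
    def test_simple_mean(self):
        fetuses = [
            _fetus("a", "L1", "WT", "water", 1.0),
            _fetus("b", "L1", "WT", "water", 1.2),
        ]
        s = litter_summaries(fetuses, "fetal_weight")
        assert len(s) == 1
        assert s["value"].iloc[0] == pytest.approx(1.1)

    def test_single_pup_litter(self):
        s = litter_summaries([_fetus("a", "L1", "P0", "SC", 0.87)], "fetal_weight")
        assert s["value"].iloc[0] == 0.87 and s["n_pups"].iloc[0] == 1

    def test_litter_missing_genotype_contributes_one_cell(self):
        fetuses = [_fetus("a", "L1", "WT", "water", 1.0)]
        s = litter_summaries(fetuses, "fetal_weight")
        assert set(s["genotype"]) == {"WT"}

    def test_grand_mean_near_generator_mean(self):
        cfg = GeneratorConfig(seed=31)
        _, fetuses = generate_cohort(cfg)
        s = litter_summaries(fetuses, "fetal_weight")
        cell = s[(s.genotype == "WT") & (s.treatment == "water")]
        assert cell["value"].mean() == pytest.approx(1.20, abs=0.05)

    def test_missing_endpoint_rejected(self):
        with pytest.raises(KeyError):
            litter_summaries([_fetus("a", "L1", "WT", "water", 1.0)], "nope")


class TestPermutationTest:
    def test_all_identical_summaries_p_one(self):
        fetuses = [
            _fetus(f"f{i}", f"L{i}", "WT", trt, 1.0)
            for i, trt in enumerate(["water", "water", "SC", "SC"])
        ]
        s = litter_summaries(fetuses, "fetal_weight")
        assert permutation_test(s, "treatment", 99, seed=0).p == 1.0

    def test_type_one_error_calibration(self):
        # 1000 null datasets at alpha=0.05; permutation p-values are valid,
        # so the rejection rate must sit near the nominal level
        rejections = 0
        pvals = []
        for i in range(1000):
            fetuses = _null_cohort(seed=10_000 + i)
            s = litter_summaries(fetuses, "fetal_weight")
            p = permutation_test(s, "treatment", 199, seed=20_000 + i).p
            pvals.append(p)
            rejections += p <= 0.05
        assert 0.03 <= rejections / 1000 <= 0.07
        # and approximately uniform on (0, 1]
        ks = sps.kstest(pvals, "uniform")
        assert ks.statistic < 0.05

    def test_power_against_large_treatment_effect(self):
        m_lo = CellMeans(1.0, 0.08, 28, 25, 24)
        m_hi = CellMeans(1.5, 0.08, 28, 25, 24)  # ~7 between-litter SDs
        gm = {("WT", "water"): m_lo, ("P0", "water"): m_lo,
              ("WT", "SC"): m_hi, ("P0", "SC"): m_hi}
        hits = 0
        for i in range(40):
            cfg = GeneratorConfig(n_litters={"water": 8, "SC": 8},
                                  group_means=gm, seed=500 + i)
            s = litter_summaries(generate_cohort(cfg)[1], "fetal_weight")
            if permutation_test(s, "treatment", 999, seed=900 + i).p < 0.01:
                hits += 1
        assert hits >= 38  # >= 95% of replicates

    def test_genotype_permuted_within_litter(self):
        fetuses = _null_cohort(seed=42)
        s = litter_summaries(fetuses, "fetal_weight")
        res = permutation_test(s, "genotype", 199, seed=7)
        assert 0.0 < res.p <= 1.0

    def test_requires_two_litters_per_level(self):
        fetuses = [
            _fetus("a", "L1", "WT", "water", 1.0),
            _fetus("b", "L2", "WT", "SC", 1.1),
            _fetus("c", "L3", "WT", "SC", 1.2),
        ]
        s = litter_summaries(fetuses, "fetal_weight")
        with pytest.raises(ValueError):
            permutation_test(s, "treatment", 99, seed=0)

    def test_interaction_null_p_not_extreme(self):
        s = litter_summaries(_null_cohort(seed=3), "fetal_weight")
        res = interaction_permutation_test(s, 499, seed=11)
        assert 0.0 < res.p <= 1.0


class TestSequentialSidak:
    def test_single_p_unchanged(self):
        assert sequential_sidak([0.2]) == pytest.approx([0.2])

    def test_hand_computed_pair(self):
        adj = sequential_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert adj[1] == pytest.approx(0.04)

    def test_all_ones(self):
        assert sequential_sidak([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_original_order_preserved(self):
        adj = sequential_sidak([0.04, 0.01])
        assert adj[1] == pytest.approx(1 - 0.99**2)
        assert adj[0] == pytest.approx(0.04)

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=10)
        adj = sequential_sidak(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sequential_sidak([0.5, 1.2])


class TestRatiosAndT:
    def test_per_pup_ratio(self):
        per_pup, cells = fetal_placental_ratio(
            [_fetus("a", "L1", "WT", "water", 1.0, 0.1)]
        )
        assert per_pup["fp_ratio"].iloc[0] == pytest.approx(10.0)

    def test_ratio_unit_invariance(self):
        f1 = [_fetus("a", "L1", "WT", "water", 1.0, 0.1)]
        f2 = [_fetus("a", "L1", "WT", "water", 1000.0, 100.0)]  # mg
        r1, _ = fetal_placental_ratio(f1)
        r2, _ = fetal_placental_ratio(f2)
        assert r1["fp_ratio"].iloc[0] == pytest.approx(r2["fp_ratio"].iloc[0])

    def test_zero_placental_weight_is_error_row(self):
        per_pup, _ = fetal_placental_ratio(
            [_fetus("a", "L1", "WT", "water", 1.0, 0.0),
             _fetus("b", "L1", "WT", "water", 1.0, 0.1)]
        )
        assert per_pup["fp_ratio"].isna().iloc[0]
        assert per_pup["fp_ratio"].notna().iloc[1]

    def test_p0_ratio_exceeds_wt_on_calibrated_cohort(self, default_cohort):
        _, _, fetuses, _ = default_cohort
        _, cells = fetal_placental_ratio(fetuses)
        get = lambda g, t: float(
            cells[(cells.genotype == g) & (cells.treatment == t)]["mean"].iloc[0]
        )
        assert get("P0", "water") > get("WT", "water")
        assert get("P0", "SC") > get("WT", "SC")

    def test_t_identical_groups(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_t_matches_welch_formula(self):
        a = np.array([8.1, 7.9, 8.4, 8.0, 7.7])
        b = np.array([8.6, 8.9, 8.3, 8.8])
        # brute-force Welch formula as the oracle
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert 0 < p < 1

    def test_t_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestCompareGroups:
    def test_full_comparison_structure(self, default_cohort):
        _, _, fetuses, _ = default_cohort
        cmp_ = compare_groups(fetuses, "fetal_weight", n_perm=199, seed=5)
        assert set(cmp_.contrasts.columns) == {"contrast", "raw_p", "adj_p"}
        assert (cmp_.contrasts["adj_p"] >= cmp_.contrasts["raw_p"] - 1e-12).all()
        assert 0 < cmp_.p_genotype <= 1
        # calibrated genotype effect (1.20 vs 0.94) is unmissable
        assert cmp_.p_genotype < 0.05
        assert len(cmp_.cells) == 4

    def test_no_pup_changes_litter_under_permutation(self, default_cohort):
        # the permutation operates on litter summaries, so litter composition
        # is preserved by construction; verify summaries are litter-unique
        _, _, fetuses, _ = default_cohort
        s = litter_summaries(fetuses, "fetal_weight")
        assert not s.duplicated(["litter_id", "genotype"]).any()

    def test_delegated_mixed_model_runs(self, default_cohort):
        _, _, fetuses, _ = default_cohort
        cmp_ = compare_groups(
            fetuses, "fetal_weight", n_perm=99, seed=5,
            method="delegated_mixed_model",
        )
        assert 0 <= cmp_.p_genotype <= 1
        assert cmp_.p_genotype < 0.05
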