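"""Subject-relabeling permutation inference and FDR."""

from itertools import combinations

import numpy as np
import pytest

from scnet import (
    CohortSpec,
    DensityGrid,
    build_stack,
    clustering_coefficient,
    fdr_bh,
    generate_cohort,
    global_metric_difference_test,
    group_correlation,
    nodal_betweenness_test,
    permute_groups,
    residualize,
)
from scnet.permutation import PermutationSpec

from oracles import bh_oracle


class TestPermuteGroups:
    def test_partition_contract(self):
        a, b = permute_groups(70, (32, 38), seed=0, index=0)
        assert len(a) == 32 and len(b) == 38
        assert not set(a) & set(b)
        assert set(a) | set(b) == set(range(70))

    def test_reproducible_given_seed_and_index(self):
        a1, b1 = permute_groups(20, (8, 12), seed=5, index=17)
        a2, b2 = permute_groups(20, (8, 12), seed=5, index=17)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(b1, b2)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            permute_groups(10, (4, 5), seed=0, index=0)

    def test_partitions_are_uniform(self):
        # all C(8,4)=70 group-A selections should be equally likely
        n_draws = 10_000
        counts = {frozenset(c): 0 for c in combinations(range(8), 2 * 2)}
        counts = {frozenset(c): 0 for c in combinations(range(8), 4)}
        for k in range(n_draws):
            a, _ = permute_groups(8, (4, 4), seed=123, index=k)
            counts[frozenset(a.tolist())] += 1
        p = 1 / 70
        se = np.sqrt(p * (1 - p) / n_draws)
        freqs = np.array(list(counts.values())) / n_draws
        assert np.all(np.abs(freqs - p) < 3.5 * se)


class TestFdrBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.04]), [0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-12
        )

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            np.testing.assert_allclose(fdr_bh(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_bh([1.5])


@pytest.fixture(scope="module")
def null_resid():
    spec = CohortSpec(
        n_regions=20, n_per_group=(12, 12), n_modules=4,
        within_r_by_group=(0.5, 0.5), between_r=0.1, seed=77,
    )
    table, _ = generate_cohort(spec)
    resid = residualize(table)
    rows_a = resid.rows_for(table.loc[table["group"] == "control", "subject_id"])
    rows_b = resid.rows_for(table.loc[table["group"] == "patient", "subject_id"])
    return resid, rows_a, rows_b


class TestGlobalMetricTest:
    def test_identical_groups_give_zero_difference_and_p_one(self, null_resid):
        resid, rows_a, _ = null_resid
        res = global_metric_difference_test(
            resid, rows_a, rows_a, DensityGrid((0.2, 0.3)), "Cp",
            PermutationSpec(n_perm=25, seed=1),
        )
        np.testing.assert_allclose(res.observed, 0.0, atol=1e-14)
        np.testing.assert_allclose(res.p_raw, 1.0)

    def test_observed_matches_direct_metric_computation(self, null_resid):
        resid, rows_a, rows_b = null_resid
        grid = DensityGrid((0.15, 0.25))
        res = global_metric_difference_test(
            resid, rows_a, rows_b, grid, "Cp", PermutationSpec(n_perm=9, seed=2)
        )
        direct = []
        for rows in (rows_a, rows_b):
            stack = build_stack(group_correlation(resid, rows), grid)
            direct.append([clustering_coefficient(g)[1] for _, g in stack])
        np.testing.assert_allclose(res.observed, np.array(direct[0]) - direct[1], atol=1e-14)

    def test_full_determinism(self, null_resid):
        resid, rows_a, rows_b = null_resid
        spec = PermutationSpec(n_perm=19, seed=4)
        grid = DensityGrid((0.2,))
        r1 = global_metric_difference_test(resid, rows_a, rows_b, grid, "Cp", spec)
        r2 = global_metric_difference_test(resid, rows_a, rows_b, grid, "Cp", spec)
        np.testing.assert_array_equal(r1.null_samples, r2.null_samples)
        np.testing.assert_array_equal(r1.p_raw, r2.p_raw)

    def test_pvalues_never_zero_and_fdr_dominates(self, null_resid):
        resid, rows_a, rows_b = null_resid
        res = global_metric_difference_test(
            resid, rows_a, rows_b, DensityGrid((0.1, 0.2, 0.3)), "Eglob",
            PermutationSpec(n_perm=39, seed=6),
        )
        assert np.all(res.p_raw > 0)
        assert np.all(res.p_fdr >= res.p_raw - 1e-15)
        assert np.all(res.null_ci_low <= res.null_ci_high)

    def test_small_world_metric_runs_with_reduced_ensemble(self, null_resid):
        resid, rows_a, rows_b = null_resid
        res = global_metric_difference_test(
            resid, rows_a, rows_b, DensityGrid((0.3,)), "sigma",
            PermutationSpec(n_perm=3, seed=8, n_random_small_world=3),
        )
        assert np.isfinite(res.observed).all()

    def test_unknown_metric_rejected(self, null_resid):
        resid, rows_a, rows_b = null_resid
        with pytest.raises(ValueError, match="unknown metric"):
            global_metric_difference_test(
                resid, rows_a, rows_b, DensityGrid((0.2,)), "degree",
                PermutationSpec(n_perm=3, seed=0),
            )

    def test_null_pvalues_super_uniform(self):
        """Under exchangeable null cohorts the permutation p-values must be
        (super-)uniform: ECDF(t) <= t + sampling error."""
        n_rep = 200
        pvals = np.empty(n_rep)
        grid = DensityGrid((0.2,))
        for rep in range(n_rep):
            spec = CohortSpec(
                n_regions=16, n_per_group=(10, 10), n_modules=4,
                within_r_by_group=(0.4, 0.4), between_r=0.1, seed=10_000 + rep,
            )
            table, _ = generate_cohort(spec)
            resid = residualize(table)
            ga = resid.rows_for(table.loc[table["group"] == "control", "subject_id"])
            gb = resid.rows_for(table.loc[table["group"] == "patient", "subject_id"])
            res = global_metric_difference_test(
                resid, ga, gb, grid, "Cp", PermutationSpec(n_perm=99, seed=rep)
            )
            pvals[rep] = res.p_raw[0]
        assert np.all(pvals > 0)
        grid_t = np.linspace(0.01, 1.0, 100)
        ecdf = (pvals[None, :] <= grid_t[:, None]).mean(axis=1)
        assert np.max(ecdf - grid_t) < 0.08
        assert 0.01 <= (pvals <= 0.05).mean() <= 0.10


class TestNodalTest:
    def test_identical_groups_all_p_one(self, null_resid):
        resid, rows_a, _ = null_resid
        res = nodal_betweenness_test(
            resid, rows_a, rows_a, DensityGrid((0.2, 0.3)),
            PermutationSpec(n_perm=9, seed=3),
        )
        np.testing.assert_allclose(res.p_raw, 1.0)
        assert len(res.index) == 20

    def test_planted_module_effect_localizes(self):
        """Raising one module's within-correlation only in group A should
        concentrate the smallest nodal p-values in that module."""
        from scnet.synthetic import even_module_assignment, _psd_sqrt, META_COLUMNS
        import pandas as pd

        rng = np.random.default_rng(55)
        n, n_sub = 20, 200
        modules = even_module_assignment(n, 4)
        from scnet import make_modular_correlation

        boost = modules == 0
        r_b = make_modular_correlation(n, modules, 0.3, 0.05)
        r_a = r_b.copy()
        r_a[np.ix_(boost, boost)] = 0.95
        np.fill_diagonal(r_a, 1.0)
        rows = []
        for gname, r in (("control", r_a), ("patient", r_b)):
            L = _psd_sqrt(r)
            for i in range(n_sub):
                z = rng.standard_normal(n)
                rows.append([f"{gname[0]}{i}", gname, 60.0, 0, 10.0, *(L @ z)])
        table = pd.DataFrame(rows, columns=list(META_COLUMNS) + [f"R{j:02d}" for j in range(n)])
        table["age"] = rng.uniform(55, 80, len(table))
        table["sex"] = rng.integers(0, 2, len(table))
        table["education"] = rng.uniform(6, 16, len(table))
        resid = residualize(table, include_mean_volume=False)
        ga = resid.rows_for(table.loc[table["group"] == "control", "subject_id"])
        gb = resid.rows_for(table.loc[table["group"] == "patient", "subject_id"])
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)  # sparse permuted graphs
            res = nodal_betweenness_test(
                resid, ga, gb, DensityGrid((0.10, 0.15, 0.20, 0.25, 0.30)),
                PermutationSpec(n_perm=99, seed=9),
            )
        top5 = np.argsort(res.p_raw)[:5]
        in_module = np.isin(top5, np.nonzero(boost)[0])
        assert in_module.sum() >= 3
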