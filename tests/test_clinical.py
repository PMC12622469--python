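"""TII scoring, dispatched tests, correlations, DE filter, utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephroimc.clinical import (
    compare_multi_groups,
    compare_two_groups,
    correlate,
    de_filter,
    normalize_to_creatinine,
    score_tii,
    tii_field_score,
)


class TestTII:
    @pytest.mark.parametrize(
        "frac, score",
        [
            (0.0, 0),
            (0.05, 1),
            (0.10, 2),  # exactly 10% belongs to the 10-25% bin
            (0.25, 2),
            (0.30, 3),
            (0.50, 3),
            (0.75, 4),
            (0.76, 5),
            (1.0, 5),
        ],
    )
    def test_field_scale(self, frac, score):
        assert tii_field_score(frac) == score

    def test_mean_of_fields(self):
        fields = [0.15] * 5 + [0.30] * 5  # five 2s and five 3s
        assert score_tii(fields) == 2.5

    def test_minimum_field_count_enforced(self):
        with pytest.raises(ValueError, match="at least 10"):
            score_tii([0.3] * 9)
        assert score_tii([0.3] * 9, min_fields=5) == 3.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=10, max_size=15),
        st.integers(0, 9),
        st.floats(0, 1),
    )
    def test_monotone_in_any_field(self, fracs, idx, bump):
        """Raising one field's injured fraction never lowers the TII."""
        before = score_tii(fracs)
        fracs2 = list(fracs)
        fracs2[idx] = min(1.0, fracs2[idx] + bump)
        assert score_tii(fracs2) >= before


class TestTwoGroups:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_two_groups(x, x)
        assert res.p == 1.0
        assert res.direction == 0

    def test_exact_mwu_matches_enumeration(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([6.0, 7, 8, 9, 10])
        res = compare_two_groups(x, y, method="mann-whitney")
        assert res.test_used == "mann-whitney"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(2.0 / 252.0)

    @pytest.mark.parametrize("nx, ny", [(4, 4), (5, 6), (6, 8)])
    def test_exact_mwu_full_enumeration_oracle(self, nx, ny):
        """Exact two-sided MWU p equals brute-force enumeration of all
        rank assignments for small untied samples."""
        rng = np.random.default_rng(nx * 100 + ny)
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = pooled[:nx], pooled[nx:]

        def u_stat(a, b):
            return sum((ai > bj) for ai, bj in itertools.product(a, b))

        u_obs = u_stat(x, y)
        n_tot = 0
        n_extreme = 0
        mu = nx * ny / 2.0
        for combo in itertools.combinations(range(nx + ny), nx):
            a = pooled[list(combo)]
            b = np.delete(pooled, list(combo))
            u = u_stat(a, b)
            n_tot += 1
            if abs(u - mu) >= abs(u_obs - mu):
                n_extreme += 1
        expected_p = n_extreme / n_tot
        res = compare_two_groups(x, y, method="mann-whitney")
        assert res.test_used == "mann-whitney"
        assert res.p == pytest.approx(expected_p, rel=1e-9)

    def test_dispatch_selects_t_for_normal_equal_variance(self):
        # under normality P(pass both Shapiros and Levene) ~ 0.95^3 = 0.857;
        # bound set 3+ binomial SDs below that mean
        picks = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            x = rng.normal(0, 1, 30)
            y = rng.normal(0.3, 1, 30)
            if compare_two_groups(x, y).test_used == "t":
                picks += 1
        assert picks >= 0.78 * n_sim

    def test_degenerate_equal_constants(self):
        res = compare_two_groups([2.0] * 5, [2.0] * 5)
        assert res.degenerate and res.p == 1.0

    def test_dispatch_deterministic(self):
        rng = np.random.default_rng(7)
        x, y = rng.exponential(1, 20), rng.exponential(2, 20)
        r1, r2 = compare_two_groups(x, y), compare_two_groups(x, y)
        assert r1.test_used == r2.test_used and r1.p == r2.p


class TestMultiGroups:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        res = compare_multi_groups([g, g, g])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_anova_significant(self):
        groups = {"a": [1.0, 2, 3], "b": [11.0, 12, 13], "c": [21.0, 22, 23]}
        res = compare_multi_groups(groups)
        # closed form: MSbetween = 300, MSwithin = 1 -> F = 300
        assert res.test_used == "anova+tukey"
        assert res.statistic == pytest.approx(300.0)
        assert res.p < 0.001
        assert (res.posthoc["reject"].astype(bool)).all()

    def test_skewed_groups_dispatch_kruskal(self):
        picks = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            groups = [rng.lognormal(0, 2.0, 15) for _ in range(3)]
            res = compare_multi_groups(groups)
            if res.test_used.startswith("kruskal"):
                picks += 1
        assert picks >= 18

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 3"):
            compare_multi_groups([[1.0, 2, 3], [1.0, 2], [1.0, 2, 3]])


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.array([0.1, 0.9, 0.4, 0.6, 0.3, 0.8, 0.2])
        r, p, used = correlate(x, 2 * x + 1, method="pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_spearman_rho_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        r, _, _ = correlate(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)

    def test_hand_computed_spearman(self):
        # d = (1,-1,1,-1,0) -> rho = 1 - 6*4/(5*24) = 0.8... recompute:
        # sum d^2 = 1+1+1+1+0 = 4 -> rho = 1 - 24/120 = 0.8? No:
        # pairs (1,2),(2,1),(3,4),(4,3),(5,5): sum d^2 = 1+1+1+1+0 = 4;
        # rho = 1 - 6*4/(5*(25-1)) = 1 - 24/120 = 0.8. Using the stated
        # permutation y = (2,1,4,3,5): rho = 0.8
        r, _, _ = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], method="spearman")
        assert r == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        r, p, used = correlate([1.0] * 6, [1.0, 2, 3, 4, 5, 6])
        assert used == "undefined" and np.isnan(r)

    def test_auto_dispatch_normal_gives_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 0.5, 50)
        _, _, used = correlate(x, y, method="auto")
        assert used == "pearson"


class TestUtilities:
    def test_creatinine_ratio(self):
        assert normalize_to_creatinine(100.0, 50.0) == 2.0
        assert normalize_to_creatinine(0.0, 50.0) == 0.0
        assert normalize_to_creatinine(200.0, 100.0) == normalize_to_creatinine(100.0, 50.0)

    def test_creatinine_nonpositive_fails(self):
        with pytest.raises(ValueError):
            normalize_to_creatinine(10.0, 0.0)

    @pytest.mark.parametrize(
        "log2fc, fdr, kept, direction",
        [
            (1.6, 0.01, True, "up"),
            (1.5, 0.01, False, None),  # strict threshold
            (-1.8, 0.04, True, "down"),
            (2.0, 0.05, False, None),  # strict FDR
        ],
    )
    def test_de_filter_boundaries(self, log2fc, fdr, kept, direction):
        df = pd.DataFrame({"gene": ["g"], "log2fc": [log2fc], "fdr": [fdr]})
        up, down = de_filter(df)
        if not kept:
            assert up.empty and down.empty
        elif direction == "up":
            assert len(up) == 1 and down.empty
        else:
            assert len(down) == 1 and up.empty

    def test_de_filter_toy_table_partition(self):
        df = pd.DataFrame(
            {
                "gene": list("abcd"),
                "log2fc": [2.0, -1.8, 0.5, 3.0],
                "fdr": [0.001, 0.04, 0.001, 0.2],
            }
        )
        up, down = de_filter(df)
        assert list(up["gene"]) == ["a"]
        assert list(down["gene"]) == ["b"]
        kept = pd.concat([up, down])
        dropped = df.loc[~df.index.isin(kept.index)]
        assert len(kept) + len(dropped) == len(df)
        assert set(kept.index).isdisjoint(dropped.index)


class TestAbundanceClinical:
    def test_noise_free_sign_pattern(self):
        from nephroimc.clinical import abundance_clinical_matrix
        from nephroimc.synthetic import CohortSpec, sample_level_cohort

        spec = CohortSpec(seed=3)
        spec.clinical_model = spec.clinical_model.without_noise()
        dens, clinical = sample_level_cohort(spec)
        out = abundance_clinical_matrix(dens, clinical, method="spearman")
        mac = out[out["feature"] == "resident_macrophage"].set_index("clinical")
        assert mac.loc["serum_cr", "r"] > 0
        assert mac.loc["crp", "r"] > 0
        assert mac.loc["tii", "r"] > 0
        assert mac.loc["egfr", "r"] < 0
        assert mac.loc["cxcl9_urine", "r"] > 0

    def test_macrophage_cxcl9_power_across_seeds(self):
        from nephroimc.clinical import abundance_clinical_matrix
        from nephroimc.synthetic import CohortSpec, sample_level_cohort

        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            dens, clinical = sample_level_cohort(CohortSpec(seed=s))
            out = abundance_clinical_matrix(dens, clinical)
            row = out[(out["feature"] == "resident_macrophage")
                      & (out["clinical"] == "cxcl9_urine")].iloc[0]
            if row["r"] > 0 and row["p"] < 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_permuted_labels_kill_correlation(self):
        from nephroimc.clinical import abundance_clinical_matrix
        from nephroimc.synthetic import CohortSpec, sample_level_cohort

        rng = np.random.default_rng(0)
        dens, clinical = sample_level_cohort(CohortSpec(seed=9))
        coefs = []
        for _ in range(5):
            perm = clinical.copy()
            perm["sample_id"] = rng.permutation(perm["sample_id"].to_numpy())
            out = abundance_clinical_matrix(dens, perm)
            coefs.extend(out["r"].dropna().tolist())
        assert np.median(np.abs(coefs)) < 0.3
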