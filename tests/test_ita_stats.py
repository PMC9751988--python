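"""Correlation engine, BH adjustment, adjusted ITA and Fisher significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isoita.ita_stats import (
    adjusted_ita,
    background_ita,
    bh_adjust,
    compute_ita_profile,
    count_anticorrelated,
    fisher_one_sided,
    signed_log,
    spearman,
    spearman_matrix,
)

from _oracles import bh_oracle, fisher_tail_oracle, spearman_oracle


class TestSpearman:
    def test_perfect_antimonotone(self):
        x = np.arange(10.0)
        rho, p = spearman(x, -(x ** 3))
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        rho, p = spearman(np.arange(5.0), np.ones(5))
        assert np.isnan(rho) and np.isnan(p)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])

    def test_matches_midrank_pearson_oracle(self, rng):
        for _ in range(25):
            x = rng.integers(0, 8, size=20).astype(float)  # ties guaranteed
            y = rng.normal(size=20)
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matrix_route_matches_scipy_pairwise(self, rng):
        X = rng.integers(0, 6, size=(4, 30)).astype(float)
        Y = rng.normal(size=(7, 30))
        Y[2] = np.round(Y[2])  # more ties
        rho, p = spearman_matrix(X, Y)
        for i in range(4):
            for j in range(7):
                ref = sps.spearmanr(X[i], Y[j])
                assert rho[i, j] == pytest.approx(ref.statistic, abs=1e-12)
                assert p[i, j] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matrix_route_flags_constant_rows(self, rng):
        X = np.vstack([np.ones(10), rng.normal(size=10)])
        Y = rng.normal(size=(3, 10))
        rho, p = spearman_matrix(X, Y)
        assert np.isnan(rho[0]).all() and np.isfinite(rho[1]).all()


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_all_equal_closed_form(self):
        assert bh_adjust([0.01] * 10) == pytest.approx([0.01] * 10)

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_oracle(list(p)), abs=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCountAnticorrelated:
    def test_thresholds_are_strict(self):
        assert count_anticorrelated([-0.3], [0.01]) == 0
        assert count_anticorrelated([-0.5], [0.049]) == 1
        assert count_anticorrelated([-0.5], [0.05]) == 0

    def test_ten_record_fixture_hand_tally(self):
        rho = [-0.9, -0.4, -0.31, -0.3, -0.29, 0.5, -0.6, -0.35, -0.99, 0.0]
        fdr = [0.001, 0.2, 0.04, 0.01, 0.001, 0.001, 0.049, 0.051, 0.05, 0.001]
        # counted: indices 0, 2, 6 -> 3 records
        assert count_anticorrelated(rho, fdr) == 3


class TestAdjustedIta:
    @pytest.mark.parametrize(
        "m_tar,n_tar,m_nontar,n_nontar,expected",
        [(10, 100, 0, 1000, 10.0), (10, 100, 100, 1000, 0.0), (1, 1, 300, 1000, 0.7)],
    )
    def test_worked_values(self, m_tar, n_tar, m_nontar, n_nontar, expected):
        assert adjusted_ita(m_tar, n_tar, m_nontar, n_nontar) == pytest.approx(expected)

    def test_hub_tf_scenario_goes_negative(self):
        # one functional target among several predicted; heavy background
        # anti-correlation by transitivity through the hub TF's own targets
        assert adjusted_ita(1, 10, 300, 1000) < 0
        # with a single predicted target the statistic is bounded below by 0
        assert adjusted_ita(1, 1, 999, 1000) >= 0

    def test_linearity_and_sign_flip(self):
        base = adjusted_ita(5, 50, 10, 200)
        assert adjusted_ita(6, 50, 10, 200) == pytest.approx(base + 1)
        assert adjusted_ita(5, 50, 11, 200) == pytest.approx(base - 50 / 200)
        assert adjusted_ita(4, 40, 10, 100) == pytest.approx(0.0)

    def test_no_background_rejected(self):
        with pytest.raises(ValueError):
            adjusted_ita(1, 1, 0, 0)

    def test_background_component(self):
        assert background_ita(0, 50, 10, 200) == pytest.approx(2.5)


class TestFisherOneSided:
    def test_zero_numerator_gives_p_one(self):
        assert fisher_one_sided(0, 10, 3, 100) == pytest.approx(1.0)

    def test_worked_table_matches_tail_sum(self):
        p = fisher_one_sided(3, 10, 10, 100)
        assert p == pytest.approx(fisher_tail_oracle(3, 10, 10, 100), abs=1e-12)

    def test_monotone_in_m_tar_at_fixed_margins(self):
        n_tar, n_nontar, K = 20, 80, 15
        ps = [fisher_one_sided(m, n_tar, K - m, n_nontar) for m in range(0, K + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_agrees_with_scipy_alternative_greater(self):
        table = [[7, 13], [5, 95]]
        ref = sps.fisher_exact(table, alternative="greater").pvalue
        assert fisher_one_sided(7, 20, 5, 100) == pytest.approx(ref, abs=1e-12)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(5, 3, 0, 10)


class TestSignedLog:
    @pytest.mark.parametrize("y,expected", [(0, 0), (1, 1), (-1, -1), (3, 2), (-3, -2)])
    def test_spot_values(self, y, expected):
        assert signed_log(y) == pytest.approx(expected)

    def test_odd_function(self, rng):
        y = rng.normal(scale=10, size=100)
        assert signed_log(-y) == pytest.approx(-signed_log(y))


def _toy_dataset(rng, n_samples=40):
    """Five isomiRs, twelve transcripts, one group, known membership."""
    iso_ids = [f"i{k}|0" for k in range(5)]
    tx_ids = [f"T{k}" for k in range(12)]
    iso = pd.DataFrame(rng.normal(5, 1, size=(5, n_samples)), index=iso_ids)
    tx = pd.DataFrame(rng.normal(5, 1, size=(12, n_samples)), index=tx_ids)
    # make i0's four targets strongly repressed
    for k in range(4):
        tx.iloc[k] = 10 - iso.iloc[0] + rng.normal(0, 0.1, n_samples)
    samples = [f"s{j}" for j in range(n_samples)]
    iso.columns = tx.columns = samples
    groups = pd.Series("G", index=pd.Index(samples, name="sample_id"))
    interactions = pd.DataFrame(
        {
            "isomir": ["i0|0", "i0|0", "i0|0", "i0|0", "i1|0", "i2|0", "i3|0", "i4|0"],
            "transcript_id": ["T0", "T1", "T2", "T3", "T4", "T5", "T4", "T5"],
            "window_start": [1, 2, 3, 4, 5, 6, 7, 8],
            "region": ["3UTR"] * 8,
            "seed_type": ["8mer", "6mer", "7mer-m8", "8mer", "6mer", "8mer", "6mer", "8mer"],
            "source": ["RNA22"] * 8,
        }
    )
    nontargets = {i: {f"T{k}" for k in range(6, 12)} for i in iso_ids}
    return iso, tx, groups, interactions, nontargets


class TestComputeItaProfile:
    def test_counts_consistent_with_correlation_table(self, rng):
        iso, tx, groups, interactions, nontargets = _toy_dataset(rng)
        ita, corr = compute_ita_profile(
            iso, tx, groups, interactions, nontargets,
            min_group_size=10, return_correlations=True,
        )
        # recompute m/n by manually thresholding the emitted correlation table
        for _, row in ita.iterrows():
            sub = corr[corr["isomir"] == row["isomir"]]
            tar = sub[sub["role"] == "target"]
            non = sub[sub["role"] == "nontarget"]
            assert row["n_tar"] == tar["rho"].notna().sum()
            assert row["n_nontar"] == non["rho"].notna().sum()
            assert row["m_tar"] == ((tar["rho"] < -0.3) & (tar["fdr"] < 0.05)).sum()
            assert row["m_nontar"] == ((non["rho"] < -0.3) & (non["fdr"] < 0.05)).sum()

    def test_planted_isomir_detected(self, rng):
        iso, tx, groups, interactions, nontargets = _toy_dataset(rng)
        ita = compute_ita_profile(iso, tx, groups, interactions, nontargets, min_group_size=10)
        by_iso = ita.set_index("isomir")
        assert by_iso.loc["i0|0", "m_tar"] == 4
        assert by_iso.loc["i0|0", "adjusted_ita"] == pytest.approx(4.0)
        assert by_iso.loc["i0|0", "fisher_fdr"] < 0.05
        assert (by_iso.drop("i0|0")["m_tar"] == 0).all()

    def test_record_invariants(self, rng):
        iso, tx, groups, interactions, nontargets = _toy_dataset(rng)
        ita = compute_ita_profile(iso, tx, groups, interactions, nontargets, min_group_size=10)
        assert (ita["m_tar"] <= ita["n_tar"]).all()
        assert (ita["m_nontar"] <= ita["n_nontar"]).all()
        assert (ita["fisher_fdr"] >= ita["fisher_p"] - 1e-15).all()
        assert (ita["adjusted_ita"] <= ita["m_tar"]).all()
        assert ita["adjusted_ita_signed_log"].tolist() == pytest.approx(
            [signed_log(v) for v in ita["adjusted_ita"]]
        )

    def test_seed_type_strata_cover_pairs(self, rng):
        iso, tx, groups, interactions, nontargets = _toy_dataset(rng)
        ita = compute_ita_profile(
            iso, tx, groups, interactions, nontargets,
            strata=("pooled", "seed_type"), min_group_size=10,
        )
        strata = set(ita["stratum"])
        assert {"all", "8mer", "6mer", "7mer-m8"} <= strata
        pooled = ita[ita["stratum"] == "all"].set_index("isomir")["n_tar"]
        per_type = ita[ita["stratum"] != "all"].groupby("isomir")["n_tar"].sum()
        assert (per_type <= pooled.loc[per_type.index]).all() or (
            per_type == pooled.loc[per_type.index]
        ).all()

    def test_small_group_skipped_with_warning(self, rng, caplog):
        iso, tx, groups, interactions, nontargets = _toy_dataset(rng)
        with caplog.at_level("WARNING"):
            ita = compute_ita_profile(iso, tx, groups, interactions, nontargets, min_group_size=100)
        assert ita.empty and "skipped" in caplog.text

    def test_constant_transcript_excluded_from_counts(self, rng):
        iso, tx, groups, interactions, nontargets = _toy_dataset(rng)
        tx.loc["T6"] = 1.0  # constant non-target
        ita = compute_ita_profile(iso, tx, groups, interactions, nontargets, min_group_size=10)
        assert (ita["n_nontar"] == 5).all()
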