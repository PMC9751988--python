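"""Determinism, planted structure, and statistical calibration of the generator."""

import dataclasses
from pathlib import Path

import numpy as np
import pytest

from isoita.ita_stats import spearman_matrix
from isoita.seed_model import build_kmer_index, classify_site, compose_nontarget_set
from isoita.synthetic_data import (
    ROLE_CONFOUNDED_NONTARGET,
    ROLE_INDEPENDENT_NONTARGET,
    ROLE_TRUE_TARGET,
    SimulationConfig,
    build_site_window,
    generate_expression,
    generate_transcriptome,
    predict_sites,
    write_fixture_bundle,
)

from _oracles import brute_force_nontargets
from conftest import random_isomir

TINY = SimulationConfig(
    n_transcripts=90,
    n_isomirs=5,
    n_active=2,
    targets_per_isomir=6,
    nontargets_per_isomir=8,
    n_silent_transcripts=4,
    n_samples_per_group=50,
    group_labels=("A",),
    seed=11,
)


class TestConfig:
    def test_positive_beta_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(beta=0.5)

    def test_too_few_transcripts_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            SimulationConfig(n_transcripts=50)

    def test_unknown_mapping_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig.from_mapping({"nope": 1})


class TestPlantedSites:
    @pytest.mark.parametrize("seed_type", ["8mer", "7mer-m8", "7mer-A1", "6mer"])
    def test_built_window_classifies_as_requested(self, rng, seed_type):
        for i in range(10):
            iso = random_isomir(rng, i)
            window = build_site_window(iso, seed_type, rng)
            assert classify_site(iso, window) == seed_type

    def test_all_planted_sites_classify_and_lie_in_region(self):
        transcripts, isomirs, truth = generate_transcriptome(TINY)
        tmap = {t.transcript_id: t for t in transcripts}
        iso_map = {str(iso.id): iso for iso in isomirs}
        assert len(truth.sites) == TINY.n_active * TINY.targets_per_isomir
        for row in truth.sites.itertuples():
            t = tmap[row.transcript_id]
            window = t.seq[row.window_start : row.window_start + 8]
            assert classify_site(iso_map[row.isomir], window) == row.seed_type
            assert row.window_start >= t.cds_end  # default planted region is 3UTR


class TestRoles:
    def test_roles_partition_all_pairs(self):
        _, isomirs, truth = generate_transcriptome(TINY)
        counts = truth.roles.groupby(["isomir", "transcript_id"]).size()
        assert (counts == 1).all()
        assert len(truth.roles) == TINY.n_isomirs * TINY.n_transcripts

    def test_designated_nontargets_have_no_admissible_6mers(self):
        transcripts, isomirs, truth = generate_transcriptome(TINY)
        index = build_kmer_index(transcripts, k=6)
        tx_map = {t.transcript_id: t.seq for t in transcripts}
        roles = truth.roles.set_index(["isomir", "transcript_id"])["role"]
        for iso in isomirs:
            nontar = compose_nontarget_set(iso, index)
            assert len(nontar) >= TINY.nontargets_per_isomir
            # scan-based set agrees with the per-position brute-force oracle
            assert nontar == brute_force_nontargets(iso.seq, tx_map)
            labelled = {
                t
                for (i, t), r in roles.items()
                if i == str(iso.id)
                and r in (ROLE_INDEPENDENT_NONTARGET, ROLE_CONFOUNDED_NONTARGET)
            }
            assert labelled == nontar

    def test_true_targets_carry_their_planted_site(self):
        _, _, truth = generate_transcriptome(TINY)
        planted = set(zip(truth.sites["isomir"], truth.sites["transcript_id"]))
        by_role = truth.roles[truth.roles["role"] == ROLE_TRUE_TARGET]
        assert set(zip(by_role["isomir"], by_role["transcript_id"])) == planted


class TestExpression:
    def test_counts_are_nonnegative_integers(self):
        _, _, truth = generate_transcriptome(TINY)
        iso_counts, tx_counts, groups = generate_expression(TINY, truth)
        for m in (iso_counts, tx_counts):
            arr = m.to_numpy()
            assert (arr >= 0).all() and np.array_equal(arr, np.rint(arr))
        assert groups.value_counts().to_dict() == {"A": TINY.n_samples_per_group}

    def test_variant_split_preserves_5prime_totals(self):
        from isoita.expression import aggregate_5prime_isomirs

        _, isomirs, truth = generate_transcriptome(TINY)
        iso_counts, _, _ = generate_expression(TINY, truth)
        assert len(iso_counts) == TINY.n_isomirs * TINY.n_3p_variants
        agg = aggregate_5prime_isomirs(iso_counts)
        assert set(agg.index) == {str(iso.id) for iso in isomirs}

    def test_null_correlations_centred_at_zero(self):
        cfg = dataclasses.replace(TINY, beta=0.0, n_samples_per_group=100)
        _, _, truth = generate_transcriptome(cfg)
        iso_counts, tx_counts, _ = generate_expression(cfg, truth)
        from isoita.expression import aggregate_5prime_isomirs

        X = np.log2(aggregate_5prime_isomirs(iso_counts).to_numpy() + 1.0)
        Y = np.log2(tx_counts.to_numpy() + 1.0)
        rho, _ = spearman_matrix(X, Y)
        finite = rho[np.isfinite(rho)]
        assert finite.size >= 400
        assert abs(np.nanmean(finite)) < 0.05

    def test_planted_pairs_strongly_anticorrelated(self):
        cfg = dataclasses.replace(TINY, n_samples_per_group=200)
        _, _, truth = generate_transcriptome(cfg)
        iso_counts, tx_counts, _ = generate_expression(cfg, truth)
        from isoita.expression import aggregate_5prime_isomirs

        agg = np.log2(aggregate_5prime_isomirs(iso_counts) + 1.0)
        txl = np.log2(tx_counts + 1.0)
        rho, _ = spearman_matrix(agg.to_numpy(), txl.to_numpy())
        iso_pos = {i: k for k, i in enumerate(agg.index)}
        tx_pos = {t: k for k, t in enumerate(txl.index)}
        planted = [
            rho[iso_pos[i], tx_pos[t]]
            for i, t in zip(truth.sites["isomir"], truth.sites["transcript_id"])
        ]
        assert np.mean(np.array(planted) < -0.3) > 0.95

    def test_confounding_inflates_background_anticorrelation(self):
        base = dataclasses.replace(TINY, n_isomirs=6, n_active=2, n_samples_per_group=100)
        conf = dataclasses.replace(base, confounded_fraction=0.3, n_confounded=2)

        def mean_nontarget_anticorr_rate(cfg):
            _, isomirs, truth = generate_transcriptome(cfg)
            iso_counts, tx_counts, _ = generate_expression(cfg, truth)
            from isoita.expression import aggregate_5prime_isomirs

            agg = np.log2(aggregate_5prime_isomirs(iso_counts) + 1.0)
            txl = np.log2(tx_counts + 1.0)
            rho, _ = spearman_matrix(agg.to_numpy(), txl.to_numpy())
            iso_pos = {i: k for k, i in enumerate(agg.index)}
            tx_pos = {t: k for k, t in enumerate(txl.index)}
            conf_ids = [str(iso.id) for iso in isomirs[cfg.n_active : cfg.n_active + 2]]
            nt = truth.roles[
                truth.roles["role"].isin([ROLE_INDEPENDENT_NONTARGET, ROLE_CONFOUNDED_NONTARGET])
            ]
            rates = []
            for iso in conf_ids:
                rows = nt[nt["isomir"] == iso]
                vals = [rho[iso_pos[iso], tx_pos[t]] for t in rows["transcript_id"]]
                rates.append(np.nanmean(np.array(vals) < -0.3))
            return float(np.mean(rates))

        assert mean_nontarget_anticorr_rate(conf) > mean_nontarget_anticorr_rate(base)


class TestBundle:
    def test_same_seed_bytes_identical(self, tmp_path):
        a = write_fixture_bundle(TINY, tmp_path / "a")
        b = write_fixture_bundle(TINY, tmp_path / "b")
        for key in a:
            assert Path(a[key]).read_bytes() == Path(b[key]).read_bytes(), key

    def test_different_seed_changes_sequences(self, tmp_path):
        a = write_fixture_bundle(TINY, tmp_path / "a")
        other = dataclasses.replace(TINY, seed=12)
        b = write_fixture_bundle(other, tmp_path / "b")
        assert Path(a["transcript_fasta"]).read_text() != Path(b["transcript_fasta"]).read_text()

    def test_prediction_tables_cover_planted_sites(self, tmp_path):
        transcripts, isomirs, truth = generate_transcriptome(TINY)
        sites = predict_sites(transcripts, isomirs)
        predicted = set(zip(sites["isomir"], sites["transcript_id"], sites["window_start"]))
        for row in truth.sites.itertuples():
            assert (row.isomir, row.transcript_id, row.window_start) in predicted
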