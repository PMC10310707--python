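"""The synthetic cohort generator: catalog, inheritance, noise injection."""

import numpy as np
import pandas as pd
import pytest

from strdnm.simulate import (
    SimConfig,
    generate_catalog,
    inject_errors,
    simulate_pedigrees,
    simulate_trio_counts,
)
from strdnm.trio import call_mdnms
from tests.conftest import ZERO_ERROR, zero_noise_config


class TestCatalog:
    def test_pure_dinucleotide_mix(self):
        cfg = SimConfig(n_markers=500, motif_length_mix={2: 1.0})
        cat = generate_catalog(cfg, np.random.default_rng(0))
        assert (cat["motif_length"] == 2).all()

    def test_seed_determinism(self):
        cfg = SimConfig(n_markers=300)
        a = generate_catalog(cfg, np.random.default_rng(11))
        b = generate_catalog(cfg, np.random.default_rng(11))
        pd.testing.assert_frame_equal(a, b)

    def test_motif_mix_within_sampling_error(self):
        cfg = SimConfig(n_markers=20_000)
        cat = generate_catalog(cfg, np.random.default_rng(1))
        obs = cat["motif_length"].value_counts(normalize=True)
        for length, p in cfg.motif_length_mix.items():
            se = np.sqrt(p * (1 - p) / len(cat))
            assert abs(obs.get(length, 0.0) - p) < 3 * se + 1e-9

    def test_attribute_bounds(self):
        cfg = SimConfig(n_markers=2000)
        cat = generate_catalog(cfg, np.random.default_rng(2))
        assert (cat["rrt_length"] <= 140).all()
        assert (cat["rrt_length"] >= cat["motif_length"]).all()
        assert ((cat["purity"] > 0) & (cat["purity"] <= 1)).all()
        assert (cat["start"] < cat["end"]).all()

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_catalog(
                SimConfig(n_markers=10, motif_length_mix={1: 0.5, 2: 0.4}),
                np.random.default_rng(0),
            )


class TestPedigreeSimulation:
    def test_poisson_mean_without_age_effect(self):
        cfg = zero_noise_config(
            n_markers=300,
            n_trios=2000,
            n_threegen_families=0,
            alpha_p=10.0,
            beta_p=0.0,
            alpha_m=3.0,
            beta_m=0.0,
        )
        rng = np.random.default_rng(3)
        cat = generate_catalog(cfg, rng)
        sim = simulate_pedigrees(cat, cfg, rng)
        per_trio = sim.truth.groupby("child_id").size()
        mean = per_trio.reindex(sim.trios["child_id"]).fillna(0).mean()
        se = np.sqrt(13.0 / 2000)
        assert abs(mean - 13.0) < 3 * se

    def test_all_paternal_when_maternal_rate_zero(self):
        cfg = zero_noise_config(
            n_markers=200, n_trios=100, n_threegen_families=0, alpha_m=0.0, beta_m=0.0
        )
        rng = np.random.default_rng(4)
        cat = generate_catalog(cfg, rng)
        sim = simulate_pedigrees(cat, cfg, rng)
        assert (sim.truth["parent_of_origin"] == "paternal").all()

    def test_paternal_share_matches_configured_expectation(self):
        cfg = zero_noise_config(n_markers=250, n_trios=600, n_threegen_families=0)
        rng = np.random.default_rng(5)
        cat = generate_catalog(cfg, rng)
        sim = simulate_pedigrees(cat, cfg, rng)
        mu_p = cfg.alpha_p + cfg.beta_p * sim.trios["father_age"]
        mu_m = cfg.alpha_m + cfg.beta_m * sim.trios["mother_age"]
        expected = mu_p.sum() / (mu_p.sum() + mu_m.sum())
        observed = (sim.truth["parent_of_origin"] == "paternal").mean()
        se = np.sqrt(expected * (1 - expected) / len(sim.truth))
        assert abs(observed - expected) < 4 * se

    def test_rate_ordering_follows_motif_weights(self, noisy_cohort):
        truth = noisy_cohort["sim"].truth
        cat = noisy_cohort["catalog"]
        per_marker = truth.groupby("marker_id").size()
        by_len = (
            cat.assign(events=cat["marker_id"].map(per_marker).fillna(0))
            .groupby("motif_length")["events"]
            .mean()
        )
        # dinucleotides mutate more often than homopolymers and hexamers
        assert by_len[2] > by_len[1]
        assert by_len[2] > by_len.get(6, 0.0)

    def test_negative_mean_config_rejected(self):
        cfg = zero_noise_config(alpha_p=0.5, beta_p=-0.1)
        with pytest.raises(ValueError):
            cfg.validate()


class TestErrorInjection:
    def test_zero_noise_identity(self, zero_noise_cohort):
        obs = zero_noise_cohort["observed"]
        truth = zero_noise_cohort["sim"].truth_genotypes
        merged = truth.merge(
            obs, on=["marker_id", "individual_id"], suffixes=("_t", "_o")
        )
        assert len(merged) == len(truth)
        assert (merged["allele1_t"] == merged["allele1_o"]).all()
        assert (merged["allele2_t"] == merged["allele2_o"]).all()
        assert (obs["gq"] > 60).all()

    def test_homopolymer_only_errors(self):
        cfg = zero_noise_config(
            n_markers=300,
            n_trios=50,
            n_threegen_families=0,
            genotyping_error_rate={**ZERO_ERROR, 1: 0.05},
        )
        rng = np.random.default_rng(6)
        cat = generate_catalog(cfg, rng)
        sim = simulate_pedigrees(cat, cfg, rng)
        obs = inject_errors(sim, cfg, rng)
        merged = sim.truth_genotypes.merge(
            obs, on=["marker_id", "individual_id"], suffixes=("_t", "_o")
        ).merge(cat[["marker_id", "motif_length"]], on="marker_id")
        discordant = (merged["allele1_t"] != merged["allele1_o"]) | (
            merged["allele2_t"] != merged["allele2_o"]
        )
        assert discordant.any()
        assert (merged.loc[discordant, "motif_length"] == 1).all()

    def test_dropout_creates_high_support_spurious_calls(self):
        cfg = zero_noise_config(
            n_markers=300, n_trios=120, n_threegen_families=0, dropout_rate=2e-3
        )
        rng = np.random.default_rng(7)
        cat = generate_catalog(cfg, rng)
        sim = simulate_pedigrees(cat, cfg, rng)
        obs = inject_errors(sim, cfg, rng)
        res = call_mdnms(obs, sim.pedigree, cat)
        calls = res["calls"]
        truth_events = set(sim.truth["event_id"])
        spurious = calls[~calls["call_id"].isin(truth_events)]
        assert len(spurious) > 0
        # dropout leaves the transmitted allele visible in parental reads
        assert (spurious["parental_support"] == "high").mean() > 0.5

    def test_seed_determinism_through_noise(self):
        cfg = SimConfig(n_markers=150, n_trios=30, n_threegen_families=5)
        frames = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            cat = generate_catalog(cfg, rng)
            sim = simulate_pedigrees(cat, cfg, rng)
            frames.append(inject_errors(sim, cfg, rng))
        pd.testing.assert_frame_equal(frames[0], frames[1])


class TestTrioCountGenerator:
    def test_phased_share_and_totals(self):
        cfg = SimConfig()
        rng = np.random.default_rng(8)
        d = simulate_trio_counts(cfg, 4000, rng, phased_fraction=0.6)
        total = (d["y_p"] + d["y_m"] + d["y_u"]).sum()
        phased = (d["y_p"] + d["y_m"]).sum()
        assert phased / total == pytest.approx(0.6, abs=0.02)
        mean_total = (d["y_p"] + d["y_m"] + d["y_u"]).mean()
        assert mean_total == pytest.approx(12.7, abs=0.5)

    def test_event_mode_thins_per_event(self):
        cfg = SimConfig()
        rng = np.random.default_rng(9)
        d = simulate_trio_counts(cfg, 500, rng, phasing_mode="event")
        mixed = ((d["y_p"] + d["y_m"]) > 0) & (d["y_u"] > 0)
        assert mixed.any()  # impossible under trio-level phasing
        d2 = simulate_trio_counts(cfg, 500, np.random.default_rng(9), phasing_mode="trio")
        mixed2 = ((d2["y_p"] + d2["y_m"]) > 0) & (d2["y_u"] > 0)
        assert not mixed2.any()
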