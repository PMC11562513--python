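"""Synthetic-cohort generators: determinism, distributional targets, truth."""

import numpy as np
import pandas as pd
import pytest

from neovax.cohort import (ConsistencyError, GroundTruth, assign_hla,
                           choose_ground_truth, generate_proteome, patient_ids,
                           simulate_assays, simulate_followup, simulate_variants)
from neovax.config import CohortConfig, ConfigError

AA = set("ACDEFGHIKLMNPQRSTVWY")


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestConfig:
    def test_proportions_validated(self):
        with pytest.raises(ConfigError):
            CohortConfig(missense_fraction=1.5)

    def test_length_range_validated(self):
        with pytest.raises(ConfigError):
            CohortConfig(protein_length_range=(10, 20))
        with pytest.raises(ConfigError):
            CohortConfig(protein_length_range=(100, 50))


class TestProteome:
    def test_single_short_protein_reproducible(self):
        cfg = CohortConfig(n_proteins=1, protein_length_range=(30, 30), seed=1)
        p1, _ = generate_proteome(cfg, _rng(1))
        p2, _ = generate_proteome(cfg, _rng(1))
        assert p1 == p2
        (seq,) = p1.values()
        assert len(seq) == 30 and set(seq) <= AA

    def test_seeded_determinism_at_scale(self):
        cfg = CohortConfig(n_proteins=100, seed=7)
        assert generate_proteome(cfg, _rng(7))[0] == generate_proteome(cfg, _rng(7))[0]

    def test_degenerate_length_range(self):
        cfg = CohortConfig(n_proteins=10, protein_length_range=(30, 30))
        proteome, expr = generate_proteome(cfg, _rng(3))
        assert all(len(s) == 30 for s in proteome.values())
        assert (expr["tpm"] >= 0).all()
        assert len(set(proteome)) == 10


def _variants(cfg, seed=0):
    rng = _rng(seed)
    proteome, expr = generate_proteome(cfg, rng)
    hla = assign_hla(cfg, rng)
    return simulate_variants(proteome, expr, hla, cfg, rng)


class TestVariants:
    def test_pure_missense_config(self):
        cfg = CohortConfig(missense_fraction=1.0, n_patients=6, n_proteins=20)
        variants, _ = _variants(cfg)
        assert (variants["type"] == "missense").all()

    def test_same_seed_gives_identical_tables(self):
        cfg = CohortConfig(n_patients=4, n_proteins=20)
        v1, p1 = _variants(cfg, seed=5)
        v2, p2 = _variants(cfg, seed=5)
        pd.testing.assert_frame_equal(v1, v2)
        assert p1 == p2

    def test_variants_consistent_with_edited_proteome(self):
        cfg = CohortConfig(n_patients=4, n_proteins=20)
        variants, proteome = _variants(cfg)
        for row in variants.itertuples(index=False):
            assert 1 <= row.position <= len(proteome[row.protein_id])
            assert proteome[row.protein_id][row.position - 1] == row.ref
            assert 0 < row.vaf <= 1

    def test_median_and_missense_fraction_recovered(self):
        cfg = CohortConfig(n_patients=18, mutations_per_patient_median=21,
                           n_proteins=40)
        counts, n_missense, n_total = [], 0, 0
        for seed in range(20):
            variants, _ = _variants(cfg, seed=seed)
            counts.extend(variants.groupby("patient_id").size().tolist())
            n_missense += (variants["type"] == "missense").sum()
            n_total += len(variants)
        assert abs(np.median(counts) - 21) <= 2
        assert abs(n_missense / n_total - cfg.missense_fraction) <= 0.02

    def test_planted_variants_are_expressed_missense(self):
        cfg = CohortConfig(n_patients=6, n_proteins=30)
        variants, _ = _variants(cfg)
        planted = variants[variants["planted_allele"] != ""]
        assert len(planted) > 0
        assert (planted["type"] == "missense").all()
        assert (planted["tpm"] > 0).all()
        assert (planted["rna_alt_reads"] >= 1).all()


DESIGNS = {"SYN01": ["SYN01_N1", "SYN01_N2"], "SYN02": ["SYN02_N1"]}


class TestAssays:
    def test_truth_outside_designs_rejected(self):
        cfg = CohortConfig(n_patients=2)
        truth = GroundTruth(immunogenic_epitopes={("SYN01", "nope")})
        with pytest.raises(ConsistencyError):
            simulate_assays(DESIGNS, truth, cfg, _rng(0))

    def test_seeded_determinism(self):
        cfg = CohortConfig(n_patients=2, n_clonotypes=100, clonotype_depth=1000)
        truth = GroundTruth(immunogenic_epitopes={("SYN01", "SYN01_N1")})
        a = simulate_assays(DESIGNS, truth, cfg, _rng(4))
        b = simulate_assays(DESIGNS, truth, cfg, _rng(4))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_background_wells_within_stated_range(self):
        cfg = CohortConfig(n_patients=2, n_clonotypes=50, clonotype_depth=500)
        designs = {f"P{i}": [f"P{i}_N1"] for i in range(30)}
        eli, _, _ = simulate_assays(designs, GroundTruth(), cfg, _rng(0))
        bg = eli[eli["stimulus"] == "no-peptide"]["count"]
        assert 10 <= bg.mean() <= 120   # no-peptide means drawn in 10-120

    def test_immunogenic_epitopes_separate_from_background(self):
        cfg = CohortConfig(n_clonotypes=50, clonotype_depth=500)
        truth = GroundTruth(immunogenic_epitopes={("SYN01", "SYN01_N1")})
        eli, ics, clono = simulate_assays(DESIGNS, truth, cfg, _rng(1))
        pooled = eli[(eli["stimulus"] == "pooled-OP") & (eli["patient"] == "SYN01")]
        bg = eli[(eli["patient"] == "SYN01") & (eli["stimulus"] == "no-peptide")
                 & (eli["timepoint"] == "post")]["count"].mean()
        hot = pooled[(pooled["neoantigen"] == "SYN01_N1")
                     & (pooled["timepoint"] == "post")]["count"].mean()
        cold = pooled[(pooled["neoantigen"] == "SYN01_N2")
                      & (pooled["timepoint"] == "post")]["count"].mean()
        assert hot - bg > 200          # immunogenic: clear effect over background
        assert abs(cold - bg) < 100    # non-immunogenic: background-distributed
        # expanded truth clonotypes recorded for the immunogenic condition
        assert any(p == "SYN01" and c == "SYN01_N1"
                   for p, c, _ in truth.expanded_clonotypes)

    def test_unit_expansion_factor_is_null(self):
        cfg = CohortConfig(expansion_factor=1.0, n_clonotypes=100,
                           clonotype_depth=2000)
        truth = GroundTruth(immunogenic_epitopes={("SYN01", "SYN01_N1")})
        _, _, clono = simulate_assays(DESIGNS, truth, cfg, _rng(2))
        assert not truth.expanded_clonotypes
        stim = clono[clono["condition"] == "SYN01_N1"]
        pre = stim[stim["timepoint"] == "pre"]["count"]
        post = stim[stim["timepoint"] == "post"]["count"]
        assert abs(pre.sum() - post.sum()) < 1e-9  # same depth, same law


class TestGroundTruth:
    def test_truth_subset_of_designs(self):
        cfg = CohortConfig(immunogenic_fraction=0.5)
        truth = choose_ground_truth(DESIGNS, cfg, _rng(0))
        vaccinated = {(p, n) for p, neos in DESIGNS.items() for n in neos}
        assert truth.immunogenic_epitopes <= vaccinated

    def test_zero_fraction_gives_empty_truth(self):
        cfg = CohortConfig(immunogenic_fraction=0.0)
        assert not choose_ground_truth(DESIGNS, cfg, _rng(0)).immunogenic_epitopes


class TestFollowup:
    def test_zero_recurrence_rate_all_censored(self):
        cfg = CohortConfig(recurrence_rate=0.0)
        fu = simulate_followup(cfg, _rng(0))
        vacc = fu[fu["arm"] == "vaccinated"]
        assert not vacc["event"].any()
        assert (fu["time_months"] > 0).all()

    def test_seeded_determinism(self):
        cfg = CohortConfig()
        pd.testing.assert_frame_equal(simulate_followup(cfg, _rng(9)),
                                      simulate_followup(cfg, _rng(9)))

    def test_mean_event_count_matches_rate(self):
        cfg = CohortConfig(recurrence_rate=2 / 18, n_patients=18)
        events = [simulate_followup(cfg, _rng(s))
                  .query("arm == 'vaccinated'")["event"].sum()
                  for s in range(50)]
        assert abs(np.mean(events) - 2.0) < 0.6

    def test_control_arm_has_higher_hazard(self):
        cfg = CohortConfig(n_controls=200)
        fu = simulate_followup(cfg, _rng(3))
        ctrl = fu[fu["arm"] == "control"]
        vacc = fu[fu["arm"] == "vaccinated"]
        assert ctrl["event"].mean() > vacc["event"].mean()


def test_patient_ids_are_stable():
    cfg = CohortConfig(n_patients=3)
    assert patient_ids(cfg) == ["SYN01", "SYN02", "SYN03"]
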