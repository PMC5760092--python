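"""Generator contracts: determinism, planted marginals, strand and
operon conventions, noiseless identities, and the noise model's mean
behaviour."""

import numpy as np
import pandas as pd
import pytest

from regulonscope import chip
from regulonscope.simulate import (
    SimulationConfig,
    binding_site_carriers,
    generate_genome,
    plant_regulon,
    simulate_chip_track,
    simulate_decay,
    simulate_expression,
    simulate_proteome,
    protein_lengths_from_annotation,
)


class TestGenerateGenome:
    def test_empty_genome(self):
        annotation, operons = generate_genome(SimulationConfig(n_genes=0, n_operons=0))
        assert len(annotation) == 0
        assert len(operons) == 0

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=1, n_genes=10, n_operons=2, noise_cv=0.0)
        a1, o1 = generate_genome(cfg)
        a2, o2 = generate_genome(cfg)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        pd.testing.assert_frame_equal(o1.members, o2.members)
        assert len(a1) == 10
        assert len(o1) == 2
        for _, members in o1.iter_operons():
            assert len(members) >= 2

    def test_minus_strand_translation_start_is_larger_coordinate(self, small_genome):
        annotation, _ = small_genome
        minus = annotation.genes[annotation.genes["strand"] == "-"]
        assert len(minus) > 0
        assert (minus["translation_start"] == minus["end"]).all()
        plus = annotation.genes[annotation.genes["strand"] == "+"]
        assert (plus["translation_start"] == plus["start"]).all()

    def test_orfs_do_not_overlap(self, small_genome):
        annotation, _ = small_genome
        g = annotation.genes.sort_values("start")
        assert (g["start"].iloc[1:].to_numpy() > g["end"].iloc[:-1].to_numpy()).all()
        assert g["end"].max() <= annotation.genome_length

    def test_operon_members_contiguous_same_strand_in_transcription_order(self, small_genome):
        annotation, operons = small_genome
        genes = annotation.genes.set_index("gene_id")
        order = {g: i for i, g in enumerate(annotation.genes.sort_values("start")["gene_id"])}
        for _, members in operons.iter_operons():
            strands = genes.loc[members, "strand"].unique()
            assert len(strands) == 1
            idx = [order[m] for m in members]
            # genomically contiguous
            assert sorted(idx) == list(range(min(idx), max(idx) + 1))
            # rank order follows transcription: ascending starts on '+', descending on '-'
            starts = genes.loc[members, "start"].tolist()
            if strands[0] == "+":
                assert starts == sorted(starts)
            else:
                assert starts == sorted(starts, reverse=True)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="too small"):
            generate_genome(SimulationConfig(n_genes=50, n_operons=0, genome_length=1000))


class TestPlantRegulon:
    def test_zero_case_all_none(self, small_genome, small_config):
        annotation, operons = small_genome
        truth = plant_regulon(annotation, operons, 0, 0, 0, small_config)
        assert (truth["direction"] == "none").all()
        assert (truth["planted_fold"] == 1.0).all()
        assert not truth["direct"].any()

    def test_exact_marginal_counts(self, small_truth):
        assert (small_truth["direction"] == "up").sum() == 30
        assert (small_truth["direction"] == "down").sum() == 8
        assert small_truth["direct"].sum() == 18

    def test_direct_implies_up_and_fold_one_iff_none(self, small_truth):
        assert (small_truth.loc[small_truth["direct"], "direction"] == "up").all()
        none = small_truth["direction"] == "none"
        assert (small_truth.loc[none, "planted_fold"] == 1.0).all()
        assert (small_truth.loc[~none, "planted_fold"] != 1.0).all()

    def test_direct_operon_members_share_leader_binding_site(self, small_genome, small_truth):
        annotation, operons = small_genome
        carriers = set(binding_site_carriers(small_truth, operons))
        leaders = set(operons.leaders())
        op_of = operons.operon_of()
        for g in small_truth.index[small_truth["direct"]]:
            if g in op_of.index:
                # a non-leader direct member's operon leader carries the site
                assert operons.leaders()[op_of[g]] in carriers
            else:
                assert g in carriers
        assert all((c in leaders) or (c not in op_of.index) for c in carriers)

    def test_infeasible_counts_raise(self, small_genome, small_config):
        annotation, operons = small_genome
        with pytest.raises(ValueError, match="infeasible"):
            plant_regulon(annotation, operons, n_up=10, n_down=0, n_direct=20,
                          config=small_config)


class TestChipTrack:
    def test_no_direct_genes_stays_below_threshold(self, small_genome, small_config):
        annotation, operons = small_genome
        truth = plant_regulon(annotation, operons, 0, 0, 0, small_config)
        track = simulate_chip_track(annotation, operons, truth, small_config)
        assert track.values.max() < 10

    def test_single_peak_lands_upstream_of_its_gene(self):
        cfg = SimulationConfig(seed=3, n_genes=20, n_operons=0, noise_cv=0.0)
        annotation, operons = generate_genome(cfg)
        truth = plant_regulon(annotation, operons, 1, 0, 1, cfg)
        track = simulate_chip_track(annotation, operons, truth, cfg)
        peaks = chip.call_peaks(track)
        assert len(peaks) == 1
        gene = truth.index[truth["direct"]][0]
        row = annotation.genes.set_index("gene_id").loc[gene]
        d = peaks[0].max_position - row["translation_start"]
        if row["strand"] == "-":
            d = -d
        # upstream within the promoter window, +/- one bin of positional slack
        assert -200 - cfg.bin_width <= d <= 0

    def test_densities_never_negative(self, small_genome, small_truth):
        annotation, operons = small_genome
        cfg = SimulationConfig(seed=11, n_genes=300, n_operons=30, noise_cv=0.4)
        track = simulate_chip_track(annotation, operons, small_truth, cfg)
        assert (track.values >= 0).all()


class TestExpression:
    def test_noiseless_planted_ratios(self, small_genome, small_truth, small_config):
        annotation, _ = small_genome
        expr = simulate_expression(annotation, small_truth, config=small_config)
        up = small_truth.index[(small_truth["direction"] == "up")][0]
        v = expr.values
        assert v.loc[up, "dep6"] / v.loc[up, "ref"] == pytest.approx(8.0)
        assert v.loc[up, "rpoHdel_dep6"] / v.loc[up, "ref"] == pytest.approx(1.0)
        # attenuated mutant: half the log2 fold
        assert v.loc[up, "d252g_dep6"] / v.loc[up, "ref"] == pytest.approx(8.0 ** 0.5)

    def test_unknown_condition_rejected(self, small_genome, small_truth, small_config):
        annotation, _ = small_genome
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_expression(annotation, small_truth, ["ref", "heatshock"], small_config)

    def test_noisy_log_ratio_centred_on_planted_fold(self):
        cfg = SimulationConfig(seed=5, n_genes=1000, n_operons=0, noise_cv=0.2)
        annotation, operons = generate_genome(cfg)
        truth = plant_regulon(annotation, operons, 1000, 0, 0, cfg)
        e1 = simulate_expression(annotation, truth, config=cfg)
        e2 = simulate_expression(annotation, truth, config=cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        log_ratio = np.log2(e1.values["dep6"] / e1.values["ref"])
        # each log2 ratio has sd ~ sqrt(2)*sigma/ln2; mean over n genes
        sigma = np.sqrt(np.log(1 + cfg.noise_cv**2))
        se = np.sqrt(2) * sigma / np.log(2) / np.sqrt(len(log_ratio))
        assert abs(log_ratio.mean() - 3.0) < 3 * se


class TestProteome:
    def test_columns_sum_to_hundred(self, small_genome, small_truth):
        annotation, _ = small_genome
        cfg = SimulationConfig(seed=11, n_genes=300, n_operons=30, noise_cv=0.3)
        lengths = protein_lengths_from_annotation(annotation)
        table, _ = simulate_proteome(small_truth, lengths, cfg)
        assert np.allclose(table.values.sum(axis=0), 100.0, atol=1e-9)

    def test_single_protein_is_always_hundred(self):
        truth = pd.DataFrame(
            {"direction": ["none"], "direct": [False], "planted_fold": [1.0]},
            index=pd.Index(["p1"], name="gene_id"),
        )
        table, _ = simulate_proteome(truth, pd.Series([100.0], index=["p1"]),
                                     SimulationConfig(n_genes=1, n_operons=0, noise_cv=0.5))
        assert np.allclose(table.values.to_numpy(), 100.0)

    def test_noiseless_fold_recovered_after_drift_correction(self, small_genome, small_truth):
        annotation, _ = small_genome
        cfg = SimulationConfig(seed=11, n_genes=300, n_operons=30, noise_cv=0.0,
                               effect_up=2.0, effect_down=0.5, proteome_concordance=1.0,
                               protein_response_damping=1.0)
        truth = small_truth.copy()
        truth.loc[truth["direction"] == "up", "planted_fold"] = 2.0
        truth.loc[truth["direction"] == "down", "planted_fold"] = 0.5
        lengths = protein_lengths_from_annotation(annotation)
        table, ptruth = simulate_proteome(truth, lengths, cfg)
        exp = table.values[table.samples_for("dep12")].mean(axis=1)
        ctrl = table.values[table.samples_for("ref")].mean(axis=1)
        # the sum-to-100 normalization scales every ratio by total_ctrl/total_exp
        null = ptruth["protein_fold"] == 1.0
        drift = (exp[null] / ctrl[null]).iloc[0]
        gene = ptruth.index[ptruth["protein_fold"] == 2.0][0]
        assert (exp[gene] / ctrl[gene]) / drift == pytest.approx(2.0, rel=1e-9)


class TestDecay:
    def test_stable_protein_noiseless_is_flat_hundred(self):
        course = simulate_decay(float("inf"), (0, 30, 60, 120), 0.0)
        assert np.allclose(course.data["intensity"], 100.0)

    def test_closed_form_halving(self):
        course = simulate_decay(20.0, (0, 10, 20, 40), 0.0)
        expected = [100.0, 100 * 2 ** -0.5, 50.0, 25.0]
        assert np.allclose(course.data["intensity"], expected)

    def test_seed_reproduces_noisy_course(self):
        c1 = simulate_decay(30.0, (0, 15, 30, 60), 0.1, seed=9, n_replicates=3)
        c2 = simulate_decay(30.0, (0, 15, 30, 60), 0.1, seed=9, n_replicates=3)
        pd.testing.assert_frame_equal(c1.data, c2.data)
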