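"""Synthetic-study generator: geometry, planted signal, determinism."""
import numpy as np
import pandas as pd
import pytest

from medipchip import (generate_genome, plant_truth, simulate_expression,
                       simulate_hybridizations, simulate_promoter_sequences)
from medipchip.annotation import DOWNSTREAM_SPAN, UPSTREAM_SPAN
from medipchip.simulate import SyntheticTruth


class TestGenerateGenome:
    def test_probe_count_follows_spacing_arithmetic(self):
        ann = generate_genome(1, 10_000_000, 200, {1: 0.5, 2: 0.3, 8: 0.2},
                              seed=7)
        assert len(ann.promoters) == 200
        # ~200 promoters x 4,850 bp / 100 bp spacing
        assert abs(len(ann.probes) - 9_700) / 9_700 < 0.05

    def test_zero_promoters_gives_empty_lists(self):
        ann = generate_genome(1, 10_000_000, 0, seed=1)
        assert len(ann.promoters) == 0
        assert len(ann.probes) == 0

    def test_deterministic_for_fixed_seed(self):
        a = generate_genome(1, 5_000_000, 50, seed=9)
        b = generate_genome(1, 5_000_000, 50, seed=9)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.promoters, b.promoters)
        for c in a.cpg_positions:
            np.testing.assert_array_equal(a.cpg_positions[c],
                                          b.cpg_positions[c])

    def test_promoter_interval_geometry(self, small_annotation):
        prom = small_annotation.promoters
        plus = prom[prom["strand"] == "+"]
        assert (plus["start"] == plus["tss"] - UPSTREAM_SPAN).all()
        assert (plus["end"] == plus["tss"] + DOWNSTREAM_SPAN).all()
        minus = prom[prom["strand"] == "-"]
        assert (minus["start"] == minus["tss"] - DOWNSTREAM_SPAN).all()
        assert (minus["end"] == minus["tss"] + UPSTREAM_SPAN).all()

    def test_probes_lie_in_exactly_one_promoter(self, small_annotation):
        prom = small_annotation.promoters.set_index("gene_id")
        probes = small_annotation.probes
        assert probes["gc_fraction"].between(0, 1).all()
        assert (probes["end"] - probes["start"]).between(50, 75).all()
        for _, p in probes.sample(50, random_state=0).iterrows():
            host = prom.loc[p["gene_id"]]
            assert host["start"] <= p["start"] < p["end"] <= host["end"]

    def test_median_probe_spacing_near_100bp(self, small_annotation):
        probes = small_annotation.probes
        spacings = []
        for _, grp in probes.groupby("gene_id"):
            mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
            spacings.extend(np.diff(np.sort(mids)))
        assert abs(np.median(spacings) - 100) <= 5

    def test_cpg_positions_strictly_increasing(self, small_annotation):
        for pos in small_annotation.cpg_positions.values():
            assert (np.diff(pos) > 0).all()

    def test_realized_cpg_density_matches_class(self):
        ann = generate_genome(1, 10_000_000, 100, {2: 1.0}, seed=3,
                              intergenic_cpg_per_100bp=0.0)
        dens = [ann.cpg_density(r["chrom"], r["start"], r["end"])
                for _, r in ann.promoters.iterrows()]
        assert abs(np.mean(dens) - 2.0) < 0.1

    def test_sizing_error_when_promoters_do_not_fit(self):
        with pytest.raises(ValueError, match="fit"):
            generate_genome(1, 100_000, 50, seed=0)


class TestSimulateHybridizations:
    def test_null_mean_m_near_zero(self, small_annotation):
        truth = SyntheticTruth.empty(0)
        hybs = simulate_hybridizations(small_annotation, truth, noise_sd=0.3,
                                       dye_bias_amplitude=0.0, n_pairs=2,
                                       seed=5)
        n = len(small_annotation.probes)
        for h in (1, 2):
            m = hybs.channel("cy5", h) - hybs.channel("cy3", h)
            assert abs(m.mean()) < 3 * 0.3 / np.sqrt(n)

    def test_planted_dmr_shifts_m_by_delta(self, small_annotation):
        truth = plant_truth(small_annotation, n_dmrs=1, dmr_delta_m=2.0,
                            dmr_probe_range=(8, 8), de_background_fraction=0,
                            cluster_de_fraction=0, n_clusters=0, seed=2)
        hybs = simulate_hybridizations(small_annotation, truth, noise_sd=0.3,
                                       dye_bias_amplitude=0.0, n_pairs=3,
                                       seed=4)
        d = truth.planted_dmrs.iloc[0]
        probes = small_annotation.probes
        mid = (probes["start"] + probes["end"]) // 2
        mask = ((probes["chrom"] == d["chrom"]) & (mid >= d["start"])
                & (mid < d["end"])).to_numpy()
        assert mask.sum() == 8
        ms = np.concatenate([
            (hybs.channel("cy5", h) - hybs.channel("cy3", h))[mask]
            for h in (1, 2, 3)])
        assert abs(abs(ms.mean()) - 2.0) < 3 * 0.3 / np.sqrt(8 * 3)

    def test_dmr_outside_probes_warns(self, small_annotation):
        truth = SyntheticTruth.empty(0)
        truth.planted_dmrs = pd.DataFrame(
            [{"chrom": "chr1", "start": 1_999_000, "end": 1_999_500,
              "delta_m": 2.0, "sign": 1, "gene_id": "nowhere"}])
        with pytest.warns(UserWarning, match="cannot be recovered"):
            simulate_hybridizations(small_annotation, truth, seed=0)

    @pytest.mark.parametrize("kwargs", [dict(n_pairs=0), dict(noise_sd=0.0)])
    def test_parameter_validation(self, small_annotation, kwargs):
        with pytest.raises(ValueError):
            simulate_hybridizations(small_annotation, SyntheticTruth.empty(0),
                                    seed=0, **kwargs)


class TestSimulateExpression:
    def test_planted_gene_fold_and_mean_difference(self, small_annotation):
        rng_gene = small_annotation.gene_bodies["gene_id"].iloc[3]
        truth = SyntheticTruth.empty(0)
        truth.planted_de_genes = pd.DataFrame(
            [{"gene_id": rng_gene, "direction": "up", "multiplier": 2.0}])
        sig, sheet = simulate_expression(small_annotation, truth,
                                         n_per_group=4, batch_effect_sd=0.01,
                                         noise_sd=0.02, seed=8)
        assert (sig.to_numpy() > 0).all()
        treated = sheet.loc[sheet["treatment"] == "treated", "sample"]
        control = sheet.loc[sheet["treatment"] == "control", "sample"]
        fold = sig.loc[rng_gene, treated].mean() / sig.loc[rng_gene, control].mean()
        diff = sig.loc[rng_gene, treated].mean() - sig.loc[rng_gene, control].mean()
        assert abs(fold - 2.0) < 0.15
        assert diff > 10

    def test_deterministic(self, small_annotation):
        t = SyntheticTruth.empty(0)
        a, _ = simulate_expression(small_annotation, t, seed=3)
        b, _ = simulate_expression(small_annotation, t, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_replicates_rejected(self, small_annotation):
        with pytest.raises(ValueError, match="n_per_group"):
            simulate_expression(small_annotation, SyntheticTruth.empty(0),
                                n_per_group=1, seed=0)


class TestSimulatePromoterSequences:
    def test_sequences_match_promoter_lengths_and_cpg(self, small_annotation):
        truth = SyntheticTruth.empty(0)
        seqs = simulate_promoter_sequences(small_annotation, truth,
                                           "ACGTACGTACGTACGTACGT", seed=1)
        prom = small_annotation.promoters.set_index("gene_id")
        for gid, seq in list(seqs.items())[:5]:
            row = prom.loc[gid]
            assert len(seq) == row["end"] - row["start"]
            n_cg = seq.count("CG")
            n_ann = small_annotation.count_cpg(row["chrom"], row["start"],
                                               row["end"] - 1)
            assert abs(n_cg - n_ann) <= max(3, 0.3 * n_ann)

    def test_planted_motif_round_trip(self, small_annotation):
        truth = plant_truth(small_annotation, n_dmrs=1, n_clusters=0,
                            cluster_de_fraction=0, de_background_fraction=0,
                            motif_fraction=0.25, motif_length=20, seed=6)
        motif = "TGCAGGATCAAGTACCAATC"
        seqs = simulate_promoter_sequences(small_annotation, truth, motif,
                                           background_rate=0.0, seed=7)
        planted = set(truth.planted_motif_sites)
        for gid, offsets in truth.planted_motif_sites.items():
            for off in offsets:
                assert seqs[gid][off:off + 20] == motif
        # 20-mer chance matches are ~0.25^20 per position: effectively none
        others = {g: s for g, s in seqs.items() if g not in planted}
        assert not any(motif in s for s in others.values())

    def test_empty_request(self):
        ann = generate_genome(1, 10_000_000, 0, seed=0)
        assert simulate_promoter_sequences(ann, SyntheticTruth.empty(0),
                                           "ACGTACGT", seed=0) == {}

    def test_motif_longer_than_promoter_rejected(self, small_annotation):
        with pytest.raises(ValueError, match="longer"):
            simulate_promoter_sequences(small_annotation,
                                        SyntheticTruth.empty(0),
                                        "A" * 5000, seed=0)


class TestPlantTruth:
    def test_planted_dmrs_do_not_overlap_and_have_density(self,
                                                          small_annotation):
        truth = plant_truth(small_annotation, n_dmrs=6, seed=5)
        truth.validate(small_annotation)
        for _, d in truth.planted_dmrs.iterrows():
            assert small_annotation.cpg_density(
                d["chrom"], d["start"], d["end"]) >= 1.0

    def test_truth_json_round_trip(self, small_annotation, tmp_path):
        truth = plant_truth(small_annotation, n_dmrs=3, motif_fraction=0.1,
                            seed=5)
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        pd.testing.assert_frame_equal(
            truth.planted_dmrs.reset_index(drop=True),
            back.planted_dmrs.reset_index(drop=True), check_dtype=False)
        assert back.planted_motif_sites == truth.planted_motif_sites
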