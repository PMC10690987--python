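"""Tests of the synthetic-data generator's planted ground truth."""

import numpy as np
import pytest

import saltmem as sm
from saltmem.simdata import CLASS_SIGNS


def small_config(**kw):
    defaults = dict(
        n_genes=400,
        tf_families={"WRKY": (20, 2.0), "MYB": (15, 1.0)},
        seed=7,
    )
    defaults.update(kw)
    return sm.SimConfig(**defaults)


class TestSimulateCounts:
    def test_reproducible_and_seed_sensitive(self):
        cm1, _ = sm.simulate_counts(small_config(seed=3))
        cm2, _ = sm.simulate_counts(small_config(seed=3))
        cm3, _ = sm.simulate_counts(small_config(seed=4))
        assert cm1.counts.equals(cm2.counts)
        assert not cm1.counts.equals(cm3.counts)

    def test_null_only_class_has_zero_effects(self):
        cfg = small_config(class_proportions={"NULL": 1.0})
        _, truth = sm.simulate_counts(cfg)
        assert (truth.true_log2_effects.to_numpy() == 0).all()
        assert (truth.classes == "NULL").all()

    def test_true_effect_signs_match_class(self):
        _, truth = sm.simulate_counts(small_config())
        for gene, cls in truth.classes.items():
            e1, e2 = truth.true_log2_effects.loc[gene]
            assert np.sign(e1) == CLASS_SIGNS[cls][0]
            assert np.sign(e2) == CLASS_SIGNS[cls][1]

    def test_pm_empirical_fold_change_matches_nb_moment_oracle(self):
        """The fraction of PM genes whose empirical T1_3h/T1_0h mean ratio
        falls within half a log2 unit of the planted 8-fold change matches
        an independent Monte-Carlo draw from the same NB moments."""
        cfg = sm.SimConfig(
            n_genes=2000,
            class_proportions={"NULL": 0.5, "PM": 0.5},
            tf_families={},
            size_factor_range=(1.0, 1.0),
            seed=1,
        )
        cm, truth = sm.simulate_counts(cfg)
        pm = truth.classes.index[truth.classes == "PM"]
        ratio = (
            cm.counts.loc[pm, cm.samples_of("T1_3h")].mean(axis=1)
            / cm.counts.loc[pm, cm.samples_of("T1_0h")].mean(axis=1)
        )
        in_window = (ratio >= 2**2.5) & (ratio <= 2**3.5)

        # independent oracle: direct NB draws at the configured moments
        rng = np.random.default_rng(99)
        n_mc = 50_000
        base = rng.lognormal(cfg.baseline_logmean_mu, cfg.baseline_logmean_sigma, n_mc)
        alpha = cfg.dispersion * rng.lognormal(0.0, 0.25, n_mc)
        r = 1.0 / alpha
        m0 = rng.negative_binomial(r[:, None], (r / (r + base))[:, None], (n_mc, 3)).mean(1)
        m1 = rng.negative_binomial(
            r[:, None], (r / (r + 8 * base))[:, None], (n_mc, 3)
        ).mean(1)
        mc_ratio = m1 / m0
        oracle = ((mc_ratio >= 2**2.5) & (mc_ratio <= 2**3.5)).mean()

        se = np.sqrt(oracle * (1 - oracle) / len(pm))
        assert abs(in_window.mean() - oracle) <= 4 * se
        assert in_window.mean() >= 0.85  # the great majority sit near 8-fold

    def test_zero_dispersion_is_poisson_like(self):
        cfg = sm.SimConfig(
            n_genes=10_000,
            class_proportions={"NULL": 1.0},
            dispersion=0.0,
            baseline_logmean_sigma=0.0,
            size_factor_range=(1.0, 1.0),
            tf_families={},
            seed=2,
        )
        cm, _ = sm.simulate_counts(cfg)
        col = cm.counts.iloc[:, 0].to_numpy()
        assert col.var() / col.mean() == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize(
        "field,value",
        [("dispersion", -0.1), ("effect_first", float("inf")),
         ("class_proportions", {"NULL": 0.5})],
    )
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            sm.simulate_counts(small_config(**{field: value}))


class TestSimulateAnnotations:
    def test_no_enrichment_matches_genome_frequency(self):
        fracs = []
        for seed in range(50):
            cfg = small_config(seed=seed, tf_families={"FAM": (40, 1.0)})
            _, truth = sm.simulate_counts(cfg)
            fam = sm.simulate_annotations(cfg, truth)
            mem = truth.memory_genes()
            fracs.append(sum(1 for g in mem if fam[g] == "FAM") / max(len(mem), 1))
        assert np.mean(fracs) == pytest.approx(0.1, abs=0.03)  # genome freq 40/400

    def test_multiplier_two_doubles_memory_frequency(self):
        fracs = []
        for seed in range(50):
            cfg = sm.SimConfig(n_genes=1000, seed=seed, tf_families={"FAM": (60, 2.0)})
            _, truth = sm.simulate_counts(cfg)
            fam = sm.simulate_annotations(cfg, truth)
            mem = truth.memory_genes()
            fracs.append(sum(1 for g in mem if fam[g] == "FAM") / len(mem))
        assert np.mean(fracs) == pytest.approx(0.12, abs=0.02)

    def test_empty_families_maps_every_gene_to_none(self):
        cfg = small_config(tf_families={})
        _, truth = sm.simulate_counts(cfg)
        fam = sm.simulate_annotations(cfg, truth)
        assert fam.isna().all()

    def test_oversized_family_rejected(self):
        cfg = small_config(tf_families={"HUGE": (10_000, 1.0)})
        with pytest.raises(ValueError):
            _, truth = sm.simulate_counts(cfg)


class TestSimulateNetwork:
    def test_no_background_one_clique_of_four_has_six_edges(self):
        cfg = small_config(hub_spec=(4, 4, 0.0))
        _, truth = sm.simulate_counts(cfg)
        graph = sm.simulate_network(cfg, truth)
        assert graph.number_of_edges() == 6
        assert len(truth.hubs) == 4

    def test_no_background_no_clique_is_empty(self):
        cfg = small_config(hub_spec=(0, 0, 0.0))
        _, truth = sm.simulate_counts(cfg)
        graph = sm.simulate_network(cfg, truth)
        assert graph.number_of_edges() == 0

    def test_er_edge_count_within_three_sd(self):
        cfg = sm.SimConfig(
            n_genes=1000, seed=9,
            tf_families={"FAM": (50, 1.0)},
            hub_spec=(0, 0, 0.1),
        )
        _, truth = sm.simulate_counts(cfg)
        graph = sm.simulate_network(cfg, truth)
        n_pairs = 50 * 49 / 2
        mean, sd = n_pairs * 0.1, np.sqrt(n_pairs * 0.1 * 0.9)
        assert abs(graph.number_of_edges() - mean) <= 3 * sd

    def test_planted_hubs_induce_clique(self, strong_sim):
        graph, truth = strong_sim["graph"], strong_sim["truth"]
        hubs = sorted(truth.hubs)
        for i, u in enumerate(hubs):
            for v in hubs[i + 1:]:
                assert graph.has_edge(u, v)

    def test_simple_graph(self, strong_sim):
        graph = strong_sim["graph"]
        assert all(u != v for u, v in graph.edges)


class TestSimulatePromoters:
    def test_planted_word_written_at_recorded_position(self, strong_sim):
        truth, promoters = strong_sim["truth"], strong_sim["promoters"]
        consensi = strong_sim["consensi"]
        assert len(truth.motif_instances) > 0
        for fam, gene, offset, strand in truth.motif_instances[:200]:
            word = consensi[fam]
            sub = promoters[gene].seq[offset : offset + len(word)]
            expected = word if strand == "+" else sm.motifscan.reverse_complement(word)
            assert sub == expected

    def test_positions_inside_promoter(self, strong_sim):
        truth = strong_sim["truth"]
        length, _, _ = strong_sim["config"].promoter_spec
        w = strong_sim["config"].motif_width
        for _, _, offset, _ in truth.motif_instances:
            assert 0 <= offset <= length - w

    def test_zero_rate_plants_nothing(self):
        cfg = small_config(promoter_spec=(1000, 0.5, 0.0))
        _, truth = sm.simulate_counts(cfg)
        sm.simulate_annotations(cfg, truth)
        _, _ = sm.simulate_promoters(cfg, truth)
        assert truth.motif_instances == []

    def test_gc_content_near_target(self):
        cfg = sm.SimConfig(
            n_genes=500, seed=5, tf_families={}, promoter_spec=(1000, 0.5, 0.0)
        )
        _, truth = sm.simulate_counts(cfg)
        promoters, _ = sm.simulate_promoters(cfg, truth)
        seq = "".join(p.seq for p in promoters.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_motif_wider_than_promoter_rejected(self):
        with pytest.raises(ValueError):
            small_config(promoter_spec=(6, 0.5, 1.0)).validate()
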