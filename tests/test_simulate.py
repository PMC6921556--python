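"""Generator self-consistency: determinism, mean parameterization,
planted-structure bookkeeping and read conservation."""

import numpy as np
import pandas as pd
import pytest

from nidyn.core import CATEGORIES, CONDITIONS
from nidyn.errors import SizingError, ValidationError
from nidyn.simulate import (
    SimulationConfig,
    build_truth_table,
    condition_means,
    make_genome_annotation,
    simulate_chip_reads,
    simulate_counts,
    simulate_qpcr,
    simulate_tf_catalog,
)


class TestAnnotation:
    def test_windows_disjoint_and_in_bounds(self):
        cfg = SimulationConfig(n_genes=10, genome_length=1_000_000, seed=7,
                               n_per_category={})
        ann = make_genome_annotation(cfg)
        assert len(ann) == 10
        assert ann["gene_id"].is_unique
        lo = ann["tss"] - cfg.flank
        hi = ann["tss"] + cfg.flank
        assert (lo >= 0).all() and (hi <= cfg.genome_length).all()
        order = np.argsort(lo.to_numpy())
        assert (hi.to_numpy()[order][:-1] <= lo.to_numpy()[order][1:]).all()

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=50, genome_length=1_000_000, seed=7,
                               n_per_category={})
        pd.testing.assert_frame_equal(make_genome_annotation(cfg), make_genome_annotation(cfg))

    def test_packing_feasibility(self):
        # 1000 genes x (4 kb window + 100 bp gap) = 4.1 Mb exactly
        ok = SimulationConfig(n_genes=1000, genome_length=4_100_000, n_per_category={})
        assert len(make_genome_annotation(ok)) == 1000
        short = SimulationConfig(n_genes=1000, genome_length=3_000_000, n_per_category={})
        with pytest.raises(SizingError):
            make_genome_annotation(short)


class TestCounts:
    def test_category_bookkeeping(self):
        cfg = SimulationConfig(n_genes=200, genome_length=1_000_000,
                               n_per_category={c: 20 for c in CATEGORIES}, seed=3)
        ann = make_genome_annotation(cfg)
        _, truth = simulate_counts(ann, cfg)
        counts = truth["category"].value_counts()
        for c in CATEGORIES:
            assert counts[c] == 20
        assert counts["none"] == 200 - 120
        assert len(truth) == len(ann)
        assert truth["gene_id"].is_unique

    def test_truth_sign_rules(self, counts_truth):
        _, truth = counts_truth
        sign = {
            "TU": (1, 0), "TD": (-1, 0), "PU-A": (1, 1), "PU-B": (0, 1),
            "PD-A": (-1, -1), "PD-B": (0, -1), "none": (0, 0),
        }
        for _, row in truth.iterrows():
            sa, sb = sign[row["category"]]
            assert np.sign(row["planted_log2fc_A"]) == sa
            assert np.sign(row["planted_log2fc_B"]) == sb

    def test_mean_parameterization_monte_carlo(self):
        """Empirical Ni-W/UT mean ratio of a PU-B gene converges to the fold."""
        cfg = SimulationConfig(n_genes=12, genome_length=100_000,
                               n_per_category={"PU-B": 2}, baseline_mean=100,
                               nb_dispersion=0.05, fold_change=4, seed=11)
        ann = make_genome_annotation(cfg)
        truth = build_truth_table(ann, cfg)
        means = condition_means(truth, cfg)
        gene = truth.loc[truth["category"] == "PU-B", "gene_id"].iloc[0]
        rng = np.random.default_rng(5)
        size = 1 / cfg.nb_dispersion
        draws_w = rng.negative_binomial(
            size, size / (size + means.loc[gene, "Ni-W"]), size=10_000
        )
        draws_ut = rng.negative_binomial(
            size, size / (size + means.loc[gene, "UT"]), size=10_000
        )
        assert 3.8 <= draws_w.mean() / draws_ut.mean() <= 4.2

    def test_unit_fold_change_means_identical(self):
        cfg = SimulationConfig(n_genes=30, genome_length=200_000,
                               n_per_category={c: 3 for c in CATEGORIES},
                               fold_change=1.0, seed=1)
        ann = make_genome_annotation(cfg)
        truth = build_truth_table(ann, cfg)
        means = condition_means(truth, cfg)
        assert (means.nunique(axis=1) == 1).all()

    def test_determinism(self, annotation, small_config):
        c1, t1 = simulate_counts(annotation, small_config)
        c2, t2 = simulate_counts(annotation, small_config)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        pd.testing.assert_frame_equal(t1, t2)


@pytest.fixture(scope="module")
def chip_setup():
    cfg = SimulationConfig(n_genes=60, genome_length=300_000,
                           n_per_category={c: 6 for c in CATEGORIES},
                           chip_reads_per_sample=30_000, seed=9)
    ann = make_genome_annotation(cfg)
    truth = build_truth_table(ann, cfg)
    return cfg, ann, truth


class TestChipReads:

    def test_reads_within_bounds_and_deterministic(self, chip_setup):
        cfg, ann, truth = chip_setup
        r1 = simulate_chip_reads(ann, truth, cfg)
        r2 = simulate_chip_reads(ann, truth, cfg)
        for cond in CONDITIONS:
            pd.testing.assert_frame_equal(r1[cond], r2[cond])
            assert (r1[cond]["start"] >= 0).all()
            assert (r1[cond]["end"] <= cfg.genome_length).all()
            assert (r1[cond]["start"] < r1[cond]["end"]).all()
            # target depth reached within condition-composition drift
            assert abs(len(r1[cond]) - cfg.chip_reads_per_sample) < 0.1 * cfg.chip_reads_per_sample

    def test_planted_promoter_ratio_monte_carlo(self, chip_setup):
        """PD-B multipliers (UT=4, Ni-W=1): background-corrected mean
        promoter count ratio converges to 4 within +-10%."""
        cfg, ann, truth = chip_setup
        gene = truth.loc[truth["category"] == "PD-B", "gene_id"].iloc[0]
        row = ann.set_index("gene_id").loc[gene]
        lo, hi = row["tss"] - cfg.flank, row["tss"] + cfg.flank
        # expected uniform-background reads falling in one window
        bg_expected = (
            cfg.chip_background_fraction
            * cfg.chip_reads_per_sample
            * (2 * cfg.flank)
            / cfg.genome_length
        )
        tot = {"UT": 0.0, "Ni-W": 0.0}
        n_reps = 100
        for rep in range(n_reps):
            reads = simulate_chip_reads(ann, truth, cfg.with_seed(1000 + rep))
            for cond in tot:
                df = reads[cond]
                five = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
                tot[cond] += int(((five >= lo) & (five < hi)).sum())
        ratio = (tot["UT"] - n_reps * bg_expected) / (tot["Ni-W"] - n_reps * bg_expected)
        assert 3.6 <= ratio <= 4.4

    def test_window_outside_chromosome_raises(self, chip_setup):
        cfg, ann, truth = chip_setup
        bad = ann.copy()
        bad.loc[bad.index[-1], "tss"] = cfg.genome_length - 10
        with pytest.raises(SizingError):
            simulate_chip_reads(bad, truth, cfg)


@pytest.fixture(scope="module")
def catalog_setup():
    cfg = SimulationConfig(n_genes=500, genome_length=3_000_000,
                           n_per_category={"PU-B": 50}, seed=21,
                           tf_f_fg=0.8, tf_f_bg=0.1, tf_null_rate=0.2,
                           n_null_tfs=3)
    ann = make_genome_annotation(cfg)
    truth = build_truth_table(ann, cfg)
    return cfg, ann, truth


class TestTFCatalog:

    def test_target_overlap_binomial(self, catalog_setup):
        cfg, ann, truth = catalog_setup
        udhs, peaks = simulate_tf_catalog(ann, truth, cfg)
        fg_genes = set(truth.loc[truth["category"] == "PU-B", "gene_id"])
        gene_udhs = dict(zip(ann["gene_id"], udhs["udhs_id"][: len(ann)]))
        fg_ids = {gene_udhs[g] for g in fg_genes}
        target = peaks["TF_target1"]
        bound_ids = set()
        pos = {(r.chrom, r.start, r.end): u for r, u in zip(udhs.itertuples(), udhs["udhs_id"])}
        for r in target.itertuples():
            bound_ids.add(pos[(r.chrom, r.start, r.end)])
        hits = len(bound_ids & fg_ids)
        # Binomial(50, 0.8): mean 40, sd ~2.8; allow 3 sd
        assert abs(hits - 40) <= 3 * np.sqrt(50 * 0.8 * 0.2)

    def test_udhs_size_without_distractors(self, catalog_setup):
        cfg, ann, truth = catalog_setup
        udhs, _ = simulate_tf_catalog(ann, truth, cfg)
        assert len(udhs) == len(ann)
        assert udhs["udhs_id"].is_unique

    def test_null_tf_rate_uniform(self, catalog_setup):
        cfg, ann, truth = catalog_setup
        udhs, peaks = simulate_tf_catalog(ann, truth, cfg)
        fg_genes = set(truth.loc[truth["category"] == "PU-B", "gene_id"])
        is_fg = np.array([g in fg_genes for g in ann["gene_id"]])
        null_peaks = peaks["TF_null01"]
        starts = set(null_peaks["start"])
        bound = udhs["start"][: len(ann)].isin(starts).to_numpy()
        # same binding rate in expectation on fg and bg promoters
        p_fg, p_bg = bound[is_fg].mean(), bound[~is_fg].mean()
        assert abs(p_fg - p_bg) < 0.2


class TestQPCR:
    def test_ordering_and_determinism(self, counts_truth, small_config):
        _, truth = counts_truth
        q1 = simulate_qpcr(truth, small_config)
        q2 = simulate_qpcr(truth, small_config)
        pd.testing.assert_frame_equal(q1, q2)
        pu = truth.loc[truth["category"].isin(["PU-A", "PU-B"]), "gene_id"]
        sub = q1[q1["gene_id"].isin(pu)]
        means = sub.groupby(["gene_id", "condition"])["fold_enrichment"].mean().unstack()
        assert (means["UT"] > means["Ni-W"]).all()

    def test_zero_noise_reproduces_means(self, counts_truth, small_config):
        from dataclasses import replace

        _, truth = counts_truth
        cfg = replace(small_config, qpcr_noise_sd=0.0)
        q = simulate_qpcr(truth, cfg)
        pu = set(truth.loc[truth["category"] == "PU-B", "gene_id"])
        sub = q[q["gene_id"].isin(pu)]
        assert (sub.loc[sub["condition"] == "UT", "fold_enrichment"] == 4.0).all()
        assert (sub.loc[sub["condition"] == "Ni-W", "fold_enrichment"] == 1.0).all()


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ValidationError):
        SimulationConfig(fold_change=0.5)
    with pytest.raises(ValidationError):
        SimulationConfig(n_replicates=1)
    with pytest.raises(ValidationError):
        SimulationConfig(n_genes=10, n_per_category={"TU": 11})
    with pytest.raises(ValidationError):
        SimulationConfig(n_per_category={"XX": 1})
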