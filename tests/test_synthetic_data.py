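"""Generator ground truth: trajectories, sampling, reads, paired cells."""

import numpy as np
import pytest
from scipy import stats

from repseq.synthetic_data import (ConfigurationError, GenerativeConfig,
                                   SimulationError, get_reference,
                                   simulate_cohort, simulate_paired_sc,
                                   simulate_reads, simulate_repertoire)


def noiseless_config(**kw):
    defaults = dict(n_donors=3, donor_intercept_sd=0.0, residual_sd=0.0,
                    true_richness_by_subset={"CD4_naive": 1000},
                    seed=11)
    defaults.update(kw)
    return GenerativeConfig(**defaults)


class TestCohort:
    def test_zero_slope_zero_noise_keeps_richness_constant(self):
        cfg = noiseless_config(annual_pct_change={})
        _, truths = simulate_cohort(cfg)
        for t in truths:
            for chain in ("alpha", "beta"):
                assert (t.richness[(2, "CD4_naive", chain)]
                        == t.richness[(1, "CD4_naive", chain)])

    def test_cohort_bookkeeping(self):
        cfg = GenerativeConfig(n_donors=30, seed=2)
        profiles, truths = simulate_cohort(cfg)
        assert len(truths) == 30
        assert len(profiles) == 60
        for t in truths:
            age1, age2 = t.ages
            assert 7.0 <= age2 - age1 <= 11.0
            assert 28.0 <= age1 <= 76.0
        sexes = [p.sex for p in profiles if p.visit == 1]
        assert sexes.count("male") == 15 and sexes.count("female") == 15

    def test_decline_matches_closed_form_compounding(self):
        # -3 %/year over a known gap: R2 = round(R1 · 0.97^gap)
        cfg = noiseless_config(
            annual_pct_change={("CD4_naive", "alpha"): -3.0,
                               ("CD4_naive", "beta"): -3.0})
        _, truths = simulate_cohort(cfg)
        for t in truths:
            gap = t.ages[1] - t.ages[0]
            for chain in ("alpha", "beta"):
                r1 = t.richness[(1, "CD4_naive", chain)]
                expected = round(r1 * (1 - 0.03) ** gap)
                assert t.richness[(2, "CD4_naive", chain)] == expected

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            GenerativeConfig(clone_size_distribution="zipf-ish")

    def test_frequencies_sum_to_one(self):
        cfg = noiseless_config()
        _, truths = simulate_cohort(cfg)
        f = truths[0].frequencies(1, "CD4_naive", "alpha")
        assert abs(f.sum() - 1.0) < 1e-12

    def test_retained_clones_subset_of_both_visits(self):
        cfg = GenerativeConfig(
            n_donors=2, true_richness_by_subset={"CD8_memory": 300},
            retention_fraction=0.5, seed=4)
        _, truths = simulate_cohort(cfg)
        t = truths[0]
        v1 = set(t.clones(1, "CD8_memory", "beta"))
        v2 = set(t.clones(2, "CD8_memory", "beta"))
        retained = set(t.retained_clones("CD8_memory", "beta"))
        assert retained <= (v1 & v2)

    def test_fixed_seed_reproducible(self):
        cfg = GenerativeConfig(n_donors=2, seed=9)
        _, t_a = simulate_cohort(cfg)
        _, t_b = simulate_cohort(GenerativeConfig(n_donors=2, seed=9))
        assert t_a[0].richness == t_b[0].richness
        tab_a = simulate_repertoire(t_a[0], "CD4_naive", "alpha", 200,
                                    seed=3)
        tab_b = simulate_repertoire(t_b[0], "CD4_naive", "alpha", 200,
                                    seed=3)
        assert tab_a.df.equals(tab_b.df)


@pytest.fixture(scope="module")
def truth():
    _, truths = simulate_cohort(noiseless_config())
    return truths[0]


@pytest.fixture(scope="module")
def table():
    _, truths = simulate_cohort(noiseless_config(
        true_richness_by_subset={"CD4_naive": 50}))
    return simulate_repertoire(truths[0], "CD4_naive", "alpha", 100,
                               seed=2)


class TestRepertoireSampling:
    def test_census_recovers_true_richness(self, truth):
        pop = int(truth.cell_counts(1, "CD4_naive", "alpha").sum())
        table = simulate_repertoire(truth, "CD4_naive", "alpha", pop,
                                    seed=0)
        assert table.n_clonotypes == truth.richness[(1, "CD4_naive",
                                                     "alpha")]
        assert table.total_umi == pop

    def test_single_cell_single_clonotype(self):
        cfg = noiseless_config(clone_size_distribution="uniform")
        _, truths = simulate_cohort(cfg)
        table = simulate_repertoire(truths[0], "CD4_naive", "alpha", 1,
                                    seed=1)
        assert table.n_clonotypes == 1
        assert table.total_umi == 1

    def test_oversampling_rejected(self, truth):
        pop = int(truth.cell_counts(1, "CD4_naive", "alpha").sum())
        with pytest.raises(SimulationError):
            simulate_repertoire(truth, "CD4_naive", "alpha", pop + 1,
                                seed=0)

    def test_unique_count_matches_brute_force_sampling_oracle(self):
        """Mean observed unique vs explicit cell-label subsampling."""
        cfg = noiseless_config(
            true_richness_by_subset={"CD4_naive": 500}, seed=21)
        _, truths = simulate_cohort(cfg)
        truth = truths[0]
        counts = truth.cell_counts(1, "CD4_naive", "alpha")
        n_cells = 1000
        # oracle: label every cell with its clone, shuffle, count unique
        labels = np.repeat(np.arange(len(counts)), counts)
        rng = np.random.default_rng(7)
        oracle = np.array([
            len(np.unique(rng.choice(labels, size=n_cells, replace=False)))
            for _ in range(100)], dtype=float)
        observed = np.array([
            simulate_repertoire(truth, "CD4_naive", "alpha", n_cells,
                                seed=1000 + i).n_clonotypes
            for i in range(100)], dtype=float)
        # means agree within combined Monte-Carlo error (4 SE)
        se = np.sqrt(oracle.var() / 100 + observed.var() / 100)
        assert abs(oracle.mean() - observed.mean()) < 4 * max(se, 1e-9)


class TestReads:
    def test_error_free_reads_equal_source_sequence(self, table,
                                                    reference):
        reads, sidecar = simulate_reads(table, 3, 0.0, "ACGTACGT", seed=0)
        by_nt = {row.junction: row for row in table.df.itertuples()}
        for read in reads[:30]:
            seq = str(read.seq)
            umi = seq[8:20]
            key = sidecar[umi]
            tcr = seq[20:]
            row = by_nt[key[4]]
            expected = (reference.v(row.v_call).tag + row.junction
                        + reference.j(row.j_call).tag)
            assert tcr == expected

    def test_read_count_conservation(self, table):
        reads, sidecar = simulate_reads(table, 3, 0.0, "ACGTACGT", seed=0)
        assert len(sidecar) == table.total_umi
        assert len(reads) == 3 * table.total_umi

    def test_error_rate_matches_binomial_expectation(self, table,
                                                     reference):
        reads, sidecar = simulate_reads(table, 3, 0.01, "ACGTACGT",
                                        seed=3)
        by_nt = {row.junction: row for row in table.df.itertuples()}
        mismatches, length = [], None
        for read in reads[:1000]:
            seq = str(read.seq)
            row = by_nt[sidecar[seq[8:20]][4]]
            truth_nt = (reference.v(row.v_call).tag + row.junction
                        + reference.j(row.j_call).tag)
            obs = seq[20:]
            mismatches.append(sum(a != b for a, b in zip(obs, truth_nt)))
            length = len(truth_nt)
        n = len(mismatches)
        expected = 0.01 * length
        ci = 4 * np.sqrt(length * 0.01 * 0.99 / n)
        assert abs(np.mean(mismatches) - expected) < ci

    def test_fastq_bytewise_reproducible(self, table, tmp_path):
        from repseq.synthetic_data import write_fastq
        paths = []
        for tag in "ab":
            reads, _ = simulate_reads(table, 2, 0.005, "ACGTACGT", seed=9)
            p = tmp_path / f"{tag}.fastq"
            write_fastq(reads, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestPairedSingleCell:
    def test_no_dual_alpha(self):
        sc = simulate_paired_sc(200, 0.0, seed=0)
        alpha_per_cell = (sc[sc.chain == "alpha"]
                          .groupby("cell_id").size())
        assert (alpha_per_cell == 1).all()

    def test_dual_alpha_fraction_within_binomial_ci(self):
        # generative single-α fraction 0.87 (the CD4 setting)
        n = 10_000
        sc = simulate_paired_sc(n, 0.13, seed=1)
        alpha_per_cell = (sc[sc.chain == "alpha"]
                          .groupby("cell_id").size())
        single = float((alpha_per_cell == 1).mean())
        lo, hi = stats.binom.interval(0.999, n, 0.87)
        assert lo / n <= single <= hi / n

    def test_single_cell_has_one_beta(self):
        sc = simulate_paired_sc(1, 0.5, seed=2)
        assert (sc.chain == "beta").sum() == 1


def test_uniform_repertoire_isi_equals_clone_count():
    """Ties the generator to the diversity module: even clone sizes give
    ISI ≈ clone count."""
    from repseq.diversity import inverse_simpson
    cfg = noiseless_config(clone_size_distribution="uniform",
                           true_richness_by_subset={"CD4_naive": 200})
    _, truths = simulate_cohort(cfg)
    pop = int(truths[0].cell_counts(1, "CD4_naive", "alpha").sum())
    table = simulate_repertoire(truths[0], "CD4_naive", "alpha", pop,
                                seed=0)
    isi = inverse_simpson(table)
    assert isi == pytest.approx(table.n_clonotypes, rel=1e-9)


def test_stop_codon_fraction_exercises_functional_filter():
    """A nonzero stop-codon fraction plants nonproductive CDR3s that the
    functional filter then removes."""
    from repseq.umi_pipeline import AnnotatedRecord, TCRSequence, \
        SampleId, filter_functional
    cfg = noiseless_config(stop_codon_fraction=0.3,
                           true_richness_by_subset={"CD4_naive": 300})
    _, truths = simulate_cohort(cfg)
    clones = truths[0].clones(1, "CD4_naive", "alpha")
    n_stop = sum("*" in aa for _, _, _, aa in clones)
    assert 0 < n_stop < len(clones)
    sample = SampleId("D01", 1, "CD4_naive", "alpha")
    records = [AnnotatedRecord(sample, f"UMI{i}",
                               TCRSequence("alpha", v, j, aa, nt), 3)
               for i, (v, j, nt, aa) in enumerate(clones)]
    kept = filter_functional(records)
    assert len(kept) == len(clones) - n_stop
    assert all("*" not in r.tcr.cdr3_aa for r in kept)


def test_yaml_round_trip(tmp_path):
    cfg = GenerativeConfig(n_donors=5, seed=3,
                           annual_pct_change={("CD4_naive", "beta"): -2.0})
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = GenerativeConfig.from_yaml(path)
    assert back == cfg
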