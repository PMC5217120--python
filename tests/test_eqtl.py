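"""The two-haplotype linear model, filtering, sharing, and QC checks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exorna import (
    HaplotypeBlock,
    effect_correlation,
    eqtl_expression_filter,
    fit_haplotype_model,
    kmer_bias_check,
    map_eqtls,
    shared_eqtls,
)
from exorna.eqtl import count_kmers, rank_haplotypes_by_associations, sex_confounding_check


class TestFitHaplotypeModel:
    def test_exact_linear_case(self):
        """log(Y+1) = mu + 1*p exactly: beta_p = 1, R^2 = 1, perfect fit."""
        p = np.array([0, 0, 1, 1])
        m = np.array([0, 1, 0, 1])
        y = np.exp(2.0 + 1.0 * p) - 1
        fit = fit_haplotype_model(y, p, m)
        assert fit.beta_p == pytest.approx(1.0, abs=1e-10)
        assert fit.beta_m == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.perfect_fit

    def test_closed_form_f_to_p_mapping(self):
        """For k = 2, n = 11: p = (1 + 2F/8)^(-4); R^2 = 0.5 gives p = 1/16."""
        rng = np.random.default_rng(0)
        n = 11
        p = np.array([0, 1] * 5 + [0], dtype=float)
        m = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1], dtype=float)
        X = np.column_stack([np.ones(n), p, m])
        signal = X @ np.array([1.0, 0.8, -0.5])
        signal_c = signal - signal.mean()
        r0 = rng.standard_normal(n)
        resid = r0 - X @ np.linalg.lstsq(X, r0, rcond=None)[0]
        resid *= np.sqrt((signal_c @ signal_c) / (resid @ resid))  # R^2 = 0.5
        y = np.exp(signal + resid) - 1
        fit = fit_haplotype_model(y, p, m)
        assert fit.r2 == pytest.approx(0.5, abs=1e-10)
        assert fit.f_stat == pytest.approx(4.0, abs=1e-8)
        assert fit.pvalue == pytest.approx(1 / 16, abs=1e-10)
        assert fit.pvalue == pytest.approx((1 + 2 * fit.f_stat / 8) ** -4, abs=1e-12)

    def test_constant_regressor_dropped(self):
        y = np.array([1.0, 2, 3, 4, 5, 6])
        p = np.zeros(6)
        m = np.array([0, 1, 0, 1, 0, 1])
        fit = fit_haplotype_model(y, p, m)
        assert fit.df_model == 1
        assert np.isnan(fit.beta_p) or fit.beta_p == 0.0

    def test_both_constant_untestable(self):
        fit = fit_haplotype_model(np.arange(5.0), np.zeros(5), np.ones(5))
        assert fit.untestable

    def test_encoding_flip_invariance(self):
        """Flipping a block's 0/1 labels flips beta sign, not R^2/F/p."""
        rng = np.random.default_rng(1)
        p = rng.integers(0, 2, 11).astype(float)
        m = rng.integers(0, 2, 11).astype(float)
        y = rng.lognormal(3, 1, 11)
        a = fit_haplotype_model(y, p, m)
        b = fit_haplotype_model(y, 1 - p, m)
        assert b.beta_p == pytest.approx(-a.beta_p)
        assert b.r2 == pytest.approx(a.r2)
        assert b.pvalue == pytest.approx(a.pvalue)

    def test_log_base_invariance(self):
        """log2 rescales betas by 1/ln 2 and leaves R^2 and p unchanged."""
        rng = np.random.default_rng(2)
        p = rng.integers(0, 2, 11).astype(float)
        m = rng.integers(0, 2, 11).astype(float)
        y = rng.lognormal(3, 1, 11)
        nat = fit_haplotype_model(y, p, m, log=np.log)
        base2 = fit_haplotype_model(y, p, m, log=np.log2)
        assert base2.beta_p == pytest.approx(nat.beta_p / np.log(2))
        assert base2.r2 == pytest.approx(nat.r2)
        assert base2.pvalue == pytest.approx(nat.pvalue)

    def test_too_few_children_rejected(self):
        with pytest.raises(ValueError, match="children"):
            fit_haplotype_model(np.ones(3), np.array([0, 1, 0]), np.array([0, 0, 1]))


class TestExpressionFilter:
    def test_median_threshold_inclusive(self):
        norm = pd.DataFrame(
            {"c1": [9.9, 10.0, 10.1], "c2": [9.9, 10.0, 10.1], "c3": [9.9, 10.0, 10.1]},
            index=["low", "edge", "high"],
        )
        kept = eqtl_expression_filter(norm, ["c1", "c2", "c3"])
        assert kept == ["edge", "high"]

    def test_multi_locus_excluded(self):
        norm = pd.DataFrame({"c1": [100.0, 100.0]}, index=["uni", "multi"])
        kept = eqtl_expression_filter(norm, ["c1"], multi_locus={"multi"})
        assert kept == ["uni"]

    def test_variant_overlap_excluded(self):
        norm = pd.DataFrame({"c1": [100.0, 100.0]}, index=["hit", "clean"])
        intervals = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 500], "end": [122, 522]},
            index=["hit", "clean"],
        )
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [110]})
        kept = eqtl_expression_filter(
            norm, ["c1"], intervals=intervals, variant_positions=variants
        )
        assert kept == ["clean"]

    def test_missing_interval_raises(self):
        norm = pd.DataFrame({"c1": [100.0]}, index=["ghost"])
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [1]})
        with pytest.raises(KeyError, match="ghost"):
            eqtl_expression_filter(
                norm, ["c1"], intervals=pd.DataFrame(columns=["chrom", "start", "end"]),
                variant_positions=variants,
            )


class TestMapEqtls:
    def test_identical_counts_give_identical_tables(self, study, haplotype_run):
        kwargs = dict(
            blocks=haplotype_run["blocks"],
            annotation=study["annotation"],
            pedigree=study["pedigree"],
        )
        a = map_eqtls(study["counts"], compartment="cell", **kwargs)
        b = map_eqtls(study["counts"], compartment="cell", **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_eqtls_detected_in_cells(self, study, haplotype_run):
        """Every planted effect is tested and at least nominally detected."""
        fits = map_eqtls(
            study["counts"],
            haplotype_run["blocks"],
            study["annotation"],
            study["pedigree"],
            "cell",
            variant_positions=study["genotypes"].markers[["chrom", "pos"]],
        )
        planted = list(study["truth"].eqtl_transcripts)
        for transcript in planted:
            assert transcript in fits.index
            assert fits.at[transcript, "pvalue"] <= 0.05
            assert fits.at[transcript, "beta_p"] == pytest.approx(1.5, abs=0.75)
        n_fdr = sum(fits.at[t, "qvalue"] <= 0.20 for t in planted)
        assert n_fdr >= len(planted) - 1

    def test_planted_eqtl_power_at_20_percent_fdr(self):
        """>= 80% of planted cis effects reach a 20% FDR in cells, over seeds."""
        from exorna import (
            infer_transmissions,
            mendelian_filter,
            phase_parents,
            segment_blocks,
            simulate_study,
        )
        from exorna.simulate import SimulationConfig

        detected = total = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=500 + seed)
            pedigree, genotypes, annotation, counts, truth = simulate_study(cfg)
            filtered, _ = mendelian_filter(genotypes, pedigree)
            phased = phase_parents(filtered, pedigree)
            blocks = segment_blocks(infer_transmissions(filtered, phased, pedigree))
            fits = map_eqtls(counts, blocks, annotation, pedigree, "cell")
            for t in truth.eqtl_transcripts:
                if t in fits.index:
                    total += 1
                    detected += fits.at[t, "qvalue"] <= 0.20
        assert total >= 25
        assert detected / total >= 0.8

    def test_multi_locus_mature_never_tested(self, study, haplotype_run):
        fits = map_eqtls(
            study["counts"],
            haplotype_run["blocks"],
            study["annotation"],
            study["pedigree"],
            "cell",
        )
        assert "sim-miR-dup-5p" not in fits.index


class TestSharingAndCorrelation:
    def _fits(self, betas_p, qvalues):
        return pd.DataFrame(
            {
                "beta_p": betas_p,
                "beta_m": np.zeros(len(betas_p)),
                "qvalue": qvalues,
            },
            index=[f"t{i}" for i in range(len(betas_p))],
        )

    def test_identical_effects_correlate_perfectly(self):
        rng = np.random.default_rng(3)
        b = rng.standard_normal(10)
        out = effect_correlation(self._fits(b, b * 0 + 1), self._fits(b, b * 0 + 1))
        assert out["r_beta_p"] == pytest.approx(1.0)

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            effect_correlation(self._fits([1, 2], [1, 1]), self._fits([1, 2], [1, 1]))

    def test_shared_requires_both_compartments(self):
        cell = self._fits([1, 2, 3], [0.05, 0.5, 0.1])
        exo = self._fits([1, 2, 3], [0.5, 0.05, 0.15])
        assert list(shared_eqtls(cell, exo, fdr=0.20).index) == ["t2"]
        assert shared_eqtls(cell, exo, fdr=0.0).empty

    def test_no_hits_gives_empty(self):
        cell = self._fits([1.0], [0.9])
        assert shared_eqtls(cell, cell, fdr=0.2).empty


def _block(p_codes, m_codes=None):
    children = [f"C{i + 1:02d}" for i in range(len(p_codes))]
    m_codes = m_codes if m_codes is not None else p_codes
    return HaplotypeBlock(
        "chr1", 0, 1_000_000,
        dict(zip(children, p_codes)), dict(zip(children, m_codes)),
    )


class TestKmerChecks:
    def test_fastq_reads_feed_the_check(self, tmp_path):
        """Unmapped FASTQ files round-trip into the k-mer bias check."""
        from exorna import SimulationConfig, simulate_hairpin_alignments
        from exorna.eqtl import load_reads_fastq

        cfg = SimulationConfig(seed=90)
        reads = {}
        for i in range(6):
            child = f"C{i + 1:02d}"
            aln = simulate_hairpin_alignments(
                cfg, n_reads=1, n_unmapped=50, kmer_rate=0.0,
                rng=np.random.default_rng(90 + i),
            )
            path = tmp_path / f"{child}.fastq"
            aln.write_fastq(path)
            reads[child] = load_reads_fastq(path)
        assert all(len(r) == 50 for r in reads.values())
        assert all(len(s) == 36 for s in reads["C01"])
        out = kmer_bias_check(reads, _block([0, 1] * 3), beta=1.0)
        assert out["pass"]

    def test_kmer_window_count(self):
        assert count_kmers(["ACGTACGTACG"], k=10) == {
            "ACGTACGTAC": 1,
            "CGTACGTACG": 1,
        }

    def test_identical_read_sets_pass(self):
        reads = {f"C{i + 1:02d}": ["ACGTACGTACGTACG"] * 3 for i in range(8)}
        block = _block([0, 1] * 4)
        out = kmer_bias_check(reads, block, beta=1.0)
        assert out["pass"]

    def test_planted_kmer_in_low_group_fails(self):
        rng = np.random.default_rng(4)
        kmer = "GATTACAGAT"
        reads = {}
        block = _block([0, 1] * 4)
        for i in range(8):
            child = f"C{i + 1:02d}"
            base = ["".join(rng.choice(list("ACGT"), 36)) for _ in range(40)]
            if block.paternal[child] == 0:  # low-expression group under beta > 0
                base += [kmer + "ACGTACGTACGTACGTACGTACGTGT" for _ in range(30)]
            reads[child] = base
        out = kmer_bias_check(reads, block, beta=1.0)
        assert not out["pass"]
        assert kmer in [k for k, _ in out["offending_kmers"]]

    def test_empty_reads_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kmer_bias_check({"C01": []}, _block([0, 1]), beta=1.0)


class TestHaplotypeRanking:
    def test_identical_blocks_get_identical_counts(self, study, haplotype_run):
        blocks = haplotype_run["blocks"][:4]
        twin = HaplotypeBlock(
            "chrX", 0, 10, dict(blocks[0].paternal), dict(blocks[0].maternal)
        )
        table = rank_haplotypes_by_associations(
            study["counts"], blocks + [twin], study["pedigree"], "cell"
        )
        assert (
            table.at[twin.block_id, "n_associated"]
            == table.at[blocks[0].block_id, "n_associated"]
        )

    def test_null_counts_near_binomial_expectation(self, study, haplotype_run):
        table = rank_haplotypes_by_associations(
            study["counts"], haplotype_run["blocks"], study["pedigree"], "exosome"
        )
        n_transcripts = table["n_associated"].max()
        # counts should look like Binomial(n_tested, ~0.05): far below half
        assert table["n_associated"].median() <= 0.15 * 120


def test_sex_check_reports_fisher_p(study, haplotype_run):
    block = haplotype_run["blocks"][0]
    out = sex_confounding_check(block, study["pedigree"])
    assert 0 <= out["pvalue"] <= 1
    assert np.asarray(out["table"]).sum() == len(study["pedigree"].children)
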