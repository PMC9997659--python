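"""Filtering, logCPM, precision weights, moderated fits, BH, splice plots."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from djsplice.dje import (
    bh_fdr,
    export_spliceplot,
    filter_junctions,
    fit_dje,
    logcpm,
    moderated_fit,
    variance_weights,
)
from djsplice.junctions import Junction, JunctionTable
from djsplice.simulate import CohortSpec, simulate_cohort
from djsplice.junctions import annotate_junctions


def _table(count_rows, libsizes=None, samples=None):
    n_s = len(count_rows[0])
    samples = samples or [f"s{i}" for i in range(n_s)]
    juncs = [Junction("chr1", "+", 100 * i + 10, 100 * i + 90)
             for i in range(len(count_rows))]
    df = pd.DataFrame(count_rows, index=[j.key for j in juncs],
                      columns=samples)
    libs = None if libsizes is None else dict(zip(samples, libsizes))
    return JunctionTable(juncs, df, libs)


class TestFilter:
    def test_mean_below_threshold_removed(self):
        t = _table([[9] * 8])
        assert len(filter_junctions(t, 10)) == 0

    def test_boundary_mean_exactly_ten_retained(self):
        t = _table([[10] * 8, [9, 11, 9, 11, 9, 11, 9, 11]])
        assert len(filter_junctions(t, 10)) == 2

    def test_matches_brute_force_row_mean_filter(self):
        spec = CohortSpec(n_samples_per_group=(8, 8), gene_abundance=12.0,
                          nb_dispersion=0.4, seed=6)
        table, _, _ = simulate_cohort(spec)
        kept = set(filter_junctions(table, 10).counts.index)
        brute = {k for k in table.counts.index
                 if table.counts.loc[k].mean() >= 10}
        assert kept == brute

    def test_library_sizes_unchanged(self, cassette_cohort):
        table, _, _ = cassette_cohort
        f = filter_junctions(table, 10)
        pd.testing.assert_series_equal(f.library_sizes, table.library_sizes)

    def test_idempotent_after_self_merge(self):
        t = _table([[12] * 4, [2] * 4])
        once = filter_junctions(t, 10)
        twice = filter_junctions(once, 10)
        assert once == twice


class TestLogcpm:
    def test_hand_arithmetic(self):
        t = _table([[0], [499999]], libsizes=[10 ** 6 - 1])
        y = logcpm(t)
        assert y.iloc[0, 0] == pytest.approx(np.log2(0.5))  # == -1
        assert y.iloc[1, 0] == pytest.approx(np.log2(499999.5))

    def test_doubling_count_increases_logcpm(self):
        a = logcpm(_table([[50]], libsizes=[10 ** 6]))
        b = logcpm(_table([[100]], libsizes=[10 ** 6]))
        assert b.iloc[0, 0] > a.iloc[0, 0]

    def test_zero_library_size_rejected(self):
        t = _table([[0]], libsizes=[5])
        t.library_sizes.iloc[0] = 0.0
        with pytest.raises(ValueError, match="library sizes"):
            logcpm(t)


class TestWeights:
    def test_homoskedastic_matrix_gets_near_constant_weights(self):
        rng = np.random.default_rng(1)
        y = pd.DataFrame(rng.normal(6, 1, (300, 16)))
        w = variance_weights(y, ["A"] * 8 + ["B"] * 8)
        # all weights within +/-20% of some common constant c: taking c as
        # the geometric midpoint, this requires max/min <= 1.2/0.8
        arr = w.to_numpy()
        assert arr.max() / arr.min() <= 1.5

    def test_high_variance_low_mean_block_downweighted(self):
        rng = np.random.default_rng(2)
        lo = rng.normal(2, 3, (100, 16))   # low mean, noisy
        hi = rng.normal(10, 0.5, (100, 16))  # high mean, tight
        y = pd.DataFrame(np.vstack([lo, hi]))
        w = variance_weights(y, ["A"] * 8 + ["B"] * 8)
        assert w.iloc[:100].mean().mean() < w.iloc[100:].mean().mean()

    def test_single_junction_falls_back_to_unit_weights(self):
        y = pd.DataFrame(np.random.default_rng(3).normal(5, 1, (1, 8)))
        w = variance_weights(y, ["A"] * 4 + ["B"] * 4)
        assert (w.to_numpy() == 1.0).all()

    def test_underdetermined_design_rejected(self):
        y = pd.DataFrame(np.zeros((5, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            variance_weights(y, ["A", "B"])


class TestModeration:
    def test_d0_zero_equals_ordinary_weighted_t(self):
        rng = np.random.default_rng(7)
        y = pd.DataFrame(rng.normal(0, 1, (40, 12)))
        w = pd.DataFrame(rng.uniform(0.5, 2.0, (40, 12)))
        groups = ["A"] * 6 + ["B"] * 6
        fit0, params = moderated_fit(y, groups, weights=w, d0=0)
        assert params.d0 == 0
        # ordinary weighted t computed independently per row (statsmodels)
        import statsmodels.api as sm

        x = sm.add_constant(np.r_[np.ones(6), np.zeros(6)])
        for i in range(0, 40, 7):
            res = sm.WLS(y.iloc[i].to_numpy(), x,
                         weights=w.iloc[i].to_numpy()).fit()
            assert fit0["t"].iloc[i] == pytest.approx(res.tvalues[1])
            assert fit0["p"].iloc[i] == pytest.approx(res.pvalues[1])

    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(8)
        y = pd.DataFrame(rng.normal(0, rng.uniform(0.5, 2, (60, 1)),
                                    (60, 10)))
        fit, params = moderated_fit(y, ["A"] * 5 + ["B"] * 5)
        lo = np.minimum(fit["s2"], params.s0_sq)
        hi = np.maximum(fit["s2"], params.s0_sq)
        assert ((fit["s2_post"] >= lo - 1e-12) &
                (fit["s2_post"] <= hi + 1e-12)).all()

    def test_large_d0_shrinks_everything_to_prior(self):
        rng = np.random.default_rng(9)
        y = pd.DataFrame(rng.normal(0, 1, (30, 10)))
        fit, params = moderated_fit(y, ["A"] * 5 + ["B"] * 5, d0=1e9)
        np.testing.assert_allclose(fit["s2_post"], params.s0_sq, rtol=1e-5)

    def test_too_few_samples_per_group_rejected(self):
        y = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_fit(y, ["A", "A", "B"])

    def test_matches_limma_ebayes_oracle(self, tmp_path):
        """Dual-route check: lmFit+eBayes (Bioconductor limma via Rscript)
        on the same matrix must agree with the moderated fit."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(42)
        y = rng.normal(5, 1, (50, 12)) * rng.uniform(0.5, 2, (50, 1))
        y[:5, :6] += 2
        df = pd.DataFrame(y, index=[f"j{i}" for i in range(50)],
                          columns=[f"s{i}" for i in range(12)])
        mat = tmp_path / "mat.tsv"
        out = tmp_path / "r_fit.tsv"
        df.to_csv(mat, sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{mat}", row.names=1))
grp <- factor(c(rep("T",6), rep("N",6)), levels=c("N","T"))
fit <- eBayes(lmFit(m, model.matrix(~grp)))
write.table(data.frame(logFC=fit$coefficients[,2], t=fit$t[,2],
                       p=fit$p.value[,2]), "{out}", sep="\\t", quote=FALSE)
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        r_fit = pd.read_csv(out, sep="\t", index_col=0)
        fit, _ = moderated_fit(df, ["T"] * 6 + ["N"] * 6)
        np.testing.assert_allclose(fit["logFC"], r_fit["logFC"], atol=1e-8)
        np.testing.assert_allclose(fit["t"], r_fit["t"], atol=1e-6)
        np.testing.assert_allclose(fit["p"], r_fit["p"], atol=1e-6)


def _brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_subsets_of_six_match_brute_force(self):
        base = [0.001, 0.02, 0.04, 0.2, 0.5, 0.97]
        for r in range(1, 7):
            for subset in itertools.combinations(base, r):
                np.testing.assert_allclose(bh_fdr(list(subset)),
                                           _brute_force_bh(subset))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=12),
           st_.randoms(use_true_random=False))
    def test_output_invariant_to_input_ordering(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        shuffled = [ps[i] for i in idx]
        direct = bh_fdr(ps)
        via = bh_fdr(shuffled)
        for pos, i in enumerate(idx):
            assert via[pos] == pytest.approx(direct[i])


class TestFitDje:
    def test_null_cohort_controls_type_I_error(self):
        spec = CohortSpec(n_genes=40, n_samples_per_group=(30, 30),
                          cassette_genes=[], seed=13)
        table, ann, truth = simulate_cohort(spec)
        st = annotate_junctions(table, ann)
        groups = pd.Series(truth["groups"], index=truth["samples"])
        res = fit_dje(filter_junctions(table), groups, st)
        frac = (res.table["FDR_abs"] < 0.05).mean()
        n = len(res.table)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_cassette_cohort_recovers_fig_signature(self, cassette_cohort,
                                                    cassette_statuses,
                                                    cohort_groups):
        table, _, truth = cassette_cohort
        res = fit_dje(filter_junctions(table), cohort_groups,
                      cassette_statuses)
        g = truth["genes"]["gene_1"]
        tab = res.table
        ups = set(tab.index[(tab.gene_id == "gene_1") & (tab["class"] == "up")])
        downs = set(tab.index[(tab.gene_id == "gene_1") &
                              (tab["class"] == "down")])
        assert ups == set(g["inclusion_junctions"])
        assert downs == {g["skipping_junction"]}
        # nothing else in the cohort is called
        assert (tab[tab.gene_id != "gene_1"]["class"] == "ns").all()

    def test_single_junction_gene_excluded_from_relative_testing(self):
        rng = np.random.default_rng(5)
        t = _table([rng.poisson(50, 8).tolist()], libsizes=[1e5] * 8)
        st = pd.DataFrame({"gene_id": ["solo"], "status": ["annotated"],
                           "txn_index": [1]}, index=t.counts.index)
        res = fit_dje(t, ["A"] * 4 + ["B"] * 4, st)
        row = res.table.iloc[0]
        assert not row["rel_tested"]
        assert np.isnan(row["logFC_rel"])
        assert row["class"] == "ns"

    def test_detection_rate_monotone_in_psi_separation(self):
        # power grows with the programmed inclusion switch |psi_A - psi_B|
        rates = []
        for psi_a in (0.15, 0.4, 0.9):
            hits = 0
            for seed in range(4):
                spec = CohortSpec(
                    n_genes=6, n_samples_per_group=(8, 8),
                    cassette_genes=[("gene_1", psi_a, 0.1)],
                    gene_abundance=60.0, seed=100 + seed)
                table, ann, truth = simulate_cohort(spec)
                st = annotate_junctions(table, ann)
                groups = pd.Series(truth["groups"], index=truth["samples"])
                res = fit_dje(filter_junctions(table), groups, st, cutoff=0.5)
                g = truth["genes"]["gene_1"]
                keys = [k for k in g["inclusion_junctions"]
                        if k in res.table.index]
                hits += sum(res.table.at[k, "class"] == "up" for k in keys)
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0


class TestSplicePlot:
    def test_cassette_gene_plot_records(self, cassette_cohort,
                                        cassette_statuses, cohort_groups):
        table, _, truth = cassette_cohort
        res = fit_dje(filter_junctions(table), cohort_groups,
                      cassette_statuses)
        plot = export_spliceplot(res, cassette_statuses, "gene_1")
        colors = {r["junction"]: r["color"] for r in plot["junctions"]}
        g = truth["genes"]["gene_1"]
        assert all(colors[k] == "red" for k in g["inclusion_junctions"])
        assert colors[g["skipping_junction"]] == "blue"
        novel = {r["junction"]: r["novel"] for r in plot["junctions"]}
        assert all(novel[k] for k in g["inclusion_junctions"])
        assert not novel[g["skipping_junction"]]
        # indices ascend along transcription for this reverse-strand gene
        idx = [r["txn_index"] for r in plot["junctions"]]
        assert idx == sorted(idx)
        assert min(idx) in plot["labeled_indices"]
        assert max(idx) in plot["labeled_indices"]

    def test_all_ns_gene_all_black(self, cassette_cohort, cassette_statuses,
                                   cohort_groups):
        table, _, _ = cassette_cohort
        res = fit_dje(filter_junctions(table), cohort_groups,
                      cassette_statuses)
        plot = export_spliceplot(res, cassette_statuses, "gene_2")
        assert all(r["color"] == "black" for r in plot["junctions"])

    def test_unknown_gene_rejected(self, cassette_cohort, cassette_statuses,
                                   cohort_groups):
        table, _, _ = cassette_cohort
        res = fit_dje(filter_junctions(table), cohort_groups,
                      cassette_statuses)
        with pytest.raises(KeyError):
            export_spliceplot(res, cassette_statuses, "no_such_gene")
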