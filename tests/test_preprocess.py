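"""Differential expression, FDR control and the selection cascade."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from paracrine.exceptions import (
    ConsistencyError,
    DegenerateGeneError,
    DomainError,
    InsufficientReplicationError,
    PairingError,
    ParameterError,
)
from paracrine.preprocess import (
    bh_adjust,
    correlation_baseline,
    high_variance_subset,
    moderated_t_test,
    select_network_genes,
    select_secreted_candidates,
    select_target_genes,
    standardize,
)
from paracrine.simulate import make_benchmark

from conftest import make_matrix


class TestModeratedT:
    def test_identical_groups_give_zero_t_unit_p(self, rng):
        vals = rng.normal(size=(30, 10))
        vals[0] = 5.0  # identical in both groups
        case = make_matrix(vals[:, :5])
        ctrl = make_matrix(vals[:, 5:])
        de = moderated_t_test(case, ctrl)
        assert de.loc["g01", "log2_fold_change"] == 0
        assert de.loc["g01", "moderated_t"] == 0
        assert de.loc["g01", "p_value"] == 1.0

    def test_zero_prior_df_equals_ordinary_pooled_t(self, rng):
        a = rng.normal(size=(50, 6))
        b = rng.normal(size=(50, 4))
        de = moderated_t_test(make_matrix(a), make_matrix(b), prior_df=0)
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(de["moderated_t"], t_ref, atol=1e-10)
        assert np.allclose(de["p_value"], p_ref, atol=1e-10)

    def test_infinite_prior_df_pools_all_variances(self, rng):
        a = rng.normal(size=(40, 5))
        b = rng.normal(size=(40, 5))
        de = moderated_t_test(make_matrix(a), make_matrix(b), prior_df=np.inf)
        # all genes share one posterior variance: t proportional to the fold change
        ratio = de["moderated_t"] / de["log2_fold_change"]
        ratio = ratio[de["log2_fold_change"].abs() > 1e-12]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_matches_limma_reference(self, tmp_path, rng):
        """Independent oracle: limma's eBayes on the same two-group design."""
        n1, n2, n_genes = 6, 4, 80
        data = rng.normal(8, 1, size=(n_genes, n1 + n2))
        data[:10, :n1] += 2.0
        genes = [f"g{i:03d}" for i in range(n_genes)]
        df = pd.DataFrame(data, index=genes)
        df.to_csv(tmp_path / "in.tsv", sep="\t")
        script = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{tmp_path}/in.tsv", row.names=1))
design <- cbind(Intercept=1, Case=c(rep(1,{n1}), rep(0,{n2})))
fit <- eBayes(lmFit(x, design))
out <- data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"], d0=fit$df.prior)
write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
"""
        (tmp_path / "cmp.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "cmp.R")], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        mine = moderated_t_test(make_matrix(data[:, :n1], genes=genes),
                                make_matrix(data[:, n1:], genes=genes))
        assert abs(mine.attrs["prior_df"] - ref["d0"].iloc[0]) < 1e-6
        assert np.allclose(mine["moderated_t"], ref["t"], atol=1e-8)
        assert np.allclose(mine["p_value"], ref["p"], atol=1e-8)

    def test_null_pvalues_roughly_uniform(self, rng):
        a = rng.normal(size=(2000, 15))
        b = rng.normal(size=(2000, 4))
        de = moderated_t_test(make_matrix(a), make_matrix(b))
        ks = stats.kstest(de["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_insufficient_replication_rejected(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 1))
        with pytest.raises(InsufficientReplicationError):
            moderated_t_test(make_matrix(a), make_matrix(b))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.all(bh_adjust([1.0] * 5) == 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            bh_adjust([0.1, 1.5])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
    def test_agrees_with_statsmodels(self, ps):
        mine = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            mine = bh_adjust(p)
            m = p.size
            brute = np.empty(m)
            for i in range(m):
                # q_i = min over p_(j) >= p_i of p_(j) * m / rank(j)
                order = np.argsort(p, kind="mergesort")
                vals = [p[j] * m / (np.where(order == j)[0][0] + 1) for j in order]
                brute[i] = min(
                    v for j, v in zip(order, vals) if p[j] >= p[i]
                )
            assert np.allclose(mine, np.minimum(brute, 1.0), atol=1e-12)


class TestTargetSelection:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["q_value", "log2_fold_change"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_strict_thresholds(self):
        de = self._de([(0.0005, 1.5), (0.0005, 1.0), (0.001, 1.5), (0.0009, -1.2)])
        assert select_target_genes(de) == ["g0", "g3"]

    def test_planted_truth_recovered_at_high_power(self):
        _, _, tumor, _ = make_benchmark(
            n_network=60, n_secreted=15, n_regulators=5, n_responsive=60,
            n_null=40, n_samples=100, n_controls=30, seed=21,
        )
        de = moderated_t_test(tumor.by_role("tumor_stimulated"), tumor.by_role("tumor_control"))
        selected = set(select_target_genes(de))
        planted = {g for g in de.index if g.startswith("TG")}
        assert selected == planted


class TestSecretedCascade:
    def _toy(self):
        # 10 genes x 15 samples engineered so each filter bites exactly once
        rng = np.random.default_rng(5)
        vals = np.zeros((10, 15))
        vals[:6] = 10.0 + rng.normal(0, 1.0, size=(6, 15))  # g01..g06 expressed
        vals[5] = 10.0  # g06: expressed but constant -> lowest IQR, dropped
        genes = [f"g{i + 1:02d}" for i in range(10)]
        flags = pd.DataFrame(False, index=genes,
                             columns=["secreted_annotation", "receptor",
                                      "growth_factor", "detected_in_cm"])
        flags.loc[[f"g{i + 1:02d}" for i in range(8)], "secreted_annotation"] = True
        flags.loc["g07", "receptor"] = True  # removed by filter 2
        flags.loc[["g01", "g02", "g03", "g04"], "detected_in_cm"] = True
        flags.loc["g05", "growth_factor"] = True  # undetected but rescued
        return make_matrix(vals, genes=genes), flags

    def test_hand_traced_cascade(self):
        stromal, flags = self._toy()
        result, audit = select_secreted_candidates(stromal, flags, with_audit=True)
        assert audit["secreted_annotation"] == 8
        assert audit["not_receptor"] == 7
        assert audit["expressed"] == 6  # g08 never exceeds the global 40th pct
        assert audit["iqr_filter"] == 5  # g06 dropped as the IQR-lowest
        assert result == ["g01", "g02", "g03", "g04", "g05"]

    def test_all_flags_false_gives_empty_list(self, rng):
        stromal = make_matrix(rng.normal(8, 1, size=(5, 10)))
        flags = pd.DataFrame(False, index=stromal.genes,
                             columns=["secreted_annotation", "receptor",
                                      "growth_factor", "detected_in_cm"])
        with pytest.warns(UserWarning):
            assert select_secreted_candidates(stromal, flags) == []

    def test_receptor_always_excluded(self):
        stromal, flags = self._toy()
        flags.loc["g01", "receptor"] = True
        assert "g01" not in select_secreted_candidates(stromal, flags)

    def test_gene_order_does_not_change_selection(self, rng):
        stromal, flags = self._toy()
        perm = list(rng.permutation(stromal.genes))
        shuffled = stromal.subset_genes(perm)
        assert set(select_secreted_candidates(stromal, flags)) == set(
            select_secreted_candidates(shuffled, flags.loc[perm])
        )

    def test_missing_flag_rows_rejected(self, rng):
        stromal = make_matrix(rng.normal(size=(4, 6)))
        flags = pd.DataFrame(False, index=stromal.genes[:2],
                             columns=["secreted_annotation", "receptor",
                                      "growth_factor", "detected_in_cm"])
        with pytest.raises(ConsistencyError):
            select_secreted_candidates(stromal, flags)


class TestNetworkGenes:
    def test_total_arithmetic(self, rng):
        vals = rng.normal(10, 2, size=(100, 15))
        stromal = make_matrix(vals)
        secreted = stromal.genes[:40]
        got = select_network_genes(stromal, secreted, total=80)
        assert len(got) == 80
        assert set(secreted) <= set(got)

    def test_shortfall_warns_and_returns_qualifiers(self, rng):
        vals = np.zeros((20, 10))
        vals[:5] = rng.normal(10, 1, size=(5, 10))  # only 5 expressed
        stromal = make_matrix(vals)
        with pytest.warns(UserWarning):
            got = select_network_genes(stromal, stromal.genes[:2], total=20)
        assert len(got) < 20

    def test_total_below_secreted_rejected(self, rng):
        stromal = make_matrix(rng.normal(size=(10, 8)))
        with pytest.raises(ParameterError):
            select_network_genes(stromal, stromal.genes[:5], total=3)

    def test_iqr_ties_broken_lexicographically(self):
        vals = np.tile(np.linspace(8, 12, 8), (6, 1))  # identical IQRs
        stromal = make_matrix(vals)
        got = select_network_genes(stromal, [], total=3)
        assert got == sorted(stromal.genes)[:3]


class TestStandardize:
    def test_constant_gene_rejected(self, rng):
        vals = rng.normal(size=(3, 8))
        vals[1] = 4.2
        with pytest.raises(DegenerateGeneError, match="g02"):
            standardize(make_matrix(vals))

    def test_means_zero_sds_one(self, rng):
        out = standardize(make_matrix(rng.normal(5, 3, size=(20, 12))))
        vals = out.array()
        assert np.max(np.abs(vals.mean(axis=1))) < 1e-12
        assert np.max(np.abs(vals.std(axis=1, ddof=1) - 1)) < 1e-12

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        m = standardize(make_matrix(rng.normal(size=(5, 9))))
        again = standardize(m)
        assert np.allclose(m.array(), again.array(), atol=1e-12)


class TestCorrelationBaseline:
    def test_identity_pair_counted(self, rng):
        x = rng.normal(size=(1, 15))
        secreted = make_matrix(x, genes=["x"])
        targets = make_matrix(np.vstack([x, rng.normal(size=(1, 15))]), genes=["y", "z"])
        counts = correlation_baseline(secreted, targets)
        assert counts["x"] >= 1

    def test_null_count_matches_theory(self, rng):
        # P(|r| > 0.7) for independent normals at n = 15
        n, cutoff = 15, 0.7
        t_crit = cutoff * np.sqrt((n - 2) / (1 - cutoff**2))
        p_exceed = 2 * stats.t.sf(t_crit, n - 2)
        n_sec, n_tgt, n_rep = 50, 100, 10
        total = 0
        for rep in range(n_rep):
            r2 = np.random.default_rng(rep)
            counts = correlation_baseline(
                make_matrix(r2.normal(size=(n_sec, n))),
                make_matrix(r2.normal(size=(n_tgt, n))),
                cutoff=cutoff,
            )
            total += counts.sum()
        rate = total / (n_sec * n_tgt * n_rep)
        assert abs(rate - p_exceed) < 3 * np.sqrt(p_exceed / (n_sec * n_tgt * n_rep))

    def test_planted_regulators_surface_despite_decoys(self):
        """Planted regulators always correlate with most of their targets and
        rank in the top half; network-correlated decoys may tie them, which
        is the known weakness of the naive baseline that motivates the
        causal analysis."""
        for seed in range(10):
            model, stromal, tumor, _ = make_benchmark(
                n_network=40, n_secreted=12, n_regulators=3, n_responsive=18,
                n_null=6, n_samples=15, seed=seed,
            )
            counts = correlation_baseline(
                stromal.subset_genes(sorted(model.secreted)),
                tumor.by_role("tumor_stimulated"),
            )
            n_targets = {x: 0 for x in model.regulators}
            for (x, _y) in model.regulator_effects:
                n_targets[x] += 1
            ranks = {g: i for i, g in enumerate(counts.index)}
            for x in model.regulators:
                assert counts[x] >= 0.8 * n_targets[x]
                assert ranks[x] < len(counts) // 2

    def test_unpaired_samples_rejected(self, rng):
        with pytest.raises(PairingError):
            correlation_baseline(
                make_matrix(rng.normal(size=(3, 10))),
                make_matrix(rng.normal(size=(3, 9))),
            )


class TestHighVariance:
    def test_full_count_returns_everything(self, rng):
        m = make_matrix(rng.normal(size=(7, 9)))
        assert set(high_variance_subset(m, 7)) == set(m.genes)

    def test_hand_ranked_toy(self):
        vals = np.array([
            np.linspace(0, 4, 6),    # var medium
            np.linspace(0, 10, 6),   # var largest
            np.full(6, 3.0),         # var zero
            np.linspace(0, 1, 6),    # var small
            np.linspace(0, 8, 6),    # var second
        ])
        m = make_matrix(vals)
        assert high_variance_subset(m, 3) == ["g02", "g05", "g01"]

    def test_zero_variance_gene_never_beats_positive(self, rng):
        vals = rng.normal(size=(4, 8))
        vals[2] = 1.0
        m = make_matrix(vals)
        assert "g03" not in high_variance_subset(m, 3)

    def test_top_n_too_large_rejected(self, rng):
        with pytest.raises(ParameterError):
            high_variance_subset(make_matrix(rng.normal(size=(3, 5))), 4)
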