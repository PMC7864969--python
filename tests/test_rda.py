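"""Hellinger RDA, VIF pruning, variance partitioning, interaction test."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import hzadapt as hz
from hzadapt import FreqTable
from hzadapt.rda import (
    build_predictors,
    hellinger_transform,
    interaction_model_test,
    rda_fit,
    variance_partition4,
    vif_prune,
)


def freq_table(freqs):
    freqs = np.asarray(freqs, dtype=float)
    P, L = freqs.shape
    return FreqTable(freqs, np.full((P, L), 12),
                     [f"p{i}" for i in range(P)], [f"l{j}:1" for j in range(L)])


class TestHellinger:
    def test_simple_rows(self):
        # abundances (4,0) -> (1,0); (1,1) -> (1/sqrt2, 1/sqrt2)
        F = FreqTable(np.array([[1.0, 0.0], [0.5, 0.5]]),
                      np.full((2, 2), 8), ["a", "b"], ["l0:1", "l1:1"])
        Y = hellinger_transform(F)
        assert Y.loc["a"].tolist() == pytest.approx([1.0, 0.0])
        assert Y.loc["b"].tolist() == pytest.approx([0.70711, 0.70711], abs=1e-5)

    def test_unit_row_sum_of_squares(self, rng):
        F = freq_table(rng.uniform(0, 1, size=(6, 40)))
        Y = hellinger_transform(F).to_numpy()
        assert np.allclose((Y**2).sum(axis=1), 1.0)

    def test_zero_row_rejected(self):
        F = freq_table(np.vstack([np.zeros(5), np.full(5, 0.5)]))
        with pytest.raises(ValueError, match="p0"):
            hellinger_transform(F)

    def test_missing_cells_mean_imputed(self):
        freqs = np.array([[0.5, np.nan], [0.5, 0.4], [0.5, 0.6]])
        n = np.array([[4, 0], [4, 4], [4, 4]])
        F = FreqTable(freqs, n, ["a", "b", "c"], ["l0:1", "l1:1"])
        Y = hellinger_transform(F)
        assert np.isfinite(Y.to_numpy()).all()


class TestVif:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        Xr, dropped = vif_prune(X)
        assert len(dropped) == 1 and dropped[0] in ("a", "b")

    def test_orthogonal_columns_untouched(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        X = pd.DataFrame(q, columns=list("abc"))
        Xr, dropped = vif_prune(X)
        assert dropped == []

    def test_closed_form_three_columns(self, rng):
        # VIF_j = 1/(1 - R2_j); verify against the correlation closed form
        n = 2000
        z = rng.normal(size=(n, 3))
        r = 0.8
        X = pd.DataFrame({
            "a": z[:, 0],
            "b": r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1],
            "c": z[:, 2],
        })
        M = (X - X.mean()) / X.std()
        R = M.corr().to_numpy()
        expected_vif_a = 1.0 / (1.0 - R[0, 1] ** 2 * 1.0)  # only b correlates
        # prune with a threshold above the expected VIF: nothing drops
        _, dropped = vif_prune(X, threshold=expected_vif_a + 0.5)
        assert dropped == []
        # and with a threshold just below it: one of the pair drops
        _, dropped = vif_prune(X, threshold=expected_vif_a - 0.5)
        assert len(dropped) == 1


class TestRdaFit:
    def test_exact_linear_response(self, rng):
        X = rng.normal(size=(20, 3))
        B = rng.normal(size=(3, 50))
        Y = X @ B
        res = rda_fit(Y, X, n_perm=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_self_conditioning_zero(self, rng):
        X = rng.normal(size=(15, 2))
        Y = rng.normal(size=(15, 30))
        res = rda_fit(Y, X, Z=X, n_perm=0)
        assert res.r2 == 0.0

    def test_adjusted_r2_formula(self, rng):
        n, m = 25, 4
        X = rng.normal(size=(n, m))
        Y = rng.normal(size=(n, 60))
        res = rda_fit(Y, X, n_perm=0)
        assert res.r2_adj == pytest.approx(
            1 - (1 - res.r2) * (n - 1) / (n - m - 1), abs=1e-12)
        assert res.r2_adj <= res.r2

    def test_matches_vegan_rda(self, rng, tmp_path):
        # independent oracle: vegan::rda on the same small matrices
        Y = rng.normal(size=(12, 8))
        X = rng.normal(size=(12, 2))
        np.savetxt(tmp_path / "Y.tsv", Y, delimiter="\t")
        np.savetxt(tmp_path / "X.tsv", X, delimiter="\t")
        script = f"""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.table("{tmp_path}/Y.tsv"))
        X <- as.data.frame(read.table("{tmp_path}/X.tsv"))
        m <- rda(Y ~ V1 + V2, data = X)
        cat(format(RsquareAdj(m)$r.squared, digits=12), format(RsquareAdj(m)$adj.r.squared, digits=12), sep="\\n")
        """
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        if out.returncode != 0:
            pytest.skip(f"vegan oracle unavailable: {out.stderr[:200]}")
        r2_ref, r2adj_ref = map(float, out.stdout.split())
        res = rda_fit(Y, X, n_perm=0)
        assert res.r2 == pytest.approx(r2_ref, abs=1e-6)
        assert res.r2_adj == pytest.approx(r2adj_ref, abs=1e-6)


class TestVarpart:
    def _blocks(self, rng, n=30):
        return {k: pd.DataFrame(rng.normal(size=(n, 2)),
                                columns=[f"{k}{j}" for j in range(2)])
                for k in ("env", "geo", "ancestry", "structure")}

    def test_inclusion_exclusion_identity(self, rng):
        blocks = self._blocks(rng)
        Y = rng.normal(size=(30, 40))
        vp = variance_partition4(Y, blocks)
        full = rda_fit(Y, pd.concat(blocks.values(), axis=1), n_perm=0).r2_adj
        assert vp["adj_r2"].sum() == pytest.approx(full, abs=1e-10)

    def test_dominant_block_identified(self, rng):
        blocks = self._blocks(rng)
        Y = blocks["geo"].to_numpy() @ rng.normal(size=(2, 40))
        Y = Y + 0.05 * rng.normal(size=Y.shape)
        vp = variance_partition4(Y, blocks).set_index("region")
        pure = {k: vp.loc[k, "adj_r2"] for k in blocks}
        assert pure["geo"] == max(pure.values())
        assert pure["geo"] > 0.5

    def test_matches_vegan_varpart(self, rng, tmp_path):
        # independent oracle on two-set partitioning: vegan::varpart reports
        # the pure fractions of each predictor table
        n = 20
        Y = rng.normal(size=(n, 10))
        A = rng.normal(size=(n, 2))
        B = rng.normal(size=(n, 2))
        for name, M in (("Y", Y), ("A", A), ("B", B)):
            np.savetxt(tmp_path / f"{name}.tsv", M, delimiter="\t")
        script = f"""
        suppressMessages(library(vegan))
        Y <- as.matrix(read.table("{tmp_path}/Y.tsv"))
        A <- as.matrix(read.table("{tmp_path}/A.tsv"))
        B <- as.matrix(read.table("{tmp_path}/B.tsv"))
        v <- varpart(Y, A, B)
        f <- v$part$indfract$Adj.R.square
        cat(format(f, digits=12), sep="\\n")
        """
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        if out.returncode != 0:
            pytest.skip(f"vegan oracle unavailable: {out.stderr[:200]}")
        # indfract rows: [a]=X1|X2, [b]=X2|X1, [c]=shared, [d]=residual
        pure_a, pure_b, shared, _resid = map(float, out.stdout.split())
        ra = rda_fit(Y, A, n_perm=0).r2_adj
        rb = rda_fit(Y, B, n_perm=0).r2_adj
        rab = rda_fit(Y, np.column_stack([A, B]), n_perm=0).r2_adj
        assert rab - rb == pytest.approx(pure_a, abs=1e-6)
        assert rab - ra == pytest.approx(pure_b, abs=1e-6)
        assert ra + rb - rab == pytest.approx(shared, abs=1e-6)


class TestPredictorsAndInteraction:
    def test_duplicate_gradients_one_pc(self, small_filtered):
        env, pmap, truth = (small_filtered["env"], small_filtered["pmap"],
                            small_filtered["truth"])
        pops = pmap.populations_of_group("HYB")
        vals = pd.DataFrame({
            "g1": env.values.loc[pops, env.gradients[0]],
            "g2": env.values.loc[pops, env.gradients[0]],  # exact duplicate
        })
        env2 = hz.EnvTable(vals, pd.DataFrame(
            {"name": ["g1", "g2"], "class": "other", "divergence_rank": np.nan}))
        omega = np.eye(len(pops))
        anc = truth.ancestry.loc[pops]
        pred = build_predictors(env2, pmap, anc, omega, pops)
        assert pred.env.shape[1] == 1

    def test_pcs_orthogonal_and_target_honoured(self, small_filtered):
        env, pmap, truth = (small_filtered["env"], small_filtered["pmap"],
                            small_filtered["truth"])
        pops = pmap.populations_of_group("HYB")
        omega = np.eye(len(pops))
        pred = build_predictors(env, pmap, truth.ancestry.loc[pops], omega, pops,
                                var_target=0.9)
        E = pred.env.to_numpy()
        G = E.T @ E
        assert np.allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        # minimal count: dropping the last axis must fall below the target
        Es = (env.values.loc[pops] - env.values.loc[pops].mean()) / env.values.loc[pops].std()
        s = np.linalg.svd(Es.to_numpy(), compute_uv=False)
        var = np.cumsum(s**2) / np.sum(s**2)
        k = E.shape[1]
        assert var[k - 1] >= 0.9
        assert k == 1 or var[k - 2] < 0.9

    def test_interaction_recovery_and_nesting(self, rng):
        n = 60
        env = pd.DataFrame({"e": rng.normal(size=n)})
        anc = pd.DataFrame({"anc": rng.normal(size=n)})
        inter = env["e"].to_numpy() * anc["anc"].to_numpy()
        Y = np.outer(env["e"], rng.normal(size=20)) \
            + np.outer(anc["anc"], rng.normal(size=20)) \
            + 2.0 * np.outer(inter, rng.normal(size=20)) \
            + 0.5 * rng.normal(size=(n, 20))
        res = interaction_model_test(Y, env, anc, n_perm=199, seed=4)
        assert res["p_added"] < 0.05
        assert res["r2_model1"] >= res["r2_model2"]

    def test_additive_truth_interaction_not_preferred(self, rng):
        n = 60
        env = pd.DataFrame({"e": rng.normal(size=n)})
        anc = pd.DataFrame({"anc": rng.normal(size=n)})
        Y = np.outer(env["e"], rng.normal(size=20)) \
            + np.outer(anc["anc"], rng.normal(size=20)) \
            + 1.0 * rng.normal(size=(n, 20))
        res = interaction_model_test(Y, env, anc, n_perm=199, seed=4)
        assert res["p_added"] > 0.05
        assert res["r2_model1"] >= res["r2_model2"]  # nesting always holds
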