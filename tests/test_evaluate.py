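"""Fold construction, phenotype adjustment, metrics and pipeline behavior."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from panelblup import (
    accuracy,
    adjust_phenotypes,
    bias_slope,
    make_folds,
    mas_fit,
    mas_predict,
    run_cv_cell,
    run_cv_experiment,
    run_external_validation,
    run_mas_experiment,
    summarize_records,
)
from panelblup.evaluate import _fit_training
from panelblup.genotypes import align_phenotypes


def pheno_frame(cgs, values=None, ids=None):
    n = len(cgs)
    return pd.DataFrame(
        {
            "animal_id": ids if ids is not None else [f"a{i:03d}" for i in range(n)],
            "cg": cgs,
            "y": values if values is not None else np.zeros(n),
        }
    )


class TestMakeFolds:
    def test_exact_division(self):
        ph = pheno_frame(["g1"] * 20)
        f = make_folds(ph, n_folds=10, seed=0)
        assert f["fold"].value_counts().eq(2).all()

    def test_per_cg_balance_brute_force(self):
        rng = np.random.default_rng(1)
        cgs = np.repeat([f"g{i:02d}" for i in range(32)], rng.integers(5, 40, 32))
        ph = pheno_frame(cgs, ids=[f"a{i:04d}" for i in range(len(cgs))])
        f = make_folds(ph, n_folds=10, seed=2)
        merged = ph.merge(f, on="animal_id")
        for cg, grp in merged.groupby("cg"):
            loads = grp["fold"].value_counts().reindex(range(1, 11), fill_value=0)
            assert loads.max() - loads.min() <= 1
        total = merged["fold"].value_counts()
        assert total.max() - total.min() <= 32

    def test_deterministic(self):
        ph = pheno_frame(np.repeat(["g1", "g2", "g3"], 10))
        f1 = make_folds(ph, 5, seed=3)
        f2 = make_folds(ph, 5, seed=3)
        pd.testing.assert_frame_equal(f1, f2)

    def test_small_cg_rejected(self):
        ph = pheno_frame(["g1"] * 4 + ["g2"] * 10)
        with pytest.raises(ValueError, match="minimum of 5"):
            make_folds(ph, 2, seed=0)

    def test_too_few_folds(self):
        ph = pheno_frame(["g1"] * 10)
        with pytest.raises(ValueError):
            make_folds(ph, 1, seed=0)


class TestAdjustPhenotypes:
    def test_balanced_groups_equal_centering(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(30)
        ph = pheno_frame(np.repeat(["g1", "g2", "g3"], 10), values=y)
        adj = adjust_phenotypes(ph, "y", ["cg"])
        manual = y - pd.Series(y).groupby(ph["cg"].values).transform("mean").to_numpy()
        np.testing.assert_allclose(adj["adjusted"].to_numpy(), manual, atol=1e-10)

    def test_residuals_sum_to_zero_within_levels(self):
        rng = np.random.default_rng(5)
        cgs = rng.choice(["g1", "g2", "g3", "g4"], 60)
        ph = pheno_frame(cgs, values=rng.standard_normal(60) + 3)
        adj = adjust_phenotypes(ph, "y", ["cg"])
        merged = ph.assign(r=adj["adjusted"].to_numpy())
        assert merged.groupby("cg")["r"].sum().abs().max() < 1e-8

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        cgs = rng.choice(["g1", "g2", "g3"], 40)
        yrs = rng.choice(["2014", "2015"], 40)
        y = rng.standard_normal(40)
        ph = pheno_frame(cgs, values=y)
        ph["year"] = yrs
        adj = adjust_phenotypes(ph, "y", ["cg", "year"])
        X = np.column_stack(
            [
                np.ones(40),
                (cgs == "g2").astype(float),
                (cgs == "g3").astype(float),
                (yrs == "2015").astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(adj["adjusted"].to_numpy(), y - X @ beta, atol=1e-8)

    def test_single_record_level_flagged(self):
        ph = pheno_frame(["g1"] * 6 + ["solo"], values=np.arange(7.0))
        with pytest.warns(UserWarning, match="single-record"):
            adj = adjust_phenotypes(ph, "y", ["cg"])
        assert adj["flagged"].iloc[-1]
        assert abs(adj["adjusted"].iloc[-1]) < 1e-10


class TestAccuracy:
    def test_perfect_rank_agreement(self):
        g = np.array([0.1, 0.5, 0.9, 1.4, 2.0])
        assert accuracy(g, np.exp(g), h2=1.0) == pytest.approx(1.0)

    def test_reversed_ranks_exceed_unity(self):
        g = np.arange(10.0)
        assert accuracy(g, -g, h2=0.25) == pytest.approx(-2.0)

    def test_matches_midrank_pearson_oracle(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 5, 50).astype(float)  # ties on purpose
        y = rng.standard_normal(50)
        got = accuracy(g, y, h2=0.36)
        r = np.corrcoef(rankdata(g), rankdata(y))[0, 1]
        assert got == pytest.approx(r / 0.6, rel=1e-10)

    def test_pearson_option(self):
        rng = np.random.default_rng(8)
        g, y = rng.standard_normal(30), rng.standard_normal(30)
        assert accuracy(g, y, 1.0, method="pearson") == pytest.approx(np.corrcoef(g, y)[0, 1])

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            accuracy(np.ones(5), np.arange(5.0), 0.5)
        with pytest.raises(ValueError):
            accuracy(np.arange(5.0), np.arange(5.0), 0.0)


class TestBiasSlope:
    def test_identity_and_affine(self):
        g = np.random.default_rng(9).standard_normal(20)
        assert bias_slope(g, g) == pytest.approx(1.0)
        assert bias_slope(g, 2 * g + 3) == pytest.approx(2.0)

    def test_cov_var_oracle(self):
        rng = np.random.default_rng(10)
        g, y = rng.standard_normal(40), rng.standard_normal(40)
        assert bias_slope(g, y) == pytest.approx(
            np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1), abs=1e-10
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            bias_slope(np.ones(5), np.arange(5.0))


class TestMAS:
    def test_hand_least_squares(self):
        y = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        dosage = np.array([0, 0, 1, 1, 2, 2])
        model = mas_fit(y, ["g1"] * 6, dosage)
        assert model.effect == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(mas_predict(model, dosage), dosage.astype(float))

    def test_null_effect_within_two_se(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            dosage = rng.integers(0, 3, 300)
            y = rng.standard_normal(300)
            cg = rng.choice(["g1", "g2", "g3"], 300)
            model = mas_fit(y, cg, dosage)
            hits += abs(model.effect) < 2 * model.se
        assert hits >= 9

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            mas_fit(np.arange(6.0), ["g"] * 6, np.ones(6))

    def test_aliased_with_cg_errors(self):
        # dosage perfectly determined by group membership
        dosage = np.array([0, 0, 0, 2, 2, 2])
        cg = ["g1"] * 3 + ["g2"] * 3
        with pytest.raises(ValueError, match="aliased"):
            mas_fit(np.random.default_rng(0).standard_normal(6), cg, dosage)


@pytest.fixture(scope="module")
def tiny_cv_setup(small_dataset):
    d = small_dataset
    kwargs = dict(
        sizes=(20,), random_sizes=(20,), n_random_reps=2,
        n_folds=3, n_replicates=1, seed=314,
    )
    records = run_cv_experiment(d.genotypes_train, d.pheno_train, "wbsf_like", **kwargs)
    return d, kwargs, records


class TestPipeline:
    def test_rerun_is_bit_identical(self, tiny_cv_setup):
        d, kwargs, records = tiny_cv_setup
        again = run_cv_experiment(d.genotypes_train, d.pheno_train, "wbsf_like", **kwargs)
        pd.testing.assert_frame_equal(records, again)

    def test_single_cell_reproduction(self, tiny_cv_setup):
        d, kwargs, records = tiny_cv_setup
        row = records[(records.strategy == "random") & (records.fold == 2) & (records.random_rep == 1)].iloc[0]
        cell = run_cv_cell(
            d.genotypes_train, d.pheno_train, "wbsf_like", seed=kwargs["seed"],
            replicate=1, fold=2, strategy="random", size=20, random_rep=1,
            n_folds=kwargs["n_folds"],
        )
        assert cell["accuracy"] == row["accuracy"]  # bit-identical
        assert cell["slope"] == row["slope"]

    def test_full_equals_top_k_at_panel_size(self, tiny_cv_setup):
        d, kwargs, records = tiny_cv_setup
        m = d.genotypes_train.n_snps
        extra = run_cv_experiment(
            d.genotypes_train, d.pheno_train, "wbsf_like",
            sizes=(m,), random_sizes=(), n_random_reps=0,
            n_folds=3, n_replicates=1, seed=314,
        )
        full = extra[extra.strategy == "full"].sort_values("fold")
        top = extra[extra.strategy == "top"].sort_values("fold")
        np.testing.assert_allclose(full["accuracy"].to_numpy(), top["accuracy"].to_numpy())
        np.testing.assert_allclose(full["slope"].to_numpy(), top["slope"].to_numpy())

    def test_no_leakage_from_test_fold(self, small_dataset):
        d = small_dataset
        G, ph = align_phenotypes(d.genotypes_train, d.pheno_train, "wbsf_like")
        train_idx = np.arange(0, 200)
        art1 = _fit_training(G, ph, "wbsf_like", train_idx, 0.01)
        ph2 = ph.copy()
        ph2.loc[ph2.index[250:], "wbsf_like"] += 100.0  # corrupt held-out records
        art2 = _fit_training(G, ph2, "wbsf_like", train_idx, 0.01)
        assert art1.vc.sigma_u2 == art2.vc.sigma_u2
        assert art1.ranking["snp_id"].tolist() == art2.ranking["snp_id"].tolist()
        np.testing.assert_array_equal(art1.fit.u, art2.fit.u)

    def test_summary_matches_brute_force(self, tiny_cv_setup):
        _, _, records = tiny_cv_setup
        s = summarize_records(records).set_index(["strategy", "size"])
        sub = records[(records.strategy == "random") & (records["size"] == 20)]["accuracy"].dropna()
        assert s.loc[("random", 20), "accuracy_mean"] == pytest.approx(sub.mean())
        assert s.loc[("random", 20), "accuracy_se"] == pytest.approx(
            sub.std(ddof=1) / np.sqrt(len(sub))
        )

    def test_external_copy_of_training_matches_in_sample(self, small_dataset):
        d = small_dataset
        trait = "marb_like"
        G_tr, ph_tr = align_phenotypes(d.genotypes_train, d.pheno_train, trait)
        # external cohort = renamed copy of the training cohort, one year level
        G_ext = G_tr.subset()
        G_ext.animal_ids = np.array([f"cp_{a}" for a in G_tr.animal_ids], dtype=object)
        ph_ext = ph_tr.copy()
        ph_ext["animal_id"] = [f"cp_{a}" for a in ph_tr["animal_id"]]
        ph_ext["year"] = "y1"
        ext = run_external_validation(
            G_tr, ph_tr, trait, G_ext, ph_ext, sizes=(), random_sizes=(), n_random_reps=0, seed=1
        )
        # in-sample reference: same full fit, predicting the training animals
        art = _fit_training(G_tr, ph_tr, trait, np.arange(G_tr.n_animals), 0.01)
        from panelblup import predict_gebv
        from panelblup.gblup import backsolve_snp_effects, solve_mme
        from panelblup.grm import regularize_grm, vanraden_grm

        Gm = regularize_grm(vanraden_grm(G_tr, art.freqs.to_numpy()), 0.01)
        fit = solve_mme(art.y, art.X, Gm, art.vc)
        ahat = backsolve_snp_effects(fit, G_tr, Gm)
        gebv = predict_gebv(ahat, art.freqs.to_numpy(), G_tr)
        y_adj = ph_tr[trait] - ph_tr[trait].mean()
        ref = accuracy(gebv, y_adj.to_numpy(), art.vc.h2)
        assert ext["accuracy"].iloc[0] == pytest.approx(ref, rel=1e-8)

    def test_duplicated_external_animals_rejected(self, small_dataset):
        d = small_dataset
        with pytest.raises(ValueError, match="duplicated"):
            run_external_validation(
                d.genotypes_train, d.pheno_train, "marb_like",
                d.genotypes_train, d.pheno_train.assign(year="y1"),
                sizes=(), random_sizes=(), n_random_reps=0,
            )

    def test_mas_records_shape(self, small_dataset):
        d = small_dataset
        rec = run_mas_experiment(
            d.genotypes_train, d.pheno_train, "wbsf_like",
            G_external=d.genotypes_external, pheno_external=d.pheno_external,
            n_folds=3, n_replicates=1, seed=5,
        )
        assert (rec.strategy == "mas").all()
        assert set(rec.cohort) == {"cv", "external"}
        assert (rec[rec.cohort == "cv"]["size"] == 1).all()
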