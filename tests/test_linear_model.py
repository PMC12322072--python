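"""Design construction, voom weights, consensus correlation, GLS, contrasts
and empirical-Bayes moderation."""

import math

import numpy as np
import pandas as pd
import pytest

import myocounter as mc
import myocounter.linmodel as lm
from myocounter import normalize
from myocounter.errors import ValidationError
from myocounter.simulate import COMPARISONS, SimulationConfig, simulate_cohort


def sheet_of(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "subtype", "cartridge", "fov", "conservation", "patient_id"]
    )


def test_design_column_counts():
    sheet = sheet_of(
        [
            ["S1", "NDC", "C1", 555, "Cryopreserved", "P1"],
            ["S2", "NDC", "C2", 555, "Cryopreserved", "P2"],
            ["S3", "Mi2", "C1", 555, "Cryopreserved", "P3"],
            ["S4", "Mi2", "C2", 555, "Cryopreserved", "P4"],
        ]
    )
    design = lm.build_design(sheet)
    assert design.matrix.shape[1] == 3  # 2 subtype + 1 cartridge
    assert design.subtype_columns == ["NDC", "Mi2"]
    assert design.nuisance_columns == ["cartridge[C2]"]


def test_design_study_cohort_has_eleven_columns(default_cohort):
    _, sheet, _ = default_cohort
    design = lm.build_design(sheet)
    # 4 subtypes + 6 cartridge + 1 conservation treatment columns
    assert design.matrix.shape[1] == 11
    assert len(design.subtype_columns) == 4
    assert len(design.nuisance_columns) == 7


def test_design_detects_aliasing():
    # cartridge C2 used only by the one Mi2 sample: perfectly nested
    sheet = sheet_of(
        [
            ["S1", "NDC", "C1", 555, "Cryopreserved", "P1"],
            ["S2", "NDC", "C1", 555, "Cryopreserved", "P2"],
            ["S3", "Mi2", "C2", 555, "Cryopreserved", "P3"],
        ]
    )
    with pytest.raises(ValidationError, match="aliased"):
        lm.build_design(sheet)


@pytest.fixture(scope="module")
def voom_setup(request):
    config = SimulationConfig(
        n_per_subtype={"NDC": 6, "Mi2": 6, "TIF1g": 6, "irMyositis": 6},
        n_genes=520,
        n_housekeeping=20,
        block_min_baseline=0.0,
        n_cartridges=2,
        seed=23,
    )
    records, sheet, truth = simulate_cohort(config)
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    factors = normalize.normalization_factors(matrix)
    design = lm.build_design(sheet)
    v = lm.voom_transform(matrix, factors, design)
    return v, design, sheet, truth


def test_voom_weights_positive_and_track_abundance(voom_setup):
    v, *_ = voom_setup
    assert (v.weights > 0).all()
    abundance = v.E.mean(axis=1).to_numpy()
    order = np.argsort(abundance)
    n10 = max(len(order) // 10, 1)
    w_med = np.median(v.weights, axis=1)
    # counts: variance of log2 falls with abundance, so weights rise
    assert np.median(w_med[order[-n10:]]) > np.median(w_med[order[:n10]])


def test_voom_homoscedastic_data_gives_flat_weights():
    """Gaussian noise on the log scale with no mean-variance trend yields a
    nearly constant weight surface (CV < 0.2)."""
    rng = np.random.default_rng(4)
    n, g = 20, 500
    sheet = sheet_of(
        [[f"S{i}", "NDC", "C1", 555, "Cryopreserved", f"P{i}"] for i in range(n)]
    )
    design = lm.build_design(sheet)
    mu = rng.uniform(4, 12, size=g)
    e = mu[:, None] + rng.normal(0, 0.4, size=(g, n))
    counts = np.rint(2.0 ** e).astype(int)
    from conftest import make_matrix

    m = make_matrix({f"G{i}": counts[i].tolist() for i in range(g)}, ["Endogenous"] * g, sheet)
    factors = normalize.NormalizationFactors(
        codeset_factor=pd.Series(1.0, index=m.values.columns),
        tmm_factor=pd.Series(1.0, index=m.values.columns),
        library_size=m.library_sizes(),
    )
    v = lm.voom_transform(m, factors, design)
    cv = v.weights.std() / v.weights.mean()
    assert cv < 0.2


def test_consensus_all_singletons_returns_zero(voom_setup):
    v, design, sheet, _ = voom_setup
    with pytest.warns(UserWarning, match="no block"):
        cc = lm.estimate_consensus_correlation(v, design, list(sheet["sample_id"]))
    assert cc.rho_c == 0.0


def test_consensus_duplicated_columns_near_one(voom_setup):
    """Literally identical biopsies per patient drive the consensus above 0.9."""
    v, design, sheet, _ = voom_setup
    e = pd.concat([v.E, v.E.add_suffix("_dup", axis=1)], axis=1)
    w = np.hstack([v.weights, v.weights])
    dup_sheet = pd.concat([sheet, sheet.assign(sample_id=sheet["sample_id"] + "_dup")])
    design2 = lm.DesignMatrix(
        matrix=pd.DataFrame(
            np.vstack([design.matrix.to_numpy()] * 2),
            index=e.columns,
            columns=design.column_names,
        ),
        subtype_columns=design.subtype_columns,
        nuisance_columns=design.nuisance_columns,
    )
    v2 = lm.VoomObject(E=e, weights=w, design=design2, trend_x=v.trend_x, trend_y=v.trend_y,
                       log2_effective_libsize=pd.Series(10.0, index=e.columns))
    blocks = list(sheet["sample_id"]) * 2
    cc = lm.estimate_consensus_correlation(v2, design2, blocks)
    assert cc.rho_c > 0.9


def test_gls_reduces_to_ols_and_contrast_linearity(voom_setup):
    v, design, sheet, _ = voom_setup
    ones = lm.VoomObject(
        E=v.E, weights=np.ones_like(v.weights), design=design,
        trend_x=v.trend_x, trend_y=v.trend_y, log2_effective_libsize=v.log2_effective_libsize,
    )
    fit = lm.fit_linear_models(ones, design, rho_c=0.0)
    x = design.matrix.to_numpy()
    beta_ols = v.E.to_numpy() @ np.linalg.pinv(x).T
    assert np.abs(fit.beta.to_numpy() - beta_ols).max() < 1e-10

    cf = lm.apply_contrasts(fit)
    lhs = cf.log2fc["irMyositis-Mi2"] - cf.log2fc["irMyositis-TIF1g"]
    assert np.abs(lhs - cf.log2fc["TIF1g-Mi2"]).max() < 1e-9
    # contrast columns sum to zero over subtype coefficients
    sub = cf.contrast_matrix.loc[design.subtype_columns]
    assert np.allclose(sub.sum(axis=0), 0.0)
    nuis = cf.contrast_matrix.loc[design.nuisance_columns]
    assert np.allclose(nuis, 0.0)


def gls_oracle(y, w, x, r_corr):
    """Literal matrix-algebra GLS for one gene."""
    dinv_half = np.diag(1.0 / np.sqrt(w))
    v_cov = dinv_half @ r_corr @ dinv_half
    vi = np.linalg.inv(v_cov)
    a = x.T @ vi @ x
    beta = np.linalg.solve(a, x.T @ vi @ y)
    resid = y - x @ beta
    s2 = resid @ vi @ resid / (len(y) - x.shape[1])
    return beta, np.sqrt(np.diag(np.linalg.inv(a))), math.sqrt(s2)


def test_gls_matches_literal_oracle_small_instances():
    """Batched GLS equals the textbook formula on <= 8-sample instances."""
    rng = np.random.default_rng(8)
    for trial in range(30):
        n = int(rng.integers(4, 9))
        p = int(rng.integers(1, min(3, n - 1) + 1))
        g = int(rng.integers(1, 6))
        x = rng.normal(size=(n, p))
        y = rng.normal(size=(g, n))
        w = rng.uniform(0.3, 3.0, size=(g, n))
        blocks = [f"P{i // 2}" for i in range(n)]
        rho = float(rng.uniform(-0.4, 0.8))
        same = (np.array(blocks)[:, None] == np.array(blocks)[None, :]) & ~np.eye(n, dtype=bool)
        r_corr = np.eye(n) + rho * same
        design = lm.DesignMatrix(
            matrix=pd.DataFrame(x, index=[f"S{i}" for i in range(n)],
                                columns=[f"c{j}" for j in range(p)]),
            subtype_columns=[f"c{j}" for j in range(p)],
            nuisance_columns=[],
        )
        v = lm.VoomObject(
            E=pd.DataFrame(y, index=[f"g{i}" for i in range(g)], columns=design.matrix.index),
            weights=w, design=design, trend_x=np.array([0.0]), trend_y=np.array([1.0]),
            log2_effective_libsize=pd.Series(10.0, index=design.matrix.index),
        )
        fit = lm.fit_linear_models(v, design, rho_c=rho, blocks=blocks)
        for gi in range(g):
            beta, u, sigma = gls_oracle(y[gi], w[gi], x, r_corr)
            assert np.abs(fit.beta.to_numpy()[gi] - beta).max() < 1e-10
            assert np.abs(fit.stdev_unscaled.to_numpy()[gi] - u).max() < 1e-10
            assert abs(fit.sigma.iloc[gi] - sigma) < 1e-10


def test_null_fold_changes_centred(voom_setup):
    """With equal subtype means in truth, estimated log2FCs centre on zero."""
    config = SimulationConfig(
        n_per_subtype={"NDC": 6, "Mi2": 6, "TIF1g": 6, "irMyositis": 6},
        n_genes=520, n_housekeeping=20, block_min_baseline=0.0,
        batch_effect_sd=0.0, conservation_effect_sd=0.0, patient_block_sd=0.0,
        n_cartridges=1, seed=29,
    )
    records, sheet, _ = simulate_cohort(config)
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    factors = normalize.normalization_factors(matrix)
    design = lm.build_design(sheet)
    v = lm.voom_transform(matrix, factors, design)
    fit = lm.fit_linear_models(v, design)
    cf = lm.apply_contrasts(fit)
    assert np.abs(cf.log2fc.mean(axis=0)).max() < 0.05


def test_planted_sign_recovery(default_cohort, default_run):
    """>= 95% of planted block genes get the correct fold-change sign."""
    _, _, truth = default_cohort
    cf = default_run.contrasts
    hits = total = 0
    for comparison in COMPARISONS:
        sign = truth.true_sign[comparison]
        planted = sign.index[(sign != 0) & sign.index.isin(cf.log2fc.index)]
        hits += (np.sign(cf.log2fc.loc[planted, comparison]) == sign.loc[planted]).sum()
        total += len(planted)
    assert hits / total >= 0.95


def test_ebayes_prior_zero_recovers_ordinary_t(default_run):
    fit, cf = default_run.fit, default_run.contrasts
    eb = lm.ebayes_moderate(cf, fit, prior_df=0.0)
    u = cf.u_contrast.to_numpy()
    t_ord = cf.log2fc.to_numpy() / (u * fit.sigma.to_numpy()[:, None])
    assert np.abs(eb.t_mod.to_numpy() - t_ord).max() < 1e-10


def test_ebayes_posterior_variance_convexity(default_run):
    eb, fit = default_run.ebayes, default_run.fit
    s2 = fit.sigma.to_numpy() ** 2
    lo = np.minimum(s2, eb.s0_sq) - 1e-12
    hi = np.maximum(s2, eb.s0_sq) + 1e-12
    assert ((eb.s_post_sq.to_numpy() >= lo) & (eb.s_post_sq.to_numpy() <= hi)).all()
    assert ((eb.p_t.to_numpy() >= 0) & (eb.p_t.to_numpy() <= 1)).all()
    assert ((eb.p_F.to_numpy() >= 0) & (eb.p_F.to_numpy() <= 1)).all()


def test_ebayes_strong_shrinkage_when_variances_equal():
    """With a common true variance the estimated prior df exceeds the residual
    df (strong pooling) in >= 90% of 20 replicates."""
    rng = np.random.default_rng(31)
    n, p, g = 12, 2, 300
    x = np.hstack([np.ones((n, 1)), rng.normal(size=(n, 1))])
    wins = 0
    for _ in range(20):
        y = rng.normal(0.0, 1.0, size=(g, n))
        design = lm.DesignMatrix(
            matrix=pd.DataFrame(x, index=[f"S{i}" for i in range(n)], columns=["a", "b"]),
            subtype_columns=["a", "b"], nuisance_columns=[],
        )
        v = lm.VoomObject(
            E=pd.DataFrame(y, index=[f"g{i}" for i in range(g)], columns=design.matrix.index),
            weights=np.ones_like(y), design=design, trend_x=np.array([0.0]),
            trend_y=np.array([1.0]), log2_effective_libsize=pd.Series(10.0, index=design.matrix.index),
        )
        fit = lm.fit_linear_models(v, design)
        cov = np.broadcast_to(np.linalg.inv(x.T @ x), (g, p, p)).copy()
        cf = lm.ContrastFit(
            contrast_matrix=pd.DataFrame(np.array([[1.0], [0.0]]), index=["a", "b"], columns=["c"]),
            log2fc=fit.beta[["a"]].rename(columns={"a": "c"}),
            u_contrast=fit.stdev_unscaled[["a"]].rename(columns={"a": "c"}),
            cov_contrast=cov[:, :1, :1],
            fit=fit,
        )
        eb = lm.ebayes_moderate(cf, fit)
        if eb.d0 > fit.df_residual:
            wins += 1
    assert wins >= 18


def test_batch_correction_identity_idempotence_and_removal(voom_setup):
    config = SimulationConfig(
        n_per_subtype={"NDC": 10, "Mi2": 10},
        n_genes=320, n_housekeeping=20, block_min_baseline=0.0,
        batch_effect_sd=2.0, conservation_effect_sd=0.0, patient_block_sd=0.0,
        n_cartridges=2, seed=37,
    )
    records, sheet, _ = simulate_cohort(config)
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    factors = normalize.normalization_factors(matrix)
    design = lm.build_design(sheet)
    v = lm.voom_transform(matrix, factors, design)
    fit = lm.fit_linear_models(v, design)
    corrected = lm.batch_corrected_log2cpm(v, fit)

    cart = sheet.set_index("sample_id")["cartridge"]
    c1, c2 = cart[cart == "C1"].index, cart[cart == "C2"].index
    gap = (corrected[c1].mean(axis=1) - corrected[c2].mean(axis=1)).abs().mean()
    assert gap < 0.1

    # idempotence: refitting on corrected data estimates ~zero nuisance effects
    v2 = lm.VoomObject(E=corrected, weights=v.weights, design=design,
                       trend_x=v.trend_x, trend_y=v.trend_y,
                       log2_effective_libsize=v.log2_effective_libsize)
    fit2 = lm.fit_linear_models(v2, design)
    twice = lm.batch_corrected_log2cpm(v2, fit2)
    assert np.abs(twice.to_numpy() - corrected.to_numpy()).max() < 1e-9

    # zero nuisance effects -> identity
    fit0 = lm.LinearFit(
        beta=fit.beta.assign(**{c: 0.0 for c in design.nuisance_columns}),
        cov_unscaled=fit.cov_unscaled, stdev_unscaled=fit.stdev_unscaled,
        sigma=fit.sigma, df_residual=fit.df_residual, design=design, rho_c=0.0,
    )
    same = lm.batch_corrected_log2cpm(v, fit0)
    assert np.abs(same.to_numpy() - v.E.to_numpy()).max() == 0.0


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma

    for y in (1e-5, 0.01, 0.5, 2.0, 1e3, 1e8):
        x = lm.trigamma_inverse(y)
        assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)
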