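"""QC filtering and normalization arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

import myocounter as mc
from myocounter import normalize
from myocounter.errors import ValidationError
from myocounter.simulate import SimulationConfig, simulate_cohort

from conftest import make_matrix


def test_cpm_columns_sum_to_million(small_cohort):
    records, sheet, _ = small_cohort
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    cpm = normalize.compute_cpm(matrix)
    mask = matrix.class_mask("Endogenous", "Housekeeping").to_numpy()
    sums = cpm.values.loc[mask].sum(axis=0)
    assert np.allclose(sums, 1e6)


def test_cpm_hand_examples():
    m = make_matrix({"A": [250000], "B": [750000]}, ["Endogenous", "Endogenous"])
    cpm = normalize.compute_cpm(m)
    assert cpm.values["S1"].tolist() == [250000.0, 750000.0]
    m2 = make_matrix({"A": [1], "B": [1]}, ["Endogenous", "Endogenous"])
    assert normalize.compute_cpm(m2).values["S1"].tolist() == [500000.0, 500000.0]


def test_negative_cutoff_sd_zero_and_hand_value():
    m = make_matrix(
        {"A": [100, 100], "N1": [16, 16], "N2": [16, 16]},
        ["Endogenous", "Negative", "Negative"],
    )
    assert normalize.negative_control_cutoff(m) == pytest.approx(16.0)
    m2 = make_matrix(
        {"A": [100, 100], "N1": [4, 4], "N2": [16, 16]},
        ["Endogenous", "Negative", "Negative"],
    )
    # log2 averages {2, 4}: threshold 2^(3 + 2*sqrt(2))
    assert normalize.negative_control_cutoff(m2) == pytest.approx(2 ** (3 + 2 * math.sqrt(2)))
    # linear reading of the same rule
    assert normalize.negative_control_cutoff(m2, scale="linear") == pytest.approx(
        10 + 2 * np.std([4, 16], ddof=1)
    )


def test_negative_cutoff_needs_two_probes():
    m = make_matrix({"A": [100], "N1": [16]}, ["Endogenous", "Negative"])
    with pytest.raises(ValidationError, match="negative"):
        normalize.negative_control_cutoff(m)


def test_filter_boundary_at_k_samples():
    """A gene above the cutoff in exactly k samples is retained; in k-1 it is
    removed; threshold 0 keeps every expressed gene."""
    n = 10
    high, low = [1] * n, [1] * n
    for i in range(4):
        high[i] = 1000
    for i in range(3):
        low[i] = 1000
    base = {"G1": high, "G2": low, "HK": [500] * n}
    m = make_matrix(base, ["Endogenous", "Endogenous", "Housekeeping"])
    report = normalize.filter_low_expression(m, threshold_count=50.0, k=4)
    assert report.retained == ["G1"]
    assert report.removed == ["G2"]
    vacuous = normalize.filter_low_expression(m, threshold_count=0.0, k=4)
    assert set(vacuous.retained) == {"G1", "G2"}
    with pytest.raises(ValidationError):
        normalize.filter_low_expression(m, threshold_count=1.0, k=n + 1)


def test_filter_monotone_in_threshold(default_matrix):
    thresholds = [0.0, 5.0, 20.0, 100.0]
    retained = [
        set(normalize.filter_low_expression(default_matrix, t).retained) for t in thresholds
    ]
    for bigger, smaller in zip(retained, retained[1:]):
        assert smaller <= bigger


def test_codeset_factors_hand_example_and_equalization(default_matrix):
    m = make_matrix(
        {"HK1": [100, 400], "A": [10, 10]},
        ["Housekeeping", "Endogenous"],
    )
    factors = normalize.codeset_scaling_factors(m)
    assert factors.tolist() == pytest.approx([2.5, 0.625])
    # identical samples -> unit factors
    m2 = make_matrix({"HK1": [7, 7], "A": [1, 1]}, ["Housekeeping", "Endogenous"])
    assert normalize.codeset_scaling_factors(m2).tolist() == [1.0, 1.0]
    # equalization on realistic data
    factors = normalize.codeset_scaling_factors(default_matrix)
    hk = default_matrix.values.loc[default_matrix.class_mask("Housekeeping").to_numpy()]
    scaled = hk.where(hk > 0, 1) * factors
    geomeans = np.exp(np.log(scaled).mean(axis=0))
    assert np.allclose(geomeans, geomeans.iloc[0], rtol=1e-9)


def test_tmm_unit_for_scaled_and_identical_columns():
    rng = np.random.default_rng(0)
    base = rng.integers(50, 5000, size=60)
    m = make_matrix(
        {f"G{i}": [int(v), int(3 * v)] for i, v in enumerate(base)},
        ["Endogenous"] * 60,
    )
    factors = normalize.tmm_factors(m)
    assert np.allclose(factors, 1.0, atol=1e-12)


def test_tmm_matches_literal_formula_oracle(default_matrix):
    """Vectorised TMM equals a step-by-step transcription of the definition."""
    factors = normalize.tmm_factors(default_matrix)

    values = default_matrix.values.loc[
        default_matrix.class_mask("Endogenous", "Housekeeping").to_numpy()
    ].to_numpy(dtype=float)
    lib = values.sum(axis=0)
    uq = np.array([np.quantile(values[:, j] / lib[j], 0.75) for j in range(values.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    oracle = []
    for j in range(values.shape[1]):
        obs, refv = values[:, j], values[:, ref]
        keep = (obs > 0) & (refv > 0)
        o, rv = obs[keep], refv[keep]
        m_vals = np.log2((o / lib[j]) / (rv / lib[ref]))
        a_vals = 0.5 * np.log2((o / lib[j]) * (rv / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - rv) / (lib[ref] * rv)
        n = len(m_vals)
        if np.max(np.abs(m_vals)) < 1e-6:
            oracle.append(1.0)
            continue
        lo_m = math.floor(n * 0.30) + 1
        lo_a = math.floor(n * 0.05) + 1
        rm = pd.Series(m_vals).rank().to_numpy()
        ra = pd.Series(a_vals).rank().to_numpy()
        sel = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        oracle.append(2.0 ** (np.sum(m_vals[sel] / w[sel]) / np.sum(1.0 / w[sel])))
    oracle = np.array(oracle)
    oracle /= np.exp(np.mean(np.log(oracle)))
    assert np.allclose(factors.to_numpy(), oracle, atol=1e-8)


def test_tmm_near_unity_without_planted_batch_effects():
    config = SimulationConfig(
        n_per_subtype={"NDC": 6, "Mi2": 6},
        n_genes=300,
        n_housekeeping=20,
        batch_effect_sd=0.0,
        conservation_effect_sd=0.0,
        patient_block_sd=0.0,
        block_min_baseline=0.0,
        n_cartridges=1,
        seed=13,
    )
    records, sheet, _ = simulate_cohort(config)
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    factors = normalize.tmm_factors(matrix)
    assert (np.abs(factors - 1.0) < 0.1).all()


def test_factor_permutation_equivariance(default_matrix):
    perm = list(reversed(default_matrix.values.columns))
    ann = default_matrix.sample_annotations.set_index("sample_id").loc[perm].reset_index()
    permuted = mc.rcc.CountMatrix(
        values=default_matrix.values[perm],
        probe_annotations=default_matrix.probe_annotations.copy(),
        sample_annotations=ann,
        scale="raw",
    )
    f1 = normalize.codeset_scaling_factors(default_matrix)
    f2 = normalize.codeset_scaling_factors(permuted)
    assert np.allclose(f1.loc[perm], f2)
    t1 = normalize.tmm_factors(default_matrix)
    t2 = normalize.tmm_factors(permuted)
    assert np.allclose(t1.loc[perm], t2)


def test_log2cpm_offset_scale_and_monotonicity():
    m = make_matrix({"A": [0], "B": [10], "C": [999989]}, ["Endogenous"] * 3)
    factors = normalize.NormalizationFactors(
        codeset_factor=pd.Series([999999 / m.library_sizes().mean()], index=["S1"]),
        tmm_factor=pd.Series([1.0], index=["S1"]),
        library_size=m.library_sizes(),
    )
    # effective libsize pinned to 1e6 - 1: a zero count maps to log2(0.5)
    out = normalize.log2_cpm(m, factors)
    assert out.values.at["A", "S1"] == pytest.approx(math.log2(0.5), abs=1e-6)
    assert out.values.at["A", "S1"] < out.values.at["B", "S1"] < out.values.at["C", "S1"]

    # doubling counts and library leaves values nearly unchanged
    m1 = make_matrix({f"G{i}": [100 + i] for i in range(1000)}, ["Endogenous"] * 1000)
    m2 = make_matrix({f"G{i}": [2 * (100 + i)] for i in range(1000)}, ["Endogenous"] * 1000)
    unit = lambda m: normalize.NormalizationFactors(
        codeset_factor=pd.Series([1.0], index=["S1"]),
        tmm_factor=pd.Series([1.0], index=["S1"]),
        library_size=m.library_sizes(),
    )
    v1 = normalize.log2_cpm(m1, unit(m1)).values
    v2 = normalize.log2_cpm(m2, unit(m2)).values
    assert np.abs(v1.to_numpy() - v2.to_numpy()).max() < 1e-2


def test_pca_diagnostic_separates_planted_batches():
    """Silhouette of batch labels on PC1/2 drops after removing the batch
    effect via the linear model."""
    from sklearn.metrics import silhouette_score

    import myocounter.linmodel as lm

    config = SimulationConfig(
        n_per_subtype={"NDC": 8, "Mi2": 8},
        n_genes=300,
        n_housekeeping=20,
        batch_effect_sd=2.0,
        conservation_effect_sd=0.0,
        patient_block_sd=0.0,
        block_min_baseline=0.0,
        n_cartridges=2,
        seed=17,
    )
    records, sheet, _ = simulate_cohort(config)
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    factors = normalize.normalization_factors(matrix)
    design = lm.build_design(sheet)
    v = lm.voom_transform(matrix, factors, design)
    fit = lm.fit_linear_models(v, design)
    corrected = lm.batch_corrected_log2cpm(v, fit)

    def scores(values):
        cm = mc.rcc.CountMatrix(
            values=values,
            probe_annotations=pd.DataFrame(
                {"name": values.index, "code_class": "Endogenous", "accession": ""}
            ),
            sample_annotations=matrix.sample_annotations.copy(),
            scale="log2cpm",
        )
        table = normalize.pca_batch_diagnostic(cm, sheet)
        return table[["PC1", "PC2"]].to_numpy(), table["cartridge"]

    before, labels = scores(v.E)
    after, _ = scores(corrected)
    assert silhouette_score(before, labels) > silhouette_score(after, labels)


def test_pca_duplicate_samples_and_orthonormal_loadings(small_cohort):
    records, sheet, _ = small_cohort
    matrix = mc.rcc.assemble_count_matrix(records, sheet)
    log2 = np.log2(matrix.values + 0.5)
    dup = log2.copy()
    dup[dup.columns[1]] = dup[dup.columns[0]]
    cm = mc.rcc.CountMatrix(
        values=dup,
        probe_annotations=matrix.probe_annotations.copy(),
        sample_annotations=matrix.sample_annotations.copy(),
        scale="log2cpm",
    )
    table = normalize.pca_batch_diagnostic(cm, sheet)
    assert table.loc[0, ["PC1", "PC2"]].tolist() == pytest.approx(
        table.loc[1, ["PC1", "PC2"]].tolist()
    )
    constant = mc.rcc.CountMatrix(
        values=pd.DataFrame(1.0, index=log2.index, columns=log2.columns),
        probe_annotations=matrix.probe_annotations.copy(),
        sample_annotations=matrix.sample_annotations.copy(),
        scale="log2cpm",
    )
    with pytest.raises(ValidationError, match="constant"):
        normalize.pca_batch_diagnostic(constant, sheet)
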