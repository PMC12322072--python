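"""Probe-level QC and between-sample normalization.

Implements, in pipeline order: counts-per-million, the negative-control-derived
low-expression filter, housekeeping CodeSet content scaling, trimmed-mean-of-
M-values (TMM) compositional factors, log2-CPM, and a PCA batch diagnostic.

Library size is defined as the per-sample sum of Endogenous + Housekeeping
counts; the spike-like control probes are excluded so they cannot drive CPM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rcc import CountMatrix


@dataclass
class FilterReport:
    """Outcome of the low-expression filter over endogenous genes."""

    threshold_count: float
    cutoff_cpm: float
    per_gene_pass_counts: pd.Series
    retained: list[str]
    removed: list[str]


@dataclass
class NormalizationFactors:
    """Per-sample scaling: CodeSet content factors (count multipliers), TMM
    factors (library-size multipliers) and raw library sizes."""

    codeset_factor: pd.Series
    tmm_factor: pd.Series
    library_size: pd.Series

    def effective_library_size(self) -> pd.Series:
        """Library size after both normalizations.

        CodeSet content normalization replaces the total-count estimate of the
        per-sample scale by the housekeeping one: the effective size is the
        cohort-mean library size divided by the CodeSet count multiplier
        (samples with weak housekeeping signal get a smaller effective
        library), then multiplied by the TMM factor.  Using the raw library
        size *and* the CodeSet factor together would correct the same scale
        twice.
        """
        return float(self.library_size.mean()) / self.codeset_factor * self.tmm_factor


def compute_cpm(m: CountMatrix) -> CountMatrix:
    """Counts per million over the Endogenous + Housekeeping library size."""
    lib = m.library_sizes()
    zero = lib[lib <= 0]
    if len(zero):
        raise ValidationError(f"zero library size for samples: {sorted(zero.index)}")
    cpm = m.values / lib * 1e6
    return CountMatrix(
        values=cpm,
        probe_annotations=m.probe_annotations.copy(),
        sample_annotations=m.sample_annotations.copy(),
        scale="cpm",
    )


def negative_control_cutoff(m: CountMatrix, scale: str = "log2") -> float:
    """Background threshold from negative-control probes.

    Each negative probe's counts are averaged across samples.  With
    ``scale="log2"`` (default) the threshold is ``2^(mean + 2 sd)`` of the log2
    per-probe averages; with ``scale="linear"`` it is ``mean + 2 sd`` of the
    averages themselves.  The log2 form is the one under which the
    two-sigma rule is dimensionally meaningful for count data.
    """
    neg = m.values.loc[m.class_mask("Negative").to_numpy()]
    if len(neg) < 2:
        raise ValidationError("need >= 2 negative-control probes (sd undefined)")
    per_probe_avg = neg.mean(axis=1).to_numpy(dtype=float)
    if scale == "log2":
        logs = np.log2(np.maximum(per_probe_avg, 1e-12))
        return float(2.0 ** (logs.mean() + 2.0 * logs.std(ddof=1)))
    if scale == "linear":
        return float(per_probe_avg.mean() + 2.0 * per_probe_avg.std(ddof=1))
    raise ValidationError(f"unknown scale {scale!r}")


def filter_low_expression(m: CountMatrix, threshold_count: float, k: int = 4) -> FilterReport:
    """Remove endogenous genes expressed above background in fewer than ``k``
    samples (``k`` defaults to the smallest subtype's size).

    The count-scale threshold is mapped to CPM via the median library size; a
    gene is retained iff its CPM exceeds that cutoff in at least ``k`` samples.
    Housekeeping probes are never filtered (they are kept for normalization
    and excluded from differential testing downstream).
    """
    if m.scale != "raw":
        raise ValidationError("filter_low_expression expects raw counts")
    n_samples = m.values.shape[1]
    if k > n_samples:
        raise ValidationError(f"k={k} exceeds sample count {n_samples}")
    lib = m.library_sizes()
    cutoff_cpm = threshold_count / float(lib.median()) * 1e6
    cpm = m.values / lib * 1e6
    endo_mask = m.class_mask("Endogenous")
    endo_cpm = cpm.loc[endo_mask.to_numpy()]
    pass_counts = (endo_cpm > cutoff_cpm).sum(axis=1)
    retained = sorted(pass_counts.index[pass_counts >= k])
    removed = sorted(pass_counts.index[pass_counts < k])
    return FilterReport(
        threshold_count=float(threshold_count),
        cutoff_cpm=float(cutoff_cpm),
        per_gene_pass_counts=pass_counts,
        retained=retained,
        removed=removed,
    )


def apply_filter(m: CountMatrix, report: FilterReport) -> CountMatrix:
    """Drop removed endogenous genes; keep housekeeping and control probes."""
    keep = [
        name
        for name, cls in zip(m.probe_annotations["name"], m.probe_annotations["code_class"])
        if cls != "Endogenous" or name in set(report.retained)
    ]
    return m.subset_probes(keep)


def codeset_scaling_factors(m: CountMatrix) -> pd.Series:
    """Housekeeping CodeSet content normalization factors (count multipliers).

    factor_s = mean_over_samples(geomean housekeeping) / geomean_s; zeros are
    replaced by 1 before the geometric mean so factors stay finite.
    """
    hk = m.values.loc[m.class_mask("Housekeeping").to_numpy()].to_numpy(dtype=float)
    if hk.shape[0] < 1:
        raise ValidationError("no housekeeping probes present")
    all_zero = (hk == 0).all(axis=0)
    if all_zero.any():
        bad = sorted(np.asarray(m.values.columns)[all_zero])
        raise ValidationError(f"samples with all-zero housekeeping counts: {bad}")
    hk = np.where(hk == 0, 1.0, hk)
    geomeans = np.exp(np.log(hk).mean(axis=0))
    factors = geomeans.mean() / geomeans
    return pd.Series(factors, index=m.values.columns, name="codeset_factor")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.30, sum_trim: float = 0.05,
) -> float:
    """Weighted doubly-trimmed mean of M-values of one sample vs the reference.

    Canonical TMM: 30% trim on M, 5% on A, precision weights from the delta
    method; genes with a zero count in either sample are excluded.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / n_obs, ref / n_ref
    m_vals = np.log2(p_o / p_r)
    a_vals = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m_vals) & np.isfinite(a_vals) & (a_vals > -1e10)
    m_vals, a_vals, w = m_vals[finite], a_vals[finite], w[finite]
    n = m_vals.size
    if n == 0:
        return 1.0
    if float(np.max(np.abs(m_vals))) < 1e-6:
        return 1.0
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m_vals).rank().to_numpy()
    rank_a = pd.Series(a_vals).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m_vals[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factor = 2.0 ** f
    if not np.isfinite(factor):
        return 1.0
    return float(factor)


def tmm_factors(
    m: CountMatrix,
    library_sizes: pd.Series | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """TMM scale factors (library-size multipliers), rescaled to multiply to 1.

    ``library_sizes`` is the scale TMM refines (CodeSet-effective sizes in the
    pipeline; raw column sums by default).  Reference sample: the one whose
    upper-quartile CPM is closest to the mean upper-quartile across samples.
    """
    values = m.values.loc[m.class_mask("Endogenous", "Housekeeping").to_numpy()].to_numpy(dtype=float)
    samples = list(m.values.columns)
    if len(samples) < 2:
        warnings.warn("TMM undefined for < 2 samples; returning unit factors")
        return pd.Series(1.0, index=m.values.columns, name="tmm_factor")
    if library_sizes is None:
        lib = values.sum(axis=0)
    else:
        lib = library_sizes.reindex(m.values.columns).to_numpy(dtype=float)
    if (lib <= 0).any() or np.isnan(lib).any():
        raise ValidationError("non-positive library size")
    uq = np.array([np.quantile(values[:, j] / lib[j], 0.75) for j in range(len(samples))])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(values[:, j], values[:, ref_idx], lib[j], lib[ref_idx], logratio_trim, sum_trim)
            for j in range(len(samples))
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.values.columns, name="tmm_factor")


def normalization_factors(m: CountMatrix) -> NormalizationFactors:
    """Convenience bundle: CodeSet factors, then TMM refined on the
    CodeSet-effective library sizes (the pipeline's stage order)."""
    codeset = codeset_scaling_factors(m)
    lib = m.library_sizes()
    codeset_effective = float(lib.mean()) / codeset
    return NormalizationFactors(
        codeset_factor=codeset,
        tmm_factor=tmm_factors(m, library_sizes=codeset_effective),
        library_size=lib,
    )


def log2_cpm(m: CountMatrix, factors: NormalizationFactors) -> CountMatrix:
    """log2((count + 0.5) / (effective library size + 1) * 1e6)."""
    if m.scale != "raw":
        raise ValidationError("log2_cpm expects raw counts")
    eff = factors.effective_library_size().reindex(m.values.columns)
    if eff.isna().any() or (eff <= 0).any():
        raise ValidationError("invalid effective library sizes")
    values = np.log2((m.values + 0.5) / (eff + 1.0) * 1e6)
    return CountMatrix(
        values=values,
        probe_annotations=m.probe_annotations.copy(),
        sample_annotations=m.sample_annotations.copy(),
        scale="log2cpm",
    )


def pca_batch_diagnostic(m: CountMatrix, sheet: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Principal-component scores of samples from gene-centred expression.

    Deterministic up to sign; each component's sign is fixed by making its
    largest-magnitude gene loading positive.  Returns one row per sample with
    PC scores, explained variance fractions, and sheet metadata attached.
    """
    if m.values.shape[1] < 3:
        raise ValidationError("need >= 3 samples for a PCA diagnostic")
    x = m.values.to_numpy(dtype=float)
    centred = (x - x.mean(axis=1, keepdims=True)).T  # samples x genes
    if np.allclose(centred, 0.0):
        raise ValidationError("constant expression matrix; PCA undefined")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    n_components = min(n_components, len(s))
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        pivot = int(np.argmax(np.abs(vt[j])))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            scores[:, j] *= -1.0
    var_frac = (s ** 2) / np.sum(s ** 2)
    out = pd.DataFrame(
        scores,
        columns=[f"PC{j + 1}" for j in range(n_components)],
        index=pd.Index(m.values.columns, name="sample_id"),
    )
    for j in range(n_components):
        out[f"PC{j + 1}_var_frac"] = var_frac[j]
    meta = sheet.set_index("sample_id")
    return out.join(meta, how="left").reset_index()
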