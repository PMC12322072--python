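"""End-to-end orchestration: raw cohort counts to decision matrix and
batch-corrected expression, in the canonical stage order."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import linmodel, multiple_testing, normalize
from .rcc import CountMatrix


@dataclass
class DGEResult:
    """Everything downstream modules consume, bundled."""

    filter_report: normalize.FilterReport
    factors: normalize.NormalizationFactors
    design: linmodel.DesignMatrix
    voom: linmodel.VoomObject
    consensus: linmodel.ConsensusCorrelation
    fit: linmodel.LinearFit
    contrasts: linmodel.ContrastFit
    ebayes: linmodel.EBayesStats
    decisions: multiple_testing.DecisionMatrix
    corrected_log2cpm: pd.DataFrame


def run_dge(
    matrix: CountMatrix,
    sheet: pd.DataFrame,
    alpha: float = 0.05,
    k_min_samples: int = 4,
    use_blocks: bool = True,
    span: float = 0.5,
) -> DGEResult:
    """Run filter -> normalization -> voom -> consensus correlation -> GLS ->
    contrasts -> moderation -> hierarchical decisions on a raw cohort matrix."""
    cutoff = normalize.negative_control_cutoff(matrix)
    report = normalize.filter_low_expression(matrix, cutoff, k=k_min_samples)
    filtered = normalize.apply_filter(matrix, report)
    factors = normalize.normalization_factors(filtered)
    design = linmodel.build_design(sheet)
    voom = linmodel.voom_transform(filtered, factors, design)

    blocks = list(sheet["patient_id"])
    if use_blocks and pd.Series(blocks).duplicated().any():
        consensus = linmodel.estimate_consensus_correlation(voom, design, blocks)
    else:
        consensus = linmodel.ConsensusCorrelation(
            rho_c=0.0, per_gene_atanh=pd.Series(0.0, index=voom.E.index)
        )
    fit = linmodel.fit_linear_models(voom, design, consensus.rho_c, blocks)
    contrasts = linmodel.apply_contrasts(fit)
    ebayes = linmodel.ebayes_moderate(contrasts, fit)
    decisions = multiple_testing.hierarchical_decide(
        ebayes.p_F, ebayes.p_t, ebayes.t_mod, alpha=alpha
    )
    corrected = linmodel.batch_corrected_log2cpm(voom, fit)
    return DGEResult(
        filter_report=report,
        factors=factors,
        design=design,
        voom=voom,
        consensus=consensus,
        fit=fit,
        contrasts=contrasts,
        ebayes=ebayes,
        decisions=decisions,
        corrected_log2cpm=corrected,
    )
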