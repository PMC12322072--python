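"""FDR control: BH adjustment, F-test gene selection, and the hierarchical
post-hoc procedure yielding per-gene, per-comparison calls in {-1, 0, +1}.

The hierarchical procedure controls error both across genes and across the
six pairwise comparisons: (1) genes are screened by their BH-adjusted F-test
p-values at the nominal FDR; (2) the comparison-level threshold is rescaled
by the fraction of genes that survived; (3) each surviving gene's six t-test
p-values are BH-adjusted within the gene and called at the rescaled level,
signed by the t statistic.  Screened-out genes get all-zero rows, so the
final calls are never more liberal than plain per-comparison BH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .linmodel import ContrastFit, EBayesStats


@dataclass
class DecisionMatrix:
    decisions: pd.DataFrame  # genes x 6, entries in {-1, 0, +1}
    alpha: float
    alpha2: float
    f_selected: list[str]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    stepped = p[order] * m / ranks
    adjusted_sorted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def select_by_f(p_f: pd.Series, alpha: float = 0.05) -> tuple[list[str], int]:
    """Genes whose BH-adjusted F p-value is <= alpha."""
    adjusted = bh_adjust(p_f.to_numpy())
    selected = sorted(p_f.index[adjusted <= alpha])
    return selected, len(selected)


def hierarchical_decide(
    p_f: pd.Series,
    p_t: pd.DataFrame,
    t_signs: pd.DataFrame,
    alpha: float = 0.05,
) -> DecisionMatrix:
    """Three-step hierarchical post-hoc decision (see module docstring)."""
    if len(p_f) == 0:
        raise ValidationError("empty gene set")
    if not p_f.index.equals(p_t.index) or not p_t.index.equals(t_signs.index):
        raise ValidationError("p_F, p_t and t_signs must share a gene index")
    if list(p_t.columns) != list(t_signs.columns):
        raise ValidationError("p_t and t_signs must share comparison columns")
    selected, n_sel = select_by_f(p_f, alpha)
    scaling = n_sel / len(p_f)
    alpha2 = alpha * scaling
    decisions = pd.DataFrame(0, index=p_f.index, columns=p_t.columns, dtype=int)
    if n_sel:
        sel_p = p_t.loc[selected].to_numpy()
        sel_signs = np.sign(t_signs.loc[selected].to_numpy()).astype(int)
        adjusted = np.vstack([bh_adjust(row) for row in sel_p])
        calls = np.where(adjusted <= alpha2, sel_signs, 0)
        decisions.loc[selected] = calls
    return DecisionMatrix(decisions=decisions, alpha=alpha, alpha2=alpha2, f_selected=selected)


def count_decisions(d: DecisionMatrix) -> pd.DataFrame:
    """Per-comparison tallies of up- and down-regulated genes."""
    up = (d.decisions == 1).sum(axis=0)
    down = (d.decisions == -1).sum(axis=0)
    return pd.DataFrame({"n_up": up, "n_down": down})


def volcano_table(
    cf: ContrastFit,
    eb: EBayesStats,
    d: DecisionMatrix,
    pathway_membership: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Long-format per-gene, per-comparison table: log2FC, within-gene BH
    adjusted p, decision, and optional pathway membership flags.  Rows ordered
    by comparison then gene name."""
    rows = []
    adj = {
        gene: bh_adjust(eb.p_t.loc[gene].to_numpy())
        for gene in eb.p_t.index
    }
    for comparison_idx, comparison in enumerate(cf.log2fc.columns):
        for gene in sorted(cf.log2fc.index):
            row = {
                "comparison": comparison,
                "gene": gene,
                "log2fc": float(cf.log2fc.at[gene, comparison]),
                "p": float(eb.p_t.at[gene, comparison]),
                "p_adjusted": float(adj[gene][comparison_idx]),
                "decision": int(d.decisions.at[gene, comparison]),
            }
            if pathway_membership:
                for name, members in pathway_membership.items():
                    row[f"in_{name}"] = gene in members
            rows.append(row)
    return pd.DataFrame(rows)
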