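"""Spearman correlation of irDEGs with immune-cell marker genes.

Rank correlations (midrank ties) are computed on batch-corrected log2-CPM;
p-values come from the asymptotic t approximation at n >= 10 and from the
exact permutation null below that; BH adjustment runs over the strict upper
triangle at 5% FDR.  Marker sets whose members show no significant positive
within-set correlation are screened out before agglomerative clustering
(complete linkage on 1 - rho) with a fixed-k dendrogram cut.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .multiple_testing import bh_adjust

_DEFAULT_PANEL = {
    "nk": ("GTF3C1", "ZNF205", "GZMB", "IL21R"),
    "b_cell": ("CD19", "MS4A1", "CD22", "CD79A", "CD79B", "TNFRSF17"),
    "t_cell": ("CD3D", "CD3E", "CD3G", "CD4", "CD8A", "CD8B"),
    "apc": ("CD68", "CD163", "CCL13", "CD209"),
}


@dataclass(frozen=True)
class MarkerPanel:
    """Named, disjoint immune-cell marker gene sets."""

    sets: dict = field(default_factory=lambda: {k: frozenset(v) for k, v in _DEFAULT_PANEL.items()})

    def __post_init__(self) -> None:
        all_genes: list[str] = []
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"marker set {name!r} is empty")
            all_genes.extend(members)
        if len(all_genes) != len(set(all_genes)):
            raise ValidationError("marker sets must be disjoint")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "MarkerPanel":
        if path is None:
            text = resources.files("myocounter.data").joinpath("markers.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls(sets={name: frozenset(members) for name, members in raw.items()})

    def all_genes(self) -> list[str]:
        return sorted(g for members in self.sets.values() for g in members)


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: int


def _midrank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)

def _spearman_p_exact(rank_a: np.ndarray, rank_b: np.ndarray, rho: float) -> float:
    """Two-sided p from the full permutation null, conditioning on the two
    observed (possibly tied) rank vectors."""
    n = rank_a.size
    perms = _all_permutations(n)
    a = rank_a - rank_a.mean()
    b = rank_b - rank_b.mean()
    norm = math.sqrt(float(a @ a) * float(b @ b))
    if norm == 0:
        return math.nan
    null = (b[perms] @ a) / norm
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def _spearman_p(rho: float, n: int, rank_a: np.ndarray | None = None, rank_b: np.ndarray | None = None) -> float:
    if not math.isfinite(rho):
        return math.nan
    if n < 10 and rank_a is not None:
        return _spearman_p_exact(rank_a, rank_b, rho)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def spearman_matrix(expression: pd.DataFrame, genes: list[str]) -> CorrelationMatrix:
    """Pairwise Spearman correlations (midrank ties) over samples for the given
    genes, with p and BH q over the strict upper triangle, mirrored."""
    missing = sorted(set(genes) - set(expression.index))
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")
    genes = list(dict.fromkeys(genes))
    n = expression.shape[1]
    if n < 4:
        raise ValidationError("need >= 4 samples for correlation testing")
    data = expression.loc[genes].to_numpy(dtype=float)
    constant = np.array([np.ptp(row) == 0 for row in data])
    if constant.any():
        warnings.warn(
            f"constant expression for {sorted(np.asarray(genes)[constant])}; "
            "their correlations are undefined and recorded as missing"
        )
    ranks = np.vstack([_midrank(row) for row in data])
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred ** 2).sum(axis=1))
    norms_safe = np.where(norms == 0, 1.0, norms)
    rho = (centred @ centred.T) / np.outer(norms_safe, norms_safe)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)

    m = len(genes)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(p, 0.0)
    triu = [(i, j) for i in range(m) for j in range(i + 1, m)]
    for i, j in triu:
        if not math.isnan(rho[i, j]):
            p[i, j] = p[j, i] = _spearman_p(rho[i, j], n, ranks[i], ranks[j])
    flat = np.array([p[i, j] for i, j in triu])
    valid = ~np.isnan(flat)
    q = np.full((m, m), np.nan)
    np.fill_diagonal(q, 0.0)
    if valid.any():
        adjusted = np.full(len(flat), np.nan)
        adjusted[valid] = bh_adjust(flat[valid])
        for (i, j), val in zip(triu, adjusted):
            q[i, j] = q[j, i] = val
    idx = pd.Index(genes, name="gene")
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        q=pd.DataFrame(q, index=idx, columns=idx),
        n=n,
    )


def marker_coherence(
    c: CorrelationMatrix, panel: MarkerPanel, alpha: float = 0.05
) -> tuple[dict, pd.DataFrame]:
    """Screen marker sets: a set is excluded iff no within-set pair is both
    significantly (q <= alpha) and positively correlated."""
    retained = {}
    report = []
    for name, members in sorted(panel.sets.items()):
        missing = sorted(set(members) - set(c.rho.index))
        if missing:
            raise ValidationError(f"marker set {name!r}: genes not scored: {missing}")
        members = sorted(members)
        coherent = False
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                q = c.q.at[a, b]
                if not pd.isna(q) and q <= alpha and c.rho.at[a, b] > 0:
                    coherent = True
        if coherent:
            retained[name] = frozenset(members)
        report.append({"marker_set": name, "retained": coherent})
    return retained, pd.DataFrame(report)


def cluster_and_cut(c: CorrelationMatrix, k: int = 4, method: str = "complete") -> pd.Series:
    """Agglomerative clustering on distance 1 - rho with a fixed-k cut.

    Genes are processed in name order so the labelling is deterministic;
    labels are renumbered by first appearance.
    """
    genes = sorted(c.rho.index)
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds the number of genes ({len(genes)})")
    rho = c.rho.loc[genes, genes].to_numpy(dtype=float)
    if np.isnan(rho).any():
        raise ValidationError("missing correlations among clustered genes")
    dist = np.clip(1.0 - rho, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    labels = fcluster(linkage(squareform(dist, checks=False), method=method), t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    canonical = []
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        canonical.append(relabel[lab])
    return pd.Series(canonical, index=pd.Index(genes, name="gene"), name="cluster")
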