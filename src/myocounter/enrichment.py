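"""Preranked gene-set enrichment on log2 fold-changes.

The running statistic is the weighted Kolmogorov-Smirnov walk: descending the
ranked list, hitting a member increments by |score|^exponent (normalized by
the member total) and missing decrements by 1/(N - N_hit); the enrichment
score ES is the signed maximal excursion and the core (leading edge) is the
member subset at or before the extremum (at or after it for negative ES).
The null is gene-label permutation: random member sets of equal effective
size.  NES normalizes ES by the mean magnitude of same-sign null scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .multiple_testing import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.id!r} has no members")


@dataclass
class RankedList:
    """Genes sorted by descending score; ties broken by gene-name order."""

    genes: list[str]
    scores: np.ndarray

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        if s.index.duplicated().any():
            raise ValidationError("ranked list has duplicate genes")
        if not np.isfinite(s.to_numpy(dtype=float)).all():
            raise ValidationError("ranking scores must be finite")
        ordered = s.sort_index().sort_values(ascending=False, kind="stable")
        return cls(genes=list(ordered.index), scores=ordered.to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.genes)


def load_gene_sets(
    path: str | Path,
    universe: Sequence[str],
    min_size: int = 3,
    max_size: int = 100,
) -> tuple[list[GeneSet], pd.DataFrame]:
    """Read a GMT file (tab-separated: id, description, members...) and keep
    sets whose intersection with the universe has size in [min_size, max_size].
    Returns (collection, report of dropped sets)."""
    path = Path(path)
    universe_set = set(universe)
    kept: list[GeneSet] = []
    dropped = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}: line {lineno}: malformed GMT line (need >= 3 fields)")
        set_id, name, *members = fields
        members = [m for m in members if m]
        effective = sorted(set(members) & universe_set)
        if min_size <= len(effective) <= max_size:
            kept.append(GeneSet(id=set_id, name=name, members=frozenset(effective)))
        else:
            dropped.append({"id": set_id, "effective_size": len(effective)})
    return kept, pd.DataFrame(dropped, columns=["id", "effective_size"])


def _running_scores(r: RankedList, member_mask: np.ndarray, exponent: float) -> np.ndarray:
    """Cumulative KS walk for one (or many) indicator row(s) over the list."""
    scores = np.abs(r.scores) ** exponent
    n = len(r)
    n_hit = member_mask.sum(axis=-1, keepdims=True)
    hit_total = (member_mask * scores).sum(axis=-1, keepdims=True)
    hit_total = np.where(hit_total == 0, 1.0, hit_total)  # all-zero scores: uniform steps
    hit_incr = np.where(
        member_mask,
        np.where((member_mask * scores) > 0, scores / hit_total, 1.0 / np.maximum(n_hit, 1)),
        0.0,
    )
    miss_incr = np.where(member_mask, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(hit_incr - miss_incr, axis=-1)


def enrichment_score(
    r: RankedList, s: GeneSet, exponent: float = 1.0
) -> tuple[float, list[str]]:
    """ES and leading-edge core of one gene set against the ranked list."""
    member_mask = np.array([g in s.members for g in r.genes])
    if not member_mask.any():
        raise ValidationError(f"gene set {s.id!r} is disjoint from the ranked list")
    running = _running_scores(r, member_mask, exponent)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        core = [g for j, g in enumerate(r.genes) if member_mask[j] and j <= i_max]
    else:
        es = float(running[i_min])
        core = [g for j, g in enumerate(r.genes) if member_mask[j] and j >= i_min]
    return es, core


def _null_es(
    r: RankedList, size: int, n_perm: int, rng: np.random.Generator, exponent: float
) -> np.ndarray:
    n = len(r)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=size, replace=False)] = True
    running = _running_scores(r, masks, exponent)
    hi = running.max(axis=1)
    lo = running.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def gsea(
    r: RankedList,
    collection: Sequence[GeneSet],
    comparison: str = "",
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Preranked GSEA over a collection; one row per gene set with ES, NES,
    permutation p, BH-adjusted p and the leading-edge core genes."""
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-value resolution")
    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for gs in sorted(collection, key=lambda g: g.id):
        es, core = enrichment_score(r, gs, exponent)
        size = len(gs.members & set(r.genes))
        if size not in null_cache:
            null_cache[size] = _null_es(r, size, n_perm, rng, exponent)
        null = null_cache[size]
        same_sign = null[null * es >= 0] if es != 0 else null
        if same_sign.size == 0:
            same_sign = np.abs(null)
        nes = es / float(np.mean(np.abs(same_sign))) if np.mean(np.abs(same_sign)) > 0 else 0.0
        p = (1.0 + float(np.sum(np.abs(same_sign) >= abs(es)))) / (1.0 + same_sign.size)
        rows.append(
            {
                "set_id": gs.id,
                "name": gs.name,
                "comparison": comparison,
                "effective_size": size,
                "es": es,
                "nes": nes,
                "p": min(p, 1.0),
                "core_genes": tuple(core),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adjusted"] <= alpha
    else:
        out["p_adjusted"] = []
        out["significant"] = []
    return out


def enrichment_map(results: pd.DataFrame, jaccard_min: float = 0.2, alpha: float = 0.05) -> nx.Graph:
    """Graph over significant gene sets; nodes annotate per-comparison core
    sizes, and an edge joins two sets whose unions of core genes (across
    comparisons) have Jaccard similarity above ``jaccard_min``."""
    sig = results[results["p_adjusted"] <= alpha]
    if not len(sig):
        raise ValidationError("no significant enrichment results to map")
    graph = nx.Graph()
    unions: dict[str, set[str]] = {}
    for set_id, group in sig.groupby("set_id"):
        union: set[str] = set()
        core_sizes = {}
        for _, row in group.iterrows():
            union |= set(row["core_genes"])
            core_sizes[row["comparison"]] = len(row["core_genes"])
        unions[set_id] = union
        graph.add_node(set_id, union_size=len(union), core_sizes=core_sizes)
    ids = sorted(unions)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(unions[a] & unions[b])
            denom = len(unions[a] | unions[b])
            jaccard = inter / denom if denom else 0.0
            if jaccard > jaccard_min:
                graph.add_edge(a, b, jaccard=jaccard)
    return graph


def select_core_f_significant(results: pd.DataFrame, f_selected: Sequence[str], alpha: float = 0.05) -> list[str]:
    """Genes in at least one significant enrichment core (any comparison) that
    also carry a significant F statistic."""
    sig = results[results["p_adjusted"] <= alpha]
    core_union: set[str] = set()
    for core in sig["core_genes"]:
        core_union |= set(core)
    return sorted(core_union & set(f_selected))
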