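"""Synthetic nCounter cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a 770-gene panel (730 endogenous + 40 housekeeping probes) with 8
negative and 6 positive controls, negative-binomial endogenous counts with
gene-wise dispersion, cartridge (batch) and conservation effects, shared
random intercepts for repeated biopsies of the same patient, per-sample
library-size factors, and planted subtype-specific log2 fold-change blocks
(an interferon-stimulated-gene-like block up in dermatomyositis versus
control and flat in irMyositis, and a type-II-interferon-like block with
the opposite pattern).

Mean model, per endogenous/housekeeping gene g and sample s::

    log2 mu_gs = baseline_g + subtype_effect_g(subtype_s) + batch_g(cartridge_s)
                 + conservation_g(method_s) + patient_intercept(patient_s)
                 + log2(library_factor_s)

Counts are NegBinomial(mu, phi) with variance mu + phi * mu^2 (gamma-Poisson
mixture); phi_g is drawn log-uniformly.  Negative controls are
Poisson(lambda_neg) flat across samples; positive controls follow the
six-step geometric titration ladder {128, 32, 8, 2, 0.5, 0.125} scaled by a
gain constant and the library factor.  Patient intercepts are gene-shared
scalars so the consensus within-patient correlation has a single true value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import ValidationError
from .rcc import (
    CONSERVATION_METHODS,
    ProbeDefinition,
    SampleAttributes,
    SampleRecord,
    SUBTYPES,
    write_rcc,
    write_sample_sheet,
)

#: The six pairwise subtype comparisons, in fixed pipeline order.
COMPARISON_PAIRS: tuple[tuple[str, str], ...] = (
    ("Mi2", "NDC"),
    ("TIF1g", "NDC"),
    ("irMyositis", "NDC"),
    ("TIF1g", "Mi2"),
    ("irMyositis", "Mi2"),
    ("irMyositis", "TIF1g"),
)
COMPARISONS: tuple[str, ...] = tuple(f"{a}-{b}" for a, b in COMPARISON_PAIRS)

#: nCounter-style positive-control titration ladder (arbitrary concentration units).
POSITIVE_LADDER: tuple[float, ...] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

LN2_SQ = math.log(2.0) ** 2


@dataclass(frozen=True)
class SignatureBlock:
    """A block of genes sharing per-subtype log2 expression offsets."""

    label: str
    size: int
    effects: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError(f"block {self.label!r}: size must be >= 1")
        for subtype, eff in self.effects.items():
            if subtype not in SUBTYPES:
                raise ValidationError(f"block {self.label!r}: unknown subtype {subtype!r}")
            if not math.isfinite(eff):
                raise ValidationError(f"block {self.label!r}: non-finite effect")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Effect sizes and standard deviations are in log2 units.  ``patient_block_sd``
    is the standard deviation tau of the gene-shared patient random intercept;
    ``paired_fraction`` is the fraction of samples (per subtype) that belong to
    two-biopsy patients.
    """

    n_per_subtype: Mapping[str, int] = field(
        default_factory=lambda: {"NDC": 4, "Mi2": 8, "TIF1g": 6, "irMyositis": 17}
    )
    n_genes: int = 770
    n_housekeeping: int = 40
    n_neg: int = 8
    n_pos: int = 6
    baseline_log2_mean_range: tuple[float, float] = (1.0, 11.0)
    block_min_baseline: float = 4.0
    dispersion_range: tuple[float, float] = (0.01, 0.25)
    batch_effect_sd: float = 0.3
    conservation_effect_sd: float = 0.2
    # implies a within-patient correlation near 0.5 at the median dispersion,
    # in the range duplicate-correlation analyses report for repeated biopsies
    patient_block_sd: float = 0.35
    paired_fraction: float = 0.0
    signature_blocks: Sequence[SignatureBlock] = ()
    library_size_range: tuple[float, float] = (0.75, 1.5)
    neg_lambda: float = 5.0
    neg_probe_sd: float = 0.6  # log2 spread of per-probe background levels
    pos_gain: float = 60.0
    n_cartridges: int = 2
    cartridge_assignment: Sequence[str] | None = None
    conservation_assignment: Sequence[str] | None = None
    ffpe_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_subtype:
            raise ValidationError("n_per_subtype must name at least one subtype")
        for subtype, n in self.n_per_subtype.items():
            if subtype not in SUBTYPES:
                raise ValidationError(f"unknown subtype {subtype!r}")
            if n < 1:
                raise ValidationError(f"subtype {subtype!r}: need >= 1 sample")
        if self.n_housekeeping >= self.n_genes:
            raise ValidationError("n_housekeeping must be < n_genes")
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValidationError("paired_fraction must lie in [0, 1]")
        if not 0.0 <= self.ffpe_fraction <= 1.0:
            raise ValidationError("ffpe_fraction must lie in [0, 1]")
        for name in ("batch_effect_sd", "conservation_effect_sd", "patient_block_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("baseline_log2_mean_range", "dispersion_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
                raise ValidationError(f"{name} must be a finite (lo, hi) interval")
        if self.dispersion_range[0] < 0:
            raise ValidationError("dispersions must be >= 0")
        if self.library_size_range[0] <= 0:
            raise ValidationError("library factors must be positive")
        n_total = sum(self.n_per_subtype.values())
        for name in ("cartridge_assignment", "conservation_assignment"):
            val = getattr(self, name)
            if val is not None and len(val) != n_total:
                raise ValidationError(f"{name} must have one entry per sample ({n_total})")
        if self.conservation_assignment is not None:
            bad = sorted(set(self.conservation_assignment) - set(CONSERVATION_METHODS))
            if bad:
                raise ValidationError(f"unknown conservation methods: {bad}")
        total_block = sum(b.size for b in self.signature_blocks)
        if total_block > self.n_genes - self.n_housekeeping:
            raise ValidationError("signature blocks exceed the number of endogenous genes")
        labels = [b.label for b in self.signature_blocks]
        if len(set(labels)) != len(labels):
            raise ValidationError("signature block labels must be unique")


@dataclass
class GroundTruth:
    """Planted effects of a simulated cohort, for recovery tests."""

    true_log2fc: pd.DataFrame  # endogenous genes x comparisons
    true_sign: pd.DataFrame  # same shape, entries in {-1, 0, +1}
    true_block_correlation: float
    planted_irdegs: list[str]
    block_genes: dict[str, list[str]]
    library_factors: pd.Series
    tau: float


def _log2_count_variance(dispersion: float | np.ndarray, baseline_log2_mean: float | np.ndarray):
    """Approximate Var(log2 count) of a gamma-Poisson draw: the gamma mixing
    part is trigamma(1/phi) exactly, plus the Poisson 1/mu term."""
    phi = np.maximum(np.asarray(dispersion, dtype=float), 1e-8)
    mu = np.power(2.0, np.asarray(baseline_log2_mean, dtype=float))
    return (special.polygamma(1, 1.0 / phi) + 1.0 / mu) / LN2_SQ


def tau_for_block_correlation(
    target_rho: float, dispersion: float, baseline_log2_mean: float = 9.0
) -> float:
    """Patient-intercept sd giving an approximate within-patient correlation
    at the given dispersion and baseline abundance."""
    if not 0.0 <= target_rho < 1.0:
        raise ValidationError("target_rho must lie in [0, 1)")
    resid_var = float(_log2_count_variance(dispersion, baseline_log2_mean))
    return math.sqrt(target_rho / (1.0 - target_rho) * resid_var)


def _gene_names(config: SimulationConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    n_endo = config.n_genes - config.n_housekeeping
    endo = [f"G{i + 1:04d}" for i in range(n_endo)]
    hk = [f"HK{i + 1:02d}" for i in range(config.n_housekeeping)]
    neg = [f"NEG_{chr(ord('A') + i)}" for i in range(config.n_neg)]
    pos = [f"POS_{chr(ord('A') + i)}" for i in range(config.n_pos)]
    return endo, hk, neg, pos


def _build_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    sample_no = 0
    patient_no = 0
    for subtype in [s for s in SUBTYPES if s in config.n_per_subtype]:
        n_s = config.n_per_subtype[subtype]
        n_pairs = int(config.paired_fraction * n_s // 2)
        ids: list[str] = []
        for _ in range(n_pairs):
            patient_no += 1
            ids.extend([f"P{patient_no:03d}"] * 2)
        while len(ids) < n_s:
            patient_no += 1
            ids.append(f"P{patient_no:03d}")
        for pid in ids:
            sample_no += 1
            rows.append({"sample_id": f"S{sample_no:03d}", "subtype": subtype, "patient_id": pid})
    sheet = pd.DataFrame(rows)
    n_total = len(sheet)

    if config.cartridge_assignment is not None:
        sheet["cartridge"] = list(config.cartridge_assignment)
    else:
        carts = [f"C{i + 1}" for i in range(config.n_cartridges)]
        sheet["cartridge"] = [carts[i % len(carts)] for i in range(n_total)]
    if config.conservation_assignment is not None:
        sheet["conservation"] = list(config.conservation_assignment)
    else:
        n_ffpe = int(round(config.ffpe_fraction * n_total))
        ffpe_idx = rng.choice(n_total, size=n_ffpe, replace=False) if n_ffpe else []
        conservation = np.array(["Cryopreserved"] * n_total, dtype=object)
        conservation[list(ffpe_idx)] = "FFPE"
        sheet["conservation"] = conservation
    sheet["fov"] = 555
    return sheet[["sample_id", "subtype", "cartridge", "fov", "conservation", "patient_id"]]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleRecord], pd.DataFrame, GroundTruth]:
    """Draw one cohort.  Deterministic given ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    sheet = _build_sheet(config, rng)
    n_samples = len(sheet)
    endo, hk, neg, pos = _gene_names(config)
    genes = endo + hk  # quantified genes (endogenous first, then housekeeping)
    n_genes = len(genes)

    # gene-level parameters
    baseline = rng.uniform(*config.baseline_log2_mean_range, size=n_genes)
    lo, hi = config.dispersion_range
    if lo <= 0:
        dispersion = np.full(n_genes, lo) if lo == hi else rng.uniform(lo, hi, size=n_genes)
    else:
        dispersion = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_genes))
    dispersion[len(endo):] = config.dispersion_range[0]  # housekeeping: low dispersion

    # planted subtype effect matrix (genes x subtypes), endogenous only;
    # signature blocks land on clearly expressed genes (baseline floor), the
    # way disease signatures in this panel sit well above background
    subtype_levels = [s for s in SUBTYPES if s in config.n_per_subtype]
    effects = np.zeros((n_genes, len(subtype_levels)))
    eligible = np.where(baseline[: len(endo)] >= config.block_min_baseline)[0]
    n_block_genes = sum(b.size for b in config.signature_blocks)
    if n_block_genes > eligible.size:
        raise ValidationError(
            f"only {eligible.size} endogenous genes above block_min_baseline for "
            f"{n_block_genes} signature genes"
        )
    available = eligible.copy()
    rng.shuffle(available)
    cursor = 0
    block_genes: dict[str, list[str]] = {}
    for block in config.signature_blocks:
        idx = available[cursor : cursor + block.size]
        cursor += block.size
        block_genes[block.label] = sorted(endo[i] for i in idx)
        for j, subtype in enumerate(subtype_levels):
            effects[idx, j] += block.effects.get(subtype, 0.0)

    # nuisance effects
    cartridges = list(dict.fromkeys(sheet["cartridge"]))
    batch = rng.normal(0.0, config.batch_effect_sd, size=(n_genes, len(cartridges)))
    conservation_shift = rng.normal(0.0, config.conservation_effect_sd, size=n_genes)
    patients = list(dict.fromkeys(sheet["patient_id"]))
    # gene-specific random intercepts: a patient-shared scaling of *all* genes
    # would also scale the library size and cancel under CPM normalization,
    # leaving nothing for the consensus-correlation estimator to recover
    patient_intercept = rng.normal(0.0, config.patient_block_sd, size=(n_genes, len(patients)))
    lib_lo, lib_hi = config.library_size_range
    library_factor = np.exp(rng.uniform(math.log(lib_lo), math.log(lib_hi), size=n_samples))

    subtype_idx = np.array([subtype_levels.index(s) for s in sheet["subtype"]])
    cart_idx = np.array([cartridges.index(c) for c in sheet["cartridge"]])
    patient_idx = np.array([patients.index(p) for p in sheet["patient_id"]])
    is_ffpe = (sheet["conservation"] == "FFPE").to_numpy()

    log2_mu = (
        baseline[:, None]
        + effects[:, subtype_idx]
        + batch[:, cart_idx]
        + np.where(is_ffpe[None, :], conservation_shift[:, None], 0.0)
        + patient_intercept[:, patient_idx]
        + np.log2(library_factor)[None, :]
    )
    mu = np.power(2.0, log2_mu)

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    phi = dispersion[:, None]
    poisson_rows = dispersion <= 1e-8
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        shape = 1.0 / phi[nb_rows]
        lam = rng.gamma(shape, mu[nb_rows] * phi[nb_rows])
        counts[nb_rows] = rng.poisson(lam)

    # probe-specific background: non-specific binding differs between probes
    neg_level = config.neg_lambda * np.power(
        2.0, rng.normal(0.0, config.neg_probe_sd, size=config.n_neg)
    )
    neg_counts = rng.poisson(neg_level[:, None], size=(config.n_neg, n_samples))
    ladder = np.array(POSITIVE_LADDER[: config.n_pos])
    pos_counts = rng.poisson(ladder[:, None] * config.pos_gain * library_factor[None, :])

    probes = tuple(
        [ProbeDefinition(g, "Endogenous", f"SYN_{g}") for g in endo]
        + [ProbeDefinition(g, "Housekeeping", f"SYN_{g}") for g in hk]
        + [ProbeDefinition(g, "Negative", f"SYN_{g}") for g in neg]
        + [ProbeDefinition(g, "Positive", f"SYN_{g}") for g in pos]
    )
    records = []
    for j, row in sheet.iterrows():
        all_counts = {g: int(counts[i, j]) for i, g in enumerate(genes)}
        all_counts.update({g: int(neg_counts[i, j]) for i, g in enumerate(neg)})
        all_counts.update({g: int(pos_counts[i, j]) for i, g in enumerate(pos)})
        records.append(
            SampleRecord(
                attributes=SampleAttributes(sample_id=row["sample_id"], fov_count=int(row["fov"])),
                probes=probes,
                counts=all_counts,
            )
        )

    truth = _ground_truth(
        config, endo, effects[: len(endo)], subtype_levels, baseline[: len(endo)],
        dispersion[: len(endo)], block_genes, library_factor, sheet,
    )
    return records, sheet, truth


def _ground_truth(
    config: SimulationConfig,
    endo: list[str],
    effects: np.ndarray,
    subtype_levels: list[str],
    baseline: np.ndarray,
    dispersion: np.ndarray,
    block_genes: dict[str, list[str]],
    library_factor: np.ndarray,
    sheet: pd.DataFrame,
) -> GroundTruth:
    fc = {}
    for a, b in COMPARISON_PAIRS:
        name = f"{a}-{b}"
        if a in subtype_levels and b in subtype_levels:
            fc[name] = effects[:, subtype_levels.index(a)] - effects[:, subtype_levels.index(b)]
        else:
            fc[name] = np.full(len(endo), np.nan)
    true_log2fc = pd.DataFrame(fc, index=pd.Index(endo, name="gene"))
    true_sign = np.sign(true_log2fc).fillna(0.0).astype(int)

    resid_var = _log2_count_variance(dispersion, baseline)
    tau_sq = config.patient_block_sd ** 2
    rho = tau_sq / (tau_sq + float(np.median(resid_var))) if tau_sq > 0 else 0.0

    irdegs = planted_irdeg_list(true_sign)
    return GroundTruth(
        true_log2fc=true_log2fc,
        true_sign=true_sign,
        true_block_correlation=rho,
        planted_irdegs=irdegs,
        block_genes=block_genes,
        library_factors=pd.Series(library_factor, index=sheet["sample_id"].to_numpy()),
        tau=float(config.patient_block_sd),
    )


def planted_irdeg_list(true_sign: pd.DataFrame) -> list[str]:
    """Genes whose planted signs satisfy the irDEG pattern: same-direction
    non-zero in both irMyositis-vs-dermatomyositis comparisons, and zero or
    opposite in each dermatomyositis-vs-control comparison."""
    need = {"irMyositis-Mi2", "irMyositis-TIF1g", "Mi2-NDC", "TIF1g-NDC"}
    if not need.issubset(true_sign.columns):
        return []
    s_im = true_sign["irMyositis-Mi2"]
    s_it = true_sign["irMyositis-TIF1g"]
    s_mn = true_sign["Mi2-NDC"]
    s_tn = true_sign["TIF1g-NDC"]
    ok = (s_im != 0) & (s_im == s_it) & (s_mn * s_im <= 0) & (s_tn * s_im <= 0)
    return sorted(true_sign.index[ok])


def default_cohort_config(seed: int = 0) -> SimulationConfig:
    """Cohort shaped like the study: 4 NDC / 8 Mi2 / 6 TIF1g / 17 irMyositis
    samples over 7 cartridges, 7 FFPE biopsies, and two irMyositis patients
    contributing paired biopsies; with an ISG-like block up in both
    dermatomyositis subtypes versus control, and a type-II-interferon-like
    block with the opposite pattern."""
    cartridges = (
        ["C12"] * 4
        + ["C49", "C49"] + ["C15"] * 6
        + ["C15"] * 4 + ["C19", "C20"]
        + ["C15", "C49", "C12", "C12", "C12", "C14", "C12"]
        + ["C20"] * 6
        + ["C19", "C48", "C48", "C49"]
    )
    conservation = (
        ["FFPE", "FFPE", "Cryopreserved", "Cryopreserved"]
        + ["Cryopreserved"] * 8
        + ["Cryopreserved"] * 6
        + ["Cryopreserved", "Cryopreserved", "FFPE", "FFPE", "FFPE", "FFPE", "FFPE"]
        + ["Cryopreserved"] * 10
    )
    blocks = [
        SignatureBlock(
            label="ISG_like",
            size=40,
            effects={"Mi2": 2.0, "TIF1g": 2.0, "irMyositis": 0.0, "NDC": 0.0},
        ),
        SignatureBlock(
            label="typeII_IFN_like",
            size=20,
            effects={"Mi2": -2.0, "TIF1g": -2.0, "irMyositis": 0.0, "NDC": 0.0},
        ),
    ]
    # irMyositis paired patients: 4/17 samples from two-biopsy patients
    return SimulationConfig(
        n_per_subtype={"NDC": 4, "Mi2": 8, "TIF1g": 6, "irMyositis": 17},
        signature_blocks=blocks,
        cartridge_assignment=cartridges,
        conservation_assignment=conservation,
        paired_fraction=4.0 / 17.0,
        seed=seed,
    )


# -- synthetic downstream resources ---------------------------------------------


def synthetic_gene_sets(
    truth: GroundTruth,
    universe: Sequence[str],
    n_random: int = 50,
    size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
) -> list[tuple[str, str, list[str]]]:
    """Gene-set collection for enrichment runs: one set per planted block plus
    random draws from the universe.  Returns (id, description, members) rows."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: list[tuple[str, str, list[str]]] = []
    for label, members in truth.block_genes.items():
        sets.append((label, f"planted {label} block", sorted(members)))
    for i in range(n_random):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = sorted(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets.append((f"RANDOM_{i + 1:03d}", "random control set", list(members)))
    return sets


def write_gmt(sets: Sequence[tuple[str, str, Sequence[str]]], path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join([sid, desc, *members]) for sid, desc, members in sets]
    path.write_text("\n".join(lines) + "\n")
    return path


def synthetic_regulatory_graph(
    seed_genes: Sequence[str],
    seed: int = 0,
    n_connectors: int = 15,
    extra_genes: Sequence[str] = ("CD274", "PDCD1", "CTLA4"),
    dropout: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Small regulatory interaction graph wiring seed genes through connector
    hubs, as node/edge tables.

    Connectors stand in for curated pathway intermediaries that are not on the
    panel.  ``dropout`` seed genes are deliberately left out of the graph to
    exercise the absent-gene reporting path.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    seed_genes = sorted(dict.fromkeys([*seed_genes, *extra_genes]))
    present = seed_genes[: max(0, len(seed_genes) - dropout)] if dropout else list(seed_genes)
    connectors = [f"REG{i + 1:02d}" for i in range(n_connectors)]
    modes = np.array(["positive", "negative", "unspecified"])
    compartments = np.array(["cytosol", "nucleoplasm", "plasma membrane", "extracellular region"])

    edges = []
    for i, gene in enumerate(present):
        hub = connectors[i % n_connectors]
        mode = str(rng.choice(modes, p=[0.6, 0.25, 0.15]))
        if rng.random() < 0.5:
            edges.append((gene, hub, mode, f"SYNPATH_{i % 5 + 1}"))
        else:
            edges.append((hub, gene, mode, f"SYNPATH_{i % 5 + 1}"))
    for i in range(n_connectors):
        j = (i + 1) % n_connectors
        edges.append((connectors[i], connectors[j], "positive", "SYNPATH_HUB"))
    # a few direct seed-seed regulations
    if len(present) >= 2:
        n_direct = min(8, len(present) - 1)
        picks = rng.choice(len(present), size=(n_direct, 2))
        for a, b in picks:
            if a != b:
                edges.append((present[a], present[b], str(rng.choice(modes)), "SYNPATH_DIRECT"))
    edge_df = pd.DataFrame(edges, columns=["source", "target", "mode", "pathway_id"]).drop_duplicates()
    nodes = sorted(set(edge_df["source"]) | set(edge_df["target"]))
    node_df = pd.DataFrame(
        {
            "gene": nodes,
            "compartments": [
                ";".join(sorted(rng.choice(compartments, size=int(rng.integers(1, 3)), replace=False)))
                for _ in nodes
            ],
        }
    )
    return node_df, edge_df


def write_cohort(
    records: Sequence[SampleRecord],
    sheet: pd.DataFrame,
    truth: GroundTruth,
    outdir: str | Path,
) -> Path:
    """Write RCC files, the sample sheet, and ground-truth tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rcc_dir = outdir / "rcc"
    rcc_dir.mkdir(exist_ok=True)
    for rec in records:
        write_rcc(rec, rcc_dir / f"{rec.attributes.sample_id}.RCC")
    write_sample_sheet(sheet, outdir / "sheet.tsv")
    truth.true_log2fc.to_csv(outdir / "truth_log2fc.tsv", sep="\t")
    truth.true_sign.to_csv(outdir / "truth_sign.tsv", sep="\t")
    pd.Series(truth.planted_irdegs, name="gene").to_csv(outdir / "truth_irdegs.tsv", sep="\t", index=False)
    return outdir
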