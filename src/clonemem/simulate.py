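"""Synthetic multi-generation RNA-seq counts and trait tables with planted truth.

Emulates a clonal stress/recovery/re-stress design: five sequenced groups
(P1 control CK, P1 stressed S, and the stressed lineage sampled again at
P2 and P3 under control conditions and at P4 under re-exposure), three
replicates each.  Genes are planted into memory classes (sustained response
through P2/P3, transient, fluctuating, null) and traits into weaken /
strengthen reaction-norm classes, so every downstream stage of the pipeline
has ground truth to validate against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "GROUP_DESIGN",
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_traits",
    "write_simulation",
]

#: Ordered sequenced groups: P1 control, P1 stressed, stressed lineage at
#: P2/P3 (recovery, control conditions) and at P4 (re-exposure).
GROUPS: tuple[str, ...] = ("CK", "S", "P1S-P2CK", "P1S-P3CK", "P1S-P4S")

#: Design labels (stage, lineage, condition) for each sequenced group.
GROUP_DESIGN: Mapping[str, tuple[str, str, str]] = {
    "CK": ("P1", "P1CK", "CK"),
    "S": ("P1", "P1S", "S"),
    "P1S-P2CK": ("P2", "P1S", "CK"),
    "P1S-P3CK": ("P3", "P1S", "CK"),
    "P1S-P4S": ("P4", "P1S", "S"),
}

#: Planted gene classes recognised by the generator.
GENE_CLASSES: tuple[str, ...] = (
    "tmg3_up",
    "tmg3_down",
    "tmg2_only_up",
    "tmg2_only_down",
    "transient",
    "fluctuating",
    "null",
)

# Trait roster mirroring the measured phenotypes of the study system:
# growth/photosynthesis traits suppressed by the stressor (weaken class),
# antioxidant/osmolyte traits induced by it (strengthen class), and traits
# the stressor leaves unchanged.
DEFAULT_WEAKEN_TRAITS: tuple[str, ...] = (
    "biomass", "leaf_number", "leaf_area", "chl_b", "Fm", "FvFm",
)
DEFAULT_STRENGTHEN_TRAITS: tuple[str, ...] = (
    "POD", "SOD", "proline", "soluble_sugar", "soluble_protein",
)
DEFAULT_NULL_TRAITS: tuple[str, ...] = ("root_length", "CAT", "APX")


def _default_class_counts() -> dict[str, int]:
    return {
        "tmg3_up": 150,
        "tmg3_down": 150,
        "tmg2_only_up": 100,
        "tmg2_only_down": 100,
        "transient": 200,
        "fluctuating": 200,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Counts are negative binomial with variance ``m + phi * m**2``; per-gene
    dispersions ``phi`` are drawn log-uniformly on ``dispersion_range`` and
    per-sample library-size factors uniformly on ``libsize_range``.  The
    planted log2 effect is ``base_lfc`` in the P1 stress group and is
    rescaled per stage by ``attenuation`` (P2, P3, P4); the default P4
    multiplier 1.2 > 1 encodes the strengthened re-exposure response of
    memory genes.
    """

    n_genes: int = 5000
    n_reps: int = 3
    class_counts: Mapping[str, int] = field(default_factory=_default_class_counts)
    base_lfc: float = 2.0
    attenuation: tuple[float, float, float] = (0.7, 0.5, 1.2)
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    libsize_range: tuple[float, float] = (0.7, 1.4)
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    # trait generator
    n_trait_reps: int = 6
    trait_baseline: float = 100.0
    trait_effect: float = 30.0
    trait_noise_sd: float = 1.5
    trait_memory_gain: float = 0.5
    weaken_traits: Sequence[str] = DEFAULT_WEAKEN_TRAITS
    strengthen_traits: Sequence[str] = DEFAULT_STRENGTHEN_TRAITS
    null_traits: Sequence[str] = DEFAULT_NULL_TRAITS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reps < 1 or self.n_trait_reps < 1:
            raise ValueError("n_genes, n_reps and n_trait_reps must be positive")
        unknown = set(self.class_counts) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ValueError("sum of class_counts exceeds n_genes")
        for name in ("dispersion_range", "libsize_range", "baseline_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval, got {(lo, hi)}")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be non-negative")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Planted ground truth: one class label per gene and per trait.

    ``gene_classes`` maps gene_id -> planted class; ``gene_signs`` carries the
    response sign (+1/-1, 0 for null).  ``trait_classes`` maps trait ->
    {weaken, strengthen, none}.
    """

    gene_classes: pd.Series
    gene_signs: pd.Series
    trait_classes: pd.Series

    def tmg2_union(self) -> pd.Index:
        """Genes planted with a memory pattern that persists through P2."""
        mask = self.gene_classes.isin(
            ["tmg3_up", "tmg3_down", "tmg2_only_up", "tmg2_only_down"]
        )
        return self.gene_classes.index[mask]

    def tmg3_set(self) -> pd.Index:
        mask = self.gene_classes.isin(["tmg3_up", "tmg3_down"])
        return self.gene_classes.index[mask]


def _stage_multiplier(cfg: SimConfig, group: str) -> float:
    p2, p3, p4 = cfg.attenuation
    return {"CK": 0.0, "S": 1.0, "P1S-P2CK": p2, "P1S-P3CK": p3, "P1S-P4S": p4}[group]


def planted_lfc(cfg: SimConfig, klass: str, sign: int, group: str) -> float:
    """Planted log2 fold change (vs CK) for one gene class in one group.

    Memory classes keep their sign across groups with per-stage attenuation;
    ``tmg2_only`` loses the effect at P3; ``transient`` responds only in S;
    ``fluctuating`` alternates sign (+, -, +, -) across the four non-control
    groups at full effect size.
    """
    if group == "CK" or klass == "null":
        return 0.0
    mult = _stage_multiplier(cfg, group)
    if klass in ("tmg3_up", "tmg3_down"):
        return sign * cfg.base_lfc * mult
    if klass in ("tmg2_only_up", "tmg2_only_down"):
        return 0.0 if group == "P1S-P3CK" else sign * cfg.base_lfc * mult
    if klass == "transient":
        return sign * cfg.base_lfc if group == "S" else 0.0
    if klass == "fluctuating":
        k = GROUPS.index(group)  # 1..4
        return sign * cfg.base_lfc * (1.0 if k % 2 == 1 else -1.0)
    raise ValueError(f"unknown class {klass!r}")


def _assign_classes(cfg: SimConfig, rng: np.random.Generator):
    labels = []
    signs = []
    for klass in GENE_CLASSES[:-1]:
        n = int(cfg.class_counts.get(klass, 0))
        labels += [klass] * n
        if klass.endswith("_up"):
            signs += [1] * n
        elif klass.endswith("_down"):
            signs += [-1] * n
        else:
            signs += list(rng.choice([1, -1], n))
    n_null = cfg.n_genes - len(labels)
    labels += ["null"] * n_null
    signs += [0] * n_null
    return np.array(labels), np.array(signs)


def simulate_counts(cfg: SimConfig) -> tuple["pd.DataFrame", pd.DataFrame, SimTruth]:
    """Simulate a gene x sample count matrix for the five-group design.

    Returns ``(counts, samples, truth)``: integer counts (genes x samples),
    a sample sheet with stage/lineage/condition/replicate labels, and the
    planted truth.  Deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(cfg.n_genes)], name="gene_id")
    labels, signs = _assign_classes(cfg, rng)

    lo, hi = cfg.dispersion_range
    phi = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_genes))
    blo, bhi = cfg.baseline_range
    baseline = np.exp(rng.uniform(np.log(blo), np.log(bhi), cfg.n_genes))

    sample_rows = []
    cols = {}
    for group in GROUPS:
        stage, lineage, condition = GROUP_DESIGN[group]
        lfc = np.array(
            [planted_lfc(cfg, k, s, group) for k, s in zip(labels, signs)]
        )
        group_mean = baseline * np.exp2(lfc)
        for rep in range(1, cfg.n_reps + 1):
            sid = f"{group}_r{rep}"
            lib = rng.uniform(*cfg.libsize_range)
            mu = group_mean * lib
            n_nb = 1.0 / phi
            cols[sid] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
            sample_rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "stage": stage,
                    "lineage": lineage,
                    "condition": condition,
                    "replicate": rep,
                    "libsize_factor": lib,
                }
            )

    counts = pd.DataFrame(cols, index=gene_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = SimTruth(
        gene_classes=pd.Series(labels, index=gene_ids, name="class"),
        gene_signs=pd.Series(signs, index=gene_ids, name="sign"),
        trait_classes=_trait_truth(cfg),
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# traits


def _trait_truth(cfg: SimConfig) -> pd.Series:
    out = {}
    for t in cfg.weaken_traits:
        out[t] = "weaken"
    for t in cfg.strengthen_traits:
        out[t] = "strengthen"
    for t in cfg.null_traits:
        out[t] = "none"
    s = pd.Series(out, name="trait_class")
    s.index.name = "trait"
    return s


def trait_group_mean(cfg: SimConfig, klass: str, stage: str, lineage: str,
                     condition: str) -> float:
    """Deterministic group mean for one trait class in one design cell.

    Weaken traits drop by the full effect under stress in P1 and in the
    control-lineage P4 re-exposure, but only by half the effect in the
    stressed lineage at P4 (pre-adaptation).  Strengthen traits rise
    symmetrically, with the stressed lineage overshooting at P4.  During the
    recovery stages P2/P3 the stressed lineage carries a decaying residual
    (30% then 10% of the effect), which couples the trait profile to the
    planted memory-gene expression profile across the five sequenced groups.
    """
    b, e, g = cfg.trait_baseline, cfg.trait_effect, cfg.trait_memory_gain
    if klass == "none":
        return b
    direction = -1.0 if klass == "weaken" else 1.0
    if condition == "S":
        if stage == "P1":
            return b + direction * e
        if stage == "P4":
            full = b + direction * e
            if lineage == "P1S":
                # weaken: attenuated drop; strengthen: amplified rise
                factor = (1.0 - g) if klass == "weaken" else (1.0 + g)
                return b + direction * e * factor
            return full
        return b + direction * e
    # control conditions: stressed lineage keeps a decaying residual
    residual = {"P1": 0.0, "P2": 0.3, "P3": 0.1, "P4": 0.0}[stage]
    if lineage == "P1S":
        return b + direction * e * residual
    return b


#: Design cells emitted by the trait generator: the P1 dose groups, the
#: recovery stages of both lineages, and the full P4 reaction-norm quadruple.
TRAIT_CELLS: tuple[tuple[str, str, str], ...] = (
    ("P1", "P1CK", "CK"),
    ("P1", "P1S", "S"),
    ("P2", "P1CK", "CK"),
    ("P2", "P1S", "CK"),
    ("P3", "P1CK", "CK"),
    ("P3", "P1S", "CK"),
    ("P4", "P1CK", "CK"),
    ("P4", "P1CK", "S"),
    ("P4", "P1S", "CK"),
    ("P4", "P1S", "S"),
)


def simulate_traits(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate replicate-level trait measurements with planted reaction norms.

    Returns a tidy table (trait, stage, lineage, condition, replicate, value)
    with ``cfg.n_trait_reps`` Gaussian replicates per design cell, and the
    planted truth.  The trait RNG stream is offset from the count stream so
    counts and traits are independently reproducible.
    """
    rng = np.random.default_rng(cfg.seed + 10_007)
    truth = _trait_truth(cfg)
    rows = []
    for trait, klass in truth.items():
        for stage, lineage, condition in TRAIT_CELLS:
            m = trait_group_mean(cfg, klass, stage, lineage, condition)
            vals = m + rng.normal(0.0, cfg.trait_noise_sd, cfg.n_trait_reps)
            for rep, v in enumerate(vals, start=1):
                rows.append(
                    {
                        "trait": trait,
                        "stage": stage,
                        "lineage": lineage,
                        "condition": condition,
                        "replicate": rep,
                        "value": v,
                    }
                )
    table = pd.DataFrame(rows)
    gene_truth = SimTruth(
        gene_classes=pd.Series(dtype=object),
        gene_signs=pd.Series(dtype=int),
        trait_classes=truth,
    )
    return table, gene_truth


def write_simulation(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run both generators and write TSV/CSV artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, samples, truth = simulate_counts(cfg)
    traits, _ = simulate_traits(cfg)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.csv",
        "traits": outdir / "traits.csv",
        "gene_truth": outdir / "gene_truth.csv",
        "trait_truth": outdir / "trait_truth.csv",
    }
    counts.to_csv(paths["counts"], sep="\t")
    samples.to_csv(paths["samples"])
    traits.to_csv(paths["traits"], index=False)
    pd.DataFrame(
        {"class": truth.gene_classes, "sign": truth.gene_signs}
    ).to_csv(paths["gene_truth"])
    truth.trait_classes.to_frame().to_csv(paths["trait_truth"])
    return paths
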