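"""End-to-end orchestration: simulate/load -> DE -> memory -> traits -> network.

A run is driven by a :class:`RunConfig` (YAML-loadable), executes every stage
deterministically for a given seed, writes all stage artifacts into the
output directory and returns a validated :class:`RunReport` (a pydantic
model whose JSON schema is the bundled report schema).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import coexpression, diffexpr, memory, traits as traits_mod
from .diffexpr import CountMatrix
from .simulate import SimConfig, simulate_counts, simulate_traits

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_run_config"]


class RunConfig(BaseModel):
    """Configuration of a full pipeline run.

    Either ``counts_path``/``samples_path``/``traits_path`` point at existing
    input files, or the bundled generator is used with ``sim`` overrides.
    """

    counts_path: Optional[str] = None
    samples_path: Optional[str] = None
    traits_path: Optional[str] = None
    sim: dict = Field(default_factory=dict)
    alpha: float = 0.05
    lfc_threshold: float = 0.5
    power: float = 20.0
    min_module_size: int = 30
    merge_height: float = 0.25
    edge_fraction: float = 0.30
    hub_fraction: float = 0.10
    seed: int = 0
    outdir: Optional[str] = None

    @model_validator(mode="after")
    def _check_ranges(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not (0 < self.edge_fraction <= 1 and 0 < self.hub_fraction <= 1):
            raise ValueError("edge/hub fractions must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        for p in (self.counts_path, self.samples_path, self.traits_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return self


class ContrastCounts(BaseModel):
    up: int
    down: int

    @property
    def total(self) -> int:
        return self.up + self.down


class RunReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    seed: int
    config: dict
    n_genes_tested: int
    deg_counts: dict[str, ContrastCounts]
    pattern_counts: dict[str, int]
    tmg2_counts: dict[str, int]          # up / down
    tmg3_counts: dict[str, int]
    trait_classes: dict[str, str]
    n_modules: int
    module_sizes: dict[str, int]
    module_classes: dict[str, str]
    tmg_fractions: dict[str, Optional[float]]
    tmg_enrichment_p: float
    hub_counts: dict[str, int]
    hub_tmg_fraction: float
    version: str = "0.1.0"

    @model_validator(mode="after")
    def _check_consistency(self):
        tmg2 = self.tmg2_counts["up"] + self.tmg2_counts["down"]
        tmg3 = self.tmg3_counts["up"] + self.tmg3_counts["down"]
        if tmg3 > tmg2:
            raise ValueError("TMG3 count exceeds TMG2 count")
        if sum(self.pattern_counts.values()) != self.n_genes_tested:
            raise ValueError("pattern counts do not partition the gene universe")
        return self

    @classmethod
    def json_schema(cls) -> dict:
        return cls.model_json_schema()


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _load_inputs(cfg: RunConfig):
    if cfg.counts_path:
        counts = pd.read_csv(cfg.counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(cfg.samples_path, index_col=0)
        trait_table = pd.read_csv(cfg.traits_path)
        truth = None
    else:
        sim_cfg = SimConfig(**{**cfg.sim, "seed": cfg.seed})
        counts, samples, truth = simulate_counts(sim_cfg)
        trait_table, _ = simulate_traits(sim_cfg)
    return CountMatrix(counts, samples), trait_table, truth


def _traits_per_sample(
    trait_table: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Map trait group means onto RNA samples (group-mean mapping)."""
    means = trait_table.groupby(
        ["trait", "stage", "lineage", "condition"]
    )["value"].mean()
    out = {}
    for trait in trait_table["trait"].unique():
        vals = []
        for sid, row in samples.iterrows():
            key = (trait, row["stage"], row["lineage"], row["condition"])
            if key not in means.index:
                raise KeyError(
                    f"trait {trait!r} has no measurement for design cell {key[1:]}"
                )
            vals.append(means.loc[key])
        out[trait] = vals
    return pd.DataFrame(out, index=samples.index)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage in order and return the validated report.

    Stage artifacts (DE tables, memory classification, trait classes, module
    assignment, eigengenes, module-trait matrix, edge list, hubs, report
    JSON, resolved config) are written to ``cfg.outdir`` when set.
    """
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.model_dump()))

    cm, trait_table, _truth = _load_inputs(cfg)

    # differential expression: the four contrasts vs the P1 control
    results = diffexpr.run_contrasts(
        cm, alpha=cfg.alpha, lfc_threshold=cfg.lfc_threshold
    )
    deg_counts = {
        name: ContrastCounts(up=r.n_up(), down=r.n_down())
        for name, r in results.items()
    }

    # transcriptional memory classification
    dirs = memory.build_direction_table(results)
    classification = memory.classify_patterns(dirs)
    tmg2 = memory.identify_tmg2(dirs)
    tmg3 = memory.identify_tmg3(dirs)

    # trait reaction norms
    trait_classes = traits_mod.classify_all_traits(trait_table, alpha=cfg.alpha)

    # co-expression network on the DEG union
    deg_union = dirs.index[(dirs != "ns").any(axis=1)]
    norm = cm.drop_unexpressed()
    s = results["P1"].size_factors
    expr = norm.counts.loc[deg_union] / s
    z = coexpression.standardize(expr)
    net = coexpression.build_network(
        z,
        power=cfg.power,
        min_module_size=cfg.min_module_size,
        merge_height=cfg.merge_height,
        edge_fraction=cfg.edge_fraction,
        hub_fraction=cfg.hub_fraction,
    )
    traits_per_sample = _traits_per_sample(trait_table, cm.samples)
    assoc = coexpression.module_trait_association(
        net.eigengenes, traits_per_sample, alpha=cfg.alpha
    )
    module_classes = coexpression.classify_modules(
        assoc, trait_classes["label"]
    )
    enrich = coexpression.tmg_module_enrichment(
        net.modules[net.modules != "grey"],
        module_classes,
        classification["label"],
    )
    hub_all = [g for hs in net.hubs.values() for g in hs]
    hub_tmg = classification.loc[
        classification.index.intersection(pd.Index(hub_all))
    ]["label"].isin(["TMG3", "TMG2-only"])
    hub_tmg_fraction = float(hub_tmg.mean()) if len(hub_all) else 0.0

    tmg_fractions = {
        k: (None if math.isnan(v) else v)
        for k, v in enrich["fractions"].items()
    }
    assigned = net.modules[net.modules != "grey"]
    report = RunReport(
        seed=cfg.seed,
        config=cfg.model_dump(),
        n_genes_tested=len(dirs),
        deg_counts=deg_counts,
        pattern_counts=classification["label"].value_counts().to_dict(),
        tmg2_counts={
            "up": int((tmg2 == "up").sum()),
            "down": int((tmg2 == "down").sum()),
        },
        tmg3_counts={
            "up": int((tmg3 == "up").sum()),
            "down": int((tmg3 == "down").sum()),
        },
        trait_classes=trait_classes["label"].to_dict(),
        n_modules=int(assigned.nunique()),
        module_sizes={
            m: int(n) for m, n in net.module_sizes().items() if m != "grey"
        },
        module_classes=module_classes.to_dict(),
        tmg_fractions=tmg_fractions,
        tmg_enrichment_p=enrich["fisher_p"],
        hub_counts={m: len(h) for m, h in net.hubs.items()},
        hub_tmg_fraction=hub_tmg_fraction,
    )

    if outdir:
        for name, r in results.items():
            r.table.to_csv(outdir / f"de_{name}.tsv", sep="\t")
        classification.to_csv(outdir / "memory_classification.tsv", sep="\t")
        trait_classes.to_csv(outdir / "trait_classes.csv")
        net.modules.to_frame().to_csv(outdir / "modules.csv")
        net.eigengenes.to_csv(outdir / "eigengenes.csv")
        assoc.to_csv(outdir / "module_trait_association.csv", index=False)
        net.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        pd.Series(
            {m: ",".join(h) for m, h in net.hubs.items()}, name="hubs"
        ).to_csv(outdir / "hubs.csv")
        with open(outdir / "report.json", "w") as fh:
            fh.write(report.model_dump_json(indent=2))
        with open(outdir / "report.schema.json", "w") as fh:
            json.dump(RunReport.json_schema(), fh, indent=2)
    return report
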