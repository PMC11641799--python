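"""Negative-binomial differential expression against the P1 control group.

Median-of-ratios normalization, pooled method-of-moments dispersion with
trend shrinkage, per-contrast Wald tests with Benjamini-Hochberg adjustment,
and ternary direction calls at the adjusted-p / log2-fold-change thresholds
used throughout the pipeline (alpha = 0.05, |log2FC| > 0.5).

All four contrasts share the single P1 CK group as reference: only five
groups were sequenced, so no stage-matched control exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ContrastResult",
    "CONTRASTS",
    "size_factors",
    "estimate_dispersion",
    "wald_test",
    "run_contrasts",
    "load_contrast_table",
]

#: contrast name -> (reference group, test group)
CONTRASTS: dict[str, tuple[str, str]] = {
    "P1": ("CK", "S"),
    "P2": ("CK", "P1S-P2CK"),
    "P3": ("CK", "P1S-P3CK"),
    "P4": ("CK", "P1S-P4S"),
}

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 0.5


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus the per-sample design sheet.

    ``samples`` is indexed by sample id and must provide ``group``,
    ``stage``, ``lineage`` and ``condition`` columns; its index must match
    the count columns exactly.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows disagree")
        for col in ("group", "stage", "lineage", "condition"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
            if self.samples[col].isna().any():
                raise ValueError(f"sample sheet column {col!r} has missing labels")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("counts must be finite")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")

    def drop_unexpressed(self) -> "CountMatrix":
        """Remove genes with zero counts in every sample (undefined fold change)."""
        keep = (self.counts.sum(axis=1) > 0)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d genes with all-zero counts", n_dropped)
        return CountMatrix(self.counts.loc[keep], self.samples)

    def group_columns(self, group: str) -> list[str]:
        cols = list(self.samples.index[self.samples["group"] == group])
        if not cols:
            raise KeyError(f"unknown or empty group {group!r}")
        return cols


@dataclass
class ContrastResult:
    """Per-gene test results for one contrast against the P1 control.

    ``table`` columns: baseMeanA, baseMeanB, log2fc, se, stat, p_raw, p_adj,
    direction (up/down/ns).
    """

    name: str
    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    alpha: float = DEFAULT_ALPHA
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD

    @property
    def directions(self) -> pd.Series:
        return self.table["direction"]

    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For genes expressed in every sample, each sample's factor is the median
    of count / (gene geometric mean).  Genes with a zero anywhere are
    excluded from the reference, as their geometric mean is zero.
    """
    arr = counts.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if not pos.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "filter low-coverage samples or genes before normalization"
        )
    sub = arr[pos]
    log_gm = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_gm[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def _pooled_moments_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]):
    """Per-gene method-of-moments dispersion pooled across groups."""
    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            raise ValueError("dispersion estimation needs >=2 replicates per group")
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += w * contrib
        den += w
    return np.maximum(0.0, num / den)


def estimate_dispersion(
    cm: CountMatrix,
    s: pd.Series,
    shrink: float = 0.5,
) -> pd.Series:
    """Estimate per-gene NB dispersions from normalized counts.

    Raw estimates are pooled method-of-moments values across replicate
    groups, phi = max(0, (var - mean) / mean^2), then shrunk ``shrink`` of
    the way toward a mean-dispersion trend phi_tr(mu) = a + b / mu fitted by
    least squares over genes (the standard hyperbolic trend of NB RNA-seq
    dispersion).  Deterministic.
    """
    norm = cm.counts.to_numpy(dtype=float) / s.to_numpy()[None, :]
    groups = cm.samples["group"]
    group_idx = [
        np.flatnonzero((groups == g).to_numpy()) for g in groups.unique()
    ]
    raw = _pooled_moments_dispersion(norm, group_idx)
    mean_all = norm.mean(axis=1)

    ok = mean_all > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean_all[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    a, b = coef
    a = max(a, 1e-8)
    b = max(b, 0.0)
    trend = a + b / np.maximum(mean_all, 1e-8)
    phi = (1.0 - shrink) * raw + shrink * trend
    return pd.Series(np.maximum(phi, 0.0), index=cm.counts.index, name="dispersion")


def wald_test(
    cm: CountMatrix,
    s: pd.Series,
    phi: pd.Series,
    group_a: str,
    group_b: str,
    name: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    zero_mean_floor: float = 0.5,
) -> ContrastResult:
    """NB Wald test of group B vs group A on normalized group means.

    Group means of normalized counts estimate the NB means; all-zero group
    means are floored at ``zero_mean_floor`` so the fold change is defined.
    The delta-method standard error of log2(mean_B / mean_A) uses the NB
    variance m + phi m^2 of each group mean; the Wald statistic is referred
    to a standard normal, p-values are BH-adjusted across genes, and the
    ternary direction call applies the (alpha, lfc_threshold) gates.
    """
    cols_a = cm.group_columns(group_a)
    cols_b = cm.group_columns(group_b)
    phi_v = phi.reindex(cm.counts.index).to_numpy()

    norm = cm.counts.to_numpy(dtype=float) / s.to_numpy()[None, :]
    col_pos = {c: i for i, c in enumerate(cm.counts.columns)}
    a = norm[:, [col_pos[c] for c in cols_a]]
    b = norm[:, [col_pos[c] for c in cols_b]]

    mean_a_raw = a.mean(axis=1)
    mean_b_raw = b.mean(axis=1)
    mean_a = np.maximum(mean_a_raw, zero_mean_floor)
    mean_b = np.maximum(mean_b_raw, zero_mean_floor)

    log2fc = np.log2(mean_b / mean_a)
    var_a = (mean_a + phi_v * mean_a**2) / a.shape[1]
    var_b = (mean_b + phi_v * mean_b**2) / b.shape[1]
    # Var(log2 m) = Var(m) / (m ln2)^2
    se = np.sqrt(var_a / mean_a**2 + var_b / mean_b**2) / np.log(2.0)
    stat = np.where((mean_a_raw == mean_b_raw), 0.0, log2fc / se)
    p_raw = 2.0 * stats.norm.sf(np.abs(stat))
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    direction = np.where(
        (p_adj < alpha) & (log2fc > lfc_threshold),
        "up",
        np.where((p_adj < alpha) & (log2fc < -lfc_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "baseMeanA": mean_a_raw,
            "baseMeanB": mean_b_raw,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
        },
        index=cm.counts.index,
    )
    return ContrastResult(
        name=name or f"{group_b}_vs_{group_a}",
        table=table,
        size_factors=s,
        dispersions=pd.Series(phi_v, index=cm.counts.index, name="dispersion"),
        alpha=alpha,
        lfc_threshold=lfc_threshold,
    )


def run_contrasts(
    cm: CountMatrix,
    contrasts: dict[str, tuple[str, str]] | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> dict[str, ContrastResult]:
    """Normalize once, estimate dispersions once, and test every contrast."""
    contrasts = contrasts or CONTRASTS
    cm = cm.drop_unexpressed()
    s = size_factors(cm.counts)
    phi = estimate_dispersion(cm, s)
    return {
        name: wald_test(
            cm, s, phi, ref, test, name=name,
            alpha=alpha, lfc_threshold=lfc_threshold,
        )
        for name, (ref, test) in contrasts.items()
    }


def load_contrast_table(
    path,
    name: str,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> ContrastResult:
    """Adapter for externally computed DE tables.

    Accepts a TSV with columns ``gene_id``, ``log2fc`` and ``p_adj`` (extra
    columns pass through); recomputes the ternary direction call at the
    pipeline thresholds so downstream memory classification is consistent.
    """
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    if not {"log2fc", "p_adj"} <= set(df.columns):
        raise ValueError("external DE table needs gene_id, log2fc, p_adj columns")
    df["direction"] = np.where(
        (df["p_adj"] < alpha) & (df["log2fc"] > lfc_threshold),
        "up",
        np.where(
            (df["p_adj"] < alpha) & (df["log2fc"] < -lfc_threshold), "down", "ns"
        ),
    )
    return ContrastResult(
        name=name,
        table=df,
        size_factors=pd.Series(dtype=float),
        dispersions=pd.Series(dtype=float),
        alpha=alpha,
        lfc_threshold=lfc_threshold,
    )
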