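"""Trait-level statistics: Fisher's LSD, reaction-norm classification, ddCt.

Fisher's least significant difference test performs unprotected pairwise
t-comparisons using the pooled one-way-ANOVA error mean square (df = N - k);
the omnibus F statistic is reported alongside.  The weaken/strengthen
classifier operationalizes the P4 reaction norm: a trait whose stress
response in the re-exposed generation is damped (weaken, pre-adaptation) or
amplified (strengthen) in the offspring of stressed parents relative to the
offspring of control parents, with the lineage contrast under stress
required to be LSD-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LSDResult",
    "lsd_test",
    "compact_letters",
    "TraitClass",
    "classify_trait",
    "classify_all_traits",
    "ddct",
    "ddct_table",
]


@dataclass
class LSDResult:
    """Pairwise LSD comparisons for one trait.

    ``pairs`` columns: group_a, group_b, mean_a, mean_b, diff, t, p,
    degenerate.  ``mse`` is the pooled within-group mean square with
    ``df`` = N - k error degrees of freedom; ``f_stat``/``f_p`` give the
    omnibus one-way ANOVA.
    """

    trait: str
    pairs: pd.DataFrame
    group_means: pd.Series
    mse: float
    df: int
    f_stat: float
    f_p: float

    def p_for(self, group_a: Hashable, group_b: Hashable) -> float:
        key = {group_a, group_b}
        for _, row in self.pairs.iterrows():
            if {row["group_a"], row["group_b"]} == key:
                return float(row["p"])
        raise KeyError(f"no comparison between {group_a!r} and {group_b!r}")


def _group_arrays(
    table: pd.DataFrame, trait: str, groups: Sequence[Hashable] | None,
    group_cols: Sequence[str],
) -> dict[Hashable, np.ndarray]:
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise KeyError(f"trait {trait!r} not in table")
    out: dict[Hashable, np.ndarray] = {}
    for key, grp in sub.groupby(list(group_cols), sort=False):
        if len(group_cols) == 1:
            key = key[0] if isinstance(key, tuple) else key
        out[key] = grp["value"].to_numpy(dtype=float)
    if groups is not None:
        missing = [g for g in groups if g not in out]
        if missing:
            raise KeyError(f"groups missing for trait {trait!r}: {missing}")
        out = {g: out[g] for g in groups}
    return out


def lsd_test(
    table: pd.DataFrame,
    trait: str,
    groups: Sequence[Hashable] | None = None,
    group_cols: Sequence[str] = ("stage", "lineage", "condition"),
) -> LSDResult:
    """Fisher's LSD over the groups of one trait.

    Pools the within-group variance across all k groups (one-way ANOVA MSE),
    then tests each pair with t = (m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j)) on
    N - k degrees of freedom, two-sided, with no multiplicity correction.

    With all values identical within groups (MSE = 0) the comparison is
    degenerate: p = 1 for zero differences, p = 0 (flagged) otherwise.
    """
    data = _group_arrays(table, trait, groups, group_cols)
    if len(data) < 2:
        raise ValueError("LSD needs >=2 groups")
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has <2 replicates")
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in group {g!r}")

    k = len(data)
    n_total = sum(len(v) for v in data.values())
    df_err = n_total - k
    means = {g: v.mean() for g, v in data.items()}
    sse = sum(((v - means[g]) ** 2).sum() for g, v in data.items())
    mse = sse / df_err
    grand = np.concatenate(list(data.values())).mean()
    ssb = sum(len(v) * (means[g] - grand) ** 2 for g, v in data.items())
    msb = ssb / (k - 1)
    if mse > 0:
        f_stat = msb / mse
        f_p = float(stats.f.sf(f_stat, k - 1, df_err))
    else:
        f_stat = np.inf if msb > 0 else 0.0
        f_p = 0.0 if msb > 0 else 1.0

    rows = []
    for ga, gb in combinations(data, 2):
        na, nb = len(data[ga]), len(data[gb])
        diff = means[ga] - means[gb]
        if mse > 0:
            t = diff / np.sqrt(mse * (1.0 / na + 1.0 / nb))
            p = float(2.0 * stats.t.sf(abs(t), df_err))
            degenerate = False
        else:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
            p = 1.0 if diff == 0 else 0.0
            degenerate = diff != 0
        rows.append(
            {
                "group_a": ga, "group_b": gb,
                "mean_a": means[ga], "mean_b": means[gb],
                "diff": diff, "t": t, "p": p, "degenerate": degenerate,
            }
        )
    return LSDResult(
        trait=trait,
        pairs=pd.DataFrame(rows),
        group_means=pd.Series(means, name="mean"),
        mse=float(mse),
        df=df_err,
        f_stat=float(f_stat),
        f_p=float(f_p),
    )


def compact_letters(result: LSDResult, alpha: float = 0.05) -> dict[Hashable, str]:
    """Greedy compact letter display from the pairwise LSD p-matrix.

    Groups are scanned in descending-mean order; each group joins every
    existing letter whose members it does not differ from significantly,
    and opens a new letter if it joins none.  Ties in mean are broken by
    group key order for determinism.
    """
    p = {}
    for _, row in result.pairs.iterrows():
        p[frozenset((row["group_a"], row["group_b"]))] = row["p"]
    order = sorted(
        result.group_means.index,
        key=lambda g: (-result.group_means[g], str(g)),
    )
    letters: list[set[Hashable]] = []
    for g in order:
        joined = False
        for members in letters:
            if all(p[frozenset((g, m))] >= alpha for m in members):
                members.add(g)
                joined = True
        if not joined:
            letters.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[Hashable, str] = {g: "" for g in result.group_means.index}
    for letter, members in zip(alphabet, letters):
        for g in members:
            out[g] += letter
    return out


@dataclass
class TraitClass:
    """Weaken/strengthen/unclassified call with its supporting statistics."""

    trait: str
    label: str
    delta_ck: float
    delta_s: float
    lineage_p: float
    lsd: LSDResult


# P4 reaction-norm cells: (lineage, condition)
_P4_CELLS = [("P1CK", "CK"), ("P1CK", "S"), ("P1S", "CK"), ("P1S", "S")]


def classify_trait(
    table: pd.DataFrame, trait: str, alpha: float = 0.05
) -> TraitClass:
    """Classify one trait from its P4 reaction norm.

    With Delta_CK = mean(P1CK-P4S) - mean(P1CK-P4CK) and Delta_S =
    mean(P1S-P4S) - mean(P1S-P4CK), and L the LSD p-value of the
    P1CK-P4S vs P1S-P4S lineage contrast:

    * weaken:      Delta_CK < 0, Delta_S < 0, Delta_S > Delta_CK, L < alpha
    * strengthen:  Delta_CK > 0, Delta_S > 0, Delta_S > Delta_CK, L < alpha
    * otherwise unclassified (covers no-effect and inconsistent traits).
    """
    p4 = table[table["stage"] == "P4"]
    groups = [("P4",) + cell for cell in _P4_CELLS]
    lsd = lsd_test(p4, trait, groups=groups)
    m = lsd.group_means
    delta_ck = m[("P4", "P1CK", "S")] - m[("P4", "P1CK", "CK")]
    delta_s = m[("P4", "P1S", "S")] - m[("P4", "P1S", "CK")]
    lineage_p = lsd.p_for(("P4", "P1CK", "S"), ("P4", "P1S", "S"))

    label = "unclassified"
    if delta_s > delta_ck and lineage_p < alpha:
        if delta_ck < 0 and delta_s < 0:
            label = "weaken"
        elif delta_ck > 0 and delta_s > 0:
            label = "strengthen"
    return TraitClass(
        trait=trait,
        label=label,
        delta_ck=float(delta_ck),
        delta_s=float(delta_s),
        lineage_p=float(lineage_p),
        lsd=lsd,
    )


def classify_all_traits(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for trait in pd.unique(table["trait"]):
        tc = classify_trait(table, trait, alpha=alpha)
        rows.append(
            {
                "trait": trait,
                "label": tc.label,
                "delta_ck": tc.delta_ck,
                "delta_s": tc.delta_s,
                "lineage_p": tc.lineage_p,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control); returns 2**(-ddCt).
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    d = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-d))


def ddct_table(ct: pd.DataFrame, control_sample: str) -> pd.DataFrame:
    """Apply 2^-ddCt to a tidy Ct table.

    ``ct`` columns: sample, target_gene, ct_target, ct_reference;
    ``control_sample`` names the calibrator row per target gene.
    """
    out = []
    for gene, sub in ct.groupby("target_gene"):
        ctrl = sub[sub["sample"] == control_sample]
        if ctrl.empty:
            raise KeyError(f"control sample {control_sample!r} missing for {gene}")
        c = ctrl.iloc[0]
        for _, row in sub.iterrows():
            out.append(
                {
                    "sample": row["sample"],
                    "target_gene": gene,
                    "fold_change": ddct(
                        row["ct_target"], row["ct_reference"],
                        c["ct_target"], c["ct_reference"],
                    ),
                }
            )
    return pd.DataFrame(out)
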