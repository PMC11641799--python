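"""Three-step transcriptional-memory gene identification and pattern taxonomy.

A transcriptional memory gene responds to the stressor in P1, keeps the same
direction of differential expression after the stress is removed (P2, and
for the stronger class also P3), and responds again in the same direction on
re-exposure in P4.  The identification runs on ternary direction calls
(up/down/ns vs the P1 control) from the four contrasts:

1. robust responsive: same non-ns direction in P1 and P4;
2. TMG2: robust genes whose direction persists into P2;
3. TMG3: TMG2 genes whose direction also persists into P3.

The remaining genes fall into the descriptive taxonomy: transient (DE in
exactly one contrast), fluctuating (DE in two or more contrasts with
conflicting signs, not robust), or non-responsive.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import ContrastResult

__all__ = [
    "CONTRAST_ORDER",
    "LABELS",
    "build_direction_table",
    "robust_responsive",
    "identify_tmg2",
    "identify_tmg3",
    "classify_patterns",
]

CONTRAST_ORDER: tuple[str, ...] = ("P1", "P2", "P3", "P4")

LABELS: tuple[str, ...] = (
    "TMG3",
    "TMG2-only",
    "robust-responsive",
    "transient",
    "fluctuating",
    "non-responsive",
)

_DIRECTIONS = {"up", "down", "ns"}


def build_direction_table(
    results: Mapping[str, ContrastResult] | Sequence[ContrastResult],
) -> pd.DataFrame:
    """Assemble the per-gene direction tuple (d_P1..d_P4) from four contrasts.

    The gene universe is the intersection of genes tested in all four
    contrasts; genes missing from any contrast are excluded.
    """
    if not isinstance(results, Mapping):
        results = {r.name: r for r in results}
    missing = [c for c in CONTRAST_ORDER if c not in results]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    universe = None
    for c in CONTRAST_ORDER:
        idx = results[c].table.index
        universe = idx if universe is None else universe.intersection(idx)
    table = pd.DataFrame(
        {f"d_{c}": results[c].directions.reindex(universe) for c in CONTRAST_ORDER}
    )
    bad = ~table.isin(_DIRECTIONS).all(axis=1)
    if bad.any():
        raise ValueError("direction table contains values outside {up, down, ns}")
    return table


def _check_table(dirs: pd.DataFrame, needed: Sequence[str]) -> None:
    for c in needed:
        if f"d_{c}" not in dirs.columns:
            raise ValueError(f"direction table lacks contrast {c}")


def robust_responsive(dirs: pd.DataFrame) -> pd.Series:
    """Genes with the same non-ns direction in P1 and P4, with that sign."""
    _check_table(dirs, ("P1", "P4"))
    mask = (dirs["d_P1"] == dirs["d_P4"]) & (dirs["d_P1"] != "ns")
    return dirs.loc[mask, "d_P1"].rename("sign")


def identify_tmg2(dirs: pd.DataFrame) -> pd.Series:
    """Robust responsive genes whose direction persists into P2."""
    _check_table(dirs, ("P1", "P2", "P4"))
    robust = robust_responsive(dirs)
    keep = dirs.loc[robust.index, "d_P2"] == robust
    return robust[keep]


def identify_tmg3(dirs: pd.DataFrame) -> pd.Series:
    """TMG2 genes whose direction also persists into P3."""
    _check_table(dirs, CONTRAST_ORDER)
    tmg2 = identify_tmg2(dirs)
    keep = dirs.loc[tmg2.index, "d_P3"] == tmg2
    return tmg2[keep]


def classify_patterns(dirs: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene exactly one pattern label and a sign.

    Priority: TMG3 > TMG2-only > robust-responsive > transient > fluctuating
    > non-responsive.  Sign is the shared direction for memory/robust
    classes, the single direction for transient genes, "mixed" for
    fluctuating genes and "none" otherwise.
    """
    _check_table(dirs, CONTRAST_ORDER)
    cols = [f"d_{c}" for c in CONTRAST_ORDER]
    d = dirs[cols]

    robust = robust_responsive(dirs)
    tmg2 = identify_tmg2(dirs)
    tmg3 = identify_tmg3(dirs)

    n_up = (d == "up").sum(axis=1)
    n_down = (d == "down").sum(axis=1)
    n_de = n_up + n_down

    label = pd.Series("non-responsive", index=dirs.index, name="label")
    sign = pd.Series("none", index=dirs.index, name="sign")

    fluct = (n_de >= 2) & (n_up > 0) & (n_down > 0)
    label[fluct] = "fluctuating"
    sign[fluct] = "mixed"

    transient = n_de == 1
    label[transient] = "transient"
    sign[transient & (n_up == 1)] = "up"
    sign[transient & (n_down == 1)] = "down"

    label[robust.index] = "robust-responsive"
    sign[robust.index] = robust
    label[tmg2.index] = "TMG2-only"
    label[tmg3.index] = "TMG3"
    return pd.concat([label, sign, dirs[cols]], axis=1)
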