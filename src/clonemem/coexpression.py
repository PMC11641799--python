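"""Weighted co-expression network analysis on differentially expressed genes.

Implements the WGCNA-style workflow: per-gene standardization of expression,
soft-threshold selection by scale-free topology fit, unsigned adjacency
|cor|^beta, topological overlap, average-linkage module detection with
eigengene merging, module eigengenes, module-trait Pearson association,
top-weight edge filtering, per-module hub genes, and enrichment of
transcriptional-memory genes across module classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "standardize",
    "pick_soft_threshold",
    "topological_overlap",
    "CoexpressionNetwork",
    "build_network",
    "module_eigengenes",
    "module_trait_association",
    "classify_modules",
    "hub_genes",
    "tmg_module_enrichment",
]

#: module label palette, in assignment order (largest module first); "grey"
#: is reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
)


def standardize(
    expr: pd.DataFrame,
    log_transform: bool = True,
    max_missing_frac: float = 0.5,
    quantile_normalize: bool = False,
) -> pd.DataFrame:
    """Standardize a genes x samples expression matrix for network building.

    Applies log2(x + 1) (for non-negative abundance units such as FPKM),
    drops genes missing in more than ``max_missing_frac`` of samples or with
    zero variance, then z-scores each gene.  Remaining missing entries are
    left as NaN and handled pairwise by the correlation step.
    """
    if expr.shape[1] < 4:
        raise ValueError("need >=4 samples to standardize for network analysis")
    x = expr.astype(float)
    if quantile_normalize:
        ranks = x.rank(axis=0, method="average")
        means = np.sort(x.to_numpy(), axis=0)
        ref = np.nanmean(means, axis=1)
        x = ranks.apply(lambda col: np.interp(
            col, np.arange(1, len(ref) + 1), ref))
    if log_transform:
        if (x < 0).any().any():
            raise ValueError("log transform requires non-negative values")
        x = np.log2(x + 1.0)
    frac_missing = x.isna().mean(axis=1)
    x = x[frac_missing <= max_missing_frac]
    sd = x.std(axis=1, ddof=1)
    x = x[sd > 0]
    z = x.sub(x.mean(axis=1), axis=0).div(x.std(axis=1, ddof=1), axis=0)
    return z


def _abs_corr(z: pd.DataFrame) -> np.ndarray:
    arr = z.to_numpy()
    if np.isnan(arr).any():
        c = z.T.corr().to_numpy()  # pairwise-complete
    else:
        c = np.corrcoef(arr)
    c = np.clip(c, -1.0, 1.0)
    if not np.isfinite(c).all():
        raise ValueError("non-finite correlations; filter degenerate genes first")
    return c


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of log10 p(k) vs log10 k over equal-occupancy bins.

    Returns (signed_r2, slope); a scale-free network has a negative slope,
    reported as positive signed R^2 (WGCNA convention)."""
    k = k[k > 0]
    if len(k) < 2 * n_bins:
        raise ValueError("too few genes to bin the degree distribution")
    order = np.argsort(k)
    bins = np.array_split(order, n_bins)
    log_k = np.array([np.log10(k[b].mean()) for b in bins])
    dens = np.array([len(b) / len(k) for b in bins])
    widths = []
    edges = [k[bins[0]].min()] + [k[b].max() for b in bins]
    for i, b in enumerate(bins):
        widths.append(max(edges[i + 1] - edges[i], 1e-12))
    log_p = np.log10(dens / np.array(widths))
    slope, intercept, r, _, _ = stats.linregress(log_k, log_p)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(
    z: pd.DataFrame, powers: range | list[int] = range(1, 21)
) -> pd.DataFrame:
    """Scale-free topology fit index and connectivity per candidate power."""
    c = np.abs(_abs_corr(z))
    np.fill_diagonal(c, 0.0)
    rows = []
    for beta in powers:
        a = c**beta
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append(
            {
                "power": beta,
                "sft_r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
    return pd.DataFrame(rows).set_index("power")


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with unit diagonal; k_i excludes the diagonal, and the shared-
    neighbour sum runs over u != i, j.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < 0 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0  # (i,j) entry sums over u != i (a0_ii=0) and u != j
    num = shared + a0
    den = np.minimum.outer(k, k) + 1.0 - a0
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class CoexpressionNetwork:
    """A fitted co-expression network and its derived structures."""

    expr: pd.DataFrame            # standardized genes x samples
    power: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    modules: pd.Series            # gene -> color ("grey" = unassigned)
    eigengenes: pd.DataFrame      # samples x modules
    edges: pd.DataFrame           # filtered edge list: gene_a, gene_b, weight
    degree: pd.Series             # degree on the filtered graph
    hubs: dict[str, list[str]] = field(default_factory=dict)
    edge_fraction: float = 0.30
    hub_fraction: float = 0.10

    def module_sizes(self) -> pd.Series:
        return self.modules.value_counts()


def _cut_tree_static(
    link: np.ndarray, n_genes: int, min_module_size: int, n_heights: int = 200
) -> np.ndarray:
    """Static tree cut: scan heights downward from just below the top merge,
    keeping the height that yields the most clusters of at least
    ``min_module_size`` genes (ties resolved toward the higher cut)."""
    h_max = link[:, 2].max()
    best_labels, best_count = None, -1
    for frac in np.linspace(0.99, 0.05, n_heights):
        h = frac * h_max
        lab = fcluster(link, t=h, criterion="distance")
        sizes = np.bincount(lab)
        count = int((sizes[1:] >= min_module_size).sum())
        if count > best_count:
            best_count, best_labels = count, lab
    return best_labels


def module_eigengenes(z: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """First-principal-component eigengene of each module (samples x modules).

    Per module, the first right singular vector of the gene-centered module
    submatrix gives the per-sample scores, scaled to unit norm and
    sign-aligned to correlate positively with the module's average profile.
    Grey (unassigned) genes are excluded.
    """
    out = {}
    for mod in modules.unique():
        if mod == "grey":
            continue
        genes = modules.index[modules == mod]
        if len(genes) < 2:
            raise ValueError(f"module {mod!r} has fewer than 2 genes")
        sub = z.loc[genes].to_numpy()
        sub = sub - sub.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        avg = sub.mean(axis=0)
        if np.corrcoef(e, avg)[0, 1] < 0:
            e = -e
        out[mod] = e
    return pd.DataFrame(out, index=z.columns)


def _merge_similar_modules(
    z: pd.DataFrame, modules: pd.Series, merge_height: float
) -> pd.Series:
    """Iteratively merge the module pair with the most similar eigengenes
    while their eigengene correlation is >= 1 - merge_height."""
    modules = modules.copy()
    threshold = 1.0 - merge_height
    while True:
        mods = [m for m in modules.unique() if m != "grey"]
        if len(mods) < 2:
            return modules
        eg = module_eigengenes(z, modules)
        c = eg.corr()
        np.fill_diagonal(c.values, -np.inf)
        i, j = np.unravel_index(np.argmax(c.to_numpy()), c.shape)
        if c.iat[i, j] < threshold:
            return modules
        a, b = c.index[i], c.columns[j]
        keep, absorb = (a, b) if (modules == a).sum() >= (modules == b).sum() else (b, a)
        modules[modules == absorb] = keep
    return modules


def _filter_edges(
    weight: pd.DataFrame, edge_fraction: float
) -> tuple[pd.DataFrame, pd.Series]:
    genes = weight.index
    w = weight.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = w[iu, ju]
    n_keep = int(math.ceil(edge_fraction * len(vals)))
    order = np.argsort(-vals, kind="stable")[:n_keep]
    edges = pd.DataFrame(
        {
            "gene_a": genes[iu[order]],
            "gene_b": genes[ju[order]],
            "weight": vals[order],
        }
    )
    degree = pd.Series(0, index=genes, dtype=int)
    counts_a = edges["gene_a"].value_counts()
    counts_b = edges["gene_b"].value_counts()
    degree = degree.add(counts_a, fill_value=0).add(counts_b, fill_value=0).astype(int)
    return edges, degree


def build_network(
    z: pd.DataFrame,
    power: float = 20.0,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    edge_fraction: float = 0.30,
    hub_fraction: float = 0.10,
    edge_weight: str = "tom",
) -> CoexpressionNetwork:
    """Construct the unsigned weighted network and detect modules.

    Adjacency is |PCC|^power; modules come from average-linkage clustering
    of the TOM dissimilarity with a static height cut (>= min_module_size,
    smaller clusters -> grey) followed by eigengene merging at
    ``1 - merge_height``.  The edge list keeps the top ``edge_fraction`` of
    pairs ranked by ``edge_weight`` ("tom" or "adjacency"); hubs are the top
    ``hub_fraction`` of each module by degree on that filtered graph.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    genes = z.index
    c = _abs_corr(z)
    a = np.abs(c) ** power
    np.fill_diagonal(a, 1.0)
    tom = topological_overlap(a)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    link = linkage(squareform(dissim, checks=False), method="average")
    raw_labels = _cut_tree_static(link, len(genes), min_module_size)

    modules = pd.Series("grey", index=genes, name="module", dtype=object)
    sizes = pd.Series(raw_labels).value_counts()
    kept = [lab for lab, n in sizes.items() if n >= min_module_size]
    # name modules by size rank for stable, WGCNA-style color labels
    for color, lab in zip(MODULE_COLORS, kept):
        modules[raw_labels == lab] = color
    if len(kept) > len(MODULE_COLORS):
        for extra, lab in enumerate(kept[len(MODULE_COLORS):]):
            modules[raw_labels == lab] = f"module{extra + len(MODULE_COLORS)}"

    if (modules != "grey").any():
        modules = _merge_similar_modules(z, modules, merge_height)
        eigengenes = module_eigengenes(z, modules)
    else:
        eigengenes = pd.DataFrame(index=z.columns)

    weight_df = pd.DataFrame(
        tom if edge_weight == "tom" else a, index=genes, columns=genes
    )
    edges, degree = _filter_edges(weight_df, edge_fraction)
    net = CoexpressionNetwork(
        expr=z,
        power=power,
        adjacency=pd.DataFrame(a, index=genes, columns=genes),
        tom=pd.DataFrame(tom, index=genes, columns=genes),
        modules=modules,
        eigengenes=eigengenes,
        edges=edges,
        degree=degree,
        edge_fraction=edge_fraction,
        hub_fraction=hub_fraction,
    )
    net.hubs = hub_genes(net)
    return net


def hub_genes(net: CoexpressionNetwork) -> dict[str, list[str]]:
    """Top ceil(hub_fraction x size) genes per module by filtered-graph degree.

    Ties are broken by total incident edge weight, then lexicographic id.
    """
    incident = pd.Series(0.0, index=net.modules.index)
    for col in ("gene_a", "gene_b"):
        w = net.edges.groupby(col)["weight"].sum()
        incident = incident.add(w, fill_value=0.0)
    hubs: dict[str, list[str]] = {}
    for mod in net.modules.unique():
        if mod == "grey":
            continue
        genes = list(net.modules.index[net.modules == mod])
        if not genes:
            raise ValueError(f"empty module {mod!r}")
        n_hub = math.ceil(net.hub_fraction * len(genes))
        ranked = sorted(
            genes,
            key=lambda g: (-net.degree.get(g, 0), -incident.get(g, 0.0), g),
        )
        hubs[mod] = ranked[:n_hub]
    return hubs


def corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t approximation."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def module_trait_association(
    eigengenes: pd.DataFrame,
    traits_per_sample: pd.DataFrame,
    pcc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson association of each module eigengene with each trait.

    ``traits_per_sample`` is samples x traits on the same sample index as
    the eigengenes (the pipeline maps replicate trait group means onto RNA
    samples).  Significance flag: PCC > pcc_threshold and p < alpha.
    """
    if not eigengenes.index.equals(traits_per_sample.index):
        missing = traits_per_sample.index.symmetric_difference(eigengenes.index)
        raise ValueError(f"trait values missing for samples: {list(missing)}")
    n = len(eigengenes)
    rows = []
    for mod in eigengenes.columns:
        for trait in traits_per_sample.columns:
            r = float(np.corrcoef(
                eigengenes[mod], traits_per_sample[trait])[0, 1])
            p = float(corr_pvalue(np.array([r]), n)[0])
            rows.append(
                {
                    "module": mod,
                    "trait": trait,
                    "pcc": r,
                    "p": p,
                    "significant": (r > pcc_threshold) and (p < alpha),
                }
            )
    return pd.DataFrame(rows)


def classify_modules(
    association: pd.DataFrame, trait_classes: pd.Series
) -> pd.Series:
    """Label modules weaken-related / strengthen-related / other.

    A module is weaken-related if significantly associated with at least one
    weaken trait (strengthen likewise); a module significant for both sides
    takes the class of its largest |PCC| association.
    """
    labels = {}
    for mod, sub in association.groupby("module"):
        sig = sub[sub["significant"]].copy()
        if sig.empty:
            labels[mod] = "other"
            continue
        sig["trait_class"] = sig["trait"].map(trait_classes)
        sig = sig[sig["trait_class"].isin(["weaken", "strengthen"])]
        if sig.empty:
            labels[mod] = "other"
            continue
        best = sig.loc[sig["pcc"].abs().idxmax()]
        labels[mod] = f"{best['trait_class']}-related"
    return pd.Series(labels, name="module_class")


def tmg_module_enrichment(
    modules: pd.Series,
    module_classes: pd.Series,
    memory_labels: pd.Series,
) -> dict:
    """TMG share of each module class, with a Fisher exact test.

    The TMG set is TMG2 in the inclusive sense (labels TMG3 or TMG2-only).
    The 2x2 test contrasts trait-related module genes (weaken- plus
    strengthen-related) against other module genes, TMG vs not.
    """
    common = modules.index.intersection(memory_labels.index)
    modules = modules.loc[common]
    is_tmg = memory_labels.loc[common].isin(["TMG3", "TMG2-only"])
    gene_class = modules.map(module_classes).fillna("other")

    if len(common) == 0:
        raise ValueError("module assignment and memory labels share no genes")
    fractions = {}
    counts = {}
    for cls in ("weaken-related", "strengthen-related", "other"):
        genes = gene_class == cls
        n = int(genes.sum())
        n_tmg = int((genes & is_tmg).sum())
        fractions[cls] = n_tmg / n if n else float("nan")
        counts[cls] = {"n_genes": n, "n_tmg": n_tmg}

    related = gene_class.isin(["weaken-related", "strengthen-related"])
    table = [
        [int((related & is_tmg).sum()), int((related & ~is_tmg).sum())],
        [int((~related & is_tmg).sum()), int((~related & ~is_tmg).sum())],
    ]
    _, p = stats.fisher_exact(table)
    return {
        "fractions": fractions,
        "counts": counts,
        "fisher_table": table,
        "fisher_p": float(p),
    }
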