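"""Signed weighted SNP interaction network and module detection.

The pairwise interaction coefficients are normalized to [-1, 1], passed
through the signed soft-threshold transform ``((1 + s) / 2) ** power`` and
combined into a topological overlap similarity.  Modules come from
average-linkage hierarchical clustering of the TOM dissimilarity with a
deterministic adaptive branch cut; small or incoherent clusters fall into
the unassigned "grey" bin.  Modules are summarized per sample by their
eigenSNP (first principal component of the standardized genotype
submatrix) and per SNP by soft connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import MISSING
from .genotype_io import GenotypeMatrix
from .epistasis_scan import STATUS_OK

GREY = "grey"

# conventional module color sequence, largest module first
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


@dataclass
class AdjacencyMatrix:
    values: np.ndarray
    power_beta: int
    normalization_constant: float

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("adjacency must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        np.fill_diagonal(self.values, 0.0)


@dataclass
class ModulePartition:
    snp_ids: list[str]
    assignment: dict[str, str]
    linkage: np.ndarray | None = None
    min_module_size: int = 30
    cut_info: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return [self.assignment[s] for s in self.snp_ids]

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.assignment.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def modules(self) -> list[str]:
        """Module labels except grey, largest first."""
        sizes = self.module_sizes()
        return sorted(
            (m for m in sizes if m != GREY), key=lambda m: (-sizes[m], m)
        )

    def members(self, module: str) -> list[str]:
        return [s for s in self.snp_ids if self.assignment[s] == module]


@dataclass
class EigenSNPSet:
    """Per-module eigenSNP vectors (length n_samples, SD 1, mean 0)."""

    sample_ids: list[str]
    vectors: dict[str, np.ndarray]
    variance_explained: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=self.sample_ids)


# ---------------------------------------------------------------------------


def signed_adjacency(
    beta3_matrix: np.ndarray,
    power_beta: int,
    status_matrix: np.ndarray | None = None,
    clip_quantile: float | None = None,
) -> AdjacencyMatrix:
    """Signed soft-threshold adjacency from an interaction matrix.

    Coefficients are scaled by the largest absolute off-diagonal value so
    the similarity s lies in [-1, 1]; failed cells get s = 0.  With
    ``clip_quantile`` the normalization constant is that quantile of the
    |coefficient| distribution instead of the maximum (values beyond it are
    clipped), which keeps a few wild estimates from flattening the scale.
    """
    if power_beta < 1:
        raise ValueError("power_beta must be >= 1")
    b = np.asarray(beta3_matrix, dtype=float).copy()
    if not np.allclose(b, b.T, equal_nan=True):
        raise ValueError("beta3 matrix must be symmetric")
    off = ~np.eye(b.shape[0], dtype=bool)
    ok = off if status_matrix is None else (np.asarray(status_matrix) == STATUS_OK) & off
    b[~ok] = 0.0
    if not ok.any():
        raise ValueError("no interaction signal: all usable coefficients are zero")
    mags = np.abs(b[ok])
    norm = float(
        np.max(mags) if clip_quantile is None else np.quantile(mags, clip_quantile)
    )
    if norm == 0.0:
        raise ValueError("no interaction signal: all usable coefficients are zero")
    s = np.clip(b / norm, -1.0, 1.0)
    a = ((1.0 + s) / 2.0) ** power_beta
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(a, power_beta, norm)


def scale_free_fit_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) on log10 k over connectivity bins."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / k.size)
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_power(
    beta3_matrix: np.ndarray,
    candidate_powers: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.8,
    status_matrix: np.ndarray | None = None,
) -> int:
    """Smallest soft-threshold power reaching the scale-free fit target.

    Falls back to 12 with a warning when no candidate qualifies.
    """
    for power in sorted(candidate_powers):
        adj = signed_adjacency(beta3_matrix, power, status_matrix)
        k = adj.values.sum(axis=1)
        if scale_free_fit_r2(k) >= target_r2:
            return power
    warnings.warn(
        f"no candidate power reached scale-free fit R^2 >= {target_r2}; "
        "falling back to 12"
    )
    return 12


def tom_similarity(adjacency: AdjacencyMatrix) -> np.ndarray:
    """Topological overlap similarity; diagonal 1."""
    a = adjacency.values
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj (diagonal of a is 0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _harvest_branches(
    linkage: np.ndarray,
    dissim: np.ndarray,
    min_module_size: int,
    alpha: float,
) -> list[list[int]]:
    """Top-down branch harvesting on an average-linkage tree.

    A branch is accepted as a module when its mean internal dissimilarity is
    clearly below the matrix-wide mean (factor ``alpha``) *and* its two
    children are not separated at background level — otherwise the walk
    descends, so a branch gluing two genuine modules (or a module plus
    scattered background) is split rather than accepted.  Leaves that end up
    in no accepted branch stay unassigned.
    """
    n = dissim.shape[0]
    overall = float(dissim[np.triu_indices(n, k=1)].mean())
    threshold = alpha * overall + 1e-12

    # bottom-up: leaf sets, within-branch pair sums, child-cross means
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    within_sum = [0.0] * n
    pair_count = [0] * n
    cross_mean = [0.0] * n
    children: list[tuple[int, int]] = [(-1, -1)] * n
    for k in range(linkage.shape[0]):
        left, right = int(linkage[k, 0]), int(linkage[k, 1])
        li, ri = members[left], members[right]
        cross = float(dissim[np.ix_(li, ri)].sum())
        members.append(np.concatenate([li, ri]))
        within_sum.append(within_sum[left] + within_sum[right] + cross)
        pair_count.append(pair_count[left] + pair_count[right] + li.size * ri.size)
        cross_mean.append(cross / (li.size * ri.size))
        children.append((left, right))

    modules: list[list[int]] = []
    stack = [len(members) - 1]  # root
    while stack:
        node = stack.pop()
        idx = members[node]
        if idx.size < min_module_size:
            continue
        within = within_sum[node] / pair_count[node]
        if within <= threshold and cross_mean[node] <= threshold:
            modules.append(sorted(int(i) for i in idx))
            continue
        left, right = children[node]
        if left >= 0:
            stack.extend((left, right))
    return modules


def cluster_and_cut(
    tom_dissimilarity: np.ndarray,
    min_module_size: int = 30,
    cohesion_alpha: float = 0.95,
    snp_ids: list[str] | None = None,
) -> ModulePartition:
    """Average-linkage clustering with a deterministic adaptive branch cut.

    The dendrogram is walked top-down and cohesive branches are harvested
    as modules (see ``_harvest_branches``); branches smaller than
    ``min_module_size`` and incoherent background go to grey.  Module
    labels follow the conventional color sequence, largest module first.
    """
    d = np.asarray(tom_dissimilarity, dtype=float)
    n = d.shape[0]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(n)]
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    if n < min_module_size:
        warnings.warn("fewer SNPs than min_module_size; all grey")
        return ModulePartition(snp_ids, {s: GREY for s in snp_ids}, None,
                               min_module_size)
    dsym = 0.5 * (d + d.T)
    np.fill_diagonal(dsym, 0.0)
    condensed = squareform(dsym, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")

    if float(linkage[:, 2].max()) <= 1e-12:  # everything identical
        return ModulePartition(
            snp_ids, {s: MODULE_COLORS[0] for s in snp_ids}, linkage,
            min_module_size, {"cut": 0.0, "rule": "degenerate"},
        )

    harvested = _harvest_branches(linkage, dsym, min_module_size, cohesion_alpha)
    kept = sorted(
        [(i, idx) for i, idx in enumerate(harvested)],
        key=lambda t: (-len(t[1]), t[1][0]),
    )

    assignment = {s: GREY for s in snp_ids}
    for rank, (_lab, idx) in enumerate(kept):
        color = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        for i in idx:
            assignment[snp_ids[i]] = color
    return ModulePartition(
        snp_ids, assignment, linkage, min_module_size,
        {"rule": "branch-harvest", "alpha": cohesion_alpha,
         "overall_dissim": float(condensed.mean())},
    )


# ---------------------------------------------------------------------------
# eigenSNPs


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries, then z-score columns (ddof=1).

    Zero-variance columns are dropped with a warning.
    """
    x = np.asarray(values, dtype=float).copy()
    x[x == MISSING] = np.nan
    means = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(means, inds[1])
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    x = x[:, keep]
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def eigen_snp(module_values: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component across samples of a module's genotypes.

    Returns the eigenSNP (mean 0, SD 1 with ddof=1) and the fraction of
    standardized-genotype variance it explains.  The sign is anchored so the
    eigenSNP correlates non-negatively with the mean standardized genotype.
    """
    z = _standardize_columns(module_values)
    if z.shape[1] < 1 or z.shape[0] < 3:
        raise ValueError("module needs >= 1 usable SNP and >= 3 samples")
    u, svals, _vt = np.linalg.svd(z, full_matrices=False)
    vec = u[:, 0]
    var_explained = float(svals[0] ** 2 / np.sum(svals**2))
    anchor = z.mean(axis=1)
    if float(vec @ anchor) < 0:
        vec = -vec
    vec = vec - vec.mean()
    sd = vec.std(ddof=1)
    if sd > 0:
        vec = vec / sd
    return vec, var_explained


def compute_eigen_snps(
    gm: GenotypeMatrix, partition: ModulePartition
) -> EigenSNPSet:
    vectors: dict[str, np.ndarray] = {}
    variance: dict[str, float] = {}
    ids = gm.snp_ids
    col_of = {s: j for j, s in enumerate(ids)}
    for module in partition.modules():
        cols = [col_of[s] for s in partition.members(module) if s in col_of]
        if len(cols) < 2:
            continue
        vec, ve = eigen_snp(gm.values[:, cols])
        vectors[module] = vec
        variance[module] = ve
    return EigenSNPSet(list(gm.sample_ids), vectors, variance)


def merge_close_modules(
    partition: ModulePartition,
    gm: GenotypeMatrix,
    cut_height: float = 0.25,
) -> tuple[ModulePartition, EigenSNPSet]:
    """Iteratively merge module pairs with eigenSNP correlation >= 1 - height.

    EigenSNPs are recomputed after every merge until no pair qualifies; the
    merged module keeps the larger member's label.
    """
    assignment = dict(partition.assignment)
    while True:
        part = ModulePartition(partition.snp_ids, assignment, partition.linkage,
                               partition.min_module_size, partition.cut_info)
        eigen = compute_eigen_snps(gm, part)
        mods = [m for m in part.modules() if m in eigen.vectors]
        if len(mods) < 2:
            return part, eigen
        best: tuple[float, str, str] | None = None
        for a_i in range(len(mods) - 1):
            for b_i in range(a_i + 1, len(mods)):
                a, b = mods[a_i], mods[b_i]
                r = float(np.corrcoef(eigen.vectors[a], eigen.vectors[b])[0, 1])
                if r >= 1.0 - cut_height and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            return part, eigen
        _, a, b = best
        sizes = part.module_sizes()
        winner, loser = (a, b) if sizes[a] >= sizes[b] else (b, a)
        for s, lab in assignment.items():
            if lab == loser:
                assignment[s] = winner


def soft_connectivity(
    adjacency: AdjacencyMatrix, partition: ModulePartition | None = None
) -> pd.DataFrame:
    """Per-SNP sum of adjacencies, sorted descending within module."""
    k = adjacency.values.sum(axis=1)
    n = k.size
    snp_ids = partition.snp_ids if partition is not None else [f"snp{i}" for i in range(n)]
    modules = (
        [partition.assignment[s] for s in snp_ids]
        if partition is not None
        else [GREY] * n
    )
    df = pd.DataFrame({"snp_id": snp_ids, "module": modules, "connectivity": k})
    return df.sort_values(
        ["module", "connectivity", "snp_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def dendrogram_newick(partition: ModulePartition) -> str:
    """Newick serialization of the clustering tree (branch lengths = heights)."""
    if partition.linkage is None:
        raise ValueError("partition carries no dendrogram")
    tree = hierarchy.to_tree(partition.linkage)
    ids = partition.snp_ids

    def walk(node) -> str:
        if node.is_leaf():
            return ids[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - (node.left.dist if not node.left.is_leaf() else 0.0)
        dr = node.dist - (node.right.dist if not node.right.is_leaf() else 0.0)
        return f"({left}:{max(dl, 0.0):.6g},{right}:{max(dr, 0.0):.6g})"

    return walk(tree) + ";"
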