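"""Module eigenSNP <-> trait association, module selection and hub tables."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .snp_network import GREY, EigenSNPSet, ModulePartition


def module_trait_correlation(
    eigen_set: EigenSNPSet,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each module eigenSNP with each trait column.

    Two-sided t-test with df = n - 2; Bonferroni adjustment across all
    module x trait cells.
    """
    rows = []
    modules = sorted(eigen_set.vectors)
    trait_names = list(traits.columns)
    for module in modules:
        vec = eigen_set.vectors[module]
        for trait in trait_names:
            y = traits[trait].to_numpy(dtype=float)
            mask = np.isfinite(y) & np.isfinite(vec)
            x, yy = vec[mask], y[mask]
            n = x.size
            if n < 4:
                raise ValueError(f"fewer than 4 complete samples for {module}/{trait}")
            if np.ptp(yy) == 0:
                raise ValueError(f"zero-variance trait {trait!r}")
            r, p = stats.pearsonr(x, yy)
            rows.append((module, trait, float(r), float(max(p, 1e-300)), n))
    df = pd.DataFrame(rows, columns=["module", "trait", "r", "p", "n"])
    n_tests = len(df)
    df["p_adj"] = np.minimum(df["p"] * n_tests, 1.0)
    return df


def select_significant_modules(
    result: pd.DataFrame,
    r_min: float = 0.4,
    p_max: float = 0.05,
    top_n: int | None = 3,
) -> list[str]:
    """Modules with |r| > r_min and p <= p_max for at least one trait.

    If ``top_n`` is given, only the top_n modules by smallest qualifying p
    survive.  Grey is never selectable.
    """
    hits = result[
        (result["r"].abs() > r_min)
        & (result["p"] <= p_max)
        & (result["module"] != GREY)
    ]
    if hits.empty:
        return []
    best = hits.groupby("module")["p"].min().sort_values(kind="mergesort")
    modules = list(best.index)
    if top_n is not None:
        modules = modules[:top_n]
    return modules


def extract_hub_snps(
    selected_modules: list[str],
    partition: ModulePartition,
    connectivity: pd.DataFrame,
    gm: GenotypeMatrix,
    module_traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All member SNPs of the selected modules with their connectivity.

    Rows are sorted by descending connectivity within module; row count is
    exactly the sum of selected-module sizes.
    """
    if not selected_modules:
        warnings.warn("no modules selected; hub table is empty")
        return pd.DataFrame(
            columns=["snp_id", "module", "traits", "connectivity", "chrom", "pos"]
        )
    kmap = dict(zip(connectivity["snp_id"], connectivity["connectivity"]))
    meta = {s.snp_id: (s.chrom, s.pos_bp) for s in gm.snps}
    trait_map: dict[str, str] = {}
    if module_traits is not None:
        for module in selected_modules:
            sub = module_traits[module_traits["module"] == module]
            trait_map[module] = ",".join(sorted(sub["trait"].unique()))
    rows = []
    for module in selected_modules:
        for snp in partition.members(module):
            chrom, pos = meta.get(snp, ("NA", -1))
            rows.append(
                (snp, module, trait_map.get(module, ""), kmap.get(snp, 0.0),
                 chrom, pos)
            )
    df = pd.DataFrame(
        rows, columns=["snp_id", "module", "traits", "connectivity", "chrom", "pos"]
    )
    return (
        df.sort_values(["module", "connectivity", "snp_id"],
                       ascending=[True, False, True])
        .reset_index(drop=True)
    )


def write_module_trait(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_hub_table(hub: pd.DataFrame, path: str | Path) -> None:
    hub.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_module_trait_heatmap(result: pd.DataFrame, path: str | Path) -> None:
    """Module x trait correlation heatmap (matplotlib optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = result.pivot(index="module", columns="trait", values="r")
    pvals = result.pivot(index="module", columns="trait", values="p")
    fig, ax = plt.subplots(figsize=(4 + pivot.shape[1], 1 + 0.4 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), cmap="RdYlGn_r", vmin=-1, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            ax.text(j, i, f"{pivot.iat[i, j]:.2f}\n({pvals.iat[i, j]:.2g})",
                    ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
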