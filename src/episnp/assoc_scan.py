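"""Single-SNP quantitative-trait association and top-K selection.

Each SNP is tested by OLS of the trait on the 0/1/2 genotype with an
intercept; the reported p-value is the two-sided t-test on the slope.
Missing genotypes are dropped per SNP (complete-case).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import MISSING
from .genotype_io import GenotypeMatrix


@dataclass
class AssocResult:
    snp_id: str
    beta: float
    se: float
    t_stat: float
    p: float
    n_used: int
    testable: bool = True


def single_snp_assoc(
    genotype_column: np.ndarray, trait: np.ndarray, snp_id: str = ""
) -> AssocResult:
    """OLS slope t-test of trait on one coded genotype column.

    A constant genotype (or fewer than 3 complete cases) yields a flagged
    untestable result with p = 1 rather than an exception.
    """
    g = np.asarray(genotype_column, dtype=float)
    y = np.asarray(trait, dtype=float)
    mask = (g != MISSING) & np.isfinite(y)
    g, y = g[mask], y[mask]
    n = g.size
    if n < 3 or np.ptp(g) == 0:
        return AssocResult(snp_id, np.nan, np.nan, 0.0, 1.0, n, testable=False)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = float(gc @ gc)
    beta = float(gc @ yc) / sxx
    resid = yc - beta * gc
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = float(2 * stats.t.sf(abs(t), df))
    return AssocResult(snp_id, beta, se, float(t), max(p, np.finfo(float).tiny), n)


def assoc_scan(gm: GenotypeMatrix, trait: np.ndarray) -> pd.DataFrame:
    """Run single_snp_assoc over every column; returns a tidy frame."""
    trait = np.asarray(trait, dtype=float)
    if trait.size != gm.n_samples:
        raise ValueError("trait length does not match sample count")
    rows = []
    for j, rec in enumerate(gm.snps):
        r = single_snp_assoc(gm.values[:, j], trait, rec.snp_id)
        rows.append(
            (rec.snp_id, rec.chrom, rec.pos_bp, r.beta, r.se, r.t_stat, r.p,
             r.n_used, r.testable)
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "beta", "se", "t", "p", "n", "testable"],
    )


def select_top_k(results: pd.DataFrame, k: int = 7000) -> list[str]:
    """Return the k most associated SNP ids.

    Ranking: testable first, then ascending p, ties by descending |t| then
    snp_id.  The returned list preserves the input (genome) order so that a
    matrix subset keeps its positional sorting.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = results.copy()
    df["_abs_t"] = df["t"].abs().fillna(0.0)
    ranked = df.sort_values(
        by=["testable", "p", "_abs_t", "snp_id"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    chosen = set(ranked["snp_id"].head(k))
    return [s for s in results["snp_id"] if s in chosen]


def write_assoc(results: pd.DataFrame, path: str | Path) -> None:
    results.drop(columns=["testable"], errors="ignore").to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
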