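"""Exhaustive pairwise SNP-SNP interaction regression.

Every unordered SNP pair (i, j) is fitted by OLS on the design
``[1, g_i, g_j, g_i * g_j]``; the interaction coefficient (beta3) is tested
two-sided against zero with ``df = n - 4``.  Missing genotypes are dropped
per pair (complete-case).  The all-pairs scanner batches the normal
equations so that a chromosome-scale scan stays in vectorized numpy, and is
required to agree elementwise with the per-pair fitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import MISSING
from .genotype_io import GenotypeMatrix

STATUS_OK = 0
STATUS_COLLINEAR = 1
STATUS_INSUFFICIENT = 2
STATUS_NAMES = {STATUS_OK: "ok", STATUS_COLLINEAR: "collinear",
                STATUS_INSUFFICIENT: "insufficient"}

_COND_MAX = 1e10  # condition-number cutoff for a usable normal matrix
_MIN_CASES = 5


@dataclass
class PairModelFit:
    snp_i: str
    snp_j: str
    mu: float
    beta1: float
    beta2: float
    beta3: float
    se3: float
    t3: float
    p3: float
    n_used: int
    status: str


@dataclass
class EpistasisResult:
    """Symmetric beta3 / p-value / status matrices over a SNP set.

    Diagonal convention: beta3 = 0, p3 = 1 (self-interaction undefined).
    """

    snp_order: list[str]
    beta3: np.ndarray
    p3: np.ndarray
    status: np.ndarray

    def ok_mask(self) -> np.ndarray:
        mask = self.status == STATUS_OK
        np.fill_diagonal(mask, False)
        return mask

    def to_pair_frame(self) -> pd.DataFrame:
        n = len(self.snp_order)
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "snp_i": np.asarray(self.snp_order, dtype=object)[iu[0]],
                "snp_j": np.asarray(self.snp_order, dtype=object)[iu[1]],
                "beta3": self.beta3[iu],
                "p3": self.p3[iu],
                "status": [STATUS_NAMES[s] for s in self.status[iu]],
            }
        )

    def write_pairs(self, path: str | Path) -> None:
        self.to_pair_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def _p_from_t(t: float, df: int) -> float:
    if not np.isfinite(t):
        return float(np.finfo(float).tiny)
    return float(max(2 * stats.t.sf(abs(t), df), np.finfo(float).tiny))


def fit_pair_model(
    col_i: np.ndarray,
    col_j: np.ndarray,
    trait: np.ndarray,
    snp_i: str = "i",
    snp_j: str = "j",
) -> PairModelFit:
    """Fit the four-parameter interaction model to one SNP pair."""
    gi = np.asarray(col_i, dtype=float)
    gj = np.asarray(col_j, dtype=float)
    y = np.asarray(trait, dtype=float)
    mask = (gi != MISSING) & (gj != MISSING) & np.isfinite(y)
    gi, gj, y = gi[mask], gj[mask], y[mask]
    n = gi.size
    nan = float("nan")
    if n < _MIN_CASES:
        return PairModelFit(snp_i, snp_j, nan, nan, nan, nan, nan, nan, nan, n,
                            "insufficient")
    X = np.column_stack([np.ones(n), gi, gj, gi * gj])
    xtx = X.T @ X
    if np.linalg.cond(xtx) > _COND_MAX:
        return PairModelFit(snp_i, snp_j, nan, nan, nan, nan, nan, nan, nan, n,
                            "collinear")
    xty = X.T @ y
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    resid = y - X @ beta
    df = n - 4
    sigma2 = max(float(resid @ resid) / df, 0.0)
    se3 = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    t3 = beta[3] / se3 if se3 > 0 else (np.inf if beta[3] != 0 else 0.0)
    p3 = _p_from_t(t3, df) if se3 > 0 or beta[3] != 0 else 1.0
    return PairModelFit(
        snp_i, snp_j, float(beta[0]), float(beta[1]), float(beta[2]),
        float(beta[3]), se3, float(t3), p3, n, "ok",
    )


def scan_all_pairs(gm: GenotypeMatrix, trait: np.ndarray) -> EpistasisResult:
    """Fit the interaction model for every unordered SNP pair.

    Batches the per-pair normal equations: for each anchor SNP i the
    cross-moment sums against all j > i come from masked matrix-vector
    products, giving one stacked 4x4 solve per anchor.
    """
    if gm.n_snps < 2:
        raise ValueError("need at least two SNPs to scan pairs")
    y = np.asarray(trait, dtype=float)
    if y.size != gm.n_samples:
        raise ValueError("trait length does not match sample count")

    obs = (gm.values != MISSING) & np.isfinite(y)[:, None]
    G = np.where(obs, gm.values, 0).astype(float)
    G2 = G * G
    Mf = obs.astype(float)
    p = gm.n_snps

    beta3 = np.zeros((p, p))
    p3 = np.ones((p, p))
    status = np.full((p, p), STATUS_OK, dtype=np.int8)
    np.fill_diagonal(status, STATUS_INSUFFICIENT)

    for i in range(p - 1):
        mi = Mf[:, i]
        ai = G[:, i]          # already zeroed where unobserved
        a2i = G2[:, i]
        cols = slice(i + 1, p)
        Mj, Aj, A2j = Mf[:, cols], G[:, cols], G2[:, cols]

        n_u = mi @ Mj
        s_i = ai @ Mj
        s_j = mi @ Aj
        s_ii = a2i @ Mj
        s_jj = mi @ A2j
        s_ij = ai @ Aj
        s_iij = a2i @ Aj
        s_ijj = ai @ A2j
        s_iijj = a2i @ A2j
        sy = (y * mi) @ Mj
        s_iy = (y * ai) @ Mj
        s_jy = (y * mi) @ Aj
        s_ijy = (y * ai) @ Aj
        yy = (y * y * mi) @ Mj

        m = n_u.size
        xtx = np.empty((m, 4, 4))
        xtx[:, 0, 0] = n_u
        xtx[:, 0, 1] = xtx[:, 1, 0] = s_i
        xtx[:, 0, 2] = xtx[:, 2, 0] = s_j
        xtx[:, 0, 3] = xtx[:, 3, 0] = s_ij
        xtx[:, 1, 1] = s_ii
        xtx[:, 1, 2] = xtx[:, 2, 1] = s_ij
        xtx[:, 1, 3] = xtx[:, 3, 1] = s_iij
        xtx[:, 2, 2] = s_jj
        xtx[:, 2, 3] = xtx[:, 3, 2] = s_ijj
        xtx[:, 3, 3] = s_iijj
        xty = np.stack([sy, s_iy, s_jy, s_ijy], axis=1)

        enough = n_u >= _MIN_CASES
        usable = enough.copy()
        if usable.any():
            conds = np.linalg.cond(xtx[usable])
            good = np.isfinite(conds) & (conds <= _COND_MAX)
            idx = np.flatnonzero(usable)
            usable[idx[~good]] = False

        row_beta3 = np.zeros(m)
        row_p3 = np.ones(m)
        row_status = np.where(enough, STATUS_COLLINEAR, STATUS_INSUFFICIENT)
        if usable.any():
            inv = np.linalg.inv(xtx[usable])
            beta = np.einsum("kab,kb->ka", inv, xty[usable])
            rss = yy[usable] - np.einsum("ka,ka->k", beta, xty[usable])
            df = n_u[usable] - 4
            sigma2 = np.maximum(rss, 0.0) / df
            se3 = np.sqrt(sigma2 * inv[:, 3, 3])
            b3 = beta[:, 3]
            with np.errstate(divide="ignore", invalid="ignore"):
                t3 = np.where(se3 > 0, b3 / np.where(se3 > 0, se3, 1.0), np.inf)
            pvals = 2 * stats.t.sf(np.abs(t3), df)
            pvals = np.where(se3 > 0, pvals, np.where(b3 != 0, 0.0, 1.0))
            pvals = np.maximum(pvals, np.finfo(float).tiny)
            row_beta3[usable] = b3
            row_p3[usable] = pvals
            row_status[usable] = STATUS_OK

        beta3[i, i + 1:] = beta3[i + 1:, i] = row_beta3
        p3[i, i + 1:] = p3[i + 1:, i] = row_p3
        status[i, i + 1:] = status[i + 1:, i] = row_status

    return EpistasisResult(gm.snp_ids, beta3, p3, status)


def chrom_pair_overview(
    result: EpistasisResult, gm: GenotypeMatrix, q: float = 0.9
) -> pd.DataFrame:
    """Chromosome-pair matrix of q-quantiles of -log10(p3).

    Quantiles use linear interpolation (numpy's default, type-7); cells with
    no testable pairs are NaN.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    chroms = [s.chrom for s in gm.snps]
    uniq = sorted(set(chroms), key=lambda c: (len(c), c))
    cidx = {c: k for k, c in enumerate(uniq)}
    nc = len(uniq)
    buckets: list[list[list[float]]] = [[[] for _ in range(nc)] for _ in range(nc)]
    ok = result.ok_mask()
    neglog = -np.log10(result.p3)
    p = len(chroms)
    for i in range(p - 1):
        a = cidx[chroms[i]]
        for j in range(i + 1, p):
            if ok[i, j]:
                b = cidx[chroms[j]]
                lo, hi = min(a, b), max(a, b)
                buckets[lo][hi].append(neglog[i, j])
    mat = np.full((nc, nc), np.nan)
    for a in range(nc):
        for b in range(a, nc):
            if buckets[a][b]:
                val = float(np.quantile(buckets[a][b], q))
                mat[a, b] = mat[b, a] = val
    return pd.DataFrame(mat, index=uniq, columns=uniq)


def plot_chrom_overview(overview: pd.DataFrame, path: str | Path) -> None:
    """Heatmap of the chromosome-pair overview (matplotlib optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(overview.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(overview.columns)), overview.columns, rotation=90)
    ax.set_yticks(range(len(overview.index)), overview.index)
    fig.colorbar(im, ax=ax, label="-log10(p) quantile")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
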