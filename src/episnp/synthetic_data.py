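"""Seeded genotype/phenotype simulator with planted epistasis.

Genotypes come from a Gaussian copula: within each LD block a latent
AR(1)-correlated multivariate normal is thresholded at the Hardy-Weinberg
genotype quantiles for the SNP's target minor-allele frequency, yielding
0/1/2 calls with controllable LD.  The quantitative trait is built from the
interaction model (intercept + planted main effects + planted pairwise
product effects + Gaussian noise) and affinely rescaled to a target
mean/SD, then decomposed into feed-record columns so the phenotype module
reconstructs it exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import MISSING
from .genotype_io import GenotypeMatrix, SNPRecord, write_plink_text

PROFILES = {
    "tiny": dict(n_samples=20, n_snps=50, n_chromosomes=2),
    "standard": dict(n_samples=60, n_snps=500, n_chromosomes=5),
    "breedlike": dict(n_samples=59, n_snps=5000, n_chromosomes=18),
}


@dataclass
class SimConfig:
    n_samples: int = 60
    n_snps: int = 500
    n_chromosomes: int = 5
    ld_block_size: int = 10
    within_block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    planted_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    planted_mains: list[tuple[int, float]] = field(default_factory=list)
    mu: float = 0.0
    noise_sd: float = 1.0
    trait_target_mean: float = 1.96
    trait_target_sd: float = 0.07
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        for i, j, _b in self.planted_pairs:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                raise ValueError("planted pair index out of range")
        for i, _b in self.planted_mains:
            if not 0 <= i < self.n_snps:
                raise ValueError("planted main index out of range")


@dataclass
class TruthSet:
    config: dict
    realized_maf: list[float]
    planted_module_membership: dict[str, list[int]]
    variance_decomposition: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))


def recovery_config(seed: int = 0) -> SimConfig:
    """Standard-profile config with one planted epistatic region.

    Three interaction pairs sit inside a single 30-SNP LD block; the block's
    internal correlation makes every pair of region SNPs a proxy for the
    planted products, so the region emerges as one trait-associated module.
    Used by the end-to-end recovery tests.
    """
    return SimConfig(
        n_samples=60,
        n_snps=500,
        n_chromosomes=5,
        ld_block_size=30,
        within_block_rho=0.97,
        maf_range=(0.3, 0.5),
        planted_pairs=[(2, 8, 2.0), (4, 10, 2.0), (6, 12, 2.0)],
        noise_sd=0.3,
        seed=seed,
    )


def _rngs(seed: int, *streams: str) -> dict[str, np.random.Generator]:
    """Independent child generators split from one root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(streams))
    return {name: np.random.default_rng(c) for name, c in zip(streams, children)}


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Gaussian-copula genotypes in AR(1) LD blocks, independent across blocks."""
    rngs = _rngs(config.seed, "latent", "maf", "missing", "positions")
    n, p = config.n_samples, config.n_snps
    mafs = rngs["maf"].uniform(*config.maf_range, size=p)
    rho = config.within_block_rho

    latent = np.empty((n, p))
    start = 0
    while start < p:
        width = min(config.ld_block_size, p - start)
        # AR(1): innovations scaled so each column is standard normal
        eps = rngs["latent"].standard_normal((n, width))
        block = np.empty((n, width))
        block[:, 0] = eps[:, 0]
        for k in range(1, width):
            block[:, k] = rho * block[:, k - 1] + np.sqrt(1 - rho**2) * eps[:, k]
        latent[:, start : start + width] = block
        start += width

    values = np.empty((n, p), dtype=np.int8)
    snps = []
    per_chrom = int(np.ceil(p / config.n_chromosomes))
    for j in range(p):
        q = mafs[j]
        # genotype cutpoints under Hardy-Weinberg proportions
        c0 = stats.norm.ppf((1 - q) ** 2)
        c1 = stats.norm.ppf((1 - q) ** 2 + 2 * q * (1 - q))
        col = np.where(latent[:, j] < c0, 0, np.where(latent[:, j] < c1, 1, 2))
        values[:, j] = col
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom + 1) * 1000
        snps.append(
            SNPRecord(
                snp_id=f"snp{j:05d}", chrom=chrom, pos_bp=pos,
                allele_a="A", allele_b="G", minor_allele="A", maf=float(q),
            )
        )
    if config.missing_rate > 0:
        mask = rngs["missing"].random((n, p)) < config.missing_rate
        values[mask] = MISSING
    sample_ids = [f"sample{i:03d}" for i in range(n)]
    return GenotypeMatrix(values, snps, sample_ids)


def build_trait(
    gm: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, float]]:
    """Raw interaction-model trait and its variance decomposition."""
    g = np.where(gm.values == MISSING, 0, gm.values).astype(float)
    signal = np.full(gm.n_samples, config.mu, dtype=float)
    for i, b1 in config.planted_mains:
        signal += b1 * g[:, i]
    for i, j, b3 in config.planted_pairs:
        signal += b3 * g[:, i] * g[:, j]
    noise = rng.normal(0.0, config.noise_sd, size=gm.n_samples)
    y = signal + noise
    var_total = float(np.var(y)) or 1.0
    decomp = {
        "signal": float(np.var(signal)) / var_total,
        "noise": float(np.var(noise)) / var_total,
    }
    return y, decomp


def simulate_phenotypes(
    gm: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Phenotype table whose FC/DW ratio reproduces the simulated trait.

    The trait is rescaled to ``trait_target_mean`` / ``trait_target_sd``
    and planted as FCR; DW, test duration, DFI and age are generated so the
    derived columns (FCR, RFI) carry signal.
    """
    rngs = _rngs(config.seed + 1, "noise", "covars")
    y_raw, decomp = build_trait(gm, config, rngs["noise"])
    sd = float(np.std(y_raw))
    if sd > 0:
        y = (y_raw - y_raw.mean()) / sd * config.trait_target_sd
        y = y + config.trait_target_mean
    else:
        y = np.full_like(y_raw, config.trait_target_mean)
    n = gm.n_samples
    covars = rngs["covars"]
    dw = covars.normal(65.0, 8.0, size=n).clip(min=30.0)
    test_days = covars.integers(41, 71, size=n).astype(float)
    initial_weight = covars.normal(28.0, 1.5, size=n)
    fc = y * dw  # FC / DW == trait exactly
    dw_per_day = dw / test_days
    rfi_noise = covars.normal(0.0, 0.12, size=n)
    # daily intake linear in growth rate and start weight plus an RFI residual
    dfi = 0.8 + 1.4 * dw_per_day + 0.02 * initial_weight + rfi_noise
    # fold the trait into intake so RFI correlates with the planted signal
    dfi = dfi + 0.5 * (y - y.mean())
    age = covars.normal(125.0, 3.0, size=n).round(1)
    table = pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "fc": fc,
            "dw": dw,
            "dfi": dfi,
            "initial_weight": initial_weight,
            "age_days": age,
            "test_days": test_days,
        }
    )
    return table, decomp


def truth_set(config: SimConfig, gm: GenotypeMatrix, decomp: dict[str, float]) -> TruthSet:
    obs = np.where(gm.values == MISSING, np.nan, gm.values).astype(float)
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(obs, axis=0) / 2.0
    realized = [float(min(f, 1 - f)) if np.isfinite(f) else 0.0 for f in freqs]
    members = sorted({k for i, j, _ in config.planted_pairs for k in (i, j)})
    cfg = asdict(config)
    cfg["maf_range"] = list(config.maf_range)
    return TruthSet(
        config=cfg,
        realized_maf=realized,
        planted_module_membership={"planted": members},
        variance_decomposition=decomp,
    )


def make_fixture(
    profile_name: str,
    out_dir: str | Path,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Write a complete seeded fixture (genotypes, phenotypes, annotation, truth)."""
    if profile_name not in PROFILES:
        raise ValueError(f"unknown profile {profile_name!r}; choose from {sorted(PROFILES)}")
    params = dict(PROFILES[profile_name])
    params.update(overrides)
    config = SimConfig(seed=seed, **params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gm = simulate_genotypes(config)
    table, decomp = simulate_phenotypes(gm, config)
    write_plink_text(
        gm,
        ped_path=out / "genotypes.ped",
        map_path=out / "genotypes.map",
        tped_path=out / "genotypes.tped",
        tfam_path=out / "genotypes.tfam",
    )
    table.to_csv(out / "phenotypes.tsv", sep="\t", index=False, float_format="%.10g")
    _write_toy_gff3(gm, out / "annotation.gff3", config)
    truth_set(config, gm, decomp).to_json(out / "truth.json")
    return config


def _write_toy_gff3(gm: GenotypeMatrix, path: Path, config: SimConfig) -> None:
    """One gene per ~5 SNP positions so roughly half the SNPs are genic."""
    lines = ["##gff-version 3"]
    by_chrom: dict[str, list[int]] = {}
    for s in gm.snps:
        by_chrom.setdefault(s.chrom, []).append(s.pos_bp)
    gid = 0
    for chrom in sorted(by_chrom, key=lambda c: (len(c), c)):
        positions = sorted(by_chrom[chrom])
        for k in range(0, len(positions), 5):
            start = positions[k]
            end = positions[min(k + 2, len(positions) - 1)] + 100
            strand = "+" if gid % 2 == 0 else "-"
            lines.append(
                f"{chrom}\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID=gene{gid:04d};Name=G{gid:04d}"
            )
            gid += 1
    path.write_text("\n".join(lines) + "\n")
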