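"""PLINK-style text genotype input/output, numeric coding and QC.

Genotypes are coded per SNP as counts of the minor allele: 2 = homozygote
minor, 1 = heterozygote, 0 = homozygote major; missing calls carry the
``MISSING`` sentinel and never enter allele-frequency denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import MISSING

DEFAULT_AUTOSOMES = frozenset(str(c) for c in range(1, 19))


class PlinkParseError(ValueError):
    """Raised on malformed PED/MAP/TPED/TFAM content."""


class QCError(ValueError):
    """Raised when QC removes every sample or every SNP."""


@dataclass
class SNPRecord:
    """Per-SNP metadata carried alongside one coded genotype column."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str = "0"
    allele_b: str = "0"
    minor_allele: str = "0"
    maf: float = 0.0


@dataclass
class GenotypeMatrix:
    """Samples x SNPs integer matrix in minor-allele-count coding.

    ``values[i, j]`` is the number of copies of ``snps[j].minor_allele``
    carried by ``sample_ids[i]``, or ``MISSING``.
    """

    values: np.ndarray
    snps: list[SNPRecord]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x snps)")
        if self.values.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.snps)} snps"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset; masks are boolean or index arrays."""
        vals = self.values
        samples = self.sample_ids
        snps = self.snps
        if sample_mask is not None:
            sample_mask = np.asarray(sample_mask)
            vals = vals[sample_mask, :]
            samples = list(np.asarray(samples, dtype=object)[sample_mask])
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            vals = vals[:, snp_mask]
            snps = list(np.asarray(snps, dtype=object)[snp_mask])
        return GenotypeMatrix(vals.copy(), [replace(s) for s in snps], list(samples))

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return self.subset(sample_mask=np.asarray(rows, dtype=int))


@dataclass
class QCReport:
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tvalue"]
        lines.append(f"n_samples_in\t{self.n_samples_in}")
        lines.append(f"n_samples_out\t{self.n_samples_out}")
        lines.append(f"n_snps_in\t{self.n_snps_in}")
        lines.append(f"n_snps_out\t{self.n_snps_out}")
        for key, val in self.removed.items():
            lines.append(f"removed_{key}\t{val}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coding


def code_genotypes(
    allele_pairs: Sequence[tuple[str, str]],
) -> tuple[np.ndarray, str, float]:
    """Code one SNP's allele calls as minor-allele counts.

    Parameters
    ----------
    allele_pairs
        One ``(a1, a2)`` pair of single-character allele strings per sample;
        ``"0"`` marks a missing allele (both alleles missing = missing call).

    Returns
    -------
    column, minor_allele, maf
        ``column`` has entries in {0, 1, 2, MISSING}.  At an exact 0.5
        frequency tie the lexicographically smaller allele is minor.
    """
    counts: dict[str, int] = {}
    for a1, a2 in allele_pairs:
        for a in (a1, a2):
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
    if len(counts) > 2:
        raise ValueError(f"more than two alleles observed: {sorted(counts)}")
    if not counts:
        col = np.full(len(allele_pairs), MISSING, dtype=np.int8)
        return col, "0", 0.0

    alleles = sorted(counts)  # lexicographic => deterministic tie-break
    if len(alleles) == 1:
        minor = major = alleles[0]
        maf = 0.0
    else:
        total = counts[alleles[0]] + counts[alleles[1]]
        freq0 = counts[alleles[0]] / total
        if freq0 <= 0.5:  # tie at 0.5 -> lexicographically smaller is minor
            minor, major = alleles[0], alleles[1]
            maf = freq0
        else:
            minor, major = alleles[1], alleles[0]
            maf = 1.0 - freq0
    monomorphic = len(alleles) == 1
    col = np.empty(len(allele_pairs), dtype=np.int8)
    for i, (a1, a2) in enumerate(allele_pairs):
        if a1 == "0" or a2 == "0":
            col[i] = MISSING
        elif monomorphic:  # the only observed allele is the major allele
            col[i] = 0
        else:
            col[i] = (a1 == minor) + (a2 == minor)
    return col, minor, maf


def recode_matrix(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Recompute minor allele and MAF per SNP on the current sample set.

    Needed after subsetting samples: the minor allele may flip, and the
    0/1/2 coding must track the subset's minor allele.
    """
    vals = gm.values.copy()
    snps = []
    for j, rec in enumerate(gm.snps):
        col = vals[:, j]
        obs = col[col != MISSING]
        n_minor = int(np.sum(obs))  # copies of current minor allele
        n_total = 2 * obs.size
        rec = replace(rec)
        if n_total == 0:
            rec.maf = 0.0
        else:
            freq = n_minor / n_total
            if freq > 0.5 or (
                math.isclose(freq, 0.5)
                and rec.minor_allele != "0"
                and _other_allele(rec) < rec.minor_allele
            ):
                # flip coding so the subset's minor allele is counted
                flip = col != MISSING
                vals[flip, j] = 2 - vals[flip, j]
                rec.minor_allele = _other_allele(rec)
                freq = 1.0 - freq if freq > 0.5 else freq
            rec.maf = min(freq, 1.0 - freq) if n_total else 0.0
        snps.append(rec)
    return GenotypeMatrix(vals, snps, list(gm.sample_ids))


def _other_allele(rec: SNPRecord) -> str:
    if rec.minor_allele == rec.allele_a:
        return rec.allele_b
    return rec.allele_a


# ---------------------------------------------------------------------------
# PED/MAP and TPED/TFAM readers


def _read_map(map_path: str | Path) -> list[SNPRecord]:
    records = []
    seen = set()
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise PlinkParseError(f"{map_path}: line {ln}: expected 4 columns")
        chrom, snp_id, _cm, pos = parts[0], parts[1], parts[2], parts[3]
        if snp_id in seen:
            raise PlinkParseError(f"{map_path}: line {ln}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        records.append(SNPRecord(snp_id=snp_id, chrom=chrom, pos_bp=int(pos)))
    return records


def read_plink_text(
    ped_path: str | Path | None = None,
    map_path: str | Path | None = None,
    tped_path: str | Path | None = None,
    tfam_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read PED/MAP or TPED/TFAM whitespace-delimited genotypes.

    Exactly one dialect must be supplied.  Sample and SNP order follow the
    files; alleles are converted to 0/1/2 minor-allele counts.
    """
    if ped_path is not None and map_path is not None:
        return _read_ped(ped_path, map_path)
    if tped_path is not None and tfam_path is not None:
        return _read_tped(tped_path, tfam_path)
    raise ValueError("provide ped_path+map_path or tped_path+tfam_path")


def _read_ped(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    snps = _read_map(map_path)
    n_snps = len(snps)
    sample_ids: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise PlinkParseError(
                f"{ped_path}: line {ln}: expected {6 + 2 * n_snps} columns "
                f"(6 + 2 x {n_snps} SNPs), got {len(parts)}"
            )
        sample_ids.append(parts[1])
        rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
        )
    return _assemble(rows, snps, sample_ids)


def _read_tped(tped_path: str | Path, tfam_path: str | Path) -> GenotypeMatrix:
    sample_ids = []
    for ln, line in enumerate(Path(tfam_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise PlinkParseError(f"{tfam_path}: line {ln}: expected >= 2 columns")
        sample_ids.append(parts[1])
    n = len(sample_ids)
    snps: list[SNPRecord] = []
    columns: list[list[tuple[str, str]]] = []
    seen = set()
    for ln, line in enumerate(Path(tped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4 + 2 * n:
            raise PlinkParseError(
                f"{tped_path}: line {ln}: expected {4 + 2 * n} columns, got {len(parts)}"
            )
        chrom, snp_id, _cm, pos = parts[:4]
        if snp_id in seen:
            raise PlinkParseError(f"{tped_path}: line {ln}: duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        snps.append(SNPRecord(snp_id=snp_id, chrom=chrom, pos_bp=int(pos)))
        columns.append([(parts[4 + 2 * i], parts[5 + 2 * i]) for i in range(n)])
    rows = [[columns[j][i] for j in range(len(snps))] for i in range(n)]
    return _assemble(rows, snps, sample_ids)


def _assemble(
    rows: list[list[tuple[str, str]]],
    snps: list[SNPRecord],
    sample_ids: list[str],
) -> GenotypeMatrix:
    n, p = len(rows), len(snps)
    values = np.full((n, p), MISSING, dtype=np.int8)
    for j, rec in enumerate(snps):
        pairs = [rows[i][j] for i in range(n)]
        col, minor, maf = code_genotypes(pairs)
        values[:, j] = col
        obs_alleles = sorted({a for pair in pairs for a in pair if a != "0"})
        rec.minor_allele = minor
        rec.maf = maf
        if obs_alleles:
            if len(obs_alleles) == 1:
                rec.allele_a = rec.allele_b = obs_alleles[0]
            else:
                major = obs_alleles[0] if obs_alleles[1] == minor else obs_alleles[1]
                rec.allele_a, rec.allele_b = minor, major
    return GenotypeMatrix(values, snps, sample_ids)


# ---------------------------------------------------------------------------
# writers (round-trip support)


def _allele_pair(rec: SNPRecord, code: int) -> tuple[str, str]:
    minor = rec.minor_allele
    major = _other_allele(rec)
    if code == MISSING:
        return "0", "0"
    if code == 2:
        return minor, minor
    if code == 1:
        return minor, major
    return major, major


def write_plink_text(
    gm: GenotypeMatrix,
    ped_path: str | Path | None = None,
    map_path: str | Path | None = None,
    tped_path: str | Path | None = None,
    tfam_path: str | Path | None = None,
) -> None:
    """Write PED/MAP and/or TPED/TFAM for a coded genotype matrix."""
    if map_path is not None:
        lines = [f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}" for s in gm.snps]
        Path(map_path).write_text("\n".join(lines) + "\n")
    if ped_path is not None:
        out = []
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, rec in enumerate(gm.snps):
                fields.extend(_allele_pair(rec, int(gm.values[i, j])))
            out.append(" ".join(fields))
        Path(ped_path).write_text("\n".join(out) + "\n")
    if tfam_path is not None:
        lines = [f"{sid} {sid} 0 0 0 -9" for sid in gm.sample_ids]
        Path(tfam_path).write_text("\n".join(lines) + "\n")
    if tped_path is not None:
        out = []
        for j, rec in enumerate(gm.snps):
            fields = [rec.chrom, rec.snp_id, "0", str(rec.pos_bp)]
            for i in range(gm.n_samples):
                fields.extend(_allele_pair(rec, int(gm.values[i, j])))
            out.append(" ".join(fields))
        Path(tped_path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test probability.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability.  Monomorphic input returns 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    if n_minor == 0:
        return 1.0

    # log-probability of each compatible heterozygote count (same parity)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    valid = hom_major >= 0
    hets, hom_minor, hom_major = hets[valid], hom_minor[valid], hom_major[valid]
    from scipy.special import gammaln

    logp = (
        hets * math.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    logp -= logsumexp_stable(logp)
    probs = np.exp(logp)
    obs_idx = int(np.nonzero(hets == n_het)[0][0])
    # relative tolerance guards against floating round-off at ties
    return float(min(1.0, probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum()))


def logsumexp_stable(logs: np.ndarray) -> float:
    m = float(np.max(logs))
    return m + math.log(float(np.sum(np.exp(logs - m))))


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCParams:
    """Thresholds with the conventional defaults for this analysis.

    Sample call rate uses "<= threshold removed"; SNP call rate uses
    "< threshold removed" (deliberately asymmetric operators).
    """

    sample_call_rate: float = 0.90
    snp_call_rate: float = 0.90
    maf_min: float = 0.01
    hwe_p_min: float = 1e-7
    autosomes: frozenset[str] = DEFAULT_AUTOSOMES


def apply_qc(
    gm: GenotypeMatrix, params: QCParams | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample- then SNP-level filters, recoding stats after each stage.

    Filter order: (1) sample call rate, then per-SNP stats are recomputed on
    the retained samples; (2) non-autosomal / missing-position SNPs;
    (3) SNP call rate; (4) MAF; (5) HWE.  Each removed SNP is attributed to
    the first filter that removes it.
    """
    params = params or QCParams()
    report = QCReport(
        n_samples_in=gm.n_samples,
        n_snps_in=gm.n_snps,
        removed={
            "sample_call_rate": 0,
            "non_autosomal": 0,
            "no_position": 0,
            "snp_call_rate": 0,
            "maf": 0,
            "hwe": 0,
        },
    )
    # (1) samples
    called = gm.values != MISSING
    sample_rate = called.mean(axis=1) if gm.n_snps else np.ones(gm.n_samples)
    keep_samples = sample_rate > params.sample_call_rate
    report.removed["sample_call_rate"] = int((~keep_samples).sum())
    if not keep_samples.any():
        raise QCError("empty after QC: all samples removed by call-rate filter")
    gm = recode_matrix(gm.subset(sample_mask=keep_samples))

    keep = np.ones(gm.n_snps, dtype=bool)
    called = gm.values != MISSING
    for j, rec in enumerate(gm.snps):
        if rec.chrom not in params.autosomes:
            keep[j] = False
            report.removed["non_autosomal"] += 1
            continue
        if rec.pos_bp <= 0:
            keep[j] = False
            report.removed["no_position"] += 1
            continue
        rate = called[:, j].mean()
        if rate < params.snp_call_rate:
            keep[j] = False
            report.removed["snp_call_rate"] += 1
            continue
        if rec.maf < params.maf_min:
            keep[j] = False
            report.removed["maf"] += 1
            continue
        col = gm.values[called[:, j], j]
        p = hwe_exact_p(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
        if p < params.hwe_p_min:
            keep[j] = False
            report.removed["hwe"] += 1
    if not keep.any():
        raise QCError("empty after QC: all SNPs removed")
    out = gm.subset(snp_mask=keep)
    report.n_samples_out = out.n_samples
    report.n_snps_out = out.n_snps
    return out, report
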