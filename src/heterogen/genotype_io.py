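"""Genotype input/output, quality control, imputation and design-matrix coding.

Genotypes are held as an n_samples x n_snps matrix of counted-allele dosages
in {0, 1, 2} with ``-1`` marking missing calls.  The counted allele is the
PLINK A1 allele / VCF ALT allele.  From a clean panel the module builds the
centered additive coding ``Z`` (dosage minus ``2p``) and the centered
dominance coding ``W`` (heterozygosity indicator minus the Hardy-Weinberg
expected heterozygosity ``2p(1-p)``), the two matrices every downstream
kinship, variance-component and association stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

MISSING = -1

#: Sus scrofa autosome labels; anything else (X, Y, MT, scaffolds) is
#: non-autosomal for QC purposes.  Overridable in qc_filter.
PIG_AUTOSOMES = frozenset(str(c) for c in range(1, 19))


class GenotypeFormatError(ValueError):
    """A genotype file is malformed or internally inconsistent."""


class EmptyPanelError(ValueError):
    """Every SNP was removed by a filter step."""


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls plus the SNP map and sample identifiers.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length n).
    snps
        DataFrame with columns ``id``, ``chrom``, ``pos`` (1-based),
        ``a1`` (counted allele), ``a2``; one row per SNP, order matching
        the columns of ``calls``.
    calls
        ``(n, m)`` int8 array of counted-allele dosages; ``-1`` = missing.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeFormatError("calls contain values outside {0,1,2,missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNPs selected by ``index``."""
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )


@dataclass
class QCReport:
    """Per-step tallies of the SNP quality-control chain."""

    n_input_snps: int
    n_removed_nonautosomal: int = 0
    n_removed_callrate: int = 0
    n_removed_maf: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return (
            self.n_input_snps
            - self.n_removed_nonautosomal
            - self.n_removed_callrate
            - self.n_removed_maf
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": ["input", "nonautosomal", "callrate", "maf", "retained"],
                "n_snps": [
                    self.n_input_snps,
                    self.n_removed_nonautosomal,
                    self.n_removed_callrate,
                    self.n_removed_maf,
                    self.n_retained,
                ],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DesignPair:
    """Centered additive (Z) and dominance (W) design matrices.

    ``Z[i, j] = m_ij - 2 p_j`` for dosage ``m`` and counted-allele frequency
    ``p_j``; ``W[i, j] = h_ij - 2 p_j (1 - p_j)`` for the heterozygosity
    indicator ``h``.  The W columns have mean exactly zero only when the
    sample is at Hardy-Weinberg proportions; Z columns are exactly centered
    whenever ``p`` is estimated from the same samples.
    """

    Z: np.ndarray
    W: np.ndarray
    p: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    @property
    def n_snps(self) -> int:
        return self.Z.shape[1]

    def het_weights(self) -> np.ndarray:
        """Per-SNP expected heterozygosity 2p(1-p)."""
        return 2.0 * self.p * (1.0 - self.p)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# SNP-major 2-bit codes -> counted (A1) allele dosage
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1.9 bed/bim/fam triple.

    The counted allele is A1 (bim column 5).  Sample and SNP order follow
    the fam/bim files exactly; chromosome labels are carried verbatim.
    """
    prefix = Path(prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    snps = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )[["id", "chrom", "pos", "a1", "a2"]]
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = fam_df[1].tolist()
    n, m = len(samples), len(snps)

    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK 1 bed)")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * m:
        raise GenotypeFormatError(
            f"{bed}: payload is {body.size} bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack the four 2-bit fields per byte, little-end-first
    codes = np.stack([(body >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2)
    calls = _BED_DECODE[codes.reshape(m, -1)[:, :n]].T
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK 1.9 bed/bim/fam triple (A1 = counted)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = g.snps.copy()
    bim["cm"] = 0
    bim[["chrom", "id", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )
    fam = pd.DataFrame(
        {"fid": g.samples, "iid": g.samples, "f": 0, "m": 0, "sex": 0, "ph": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    enc = np.zeros((m, 4 * bytes_per_snp), dtype=np.uint8)
    code_lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        code_lut[dosage if dosage != MISSING else 3] = code
    calls = g.calls.T.copy()
    calls[calls == MISSING] = 3
    enc[:, :n] = code_lut[calls]
    enc = enc.reshape(m, bytes_per_snp, 4)
    packed = enc[:, :, 0] | (enc[:, :, 1] << 2) | (enc[:, :, 2] << 4) | (enc[:, :, 3] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.astype(np.uint8).tofile(fh)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT field) into a GenotypeMatrix.

    The ALT allele is the counted allele.  Multiallelic records are skipped
    with a warning; records without GT raise a format error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, cols = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if v.gt_types is None or len(v.gt_types) != len(samples):
            raise GenotypeFormatError(f"{path}: record without usable GT field")
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(v.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(col.astype(np.int8))
        rows.append((v.ID or f"{v.CHROM}:{v.POS}", str(v.CHROM), v.POS, v.ALT[0], v.REF))
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic VCF record(s)")
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic records with GT found")
    snps = pd.DataFrame(rows, columns=["id", "chrom", "pos", "a1", "a2"])
    calls = np.column_stack(cols)
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 (REF = a2, ALT = a1 = counted allele)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, snp in g.snps.iterrows():
            gts = "\t".join(gt_str[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.a2}\t{snp.a1}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# QC / imputation / coding
# ---------------------------------------------------------------------------


def _chrom_is_autosomal(labels: pd.Series, autosomes: frozenset[str]) -> np.ndarray:
    stripped = labels.astype(str).str.replace("^chr", "", regex=True, case=False)
    return stripped.isin(autosomes).to_numpy()


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    autosomes_only: bool = True,
    phase: Literal["pre", "post"] = "pre",
    autosomes: frozenset[str] = PIG_AUTOSOMES,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP quality control in the two phases the analysis chain uses.

    ``phase="pre"`` (before imputation) drops non-autosomal SNPs, then SNPs
    with call rate strictly below ``call_rate_min``.  ``phase="post"``
    (after imputation) drops SNPs with folded minor-allele frequency below
    ``maf_min``.  Raises :class:`EmptyPanelError` if nothing survives.
    """
    if g.n_snps == 0:
        raise EmptyPanelError("input panel has no SNPs")
    report = QCReport(
        n_input_snps=g.n_snps,
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "autosomes_only": autosomes_only,
            "phase": phase,
        },
    )
    keep = np.ones(g.n_snps, dtype=bool)
    if phase == "pre":
        if autosomes_only:
            auto = _chrom_is_autosomal(g.snps["chrom"], autosomes)
            report.n_removed_nonautosomal = int((~auto).sum())
            keep &= auto
        observed = (g.calls != MISSING).mean(axis=0)
        low = keep & (observed < call_rate_min)
        report.n_removed_callrate = int(low.sum())
        keep &= ~low
    elif phase == "post":
        if g.has_missing():
            raise ValueError("post-imputation QC requires a panel without missing calls")
        p = allele_frequencies(g)
        maf = np.minimum(p, 1.0 - p)
        low = maf < maf_min
        report.n_removed_maf = int(low.sum())
        keep &= ~low
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown phase {phase!r}")
    if not keep.any():
        raise EmptyPanelError(f"QC phase {phase!r} removed every SNP")
    return g.take_snps(np.flatnonzero(keep)), report


def impute_missing(
    g: GenotypeMatrix,
    method: Literal["mode", "frequency_draw"] = "mode",
    seed: int | None = None,
) -> GenotypeMatrix:
    """Fill missing calls per SNP.

    ``mode`` replaces by the most frequent observed genotype (ties broken
    toward the smaller code); ``frequency_draw`` samples from the observed
    genotype frequencies with ``seed``.  A SNP with no observed call at all
    cannot be imputed and raises.
    """
    if not g.has_missing():
        return replace(g, calls=g.calls.copy())
    calls = g.calls.copy()
    obs_counts = np.stack([(calls == k).sum(axis=0) for k in (0, 1, 2)])  # (3, m)
    if (obs_counts.sum(axis=0) == 0).any():
        j = int(np.flatnonzero(obs_counts.sum(axis=0) == 0)[0])
        raise ValueError(f"SNP {g.snps['id'].iloc[j]!r} has zero observed calls")
    miss_i, miss_j = np.nonzero(calls == MISSING)
    if method == "mode":
        fill = obs_counts.argmax(axis=0).astype(np.int8)  # argmax -> smallest on tie
        calls[miss_i, miss_j] = fill[miss_j]
    elif method == "frequency_draw":
        if seed is None:
            raise ValueError("frequency_draw imputation requires a seed")
        rng = np.random.default_rng(seed)
        freqs = obs_counts / obs_counts.sum(axis=0, keepdims=True)
        u = rng.random(miss_i.size)
        cum = np.cumsum(freqs[:, miss_j], axis=0)
        calls[miss_i, miss_j] = (u >= cum[0]).astype(np.int8) + (u >= cum[1])
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return replace(g, calls=calls)


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per SNP, p_i = (column dosage sum) / 2n."""
    if g.has_missing():
        raise ValueError("panel has missing calls; run impute_missing first")
    return g.calls.sum(axis=0, dtype=np.float64) / (2.0 * g.n_samples)


def build_designs(g: GenotypeMatrix) -> DesignPair:
    """Build the centered additive/dominance design pair from a clean panel.

    Monomorphic SNPs (p = 0 or 1) yield all-zero columns in both matrices
    and a warning; they contribute nothing downstream.
    """
    p = allele_frequencies(g)
    mono = (p == 0.0) | (p == 1.0)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s) contribute zero columns to Z and W"
        )
    m = g.calls.astype(np.float64)
    Z = m - 2.0 * p
    het = (g.calls == 1).astype(np.float64)
    W = het - 2.0 * p * (1.0 - p)
    Z[:, mono] = 0.0
    W[:, mono] = 0.0
    return DesignPair(Z=Z, W=W, p=p, snps=g.snps.copy(), samples=list(g.samples))


def full_qc(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    autosomes_only: bool = True,
    impute_method: Literal["mode", "frequency_draw"] = "mode",
    seed: int | None = 0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full chain: autosome + call-rate filters, imputation, MAF filter."""
    g1, rep1 = qc_filter(
        g, call_rate_min=call_rate_min, maf_min=maf_min,
        autosomes_only=autosomes_only, phase="pre",
    )
    g2 = impute_missing(g1, method=impute_method, seed=seed)
    g3, rep2 = qc_filter(g2, maf_min=maf_min, phase="post")
    report = QCReport(
        n_input_snps=rep1.n_input_snps,
        n_removed_nonautosomal=rep1.n_removed_nonautosomal,
        n_removed_callrate=rep1.n_removed_callrate,
        n_removed_maf=rep2.n_removed_maf,
        thresholds={
            "call_rate_min": call_rate_min,
            "maf_min": maf_min,
            "autosomes_only": autosomes_only,
            "impute_method": impute_method,
        },
    )
    return g3, report
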