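"""Synthetic genotypes, F1 cross structures, and QTN phenotypes.

Everything the analysis chain assumes about real data is emulated here so
the whole pipeline can run without downloads: an 80K-array-like biallelic
autosomal SNP panel at Hardy-Weinberg proportions (optionally with AR(1)
linkage disequilibrium), a two-pool F1 cross with a sire/dam pedigree
(defaults: 6 sires x 24 dams -> 171 offspring, the Duroc x Liangguang
design), and QTN phenotypes: 20 causal SNPs with standard-normal effects
and heritability 0.5, in an additive or a dominance mode.  The generators
are the study conditions for every simulation-based check, and all of them
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import DesignPair, GenotypeMatrix
from .gwas_scan import EnsembleResult, ScanResult, Thresholds


@dataclass
class SimulationSpec:
    """Settings for a plain HWE panel and its QTN phenotypes."""

    n_individuals: int = 171
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.0  # AR(1) parameter for adjacent-SNP latent correlation
    n_qtn: int = 20
    h2: float = 0.5
    mode: Literal["additive", "dominance"] = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.n_qtn > self.n_snps:
            raise ValueError("n_qtn cannot exceed n_snps")


@dataclass
class CrossSpec:
    """Settings for a two-pool F1 cross with a sire/dam pedigree."""

    n_sires: int = 6
    n_dams: int = 24
    n_offspring: int = 171
    divergence: float = 0.2  # Fst-like drift between the parental pools
    p1_trait_mean: float = 100.0  # sire-breed non-genetic trait baseline
    p2_trait_mean: float = 80.0  # dam-breed baseline
    dominance_degree: float = 0.5  # d_j = degree * |a_j| at trait loci
    n_trait_loci: int = 300
    residual_sd_frac: float = 1.0  # residual SD as fraction of genic SD
    seed: int = 0


@dataclass
class SimTruth:
    """Ground truth of one simulated phenotype."""

    qtn_indices: np.ndarray
    qtn_ids: list[str]
    effects: np.ndarray
    additive_values: np.ndarray
    dominance_values: np.ndarray
    realized_h2: float
    mode: str


@dataclass
class CrossResult:
    """Genotypes, pedigree and trait values of a simulated F1 cross."""

    genotypes: GenotypeMatrix  # sires, then dams, then offspring
    pedigree: pd.DataFrame  # offspring id, sire, dam
    traits: pd.DataFrame  # id, role (sire/dam/offspring), sire (group), value
    p1_mean: float  # mean sire-pool trait value
    p2_mean: float  # mean dam-pool trait value


def _snp_map(m: int, rng: np.random.Generator, n_chrom: int = 18) -> pd.DataFrame:
    """SNP ids and an ordered physical map spread over the autosomes."""
    chrom = np.repeat(np.arange(1, n_chrom + 1), int(np.ceil(m / n_chrom)))[:m]
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, n_chrom + 1):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.cumsum(rng.integers(1_000, 50_000, size=idx.size))
    return pd.DataFrame(
        {
            "id": [f"SNP{j + 1}" for j in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }
    )


def _counted_freqs(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw MAFs then randomize which allele is counted (so p may exceed 0.5)."""
    maf = rng.uniform(*spec.maf_range, size=spec.n_snps)
    flip = rng.random(spec.n_snps) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """HWE genotypes; with ``ld_decay > 0``, haplotypes come from AR(1)
    latent Gaussians thresholded at the allele-frequency quantile, inducing
    exponentially decaying LD between neighboring SNPs."""
    rng = np.random.default_rng(spec.seed)
    p = _counted_freqs(spec, rng)
    n, m = spec.n_individuals, spec.n_snps
    if spec.ld_decay > 0.0:
        rho = spec.ld_decay
        thresh = stats.norm.ppf(p)
        calls = np.zeros((n, m), dtype=np.int8)
        for _ in range(2):  # two independent haplotypes per individual
            z = rng.standard_normal((n, m))
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
            calls += (z < thresh).astype(np.int8)
    else:
        calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    snps = _snp_map(m, rng)
    snps["p_drawn"] = p  # generator truth, handy for calibration checks
    return GenotypeMatrix(
        samples=[f"IND{i + 1}" for i in range(n)],
        snps=snps,
        calls=calls,
    )


def simulate_phenotype(
    g: GenotypeMatrix, spec: SimulationSpec
) -> tuple[np.ndarray, SimTruth]:
    """QTN phenotype on an existing panel.

    ``n_qtn`` SNPs are drawn uniformly (monomorphic picks are resampled and
    logged), each with a standard-normal effect applied to the additive
    dosage (mode ``additive``) or the 0/1/0 heterozygosity coding (mode
    ``dominance``).  The residual vector is decorrelated from the genetic
    values and rescaled so the realized heritability equals ``h2`` exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = g.n_samples
    freqs = g.calls.mean(axis=0) / 2.0
    poly = np.flatnonzero((freqs > 0) & (freqs < 1))
    if poly.size < spec.n_qtn:
        raise ValueError("not enough polymorphic SNPs to place the QTNs")
    qtn = rng.choice(poly, size=spec.n_qtn, replace=False)
    n_mono = g.n_snps - poly.size
    if n_mono:
        warnings.warn(f"{n_mono} monomorphic SNP(s) excluded from QTN sampling")
    effects = rng.standard_normal(spec.n_qtn)

    dosage = g.calls[:, qtn].astype(np.float64)
    het = (g.calls[:, qtn] == 1).astype(np.float64)
    if spec.mode == "additive":
        gv = dosage @ effects
        add_vals, dom_vals = gv, np.zeros(n)
    elif spec.mode == "dominance":
        gv = het @ effects
        add_vals, dom_vals = np.zeros(n), gv
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")

    gv_c = gv - gv.mean()
    var_g = float(gv_c @ gv_c) / n
    if var_g == 0:
        raise ValueError("genetic values are constant; cannot hit the target h2")
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= gv_c * (float(e @ gv_c) / float(gv_c @ gv_c))  # exact decorrelation
    e *= np.sqrt(var_g * (1.0 - spec.h2) / spec.h2 / (float(e @ e) / n))
    y = gv_c + e
    realized = var_g / (var_g + float(e @ e) / n)
    truth = SimTruth(
        qtn_indices=np.sort(qtn),
        qtn_ids=[g.snps["id"].iloc[j] for j in np.sort(qtn)],
        effects=effects[np.argsort(qtn)],
        additive_values=add_vals,
        dominance_values=dom_vals,
        realized_h2=float(realized),
        mode=spec.mode,
    )
    return y, truth


def simulate_polygenic_phenotype(
    designs: DesignPair,
    sigma2_a: float,
    sigma2_d: float,
    sigma2_e: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phenotype from the two-kernel model: y = ua + ud + e.

    Per-SNP effects are drawn i.i.d. so that Var(ua) = sigma2_a * Ga and
    Var(ud) = sigma2_d * Gd with the same denominators the GRMs use, giving
    data exactly from the variance-decomposition model.  Returns (y, ua, ud).
    """
    rng = np.random.default_rng(seed)
    n = designs.Z.shape[0]
    c_a = float(designs.het_weights().sum())
    c_d = float((designs.het_weights() ** 2).sum())
    alpha = rng.standard_normal(designs.n_snps) * np.sqrt(sigma2_a / c_a)
    delta = rng.standard_normal(designs.n_snps) * np.sqrt(sigma2_d / c_d)
    ua = designs.Z @ alpha
    ud = designs.W @ delta
    e = rng.standard_normal(n) * np.sqrt(sigma2_e)
    return ua + ud + e, ua, ud


# ---------------------------------------------------------------------------
# F1 cross
# ---------------------------------------------------------------------------


def simulate_f1_cross(cspec: CrossSpec, n_snps: int = 5000) -> CrossResult:
    """Two diverged parental pools, a sire/dam pedigree, and F1 offspring.

    Pool allele frequencies drift apart by a Balding-Nichols draw with the
    ``divergence`` parameter; each offspring receives one gamete sampled
    from its sire's genotype and one from its dam's.  Trait values carry
    additive effects plus positive dominance at the trait loci, so with
    diverged pools the offspring's excess heterozygosity produces true
    mid-parent heterosis by construction.
    """
    rng = np.random.default_rng(cspec.seed)
    anc = rng.uniform(0.1, 0.9, size=n_snps)
    if cspec.divergence > 0:
        f = cspec.divergence
        a, b = anc * (1 - f) / f, (1 - anc) * (1 - f) / f
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    else:
        p1 = p2 = anc

    sires = rng.binomial(2, p1, size=(cspec.n_sires, n_snps)).astype(np.int8)
    dams = rng.binomial(2, p2, size=(cspec.n_dams, n_snps)).astype(np.int8)

    dams_per_sire = cspec.n_dams // cspec.n_sires
    dam_sire = np.repeat(np.arange(cspec.n_sires), dams_per_sire)
    if dam_sire.size < cspec.n_dams:  # leftover dams cycle through the sires
        dam_sire = np.concatenate(
            [dam_sire, np.arange(cspec.n_dams - dam_sire.size) % cspec.n_sires]
        )
    off_dam = np.arange(cspec.n_offspring) % cspec.n_dams
    off_sire = dam_sire[off_dam]

    def gamete(parent_calls: np.ndarray) -> np.ndarray:
        # one allele per SNP: P(allele=1) = dosage / 2 (free recombination)
        return (rng.random(parent_calls.shape) < parent_calls / 2.0).astype(np.int8)

    offspring = gamete(sires[off_sire]) + gamete(dams[off_dam])

    calls = np.vstack([sires, dams, offspring])
    sire_ids = [f"S{i + 1}" for i in range(cspec.n_sires)]
    dam_ids = [f"D{i + 1}" for i in range(cspec.n_dams)]
    off_ids = [f"F{i + 1}" for i in range(cspec.n_offspring)]
    geno = GenotypeMatrix(
        samples=sire_ids + dam_ids + off_ids, snps=_snp_map(n_snps, rng), calls=calls
    )
    pedigree = pd.DataFrame(
        {
            "id": off_ids,
            "sire": [sire_ids[s] for s in off_sire],
            "dam": [dam_ids[d] for d in off_dam],
        }
    )

    # trait: additive + positive dominance at a subset of loci
    loci = rng.choice(n_snps, size=min(cspec.n_trait_loci, n_snps), replace=False)
    a_eff = rng.standard_normal(loci.size)
    d_eff = cspec.dominance_degree * np.abs(a_eff)
    scale = 1.0 / np.sqrt(loci.size)  # keep genic variance O(1)

    def genetic_value(block: np.ndarray) -> np.ndarray:
        dos = block[:, loci].astype(np.float64)
        het = (block[:, loci] == 1).astype(np.float64)
        return scale * (dos - 1.0) @ a_eff + scale * het @ d_eff

    gv = genetic_value(calls)
    base = np.concatenate(
        [
            np.full(cspec.n_sires, cspec.p1_trait_mean),
            np.full(cspec.n_dams, cspec.p2_trait_mean),
            np.full(cspec.n_offspring, (cspec.p1_trait_mean + cspec.p2_trait_mean) / 2.0),
        ]
    )
    noise = rng.standard_normal(calls.shape[0]) * cspec.residual_sd_frac * gv.std()
    values = base + gv + noise
    roles = (
        ["sire"] * cspec.n_sires + ["dam"] * cspec.n_dams + ["offspring"] * cspec.n_offspring
    )
    group = (
        sire_ids
        + [sire_ids[s] for s in dam_sire]
        + [sire_ids[s] for s in off_sire]
    )
    traits = pd.DataFrame(
        {"id": geno.samples, "role": roles, "sire": group, "value": values}
    )
    p1_mean = float(values[: cspec.n_sires].mean())
    p2_mean = float(values[cspec.n_sires : cspec.n_sires + cspec.n_dams].mean())
    return CrossResult(
        genotypes=geno, pedigree=pedigree, traits=traits, p1_mean=p1_mean, p2_mean=p2_mean
    )


# ---------------------------------------------------------------------------
# detection scoring
# ---------------------------------------------------------------------------


def evaluate_detection(
    ensemble: EnsembleResult,
    truth: SimTruth,
    snp_map: pd.DataFrame,
    window_bp: int = 0,
    scans: list[ScanResult] | None = None,
    thresholds: Thresholds | None = None,
) -> dict:
    """True/false-positive counts for an ensemble against the planted QTNs.

    A hit is true when it is a QTN (``window_bp=0``) or lies within
    ``window_bp`` of one on the same chromosome.  When ``scans`` and
    ``thresholds`` are supplied, each single engine is additionally scored
    at the genome-wide significant threshold (one bar per engine, as in a
    model-comparison figure).
    """
    qtn = snp_map.iloc[truth.qtn_indices]

    def count_true(ids: pd.Series, chroms: pd.Series, poss: pd.Series) -> int:
        if window_bp == 0:
            return int(ids.isin(truth.qtn_ids).sum())
        hit = 0
        for ch, pos in zip(chroms, poss):
            near = qtn[(qtn["chrom"].astype(str) == str(ch))
                       & ((qtn["pos"] - pos).abs() <= window_bp)]
            hit += int(not near.empty)
        return hit

    tp = count_true(ensemble.table["snp"], ensemble.table["chrom"], ensemble.table["pos"])
    result = {"tp": tp, "fp": len(ensemble.table) - tp, "n_qtn": len(truth.qtn_ids)}
    if scans is not None and thresholds is not None:
        per_engine = {}
        for s in scans:
            sub = s.table[s.table["p"] < thresholds.significant]
            per_engine[s.engine] = count_true(sub["snp"], sub["chrom"], sub["pos"])
        result["per_engine_tp"] = per_engine
    return result
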