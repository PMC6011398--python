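"""Synthetic genotype/phenotype generation and annotation fixtures.

Genotypes are drawn from a Gaussian-copula haplotype model: per haplotype a
latent multivariate normal with block-constant correlation rho is
thresholded at Phi^-1(1 - MAF) to give the minor allele, and the genotype
is the sum of two independent haplotypes, so marginal sites satisfy
Hardy-Weinberg equilibrium at their MAF while blocks carry tunable LD.

Binary phenotypes follow a logistic penetrance with additive main effects,
optional centered product-term interactions, and optional explicit 3x3
log-odds penetrance increments per SNP pair; case-control ascertainment
draws genotype rows until exact case/control quotas are met.  The
carrier-XOR construction gives a pure-epistasis pair: at minor-allele
frequency 1 - sqrt(1/2) (carrier probability 1/2) a penetrance increment
applied when exactly one SNP of the pair carries a minor allele has
provably zero marginal effect per SNP, isolating the interaction signal
that collective (CL) inference can see and per-SNP (IL) tests cannot.

Quantitative traits (y = linear predictor + Gaussian noise) emulate the
dichotomize-at-threshold design of the outbred-mouse glucose phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .io import (
    GeneRecord,
    GeneSetCollection,
    GeneTable,
    GenotypeData,
    SnpInfo,
    write_gene_sets,
    write_gene_table,
    write_genotypes_tsv,
    write_plink,
)

logger = logging.getLogger("ddascan")

#: MAF at which the carrier probability P(g >= 1) is exactly 1/2.
XOR_MAF: float = 1.0 - np.sqrt(0.5)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class SimSpec:
    """Genotype-simulation design.

    ``ld_blocks`` is a list of (block_size, rho) consumed from the first SNP
    onward; SNPs not covered by a block are independent.  Explicit ``mafs``
    override the uniform draw from ``maf_range``.
    """

    n_samples: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0
    mafs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("ld_blocks sizes sum beyond n_snps")
        for size, rho in self.ld_blocks:
            if size < 1 or not (-1 < rho < 1):
                raise ValueError(f"invalid LD block ({size}, {rho})")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if self.mafs.shape != (self.n_snps,):
                raise ValueError("mafs length must equal n_snps")
            if ((self.mafs <= 0) | (self.mafs > 0.5)).any():
                raise ValueError("mafs must lie in (0, 0.5]")

    def resolve_mafs(self, rng: np.random.Generator) -> np.ndarray:
        if self.mafs is not None:
            return self.mafs
        lo, hi = self.maf_range
        return rng.uniform(lo, hi, size=self.n_snps)


@dataclass
class EffectSpec:
    """Penetrance model on the logit scale.

    logit P(case | g) = beta0 + sum_i beta[i] g_i
                      + sum_{ij} gamma[(i,j)] (g_i - c_i)(g_j - c_j)
                      + sum_{ij} pair_tables[(i,j)][g_i, g_j]

    Product-term codings are centered at the population mean c_i = 2 MAF_i.
    """

    beta0: float = 0.0
    beta: dict[int, float] = field(default_factory=dict)
    gamma: dict[tuple[int, int], float] = field(default_factory=dict)
    pair_tables: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, table in list(self.pair_tables.items()):
            t = np.asarray(table, dtype=float)
            if t.shape != (3, 3) or not np.isfinite(t).all():
                raise ValueError(f"pair table {key} must be a finite 3x3 array")
            self.pair_tables[key] = t

    def max_index(self) -> int:
        idx = list(self.beta)
        for i, j in list(self.gamma) + list(self.pair_tables):
            idx += [i, j]
        return max(idx, default=-1)

    def linear_predictor(self, matrix: np.ndarray, mafs: Optional[np.ndarray] = None) -> np.ndarray:
        g = matrix.astype(float)
        eta = np.full(g.shape[0], self.beta0)
        for i, b in self.beta.items():
            eta += b * g[:, i]
        if self.gamma:
            if mafs is None:
                centers = g.mean(axis=0)
            else:
                centers = 2.0 * np.asarray(mafs, dtype=float)
            for (i, j), gam in self.gamma.items():
                eta += gam * (g[:, i] - centers[i]) * (g[:, j] - centers[j])
        for (i, j), table in self.pair_tables.items():
            eta += table[matrix[:, i], matrix[:, j]]
        return eta


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

def _block_chol(size: int, rho: float) -> np.ndarray:
    M = np.full((size, size), rho)
    np.fill_diagonal(M, 1.0)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        raise ValueError(
            f"block correlation (size={size}, rho={rho}) is not positive definite"
        )


def _draw_genotypes(rng: np.random.Generator, n: int, spec: SimSpec, mafs: np.ndarray) -> np.ndarray:
    thresholds = norm.ppf(1.0 - mafs)
    chols = [(size, _block_chol(size, rho)) for size, rho in spec.ld_blocks]
    genotype = np.zeros((n, spec.n_snps), dtype=np.int8)
    for _hap in range(2):
        Z = rng.standard_normal((n, spec.n_snps))
        offset = 0
        for size, L in chols:
            Z[:, offset:offset + size] = Z[:, offset:offset + size] @ L.T
            offset += size
        genotype += (Z > thresholds).astype(np.int8)
    return genotype


def _snp_metadata(n_snps: int, spacing: int = 5000) -> list[SnpInfo]:
    return [
        SnpInfo(id=f"snp{i:05d}", chrom="1", pos=1 + i * spacing, alleles=("A", "B"))
        for i in range(n_snps)
    ]


def simulate_genotypes(spec: SimSpec) -> GenotypeData:
    """Draw an n x m genotype matrix from the Gaussian-copula haplotype model."""
    rng = np.random.default_rng(spec.seed)
    mafs = spec.resolve_mafs(rng)
    matrix = _draw_genotypes(rng, spec.n_samples, spec, mafs)
    sample_ids = [f"S{i:06d}" for i in range(spec.n_samples)]
    return GenotypeData(matrix, _snp_metadata(spec.n_snps), sample_ids)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

def simulate_case_control(
    spec: SimSpec,
    effects: EffectSpec,
    n_case: int,
    n_ctrl: int,
    seed: int,
    max_draw_factor: int = 200,
) -> GenotypeData:
    """Ascertained case-control sample under a logistic penetrance.

    Genotype rows are drawn from ``spec`` in batches; each row becomes a
    case with probability logistic(linear predictor) and is kept until
    exactly ``n_case`` cases and ``n_ctrl`` controls have accumulated.
    Raises when either class accrues too slowly (acceptance below
    1 / ``max_draw_factor``), suggesting a beta0 adjustment.
    """
    if effects.max_index() >= spec.n_snps:
        raise ValueError("effect refers to a SNP index outside the genotype spec")
    rng = np.random.default_rng(seed)
    mafs = spec.resolve_mafs(np.random.default_rng(spec.seed))
    target = n_case + n_ctrl
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    drawn = 0
    batch = max(target, 1000)
    while len(cases) < n_case or len(ctrls) < n_ctrl:
        if drawn > max_draw_factor * target:
            raise ValueError(
                f"ascertainment too slow: {len(cases)}/{n_case} cases, "
                f"{len(ctrls)}/{n_ctrl} controls after {drawn} draws; adjust beta0"
            )
        g = _draw_genotypes(rng, batch, spec, mafs)
        drawn += batch
        eta = effects.linear_predictor(g, mafs=mafs)
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        for row, is_case in zip(g, y):
            if is_case and len(cases) < n_case:
                cases.append(row)
            elif not is_case and len(ctrls) < n_ctrl:
                ctrls.append(row)
    matrix = np.vstack(cases + ctrls)
    labels = np.concatenate([np.ones(n_case, dtype=np.int8), np.zeros(n_ctrl, dtype=np.int8)])
    # interleave deterministically so folds see both classes everywhere
    order = np.random.default_rng(seed + 1).permutation(target)
    sample_ids = [f"S{i:06d}" for i in range(target)]
    return GenotypeData(matrix[order], _snp_metadata(spec.n_snps), sample_ids, labels[order])


def make_pure_epistasis_effects(
    pairs: Sequence[tuple[int, int]],
    gamma: float,
    mafs: np.ndarray,
    beta0: float = 0.0,
    maf_tol: float = 1e-6,
) -> EffectSpec:
    """Carrier-XOR interaction pairs with exactly zero marginal effects.

    Each pair gets a log-odds increment of ``gamma`` when exactly one of
    the two SNPs carries at least one minor allele.  The participating SNPs
    must have MAF = 1 - sqrt(1/2) (carrier probability 1/2), which makes
    each SNP's marginal penetrance flat while the pair remains informative.
    """
    mafs = np.asarray(mafs, dtype=float)
    tables: dict[tuple[int, int], np.ndarray] = {}
    for i, j in pairs:
        for k in (i, j):
            if abs(mafs[k] - XOR_MAF) > maf_tol:
                raise ValueError(
                    f"SNP {k}: carrier-XOR pairs need MAF = {XOR_MAF:.6f} "
                    f"(carrier probability 1/2), got {mafs[k]:.6f}"
                )
        carrier = np.array([0.0, 1.0, 1.0])
        xor = np.abs(np.subtract.outer(carrier, carrier))  # 1 iff exactly one carrier
        tables[(i, j)] = gamma * xor
    return EffectSpec(beta0=beta0, pair_tables=tables)


def simulate_quantitative(
    G: GenotypeData,
    effects: EffectSpec,
    sigma: float,
    seed: int,
) -> np.ndarray:
    """Quantitative trait: linear predictor of ``effects`` plus N(0, sigma^2).

    Product-term codings are centered at the empirical column means.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    eta = effects.linear_predictor(G.matrix)
    return eta + rng.normal(0.0, sigma, size=G.n_samples)


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixturePaths:
    plink_prefix: Path
    tsv: Path
    genes_bed: Path
    gene_sets_gmt: Path
    genotypes: GenotypeData  # repositioned copy actually written


def emit_annotation_fixtures(
    G: GenotypeData,
    gene_design: dict[str, Sequence[int]],
    outdir: str | Path,
    gene_sets: Optional[dict[str, Sequence[str]]] = None,
    window_bp: int = 50_000,
) -> FixturePaths:
    """Write BED/GMT/PLINK/TSV fixtures whose proximity assignment at the
    given window reproduces ``gene_design`` exactly.

    Genes must claim disjoint SNP index sets; each gene's SNPs are placed
    contiguously inside its interval, genes are spaced more than twice the
    window apart, and unassigned SNPs go to a separate chromosome, so
    re-running the 50 kb proximity assignment returns the design verbatim.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    claimed: set[int] = set()
    for gene, idx in gene_design.items():
        overlap = claimed & set(idx)
        if overlap:
            raise ValueError(
                f"gene {gene}: SNPs {sorted(overlap)} already claimed; "
                "fixture gene designs must be disjoint"
            )
        claimed |= set(idx)

    spacing = 100
    gap = 2 * window_bp + 100_000
    new_snps: list[Optional[SnpInfo]] = [None] * G.n_snps
    records: list[GeneRecord] = []
    cursor = gap
    for gene in sorted(gene_design):
        idx = list(gene_design[gene])
        start = cursor
        end = start + spacing * max(len(idx), 1)
        for k, snp_i in enumerate(idx):
            old = G.snps[snp_i]
            new_snps[snp_i] = SnpInfo(
                id=old.id, chrom="1", pos=start + k * spacing + 1, alleles=old.alleles
            )
        records.append(GeneRecord(gene_id=gene, chrom="1", start=start, end=end))
        cursor = end + gap
    pos_u = 1
    for i in range(G.n_snps):
        if new_snps[i] is None:
            old = G.snps[i]
            new_snps[i] = SnpInfo(id=old.id, chrom="U", pos=pos_u, alleles=old.alleles)
            pos_u += spacing

    repositioned = GenotypeData(G.matrix.copy(), new_snps, list(G.sample_ids), G.labels)
    plink_prefix = outdir / "genotypes"
    tsv = outdir / "genotypes.tsv"
    genes_bed = outdir / "genes.bed"
    gmt = outdir / "gene_sets.gmt"
    write_plink(repositioned, plink_prefix)
    write_genotypes_tsv(repositioned, tsv)
    write_gene_table(GeneTable(records), genes_bed)
    if gene_sets is None:
        gene_sets = {"ALL": sorted(gene_design)}
    collection = GeneSetCollection(
        sets={name: set(members) for name, members in gene_sets.items()},
        descriptions={name: "synthetic fixture" for name in gene_sets},
    )
    write_gene_sets(collection, gmt)
    logger.info("wrote annotation fixtures to %s", outdir)
    return FixturePaths(
        plink_prefix=plink_prefix, tsv=tsv, genes_bed=genes_bed,
        gene_sets_gmt=gmt, genotypes=repositioned,
    )
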