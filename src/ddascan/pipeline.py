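"""Config-driven orchestration of the full association analysis.

A run goes: load (PLINK/TSV + BED + GMT) or simulate a scenario -> build
SNP groups (min size, dedupe, optional LD pruning) -> cross-validated
epsilon-optimized AUC scan -> permutation null on a calibration subset of
groups -> AUC-to-p calibration regression -> p-values for all groups ->
Bonferroni flagging and Benjamini-Hochberg q-values.  A manifest records
the seed, a config hash, package versions and per-stage counts so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .io import GenotypeData, read_gene_sets, read_gene_table, read_genotypes
from .grouping import assign_snps_to_genes, build_snp_groups
from .scan import ScanConfig, group_scores_frame, scan_groups, scan_snps
from .significance import (
    bh_fdr,
    bonferroni_threshold,
    calibrate_auc_to_p,
    permutation_null,
    permutation_pvalue,
    predict_pvalues,
    select_calibration_groups,
)
from .simulate import (
    XOR_MAF,
    EffectSpec,
    SimSpec,
    make_pure_epistasis_effects,
    simulate_case_control,
)

logger = logging.getLogger("ddascan")


def stage_seed(seed: int, stage: int) -> int:
    """Derive a per-stage seed from the global seed (counter-based, < 2^31)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A fully seeded synthetic dataset design.

    ``effect_kind``: 'null' (labels independent of genotypes), 'main'
    (additive log-odds ``effect_size`` per minor allele on
    ``n_effect_snps`` SNPs of the causal group), 'epistasis'
    (``n_effect_pairs`` carrier-XOR pairs with log-odds increment
    ``effect_size`` in the causal group; the paired SNPs are pinned to
    MAF = 1 - sqrt(1/2); the intercept is centered so overall prevalence
    stays near 1/2), or 'gradient' (every group k carries
    ``n_effect_snps`` additive SNPs with per-allele log-odds
    ``effect_size`` * k / (n_groups - 1), giving a spread of association
    strengths for calibration studies).
    """

    n_case: int = 250
    n_ctrl: int = 250
    n_groups: int = 10
    snps_per_group: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    ld_block_size: int = 0
    effect_kind: str = "null"
    effect_size: float = 0.0
    n_effect_snps: int = 0
    n_effect_pairs: int = 0
    causal_group: int = 0

    def __post_init__(self) -> None:
        if self.effect_kind not in ("null", "main", "epistasis", "gradient"):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.causal_group >= self.n_groups:
            raise ValueError("causal_group out of range")

    @property
    def n_snps(self) -> int:
        return self.n_groups * self.snps_per_group

    def group_indices(self, k: int) -> np.ndarray:
        start = k * self.snps_per_group
        return np.arange(start, start + self.snps_per_group)

    def build(self, seed: int) -> tuple[GenotypeData, dict[str, set[int]]]:
        """Simulate the dataset; returns (genotypes+labels, gene_map)."""
        rng = np.random.default_rng(seed)
        lo, hi = self.maf_range
        mafs = rng.uniform(lo, hi, size=self.n_snps)
        causal = self.group_indices(self.causal_group)
        effects = EffectSpec(beta0=0.0)
        if self.effect_kind == "main":
            chosen = causal[: self.n_effect_snps]
            effects = EffectSpec(
                beta0=0.0, beta={int(i): self.effect_size for i in chosen}
            )
        elif self.effect_kind == "epistasis":
            pair_snps = causal[: 2 * self.n_effect_pairs]
            mafs[pair_snps] = XOR_MAF
            pairs = [
                (int(pair_snps[2 * k]), int(pair_snps[2 * k + 1]))
                for k in range(self.n_effect_pairs)
            ]
            # each XOR increment fires with probability 1/2; center the
            # intercept so the pre-ascertainment prevalence stays near 1/2
            beta0 = -0.5 * self.effect_size * self.n_effect_pairs
            effects = make_pure_epistasis_effects(pairs, self.effect_size, mafs, beta0=beta0)
        elif self.effect_kind == "gradient":
            beta: dict[int, float] = {}
            denom = max(self.n_groups - 1, 1)
            for k in range(self.n_groups):
                bk = self.effect_size * k / denom
                for i in self.group_indices(k)[: self.n_effect_snps]:
                    beta[int(i)] = bk
            mean_shift = sum(b * 2 * mafs[i] for i, b in beta.items())
            effects = EffectSpec(beta0=-mean_shift, beta=beta)
        blocks = []
        if self.ld_block_size > 1:
            n_blocks = self.n_snps // self.ld_block_size
            blocks = [(self.ld_block_size, self.ld_rho)] * n_blocks
        spec = SimSpec(
            n_samples=self.n_case + self.n_ctrl, n_snps=self.n_snps,
            maf_range=self.maf_range, ld_blocks=blocks, seed=seed, mafs=mafs,
        )
        G = simulate_case_control(spec, effects, self.n_case, self.n_ctrl, seed=seed + 1)
        gene_map = {
            f"G{k:04d}": set(int(i) for i in self.group_indices(k))
            for k in range(self.n_groups)
        }
        return G, gene_map


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of input paths / scenario."""

    mode: str = "pathway-scan"  # {snp-scan, gene-scan, pathway-scan}
    genotypes: Optional[str] = None
    genotype_format: str = "plink-bed"
    genes_bed: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    scenario: Optional[Scenario] = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    permutation_R: int = 1000
    calibration_quantile: float = 0.25
    calibration_cap: Optional[int] = None
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    min_snps: Optional[int] = None  # default: 20 pathway mode, 1 gene mode
    dedupe: bool = True
    window_bp: int = 50_000
    seed: int = 0
    outdir: str = "ddascan_out"

    def __post_init__(self) -> None:
        if self.mode not in ("snp-scan", "gene-scan", "pathway-scan"):
            raise ValueError(f"unknown mode {self.mode!r}")
        has_files = self.genotypes is not None
        has_scenario = self.scenario is not None
        if has_files == has_scenario:
            raise ValueError("exactly one of input paths / scenario must be given")
        if has_files:
            if self.mode != "snp-scan" and self.genes_bed is None:
                raise ValueError(f"mode {self.mode} requires genes_bed")
            if self.mode == "pathway-scan" and self.gene_sets_gmt is None:
                raise ValueError("pathway-scan requires gene_sets_gmt")

    def effective_min_snps(self) -> int:
        if self.min_snps is not None:
            return self.min_snps
        return 20 if self.mode == "pathway-scan" else 1

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            raise TypeError(type(o))

        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # output location does not affect any result byte
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    group_scores: pd.DataFrame
    snp_scores: Optional[pd.DataFrame]
    manifest: dict
    bonferroni: float
    outdir: Path


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        G, gene_map = config.scenario.build(stage_seed(config.seed, 0))
        gene_sets = None
        if config.mode == "pathway-scan":
            # one pathway per simulated gene group
            from .io import GeneSetCollection

            gene_sets = GeneSetCollection(
                sets={f"P_{g}": {g} for g in gene_map},
                descriptions={f"P_{g}": "simulated" for g in gene_map},
            )
        return G, gene_map, gene_sets
    G = read_genotypes(config.genotypes, format=config.genotype_format)
    gene_map = None
    gene_sets = None
    if config.mode != "snp-scan":
        genes = read_gene_table(config.genes_bed)
        gene_map = assign_snps_to_genes(G.snps, genes, window_bp=config.window_bp)
    if config.mode == "pathway-scan":
        gene_sets = read_gene_sets(config.gene_sets_gmt)
    return G, gene_map, gene_sets


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; writes tables and a run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    logger.info("stage: load/simulate")
    try:
        G, gene_map, gene_sets = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage load/simulate failed: {exc}") from exc
    if G.labels is None:
        raise RuntimeError("stage load/simulate failed: genotypes carry no phenotype labels")
    counts["n_samples"] = G.n_samples
    counts["n_snps"] = G.n_snps
    counts["n_cases"] = int(G.labels.sum())

    snp_frame = None
    if config.mode == "snp-scan":
        logger.info("stage: snp scan")
        snp_frame = scan_snps(G, G.labels)
        snp_frame.to_csv(outdir / "snp_scores.tsv", sep="\t", index=False)
        counts["n_snps_tested"] = int(snp_frame["p"].notna().sum())
        manifest = _manifest(config, counts)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineResult(
            group_scores=pd.DataFrame(), snp_scores=snp_frame,
            manifest=manifest, bonferroni=np.nan, outdir=outdir,
        )

    logger.info("stage: group construction")
    try:
        groups = build_snp_groups(
            gene_map, gene_sets=gene_sets,
            min_snps=config.effective_min_snps(), dedupe=config.dedupe,
        )
    except Exception as exc:
        raise RuntimeError(f"stage group construction failed: {exc}") from exc
    if not groups:
        raise RuntimeError("stage group construction failed: no groups pass the size filter")
    counts["n_groups"] = len(groups)

    logger.info("stage: scan (%d groups)", len(groups))
    scan_cfg = dataclasses.replace(config.scan, seed=stage_seed(config.seed, 1))
    try:
        scores = scan_groups(G, G.labels, groups, scan_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage scan failed: {exc}") from exc
    counts["n_groups_scored"] = sum(1 for s in scores if s.error is None)

    logger.info("stage: permutation calibration")
    by_name = {g.name: g for g in groups}
    try:
        calib_names = select_calibration_groups(
            scores, quantile=config.calibration_quantile, cap=config.calibration_cap
        )
        pairs_cl, pairs_il = [], []
        perm_seed = stage_seed(config.seed, 2)
        for k, name in enumerate(calib_names):
            score = next(s for s in scores if s.name == name)
            perm_cfg = dataclasses.replace(scan_cfg, seed=(perm_seed + k) % 2**31)
            null = permutation_null(G, G.labels, by_name[name], config.permutation_R, perm_cfg)
            pairs_cl.append((score.auc_cl, permutation_pvalue(score.auc_cl, null)))
            pairs_il.append((score.auc_il, permutation_pvalue(score.auc_il, null, il=True)))
        fit_cl = calibrate_auc_to_p(pairs_cl)
        fit_il = calibrate_auc_to_p(pairs_il)
    except Exception as exc:
        group_scores_frame(scores).to_csv(outdir / "group_scores.tsv", sep="\t", index=False)
        raise RuntimeError(f"stage permutation calibration failed: {exc}") from exc
    counts["n_calibration_groups"] = len(calib_names)

    logger.info("stage: p-value prediction and multiple-testing control")
    valid = [s for s in scores if s.error is None]
    p_cl, extra_cl = predict_pvalues(fit_cl, [s.auc_cl for s in valid])
    p_il, _ = predict_pvalues(fit_il, [s.auc_il for s in valid])
    for s, pc, pi, ex in zip(valid, p_cl, p_il, extra_cl):
        s.p_cl, s.p_il, s.extrapolated = float(pc), float(pi), bool(ex)
    qs = bh_fdr([s.p_cl for s in valid])
    for s, q in zip(valid, qs):
        s.q_value = float(q)
    bonf = bonferroni_threshold(config.alpha, len(valid))
    counts["n_bonferroni_hits"] = int(sum(s.p_cl < bonf for s in valid))
    counts["n_fdr_hits"] = int(sum(s.q_value < config.fdr_threshold for s in valid))

    frame = group_scores_frame(scores)
    frame.to_csv(outdir / "group_scores.tsv", sep="\t", index=False)
    calib_dump = {
        "cl": {"r_squared": fit_cl.r_squared, "auc_range": list(fit_cl.auc_range),
               "monotone": fit_cl.monotone, "pairs": pairs_cl},
        "il": {"r_squared": fit_il.r_squared, "auc_range": list(fit_il.auc_range),
               "monotone": fit_il.monotone, "pairs": pairs_il},
        "bonferroni_threshold": bonf,
    }
    (outdir / "calibration.json").write_text(json.dumps(calib_dump, indent=2, sort_keys=True))
    manifest = _manifest(config, counts)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        group_scores=frame, snp_scores=snp_frame, manifest=manifest,
        bonferroni=bonf, outdir=outdir,
    )


def _manifest(config: PipelineConfig, counts: dict[str, int]) -> dict:
    return {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "versions": {
            "ddascan": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
    }
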