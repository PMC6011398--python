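"""Cross-validated AUC scoring of SNP groups and genome-wide scans.

Each SNP group is scored by the mean held-out AUC of the DDA discriminant
under seeded stratified K-fold cross-validation (default 5-fold: 80% of
individuals fit the class models, 20% are scored).  The coupling
regularizer epsilon is optimized over a grid in [0, 1] on the *same* fold
partition for every grid value; the reported collective-loci (CL) AUC is
the grid maximum and the independent-loci (IL) AUC is the value at
epsilon = 0, so CL >= IL holds by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeData, MISSING
from .grouping import SnpGroup, ld_prune_group
from .dda import (
    DEFAULT_COND_CAP,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_RIDGE_DELTA,
    _fields_couplings_grid,
    _score_from_params,
    il_snp_test,
)

logger = logging.getLogger("ddascan")


@dataclass(frozen=True)
class ScanConfig:
    """Knobs for group scoring.

    epsilon_grid must contain 0 so the IL special case is always evaluated.
    """

    n_folds: int = 5
    epsilon_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    seed: int = 0
    stratified: bool = True
    r2_max: Optional[float] = None  # None disables per-group LD pruning
    cond_cap: float = DEFAULT_COND_CAP
    ridge_delta: float = DEFAULT_RIDGE_DELTA

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        grid = np.asarray(self.epsilon_grid, dtype=float)
        if grid.size == 0 or (grid < 0).any() or (grid > 1).any():
            raise ValueError("epsilon_grid must lie in [0, 1]")
        if 0.0 not in grid:
            raise ValueError("epsilon_grid must contain 0")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("epsilon_grid must be sorted and unique")


@dataclass
class GroupScore:
    """Per-group scan result; p/q fields are filled by the significance stage."""

    name: str
    n_snps: int
    epsilon_star: float
    auc_cl: float
    auc_il: float
    p_cl: float = np.nan
    p_il: float = np.nan
    q_value: float = np.nan
    extrapolated: bool = False
    error: Optional[str] = None


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _average_ranks(scores: np.ndarray) -> np.ndarray:
    """Midranks (ties get the average of their rank range), 1-based."""
    order = np.argsort(scores, kind="stable")
    sorted_s = scores[order]
    new_group = np.empty(scores.size, dtype=bool)
    new_group[0] = True
    np.not_equal(sorted_s[1:], sorted_s[:-1], out=new_group[1:])
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    hi = np.cumsum(counts)
    avg = hi - (counts - 1) / 2.0
    ranks = np.empty(scores.size)
    ranks[order] = avg[group]
    return ranks


def auc(scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score) + 1/2 P(tie).

    Computed from average ranks; ties contribute one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    r = _average_ranks(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# Cross-validation engine
# ---------------------------------------------------------------------------

def fold_indices(
    labels: np.ndarray, n_folds: int, seed: int, stratified: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (stratified) K-fold partition; depends only on (labels, K, seed).

    Stratified mode shuffles each class separately and deals its members
    round-robin into the K test folds, so every fold's class ratio matches
    the sample's to within one individual (same guarantee as
    sklearn's StratifiedKFold, which the test suite cross-checks, but
    cheap enough for permutation inner loops).
    """
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    if stratified:
        for y in np.unique(labels):
            members = np.flatnonzero(labels == y)
            rng.shuffle(members)
            fold_of[members] = np.arange(members.size) % n_folds
    else:
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % n_folds
    out = []
    for k in range(n_folds):
        te = np.flatnonzero(fold_of == k)
        tr = np.flatnonzero(fold_of != k)
        out.append((tr, te))
    return out


def _impute_columns(sub: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Training-mode imputation on a genotype submatrix (columns = group SNPs)."""
    if not (sub == MISSING).any():
        return sub
    sub = sub.copy()
    for c in range(sub.shape[1]):
        col = sub[:, c]
        if not (col == MISSING).any():
            continue
        tr = col[train]
        tr = tr[tr != MISSING]
        if tr.size == 0:
            raise ValueError(f"group column {c}: all training genotypes missing")
        mode = int(np.argmax(np.bincount(tr, minlength=3)))
        col[col == MISSING] = mode
    return sub


def _encode(sub: np.ndarray) -> np.ndarray:
    n, m = sub.shape
    X = np.zeros((n, 2 * m), dtype=np.float64)
    X[:, 0::2] = sub == 1
    X[:, 1::2] = sub == 2
    return X


def cv_auc_curve(
    G: GenotypeData,
    labels: np.ndarray,
    group: SnpGroup,
    epsilon_grid: Sequence[float] | np.ndarray,
    config: ScanConfig,
    folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> np.ndarray:
    """Mean held-out AUC at every epsilon of the grid, on a shared fold
    partition.

    Per fold: impute the group's missing calls with training-set modes,
    encode, fit both class models at every grid epsilon (count statistics
    shared across the grid), score the held-out fold, and average the K
    test AUCs per epsilon.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both phenotype classes required")
    if len(group) == 0:
        raise ValueError(f"group {group.name} is empty")
    eps = np.asarray(epsilon_grid, dtype=float)
    if folds is None:
        folds = fold_indices(labels, config.n_folds, config.seed, config.stratified)

    sub_all = G.matrix[:, group.snp_indices]
    aucs = np.zeros((len(folds), eps.size))
    for k, (tr, te) in enumerate(folds):
        if np.unique(labels[te]).size < 2 or np.unique(labels[tr]).size < 2:
            raise ValueError(f"fold {k} contains a single phenotype class")
        sub = _impute_columns(sub_all, tr)
        X = _encode(sub)
        params = {}
        for y in (0, 1):
            rows = tr[labels[tr] == y]
            _, _, _, H, Js = _fields_couplings_grid(
                X[rows], eps, config.pseudocount, config.cond_cap, config.ridge_delta
            )
            params[y] = (H, Js)
        Xte, yte = X[te], labels[te]
        H1, J1 = params[1]
        H0, J0 = params[0]
        for e in range(eps.size):
            s = _score_from_params(Xte, H1[e] - H0[e], J1[e] - J0[e])
            aucs[k, e] = auc(s, yte)
    return aucs.mean(axis=0)


def cv_auc(
    G: GenotypeData,
    labels: np.ndarray,
    group: SnpGroup,
    epsilon: float,
    config: ScanConfig,
) -> float:
    """Mean held-out AUC at a single epsilon (see :func:`cv_auc_curve`)."""
    return float(cv_auc_curve(G, labels, group, [epsilon], config)[0])


def optimize_epsilon(
    G: GenotypeData,
    labels: np.ndarray,
    group: SnpGroup,
    config: ScanConfig,
    folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> tuple[float, float, float]:
    """Maximize the cross-validated AUC over the epsilon grid.

    All grid values are evaluated on the same fold partition; ties resolve
    to the smallest epsilon.  Returns (epsilon_star, auc_star, auc_at_zero).
    """
    grid = np.asarray(config.epsilon_grid, dtype=float)
    curve = cv_auc_curve(G, labels, group, grid, config, folds=folds)
    best = int(np.argmax(curve))  # first occurrence of the max -> smallest epsilon
    zero_idx = int(np.flatnonzero(grid == 0.0)[0])
    return float(grid[best]), float(curve[best]), float(curve[zero_idx])


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

def scan_groups(
    G: GenotypeData,
    labels: np.ndarray,
    groups: list[SnpGroup],
    config: ScanConfig,
) -> list[GroupScore]:
    """Score every group; rows sorted by CL AUC descending.

    Per-group failures are logged and reported as NA rows; the scan
    continues.  Duplicate group names abort before scanning.
    """
    if not groups:
        raise ValueError("at least one group required")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate group names: {', '.join(dupes)}")
    results: list[GroupScore] = []
    for g in groups:
        try:
            if config.r2_max is not None:
                g = ld_prune_group(G, g, config.r2_max)
            eps_star, auc_star, auc0 = optimize_epsilon(G, labels, g, config)
            results.append(
                GroupScore(
                    name=g.name, n_snps=len(g), epsilon_star=eps_star,
                    auc_cl=auc_star, auc_il=auc0,
                )
            )
        except Exception as exc:  # per-group failure must not kill the scan
            logger.error("group %s failed: %s", g.name, exc)
            results.append(
                GroupScore(
                    name=g.name, n_snps=len(g), epsilon_star=np.nan,
                    auc_cl=np.nan, auc_il=np.nan, error=str(exc),
                )
            )
        else:
            logger.info(
                "scored %s: n_snps=%d eps*=%.2f AUC_CL=%.4f AUC_IL=%.4f",
                g.name, len(g), eps_star, auc_star, auc0,
            )
    results.sort(key=lambda r: (-(r.auc_cl if np.isfinite(r.auc_cl) else -np.inf), r.name))
    return results


def scan_snps(G: GenotypeData, labels: np.ndarray) -> pd.DataFrame:
    """Per-SNP IL association scan (Manhattan-plot input).

    Monomorphic SNPs get NA statistic/p rows.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both phenotype classes required")
    rows = []
    for i, s in enumerate(G.snps):
        col = G.matrix[:, i]
        vals = col[col != MISSING]
        if vals.size == 0 or np.unique(vals).size < 2:
            rows.append((s.id, s.chrom, s.pos, np.nan, np.nan))
            continue
        res = il_snp_test(G, labels, i)
        rows.append((s.id, s.chrom, s.pos, res.statistic, res.pvalue))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "statistic", "p"])


def group_scores_frame(scores: list[GroupScore]) -> pd.DataFrame:
    """Tabular view of scan results, suitable for TSV output."""
    return pd.DataFrame(
        [
            {
                "group": s.name, "n_snps": s.n_snps, "epsilon_star": s.epsilon_star,
                "auc_cl": s.auc_cl, "auc_il": s.auc_il, "p_cl": s.p_cl,
                "p_il": s.p_il, "q_value": s.q_value,
                "calibration_extrapolated": s.extrapolated,
            }
            for s in scores
        ]
    )
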