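"""Permutation calibration and multiple-testing control.

Because the reported group statistic is an epsilon-optimized
cross-validated AUC, its null distribution is shifted above 0.5; a valid
p-value therefore comes from phenotype-label permutations in which epsilon
is *re-optimized for every replicate*, reproducing the selection bias under
the null.  Running permutations for every group is expensive, so p-values
are obtained in two steps: permutation p-values are computed for a
calibration subset of groups, a quadratic orthogonal-polynomial regression
of log10(p) on AUC is fitted to those pairs, and the regression converts
every group's AUC into a p-value.  Bonferroni thresholds (alpha / m) and
Benjamini-Hochberg q-values control family-wise error and FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import GenotypeData
from .grouping import SnpGroup
from .scan import GroupScore, ScanConfig, optimize_epsilon

logger = logging.getLogger("ddascan")


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Epsilon-re-optimized AUCs under phenotype-label permutation.

    ``null_aucs`` are the grid-maximized (CL) values; ``null_aucs_il`` the
    epsilon = 0 values from the same replicates, usable to calibrate IL
    p-values at no extra cost.
    """

    group_name: str
    n_replicates: int
    null_aucs: np.ndarray
    null_aucs_il: np.ndarray
    seed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.null_aucs = np.asarray(self.null_aucs, dtype=float)
        self.null_aucs_il = np.asarray(self.null_aucs_il, dtype=float)
        if self.null_aucs.size < 1:
            raise ValueError("need at least one successful replicate")
        if ((self.null_aucs < 0) | (self.null_aucs > 1)).any():
            raise ValueError("null AUCs must lie in [0, 1]")


def permutation_null(
    G: GenotypeData,
    labels: np.ndarray,
    group: SnpGroup,
    R: int,
    config: ScanConfig,
) -> NullDistribution:
    """R label-permutation replicates with per-replicate epsilon optimization.

    Each replicate permutes the labels uniformly at random, draws a fresh
    fold seed, and records the grid-optimized AUC (and the epsilon = 0 AUC).
    Failed replicates are dropped and counted.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    aucs, aucs_il = [], []
    n_failed = 0
    for r in range(R):
        perm = rng.permutation(labels)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        rep_config = ScanConfig(
            n_folds=config.n_folds, epsilon_grid=config.epsilon_grid,
            pseudocount=config.pseudocount, seed=fold_seed,
            stratified=config.stratified, r2_max=None,
            cond_cap=config.cond_cap, ridge_delta=config.ridge_delta,
        )
        try:
            _, auc_star, auc0 = optimize_epsilon(G, perm, group, rep_config)
        except Exception as exc:
            n_failed += 1
            logger.warning("permutation replicate %d for %s failed: %s", r, group.name, exc)
            continue
        aucs.append(auc_star)
        aucs_il.append(auc0)
    return NullDistribution(
        group_name=group.name, n_replicates=len(aucs),
        null_aucs=np.array(aucs), null_aucs_il=np.array(aucs_il),
        seed=config.seed, n_failed=n_failed,
    )


def permutation_pvalue(auc_obs: float, null: NullDistribution, il: bool = False) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (R + 1).

    Ties count toward the numerator; the estimate can never be 0 and never
    exceeds 1.
    """
    aucs = null.null_aucs_il if il else null.null_aucs
    R = aucs.size
    return float((1 + int((aucs >= auc_obs).sum())) / (R + 1))


# ---------------------------------------------------------------------------
# AUC -> p calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationFit:
    """Quadratic orthogonal-polynomial regression of log10(p) on AUC.

    The monomial design [1, a, a^2] over the training AUCs is
    orthonormalized by a thin QR decomposition; ``coef`` are the
    coefficients in the orthonormal basis and ``r_inv`` maps new monomial
    rows into it, so prediction is numerically stable far from the
    training mean.
    """

    coef: np.ndarray          # (3,) coefficients in the orthonormal basis
    r_inv: np.ndarray         # (3, 3) inverse of the QR R factor
    r_squared: float
    auc_range: tuple[float, float]
    monotone: bool = True

    def basis(self, aucs: np.ndarray) -> np.ndarray:
        V = np.vander(np.asarray(aucs, dtype=float), 3, increasing=True)
        return V @ self.r_inv

    def log10_p(self, aucs: np.ndarray) -> np.ndarray:
        return self.basis(np.asarray(aucs, dtype=float)) @ self.coef


def calibrate_auc_to_p(pairs: Sequence[tuple[float, float]]) -> CalibrationFit:
    """Fit log10(p) ~ orthogonal quadratic in AUC over permutation-tested groups.

    Requires >= 4 pairs with p in (0, 1].  Warns if the fitted quadratic is
    non-monotone inside the fitted AUC range (a symptom of too-narrow an
    AUC spread in the calibration subset).
    """
    pairs = list(pairs)
    if len(pairs) < 4:
        raise ValueError(f"need at least 4 (auc, p) pairs, got {len(pairs)}")
    aucs = np.array([a for a, _ in pairs], dtype=float)
    ps = np.array([p for _, p in pairs], dtype=float)
    if ((ps <= 0) | (ps > 1)).any():
        raise ValueError("all p-values must lie in (0, 1]")
    if np.ptp(aucs) == 0:
        raise ValueError("zero variance in AUC; cannot calibrate")
    y = np.log10(ps)
    V = np.vander(aucs, 3, increasing=True)
    Q, R = np.linalg.qr(V)
    coef = Q.T @ y
    fitted = Q @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r_inv = np.linalg.inv(R)
    lo, hi = float(aucs.min()), float(aucs.max())
    # monomial coefficients b0 + b1 a + b2 a^2; derivative sign on [lo, hi]
    b = r_inv @ coef
    d_lo, d_hi = b[1] + 2 * b[2] * lo, b[1] + 2 * b[2] * hi
    monotone = bool(d_lo * d_hi >= 0)
    if not monotone:
        logger.warning(
            "calibration fit is non-monotone within AUC range [%.3f, %.3f]", lo, hi
        )
    return CalibrationFit(
        coef=coef, r_inv=r_inv, r_squared=float(np.clip(r2, 0.0, 1.0)),
        auc_range=(lo, hi), monotone=monotone,
    )


def predict_pvalues(
    fit: CalibrationFit, aucs: Sequence[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert AUCs into p-values through the calibration regression.

    Returns (p, extrapolated): p = 10^fit(auc) clipped into (0, 1];
    ``extrapolated`` flags AUCs outside the fitted range.
    """
    aucs = np.asarray(aucs, dtype=float)
    log_p = fit.log10_p(aucs)
    p = np.minimum(np.power(10.0, log_p), 1.0)
    lo, hi = fit.auc_range
    extrapolated = (aucs < lo) | (aucs > hi)
    return p, extrapolated


def select_calibration_groups(
    scores: list[GroupScore],
    quantile: float = 0.25,
    cap: Optional[int] = None,
) -> list[str]:
    """Pick the calibration subset: groups at or below a SNP-count quantile.

    Permutation cost grows with group size, so calibration uses the smaller
    groups (SNP count <= the given quantile of all group sizes); ``cap``
    limits the subset further, keeping the smallest.
    """
    valid = [s for s in scores if np.isfinite(s.auc_cl)]
    if not valid:
        raise ValueError("no successfully scored groups")
    sizes = np.array([s.n_snps for s in valid])
    cutoff = np.quantile(sizes, quantile)
    subset = [s for s in valid if s.n_snps <= cutoff]
    if len(subset) < 4:  # regression needs at least 4 points
        subset = sorted(valid, key=lambda s: s.n_snps)[: max(4, len(subset))]
    if cap is not None and len(subset) > cap:
        subset = sorted(subset, key=lambda s: s.n_snps)[:cap]
    return [s.name for s in subset]


# ---------------------------------------------------------------------------
# Multiple-testing control
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order restored."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
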