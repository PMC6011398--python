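"""Discrete discriminant analysis (DDA) core.

The genotypic model treats each SNP's three genotype categories {0, 1, 2}
without an additive constraint.  Category 0 (major-allele homozygote) is
the reference; the two non-reference categories give each SNP two binary
indicator columns, hence 2 free field parameters per SNP and a 2x2 coupling
block — 4 free parameters — per SNP pair.

Per phenotype class, the model holds pseudocounted category frequencies
f_i(a), fields h_i(a), and pairwise couplings J_{(i,a),(j,b)} obtained by
naive mean-field inversion: the covariance matrix C of the indicator
columns is regularized by interpolating its cross-SNP blocks with a factor
``epsilon`` in [0, 1] (0 = non-interacting, 1 = fully interacting), and the
couplings are the negated cross-SNP blocks of C(epsilon)^-1.  Fields are
chosen so that the model's single-site conditionals reproduce the observed
category frequencies under the mean-field closure:

    h_i(a) = ln(f_i(a) / f_i(0)) - sum_{j != i, b} J_{(i,a),(j,b)} f_j(b)

At epsilon = 0 the couplings vanish exactly and the model reduces to the
independent-loci (IL) per-SNP log-frequency-ratio score.

Individuals are scored by the difference of class log-unnormalized
likelihoods (normalization constants drop out of rank statistics such as
the AUC):

    s(x) = sum_{i,a} [h1 - h0]_i(a) x_i(a)
         + 1/2 sum_{i != j, a, b} [J1 - J0]_{(i,a),(j,b)} x_i(a) x_j(b)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .io import GenotypeData, MISSING
from .grouping import SnpGroup

logger = logging.getLogger("ddascan")

#: Default pseudocount per genotype category (lambda/3 per joint cell).
DEFAULT_PSEUDOCOUNT: float = 0.5
#: Condition-number cap beyond which a ridge is added before inversion.
DEFAULT_COND_CAP: float = 1e12
#: Ridge scale, multiplied by tr(C)/dim.
DEFAULT_RIDGE_DELTA: float = 1e-6


# ---------------------------------------------------------------------------
# Encoding and imputation
# ---------------------------------------------------------------------------

@dataclass
class EncodedMatrix:
    """Binary indicator encoding: two columns per SNP (categories 1 and 2)."""

    data: np.ndarray                      # (n_samples, 2*m) float64
    snp_indices: np.ndarray               # m original column indices

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1] // 2

    def column_map(self) -> list[tuple[int, int]]:
        """(snp_index, category) for each indicator column."""
        out = []
        for i in self.snp_indices:
            out.append((int(i), 1))
            out.append((int(i), 2))
        return out


def encode_genotypic(G: GenotypeData, snp_indices: Sequence[int] | np.ndarray) -> EncodedMatrix:
    """Encode selected SNPs under the genotypic (2 df per SNP) model.

    Genotype 0 -> (0, 0); 1 -> (1, 0); 2 -> (0, 1).  Missing values must be
    imputed first (see :func:`impute_missing`).
    """
    idx = np.asarray(snp_indices, dtype=np.int64)
    sub = G.matrix[:, idx]
    if (sub == MISSING).any():
        raise ValueError(
            "missing genotypes among selected SNPs; run impute_missing first"
        )
    n, m = sub.shape
    X = np.zeros((n, 2 * m), dtype=np.float64)
    X[:, 0::2] = sub == 1
    X[:, 1::2] = sub == 2
    return EncodedMatrix(data=X, snp_indices=idx)


def impute_missing(
    G: GenotypeData,
    group: SnpGroup,
    train_sample_indices: Sequence[int] | np.ndarray,
) -> GenotypeData:
    """Replace missing calls in the group's SNPs by the training-set mode.

    The per-SNP modal genotype is computed on training samples only and
    applied to all samples (no leakage from test to train).  Ties break
    toward the smaller genotype value.
    """
    train = np.asarray(train_sample_indices, dtype=np.int64)
    matrix = G.matrix.copy()
    for i in group.snp_indices:
        col = matrix[:, i]
        if not (col == MISSING).any():
            continue
        tr = col[train]
        tr = tr[tr != MISSING]
        if tr.size == 0:
            raise ValueError(
                f"SNP {G.snps[i].id}: all training genotypes missing; cannot impute"
            )
        counts = np.bincount(tr, minlength=3)
        mode = int(np.argmax(counts))  # argmax takes the first max: smaller genotype
        col[col == MISSING] = mode
    return GenotypeData(matrix, G.snps, G.sample_ids, G.labels)


# ---------------------------------------------------------------------------
# Class-conditional model fitting
# ---------------------------------------------------------------------------

@dataclass
class ClassModel:
    """Fitted per-class DDA model at a given epsilon."""

    f0: np.ndarray                 # (m,) reference-category frequencies
    fnr: np.ndarray                # (2m,) non-reference frequencies, SNP-interleaved
    h: np.ndarray                  # (2m,) fields for categories 1, 2 per SNP
    J: np.ndarray                  # (2m, 2m) couplings; within-SNP blocks zero
    epsilon: float
    pseudocount: float
    n_train: int
    snp_indices: np.ndarray
    _pair_counts: np.ndarray = field(repr=False, default=None)  # X^T X

    @property
    def n_snps(self) -> int:
        return self.f0.size

    def category_frequencies(self) -> np.ndarray:
        """(3, m) array of pseudocounted frequencies over {0, 1, 2}."""
        m = self.n_snps
        out = np.empty((3, m))
        out[0] = self.f0
        out[1] = self.fnr[0::2]
        out[2] = self.fnr[1::2]
        return out

    def pair_frequencies(self, i: int, j: int) -> np.ndarray:
        """Pseudocounted 3x3 joint frequency table for SNP pair (i, j).

        Rows index SNP i's genotype, columns SNP j's.  Marginal consistency
        sum_b fpair(a, b) = f_i(a) holds exactly by the lambda/3 scheme.
        """
        if i == j:
            raise ValueError("pair_frequencies requires two distinct SNPs")
        lam, n = self.pseudocount, self.n_train
        denom = n + 3 * lam
        out = np.empty((3, 3))
        f_i = self.category_frequencies()[:, i]
        f_j = self.category_frequencies()[:, j]
        for a in (1, 2):
            for b in (1, 2):
                c = self._pair_counts[2 * i + (a - 1), 2 * j + (b - 1)]
                out[a, b] = (c + lam / 3) / denom
        for a in (1, 2):
            out[a, 0] = f_i[a] - out[a, 1] - out[a, 2]
        for b in (0, 1, 2):
            out[0, b] = f_j[b] - out[1, b] - out[2, b]
        return out

    def to_dict(self) -> dict:
        """JSON-serializable dump of fields, couplings and hyperparameters."""
        return {
            "epsilon": self.epsilon,
            "pseudocount": self.pseudocount,
            "n_train": self.n_train,
            "snp_indices": self.snp_indices.tolist(),
            "frequencies": self.category_frequencies().tolist(),
            "fields": self.h.tolist(),
            "couplings": self.J.tolist(),
        }


def _zero_within_snp_blocks(M: np.ndarray) -> None:
    """Zero the 2x2 within-SNP diagonal blocks of a (2m, 2m) matrix, in place."""
    m2 = M.shape[-1]
    idx = np.arange(0, m2, 2)
    M[..., idx, idx] = 0.0
    M[..., idx + 1, idx + 1] = 0.0
    M[..., idx, idx + 1] = 0.0
    M[..., idx + 1, idx] = 0.0


def _class_statistics(X: np.ndarray, lam: float):
    """Counts -> (f0, fnr, C, D_full, pair_counts) for one class submatrix."""
    n = X.shape[0]
    denom = n + 3 * lam
    s1 = X.sum(axis=0)                       # (2m,) category counts
    pair_counts = X.T @ X                    # (2m, 2m) joint counts
    fnr = (s1 + lam) / denom
    n0 = n - s1[0::2] - s1[1::2]
    f0 = (n0 + lam) / denom
    C = (pair_counts + lam / 3.0) / denom - np.outer(fnr, fnr)
    # exact within-SNP blocks: f_i(a) delta_ab - f_i(a) f_i(b)
    m = fnr.size // 2
    for k in range(0, 2 * m, 2):
        fa, fb = fnr[k], fnr[k + 1]
        C[k, k] = fa * (1 - fa)
        C[k + 1, k + 1] = fb * (1 - fb)
        C[k, k + 1] = C[k + 1, k] = -fa * fb
    D_full = np.zeros_like(C)
    for k in range(0, 2 * m, 2):
        D_full[k:k + 2, k:k + 2] = C[k:k + 2, k:k + 2]
    return f0, fnr, C, D_full, pair_counts


def _fields_couplings_grid(
    X: np.ndarray,
    epsilons: np.ndarray,
    lam: float,
    cond_cap: float,
    ridge_delta: float,
):
    """Fit (h, J) for every epsilon in one pass; shared count statistics.

    Returns (f0, fnr, pair_counts, H (k, 2m), Js (k, 2m, 2m)).
    """
    f0, fnr, C, D_full, pair_counts = _class_statistics(X, lam)
    Coff = C - D_full
    eps = np.asarray(epsilons, dtype=float)
    Cs = D_full[None, :, :] + eps[:, None, None] * Coff[None, :, :]
    dim = C.shape[0]

    # C(eps) is symmetric PD in exact arithmetic; invert first and fall back
    # to a ridge when the 1-norm condition estimate ||C||_1 ||C^-1||_1
    # exceeds the cap (cheap, within a factor of dim of the 2-norm value)
    try:
        K = np.linalg.inv(Cs)
    except np.linalg.LinAlgError:
        K = np.full_like(Cs, np.nan)
    norm_c = np.abs(Cs).sum(axis=1).max(axis=1)
    norm_k = np.abs(K).sum(axis=1).max(axis=1)
    cond = norm_c * norm_k
    bad = ~np.isfinite(cond) | (cond > cond_cap)
    if bad.any():
        for k in np.flatnonzero(bad):
            ridge = ridge_delta * np.trace(Cs[k]) / dim
            Cs[k] += ridge * np.eye(dim)
            logger.warning(
                "ill-conditioned covariance at epsilon=%.3g (cond~%.2e); "
                "added ridge %.3e", eps[k], cond[k], ridge,
            )
            try:
                K[k] = np.linalg.inv(Cs[k])
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"covariance at epsilon={eps[k]:.3g} singular even after ridge"
                ) from exc

    Js = -K
    _zero_within_snp_blocks(Js)
    # exact zero couplings at epsilon = 0 (C(0) is block-diagonal)
    Js[eps == 0.0] = 0.0
    base = np.log(fnr / np.repeat(f0, 2))
    H = base[None, :] - Js @ fnr
    return f0, fnr, pair_counts, H, Js


def fit_class_model(
    X: EncodedMatrix | np.ndarray,
    epsilon: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    cond_cap: float = DEFAULT_COND_CAP,
    ridge_delta: float = DEFAULT_RIDGE_DELTA,
    snp_indices: Optional[np.ndarray] = None,
) -> ClassModel:
    """Fit the class-conditional model at a single epsilon.

    ``X`` is the indicator encoding restricted to samples of one phenotype
    class.  ``epsilon`` in [0, 1] scales the cross-SNP covariance blocks
    before inversion; ``pseudocount`` is the per-category lambda (lambda/3
    per joint cell), which guarantees finite logs and exact marginal
    consistency of the joint frequencies.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if isinstance(X, EncodedMatrix):
        snp_indices = X.snp_indices
        X = X.data
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples in the class")
    if snp_indices is None:
        snp_indices = np.arange(X.shape[1] // 2)
    f0, fnr, pair_counts, H, Js = _fields_couplings_grid(
        X, np.array([epsilon]), pseudocount, cond_cap, ridge_delta
    )
    return ClassModel(
        f0=f0, fnr=fnr, h=H[0], J=Js[0],
        epsilon=float(epsilon), pseudocount=pseudocount,
        n_train=X.shape[0], snp_indices=np.asarray(snp_indices),
        _pair_counts=pair_counts,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_individuals(
    model_case: ClassModel,
    model_ctrl: ClassModel,
    X: EncodedMatrix | np.ndarray,
) -> np.ndarray:
    """Per-sample discriminant score (case vs control log-likelihood ratio
    up to an additive constant).

    Both models must have been fitted on the same SNP list at the same
    epsilon.  AUC and any other rank statistic are invariant to the dropped
    normalization constants.
    """
    if model_case.n_snps != model_ctrl.n_snps or not np.array_equal(
        model_case.snp_indices, model_ctrl.snp_indices
    ):
        raise ValueError("case and control models were fitted on different SNP lists")
    if model_case.epsilon != model_ctrl.epsilon:
        raise ValueError("case and control models were fitted at different epsilon")
    if isinstance(X, EncodedMatrix):
        X = X.data
    dh = model_case.h - model_ctrl.h
    dJ = model_case.J - model_ctrl.J
    return X @ dh + 0.5 * np.einsum("nk,nk->n", X @ dJ, X)


def _score_from_params(X: np.ndarray, dh: np.ndarray, dJ: np.ndarray) -> np.ndarray:
    return X @ dh + 0.5 * np.einsum("nk,nk->n", X @ dJ, X)


# ---------------------------------------------------------------------------
# Independent-loci single-SNP test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpTestResult:
    statistic: float
    pvalue: float
    df: int
    reduced_df: bool  # an empty pooled genotype category was dropped

    def __iter__(self):
        yield self.statistic
        yield self.pvalue


def il_snp_test(G: GenotypeData, labels: np.ndarray, snp_index: int) -> SnpTestResult:
    """Non-interacting single-SNP association test.

    Likelihood-ratio (G-) statistic 2 * sum O ln(O/E) over the 2x3
    phenotype-by-genotype table, expected counts from the margins; p from
    the chi-square upper tail with 2 df.  Genotype categories empty in the
    pooled data are dropped with the df reduced accordingly (flagged).
    Missing calls are excluded.
    """
    labels = np.asarray(labels)
    col = G.matrix[:, snp_index]
    ok = col != MISSING
    col, lab = col[ok], labels[ok]
    if np.unique(lab).size < 2:
        raise ValueError("both phenotype classes required")
    table = np.zeros((2, 3))
    for y in (0, 1):
        table[y] = np.bincount(col[lab == y], minlength=3)
    pooled = table.sum(axis=0)
    keep = pooled > 0
    if keep.sum() < 2:
        raise ValueError(
            f"SNP {G.snps[snp_index].id} is monomorphic in the pooled data"
        )
    reduced = bool((~keep).any())
    t = table[:, keep]
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    E = np.outer(rows, cols) / t.sum()
    stat = float(2.0 * special.xlogy(t, t / E).sum())
    df = int(keep.sum() - 1)
    p = float(stats.chi2.sf(stat, df))
    return SnpTestResult(statistic=stat, pvalue=p, df=df, reduced_df=reduced)
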