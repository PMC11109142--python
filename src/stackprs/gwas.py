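"""Data splitting and per-SNP association on the training partition.

The cohort is first split 9:1 into (train+validation) and test, then the
retained 90% is split 8:2 into train and validation — 72% / 18% / 10% overall,
stratified by case status for binary traits.  Association is computed on the
training partition only, so neither threshold selection nor model fitting ever
sees validation or test phenotypes through the summary statistics.

Association models are marginal: per variant, ``y ~ intercept + dosage``.
Quantitative traits use closed-form least squares with a t-test on the slope;
binary traits use logistic regression fitted by iteratively reweighted least
squares (Newton scoring) with a Wald test.  Missing dosages are mean-imputed
within the training partition.  Degenerate fits (zero-variance dosage,
separation, non-convergence) are recorded with beta 0, p 1 and a flag rather
than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import MISSING, GenotypeMatrix, SummaryStats

__all__ = [
    "DataSplit",
    "make_split",
    "assoc_quantitative",
    "assoc_binary",
    "threshold_variants",
]


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train / validation / test sample indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split partitions must be pairwise disjoint")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)


def _split_indices(idx: np.ndarray, frac_out: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(idx)
    n_out = int(round(frac_out * len(idx)))
    return idx[n_out:], idx[:n_out]


def make_split(phenotype: np.ndarray, trait_type: str, seed: int = 0) -> DataSplit:
    """9:1 test split then 8:2 validation split, stratified for binary traits."""
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values; drop them before splitting")

    stratified = trait_type == "binary"
    strata = [np.flatnonzero(y == v) for v in (0.0, 1.0)] if stratified else [np.arange(n)]
    if stratified:
        for s, lab in zip(strata, ("controls", "cases")):
            if len(s) < 3:
                raise ValueError(f"stratum {lab} has {len(s)} members; need at least 3")

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for s in strata:
        rest, te = _split_indices(s, 0.1, rng)
        tr, va = _split_indices(rest, 0.2, rng)
        train.append(tr)
        val.append(va)
        test.append(te)
    return DataSplit(
        train_idx=np.sort(np.concatenate(train)),
        val_idx=np.sort(np.concatenate(val)),
        test_idx=np.sort(np.concatenate(test)),
        stratified=stratified,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


def _design(g: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training-partition dosages, mean-imputed; returns (X, freqs, n_obs)."""
    x = g.genotypes[np.asarray(idx), :].astype(float)
    obs = x != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(obs, x, 0.0).sum(axis=0) / np.maximum(n_obs, 1)
    x = np.where(obs, x, means[None, :])
    freqs = means / 2.0
    return x, freqs, n_obs


def _base_table(g: GenotypeMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "vid": g.vids,
            "chrom": [v.chrom for v in g.variants],
            "pos": [v.pos for v in g.variants],
            "a1": [v.allele1 for v in g.variants],
            "a2": [v.allele2 for v in g.variants],
        }
    )


def assoc_quantitative(g: GenotypeMatrix, y: np.ndarray, idx: np.ndarray) -> SummaryStats:
    """Per-variant simple linear regression of phenotype on dosage.

    Slope, its standard error, and a two-sided p-value from the t distribution
    with n−2 degrees of freedom, vectorised across variants.
    """
    idx = np.asarray(idx)
    yv = np.asarray(y, dtype=float)[idx]
    X, freqs, _ = _design(g, idx)
    n = len(idx)
    if n < 3:
        raise ValueError("need at least 3 training samples")

    xc = X - X.mean(axis=0)
    yc = yv - yv.mean()
    sxx = (xc * xc).sum(axis=0)
    degenerate = sxx <= 0.0
    sxx_safe = np.where(degenerate, 1.0, sxx)
    beta = (xc * yc[:, None]).sum(axis=0) / sxx_safe
    resid = yc[:, None] - xc * beta[None, :]
    sigma2 = (resid * resid).sum(axis=0) / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero residual variance with a nonzero slope is an exact fit: p -> 0
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.where(beta != 0.0, np.inf, 0.0))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    beta[degenerate] = 0.0
    se[degenerate] = np.nan
    p[degenerate] = 1.0

    t_out = _base_table(g)
    t_out["beta"] = beta
    t_out["se"] = se
    t_out["p"] = p
    t_out["freq"] = freqs
    t_out["n"] = n
    t_out["flag"] = np.where(degenerate, "zero_variance", "")
    return SummaryStats(table=t_out)


def assoc_binary(
    g: GenotypeMatrix,
    y: np.ndarray,
    idx: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> SummaryStats:
    """Per-variant univariate logistic regression (intercept + dosage).

    Newton/IRLS iterated to gradient norm < ``tol``, vectorised over variants;
    Wald two-sided p-values.  Perfect separation or non-convergence is flagged
    (beta 0, p 1) instead of diverging.
    """
    idx = np.asarray(idx)
    yv = np.asarray(y, dtype=float)[idx]
    if not (np.any(yv == 0.0) and np.any(yv == 1.0)):
        raise ValueError("both classes must be present in the training partition")
    X, freqs, _ = _design(g, idx)
    n, m = X.shape

    b0 = np.full(m, np.log(yv.mean() / (1.0 - yv.mean())))
    b1 = np.zeros(m)
    active = X.std(axis=0) > 0.0
    converged = np.zeros(m, dtype=bool)

    for _ in range(max_iter):
        todo = active & ~converged
        if not todo.any():
            break
        eta = b0[None, :] + X * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        r = yv[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (r * X).sum(axis=0)
        s00 = w.sum(axis=0)
        s01 = (w * X).sum(axis=0)
        s11 = (w * X * X).sum(axis=0)
        det = s00 * s11 - s01 * s01
        ok = todo & (det > 1e-12)
        det_safe = np.where(det > 1e-12, det, 1.0)
        d0 = (s11 * g0 - s01 * g1) / det_safe
        d1 = (s00 * g1 - s01 * g0) / det_safe
        # damp huge Newton steps (separation drifts off to infinity otherwise)
        step = np.maximum(np.abs(d0), np.abs(d1))
        damp = np.where(step > 10.0, 10.0 / np.maximum(step, 1e-300), 1.0)
        b0[ok] += (d0 * damp)[ok]
        b1[ok] += (d1 * damp)[ok]
        gn = np.sqrt(g0 * g0 + g1 * g1)
        converged |= active & (gn < tol)

    # final information matrix for standard errors
    eta = b0[None, :] + X * b1[None, :]
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = mu * (1.0 - mu)
    s00 = w.sum(axis=0)
    s01 = (w * X).sum(axis=0)
    s11 = (w * X * X).sum(axis=0)
    det = s00 * s11 - s01 * s01
    bad = (~active) | (~converged) | (det <= 1e-12) | (np.abs(b1) > 30.0)
    det_safe = np.where(det > 1e-12, det, 1.0)
    se = np.sqrt(np.where(bad, np.nan, s00 / det_safe))
    with np.errstate(invalid="ignore"):
        z = np.where(bad, 0.0, b1 / np.where(se > 0, se, 1.0))
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    beta = np.where(bad, 0.0, b1)
    p = np.where(bad, 1.0, p)
    flags = np.where(~active, "zero_variance", np.where(bad & active, "not_converged", ""))

    t_out = _base_table(g)
    t_out["beta"] = beta
    t_out["se"] = se
    t_out["p"] = p
    t_out["freq"] = freqs
    t_out["n"] = n
    t_out["flag"] = flags
    return SummaryStats(table=t_out)


def threshold_variants(stats: SummaryStats, p_t: float) -> list[str]:
    """Vids with p strictly below ``p_t``, ordered by (chrom, pos)."""
    t = stats.table
    sel = t.loc[t["p"].to_numpy() < p_t]
    sel = sel.sort_values(["chrom", "pos", "vid"], kind="mergesort")
    return sel["vid"].tolist()
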