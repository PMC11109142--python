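"""Linear polygenic scores: additive scoring, LD clumping, P+T and a
validation-driven threshold search.

The score of individual *i* over a marker set M is the weighted allele count
``PRS_i = sum_j X_ij * beta_j`` — the classical additive PRS.  Clumping is the
greedy index-variant selection by ascending p-value: each index variant
absorbs every unprocessed variant on the same chromosome within the physical
window whose dosage r² with it reaches the threshold (defaults r² ≥ 0.1,
window 250 kb).  P+T scores with the clumped set at a fixed cutoff
(p < 5e-8 by default); the threshold search instead scans a grid of cutoffs,
picks the one maximising the validation metric, and reports test-set scores.

LD (r²) is always computed on the training partition's genotypes; no external
reference panel is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix, SummaryStats
from .gwas import DataSplit
from .metrics import nagelkerke_r2, r_squared

__all__ = [
    "AlleleMismatchError",
    "ClumpResult",
    "PtResult",
    "PrsiceResult",
    "score_prs",
    "pairwise_r2",
    "clump",
    "pt_prs",
    "prsice_search",
    "default_threshold_grid",
]


class AlleleMismatchError(ValueError):
    """Summary-stats alleles cannot be reconciled with the genotype alleles."""


@dataclass
class ClumpResult:
    retained: list[str]
    #: removed vid -> (index vid that absorbed it, their r²)
    absorbed: dict[str, tuple[str, float]] = field(default_factory=dict)


@dataclass
class PtResult:
    scores: np.ndarray
    retained: list[str]
    clump: ClumpResult


@dataclass
class PrsiceResult:
    best_threshold: float
    test_scores: np.ndarray
    retained: list[str]
    #: threshold -> (n variants, validation metric)
    curve: dict[float, tuple[int, float]] = field(default_factory=dict)
    clump: ClumpResult | None = None


def _reconcile_orientation(g: GenotypeMatrix, stats: SummaryStats, vids: list[str]) -> np.ndarray:
    """+1 where the stats counted allele is the genotype A1, -1 where it is A2.

    A -1 orientation means the effect-allele dosage is ``2 - x``.  Anything
    else (allele set mismatch) raises, naming the variant.
    """
    srows = stats.indexed()
    orient = np.empty(len(vids))
    vmap = {v.vid: v for v in g.variants}
    for k, vid in enumerate(vids):
        v = vmap[vid]
        s = srows.loc[vid]
        if (s["a1"], s["a2"]) == (v.allele1, v.allele2):
            orient[k] = 1.0
        elif (s["a1"], s["a2"]) == (v.allele2, v.allele1):
            orient[k] = -1.0
        else:
            raise AlleleMismatchError(
                f"variant {vid}: summary-stats alleles {s['a1']}/{s['a2']} do not match "
                f"genotype alleles {v.allele1}/{v.allele2}"
            )
    return orient


def score_prs(
    g: GenotypeMatrix,
    stats: SummaryStats,
    vids: list[str],
    missing_fill: dict[str, float] | None = None,
) -> np.ndarray:
    """Additive PRS over the given marker set.

    Each variant contributes ``(count of the stats' effect allele) * beta``;
    swapped-allele variants count ``2 - x``.  A missing dosage contributes the
    variant's fill value (``missing_fill``, typically the training-mean
    dosage; defaults to the in-sample mean).
    """
    if len(vids) == 0:
        return np.zeros(g.n_samples)
    unknown = [v for v in vids if v not in set(g.vids)]
    if unknown:
        raise KeyError(f"vids absent from genotypes: {unknown[:5]}")
    sub = g.subset_variants(vids)
    orient = _reconcile_orientation(g, stats, vids)
    srows = stats.indexed()
    betas = srows.loc[vids, "beta"].to_numpy(dtype=float)

    x = sub.genotypes.astype(float)
    obs = x != MISSING
    if missing_fill is not None:
        fill = np.array([missing_fill[v] for v in vids])
    else:
        with np.errstate(invalid="ignore"):
            fill = np.where(obs, x, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    x = np.where(obs, x, fill[None, :])
    effect_dosage = np.where(orient[None, :] > 0, x, 2.0 - x)
    return effect_dosage @ betas


def pairwise_r2(g: GenotypeMatrix, vid_a: str, vid_b: str, idx: np.ndarray | None = None) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    rows = np.asarray(idx) if idx is not None else np.arange(g.n_samples)
    vmap = g.vid_index()
    xa = g.genotypes[rows, vmap[vid_a]].astype(float)
    xb = g.genotypes[rows, vmap[vid_b]].astype(float)
    ok = (xa != MISSING) & (xb != MISSING)
    xa, xb = xa[ok], xb[ok]
    if len(xa) < 2 or xa.std() == 0.0 or xb.std() == 0.0:
        return 0.0
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def _r2_against(x_index: np.ndarray, X: np.ndarray) -> np.ndarray:
    """r² of one (mean-imputed) dosage column against many, vectorised."""
    xc = x_index - x_index.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Xc * Xc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc.T @ xc) / np.where(denom > 0, denom, 1.0), 0.0)
    return r * r


def clump(
    g: GenotypeMatrix,
    stats: SummaryStats,
    idx: np.ndarray | None = None,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> ClumpResult:
    """Greedy LD clumping by ascending p-value.

    Repeatedly take the unprocessed variant with the smallest p-value as an
    index variant and absorb every other unprocessed variant on the same
    chromosome within ``window_kb`` kb whose r² with it is at least
    ``r2_threshold``.  Ties on p break by (chrom, pos), then vid.
    """
    srows = stats.indexed()
    missing = [v for v in g.vids if v not in srows.index]
    if missing:
        raise KeyError(f"summary statistics missing variants: {missing[:5]}")

    rows = np.asarray(idx) if idx is not None else np.arange(g.n_samples)
    X = g.genotypes[rows, :].astype(float)
    obs = X != MISSING
    means = np.where(obs, X, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    X = np.where(obs, X, means[None, :])

    chroms = g.chroms()
    pos = g.positions()
    info = srows.loc[g.vids]
    order = sorted(
        range(g.n_variants),
        key=lambda j: (info["p"].iloc[j], chroms[j], pos[j], g.vids[j]),
    )

    window_bp = window_kb * 1000.0
    unprocessed = np.ones(g.n_variants, dtype=bool)
    retained: list[str] = []
    absorbed: dict[str, tuple[str, float]] = {}
    for j in order:
        if not unprocessed[j]:
            continue
        unprocessed[j] = False
        retained.append(g.vids[j])
        near = unprocessed & (chroms == chroms[j]) & (np.abs(pos - pos[j]) < window_bp)
        cand = np.flatnonzero(near)
        if cand.size:
            r2 = _r2_against(X[:, j], X[:, cand])
            for k, jj in enumerate(cand):
                if r2[k] >= r2_threshold:
                    unprocessed[jj] = False
                    absorbed[g.vids[jj]] = (g.vids[j], float(r2[k]))
    return ClumpResult(retained=retained, absorbed=absorbed)


def pt_prs(
    g: GenotypeMatrix,
    stats: SummaryStats,
    split: DataSplit,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> PtResult:
    """P+T: clump on training genotypes, cut at ``p < p_threshold``, score all samples."""
    cl = clump(g, stats, idx=split.train_idx, r2_threshold=r2_threshold, window_kb=window_kb)
    srows = stats.indexed()
    retained = [v for v in cl.retained if srows.loc[v, "p"] < p_threshold]
    # deterministic (chrom, pos) order for the final marker set
    vmap = {v.vid: (v.chrom, v.pos) for v in g.variants}
    retained.sort(key=lambda v: vmap[v])
    if not retained:
        warnings.warn(f"no clumped variant passes p < {p_threshold}; P+T scores are all zero")
        return PtResult(scores=np.zeros(g.n_samples), retained=[], clump=cl)
    fill = _train_mean_dosage(g, split.train_idx, retained)
    scores = score_prs(g, stats, retained, missing_fill=fill)
    return PtResult(scores=scores, retained=retained, clump=cl)


def _train_mean_dosage(g: GenotypeMatrix, train_idx: np.ndarray, vids: list[str]) -> dict[str, float]:
    sub = g.subset_variants(vids).subset_samples(np.asarray(train_idx))
    x = sub.genotypes.astype(float)
    obs = x != MISSING
    means = np.where(obs, x, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    return dict(zip(vids, means))


def default_threshold_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced p-value cutoffs from 5e-8 (the genome-wide standard) to 1."""
    return np.geomspace(5e-8, 1.0, n_points)


def prsice_search(
    g: GenotypeMatrix,
    stats: SummaryStats,
    split: DataSplit,
    phenotype: np.ndarray,
    trait_type: str,
    grid: np.ndarray | None = None,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> PrsiceResult:
    """Validation-driven p-value-threshold search over a fixed clumped set.

    Clumps once on the training genotypes, scores the validation partition at
    every grid threshold, selects the threshold maximising the validation
    metric (Nagelkerke R² for binary traits, R² for quantitative), and
    returns test-partition scores at that threshold.
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")

    cl = clump(g, stats, idx=split.train_idx, r2_threshold=r2_threshold, window_kb=window_kb)
    srows = stats.indexed()
    vmap = {v.vid: (v.chrom, v.pos) for v in g.variants}
    clumped = sorted(cl.retained, key=lambda v: vmap[v])
    pvals = srows.loc[clumped, "p"].to_numpy(dtype=float)

    y = np.asarray(phenotype, dtype=float)
    yv = y[split.val_idx]
    fill_all = _train_mean_dosage(g, split.train_idx, clumped)

    curve: dict[float, tuple[int, float]] = {}
    best: tuple[float, float] | None = None  # (metric, -threshold? keep first max)
    best_thr = None
    for thr in grid:
        vids = [v for v, p in zip(clumped, pvals) if p < thr]
        if not vids:
            curve[float(thr)] = (0, float("-inf"))
            continue
        scores = score_prs(g, stats, vids, missing_fill={v: fill_all[v] for v in vids})
        sv = scores[split.val_idx]
        if np.std(sv) == 0.0:
            metric = 0.0
        elif trait_type == "binary":
            metric = nagelkerke_r2(yv, sv)
        else:
            metric = r_squared(yv, sv)
        curve[float(thr)] = (len(vids), float(metric))
        if best is None or metric > best[0]:
            best = (metric, thr)
            best_thr = float(thr)
    if best_thr is None:
        raise ValueError("every grid threshold yields an empty marker set")

    vids = [v for v, p in zip(clumped, pvals) if p < best_thr]
    scores = score_prs(g, stats, vids, missing_fill={v: fill_all[v] for v in vids})
    return PrsiceResult(
        best_threshold=best_thr,
        test_scores=scores[split.test_idx],
        retained=vids,
        curve=curve,
        clump=cl,
    )
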