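"""The stacked polygenic-score model.

Construction follows the stacked-generalisation recipe specialised to
p-value-thresholded SNP sets:

1. From training-partition GWAS summary statistics, build one SNP set per
   threshold in a strictly decreasing grid ``p_1 > p_2 > ... > p_T`` (the
   sets are therefore nested, Z_{t+1} ⊆ Z_t).
2. Per threshold, grid-search feed-forward base learners on train/validation.
3. Concatenate the base learners' validation-set outputs into an
   n_val × T feature matrix.
4. Fit a plain linear meta-learner on those features — logistic regression
   for binary traits, ordinary least squares for quantitative ones, no
   regularisation — so the final score is
   H(Z_{1:T}) = h'(h_1(Z_1), ..., h_T(Z_T)).

Because the meta-learner's model class contains every single-base-model
restriction (zero out the other columns), its validation fit is never worse
than any individual base model's; the stored validation metrics are computed
from the meta fit itself so this dominance holds exactly.  The test partition
is touched by no training stage; an index audit is kept on the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .dnn_base import BaseModel, BaseModelSpec, grid_search, logistic, predict
from .gwas import DataSplit, threshold_variants
from .io_formats import MISSING, GenotypeMatrix, SummaryStats
from .metrics import nagelkerke_from_loglik, null_loglik, r_squared
from .prs_linear import clump

__all__ = [
    "ThresholdGrid",
    "MetaLearner",
    "StackedModel",
    "make_threshold_sets",
    "meta_features",
    "train_meta",
    "fit_snprs",
    "predict_snprs",
]

DEFAULT_THRESHOLDS = (5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-8)


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly decreasing p-value thresholds, each in (0, 1]."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 2:
            raise ValueError("need at least two thresholds")
        if any(not (0.0 < p <= 1.0) for p in t):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(nxt >= prev for prev, nxt in zip(t[:-1], t[1:])):
            raise ValueError("thresholds must be strictly decreasing (duplicates rejected)")

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)


@dataclass
class MetaLearner:
    """Linear aggregator over base-model outputs (+ intercept)."""

    trait_type: str
    coef: np.ndarray
    intercept: float
    #: maximised log-likelihood of the logistic fit (binary traits only)
    loglik: float | None = None

    def linear_predictor(self, features: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(features, dtype=float) @ self.coef

    def predict(self, features: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(features)
        if self.trait_type == "binary":
            return logistic(eta)
        return eta


@dataclass
class StackedModel:
    """Threshold grid, per-threshold base networks, and the linear meta-learner."""

    grid: ThresholdGrid
    base_models: list[BaseModel]
    meta: MetaLearner
    trait_type: str
    #: validation metric of each base model, grid order
    base_val_metrics: list[float] = field(default_factory=list)
    #: validation metric of the stacked model, from the meta fit itself
    stacked_val_metric: float = float("nan")
    #: sample indices each stage saw, for the leakage audit
    index_audit: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.base_models) != len(self.grid.thresholds):
            raise ValueError("one base model per threshold required")
        if not np.all(np.isfinite(self.meta.coef)):
            raise ValueError("meta coefficients must be finite")


def make_threshold_sets(
    g: GenotypeMatrix,
    stats: SummaryStats,
    grid: ThresholdGrid,
) -> list[tuple[float, list[str]]]:
    """Per-threshold SNP sets (threshold, vids); nested since the grid decreases.

    Thresholds selecting no variant are dropped with a warning; fewer than two
    surviving thresholds is an error.
    """
    out = []
    for p_t in grid:
        vids = threshold_variants(stats, p_t)
        if not vids:
            warnings.warn(f"threshold {p_t:g} selects no variants; dropped from the grid")
            continue
        out.append((p_t, vids))
    if len(out) < 2:
        raise ValueError("fewer than two thresholds select any variants")
    return out


def meta_features(
    base_models: list[BaseModel],
    g: GenotypeMatrix,
    idx: np.ndarray,
) -> np.ndarray:
    """n_samples × T matrix of base-model outputs on the given samples."""
    idx = np.asarray(idx)
    cols = []
    for model in base_models:
        Z = _dosage_block(g, model.vids, idx)
        cols.append(predict(model, Z))
    return np.column_stack(cols)


def _dosage_block(g: GenotypeMatrix, vids: list[str], idx: np.ndarray) -> np.ndarray:
    """Dosage columns for the given vids/samples, mean-imputed per column."""
    vmap = g.vid_index()
    cols = [vmap[v] for v in vids]
    x = g.genotypes[np.asarray(idx)[:, None], np.asarray(cols)[None, :]].astype(float)
    obs = x != MISSING
    if not obs.all():
        means = np.where(obs, x, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
        x = np.where(obs, x, means[None, :])
    return x


def train_meta(yhat_val: np.ndarray, y_val: np.ndarray, trait_type: str) -> MetaLearner:
    """Fit the linear aggregator on validation-set base outputs.

    Binary: maximum-likelihood logistic regression (intercept + T columns,
    no regularisation).  Quantitative: ordinary least squares.  All-constant
    feature matrices degrade to an intercept-only fit with a warning.
    """
    F = np.atleast_2d(np.asarray(yhat_val, dtype=float))
    if F.shape[0] == 1 and len(y_val) != 1:
        F = F.T
    y = np.asarray(y_val, dtype=float)
    n, T = F.shape
    if n < T + 1:
        raise ValueError(f"{n} validation samples cannot identify {T}+1 meta parameters")

    variable = F.std(axis=0) > 0.0
    if not variable.any():
        warnings.warn("all meta features are constant; intercept-only meta-learner")
        if trait_type == "binary":
            p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            return MetaLearner(trait_type, np.zeros(T), float(np.log(p / (1 - p))),
                               loglik=null_loglik(y))
        return MetaLearner(trait_type, np.zeros(T), float(y.mean()))

    Fv = F[:, variable]
    X = np.column_stack([np.ones(n), Fv])
    coef = np.zeros(T)
    if trait_type == "binary":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            try:
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True):
                    raise RuntimeError("newton failed")
            except Exception:
                res = model.fit(disp=0, method="bfgs", maxiter=2000)
        coef[variable] = res.params[1:]
        return MetaLearner(trait_type, coef, float(res.params[0]), loglik=float(res.llf))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coef[variable] = beta[1:]
    return MetaLearner(trait_type, coef, float(beta[0]))


def fit_snprs(
    g: GenotypeMatrix,
    phenotype: np.ndarray,
    split: DataSplit,
    stats: SummaryStats,
    grid: ThresholdGrid,
    dnn_grid: list[BaseModelSpec],
    trait_type: str,
    pre_clump: bool = False,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
) -> StackedModel:
    """Full stacked-model construction.

    ``stats`` must come from the training partition of ``split`` only.  With
    ``pre_clump`` the per-threshold SNP sets are LD-clumped on the training
    genotypes before network training (intended for imputed, LD-dense data).
    """
    y = np.asarray(phenotype, dtype=float)
    sets = make_threshold_sets(g, stats, grid)
    if pre_clump:
        cl = clump(g, stats, idx=split.train_idx, r2_threshold=clump_r2,
                   window_kb=clump_window_kb)
        keep = set(cl.retained)
        sets = [(p_t, [v for v in vids if v in keep]) for p_t, vids in sets]
        sets = [(p_t, vids) for p_t, vids in sets if vids]
        if len(sets) < 2:
            raise ValueError("fewer than two thresholds survive pre-clumping")

    surviving = ThresholdGrid(tuple(p for p, _ in sets))
    base_models: list[BaseModel] = []
    base_metrics: list[float] = []
    for k, (p_t, vids) in enumerate(sets):
        Z_tr = _dosage_block(g, vids, split.train_idx)
        Z_va = _dosage_block(g, vids, split.val_idx)
        specs = [s.__class__(**{**s.__dict__, "seed": s.seed + 7919 * k}) for s in dnn_grid]
        model, _table = grid_search(
            Z_tr, y[split.train_idx], Z_va, y[split.val_idx],
            specs, trait_type, threshold=p_t, vids=vids,
        )
        base_models.append(model)
        base_metrics.append(model.val_metric)

    F_val = meta_features(base_models, g, split.val_idx)
    meta = train_meta(F_val, y[split.val_idx], trait_type)

    if trait_type == "binary":
        stacked_metric = nagelkerke_from_loglik(
            float(meta.loglik), null_loglik(y[split.val_idx]), len(split.val_idx)
        )
    else:
        fitted = meta.predict(F_val)
        stacked_metric = r_squared(y[split.val_idx], fitted) if np.std(fitted) > 0 else 0.0

    return StackedModel(
        grid=surviving,
        base_models=base_models,
        meta=meta,
        trait_type=trait_type,
        base_val_metrics=base_metrics,
        stacked_val_metric=stacked_metric,
        index_audit={
            "train": np.asarray(split.train_idx).tolist(),
            "val": np.asarray(split.val_idx).tolist(),
            "test": np.asarray(split.test_idx).tolist(),
        },
    )


def predict_snprs(model: StackedModel, g: GenotypeMatrix, idx: np.ndarray | None = None) -> np.ndarray:
    """Stacked score: base outputs fed through the linear meta-learner.

    Binary traits return the meta probability (the reported PRS);
    quantitative traits return the linear combination.
    """
    rows = np.asarray(idx) if idx is not None else np.arange(g.n_samples)
    F = meta_features(model.base_models, g, rows)
    return model.meta.predict(F)


# ---------------------------------------------------------------------------
# model archive (text form, for the CLI)
# ---------------------------------------------------------------------------


def save_stacked_model(model: StackedModel, path: str) -> None:
    """JSON archive: grid, meta coefficients, per-base spec/vids/weights."""

    def arr(a):
        return np.asarray(a).tolist()

    bases = []
    for bm in model.base_models:
        net = bm.network
        layers = []
        for layer in net.layers:
            ld = {k: arr(v) for k, v in layer.items()}
            layers.append(ld)
        bases.append(
            {
                "spec": {**bm.spec.__dict__, "width_divisors": list(bm.spec.width_divisors)},
                "threshold": bm.threshold,
                "vids": bm.vids,
                "input_mean": arr(bm.input_mean),
                "input_sd": arr(bm.input_sd),
                "layers": layers,
                "out_W": arr(net.out_W),
                "out_b": arr(net.out_b),
                "val_loss": bm.val_loss,
                "val_metric": bm.val_metric,
                "epochs_run": bm.epochs_run,
            }
        )
    doc = {
        "trait_type": model.trait_type,
        "thresholds": list(model.grid.thresholds),
        "meta": {
            "coef": arr(model.meta.coef),
            "intercept": model.meta.intercept,
            "loglik": model.meta.loglik,
        },
        "base_val_metrics": model.base_val_metrics,
        "stacked_val_metric": model.stacked_val_metric,
        "base_models": bases,
        "index_audit": model.index_audit,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_stacked_model(path: str) -> StackedModel:
    from .dnn_base import Network

    with open(path) as fh:
        doc = json.load(fh)
    bases = []
    for b in doc["base_models"]:
        spec_kw = dict(b["spec"])
        spec_kw["width_divisors"] = tuple(spec_kw["width_divisors"])
        spec = BaseModelSpec(**spec_kw)
        net = Network(spec, len(b["input_mean"]), doc["trait_type"])
        for layer, ld in zip(net.layers, b["layers"]):
            for k, v in ld.items():
                layer[k] = np.asarray(v, dtype=float)
        net.out_W = np.asarray(b["out_W"], dtype=float)
        net.out_b = np.asarray(b["out_b"], dtype=float)
        bases.append(
            BaseModel(
                spec=spec,
                trait_type=doc["trait_type"],
                threshold=b["threshold"],
                vids=b["vids"],
                input_mean=np.asarray(b["input_mean"], dtype=float),
                input_sd=np.asarray(b["input_sd"], dtype=float),
                network=net,
                val_loss=b["val_loss"],
                val_metric=b["val_metric"],
                epochs_run=b["epochs_run"],
            )
        )
    meta = MetaLearner(
        trait_type=doc["trait_type"],
        coef=np.asarray(doc["meta"]["coef"], dtype=float),
        intercept=doc["meta"]["intercept"],
        loglik=doc["meta"]["loglik"],
    )
    return StackedModel(
        grid=ThresholdGrid(tuple(doc["thresholds"])),
        base_models=bases,
        meta=meta,
        trait_type=doc["trait_type"],
        base_val_metrics=doc["base_val_metrics"],
        stacked_val_metric=doc["stacked_val_metric"],
        index_audit=doc.get("index_audit", {}),
    )
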