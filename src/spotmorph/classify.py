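"""Haplogroup classification: stepwise LDA and a multilayer perceptron.

Two classifiers are fitted to the per-specimen feature table:

* a forward-stepwise linear discriminant function analysis (LDFA) in which
  variables enter by the partial F of their Wilks' lambda reduction and may
  leave again when their partial F drops below the removal threshold, and
* a single-hidden-layer perceptron trained full-batch with a quasi-Newton
  optimizer on a 60/40 per-group split, where specimens misclassified by
  the LDFA are forced into the validation sample for a harder check.

Variable importance for the network is estimated by permutation: the ratio
of the evaluation error after shuffling one feature column to the baseline
error (about 1 for an uninformative variable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Wilks' lambda machinery


def _sscp(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) sum-of-squares-and-cross-products."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for g in np.unique(y):
        sub = x[y == g]
        c = sub - sub.mean(axis=0)
        w += c.T @ c
    return w, t


def wilks_lambda(x: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for the given variable block."""
    if x.shape[1] == 0:
        return 1.0
    w, t = _sscp(x, y)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(t)
    if sign_w <= 0 or sign_t <= 0:
        return float("nan")
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(lambda_small: float, lambda_big: float, n: int, g: int, p_small: int) -> float:
    """Partial F for adding one variable to a p_small-variable model."""
    if not np.isfinite(lambda_big) or lambda_big <= 0:
        return float("nan")
    return ((n - g - p_small) / (g - 1)) * (lambda_small / lambda_big - 1.0)


def _rao_f(lam: float, n: int, g: int, p: int) -> tuple[float, float, float, float]:
    """Rao's F approximation for the overall Wilks' lambda."""
    q = g - 1
    denom = p * p + q * q - 5
    s = math.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    m = n - 1 - (p + g) / 2
    df2 = m * s - p * q / 2 + 1
    lam_s = lam ** (1.0 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    pval = float(sps.f.sf(f, df1, df2))
    return f, df1, df2, pval


# ---------------------------------------------------------------------------
# LDA model


@dataclass
class LDAModel:
    selected_vars: list[str]
    step_trace: pd.DataFrame  # action, variable, wilks, F, p
    classes: np.ndarray
    group_means: pd.DataFrame
    pooled_covariance: pd.DataFrame
    canonical_axes: np.ndarray  # (p_selected, n_axes)
    scores: pd.DataFrame  # per-specimen canonical coordinates
    confusion_resub: pd.DataFrame
    confusion_loo: pd.DataFrame
    accuracy_resub: float  # percent
    accuracy_loo: float  # percent
    wilks: float
    wilks_f: float
    wilks_df: tuple[float, float]
    wilks_p: float
    priors: np.ndarray
    misclassified_resub: list = field(default_factory=list)
    fit_labels: pd.Series | None = None  # labels of the specimens used at fit time

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = features[self.selected_vars].to_numpy(dtype=float)
        return _gaussian_classify(
            x,
            self.group_means.to_numpy(),
            self.pooled_covariance.to_numpy(),
            self.classes,
            self.priors,
        )


def _gaussian_classify(x, means, cov, classes, priors) -> np.ndarray:
    cov_inv = np.linalg.pinv(cov)
    scores = np.empty((len(x), len(classes)))
    for k, mu in enumerate(means):
        a = cov_inv @ mu
        scores[:, k] = x @ a - 0.5 * mu @ a + math.log(priors[k])
    return classes[np.argmax(scores, axis=1)]


def _confusion(y_true, y_pred, classes) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    mat.index.name = "true"
    mat.columns.name = "predicted"
    return mat


def stepwise_lda(
    features: pd.DataFrame,
    labels,
    f_enter: float = 4.0,
    f_remove: float = 3.9,
    priors: str = "equal",
    allow_empty: bool = False,
    feature_columns: list[str] | None = None,
) -> LDAModel:
    """Forward-stepwise LDFA with Wilks' lambda partial-F selection.

    At each step the candidate variable with the largest partial F enters
    if F >= ``f_enter``; previously entered variables whose partial F falls
    below ``f_remove`` are removed.  The final model is a linear (pooled
    covariance) Gaussian classifier with equal group priors by default; it
    reports canonical scores, resubstitution and leave-one-out confusion
    matrices, and the overall Wilks' lambda with Rao's F approximation.

    ``allow_empty=True`` returns a prior-only model instead of raising when
    no variable reaches ``f_enter`` (useful for null-data controls).
    """
    labels = np.asarray(labels)
    cols = list(feature_columns or [c for c in features.columns if features[c].dtype.kind == "f"])
    data = features[cols].astype(float)
    complete = ~data.isna().any(axis=1)
    if not complete.all():
        logger.warning("stepwise_lda: dropping %d incomplete specimens", int((~complete).sum()))
    data = data.loc[complete.to_numpy()]
    labels = labels[complete.to_numpy()]
    classes = np.unique(labels)
    g = len(classes)
    n = len(data)
    if g < 2:
        raise ValueError("need at least 2 groups")
    for cls in classes:
        if (labels == cls).sum() < 2:
            raise ValueError(f"group {cls!r} has fewer than 2 specimens")

    x_all = data.to_numpy()
    selected: list[int] = []
    trace_rows = []
    current_lambda = 1.0
    while True:
        changed = False
        # forward step
        best_f, best_j, best_lambda = -np.inf, None, None
        for j in range(len(cols)):
            if j in selected:
                continue
            lam = wilks_lambda(x_all[:, selected + [j]], labels)
            f = _partial_f(current_lambda, lam, n, g, len(selected))
            if not np.isfinite(f):
                continue
            if f > best_f:
                best_f, best_j, best_lambda = f, j, lam
        if best_j is not None and best_f >= f_enter:
            selected.append(best_j)
            current_lambda = best_lambda
            trace_rows.append(
                {
                    "action": "enter",
                    "variable": cols[best_j],
                    "wilks": current_lambda,
                    "F": best_f,
                    "p": float(sps.f.sf(best_f, g - 1, n - g - len(selected) + 1)),
                }
            )
            changed = True
        # backward step
        removed = True
        while removed and len(selected) > 1:
            removed = False
            worst_f, worst_j, worst_lambda = np.inf, None, None
            for j in selected:
                rest = [k for k in selected if k != j]
                lam_rest = wilks_lambda(x_all[:, rest], labels)
                f = _partial_f(lam_rest, current_lambda, n, g, len(rest))
                if np.isfinite(f) and f < worst_f:
                    worst_f, worst_j, worst_lambda = f, j, lam_rest
            if worst_j is not None and worst_f < f_remove:
                selected.remove(worst_j)
                current_lambda = worst_lambda
                trace_rows.append(
                    {
                        "action": "remove",
                        "variable": cols[worst_j],
                        "wilks": current_lambda,
                        "F": worst_f,
                        "p": float(sps.f.sf(worst_f, g - 1, n - g - len(selected))),
                    }
                )
                removed = True
                changed = True
        if not changed:
            break

    if not selected:
        if not allow_empty:
            raise ValueError("no discriminative variables (no candidate reached f_enter)")
        logger.warning("stepwise_lda: no variable reached f_enter; prior-only model")

    sel_cols = [cols[j] for j in selected]
    x = x_all[:, selected] if selected else np.zeros((n, 0))
    prior_vec = (
        np.full(g, 1.0 / g)
        if priors == "equal"
        else np.array([(labels == c).mean() for c in classes])
    )
    means = np.array(
        [x[labels == c].mean(axis=0) if selected else np.zeros(0) for c in classes]
    )
    if selected:
        w, _ = _sscp(x, labels)
        pooled = w / (n - g)
        between = np.zeros_like(pooled)
        grand = x.mean(axis=0)
        for k, c in enumerate(classes):
            d = (means[k] - grand)[:, None]
            between += (labels == c).sum() * (d @ d.T)
        between /= max(1, n - 1)
        # canonical axes: eigenvectors of pooled^-1 * between, scaled so the
        # pooled within-group variance along each axis is 1
        evals, evecs = sla.eigh(between, pooled)
        order = np.argsort(evals)[::-1]
        n_axes = min(g - 1, len(selected))
        axes = evecs[:, order[:n_axes]]
        scores = pd.DataFrame(
            (x - grand) @ axes,
            index=data.index,
            columns=[f"canon_{i+1}" for i in range(n_axes)],
        )
        overall_lambda = current_lambda
        f_stat, df1, df2, pval = _rao_f(overall_lambda, n, g, len(selected))
        y_resub = _gaussian_classify(x, means, pooled, classes, prior_vec)
        y_loo = np.empty(n, dtype=classes.dtype)
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            xi, yi = x[keep], labels[keep]
            mi = np.array([xi[yi == c].mean(axis=0) for c in classes])
            wi, _ = _sscp(xi, yi)
            y_loo[i] = _gaussian_classify(
                x[i : i + 1], mi, wi / (n - 1 - g), classes, prior_vec
            )[0]
    else:
        pooled = np.zeros((0, 0))
        axes = np.zeros((0, 0))
        scores = pd.DataFrame(index=data.index)
        overall_lambda, f_stat, df1, df2, pval = 1.0, float("nan"), 0.0, 0.0, float("nan")
        majority = classes[int(np.argmax(prior_vec))]
        y_resub = np.full(n, majority, dtype=classes.dtype)
        y_loo = y_resub.copy()

    conf_resub = _confusion(labels, y_resub, classes)
    conf_loo = _confusion(labels, y_loo, classes)
    mis = [i for i, (t, p) in enumerate(zip(labels, y_resub)) if t != p]
    return LDAModel(
        selected_vars=sel_cols,
        step_trace=pd.DataFrame(trace_rows, columns=["action", "variable", "wilks", "F", "p"]),
        classes=classes,
        group_means=pd.DataFrame(means, index=classes, columns=sel_cols),
        pooled_covariance=pd.DataFrame(pooled, index=sel_cols, columns=sel_cols),
        canonical_axes=axes,
        scores=scores,
        confusion_resub=conf_resub,
        confusion_loo=conf_loo,
        accuracy_resub=100.0 * float((y_resub == labels).mean()),
        accuracy_loo=100.0 * float((y_loo == labels).mean()),
        wilks=overall_lambda,
        wilks_f=f_stat,
        wilks_df=(df1, df2),
        wilks_p=pval,
        priors=prior_vec,
        misclassified_resub=[data.index[i] for i in mis],
        fit_labels=pd.Series(labels, index=data.index, name="group"),
    )


# ---------------------------------------------------------------------------
# train/validation split


@dataclass
class SplitPlan:
    train_ids: list
    validation_ids: list
    forced_validation_ids: list
    seed: int


def make_split(
    labels: pd.Series,
    train_frac: float = 0.6,
    forced_validation_ids=(),
    seed: int = 0,
) -> SplitPlan:
    """Per-group random train/validation split with forced validation ids.

    Within each group, round(train_frac * n) specimens are drawn for
    training (half-up rounding) after reserving the forced ids to the
    validation side; the draw is deterministic given ``seed``.  If a group's
    forced ids exceed its validation quota the quota expands with a warning,
    but never beyond half the group: a degenerate upstream classifier that
    misclassifies most of a group must not strip that group's training
    sample, so excess forced ids (in sorted order) return to the random
    pool.
    """
    labels = pd.Series(labels)
    forced = set(forced_validation_ids)
    unknown = forced - set(labels.index)
    if unknown:
        raise ValueError(f"forced ids not among specimens: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    for grp in sorted(labels.unique()):
        ids = sorted(labels.index[labels == grp])
        n = len(ids)
        n_train = int(math.floor(train_frac * n + 0.5))
        forced_grp = [i for i in ids if i in forced]
        quota = n - n_train
        honored = forced_grp
        if len(forced_grp) > quota:
            quota_max = n - n // 2  # keep at least half the group trainable
            if len(forced_grp) > quota_max:
                logger.warning(
                    "make_split: group %r has %d forced ids but only %d can be honored; "
                    "the rest return to the random pool",
                    grp,
                    len(forced_grp),
                    quota_max,
                )
                honored = forced_grp[:quota_max]
            else:
                logger.warning(
                    "make_split: group %r has %d forced validation ids, expanding its "
                    "validation quota from %d",
                    grp,
                    len(forced_grp),
                    quota,
                )
            n_train = min(n_train, n - len(honored))
        candidates = [i for i in ids if i not in set(honored)]
        chosen = rng.permutation(len(candidates))[:n_train]
        train_ids.extend(candidates[i] for i in sorted(chosen))
    validation_ids = [i for i in labels.index if i not in set(train_ids)]
    return SplitPlan(
        train_ids=train_ids,
        validation_ids=validation_ids,
        forced_validation_ids=forced,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# multilayer perceptron


@dataclass
class MLPConfig:
    hidden_units: int = 20
    hidden_activation: str = "tanh"  # tanh | logistic | sine
    loss: str = "cross_entropy"  # cross_entropy | sum_of_squares
    max_epochs: int = 300
    seed: int = 0
    alpha: float = 1e-4  # L2 penalty for conditioning

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.hidden_activation not in ("tanh", "logistic", "sine"):
            raise ValueError("hidden_activation must be tanh, logistic or sine")
        if self.loss not in ("cross_entropy", "sum_of_squares"):
            raise ValueError("loss must be cross_entropy or sum_of_squares")


_ACTS = {
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "logistic": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda z, a: a * (1.0 - a)),
    "sine": (np.sin, lambda z, a: np.cos(z)),
}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLPModel:
    config: MLPConfig
    classes: np.ndarray
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    weights: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    split: SplitPlan | None
    train_loss: float
    n_iter: int
    confusion_train: pd.DataFrame | None = None
    confusion_validation: pd.DataFrame | None = None
    accuracy_train: float = float("nan")  # percent
    accuracy_validation: float = float("nan")  # percent

    def _forward(self, x: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self.weights
        act, _ = _ACTS[self.config.hidden_activation]
        hidden = act(x @ w1 + b1)
        out = hidden @ w2 + b2
        if self.config.loss == "cross_entropy":
            return _softmax(out)
        return 1.0 / (1.0 + np.exp(-out))

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features[self.feature_names].to_numpy(dtype=float)
        x = (np.asarray(features, dtype=float) - self.scaler_mean) / self.scaler_std
        return self.classes[np.argmax(self._forward(x), axis=1)]


def _mlp_loss_grad(theta, x, onehot, shapes, activation, loss, alpha):
    (d, h, k) = shapes
    i0 = 0
    w1 = theta[i0 : i0 + d * h].reshape(d, h); i0 += d * h
    b1 = theta[i0 : i0 + h]; i0 += h
    w2 = theta[i0 : i0 + h * k].reshape(h, k); i0 += h * k
    b2 = theta[i0 : i0 + k]
    act, dact = _ACTS[activation]
    z1 = x @ w1 + b1
    a1 = act(z1)
    z2 = a1 @ w2 + b2
    n = len(x)
    if loss == "cross_entropy":
        p = _softmax(z2)
        eps = 1e-12
        value = -np.sum(onehot * np.log(p + eps)) / n
        delta2 = (p - onehot) / n
    else:
        p = 1.0 / (1.0 + np.exp(-z2))
        value = np.sum((p - onehot) ** 2) / n
        delta2 = 2.0 * (p - onehot) * p * (1.0 - p) / n
    value += 0.5 * alpha * (np.sum(w1 * w1) + np.sum(w2 * w2))
    g_w2 = a1.T @ delta2 + alpha * w2
    g_b2 = delta2.sum(axis=0)
    delta1 = (delta2 @ w2.T) * dact(z1, a1)
    g_w1 = x.T @ delta1 + alpha * w1
    g_b1 = delta1.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
    return value, grad


def train_mlp(
    features: pd.DataFrame,
    labels: pd.Series,
    split: SplitPlan | None,
    cfg: MLPConfig,
    feature_columns: list[str] | None = None,
) -> MLPModel:
    """Train the single-hidden-layer network on the split's training rows.

    Inputs are z-scored with training-set statistics; the weights are
    optimized full-batch with L-BFGS (a quasi-Newton method) for at most
    ``cfg.max_epochs`` iterations.  Fully reproducible given (cfg.seed,
    split).  ``split=None`` trains on all rows (no validation metrics).
    """
    labels = pd.Series(labels)
    cols = list(feature_columns or [c for c in features.columns if features[c].dtype.kind == "f"])
    data = features[cols].astype(float)
    if data.isna().any().any():
        keep = ~data.isna().any(axis=1)
        logger.warning("train_mlp: dropping %d incomplete specimens", int((~keep).sum()))
        data, labels = data.loc[keep], labels.loc[keep.index[keep]]
    classes = np.unique(labels)
    k = len(classes)
    train_index = list(split.train_ids) if split is not None else list(data.index)
    train_index = [i for i in train_index if i in data.index]
    x_train = data.loc[train_index].to_numpy()
    y_train = labels.loc[train_index].to_numpy()

    mean = x_train.mean(axis=0)
    std = x_train.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    xs = (x_train - mean) / std
    onehot = (y_train[:, None] == classes[None, :]).astype(float)

    d, h = xs.shape[1], cfg.hidden_units
    rng = np.random.default_rng(cfg.seed)
    theta0 = np.concatenate(
        [
            rng.normal(0, 1.0 / math.sqrt(d), d * h),
            np.zeros(h),
            rng.normal(0, 1.0 / math.sqrt(h), h * k),
            np.zeros(k),
        ]
    )
    res = optimize.minimize(
        _mlp_loss_grad,
        theta0,
        args=(xs, onehot, (d, h, k), cfg.hidden_activation, cfg.loss, cfg.alpha),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_epochs, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise FloatingPointError(
            f"MLP training diverged (loss={res.fun}); try fewer hidden units or tanh activation"
        )
    i0 = 0
    w1 = res.x[i0 : i0 + d * h].reshape(d, h); i0 += d * h
    b1 = res.x[i0 : i0 + h]; i0 += h
    w2 = res.x[i0 : i0 + h * k].reshape(h, k); i0 += h * k
    b2 = res.x[i0 : i0 + k]

    model = MLPModel(
        config=cfg,
        classes=classes,
        feature_names=cols,
        scaler_mean=mean,
        scaler_std=std,
        weights=(w1, b1, w2, b2),
        split=split,
        train_loss=float(res.fun),
        n_iter=int(res.nit),
    )
    pred_train = model.predict(data.loc[train_index])
    model.confusion_train = _confusion(y_train, pred_train, classes)
    model.accuracy_train = 100.0 * float((pred_train == y_train).mean())
    if split is not None:
        val_index = [i for i in split.validation_ids if i in data.index]
        if val_index:
            y_val = labels.loc[val_index].to_numpy()
            pred_val = model.predict(data.loc[val_index])
            model.confusion_validation = _confusion(y_val, pred_val, classes)
            model.accuracy_validation = 100.0 * float((pred_val == y_val).mean())
    return model


def search_topology(
    features: pd.DataFrame,
    labels: pd.Series,
    split: SplitPlan,
    hidden_grid=range(5, 26, 5),
    activations=("tanh",),
    losses=("cross_entropy",),
    max_epochs: int = 300,
    seed: int = 0,
    feature_columns: list[str] | None = None,
) -> tuple[MLPModel, pd.DataFrame]:
    """Automated network search over a topology grid.

    Every configuration is trained and ranked by validation accuracy; ties
    are broken by fewer hidden units, then lower validation loss (taken as
    the validation misclassification fraction, then training loss).
    """
    hidden_grid = list(hidden_grid)
    if not hidden_grid:
        raise ValueError("empty hidden_grid")
    rows, models = [], []
    for h in hidden_grid:
        for act in activations:
            for loss in losses:
                cfg = MLPConfig(
                    hidden_units=h,
                    hidden_activation=act,
                    loss=loss,
                    max_epochs=max_epochs,
                    seed=seed,
                )
                try:
                    model = train_mlp(features, labels, split, cfg, feature_columns)
                except FloatingPointError as exc:
                    logger.warning("search_topology: skipping %s/%s/%d (%s)", act, loss, h, exc)
                    continue
                rows.append(
                    {
                        "hidden_units": h,
                        "activation": act,
                        "loss": loss,
                        "accuracy_validation": model.accuracy_validation,
                        "accuracy_train": model.accuracy_train,
                        "train_loss": model.train_loss,
                        "n_iter": model.n_iter,
                    }
                )
                models.append(model)
    if not models:
        raise RuntimeError("all topology candidates failed to train")
    leaderboard = pd.DataFrame(rows)
    order = leaderboard.sort_values(
        by=["accuracy_validation", "hidden_units", "train_loss"],
        ascending=[False, True, True],
        kind="mergesort",
    ).index
    leaderboard = leaderboard.loc[order].reset_index(drop=True)
    best = models[order[0]]
    return best, leaderboard


# ---------------------------------------------------------------------------
# permutation importance


@dataclass
class ImportanceReport:
    importance: pd.Series  # permuted-error / baseline-error per variable
    repetitions: int
    seed: int
    baseline_error: float


def permutation_importance(
    model: MLPModel,
    features: pd.DataFrame,
    labels: pd.Series,
    reps: int = 50,
    seed: int = 0,
    eval_ids=None,
) -> ImportanceReport:
    """Permutation variable importance on the evaluation set.

    For each feature column, the mean over ``reps`` shuffles of
    (error after permuting the column) / (baseline error); uninformative
    variables score about 1.  Errors are misclassification fractions with
    add-one smoothing ((miscount + 1)/(n + 1)) so a zero baseline cannot
    blow up the ratio.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = pd.Series(labels)
    if eval_ids is None:
        eval_ids = model.split.validation_ids if model.split is not None else list(features.index)
    eval_ids = [i for i in eval_ids if i in features.index]
    x = features.loc[eval_ids, model.feature_names].to_numpy(dtype=float)
    y = labels.loc[eval_ids].to_numpy()
    n = len(y)

    def _error(mat: np.ndarray) -> float:
        pred = model.predict(mat)
        return (int((pred != y).sum()) + 1.0) / (n + 1.0)

    baseline = _error(x)
    rng = np.random.default_rng(seed)
    ratios = {}
    for j, name in enumerate(model.feature_names):
        acc = 0.0
        for _ in range(reps):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(n), j]
            acc += _error(xp) / baseline
        ratios[name] = acc / reps
    return ImportanceReport(
        importance=pd.Series(ratios).sort_values(ascending=False),
        repetitions=reps,
        seed=seed,
        baseline_error=baseline,
    )
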