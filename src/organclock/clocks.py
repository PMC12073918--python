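"""Organ-specific biological-age clocks and age gaps.

One predictor per organ system is trained on non-case participants to
regress chronological age on the organ's biomarker panel, with
age-distance sample weights (participants further from the mean age are
weighted more heavily to tame heteroskedastic residuals).  The test set
is selected from non-cases so its medians of age, BMI and packyears
match the case group's.  The age gap is predicted minus chronological
age, in years; the composite gap averages the six non-hepatic predicted
ages.

Two interchangeable backends satisfy the same predict contract: a
weighted ridge pipeline (default, deterministic and desk-scale fast)
and a small fully-connected network (relu, dropout, adam, mini-batches,
validation split with patience and best-weight restore).

Because any regression of age on noisy markers shrinks predictions
toward the mean age, a planted latent shift of d years surfaces in raw
gaps as roughly R**2 x d.  ``age_gap(..., correct_bias=True)`` applies
the standard slope correction (divide centred predictions by the
training-set slope of predicted on true age) to restore the latent
scale at the cost of larger residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stage_rng

__all__ = [
    "ClockSpec",
    "OrganClock",
    "OrganClockResults",
    "MatchingError",
    "compute_sample_weights",
    "build_splits",
    "compute_age_gaps",
    "abs_residual_slope",
]


class MatchingError(RuntimeError):
    """Raised when median matching cannot reach the configured tolerance."""


# ---------------------------------------------------------------------------
# sample weights


def compute_sample_weights(ages: np.ndarray, cap: float = 5.0) -> np.ndarray:
    """Age-distance weights: w(a) = 1 + |a - mean| / sd, capped, mean-normalised.

    Positive, non-decreasing in distance from the mean age; all ones for
    zero-variance ages.  Returned weights have mean exactly 1.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    sd = ages.std()
    if sd == 0:
        return np.ones_like(ages)
    w = 1.0 + np.abs(ages - ages.mean()) / sd
    w = np.minimum(w, cap)
    return w / w.mean()


# ---------------------------------------------------------------------------
# train/test split with median matching


def _median_matched_sample(
    pool: pd.DataFrame,
    cases: pd.DataFrame,
    variables: tuple[str, ...],
    n_test: int,
    rng: np.random.Generator,
    tolerances: dict[str, float] | None = None,
) -> pd.Index:
    """1:k nearest-neighbour quota sampling without replacement.

    Each case claims ~n_test/n_cases of its nearest non-cases, with
    distances scaled by the per-variable matching tolerance so the
    tightest-toleranced variable (age) dominates the metric; the
    selected test set then mirrors the case joint distribution and
    therefore its medians.
    """
    from scipy.spatial import cKDTree

    if tolerances:
        scale = pd.Series({v: tolerances.get(v, 1.0) for v in variables})
    else:
        scale = pool[list(variables)].std(ddof=0).replace(0.0, 1.0)
    z_pool = (pool[list(variables)] / scale).to_numpy(dtype=float)
    z_case = (cases[list(variables)] / scale).to_numpy(dtype=float)

    n_cases = len(z_case)
    base, extra = divmod(n_test, n_cases)
    order = rng.permutation(n_cases)
    quotas = np.full(n_cases, base)
    quotas[order[:extra]] += 1

    tree = cKDTree(z_pool)
    taken = np.zeros(len(pool), dtype=bool)
    for i in order:
        need = int(quotas[i])
        if need == 0:
            continue
        k = min(max(4 * need, need + 32), len(pool))
        while True:
            _, nn = tree.query(z_case[i], k=k)
            nn = np.atleast_1d(nn)
            fresh = nn[~taken[nn]][:need]
            if len(fresh) == need or k == len(pool):
                break
            k = min(k * 2, len(pool))
        taken[fresh] = True
    shortfall = n_test - int(taken.sum())
    if shortfall > 0:
        rest = np.flatnonzero(~taken)
        taken[rng.choice(rest, size=min(shortfall, len(rest)), replace=False)] = True
    return pool.index[taken]


def _repair_medians(
    pool: pd.DataFrame,
    cases: pd.DataFrame,
    variables: tuple[str, ...],
    selected: pd.Index,
    tolerances: dict[str, float],
) -> pd.Index:
    """Swap selected/unselected controls until each median is in tolerance.

    One variable at a time: while the selected median sits more than the
    tolerance away from the case median, exchange the selected unit
    farthest on the heavy side for the unselected control nearest the
    case median on the light side.  Bounded sweeps; gives up quietly and
    lets the caller's tolerance check raise.
    """
    selected = pd.Index(selected)
    for var in variables:
        target = float(cases[var].median())
        half_tol = 0.5 * tolerances.get(var, np.inf)
        if not np.isfinite(half_tol):
            continue
        for _ in range(len(pool)):
            sel_vals = pool.loc[selected, var].astype(float)
            diff = float(sel_vals.median()) - target
            if abs(diff) <= half_tol:
                break
            unselected = pool.index.difference(selected)
            un_vals = pool.loc[unselected, var].astype(float)
            if diff > 0:  # selected too heavy above target
                out = sel_vals.idxmax()
                candidates = un_vals[un_vals < target]
            else:
                out = sel_vals.idxmin()
                candidates = un_vals[un_vals > target]
            if candidates.empty:
                break
            incoming = (candidates - target).abs().idxmin()
            selected = selected.drop(out).append(pd.Index([incoming]))
    return selected


def build_splits(
    participants: pd.DataFrame,
    status: pd.DataFrame,
    test_fraction: float = 0.214,
    match_vars: tuple[str, ...] = ("age", "bmi", "packyears"),
    tolerances: dict[str, float] | None = None,
    match: bool = True,
    seed: int = 0,
) -> dict[str, pd.Index]:
    """Case-median-matched test set and disjoint training set.

    Cases and participants with unknown/excluded/prevalent status never
    enter either pool.  ``match=False`` (equivalently infinite
    tolerances) skips matching and draws a simple random test subset.
    Default tolerances: age 0.5 y, BMI 0.5 kg/m^2, packyears 1.0.
    """
    st = status["status"]
    case_ids = st.index[st == "incident"]
    pool_ids = st.index[st == "control"]
    if len(case_ids) == 0:
        raise MatchingError("no incident cases to match against")
    pool = participants.loc[pool_ids, list(match_vars)].astype(float)
    cases = participants.loc[case_ids, list(match_vars)].astype(float)
    rng = stage_rng(seed, "splits")
    n_test = int(round(test_fraction * len(pool)))

    defaults = {"age": 0.5, "bmi": 0.5, "packyears": 1.0}
    tol = {**{v: defaults.get(v, 0.5) for v in match_vars}, **(tolerances or {})}
    if not match or all(np.isinf(t) for t in tol.values()):
        test_idx = pd.Index(rng.choice(pool.index.to_numpy(), size=n_test, replace=False))
    else:
        test_idx = _median_matched_sample(pool, cases, tuple(match_vars), n_test, rng, tol)
        test_idx = _repair_medians(pool, cases, tuple(match_vars), test_idx, tol)
        for var in match_vars:
            gap = abs(float(pool.loc[test_idx, var].median()) - float(cases[var].median()))
            if gap > tol[var]:
                raise MatchingError(f"median matching failed for {var!r}: off by {gap:.3f} (tolerance {tol[var]})")
    train_idx = pool.index.difference(test_idx)
    return {"train": train_idx, "test": pd.Index(test_idx)}


# ---------------------------------------------------------------------------
# clock model


@dataclass(frozen=True)
class ClockSpec:
    """Training protocol for one organ clock.

    Defaults keep the full-scale protocol (3 hidden layers of
    2000/1000/250 relu units with 0.5 dropout, adam, MSE, 2000 epochs,
    batch 100, validation split 0.2, patience 1000 with best-weight
    restore); :meth:`desk_scale` shrinks the schedule for laptop-sized
    runs.  The ridge backend ignores the network fields.
    """

    hidden_layer_sizes: tuple[int, ...] = (2000, 1000, 250)
    dropout: float = 0.5
    activation: str = "relu"
    loss: str = "mse"
    epochs: int = 2000
    batch_size: int = 100
    validation_fraction: float = 0.2
    patience: int = 1000
    backend: str = "weighted-ridge"  # or "network"
    ridge_alpha: float = 1.0
    learning_rate: float = 1e-3
    min_rows: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.backend not in ("weighted-ridge", "network"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @classmethod
    def desk_scale(cls, **overrides) -> "ClockSpec":
        base = cls(hidden_layer_sizes=(64, 32, 16), epochs=200, patience=100)
        return replace(base, **overrides)


class OrganClock:
    """Model object: biomarker panel -> chronological age regressor."""

    def __init__(
        self,
        panel: pd.DataFrame,
        ages: pd.Series | np.ndarray,
        weights: np.ndarray | None = None,
        spec: ClockSpec | None = None,
        organ: str = "",
    ) -> None:
        self.spec = spec or ClockSpec()
        self.organ = organ
        X = np.asarray(panel, dtype=float)
        y = np.asarray(ages, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("panel and ages must align row-wise")
        if X.shape[0] < self.spec.min_rows:
            raise ValueError(f"need at least {self.spec.min_rows} rows, got {X.shape[0]}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in panel or ages; impute first")
        self.X, self.y = X, y
        self.weights = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
        self.feature_names = list(panel.columns) if isinstance(panel, pd.DataFrame) else None

    def fit(self, seed: int = 0) -> "OrganClockResults":
        if self.spec.backend == "weighted-ridge":
            predictor, meta = self._fit_ridge()
        else:
            predictor, meta = self._fit_network(seed)
        pred_train = predictor(self.X)
        # slope of predicted on true age over the training sample; used by
        # the optional shrinkage correction
        age_c = self.y - self.y.mean()
        bias_slope = float(age_c @ (pred_train - pred_train.mean()) / (age_c @ age_c))
        return OrganClockResults(
            organ=self.organ,
            spec=self.spec,
            predictor=predictor,
            n=len(self.y),
            seed=seed,
            train_age_mean=float(self.y.mean()),
            train_pred_mean=float(pred_train.mean()),
            bias_slope=bias_slope,
            weighted_train_residual=float(np.average(pred_train - self.y, weights=self.weights)),
            feature_names=self.feature_names,
            **meta,
        )

    def _fit_ridge(self):
        from sklearn.linear_model import Ridge
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        pipe = make_pipeline(StandardScaler(), Ridge(alpha=self.spec.ridge_alpha))
        pipe.fit(self.X, self.y, ridge__sample_weight=self.weights)
        return (lambda X: pipe.predict(np.asarray(X, dtype=float))), {
            "epochs_run": 0,
            "restored_best": False,
        }

    def _fit_network(self, seed: int):
        net = _DenseNet(self.spec, stage_rng(seed, f"clock:{self.organ}"))
        epochs_run, restored = net.fit(self.X, self.y, self.weights)
        return net.predict, {"epochs_run": epochs_run, "restored_best": restored}


@dataclass
class OrganClockResults:
    """Fitted clock with training metadata; callable on new panels."""

    organ: str
    spec: ClockSpec
    predictor: object = field(repr=False)
    n: int = 0
    seed: int = 0
    epochs_run: int = 0
    restored_best: bool = False
    train_age_mean: float = np.nan
    train_pred_mean: float = np.nan
    bias_slope: float = np.nan
    weighted_train_residual: float = np.nan
    feature_names: list | None = None

    def predict(self, panel, correct_bias: bool = False) -> np.ndarray:
        pred = np.asarray(self.predictor(np.asarray(panel, dtype=float)), dtype=float)
        if correct_bias:
            pred = self.train_age_mean + (pred - self.train_pred_mean) / self.bias_slope
        return pred

    def evaluate(self, panel, ages, split: str = "test") -> dict:
        """Pearson r between predicted and chronological age."""
        pred = self.predict(panel)
        ages = np.asarray(ages, dtype=float)
        r = float(np.corrcoef(pred, ages)[0, 1]) if len(ages) > 1 else np.nan
        return {"organ": self.organ, "split": split, "r": r, "n": len(ages)}

    def age_gap(self, panel, ages, correct_bias: bool = False) -> np.ndarray:
        return self.predict(panel, correct_bias=correct_bias) - np.asarray(ages, dtype=float)

    def summary(self) -> str:
        lines = [
            f"Organ clock: {self.organ or '<unnamed>'} ({self.spec.backend})",
            f"  n train                 {self.n}",
            f"  epochs run              {self.epochs_run}",
            f"  restored best weights   {self.restored_best}",
            f"  slope(pred ~ age)       {self.bias_slope:.3f}",
            f"  weighted mean residual  {self.weighted_train_residual:.4f} y",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# numpy network backend


class _DenseNet:
    """Fully-connected regression net: relu, inverted dropout, adam, MSE.

    Trains on standardised features/targets with a validation split,
    patience-based early stopping and best-weight restore.
    """

    def __init__(self, spec: ClockSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng

    def _init_params(self, n_in: int) -> list:
        sizes = [n_in, *self.spec.hidden_layer_sizes, 1]
        params = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            W = self.rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
            params.append([W, np.zeros(b)])
        return params

    def _forward(self, X: np.ndarray, params: list, train: bool = False):
        cache = []
        h = X
        n_layers = len(params)
        for i, (W, b) in enumerate(params):
            z = h @ W + b
            last = i == n_layers - 1
            if not last:
                a = np.maximum(z, 0.0)
                if train and self.spec.dropout > 0:
                    keep = 1.0 - self.spec.dropout
                    mask = (self.rng.uniform(size=a.shape) < keep) / keep
                    a = a * mask
                else:
                    mask = None
                cache.append((h, z, mask))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h[:, 0], cache

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[int, bool]:
        spec = self.spec
        self.x_mean, self.x_sd = X.mean(axis=0), X.std(axis=0)
        self.x_sd[self.x_sd == 0] = 1.0
        self.y_mean, self.y_sd = y.mean(), max(y.std(), 1e-12)
        Xs = (X - self.x_mean) / self.x_sd
        ys = (y - self.y_mean) / self.y_sd

        n = len(ys)
        order = self.rng.permutation(n)
        n_val = max(int(round(spec.validation_fraction * n)), 1)
        val, tr = order[:n_val], order[n_val:]
        Xt, yt, wt = Xs[tr], ys[tr], w[tr]
        Xv, yv = Xs[val], ys[val]

        params = self._init_params(X.shape[1])
        adam_m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        adam_v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
        b1, b2, eps, lr = 0.9, 0.999, 1e-8, spec.learning_rate
        t = 0

        best_loss, best_params, best_epoch = np.inf, None, 0
        stopped_early = False
        for epoch in range(spec.epochs):
            perm = self.rng.permutation(len(yt))
            for start in range(0, len(yt), spec.batch_size):
                idx = perm[start : start + spec.batch_size]
                xb, yb, wb = Xt[idx], yt[idx], wt[idx]
                pred, cache = self._forward(xb, params, train=True)
                grad_out = 2.0 * wb * (pred - yb) / max(wb.sum(), eps)
                delta = grad_out[:, None]
                grads = [None] * len(params)
                for i in range(len(params) - 1, -1, -1):
                    h_in, z, mask = cache[i]
                    gW = h_in.T @ delta
                    gb = delta.sum(axis=0)
                    grads[i] = (gW, gb)
                    if i > 0:
                        delta = delta @ params[i][0].T
                        _, z_prev, mask_prev = cache[i - 1]
                        delta = delta * (z_prev > 0)
                        if mask_prev is not None:
                            delta = delta * mask_prev
                t += 1
                for i, (gW, gb) in enumerate(grads):
                    for j, g in enumerate((gW, gb)):
                        adam_m[i][j] = b1 * adam_m[i][j] + (1 - b1) * g
                        adam_v[i][j] = b2 * adam_v[i][j] + (1 - b2) * g * g
                        m_hat = adam_m[i][j] / (1 - b1**t)
                        v_hat = adam_v[i][j] / (1 - b2**t)
                        params[i][j] = params[i][j] - lr * m_hat / (np.sqrt(v_hat) + eps)
            val_pred, _ = self._forward(Xv, params, train=False)
            val_loss = float(np.mean((val_pred - yv) ** 2))
            if val_loss < best_loss:
                best_loss = val_loss
                best_params = [[W.copy(), b.copy()] for W, b in params]
                best_epoch = epoch
            elif epoch - best_epoch >= spec.patience:
                stopped_early = True
                break
        restored = False
        if best_params is not None and (stopped_early or best_epoch < epoch):
            params = best_params
            restored = True
        self.params = params
        return epoch + 1, restored

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        pred, _ = self._forward(Xs, self.params, train=False)
        return pred * self.y_sd + self.y_mean


# ---------------------------------------------------------------------------
# age gaps


def compute_age_gaps(
    models: dict[str, OrganClockResults],
    panels: dict[str, pd.DataFrame],
    participants: pd.DataFrame,
    correct_bias: bool = False,
    composite_exclude: tuple[str, ...] = ("hepatic",),
) -> pd.DataFrame:
    """Per-person, per-organ age gaps plus the composite gap.

    gap[organ] = predicted - chronological age; composite = mean of the
    predicted ages of organs outside ``composite_exclude`` minus
    chronological age.  A configured organ without a model raises.
    """
    missing = [o for o in panels if o not in models]
    if missing:
        raise KeyError(f"no fitted model for organs: {missing}")
    idx = participants.index
    ages = participants["age"].astype(float)
    gaps = pd.DataFrame(index=idx)
    predicted = {}
    for organ, panel in panels.items():
        aligned = panel.loc[idx]
        pred = models[organ].predict(aligned, correct_bias=correct_bias)
        predicted[organ] = pred
        gaps[organ] = pred - ages.to_numpy()
    included = [o for o in panels if o not in composite_exclude]
    if included:
        gaps["composite"] = np.mean([predicted[o] for o in included], axis=0) - ages.to_numpy()
    return gaps


def abs_residual_slope(pred: np.ndarray, ages: np.ndarray) -> float:
    """OLS slope of |prediction residual| on |age - mean age|.

    The heteroskedasticity summary the distance weights are meant to
    shrink: positive slopes mean residuals grow away from the mean age.
    """
    ages = np.asarray(ages, dtype=float)
    resid = np.abs(np.asarray(pred, dtype=float) - ages)
    dist = np.abs(ages - ages.mean())
    dist_c = dist - dist.mean()
    return float(dist_c @ (resid - resid.mean()) / (dist_c @ dist_c))
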