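"""Feed-forward neural-network forecasting of exposure series.

A three-layer network (input, one hidden layer, output) maps ``r``
lagged values of a series to its next value:

    x_hat = sum_l phi2_l * f( sum_k phi_lk x_k + theta_l ) + theta2

with logistic activation ``f`` by default.  Inputs and target are
min-max scaled to [0, 1] before training (exposure series are log-
transformed first by the panel-level driver, so multiplicative growth
becomes additive and the 56 groups' very different sizes share one
scale).  Training minimises squared error by full-batch Adam with early
stopping on a validation tail; everything is deterministic given the
seed.

Annual exposure histories are short (7-10 points per risk group), so the
default driver pools all 56 groups into one network with a group-index
input; per-group networks are available when histories are long enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import RiskGroup, enumerate_groups


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


_ACTIVATIONS = {
    "logistic": (_logistic, lambda a: a * (1.0 - a)),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
}


@dataclass
class AnnModel:
    """Weights and scaling of one trained network.

    ``w1`` has shape (hidden, inputs), ``b1`` (hidden,), ``w2`` (hidden,),
    ``b2`` scalar.  ``x_min/x_max`` and ``y_min/y_max`` are the min-max
    scaling parameters for inputs and target.
    """

    n_inputs: int
    n_hidden: int
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    activation: str = "logistic"
    x_min: float = 0.0
    x_max: float = 1.0
    y_min: float = 0.0
    y_max: float = 1.0
    trained: bool = False
    loss_history: np.ndarray | None = None
    seed: int | None = None
    #: 'level' feeds raw lag values; 'delta' (default in training) feeds
    #: increments relative to the newest lag and predicts the next increment,
    #: which lets the bounded activation extrapolate trends
    representation: str = "level"
    n_lags: int = 0  # lags in the raw window (delta models add extra columns)

    def scale_x(self, x):
        span = self.x_max - self.x_min
        return (np.asarray(x, dtype=float) - self.x_min) / (span if span > 0 else 1.0)

    def unscale_y(self, y):
        span = self.y_max - self.y_min
        return np.asarray(y, dtype=float) * (span if span > 0 else 1.0) + self.y_min


def ann_forward(model: AnnModel, inputs: np.ndarray) -> np.ndarray:
    """Raw forward pass on already-scaled inputs (rows = samples)."""
    act = _ACTIVATIONS[model.activation][0]
    z = inputs @ model.w1.T + model.b1
    return act(z) @ model.w2 + model.b2


def ann_predict(model: AnnModel, inputs) -> float | np.ndarray:
    """Forecast from ``r`` lagged (unscaled) values; inverse-scaled output.

    For delta-representation models the lag window is converted to
    increments internally and the predicted increment is added back to
    the newest lag, so callers always pass raw lagged values.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if model.representation == "delta":
        r = model.n_lags
        if inputs.shape[1] != model.n_inputs + 1:
            # r raw lags collapse to r-1 increments; extra static columns follow
            raise ValueError(f"expected {model.n_inputs + 1} input values")
        lags = inputs[:, :r]
        extra = inputs[:, r:]
        feats = np.column_stack([lags[:, :-1] - lags[:, -1:], extra])
        out = ann_forward(model, model.scale_x(feats))
        return (model.unscale_y(out) + lags[:, -1])[()] if out.size > 1 else float(
            model.unscale_y(out)[0] + lags[0, -1]
        )
    if inputs.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} lagged inputs")
    out = ann_forward(model, model.scale_x(inputs))
    return model.unscale_y(out)[()] if out.size > 1 else float(model.unscale_y(out)[0])


def _init_model(n_inputs: int, n_hidden: int, activation: str, seed) -> AnnModel:
    rng = np.random.default_rng(seed)
    return AnnModel(
        n_inputs=n_inputs,
        n_hidden=n_hidden,
        w1=rng.normal(0.0, 0.5, size=(n_hidden, n_inputs)),
        b1=rng.normal(0.0, 0.5, size=n_hidden),
        w2=rng.normal(0.0, 0.5, size=n_hidden),
        b2=0.0,
        activation=activation,
        seed=seed if isinstance(seed, int) else None,
    )


def _lag_matrix(series: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([series[i : len(series) - r + i] for i in range(r)])
    return X, series[r:]


def ann_train(
    series,
    r: int = 3,
    rs: int = 5,
    seed: int = 0,
    activation: str = "logistic",
    epochs: int = 4000,
    learning_rate: float = 0.02,
    validation_frac: float = 0.2,
    patience: int = 300,
    extra_inputs: np.ndarray | None = None,
    representation: str = "delta",
) -> AnnModel:
    """Train on one series' lag-r one-step-ahead pairs.

    Full-batch Adam on squared error; the last ``validation_frac`` of the
    training pairs form an early-stopping tail (best-weights restore).
    ``extra_inputs`` appends static covariate columns (e.g. a group
    index) to each lag window.  Deterministic given ``seed``.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < r + 10:
        raise ValueError(f"series too short: need at least {r + 10} points")
    X, y = _lag_matrix(series, r)
    if representation == "delta":
        feats = X[:, :-1] - X[:, -1:]
        target = y - X[:, -1]
        scale_ref = np.concatenate([feats.ravel(), target])
        if extra_inputs is not None:
            feats = np.column_stack([feats, np.asarray(extra_inputs, float)[r:]])
        model = _train_on_pairs(feats, target, scale_ref, rs, seed, activation,
                                epochs, learning_rate, validation_frac, patience)
        model.representation = "delta"
        model.n_lags = r
        return model
    if extra_inputs is not None:
        X = np.column_stack([X, np.asarray(extra_inputs, dtype=float)[r:]])
    model = _train_on_pairs(X, y, series, rs, seed, activation, epochs,
                            learning_rate, validation_frac, patience)
    model.n_lags = r
    return model


def _train_on_pairs(
    X, y, scale_ref, rs, seed, activation, epochs, learning_rate,
    validation_frac, patience,
) -> AnnModel:
    n, p = X.shape
    model = _init_model(p, rs, activation, seed)
    model.x_min = float(np.min(scale_ref))
    model.x_max = float(np.max(scale_ref))
    model.y_min, model.y_max = model.x_min, model.x_max
    Xs = model.scale_x(X)
    span = model.y_max - model.y_min
    ys = (y - model.y_min) / (span if span > 0 else 1.0)

    n_val = max(1, int(round(validation_frac * n))) if n >= 10 else 0
    tr = slice(0, n - n_val) if n_val else slice(0, n)
    va = slice(n - n_val, n) if n_val else slice(0, 0)

    act, dact = _ACTIVATIONS[activation]
    params = [model.w1, model.b1, model.w2, np.array([model.b2])]
    m_t = [np.zeros_like(p_) for p_ in params]
    v_t = [np.zeros_like(p_) for p_ in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best = None
    best_val = np.inf
    since_best = 0
    losses = []
    Xtr, ytr = Xs[tr], ys[tr]
    for t in range(1, epochs + 1):
        a = act(Xtr @ params[0].T + params[1])
        pred = a @ params[2] + params[3][0]
        err = pred - ytr
        loss = float(np.mean(err**2))
        losses.append(loss)
        # backprop
        g_out = 2.0 * err / len(err)
        g_w2 = a.T @ g_out
        g_b2 = np.array([np.sum(g_out)])
        g_hidden = np.outer(g_out, params[2]) * dact(a)
        g_w1 = g_hidden.T @ Xtr
        g_b1 = g_hidden.sum(axis=0)
        for k, g in enumerate([g_w1, g_b1, g_w2, g_b2]):
            m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
            v_t[k] = beta2 * v_t[k] + (1 - beta2) * g * g
            mhat = m_t[k] / (1 - beta1**t)
            vhat = v_t[k] / (1 - beta2**t)
            params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        if n_val:
            av = act(Xs[va] @ params[0].T + params[1])
            val = float(np.mean((av @ params[2] + params[3][0] - ys[va]) ** 2))
            if val < best_val - 1e-14:
                best_val = val
                best = [p_.copy() for p_ in params]
                since_best = 0
            else:
                since_best += 1
                if since_best > patience:
                    break
    if best is not None:
        params = best
    model.w1, model.b1, model.w2 = params[0], params[1], params[2]
    model.b2 = float(params[3][0])
    model.trained = True
    model.loss_history = np.asarray(losses)
    return model


# ---------------------------------------------------------------------------
# panel-level exposure forecasting


def forecast_exposures(
    panel: pd.DataFrame,
    horizon: int = 2,
    r: int = 3,
    rs: int = 5,
    seed: int = 0,
    mode: str = "pooled",
    epochs: int = 4000,
) -> pd.DataFrame:
    """Forecast per-group exposures ``horizon`` years ahead.

    Exposure histories are log-transformed (growth becomes additive and
    group scales comparable) and forecast recursively: the t+1 forecast
    feeds the t+2 input window.  ``mode='pooled'`` (default) trains one
    network on all 56 groups' lag windows with a group-index input --
    7-10 annual points cannot support per-group networks -- while
    ``mode='per_group'`` trains one network per group when histories
    allow.  Returns a frame (region, age_sex, year, exposed_forecast).
    """
    groups = enumerate_groups()
    years = sorted(panel["year"].unique())
    if len(years) < 5:
        raise ValueError("need at least 5 historical years per group")
    series = {}
    for g in groups:
        sub = panel[(panel["region"] == g.region) & (panel["age_sex"] == g.age_sex)]
        sub = sub.sort_values("year")
        if len(sub) != len(years):
            raise ValueError(f"missing history for group {g}")
        series[g] = np.log(sub["exposed"].to_numpy(dtype=float))

    out_rows = []
    if mode == "pooled":
        feats_list, y_list, gidx = [], [], []
        for g in groups:
            Xg, yg = _lag_matrix(series[g], r)
            feats_list.append(Xg[:, :-1] - Xg[:, -1:])
            y_list.append(yg - Xg[:, -1])
            gidx.append(np.full(len(yg), g.index / 55.0))
        feats = np.vstack(feats_list)
        target = np.concatenate(y_list)
        gcol = np.concatenate(gidx)
        scale_ref = np.concatenate([feats.ravel(), target])
        lo, span = float(scale_ref.min()), float(scale_ref.max() - scale_ref.min())
        model = _train_on_pairs(
            np.column_stack([feats, gcol * span + lo]),
            target, scale_ref, rs, seed, "logistic", epochs, 0.02, 0.2, 300,
        )
        model.representation = "delta"
        model.n_lags = r
        for g in groups:
            window = list(series[g][-r:])
            gmapped = (g.index / 55.0) * span + lo
            for h in range(1, horizon + 1):
                xin = np.array(window[-r:] + [gmapped])
                pred = float(np.atleast_1d(ann_predict(model, xin))[0])
                window.append(pred)
                out_rows.append((g.region, g.age_sex, years[-1] + h, float(np.exp(pred))))
    elif mode == "per_group":
        for g in groups:
            model = ann_train(series[g], r=r, rs=rs, seed=seed, epochs=epochs)
            window = list(series[g][-r:])
            for h in range(1, horizon + 1):
                pred = float(np.atleast_1d(ann_predict(model, np.array(window[-r:])))[0])
                window.append(pred)
                out_rows.append((g.region, g.age_sex, years[-1] + h, float(np.exp(pred))))
    else:
        raise ValueError("mode must be 'pooled' or 'per_group'")
    return pd.DataFrame(out_rows, columns=["region", "age_sex", "year", "exposed_forecast"])


def forecast_series(
    series: np.ndarray,
    horizon: int,
    r: int = 3,
    rs: int = 5,
    seed: int = 0,
    method: str = "ann",
    epochs: int = 3000,
) -> np.ndarray:
    """Forecast a single (e.g. monthly) series ``horizon`` steps ahead.

    ``method='ann'`` trains the network and iterates it recursively;
    ``method='naive_drift'`` extrapolates the mean first difference
    (cheap fallback for the adjustment-factor pipeline).
    """
    series = np.asarray(series, dtype=float)
    if method == "naive_drift":
        drift = float(np.mean(np.diff(series)))
        return series[-1] + drift * np.arange(1, horizon + 1)
    model = ann_train(series, r=r, rs=rs, seed=seed, epochs=epochs)
    window = list(series[-r:])
    out = []
    for _ in range(horizon):
        pred = float(np.atleast_1d(ann_predict(model, np.array(window[-r:])))[0])
        out.append(pred)
        window.append(pred)
    return np.asarray(out)
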