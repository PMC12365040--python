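"""Sobolev-trained feed-forward regression of log10 S.

The network maps (solute descriptors, solvent descriptors, temperature) to
log10 solubility.  Training penalizes both the value error and the error of
d log10 S / dT, where the predicted gradient is obtained by differentiating
the network with respect to its (unscaled, kelvin) temperature input and the
target gradient comes from finite differences of the experimental curve.

The derivative d y / d T is propagated alongside the ordinary forward pass
as a tangent (forward-mode) vector seeded on the temperature coordinate;
training the gradient term therefore requires backpropagating through that
tangent computation as well ("double backprop"), which the reverse pass
below implements explicitly for tanh layers:

    z = W h + b        u = W t              (primal / tangent pre-activation)
    h' = tanh(z)       t' = tanh'(z) * u

    z_bar = tanh'(z) * h'_bar + tanh''(z) * u * t'_bar
    u_bar = tanh'(z) * t'_bar
    W_bar = z_bar h^T + u_bar t^T,   b_bar = sum z_bar

Four networks trained on different random solute-grouped splits form an
ensemble; reported predictions are the member mean, uncertainty the member
sample standard deviation.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import ExperimentGroup, canonicalize, split_by_solute
from .featurization import (
    DescriptorSchema,
    ScalerState,
    SolutionInput,
    assemble_inputs,
    build_schema,
    compute_descriptors,
    fit_scaler,
    raw_solution_matrix,
    temperature_feature_derivative,
    temperature_feature_value,
)

logger = logging.getLogger("thermosolv")

COMBINE_MODES = ("concat", "add", "subtract", "multiply")
ENSEMBLE_SIZE = 4  # networks per ensemble

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    ``sobolev_weight`` multiplies the gradient-error term of the loss; the
    default makes the two terms comparable given experimental gradients of
    order 1e-2 log10/K.  ``clamp_T`` saturates the temperature input at
    inference so predicted solubility is constant above it.
    """

    schema_name: str = "rdkit_core"
    branch_layers: int = 0
    branch_width: int = 64
    combine_mode: str = "concat"
    hidden_sizes: tuple[int, ...] = (256, 256)
    sobolev_weight: float = 400.0
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 300
    patience: int = 20
    seed: int = 0
    clamp_T: float = 350.0
    temperature_feature: str = "kelvin"  # or "inverse" (1000/T van't Hoff axis)
    vant_hoff_baseline: bool = False  # closed-form linear baseline; MLP fits residuals
    baseline_ridge: float = 1e-6  # Tikhonov strength (per sample) for the baseline fit
    weight_decay: float = 0.0  # decoupled L2 on the network parameters

    def __post_init__(self) -> None:
        if self.combine_mode not in COMBINE_MODES:
            raise ValueError(f"combine_mode must be one of {COMBINE_MODES}")
        if self.sobolev_weight < 0:
            raise ValueError("sobolev_weight must be nonnegative")
        if self.branch_layers < 0:
            raise ValueError("branch_layers must be >= 0")
        if self.temperature_feature not in ("kelvin", "inverse"):
            raise ValueError("temperature_feature must be 'kelvin' or 'inverse'")


# ---------------------------------------------------------------------------
# Finite-difference gradient targets
# ---------------------------------------------------------------------------


def finite_difference_gradients(group: ExperimentGroup) -> np.ndarray:
    """Per-record d log10 S / dT targets from the experimental curve.

    Central differences at interior points, one-sided at the endpoints — the
    standard scheme for the near-linear solubility curves the targets come
    from.  A single-temperature experiment yields a masked (NaN) target.
    """
    T = group.temperatures
    y = group.log_s_values
    n = len(T)
    if n == 1:
        return np.array([np.nan])
    g = np.empty(n)
    g[0] = (y[1] - y[0]) / (T[1] - T[0])
    g[-1] = (y[-1] - y[-2]) / (T[-1] - T[-2])
    for i in range(1, n - 1):
        g[i] = (y[i + 1] - y[i - 1]) / (T[i + 1] - T[i - 1])
    return g


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def sobolev_loss(
    pred_y: np.ndarray,
    true_y: np.ndarray,
    pred_g: np.ndarray,
    true_g: np.ndarray,
    weight: float,
    mask: np.ndarray | None = None,
) -> float:
    """MSE(value) + weight * MSE(gradient over unmasked entries).

    ``mask`` is True where the gradient target is usable; with every entry
    masked (or weight 0) the gradient term contributes exactly 0.
    """
    if weight < 0:
        raise ValueError("weight must be nonnegative")
    value_term = float(np.mean((np.asarray(pred_y) - np.asarray(true_y)) ** 2))
    if weight == 0:
        return value_term
    if mask is None:
        mask = np.isfinite(np.asarray(true_g))
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        logger.info("sobolev_loss: all gradient targets masked; gradient term = 0")
        return value_term
    diff = np.asarray(pred_g)[mask] - np.asarray(true_g)[mask]
    return value_term + weight * float(np.mean(diff**2))


# ---------------------------------------------------------------------------
# Network parameters and passes
# ---------------------------------------------------------------------------


def _init_params(config: ModelConfig, n_features: int, rng: np.random.Generator) -> dict:
    """Glorot-initialized weights for branches and trunk."""

    def layer(n_in: int, n_out: int) -> list[np.ndarray]:
        limit = np.sqrt(6.0 / (n_in + n_out))
        return [rng.uniform(-limit, limit, size=(n_in, n_out)), np.zeros(n_out)]

    def branch() -> list[list[np.ndarray]]:
        layers, d = [], n_features
        for _ in range(config.branch_layers):
            layers.append(layer(d, config.branch_width))
            d = config.branch_width
        return layers

    solute, solvent = branch(), branch()
    branch_out = config.branch_width if config.branch_layers else n_features
    combined = 2 * branch_out if config.combine_mode == "concat" else branch_out
    trunk, d = [], combined + 1
    for width in config.hidden_sizes:
        trunk.append(layer(d, width))
        d = width
    return {"solute": solute, "solvent": solvent, "trunk": trunk, "out": [layer(d, 1)]}


def _branch_forward(h: np.ndarray, layers: list) -> tuple[np.ndarray, list]:
    cache = []
    for W, b in layers:
        z = h @ W + b
        a = np.tanh(z)
        cache.append((h, a))
        h = a
    return h, cache


def _forward(params: dict, X: np.ndarray, config: ModelConfig,
             tangent_seed: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Value and d value/dT (kelvin) for each row, with caches for backward.

    ``tangent_seed`` is d(temperature feature, scaled)/dT per row — the
    chain-rule factor that makes the propagated tangent a derivative in
    log10 per kelvin.
    """
    F = (X.shape[1] - 1) // 2
    s0, v0, t = X[:, :F], X[:, F:2 * F], X[:, 2 * F:]
    hs, cache_s = _branch_forward(s0, params["solute"])
    hv, cache_v = _branch_forward(v0, params["solvent"])

    mode = config.combine_mode
    if mode == "concat":
        c = np.concatenate([hs, hv], axis=1)
    elif mode == "add":
        c = hs + hv
    elif mode == "subtract":
        c = hs - hv
    else:
        c = hs * hv

    h = np.concatenate([c, t], axis=1)
    tau = np.zeros_like(h)
    tau[:, -1] = tangent_seed
    h0, tau0 = h, tau

    trunk_cache = []
    for W, b in params["trunk"]:
        z = h @ W + b
        a = np.tanh(z)
        u = tau @ W
        trunk_cache.append((h, tau, a, u))
        h = a
        tau = (1.0 - a**2) * u
    W, b = params["out"][0]
    y = (h @ W + b)[:, 0]
    g = (tau @ W)[:, 0]
    caches = {"s": cache_s, "v": cache_v, "hs": hs, "hv": hv, "h0": h0, "tau0": tau0,
              "trunk": trunk_cache, "h_last": h, "tau_last": tau}
    return y, g, caches


def _backward(params: dict, caches: dict, config: ModelConfig,
              y_bar: np.ndarray, g_bar: np.ndarray) -> dict:
    """Gradients of the loss given adjoints of value and tangent outputs."""
    grads = {k: [[np.zeros_like(W), np.zeros_like(b)] for W, b in params[k]]
             for k in ("solute", "solvent", "trunk")}
    W_out, _ = params["out"][0]
    h, tau = caches["h_last"], caches["tau_last"]
    yb, gb = y_bar[:, None], g_bar[:, None]
    grads["out"] = [[h.T @ yb + tau.T @ gb, np.array([yb.sum()])]]
    h_bar = yb @ W_out.T
    tau_bar = gb @ W_out.T

    for (W, b), (h_prev, tau_prev, a, u), g_acc in zip(
        reversed(params["trunk"]), reversed(caches["trunk"]), reversed(grads["trunk"])
    ):
        sp = 1.0 - a**2  # tanh'
        spp = -2.0 * a * sp  # tanh''
        z_bar = sp * h_bar + spp * u * tau_bar
        u_bar = sp * tau_bar
        g_acc[0] += h_prev.T @ z_bar + tau_prev.T @ u_bar
        g_acc[1] += z_bar.sum(axis=0)
        h_bar = z_bar @ W.T
        tau_bar = u_bar @ W.T

    c_bar = h_bar[:, :-1]  # temperature column adjoint is discarded (input)
    mode = config.combine_mode
    hs, hv = caches["hs"], caches["hv"]
    if mode == "concat":
        half = hs.shape[1]
        hs_bar, hv_bar = c_bar[:, :half], c_bar[:, half:]
    elif mode == "add":
        hs_bar, hv_bar = c_bar, c_bar
    elif mode == "subtract":
        hs_bar, hv_bar = c_bar, -c_bar
    else:
        hs_bar, hv_bar = c_bar * hv, c_bar * hs

    for key, cache_key, out_bar in (("solute", "s", hs_bar), ("solvent", "v", hv_bar)):
        h_bar = out_bar
        for (W, b), (h_prev, a), g_acc in zip(
            reversed(params[key]), reversed(caches[cache_key]), reversed(grads[key])
        ):
            z_bar = (1.0 - a**2) * h_bar
            g_acc[0] += h_prev.T @ z_bar
            g_acc[1] += z_bar.sum(axis=0)
            h_bar = z_bar @ W.T
    return grads


_PARAM_KEYS = ("solute", "solvent", "trunk", "out")


def _flatten(tree: dict) -> list[np.ndarray]:
    return [arr for key in _PARAM_KEYS if key in tree
            for layer in tree[key] for arr in layer]


class _Adam:
    """Adam with decoupled (AdamW-style) per-parameter weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float, decay: list[float],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.decay = decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v, d in zip(params, grads, self.m, self.v, self.decay):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= self.lr * ((m / b1t) / (np.sqrt(v / b2t) + self.eps) + d * p)


# ---------------------------------------------------------------------------
# Trained artifacts
# ---------------------------------------------------------------------------


# ---------------------------------------------------------------------------
# Van't Hoff linear baseline
#
# log10 S of a dilute solution is, to first order, a + b/T per (solute,
# solvent) pair.  With coefficients modeled linearly in the solution
# representation this becomes a bilinear form [1, rep, t, rep*t] @ w, which a
# small ridge fit solves in closed form.  Used as an optional detrending
# baseline: the Sobolev network then learns only the nonlinear residual,
# which markedly improves extrapolation to structurally unusual solutes
# (a purely linear structure-property trend extrapolates exactly, while a
# saturating network does not).
# ---------------------------------------------------------------------------


def _baseline_design(X: np.ndarray) -> np.ndarray:
    rep, t = X[:, :-1], X[:, -1:]
    return np.concatenate([np.ones_like(t), rep, t, rep * t], axis=1)


def _fit_baseline(X: np.ndarray, y: np.ndarray, ridge_per_sample: float) -> np.ndarray:
    D = _baseline_design(X)
    A = D.T @ D + ridge_per_sample * len(y) * np.eye(D.shape[1])
    return np.linalg.solve(A, D.T @ y)


def _baseline_outputs(X: np.ndarray, w: np.ndarray,
                      tangent_seed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Baseline value and its d/dT (kelvin) via the same chain rule as the net."""
    R = X.shape[1] - 1
    value = _baseline_design(X) @ w
    grad = (w[1 + R] + X[:, :-1] @ w[2 + R:]) * tangent_seed
    return value, grad


def _tangent_seeds(temperatures: np.ndarray, config: ModelConfig,
                   scaler: ScalerState) -> np.ndarray:
    """Per-row chain-rule factor d(scaled T feature)/dT in 1/kelvin."""
    dfdT = temperature_feature_derivative(np.asarray(temperatures, dtype=float),
                                          config.temperature_feature)
    return np.asarray(dfdT) / scaler.temperature_scale


@dataclass
class TrainedNetwork:
    params: dict
    config: ModelConfig
    scaler: ScalerState
    schema: DescriptorSchema
    fingerprint: str
    baseline: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)

    def forward(self, X_scaled: np.ndarray,
                temperatures: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(value, d value/dT kelvin) on pre-scaled rows at the given kelvin T."""
        seeds = _tangent_seeds(temperatures, self.config, self.scaler)
        y, g, _ = _forward(self.params, X_scaled, self.config, seeds)
        if self.baseline is not None:
            b_val, b_grad = _baseline_outputs(X_scaled, self.baseline, seeds)
            y = y + b_val
            g = g + b_grad
        return y, g


@dataclass
class Prediction:
    mean_log_s: float
    std_log_s: float


@dataclass
class EnsembleModel:
    """Four networks trained on different random solute-grouped splits."""

    members: list[TrainedNetwork]
    schema: DescriptorSchema

    def __post_init__(self) -> None:
        if len(self.members) != ENSEMBLE_SIZE:
            raise ValueError(f"an ensemble has exactly {ENSEMBLE_SIZE} members")

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config

    def _member_outputs(self, solutes: Sequence[str], solvents: Sequence[str],
                        temperatures: Sequence[float], want_gradient: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
        temperatures = np.asarray(temperatures, dtype=float)
        if np.any(temperatures <= 0):
            raise ValueError("temperatures must be positive kelvin")
        clamp = self.config.clamp_T
        T_eff = np.minimum(temperatures, clamp) if clamp is not None else temperatures
        t_feat = np.asarray(temperature_feature_value(T_eff, self.config.temperature_feature))
        solute_vecs = np.stack([compute_descriptors(s, self.schema).values for s in solutes])
        solvent_vecs = np.stack([compute_descriptors(s, self.schema).values for s in solvents])
        raw = np.concatenate([solute_vecs, solvent_vecs, t_feat[:, None]], axis=1)
        ys, gs = [], []
        for member in self.members:
            y, g = member.forward(member.scaler.transform(raw), T_eff)
            if want_gradient and clamp is not None:
                g = np.where(temperatures > clamp, 0.0, g)
            ys.append(y)
            gs.append(g)
        return np.stack(ys), np.stack(gs)

    def predict(self, solute_smiles: str, solvent_smiles: str, temperature: float) -> Prediction:
        """Ensemble mean and member-spread std of log10 S for one solution."""
        ys, _ = self._member_outputs([canonicalize(solute_smiles)],
                                     [canonicalize(solvent_smiles)], [temperature])
        return Prediction(mean_log_s=float(ys[:, 0].mean()),
                          std_log_s=float(ys[:, 0].std(ddof=1)))

    def predict_batch(self, solutes: Sequence[str], solvents: Sequence[str],
                      temperatures: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """(mean, std) arrays of log10 S over aligned triples."""
        solutes = [canonicalize(s) for s in solutes]
        solvents = [canonicalize(s) for s in solvents]
        ys, _ = self._member_outputs(solutes, solvents, temperatures)
        return ys.mean(axis=0), ys.std(axis=0, ddof=1)

    def predict_gradient(self, solutes: Sequence[str], solvents: Sequence[str],
                         temperatures: Sequence[float]) -> np.ndarray:
        """Ensemble-mean d log10 S / dT (log10/K); exactly 0 above clamp_T."""
        solutes = [canonicalize(s) for s in solutes]
        solvents = [canonicalize(s) for s in solvents]
        _, gs = self._member_outputs(solutes, solvents, temperatures, want_gradient=True)
        return gs.mean(axis=0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _stack_inputs(inputs: Sequence[SolutionInput]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([s.x for s in inputs])
    y = np.array([s.y for s in inputs])
    g = np.array([s.g for s in inputs])
    mask = np.isfinite(g)
    return X, y, np.where(mask, g, 0.0), mask


def train_network(
    train: Sequence[SolutionInput],
    val: Sequence[SolutionInput],
    config: ModelConfig,
    scaler: ScalerState,
    schema: DescriptorSchema,
) -> TrainedNetwork:
    """Train one Sobolev network with Adam and early stopping on val RMSE."""
    if not train or not val:
        raise ValueError("train and validation sets must be non-empty")
    X, y, g, mask = _stack_inputs(train)
    Xv, yv, _, _ = _stack_inputs(val)
    seeds = _tangent_seeds(np.array([s.temperature for s in train]), config, scaler)
    seeds_v = _tangent_seeds(np.array([s.temperature for s in val]), config, scaler)
    baseline = None
    if config.vant_hoff_baseline:
        baseline = _fit_baseline(X, y, config.baseline_ridge)
        b_val, b_grad = _baseline_outputs(X, baseline, seeds)
        y = y - b_val
        g = np.where(mask, g - b_grad, 0.0)
        yv = yv - _baseline_outputs(Xv, baseline, seeds_v)[0]
    n, D = X.shape
    F = (D - 1) // 2
    if config.combine_mode != "concat" and config.branch_layers == 0 and F < 1:
        raise ValueError("elementwise combine needs nonempty branches")

    rng = np.random.default_rng(config.seed)
    params = _init_params(config, F, rng)
    flat = _flatten(params)
    opt = _Adam(flat, lr=config.learning_rate, decay=[config.weight_decay] * len(flat))
    lam = config.sobolev_weight

    best_rmse, best_params, best_epoch = np.inf, copy.deepcopy(params), -1
    history: list[dict] = []
    batch = min(config.batch_size, n)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        value_losses, grad_losses = [], []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Xb, yb, gb, mb = X[idx], y[idx], g[idx], mask[idx]
            y_hat, g_hat, caches = _forward(params, Xb, config, seeds[idx])
            m = len(idx)
            y_bar = 2.0 * (y_hat - yb) / m
            n_unmasked = int(mb.sum())
            if lam > 0 and n_unmasked > 0:
                g_bar = np.where(mb, 2.0 * lam * (g_hat - gb) / n_unmasked, 0.0)
                grad_losses.append(float(np.mean((g_hat[mb] - gb[mb]) ** 2)))
            else:
                g_bar = np.zeros(m)
            value_losses.append(float(np.mean((y_hat - yb) ** 2)))
            grads = _backward(params, caches, config, y_bar, g_bar)
            opt.step(flat, _flatten(grads))
        epoch_value = float(np.mean(value_losses))
        epoch_grad = float(np.mean(grad_losses)) if grad_losses else 0.0
        if not np.isfinite(epoch_value):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={config.learning_rate}, sobolev_weight={lam}); aborting"
            )
        yv_hat, _, _ = _forward(params, Xv, config, seeds_v)
        val_rmse = float(np.sqrt(np.mean((yv_hat - yv) ** 2)))
        history.append({"epoch": epoch, "train_value_mse": epoch_value,
                        "train_gradient_mse": epoch_grad, "val_rmse": val_rmse})
        if val_rmse < best_rmse - 1e-6:
            best_rmse, best_epoch = val_rmse, epoch
            best_params = copy.deepcopy(params)
        elif epoch - best_epoch >= config.patience:
            break

    logger.info("train_network: stopped at epoch %d, best val RMSE %.4f (epoch %d)",
                history[-1]["epoch"], best_rmse, best_epoch)
    fingerprint = f"n_train={n},n_val={len(val)},seed={config.seed}"
    return TrainedNetwork(params=best_params, config=config, scaler=scaler,
                          schema=schema, fingerprint=fingerprint,
                          baseline=baseline, history=history)


def train_ensemble(
    groups: Sequence[ExperimentGroup],
    config: ModelConfig,
    val_fraction: float = 0.05,
    base_seed: int = 0,
    schema: DescriptorSchema | None = None,
) -> EnsembleModel:
    """Train a 4-member ensemble, each member on its own solute-grouped split.

    Member k re-splits the experiments with seed ``base_seed + k``, fits its
    scaler on its own training records only, and trains with the same
    architecture; ensemble spread then reflects sampling variability.
    """
    schema = schema or build_schema(config.schema_name)
    members = []
    for k in range(ENSEMBLE_SIZE):
        seed_k = base_seed + k
        split = split_by_solute(groups, val_fraction, seed=seed_k)
        raw_train = raw_solution_matrix(split.train, schema,
                                        temperature_feature=config.temperature_feature)
        scaler = fit_scaler(raw_train)
        train_inputs = assemble_inputs(split.train, scaler, schema,
                                       temperature_feature=config.temperature_feature)
        val_inputs = assemble_inputs(split.validation, scaler, schema,
                                     temperature_feature=config.temperature_feature)
        member_config = ModelConfig(**{**asdict(config), "seed": seed_k})
        members.append(train_network(train_inputs, val_inputs, member_config, scaler, schema))
    return EnsembleModel(members=members, schema=schema)


# ---------------------------------------------------------------------------
# Serialization (one directory per model, versioned layout)
# ---------------------------------------------------------------------------

ARTIFACT_VERSION = 1


def save_ensemble(ensemble: EnsembleModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(ensemble.config)
    cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
    meta = {
        "artifact_version": ARTIFACT_VERSION,
        "config": cfg,
        "schema": {"schema_id": ensemble.schema.schema_id,
                   "names": list(ensemble.schema.names)},
        "members": [],
    }
    for i, m in enumerate(ensemble.members):
        weights = {}
        for key in _PARAM_KEYS:
            for j, (W, b) in enumerate(m.params.get(key, [])):
                weights[f"{key}_{j}_W"] = W
                weights[f"{key}_{j}_b"] = b
        if m.baseline is not None:
            weights["baseline"] = m.baseline
        np.savez(directory / f"member_{i}.npz", **weights)
        meta["members"].append({
            "fingerprint": m.fingerprint,
            "layer_counts": {k: len(m.params[k]) for k in _PARAM_KEYS if k in m.params},
            "scaler": {"location": m.scaler.location.tolist(),
                       "scale": m.scaler.scale.tolist(),
                       "fitted_on": m.scaler.fitted_on},
        })
    with open(directory / "model.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    with open(directory / "model.json", "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    cfg = dict(meta["config"])
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    config = ModelConfig(**cfg)
    schema = DescriptorSchema(schema_id=meta["schema"]["schema_id"],
                              names=tuple(meta["schema"]["names"]))
    members = []
    for i, mm in enumerate(meta["members"]):
        data = np.load(directory / f"member_{i}.npz")
        params = {}
        for key, count in mm["layer_counts"].items():
            params[key] = [[data[f"{key}_{j}_W"], data[f"{key}_{j}_b"]]
                           for j in range(count)]
        scaler = ScalerState(location=np.array(mm["scaler"]["location"]),
                             scale=np.array(mm["scaler"]["scale"]),
                             fitted_on=mm["scaler"]["fitted_on"])
        baseline = data["baseline"] if "baseline" in data.files else None
        members.append(TrainedNetwork(params=params, config=config, scaler=scaler,
                                      schema=schema, fingerprint=mm["fingerprint"],
                                      baseline=baseline))
    return EnsembleModel(members=members, schema=schema)
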