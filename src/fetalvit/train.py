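"""Composite-loss training: cross-entropy + λ·MSE, Adam with decoupled weight
decay, mini-batch training with early stopping, and the experiment harnesses
(learning-rate sweep, λ sweep, component ablation).

The total loss is ``L_total = L_class + λ·L_severity`` where ``L_class`` is
cross-entropy over the class probabilities and ``L_severity`` the mean squared
error of the severity score.  λ ≥ 0 balances the two tasks; λ = 0 trains the
classifier alone (the severity head then receives no gradient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import model as M
from .model import ViTConfig

__all__ = [
    "LossBundle",
    "TrainConfig",
    "TrainState",
    "TrainingResult",
    "cross_entropy_loss",
    "severity_mse_loss",
    "composite_loss",
    "adam_init",
    "adam_step",
    "best_epoch_and_stop",
    "train_model",
    "severity_accuracy",
    "epochs_to_convergence",
    "lr_sweep",
    "lambda_sweep",
    "ablation_suite",
    "ABLATION_VARIANTS",
]

_PROB_FLOOR = 1e-12  # clamp for -ln(p) when the true class gets probability 0


@dataclass(frozen=True)
class LossBundle:
    """Components of the composite loss; l_total = l_class + λ·l_severity."""

    l_class: float
    l_severity: float
    lam: float
    l_total: float


def cross_entropy_loss(probs: np.ndarray, true_class: int) -> float:
    """−ln p(true class) for a single probability vector, clamped at
    −ln(1e−12) when the predicted probability underflows to zero."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 1 or not (0 <= true_class < p.shape[0]):
        raise ValueError("invalid probability vector or class index")
    return float(-np.log(max(p[true_class], _PROB_FLOOR)))


def severity_mse_loss(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Mean squared error between predicted and actual severity scores."""
    pred = np.atleast_1d(np.asarray(predicted, dtype=np.float64))
    act = np.atleast_1d(np.asarray(actual, dtype=np.float64))
    if pred.size == 0 or pred.shape != act.shape:
        raise ValueError("predicted/actual must be equal-length and non-empty")
    return float(np.mean((pred - act) ** 2))


def composite_loss(l_class: float, l_severity: float, lam: float) -> LossBundle:
    """Combine the two task losses with weight λ on the severity term."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return LossBundle(
        l_class=float(l_class),
        l_severity=float(l_severity),
        lam=float(lam),
        l_total=float(l_class) + float(lam) * float(l_severity),
    )


# ---------------------------------------------------------------------------
# Adam with decoupled weight decay


@dataclass
class TrainState:
    """Parameters plus Adam moments and step counter."""

    params: dict[str, np.ndarray]
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    step: int = 0
    lr: float = 1e-3
    weight_decay: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def adam_init(
    params: dict[str, np.ndarray], lr: float = 1e-3, weight_decay: float = 0.0
) -> TrainState:
    zeros = {k: np.zeros_like(v) for k, v in params.items()}
    return TrainState(
        params={k: v.copy() for k, v in params.items()},
        m=zeros,
        v={k: np.zeros_like(v) for k, v in params.items()},
        lr=lr,
        weight_decay=weight_decay,
    )


def adam_step(state: TrainState, grads: dict[str, np.ndarray]) -> TrainState:
    """One Adam update (β₁=0.9, β₂=0.999, ε=1e−8) with decoupled weight decay
    θ ← θ − η·γ·θ applied in addition to the adaptive step.  Parameters with
    no gradient entry (frozen heads in ablations) are left untouched by the
    adaptive step but still decay."""
    state.step += 1
    t = state.step
    for key, theta in state.params.items():
        g = grads.get(key)
        if g is not None:
            if g.shape != theta.shape:
                raise ValueError(f"gradient shape mismatch for {key}")
            state.m[key] = state.beta1 * state.m[key] + (1 - state.beta1) * g
            state.v[key] = state.beta2 * state.v[key] + (1 - state.beta2) * g * g
            mhat = state.m[key] / (1 - state.beta1**t)
            vhat = state.v[key] / (1 - state.beta2**t)
            theta -= state.lr * mhat / (np.sqrt(vhat) + state.eps)
        if state.weight_decay:
            theta -= state.lr * state.weight_decay * theta
    return state


# ---------------------------------------------------------------------------
# training loop


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    model: ViTConfig = field(default_factory=ViTConfig)
    lam: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 16
    max_epochs: int = 20
    patience: int = 5
    min_improvement: float = 1e-4
    seed: int = 0
    severity_range: float = 3.0  # span of the severity scale, for reporting

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be >= 1")


@dataclass
class TrainingResult:
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def best_epoch_and_stop(
    val_losses: list[float], patience: int, min_improvement: float = 1e-4
) -> tuple[int, bool]:
    """Early-stopping rule applied to a validation-loss trace.

    Returns ``(best_epoch_index, should_stop)``: training halts once the loss
    has failed to improve on the best seen by at least ``min_improvement`` for
    ``patience`` consecutive epochs.
    """
    best, best_i, since = np.inf, -1, 0
    stop = False
    for i, loss in enumerate(val_losses):
        if loss < best - min_improvement:
            best, best_i, since = loss, i, 0
        else:
            since += 1
            if since >= patience:
                stop = True
                break
    return best_i, stop


def _batch_loss_and_grads(
    params: dict[str, np.ndarray],
    imgs: np.ndarray,
    y_class: np.ndarray,
    y_sev: np.ndarray,
    cfg: TrainConfig,
) -> tuple[LossBundle, dict[str, np.ndarray], M.DualHeadOutput]:
    out, cache = M.forward(params, imgs, cfg.model, return_cache=True)
    b = imgs.shape[0]
    probs = np.maximum(out.class_probs, _PROB_FLOOR)
    l_class = float(-np.mean(np.log(probs[np.arange(b), y_class])))
    onehot = np.zeros_like(out.class_probs)
    onehot[np.arange(b), y_class] = 1.0
    dlogits = (out.class_probs - onehot) / b
    if cfg.model.use_severity_head:
        resid = out.severity_score - y_sev
        l_sev = float(np.mean(resid**2))
        dsev = cfg.lam * 2.0 * resid / b
    else:
        l_sev = 0.0
        dsev = np.zeros(b)
    grads = M.backward(params, cache, dlogits, dsev, cfg.model)
    return composite_loss(l_class, l_sev, cfg.lam), grads, out


def evaluate(
    params: dict[str, np.ndarray],
    imgs: np.ndarray,
    y_class: np.ndarray,
    y_sev: np.ndarray,
    cfg: TrainConfig,
) -> dict[str, float]:
    """Loss components plus accuracy/MAE/RMSE on a held-out split."""
    out = M.forward(params, imgs, cfg.model)
    b = imgs.shape[0]
    probs = np.maximum(out.class_probs, _PROB_FLOOR)
    l_class = float(-np.mean(np.log(probs[np.arange(b), y_class])))
    pred = out.class_probs.argmax(1)
    acc = float(np.mean(pred == y_class))
    if cfg.model.use_severity_head:
        resid = out.severity_score - y_sev
        l_sev = float(np.mean(resid**2))
        mae = float(np.mean(np.abs(resid)))
        rmse = float(np.sqrt(np.mean(resid**2)))
    else:
        l_sev = mae = rmse = 0.0
    bundle = composite_loss(l_class, l_sev, cfg.lam)
    return {
        "l_total": bundle.l_total,
        "l_class": l_class,
        "l_severity": l_sev,
        "accuracy": acc,
        "mae": mae,
        "rmse": rmse,
    }


def train_model(
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> TrainingResult:
    """Mini-batch Adam on the composite loss with early stopping.

    ``train_data``/``val_data`` are ``(images (n,H,W), class indices (n,),
    severities (n,))``.  Returns the parameters of the best-validation epoch
    and a per-epoch history of losses and metrics for both splits.
    """
    xtr, ytr, str_ = (np.asarray(a) for a in train_data)
    xva, yva, sva = (np.asarray(a) for a in val_data)
    if xtr.shape[0] == 0 or xva.shape[0] == 0:
        raise ValueError("train and validation splits must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    params = M.init_params(cfg.model, seed=int(rng.integers(0, 2**31 - 1)))
    state = adam_init(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    rows = []
    val_losses: list[float] = []
    best_params = {k: v.copy() for k, v in state.params.items()}
    n = xtr.shape[0]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bundle, grads, _ = _batch_loss_and_grads(
                state.params, xtr[idx], ytr[idx], str_[idx], cfg
            )
            if not np.isfinite(bundle.l_total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss {bundle.l_total}"
                )
            adam_step(state, grads)
        tr = evaluate(state.params, xtr, ytr, str_, cfg)
        va = evaluate(state.params, xva, yva, sva, cfg)
        rows.append(
            {"epoch": epoch}
            | {f"train_{k}": v for k, v in tr.items()}
            | {f"val_{k}": v for k, v in va.items()}
        )
        val_losses.append(va["l_total"])
        best_i, stop = best_epoch_and_stop(
            val_losses, cfg.patience, cfg.min_improvement
        )
        if best_i == epoch:
            best_params = {k: v.copy() for k, v in state.params.items()}
        if stop:
            break

    best_i, _ = best_epoch_and_stop(val_losses, cfg.patience, cfg.min_improvement)
    return TrainingResult(
        params=best_params,
        history=pd.DataFrame(rows),
        best_epoch=best_i,
        best_val_loss=val_losses[best_i],
    )


# ---------------------------------------------------------------------------
# harnesses


def severity_accuracy(mae: float, severity_range: float = 3.0) -> float:
    """Report severity regression quality on a 0–100 scale:
    100·(1 − MAE/range), floored at 0."""
    return float(max(0.0, 100.0 * (1.0 - mae / severity_range)))


def epochs_to_convergence(val_losses: np.ndarray, improvement_frac: float = 0.95) -> int:
    """First epoch (1-based) at which the validation loss has realized
    ``improvement_frac`` of the run's total improvement, i.e. loss ≤
    min + (1 − frac)·(loss₀ − min).  More robust to per-epoch noise than a
    multiplicative band around the sharp run minimum."""
    losses = np.asarray(val_losses, dtype=np.float64)
    if losses.size == 0:
        raise ValueError("empty loss trace")
    lo = losses.min()
    target = lo + (1.0 - improvement_frac) * (losses[0] - lo)
    return int(np.argmax(losses <= target)) + 1


def lr_sweep(
    train_data,
    val_data,
    cfg: TrainConfig,
    rates: list[float],
    *,
    improvement_frac: float = 0.95,
) -> pd.DataFrame:
    """Train once per learning rate and report epochs to convergence
    (see :func:`epochs_to_convergence`)."""
    rows = []
    for rate in rates:
        if rate <= 0:
            raise ValueError("learning rates must be positive")
        res = train_model(train_data, val_data, replace(cfg, lr=rate))
        losses = res.history["val_l_total"].to_numpy()
        rows.append(
            {
                "learning_rate": rate,
                "epochs": epochs_to_convergence(losses, improvement_frac),
            }
        )
    return pd.DataFrame(rows)


def lambda_sweep(
    train_data, val_data, cfg: TrainConfig, lambdas: list[float]
) -> pd.DataFrame:
    """Train one model per λ on identical data and seed; report classification
    accuracy, severity accuracy (100·(1 − MAE/range)) and percent change of
    each relative to the first λ."""
    rows = []
    for lam in lambdas:
        res = train_model(train_data, val_data, replace(cfg, lam=lam))
        ev = evaluate(res.params, *val_data, replace(cfg, lam=lam))
        rows.append(
            {
                "lambda": lam,
                "classification_accuracy": 100.0 * ev["accuracy"],
                "severity_accuracy": severity_accuracy(
                    ev["mae"], cfg.severity_range
                ),
            }
        )
    df = pd.DataFrame(rows)
    base_c = df["classification_accuracy"].iloc[0]
    base_s = df["severity_accuracy"].iloc[0]
    df["classification_change_pct"] = (
        100.0 * (df["classification_accuracy"] - base_c) / base_c if base_c else np.nan
    )
    df["severity_change_pct"] = (
        100.0 * (df["severity_accuracy"] - base_s) / base_s if base_s else np.nan
    )
    return df


ABLATION_VARIANTS = ("full", "no_positional", "no_self_attention", "single_head")


def _variant_config(cfg: TrainConfig, variant: str) -> TrainConfig:
    if variant == "full":
        return cfg
    if variant == "no_positional":
        return replace(cfg, model=replace(cfg.model, use_positional=False))
    if variant == "no_self_attention":
        return replace(cfg, model=replace(cfg.model, use_self_attention=False))
    if variant == "single_head":
        # drop the severity head; λ is forced to 0
        return replace(
            cfg, lam=0.0, model=replace(cfg.model, use_severity_head=False)
        )
    raise ValueError(f"unknown ablation variant: {variant!r}")


def ablation_suite(
    train_data, val_data, cfg: TrainConfig, variants: list[str] | None = None
) -> pd.DataFrame:
    """Retrain with components removed (positional encoding, self-attention,
    severity head) on identical data and seed, reporting validation accuracy
    and total loss per variant."""
    variants = list(variants) if variants is not None else list(ABLATION_VARIANTS)
    if not variants:
        raise ValueError("variants must be non-empty")
    rows = []
    for variant in variants:
        vcfg = _variant_config(cfg, variant)
        res = train_model(train_data, val_data, vcfg)
        ev = evaluate(res.params, *val_data, vcfg)
        rows.append(
            {
                "variant": variant,
                "accuracy": ev["accuracy"],
                "total_loss": ev["l_total"],
            }
        )
    return pd.DataFrame(rows)
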