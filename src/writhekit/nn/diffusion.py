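"""Score-based denoising diffusion over chain coordinates.

Variance-preserving forward SDE ``dx = -½ β(t) x dt + sqrt(β(t)) dW`` with
a linear variance ramp ``β(t) = β_min + t (β_max − β_min)``, t ∈ [0, 1].
Its marginals are Gaussian, ``x_t = α(t) x_0 + σ(t) ε`` with
``α(t) = exp(-½ ∫ β)`` and ``σ² = 1 − α²``, so at t = 1 samples are
indistinguishable from the isotropic-Gaussian prior on mean-centered
coordinates.  The network is trained by denoising score matching (noise
prediction, so score = −ε̂/σ); sampling integrates either the
probability-flow ODE or the reverse SDE from prior draws.

Everything here runs on the package's own autodiff engine; coordinates are
globally mean-centered and rescaled to unit standard deviation for
training, and rescaled back on sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chain import ChainCoordinates, ParameterError
from .network import NetworkConfig, ScoreNetwork
from .autodiff import Adam, Tensor


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance-preserving schedule with a linear β ramp."""

    beta_min: float = 0.1
    beta_max: float = 20.0
    horizon: float = 1.0

    def beta(self, t):
        return self.beta_min + t * (self.beta_max - self.beta_min)

    def alpha(self, t):
        """Signal coefficient exp(-½ ∫₀ᵗ β)."""
        integral = self.beta_min * t + 0.5 * (self.beta_max - self.beta_min) * t**2
        return np.exp(-0.5 * integral)

    def sigma(self, t):
        """Noise standard deviation sqrt(1 − α²); monotone increasing."""
        return np.sqrt(np.maximum(1.0 - self.alpha(t) ** 2, 1e-12))


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 3e-3
    lr_final: float = 3e-4  # cosine decay target over the epochs
    ema_decay: float = 0.98  # exponential moving average of weights
    prediction: str = "x0"  # "x0" (denoised-structure) or "eps" (noise)
    snr_clip: float = 5.0  # truncated-SNR loss weight for x0 prediction
    t_power: float = 1.5  # t ~ U^power: >1 concentrates on low noise levels
    seed: int = 0
    t_min: float = 1e-3  # avoid the σ→0 singularity of the weight
    checkpoint_every: int = 0  # epochs; 0 disables
    log_every: int = 10


@dataclass
class DiffusionModel:
    """Trained score network plus its schedule and data normalization.

    ``prediction`` selects the network parametrization: ``"x0"`` (the head
    predicts the denoised structure as a residual on the noised input;
    better conditioned for sharp data distributions) or ``"eps"`` (noise
    prediction).  Both give score fields via the Gaussian marginals:
    score = (α x̂₀ − x)/σ² = −ε̂/σ.
    """

    network: ScoreNetwork
    schedule: NoiseSchedule
    scale: float  # data std used for normalization
    prediction: str = "x0"
    loss_curve: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)

    def score(self, x_norm: np.ndarray, t) -> np.ndarray:
        B, N = x_norm.shape[0], x_norm.shape[1]
        out = self.network(x_norm, t).reshape(B, N, 3)
        sig = np.broadcast_to(self.schedule.sigma(t), (B,))[:, None, None]
        if self.prediction == "eps":
            return -out / sig
        alpha = np.broadcast_to(self.schedule.alpha(t), (B,))[:, None, None]
        x0_hat = x_norm + out
        return (alpha * x0_hat - x_norm) / sig**2


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=-2, keepdims=True)


def train_ddpm(
    ensemble: ChainCoordinates,
    network_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    schedule: NoiseSchedule | None = None,
) -> DiffusionModel:
    """Fit a denoising diffusion model to a chain ensemble.

    Minimizes the noise-prediction objective
    ``E_{t, ε} ‖ ε̂(α x₀ + σ ε, t) − ε ‖²`` with ε drawn mean-centered
    (translations are quotiented out).  Deterministic given the seeds in
    the configs.  Raises if the loss diverges.
    """
    net_cfg = network_config or NetworkConfig(n_atoms=ensemble.n_atoms)
    if net_cfg.n_atoms != ensemble.n_atoms:
        raise ParameterError("network n_atoms must match the ensemble")
    cfg = train_config or TrainConfig()
    sched = schedule or NoiseSchedule()
    rng = np.random.default_rng(cfg.seed)

    data = _center(ensemble.positions)
    scale = float(data.std())
    data = data / scale

    if cfg.prediction not in ("x0", "eps"):
        raise ParameterError("prediction must be 'x0' or 'eps'")
    net = ScoreNetwork(net_cfg)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    n = len(data)
    steps_per_epoch = max(1, n // cfg.batch_size)
    model = DiffusionModel(network=net, schedule=sched, scale=scale,
                           prediction=cfg.prediction)
    ema = net.state_dict()

    for epoch in range(cfg.epochs):
        # cosine learning-rate decay
        frac = epoch / max(cfg.epochs - 1, 1)
        opt.lr = cfg.lr_final + 0.5 * (cfg.learning_rate - cfg.lr_final) * (
            1.0 + np.cos(np.pi * frac)
        )
        order = rng.permutation(n)
        epoch_loss = 0.0
        for step in range(steps_per_epoch):
            idx = order[step * cfg.batch_size: (step + 1) * cfg.batch_size]
            x0 = data[idx]
            B, N = x0.shape[0], x0.shape[1]
            u = rng.uniform(0.0, 1.0, size=B) ** cfg.t_power
            t = cfg.t_min + (sched.horizon - cfg.t_min) * u
            eps = _center(rng.normal(size=x0.shape))
            a = sched.alpha(t)[:, None, None]
            s = sched.sigma(t)[:, None, None]
            xt = a * x0 + s * eps

            opt.zero_grad()
            pred = net.forward(xt, t)
            if cfg.prediction == "eps":
                target = eps.reshape(B * N, 3)
                weight = np.ones((B, 1))
            else:
                # residual target: x̂₀ = x_t + net(x_t), so net learns x₀ − x_t
                target = (x0 - xt).reshape(B * N, 3)
                # truncated-SNR weighting: the un-truncated weight α²/σ²
                # recovers the noise-prediction objective exactly
                snr = (a / s) ** 2
                weight = np.minimum(snr, cfg.snr_clip)[:, :, 0] / cfg.snr_clip
            diff = pred - Tensor(target)
            w = Tensor(np.repeat(weight, N, axis=0))
            loss = (diff * diff * w).mean()
            loss.backward()
            opt.step()
            for e, p in zip(ema, net.parameters()):
                e *= cfg.ema_decay
                e += (1.0 - cfg.ema_decay) * p.data
            epoch_loss += float(loss.data)
        epoch_loss /= steps_per_epoch
        if not np.isfinite(epoch_loss) or epoch_loss > 1e6:
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss {epoch_loss}"
            )
        model.loss_curve.append(epoch_loss)
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            model.checkpoints.append((epoch + 1, [e.copy() for e in ema]))
    # sample from the EMA weights (smoother score estimate)
    net.load_state_dict(ema)
    return model


def sample_ensemble(
    model: DiffusionModel,
    n_frames: int,
    method: str = "ode",
    seed: int = 0,
    n_steps: int = 100,
    t_min: float = 1e-3,
    corrector_steps: int = 0,
    corrector_snr: float = 0.15,
    corrector_below_t: float = 0.3,
    denoise_final: bool = True,
) -> ChainCoordinates:
    """Draw frames by integrating the reverse dynamics from the prior.

    ``method="ode"`` integrates the probability-flow ODE
    ``dx/dt = −½β(t)(x + score)`` with fixed-step Heun (deterministic given
    the prior draw); ``method="sde"`` uses Euler–Maruyama on the reverse
    SDE.  Optional annealed-Langevin corrector steps (applied at noise
    levels below ``corrector_below_t``, step size set by the target
    signal-to-noise ratio) equilibrate each marginal where the score is
    most accurate; with ``denoise_final`` the trajectory ends in one
    denoising jump to the predicted clean structure (x₀ parametrization
    only).  Output is mean-centered and rescaled to the training units.
    """
    if method not in ("ode", "sde"):
        raise ParameterError("method must be 'ode' or 'sde'")
    rng = np.random.default_rng(seed)
    net_cfg = model.network.config
    sched = model.schedule
    x = _center(rng.normal(size=(n_frames, net_cfg.n_atoms, 3)))
    # quadratic spacing: dense steps near t = 0 where the score is sharpest
    s = np.linspace(1.0, 0.0, n_steps + 1)
    ts = t_min + (sched.horizon - t_min) * s**2
    for k in range(n_steps):
        t, t_next = ts[k], ts[k + 1]
        dt = t_next - t  # negative
        beta = sched.beta(t)
        score = model.score(x, t)
        if not np.all(np.isfinite(score)):
            raise RuntimeError(f"NaN in score at step {k} (t={t:.4f})")
        if method == "ode":
            drift = -0.5 * beta * (x + score)
            x_pred = x + drift * dt
            beta_n = sched.beta(t_next)
            score_n = model.score(x_pred, t_next)
            drift_n = -0.5 * beta_n * (x_pred + score_n)
            x = x + 0.5 * (drift + drift_n) * dt
        else:
            drift = -0.5 * beta * x - beta * score
            noise = _center(rng.normal(size=x.shape))
            x = x + drift * dt + np.sqrt(beta * (-dt)) * noise
        if corrector_steps and t_next <= corrector_below_t:
            for _ in range(corrector_steps):
                sc = model.score(x, t_next)
                z = _center(rng.normal(size=x.shape))
                g2 = np.mean(np.sum(sc**2, axis=(1, 2)))
                z2 = np.mean(np.sum(z**2, axis=(1, 2)))
                eps = 2.0 * (corrector_snr * np.sqrt(z2 / max(g2, 1e-12))) ** 2
                x = x + eps * sc + np.sqrt(2.0 * eps) * z
        if not np.all(np.isfinite(x)):
            raise RuntimeError(f"NaN during integration at step {k}")
    if denoise_final and model.prediction == "x0":
        x = x + model.network(x, t_min).reshape(x.shape)
    x = _center(x) * model.scale
    return ChainCoordinates(x)
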