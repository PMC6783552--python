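"""Gaussian-mixture variational autoencoder for binary accessibility profiles.

Generative model per cell, with K clusters and d latent dimensions:

    c ~ Discrete(pi)                         cluster indicator
    z | c ~ N(mu_c, sigma_c^2 I)             mixture-of-Gaussians prior
    x | z ~ Bernoulli(mu_x),  mu_x = sigmoid(W z + b)

The recognition model q(z|x) = N(mu_z, sigma_z^2 I) is a ReLU MLP encoder
(default hidden widths 3200-1600-800-400) with the reparameterization
z = mu_z + sigma_z * eps. The discrete posterior factor q(c|x) is taken as
p(c|z) evaluated at the sampled z, which gives the mean-field evidence lower
bound in closed form:

    ELBO = sum_j [x_j log mu_xj + (1-x_j) log(1-mu_xj)]
         - sum_c gamma_c sum_l (1/2)[log s2_cl + (s2_zl + (mu_zl-mu_cl)^2)/s2_cl]
         + (1/2) sum_l (1 + log s2_zl)
         + sum_c gamma_c log(pi_c / gamma_c)

Training maximizes the ELBO by Adam (weight decay 5e-4, mini-batch 32) over
encoder, decoder and prior parameters jointly, after a reconstruction-only
warm-up and an EM Gaussian-mixture fit that initializes pi, mu_c, sigma_c.
All gradients are analytic numpy; the responsibilities gamma are held
constant within each gradient step (stop-gradient), an EM-style choice that
keeps every term's gradient in closed form.

A quick mode for large datasets shrinks the encoder to 1024-128 and trains
with an iteration cap of 30,000 mini-batches and early stopping after 10
epochs without improvement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.mixture import GaussianMixture

from .matrix_io import PeakByCellMatrix

__all__ = [
    "TrainConfig",
    "GMMPrior",
    "EncoderPosterior",
    "DecoderOutput",
    "Responsibilities",
    "GMVAE",
    "responsibilities",
    "elbo",
    "init_gmm",
    "fit",
    "extract_features",
    "impute",
]

log = logging.getLogger(__name__)

_VAR_FLOOR = 1e-4
_LV_MIN = float(np.log(_VAR_FLOOR))
_LV_MAX = 5.0
_MU_X_EPS = 1e-7


# ---------------------------------------------------------------------------
# configuration and value containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the model and its optimizer.

    ``encoder_dims`` are hidden-layer widths; the input width adapts to the
    number of peaks and the two heads (mean, log-variance) map the last
    hidden layer to ``latent_dim``. ``quick`` switches to the 1024-128
    encoder with an iteration cap and early stopping. The learning rate is
    a tunable the published protocol leaves open; the Adam default 1e-3
    trains reliably on the matrices this package targets.
    """

    k: int = 3
    latent_dim: int = 10
    encoder_dims: tuple[int, ...] = (3200, 1600, 800, 400)
    quick: bool = False
    batch_size: int = 32
    weight_decay: float = 5e-4
    learning_rate: float = 1e-3
    max_epochs: int = 300
    warmup_epochs: int = 20
    max_iterations: int = 30_000  # applies in quick mode
    patience: int | None = None  # epochs without improvement; quick mode: 10
    learn_pi: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.latent_dim < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("latent_dim, batch_size, max_epochs must be positive")
        if any(w < 1 for w in self.encoder_dims):
            raise ValueError("encoder widths must be positive")

    @property
    def effective_encoder_dims(self) -> tuple[int, ...]:
        return (1024, 128) if self.quick else self.encoder_dims

    @property
    def effective_patience(self) -> int | None:
        return 10 if self.quick and self.patience is None else self.patience


@dataclass
class GMMPrior:
    """Mixture weights and diagonal-Gaussian components of the latent prior."""

    pi: np.ndarray  # (K,)
    mu: np.ndarray  # (K, d)
    sigma2: np.ndarray  # (K, d)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma2 = np.atleast_2d(np.asarray(self.sigma2, dtype=float))
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be nonnegative and sum to 1")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        if not (len(self.pi) == self.mu.shape[0] == self.sigma2.shape[0]):
            raise ValueError("inconsistent component counts")

    @property
    def n_components(self) -> int:
        return len(self.pi)


@dataclass
class EncoderPosterior:
    mu_z: np.ndarray
    sigma2_z: np.ndarray
    z: np.ndarray


@dataclass
class DecoderOutput:
    mu_x: np.ndarray


@dataclass
class Responsibilities:
    gamma: np.ndarray


# ---------------------------------------------------------------------------
# pure functions of the model's quantities
# ---------------------------------------------------------------------------


def _log_gauss(z: np.ndarray, prior: GMMPrior) -> np.ndarray:
    """log [pi_c N(z | mu_c, sigma_c^2 I)] for each component; (..., K)."""
    z = np.atleast_2d(z)  # (B, d)
    diff = z[:, None, :] - prior.mu[None, :, :]  # (B, K, d)
    lv = np.log(prior.sigma2)[None, :, :]
    ll = -0.5 * np.sum(np.log(2 * np.pi) + lv + diff**2 / prior.sigma2[None], axis=2)
    return ll + np.log(np.maximum(prior.pi, 1e-300))[None, :]


def responsibilities(z: np.ndarray, prior: GMMPrior) -> Responsibilities:
    """Posterior component probabilities gamma_c = p(c|z), via log-sum-exp."""
    lw = _log_gauss(z, prior)  # (B, K)
    gamma = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    if z.ndim == 1:
        gamma = gamma[0]
    return Responsibilities(gamma)


def _kl_terms(
    mu_z: np.ndarray, sigma2_z: np.ndarray, gamma: np.ndarray, prior: GMMPrior
) -> np.ndarray:
    """Closed-form KL(q(z,c|x) || p(z,c)) per cell; inputs broadcast to 2-D."""
    mu_z = np.atleast_2d(mu_z)
    s2_z = np.atleast_2d(sigma2_z)
    gamma = np.atleast_2d(gamma)
    diff2 = (mu_z[:, None, :] - prior.mu[None]) ** 2  # (B, K, d)
    cross = 0.5 * np.sum(
        np.log(prior.sigma2)[None] + (s2_z[:, None, :] + diff2) / prior.sigma2[None],
        axis=2,
    )  # (B, K)
    kl = np.sum(gamma * cross, axis=1)
    kl -= 0.5 * np.sum(1.0 + np.log(s2_z), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = gamma * (np.log(np.maximum(prior.pi, 1e-300))[None] - np.log(gamma))
    kl -= np.sum(np.where(gamma > 0, ent, 0.0), axis=1)
    return kl


def elbo(
    x: np.ndarray,
    posterior: EncoderPosterior,
    output: DecoderOutput,
    gamma: Responsibilities | np.ndarray,
    prior: GMMPrior,
) -> float | np.ndarray:
    """Evidence lower bound: Bernoulli reconstruction minus closed-form KL.

    Accepts a single cell (1-D ``x``) or a batch (2-D, cells in rows);
    returns a scalar or a per-cell vector accordingly.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x != 0) & (x != 1)):
        raise ValueError("x must be binary (apply binarize_input first)")
    g = gamma.gamma if isinstance(gamma, Responsibilities) else np.asarray(gamma)
    mu_x = np.clip(np.atleast_2d(output.mu_x), _MU_X_EPS, 1 - _MU_X_EPS)
    x2 = np.atleast_2d(x)
    recon = np.sum(x2 * np.log(mu_x) + (1 - x2) * np.log(1 - mu_x), axis=1)
    kl = _kl_terms(posterior.mu_z, posterior.sigma2_z, g, prior)
    out = recon - kl
    return float(out[0]) if x.ndim == 1 else out


def init_gmm(latent: np.ndarray, k: int, seed: int = 0) -> GMMPrior:
    """EM fit of a K-component diagonal Gaussian mixture to latent means."""
    latent = np.asarray(latent, dtype=float)
    if latent.shape[0] < k:
        raise ValueError("need at least k cells to fit the mixture")
    gm = GaussianMixture(
        n_components=k, covariance_type="diag", n_init=5, random_state=seed,
        reg_covar=_VAR_FLOOR,
    ).fit(latent)
    sigma2 = np.maximum(gm.covariances_, _VAR_FLOOR)
    if np.any(gm.covariances_ < _VAR_FLOOR):
        log.warning("init_gmm: variance floored at %.0e for degenerate component",
                    _VAR_FLOOR)
    return GMMPrior(gm.weights_, gm.means_, sigma2)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class GMVAE:
    """Encoder / decoder / trainable GMM prior with analytic-gradient Adam.

    Parameters are plain numpy arrays in ``self.params``; the prior is kept
    as a softmax-parameterized weight vector (``rho``), component means and
    log-variances, so constraints (pi on the simplex, variances positive)
    hold after every step.
    """

    def __init__(self, n_peaks: int, config: TrainConfig):
        self.n_peaks = int(n_peaks)
        self.config = config
        self.trained = False
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        dims = (self.n_peaks, *config.effective_encoder_dims)
        d, k = config.latent_dim, config.k
        p: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            p[f"enc_W{i}"] = rng.normal(0, np.sqrt(2.0 / dims[i]),
                                        (dims[i], dims[i + 1]))
            p[f"enc_b{i}"] = np.zeros(dims[i + 1])
        h = dims[-1]
        p["Wm"] = rng.normal(0, np.sqrt(1.0 / h), (h, d))
        p["bm"] = np.zeros(d)
        p["Wv"] = rng.normal(0, np.sqrt(1.0 / h), (h, d))
        p["bv"] = np.full(d, -2.0)  # start with small posterior variance
        p["Wd"] = rng.normal(0, np.sqrt(1.0 / d), (d, self.n_peaks))
        p["bd"] = np.zeros(self.n_peaks)
        p["rho"] = np.zeros(k)
        p["mu_c"] = rng.normal(0, 1.0, (k, d))
        p["lv_c"] = np.zeros((k, d))
        self.params = p
        self._rng = rng
        self._n_hidden = len(config.effective_encoder_dims)

    # -- prior --------------------------------------------------------------

    @property
    def prior(self) -> GMMPrior:
        rho = self.params["rho"]
        pi = np.exp(rho - logsumexp(rho))
        return GMMPrior(pi, self.params["mu_c"],
                        np.exp(np.clip(self.params["lv_c"], _LV_MIN, _LV_MAX)))

    def set_prior(self, prior: GMMPrior) -> None:
        self.params["rho"] = np.log(np.maximum(prior.pi, 1e-12))
        self.params["mu_c"] = prior.mu.copy()
        self.params["lv_c"] = np.log(prior.sigma2)

    # -- forward ------------------------------------------------------------

    def _encode_hidden(self, X: np.ndarray) -> list[np.ndarray]:
        """ReLU MLP; returns [h0=X, h1, ..., hL]."""
        hs = [X]
        for i in range(self._n_hidden):
            a = hs[-1] @ self.params[f"enc_W{i}"] + self.params[f"enc_b{i}"]
            hs.append(np.maximum(a, 0.0))
        return hs

    def encode(
        self, x: np.ndarray, eps: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> EncoderPosterior:
        """Recognition model: mu_z, sigma_z^2 and one reparameterized sample."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.n_peaks:
            raise ValueError(f"expected {self.n_peaks} peaks, got {X.shape[1]}")
        h = self._encode_hidden(X)[-1]
        mu = h @ self.params["Wm"] + self.params["bm"]
        lv = np.clip(h @ self.params["Wv"] + self.params["bv"], _LV_MIN, _LV_MAX)
        if eps is None:
            eps = (rng or self._rng).standard_normal(mu.shape)
        z = mu + np.exp(0.5 * lv) * eps
        s2 = np.exp(lv)
        if single:
            return EncoderPosterior(mu[0], s2[0], z[0])
        return EncoderPosterior(mu, s2, z)

    def decode(self, z: np.ndarray) -> DecoderOutput:
        """Single-layer Bernoulli decoder: mu_x = sigmoid(W z + b)."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        Z = np.atleast_2d(z)
        if Z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"expected latent dim {self.config.latent_dim}, got {Z.shape[1]}")
        mu_x = np.clip(expit(Z @ self.params["Wd"] + self.params["bd"]),
                       _MU_X_EPS, 1 - _MU_X_EPS)
        return DecoderOutput(mu_x[0] if single else mu_x)

    # -- loss and analytic gradients ----------------------------------------

    def _loss_and_grads(
        self, X: np.ndarray, eps: np.ndarray, *, kl_on: bool = True,
        gamma: np.ndarray | None = None,
    ) -> tuple[float, float, float, dict[str, np.ndarray]]:
        """Mean negative ELBO over the batch and its parameter gradients.

        ``eps`` is the reparameterization noise, passed explicitly so the
        computation is a deterministic function of (params, X, eps) — this
        is what the finite-difference tests differentiate. ``gamma``
        overrides the responsibilities (normally recomputed from the current
        z and treated as constants, i.e. stop-gradient; pinning them makes
        the loss an exactly differentiable function for gradient checks).
        """
        p = self.params
        B = X.shape[0]
        hs = self._encode_hidden(X)
        h = hs[-1]
        mu = h @ p["Wm"] + p["bm"]
        lv_raw = h @ p["Wv"] + p["bv"]
        lv = np.clip(lv_raw, _LV_MIN, _LV_MAX)
        lv_open = (lv_raw > _LV_MIN) & (lv_raw < _LV_MAX)
        std = np.exp(0.5 * lv)
        z = mu + std * eps
        s2 = np.exp(lv)

        logits = z @ p["Wd"] + p["bd"]
        mu_x = np.clip(expit(logits), _MU_X_EPS, 1 - _MU_X_EPS)
        recon_per_cell = np.sum(
            X * np.log(mu_x) + (1 - X) * np.log(1 - mu_x), axis=1)

        prior = self.prior
        if kl_on:
            if gamma is None:
                gamma = responsibilities(z, prior).gamma  # (B, K) stop-gradient
            kl_per_cell = _kl_terms(mu, s2, gamma, prior)
        else:
            gamma = None
            kl_per_cell = np.zeros(B)

        recon = float(np.mean(recon_per_cell))
        kl = float(np.mean(kl_per_cell))
        loss = -(recon - kl)

        g: dict[str, np.ndarray] = {}
        # reconstruction backward (d of mean BCE over batch)
        dlogits = (mu_x - X) / B
        g["Wd"] = z.T @ dlogits
        g["bd"] = dlogits.sum(axis=0)
        dz = dlogits @ p["Wd"].T

        dmu = dz.copy()
        dlv = dz * 0.5 * std * eps  # through z = mu + exp(lv/2) eps
        if kl_on:
            inv_s2c = 1.0 / prior.sigma2  # (K, d)
            w = gamma[:, :, None] * inv_s2c[None]  # (B, K, d)
            diff = mu[:, None, :] - prior.mu[None]  # (B, K, d)
            dmu += np.sum(w * diff, axis=1) / B
            dlv += (0.5 * (s2 * np.sum(w, axis=1) - 1.0)) / B
            # prior gradients
            g["mu_c"] = -np.sum(w * diff, axis=0)
            g["lv_c"] = 0.5 * np.sum(
                gamma[:, :, None]
                * (1.0 - (s2[:, None, :] + diff**2) * inv_s2c[None]),
                axis=0,
            )
            lvc_open = (p["lv_c"] > _LV_MIN) & (p["lv_c"] < _LV_MAX)
            g["lv_c"] = np.where(lvc_open, g["lv_c"], 0.0) / B
            g["mu_c"] /= B
            if self.config.learn_pi:
                # d/d rho_k of mean_b[-sum_c gamma_bc log pi_c], pi = softmax(rho)
                g["rho"] = prior.pi - gamma.mean(axis=0)
        dlv *= lv_open

        dh = dmu @ p["Wm"].T + dlv @ p["Wv"].T
        g["Wm"] = h.T @ dmu
        g["bm"] = dmu.sum(axis=0)
        g["Wv"] = h.T @ dlv
        g["bv"] = dlv.sum(axis=0)
        for i in range(self._n_hidden - 1, -1, -1):
            da = dh * (hs[i + 1] > 0)
            g[f"enc_W{i}"] = hs[i].T @ da
            g[f"enc_b{i}"] = da.sum(axis=0)
            dh = da @ p[f"enc_W{i}"].T
        return loss, recon, kl, g

    # -- optimizer ----------------------------------------------------------

    def _adam_init(self) -> dict:
        return {
            "t": 0,
            "m": {k: np.zeros_like(v) for k, v in self.params.items()},
            "v": {k: np.zeros_like(v) for k, v in self.params.items()},
        }

    def _adam_step(self, grads: dict, state: dict) -> None:
        cfg = self.config
        b1, b2, eps = 0.9, 0.999, 1e-8
        state["t"] += 1
        t = state["t"]
        for name, grad in grads.items():
            if name.startswith("enc_W") or name in ("Wm", "Wv", "Wd"):
                grad = grad + cfg.weight_decay * self.params[name]
            m = state["m"][name] = b1 * state["m"][name] + (1 - b1) * grad
            v = state["v"][name] = b2 * state["v"][name] + (1 - b2) * grad**2
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[name] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        np.clip(self.params["lv_c"], _LV_MIN, _LV_MAX, out=self.params["lv_c"])

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray) -> "GMVAE":
        """Train on a (n_cells, n_peaks) binary matrix; see module docstring."""
        X = np.asarray(X, dtype=float)
        if np.any((X != 0) & (X != 1)):
            raise ValueError("input must be binary (apply binarize_input first)")
        cfg = self.config
        n = X.shape[0]
        if n < cfg.k:
            raise ValueError("need at least k cells")
        rng = self._rng

        # phase 1: reconstruction-only warm-up with deterministic z = mu_z
        adam = self._adam_init()
        for epoch in range(cfg.warmup_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = X[order[start:start + cfg.batch_size]]
                loss, recon, _, grads = self._loss_and_grads(
                    batch, np.zeros((batch.shape[0], cfg.latent_dim)),
                    kl_on=False,
                )
                self._adam_step(grads, adam)
            self.history.append(
                {"phase": "warmup", "epoch": epoch, "recon": recon,
                 "kl": 0.0, "elbo": recon})

        # phase 2: EM initialization of the mixture prior on latent means
        latent = self.encode(X, eps=np.zeros((n, cfg.latent_dim))).mu_z
        self.set_prior(init_gmm(latent, cfg.k, seed=cfg.seed))

        # phase 3: joint ELBO training
        adam = self._adam_init()
        best, since_best, iters = np.inf, 0, 0
        patience = cfg.effective_patience
        max_iters = cfg.max_iterations if cfg.quick else np.inf
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            losses, recons, kls = [], [], []
            for start in range(0, n, cfg.batch_size):
                batch = X[order[start:start + cfg.batch_size]]
                eps = rng.standard_normal((batch.shape[0], cfg.latent_dim))
                loss, recon, kl, grads = self._loss_and_grads(batch, eps)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} "
                        f"(batch mean {batch.mean():.4f}, recon {recon:.3g}, "
                        f"kl {kl:.3g})")
                self._adam_step(grads, adam)
                losses.append(loss)
                recons.append(recon)
                kls.append(kl)
                iters += 1
            mean_loss = float(np.mean(losses))
            self.history.append(
                {"phase": "joint", "epoch": epoch,
                 "recon": float(np.mean(recons)), "kl": float(np.mean(kls)),
                 "elbo": -mean_loss})
            if mean_loss < best - 1e-6:
                best, since_best = mean_loss, 0
            else:
                since_best += 1
            if patience is not None and since_best >= patience:
                log.info("early stopping at epoch %d", epoch)
                break
            if iters >= max_iters:
                log.info("iteration cap %d reached at epoch %d", max_iters, epoch)
                break
        self.trained = True
        return self

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        meta = {"n_peaks": self.n_peaks, "trained": self.trained,
                "config": asdict(self.config)}
        (path / "config.json").write_text(json.dumps(meta, indent=1))
        with open(path / "training_log.tsv", "w") as fh:
            fh.write("phase\tepoch\trecon\tkl\telbo\n")
            for row in self.history:
                fh.write(f"{row['phase']}\t{row['epoch']}\t{row['recon']:.6f}"
                         f"\t{row['kl']:.6f}\t{row['elbo']:.6f}\n")

    @classmethod
    def load(cls, path: str | Path) -> "GMVAE":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        cfg = meta["config"]
        cfg["encoder_dims"] = tuple(cfg["encoder_dims"])
        model = cls(meta["n_peaks"], TrainConfig(**cfg))
        with np.load(path / "weights.npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        model.trained = meta["trained"]
        return model


# ---------------------------------------------------------------------------
# matrix-level interface
# ---------------------------------------------------------------------------


def _cells_by_peaks(m: PeakByCellMatrix) -> np.ndarray:
    return m.dense().T.astype(float)


def fit(m: PeakByCellMatrix, cfg: TrainConfig) -> GMVAE:
    """Train a GMVAE on a binarized peak-by-cell matrix."""
    model = GMVAE(m.n_peaks, cfg)
    model.fit(_cells_by_peaks(m))
    return model


def extract_features(m: PeakByCellMatrix, model: GMVAE) -> np.ndarray:
    """Deterministic latent features mu_z, one row per cell (n_cells, d)."""
    if not model.trained:
        raise RuntimeError("model is not trained")
    X = _cells_by_peaks(m)
    post = model.encode(X, eps=np.zeros((X.shape[0], model.config.latent_dim)))
    return post.mu_z


def impute(m: PeakByCellMatrix, model: GMVAE) -> np.ndarray:
    """Denoised Bernoulli probabilities mu_x, shape (n_peaks, n_cells).

    Computed from each cell's latent mean alone — no cell-type labels enter.
    """
    if not model.trained:
        raise RuntimeError("model is not trained")
    features = extract_features(m, model)
    return model.decode(features).mu_x.T
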