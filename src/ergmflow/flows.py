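"""Conditional masked autoregressive flow (MAF) density estimator.

``q_phi(theta | x)`` is a stack of ``L`` affine autoregressive transforms
with MADE-masked single-hidden-layer conditioners of width ``H``; the
conditioning vector ``x`` (the network summary statistics) enters every
conditioner unmasked.  Fixed permutations sit between transforms and the
base density is standard normal.  Density evaluation is one forward pass;
sampling inverts each transform dimension-by-dimension.

Everything here — forward pass, reverse-mode gradients, Adam, early
stopping — is written directly against NumPy.  Both parameters and
conditioning statistics are z-scored from the training set by default,
because ERGM statistics span orders of magnitude (edges ~1e3, GWESP ~1e2).

Two training objectives are provided:

* maximum likelihood, ``-mean log q_phi(theta_b | x_b)`` — the amortised
  posterior-estimation loss when pairs are simulated from the prior;
* the atomic loss used by sequential (multi-round) estimation, a softmax
  cross-entropy over a sampled atom set with logits
  ``log q_phi(theta | x_b) - log pi(theta)``, which absorbs the
  analytically unavailable proposal-correction constant ``Z_phi(x)``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from .priors import PriorSpec

CHECKPOINT_FORMAT = "ergmflow-flow-v1"


class FlowError(ValueError):
    pass


@dataclass(frozen=True)
class FlowConfig:
    """Flow architecture and optimiser settings.

    ``hidden_units`` (H) and ``n_transforms`` (L) set the architecture; the
    optimisation fields mirror common simulation-based-inference defaults
    and are all explicit because nothing in the method itself pins them.
    """

    hidden_units: int = 50
    n_transforms: int = 5
    batch_size: int = 200
    learning_rate: float = 5e-4
    validation_fraction: float = 0.1
    patience_epochs: int = 20
    max_epochs: int = 300
    standardise: bool = True
    log_scale_clamp: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.n_transforms < 1:
            raise FlowError("hidden_units and n_transforms must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise FlowError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise FlowError("batch_size and max_epochs must be positive")


def _made_masks(dim: int, hidden: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Input->hidden and hidden->output masks plus hidden degrees.

    Input degree of position k is k+1; hidden degrees cycle over 1..dim-1
    (or 1 when dim == 1); output i (degree i+1) sees hidden units of degree
    <= i, so output i depends on inputs strictly before it.
    """
    deg_in = np.arange(1, dim + 1)
    hi = max(dim - 1, 1)
    deg_hidden = (np.arange(hidden) % hi) + 1
    m1 = (deg_hidden[:, None] >= deg_in[None, :]).astype(float)  # (H, d)
    m2 = (np.arange(1, dim + 1)[:, None] > deg_hidden[None, :]).astype(float)  # (d, H)
    return m1, m2, deg_hidden


class _Layer:
    """One affine autoregressive transform with a masked tanh conditioner."""

    PARAM_NAMES = ("W1", "C1", "b1", "W2mu", "Cmu", "bmu", "W2a", "Ca", "ba")

    def __init__(self, dim: int, dim_x: int, hidden: int, rng: np.random.Generator):
        self.dim, self.dim_x, self.hidden = dim, dim_x, hidden
        self.m1, self.m2, _ = _made_masks(dim, hidden)
        s = 1.0 / np.sqrt(dim + dim_x)
        self.W1 = rng.normal(0.0, s, size=(hidden, dim))
        self.C1 = rng.normal(0.0, s, size=(hidden, dim_x))
        self.b1 = np.zeros(hidden)
        # zero output weights -> identity transform at init (stable start)
        self.W2mu = np.zeros((dim, hidden))
        self.Cmu = np.zeros((dim, dim_x))
        self.bmu = np.zeros(dim)
        self.W2a = np.zeros((dim, hidden))
        self.Ca = np.zeros((dim, dim_x))
        self.ba = np.zeros(dim)

    def params(self) -> list[np.ndarray]:
        return [getattr(self, n) for n in self.PARAM_NAMES]

    def set_params(self, values: list[np.ndarray]) -> None:
        for n, v in zip(self.PARAM_NAMES, values):
            setattr(self, n, v)

    def _conditioner(self, u: np.ndarray, x: np.ndarray, clamp: float):
        pre = u @ (self.W1 * self.m1).T + x @ self.C1.T + self.b1
        h = np.tanh(pre)
        mu = h @ (self.W2mu * self.m2).T + x @ self.Cmu.T + self.bmu
        a_raw = h @ (self.W2a * self.m2).T + x @ self.Ca.T + self.ba
        a = clamp * np.tanh(a_raw / clamp)
        return h, mu, a_raw, a

    def forward(self, u: np.ndarray, x: np.ndarray, clamp: float):
        h, mu, a_raw, a = self._conditioner(u, x, clamp)
        z = (u - mu) * np.exp(-a)
        logdet = -a.sum(axis=1)
        cache = (u, x, h, mu, a_raw, a, z)
        return z, logdet, cache

    def backward(self, cache, gz: np.ndarray, g: np.ndarray, grads: list[np.ndarray]):
        """Accumulate parameter grads of sum_b g_b logq_b; return du.

        ``gz`` is the gradient flowing into this layer's output z; ``g`` is
        the per-sample weight on the layer's own log-det contribution.
        """
        u, x, h, mu, a_raw, a, z = cache
        e = np.exp(-a)
        ga_c = -gz * z - g[:, None]
        gmu = -gz * e
        gu = gz * e
        # smooth clamp a = c*tanh(a_raw/c): da/da_raw = 1 - tanh^2(a_raw/c)
        ga = ga_c * self._clamp_deriv(a_raw)
        gW2a = (ga.T @ h) * self.m2
        gCa = ga.T @ x
        gba = ga.sum(axis=0)
        gW2mu = (gmu.T @ h) * self.m2
        gCmu = gmu.T @ x
        gbmu = gmu.sum(axis=0)
        gh = ga @ (self.W2a * self.m2) + gmu @ (self.W2mu * self.m2)
        gpre = gh * (1.0 - h * h)
        gW1 = (gpre.T @ u) * self.m1
        gC1 = gpre.T @ x
        gb1 = gpre.sum(axis=0)
        gu = gu + gpre @ (self.W1 * self.m1)
        for acc, val in zip(
            grads, (gW1, gC1, gb1, gW2mu, gCmu, gbmu, gW2a, gCa, gba)
        ):
            acc += val
        return gu

    def set_clamp(self, clamp: float) -> None:
        self._clamp = clamp

    def _clamp_deriv(self, a_raw: np.ndarray) -> np.ndarray:
        t = np.tanh(a_raw / self._clamp)
        return 1.0 - t * t

    def invert(self, z: np.ndarray, x: np.ndarray, clamp: float) -> np.ndarray:
        u = np.zeros_like(z)
        for i in range(self.dim):
            _, mu, _, a = self._conditioner(u, x, clamp)
            u[:, i] = z[:, i] * np.exp(a[:, i]) + mu[:, i]
        return u


class ConditionalMAF:
    """Masked autoregressive flow over ``theta`` conditioned on ``x``."""

    def __init__(self, cfg: FlowConfig, dim_theta: int = 3, dim_x: int = 3):
        if dim_theta < 1 or dim_x < 1:
            raise FlowError("dimensions must be positive")
        self.cfg = cfg
        self.dim_theta = dim_theta
        self.dim_x = dim_x
        rng = np.random.default_rng(cfg.seed)
        self.layers = [
            _Layer(dim_theta, dim_x, cfg.hidden_units, rng)
            for _ in range(cfg.n_transforms)
        ]
        for lay in self.layers:
            lay.set_clamp(cfg.log_scale_clamp)
        # fixed order-reversing permutation between transforms
        self.perms = [np.arange(dim_theta)[::-1].copy() for _ in range(cfg.n_transforms)]
        self.theta_loc = np.zeros(dim_theta)
        self.theta_scale = np.ones(dim_theta)
        self.x_loc = np.zeros(dim_x)
        self.x_scale = np.ones(dim_x)
        self.trained = False
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- parameter utilities ---------------------------------------------

    def _all_params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params()]

    def _set_all_params(self, values: list[np.ndarray]) -> None:
        k = len(_Layer.PARAM_NAMES)
        for i, lay in enumerate(self.layers):
            lay.set_params([v.copy() for v in values[i * k : (i + 1) * k]])

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self._all_params()]

    # -- standardisation ---------------------------------------------------

    def set_standardisation(self, thetas: np.ndarray, xs: np.ndarray) -> None:
        t_sd = thetas.std(axis=0)
        x_sd = xs.std(axis=0)
        if np.any(t_sd == 0) or np.any(x_sd == 0):
            raise FlowError(
                "degenerate standardisation: a training column has zero variance; "
                "add simulation noise or disable standardise"
            )
        self.theta_loc = thetas.mean(axis=0)
        self.theta_scale = t_sd
        self.x_loc = xs.mean(axis=0)
        self.x_scale = x_sd

    def _std_theta(self, theta: np.ndarray) -> np.ndarray:
        return (theta - self.theta_loc) / self.theta_scale

    def _std_x(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x_loc) / self.x_scale

    # -- density & sampling -----------------------------------------------

    def _forward(self, theta_std: np.ndarray, x_std: np.ndarray):
        clamp = self.cfg.log_scale_clamp
        u = theta_std
        caches = []
        logdet = np.zeros(len(u))
        for lay, perm in zip(self.layers, self.perms):
            z, ld, cache = lay.forward(u, x_std, clamp)
            caches.append(cache)
            logdet += ld
            u = z[:, perm]
        logq = -0.5 * (u * u).sum(axis=1) - 0.5 * self.dim_theta * np.log(2 * np.pi)
        logq = logq + logdet
        return logq, u, caches

    def log_prob(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        """``log q_phi(theta | x)`` in the original (unstandardised) space."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] == 1 and theta.shape[0] > 1:
            x = np.broadcast_to(x, (theta.shape[0], self.dim_x))
        logq, _, _ = self._forward(self._std_theta(theta), self._std_x(x))
        return logq - np.log(self.theta_scale).sum()

    def _backward(self, caches, u_final: np.ndarray, g: np.ndarray) -> list[np.ndarray]:
        """Grads of ``sum_b g_b logq_b`` w.r.t. all parameters."""
        grads = [np.zeros_like(p) for p in self._all_params()]
        k = len(_Layer.PARAM_NAMES)
        gu = -u_final * g[:, None]  # d logN(u)/du weighted
        for i in range(len(self.layers) - 1, -1, -1):
            perm = self.perms[i]
            gz = np.empty_like(gu)
            gz[:, perm] = gu
            gu = self.layers[i].backward(caches[i], gz, g, grads[i * k : (i + 1) * k])
        return grads

    def sample(self, n: int, x: np.ndarray, seed: int | None = None) -> np.ndarray:
        """Draw ``n`` conditional samples at conditioning vector(s) ``x``."""
        n = int(n)
        rng = np.random.default_rng(seed)
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] == 1:
            x = np.broadcast_to(x, (n, self.dim_x))
        elif x.shape[0] != n:
            raise FlowError(f"x has {x.shape[0]} rows, expected 1 or {n}")
        xs = self._std_x(x)
        clamp = self.cfg.log_scale_clamp
        u = rng.standard_normal((n, self.dim_theta))
        for lay, perm in zip(reversed(self.layers), reversed(self.perms)):
            z = np.empty_like(u)
            z[:, perm] = u
            u = lay.invert(z, xs, clamp)
        return u * self.theta_scale + self.theta_loc


def build_flow(cfg: FlowConfig, dim_theta: int = 3, dim_x: int = 3) -> ConditionalMAF:
    return ConditionalMAF(cfg, dim_theta, dim_x)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for p, gr, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * gr
            v *= b2
            v += (1 - b2) * gr * gr
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + eps)


def _train_loop(flow: ConditionalMAF, cfg: FlowConfig, n_train: int, loss_and_grads, val_loss):
    """Shared minibatch / early-stopping skeleton.

    ``loss_and_grads(idx)`` computes the minibatch loss and applies the
    Adam step; ``val_loss()`` evaluates the held-out loss.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    best_val = np.inf
    best_params = flow.snapshot()
    since_best = 0
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        ep_losses = []
        for s in range(0, n_train, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            ep_losses.append(loss_and_grads(idx))
        vl = float(val_loss())
        flow.history["train_loss"].append(float(np.mean(ep_losses)))
        flow.history["val_loss"].append(vl)
        if vl < best_val - 1e-6:
            best_val = vl
            best_params = flow.snapshot()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience_epochs:
                break
    flow._set_all_params(best_params)
    flow.trained = True
    return flow


def fit_ml(
    flow: ConditionalMAF,
    targets: np.ndarray,
    contexts: np.ndarray,
    cfg: FlowConfig | None = None,
) -> ConditionalMAF:
    """Maximum-likelihood fit of ``q_phi(target | context)``.

    Minimises the mean negative conditional log-likelihood with Adam,
    early-stopping on a held-out split; the best-validation parameters are
    restored before returning.
    """
    cfg = cfg or flow.cfg
    targets = np.asarray(targets, dtype=float)
    contexts = np.asarray(contexts, dtype=float)
    n = len(targets)
    if n < 2:
        raise FlowError("need at least 2 training pairs")
    if cfg.standardise:
        flow.set_standardisation(targets, contexts)
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    t_std = flow._std_theta(targets)
    x_std = flow._std_x(contexts)
    params = flow._all_params()
    opt = _Adam(params, cfg.learning_rate)

    def loss_and_grads(idx):
        idx = tr_idx[idx]
        logq, u, caches = flow._forward(t_std[idx], x_std[idx])
        g = np.full(len(idx), -1.0 / len(idx))  # minimise -mean logq
        grads = flow._backward(caches, u, g)
        opt.step(params, grads)
        return -logq.mean()

    def val_loss():
        logq, _, _ = flow._forward(t_std[val_idx], x_std[val_idx])
        return -logq.mean()

    return _train_loop(flow, cfg, len(tr_idx), loss_and_grads, val_loss)


def train_flow_ml(flow: ConditionalMAF, pairs, cfg: FlowConfig | None = None) -> ConditionalMAF:
    """ML training on simulated pairs: density over theta given statistics."""
    return fit_ml(flow, pairs.thetas, pairs.stats, cfg)


# ---------------------------------------------------------------------------
# atomic loss
# ---------------------------------------------------------------------------


def _atom_sets(n_batch: int, n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Atom index matrix (n_batch, n_atoms); column 0 is the true pairing."""
    atoms = np.empty((n_batch, n_atoms), dtype=int)
    atoms[:, 0] = np.arange(n_batch)
    for b in range(n_batch):
        others = np.delete(np.arange(n_batch), b)
        atoms[b, 1:] = rng.choice(others, size=n_atoms - 1, replace=False)
    return atoms


def _atomic_logits(flow, thetas_std, x_std, log_prior, atoms):
    nb, K = atoms.shape
    th = thetas_std[atoms.reshape(-1)]
    xs = np.repeat(x_std, K, axis=0)
    logq, u, caches = flow._forward(th, xs)
    logits = (logq - log_prior[atoms.reshape(-1)]).reshape(nb, K)
    return logits, logq.reshape(nb, K), u, caches


def atomic_loss(flow: ConditionalMAF, batch, prior: PriorSpec, n_atoms: int, seed: int = 0) -> float:
    """Mean atomic cross-entropy over a batch of training pairs.

    Per element b the atom set is ``{theta_b}`` plus ``n_atoms - 1``
    contrasting parameters resampled from the batch; the contribution is
    ``-log softmax_0`` of the logits ``log q(theta | x_b) - log pi(theta)``.
    Any constant factor on an unnormalised ``q`` cancels in the softmax.
    """
    thetas = np.asarray(batch.thetas, dtype=float)
    stats = np.asarray(batch.stats, dtype=float)
    nb = len(thetas)
    if n_atoms < 1:
        raise FlowError("n_atoms must be >= 1")
    if n_atoms > nb:
        raise FlowError(f"n_atoms={n_atoms} exceeds batch size {nb}")
    rng = np.random.default_rng(seed)
    atoms = _atom_sets(nb, n_atoms, rng)
    t_std = flow._std_theta(thetas)
    x_std = flow._std_x(stats)
    # logq is evaluated in standardised space; the constant Jacobian term is
    # shared by every atom and cancels in the softmax
    log_prior = np.asarray(prior.log_pdf(thetas), dtype=float)
    logits, _, _, _ = _atomic_logits(flow, t_std, x_std, log_prior, atoms)
    lse = _logsumexp(logits)
    return float(np.mean(lse - logits[:, 0]))


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))).ravel()


def fit_atomic(
    flow: ConditionalMAF,
    thetas: np.ndarray,
    stats: np.ndarray,
    prior: PriorSpec,
    n_atoms: int,
    cfg: FlowConfig | None = None,
) -> ConditionalMAF:
    """Atomic-loss fit: proposal-corrected training for sequential rounds."""
    cfg = cfg or flow.cfg
    thetas = np.asarray(thetas, dtype=float)
    stats = np.asarray(stats, dtype=float)
    n = len(thetas)
    if n < max(2, n_atoms):
        raise FlowError("too few pairs for atomic training")
    if cfg.standardise and not flow.trained:
        flow.set_standardisation(thetas, stats)
    rng = np.random.default_rng(cfg.seed + 7)
    order = np.random.default_rng(cfg.seed).permutation(n)
    n_val = max(n_atoms, int(round(cfg.validation_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    t_std = flow._std_theta(thetas)
    x_std = flow._std_x(stats)
    log_prior = np.asarray(prior.log_pdf(thetas), dtype=float)
    params = flow._all_params()
    opt = _Adam(params, cfg.learning_rate)

    def _loss_grads(idx, update: bool):
        k = min(n_atoms, len(idx))
        atoms = _atom_sets(len(idx), k, rng)
        logits, _, u, caches = _atomic_logits(
            flow, t_std[idx], x_std[idx], log_prior[idx], atoms
        )
        lse = _logsumexp(logits)
        loss = float(np.mean(lse - logits[:, 0]))
        if update:
            soft = np.exp(logits - lse[:, None])
            gl = soft.copy()
            gl[:, 0] -= 1.0
            gl /= len(idx)
            # d loss / d logq_(b,k) = (softmax - onehot)/nb; _backward then
            # yields d loss / d params directly for the descent step
            grads = flow._backward(caches, u, gl.reshape(-1))
            opt.step(params, grads)
        return loss

    def loss_and_grads(idx):
        return _loss_grads(tr_idx[idx], update=True)

    def val_loss():
        return _loss_grads(val_idx, update=False)

    return _train_loop(flow, cfg, len(tr_idx), loss_and_grads, val_loss)


# ---------------------------------------------------------------------------
# checkpoint persistence
# ---------------------------------------------------------------------------


def save_flow(flow: ConditionalMAF, path) -> None:
    """Single-archive checkpoint: parameters, standardisation, config."""
    arrays = {}
    for i, lay in enumerate(flow.layers):
        for name, p in zip(_Layer.PARAM_NAMES, lay.params()):
            arrays[f"layer{i}_{name}"] = p
    meta = {
        "format": CHECKPOINT_FORMAT,
        "dim_theta": flow.dim_theta,
        "dim_x": flow.dim_x,
        "trained": flow.trained,
        "config": {k: getattr(flow.cfg, k) for k in FlowConfig.__dataclass_fields__},
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        theta_loc=flow.theta_loc,
        theta_scale=flow.theta_scale,
        x_loc=flow.x_loc,
        x_scale=flow.x_scale,
        **arrays,
    )


def load_flow(path) -> ConditionalMAF:
    with np.load(path if hasattr(path, "read") else str(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise FlowError(f"unknown checkpoint format {meta.get('format')!r}")
        cfg = FlowConfig(**meta["config"])
        flow = ConditionalMAF(cfg, meta["dim_theta"], meta["dim_x"])
        for i, lay in enumerate(flow.layers):
            lay.set_params([data[f"layer{i}_{n}"] for n in _Layer.PARAM_NAMES])
        flow.theta_loc = data["theta_loc"]
        flow.theta_scale = data["theta_scale"]
        flow.x_loc = data["x_loc"]
        flow.x_scale = data["x_scale"]
        flow.trained = bool(meta["trained"])
    return flow
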