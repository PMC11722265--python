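"""Conditional mixture density network (MDN).

A small feed-forward network maps a conditioning vector x to the parameters
of a diagonal-covariance Gaussian mixture over the target y, giving a
conditional density q(y|x) that supports exact log-density evaluation and
ancestral sampling. Training maximizes the conditional log-likelihood with
Adam and early stopping on a validation split; gradients are written out in
closed form (responsibility-weighted), so the whole estimator is plain
numpy and deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MDNConfig", "ConditionalMDN"]

_LS_MIN, _LS_MAX = -7.0, 5.0   # log-sigma clamp for numerical stability
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MDNConfig:
    n_components: int = 8
    hidden: tuple = (64, 64)
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 300
    patience: int = 20
    validation_fraction: float = 0.1
    weight_decay: float = 1e-6
    seed: int = 0


class ConditionalMDN:
    """q(y | x) as an MLP-parameterized diagonal Gaussian mixture."""

    def __init__(self, d_x: int, d_y: int, config: MDNConfig | None = None):
        self.d_x = d_x
        self.d_y = d_y
        self.config = config or MDNConfig()
        self._params: dict | None = None
        self.train_history_: list = []

    # ---------------- parameter handling ----------------

    def _init_params(self, rng: np.random.Generator) -> dict:
        cfg = self.config
        K, D = cfg.n_components, self.d_y
        sizes = [self.d_x, *cfg.hidden]
        p = {}
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            p[f"W{i}"] = rng.normal(0, np.sqrt(1.0 / fan_in), (sizes[i], sizes[i + 1]))
            p[f"b{i}"] = np.zeros(sizes[i + 1])
        h = sizes[-1]
        p["Wl"] = rng.normal(0, 0.01, (h, K))
        p["bl"] = np.zeros(K)
        p["Wm"] = rng.normal(0, 0.01, (h, K * D))
        # spread the component means so the mixture starts diverse
        p["bm"] = rng.normal(0, 0.5, K * D)
        p["Ws"] = rng.normal(0, 0.01, (h, K * D))
        p["bs"] = np.zeros(K * D)
        return p

    # ---------------- forward / loss ----------------

    def _forward(self, X: np.ndarray, params: dict):
        n_hidden = len(self.config.hidden)
        acts = [X]
        H = X
        for i in range(n_hidden):
            H = np.tanh(H @ params[f"W{i}"] + params[f"b{i}"])
            acts.append(H)
        K, D = self.config.n_components, self.d_y
        logits = H @ params["Wl"] + params["bl"]
        mu = (H @ params["Wm"] + params["bm"]).reshape(-1, K, D)
        ls = np.clip(H @ params["Ws"] + params["bs"], _LS_MIN, _LS_MAX).reshape(-1, K, D)
        return acts, logits, mu, ls

    @staticmethod
    def _mixture_logpdf(Y, logits, mu, ls):
        log_pi = logits - _logsumexp(logits, axis=1, keepdims=True)
        z = (Y[:, None, :] - mu) / np.exp(ls)
        log_comp = -0.5 * (z**2).sum(axis=2) - ls.sum(axis=2) - 0.5 * Y.shape[1] * _LOG2PI
        joint = log_pi + log_comp
        return _logsumexp(joint, axis=1), joint, z

    def _loss_and_grads(self, X, Y, params):
        acts, logits, mu, ls = self._forward(X, params)
        n = X.shape[0]
        K, D = self.config.n_components, self.d_y
        log_q, joint, z = self._mixture_logpdf(Y, logits, mu, ls)
        loss = -log_q.mean()

        r = np.exp(joint - log_q[:, None])                 # responsibilities
        pi = np.exp(logits - _logsumexp(logits, axis=1, keepdims=True))
        g_logits = (pi - r) / n
        inv_sig = np.exp(-ls)
        g_mu = -(r[:, :, None] * z * inv_sig) / n   # d(-logq)/dmu = -r z / sigma
        g_ls = (r[:, :, None] * (1.0 - z**2)) / n

        H = acts[-1]
        grads = {
            "Wl": H.T @ g_logits,
            "bl": g_logits.sum(axis=0),
            "Wm": H.T @ g_mu.reshape(n, K * D),
            "bm": g_mu.reshape(n, K * D).sum(axis=0),
            "Ws": H.T @ g_ls.reshape(n, K * D),
            "bs": g_ls.reshape(n, K * D).sum(axis=0),
        }
        G = (
            g_logits @ params["Wl"].T
            + g_mu.reshape(n, K * D) @ params["Wm"].T
            + g_ls.reshape(n, K * D) @ params["Ws"].T
        )
        for i in range(len(self.config.hidden) - 1, -1, -1):
            G = G * (1.0 - acts[i + 1] ** 2)
            grads[f"W{i}"] = acts[i].T @ G
            grads[f"b{i}"] = G.sum(axis=0)
            if i > 0:
                G = G @ params[f"W{i}"].T
        wd = self.config.weight_decay
        if wd:
            for k in grads:
                if k.startswith("W"):
                    grads[k] = grads[k] + wd * params[k]
        return loss, grads

    # ---------------- training ----------------

    def fit(self, X: np.ndarray, Y: np.ndarray, verbose: bool = False) -> "ConditionalMDN":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be aligned 2-D arrays")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xt, Yt, Xv, Yv = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]

        params = self._init_params(rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(va) for k, va in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = {k: p.copy() for k, p in params.items()}
        bad_epochs = 0
        n_tr = Xt.shape[0]
        self.train_history_ = []

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads = self._loss_and_grads(Xt[idx], Yt[idx], params)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "inputs may be unstandardized or degenerate"
                    )
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    params[k] = params[k] - lr_t * m[k] / (np.sqrt(v[k]) + eps)
            val_loss = -self._log_prob_params(Yv, Xv, params).mean()
            self.train_history_.append(float(val_loss))
            if val_loss < best_val - 1e-5:
                best_val = val_loss
                best_params = {k: p.copy() for k, p in params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
            if verbose and epoch % 10 == 0:
                print(f"  epoch {epoch}: val nll {val_loss:.4f}")
        self._params = best_params
        self.val_loss_ = float(best_val)
        return self

    # ---------------- inference ----------------

    def _log_prob_params(self, Y, X, params):
        _, logits, mu, ls = self._forward(np.atleast_2d(X), params)
        log_q, _, _ = self._mixture_logpdf(np.atleast_2d(Y), logits, mu, ls)
        return log_q

    def log_prob(self, Y: np.ndarray, X: np.ndarray) -> np.ndarray:
        """log q(y_i | x_i) for aligned rows (x broadcast if a single row)."""
        if self._params is None:
            raise RuntimeError("model is not fitted")
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and Y.shape[0] > 1:
            X = np.repeat(X, Y.shape[0], axis=0)
        return self._log_prob_params(Y, X, self._params)

    def sample(self, n: int, x: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Draw n samples from q(y | x) for a single conditioning vector."""
        if self._params is None:
            raise RuntimeError("model is not fitted")
        rng = np.random.default_rng(seed)
        x = np.asarray(x, dtype=float).reshape(1, -1)
        _, logits, mu, ls = self._forward(x, self._params)
        pi = np.exp(logits[0] - _logsumexp(logits[0]))
        comp = rng.choice(len(pi), size=n, p=pi / pi.sum())
        eps = rng.standard_normal((n, self.d_y))
        return mu[0][comp] + eps * np.exp(ls[0][comp])


def _logsumexp(a, axis=None, keepdims=False):
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True)) + amax
    if keepdims:
        return out
    if axis is not None:
        return np.squeeze(out, axis=axis)
    return float(np.squeeze(out))
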