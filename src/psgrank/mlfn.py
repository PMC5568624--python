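"""Three-layer feed-forward network trained by Levenberg-Marquardt.

One hidden layer of sigmoid units (12 by default), linear outputs on
one-hot targets, argmax decision. Training minimizes the sum of squared
residuals with the Levenberg-Marquardt damped Gauss-Newton update; a
held-out validation split of the training data drives early stopping.
Weight initialization and the validation split are fully determined by
the seed, so a fit is reproducible bit for bit.

The network is deliberately small: it is the second of the two reference
classifiers used to score top-d feature subsets, not a production sleep
stager.
"""

from __future__ import annotations

import numpy as np


class ConvergenceError(RuntimeError):
    """Raised when LM training produces non-finite parameters or loss."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLFNClassifier:
    """Multilayer feed-forward network, LM training, early stopping.

    Parameters
    ----------
    n_hidden : hidden sigmoid units.
    max_iter : maximum LM iterations.
    val_frac : fraction of the training data held out for early stopping.
    patience : accepted iterations without validation improvement before
        stopping.
    seed : controls weight initialization and the validation split.
    """

    def __init__(self, n_hidden: int = 12, max_iter: int = 30,
                 val_frac: float = 0.15, patience: int = 5,
                 lambda_init: float = 1e-2, seed: int = 0) -> None:
        self.n_hidden = n_hidden
        self.max_iter = max_iter
        self.val_frac = val_frac
        self.patience = patience
        self.lambda_init = lambda_init
        self.seed = seed

    # -- parameter packing --------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        h, d, c = self.n_hidden, self._d, self._c
        i = 0
        w1 = theta[i:i + h * d].reshape(h, d); i += h * d
        b1 = theta[i:i + h]; i += h
        w2 = theta[i:i + c * h].reshape(c, h); i += c * h
        b2 = theta[i:i + c]
        return w1, b1, w2, b2

    def _forward(self, theta: np.ndarray, x: np.ndarray):
        w1, b1, w2, b2 = self._unpack(theta)
        a = _sigmoid(x @ w1.T + b1)
        return a @ w2.T + b2, a

    def _jacobian(self, theta: np.ndarray, x: np.ndarray):
        """Residual Jacobian, residuals flattened sample-major."""
        w1, b1, w2, b2 = self._unpack(theta)
        n = x.shape[0]
        h, d, c = self.n_hidden, self._d, self._c
        a = _sigmoid(x @ w1.T + b1)
        g = a * (1.0 - a)  # n x h
        jac = np.empty((n * c, theta.size))
        # d residual_{ik} / d W1_{jm} = W2_{kj} g_{ij} x_{im}
        jw1 = np.einsum("kj,ij,im->ikjm", w2, g, x).reshape(n * c, h * d)
        jb1 = np.einsum("kj,ij->ikj", w2, g).reshape(n * c, h)
        jw2 = np.zeros((n, c, c, h))
        idx = np.arange(c)
        jw2[:, idx, idx, :] = a[:, None, :]
        jw2 = jw2.reshape(n * c, c * h)
        jb2 = np.tile(np.eye(c), (n, 1))
        i = 0
        jac[:, i:i + h * d] = jw1; i += h * d
        jac[:, i:i + h] = jb1; i += h
        jac[:, i:i + c * h] = jw2; i += c * h
        jac[:, i:i + c] = jb2
        yhat = a @ w2.T + b2
        return jac, yhat

    # -- training -----------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLFNClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self._d = x.shape[1]
        self._c = self.classes_.size
        targets = np.eye(self._c)[y_enc]
        rng = np.random.default_rng(self.seed)

        n = x.shape[0]
        n_val = max(int(round(self.val_frac * n)), 1) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        xt, yt = x[tr_idx], targets[tr_idx]
        xv, yv = x[val_idx], targets[val_idx]

        h, d, c = self.n_hidden, self._d, self._c
        scale1 = np.sqrt(6.0 / (d + h))
        scale2 = np.sqrt(6.0 / (h + c))
        theta = np.concatenate([
            rng.uniform(-scale1, scale1, h * d),
            np.zeros(h),
            rng.uniform(-scale2, scale2, c * h),
            np.zeros(c),
        ])

        def sse(th, xs, ys):
            pred, _ = self._forward(th, xs)
            return float(np.sum((pred - ys) ** 2))

        lam = self.lambda_init
        loss = sse(theta, xt, yt)
        best_val = sse(theta, xv, yv) if n_val else np.inf
        best_theta = theta.copy()
        stall = 0
        for _ in range(self.max_iter):
            jac, yhat = self._jacobian(theta, xt)
            r = (yhat - yt).ravel()
            jtj = jac.T @ jac
            jtr = jac.T @ r
            improved = False
            for _ in range(8):
                try:
                    step = np.linalg.solve(
                        jtj + lam * np.eye(theta.size), jtr
                    )
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                cand = theta - step
                cand_loss = sse(cand, xt, yt)
                if not np.isfinite(cand_loss):
                    raise ConvergenceError("non-finite training loss")
                if cand_loss < loss:
                    theta, loss = cand, cand_loss
                    lam = max(lam / 10, 1e-12)
                    improved = True
                    break
                lam *= 10
            if not improved or lam > 1e10:
                break
            if n_val:
                val_loss = sse(theta, xv, yv)
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_theta = theta.copy()
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
            else:
                best_theta = theta.copy()
        if not np.all(np.isfinite(best_theta)):
            raise ConvergenceError("non-finite parameters after training")
        self.theta_ = best_theta
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        pred, _ = self._forward(self.theta_, np.asarray(x, dtype=float))
        return self.classes_[np.argmax(pred, axis=1)]
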