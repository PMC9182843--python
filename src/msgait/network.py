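"""The assembled multi-scale gait network.

One backbone branch per scale factor tau, each with its own weights, followed
by the weight-update sub-network (GAP -> localized classification -> Fisher
weighting), a learned linear fusion of the per-scale weighted features, and a
softmax head on the fused global feature.  Every branch also has a local
softmax head on its GAP vector, used by the local loss.

Fisher statistics are refreshed from each training batch with an exponential
running average (momentum 0.9) and the eigenvalue weights lambda are treated
as analytically derived constants: no gradient flows through them (the
trainable parameters are the conv kernels, the per-branch classifier weights,
the fusion maps and the softmax head).  All forward and backward passes are
plain NumPy; runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .backbone import (BackboneConfig, backward_batch, default_config,
                       forward_batch, init_params, output_lengths)
from .multiscale import DEFAULT_SCALES, downsample_batch
from .wsnet import (FisherWeights, fisher_weights_from_scatter,
                    scatter_matrices, softmax)

#: dropout rate applied to the fused global feature during training
FUSION_DROPOUT = 0.8

#: momentum of the exponential running average of the scatter matrices
FISHER_MOMENTUM = 0.9


@dataclass
class ForwardState:
    """Intermediate activations of one batch, kept for the backward pass."""

    per_scale: dict
    fused: np.ndarray
    fused_dropped: np.ndarray
    fusion_mask: Optional[np.ndarray]
    logits: np.ndarray
    probs: np.ndarray


class MultiScaleGaitNet:
    """Weighted multi-scale CNN for gait identification.

    Parameters
    ----------
    n_classes
        Number of enrolled subjects.
    scales
        Block-averaging factors, one backbone branch each.
    input_length
        Window length in time steps before downsampling.
    config
        Backbone layer plan shared (in structure, not weights) by branches.
    fused_dim
        Dimension of the fused global feature.
    n_prime
        Number of Fisher discriminant directions kept per branch; defaults
        to ``min(n_classes - 1, feature channels)``.
    use_ws
        If False, the eigenvalue weights are forced to 1 (ablation switch);
        shapes and code paths are unchanged.
    """

    def __init__(
        self,
        n_classes: int,
        scales: Sequence[int] = DEFAULT_SCALES,
        input_length: int = 200,
        config: Optional[BackboneConfig] = None,
        fused_dim: int = 64,
        n_prime: Optional[int] = None,
        seed: int = 0,
        fisher_momentum: float = FISHER_MOMENTUM,
        fusion_dropout: float = FUSION_DROPOUT,
        use_ws: bool = True,
    ) -> None:
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        scales = [int(t) for t in scales]
        if len(set(scales)) != len(scales):
            raise ValueError("duplicate scales")
        self.n_classes = n_classes
        self.scales = tuple(sorted(scales))
        self.input_length = input_length
        self.config = config or default_config()
        self.fused_dim = fused_dim
        self.fisher_momentum = fisher_momentum
        self.fusion_dropout = fusion_dropout
        self.use_ws = use_ws

        last_conv = [s for s in self.config.layers if s.kind == "conv"][-1]
        self.feature_channels = last_conv.n_kernels
        self.n_prime = n_prime or min(n_classes - 1, self.feature_channels)
        if self.n_prime > n_classes - 1:
            raise ValueError("n_prime must be <= n_classes - 1")

        # validate every branch produces a non-empty feature map
        for tau in self.scales:
            if tau > input_length:
                raise ValueError(
                    f"scale tau={tau} exceeds input length {input_length}")
            output_lengths(self.config, input_length // tau)

        rng = np.random.default_rng(seed)
        c = self.feature_channels
        self.params: Dict[str, np.ndarray] = {}
        for tau in self.scales:
            for k, v in init_params(self.config, rng).items():
                self.params[f"t{tau}.{k}"] = v
            self.params[f"t{tau}.Wc"] = rng.normal(
                0.0, math.sqrt(2.0 / c), size=(c, n_classes))
            self.params[f"t{tau}.bc"] = np.zeros(n_classes)
            self.params[f"t{tau}.Wf"] = rng.normal(
                0.0, math.sqrt(2.0 / self.n_prime),
                size=(self.n_prime, fused_dim))
        self.params["W0"] = rng.normal(
            0.0, math.sqrt(2.0 / fused_dim), size=(fused_dim, n_classes))
        self.params["b0"] = np.zeros(n_classes)

        # Fisher state per branch: running scatters + current weights
        self.fisher: Dict[int, dict] = {}
        for tau in self.scales:
            eye = np.eye(n_classes)[:, : self.n_prime]
            self.fisher[tau] = {
                "sw": None,
                "sb": None,
                "fw": FisherWeights(
                    np.ones(self.n_prime), eye,
                    self.params[f"t{tau}.Wc"] @ eye),
                "weights": np.ones(self.n_prime),
            }

    # ------------------------------------------------------------------
    def _branch_params(self, tau: int) -> Dict[str, np.ndarray]:
        pre = f"t{tau}."
        return {k[len(pre):]: v for k, v in self.params.items()
                if k.startswith(pre)}

    def _update_fisher(self, tau: int, fmap: np.ndarray,
                       labels: np.ndarray) -> None:
        """Refresh one branch's scatter averages and eigen-decomposition."""
        if len(np.unique(labels)) < 2:
            return
        Wc = self.params[f"t{tau}.Wc"]
        bc = self.params[f"t{tau}.bc"]
        B, h, _ = fmap.shape
        scores = (fmap @ Wc + bc).reshape(B * h, self.n_classes)
        rep_labels = np.repeat(labels, h)
        sw_b, sb_b = scatter_matrices(scores, rep_labels)
        st = self.fisher[tau]
        if st["sw"] is None:
            st["sw"], st["sb"] = sw_b, sb_b
        else:
            mom = self.fisher_momentum
            st["sw"] = mom * st["sw"] + (1.0 - mom) * sw_b
            st["sb"] = mom * st["sb"] + (1.0 - mom) * sb_b
        fw = fisher_weights_from_scatter(st["sw"], st["sb"], self.n_prime)
        # pull eigenvectors back from score space to feature space
        proj = Wc @ fw.eigenvectors
        st["fw"] = FisherWeights(fw.lambda_, fw.eigenvectors, proj)
        lam_max = fw.lambda_.max()
        if self.use_ws and lam_max > 0:
            st["weights"] = fw.lambda_ / lam_max
        else:
            st["weights"] = np.ones(self.n_prime)

    # ------------------------------------------------------------------
    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
        labels: Optional[np.ndarray] = None,
        update_fisher: Optional[bool] = None,
    ) -> ForwardState:
        """Run a batch ``(B, input_length, 6)`` through the full network."""
        X = np.asarray(X, dtype=np.float64)
        if update_fisher is None:
            update_fisher = train and labels is not None
        B = X.shape[0]
        per_scale = {}
        fused = np.zeros((B, self.fused_dim))
        for tau in self.scales:
            xt = downsample_batch(X, tau)
            bp = self._branch_params(tau)
            fmap, caches = forward_batch(
                xt, self.config, bp, train=train, rng=rng)
            if update_fisher:
                self._update_fisher(tau, fmap, labels)
            gap = fmap.mean(axis=1)
            local_logits = gap @ bp["Wc"] + bp["bc"]
            local_probs = softmax(local_logits)
            st = self.fisher[tau]
            fhat = (gap @ st["fw"].projection) * st["weights"]
            fused = fused + fhat @ bp["Wf"]
            per_scale[tau] = {
                "fmap": fmap, "caches": caches, "gap": gap,
                "local_probs": local_probs, "fhat": fhat,
            }
        fusion_mask = None
        fused_dropped = fused
        if train and self.fusion_dropout > 0:
            if rng is None:
                raise ValueError("rng required for dropout in training mode")
            keep = 1.0 - self.fusion_dropout
            fusion_mask = (rng.random(fused.shape) < keep) / keep
            fused_dropped = fused * fusion_mask
        logits = fused_dropped @ self.params["W0"] + self.params["b0"]
        return ForwardState(per_scale, fused, fused_dropped, fusion_mask,
                            logits, softmax(logits))

    # ------------------------------------------------------------------
    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        alpha: float,
        beta: float,
        alpha_i: Sequence[float],
        train: bool = True,
        rng: Optional[np.random.Generator] = None,
        update_fisher: Optional[bool] = None,
    ) -> Tuple[dict, Dict[str, np.ndarray]]:
        """Composite loss and gradients of one batch.

        The objective is ``alpha * sum_i alpha_i CE_i + beta * CE_global``
        plus the L2 penalty on conv kernels.  Returns a dict with entries
        ``local``, ``global``, ``overall``, ``objective`` and the gradient
        dict keyed like ``self.params``.
        """
        y = np.asarray(y)
        B = X.shape[0]
        state = self.forward(X, train=train, rng=rng, labels=y,
                             update_fisher=update_fisher)
        Y = np.zeros((B, self.n_classes))
        Y[np.arange(B), y] = 1.0

        eps = 1e-7
        ce_global = float(
            -np.mean(np.log(np.clip(state.probs[np.arange(B), y], eps, None))))
        ce_locals = []
        for tau in self.scales:
            p = state.per_scale[tau]["local_probs"]
            ce_locals.append(float(
                -np.mean(np.log(np.clip(p[np.arange(B), y], eps, None)))))
        local = float(np.dot(alpha_i, ce_locals))
        overall = alpha * local + beta * ce_global
        penalty = self.config.l2_reg * sum(
            float(np.sum(v ** 2)) for k, v in self.params.items()
            if ".conv" in k and k.endswith("_W"))
        losses = {"local": local, "global": ce_global, "overall": overall,
                  "objective": overall + penalty,
                  "per_scale_local": ce_locals}

        grads: Dict[str, np.ndarray] = {}
        dlogits = beta * (state.probs - Y) / B
        grads["W0"] = state.fused_dropped.T @ dlogits
        grads["b0"] = dlogits.sum(axis=0)
        dfused = dlogits @ self.params["W0"].T
        if state.fusion_mask is not None:
            dfused = dfused * state.fusion_mask
        for i, tau in enumerate(self.scales):
            ps = state.per_scale[tau]
            bp = self._branch_params(tau)
            st = self.fisher[tau]
            grads[f"t{tau}.Wf"] = ps["fhat"].T @ dfused
            dfhat = dfused @ bp["Wf"].T
            dgap = (dfhat * st["weights"]) @ st["fw"].projection.T
            dlocal = alpha * alpha_i[i] * (ps["local_probs"] - Y) / B
            grads[f"t{tau}.Wc"] = ps["gap"].T @ dlocal
            grads[f"t{tau}.bc"] = dlocal.sum(axis=0)
            dgap = dgap + dlocal @ bp["Wc"].T
            h = ps["fmap"].shape[1]
            dfmap = np.broadcast_to(
                dgap[:, None, :] / h, ps["fmap"].shape).copy()
            _, bb_grads = backward_batch(dfmap, ps["caches"], self.config, bp)
            for k, v in bb_grads.items():
                grads[f"t{tau}.{k}"] = v
        return losses, grads

    # ------------------------------------------------------------------
    def predict(self, X: np.ndarray, batch_size: int = 128
                ) -> Tuple[np.ndarray, np.ndarray]:
        """Inference: class probabilities and fused global features."""
        X = np.asarray(X, dtype=np.float64)
        probs, feats = [], []
        for i in range(0, X.shape[0], batch_size):
            state = self.forward(X[i:i + batch_size], train=False)
            probs.append(state.probs)
            feats.append(state.fused)
        return np.concatenate(probs), np.concatenate(feats)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        """Copy of all trainable parameters and Fisher state."""
        fisher = {}
        for tau, st in self.fisher.items():
            fisher[tau] = {
                "sw": None if st["sw"] is None else st["sw"].copy(),
                "sb": None if st["sb"] is None else st["sb"].copy(),
                "lambda": st["fw"].lambda_.copy(),
                "eigenvectors": st["fw"].eigenvectors.copy(),
                "projection": st["fw"].projection.copy(),
                "weights": st["weights"].copy(),
            }
        return {"params": {k: v.copy() for k, v in self.params.items()},
                "fisher": fisher}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k] = v.copy()
        for tau, st in state["fisher"].items():
            tau = int(tau)
            self.fisher[tau]["sw"] = None if st["sw"] is None else st["sw"].copy()
            self.fisher[tau]["sb"] = None if st["sb"] is None else st["sb"].copy()
            self.fisher[tau]["fw"] = FisherWeights(
                st["lambda"].copy(), st["eigenvectors"].copy(),
                st["projection"].copy())
            self.fisher[tau]["weights"] = st["weights"].copy()
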