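"""Dual-branch convolutional classifier for 2-year time-to-progression.

Architecture: two branches with identical layout but independent weights,
one per view (coronal / sagittal MIP, 275 x 200, single channel).  Each
branch stacks four 3 x 3 valid (unpadded) convolutions with ReLU and
spatial dropout (rate 0.35), the first three followed by max-pooling of
sizes (3,3), (3,3), (2,2) and the last by global average pooling.  Feature
maps double per layer: 16, 32, 64, 128.  The two 128-vectors are
concatenated and a dense layer with softmax yields (P(TTP0), P(TTP1)),
which sum to 1.  Training uses categorical cross-entropy and Adam with
learning rate 5e-5 and a per-step decay of 1e-6 (lr_t = lr / (1 + decay*t)).

The network, backpropagation and the optimizer are implemented directly on
NumPy (convolutions as nine shifted GEMMs), which keeps training exactly
reproducible from a single integer seed and fast enough for desk-scale
phantom cohorts on one CPU.

Three training schemes are supported: (1) lesion-MIP only; (2) pre-train on
binary lesion masks then fine-tune on regular MIPs ("mip"); (3) the same
with brain-removed MIPs ("br_mip").  Per subset, five models are trained
(one per CV fold) and the fold with the highest validation AUC is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort_sampling import CohortPartition
from .evaluation import roc_auc
from .mip_engine import CANVAS_SHAPE, MIPImage
from .volume_io import TTP1

logger = logging.getLogger(__name__)

_EPS = 1e-7  # Adam epsilon


@dataclass
class ModelConfig:
    """Hyperparameters of the dual-branch CNN.

    Defaults are the full-scale ("paper") profile.  ``desk()`` is a reduced
    preset for phantom-scale runs: 10x fewer epochs with a correspondingly
    larger Adam step (1e-3, the canonical Adam default).  ``weight_decay``
    is an alternative reading of "decay rate" (L2 on the weights) and is off
    by default; ``decay`` is the per-step learning-rate decay.
    """

    conv_feature_maps: tuple[int, ...] = (16, 32, 64, 128)
    conv_kernel: int = 3
    spatial_dropout_rate: float = 0.35
    pool_sizes: tuple[tuple[int, int], ...] = ((3, 3), (3, 3), (2, 2))
    learning_rate: float = 5e-5
    decay: float = 1e-6
    weight_decay: float = 0.0
    batch_size: int = 16
    epochs_stage1: int = 200
    epochs_stage2: int = 300
    input_shape: tuple[int, int] = CANVAS_SHAPE
    seed: int = 0

    @staticmethod
    def paper(seed: int = 0) -> "ModelConfig":
        return ModelConfig(seed=seed)

    @staticmethod
    def desk(seed: int = 0) -> "ModelConfig":
        return ModelConfig(learning_rate=3e-3, decay=1e-5,
                           epochs_stage1=20, epochs_stage2=30, seed=seed)


@dataclass
class Prediction:
    patient_id: str
    p_ttp0: float
    p_ttp1: float
    scheme: str = "lesion"
    model_version: str = ""


@dataclass
class TrainedModel:
    """A trained network plus its provenance (subset, fold, scheme, CV-AUC)."""

    model: "DualBranchCNN"
    config: ModelConfig
    subset_id: str
    fold_id: int
    scheme: str
    cv_auc: float
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# layer primitives (channels-last, float32)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold k x k valid patches: (N,H,W,Cin) -> (N*Ho*Wo, Cin*k*k)."""
    sw = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    N, Ho, Wo = sw.shape[0], sw.shape[1], sw.shape[2]
    return sw.reshape(N * Ho * Wo, -1)   # patch layout (Cin, ki, kj)


def _wmat(W: np.ndarray) -> np.ndarray:
    """(k,k,Cin,Cout) -> (Cin*k*k, Cout) matching the im2col patch layout."""
    k = W.shape[0]
    return W.transpose(2, 0, 1, 3).reshape(-1, W.shape[-1])


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid convolution as a single im2col GEMM. Returns (y, cols)."""
    N, H, Wd, Cin = x.shape
    k = W.shape[0]
    Ho, Wo = H - k + 1, Wd - k + 1
    cols = _im2col(x, k)
    y = cols @ _wmat(W) + b
    return y.reshape(N, Ho, Wo, W.shape[-1]), cols


def _conv_backward(cols: np.ndarray, in_shape: tuple[int, ...],
                   W: np.ndarray, dy: np.ndarray, need_dx: bool = True):
    """Gradients of the valid convolution w.r.t. input, weights and bias.

    ``need_dx=False`` skips the input gradient (the first layer has no
    parameters below it, and its input gradient is the most expensive)."""
    N, H, Wd, Cin = in_shape
    k = W.shape[0]
    Ho, Wo = dy.shape[1], dy.shape[2]
    Cout = W.shape[-1]
    dy2 = dy.reshape(-1, Cout)
    dWmat = cols.T @ dy2
    dW = dWmat.reshape(Cin, k, k, Cout).transpose(1, 2, 0, 3)
    db = dy2.sum(axis=0)
    if not need_dx:
        return None, np.ascontiguousarray(dW), db
    dcols = (dy2 @ _wmat(W).T).reshape(N, Ho, Wo, Cin, k, k)
    dx = np.zeros(in_shape, dtype=dy.dtype)
    for di in range(k):
        for dj in range(k):
            dx[:, di:di + Ho, dj:dj + Wo, :] += dcols[:, :, :, :, di, dj]
    return dx, np.ascontiguousarray(dW), db


def _pool_forward(x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Non-overlapping max pooling with floor cropping."""
    kh, kw = size
    N, H, W, C = x.shape
    Ho, Wo = H // kh, W // kw
    return x[:, :Ho * kh, :Wo * kw, :].reshape(N, Ho, kh, Wo, kw, C).max(axis=(2, 4))


def _pool_backward(dy: np.ndarray, x: np.ndarray, out: np.ndarray,
                   size: tuple[int, int]) -> np.ndarray:
    """Max-pool gradient; ties share the gradient equally (a valid, deterministic
    subgradient that avoids an expensive argmax scatter)."""
    kh, kw = size
    N, H, W, C = x.shape
    Ho, Wo = out.shape[1], out.shape[2]
    xr = x[:, :Ho * kh, :Wo * kw, :].reshape(N, Ho, kh, Wo, kw, C)
    mask = xr == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxr = mask * (dy[:, :, None, :, None, :] / counts)
    dx = np.zeros(x.shape, dtype=dy.dtype)
    dx[:, :Ho * kh, :Wo * kw, :] = dxr.reshape(N, Ho * kh, Wo * kw, C)
    return dx


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class DualBranchCNN:
    """The network itself: parameters, forward/backward, Adam updates.

    ``input_shape`` is configurable internally (small shapes are used by the
    gradient-check tests); the public :func:`build_model` enforces the
    275 x 200 canvas.
    """

    BRANCHES = ("coronal", "sagittal")

    def __init__(self, config: ModelConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.rng = np.random.Generator(np.random.Philox(config.seed))
        self.step = 0
        self._build()

    # -- construction -------------------------------------------------------

    def _layer_plan(self) -> list[tuple[int, Optional[tuple[int, int]]]]:
        maps = self.config.conv_feature_maps
        pools = list(self.config.pool_sizes) + [None] * (len(maps) - len(self.config.pool_sizes))
        return list(zip(maps, pools))

    def _build(self) -> None:
        cfg = self.config
        k = cfg.conv_kernel
        self.params: dict[str, np.ndarray] = {}
        h, w = cfg.input_shape
        cin = 1
        for li, (cout, pool) in enumerate(self._layer_plan()):
            h, w = h - k + 1, w - k + 1
            if h <= 0 or w <= 0:
                raise ValueError(f"input {cfg.input_shape} too small for the layer stack")
            if pool is not None:
                h, w = h // pool[0], w // pool[1]
                if h == 0 or w == 0:
                    raise ValueError(f"input {cfg.input_shape} too small for the layer stack")
            for br in self.BRANCHES:
                fan_in, fan_out = k * k * cin, k * k * cout
                self.params[f"{br}_W{li}"] = _glorot(
                    self.rng, (k, k, cin, cout), fan_in, fan_out, self.dtype)
                self.params[f"{br}_b{li}"] = np.zeros(cout, dtype=self.dtype)
            cin = cout
        feat = 2 * cin
        self.params["dense_W"] = _glorot(self.rng, (feat, 2), feat, 2, self.dtype)
        self.params["dense_b"] = np.zeros(2, dtype=self.dtype)
        self.opt_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self.opt_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def reset_optimizer(self) -> None:
        """Clear Adam state and the step counter (used between training stages)."""
        self.step = 0
        for k_ in self.params:
            self.opt_m[k_][...] = 0.0
            self.opt_v[k_][...] = 0.0

    def n_parameters(self, branch: Optional[str] = None) -> int:
        if branch is None:
            return int(sum(v.size for v in self.params.values()))
        return int(sum(v.size for k_, v in self.params.items() if k_.startswith(branch)))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k_: v.copy() for k_, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k_ in self.params:
            self.params[k_] = weights[k_].astype(self.dtype).copy()

    # -- forward / backward -------------------------------------------------

    def _branch_forward(self, x: np.ndarray, br: str, training: bool,
                        rng: Optional[np.random.Generator]):
        cfg = self.config
        cache = []
        for li, (cout, pool) in enumerate(self._layer_plan()):
            in_shape = x.shape
            z, cols = _conv_forward(x, self.params[f"{br}_W{li}"], self.params[f"{br}_b{li}"])
            relu_mask = z > 0
            a = np.maximum(z, 0, out=z)          # in place: z is not reused
            if training and cfg.spatial_dropout_rate > 0:
                keep = 1.0 - cfg.spatial_dropout_rate
                dmask = (rng.uniform(size=(a.shape[0], 1, 1, a.shape[3])) < keep)
                dmask = dmask.astype(self.dtype) / keep
                a *= dmask
            else:
                dmask = None
            if pool is not None:
                out = _pool_forward(a, pool)
            else:
                out = a.mean(axis=(1, 2))        # global average pooling
            cache.append((cols if training else None, in_shape, relu_mask, dmask,
                          a if training else None, out if training else None, pool))
            x = out
        return x, cache

    def _branch_backward(self, dfeat: np.ndarray, cache, br: str, grads: dict) -> None:
        d = dfeat
        for li in reversed(range(len(self._layer_plan()))):
            cols, in_shape, relu_mask, dmask, a, out, pool = cache[li]
            if pool is not None:
                d = _pool_backward(d, a, out, pool)
            else:
                n_px = a.shape[1] * a.shape[2]
                d = np.broadcast_to(d[:, None, None, :] / n_px, a.shape).astype(self.dtype)
                d = np.ascontiguousarray(d)
            if dmask is not None:
                d *= dmask
            d *= relu_mask
            dx, dW, db = _conv_backward(cols, in_shape, self.params[f"{br}_W{li}"], d,
                                        need_dx=li > 0)
            grads[f"{br}_W{li}"] = dW
            grads[f"{br}_b{li}"] = db
            d = dx

    def forward(self, xc: np.ndarray, xs: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Class probabilities for a batch of (coronal, sagittal) image pairs."""
        fc, cache_c = self._branch_forward(xc, "coronal", training, rng)
        fs, cache_s = self._branch_forward(xs, "sagittal", training, rng)
        feat = np.concatenate([fc, fs], axis=1)
        logits = feat @ self.params["dense_W"] + self.params["dense_b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (cache_c, cache_s, feat)

    def loss_and_grads(self, xc, xs, y, rng):
        """Mean categorical cross-entropy and parameter gradients."""
        n = xc.shape[0]
        probs, (cache_c, cache_s, feat) = self.forward(xc, xs, training=True, rng=rng)
        p_true = np.clip(probs[np.arange(n), y], 1e-12, None)
        loss = float(-np.log(p_true).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: dict[str, np.ndarray] = {
            "dense_W": feat.T @ dlogits,
            "dense_b": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.params["dense_W"].T
        half = feat.shape[1] // 2
        self._branch_backward(dfeat[:, :half].astype(self.dtype), cache_c, "coronal", grads)
        self._branch_backward(dfeat[:, half:].astype(self.dtype), cache_s, "sagittal", grads)
        if self.config.weight_decay > 0:
            for k_, v in self.params.items():
                if "W" in k_:  # weights only, not biases
                    grads[k_] = grads[k_] + self.config.weight_decay * v
        return loss, grads

    def adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        self.step += 1
        t = self.step
        lr_t = cfg.learning_rate / (1.0 + cfg.decay * (t - 1))
        b1, b2 = 0.9, 0.999
        for k_, g in grads.items():
            m = self.opt_m[k_]
            v = self.opt_v[k_]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k_] -= (lr_t * mhat / (np.sqrt(vhat) + _EPS)).astype(self.dtype)

    # -- training loop ------------------------------------------------------

    def fit(self, xc, xs, y, val=None, epochs: int = 1,
            rng: Optional[np.random.Generator] = None,
            val_every: int = 5) -> list[dict]:
        """Mini-batch training; returns per-epoch history.

        Validation AUC is evaluated every ``val_every`` epochs and always at
        the last epoch (a full validation pass per epoch would dominate the
        cost of short runs).
        """
        rng = rng if rng is not None else self.rng
        n = xc.shape[0]
        bs = self.config.batch_size
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i0 in range(0, n, bs):
                idx = order[i0:i0 + bs]
                loss, grads = self.loss_and_grads(xc[idx], xs[idx], y[idx], rng)
                self.adam_step(grads)
                losses.append(loss)
            entry = {"epoch": epoch, "loss": float(np.mean(losses))}
            if val is not None and (epoch % val_every == 0 or epoch == epochs - 1):
                vxc, vxs, vy = val
                p = self.predict_proba(vxc, vxs)[:, TTP1]
                try:
                    entry["val_auc"] = roc_auc(p, vy)
                except ValueError:
                    entry["val_auc"] = float("nan")
            history.append(entry)
        return history

    def predict_proba(self, xc: np.ndarray, xs: np.ndarray, batch: int = 32) -> np.ndarray:
        out = []
        for i0 in range(0, xc.shape[0], batch):
            probs, _ = self.forward(xc[i0:i0 + batch], xs[i0:i0 + batch], training=False)
            out.append(probs)
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_model(config: Optional[ModelConfig] = None) -> DualBranchCNN:
    """Construct an untrained dual-branch CNN for 275 x 200 MIP pairs."""
    config = config if config is not None else ModelConfig()
    if tuple(config.input_shape) != CANVAS_SHAPE:
        raise ValueError(f"input shape must be {CANVAS_SHAPE}, got {config.input_shape}")
    return DualBranchCNN(config)


def _stack(mips: dict, ids: Sequence[str], view: str) -> np.ndarray:
    arrs = [np.asarray(mips[pid][view].pixels, dtype=np.float32)[..., None] for pid in ids]
    return np.stack(arrs, axis=0)


def _check_mips(mips: dict, ids: Sequence[str], variant: str) -> None:
    missing = [pid for pid in ids if pid not in mips]
    if missing:
        raise KeyError(f"missing MIPs for patients: {missing}")
    for pid in ids:
        for view in ("coronal", "sagittal"):
            img = mips[pid][view]
            if img.variant != variant:
                raise ValueError(f"{pid}/{view}: expected variant {variant!r}, got {img.variant!r}")
            if not img.normalized:
                raise ValueError(f"{pid}/{view}: MIP is not normalized")


def _fold_data(partition: CohortPartition, subset_id: str, fold_id: int, mips: dict):
    tr_ids, va_ids = partition.folds[subset_id][fold_id]
    ytr = np.array([partition.labels[p] for p in tr_ids])
    yva = np.array([partition.labels[p] for p in va_ids])
    return (tr_ids, _stack(mips, tr_ids, "coronal"), _stack(mips, tr_ids, "sagittal"), ytr,
            va_ids, _stack(mips, va_ids, "coronal"), _stack(mips, va_ids, "sagittal"), yva)


def _fold_seed(base_seed: int, fold_id: int) -> int:
    return int(np.random.SeedSequence([base_seed, fold_id]).generate_state(1, np.uint32)[0])


def train_scheme_lesion(partition: CohortPartition, subset_id: str, mips: dict,
                        config: Optional[ModelConfig] = None,
                        folds: Optional[Sequence[int]] = None
                        ) -> tuple[list[TrainedModel], dict]:
    """Scheme 1: train on lesion MIPs only, one model per CV fold.

    ``mips`` maps patient_id -> {"coronal": MIPImage, "sagittal": MIPImage}
    of the lesion variant.  Returns the trained models and a CV report of
    per-fold validation AUCs.
    """
    config = config if config is not None else ModelConfig()
    _check_mips(mips, partition.subsets[subset_id], "lesion")
    folds = list(folds) if folds is not None else list(range(len(partition.folds[subset_id])))
    models, aucs = [], {}
    for fold_id in folds:
        (tr_ids, xc, xs, ytr, va_ids, vxc, vxs, yva) = _fold_data(
            partition, subset_id, fold_id, mips)
        seed = _fold_seed(config.seed, fold_id)
        model = DualBranchCNN(replace(config, seed=seed))
        hist = model.fit(xc, xs, ytr, val=(vxc, vxs, yva), epochs=config.epochs_stage1)
        auc = hist[-1]["val_auc"]
        models.append(TrainedModel(model=model, config=config, subset_id=subset_id,
                                   fold_id=fold_id, scheme="lesion", cv_auc=auc,
                                   history=hist))
        aucs[fold_id] = auc
        logger.info("lesion scheme subset %s fold %d: val AUC %.3f", subset_id, fold_id, auc)
    return models, {"scheme": "lesion", "subset": subset_id, "fold_auc": aucs}


def train_scheme_transfer(partition: CohortPartition, subset_id: str,
                          pretrain_mips: dict, finetune_mips: dict,
                          config: Optional[ModelConfig] = None,
                          folds: Optional[Sequence[int]] = None
                          ) -> tuple[list[TrainedModel], dict]:
    """Schemes 2-3: pre-train on binary lesion masks, fine-tune on intensity MIPs.

    Stage 1 trains on the lesion-mask variant for ``epochs_stage1``; stage 2
    re-trains the same weights on the regular ("mip" scheme) or
    brain-removed ("br_mip" scheme) MIPs for ``epochs_stage2``, with the
    optimizer state re-initialized between stages and identical fold
    membership in both stages.
    """
    config = config if config is not None else ModelConfig()
    ids = partition.subsets[subset_id]
    _check_mips(pretrain_mips, ids, "lesion_mask")
    ft_variant = finetune_mips[ids[0]]["coronal"].variant
    if ft_variant not in ("mip", "brain_removed"):
        raise ValueError(f"fine-tune variant must be mip or brain_removed, got {ft_variant!r}")
    _check_mips(finetune_mips, ids, ft_variant)
    scheme = "mip" if ft_variant == "mip" else "br_mip"
    folds = list(folds) if folds is not None else list(range(len(partition.folds[subset_id])))
    models, aucs = [], {}
    for fold_id in folds:
        seed = _fold_seed(config.seed, fold_id)
        model = DualBranchCNN(replace(config, seed=seed))
        (_, xc, xs, ytr, _, vxc, vxs, yva) = _fold_data(partition, subset_id, fold_id,
                                                        pretrain_mips)
        model.fit(xc, xs, ytr, val=(vxc, vxs, yva), epochs=config.epochs_stage1)
        model.reset_optimizer()
        (_, xc, xs, ytr, _, vxc, vxs, yva) = _fold_data(partition, subset_id, fold_id,
                                                        finetune_mips)
        hist = model.fit(xc, xs, ytr, val=(vxc, vxs, yva), epochs=config.epochs_stage2)
        auc = hist[-1]["val_auc"]
        models.append(TrainedModel(model=model, config=config, subset_id=subset_id,
                                   fold_id=fold_id, scheme=scheme, cv_auc=auc,
                                   history=hist))
        aucs[fold_id] = auc
        logger.info("%s scheme subset %s fold %d: val AUC %.3f", scheme, subset_id, fold_id, auc)
    return models, {"scheme": scheme, "subset": subset_id, "fold_auc": aucs}


def select_model(models: Sequence[TrainedModel]) -> TrainedModel:
    """Keep the fold with the highest validation AUC (ties: lowest fold id)."""
    if not models:
        raise ValueError("no models to select from")
    ordered = sorted(models, key=lambda m: m.fold_id)
    best = max(ordered, key=lambda m: m.cv_auc)  # max keeps the first of ties
    return best


def predict(trained: TrainedModel, coronal: MIPImage, sagittal: MIPImage) -> Prediction:
    """Class probabilities for one patient from a (coronal, sagittal) MIP pair."""
    for img in (coronal, sagittal):
        if not img.normalized:
            raise ValueError("predict expects normalized MIPs")
    xc = coronal.pixels[None, ..., None].astype(np.float32)
    xs = sagittal.pixels[None, ..., None].astype(np.float32)
    probs = trained.model.predict_proba(xc, xs)[0]
    return Prediction(patient_id="", p_ttp0=float(probs[0]), p_ttp1=float(probs[1]),
                      scheme=trained.scheme,
                      model_version=f"{trained.subset_id}/fold{trained.fold_id}")
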