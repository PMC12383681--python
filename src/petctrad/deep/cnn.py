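"""The 2.5D CNN pair (CNN_CT, CNN_PET): construction, training, feature export.

Both networks share one architecture and differ only in input size (CT
64x64, PET 128x128).  Structural constraints, asserted at construction:

* 23 weighted layers (11 convolutions + 11 switchable-norm affines + 1 dense),
* 5 pooling layers, the last one named ``block4_pool_2``,
* 512 channels entering ``block4_pool_2``.

Feature extraction takes the global average of the 512 channel maps at
``block4_pool_2`` for each of the six lesion patches (3 orthogonal planes
x 2 modalities), giving the 3072 deep features per lesion.

Training is plain supervised binary classification of the lesion class
(sigmoid head, binary cross-entropy) with L2 regularization, mish
activations and a cosine-decayed learning rate, run by a small Adam
implementation on the package's own autograd engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ..types import CT_PATCH_SIZE, PET_PATCH_SIZE, PLANES, PatchSet
from .autograd import Var
from .layers import Conv2d, Dense, MaxPool2d, SwitchableNorm2d, mish

__all__ = ["CNNSpec", "TrainConfig", "CNN25D", "build_cnn", "train_cnn", "extract_deep_features"]

#: conv channel progression; the final 1x1 conv lifts to the 512-channel pool
_CHANNELS = [(1, 8, 3), (8, 8, 3), (8, 16, 3), (16, 16, 3), (16, 24, 3), (24, 24, 3),
             (24, 24, 3), (24, 32, 3), (32, 32, 3), (32, 32, 3), (32, 512, 1)]
#: pooling layers inserted after these conv indices (0-based, post-activation);
#: pooling early keeps the large-input layers cheap on CPU
_POOL_AFTER = {0: "block1_pool", 2: "block2_pool", 5: "block3_pool",
               8: "block4_pool_1", 10: "block4_pool_2"}
FEATURE_LAYER = "block4_pool_2"
N_DEEP_CHANNELS = 512


@dataclass
class CNNSpec:
    """Architecture summary with the printed structural counts."""

    modality: str
    input_size: int
    n_weighted_layers: int
    n_pool_layers: int
    feature_layer: str
    feature_channels: int
    layer_names: List[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_weighted_layers != 23:
            raise ValueError(f"expected 23 weighted layers, got {self.n_weighted_layers}")
        if self.n_pool_layers != 5:
            raise ValueError(f"expected 5 pooling layers, got {self.n_pool_layers}")
        if self.feature_channels != N_DEEP_CHANNELS:
            raise ValueError(f"expected 512 feature channels, got {self.feature_channels}")


@dataclass(frozen=True)
class TrainConfig:
    l2: float = 1e-4
    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 5
    seed: int = 0


class CNN25D:
    """Concrete network; owns layers, forward pass and (de)serialization."""

    def __init__(self, modality: str, seed: int = 0):
        if modality not in ("CT", "PET"):
            raise ValueError(f"unknown modality {modality!r}")
        self.modality = modality
        self.input_size = CT_PATCH_SIZE if modality == "CT" else PET_PATCH_SIZE
        rng = np.random.default_rng(seed)
        self.convs: List[Conv2d] = []
        self.norms: List[SwitchableNorm2d] = []
        self.pools: Dict[int, MaxPool2d] = {}
        for i, (ci, co, k) in enumerate(_CHANNELS):
            self.convs.append(Conv2d(ci, co, k, rng, f"conv{i}"))
            self.norms.append(SwitchableNorm2d(co, f"sn{i}"))
            if i in _POOL_AFTER:
                self.pools[i] = MaxPool2d(_POOL_AFTER[i])
        self.head = Dense(N_DEEP_CHANNELS, 1, rng, "head")
        self.spec().validate()

    # -- architecture ----------------------------------------------------
    def spec(self) -> CNNSpec:
        names = []
        for i in range(len(self.convs)):
            names += [f"conv{i}", f"sn{i}"]
            if i in _POOL_AFTER:
                names.append(_POOL_AFTER[i])
        names.append("head")
        return CNNSpec(
            modality=self.modality,
            input_size=self.input_size,
            n_weighted_layers=len(self.convs) + len(self.norms) + 1,
            n_pool_layers=len(self.pools),
            feature_layer=FEATURE_LAYER,
            feature_channels=_CHANNELS[-1][1],
            layer_names=names,
        )

    def parameters(self) -> List[Var]:
        params: List[Var] = []
        for m in [*self.convs, *self.norms, self.head]:
            params += m.parameters()
        return params

    def set_training(self, flag: bool) -> None:
        for sn in self.norms:
            sn.training = flag

    # -- forward ---------------------------------------------------------
    def features(self, x: Var) -> Var:
        """Forward to the global average of the 512 block4_pool_2 channel maps."""
        h = x
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            h = mish(norm(conv(h)))
            if i in self.pools:
                h = self.pools[i](h)
        return h.mean(axis=(2, 3))  # (N, 512)

    def logits(self, x: Var) -> Var:
        return self.features(x) @ self.head.weight + self.head.bias

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        from .autograd import no_grad

        self.set_training(False)
        with no_grad():
            p = Var(patches.reshape(-1, 1, self.input_size, self.input_size))
            return self.logits(p).sigmoid().data.ravel()

    # -- persistence -----------------------------------------------------
    def state(self) -> Dict[str, np.ndarray]:
        st: Dict[str, np.ndarray] = {}
        for m in [*self.convs, *self.norms, self.head]:
            st.update(m.state())
        return st

    def save(self, path: str) -> None:
        np.savez(
            path if path.endswith(".npz") else path + ".npz",
            __spec__=np.frombuffer(
                json.dumps({"modality": self.modality}).encode(), dtype=np.uint8
            ),
            **self.state(),
        )

    @classmethod
    def load(cls, path: str) -> "CNN25D":
        data = np.load(path if path.endswith(".npz") else path + ".npz")
        meta = json.loads(bytes(data["__spec__"]).decode())
        net = cls(meta["modality"])
        state = {k: data[k] for k in data.files if k != "__spec__"}
        for m in [*net.convs, *net.norms, net.head]:
            m.load_state(state)
        return net


def build_cnn(modality: str, seed: int = 0) -> CNN25D:
    """Construct the modality-specific 2.5D network (validates all invariants)."""
    return CNN25D(modality, seed=seed)


def _bce_loss(logits: Var, y: np.ndarray) -> Var:
    p = logits.sigmoid()
    yv = Var(y.reshape(-1, 1))
    eps = 1e-9
    return -(yv * (p + eps).log() + (1.0 - yv) * (1.0 - p + eps).log()).mean()


def train_cnn(
    patches: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig = TrainConfig(),
    model: CNN25D | None = None,
    modality: str = "PET",
) -> Tuple[CNN25D, Dict[str, list]]:
    """Train one modality network on (N, H, W) patches with binary labels.

    Returns the fitted model and a history dict with per-epoch mean loss
    and training accuracy.  Fully deterministic given ``config.seed``.
    """
    y = np.asarray(labels, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    net = model or build_cnn(modality, seed=config.seed)
    x = np.asarray(patches, dtype=np.float64).reshape(-1, 1, net.input_size, net.input_size)

    params = net.parameters()
    m_adam = [np.zeros_like(p.data) for p in params]
    v_adam = [np.zeros_like(p.data) for p in params]
    rng = np.random.default_rng(config.seed)
    history = {"loss": [], "accuracy": []}
    n = len(x)
    steps_total = max(1, config.epochs * ((n + config.batch_size - 1) // config.batch_size))
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        net.set_training(True)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # SN batch stats need >= 2 samples
            xb, yb = Var(x[idx]), y[idx]
            logits = net.logits(xb)
            loss = _bce_loss(logits, yb)
            for p in params:
                p.grad = None
            loss.backward()
            lr = config.lr * 0.5 * (1 + np.cos(np.pi * step / steps_total))
            step += 1
            for k, p in enumerate(params):
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                m_adam[k] = 0.9 * m_adam[k] + 0.1 * g
                v_adam[k] = 0.999 * v_adam[k] + 0.001 * g * g
                mhat = m_adam[k] / (1 - 0.9 ** step)
                vhat = v_adam[k] / (1 - 0.999 ** step)
                # decoupled L2 (AdamW): decay is not routed through the
                # adaptive moments, so lambda acts on the weights directly
                decay = min(1.0, lr * config.l2)
                p.data = (1.0 - decay) * p.data - lr * mhat / (np.sqrt(vhat) + 1e-8)
            losses.append(float(loss.data))
        net.set_training(False)
        proba = net.predict_proba(x)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float(np.mean((proba > 0.5) == (y > 0.5))))
    return net, history


def extract_deep_features(
    model_ct: CNN25D, model_pet: CNN25D, patch_set: PatchSet
) -> Dict[str, float]:
    """The 3072 deep features of one lesion: 512 per (modality, plane).

    Feature names follow ``DF_<MOD>_<plane>_c<k>``; CT blocks come first,
    then PET, each in plane order axial/sagittal/coronal.
    """
    from .autograd import no_grad

    patch_set.validate()
    feats: Dict[str, float] = {}
    for modality, model in (("CT", model_ct), ("PET", model_pet)):
        model.set_training(False)
        for plane in PLANES:
            patch = patch_set.get(modality, plane)
            with no_grad():
                v = Var(patch.reshape(1, 1, *patch.shape))
                vec = model.features(v).data.ravel()
            if vec.shape[0] != N_DEEP_CHANNELS or not np.all(np.isfinite(vec)):
                raise ValueError("invalid deep feature vector")
            for k, val in enumerate(vec):
                feats[f"DF_{modality}_{plane}_c{k}"] = float(val)
    return feats
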