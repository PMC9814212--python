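"""Graph-convolutional log P regressor.

Architecture: graph conv (64) -> batch norm -> ReLU -> graph pool ->
graph conv (128) -> batch norm -> ReLU -> graph pool -> atom-sum gather ->
dense (128, ReLU) -> batch norm -> dropout(0.1) -> scalar head with a
scaled tanh, y = c + s * tanh(z), where (c, s) are fit from the training
labels so the squashed output can cover the observed label range.

Trained with mean-squared-error loss and Adam; fully deterministic given the
seed (initialization, shuffling and dropout masks all flow from it).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from taulogp.featurize import FEATURE_LAYOUT_ID, NUM_ATOM_FEATURES, GraphFeatures, featurize
from taulogp.gcn.layers import (
    Adam,
    BatchNormLayer,
    DenseLayer,
    DropoutOp,
    GatherSumOp,
    GraphConvLayer,
    GraphPoolOp,
    ReluOp,
    build_batch,
)
from taulogp.gcn.metrics import rmse as _rmse

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 50
    lr: float = 1e-3
    seed: int = 0
    hidden: tuple[int, int] = (64, 128)
    dense_dim: int = 128
    dropout: float = 0.1
    scale_margin: float = 1.05


class GCNRegressor:
    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        rng = np.random.default_rng(self.config.seed)
        h1, h2 = self.config.hidden
        d = self.config.dense_dim
        self.conv1 = GraphConvLayer(NUM_ATOM_FEATURES, h1, rng)
        self.bn1 = BatchNormLayer(h1)
        self.relu1 = ReluOp()
        self.pool1 = GraphPoolOp()
        self.conv2 = GraphConvLayer(h1, h2, rng)
        self.bn2 = BatchNormLayer(h2)
        self.relu2 = ReluOp()
        self.pool2 = GraphPoolOp()
        self.gather = GatherSumOp()
        self.dense = DenseLayer(h2, d, rng)
        self.relu3 = ReluOp()
        self.bn3 = BatchNormLayer(d)
        self.drop = DropoutOp(self.config.dropout)
        self.head = DenseLayer(d, 1, rng)
        # keep the initial pre-tanh activation near the linear region; a
        # full-width init saturates the squashed head and stalls training
        self.head.params["w"] *= 0.1
        self.label_center = 0.0
        self.label_scale = 1.0
        self._feat_cache: dict[str, GraphFeatures] = {}

    # -- parameter plumbing -------------------------------------------------

    def _layer_map(self):
        return {
            "conv1": self.conv1, "bn1": self.bn1, "conv2": self.conv2, "bn2": self.bn2,
            "dense": self.dense, "bn3": self.bn3, "head": self.head,
        }

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layer_map().items():
            for pname, arr in layer.params.items():
                out[f"{lname}.{pname}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._layer_map().items():
            for pname, arr in layer.grads.items():
                out[f"{lname}.{pname}"] = arr
        return out

    def state_dict(self) -> dict:
        state = {name: arr.copy() for name, arr in self.parameters().items()}
        for bname, bn in (("bn1", self.bn1), ("bn2", self.bn2), ("bn3", self.bn3)):
            state[f"{bname}.running_mean"] = bn.running_mean.copy()
            state[f"{bname}.running_var"] = bn.running_var.copy()
            state[f"{bname}.n_updates"] = np.array(bn.n_updates)
        state["label"] = np.array([self.label_center, self.label_scale])
        return state

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        for name, arr in state.items():
            if name == "label":
                self.label_center, self.label_scale = float(arr[0]), float(arr[1])
            elif name.endswith("n_updates"):
                getattr(self, name.split(".")[0]).n_updates = int(arr)
            elif name.endswith("running_mean"):
                getattr(self, name.split(".")[0]).running_mean = np.array(arr)
            elif name.endswith("running_var"):
                getattr(self, name.split(".")[0]).running_var = np.array(arr)
            else:
                params[name][...] = arr

    # -- forward / backward -------------------------------------------------

    def forward(self, batch, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.conv1.forward(batch.node_features, batch.adjacency)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h)
        h = self.pool1.forward(h, batch.nbr_padded)
        h = self.conv2.forward(h, batch.adjacency)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h)
        h = self.pool2.forward(h, batch.nbr_padded)
        g = self.gather.forward(h, batch.membership)
        g = self.dense.forward(g)
        g = self.relu3.forward(g)
        g = self.bn3.forward(g, training)
        g = self.drop.forward(g, training, rng)
        z = self.head.forward(g)[:, 0]
        self._tanh = np.tanh(z)
        return self.label_center + self.label_scale * self._tanh

    def backward(self, dy: np.ndarray) -> None:
        dz = (dy * self.label_scale * (1.0 - self._tanh**2))[:, None]
        d = self.head.backward(dz)
        d = self.drop.backward(d)
        d = self.bn3.backward(d)
        d = self.relu3.backward(d)
        d = self.dense.backward(d)
        d = self.gather.backward(d)
        d = self.pool2.backward(d)
        d = self.relu2.backward(d)
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.pool1.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        self.conv1.backward(d)

    # -- data plumbing ------------------------------------------------------

    def _features(self, smiles: str) -> GraphFeatures | None:
        if smiles not in self._feat_cache:
            try:
                self._feat_cache[smiles] = featurize(smiles)
            except ValueError:
                self._feat_cache[smiles] = None
        return self._feat_cache[smiles]

    def set_label_scale(self, labels: np.ndarray) -> None:
        lo, hi = float(np.min(labels)), float(np.max(labels))
        self.label_center = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        self.label_scale = self.config.scale_margin * half if half > 0 else 1.0

    def predict_batch(self, molecules, batch_size: int = 256) -> np.ndarray:
        """Vectorized inference; unfeaturizable inputs yield NaN markers."""
        feats = [self._features(s) for s in molecules]
        ok = [i for i, f in enumerate(feats) if f is not None]
        preds = np.full(len(molecules), np.nan)
        for start in range(0, len(ok), batch_size):
            chunk = ok[start : start + batch_size]
            batch = build_batch([feats[i] for i in chunk])
            preds[chunk] = self.forward(batch, training=False)
        return preds

    def predict(self, smiles: str) -> float:
        return float(self.predict_batch([smiles])[0])

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = dict(asdict(self.config), feature_layout=FEATURE_LAYOUT_ID, format_version=1)
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path) -> "GCNRegressor":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("feature_layout") != FEATURE_LAYOUT_ID:
            raise ValueError("model was trained with an incompatible feature layout")
        cfg = TrainConfig(**{k: (tuple(v) if k == "hidden" else v) for k, v in meta.items()
                             if k in TrainConfig.__dataclass_fields__})
        model = cls(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


@dataclass
class EpochStats:
    epoch: int
    train_rmse: float
    valid_rmse: float


@dataclass
class TrainResult:
    model: GCNRegressor
    history: list[EpochStats] = field(default_factory=list)
    best_epoch: int = -1
    best_valid_rmse: float = float("nan")


def train(train_rows, valid_rows, config: TrainConfig | None = None) -> TrainResult:
    """Fit the regressor on variant rows (any objects with ``variant_smiles``
    and ``label``), selecting the epoch with the best validation rmse.

    Raises on non-finite loss; deterministic for a fixed config/seed.
    """
    config = config or TrainConfig()
    model = GCNRegressor(config)
    smiles_tr = [r.variant_smiles for r in train_rows]
    y_tr = np.array([r.label for r in train_rows], dtype=float)
    smiles_va = [r.variant_smiles for r in valid_rows]
    y_va = np.array([r.label for r in valid_rows], dtype=float)
    if len(smiles_tr) == 0:
        raise ValueError("train: empty training set")
    if not np.all(np.isfinite(y_tr)) or not np.all(np.isfinite(y_va)):
        raise ValueError("train: non-finite label")

    feats = [model._features(s) for s in smiles_tr]
    keep = [i for i, f in enumerate(feats) if f is not None]
    if len(keep) < len(feats):
        logger.warning("train: dropped %d unfeaturizable rows", len(feats) - len(keep))
    feats = [feats[i] for i in keep]
    y_tr = y_tr[keep]
    model.set_label_scale(y_tr)

    rng = np.random.default_rng(config.seed + 1)
    optim = Adam(lr=config.lr)
    result = TrainResult(model=model)
    best_state = model.state_dict()
    best_valid = float("inf")
    n = len(feats)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        sq_sum, count = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = build_batch([feats[i] for i in idx])
            target = y_tr[idx]
            preds = model.forward(batch, training=True, rng=rng)
            resid = preds - target
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(f"train: non-finite loss at epoch {epoch}")
            model.backward(2.0 * resid / resid.size)
            optim.step(model.parameters(), model.gradients())
            sq_sum += float(np.sum(resid**2))
            count += resid.size
        train_rmse = float(np.sqrt(sq_sum / count))
        if smiles_va:
            va_pred = model.predict_batch(smiles_va)
            mask = np.isfinite(va_pred)
            valid_rmse = _rmse(va_pred[mask], y_va[mask]) if mask.any() else float("nan")
        else:
            valid_rmse = train_rmse
        result.history.append(EpochStats(epoch=epoch, train_rmse=train_rmse, valid_rmse=valid_rmse))
        logger.info("epoch %d: train rmse %.4f, valid rmse %.4f", epoch, train_rmse, valid_rmse)
        if np.isfinite(valid_rmse) and valid_rmse < best_valid:
            best_valid = valid_rmse
            best_state = model.state_dict()
            result.best_epoch = epoch
    model.load_state_dict(best_state)
    result.best_valid_rmse = best_valid
    return result
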