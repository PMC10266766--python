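"""Self-supervised 3D-CNN over masked residue environments.

The model is trained to predict the wild-type amino acid of a residue from
the voxelized atomic environment surrounding it (the residue's own atoms
having been masked out).  Architecture: Gaussian blur of the occupancy
grid, then three conv(3³)→batchnorm→leakyReLU→maxpool(2³) blocks with 16,
32 and 64 filters, flatten, a 100-node fully connected layer whose
post-activation output is the residue representation consumed downstream,
and a final 20-way classification layer.  Training minimizes cross-entropy
with Adam (lr 3e-4, batches of 100 residues), splitting strictly by
protein, with early stopping on validation accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import _nn
from .voxel import GridSpec, VoxelGrid, gaussian_blur

logger = logging.getLogger("stabscan.representation")

N_CLASSES = 20
EMBED_DIM = 100


@dataclass(frozen=True)
class RepresentationConfig:
    """Hyperparameters of the representation model.

    The published architecture uses conv filter counts (16, 32, 64) and
    fully connected sizes (100, 20); smaller ``conv_filters`` give the
    reduced models used for fast desk-scale experiments.
    """

    conv_filters: tuple[int, int, int] = (16, 32, 64)
    kernel_edge: int = 3
    fc_sizes: tuple[int, int] = (EMBED_DIM, N_CLASSES)
    learning_rate: float = 3e-4
    batch_size: int = 100
    leaky_slope: float = 0.01
    pool_edge: int = 2
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if len(self.conv_filters) != 3:
            raise ValueError("exactly three conv layers")
        if self.fc_sizes[1] != N_CLASSES:
            raise ValueError("output layer must have 20 nodes (amino-acid classes)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid optimizer settings")


class RepresentationModel:
    """CNN wild-type classifier exposing the 100-d latent representation.

    ``forward`` consumes *unblurred* occupancy grids and applies the
    Gaussian blur itself, controlled by the GridSpec stored in the model,
    so a checkpoint can never be run with mismatched featurization.
    """

    def __init__(self, config: RepresentationConfig = RepresentationConfig(),
                 grid_spec: GridSpec = GridSpec()):
        self.config = config
        self.grid_spec = grid_spec
        rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.conv_filters
        k, e, s = config.kernel_edge, config.pool_edge, config.leaky_slope
        side = grid_spec.side_voxels
        for _ in range(3):
            side //= e
        self.flat_dim = f3 * side ** 3
        c = grid_spec.channels
        self.net = _nn.Sequential([
            _nn.Conv3d(c, f1, k, rng), _nn.BatchNorm(f1, spatial=True),
            _nn.LeakyReLU(s), _nn.MaxPool3d(e),
            _nn.Conv3d(f1, f2, k, rng), _nn.BatchNorm(f2, spatial=True),
            _nn.LeakyReLU(s), _nn.MaxPool3d(e),
            _nn.Conv3d(f2, f3, k, rng), _nn.BatchNorm(f3, spatial=True),
            _nn.LeakyReLU(s), _nn.MaxPool3d(e),
            _nn.Flatten(),
            _nn.Dense(self.flat_dim, config.fc_sizes[0], rng),
            _nn.LeakyReLU(s),
            _nn.Dense(config.fc_sizes[0], config.fc_sizes[1], rng),
        ])
        # split points for the embedding: everything up to and including the
        # LeakyReLU after the 100-node layer is the representation trunk
        self._trunk = self.net.layers[:-1]
        self._head = self.net.layers[-1]

    # -- featurization ----------------------------------------------------
    def _blur_batch(self, grids: np.ndarray) -> np.ndarray:
        out = np.empty_like(grids, dtype=np.float32)
        for i in range(grids.shape[0]):
            out[i] = gaussian_blur(VoxelGrid(grids[i], self.grid_spec)).values
        return out

    def _check(self, grids: np.ndarray) -> np.ndarray:
        grids = np.asarray(grids, dtype=np.float32)
        if grids.ndim == 4:
            grids = grids[None]
        if grids.shape[1:] != self.grid_spec.shape:
            raise ValueError(f"grid shape {grids.shape[1:]} does not match "
                             f"model GridSpec {self.grid_spec.shape}")
        return grids

    # -- inference --------------------------------------------------------
    def forward(self, grids: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (batch, 20) from raw occupancy grids."""
        return self.net.forward(self._blur_batch(self._check(grids)), train=train)

    def classify_wt(self, grid: VoxelGrid | np.ndarray) -> np.ndarray:
        """Probability over the 20 amino acids (alphabetical one-letter
        order) for a single grid; softmax of the logits."""
        values = grid.values if isinstance(grid, VoxelGrid) else grid
        logits = self.forward(values, train=False)
        return _nn.softmax(logits)[0]

    def embed(self, grid: VoxelGrid | np.ndarray) -> np.ndarray:
        """The 100-d residue representation: post-activation output of the
        100-node layer.  ``logits_from_embedding`` applied to this vector
        reproduces ``classify_wt``'s logits exactly."""
        values = grid.values if isinstance(grid, VoxelGrid) else grid
        return self.embed_batch(values[None] if values.ndim == 4 else values)[0]

    def embed_batch(self, grids: np.ndarray) -> np.ndarray:
        x = self._blur_batch(self._check(grids))
        self.net.set_mode(False)
        for lyr in self._trunk:
            x = lyr.forward(x)
        return x

    def logits_from_embedding(self, embedding: np.ndarray) -> np.ndarray:
        return self._head.forward(np.atleast_2d(embedding).astype(np.float32))

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.net.params())

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        meta = {"config": self.config.__dict__ | {
                    "conv_filters": list(self.config.conv_filters),
                    "fc_sizes": list(self.config.fc_sizes)},
                "grid_spec": self.grid_spec.to_dict()}
        arrays = {f"arr_{i}": a for i, a in enumerate(self.net.state())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "RepresentationModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            arrays = [f[f"arr_{i}"] for i in range(len(f.files) - 1)]
        cfg = meta["config"]
        cfg["conv_filters"] = tuple(cfg["conv_filters"])
        cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
        model = cls(RepresentationConfig(**cfg),
                    GridSpec.from_dict(meta["grid_spec"]))
        model.net.load_state(arrays)
        return model


def _check_split(protein_ids: list[str], train_proteins, val_proteins):
    train_set, val_set = set(train_proteins), set(val_proteins)
    leak = train_set & val_set
    if leak:
        raise ValueError(f"protein leakage between train and validation: {sorted(leak)}")
    pid = np.asarray(protein_ids)
    tr = np.flatnonzero(np.isin(pid, list(train_set)))
    va = np.flatnonzero(np.isin(pid, list(val_set)))
    if tr.size == 0 or va.size == 0:
        raise ValueError("empty train or validation split")
    return tr, va


def train_representation(grids: np.ndarray, labels: np.ndarray,
                         protein_ids: list[str],
                         train_proteins, val_proteins,
                         config: RepresentationConfig = RepresentationConfig(),
                         grid_spec: GridSpec = GridSpec()):
    """Train the wild-type classifier; returns (model, history).

    The split is by protein (shared proteins between partitions are a hard
    error).  Early stopping restores the best-validation-accuracy
    checkpoint; ``history`` has one dict per epoch with train loss/accuracy
    and validation accuracy.
    """
    tr, va = _check_split(protein_ids, train_proteins, val_proteins)
    grids = np.asarray(grids, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)

    model = RepresentationModel(config, grid_spec)
    blurred = model._blur_batch(grids)      # precompute: blur is fixed preprocessing
    opt = _nn.Adam(model.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    def val_accuracy() -> float:
        preds = []
        for i in range(0, va.size, 256):
            idx = va[i:i + 256]
            logits = model.net.forward(blurred[idx], train=False)
            preds.append(logits.argmax(axis=1))
        return float((np.concatenate(preds) == labels[va]).mean())

    history: list[dict] = []
    best_acc, best_state, best_epoch = -1.0, model.net.state(), -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr)
        losses, hits, seen = [], 0, 0
        for i in range(0, order.size, config.batch_size):
            idx = order[i:i + config.batch_size]
            model.net.zero_grad()
            logits = model.net.forward(blurred[idx], train=True)
            loss, dlogits = _nn.cross_entropy(logits, labels[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            hits += int((logits.argmax(axis=1) == labels[idx]).sum())
            seen += idx.size
        acc = val_accuracy()
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "train_acc": hits / seen, "val_acc": acc})
        if acc > best_acc:
            best_acc, best_state, best_epoch = acc, model.net.state(), epoch
        elif epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best val acc %.3f at %d)",
                        epoch, best_acc, best_epoch)
            break
    model.net.load_state(best_state)
    return model, history


def reduced_config(seed: int = 0, **overrides) -> RepresentationConfig:
    """A small configuration for CPU-scale experiments: same architecture
    family, quartered filter counts, and a step size suited to the much
    smaller parameter count."""
    base = dict(conv_filters=(4, 8, 16), learning_rate=1e-3,
                max_epochs=30, patience=5, seed=seed)
    base.update(overrides)
    return RepresentationConfig(**base)
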