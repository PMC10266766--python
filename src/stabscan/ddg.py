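"""Downstream stability-change regressor and its supporting algebra.

The regressor maps a 142-dimensional variant feature vector — the 100-d
residue representation, one-hot wild-type and mutant amino acids, and the
two corresponding background amino-acid frequencies — through three fully
connected layers (128, 64, 16 nodes, batch-normalized leaky-ReLU between
layers) to a scalar passed through a sigmoid.  Targets are ΔΔG values in
kcal/mol compressed into (0,1) by the Fermi (logistic switching) function

    F(ΔΔG) = 1 / (1 + exp(−β (ΔΔG − α)))      β = 0.4, α = 3.0

which focuses training on the −1…7 kcal/mol range where the training
energies are most trustworthy.  The loss is the mean absolute error in
Fermi space (MAE_F).  Predictions are the median over an ensemble of
independently seeded replicas, inverted back to kcal/mol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .structure import AA_ALPHABET, AA_INDEX, Structure, residue_sites
from .voxel import GridSpec

logger = logging.getLogger("stabscan.ddg")

FEATURE_DIM = 142   # 100 embedding + 20 wt one-hot + 20 mut one-hot + 2 freqs
SCORE_CLAMP = 1e-4  # sigmoid scores are clamped to [1e-4, 1-1e-4] before inversion
DISULFIDE_SG_CUTOFF = 2.5   # Å between SG atoms of a bonded cystine pair


@dataclass(frozen=True)
class FermiParams:
    """Parameters of the switching function: steepness β (1/(kcal/mol))
    and midpoint α (kcal/mol)."""

    beta: float = 0.4
    alpha: float = 3.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class DownstreamConfig:
    fc_sizes: tuple[int, int, int] = (128, 64, 16)
    learning_rate: float = 5e-4
    batch_size: int = 40
    fermi: FermiParams = FermiParams()
    rosetta_scale: float = 2.9
    max_epochs: int = 100
    patience: int = 10
    seeds: tuple[int, ...] = tuple(range(10))

    def __post_init__(self):
        if len(self.fc_sizes) != 3:
            raise ValueError("exactly three hidden layers")
        if len(set(self.seeds)) != len(self.seeds) or not self.seeds:
            raise ValueError("seeds must be non-empty and distinct")

    @property
    def ensemble_size(self) -> int:
        return len(self.seeds)


def fermi_transform(ddg, params: FermiParams = FermiParams()):
    """Map ΔΔG (kcal/mol) into (0,1); strictly increasing."""
    ddg = np.asarray(ddg, dtype=float)
    out = 1.0 / (1.0 + np.exp(-params.beta * (ddg - params.alpha)))
    return float(out) if out.ndim == 0 else out

def inverse_fermi(score, params: FermiParams = FermiParams()):
    """Invert the switching function back to kcal/mol.

    Scores are clamped to [1e-4, 1−1e-4] first (the transform is not
    invertible at 0/1); clamping events are logged.  With β=0.4 the clamp
    saturates predictions at roughly −20 / +26 kcal/mol.
    """
    score = np.asarray(score, dtype=float)
    clamped = np.clip(score, SCORE_CLAMP, 1.0 - SCORE_CLAMP)
    n_clamped = int(np.sum(clamped != score))
    if n_clamped:
        logger.info("inverse_fermi: clamped %d score(s) to [%g, %g]",
                    n_clamped, SCORE_CLAMP, 1.0 - SCORE_CLAMP)
    out = params.alpha - np.log(1.0 / clamped - 1.0) / params.beta
    return float(out) if out.ndim == 0 else out


def convert_rosetta_units(raw, scale: float = 2.9):
    """Rescale raw Rosetta Cartesian ddG scores to kcal/mol (÷ 2.9)."""
    raw = np.asarray(raw, dtype=float)
    out = raw / scale
    return float(out) if out.ndim == 0 else out


def aa_frequencies(structures: list[Structure]) -> np.ndarray:
    """Empirical amino-acid frequencies over all scannable residues of a
    structure set (alphabetical one-letter order; sums to 1).  Persisted
    alongside any trained downstream model."""
    counts = np.zeros(20, dtype=float)
    for st in structures:
        for site in residue_sites(st):
            counts[AA_INDEX[site.wt_aa]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no residues in structure set")
    return counts / total


def build_features(embedding: np.ndarray, wt_aa: str, mut_aa: str,
                   frequencies: np.ndarray) -> np.ndarray:
    """Concatenate [embedding(100) | wt one-hot(20) | mut one-hot(20) |
    wt frequency, mut frequency] into the fixed 142-vector."""
    embedding = np.asarray(embedding, dtype=float).ravel()
    if embedding.size != 100:
        raise ValueError(f"embedding must have length 100, got {embedding.size}")
    if wt_aa not in AA_INDEX or mut_aa not in AA_INDEX:
        raise ValueError(f"non-canonical amino acid: {wt_aa!r}->{mut_aa!r}")
    wt_hot = np.zeros(20); wt_hot[AA_INDEX[wt_aa]] = 1.0
    mut_hot = np.zeros(20); mut_hot[AA_INDEX[mut_aa]] = 1.0
    freqs = np.asarray(frequencies, dtype=float)
    return np.concatenate([embedding, wt_hot, mut_hot,
                           [freqs[AA_INDEX[wt_aa]], freqs[AA_INDEX[mut_aa]]]])


# ---------------------------------------------------------------------------
# Cystine (disulfide) handling
# ---------------------------------------------------------------------------

def annotate_disulfides(structure: Structure) -> set[int]:
    """Residue indices of cysteines whose SG atom lies within 2.5 Å of
    another cysteine's SG (i.e. disulfide-bonded cystines)."""
    sg = [(res.residue_index, res.atom("SG").coords)
          for res in structure.residues
          if res.res_name == "CYS" and res.atom("SG") is not None]
    bonded: set[int] = set()
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if np.linalg.norm(sg[i][1] - sg[j][1]) < DISULFIDE_SG_CUTOFF:
                bonded.add(sg[i][0]); bonded.add(sg[j][0])
    return bonded


def filter_training_variants(records: pd.DataFrame,
                             disulfides: dict[str, set[int]]) -> pd.DataFrame:
    """Drop training variants at disulfide-bonded cystine positions.

    ``disulfides`` maps source_id → residue indices from
    :func:`annotate_disulfides`.  Free (non-bonded) cysteines are retained;
    the removal count is logged.
    """
    mask = np.ones(len(records), dtype=bool)
    for i, (pid, ridx) in enumerate(zip(records["source_id"],
                                        records["residue_index"])):
        if ridx in disulfides.get(pid, ()):
            mask[i] = False
    removed = int((~mask).sum())
    if removed:
        logger.info("filter_training_variants: removed %d variant(s) at "
                    "cystine positions", removed)
    return records[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# The regressor
# ---------------------------------------------------------------------------

class DownstreamModel:
    """One seeded replica of the feed-forward regressor."""

    def __init__(self, config: DownstreamConfig, seed: int):
        self.config, self.seed = config, seed
        rng = np.random.default_rng(seed)
        h1, h2, h3 = config.fc_sizes
        self.net = _nn.Sequential([
            _nn.Dense(FEATURE_DIM, h1, rng), _nn.BatchNorm(h1, spatial=False),
            _nn.LeakyReLU(),
            _nn.Dense(h1, h2, rng), _nn.BatchNorm(h2, spatial=False),
            _nn.LeakyReLU(),
            _nn.Dense(h2, h3, rng), _nn.BatchNorm(h3, spatial=False),
            _nn.LeakyReLU(),
            _nn.Dense(h3, 1, rng), _nn.Sigmoid(),
        ])

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Fermi-space scores in (0,1), shape (n,)."""
        x = np.atleast_2d(np.asarray(features, dtype=np.float32))
        return self.net.forward(x, train=False)[:, 0].astype(float)


@dataclass
class Ensemble:
    """Trained replica set plus everything inference needs to be
    self-consistent: Fermi parameters, the background frequency vector the
    features were built with, and the GridSpec of the representation model."""

    models: list[DownstreamModel]
    config: DownstreamConfig
    frequencies: np.ndarray
    grid_spec: GridSpec = field(default_factory=GridSpec)

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Per-model Fermi-space scores, shape (n_models, n_variants)."""
        return np.stack([m.predict_scores(features) for m in self.models])

    def save(self, path) -> None:
        meta = {"config": _config_to_dict(self.config),
                "seeds": list(self.config.seeds),
                "grid_spec": self.grid_spec.to_dict()}
        arrays = {"frequencies": self.frequencies}
        for k, m in enumerate(self.models):
            for i, a in enumerate(m.net.state()):
                arrays[f"m{k}_{i}"] = a
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Ensemble":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            config = _config_from_dict(meta["config"])
            models = []
            for k, seed in enumerate(meta["seeds"]):
                m = DownstreamModel(config, seed)
                n = len(m.net.state())
                m.net.load_state([f[f"m{k}_{i}"] for i in range(n)])
                models.append(m)
            freqs = f["frequencies"]
        return cls(models=models, config=config, frequencies=freqs,
                   grid_spec=GridSpec.from_dict(meta["grid_spec"]))


def _config_to_dict(c: DownstreamConfig) -> dict:
    d = dict(c.__dict__)
    d["fc_sizes"] = list(c.fc_sizes)
    d["seeds"] = list(c.seeds)
    d["fermi"] = {"beta": c.fermi.beta, "alpha": c.fermi.alpha}
    return d


def _config_from_dict(d: dict) -> DownstreamConfig:
    d = dict(d)
    d["fc_sizes"] = tuple(d["fc_sizes"])
    d["seeds"] = tuple(d["seeds"])
    d["fermi"] = FermiParams(**d["fermi"])
    return DownstreamConfig(**d)


@dataclass
class DdgRecord:
    """One predicted substitution."""

    source_id: str
    chain: str
    residue_index: int
    wt_aa: str
    mut_aa: str
    score_fermi: float
    ddg: float                      # kcal/mol
    per_model_scores: list[float] = field(default_factory=list)
    wt_is_cysteine: bool = False
    self_substitution: bool = False


def predict_ddg(ensemble: Ensemble, features: np.ndarray, *,
                source_id: str = "", chain: str = "", residue_index: int = 0,
                wt_aa: str = "A", mut_aa: str = "A") -> DdgRecord:
    """Ensemble prediction for one variant: median of the per-model
    Fermi-space scores, inverted to kcal/mol.

    Wild-type cysteines are flagged rather than excluded — stability
    changes at disulfide-bonded cystines are systematically underestimated
    by this family of models and should not be taken as accurate.
    """
    features = np.asarray(features, dtype=float).ravel()
    if features.size != FEATURE_DIM:
        raise ValueError(f"expected {FEATURE_DIM} features, got {features.size}")
    scores = ensemble.predict_scores(features[None])[:, 0]
    med = float(np.median(scores))
    return DdgRecord(source_id=source_id, chain=chain,
                     residue_index=residue_index, wt_aa=wt_aa, mut_aa=mut_aa,
                     score_fermi=med,
                     ddg=inverse_fermi(med, ensemble.config.fermi),
                     per_model_scores=[float(s) for s in scores],
                     wt_is_cysteine=(wt_aa == "C"),
                     self_substitution=(wt_aa == mut_aa))


def train_downstream(features: np.ndarray, ddg_kcal: np.ndarray,
                     protein_ids: list[str], train_proteins, val_proteins,
                     config: DownstreamConfig = DownstreamConfig(),
                     frequencies: np.ndarray | None = None,
                     grid_spec: GridSpec = GridSpec(),
                     restore_best: bool = True) -> Ensemble:
    """Train one replica per seed and return the :class:`Ensemble`.

    Targets arrive in kcal/mol and are Fermi-transformed before the MAE_F
    loss; optimization is Adam (lr 5e-4, batches of 40 variants) with early
    stopping per replica on validation MAE_F.  The split is by protein;
    leakage is a hard error, and targets outside [−20, 30] kcal/mol are
    rejected as likely unit errors.  ``restore_best=False`` keeps the
    final-epoch parameters instead of the best-validation checkpoint
    (useful for memorization experiments).
    """
    features = np.asarray(features, dtype=np.float32)
    ddg_kcal = np.asarray(ddg_kcal, dtype=float)
    if features.ndim != 2 or features.shape[1] != FEATURE_DIM:
        raise ValueError(f"features must be (n, {FEATURE_DIM})")
    if np.any(ddg_kcal < -20) or np.any(ddg_kcal > 30):
        bad = ddg_kcal[(ddg_kcal < -20) | (ddg_kcal > 30)]
        raise ValueError(f"targets outside [-20, 30] kcal/mol look like a unit "
                         f"error (e.g. {bad[:3]}); convert before training")
    train_set, val_set = set(train_proteins), set(val_proteins)
    leak = train_set & val_set
    if leak:
        raise ValueError(f"protein leakage between train and validation: {sorted(leak)}")
    pid = np.asarray(protein_ids)
    tr = np.flatnonzero(np.isin(pid, list(train_set)))
    va = np.flatnonzero(np.isin(pid, list(val_set)))
    if tr.size == 0 or va.size == 0:
        raise ValueError("empty train or validation split")

    targets = fermi_transform(ddg_kcal, config.fermi).astype(np.float32)
    if frequencies is None:
        frequencies = np.full(20, 0.05)

    models = []
    for seed in config.seeds:
        model = DownstreamModel(config, seed)
        opt = _nn.Adam(model.net.params(), lr=config.learning_rate)
        rng = np.random.default_rng(seed + 10_000)
        best_mae, best_state, best_epoch = np.inf, model.net.state(), -1
        for epoch in range(config.max_epochs):
            order = rng.permutation(tr)
            for i in range(0, order.size, config.batch_size):
                idx = order[i:i + config.batch_size]
                model.net.zero_grad()
                pred = model.net.forward(features[idx], train=True)[:, 0]
                _, dpred = _nn.mae_loss(pred, targets[idx])
                model.net.backward(dpred[:, None])
                opt.step()
            val_pred = model.predict_scores(features[va])
            val_mae = float(np.abs(val_pred - targets[va]).mean())
            if val_mae < best_mae:
                best_mae, best_state, best_epoch = val_mae, model.net.state(), epoch
            elif epoch - best_epoch >= config.patience:
                break
        if restore_best:
            model.net.load_state(best_state)
        logger.info("downstream seed %d: best val MAE_F %.4f (epoch %d)",
                    seed, best_mae, best_epoch)
        models.append(model)
    return Ensemble(models=models, config=config,
                    frequencies=np.asarray(frequencies, dtype=float),
                    grid_spec=grid_spec)
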