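"""The half-life classifier as a Model / Results pair.

``HalfLifeModel`` holds a labeled dataset (records, descriptor matrix,
embeddings) together with the encoding configuration; ``fit`` trains the
fusion network on a stratified train/validation split and returns a
``HalfLifeResults`` carrying the trained weights, the frozen
``FeatureState``, the training log and prediction/evaluation methods.
Cross-validated selection and ablation build on the same pair.

The shipped default configuration is the selected one: 7x7 kernel, 8
filters, 2 dense layers, units equal to the input dimension, dropout 0.2,
learning rate 1e-3, 6 epochs, batch size 32, early-stopping patience 5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from . import embeddings as emb
from . import features as feat
from .descriptors import DescriptorConfig, DescriptorGroup, descriptor_groups, encode_records
from .io import (
    LONG_LIVED,
    SHORT_LIVED,
    LabeledRecord,
    ProteinRecord,
    SequenceError,
    label_records,
    read_fasta,
    read_labels,
    validate_for_prediction,
)
from .metrics import MetricReport, compute_metrics, confusion
from .nn import HalfLifeNet, TrainingLog, projection_output_dim, train_network


@dataclass(frozen=True)
class ModelConfig:
    """The eight tuned hyperparameters plus fixed training settings."""

    kernel_size: int = 7
    n_filters: int = 8
    n_layers: int = 2
    n_units: int | str = "input_dim"
    dropout: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 6
    batch_size: int = 32
    patience: int = 5
    pool_size: int = 2
    class_weight: bool = False  # inverse-frequency loss weights; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.n_filters < 1 or self.n_layers < 1:
            raise ValueError("kernel_size, n_filters, n_layers must be >= 1")
        if isinstance(self.n_units, str) and self.n_units != "input_dim":
            raise ValueError("n_units must be an int or 'input_dim'")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training hyperparameters")

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


#: the selected configuration shipped as the default
DEFAULT_CONFIG = ModelConfig()


class HalfLifeModel:
    """A labeled protein dataset plus its encoding pipeline.

    Parameters
    ----------
    labeled_records:
        Validated records with short/long labels.
    embedder:
        Any object with an ``EmbedderSpec`` and ``embed_one``; typically a
        ``SyntheticEmbedder`` (no external weights needed).
    descriptor_config, feature_config:
        Physicochemical-descriptor and feature-processing settings.
    """

    def __init__(
        self,
        labeled_records: Sequence[LabeledRecord],
        embedder: emb.Embedder,
        descriptor_config: DescriptorConfig = DescriptorConfig(),
        feature_config: feat.FeatureProcessingConfig = feat.FeatureProcessingConfig(),
    ) -> None:
        if not labeled_records:
            raise ValueError("empty dataset")
        labels = {r.label for r in labeled_records}
        if labels != {SHORT_LIVED, LONG_LIVED}:
            raise ValueError("dataset must contain both classes")
        self.labeled_records = list(labeled_records)
        self.records = [r.record for r in labeled_records]
        self.embedder = embedder
        self.descriptor_config = descriptor_config
        self.feature_config = feature_config
        self.y = np.array(
            [1.0 if r.label == LONG_LIVED else 0.0 for r in labeled_records]
        )
        self._descriptors: pd.DataFrame | None = None
        self._bundles: list[emb.EmbeddingBundle] | None = None

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str | Path,
        labels_path: str | Path,
        embedder: emb.Embedder,
        unit: str = "minutes",
        **kwargs,
    ) -> "HalfLifeModel":
        records = read_fasta(fasta_path)
        labels = read_labels(labels_path, fasta_ids=[r.id for r in records], unit=unit)
        return cls(label_records(records, labels), embedder, **kwargs)

    # -- cached encodings --------------------------------------------------

    @property
    def descriptors(self) -> pd.DataFrame:
        if self._descriptors is None:
            self._descriptors = encode_records(self.records, self.descriptor_config)
        return self._descriptors

    @property
    def bundles(self) -> list[emb.EmbeddingBundle]:
        if self._bundles is None:
            self._bundles = emb.embed(self.records, self.embedder)
        return self._bundles

    def descriptor_block(
        self, exclude_groups: Iterable[DescriptorGroup] = ()
    ) -> tuple[np.ndarray, list[str]]:
        """Descriptor matrix with the excluded groups' columns dropped."""
        excluded = {DescriptorGroup(g) for g in exclude_groups}
        groups = descriptor_groups(self.descriptor_config)
        keep = np.array([g not in excluded for g in groups])
        df = self.descriptors
        return df.values[:, keep], [n for n, k in zip(df.columns, keep) if k]

    def residue_tensor(self, idx: np.ndarray) -> np.ndarray:
        bundles = self.bundles
        return np.stack([bundles[i].residue_matrix for i in idx])[:, None, :, :]

    def sequence_matrix(self, idx: np.ndarray) -> np.ndarray:
        bundles = self.bundles
        return np.stack([bundles[i].sequence_vector for i in idx]).astype(np.float64)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        config: ModelConfig = DEFAULT_CONFIG,
        val_fraction: float = 0.15,
        exclude_groups: Iterable[DescriptorGroup] = (),
    ) -> "HalfLifeResults":
        """Train on a stratified train/validation split of the dataset."""
        idx = np.arange(len(self.y))
        train_idx, val_idx = train_test_split(
            idx, test_size=val_fraction, random_state=config.seed, stratify=self.y
        )
        return self.fit_on_split(config, train_idx, val_idx, exclude_groups)

    def fit_on_split(
        self,
        config: ModelConfig,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
        exclude_groups: Iterable[DescriptorGroup] = (),
    ) -> "HalfLifeResults":
        """Train with explicit split indices (used by cross-validation).

        The feature state is fitted on the training rows only.
        """
        exclude_groups = tuple(DescriptorGroup(g) for g in exclude_groups)
        X_all, names = self.descriptor_block(exclude_groups)
        state = feat.fit_feature_state(
            X_all[train_idx],
            names,
            self.y[train_idx],
            self.sequence_matrix(train_idx),
            self.feature_config,
        )
        feat_train = feat.apply_state(state, X_all[train_idx], names, self.sequence_matrix(train_idx))
        feat_val = feat.apply_state(state, X_all[val_idx], names, self.sequence_matrix(val_idx))
        spec = self.embedder.spec
        net = HalfLifeNet(
            d_local=spec.d_local,
            L_padded=spec.L_padded,
            feature_dim=state.output_dim,
            kernel_size=config.kernel_size,
            n_filters=config.n_filters,
            n_layers=config.n_layers,
            n_units=config.n_units,
            dropout=config.dropout,
            pool_size=config.pool_size,
            seed=config.seed,
        )
        y_train = self.y[train_idx]
        sample_weight = None
        if config.class_weight:
            n_pos = y_train.sum()
            n_neg = len(y_train) - n_pos
            sample_weight = np.where(
                y_train == 1.0, len(y_train) / (2 * n_pos), len(y_train) / (2 * n_neg)
            )
        log = train_network(
            net,
            self.residue_tensor(train_idx),
            feat_train,
            y_train,
            self.residue_tensor(val_idx),
            feat_val,
            self.y[val_idx],
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            batch_size=config.batch_size,
            patience=config.patience,
            sample_weight=sample_weight,
        )
        return HalfLifeResults(self, config, net, state, log, exclude_groups, val_idx)


class HalfLifeResults:
    """A trained classifier with its frozen preprocessing state."""

    def __init__(
        self,
        model: HalfLifeModel,
        config: ModelConfig,
        network: HalfLifeNet,
        feature_state: feat.FeatureState,
        training_log: TrainingLog,
        exclude_groups: tuple[DescriptorGroup, ...] = (),
        val_idx: np.ndarray | None = None,
    ) -> None:
        self.model = model
        self.config = config
        self.network = network
        self.feature_state = feature_state
        self.training_log = training_log
        self.exclude_groups = exclude_groups
        self.val_idx = val_idx

    # -- prediction --------------------------------------------------------

    def _proba_for_records(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        from .descriptors import encode_records as _enc

        cfg = self.model.descriptor_config
        df = _enc(records, cfg)
        excluded = set(self.exclude_groups)
        groups = descriptor_groups(cfg)
        keep = np.array([g not in excluded for g in groups])
        X = df.values[:, keep]
        names = [n for n, k in zip(df.columns, keep) if k]
        bundles = emb.embed(records, self.model.embedder)
        feats = feat.apply_state(self.feature_state, X, names, emb.sequence_matrix(bundles))
        res = np.stack([b.residue_matrix for b in bundles])[:, None, :, :]
        return self.network.predict_proba(res, feats)

    def predict(self, records: Sequence[ProteinRecord]) -> pd.DataFrame:
        """Per-record probability of the long-lived class and hard label.

        Records failing the prediction-input contract yield an error row;
        the batch continues. A probability of exactly 0.5 is long-lived.
        """
        rows: list[dict] = []
        valid: list[ProteinRecord] = []
        for rec in records:
            try:
                validate_for_prediction(rec)
                valid.append(rec)
                rows.append({"id": rec.id})
            except SequenceError as exc:
                rows.append({"id": rec.id, "error": str(exc)})
        if valid:
            probs = self._proba_for_records(valid)
            it = iter(probs)
            for row in rows:
                if "error" not in row:
                    p = float(next(it))
                    row["probability_long_lived"] = p
                    row["predicted_class"] = LONG_LIVED if p >= 0.5 else SHORT_LIVED
        return pd.DataFrame(
            rows, columns=["id", "probability_long_lived", "predicted_class", "error"]
        )

    def evaluate(self, labeled: Sequence[LabeledRecord]) -> MetricReport:
        preds = self.predict([r.record for r in labeled])
        if preds["error"].notna().any():
            bad = preds.loc[preds["error"].notna(), "id"].tolist()
            raise SequenceError(f"evaluation records failed validation: {bad}")
        counts = confusion([r.label for r in labeled], preds["predicted_class"].tolist())
        return compute_metrics(counts)

    def validation_report(self) -> MetricReport:
        """Metrics on the fitting-time validation split."""
        if self.val_idx is None:
            raise ValueError("no validation split recorded")
        labeled = [self.model.labeled_records[i] for i in self.val_idx]
        return self.evaluate(labeled)

    # -- reporting ---------------------------------------------------------

    def log_frame(self) -> pd.DataFrame:
        log = self.training_log
        return pd.DataFrame(
            {"epoch": log.epochs, "train_loss": log.train_loss, "val_loss": log.val_loss}
        )

    def summary(self) -> str:
        state = self.feature_state
        lines = [
            "Half-life classification model",
            "=" * 46,
            f"records                 {len(self.model.y):>8d}"
            f"  (long {int(self.model.y.sum())}, short {int((1 - self.model.y).sum())})",
            f"descriptors kept (ANOVA){state.n_selected:>8d}",
            f"PCA components          {state.n_components:>8d}",
            f"network input dim       {self.network.input_dim:>8d}",
            f"excluded groups         {', '.join(g.value for g in self.exclude_groups) or 'none':>8s}",
            "-" * 46,
        ]
        for key, val in self.config.to_dict().items():
            lines.append(f"{key:<24}{val}")
        lines.append("-" * 46)
        lines.append(f"stopped at epoch        {self.training_log.stop_epoch:>8d}")
        if self.training_log.val_loss:
            lines.append(f"best val loss           {min(self.training_log.val_loss):>8.4f}")
        if self.val_idx is not None:
            rep = self.validation_report().as_dict(ndigits=3)
            lines.append("validation metrics      " + "  ".join(f"{k} {v:.3f}" for k, v in rep.items()))
        return "\n".join(lines)

    # -- persistence (JSON + npz; no pickling) ------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        spec = self.model.embedder.spec
        meta = {
            "config": self.config.to_dict(),
            "exclude_groups": [g.value for g in self.exclude_groups],
            "embedder": {
                "name": spec.name,
                "d_local": spec.d_local,
                "d_global": spec.d_global,
                "L_padded": spec.L_padded,
                "seed": getattr(self.model.embedder, "seed", None),
                "signal_map": getattr(self.model.embedder, "signal_map", {}),
            },
            "descriptor_config": dataclasses.asdict(self.model.descriptor_config),
            "feature_config": dataclasses.asdict(self.feature_state.config),
            "feature_names": self.feature_state.feature_names,
        }
        (path / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(
            path / "weights.npz",
            **{f"w{i}": w for i, w in enumerate(self.network.get_weights())},
        )
        st = self.feature_state
        np.savez(
            path / "feature_state.npz",
            means=st.means,
            stds=st.stds,
            mask=st.selected_mask,
            p_values=st.p_values,
            pca_components=st.pca.components_,
            pca_mean=st.pca.mean_,
            pca_explained_variance=st.pca.explained_variance_,
            emb_means=st.emb_means if st.emb_means is not None else np.array([]),
            emb_stds=st.emb_stds if st.emb_stds is not None else np.array([]),
        )
        self.log_frame().to_csv(path / "training_log.csv", index=False)

    @staticmethod
    def load(path: str | Path, model: HalfLifeModel) -> "HalfLifeResults":
        """Rehydrate a saved result against a compatible model object."""
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        config = ModelConfig.from_dict(meta["config"])
        st_npz = np.load(path / "feature_state.npz")
        pca = PCA()
        pca.components_ = st_npz["pca_components"]
        pca.mean_ = st_npz["pca_mean"]
        pca.explained_variance_ = st_npz["pca_explained_variance"]
        pca.n_components_ = pca.components_.shape[0]
        state = feat.FeatureState(
            feature_names=meta["feature_names"],
            means=st_npz["means"],
            stds=st_npz["stds"],
            selected_mask=st_npz["mask"].astype(bool),
            p_values=st_npz["p_values"],
            pca=pca,
            config=feat.FeatureProcessingConfig(**meta["feature_config"]),
            emb_means=st_npz["emb_means"] if st_npz["emb_means"].size else None,
            emb_stds=st_npz["emb_stds"] if st_npz["emb_stds"].size else None,
        )
        spec = model.embedder.spec
        net = HalfLifeNet(
            d_local=spec.d_local,
            L_padded=spec.L_padded,
            feature_dim=state.output_dim,
            kernel_size=config.kernel_size,
            n_filters=config.n_filters,
            n_layers=config.n_layers,
            n_units=config.n_units,
            dropout=config.dropout,
            pool_size=config.pool_size,
            seed=config.seed,
        )
        w_npz = np.load(path / "weights.npz")
        net.set_weights([w_npz[f"w{i}"] for i in range(len(w_npz.files))])
        excl = tuple(DescriptorGroup(g) for g in meta["exclude_groups"])
        return HalfLifeResults(model, config, net, state, TrainingLog(), excl)
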