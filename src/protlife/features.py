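"""Fit-and-apply feature processing: z-score, ANOVA selection, PCA.

All statistics are estimated on training rows only and frozen into a
``FeatureState``; applying the state never refits, which is what makes
per-fold refitting inside cross-validation leak-free. The physicochemical
block is z-scored (sample std, ddof=1) and filtered by a per-feature
one-way ANOVA F-test between the two classes (keep iff p <= alpha,
default 0.01); the sequence-level embedding block is centred and
projected onto the smallest PCA basis explaining >= 95% of variance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif


@dataclass(frozen=True)
class FeatureProcessingConfig:
    anova_alpha: float = 0.01
    pca_variance: float = 0.95
    zscore_embeddings: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.anova_alpha < 1:
            raise ValueError("anova_alpha must be in (0, 1)")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must be in (0, 1]")


def fit_zscore(train_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column mean, sample std (ddof=1), and a zero-variance flag."""
    X = np.asarray(train_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    means = X.mean(axis=0)
    stds = X.std(axis=0, ddof=1)
    return means, stds, stds == 0


def anova_select(
    feature_matrix: np.ndarray, labels: np.ndarray, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature one-way ANOVA F-test between the two classes.

    Returns (mask, p_values); a feature is kept iff p <= alpha. For two
    classes the F statistic equals the squared pooled two-sample t
    statistic, with p from F(1, n-2). Zero-variance features get p = 1.
    """
    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples")
    variable = X.std(axis=0) > 0
    pvals = np.ones(X.shape[1])
    if variable.any():
        _, p = f_classif(X[:, variable], y)
        pvals[variable] = np.nan_to_num(p, nan=1.0)
    return pvals <= alpha, pvals


def fit_pca(train_seq_embeddings: np.ndarray, variance: float = 0.95) -> PCA:
    """Smallest orthonormal basis whose cumulative explained variance
    reaches ``variance``. Centres but does not rescale coordinates."""
    E = np.asarray(train_seq_embeddings, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("need >= 2 embedding rows")
    if not np.any(E.std(axis=0) > 0):
        raise ValueError("degenerate embeddings: zero variance in every column")
    if variance >= 1.0:
        pca = PCA(svd_solver="full")
    else:
        pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(E)
    return pca


@dataclass
class FeatureState:
    """Frozen preprocessing statistics fitted on training data only."""

    feature_names: list[str]
    means: np.ndarray
    stds: np.ndarray
    selected_mask: np.ndarray  # over physicochemical features
    p_values: np.ndarray
    pca: PCA
    config: FeatureProcessingConfig
    emb_means: np.ndarray | None = None
    emb_stds: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())

    @property
    def n_components(self) -> int:
        return int(self.pca.components_.shape[0])

    @property
    def output_dim(self) -> int:
        return self.n_selected + self.n_components

    def checksum(self) -> str:
        """Content hash of every fitted statistic; unchanged by apply()."""
        h = hashlib.sha256()
        for arr in (
            self.means,
            self.stds,
            self.selected_mask.astype(np.uint8),
            self.p_values,
            self.pca.components_,
            self.pca.mean_,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(self.feature_names).encode())
        return h.hexdigest()


def fit_feature_state(
    physchem_matrix: np.ndarray,
    feature_names: Sequence[str],
    labels: np.ndarray,
    seq_embeddings: np.ndarray,
    config: FeatureProcessingConfig = FeatureProcessingConfig(),
) -> FeatureState:
    """Fit z-score + ANOVA on the descriptor block and PCA on embeddings."""
    X = np.asarray(physchem_matrix, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length mismatch")
    means, stds, zero_var = fit_zscore(X)
    mask, pvals = anova_select(X, labels, config.anova_alpha)
    mask = mask & ~zero_var  # F undefined on constant columns
    E = np.asarray(seq_embeddings, dtype=float)
    emb_means = emb_stds = None
    if config.zscore_embeddings:
        emb_means, emb_stds, emb_zero = fit_zscore(E)
        emb_stds = np.where(emb_zero, 1.0, emb_stds)
        E = (E - emb_means) / emb_stds
    pca = fit_pca(E, config.pca_variance)
    return FeatureState(
        feature_names=list(feature_names),
        means=means,
        stds=np.where(zero_var, 1.0, stds),
        selected_mask=mask,
        p_values=pvals,
        pca=pca,
        config=config,
        emb_means=emb_means,
        emb_stds=emb_stds,
    )


def apply_state(
    state: FeatureState,
    physchem_matrix: np.ndarray,
    feature_names: Sequence[str],
    seq_embeddings: np.ndarray,
) -> np.ndarray:
    """Transform new rows with frozen statistics; never refits.

    Output: z-scored, mask-selected descriptors concatenated with the PCA
    projection of the sequence embeddings.
    """
    if list(feature_names) != state.feature_names:
        extra = sorted(set(feature_names) - set(state.feature_names))
        missing = sorted(set(state.feature_names) - set(feature_names))
        raise ValueError(
            f"feature name mismatch (extra={extra[:5]}, missing={missing[:5]})"
        )
    X = np.asarray(physchem_matrix, dtype=float)
    Z = (X - state.means) / state.stds
    phys = Z[:, state.selected_mask]
    E = np.asarray(seq_embeddings, dtype=float)
    if state.emb_means is not None:
        E = (E - state.emb_means) / state.emb_stds
    proj = state.pca.transform(E)
    return np.concatenate([phys, proj], axis=1)


def output_names(state: FeatureState) -> list[str]:
    """Column provenance of the processed block."""
    kept = [n for n, m in zip(state.feature_names, state.selected_mask) if m]
    return kept + [f"PC{i + 1}" for i in range(state.n_components)]


def selection_report(state: FeatureState) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "feature": state.feature_names,
            "p_value": state.p_values,
            "kept": state.selected_mask,
        }
    )
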