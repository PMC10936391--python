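"""Per-synapse feature extraction and 2-D embedding (PCA then t-SNE).

Each synapse contributes one point: its frames' penultimate (post-GAP)
features are averaged, reduced to at most 20 principal components, and
then embedded in 2-D with t-SNE.  Groupings by cell, valence, or
neurotransmitter are carried as metadata for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .model import patch_features
from .reconstruct_io import Patch

__all__ = ["EmbeddingResult", "extract_features", "embed"]


@dataclass
class EmbeddingResult:
    coords: np.ndarray             # (n_synapses, 2)
    metadata: pd.DataFrame         # synapse_id, pre_cell_id, label, ...
    pca_dims: int                  # dims actually used (may be clipped)
    explained_variance_share: float
    seed: int
    warnings: list[str] = field(default_factory=list)


def extract_features(model, patches: list[Patch], input_size: int
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Frame-averaged per-synapse feature vectors.

    Returns (features, metadata): one row per synapse, features being the
    arithmetic mean of the synapse's per-frame post-GAP vectors.  Patches
    must carry synapse IDs; an empty input is an error.
    """
    if not patches:
        raise ValueError("no patches to extract features from")
    per_frame = patch_features(model, patches, input_size)
    groups: dict[str, list[int]] = {}
    for i, p in enumerate(patches):
        if not p.synapse_id:
            raise ValueError(f"patch #{i} has no synapse_id")
        groups.setdefault(p.synapse_id, []).append(i)
    sids = sorted(groups)
    feats = np.stack([per_frame[groups[s]].mean(axis=0) for s in sids])
    meta = pd.DataFrame({
        "synapse_id": sids,
        "pre_cell_id": [patches[groups[s][0]].pre_cell_id for s in sids],
        "label": [patches[groups[s][0]].label for s in sids],
        "n_frames": [len(groups[s]) for s in sids],
    })
    return feats, meta


def embed(
    features: np.ndarray,
    metadata: pd.DataFrame | None = None,
    pca_dims: int = 20,
    seed: int = 0,
    perplexity: float | None = None,
) -> EmbeddingResult:
    """PCA to ``pca_dims`` components, then t-SNE to 2-D.

    ``pca_dims`` is clipped to min(n_samples, n_features) with a warning
    recorded in the result; perplexity defaults to min(30, (n-1)/3).
    Deterministic under a fixed seed.
    """
    x = np.asarray(features, dtype=float)
    n, d = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 synapses to embed, got {n}")
    notes: list[str] = []
    dims = min(pca_dims, n, d)
    if dims < pca_dims:
        notes.append(f"pca_dims clipped from {pca_dims} to {dims} (rank bound)")
    pca = PCA(n_components=dims, random_state=seed)
    reduced = pca.fit_transform(x)
    share = float(pca.explained_variance_ratio_.sum())
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                    random_state=seed)
        coords = tsne.fit_transform(reduced)
    meta = metadata.copy() if metadata is not None else pd.DataFrame(index=range(n))
    meta["tsne_x"] = coords[:, 0]
    meta["tsne_y"] = coords[:, 1]
    return EmbeddingResult(coords=coords, metadata=meta, pca_dims=dims,
                           explained_variance_share=share, seed=seed,
                           warnings=notes)


def plot_embedding(result: EmbeddingResult, group_by: str, out_path) -> None:
    """Scatter plot coloured by a metadata column."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for value, sub in result.metadata.groupby(group_by):
        ax.scatter(sub["tsne_x"], sub["tsne_y"], s=14, label=str(value))
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(fontsize=7, markerscale=1.2)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
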