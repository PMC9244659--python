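"""Phenotype discovery: cluster ARDS patients in the embedding space.

The network's first fully connected activation is taken as a compressed
patient representation; ARDS-coded patients are grouped by k-means (k=3)
and the clusters are summarized by per-target incidence, mortality and mean
continuous inputs. A 2-D principal-component projection is exported for
visualization. Clusters are relabeled A/B/C in order of decreasing
mortality so reports are stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .multitask_rnn import MultitaskRNN
from .outcome_labels import LABEL_NAMES

CLUSTER_NAMES = ["A", "B", "C"]


@dataclass
class ClusterReport:
    """Assignments, 2-D coordinates and per-cluster summaries."""

    patient_ids: list[str]
    embeddings: np.ndarray  # (n, fc1_dim)
    coordinates: np.ndarray  # (n, 2)
    assignments: np.ndarray  # (n,) of "A"/"B"/"C"
    incidence: pd.DataFrame  # clusters x targets (+ size, mortality)
    silhouette: float


def extract_embeddings(model: MultitaskRNN, tensors: np.ndarray,
                       batch_size: int = 512) -> np.ndarray:
    """Penultimate (first-FC-layer) embedding for each patient."""
    if model.selected_epoch is None:
        raise ValueError("model carries no training history")
    outs = [
        model.forward(tensors[i : i + batch_size]).penultimate_embedding
        for i in range(0, len(tensors), batch_size)
    ]
    return np.concatenate(outs) if outs else np.zeros((0, model.config.fc1_dim))


def project_2d(embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First two principal components of mean-centered embeddings.

    Component signs are fixed by making the largest-magnitude loading of each
    component positive. Rank-deficient inputs degrade to a zero second
    coordinate. Returns (coordinates, explained variances).
    """
    emb = np.asarray(embeddings, dtype=float)
    if len(emb) < 3:
        raise ValueError("need at least 3 patients to project")
    centered = emb - emb.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    n_comp = min(2, rank) if rank > 0 else 1
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(centered)
    components = pca.components_
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            coords[:, i] = -coords[:, i]
    if coords.shape[1] < 2:
        coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
        variances = np.array([pca.explained_variance_[0], 0.0])
    else:
        variances = pca.explained_variance_[:2]
    return coords, variances


def cluster(
    embeddings: np.ndarray,
    death_flags: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> np.ndarray:
    """k-means assignments relabeled A/B/C by decreasing cluster mortality."""
    emb = np.asarray(embeddings, dtype=float)
    if len(emb) < k:
        raise ValueError(f"need at least k={k} patients to cluster")
    death = np.asarray(death_flags).astype(int)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(emb)
    # order clusters by decreasing mortality; ties broken by decreasing size,
    # then by centroid coordinates so labels are order-invariant
    stats = []
    for c in range(k):
        members = raw == c
        centroid = tuple(emb[members].mean(axis=0)) if members.any() else ()
        stats.append(
            (death[members].mean() if members.any() else 0.0, members.sum(), centroid, c)
        )
    stats.sort(key=lambda s: (-s[0], -s[1], s[2]))
    mapping = {orig: CLUSTER_NAMES[i] for i, (_, _, _, orig) in enumerate(stats)}
    return np.array([mapping[c] for c in raw])


def incidence_table(
    assignments: np.ndarray, label_frame: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster incidence of every target plus size and mortality.

    ``label_frame`` holds one row per patient with the 13 binary label
    columns, aligned with ``assignments``.
    """
    if len(assignments) != len(label_frame):
        raise ValueError("assignments must cover all patients")
    df = label_frame.copy()
    df["cluster"] = np.asarray(assignments)
    grouped = df.groupby("cluster")[LABEL_NAMES].mean()
    grouped["size"] = df.groupby("cluster").size()
    grouped["mortality"] = df.groupby("cluster")["death_12"].mean()
    return grouped


def cluster_report(
    model: MultitaskRNN,
    tensors: np.ndarray,
    label_frame: pd.DataFrame,
    patient_ids: list[str],
    seed: int = 0,
    k: int = 3,
) -> ClusterReport:
    """Full clustering pass over the ARDS-coded (ards_5) population."""
    from sklearn.metrics import silhouette_score

    ards_mask = label_frame["ards_5"].to_numpy().astype(bool)
    tensors = tensors[ards_mask]
    labels = label_frame.loc[ards_mask].reset_index(drop=True)
    ids = [pid for pid, m in zip(patient_ids, ards_mask) if m]
    emb = extract_embeddings(model, tensors)
    coords, _ = project_2d(emb)
    assignments = cluster(emb, labels["death_12"].to_numpy(), k=k, seed=seed)
    table = incidence_table(assignments, labels)
    sil = float("nan")
    if len(set(assignments)) > 1:
        sil = float(silhouette_score(emb, assignments))
    return ClusterReport(
        patient_ids=ids,
        embeddings=emb,
        coordinates=coords,
        assignments=assignments,
        incidence=table,
        silhouette=sil,
    )
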