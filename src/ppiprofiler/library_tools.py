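"""Collection-level analyses: fingerprint diversity clustering and the
physico-chemical PCA applicability-domain check.

Clustering uses hashed path-based fingerprints and complete-linkage
agglomeration on Tanimoto distance, cut so that every within-cluster pair
keeps a similarity at or above the diversity criterion; one representative
(the most central member) is taken per cluster.  The PCA check
standardises on a reference table, projects a query onto the leading axes
and flags points whose coordinates all fall inside the reference envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .chemgraph import Molecule
from .errors import DataError


@dataclass
class FingerprintSet:
    """Binary fingerprints as a (n_molecules, n_bits) boolean array."""

    ids: list[str]
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or len(self.ids) != self.bits.shape[0]:
            raise DataError("fingerprint array must be (n_molecules, n_bits)")

    def __len__(self) -> int:
        return len(self.ids)


def fingerprint_set(mols: Sequence[Molecule], n_bits: int = 2048) -> FingerprintSet:
    """Hashed path-based (Daylight-like) fingerprints, deterministic per molecule."""
    rows, ids = [], []
    for m in mols:
        fp = Chem.RDKFingerprint(m.to_rdkit(), fpSize=n_bits)
        arr = np.zeros(n_bits, dtype=bool)
        arr[list(fp.GetOnBits())] = True
        rows.append(arr)
        ids.append(m.id)
    return FingerprintSet(ids=ids, bits=np.vstack(rows) if rows else np.zeros((0, n_bits), bool))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a∧b| / |a∨b|; 0.0 when both fingerprints are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(fps: FingerprintSet) -> np.ndarray:
    """Dense pairwise similarity matrix."""
    bits = fps.bits.astype(np.int32)
    inter = bits @ bits.T
    counts = bits.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


@dataclass
class ClusterResult:
    clusters: list[list[int]]        # member indices, input order within cluster
    representatives: list[int]       # one index per cluster
    labels: np.ndarray               # cluster id per input molecule


def diversity_cluster(fps: FingerprintSet, cut: float = 0.8) -> ClusterResult:
    """Complete-linkage clustering at Tanimoto distance 1 − ``cut``.

    Complete linkage guarantees every within-cluster pair has similarity
    ≥ ``cut``.  The representative of a cluster is the member with the
    highest mean similarity to its cluster, ties resolved by input order.
    """
    n = len(fps)
    if n == 0:
        return ClusterResult([], [], np.array([], dtype=int))
    if n == 1:
        return ClusterResult([[0]], [0], np.array([0]))
    sim = tanimoto_matrix(fps)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(z, t=1.0 - cut, criterion="distance")
    clusters, representatives = [], []
    for lab in sorted(set(labels)):
        members = [int(i) for i in np.flatnonzero(labels == lab)]
        if len(members) == 1:
            rep = members[0]
        else:
            mean_sim = sim[np.ix_(members, members)].mean(axis=1)
            rep = members[int(np.argmax(mean_sim))]  # argmax keeps first on ties
        clusters.append(members)
        representatives.append(rep)
    return ClusterResult(clusters=clusters, representatives=representatives,
                         labels=np.asarray(labels))


@dataclass
class PcaModel:
    """Standardisation + loading vectors fitted on a reference table."""

    descriptor_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray              # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        Xs = (table[self.descriptor_names].to_numpy(dtype=float) - self.means) / self.scales
        return Xs @ self.loadings.T


@dataclass
class PcaDomainResult:
    model: PcaModel
    reference_coords: np.ndarray
    query_coords: np.ndarray
    inside: np.ndarray                # bool per query row


def fit_pca(reference: pd.DataFrame, columns: Sequence[str] | None = None) -> PcaModel:
    cols = list(columns) if columns is not None else list(reference.columns)
    X = reference[cols].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    pca = PCA().fit((X - scaler.mean_) / scale)
    return PcaModel(
        descriptor_names=cols,
        means=scaler.mean_,
        scales=scale,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def pca_domain(
    reference: pd.DataFrame,
    query: pd.DataFrame,
    n_axes: int = 3,
    columns: Sequence[str] | None = None,
) -> PcaDomainResult:
    """Project a query set into the reference's PCA space and flag coverage.

    A query point is "inside" when, on each of the first ``n_axes``
    principal axes, its coordinate lies within the [min, max] envelope of
    the reference scores on that axis.
    """
    model = fit_pca(reference, columns)
    ref_coords = model.transform(reference)
    q_coords = model.transform(query)
    k = min(n_axes, ref_coords.shape[1])
    lo = ref_coords[:, :k].min(axis=0)
    hi = ref_coords[:, :k].max(axis=0)
    inside = np.all((q_coords[:, :k] >= lo) & (q_coords[:, :k] <= hi), axis=1)
    return PcaDomainResult(model=model, reference_coords=ref_coords,
                           query_coords=q_coords, inside=inside)
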