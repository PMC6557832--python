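"""Spidroin family assignment by spectral clustering of a similarity network.

All-vs-all local-alignment bit scores are normalized to [0, 1] by the
geometric mean of the two self-scores (with max-symmetrization), the
normalized matrix is treated as a weighted graph, and sequences are grouped
with spectral clustering on the symmetric normalized Laplacian.  When the
cluster count is not supplied it is chosen by the largest eigengap among the
smallest ``max_k`` eigenvalues.  Terminal-domain subclustering runs the same
pipeline on the first/last 170 residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .io import SeqRecord
from .seeds import SeedSearchParams, bit_score, extract_terminal_domains, make_aligner


@dataclass
class SimilarityMatrix:
    ids: list[str]
    raw: np.ndarray          # n x n bit scores (asymmetry allowed)
    normalized: np.ndarray   # n x n in [0, 1], symmetric, unit diagonal


@dataclass
class ClusterAssignment:
    ids: list[str]
    labels: np.ndarray
    k: int
    eigengaps: np.ndarray
    seed: int


def all_vs_all_similarity(seqs: Sequence[SeqRecord],
                          params: Optional[SeedSearchParams] = None,
                          molecule: str = "protein") -> np.ndarray:
    """raw[i, j] = bit score of the best local alignment of i against j."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    params = params or SeedSearchParams()
    aligner = make_aligner(molecule, params)
    n = len(seqs)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = float(aligner.score(seqs[i].sequence, seqs[j].sequence))
            raw[i, j] = raw[j, i] = bit_score(s, molecule, params)
    return raw


def normalize_similarity(raw: np.ndarray, method: str = "geometric") -> np.ndarray:
    """Scale bit scores to [0, 1] by self-score.

    ``geometric``: max(raw_ij, raw_ji) / sqrt(raw_ii * raw_jj);
    ``min_self``:  max(raw_ij, raw_ji) / min(raw_ii, raw_jj).
    Output is symmetric, clipped to [0, 1], with a forced unit diagonal.
    """
    self_scores = np.diag(raw).astype(float)
    if np.any(self_scores <= 0):
        raise ValueError("self-scores must be positive for normalization")
    sym = np.maximum(raw, raw.T)
    if method == "geometric":
        denom = np.sqrt(np.outer(self_scores, self_scores))
    elif method == "min_self":
        denom = np.minimum.outer(self_scores, self_scores)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    norm = np.clip(sym / denom, 0.0, 1.0)
    np.fill_diagonal(norm, 1.0)
    return norm


def spectral_cluster(normalized: np.ndarray, k: Optional[int] = None,
                     seed: int = 0, max_k: int = 12,
                     ids: Optional[Sequence[str]] = None) -> ClusterAssignment:
    """Spectral clustering on the symmetric normalized Laplacian
    L = I - D^{-1/2} A D^{-1/2} (self-loops removed from A).

    If ``k`` is None it is the position of the largest gap in the sorted
    smallest eigenvalues of L.  Rows of the first k eigenvectors are
    length-normalized and grouped by k-means (fixed seed, 10 restarts).
    Nodes with no off-diagonal similarity become singleton clusters.
    """
    n = normalized.shape[0]
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    A = normalized.astype(float).copy()
    np.fill_diagonal(A, 0.0)
    degrees = A.sum(axis=1)
    isolated = np.flatnonzero(degrees <= 0)
    connected = np.flatnonzero(degrees > 0)
    if isolated.size:
        warnings.warn(f"{isolated.size} sequence(s) share no similarity with "
                      "any other; each becomes its own cluster")

    labels = np.full(n, -1, dtype=int)
    eigengaps = np.array([])
    k_core = 0
    if connected.size:
        Ac = A[np.ix_(connected, connected)]
        d = Ac.sum(axis=1)
        d_isqrt = 1.0 / np.sqrt(d)
        L = np.eye(connected.size) - d_isqrt[:, None] * Ac * d_isqrt[None, :]
        m = min(connected.size, max_k + 1)
        evals = scipy.linalg.eigh(L, eigvals_only=True,
                                  subset_by_index=[0, m - 1])
        eigengaps = np.diff(evals)
        if k is None:
            k_core = int(np.argmax(eigengaps)) + 1 if eigengaps.size else 1
        else:
            k_core = max(1, min(k, connected.size))
        if k_core == 1:
            labels[connected] = 0
        else:
            _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, k_core - 1])
            norms = np.linalg.norm(vecs, axis=1)
            norms[norms == 0] = 1.0
            embedding = vecs / norms[:, None]
            km = KMeans(n_clusters=k_core, n_init=10, random_state=seed)
            labels[connected] = km.fit_predict(embedding)
    for extra, idx in enumerate(isolated):
        labels[idx] = k_core + extra
    return ClusterAssignment(ids, labels, k_core + isolated.size, eigengaps, seed)


def cluster_sequences(seqs: Sequence[SeqRecord], k: Optional[int] = None,
                      seed: int = 0, max_k: int = 12,
                      params: Optional[SeedSearchParams] = None,
                      normalization: str = "geometric",
                      molecule: str = "protein",
                      ) -> tuple[SimilarityMatrix, ClusterAssignment]:
    raw = all_vs_all_similarity(seqs, params, molecule)
    norm = normalize_similarity(raw, normalization)
    sim = SimilarityMatrix([s.id for s in seqs], raw, norm)
    assignment = spectral_cluster(norm, k=k, seed=seed, max_k=max_k, ids=sim.ids)
    return sim, assignment


def cluster_terminal_domains(proteins: Sequence[SeqRecord], terminus: str,
                             n_residues: int = 170, k: Optional[int] = None,
                             seed: int = 0, max_k: int = 12,
                             params: Optional[SeedSearchParams] = None,
                             ) -> tuple[SimilarityMatrix, ClusterAssignment]:
    """Subcluster N- or C-terminal domains (first/last ``n_residues``)."""
    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    domains = []
    for rec in proteins:
        head, tail = extract_terminal_domains(rec.sequence, n_residues)
        domains.append(SeqRecord(rec.id, head if terminus == "N" else tail))
    return cluster_sequences(domains, k=k, seed=seed, max_k=max_k, params=params)


def cluster_purity(labels: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of sequences in the majority true class of their cluster."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    total = 0
    for lab in np.unique(labels):
        members = truth[labels == lab]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / len(labels)
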