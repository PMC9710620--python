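"""Cross-species co-embedding anchored on landmark pairs.

The model network's diffusion-state matrix is symmetrized into a PSD kernel
D1 and factorized as D1 = N·Nᵀ with N = V·diag(sqrt(lambda)) from the
eigendecomposition (negative eigenvalues clipped to zero).  Target-network
nodes are then mapped into the model space by solving the underdetermined
landmark system N_L · C2ᵀ = T_L for the minimum-norm solution
C2ᵀ = pinv(N_L) · T_L, where N_L are the landmark rows of N and T_L the
landmark rows of the target diffusion-state matrix.  The cross-species
similarity matrix is D12 = N · C2ᵀ (model rows × target columns).

Ranking conventions: across species, neighbors are ranked by *similarity*
descending on D12; within the target network, by *distance* ascending on
the pairwise L1 matrix of target diffusion states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .dsd import DiffusionState
from .landmarks import LandmarkSet
from .netio import MundoError

#: Relative singular-value cutoff for the Moore-Penrose pseudoinverse.
PINV_RCOND = 1e-10


@dataclass(frozen=True)
class ModelEmbedding:
    """RKHS-style factor N of the model kernel (kernel = N·Nᵀ)."""

    n_mat: np.ndarray
    kernel: np.ndarray
    nodes: tuple[str, ...]

    def landmark_rows(self, proteins: tuple[str, ...]) -> np.ndarray:
        idx = []
        lookup = {n: i for i, n in enumerate(self.nodes)}
        for prot in proteins:
            if prot not in lookup:
                raise MundoError(f"landmark protein {prot!r} absent from model network")
            idx.append(lookup[prot])
        return self.n_mat[idx]


@dataclass(frozen=True)
class CoEmbedding:
    """Target vectors in model space plus derived similarity/distance matrices.

    ``d12`` rows align to ``model_nodes``, columns to ``target_nodes``;
    ``p_mat`` is the pairwise L1 distance matrix of target diffusion states
    (exactly the target DSD matrix).
    """

    c_mat: np.ndarray
    d12: np.ndarray
    p_mat: np.ndarray
    model_nodes: tuple[str, ...]
    target_nodes: tuple[str, ...]
    landmark_ref: LandmarkSet

    def target_index(self, node: str) -> int:
        try:
            return self.target_nodes.index(node)
        except ValueError:
            raise MundoError(f"node {node!r} not in target network") from None

    def similarity_order(self, j: int) -> np.ndarray:
        """Model-node indices by d12 similarity to target column j
        descending, ties lexicographic by node id (memoized)."""
        cache = self.__dict__.setdefault("_order_cache", {})
        if j not in cache:
            names = self.__dict__.setdefault(
                "_names_arr", np.asarray(self.model_nodes))
            cache[j] = np.lexsort((names, -self.d12[:, j]))
        return cache[j]


def factorize_kernel(k: np.ndarray, nodes: tuple[str, ...]) -> ModelEmbedding:
    """Eigendecompose a symmetric kernel, clip negative eigenvalues to zero
    and return the factor N = V·diag(sqrt(lambda)) with N·Nᵀ = kernel."""
    if not np.any(k):
        raise MundoError("all-zero kernel cannot be factorized")
    w, v = np.linalg.eigh(k)
    w_clipped = np.clip(w, 0.0, None)
    n_mat = v * np.sqrt(w_clipped)[None, :]
    return ModelEmbedding(n_mat=n_mat, kernel=v @ np.diag(w_clipped) @ v.T, nodes=nodes)


def model_embedding(model_ds: DiffusionState) -> ModelEmbedding:
    """Factorize the model similarity kernel (He + Heᵀ)/2.

    The diffusion-state matrix is not symmetric in general; symmetrizing and
    clipping negative eigenvalues yields the nearest factorizable kernel so
    real square roots of the spectrum exist.  For fidelity with the original
    co-embedding formulation a regularized-Laplacian kernel can be factorized
    instead via ``factorize_kernel(regularized_laplacian_kernel(A), nodes)``.
    """
    return factorize_kernel(0.5 * (model_ds.he + model_ds.he.T), model_ds.nodes)


def regularized_laplacian_kernel(adjacency: np.ndarray) -> np.ndarray:
    """(I + L)⁻¹ with L the combinatorial Laplacian; PSD for any graph."""
    deg = adjacency.sum(axis=1)
    lap = np.diag(deg) - adjacency
    return np.linalg.inv(np.eye(len(deg)) + lap)


def coembed_target(
    model_emb: ModelEmbedding,
    target_ds: DiffusionState,
    lm: LandmarkSet,
) -> CoEmbedding:
    """Co-embed target nodes into the model space via the landmark solve.

    The target similarity kernel D2 is the symmetrized target
    diffusion-state matrix (same construction as the model kernel).  With
    N_L the landmark rows of N and T_L the landmark rows of D2 (both in
    bijection order), the minimum-norm solution of N_L · C2ᵀ = T_L is
    C2ᵀ = pinv(N_L) · T_L.  When N_L has full row rank the landmark
    similarities are reconstructed exactly, and co-embedding a network with
    itself over all nodes reproduces the model kernel in D12.
    """
    if len(lm) < 1:
        raise MundoError("at least one landmark is required")
    n_l = model_emb.landmark_rows(lm.model_proteins)

    t_lookup = {n: i for i, n in enumerate(target_ds.nodes)}
    t_idx = []
    for prot in lm.target_proteins:
        if prot not in t_lookup:
            raise MundoError(f"landmark protein {prot!r} absent from target network")
        t_idx.append(t_lookup[prot])
    t_kernel = 0.5 * (target_ds.he + target_ds.he.T)
    t_l = t_kernel[t_idx]

    c2_t = np.linalg.pinv(n_l, rcond=PINV_RCOND) @ t_l  # (m_dims, n_target)
    d12 = model_emb.n_mat @ c2_t
    p_mat = squareform(pdist(target_ds.he, metric="cityblock"))
    return CoEmbedding(
        c_mat=c2_t.T,
        d12=d12,
        p_mat=p_mat,
        model_nodes=model_emb.nodes,
        target_nodes=target_ds.nodes,
        landmark_ref=lm,
    )


def cross_neighbors(ce: CoEmbedding, target_node: str, c: int) -> list[str]:
    """The c model nodes most similar to ``target_node`` under D12,
    descending similarity, ties broken lexicographically by node id."""
    if c < 0:
        raise MundoError("c must be >= 0")
    if c == 0:
        return []
    order = ce.similarity_order(ce.target_index(target_node))
    return [ce.model_nodes[i] for i in order[:c]]
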