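"""Feature representations of a fused multi-species network.

Four representations are supported, each yielding a genes x features
matrix whose rows can be fed directly to a supervised classifier:

* ``adjmat`` — each gene's row of the fused weighted adjacency matrix;
* ``rwr``    — random-walk-with-restart kernel, F = alpha (I - (1-alpha) P)^-1
  with P the row-normalised adjacency, so a gene's features are its
  smoothed outgoing neighbourhood;
* ``svd``    — truncated SVD projection U_d Sigma_d of a feature matrix;
* ``n2v``    — node2vec embedding (biased random walks + skip-gram).

A PCA diagnostic quantifies how well a representation mixes genes from
different species: ortholog-linked cross-species pairs should sit closer
together than random cross-species pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from zoonet.embedding import node2vec_embedding
from zoonet.multinet import GenePair, MultiSpeciesNetwork, OrthologGroupTable

__all__ = [
    "FeatureMatrix",
    "adjacency_features",
    "rwr_features",
    "svd_features",
    "node2vec_features",
    "pca_species_projection",
    "SpeciesMixing",
]


@dataclass
class FeatureMatrix:
    """Genes x features matrix tagged with its representation method."""

    gene_index: list[GenePair]
    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.gene_index):
            raise ValueError("row count does not match gene_index length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN/Inf")
        self._pos = {g: i for i, g in enumerate(self.gene_index)}

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows_for(self, genes) -> np.ndarray:
        """Feature rows for the given (species, gene) identifiers."""
        missing = [g for g in genes if g not in self._pos]
        if missing:
            raise KeyError(f"genes missing from feature index: {missing[:5]}")
        return self.values[[self._pos[g] for g in genes]]

    def species_rows(self, species: str) -> tuple[list[GenePair], np.ndarray]:
        idx = [i for i, (s, _) in enumerate(self.gene_index) if s == species]
        return [self.gene_index[i] for i in idx], self.values[idx]


def adjacency_features(msn: MultiSpeciesNetwork) -> FeatureMatrix:
    """Fused adjacency rows as features (AdjMat representation)."""
    if msn.n_genes == 0:
        raise ValueError("empty network")
    A = np.asarray(msn.adjacency().todense(), dtype=np.float64)
    np.fill_diagonal(A, 0.0)
    return FeatureMatrix(
        gene_index=list(msn.gene_index),
        values=A,
        method="adjmat",
        params={"scheme": msn.weighting_scheme},
    )


def rwr_features(msn: MultiSpeciesNetwork, alpha: float = 0.85) -> FeatureMatrix:
    """Random-walk-with-restart kernel of the fused network.

    F = alpha (I - (1 - alpha) P)^{-1}, with P the row-normalised
    adjacency (directed edges respected).  Rows with zero out-degree get
    a uniform teleport row.  Every row of F sums to one.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1]")
    A = np.asarray(msn.adjacency().todense(), dtype=np.float64)
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    out = A.sum(axis=1)
    sinks = out == 0
    if sinks.any():
        A[sinks] = 1.0 / n
        out[sinks] = 1.0
    P = A / out[:, None]
    F = alpha * np.linalg.inv(np.eye(n) - (1.0 - alpha) * P)
    return FeatureMatrix(
        gene_index=list(msn.gene_index),
        values=F,
        method="rwr",
        params={"alpha": alpha, "n_teleport_rows": int(sinks.sum())},
    )


def svd_features(fm: FeatureMatrix, d: int) -> FeatureMatrix:
    """Project a feature matrix to d dimensions with truncated SVD.

    Rows are U_d Sigma_d.  The sign of each component is fixed so that
    its largest-magnitude entry (in U) is positive, making the output
    deterministic.
    """
    n, m = fm.values.shape
    if not (1 <= d <= min(n, m)):
        raise ValueError(f"d={d} must be in [1, {min(n, m)}]")
    U, s, _ = np.linalg.svd(fm.values, full_matrices=False)
    U, s = U[:, :d], s[:d]
    for k in range(d):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return FeatureMatrix(
        gene_index=list(fm.gene_index),
        values=U * s,
        method="svd",
        params={"d": d, "source": fm.method},
    )


def node2vec_features(
    msn: MultiSpeciesNetwork,
    d: int = 500,
    p: float = 1.0,
    q: float = 1.0,
    num_walks: int = 10,
    walk_length: int = 80,
    window: int = 10,
    epochs: int = 1,
    seed: int = 0,
) -> FeatureMatrix:
    """node2vec embedding of the fused network.

    Walks start from every node; directed degree-scheme cross edges are
    traversed only in their outgoing direction, undirected within-species
    edges both ways, and edge weights bias transition probabilities
    proportionally.  Identical seeds and inputs give identical output.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    W = node2vec_embedding(
        msn.adjacency(),
        dim=d,
        p=p,
        q=q,
        num_walks=num_walks,
        walk_length=walk_length,
        window=window,
        epochs=epochs,
        seed=seed,
    )
    return FeatureMatrix(
        gene_index=list(msn.gene_index),
        values=W.astype(np.float64),
        method="n2v",
        params={
            "d": d,
            "p": p,
            "q": q,
            "num_walks": num_walks,
            "walk_length": walk_length,
            "window": window,
            "epochs": epochs,
            "seed": seed,
        },
    )


@dataclass
class SpeciesMixing:
    """PCA coordinates plus the ortholog mixing score.

    ``score`` is the mean PC-space distance over ortholog-linked
    cross-species gene pairs divided by the same mean over an
    equal-sized random sample of cross-species pairs; values below one
    mean orthologs sit closer together than chance.
    """

    coordinates: np.ndarray
    gene_index: list[GenePair]
    score: float | None
    n_ortholog_pairs: int


def pca_species_projection(
    fm: FeatureMatrix,
    groups: OrthologGroupTable | None = None,
    n_components: int = 2,
    seed: int = 0,
) -> SpeciesMixing:
    """Top principal components of a representation plus a species-mixing score.

    When ``groups`` is None (or yields no cross-species pairs present in
    the feature index) the mixing score is undefined (None).
    """
    if fm.dim < n_components:
        raise ValueError(f"need >= {n_components} feature columns, have {fm.dim}")
    coords = PCA(n_components=n_components, random_state=0).fit_transform(fm.values)

    pos = {g: i for i, g in enumerate(fm.gene_index)}
    ortho_pairs: set[tuple[int, int]] = set()
    if groups is not None:
        for members in groups.groups.values():
            present = sorted(m for m in members if m in pos)
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    a, b = present[i], present[j]
                    if a[0] != b[0]:
                        ortho_pairs.add((pos[a], pos[b]))
    if not ortho_pairs:
        return SpeciesMixing(coords, list(fm.gene_index), None, 0)

    pairs = np.array(sorted(ortho_pairs))
    d_orth = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1).mean()

    rng = np.random.default_rng(seed)
    species = np.array([s for s, _ in fm.gene_index])
    idx_by_sp = {s: np.where(species == s)[0] for s in np.unique(species)}
    sp_labels = sorted(idx_by_sp)
    rand_d = []
    for _ in range(len(pairs)):
        sa, sb = rng.choice(len(sp_labels), size=2, replace=False)
        i = rng.choice(idx_by_sp[sp_labels[sa]])
        j = rng.choice(idx_by_sp[sp_labels[sb]])
        rand_d.append(np.linalg.norm(coords[i] - coords[j]))
    d_rand = float(np.mean(rand_d))
    score = float(d_orth / d_rand) if d_rand > 0 else 0.0
    return SpeciesMixing(coords, list(fm.gene_index), score, len(pairs))
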