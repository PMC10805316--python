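"""Self-contained node2vec: biased second-order random walks + skip-gram.

The walker runs on a (possibly asymmetric) weighted adjacency matrix:
undirected within-species edges appear in both directions, while
degree-scheme cross-species edges are directed, so transitions only ever
follow outgoing edges.  Walk biases follow the node2vec scheme: stepping
back to the previous node is reweighted by 1/p, staying among the
previous node's neighbours keeps weight 1, and moving outward is
reweighted by 1/q.

Embeddings are trained with skip-gram and negative sampling (SGNS) in
vectorised numpy minibatches.  With a fixed seed the whole procedure is
deterministic, which the test-suite relies on.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

__all__ = ["simulate_walks", "train_sgns", "node2vec_embedding"]


def _row_normalize_structures(adj: sp.csr_matrix):
    """Per-node out-neighbour arrays and cumulative transition probabilities."""
    adj = adj.tocsr()
    n = adj.shape[0]
    nbrs: list[np.ndarray] = []
    cumprobs: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for i in range(n):
        lo, hi = adj.indptr[i], adj.indptr[i + 1]
        idx = adj.indices[lo:hi]
        w = adj.data[lo:hi].astype(np.float64)
        nbrs.append(idx)
        weights.append(w)
        if w.size:
            c = np.cumsum(w)
            cumprobs.append(c / c[-1])
        else:
            cumprobs.append(np.empty(0))
    return nbrs, weights, cumprobs


def simulate_walks(
    adj: sp.csr_matrix,
    num_walks: int = 10,
    walk_length: int = 80,
    p: float = 1.0,
    q: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate biased random walks starting from every node.

    Returns an int array of shape (num_walks * n_nodes, walk_length);
    walks that hit a sink node are padded with -1.
    """
    if p <= 0 or q <= 0:
        raise ValueError("p and q must be positive")
    if rng is None:
        rng = np.random.default_rng()
    n = adj.shape[0]
    nbrs, weights, cumprobs = _row_normalize_structures(adj)
    first_order = p == 1.0 and q == 1.0
    nbr_sets = None if first_order else [set(a.tolist()) for a in nbrs]

    walks = np.full((num_walks * n, walk_length), -1, dtype=np.int64)
    starts = np.tile(np.arange(n), num_walks)
    # one shuffled permutation per pass keeps walk order seed-stable
    for w_i, start in enumerate(starts):
        walk = walks[w_i]
        walk[0] = start
        cur = start
        prev = -1
        for step in range(1, walk_length):
            nb = nbrs[cur]
            if nb.size == 0:
                break
            if first_order or prev < 0:
                nxt = nb[np.searchsorted(cumprobs[cur], rng.random(), side="right")]
            else:
                w = weights[cur].copy()
                prev_nbrs = nbr_sets[prev]
                for k, cand in enumerate(nb):
                    if cand == prev:
                        w[k] /= p
                    elif cand not in prev_nbrs:
                        w[k] /= q
                c = np.cumsum(w)
                nxt = nb[np.searchsorted(c / c[-1], rng.random(), side="right")]
            walk[step] = nxt
            prev, cur = cur, nxt
    return walks


def _context_pairs(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) pairs within the window, both directions."""
    centers, contexts = [], []
    for off in range(1, window + 1):
        a = walks[:, :-off].ravel()
        b = walks[:, off:].ravel()
        ok = (a >= 0) & (b >= 0)
        a, b = a[ok], b[ok]
        centers.append(a)
        contexts.append(b)
        centers.append(b)
        contexts.append(a)
    return np.concatenate(centers), np.concatenate(contexts)


def train_sgns(
    walks: np.ndarray,
    n_nodes: int,
    dim: int,
    window: int = 10,
    epochs: int = 1,
    negative: int = 5,
    learning_rate: float = 0.025,
    batch_size: int = 2_048,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Skip-gram with negative sampling over a walk corpus.

    Negative samples follow the standard unigram^0.75 distribution over
    corpus frequencies.  The learning rate decays linearly over batches.
    Within a minibatch, accumulated gradients on a node are averaged
    over its occurrences, which keeps updates on high-frequency hub
    nodes bounded.  Returns the input (center) embedding matrix,
    float32, shape (n_nodes, dim).
    """
    if rng is None:
        rng = np.random.default_rng()
    centers, contexts = _context_pairs(walks, window)
    n_pairs = centers.size
    # small corpora need enough optimisation steps per epoch
    batch_size = int(min(batch_size, max(64, n_pairs // 100)))

    counts = np.bincount(walks[walks >= 0].ravel(), minlength=n_nodes).astype(np.float64)
    noise = counts**0.75
    noise_sum = noise.sum()
    if noise_sum == 0:
        raise ValueError("empty walk corpus")
    noise_cdf = np.cumsum(noise / noise_sum)

    W = ((rng.random((n_nodes, dim)) - 0.5) / dim).astype(np.float32)
    C = np.zeros((n_nodes, dim), dtype=np.float32)

    n_batches_total = epochs * max(1, -(-n_pairs // batch_size))
    batch_no = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            idx = order[lo : lo + batch_size]
            ctr = centers[idx]
            pos = contexts[idx]
            b = ctr.size
            neg = np.searchsorted(noise_cdf, rng.random((b, negative)), side="right")

            lr = learning_rate * max(1e-4, 1.0 - batch_no / n_batches_total)
            batch_no += 1

            v = W[ctr]  # (b, d)
            u_pos = C[pos]  # (b, d)
            u_neg = C[neg]  # (b, k, d)

            s_pos = expit(np.einsum("bd,bd->b", v, u_pos))
            s_neg = expit(np.einsum("bd,bkd->bk", v, u_neg))

            g_pos = (s_pos - 1.0).astype(np.float32)  # (b,)
            g_neg = s_neg.astype(np.float32)  # (b, k)

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            grad_u_pos = g_pos[:, None] * v
            grad_u_neg = g_neg[:, :, None] * v[:, None, :]

            _scatter_mean_update(W, ctr, grad_v, lr, dim)
            ctx_idx = np.concatenate([pos, neg.ravel()])
            ctx_grad = np.concatenate([grad_u_pos, grad_u_neg.reshape(-1, dim)])
            _scatter_mean_update(C, ctx_idx, ctx_grad, lr, dim)
    return W


def _scatter_mean_update(M: np.ndarray, idx: np.ndarray, grad: np.ndarray,
                         lr: float, dim: int) -> None:
    """M[idx] -= lr * mean of grad rows per index (duplicate-safe)."""
    acc = np.zeros_like(M)
    np.add.at(acc, idx, grad.astype(np.float32))
    counts = np.bincount(idx, minlength=M.shape[0]).astype(np.float32)
    touched = counts > 0
    M[touched] -= lr * acc[touched] / counts[touched, None]


def node2vec_embedding(
    adj: sp.csr_matrix,
    dim: int,
    p: float = 1.0,
    q: float = 1.0,
    num_walks: int = 10,
    walk_length: int = 80,
    window: int = 10,
    epochs: int = 1,
    negative: int = 5,
    learning_rate: float = 0.025,
    seed: int | None = None,
) -> np.ndarray:
    """End-to-end node2vec on an adjacency matrix; seeded and deterministic."""
    rng = np.random.default_rng(seed)
    walks = simulate_walks(
        adj, num_walks=num_walks, walk_length=walk_length, p=p, q=q, rng=rng
    )
    return train_sgns(
        walks,
        n_nodes=adj.shape[0],
        dim=dim,
        window=window,
        epochs=epochs,
        negative=negative,
        learning_rate=learning_rate,
        rng=rng,
    )
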