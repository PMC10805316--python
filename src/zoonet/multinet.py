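"""Load per-species networks and ortholog groups; fuse them into one network.

A multi-species network retains each species' undirected weighted edges
unchanged and adds cross-species edges between genes that share an
orthologous group.  Two cross-edge weighting schemes are supported:

``uniform``
    every cross edge is undirected with a constant weight (default 1.0).
``degree``
    each ordered cross pair (g -> h) gets a directed edge weighted
    ``beta * deg_within(g) / n_cross(g)``, where ``n_cross(g)`` counts
    g's distinct cross-species partner genes.  A random walker at g is
    then equally likely to stay within its species or cross over, which
    encourages walks to traverse species boundaries.

Genes are namespaced internally as ``(species, gene)`` pairs so identical
identifiers in two species never collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

GenePair = tuple[str, str]  # (species, gene)


class NetworkParseError(ValueError):
    """Raised when an edge-list or ortholog file cannot be parsed."""


@dataclass
class SpeciesNetwork:
    """Undirected weighted molecular network for one species.

    Parameters
    ----------
    species : str
        Short species label, e.g. ``"hu"``.
    genes : tuple of str
        Ordered gene identifiers (Entrez-style strings).
    edges : dict
        Mapping of unordered gene pairs (stored as sorted 2-tuples) to
        weights in (0, 1].
    """

    species: str
    genes: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"edge endpoint not in gene list: {(a, b)}")
            if not (0.0 < w):
                raise ValueError(f"non-positive weight {w} on edge {(a, b)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, gene: str) -> dict[str, float]:
        """Neighbors of ``gene`` with edge weights."""
        if gene not in set(self.genes):
            raise KeyError(gene)
        out: dict[str, float] = {}
        for (a, b), w in self.edges.items():
            if a == gene:
                out[b] = w
            elif b == gene:
                out[a] = w
        return out


@dataclass
class OrthologGroupTable:
    """Mapping of ortholog-group id -> set of (species, gene) members."""

    groups: dict[str, frozenset[GenePair]] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def groups_of(self, member: GenePair) -> set[str]:
        return {gid for gid, mem in self.groups.items() if member in mem}


@dataclass
class MultiSpeciesNetwork:
    """Fused network: within-species blocks plus cross-species ortholog edges.

    ``within`` is a symmetric sparse matrix holding the unchanged
    within-species edges; ``cross`` holds cross-species edges with entry
    (i, j) being the weight of the (possibly directed) edge i -> j.
    Under the uniform scheme ``cross`` is symmetric.
    """

    gene_index: list[GenePair]
    within: sp.csr_matrix
    cross: sp.csr_matrix
    weighting_scheme: str
    scheme_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._pos = {g: i for i, g in enumerate(self.gene_index)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for s, _ in self.gene_index:
            if s not in seen:
                seen.append(s)
        return seen

    def index_of(self, gene: GenePair) -> int:
        return self._pos[gene]

    def species_mask(self, species: str) -> np.ndarray:
        return np.array([s == species for s, _ in self.gene_index])

    def adjacency(self) -> sp.csr_matrix:
        """Combined (possibly asymmetric) adjacency of the fused network."""
        return (self.within + self.cross).tocsr()

    def cross_edge_count(self) -> int:
        """Number of distinct unordered cross-species gene pairs linked."""
        coo = self.cross.tocoo()
        return len({(min(i, j), max(i, j)) for i, j in zip(coo.row, coo.col)})

    def to_edge_table(self):
        """Fused network as a DataFrame (species_a, gene_a, species_b, gene_b, weight, directed)."""
        import pandas as pd

        rows = []
        w_coo = sp.triu(self.within, k=1).tocoo()
        for i, j, w in zip(w_coo.row, w_coo.col, w_coo.data):
            sa, ga = self.gene_index[i]
            sb, gb = self.gene_index[j]
            rows.append((sa, ga, sb, gb, float(w), False))
        c_coo = self.cross.tocoo()
        directed = self.weighting_scheme == "degree"
        seen = set()
        for i, j, w in zip(c_coo.row, c_coo.col, c_coo.data):
            if not directed:
                key = (min(i, j), max(i, j))
                if key in seen:
                    continue
                seen.add(key)
            sa, ga = self.gene_index[i]
            sb, gb = self.gene_index[j]
            rows.append((sa, ga, sb, gb, float(w), directed))
        return pd.DataFrame(
            rows,
            columns=["species_a", "gene_a", "species_b", "gene_b", "weight", "directed"],
        )


def load_species_network(
    path,
    species: str,
    allowed_genes: set[str] | None = None,
    include_genes: Iterable[str] | None = None,
) -> SpeciesNetwork:
    """Read a 2- or 3-column TSV edge list (geneA, geneB[, weight]).

    Missing weights default to 1.0.  Duplicate pairs keep the maximum
    weight; self-loops are dropped; genes outside ``allowed_genes`` (when
    given) are removed.  ``include_genes`` adds genes even when they have
    no edges, so node lists survive a write/load round trip.  Lines
    starting with ``#`` are comments.
    """
    edges: dict[tuple[str, str], float] = {}
    genes: dict[str, None] = {}
    if include_genes is not None:
        for g in include_genes:
            if allowed_genes is None or g in allowed_genes:
                genes.setdefault(g)
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space-separated input
                parts = line.split()
            if len(parts) not in (2, 3):
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: bad weight {parts[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if not (0.0 < w <= 1.0):
                raise NetworkParseError(
                    f"{path}: line {lineno}: weight {w} outside (0, 1]"
                )
            if a == b:
                continue
            if allowed_genes is not None and (a not in allowed_genes or b not in allowed_genes):
                continue
            key = (a, b) if a <= b else (b, a)
            edges[key] = max(edges.get(key, 0.0), w)
            genes.setdefault(a)
            genes.setdefault(b)
    if n_lines == 0:
        logger.warning("empty network file %s for species %s", path, species)
    return SpeciesNetwork(species=species, genes=tuple(sorted(genes)), edges=edges)


def load_ortholog_groups(
    path,
    allowed_species: set[str] | None = None,
) -> OrthologGroupTable:
    """Read a 3-column TSV (group_id, species, gene) into an OrthologGroupTable.

    Rows referencing species outside ``allowed_species`` are dropped (the
    count is logged).  Duplicate rows deduplicate silently.
    """
    groups: dict[str, set[GenePair]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            gid, spp, gene = parts
            if allowed_species is not None and spp not in allowed_species:
                dropped += 1
                continue
            groups.setdefault(gid, set()).add((spp, gene))
    if dropped:
        logger.info("dropped %d ortholog rows with unknown species", dropped)
    return OrthologGroupTable(groups={g: frozenset(m) for g, m in groups.items()})


def within_degree(net: SpeciesNetwork, gene: str) -> float:
    """Weighted degree of ``gene`` inside its own species network."""
    if gene not in set(net.genes):
        raise KeyError(gene)
    return float(sum(w for (a, b), w in net.edges.items() if gene in (a, b)))


def _cross_pairs(
    nets: Mapping[str, SpeciesNetwork],
    groups: OrthologGroupTable,
) -> set[tuple[GenePair, GenePair]]:
    """Deduplicated unordered cross-species member pairs over all groups."""
    pairs: set[tuple[GenePair, GenePair]] = set()
    gene_sets = {spp: set(net.genes) for spp, net in nets.items()}
    n_missing = 0
    for members in groups.groups.values():
        present = []
        for spp, gene in members:
            if spp not in gene_sets or gene not in gene_sets[spp]:
                n_missing += 1
                continue
            present.append((spp, gene))
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                if a[0] == b[0]:
                    continue
                pairs.add((a, b) if a <= b else (b, a))
    if n_missing:
        logger.info("ignored %d ortholog members absent from their species network", n_missing)
    return pairs


def build_multispecies_network(
    nets: Iterable[SpeciesNetwork],
    groups: OrthologGroupTable,
    scheme: str = "uniform",
    uniform_weight: float = 1.0,
    beta: float = 1.0,
    floor_weight: float = 1e-3,
) -> MultiSpeciesNetwork:
    """Fuse species networks with ortholog-derived cross-species edges.

    Within-species edges are retained unchanged.  For every pair of genes
    in an ortholog group that come from different species an edge is
    added; see module docstring for the two weighting schemes.

    Parameters
    ----------
    scheme : {"uniform", "degree"}
    uniform_weight : float
        Constant weight for uniform-scheme cross edges (default 1.0).
    beta : float
        Multiplier on the degree-scheme weight.
    floor_weight : float
        Weight assigned per outgoing cross edge when the source gene has
        within-species degree zero, so orphan genes stay reachable.
    """
    nets = list(nets)
    if scheme not in ("uniform", "degree"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    labels = [n.species for n in nets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate species labels in {labels}")
    by_species = {n.species: n for n in nets}

    gene_index: list[GenePair] = []
    for net in nets:
        gene_index.extend((net.species, g) for g in net.genes)
    pos = {g: i for i, g in enumerate(gene_index)}
    n = len(gene_index)

    rows, cols, data = [], [], []
    for net in nets:
        for (a, b), w in net.edges.items():
            i, j = pos[(net.species, a)], pos[(net.species, b)]
            rows += [i, j]
            cols += [j, i]
            data += [w, w]
    within = sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    pairs = _cross_pairs(by_species, groups)
    # distinct cross partners per gene (group memberships do not multi-count)
    partners: dict[GenePair, set[GenePair]] = {}
    for a, b in pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    c_rows, c_cols, c_data = [], [], []
    n_orphans = 0
    if scheme == "uniform":
        for a, b in pairs:
            i, j = pos[a], pos[b]
            c_rows += [i, j]
            c_cols += [j, i]
            c_data += [uniform_weight, uniform_weight]
    else:
        deg_cache: dict[GenePair, float] = {}
        for g, partner_set in partners.items():
            d = deg_cache.get(g)
            if d is None:
                d = within_degree(by_species[g[0]], g[1])
                deg_cache[g] = d
            if d > 0:
                w = beta * d / len(partner_set)
            else:
                w = floor_weight
                n_orphans += 1
            i = pos[g]
            for h in partner_set:
                c_rows.append(i)
                c_cols.append(pos[h])
                c_data.append(w)
        if n_orphans:
            logger.info("%d genes with zero within-degree given floor cross weight", n_orphans)
    cross = sp.csr_matrix((c_data, (c_rows, c_cols)), shape=(n, n))

    params = {"beta": beta, "floor_weight": floor_weight} if scheme == "degree" else {
        "uniform_weight": uniform_weight
    }
    return MultiSpeciesNetwork(
        gene_index=gene_index,
        within=within,
        cross=cross,
        weighting_scheme=scheme,
        scheme_params=params,
    )


def write_fused_network(msn: MultiSpeciesNetwork, path) -> None:
    """Export the fused network as TSV (species_a, gene_a, species_b, gene_b, weight, directed)."""
    msn.to_edge_table().to_csv(path, sep="\t", index=False)
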