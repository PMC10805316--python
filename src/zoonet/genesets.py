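"""Gene-set collections: propagation, filtering, and redundancy reduction.

Annotations are propagated up an ontology (child -> parent table), cut
down to genes present in a network and to terms within a size band, and
optionally reduced to a non-redundant subset: terms whose gene sets both
overlap strongly (overlap coefficient) and share a high Jaccard index
are linked in a term-similarity graph, and one representative term is
kept per connected component — the term with the highest mean Jaccard
similarity to the other members, ties broken lexicographically.

For cross-species knowledge-transfer evaluation, a matched collection
keeps only terms that independently pass the study-bias >=10 train /
>=10 test rule in *both* species, with per-term gene sets being the
species-namespaced union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "TermSimilarityGraph",
    "propagate_annotations",
    "filter_collection",
    "term_similarity_graph",
    "nonredundant_terms",
    "matched_collection",
    "read_gmt",
    "write_gmt",
    "read_ontology_table",
]


@dataclass
class GeneSetCollection:
    """Mapping term-id -> annotated gene set with provenance of filtering."""

    terms: dict[str, frozenset[Hashable]]
    names: dict[str, str] = field(default_factory=dict)
    task: str = "synthetic"
    species_scope: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise ValueError(f"empty gene sets for terms {empty[:5]}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def all_genes(self) -> frozenset[Hashable]:
        out: set[Hashable] = set()
        for g in self.terms.values():
            out |= g
        return frozenset(out)

    def name_of(self, term: str) -> str:
        return self.names.get(term, term)


@dataclass
class TermSimilarityGraph:
    """Term pairs whose overlap coefficient and Jaccard both exceed thresholds."""

    graph: nx.Graph
    scores: dict[tuple[str, str], tuple[float, float]]  # (overlap, jaccard)
    overlap_threshold: float
    jaccard_threshold: float


def propagate_annotations(
    annotations: Mapping[str, set],
    ontology: Mapping[str, set[str]],
) -> dict[str, set]:
    """Propagate annotations from specific terms to all their ancestors.

    ``ontology`` maps child term -> set of parent terms and must be
    acyclic.  A gene annotated to a term becomes annotated to every
    ancestor, counted once per term regardless of path multiplicity.
    """
    dag = nx.DiGraph()
    dag.add_nodes_from(annotations)
    for child, parents in ontology.items():
        for parent in parents:
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")
    out: dict[str, set] = {t: set(g) for t, g in annotations.items()}
    for term, genes in annotations.items():
        if term in dag:
            for anc in nx.descendants(dag, term):  # edges point child -> parent
                out.setdefault(anc, set()).update(genes)
    return {t: g for t, g in out.items() if g}


def filter_collection(
    annotations: Mapping[str, set],
    network_genes: set,
    min_size: int,
    max_size: int,
    names: Mapping[str, str] | None = None,
    task: str = "synthetic",
    species_scope: tuple[str, ...] = (),
    allowed_terms: set[str] | None = None,
) -> GeneSetCollection:
    """Restrict annotations to network genes, then apply the term-size band.

    Genes outside ``network_genes`` are removed first; the size filter
    (inclusive, ``min_size <= |genes| <= max_size``) applies to the
    reduced sets.  ``allowed_terms``, when given, models a curated list
    of specific terms.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("need 1 <= min_size <= max_size")
    kept: dict[str, frozenset] = {}
    for term, genes in annotations.items():
        if allowed_terms is not None and term not in allowed_terms:
            continue
        on_net = frozenset(genes) & frozenset(network_genes)
        if min_size <= len(on_net) <= max_size:
            kept[term] = frozenset(on_net)
    if not kept:
        logger.warning("term-size filter left an empty collection")
    return GeneSetCollection(
        terms=kept,
        names={t: (names or {}).get(t, t) for t in kept},
        task=task,
        species_scope=species_scope,
        provenance={"min_size": min_size, "max_size": max_size,
                    "n_input_terms": len(annotations)},
    )


def _overlap_jaccard(a: frozenset, b: frozenset) -> tuple[float, float]:
    inter = len(a & b)
    overlap = inter / min(len(a), len(b))
    jaccard = inter / len(a | b)
    return overlap, jaccard


def term_similarity_graph(
    gsc: GeneSetCollection,
    overlap_threshold: float = 0.5,
    jaccard_threshold: float = 0.5,
) -> TermSimilarityGraph:
    """Score all unordered term pairs; link pairs exceeding both thresholds.

    The overlap score is the overlap coefficient |A∩B| / min(|A|, |B|);
    both inequalities are strict.
    """
    if gsc.n_terms == 0:
        raise ValueError("empty collection")
    g = nx.Graph()
    g.add_nodes_from(gsc.terms)
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for t1, t2 in combinations(sorted(gsc.terms), 2):
        ov, jc = _overlap_jaccard(gsc.terms[t1], gsc.terms[t2])
        scores[(t1, t2)] = (ov, jc)
        if ov > overlap_threshold and jc > jaccard_threshold:
            g.add_edge(t1, t2)
    return TermSimilarityGraph(g, scores, overlap_threshold, jaccard_threshold)


def nonredundant_terms(
    graph: TermSimilarityGraph,
    gsc: GeneSetCollection,
) -> GeneSetCollection:
    """One representative term per connected component of the similarity graph.

    Singleton components keep their term; larger components keep the
    term with the highest mean Jaccard similarity to all other component
    members, ties broken by lexicographically smallest term-id.
    """
    if not set(graph.graph.nodes) <= set(gsc.terms):
        raise ValueError("similarity graph contains terms absent from the collection")
    reps: list[str] = []
    for comp in nx.connected_components(graph.graph):
        comp = sorted(comp)
        if len(comp) == 1:
            reps.append(comp[0])
            continue
        best_term, best_mean = None, -1.0
        for t in comp:
            sims = [
                _overlap_jaccard(gsc.terms[t], gsc.terms[o])[1]
                for o in comp
                if o != t
            ]
            mean = sum(sims) / len(sims)
            if mean > best_mean + 1e-12:
                best_term, best_mean = t, mean
        reps.append(best_term)
    reps = sorted(reps)
    return GeneSetCollection(
        terms={t: gsc.terms[t] for t in reps},
        names={t: gsc.name_of(t) for t in reps},
        task=gsc.task,
        species_scope=gsc.species_scope,
        provenance={**gsc.provenance, "nonredundant": True,
                    "overlap_threshold": graph.overlap_threshold,
                    "jaccard_threshold": graph.jaccard_threshold},
    )


def matched_collection(
    gsc_a: GeneSetCollection,
    gsc_b: GeneSetCollection,
    splits_a: Mapping[str, object],
    splits_b: Mapping[str, object],
    species_a: str,
    species_b: str,
    overlap_threshold: float = 0.5,
    jaccard_threshold: float = 0.5,
    min_train: int = 10,
    min_test: int = 10,
) -> GeneSetCollection:
    """Matched cross-species collection for knowledge-transfer evaluation.

    A term is kept only when each species independently has at least
    ``min_train`` training and ``min_test`` testing genes in its
    study-bias split.  Kept terms get the species-namespaced union of
    both species' gene sets, and redundancy is removed on the combined
    sets.
    """
    shared = set(gsc_a.terms) & set(gsc_b.terms)
    combined: dict[str, frozenset] = {}
    for term in sorted(shared):
        sa, sb = splits_a.get(term), splits_b.get(term)
        if sa is None or sb is None:
            continue
        if (len(sa.train_pos) < min_train or len(sa.test_pos) < min_test
                or len(sb.train_pos) < min_train or len(sb.test_pos) < min_test):
            continue
        combined[term] = frozenset(
            {(species_a, g) for g in gsc_a.terms[term]}
            | {(species_b, g) for g in gsc_b.terms[term]}
        )
    if not combined:
        logger.warning("no matched terms between %s and %s", species_a, species_b)
        return GeneSetCollection(
            terms={}, task=gsc_a.task, species_scope=(species_a, species_b),
            provenance={"matched": True},
        )
    merged = GeneSetCollection(
        terms=combined,
        names={t: gsc_a.name_of(t) for t in combined},
        task=gsc_a.task,
        species_scope=(species_a, species_b),
        provenance={"matched": True, "min_train": min_train, "min_test": min_test},
    )
    sim = term_similarity_graph(merged, overlap_threshold, jaccard_threshold)
    return nonredundant_terms(sim, merged)


# ---------------------------------------------------------------------------
# file dialects


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT file (term_id <TAB> name <TAB> gene...)."""
    anns: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            anns[parts[0]] = set(parts[2:])
            names[parts[0]] = parts[1]
    return anns, names


def write_gmt(annotations: Mapping[str, set], path, names: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations):
            name = (names or {}).get(term, term)
            genes = "\t".join(sorted(annotations[term]))
            fh.write(f"{term}\t{name}\t{genes}\n")


def read_ontology_table(path) -> dict[str, set[str]]:
    """Read a child <TAB> parent TSV into child -> parents mapping."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            out.setdefault(child, set()).add(parent)
    return out
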