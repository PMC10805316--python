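"""Study-bias splits, negative/neutral selection, training, prediction.

Instead of random train/test splits, genes annotated to a term are split
by how well-studied they are (publication counts, gene2pubmed-style):
well-published genes train the model, poorly characterised genes test
it, emulating the discovery of novel genes.  Negatives for a term are
genes annotated to some other term, except genes of terms that overlap
the target significantly (one-sided Fisher exact test, Benjamini-
Hochberg FDR), which are set aside as neutral.

Classifiers are L2-regularised logistic regression models (strength 1,
the scikit-learn default) on any network feature representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np
from scipy.special import expit
from scipy.stats import hypergeom
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from zoonet.genesets import GeneSetCollection
from zoonet.multinet import OrthologGroupTable
from zoonet.represent import FeatureMatrix

__all__ = [
    "AnnotationSplit",
    "TrainedModel",
    "study_bias_split",
    "select_negatives",
    "add_ortholog_positives",
    "train_classifier",
    "predict_genome",
]


@dataclass
class AnnotationSplit:
    """Per-term train/test positives, negatives, and neutral-excluded genes."""

    term: str
    train_pos: frozenset[Hashable]
    test_pos: frozenset[Hashable]
    train_neg: frozenset[Hashable] = frozenset()
    test_neg: frozenset[Hashable] = frozenset()
    neutral: frozenset[Hashable] = frozenset()

    def __post_init__(self) -> None:
        pos = self.train_pos | self.test_pos
        neg = self.train_neg | self.test_neg
        if pos & neg or pos & self.neutral or neg & self.neutral:
            raise ValueError(f"{self.term}: positive/negative/neutral sets overlap")
        if self.train_pos & self.test_pos or self.train_neg & self.test_neg:
            raise ValueError(f"{self.term}: train/test sets overlap")


@dataclass
class TrainedModel:
    """Fitted logistic-regression weights aligned to feature columns."""

    weights: np.ndarray
    intercept: float
    l2_strength: float
    term: str = ""
    feature_method: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or not math.isfinite(self.intercept):
            raise ValueError("non-finite model parameters")

    @property
    def dim(self) -> int:
        return self.weights.shape[0]


def _split_by_study_bias(
    genes,
    counts: Mapping[Hashable, int],
    train_fraction: float,
) -> tuple[list, list]:
    """Sort by publication count desc (gene-id asc breaks ties); top ceil(f*n) train."""
    ranked = sorted(genes, key=lambda g: (-counts.get(g, 0), g))
    n_train = math.ceil(train_fraction * len(ranked))
    return ranked[:n_train], ranked[n_train:]


def study_bias_split(
    gsc: GeneSetCollection,
    pubmed_counts: Mapping[Hashable, int],
    train_fraction: float = 2 / 3,
    min_train: int = 10,
    min_test: int = 10,
) -> dict[str, AnnotationSplit]:
    """Split each term's positives into train/test by publication count.

    Genes with no recorded count default to zero.  Terms with fewer than
    ``min_train`` training or ``min_test`` testing genes are dropped.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1)")
    out: dict[str, AnnotationSplit] = {}
    for term in sorted(gsc.terms):
        train, test = _split_by_study_bias(gsc.terms[term], pubmed_counts, train_fraction)
        if len(train) < min_train or len(test) < min_test:
            continue
        out[term] = AnnotationSplit(
            term=term, train_pos=frozenset(train), test_pos=frozenset(test)
        )
    return out


def _fisher_one_sided(k: int, n_t: int, n_s: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe, n_t, n_s): enrichment tail."""
    return float(hypergeom.sf(k - 1, universe, n_t, n_s))


def select_negatives(
    splits: Mapping[str, AnnotationSplit],
    gsc: GeneSetCollection,
    pubmed_counts: Mapping[Hashable, int],
    fdr_threshold: float = 0.05,
    train_fraction: float = 2 / 3,
) -> dict[str, AnnotationSplit]:
    """Complete splits with negatives and neutral genes.

    The gene universe is every gene annotated to at least one term of
    the collection.  For a target term T, every other term S is tested
    for overlap enrichment with a one-sided Fisher exact test over the
    universe; after Benjamini-Hochberg correction across terms, genes of
    significant terms (outside T) are neutral, and all remaining
    annotated non-T genes are negatives, split train/test by the same
    publication-count rule as positives.
    """
    universe = gsc.all_genes()
    n_u = len(universe)
    out: dict[str, AnnotationSplit] = {}
    for term in sorted(splits):
        split = splits[term]
        t_genes = split.train_pos | split.test_pos
        if not t_genes <= universe:
            raise ValueError(
                f"{term}: positives outside the annotation universe "
                f"({len(t_genes - universe)} genes)"
            )
        others = [s for s in sorted(gsc.terms) if s != term]
        neutral: set = set()
        if others:
            pvals = [
                _fisher_one_sided(
                    len(t_genes & gsc.terms[s]), len(t_genes), len(gsc.terms[s]), n_u
                )
                for s in others
            ]
            reject, _, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
            for s, rej in zip(others, reject):
                if rej:
                    neutral |= set(gsc.terms[s])
        neutral -= t_genes
        negatives = universe - t_genes - neutral
        train_neg, test_neg = _split_by_study_bias(negatives, pubmed_counts, train_fraction)
        out[term] = AnnotationSplit(
            term=term,
            train_pos=split.train_pos,
            test_pos=split.test_pos,
            train_neg=frozenset(train_neg),
            test_neg=frozenset(test_neg),
            neutral=frozenset(neutral),
        )
    return out


def add_ortholog_positives(
    positives: frozenset[tuple[str, str]],
    groups: OrthologGroupTable,
    species_scope: tuple[str, ...],
) -> frozenset[tuple[str, str]]:
    """Augment positives with their cross-species ortholog partners.

    Positives must be (species, gene) namespaced.  Partners outside
    ``species_scope`` are ignored; with a single-species scope the input
    is returned unchanged.  Genes are only ever added, never removed.
    """
    scope = set(species_scope)
    if len(scope) <= 1:
        return frozenset(positives)
    augmented = set(positives)
    for members in groups.groups.values():
        if any(m in positives for m in members):
            augmented |= {m for m in members if m[0] in scope}
    return frozenset(augmented)


def train_classifier(
    features: FeatureMatrix,
    train_pos,
    train_neg,
    l2_strength: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> TrainedModel:
    """Fit L2-regularised logistic regression on labelled feature rows.

    The convex objective plus fixed solver settings make the fit
    deterministic for fixed inputs.
    """
    train_pos, train_neg = sorted(train_pos), sorted(train_neg)
    if not train_pos or not train_neg:
        raise ValueError("need at least one positive and one negative training gene")
    if set(train_pos) & set(train_neg):
        raise ValueError("training positives and negatives overlap")
    X = features.rows_for(train_pos + train_neg)
    y = np.r_[np.ones(len(train_pos)), np.zeros(len(train_neg))]
    clf = LogisticRegression(
        C=1.0 / l2_strength, solver="lbfgs", tol=tol, max_iter=max_iter
    )
    clf.fit(X, y)
    return TrainedModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        l2_strength=l2_strength,
        feature_method=features.method,
        metadata={"n_pos": len(train_pos), "n_neg": len(train_neg)},
    )


def predict_genome(
    model: TrainedModel,
    features: FeatureMatrix,
    target_species: str | None = None,
    train_genes=None,
    exclude_train: bool = False,
):
    """Genome-wide prediction probabilities for one (or every) species.

    Returns a DataFrame indexed by (species, gene) with columns
    ``score`` (logistic probability) and ``is_train``.  Training genes
    are flagged by default and dropped only when ``exclude_train``.
    """
    import pandas as pd

    if model.dim != features.dim:
        raise ValueError(
            f"feature dim {features.dim} does not match model dim {model.dim}"
        )
    if target_species is None:
        genes, rows = list(features.gene_index), features.values
    else:
        genes, rows = features.species_rows(target_species)
    z = rows @ model.weights + model.intercept
    scores = expit(z)
    train_set = set(train_genes or ())
    df = pd.DataFrame(
        {
            "score": scores,
            "is_train": [g in train_set for g in genes],
        },
        index=pd.MultiIndex.from_tuples(genes, names=["species", "gene"]),
    )
    if exclude_train:
        df = df[~df["is_train"]]
    return df.sort_values("score", ascending=False)
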