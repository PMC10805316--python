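"""Shared fixtures: the desk-scale benchmark world and its representations.

The heavy artifacts (planted-module world, fused network, node2vec
embedding, per-term evaluations) are computed once per session and
shared by the recovery/transfer/mixing tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from zoonet import (
    adjacency_features,
    build_multispecies_network,
    evaluate_term,
    filter_collection,
    generate_world,
    matched_rank,
    node2vec_features,
    predict_genome,
    select_negatives,
    study_bias_split,
    train_classifier,
)
from zoonet.synthdata import TRANSFER_SMALL

warnings.filterwarnings("ignore", category=FutureWarning)

PRESET_SEED = 7
N2V_BENCH = dict(d=64, walk_length=40, window=5, epochs=5, seed=1)


def ns(sp, genes):
    """Namespace plain per-species gene ids as (species, gene) pairs."""
    return frozenset((sp, g) for g in genes)


@pytest.fixture(scope="session")
def transfer_world():
    return generate_world(TRANSFER_SMALL, seed=PRESET_SEED)


@pytest.fixture(scope="session")
def transfer_msn(transfer_world):
    return build_multispecies_network(
        transfer_world.networks.values(), transfer_world.groups, scheme="degree"
    )


@pytest.fixture(scope="session")
def transfer_n2v(transfer_msn):
    return node2vec_features(transfer_msn, **N2V_BENCH)


@pytest.fixture(scope="session")
def transfer_adj(transfer_msn):
    return adjacency_features(transfer_msn)


@pytest.fixture(scope="session")
def transfer_splits(transfer_world):
    """Completed study-bias splits for both species of the benchmark world."""
    w = transfer_world
    out = {}
    for sp in w.config.species:
        gsc = filter_collection(
            w.annotations[sp], set(w.networks[sp].genes), 10, 200, species_scope=(sp,)
        )
        splits = study_bias_split(gsc, w.pubmed_counts)
        out[sp] = select_negatives(splits, gsc, w.pubmed_counts)
    return out


@pytest.fixture(scope="session")
def within_species_ratios(transfer_n2v, transfer_splits, transfer_world):
    """log2(auPRC/prior) on held-out genes, species A, n2v features."""
    sp = transfer_world.config.species[0]
    ratios = []
    for term, s in transfer_splits[sp].items():
        model = train_classifier(transfer_n2v, ns(sp, s.train_pos), ns(sp, s.train_neg))
        preds = predict_genome(model, transfer_n2v, target_species=sp)
        scores = dict(zip(preds.index, preds["score"]))
        res = evaluate_term(term, scores, ns(sp, s.test_pos), ns(sp, s.test_neg))
        ratios.append(res.log2_ratio)
    return ratios


def _transfer_metrics(fm, splits, source, target):
    ratios, ranks = [], []
    for term in sorted(splits[source]):
        s = splits[source][term]
        model = train_classifier(
            fm,
            ns(source, s.train_pos | s.test_pos),
            ns(source, s.train_neg | s.test_neg),
        )
        preds = predict_genome(model, fm, target_species=target)
        scores = dict(zip(preds.index, preds["score"]))
        per_term = {}
        for other in sorted(splits[target]):
            st = splits[target][other]
            res = evaluate_term(
                other, scores, ns(target, st.test_pos), ns(target, st.test_neg)
            )
            per_term[other] = res.log2_ratio
        ratios.append(per_term[term])
        ranks.append(matched_rank(per_term[term], list(per_term.values())))
    return np.array(ratios), np.array(ranks)


@pytest.fixture(scope="session")
def cross_species_results(transfer_n2v, transfer_adj, transfer_splits, transfer_world):
    """A->B transfer metrics for the n2v and adjacency representations."""
    src, tgt = transfer_world.config.species[:2]
    out = {}
    for name, fm in [("n2v", transfer_n2v), ("adjmat", transfer_adj)]:
        ratios, ranks = _transfer_metrics(fm, transfer_splits, src, tgt)
        out[name] = {"log2_ratios": ratios, "matched_ranks": ranks}
    return out
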