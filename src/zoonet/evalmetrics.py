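"""Evaluation metrics: auPRC, prior-normalised log-ratio, ranking, enrichment.

Gene classification is heavily imbalanced, so performance is reported as
the area under the precision-recall curve (auPRC) normalised by the
prior P/(P+N) — the expected auPRC of a random classifier — and
log-transformed.  log2(auPRC/prior) counts the two-fold improvements
over random expectation: 1 means twice random, 2 means four times.

The auPRC is the step sum over thresholds placed at every unique score,
with tied scores grouped at one threshold and no interpolation:

    auPRC = sum_n (Recall_n - Recall_{n-1}) * Precision_n

Representation comparisons use the Wilcoxon signed-rank test with
Bonferroni correction; top-prediction enrichment uses a one-sided
hypergeometric test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, wilcoxon

from zoonet.genesets import GeneSetCollection
from zoonet.multinet import OrthologGroupTable

__all__ = [
    "EvalResult",
    "auprc",
    "prior",
    "log2_auprc_over_prior",
    "evaluate_term",
    "matched_rank",
    "compare_representations",
    "enrich_top_predictions",
]


@dataclass
class EvalResult:
    """Per-term evaluation record."""

    term: str
    auprc: float
    prior: float
    log2_ratio: float
    n_pos: int
    n_neg: int
    matched_rank: int | None = None


def auprc(scores: Mapping[Hashable, float], labels: Mapping[Hashable, bool]) -> float:
    """Step-sum auPRC with thresholds at each unique prediction score.

    ``labels`` maps gene -> True (positive) / False (negative); neutral
    genes must already be excluded.  Only genes present in ``labels``
    are evaluated.
    """
    genes = list(labels)
    y = np.array([bool(labels[g]) for g in genes])
    s = np.array([float(scores[g]) for g in genes])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    # group tied scores at a single threshold
    boundaries = np.r_[np.where(np.diff(s) != 0)[0], len(s) - 1]
    tp = np.cumsum(y)[boundaries].astype(float)
    n_pred = boundaries + 1.0
    precision = tp / n_pred
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def prior(labels: Mapping[Hashable, bool]) -> float:
    """Fraction of labelled genes that are positive, P/(P+N)."""
    if not labels:
        raise ValueError("empty labels")
    y = np.array([bool(v) for v in labels.values()])
    return float(y.mean())


def log2_auprc_over_prior(auprc_value: float, prior_value: float) -> float:
    """Number of two-fold increases of auPRC over the random-classifier prior."""
    if auprc_value <= 0 or prior_value <= 0:
        raise ValueError("auprc and prior must be positive")
    return math.log2(auprc_value / prior_value)


def evaluate_term(
    term: str,
    scores: Mapping[Hashable, float],
    positives,
    negatives,
) -> EvalResult:
    """Bundle auPRC, prior and the log2 ratio for one term's labelled genes."""
    labels = {g: True for g in positives}
    labels.update({g: False for g in negatives})
    a = auprc(scores, labels)
    p = prior(labels)
    return EvalResult(
        term=term,
        auprc=a,
        prior=p,
        log2_ratio=log2_auprc_over_prior(a, p),
        n_pos=len(positives),
        n_neg=len(labels) - len(positives),
    )


def matched_rank(matched_metric: float, all_metrics: Sequence[float]) -> int:
    """Rank of the matched term's metric among all terms (1 = best).

    Ties share the minimum (best) rank.  ``all_metrics`` must include
    the matched term's own value.
    """
    arr = list(all_metrics)
    if not any(math.isclose(matched_metric, m) or matched_metric == m for m in arr):
        raise ValueError("matched term's metric not present in the collection metrics")
    return 1 + sum(1 for m in arr if m > matched_metric)


def compare_representations(
    paired_metrics: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    n_comparisons: int | None = None,
    fwer: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon signed-rank comparisons with Bonferroni control.

    ``paired_metrics`` maps a comparison label to a pair of equal-length
    metric vectors (paired by term).  Zero differences are dropped
    (standard signed-rank practice); an all-zero difference vector gets
    p = 1 and is flagged degenerate.  The Bonferroni-adjusted p-value is
    min(1, p * n_comparisons), significant when below ``fwer``, with the
    direction given by the sign of the median difference.
    """
    if n_comparisons is None:
        n_comparisons = len(paired_metrics)
    rows = []
    for name in sorted(paired_metrics):
        a, b = paired_metrics[name]
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.shape != b.shape:
            raise ValueError(f"{name}: paired vectors differ in length")
        diffs = a - b
        degenerate = bool(np.all(diffs == 0))
        if degenerate:
            p = 1.0
        else:
            p = float(wilcoxon(a, b, zero_method="wilcox", method="auto").pvalue)
        p_adj = min(1.0, p * n_comparisons)
        rows.append(
            {
                "comparison": name,
                "n_pairs": len(a),
                "median_diff": float(np.median(diffs)),
                "p_value": p,
                "p_bonferroni": p_adj,
                "significant": bool(p_adj < fwer) and not degenerate,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def enrich_top_predictions(
    scores: Mapping[Hashable, float],
    gsc: GeneSetCollection,
    top_k: int = 100,
    fdr_threshold: float = 0.05,
    groups: OrthologGroupTable | None = None,
    train_positives=None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each term among the top-k predictions.

    The universe is the set of scored genes; each term's gene set is
    intersected with it.  Output rows are sorted by (FDR, raw p, term)
    with 1-based ranks.  When ``groups`` and ``train_positives`` are
    given, ``pos_ortholog_overlap`` counts the term genes sharing an
    ortholog group with any training positive — zero means the term has
    no ortholog link to the training set (the phenolog case).
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > len(scores):
        raise ValueError(f"top_k={top_k} exceeds the {len(scores)} scored genes")
    universe = set(scores)
    ranked = sorted(universe, key=lambda g: (-scores[g], g))
    top = set(ranked[:top_k])

    partner_of_pos: set = set()
    if groups is not None and train_positives:
        pos = set(train_positives)
        for members in groups.groups.values():
            if any(m in pos for m in members):
                partner_of_pos |= set(members)

    rows = []
    for term in sorted(gsc.terms):
        term_genes = set(gsc.terms[term]) & universe
        if not term_genes:
            continue
        k = len(top & term_genes)
        p = float(hypergeom.sf(k - 1, len(universe), len(term_genes), top_k))
        row = {
            "term": term,
            "name": gsc.name_of(term),
            "n_term_genes": len(term_genes),
            "n_overlap_topk": k,
            "p_value": p,
        }
        if groups is not None and train_positives:
            row["pos_ortholog_overlap"] = len(
                {g for g in gsc.terms[term] if g in partner_of_pos}
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    from statsmodels.stats.multitest import multipletests

    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_threshold
    df = df.sort_values(["fdr", "p_value", "term"]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
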