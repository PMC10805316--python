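"""End-to-end orchestration: fuse -> represent -> split -> train -> evaluate.

A run is described by a single :class:`RunConfig` (serialisable to/from
YAML, unknown keys rejected).  One global seed fans out to per-stage
seeds by stable hashing, so changing one stage's settings does not
perturb another stage's randomness.  Feature matrices are cached on
disk keyed by a hash of everything upstream of them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from zoonet import evalmetrics, genesets, mlpipe, multinet, represent
from zoonet.synthdata import read_pubmed_counts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_within_species_benchmark", "run_cross_species_transfer"]

KNOWN_METHODS = ("adjmat", "rwr", "svd", "n2v")


class RepresentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "n2v"
    dim: int = 500
    p: float = 1.0
    q: float = 1.0
    num_walks: int = 10
    walk_length: int = 80
    window: int = 10
    epochs: int = 1
    alpha: float = 0.85  # rwr restart probability


class RunConfig(BaseModel):
    """All settings of an end-to-end run; every field has a default."""

    model_config = ConfigDict(extra="forbid")

    nets: dict[str, str] = Field(default_factory=dict)  # species -> edge list path
    gene_lists: dict[str, str] = Field(default_factory=dict)  # species -> node list
    orthologs: str = ""
    gmts: dict[str, str] = Field(default_factory=dict)  # species -> GMT path
    ontology: str = ""
    pubmed: str = ""
    species: list[str] = Field(default_factory=list)

    scheme: str = "degree"
    uniform_weight: float = 1.0
    beta: float = 1.0

    representations: list[RepresentationConfig] = Field(
        default_factory=lambda: [RepresentationConfig()]
    )

    min_term_size: int = 10
    max_term_size: int = 200
    overlap_threshold: float = 0.5
    jaccard_threshold: float = 0.5
    nonredundant: bool = False

    train_fraction: float = 2 / 3
    fdr_threshold: float = 0.05
    l2_strength: float = 1.0
    fwer: float = 0.01
    top_k: int = 100
    augment_ortholog_positives: bool = False

    seed: int = 0
    out_dir: str = "zoo_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage sub-seed derived from the global seed."""
        return zlib.crc32(f"{self.seed}:{stage}".encode()) % (2**31)


def _config_hash(cfg: RunConfig, extra: str = "") -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str) + extra
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_world_files(cfg: RunConfig):
    nets = []
    for sp in cfg.species:
        include = None
        if sp in cfg.gene_lists:
            include = [
                ln.strip() for ln in open(cfg.gene_lists[sp]) if ln.strip()
            ]
        nets.append(multinet.load_species_network(cfg.nets[sp], sp, include_genes=include))
    groups = multinet.load_ortholog_groups(cfg.orthologs, allowed_species=set(cfg.species))
    return nets, groups


def _build_features(
    cfg: RunConfig,
    msn: multinet.MultiSpeciesNetwork,
    rep: RepresentationConfig,
    cache_dir: Path | None = None,
    force: bool = False,
) -> represent.FeatureMatrix:
    if rep.method not in KNOWN_METHODS:
        raise ValueError(f"unknown representation {rep.method!r}; choose from {KNOWN_METHODS}")
    key = _config_hash(cfg, extra=json.dumps(rep.model_dump(), sort_keys=True))
    if cache_dir is not None:
        cache_file = cache_dir / f"features_{rep.method}_{key}.npz"
        if cache_file.exists() and not force:
            data = np.load(cache_file, allow_pickle=False)
            gene_index = [tuple(x) for x in data["gene_index"]]
            return represent.FeatureMatrix(
                gene_index=gene_index, values=data["values"],
                method=rep.method, params=rep.model_dump(),
            )
    if rep.method == "adjmat":
        fm = represent.adjacency_features(msn)
    elif rep.method == "rwr":
        fm = represent.rwr_features(msn, alpha=rep.alpha)
    elif rep.method == "svd":
        fm = represent.svd_features(represent.adjacency_features(msn), d=rep.dim)
    else:
        fm = represent.node2vec_features(
            msn, d=rep.dim, p=rep.p, q=rep.q, num_walks=rep.num_walks,
            walk_length=rep.walk_length, window=rep.window, epochs=rep.epochs,
            seed=cfg.stage_seed(f"n2v:{rep.dim}:{rep.p}:{rep.q}"),
        )
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            cache_dir / f"features_{rep.method}_{key}.npz",
            gene_index=np.array(fm.gene_index, dtype=str),
            values=fm.values,
        )
    return fm


def _species_collection(cfg: RunConfig, sp: str, network_genes: set[str]):
    anns, names = genesets.read_gmt(cfg.gmts[sp])
    if cfg.ontology:
        ontology = genesets.read_ontology_table(cfg.ontology)
        anns = genesets.propagate_annotations(anns, ontology)
    gsc = genesets.filter_collection(
        anns, network_genes, cfg.min_term_size, cfg.max_term_size,
        names=names, species_scope=(sp,),
    )
    if cfg.nonredundant and gsc.n_terms:
        sim = genesets.term_similarity_graph(
            gsc, cfg.overlap_threshold, cfg.jaccard_threshold
        )
        gsc = genesets.nonredundant_terms(sim, gsc)
    return gsc


def _completed_splits(cfg: RunConfig, gsc, counts):
    splits = mlpipe.study_bias_split(gsc, counts, train_fraction=cfg.train_fraction)
    return mlpipe.select_negatives(
        splits, gsc, counts, fdr_threshold=cfg.fdr_threshold,
        train_fraction=cfg.train_fraction,
    )


def _namespaced(sp: str, genes) -> frozenset:
    return frozenset((sp, g) for g in genes)


def _write_manifest(cfg: RunConfig, out: Path, stages: dict) -> None:
    manifest = {
        "config": cfg.model_dump(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_within_species_benchmark(cfg: RunConfig) -> Path:
    """Train and evaluate within each species, one classifier per term.

    Writes ``eval.tsv`` (term-level metrics per representation and
    species), ``comparisons.tsv`` (Wilcoxon + Bonferroni table against
    the first configured representation) and ``manifest.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    t0 = time.time()
    nets, groups = _load_world_files(cfg)
    msn = multinet.build_multispecies_network(
        nets, groups, scheme=cfg.scheme,
        uniform_weight=cfg.uniform_weight, beta=cfg.beta,
    )
    counts = read_pubmed_counts(cfg.pubmed) if cfg.pubmed else {}
    stages["fuse_s"] = round(time.time() - t0, 3)

    records = []
    for rep in cfg.representations:
        t0 = time.time()
        fm = _build_features(cfg, msn, rep, cache_dir=out / "cache")
        stages[f"features_{rep.method}_s"] = round(time.time() - t0, 3)
        for sp in cfg.species:
            net = next(n for n in nets if n.species == sp)
            gsc = _species_collection(cfg, sp, set(net.genes))
            if gsc.n_terms == 0:
                logger.warning("species %s: empty collection after filtering", sp)
                continue
            splits = _completed_splits(cfg, gsc, counts)
            for term, split in splits.items():
                model = mlpipe.train_classifier(
                    fm, _namespaced(sp, split.train_pos), _namespaced(sp, split.train_neg),
                    l2_strength=cfg.l2_strength,
                )
                preds = mlpipe.predict_genome(model, fm, target_species=sp)
                scores = {g: s for g, s in zip(preds.index, preds["score"])}
                res = evalmetrics.evaluate_term(
                    term, scores,
                    _namespaced(sp, split.test_pos), _namespaced(sp, split.test_neg),
                )
                records.append(
                    {"representation": rep.method, "species": sp, "term": term,
                     "auprc": res.auprc, "prior": res.prior,
                     "log2_ratio": res.log2_ratio,
                     "n_pos": res.n_pos, "n_neg": res.n_neg}
                )
    eval_df = pd.DataFrame(records)
    eval_df.to_csv(out / "eval.tsv", sep="\t", index=False)

    if len(cfg.representations) > 1 and not eval_df.empty:
        base = cfg.representations[0].method
        paired = {}
        for rep in cfg.representations[1:]:
            merged = eval_df[eval_df.representation == base].merge(
                eval_df[eval_df.representation == rep.method],
                on=["species", "term"], suffixes=("_a", "_b"),
            )
            if len(merged) >= 6:
                paired[f"{rep.method}_vs_{base}"] = (
                    merged["log2_ratio_b"].to_numpy(), merged["log2_ratio_a"].to_numpy()
                )
        if paired:
            evalmetrics.compare_representations(paired, fwer=cfg.fwer).to_csv(
                out / "comparisons.tsv", sep="\t", index=False
            )
    _write_manifest(cfg, out, stages)
    return out


def run_cross_species_transfer(
    cfg: RunConfig, source_species: str, target_species: str
) -> Path:
    """Train on one species' annotations, evaluate on another's.

    Uses the matched non-redundant collection (terms passing the
    >=10/>=10 study-bias rule in both species).  For each matched term,
    a classifier trained on source-species genes is evaluated on every
    target-species term, producing per-term metrics and matched-rank
    tables for each representation.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    nets, groups = _load_world_files(cfg)
    msn = multinet.build_multispecies_network(
        nets, groups, scheme=cfg.scheme,
        uniform_weight=cfg.uniform_weight, beta=cfg.beta,
    )
    counts = read_pubmed_counts(cfg.pubmed) if cfg.pubmed else {}

    net_s = next(n for n in nets if n.species == source_species)
    net_t = next(n for n in nets if n.species == target_species)
    gsc_s = _species_collection(cfg, source_species, set(net_s.genes))
    gsc_t = _species_collection(cfg, target_species, set(net_t.genes))
    splits_s = _completed_splits(cfg, gsc_s, counts)
    splits_t = _completed_splits(cfg, gsc_t, counts)

    matched = genesets.matched_collection(
        gsc_s, gsc_t, splits_s, splits_t, source_species, target_species,
        overlap_threshold=cfg.overlap_threshold,
        jaccard_threshold=cfg.jaccard_threshold,
    )
    if matched.n_terms == 0:
        raise ValueError(
            f"no matched terms between {source_species} and {target_species}"
        )

    records = []
    for rep in cfg.representations:
        fm = _build_features(cfg, msn, rep, cache_dir=out / "cache")
        term_metrics: dict[str, float] = {}
        for term in sorted(matched.terms):
            split_s = splits_s[term]
            train_pos = _namespaced(source_species, split_s.train_pos | split_s.test_pos)
            train_neg = _namespaced(source_species, split_s.train_neg | split_s.test_neg)
            if cfg.augment_ortholog_positives:
                train_pos = mlpipe.add_ortholog_positives(
                    train_pos, groups, (source_species, target_species)
                )
                train_neg = train_neg - train_pos
            model = mlpipe.train_classifier(fm, train_pos, train_neg,
                                            l2_strength=cfg.l2_strength)
            preds = mlpipe.predict_genome(model, fm, target_species=target_species)
            scores = {g: s for g, s in zip(preds.index, preds["score"])}
            # evaluate this classifier against every target-species term
            per_term = {}
            for other in sorted(matched.terms):
                sp_t = splits_t[other]
                res = evalmetrics.evaluate_term(
                    other, scores,
                    _namespaced(target_species, sp_t.test_pos),
                    _namespaced(target_species, sp_t.test_neg),
                )
                per_term[other] = res.log2_ratio
            rank = evalmetrics.matched_rank(per_term[term], list(per_term.values()))
            term_metrics[term] = per_term[term]
            records.append(
                {"representation": rep.method, "term": term,
                 "log2_ratio": per_term[term], "matched_rank": rank,
                 "n_terms": len(per_term)}
            )
    df = pd.DataFrame(records)
    df.to_csv(out / "transfer_eval.tsv", sep="\t", index=False)
    (
        df.groupby("representation")
        .agg(median_log2_ratio=("log2_ratio", "median"),
             median_matched_rank=("matched_rank", "median"))
        .reset_index()
        .to_csv(out / "transfer_summary.tsv", sep="\t", index=False)
    )
    _write_manifest(cfg, out, stages)
    return out
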