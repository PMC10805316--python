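"""Seeded synthetic multi-species worlds for end-to-end testing.

Each world emulates the statistical structure the evaluation protocol
assumes: per-species planted-partition (stochastic block model)
networks whose dense blocks are conserved functional modules, ortholog
groups of mixed cardinality linking matched modules across species,
annotations derived from module membership with configurable noise, and
heavy-tailed (discretised log-normal) publication counts that make
study-bias splits meaningful.

A special scenario builds "phenolog" worlds: matched modules whose
*annotated* gene subsets share zero ortholog groups across species while
the unannotated module remainder stays cross-linked, so any cross-
species signal must travel through the network rather than direct
orthology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from zoonet.genesets import write_gmt
from zoonet.multinet import OrthologGroupTable, SpeciesNetwork

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "world_to_inputs",
    "make_disjoint_ortholog_scenario",
    "TRANSFER_SMALL",
]


@dataclass(frozen=True)
class WorldConfig:
    """Generator settings; the defaults define the benchmark conditions."""

    species: tuple[str, ...] = ("spA", "spB")
    genes_per_species: int = 300
    n_modules: int = 6
    module_size_range: tuple[int, int] = (30, 40)
    p_in: float = 0.5
    p_out: float = 0.01
    matched_fraction: float = 1.0
    # (one-to-one, one-to-two, two-to-two) ortholog-group cardinality mix
    cardinality_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    # fraction of each matched module's genes that carry cross-species orthologs;
    # coverage is partial in real ortholog databases (high for close species
    # pairs, low for distant ones)
    ortholog_coverage: float = 0.5
    # fraction of module ortholog groups whose partner genes are functionally
    # divergent (rewired to an arbitrary gene of the other species); orthology
    # is a sequence relationship and does not guarantee conserved function
    ortholog_mismatch_rate: float = 0.2
    background_ortholog_rate: float = 0.3
    annotation_noise: float = 0.1
    pubmed_mu: float = 3.0
    pubmed_sigma: float = 1.5

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if not (0 < lo <= hi):
            raise ValueError("bad module_size_range")
        if self.n_modules * hi > self.genes_per_species:
            raise ValueError(
                f"{self.n_modules} modules of up to {hi} genes exceed "
                f"{self.genes_per_species} genes per species"
            )
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        for frac in (self.matched_fraction, self.annotation_noise,
                     self.background_ortholog_rate, self.ortholog_coverage,
                     self.ortholog_mismatch_rate, *self.cardinality_mix):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.cardinality_mix) - 1.0) > 1e-9:
            raise ValueError("cardinality_mix must sum to 1")


# study conditions of the desk-scale transfer benchmark
TRANSFER_SMALL = WorldConfig()


@dataclass
class SyntheticWorld:
    """Ground-truth record of a generated world."""

    config: WorldConfig
    seed: int
    networks: dict[str, SpeciesNetwork]
    groups: OrthologGroupTable
    truth: dict[str, dict[str, frozenset[str]]]  # module -> species -> genes
    annotations: dict[str, dict[str, set[str]]]  # species -> term -> genes
    pubmed_counts: dict[str, int]
    annotated_truth: dict[str, dict[str, frozenset[str]]] | None = None

    @property
    def terms(self) -> list[str]:
        return sorted(self.truth)


def _sample_edges(genes: list[str], membership: dict[str, str], p_in: float,
                  p_out: float, rng: np.random.Generator) -> dict:
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mods = np.array([membership.get(g, "") for g in genes])
    same = (mods[iu] == mods[ju]) & (mods[iu] != "")
    probs = np.where(same, p_in, p_out)
    mask = rng.random(iu.size) < probs
    return {(genes[i], genes[j]): 1.0 for i, j in zip(iu[mask], ju[mask])}


def _link_modules(
    a_genes: list[str],
    b_genes: list[str],
    sp_a: str,
    sp_b: str,
    mix: tuple[float, float, float],
    rng: np.random.Generator,
    prefix: str,
) -> dict[str, frozenset]:
    """Ortholog groups pairing two matched module gene lists."""
    groups: dict[str, frozenset] = {}
    a_pool = list(a_genes)
    b_pool = list(b_genes)
    rng.shuffle(a_pool)
    rng.shuffle(b_pool)
    gid = 0
    while a_pool and b_pool:
        kind = rng.choice(3, p=mix)
        n_a = 2 if kind == 2 else 1
        n_b = 1 if kind == 0 else 2
        n_a = min(n_a, len(a_pool))
        n_b = min(n_b, len(b_pool))
        members = {(sp_a, a_pool.pop()) for _ in range(n_a)}
        members |= {(sp_b, b_pool.pop()) for _ in range(n_b)}
        groups[f"{prefix}_{gid:03d}"] = frozenset(members)
        gid += 1
    return groups


def _annotate(
    truth_genes: frozenset[str],
    all_genes: list[str],
    noise: float,
    rng: np.random.Generator,
) -> set[str]:
    kept = {g for g in sorted(truth_genes) if rng.random() >= noise}
    n_add = int(round(noise * len(truth_genes)))
    outside = sorted(set(all_genes) - truth_genes)
    if n_add and outside:
        kept |= set(rng.choice(outside, size=min(n_add, len(outside)), replace=False))
    return kept or set(sorted(truth_genes)[:1])


def generate_world(config: WorldConfig = TRANSFER_SMALL, seed: int = 0) -> SyntheticWorld:
    """Generate a seeded synthetic world; identical (config, seed) -> identical world."""
    config.validate()
    rng = np.random.default_rng(seed)
    lo, hi = config.module_size_range

    networks: dict[str, SpeciesNetwork] = {}
    truth: dict[str, dict[str, frozenset[str]]] = {}
    annotations: dict[str, dict[str, set[str]]] = {}
    membership_by_sp: dict[str, dict[str, str]] = {}
    genes_by_sp: dict[str, list[str]] = {}

    n_matched = int(round(config.matched_fraction * config.n_modules))
    module_ids = [f"M{m:02d}" for m in range(config.n_modules)]
    # one size per module per species, drawn up-front for determinism
    sizes = {
        (sp, m): int(rng.integers(lo, hi + 1))
        for m in module_ids
        for sp in config.species
    }

    for sp in config.species:
        genes = [f"{sp}{i:04d}" for i in range(config.genes_per_species)]
        genes_by_sp[sp] = genes
        membership: dict[str, str] = {}
        cursor = 0
        for m in module_ids:
            size = sizes[(sp, m)]
            for g in genes[cursor : cursor + size]:
                membership[g] = m
            cursor += size
        membership_by_sp[sp] = membership
        for m in module_ids:
            truth.setdefault(m, {})[sp] = frozenset(
                g for g, mod in membership.items() if mod == m
            )
        edges = _sample_edges(genes, membership, config.p_in, config.p_out, rng)
        networks[sp] = SpeciesNetwork(species=sp, genes=tuple(genes), edges=edges)
        annotations[sp] = {
            m: _annotate(truth[m][sp], genes, config.annotation_noise, rng)
            for m in module_ids
        }

    groups: dict[str, frozenset] = {}
    for pi in range(len(config.species)):
        for pj in range(pi + 1, len(config.species)):
            sp_a, sp_b = config.species[pi], config.species[pj]
            for m in module_ids[:n_matched]:
                covered = {}
                for sp_x in (sp_a, sp_b):
                    pool = sorted(truth[m][sp_x])
                    n_cov = max(1, int(round(config.ortholog_coverage * len(pool))))
                    covered[sp_x] = sorted(
                        rng.choice(pool, size=n_cov, replace=False)
                    )
                linked = _link_modules(
                    covered[sp_a],
                    covered[sp_b],
                    sp_a,
                    sp_b,
                    config.cardinality_mix,
                    rng,
                    prefix=f"OG_{m}_{sp_a}{sp_b}",
                )
                # functionally divergent orthologs: rewire some groups'
                # partner side to arbitrary genes of the other species
                # (always keeping at least one conserved group per module)
                for k, gid in enumerate(sorted(linked)):
                    if k == 0 or rng.random() >= config.ortholog_mismatch_rate:
                        continue
                    mem = linked[gid]
                    a_side = {x for x in mem if x[0] == sp_a}
                    n_b = len(mem) - len(a_side)
                    random_b = rng.choice(genes_by_sp[sp_b], size=n_b, replace=False)
                    linked[gid] = frozenset(a_side | {(sp_b, g) for g in random_b})
                groups.update(linked)
            # sparse one-to-one links among background genes
            bg_a = sorted(set(genes_by_sp[sp_a]) - set(membership_by_sp[sp_a]))
            bg_b = sorted(set(genes_by_sp[sp_b]) - set(membership_by_sp[sp_b]))
            rng.shuffle(bg_a)
            rng.shuffle(bg_b)
            n_bg = int(config.background_ortholog_rate * min(len(bg_a), len(bg_b)))
            for k in range(n_bg):
                groups[f"OG_bg_{sp_a}{sp_b}_{k:04d}"] = frozenset(
                    {(sp_a, bg_a[k]), (sp_b, bg_b[k])}
                )

    counts: dict[str, int] = {}
    for sp in config.species:
        draws = rng.lognormal(config.pubmed_mu, config.pubmed_sigma,
                              size=config.genes_per_species)
        for g, c in zip(genes_by_sp[sp], draws):
            counts[g] = int(c)

    return SyntheticWorld(
        config=config,
        seed=seed,
        networks=networks,
        groups=OrthologGroupTable(groups=groups),
        truth=truth,
        annotations=annotations,
        pubmed_counts=counts,
    )


def make_disjoint_ortholog_scenario(
    config: WorldConfig | None = None,
    seed: int = 0,
) -> SyntheticWorld:
    """World where matched modules' annotated subsets share no orthologs.

    Each matched module's genes are split per species into an annotated
    half and an unannotated half; ortholog groups connect only the
    unannotated halves, while annotations cover only the annotated
    halves.  Cross-species signal between the annotated sets must
    therefore flow through within-species edges and the unannotated
    bridge genes — the phenolog situation.
    """
    if config is None:
        # noise-free: the construction's point is controlled ortholog
        # disjointness between the annotated subsets
        config = WorldConfig(
            genes_per_species=500, n_modules=10, module_size_range=(30, 40),
            annotation_noise=0.0,
        )
    config.validate()
    if config.module_size_range[0] < 4:
        raise ValueError("modules too small to partition into annotated/unannotated halves")
    world = generate_world(config, seed)
    rng = np.random.default_rng(seed + 1)

    ann_half: dict[str, dict[str, frozenset[str]]] = {}
    unann_half: dict[str, dict[str, frozenset[str]]] = {}
    for m in world.terms:
        ann_half[m] = {}
        unann_half[m] = {}
        for sp in config.species:
            genes = sorted(world.truth[m][sp])
            rng.shuffle(genes)
            half = len(genes) // 2
            ann_half[m][sp] = frozenset(genes[:half])
            unann_half[m][sp] = frozenset(genes[half:])

    # rebuild module ortholog groups on the unannotated halves only
    groups = {
        gid: mem
        for gid, mem in world.groups.groups.items()
        if gid.startswith("OG_bg_")
    }
    n_matched = int(round(config.matched_fraction * config.n_modules))
    for pi in range(len(config.species)):
        for pj in range(pi + 1, len(config.species)):
            sp_a, sp_b = config.species[pi], config.species[pj]
            for m in world.terms[:n_matched]:
                groups.update(
                    _link_modules(
                        sorted(unann_half[m][sp_a]),
                        sorted(unann_half[m][sp_b]),
                        sp_a,
                        sp_b,
                        config.cardinality_mix,
                        rng,
                        prefix=f"OG_{m}_{sp_a}{sp_b}",
                    )
                )

    annotations = {
        sp: {
            m: _annotate(ann_half[m][sp], sorted(world.networks[sp].genes),
                         config.annotation_noise, rng)
            for m in world.terms
        }
        for sp in config.species
    }
    return SyntheticWorld(
        config=config,
        seed=seed,
        networks=world.networks,
        groups=OrthologGroupTable(groups=groups),
        truth=world.truth,
        annotations=annotations,
        pubmed_counts=world.pubmed_counts,
        annotated_truth=ann_half,
    )


def world_to_inputs(world: SyntheticWorld, out_dir) -> dict[str, Path]:
    """Write the world as the file dialects the loader functions read.

    Emits per-species edge lists, the ortholog table, per-species GMT
    annotation files, a (flat) ontology table, the publication-count
    table and a ground-truth JSON.  Loading these files reproduces the
    in-memory world.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for sp, net in world.networks.items():
        p = out / f"{sp}_edges.tsv"
        with open(p, "w") as fh:
            fh.write("# geneA\tgeneB\tweight\n")
            for (a, b), w in sorted(net.edges.items()):
                fh.write(f"{a}\t{b}\t{w}\n")
        paths[f"net_{sp}"] = p
        # genes with no edges still need to exist downstream
        gp = out / f"{sp}_genes.txt"
        gp.write_text("".join(f"{g}\n" for g in net.genes))
        paths[f"genes_{sp}"] = gp

    p = out / "orthologs.tsv"
    with open(p, "w") as fh:
        for gid in sorted(world.groups.groups):
            for spp, gene in sorted(world.groups.groups[gid]):
                fh.write(f"{gid}\t{spp}\t{gene}\n")
    paths["orthologs"] = p

    for sp, anns in world.annotations.items():
        p = out / f"{sp}_annotations.gmt"
        write_gmt(anns, p)
        paths[f"gmt_{sp}"] = p

    p = out / "ontology.tsv"
    p.write_text("# child\tparent (flat ontology: no rows)\n")
    paths["ontology"] = p

    p = out / "pubmed_counts.tsv"
    with open(p, "w") as fh:
        for g in sorted(world.pubmed_counts):
            fh.write(f"{g}\t{world.pubmed_counts[g]}\n")
    paths["pubmed"] = p

    p = out / "truth.json"
    payload = {
        "config": asdict(world.config),
        "seed": world.seed,
        "modules": {
            m: {sp: sorted(genes) for sp, genes in per_sp.items()}
            for m, per_sp in world.truth.items()
        },
    }
    if world.annotated_truth is not None:
        payload["annotated_subsets"] = {
            m: {sp: sorted(genes) for sp, genes in per_sp.items()}
            for m, per_sp in world.annotated_truth.items()
        }
    p.write_text(json.dumps(payload, indent=2))
    paths["truth"] = p
    return paths


def read_pubmed_counts(path) -> dict[str, int]:
    """Read a gene <TAB> count table."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            gene, count = line.split("\t")[:2]
            out[gene] = int(count)
    return out
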