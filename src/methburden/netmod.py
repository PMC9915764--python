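"""PPI subnetworks enriched for differential promoter methylation.

Functional-epigenetic-module-style analysis: each gene receives a signed
statistic from its promoter CpGs (TSS200/TSS1500), modules are grown
greedily on a protein-protein interaction graph from the most
differentially methylated seed genes, and module significance comes from
permuting the gene statistics over the fixed topology.  A module's (or any
pathway's) direction is summarized by the AUROC of its member genes
against the genome-wide ranking by signed -log10(p): below 0.5 the set
concentrates at the hypomethylated end, above 0.5 at the hypermethylated
end.  Gene-set enrichment of module members uses the hypergeometric
upper tail with BH correction, restricted to sets within size bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffmeth import bh_adjust
from .synthdata import PROMOTER_FEATURES

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-level promoter statistics
# ---------------------------------------------------------------------------

def gene_promoter_stats(dmp: pd.DataFrame,
                        annotation: pd.DataFrame) -> pd.DataFrame:
    """Signed gene-level statistics from promoter CpGs.

    The gene statistic is the signed -log10(p) of the promoter CpG with
    the smallest p-value (direction from its delta-beta) — averaging
    signed statistics would cancel opposite-direction CpGs — and the mean
    promoter delta-beta is reported alongside.  Genes without promoter
    CpGs are omitted.
    """
    ann = annotation.reindex(dmp.index)
    promoter = ann["feature"].isin(PROMOTER_FEATURES) & \
        (ann["gene"].astype(str) != "")
    if not promoter.any():
        raise ValueError("no promoter-annotated probes in the DMP table")
    sub = dmp.loc[promoter.to_numpy()].copy()
    sub["gene"] = ann.loc[promoter, "gene"].to_numpy()
    sub.index.name = "probe_id"
    sub = sub.reset_index().sort_values(["p", "probe_id"], kind="mergesort")
    best = sub.groupby("gene", sort=True).first()
    p = np.clip(best["p"].to_numpy(float), 1e-300, 1.0)
    stat = -np.log10(p) * np.sign(best["delta_beta"].to_numpy())
    counts = sub.groupby("gene").size()
    mean_delta = sub.groupby("gene")["delta_beta"].mean()
    out = pd.DataFrame({
        "promoter_stat": stat,
        "n_promoter_cpgs": counts.loc[best.index].to_numpy(),
        "mean_promoter_delta": mean_delta.loc[best.index].to_numpy(),
        "best_probe": best["probe_id"].to_numpy(),
    }, index=best.index)
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# greedy module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleResult:
    seed: str
    members: list
    score: float
    p: float
    auroc: float
    n_perm: int


def _module_score(members: set, abs_stat: dict, graph: nx.Graph) -> float:
    """Induced edge weight per member gene.

    Edge weight is the mean absolute statistic of its endpoints; the score
    is the total weight of the module-induced edges divided by the number
    of members.  Densely connected, coherently hot neighborhoods raise it;
    sparsely attached or cold genes lower it.  Singletons score 0 (no
    induced edges), so a seed always absorbs its best neighbor first.
    """
    total = 0.0
    for u, v in graph.subgraph(members).edges():
        total += 0.5 * (abs_stat[u] + abs_stat[v])
    return total / len(members)


def _grow_module(seed: str, abs_stat: dict, graph: nx.Graph,
                 max_size: int) -> tuple[set, float]:
    """Greedy expansion from a seed: repeatedly add the neighboring gene
    that maximizes the module score, while the score strictly improves."""
    members = {seed}
    score = _module_score(members, abs_stat, graph)
    # incremental bookkeeping: total induced edge weight
    total_w = score * len(members)
    while len(members) < max_size:
        candidates = set()
        for g in members:
            candidates.update(graph.neighbors(g))
        candidates -= members
        if not candidates:
            break
        best_gene, best_score = None, -np.inf
        for g in sorted(candidates):  # sorted: deterministic tie-break
            add_w = sum(0.5 * (abs_stat[g] + abs_stat[nb])
                        for nb in graph.neighbors(g) if nb in members)
            s = (total_w + add_w) / (len(members) + 1)
            if s > best_score:
                best_gene, best_score = g, s
        if best_score > score:
            add_w = sum(0.5 * (abs_stat[best_gene] + abs_stat[nb])
                        for nb in graph.neighbors(best_gene) if nb in members)
            total_w += add_w
            members.add(best_gene)
            score = best_score
        else:
            break
    return members, score


def detect_subnetworks(gene_stats: pd.DataFrame, ppi: nx.Graph,
                       max_seeds: int = 10, max_size: int = 100,
                       n_perm: int = 1000, seed: int = 0,
                       merge_jaccard: float = 0.5,
                       min_overlap: int = 50) -> list[ModuleResult]:
    """Greedy detection of differentially methylated PPI modules.

    Seeds are the top genes by |promoter statistic| not absorbed by an
    earlier module; each module grows by adding the neighboring gene that
    maximizes the module's mean edge weight while it improves, up to
    ``max_size``.  Significance: the gene statistics are permuted over the
    fixed topology and the greedy growth is re-run from the same seed, so
    the null accounts for the selection of the module; p carries the +1
    correction.  Modules overlapping at Jaccard > ``merge_jaccard`` are
    merged.  Each module's direction is its members' AUROC against the
    signed-statistic ranking.
    """
    stats_ = gene_stats["promoter_stat"]
    common = [g for g in stats_.index if g in ppi]
    if len(common) < min_overlap:
        raise ValueError(f"only {len(common)} genes overlap the PPI network; "
                         f"need at least {min_overlap}")
    graph = ppi.subgraph(common).copy()
    values = stats_.loc[common].to_numpy(float)
    abs_stat = dict(zip(common, np.abs(values)))

    order = sorted(common, key=lambda g: (-abs_stat[g], g))
    rng = np.random.default_rng(seed)
    modules: list[ModuleResult] = []
    module_rank: list[int] = []
    absorbed: set = set()
    abs_values = np.abs(values)
    for g in order:
        if len(modules) >= max_seeds:
            break
        if g in absorbed:
            continue
        if graph.degree(g) == 0:
            log.info("seed %s has no PPI neighbors; skipped", g)
            continue
        members, score = _grow_module(g, abs_stat, graph, max_size)
        modules.append(ModuleResult(seed=g, members=sorted(members),
                                    score=float(score), p=np.nan, auroc=np.nan,
                                    n_perm=n_perm))
        module_rank.append(len(modules) - 1)
        absorbed |= members

    # permutation null: stats are shuffled over the fixed topology and the
    # seed is RE-SELECTED at the same rank, so the null reflects both the
    # greedy growth and the choice of the seed as a top-|stat| gene
    if modules:
        eligible = [g for g in common if graph.degree(g) > 0]
        n_ranks = len(modules)
        null = np.empty((n_perm, n_ranks))
        for i in range(n_perm):
            perm_vals = rng.permutation(abs_values)
            perm = dict(zip(common, perm_vals))
            perm_order = sorted(eligible, key=lambda g: (-perm[g], g))
            for r in range(n_ranks):
                _, null[i, r] = _grow_module(perm_order[r], perm, graph,
                                             max_size)
        for r, mod in enumerate(modules):
            mod.p = float((1 + (null[:, r] >= mod.score).sum())
                          / (n_perm + 1))
            mod.auroc = auroc_direction(mod.members, gene_stats.loc[common])

    # merge heavily overlapping modules
    merged: list[ModuleResult] = []
    for mod in modules:
        target = None
        for m in merged:
            inter = len(set(mod.members) & set(m.members))
            union = len(set(mod.members) | set(m.members))
            if union and inter / union > merge_jaccard:
                target = m
                break
        if target is None:
            merged.append(mod)
        else:
            members = sorted(set(target.members) | set(mod.members))
            target.members = members
            target.score = _module_score(set(members), abs_stat, graph)
            target.p = min(target.p, mod.p)
            target.auroc = auroc_direction(members, gene_stats.loc[common])
    return merged


# ---------------------------------------------------------------------------
# AUROC direction
# ---------------------------------------------------------------------------

def auroc_direction(member_genes, gene_stats: pd.DataFrame) -> float:
    """AUROC of a gene set against the signed-statistic ranking.

    Genes are ranked from the most significant negative (hypomethylated)
    to the most significant positive statistic, ties broken by gene id;
    the AUROC is the normalized Mann-Whitney U of the member ranks.  Below
    0.5 the set sits at the hypomethylated end.
    """
    stats_ = gene_stats["promoter_stat"]
    members = [g for g in set(member_genes) if g in stats_.index]
    if not members:
        raise ValueError("gene set does not overlap the ranked gene list")
    n_m = len(members)
    n_other = len(stats_) - n_m
    if n_other == 0:
        raise ValueError("gene set covers the whole ranked list")
    order = sorted(stats_.index, key=lambda g: (stats_[g], g))
    rank = {g: i + 1 for i, g in enumerate(order)}  # 1 = most negative
    rank_sum = sum(rank[g] for g in members)
    u = rank_sum - n_m * (n_m + 1) / 2
    return float(u / (n_m * n_other))


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def geneset_enrichment(query, genesets: dict, universe,
                       min_size: int = 10, max_size: int = 500
                       ) -> tuple[pd.DataFrame, list]:
    """Hypergeometric enrichment of a query gene set in GMT gene sets.

    Sets are restricted to the universe; sets whose restricted size falls
    outside [min_size, max_size] are skipped and reported.  p is the
    hypergeometric upper tail of the overlap; BH across the tested sets.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValueError("query gene set is empty (within the universe)")
    n_u = len(universe)
    n_q = len(query)
    rows = []
    skipped = []
    for name in sorted(genesets):
        members = set(genesets[name]) & universe
        k = len(members)
        if k < min_size or k > max_size:
            skipped.append(name)
            continue
        a = len(query & members)
        p = float(hypergeom.sf(a - 1, n_u, k, n_q))
        rows.append(dict(geneset=name, set_size=k, overlap=a,
                         expected=n_q * k / n_u, p=p))
    table = pd.DataFrame(rows, columns=["geneset", "set_size", "overlap",
                                        "expected", "p"])
    if len(table):
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["p", "geneset"],
                                  kind="mergesort").reset_index(drop=True)
    else:
        table["adj_p"] = pd.Series(dtype=float)
    return table, skipped
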