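"""Integration of DMPs with meQTLs, expression correlations and GWAS.

DMPs passing an inclusive threshold (p < 1e-4, chosen to feed enrichment
analyses that need more loci) are joined to a pre-filtered reproducible
meQTL table to form SNP-DMP pairs (SDPs), and to a CpG-gene expression
correlation table (GCPs) to form DMP-gene pairs (DGPs); CpGs present in
both define SNP-DMP-gene triads.  Enrichment of GWAS risk variants around
SDP CpGs is assessed by a permutation window test: the fraction of SDP
SNPs whose CpG window (+/- 200 kb by default, closed interval, same
chromosome) contains a genome-wide-significant GWAS SNP is compared with
the same statistic over random same-size SNP sets drawn from the meQTL
background pool (matched on MAF decile when MAF is supplied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GWAS_SIG = 5e-8
DMP_P_THRESHOLD = 1e-4


def _significant_dmps(dmps: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    return dmps[dmps["p"] < p_threshold]


def map_sdp(dmps: pd.DataFrame, meqtl: pd.DataFrame,
            p_threshold: float = DMP_P_THRESHOLD
            ) -> tuple[pd.DataFrame, dict]:
    """SNP-DMP pairs: inner join of sub-threshold DMPs with the meQTL table.

    Returns the pair table plus a summary (number of pairs, unique CpGs
    and SNPs, and the fraction of threshold-passing DMPs under genetic
    control).
    """
    sig = _significant_dmps(dmps, p_threshold)
    sdp = meqtl.merge(
        sig[["delta_beta", "p"]].rename(
            columns={"delta_beta": "dmp_delta_beta", "p": "dmp_p"}),
        left_on="probe_id", right_index=True, how="inner")
    n_dmps = len(sig)
    n_cpgs = sdp["probe_id"].nunique() if len(sdp) else 0
    summary = dict(
        n_pairs=int(len(sdp)),
        n_cpgs=int(n_cpgs),
        n_snps=int(sdp["snp_id"].nunique()) if len(sdp) else 0,
        n_dmps=int(n_dmps),
        frac_under_genetic_control=float(n_cpgs / n_dmps) if n_dmps else 0.0,
    )
    return sdp.reset_index(drop=True), summary


def map_dgp(dmps: pd.DataFrame, gcp: pd.DataFrame,
            p_threshold: float = DMP_P_THRESHOLD) -> pd.DataFrame:
    """DMP-gene pairs with direction-consistency annotation.

    Each DGP is classified negative/positive by the methylation-expression
    correlation sign, and annotated for concordance between the DMP's
    methylation direction, the correlation sign, and the supplied
    differential-expression status: the expected expression direction is
    sign(correlation) x sign(delta-beta) (e.g. a hypomethylated DMP with a
    positive correlation predicts the gene down), and the pair is
    ``consistent`` when the observed DEG status matches, ``inconsistent``
    when it contradicts, and ``na`` when no DEG call is available.
    """
    sig = _significant_dmps(dmps, p_threshold)
    dgp = gcp.merge(
        sig[["delta_beta", "p"]].rename(
            columns={"delta_beta": "dmp_delta_beta", "p": "dmp_p"}),
        left_on="probe_id", right_index=True, how="inner")
    if len(dgp) == 0:
        dgp["dgp_class"] = pd.Series(dtype=object)
        dgp["consistency"] = pd.Series(dtype=object)
        return dgp.reset_index(drop=True)
    if "corr_sign" in dgp.columns:
        corr_sign = np.where(dgp["corr_sign"].astype(str) == "positive",
                             1, -1)
    else:
        corr_sign = np.where(dgp["correlation"] > 0, 1, -1)
    dgp["dgp_class"] = np.where(corr_sign > 0, "positive", "negative")
    meth_dir = np.sign(dgp["dmp_delta_beta"].to_numpy())
    expected = corr_sign * meth_dir  # +1 -> gene up, -1 -> gene down
    expected_lbl = np.where(expected > 0, "up", "down")
    if "deg_status" in dgp:
        deg = dgp["deg_status"].astype(str).to_numpy()
        dgp["consistency"] = np.where(
            np.isin(deg, ["up", "down"]),
            np.where(deg == expected_lbl, "consistent", "inconsistent"),
            "na")
    else:
        dgp["consistency"] = "na"
    dgp["expected_expression"] = expected_lbl
    return dgp.reset_index(drop=True)


@dataclass
class TriadRecord:
    probe_id: str
    gene: str
    snp_ids: list
    snp_signs: list
    dgp_class: str


def triad_link(sdp: pd.DataFrame, dgp: pd.DataFrame) -> pd.DataFrame:
    """SNP-DMP-gene triads: CpGs present in both tables, one record per
    (probe, gene) with all linked SNPs aggregated."""
    if len(sdp) == 0 or len(dgp) == 0:
        return pd.DataFrame(columns=["probe_id", "gene", "snp_ids",
                                     "snp_signs", "n_snps", "dgp_class"])
    common = set(sdp["probe_id"]) & set(dgp["probe_id"])
    rows = []
    snp_by_probe = sdp[sdp["probe_id"].isin(common)].groupby("probe_id")
    for _, g in dgp[dgp["probe_id"].isin(common)].iterrows():
        snps = snp_by_probe.get_group(g["probe_id"])
        rows.append(dict(
            probe_id=g["probe_id"], gene=g["gene"],
            snp_ids=sorted(snps["snp_id"].tolist()),
            snp_signs=snps.set_index("snp_id").loc[
                sorted(snps["snp_id"])]["effect_sign"].tolist()
            if "effect_sign" in snps else [],
            n_snps=int(snps["snp_id"].nunique()),
            dgp_class=g.get("dgp_class", ""),
        ))
    return pd.DataFrame(rows)


@dataclass
class GwasEnrichment:
    fold: float
    p: float
    observed: float
    null_mean: float
    window_bp: int
    n_permutations: int
    n_sdp_snps: int


def _window_hits(meqtl: pd.DataFrame, gwas_sig: pd.DataFrame,
                 window: int) -> pd.Series:
    """Per-SNP indicator: does any of the SNP's CpG windows contain a
    genome-wide significant GWAS SNP?  Windows are closed intervals
    [pos - window, pos + window] on the CpG's chromosome."""
    hit_by_pair = np.zeros(len(meqtl), dtype=bool)
    if len(gwas_sig):
        for chrom, grp in meqtl.groupby(meqtl["cpg_chrom"].astype(str)):
            sig_bp = np.sort(gwas_sig.loc[
                gwas_sig["CHR"].astype(str) == chrom, "BP"].to_numpy())
            if len(sig_bp) == 0:
                continue
            lo = grp["cpg_pos"].to_numpy() - window
            hi = grp["cpg_pos"].to_numpy() + window
            n_in = np.searchsorted(sig_bp, hi, side="right") \
                - np.searchsorted(sig_bp, lo, side="left")
            hit_by_pair[meqtl.index.get_indexer(grp.index)] = n_in > 0
    return pd.Series(hit_by_pair, index=meqtl.index).groupby(
        meqtl["snp_id"]).any()


def gwas_window_enrichment(sdp_snps, all_meqtl: pd.DataFrame,
                           gwas: pd.DataFrame, annotation: pd.DataFrame,
                           window: int = 200_000, n_perm: int = 1000,
                           seed: int = 0,
                           snp_maf: pd.Series | None = None
                           ) -> GwasEnrichment:
    """Permutation window test for GWAS enrichment of SDP SNPs.

    ``sdp_snps`` is the set of SNP ids in the SDPs; ``all_meqtl`` is the
    background pool (every reproducible meQTL pair).  The observed
    statistic is the fraction of SDP SNPs whose CpG window contains a
    GWAS-significant SNP (p < 5e-8); the null re-draws same-size SNP sets
    from the background pool (MAF-decile matched when ``snp_maf`` is
    given).  fold = observed / mean(null); the empirical p carries the +1
    correction so it is never zero.
    """
    sdp_snps = sorted(set(sdp_snps))
    pool_snps = sorted(set(all_meqtl["snp_id"]))
    if len(sdp_snps) > len(pool_snps):
        raise ValueError("background SNP pool is smaller than the SDP set")
    if not set(sdp_snps) <= set(pool_snps):
        raise ValueError("SDP SNPs must come from the meQTL background pool")

    pairs = all_meqtl.copy().reset_index(drop=True)
    ann = annotation.loc[pairs["probe_id"]]
    pairs["cpg_chrom"] = ann["chrom"].to_numpy()
    pairs["cpg_pos"] = ann["pos"].to_numpy()

    gwas_sig = gwas[gwas["P"] < GWAS_SIG]
    hits = _window_hits(pairs, gwas_sig, window)  # indexed by snp_id
    if len(gwas_sig) == 0 or not hits.any():
        warnings.warn("no GWAS-significant SNP falls in any window; "
                      "returning fold=1, p=1")
        return GwasEnrichment(fold=1.0, p=1.0, observed=0.0, null_mean=0.0,
                              window_bp=window, n_permutations=n_perm,
                              n_sdp_snps=len(sdp_snps))

    observed = float(hits.loc[sdp_snps].mean())
    rng = np.random.default_rng(seed)
    k = len(sdp_snps)

    if snp_maf is not None:
        maf = snp_maf.reindex(pool_snps)
        deciles = pd.qcut(maf, 10, labels=False, duplicates="drop")
        target = deciles.reindex(sdp_snps)
        groups = {d: np.array([s for s in pool_snps if deciles[s] == d])
                  for d in target.dropna().unique()}
        counts = target.value_counts()

        def draw():
            picked = []
            for d, c in counts.items():
                picked.append(rng.choice(groups[d], size=int(c),
                                         replace=False))
            return np.concatenate(picked)
    else:
        pool_arr = np.array(pool_snps)

        def draw():
            return rng.choice(pool_arr, size=k, replace=False)

    hit_map = hits.to_dict()
    null = np.empty(n_perm)
    for i in range(n_perm):
        sel = draw()
        null[i] = np.mean([hit_map[s] for s in sel])
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else \
        (1.0 if observed == 0 else np.inf)
    p = float((1 + (null >= observed).sum()) / (n_perm + 1))
    return GwasEnrichment(fold=float(fold), p=p, observed=observed,
                          null_mean=null_mean, window_bp=window,
                          n_permutations=n_perm, n_sdp_snps=k)
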