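"""Integrate DMPs with meQTLs, expression pairs and GWAS signals.

Joins the sub-threshold (p < 1e-4) sex-stratified DMPs to the meQTL
table (SNP-DMP pairs), to the CpG-gene expression table (DMP-gene
pairs), intersects them into SNP-DMP-gene triads, and tests GWAS
enrichment of the SDP SNPs with the permutation window test.
"""

import argparse
import json
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from methburden import regulatory as rg


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", default="results/sim", type=Path)
    ap.add_argument("--dmp", default="results/dmp", type=Path)
    ap.add_argument("--out", default="results/regulatory", type=Path)
    ap.add_argument("--window", default=200_000, type=int)
    ap.add_argument("--n-perm", default=1000, type=int)
    ap.add_argument("--seed", default=1, type=int)
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    res_dir = args.sim / "resources"
    meqtl = pd.read_csv(res_dir / "meqtl.tsv", sep="\t",
                        dtype={"snp_chrom": str})
    gcp = pd.read_csv(res_dir / "gcp.tsv", sep="\t")
    gwas = pd.read_csv(res_dir / "gwas.tsv", sep="\t", dtype={"CHR": str})
    ann = pd.read_csv(args.sim / "discovery" / "annotation.tsv", sep="\t",
                      index_col=0, dtype={"chrom": str})

    summary = {}
    for stratum in ("female", "male"):
        dmps = pd.read_csv(args.dmp / f"dmp_{stratum}.tsv", sep="\t",
                           index_col=0)
        sdp, sdp_summary = rg.map_sdp(dmps, meqtl)
        dgp = rg.map_dgp(dmps, gcp)
        triads = rg.triad_link(sdp, dgp)
        print(f"{stratum}: {sdp_summary['n_pairs']} SDPs "
              f"({sdp_summary['n_cpgs']} CpGs, {sdp_summary['n_snps']} "
              f"SNPs; {sdp_summary['frac_under_genetic_control']:.0%} of "
              f"DMPs under genetic control), {len(dgp)} DGPs, "
              f"{len(triads)} triads")
        sdp.to_csv(args.out / f"sdp_{stratum}.tsv", sep="\t", index=False)
        dgp.to_csv(args.out / f"dgp_{stratum}.tsv", sep="\t", index=False)
        triads.to_csv(args.out / f"triads_{stratum}.tsv", sep="\t",
                      index=False)
        entry = dict(sdp=sdp_summary, n_dgp=len(dgp), n_triads=len(triads))
        if len(sdp):
            enr = rg.gwas_window_enrichment(
                set(sdp["snp_id"]), meqtl, gwas, ann, window=args.window,
                n_perm=args.n_perm, seed=args.seed)
            print(f"  GWAS window enrichment: {enr.fold:.2f}-fold, "
                  f"p = {enr.p:.3f}")
            entry["gwas_enrichment"] = asdict(enr)
        summary[stratum] = entry

    with open(args.out / "integration_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"written under {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
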