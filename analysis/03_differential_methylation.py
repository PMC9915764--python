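"""Sex-stratified differential methylation, interaction, and replication.

Fits the moderated model per CpG within the female and male strata (plus
the sex-combined and sex-by-diagnosis interaction models) on the cleaned
discovery data, applies BH within probe families (all tested CpGs
genome-wide; chrX and chrY separately), and calls replication of the
discovery-significant DMPs in the replication cohort.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from methburden import diffmeth as dm

COVARIATES = ("age", "race", "pmi")


def load(sim: Path, pre: Path):
    betas = pd.read_csv(pre / "betas_clean.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(sim / "samples.csv", index_col=0)
    ann = pd.read_csv(sim / "annotation.tsv", sep="\t", index_col=0,
                      dtype={"chrom": str})
    covars = pd.read_csv(pre / "covariates.tsv", sep="\t", index_col=0)
    return betas, samples.loc[betas.columns], ann, covars


def families(ann, probes):
    chrom = ann.loc[probes, "chrom"].astype(str)
    fam = pd.Series("autosomal+all", index=probes)
    fam[chrom == "X"] = "chrX_only"
    fam[chrom == "Y"] = "chrY_only"
    return fam


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", default="results/sim", type=Path)
    ap.add_argument("--pre", default="results/preprocess", type=Path)
    ap.add_argument("--out", default="results/dmp", type=Path)
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    betas, samples, ann, covars = load(args.sim / "discovery", args.pre)
    extra = covars[[c for c in covars.columns if c != "non_neuron"]]

    tables = {}
    for stratum in ("female", "male", "combined"):
        t = dm.fit_dmp(betas, samples, covariates=COVARIATES,
                       stratum=stratum, annotation=ann,
                       extra_covariates=extra)
        # genome-wide family over all tested CpGs; sex chromosomes also
        # re-adjusted within their own families
        t = dm.adjust_fdr(t, pd.Series("autosomal+all", index=t.index))
        chrfam = families(ann, t.index)
        sexchrom = t[chrfam != "autosomal+all"]
        if len(sexchrom):
            t_sex = dm.adjust_fdr(sexchrom, chrfam[chrfam != "autosomal+all"])
            t.loc[t_sex.index, "adj_p_sexchrom_family"] = t_sex["adj_p"]
        tables[stratum] = t
        n_sig = int((t["adj_p"] < 0.05).sum())
        print(f"{stratum}: {n_sig} DMPs at adj.p < 0.05, "
              f"{int((t['p'] < 1e-4).sum())} at p < 1e-4")
        t.to_csv(args.out / f"dmp_{stratum}.tsv", sep="\t",
                 float_format="%.6g")

    inter = dm.fit_interaction(betas, samples, covariates=COVARIATES,
                               extra_covariates=extra)
    inter = dm.adjust_fdr(inter)
    print(f"interaction: {int((inter['adj_p'] < 0.05).sum())} CpGs at "
          f"adj.p < 0.05, {int((inter['p'] < 1e-4).sum())} at p < 1e-4")
    inter.to_csv(args.out / "dmp_interaction.tsv", sep="\t",
                 float_format="%.6g")

    # replication: stratified fits on the replication cohort, then
    # replication calls restricted to the discovery-significant DMPs
    rep_dir = args.sim / "replication"
    rep_betas = pd.read_csv(rep_dir / "betas.tsv", sep="\t", index_col=0)
    rep_samples = pd.read_csv(rep_dir / "samples.csv", index_col=0)
    rep_ann = pd.read_csv(rep_dir / "annotation.tsv", sep="\t", index_col=0,
                          dtype={"chrom": str})
    for stratum in ("female", "male"):
        rep = dm.fit_dmp(rep_betas, rep_samples, covariates=("age",),
                         stratum=stratum, annotation=rep_ann)
        disc = tables[stratum]
        if (disc["adj_p"] < 0.05).sum() == 0:
            print(f"{stratum}: no discovery DMPs to replicate")
            continue
        calls = dm.call_replication(disc, rep)
        print(f"{stratum}: {int(calls['replicated'].sum())} of "
              f"{len(calls)} discovery DMPs replicated")
        calls.to_csv(args.out / f"replication_{stratum}.tsv", sep="\t",
                     float_format="%.6g")
    print(f"written under {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
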