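"""Sex-stratified burden comparisons: counts, concordance, magnitude.

Four analyses on the cleaned discovery cohort:

1. down-sampling comparison — the male subgroup is repeatedly
   down-sampled to the female design and the DMP counts compared;
2. RRHO concordance of the female and male rankings;
3. magnitude comparison (slope of male on female delta-beta, paired t)
   on the concordant CpGs, chrX CpGs, and all tested CpGs;
4. baseline sex-difference (sDMP) calling on controls and the enrichment
   odds ratio of sex-stratified DMPs in sDMPs.
"""

import argparse
import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from methburden import burden as bd

COVARIATES = ("age", "race", "pmi")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", default="results/sim/discovery", type=Path)
    ap.add_argument("--pre", default="results/preprocess", type=Path)
    ap.add_argument("--dmp", default="results/dmp", type=Path)
    ap.add_argument("--out", default="results/burden", type=Path)
    ap.add_argument("--seed", default=1, type=int)
    ap.add_argument("--n-iter", default=200, type=int)
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    betas = pd.read_csv(args.pre / "betas_clean.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(args.sim / "samples.csv",
                          index_col=0).loc[betas.columns]
    ann = pd.read_csv(args.sim / "annotation.tsv", sep="\t", index_col=0,
                      dtype={"chrom": str})
    f = pd.read_csv(args.dmp / "dmp_female.tsv", sep="\t", index_col=0)
    m = pd.read_csv(args.dmp / "dmp_male.tsv", sep="\t", index_col=0)

    # 1. matched-sample-size DMP counts
    ds = bd.downsample_compare(betas, samples, covariates=COVARIATES,
                               n_iter=args.n_iter, seed=args.seed,
                               annotation=ann)
    print(f"down-sampling ({ds.n_iter} iterations): female count "
          f"{ds.female_count}, male median {np.median(ds.male_counts):.0f},"
          f" one-sided 95% CI of the excess [{ds.ci[0]:.2f}, {ds.ci[1]:.2f}]"
          f", p = {ds.p:.4f}")

    # 2. RRHO concordance
    common = f.index.intersection(m.index)
    rr = bd.rrho_map(f.loc[common], m.loc[common])
    conc_sig = bd.max_concordant_signal(rr)
    print(f"RRHO: max signed -log10 p {rr.max_value:.1f} at {rr.max_at}; "
          f"max concordant-quadrant signal {conc_sig:.1f}")
    rr.grid.to_csv(args.out / "rrho_grid.tsv", sep="\t",
                   float_format="%.3f")

    # 3. magnitude comparisons
    conc = bd.concordant_cpgs(f, m)
    print(f"concordant CpGs (p < 0.05 both sexes, same direction): "
          f"{len(conc)} ({(conc['direction'] == 'up').sum()} up, "
          f"{(conc['direction'] == 'down').sum()} down)")
    conc.to_csv(args.out / "concordant_cpgs.tsv", sep="\t",
                float_format="%.6g")
    comparisons = {}
    chrx = ann.index[ann["chrom"].astype(str) == "X"]
    for label, subset in [("concordant", conc.index), ("chrX", chrx),
                          ("all", None)]:
        try:
            res = bd.magnitude_comparison(f, m, subset=subset, label=label)
        except ValueError as e:
            print(f"magnitude ({label}): skipped ({e})")
            continue
        comparisons[label] = asdict(res)
        print(f"magnitude ({label}, n={res.n}): slope {res.slope:.2f}, "
              f"mean |db| F {res.mean_abs_female:.4f} vs M "
              f"{res.mean_abs_male:.4f}, paired t p {res.paired_t_p:.2g}")

    # 4. baseline sex differences and enrichment
    sdmp = bd.call_sdmp(betas, samples, covariates=("age", "race", "pmi"))
    sdmp.to_csv(args.out / "sdmp.tsv", sep="\t", float_format="%.6g")
    n_sdmp = int((sdmp["adj_p"] < 0.05).sum())
    print(f"sDMPs on controls: {n_sdmp} at adj.p < 0.05")
    universe = set(f.index)
    sdmp_set = set(sdmp.index[sdmp["adj_p"] < 0.05]) & universe
    enrich = {}
    for label, table in (("fdmp", f), ("mdmp", m)):
        hits = set(table.index[table["p"] < 1e-4])
        if not hits or not sdmp_set:
            continue
        res = bd.enrichment_or(hits, sdmp_set, universe, hit_label=label,
                               ref_label="sdmp")
        enrich[label] = asdict(res)
        print(f"{label} in sDMPs: {res.a}/{res.a + res.b} vs "
              f"{len(sdmp_set)}/{len(universe)}, OR {res.odds_ratio:.2f}, "
              f"p {res.p:.2g}")

    with open(args.out / "burden_summary.json", "w") as fh:
        json.dump(dict(
            downsample=dict(n_iter=ds.n_iter, female_count=ds.female_count,
                            male_median=float(np.median(ds.male_counts)),
                            ci=list(ds.ci), p=ds.p),
            rrho=dict(max_value=rr.max_value, max_at=list(rr.max_at),
                      step=rr.step, max_concordant=conc_sig),
            n_concordant=len(conc),
            magnitude=comparisons, n_sdmp=n_sdmp,
            sdmp_enrichment=enrich), fh, indent=2)
    print(f"written under {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
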