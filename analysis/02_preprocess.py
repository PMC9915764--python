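"""Quality control and preprocessing of the simulated discovery cohort.

Runs the full QC chain — probe filters, bad-sample removal, sex
prediction, BMIQ normalization, cell-proportion estimation, ComBat-style
batch correction, surrogate-variable estimation — and writes the cleaned
beta matrix, per-sample covariates (cell proportions + SVs) and a JSON
run report with the counts removed at every step.
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from methburden import preprocess as pp


def read_cohort(d: Path):
    betas = pd.read_csv(d / "betas.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(d / "annotation.tsv", sep="\t", index_col=0,
                      dtype={"chrom": str})
    samples = pd.read_csv(d / "samples.csv", index_col=0)
    det = pd.read_csv(d / "detection_p.tsv", sep="\t", index_col=0)
    beads = pd.read_csv(d / "beadcount.tsv", sep="\t", index_col=0)
    ref = pd.read_csv(d / "cell_reference.tsv", sep="\t", index_col=0)
    return betas, ann, samples, det, beads, ref


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", default="results/sim/discovery", type=Path)
    ap.add_argument("--out", default="results/preprocess", type=Path)
    ap.add_argument("--skip-bmiq", action="store_true")
    ap.add_argument("--skip-combat", action="store_true")
    ap.add_argument("--n-sv", default="auto")
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    betas, ann, samples, det, beads, ref = read_cohort(args.sim)

    filtered, report = pp.filter_probes(betas, ann, det, beads)
    filtered = pp.drop_bad_samples(filtered, report)
    print(f"probe filters removed {report.n_input - report.n_output}: "
          f"{report.removed_per_criterion}")
    print(f"samples retained: {filtered.shape[1]} / {betas.shape[1]}")

    sex_pred, mismatches = pp.predict_sex(filtered, ann, samples["sex"])
    print(f"sex prediction mismatches: {mismatches or 'none'}")

    if not args.skip_bmiq:
        filtered = pp.bmiq_normalize(filtered, ann)
        print("BMIQ normalization applied to type-II probes")

    props = pp.estimate_cell_proportions(filtered, ref)

    if not args.skip_combat:
        filtered = pp.correct_batch(filtered, samples.loc[filtered.columns])
        print("batch correction applied")

    design = pd.get_dummies(
        samples.loc[filtered.columns, ["diagnosis", "sex"]],
        drop_first=True).astype(float)
    design["neuron"] = props.loc[filtered.columns, "neuron"]
    n_sv = None if args.n_sv == "auto" else int(args.n_sv)
    svs, k = pp.estimate_svs(filtered, design, seed=0, n_sv=n_sv)
    print(f"surrogate variables selected: k = {k}")

    filtered.to_csv(args.out / "betas_clean.tsv", sep="\t",
                    float_format="%.5f")
    covars = props.join(svs, how="left")
    covars.to_csv(args.out / "covariates.tsv", sep="\t", float_format="%.5f")
    sex_pred.to_csv(args.out / "sex_prediction.tsv", sep="\t",
                    float_format="%.4f")
    with open(args.out / "run_report.json", "w") as fh:
        json.dump(dict(
            n_probes_in=report.n_input, n_probes_out=report.n_output,
            removed_per_criterion=report.removed_per_criterion,
            n_samples=int(filtered.shape[1]),
            sex_mismatches=list(mismatches), n_sv=int(k)), fh, indent=2)
    print(f"written under {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
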