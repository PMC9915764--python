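"""Simulate the study cohorts and regulatory resources.

Generates a discovery cohort on the study's sample-size design (41/41
female and 41/72 male case/control, with planted female effects of 0.08
and male effects of 0.05 beta units), a smaller replication cohort, and
the planted regulatory resources (meQTLs, CpG-gene expression pairs,
genotypes, expression, GWAS summary statistics, a PPI graph with a
planted module, gene sets).  Everything is written as plain-text tables
under the output directory.
"""

import argparse
import sys
from pathlib import Path

from methburden import synthdata as sd


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/sim", type=Path)
    ap.add_argument("--seed", default=2024, type=int)
    ap.add_argument("--n-probes", default=20_000, type=int)
    args = ap.parse_args(argv)

    discovery = sd.generate_cohort(sd.CohortConfig(
        n_probes=args.n_probes, seed=args.seed, dataset="discovery"))
    # replication shares the discovery probes and planted effects but
    # draws new subjects, noise and batches
    replication = sd.generate_cohort(sd.CohortConfig(
        n_probes=args.n_probes,
        n_female_cases=9, n_female_controls=11,
        n_male_cases=26, n_male_controls=30,
        seed=args.seed + 1, dataset="replication"),
        annotation=discovery.annotation, truth=discovery.truth)
    resources = sd.generate_pair_tables(
        discovery.truth, discovery.annotation, discovery.betas,
        discovery.samples, sd.PairConfig(seed=args.seed + 2))

    sd.write_cohort(discovery, args.out / "discovery")
    sd.write_cohort(replication, args.out / "replication")
    sd.write_pair_tables(resources, args.out / "resources")

    truth = discovery.truth
    print(f"discovery: {discovery.betas.shape[0]} probes x "
          f"{discovery.betas.shape[1]} samples")
    print("planted:", truth["effect_class"].value_counts().to_dict())
    print(f"replication: {replication.betas.shape[1]} samples")
    print(f"resources: {len(resources.meqtl)} meQTL pairs, "
          f"{len(resources.gcp)} GCPs, "
          f"{resources.ppi.number_of_nodes()} PPI genes, "
          f"planted module sizes "
          f"{[len(m) for m in resources.planted['module_genes']]}")
    print(f"written under {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
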