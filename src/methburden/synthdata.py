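"""Synthetic methylation cohorts with planted ground truth.

Generates complete inputs for the pipeline — beta matrix, sample sheet,
probe annotation, detection-p / beadcount companions, and the regulatory
resources (meQTL pairs, CpG-gene expression pairs, genotypes, expression,
GWAS summary statistics, a PPI graph with planted modules, gene sets) —
together with a truth table recording every planted effect, so downstream
stages can be validated by parameter recovery.

Signal is simulated on the logit(beta) (M-value-like) scale and
back-transformed, which keeps beta strictly in (0, 1) and yields the
characteristic bimodal beta distribution.  Type-II probes are compressed by
a scale factor on the logit signal, giving BMIQ a real bias to correct.
Case/control effects are planted with sex-dependent magnitude
(female > male by default) and shared probes get same-sign effects, so the
realized regime mirrors a cohort in which most disease-associated CpGs move
in the same direction in both sexes but with larger changes in females.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit

PROMOTER_FEATURES = ("TSS200", "TSS1500")
FEATURES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")
FLAG_COLUMNS = ("non_cpg", "snp_related", "multi_map", "low_quality")

_EPS = 1e-6


@dataclass
class CohortConfig:
    """Parameters of a synthetic case/control brain methylation cohort.

    Sample-size defaults follow the discovery design this pipeline targets:
    41 female cases / 41 female controls and 41 male cases / 72 male
    controls.  ``delta_female`` / ``delta_male`` are the mean absolute
    planted case-control effects on the beta scale; the default asymmetry
    (0.08 vs 0.05) plants a larger dysregulation magnitude in females.
    """

    n_probes: int = 20_000
    n_female_cases: int = 41
    n_female_controls: int = 41
    n_male_cases: int = 41
    n_male_controls: int = 72
    frac_fdmp: float = 0.01
    frac_mdmp: float = 0.01
    frac_shared: float = 0.02
    delta_female: float = 0.08
    delta_male: float = 0.05
    frac_sdmp: float = 0.03
    sdmp_delta: float = 0.08
    n_batches: int = 2
    batch_shift: float = 0.05
    chrx_frac: float = 0.04
    chry_frac: float = 0.002
    noise_sd: float = 0.35
    # probe chemistry / annotation structure
    frac_type2: float = 0.7
    type2_compression: float = 0.8
    frac_flagged: float = 0.005
    frac_bad_probes: float = 0.004
    entry_bad_frac: float = 0.0005
    # cell composition
    cell_frac: float = 0.2
    cell_effect_sd: float = 1.0
    # shared-probe effect orientation: same sign in both sexes by default;
    # True flips the male effect (the sex-by-diagnosis interaction regime)
    opposite_shared: bool = False
    n_genes: int = 1500
    dataset: str = "discovery"
    seed: int = 0

    def validate(self) -> None:
        fracs = dict(
            frac_fdmp=self.frac_fdmp,
            frac_mdmp=self.frac_mdmp,
            frac_shared=self.frac_shared,
            frac_sdmp=self.frac_sdmp,
            chrx_frac=self.chrx_frac,
            chry_frac=self.chry_frac,
        )
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_fdmp + self.frac_mdmp + self.frac_shared > 1.0:
            raise ValueError("frac_fdmp + frac_mdmp + frac_shared must be <= 1")
        counts = dict(
            n_probes=self.n_probes,
            n_female_cases=self.n_female_cases,
            n_female_controls=self.n_female_controls,
            n_male_cases=self.n_male_cases,
            n_male_controls=self.n_male_controls,
            n_batches=self.n_batches,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.delta_female < 0 or self.delta_male < 0:
            raise ValueError("planted effect magnitudes must be non-negative")
        if not 0 < self.type2_compression <= 1:
            raise ValueError("type2_compression must be in (0, 1]")


@dataclass
class SyntheticCohort:
    """Bundle of everything :func:`generate_cohort` produces.

    ``betas`` is probes x samples; ``cell_reference`` holds the pure
    neuron / non-neuron beta profiles of the cell-type-informative probes,
    derived from the generative model (the reference a deconvolution method
    would be given).
    """

    config: CohortConfig
    betas: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    detection_p: pd.DataFrame
    beadcount: pd.DataFrame
    cell_reference: pd.DataFrame


def _beta_scale_offset(baseline: np.ndarray, delta: np.ndarray,
                       compression: np.ndarray) -> np.ndarray:
    """Logit offset that moves beta from ``baseline`` by ``delta``.

    The offset is divided by the probe's compression factor so the planted
    beta-scale difference survives the type-II compression applied to the
    whole logit signal.
    """
    target = np.clip(baseline + delta, 1e-3, 1 - 1e-3)
    return (logit(target) - logit(np.clip(baseline, 1e-3, 1 - 1e-3))) / compression


def generate_cohort(config: CohortConfig,
                    annotation: pd.DataFrame | None = None,
                    truth: pd.DataFrame | None = None) -> SyntheticCohort:
    """Simulate a full case/control cohort with planted effects.

    Deterministic given ``config.seed``: a single seed fans out to
    per-component substreams so each stage of the generator is reproducible
    in isolation.

    Pass the ``annotation`` and ``truth`` of an existing cohort to draw an
    independent cohort (new subjects, noise, batches) carrying the same
    probe structure and the same planted effects — the way a replication
    study shares the discovery study's biology.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (rng_probe, rng_sample, rng_effect, rng_noise,
     rng_qc) = [np.random.default_rng(s) for s in ss.spawn(5)]

    n = config.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])

    # --- annotation -----------------------------------------------------
    if annotation is not None:
        if len(annotation) != n:
            raise ValueError("supplied annotation does not match n_probes")
        annotation = annotation.copy()
        probe_ids = annotation.index.to_numpy()
        chrom = annotation["chrom"].astype(str).to_numpy()
        design_type = annotation["design_type"].to_numpy()
        flags = {c: annotation[c].to_numpy(bool) if c in annotation
                 else np.zeros(n, bool) for c in FLAG_COLUMNS}
    else:
        n_y = int(round(config.chry_frac * n))
        n_x = int(round(config.chrx_frac * n))
        chrom = rng_probe.choice([str(c) for c in range(1, 23)], size=n)
        sexchrom_idx = rng_probe.choice(n, size=n_x + n_y, replace=False)
        chrom[sexchrom_idx[:n_x]] = "X"
        chrom[sexchrom_idx[n_x:]] = "Y"
        pos = rng_probe.integers(10_000, 200_000_000, size=n)
        design_type = np.where(rng_probe.random(n) < config.frac_type2,
                               "II", "I")
        gene_pool = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
        gene = rng_probe.choice(gene_pool, size=n)
        feature = rng_probe.choice(FEATURES, size=n)
        intergenic = rng_probe.random(n) < 0.25
        gene = np.where(intergenic, "", gene)
        feature = np.where(intergenic, "IGR", feature)
        flags = {c: rng_probe.random(n) < config.frac_flagged
                 for c in FLAG_COLUMNS}

        annotation = pd.DataFrame(
            dict(chrom=chrom, pos=pos, design_type=design_type,
                 gene=gene, feature=feature, **flags),
            index=pd.Index(probe_ids, name="probe_id"),
        )

    # --- samples --------------------------------------------------------
    groups = [
        ("F", "case", config.n_female_cases),
        ("F", "control", config.n_female_controls),
        ("M", "case", config.n_male_cases),
        ("M", "control", config.n_male_controls),
    ]
    sex = np.concatenate([[s] * k for s, _, k in groups])
    diagnosis = np.concatenate([[d] * k for _, d, k in groups])
    n_samples = len(sex)
    sample_ids = np.array([f"S{i:04d}" for i in range(n_samples)])
    samples = pd.DataFrame(
        dict(
            diagnosis=diagnosis,
            sex=sex,
            age=np.clip(rng_sample.normal(50, 15, n_samples), 18, 90).round(1),
            race=rng_sample.choice(["EA", "AA"], size=n_samples, p=[0.6, 0.4]),
            pmi=rng_sample.gamma(5.0, 3.0, n_samples).round(1),
            batch=rng_sample.integers(0, config.n_batches, n_samples).astype(str),
            dataset=config.dataset,
            neuron_true=rng_sample.beta(8, 12, n_samples).round(4),
        ),
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- planted effects ------------------------------------------------
    if truth is not None:
        if len(truth) != n:
            raise ValueError("supplied truth table does not match n_probes")
        truth = truth.copy()
        effect_class = truth["effect_class"].to_numpy(object)
        is_sdmp = truth["is_sdmp"].to_numpy(bool)
        true_df = truth["true_delta_female"].to_numpy(float)
        true_dm = truth["true_delta_male"].to_numpy(float)
        true_sex = truth["true_sex_delta"].to_numpy(float)
    else:
        clean = ~np.any(np.column_stack(list(flags.values())), axis=1)
        clean &= ~np.isin(chrom, ["X", "Y"])
        clean_idx = np.flatnonzero(clean)
        n_f = int(round(config.frac_fdmp * n))
        n_m = int(round(config.frac_mdmp * n))
        n_sh = int(round(config.frac_shared * n))
        n_sd = int(round(config.frac_sdmp * n))
        if n_f + n_m + n_sh > len(clean_idx):
            raise ValueError(
                "not enough clean autosomal probes for planted effects")
        picked = rng_effect.choice(clean_idx, size=n_f + n_m + n_sh,
                                   replace=False)
        fdmp_idx, mdmp_idx, shared_idx = np.split(picked, [n_f, n_f + n_m])
        sdmp_idx = rng_effect.choice(clean_idx,
                                     size=min(n_sd, len(clean_idx)),
                                     replace=False)

        effect_class = np.array(["null"] * n, dtype=object)
        effect_class[fdmp_idx] = "fdmp"
        effect_class[mdmp_idx] = "mdmp"
        effect_class[shared_idx] = "shared"
        is_sdmp = np.zeros(n, dtype=bool)
        is_sdmp[sdmp_idx] = True
        effect_class[is_sdmp & (effect_class == "null")] = "sdmp"

        true_df = np.zeros(n)
        true_dm = np.zeros(n)
        true_sex = np.zeros(n)
        sign_f = rng_effect.choice([-1.0, 1.0], size=n_f)
        sign_m = rng_effect.choice([-1.0, 1.0], size=n_m)
        sign_sh = rng_effect.choice([-1.0, 1.0], size=n_sh)
        true_df[fdmp_idx] = sign_f * config.delta_female
        true_dm[mdmp_idx] = sign_m * config.delta_male
        true_df[shared_idx] = sign_sh * config.delta_female
        male_sign = -sign_sh if config.opposite_shared else sign_sh
        true_dm[shared_idx] = male_sign * config.delta_male
        true_sex[sdmp_idx] = rng_effect.choice(
            [-1.0, 1.0], size=len(sdmp_idx)) * config.sdmp_delta

        truth = pd.DataFrame(
            dict(effect_class=effect_class, is_sdmp=is_sdmp,
                 true_delta_female=true_df, true_delta_male=true_dm,
                 true_sex_delta=true_sex),
            index=pd.Index(probe_ids, name="probe_id"),
        )

    # --- baselines ------------------------------------------------------
    comp = rng_probe.choice(3, size=n, p=[0.35, 0.25, 0.40])
    mu = np.where(comp == 0, rng_probe.normal(-2.5, 0.8, n),
                  np.where(comp == 1, rng_probe.normal(0.0, 0.6, n),
                           rng_probe.normal(2.5, 0.8, n)))
    # planted probes sit at intermediate methylation: variable CpGs in brain
    # are predominantly mid-range, and it keeps the beta-scale effect
    # magnitude interpretable
    planted = (effect_class != "null") | is_sdmp
    mu[planted] = rng_probe.normal(0.0, 0.5, planted.sum())
    # chrY probes are intermediate-to-methylated in males (the basis of
    # methylation-based sex prediction); females are overridden below
    y_base = chrom == "Y"
    mu[y_base] = rng_probe.normal(0.5, 0.5, y_base.sum())

    compression = np.where(design_type == "II", config.type2_compression, 1.0)
    baseline_beta = expit(compression * mu)

    is_f = (sex == "F")
    is_case = (diagnosis == "case")

    # logit-scale per-probe terms (column vectors broadcast over samples)
    off_f = _beta_scale_offset(baseline_beta, true_df, compression)
    off_m = _beta_scale_offset(baseline_beta, true_dm, compression)
    off_sex = _beta_scale_offset(baseline_beta, true_sex, compression)

    cell_informative = rng_probe.random(n) < config.cell_frac
    cell_coef = np.where(cell_informative,
                         rng_probe.normal(0.0, config.cell_effect_sd, n), 0.0)

    # per-batch beta-scale shifts summing to a max spread of batch_shift,
    # converted per probe to logit offsets so the planted shift is the
    # configured beta-scale offset at every probe
    batch_levels = np.arange(config.n_batches)
    centered = batch_levels - batch_levels.mean()
    spread = np.abs(centered).max()
    batch_beta_shift = config.batch_shift * centered / (2.0 * spread) \
        if spread > 0 else np.zeros_like(centered, dtype=float)
    batch_logit = np.stack(
        [_beta_scale_offset(baseline_beta,
                            np.full(n, s), compression)
         for s in batch_beta_shift], axis=1)          # probes x batches
    sample_batch_idx = samples["batch"].astype(int).to_numpy()

    signal = np.tile(mu[:, None], (1, n_samples))
    signal += off_sex[:, None] * is_f[None, :]
    signal += off_f[:, None] * (is_f & is_case)[None, :]
    signal += off_m[:, None] * (~is_f & is_case)[None, :]
    signal += cell_coef[:, None] * (samples["neuron_true"].to_numpy() - 0.4)[None, :]
    signal += batch_logit[:, sample_batch_idx]
    signal += rng_noise.normal(0.0, config.noise_sd, size=(n, n_samples))
    m_values = compression[:, None] * signal

    # chrX in females: one X is inactivated, pulling betas toward
    # intermediate values — compress the female chrX signal toward 0
    x_mask = (chrom == "X")
    if x_mask.any() and is_f.any():
        block = m_values[np.ix_(x_mask, is_f)]
        m_values[np.ix_(x_mask, is_f)] = 0.6 * block
    # chrY in females: no Y chromosome; signal is cross-hybridization noise
    y_mask = (chrom == "Y")
    if y_mask.any() and is_f.any():
        m_values[np.ix_(y_mask, is_f)] = rng_noise.normal(
            logit(0.1), 1.0, size=(y_mask.sum(), is_f.sum()))

    betas = expit(m_values)
    np.clip(betas, _EPS, 1 - _EPS, out=betas)
    betas = pd.DataFrame(betas, index=annotation.index, columns=samples.index)

    # --- companion QC matrices ------------------------------------------
    detection_p = rng_qc.beta(0.5, 400, size=(n, n_samples))
    beadcount = rng_qc.poisson(14, size=(n, n_samples)) + 1
    bad_entries = rng_qc.random((n, n_samples)) < config.entry_bad_frac
    detection_p[bad_entries] = rng_qc.uniform(0.011, 0.2, bad_entries.sum())
    n_bad = int(round(config.frac_bad_probes * n))
    bad_probes = rng_qc.choice(n, size=n_bad, replace=False)
    half = n_bad // 2
    for i in bad_probes[:half]:
        hit = rng_qc.random(n_samples) < 0.10
        detection_p[i, hit] = rng_qc.uniform(0.011, 0.5, hit.sum())
    for i in bad_probes[half:]:
        hit = rng_qc.random(n_samples) < 0.10
        beadcount[i, hit] = rng_qc.integers(0, 3, hit.sum())
    detection_p = pd.DataFrame(detection_p, index=annotation.index,
                               columns=samples.index)
    beadcount = pd.DataFrame(beadcount, index=annotation.index,
                             columns=samples.index)

    # --- cell reference (pure-type profiles from the generative model) ---
    ref_idx = np.flatnonzero(cell_informative)
    ref = pd.DataFrame(
        {
            "neuron": expit(compression[ref_idx]
                            * (mu[ref_idx] + cell_coef[ref_idx] * (1.0 - 0.4))),
            "non_neuron": expit(compression[ref_idx]
                                * (mu[ref_idx] + cell_coef[ref_idx] * (0.0 - 0.4))),
        },
        index=annotation.index[ref_idx],
    )

    return SyntheticCohort(config=config, betas=betas, samples=samples,
                           annotation=annotation, truth=truth,
                           detection_p=detection_p, beadcount=beadcount,
                           cell_reference=ref)


# ---------------------------------------------------------------------------
# regulatory resources: meQTL / GCP / genotypes / expression / GWAS / PPI / GMT
# ---------------------------------------------------------------------------

@dataclass
class PairConfig:
    """Parameters for the planted regulatory resources."""

    frac_meqtl_linked: float = 0.5     # fraction of planted DMP probes with SNPs
    snps_per_probe: int = 2
    geno_r: float = 0.5                # genotype-methylation correlation
    maf_range: tuple = (0.1, 0.5)
    frac_gcp_linked: float = 0.3       # fraction of planted DMP probes with genes
    gcp_rho: float = 0.8
    n_background_snps: int = 5000
    n_gwas_hits: int = 30
    gwas_enriched: bool = True         # place GWAS hits inside fDMP SNP windows
    window_bp: int = 200_000
    ppi_n_genes: int = 400
    ppi_edge_p: float = 0.02
    module_size: int = 12
    n_modules: int = 1
    n_genesets: int = 20
    seed: int = 1


@dataclass
class RegulatoryResources:
    meqtl: pd.DataFrame
    gcp: pd.DataFrame
    genotypes: pd.DataFrame
    expression: pd.DataFrame
    gwas: pd.DataFrame
    ppi: nx.Graph
    genesets: dict
    planted: dict = field(default_factory=dict)


def _genotype_from_beta(z: np.ndarray, maf: float, r: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Additive genotype correlated with a standardized methylation vector.

    A liability ``r*z + sqrt(1-r^2)*e`` is cut at the Hardy-Weinberg
    quantiles for ``maf``, so the genotype both respects the allele
    frequency and associates with the probe's realized beta values.
    """
    liab = r * z + np.sqrt(1 - r * r) * rng.standard_normal(len(z))
    order = np.argsort(liab)
    g = np.empty(len(z), dtype=int)
    p0 = (1 - maf) ** 2
    p1 = 2 * maf * (1 - maf)
    c0 = int(round(p0 * len(z)))
    c1 = int(round((p0 + p1) * len(z)))
    g[order[:c0]] = 0
    g[order[c0:c1]] = 1
    g[order[c1:]] = 2
    return g


def generate_pair_tables(truth: pd.DataFrame, annotation: pd.DataFrame,
                         betas: pd.DataFrame, samples: pd.DataFrame,
                         config: PairConfig | None = None) -> RegulatoryResources:
    """Planted meQTL/GCP/GWAS/PPI resources consistent with the cohort.

    Genotypes associate with the realized beta values of their linked CpGs
    and expression correlates (with configured sign and strength) with the
    linked CpG's logit-beta, so downstream joins and enrichment tests have
    genuine signal to recover.
    """
    if config is None:
        config = PairConfig()
    if not truth.index.equals(annotation.index):
        raise ValueError("truth and annotation must share the same probe index")
    if not truth.index.equals(betas.index):
        raise ValueError("truth and betas must share the same probe index")
    ss = np.random.SeedSequence(config.seed)
    rng_qtl, rng_gcp, rng_gwas, rng_ppi = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    dmp_mask = truth["effect_class"].isin(["fdmp", "mdmp", "shared"])
    dmp_probes = truth.index[dmp_mask]
    n_link = int(round(config.frac_meqtl_linked * len(dmp_probes)))
    linked = rng_qtl.choice(dmp_probes, size=n_link, replace=False) \
        if n_link else np.array([], dtype=object)

    # --- meQTL pairs + genotypes ---------------------------------------
    rows = []
    geno_rows = {}
    snp_counter = 0
    for probe in linked:
        z = betas.loc[probe].to_numpy()
        z = (z - z.mean()) / max(z.std(), 1e-12)
        for _ in range(config.snps_per_probe):
            snp = f"rs{snp_counter:06d}"
            snp_counter += 1
            maf = rng_qtl.uniform(*config.maf_range)
            sign = rng_qtl.choice([-1, 1])
            geno_rows[snp] = _genotype_from_beta(sign * z, maf, config.geno_r,
                                                 rng_qtl)
            rows.append(dict(
                snp_id=snp,
                snp_chrom=annotation.loc[probe, "chrom"],
                snp_pos=int(annotation.loc[probe, "pos"]
                            + rng_qtl.integers(-150_000, 150_000)),
                probe_id=probe,
                effect_sign=int(sign),
                fdr=float(rng_qtl.uniform(0, 0.05)),
            ))
    meqtl = pd.DataFrame(rows, columns=["snp_id", "snp_chrom", "snp_pos",
                                        "probe_id", "effect_sign", "fdr"])
    genotypes = pd.DataFrame(geno_rows, index=samples.index).T
    genotypes.index.name = "snp_id"

    # --- GCP pairs + expression ----------------------------------------
    n_gcp = int(round(config.frac_gcp_linked * len(dmp_probes)))
    gcp_probes = rng_gcp.choice(dmp_probes, size=n_gcp, replace=False) \
        if n_gcp else np.array([], dtype=object)
    gcp_rows = []
    expr_rows = {}
    gene_pool = sorted(set(annotation.loc[annotation["gene"] != "", "gene"]))
    used_genes = set()
    for probe in gcp_probes:
        gene = annotation.loc[probe, "gene"]
        if gene == "" or gene in used_genes:
            free = [g for g in gene_pool if g not in used_genes]
            if not free:
                break
            gene = free[rng_gcp.integers(len(free))]
        used_genes.add(gene)
        sign = int(rng_gcp.choice([-1, 1]))
        z = logit(np.clip(betas.loc[probe].to_numpy(), _EPS, 1 - _EPS))
        z = (z - z.mean()) / max(z.std(), 1e-12)
        rho = config.gcp_rho
        expr = sign * rho * z + np.sqrt(1 - rho * rho) \
            * rng_gcp.standard_normal(len(z))
        expr_rows[gene] = expr
        gcp_rows.append(dict(
            probe_id=probe, gene=gene,
            corr_sign="positive" if sign > 0 else "negative",
            correlation=float(sign * rho),
            deg_status=rng_gcp.choice(["up", "down", "ns"], p=[0.25, 0.25, 0.5]),
        ))
    gcp = pd.DataFrame(gcp_rows, columns=["probe_id", "gene", "corr_sign",
                                          "correlation", "deg_status"])
    # background genes with unrelated expression
    n_bg_genes = min(50, len(gene_pool))
    for gene in rng_gcp.choice(gene_pool, size=n_bg_genes, replace=False):
        if gene not in expr_rows:
            expr_rows[gene] = rng_gcp.standard_normal(betas.shape[1])
    expression = pd.DataFrame(expr_rows, index=samples.index).T
    expression.index.name = "gene"

    # --- GWAS summary statistics ---------------------------------------
    n_bg = config.n_background_snps
    chroms = rng_gwas.choice([str(c) for c in range(1, 23)], size=n_bg)
    bps = rng_gwas.integers(10_000, 200_000_000, size=n_bg)
    pvals = rng_gwas.uniform(1e-6, 1.0, size=n_bg)
    gwas = pd.DataFrame(dict(
        SNP=[f"gw{i:06d}" for i in range(n_bg)],
        CHR=chroms, BP=bps,
        A1=rng_gwas.choice(list("ACGT"), size=n_bg),
        A2=rng_gwas.choice(list("ACGT"), size=n_bg),
        BETA=rng_gwas.normal(0, 0.05, size=n_bg).round(4),
        P=pvals,
        MAF=rng_gwas.uniform(0.01, 0.5, size=n_bg).round(3),
    ))
    fdmp_linked = meqtl.merge(
        truth[truth["effect_class"] == "fdmp"], left_on="probe_id",
        right_index=True, how="inner") if len(meqtl) else meqtl
    hit_rows = []
    for i in range(config.n_gwas_hits):
        if config.gwas_enriched and len(fdmp_linked):
            row = fdmp_linked.iloc[int(rng_gwas.integers(len(fdmp_linked)))]
            probe = row["probe_id"]
            chrom_h = annotation.loc[probe, "chrom"]
            bp_h = int(annotation.loc[probe, "pos"]
                       + rng_gwas.integers(-config.window_bp // 2,
                                           config.window_bp // 2))
        else:
            chrom_h = rng_gwas.choice([str(c) for c in range(1, 23)])
            bp_h = int(rng_gwas.integers(10_000, 200_000_000))
        hit_rows.append(dict(
            SNP=f"gwhit{i:04d}", CHR=chrom_h, BP=max(bp_h, 1),
            A1=rng_gwas.choice(list("ACGT")), A2=rng_gwas.choice(list("ACGT")),
            BETA=float(rng_gwas.normal(0, 0.1)),
            P=float(10 ** rng_gwas.uniform(-30, -8)),
            MAF=float(rng_gwas.uniform(0.05, 0.5)),
        ))
    if hit_rows:
        gwas = pd.concat([gwas, pd.DataFrame(hit_rows)], ignore_index=True)

    # --- PPI graph with planted modules --------------------------------
    promoter = annotation["feature"].isin(PROMOTER_FEATURES) \
        & (annotation["gene"] != "")
    dmp_promoter_genes = sorted(set(
        annotation.loc[promoter & dmp_mask.to_numpy(), "gene"]))
    other_genes = [g for g in gene_pool if g not in dmp_promoter_genes]
    rng_ppi.shuffle(other_genes)
    n_other = max(config.ppi_n_genes - len(dmp_promoter_genes), 0)
    ppi_genes = sorted(set(dmp_promoter_genes) | set(other_genes[:n_other]))
    ppi = nx.Graph()
    ppi.add_nodes_from(ppi_genes)
    arr = np.array(ppi_genes)
    n_nodes = len(arr)
    upper = rng_ppi.random((n_nodes, n_nodes)) < config.ppi_edge_p
    iu, ju = np.triu_indices(n_nodes, k=1)
    for i, j in zip(iu[upper[iu, ju]], ju[upper[iu, ju]]):
        ppi.add_edge(arr[i], arr[j])

    module_genes_all = []
    pool = list(dmp_promoter_genes)
    for _ in range(config.n_modules):
        if len(pool) < config.module_size:
            warnings.warn("not enough DMP-promoter genes for a planted module")
            break
        members = list(rng_ppi.choice(pool, size=config.module_size,
                                      replace=False))
        pool = [g for g in pool if g not in members]
        shuffled = list(members)
        rng_ppi.shuffle(shuffled)
        for a, b in zip(shuffled[:-1], shuffled[1:]):   # spanning path
            ppi.add_edge(a, b)
        for i in range(len(members)):                   # densify
            for j in range(i + 1, len(members)):
                if rng_ppi.random() < 0.5:
                    ppi.add_edge(members[i], members[j])
        module_genes_all.append(sorted(members))

    # --- gene sets -------------------------------------------------------
    genesets = {}
    for k, members in enumerate(module_genes_all):
        extra = rng_ppi.choice(
            [g for g in ppi_genes if g not in members], size=8, replace=False)
        genesets[f"PLANTED_MODULE_{k}"] = sorted(set(members) | set(extra))
    for k in range(config.n_genesets):
        size = int(rng_ppi.integers(10, 80))
        genesets[f"RANDOM_SET_{k:02d}"] = sorted(
            rng_ppi.choice(gene_pool, size=size, replace=False))
    genesets["TINY_SET"] = sorted(rng_ppi.choice(gene_pool, size=5,
                                                 replace=False))
    if len(gene_pool) > 600:
        genesets["HUGE_SET"] = sorted(rng_ppi.choice(gene_pool, size=600,
                                                     replace=False))

    planted = dict(
        meqtl_probes=sorted(map(str, linked)),
        gcp_probes=sorted(map(str, gcp_probes)),
        module_genes=module_genes_all,
    )
    return RegulatoryResources(meqtl=meqtl, gcp=gcp, genotypes=genotypes,
                               expression=expression, gwas=gwas, ppi=ppi,
                               genesets=genesets, planted=planted)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_gmt(genesets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort in the pipeline's plain-text exchange formats."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.betas.to_csv(outdir / "betas.tsv", sep="\t", float_format="%.5f")
    cohort.annotation.to_csv(outdir / "annotation.tsv", sep="\t")
    cohort.samples.to_csv(outdir / "samples.csv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t")
    cohort.detection_p.to_csv(outdir / "detection_p.tsv", sep="\t",
                              float_format="%.4g")
    cohort.beadcount.to_csv(outdir / "beadcount.tsv", sep="\t")
    cohort.cell_reference.to_csv(outdir / "cell_reference.tsv", sep="\t",
                                 float_format="%.5f")


def write_pair_tables(res: RegulatoryResources, outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.meqtl.to_csv(outdir / "meqtl.tsv", sep="\t", index=False)
    res.gcp.to_csv(outdir / "gcp.tsv", sep="\t", index=False)
    res.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    res.expression.to_csv(outdir / "expression.tsv", sep="\t",
                          float_format="%.5f")
    res.gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    nx.to_pandas_edgelist(res.ppi).rename(
        columns={"source": "gene_a", "target": "gene_b"}
    ).to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    write_gmt(res.genesets, outdir / "genesets.gmt")
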