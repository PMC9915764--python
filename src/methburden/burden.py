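"""Sex-stratified dysregulation-burden comparisons.

Quantifies the two faces of the methylation dysregulation burden — how
many CpGs move (DMP counts, compared between sexes at matched sample size
by down-sampling) and how far they move (magnitude comparisons on
concordant, chrX and all tested CpGs) — together with rank-rank
hypergeometric overlap (RRHO) concordance, baseline sex-difference (sDMP)
calling on controls, and 2x2 enrichment odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .diffmeth import adjust_fdr, fit_dmp

NEGLOG_CAP = 300.0


# ---------------------------------------------------------------------------
# down-sampling DMP-count comparison
# ---------------------------------------------------------------------------

@dataclass
class DownsampleResult:
    n_iter: int
    female_count: int
    male_counts: np.ndarray
    diff: np.ndarray                 # female - male, per iteration
    ci: tuple                        # one-sided 95% interval of the difference
    p: float                         # fraction of iterations with male >= female


def downsample_compare(betas: pd.DataFrame, samplesheet: pd.DataFrame,
                       covariates=(), n_iter: int = 4000,
                       alpha: float = 0.05, seed: int = 0,
                       annotation: pd.DataFrame | None = None,
                       extra_covariates: pd.DataFrame | None = None,
                       ) -> DownsampleResult:
    """Compare DMP counts between sexes at matched sample size.

    The male subgroup is repeatedly down-sampled (without replacement,
    stratified by case/control) to the female case and control counts; the
    male DMP count (adj.p < alpha, BH over all tested CpGs) is recorded per
    iteration, while the female count is computed once on all female
    samples.  Returns the (female - male) difference distribution, its
    one-sided 95% interval [0, 95th percentile], and the empirical
    p = fraction of iterations in which the male count reached the female
    count.
    """
    sheet = samplesheet.loc[betas.columns]
    sex = sheet["sex"].astype(str)
    dx = sheet["diagnosis"].astype(str)
    f_cases = sheet.index[(sex == "F") & (dx == "case")]
    f_ctrls = sheet.index[(sex == "F") & (dx == "control")]
    m_cases = sheet.index[(sex == "M") & (dx == "case")]
    m_ctrls = sheet.index[(sex == "M") & (dx == "control")]
    if len(m_cases) < len(f_cases) or len(m_ctrls) < len(f_ctrls):
        raise ValueError(
            "male case/control counts must be >= female counts to "
            f"down-sample (M {len(m_cases)}/{len(m_ctrls)} vs "
            f"F {len(f_cases)}/{len(f_ctrls)})")

    def _count(sample_ids, stratum):
        table = fit_dmp(betas.loc[:, sample_ids], sheet.loc[sample_ids],
                        covariates=covariates, stratum=stratum,
                        annotation=annotation,
                        extra_covariates=extra_covariates)
        table = adjust_fdr(table)
        return int((table["adj_p"] < alpha).sum())

    female_count = _count(f_cases.union(f_ctrls), "female")

    rng = np.random.default_rng(seed)
    male_counts = np.empty(n_iter, dtype=int)
    m_cases_arr = np.asarray(m_cases)
    m_ctrls_arr = np.asarray(m_ctrls)
    for i in range(n_iter):
        sub = np.concatenate([
            rng.choice(m_cases_arr, size=len(f_cases), replace=False),
            rng.choice(m_ctrls_arr, size=len(f_ctrls), replace=False),
        ])
        male_counts[i] = _count(pd.Index(sub), "male")

    diff = female_count - male_counts
    ci = (0.0, float(np.percentile(diff, 95)))
    p = float((male_counts >= female_count).mean())
    return DownsampleResult(n_iter=n_iter, female_count=female_count,
                            male_counts=male_counts, diff=diff, ci=ci, p=p)


# ---------------------------------------------------------------------------
# RRHO
# ---------------------------------------------------------------------------

@dataclass
class RRHOResult:
    grid: pd.DataFrame               # signed -log10 hypergeometric p
    step: int
    n: int
    max_value: float
    max_at: tuple
    overlap: pd.DataFrame = field(repr=False, default=None)


def _signed_score(dmp: pd.DataFrame) -> pd.Series:
    p = np.clip(dmp["p"].to_numpy(float), 1e-300, 1.0)
    return pd.Series(-np.log10(p) * np.sign(dmp["delta_beta"].to_numpy()),
                     index=dmp.index)


def rrho_map(dmp_a: pd.DataFrame, dmp_b: pd.DataFrame,
             step: int | None = None) -> RRHOResult:
    """Rank-rank hypergeometric overlap map of two DMP tables.

    Both lists are ranked by -log10(p) signed by the direction of effect,
    descending (hypermethylated-and-significant first).  At each grid point
    (i*step, j*step) the one-sided hypergeometric upper-tail p of the
    overlap between the top i*step of A and top j*step of B is stored as
    -log10 p, signed positive for over-enrichment and negative for
    depletion, capped at +/-300.  The near corner of the grid carries the
    up/up concordance signal; because the bottom-tail overlap is an affine
    function of the top-tail overlap, the far corner carries down/down.
    """
    if set(dmp_a.index) != set(dmp_b.index):
        raise ValueError("RRHO requires identical probe sets in both tables")
    n = len(dmp_a)
    if step is None:
        step = max(1, n // 100)
    score_a = _signed_score(dmp_a)
    score_b = _signed_score(dmp_b).reindex(score_a.index)
    # descending score; deterministic tie-break on probe id
    order_a = score_a.sort_values(ascending=False, kind="mergesort")
    order_b = score_b.sort_values(ascending=False, kind="mergesort")
    rank_a = pd.Series(np.arange(n), index=order_a.index)
    rank_b = pd.Series(np.arange(n), index=order_b.index)
    ra = rank_a.reindex(score_a.index).to_numpy()
    rb = rank_b.reindex(score_a.index).to_numpy()

    thresholds = np.arange(step, n + 1, step)
    if thresholds[-1] != n:
        thresholds = np.append(thresholds, n)
    edges = np.concatenate([[0], thresholds])
    H, _, _ = np.histogram2d(ra, rb, bins=[edges, edges])
    overlap = H.cumsum(axis=0).cumsum(axis=1)  # |top_i(A) & top_j(B)|

    ti = thresholds[:, None].astype(float)
    tj = thresholds[None, :].astype(float)
    expected = ti * tj / n
    p_over = hypergeom.sf(overlap - 1, n, ti.astype(int), tj.astype(int))
    p_under = hypergeom.cdf(overlap, n, ti.astype(int), tj.astype(int))
    with np.errstate(divide="ignore"):
        val = np.where(overlap >= expected,
                       -np.log10(np.maximum(p_over, 1e-320)),
                       np.log10(np.maximum(p_under, 1e-320)))
    val = np.clip(val, -NEGLOG_CAP, NEGLOG_CAP)
    grid = pd.DataFrame(val, index=thresholds, columns=thresholds)
    flat = np.unravel_index(np.argmax(val), val.shape)
    return RRHOResult(grid=grid, step=step, n=n,
                      max_value=float(val[flat]),
                      max_at=(int(thresholds[flat[0]]),
                              int(thresholds[flat[1]])),
                      overlap=pd.DataFrame(overlap, index=thresholds,
                                           columns=thresholds))


def max_concordant_signal(res: RRHOResult) -> float:
    """Largest enrichment value in the two concordant quadrants (thresholds
    both below n/2 = up/up; both above = down/down)."""
    t = res.grid.index.to_numpy()
    half = res.n / 2
    lo = np.ix_(t <= half, t <= half)
    hi = np.ix_(t >= half, t >= half)
    vals = [res.grid.to_numpy()[lo].max() if (t <= half).any() else -np.inf,
            res.grid.to_numpy()[hi].max() if (t >= half).any() else -np.inf]
    return float(max(vals))


def concordant_cpgs(dmp_f: pd.DataFrame, dmp_m: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """CpGs with raw p < alpha in both sexes and the same direction of
    effect, partitioned into up- and down-regulated."""
    common = dmp_f.index.intersection(dmp_m.index)
    f = dmp_f.loc[common]
    m = dmp_m.loc[common]
    mask = (f["p"] < alpha) & (m["p"] < alpha) & \
        (np.sign(f["delta_beta"]) == np.sign(m["delta_beta"])) & \
        (f["delta_beta"] != 0)
    out = pd.DataFrame({
        "delta_female": f.loc[mask, "delta_beta"],
        "delta_male": m.loc[mask, "delta_beta"],
        "p_female": f.loc[mask, "p"],
        "p_male": m.loc[mask, "p"],
    })
    out["direction"] = np.where(out["delta_female"] > 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# magnitude comparison
# ---------------------------------------------------------------------------

@dataclass
class MagnitudeComparison:
    label: str
    n: int
    slope: float                      # male delta regressed on female delta
    intercept: float
    mean_abs_female: float
    mean_abs_male: float
    paired_t: float
    paired_t_p: float
    spearman_rho: float
    spearman_p: float


def magnitude_comparison(dmp_f: pd.DataFrame, dmp_m: pd.DataFrame,
                         subset=None, label: str = "all"
                         ) -> MagnitudeComparison:
    """Compare the magnitude of methylation changes between sexes.

    OLS slope (with intercept) of the male delta-beta on the female
    delta-beta — a slope below 1 means larger effects in females; paired
    two-sided t-test on |delta_f| - |delta_m|; Spearman correlation of the
    signed deltas.
    """
    common = dmp_f.index.intersection(dmp_m.index)
    if subset is not None:
        common = common.intersection(pd.Index(subset))
    if len(common) < 3:
        raise ValueError(f"magnitude comparison needs >= 3 probes, got "
                         f"{len(common)}")
    df = dmp_f.loc[common, "delta_beta"].to_numpy(float)
    dm = dmp_m.loc[common, "delta_beta"].to_numpy(float)
    lr = stats.linregress(df, dm)
    if np.allclose(np.abs(df), np.abs(dm)):
        tt_stat, tt_p = 0.0, 1.0   # zero paired differences: no evidence
    else:
        tt = stats.ttest_rel(np.abs(df), np.abs(dm))
        tt_stat, tt_p = tt.statistic, tt.pvalue
    rho = stats.spearmanr(df, dm)
    return MagnitudeComparison(
        label=label, n=len(common),
        slope=float(lr.slope), intercept=float(lr.intercept),
        mean_abs_female=float(np.abs(df).mean()),
        mean_abs_male=float(np.abs(dm).mean()),
        paired_t=float(tt_stat), paired_t_p=float(tt_p),
        spearman_rho=float(rho.statistic), spearman_p=float(rho.pvalue))


# ---------------------------------------------------------------------------
# baseline sex differences (sDMPs)
# ---------------------------------------------------------------------------

def call_sdmp(betas: pd.DataFrame, samplesheet: pd.DataFrame,
              covariates=(), extra_covariates: pd.DataFrame | None = None,
              annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Baseline sex-difference DMPs on control subjects only.

    Fits the moderated model with sex as the contrast (delta = F - M) on
    controls and BH-adjusts over all tested CpGs.
    """
    sheet = samplesheet.loc[betas.columns]
    ctrl = sheet.index[sheet["diagnosis"].astype(str) == "control"]
    sheet = sheet.loc[ctrl]
    if sheet["sex"].astype(str).nunique() < 2:
        raise ValueError("sDMP calling requires both sexes among controls")
    table = fit_dmp(betas.loc[:, ctrl], sheet, covariates=covariates,
                    stratum="combined", contrast="sex",
                    extra_covariates=extra_covariates)
    table["stratum"] = "sex_baseline"
    return adjust_fdr(table)


# ---------------------------------------------------------------------------
# 2x2 enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    a: int                            # |hit & ref|
    b: int                            # |hit \ ref|
    c: int                            # |ref \ hit|
    d: int                            # |universe \ (hit | ref)|
    odds_ratio: float                 # conditional MLE (primary)
    sample_odds_ratio: float
    p: float                          # Fisher exact, two-sided
    hit_label: str = "hits"
    ref_label: str = "reference"


def enrichment_or(hit_set, reference_set, universe,
                  hit_label: str = "hits",
                  ref_label: str = "reference") -> EnrichmentResult:
    """Fisher 2x2 enrichment of one set in another within a universe.

    The primary odds ratio is the conditional maximum-likelihood estimate
    (the one a Fisher exact test is built around); the simple sample odds
    ratio a*d/(b*c) is reported alongside.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    hit = set(hit_set)
    ref = set(reference_set)
    if not hit <= universe:
        raise ValueError("hit set must be a subset of the universe")
    if not ref <= universe:
        raise ValueError("reference set must be a subset of the universe")
    a = len(hit & ref)
    b = len(hit - ref)
    c = len(ref - hit)
    d = len(universe) - a - b - c
    return enrichment_from_counts(a, b, c, d, hit_label, ref_label)


def enrichment_from_counts(a: int, b: int, c: int, d: int,
                           hit_label: str = "hits",
                           ref_label: str = "reference") -> EnrichmentResult:
    """Enrichment statistics straight from 2x2 counts."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("2x2 counts must be non-negative integers")
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    cond = float(_odds_ratio(table, kind="conditional").statistic)
    if b * c > 0:
        sample = a * d / (b * c)
    else:
        sample = np.inf if a * d > 0 else 0.0
    return EnrichmentResult(a=int(a), b=int(b), c=int(c), d=int(d),
                            odds_ratio=cond, sample_odds_ratio=float(sample),
                            p=p, hit_label=hit_label, ref_label=ref_label)
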