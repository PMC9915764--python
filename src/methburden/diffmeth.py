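"""Sex-stratified and interaction differential methylation.

Per CpG, an ordinary least squares fit of the response (beta by default,
M-value optionally) on the contrast of interest plus covariates; residual
variances are shrunk across probes by empirical Bayes — a scaled
inverse-chi-square prior fit to the observed variances by the method of
moments on log s^2 yields prior degrees of freedom d0 and prior variance
s0^2, and the moderated t uses the posterior variance

    s~^2 = (d0 s0^2 + d s^2) / (d0 + d)

on d + d0 degrees of freedom.  The effect size delta-beta (case - control,
or F - M for the sex-baseline contrast) is always reported on the beta
scale, matching how methylation effect sizes are read.

BH false-discovery adjustment runs within declared probe families:
genome-wide analyses adjust over all tested CpGs in one family, while
chromosome-X- or Y-restricted analyses adjust within the sex-chromosome
subset only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.special import logit
from statsmodels.stats.multitest import multipletests

_EPS = 1e-6

STRATA = ("female", "male", "combined", "interaction", "sex_baseline")


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Fit a scaled inverse-chi-square prior to sample variances.

    Moments of log(s^2) identify the prior: the excess variance of
    log(s^2) over trigamma(df/2) is trigamma(d0/2).  Returns
    ``(d0, s0^2, posterior variances)``; d0 = inf when the variances are
    no more dispersed than chi-square sampling alone.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        # degenerate: no spread to fit a prior; pass variances through
        return np.inf, float(np.median(s2)), s2.copy()
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(z, ddof=1) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2))
    else:
        d0 = np.inf
        s02 = np.exp(np.mean(e))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return float(d0), float(s02), post


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(samplesheet: pd.DataFrame, contrast_col: str,
                 contrast_positive: str, covariates=(),
                 extra: pd.DataFrame | None = None,
                 interaction_with: str | None = None,
                 interaction_positive: str | None = None,
                 ):
    """Design matrix with intercept, contrast indicator, covariates.

    Categorical covariates are one-hot encoded (first level dropped);
    zero-variance columns are dropped with a warning.  When
    ``interaction_with`` is given the design also carries that indicator
    and the product term, whose coefficient is reported.
    """
    n = len(samplesheet)
    cols = ["intercept"]
    mats = [np.ones(n)]
    contrast = (samplesheet[contrast_col].astype(str)
                == contrast_positive).to_numpy(float)
    cols.append(contrast_col)
    mats.append(contrast)
    if interaction_with is not None:
        other = (samplesheet[interaction_with].astype(str)
                 == interaction_positive).to_numpy(float)
        cols += [interaction_with, f"{contrast_col}:{interaction_with}"]
        mats += [other, contrast * other]
    for cov in covariates:
        if cov == contrast_col:
            raise ValueError(f"contrast variable {cov!r} cannot also be a "
                             "covariate")
        s = samplesheet[cov]
        if s.dtype.kind in "ifu":
            cols.append(cov)
            mats.append(s.to_numpy(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=cov,
                                     drop_first=True)
            for c in dummies.columns:
                cols.append(c)
                mats.append(dummies[c].to_numpy(float))
    if extra is not None:
        ex = extra.loc[samplesheet.index]
        for c in ex.columns:
            cols.append(str(c))
            mats.append(ex[c].to_numpy(float))
    X = np.column_stack(mats)
    keep = [0, 1] + ([2, 3] if interaction_with is not None else [])
    for j in range(len(keep), X.shape[1]):
        if X[:, j].std() < 1e-12:
            warnings.warn(f"dropping zero-variance design column "
                          f"{cols[j]!r}")
        else:
            keep.append(j)
    X = X[:, keep]
    cols = [cols[j] for j in keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_columns(X, cols)
        raise ValueError(f"design is rank deficient; aliased columns: "
                         f"{aliased}")
    return X, cols


def _aliased_columns(X: np.ndarray, cols) -> list:
    aliased = []
    base = X[:, [0]]
    for j in range(1, X.shape[1]):
        cand = np.hstack([base, X[:, [j]]])
        if np.linalg.matrix_rank(cand) == base.shape[1]:
            aliased.append(cols[j])
        else:
            base = cand
    return aliased


# ---------------------------------------------------------------------------
# per-probe moderated fit
# ---------------------------------------------------------------------------

def _moderated_fit(Y: np.ndarray, X: np.ndarray, coef_idx: int):
    """Vectorized OLS across probes + EB moderation of one coefficient.

    Returns (coef, se_mod, t, p, df_total, d0)."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    coef_all = Y @ pinv.T                       # probes x k
    fitted = coef_all @ X.T
    resid = Y - fitted
    df = n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = (resid ** 2).sum(axis=1) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    v = xtx_inv[coef_idx, coef_idx]
    d0, _s02, s2_post = squeeze_var(s2, df)
    coef = coef_all[:, coef_idx]
    se = np.sqrt(np.maximum(s2_post, 0.0) * v)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
        t = np.where((se == 0) & (coef != 0), np.inf * np.sign(coef), t)
    df_total = df + (d0 if np.isfinite(d0) else 1e6)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where((se == 0) & (coef == 0), 1.0, p)
    return coef, se, t, p, df_total, d0


def _select_stratum(samplesheet: pd.DataFrame, stratum: str) -> pd.Index:
    if stratum == "female":
        return samplesheet.index[samplesheet["sex"].astype(str) == "F"]
    if stratum == "male":
        return samplesheet.index[samplesheet["sex"].astype(str) == "M"]
    return samplesheet.index


def fit_dmp(betas: pd.DataFrame, samplesheet: pd.DataFrame,
            covariates=(), stratum: str = "combined",
            contrast: str = "diagnosis", contrast_positive: str | None = None,
            response: str = "beta", extra_covariates: pd.DataFrame | None = None,
            annotation: pd.DataFrame | None = None,
            min_group: int = 3) -> pd.DataFrame:
    """Moderated differential methylation within one stratum.

    ``contrast='diagnosis'`` compares case vs control (delta = case -
    control); ``contrast='sex'`` compares F vs M (delta = F - M, so a
    female-hypermethylated probe gets a positive delta).  chrY probes are
    excluded from the female stratum when an annotation is supplied (no Y
    chromosome, so the values are pure cross-hybridization noise).
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    if response not in ("beta", "mvalue"):
        raise ValueError("response must be 'beta' or 'mvalue'")
    if contrast_positive is None:
        contrast_positive = {"diagnosis": "case", "sex": "F"}[contrast]
    idx = _select_stratum(samplesheet, stratum)
    sheet = samplesheet.loc[idx]
    levels = sheet[contrast].astype(str)
    n_pos = int((levels == contrast_positive).sum())
    n_neg = int(len(levels) - n_pos)
    if n_pos < min_group or n_neg < min_group:
        raise ValueError(
            f"stratum {stratum!r} needs >= {min_group} samples per "
            f"{contrast} group (got {n_pos}/{n_neg})")

    probes = betas.index
    if annotation is not None and stratum == "female":
        chry = annotation.reindex(probes)["chrom"].astype(str) == "Y"
        probes = probes[~chry.to_numpy()]
    B = betas.loc[probes, idx].to_numpy(float)

    X, _cols = build_design(sheet, contrast, contrast_positive, covariates,
                            extra=extra_covariates)
    Y = B if response == "beta" else logit(np.clip(B, _EPS, 1 - _EPS))
    coef, se, t, p, df_total, d0 = _moderated_fit(Y, X, coef_idx=1)
    if response == "beta":
        delta = coef
    else:  # report the effect on the beta scale regardless of the response
        pinv = np.linalg.pinv(X)
        delta = (B @ pinv.T)[:, 1]

    out = pd.DataFrame(
        dict(stratum=stratum, family="autosomal+all", delta_beta=delta,
             moderated_t=t, p=p, adj_p=np.nan, se=se),
        index=pd.Index(probes, name="probe_id"),
    )
    out.attrs["d0"] = d0
    out.attrs["df_total"] = df_total
    out.attrs["n_case"] = n_pos
    out.attrs["n_control"] = n_neg
    return out


def fit_interaction(betas: pd.DataFrame, samplesheet: pd.DataFrame,
                    covariates=(), response: str = "beta",
                    extra_covariates: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """Sex-by-diagnosis interaction model on the full cohort.

    The reported coefficient is the diagnosis x sex product term, i.e. the
    female case-control effect minus the male case-control effect
    (delta_F - delta_M on the response scale).
    """
    cells = pd.crosstab(samplesheet["sex"].astype(str),
                        samplesheet["diagnosis"].astype(str))
    if cells.shape != (2, 2) or (cells == 0).any().any():
        raise ValueError("interaction model requires all four sex x "
                         "diagnosis cells to be populated")
    X, _cols = build_design(samplesheet, "diagnosis", "case", covariates,
                            extra=extra_covariates,
                            interaction_with="sex", interaction_positive="F")
    B = betas.loc[:, samplesheet.index].to_numpy(float)
    Y = B if response == "beta" else logit(np.clip(B, _EPS, 1 - _EPS))
    coef, se, t, p, df_total, d0 = _moderated_fit(Y, X, coef_idx=3)
    if response != "beta":
        pinv = np.linalg.pinv(X)
        coef = (B @ pinv.T)[:, 3]
    out = pd.DataFrame(
        dict(stratum="interaction", family="autosomal+all", delta_beta=coef,
             moderated_t=t, p=p, adj_p=np.nan, se=se),
        index=pd.Index(betas.index, name="probe_id"),
    )
    out.attrs["d0"] = d0
    return out


# ---------------------------------------------------------------------------
# FDR and replication
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr(dmp: pd.DataFrame,
               families: pd.Series | dict | str | None = None) -> pd.DataFrame:
    """BH within each declared probe family.

    ``families`` maps probe_id -> family label (Series/dict), names a
    column of ``dmp``, or is None (one family over all probes).  Probes in
    an empty family are skipped with a warning.
    """
    out = dmp.copy()
    if families is None:
        fam = out["family"] if "family" in out else \
            pd.Series("autosomal+all", index=out.index)
    elif isinstance(families, str):
        fam = out[families]
    else:
        fam = pd.Series(families).reindex(out.index)
    out["family"] = fam
    out["adj_p"] = np.nan
    for label, grp in out.groupby(fam, dropna=False):
        if len(grp) == 0 or grp["p"].isna().all():
            warnings.warn(f"family {label!r} is empty; skipped")
            continue
        out.loc[grp.index, "adj_p"] = bh_adjust(grp["p"].to_numpy())
    return out


def meta_analyze(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance meta-analysis across studies sharing probes.

    Reports both the fixed-effect pooled estimate and a DerSimonian-Laird
    random-effects estimate with its tau^2.  A single study passes through
    flagged as such.
    """
    names = list(tables)
    if len(names) == 1:
        t = tables[names[0]].copy()
        t["n_studies"] = 1
        t["tau2"] = 0.0
        warnings.warn("single study supplied; meta-analysis is a "
                      "pass-through")
        return t
    common = tables[names[0]].index
    for n in names[1:]:
        common = common.intersection(tables[n].index)
    if len(common) == 0:
        raise ValueError("no probes shared across studies")
    d = np.column_stack([tables[n].loc[common, "delta_beta"] for n in names])
    se = np.column_stack([tables[n].loc[common, "se"] for n in names])
    se = np.maximum(se, 1e-12)
    w = 1.0 / se ** 2
    k = len(names)
    fe = (w * d).sum(axis=1) / w.sum(axis=1)
    fe_se = np.sqrt(1.0 / w.sum(axis=1))
    q = (w * (d - fe[:, None]) ** 2).sum(axis=1)
    denom = w.sum(axis=1) - (w ** 2).sum(axis=1) / w.sum(axis=1)
    tau2 = np.maximum(0.0, (q - (k - 1)) / np.maximum(denom, 1e-12))
    w_re = 1.0 / (se ** 2 + tau2[:, None])
    re = (w_re * d).sum(axis=1) / w_re.sum(axis=1)
    re_se = np.sqrt(1.0 / w_re.sum(axis=1))
    z = re / re_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        dict(delta_beta=re, se=re_se, p=p, adj_p=np.nan, tau2=tau2,
             fixed_delta=fe, fixed_se=fe_se,
             fixed_p=2.0 * stats.norm.sf(np.abs(fe / fe_se)),
             n_studies=k),
        index=pd.Index(common, name="probe_id"),
    )
    for n in names:
        out[f"delta_{n}"] = tables[n].loc[common, "delta_beta"]
    return out


def call_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Replication flags for the discovery-significant DMPs.

    BH is re-applied within the discovery-significant subset only (the
    replication multiple-testing family is just those probes), and a DMP
    replicates iff its replication adj.p < alpha with the same direction
    of effect as in discovery.
    """
    sig = discovery[discovery["adj_p"] < alpha]
    if len(sig) == 0:
        raise ValueError("discovery-significant set is empty")
    common = sig.index.intersection(replication.index)
    if len(common) == 0:
        raise ValueError("no discovery-significant probes overlap the "
                         "replication table")
    rep = replication.loc[common].copy()
    rep["adj_p"] = bh_adjust(rep["p"].to_numpy())
    same_sign = np.sign(rep["delta_beta"]) == \
        np.sign(sig.loc[common, "delta_beta"])
    rep["discovery_delta"] = sig.loc[common, "delta_beta"]
    rep["replicated"] = (rep["adj_p"] < alpha) & same_sign
    return rep
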