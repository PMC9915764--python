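"""Quality control and preprocessing of 450K-style beta matrices.

Stages, in the order a cohort is normally processed:

1. :func:`filter_probes` — detection-p / beadcount rules plus annotation
   flag filters (non-CpG, SNP-related, multi-mapping, low-quality probes);
   sex-chromosome probes are deliberately retained.
2. :func:`drop_bad_samples` — remove samples with too many failed probes.
3. :func:`predict_sex` — 2-means clustering on (mean chrX beta, mean chrY
   beta); mismatches against the reported sex are flagged, never dropped
   automatically.
4. :func:`bmiq_normalize` — beta-mixture quantile dilation: per sample, a
   3-state (unmethylated / hemimethylated / methylated) beta mixture is fit
   by EM separately to type-I and type-II probes, and the type-II U and M
   states are mapped onto the type-I quantiles; the H state is linearly
   dilated between them.  Type-I values are left bit-identical.
5. :func:`estimate_cell_proportions` — reference-based deconvolution by
   constrained least squares (proportions >= 0, sum <= 1).
6. :func:`correct_batch` — ComBat-style location/scale parametric empirical
   Bayes on the logit scale, protecting the biological design.
7. :func:`estimate_svs` — surrogate variables as the top right singular
   vectors of the design residual, with the dimension chosen by permutation
   parallel analysis.

All beta outputs remain strictly inside (0, 1) and every operation
preserves probe/sample identifier alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

_EPS = 1e-6
FLAG_ORDER = ("non_cpg", "snp_related", "multi_map", "low_quality")


@dataclass
class QCThresholds:
    detection_p_max: float = 0.01
    min_beads: int = 3
    max_bad_sample_frac: float = 0.05
    max_filtered_probe_frac_per_sample: float = 0.10

    def validate(self) -> None:
        if self.detection_p_max <= 0 or self.min_beads <= 0:
            raise ValueError("thresholds must be positive")
        for name in ("max_bad_sample_frac", "max_filtered_probe_frac_per_sample"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class FilterReport:
    """Per-criterion removal counts (in application order) and per-sample
    failed-probe fractions used later by :func:`drop_bad_samples`."""

    removed_per_criterion: dict = field(default_factory=dict)
    removed_probes: dict = field(default_factory=dict)
    per_sample_bad_frac: pd.Series | None = None
    n_input: int = 0
    n_output: int = 0


def _clip_beta(values: np.ndarray) -> np.ndarray:
    return np.clip(values, _EPS, 1 - _EPS)


def _logit_df(betas: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(logit(_clip_beta(betas.to_numpy(float))),
                        index=betas.index, columns=betas.columns)


def _expit_df(m: np.ndarray, like: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(_clip_beta(expit(m)), index=like.index,
                        columns=like.columns)


# ---------------------------------------------------------------------------
# probe / sample filtering
# ---------------------------------------------------------------------------

def filter_probes(betas: pd.DataFrame, annotation: pd.DataFrame,
                  detection_p: pd.DataFrame | None,
                  beadcount: pd.DataFrame | None,
                  thresholds: QCThresholds | None = None,
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove probes failing any QC criterion, in a fixed order.

    Criteria: (1) detection p above ``detection_p_max`` in more than
    ``max_bad_sample_frac`` of samples (strict >); (2) fewer than
    ``min_beads`` beads in at least ``max_bad_sample_frac`` of samples
    (>=, matching the "in at least 5% of samples" rule wording); then the
    annotation flags non_cpg, snp_related, multi_map, low_quality.
    Sex-chromosome probes are retained.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    thresholds.validate()
    if detection_p is None:
        raise ValueError("missing companion matrix: detection_p")
    if beadcount is None:
        raise ValueError("missing companion matrix: beadcount")
    for name, m in (("detection_p", detection_p), ("beadcount", beadcount)):
        if not m.index.equals(betas.index) or not m.columns.equals(betas.columns):
            raise ValueError(f"{name} matrix is not aligned with the beta matrix")
    if not annotation.index.equals(betas.index):
        annotation = annotation.loc[betas.index]

    report = FilterReport(n_input=betas.shape[0])
    det_bad = detection_p.to_numpy() > thresholds.detection_p_max
    bead_bad = beadcount.to_numpy() < thresholds.min_beads
    report.per_sample_bad_frac = pd.Series(
        (det_bad | bead_bad).mean(axis=0), index=betas.columns,
        name="bad_probe_frac")

    keep = np.ones(betas.shape[0], dtype=bool)

    def _apply(name: str, fail: np.ndarray) -> None:
        newly = fail & keep
        report.removed_per_criterion[name] = int(newly.sum())
        report.removed_probes[name] = betas.index[newly].tolist()
        keep[newly] = False

    _apply("detection_p", det_bad.mean(axis=1) > thresholds.max_bad_sample_frac)
    _apply("beadcount", bead_bad.mean(axis=1) >= thresholds.max_bad_sample_frac)
    for flag in FLAG_ORDER:
        fail = annotation[flag].to_numpy(bool) if flag in annotation else \
            np.zeros(betas.shape[0], dtype=bool)
        _apply(flag, fail)

    out = betas.loc[keep]
    report.n_output = out.shape[0]
    return out, report


def drop_bad_samples(betas: pd.DataFrame, report: FilterReport,
                     thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Drop samples whose failed-probe fraction strictly exceeds the
    threshold; a sample exactly at the threshold is retained."""
    if thresholds is None:
        thresholds = QCThresholds()
    if report.per_sample_bad_frac is None:
        raise ValueError("filter report carries no per-sample failure fractions")
    frac = report.per_sample_bad_frac.reindex(betas.columns)
    keep = frac <= thresholds.max_filtered_probe_frac_per_sample
    dropped = betas.columns[~keep]
    if len(dropped):
        log.info("dropping %d samples over the failed-probe threshold: %s",
                 len(dropped), list(dropped))
    return betas.loc[:, keep]


# ---------------------------------------------------------------------------
# sex prediction
# ---------------------------------------------------------------------------

def predict_sex(betas: pd.DataFrame, annotation: pd.DataFrame,
                reported_sex: pd.Series | None = None
                ) -> tuple[pd.DataFrame, list]:
    """Two-cluster sex assignment from sex-chromosome methylation.

    Samples are clustered by 2-means on standardized (mean chrX beta,
    mean chrY beta); the cluster with the higher chrY mean is labeled M.
    Returns the per-sample table and, when a reported sex is supplied, the
    list of samples whose prediction disagrees (they are reported, never
    dropped here).
    """
    ann = annotation.reindex(betas.index)
    x_probes = betas.index[ann["chrom"].astype(str) == "X"]
    y_probes = betas.index[ann["chrom"].astype(str) == "Y"]
    if len(x_probes) == 0 or len(y_probes) == 0:
        raise ValueError("sex prediction requires both chrX and chrY probes")
    feats = pd.DataFrame({
        "mean_chrx": betas.loc[x_probes].mean(axis=0),
        "mean_chry": betas.loc[y_probes].mean(axis=0),
    })
    z = (feats - feats.mean()) / feats.std().replace(0, 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(z.to_numpy())
    labels = km.labels_
    y_means = [feats["mean_chry"][labels == k].mean() for k in (0, 1)]
    male_cluster = int(np.argmax(y_means))
    feats["predicted_sex"] = np.where(labels == male_cluster, "M", "F")
    mismatches: list = []
    if reported_sex is not None:
        rep = reported_sex.reindex(feats.index)
        mismatches = feats.index[feats["predicted_sex"] != rep].tolist()
        feats["reported_sex"] = rep
    return feats, mismatches


# ---------------------------------------------------------------------------
# BMIQ normalization
# ---------------------------------------------------------------------------

def _beta_mm(mean: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments beta parameters, guarded away from degeneracy."""
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    var = np.clip(var, 1e-6, mean * (1 - mean) * 0.999)
    nu = mean * (1 - mean) / var - 1.0
    return np.maximum(mean * nu, 1e-2), np.maximum((1 - mean) * nu, 1e-2)


def _beta_logpdf(x: np.ndarray, logx: np.ndarray, log1mx: np.ndarray,
                 a: float, b: float) -> np.ndarray:
    return (a - 1) * logx + (b - 1) * log1mx - special.betaln(a, b)


def fit_beta_mixture(x: np.ndarray, max_iter: int = 200, tol: float = 1e-4,
                     init_centers=(0.2, 0.5, 0.8)):
    """EM fit of a 3-state beta mixture (states ordered U < H < M).

    States are initialized by nearest-center assignment; each M step
    re-estimates the beta parameters by weighted method of moments.
    Convergence is declared on the log-likelihood increment (``tol``,
    relative) or on the parameters stabilizing — the MoM-EM likelihood has
    a long flat tail during which the fitted mapping no longer changes.
    Returns ``(weights, a, b, converged)``.
    """
    x = np.clip(np.asarray(x, float), _EPS, 1 - _EPS)
    logx = np.log(x)
    log1mx = np.log1p(-x)
    centers = np.asarray(init_centers)
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    resp = np.zeros((len(x), 3))
    resp[np.arange(len(x)), assign] = 1.0
    w = resp.mean(axis=0)
    a = np.zeros(3)
    b = np.zeros(3)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        tot = resp.sum(axis=0)
        if np.any(tot < 2):  # a state emptied out; keep previous params
            tot = np.maximum(tot, 2)
        mean = (resp * x[:, None]).sum(axis=0) / tot
        var = (resp * (x[:, None] - mean[None, :]) ** 2).sum(axis=0) / tot
        a_old, b_old = a, b
        a, b = _beta_mm(mean, var)
        logpdf = np.stack(
            [_beta_logpdf(x, logx, log1mx, a[k], b[k]) for k in range(3)],
            axis=1)
        joint = logpdf + np.log(np.maximum(w, 1e-12))[None, :]
        m = joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        ll = lse.sum()
        resp = np.exp(joint - lse[:, None])
        w = resp.mean(axis=0)
        param_drift = max(np.abs(a - a_old).max(), np.abs(b - b_old).max())
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0) \
                or param_drift < 1e-3 * (1.0 + np.abs(a_old).max()):
            converged = True
            break
        ll_old = ll
    order = np.argsort(a / (a + b))  # sort states by mean: U, H, M
    return w[order], a[order], b[order], converged


def _bmiq_one_sample(b1: np.ndarray, b2: np.ndarray,
                     max_iter: int, tol: float) -> np.ndarray | None:
    """Map one sample's type-II betas onto the type-I distribution.

    Returns the transformed type-II values, or None when either mixture
    fit fails to converge (the caller falls back to identity).
    """
    w1, a1, bb1, ok1 = fit_beta_mixture(b1, max_iter, tol)
    w2, a2, bb2, ok2 = fit_beta_mixture(b2, max_iter, tol)
    if not (ok1 and ok2):
        return None
    x = np.clip(b2, _EPS, 1 - _EPS)
    logpdf = np.stack([stats.beta.logpdf(x, a2[k], bb2[k])
                       + np.log(max(w2[k], 1e-12)) for k in range(3)], axis=1)
    state = logpdf.argmax(axis=1)  # 0=U, 1=H, 2=M
    out = x.copy()

    u_mask = state == 0
    if u_mask.any():
        q = stats.beta.cdf(x[u_mask], a2[0], bb2[0])
        out[u_mask] = stats.beta.ppf(q, a1[0], bb1[0])
    m_mask = state == 2
    if m_mask.any():
        q = stats.beta.sf(x[m_mask], a2[2], bb2[2])  # upper-tail anchoring
        out[m_mask] = stats.beta.isf(q, a1[2], bb1[2])
    h_mask = state == 1
    if h_mask.any():
        lo_new = out[u_mask].max() if u_mask.any() else \
            float(stats.beta.ppf(0.99, a1[0], bb1[0]))
        hi_new = out[m_mask].min() if m_mask.any() else \
            float(stats.beta.isf(0.99, a1[2], bb1[2]))
        lo_old, hi_old = x[h_mask].min(), x[h_mask].max()
        if hi_new <= lo_new or hi_old <= lo_old:
            pass  # degenerate span: leave H untouched
        else:
            scale = (hi_new - lo_new) / (hi_old - lo_old)
            out[h_mask] = lo_new + (x[h_mask] - lo_old) * scale
    return np.clip(out, _EPS, 1 - _EPS)


def bmiq_normalize(betas: pd.DataFrame, annotation: pd.DataFrame,
                   max_iter: int = 200, tol: float = 1e-4) -> pd.DataFrame:
    """Per-sample BMIQ: type-II probes adjusted onto the type-I
    distribution; type-I probes pass through bit-identical.  Samples whose
    EM fails to converge are left unchanged with a logged warning."""
    ann = annotation.reindex(betas.index)
    t1 = (ann["design_type"] == "I").to_numpy()
    t2 = (ann["design_type"] == "II").to_numpy()
    if not t1.any() or not t2.any():
        raise ValueError("BMIQ requires both type-I and type-II probes")
    out = betas.copy()
    vals = out.to_numpy(float)
    for j, sample in enumerate(betas.columns):
        mapped = _bmiq_one_sample(vals[t1, j], vals[t2, j], max_iter, tol)
        if mapped is None:
            warnings.warn(f"BMIQ EM did not converge for sample {sample}; "
                          "leaving it unnormalized")
            continue
        vals[t2, j] = mapped
    out.iloc[:, :] = vals
    return out


# ---------------------------------------------------------------------------
# cell-type deconvolution
# ---------------------------------------------------------------------------

def estimate_cell_proportions(betas: pd.DataFrame,
                              reference: pd.DataFrame,
                              min_probes: int = 50) -> pd.DataFrame:
    """Reference-based cell deconvolution by constrained least squares.

    Per sample solves ``min ||beta - F rho||^2`` subject to ``rho >= 0``
    and ``sum(rho) <= 1`` over the probes shared with the reference.
    """
    common = betas.index.intersection(reference.index)
    if len(common) < min_probes:
        raise ValueError(
            f"only {len(common)} probes overlap the cell reference; "
            f"need at least {min_probes}")
    F = reference.loc[common].to_numpy(float)
    Y = betas.loc[common].to_numpy(float)
    k = F.shape[1]
    FtF = F.T @ F
    out = np.empty((betas.shape[1], k))
    cons = ({"type": "ineq", "fun": lambda r: 1.0 - r.sum()},)
    bounds = [(0.0, 1.0)] * k
    x0 = np.full(k, 1.0 / (k + 1))
    for j in range(Y.shape[1]):
        y = Y[:, j]
        Fty = F.T @ y
        res = minimize(
            lambda r: 0.5 * r @ FtF @ r - Fty @ r,
            x0, jac=lambda r: FtF @ r - Fty,
            bounds=bounds, constraints=cons, method="SLSQP")
        out[j] = np.clip(res.x, 0.0, 1.0)
    return pd.DataFrame(out, index=betas.columns, columns=reference.columns)


# ---------------------------------------------------------------------------
# ComBat-style batch correction
# ---------------------------------------------------------------------------

def _design_matrix(samplesheet: pd.DataFrame, columns) -> np.ndarray:
    parts = [np.ones((len(samplesheet), 1))]
    for col in columns:
        s = samplesheet[col]
        if s.dtype.kind in "ifu" and s.nunique() > 2:
            parts.append(s.to_numpy(float)[:, None])
        else:
            d = pd.get_dummies(s.astype(str), drop_first=True)
            parts.append(d.to_numpy(float))
    return np.hstack(parts)


def correct_batch(betas: pd.DataFrame, samplesheet: pd.DataFrame,
                  batch_col: str = "batch",
                  protect: tuple = ("diagnosis", "sex"),
                  max_iter: int = 100, tol: float = 1e-4) -> pd.DataFrame:
    """Location/scale parametric empirical-Bayes batch adjustment on the
    logit scale (ComBat-style), protecting the biological design.

    A single batch level passes through unchanged (with a log note); a
    batch perfectly confounded with a protected covariate raises an error
    naming the confounding.
    """
    sheet = samplesheet.loc[betas.columns]
    batch = sheet[batch_col].astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        log.info("single batch level; batch correction is the identity")
        return betas.copy()
    counts = batch.value_counts()
    if counts.min() < 2:
        raise ValueError("every batch must contain at least 2 samples")
    protect = [c for c in protect if c in sheet.columns]
    for col in protect:
        tab = pd.crosstab(batch, sheet[col].astype(str))
        if ((tab > 0).sum(axis=1) == 1).all() and \
                ((tab > 0).sum(axis=0) == 1).all():
            raise ValueError(
                f"batch '{batch_col}' is perfectly confounded with "
                f"protected covariate '{col}'")

    M = logit(_clip_beta(betas.to_numpy(float)))  # probes x samples
    n_probes, n_samples = M.shape
    B = pd.get_dummies(batch)[levels].to_numpy(float)  # samples x n_batch
    Xcov = _design_matrix(sheet, protect)[:, 1:]       # drop intercept
    X = np.hstack([B, Xcov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"batch '{batch_col}' design with protected covariates "
            f"{protect} is rank deficient (confounded)")
    coef, *_ = np.linalg.lstsq(X, M.T, rcond=None)     # (n_b + p) x probes
    gamma_hat_ls = coef[:len(levels)]                  # batch means
    nb = B.sum(axis=0)
    grand = (nb / n_samples) @ gamma_hat_ls            # weighted grand mean
    stand_mean = grand[None, :].T @ np.ones((1, n_samples)) \
        + (Xcov @ coef[len(levels):]).T
    resid = M - (X @ coef).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (M - stand_mean) / sd

    M_adj = M.copy()
    for li, level in enumerate(levels):
        idx = (batch == level).to_numpy()
        Zb = Z[:, idx]
        n_b = idx.sum()
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        # parametric priors (normal on gamma, inverse-gamma on delta)
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        d_bar = delta_hat.mean()
        d_var = max(delta_hat.var(ddof=1), 1e-12)
        lam = (2 * d_var + d_bar ** 2) / d_var
        theta = (d_bar * d_var + d_bar ** 3) / d_var
        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        ssq = ((Zb - gamma_star[:, None]) ** 2).sum(axis=1)
        for _ in range(max_iter):
            g_new = (t2 * n_b * gamma_hat + delta_star * g_bar) \
                / (t2 * n_b + delta_star)
            ssq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ssq) / (n_b / 2 + lam - 1)
            change = max(np.abs(g_new - gamma_star).max(),
                         np.abs(d_new - delta_star).max())
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        Z_adj = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
        M_adj[:, idx] = Z_adj * sd + stand_mean[:, idx]

    return _expit_df(M_adj, betas)


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------

def estimate_svs(betas: pd.DataFrame, design: pd.DataFrame | np.ndarray,
                 n_permutations: int = 20, quantile: float = 0.95,
                 seed: int = 0, n_sv: int | None = None
                 ) -> tuple[pd.DataFrame, int]:
    """Surrogate variables from the residual of logit(beta) on the design.

    The residual matrix is decomposed by SVD; the number of components k is
    chosen by permutation parallel analysis (each probe's residuals are
    permuted independently, and observed singular values must exceed the
    null's ``quantile`` percentile, counted from the top until the first
    failure).  Pass ``n_sv`` to fix k instead.  Returned SVs have zero mean
    and are mutually orthogonal.
    """
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) \
        else np.asarray(design, float)
    if X.ndim == 1:
        X = X[:, None]
    if not (X.std(axis=0) < 1e-12).any():  # ensure an intercept column
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    n_samples = X.shape[0]
    if n_samples != betas.shape[1]:
        raise ValueError("design rows must match samples")
    if n_samples < X.shape[1] + 2:
        raise ValueError("too few samples for the design "
                         f"({n_samples} samples, {X.shape[1]} covariates)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank deficient")

    M = logit(_clip_beta(betas.to_numpy(float)))
    H = X @ np.linalg.pinv(X)
    R = M - M @ H.T  # residualize each probe's sample vector
    sv_obs = np.linalg.svd(R, compute_uv=False)

    if n_sv is None:
        rng = np.random.default_rng(seed)
        max_k = min(R.shape) - 1
        null = np.empty((n_permutations, len(sv_obs)))
        for p in range(n_permutations):
            Mp = rng.permuted(M, axis=1)
            Rp = Mp - Mp @ H.T  # same residualization as the observed data
            null[p] = np.linalg.svd(Rp, compute_uv=False)
        thresh = np.quantile(null, quantile, axis=0)
        k = 0
        for i in range(max_k):
            if sv_obs[i] > thresh[i]:
                k += 1
            else:
                break
    else:
        k = int(n_sv)

    if k == 0:
        svs = pd.DataFrame(index=betas.columns)
    else:
        _, _, vt = np.linalg.svd(R, full_matrices=False)
        svs = pd.DataFrame(vt[:k].T, index=betas.columns,
                           columns=[f"sv_{i + 1}" for i in range(k)])
        svs -= svs.mean(axis=0)
    return svs, k
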