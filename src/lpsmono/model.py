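"""Normalized log-ratios and per-gene mixed-effects differential expression.

The measurement model for gene *g* on array *a*, duplicate spot *r* is

    M_{g,a,r} = mu_g + u_a + eps_{g,a,r},   u_a ~ N(0, tau^2),  eps ~ N(0, sigma^2)

the minimal mixed model consistent with duplicate spots within arrays.
With duplicates averaged per array (the default), inference on mu_g
reduces to the one-sample problem on per-array means, whose variance
sigma_B^2 = tau^2 + sigma^2/r is what the empirical-Bayes step shrinks.

Gene-wise variances are moderated toward an ensemble scale using a
scaled inverse-chi-square prior with fixed prior degrees of freedom;
significance comes from the moderated t on df + prior_df degrees of
freedom, the posterior probability of differential expression from a
two-component normal-mixture log-odds (B-statistic), and multiplicity
control from Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigurationError, DataError, ModelError
from .gpr import ArrayScan

log = logging.getLogger(__name__)

#: Lower bound on the moderated standard error (log2 units), guarding
#: against infinite statistics on degenerate (zero-variance) inputs.
SE_FLOOR = 1e-6


@dataclass
class RatioMatrix:
    """Genes x arrays matrix of log2(post/pre) expression ratios.

    ``M`` and ``A`` hold NaN where ``valid_mask`` is False; invalid cells
    are never silently zero.  Orientation: M > 0 always means the
    post-infusion sample is higher, regardless of dye assignment.
    """

    gene_ids: np.ndarray
    array_ids: np.ndarray
    M: np.ndarray            # log2 ratio, genes x arrays
    A: np.ndarray            # mean log2 intensity, genes x arrays
    valid_mask: np.ndarray   # bool, genes x arrays
    spot_count: np.ndarray   # spots aggregated per cell
    spot_level: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shape = (len(self.gene_ids), len(self.array_ids))
        for name in ("M", "A", "valid_mask", "spot_count"):
            if getattr(self, name).shape != shape:
                raise DataError(f"RatioMatrix.{name} shape mismatch")
        self.M = np.where(self.valid_mask, self.M, np.nan)
        self.A = np.where(self.valid_mask, self.A, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    def subset_genes(self, mask: np.ndarray) -> "RatioMatrix":
        return RatioMatrix(
            gene_ids=self.gene_ids[mask], array_ids=self.array_ids,
            M=self.M[mask], A=self.A[mask],
            valid_mask=self.valid_mask[mask], spot_count=self.spot_count[mask],
            spot_level=None)


def build_ratio_matrix(arrays: Sequence[ArrayScan],
                       qc_tables: Mapping[str, pd.DataFrame],
                       annotation: pd.DataFrame,
                       keep_spots: bool = False,
                       min_pass_fraction: float = 0.01) -> RatioMatrix:
    """Background-subtract, orient by dye assignment, and aggregate to genes.

    Per passing spot, ``M_raw = log2(net_post / net_pre)`` with net
    intensity = foreground median - background median; cells with a
    non-positive net intensity in either channel are invalid.  Duplicate
    passing spots of one gene on one array are averaged.

    All arrays must share one contrast and arm (the two arms of the study
    are analysed separately).  An array where fewer than
    ``min_pass_fraction`` of spots pass QC is rejected.
    """
    if not arrays:
        raise DataError("no arrays given")
    contrasts = {a.contrast for a in arrays}
    arms = {a.arm for a in arrays}
    if len(contrasts) > 1 or len(arms) > 1:
        raise DataError(
            f"arrays mix contrasts/arms: {sorted(contrasts)}, {sorted(arms)}")

    gene_map = dict(zip(annotation["spot_id"], annotation["gene_id"]))
    gene_ids = np.array(sorted(set(annotation["gene_id"].dropna())))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    array_ids = np.array([a.array_id for a in arrays])

    n_g, n_a = len(gene_ids), len(arrays)
    m_sum = np.zeros((n_g, n_a))
    a_sum = np.zeros((n_g, n_a))
    count = np.zeros((n_g, n_a), dtype=int)
    spot_rows = []

    for j, scan in enumerate(arrays):
        qc = qc_tables[scan.array_id]
        passed = qc["passed"].to_numpy()
        if len(passed) and passed.mean() < min_pass_fraction:
            raise DataError(
                f"array {scan.array_id}: only {100 * passed.mean():.2f}% of "
                f"spots passed QC; array rejected")
        spots = scan.spots.loc[passed]
        annotated = spots["spot_id"].map(gene_map)
        n_missing = annotated.isna().sum()
        if n_missing:
            log.warning("array %s: dropped %d passing spots without annotation",
                        scan.array_id, n_missing)
        spots = spots.loc[annotated.notna()]
        genes = annotated.dropna()

        if scan.dye_of_post_sample == "ch2":
            post_f, post_b, pre_f, pre_b = "f2_median", "b2_median", "f1_median", "b1_median"
        else:
            post_f, post_b, pre_f, pre_b = "f1_median", "b1_median", "f2_median", "b2_median"
        net_post = spots[post_f].to_numpy(float) - spots[post_b].to_numpy(float)
        net_pre = spots[pre_f].to_numpy(float) - spots[pre_b].to_numpy(float)
        ok = (net_post > 0) & (net_pre > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            m_raw = np.where(ok, np.log2(net_post / net_pre), np.nan)
            a_raw = np.where(ok, 0.5 * (np.log2(net_post) + np.log2(net_pre)), np.nan)

        gi = np.array([gene_index[g] for g in genes], dtype=int)
        np.add.at(m_sum[:, j], gi[ok], m_raw[ok])
        np.add.at(a_sum[:, j], gi[ok], a_raw[ok])
        np.add.at(count[:, j], gi[ok], 1)
        if keep_spots:
            spot_rows.append(pd.DataFrame({
                "array_id": scan.array_id, "gene_id": genes.to_numpy(),
                "M": m_raw, "A": a_raw}).dropna(subset=["M"]))

    valid = count > 0
    with np.errstate(invalid="ignore"):
        M = np.where(valid, m_sum / np.maximum(count, 1), np.nan)
        A = np.where(valid, a_sum / np.maximum(count, 1), np.nan)
    spot_level = pd.concat(spot_rows, ignore_index=True) if spot_rows else None
    return RatioMatrix(gene_ids=gene_ids, array_ids=array_ids, M=M, A=A,
                       valid_mask=valid, spot_count=count, spot_level=spot_level)


def normalize(matrix: RatioMatrix, method: str = "median",
              loess_span: float = 0.4) -> RatioMatrix:
    """Per-array centering of M: subtract the median, or a loess fit on A."""
    if method not in ("median", "loess"):
        raise ConfigurationError("normalization.method",
                                 f"unknown method '{method}'")
    M = matrix.M.copy()
    for j in range(M.shape[1]):
        col_valid = matrix.valid_mask[:, j]
        if not col_valid.any():
            continue
        if method == "median":
            M[col_valid, j] -= np.median(M[col_valid, j])
        else:
            from statsmodels.nonparametric.smoothers_lowess import lowess
            fitted = lowess(M[col_valid, j], matrix.A[col_valid, j],
                            frac=loess_span, return_sorted=False)
            M[col_valid, j] -= fitted
    return RatioMatrix(gene_ids=matrix.gene_ids, array_ids=matrix.array_ids,
                       M=M, A=matrix.A, valid_mask=matrix.valid_mask,
                       spot_count=matrix.spot_count, spot_level=matrix.spot_level)


# ---------------------------------------------------------------------------
# per-gene mixed-effects fit


def fit_gene(m_values: np.ndarray,
             spot_replicates: Sequence[np.ndarray] | None = None):
    """Fit the random-array-effect model for one gene.

    ``m_values``: per-array M (NaN = invalid).  If ``spot_replicates``
    (one array of duplicate-spot M values per valid array) is given, the
    two variance components are estimated by REML; otherwise inference is
    the one-sample problem on per-array means.  Returns
    ``(mu_hat, se, df, sigma_b, unscaled_sd)`` where ``sigma_b`` is the
    between-array standard deviation being moderated downstream and
    ``unscaled_sd`` satisfies ``se = sigma_b * unscaled_sd``.
    Fewer than 3 valid arrays -> all-NaN result (gene untestable).
    """
    if spot_replicates is None:
        y = np.asarray(m_values, dtype=float)
        y = y[~np.isnan(y)]
        a = len(y)
        if a < 3:
            return (np.nan,) * 5
        mu = float(np.mean(y))
        s = float(np.std(y, ddof=1))
        u = 1.0 / np.sqrt(a)
        return mu, s * u, a - 1, s, u

    groups = [np.asarray(g, dtype=float) for g in spot_replicates if len(g)]
    r = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    a = len(groups)
    if a < 3:
        return (np.nan,) * 5
    N = int(r.sum())
    sse_within = sum(((g - g.mean()) ** 2).sum() for g in groups)

    if r.min() == r.max():
        # balanced one-way random effects: ANOVA = REML
        ri = int(r[0])
        grand = means.mean()
        msb = ri * ((means - grand) ** 2).sum() / (a - 1)
        mu = float(grand)
        se = float(np.sqrt(msb / (a * ri)))
        u = 1.0 / np.sqrt(a * ri)
        return mu, se, a - 1, float(np.sqrt(msb)), u

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = r / (1.0 + lam * r)
        mu = (w * means).sum() / w.sum()
        q = sse_within + (w * (means - mu) ** 2).sum()
        sigma2 = q / (N - 1)
        return ((N - 1) * np.log(sigma2) + np.log1p(lam * r).sum()
                + np.log(w.sum()))

    res = optimize.minimize_scalar(neg2_reml, bounds=(-12.0, 8.0),
                                   method="bounded")
    lam = np.exp(res.x)
    w = r / (1.0 + lam * r)
    mu = float((w * means).sum() / w.sum())
    q = sse_within + (w * (means - mu) ** 2).sum()
    sigma2 = q / (N - 1)
    var_mu = sigma2 / w.sum()
    df = a - 1
    sigma_b = float(np.sqrt(sigma2 * (1.0 / r.mean() + lam)))  # per-array scale
    se = float(np.sqrt(var_mu))
    u = se / sigma_b if sigma_b > 0 else 1.0 / np.sqrt(N)
    return mu, se, df, sigma_b, u


def fit_all_genes(matrix: RatioMatrix) -> pd.DataFrame:
    """Vectorized per-gene fits on per-array means (duplicates pre-averaged).

    Returns a frame with gene_id, n_valid, mu_hat, se, df, sigma (the
    between-array SD), unscaled_sd; genes with < 3 valid arrays carry NaN.
    """
    M, valid = matrix.M, matrix.valid_mask
    n_valid = valid.sum(axis=1)
    filled = np.where(valid, M, 0.0)
    n_safe = np.maximum(n_valid, 1)
    mu = filled.sum(axis=1) / n_safe
    ss = (np.where(valid, (M - mu[:, None]) ** 2, 0.0)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(n_valid - 1, 1))
    u = 1.0 / np.sqrt(n_safe)
    se = sd * u
    df = n_valid - 1.0
    testable = n_valid >= 3
    for arr in (mu, sd, se, df, u):
        arr[~testable] = np.nan
    return pd.DataFrame({
        "gene_id": matrix.gene_ids, "n_valid": n_valid, "mu_hat": mu,
        "se": se, "df": df, "sigma": sd, "unscaled_sd": u,
    })


# ---------------------------------------------------------------------------
# empirical-Bayes moderation, posterior odds, FDR


def estimate_prior_scale(s2: np.ndarray, df: np.ndarray, prior_df: float) -> float:
    """Ensemble scale s0^2 of the inverse-chi-square variance prior.

    Uses the log-moment identity E[log s^2] = log(sigma^2) + psi(d/2) -
    log(d/2): the ensemble location of log s^2 is mapped onto the prior
    with the given degrees of freedom.
    """
    ok = np.isfinite(s2) & np.isfinite(df) & (s2 > 0) & (df > 0)
    if not ok.any():
        raise ModelError("no positive gene variances to pool")
    e = np.log(s2[ok]) - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    return float(np.exp(e.mean() + special.digamma(prior_df / 2)
                        - np.log(prior_df / 2)))


def _tmixture(tstat: np.ndarray, unscaled_sd: np.ndarray, df: np.ndarray,
              proportion: float) -> float:
    """Estimate the prior variance v0 of true effects from the top |t| genes.

    Port of the standard moment-matching estimator used with the
    B-statistic; returns 0 when the extreme t-statistics carry no excess
    over their null quantiles.
    """
    n = len(tstat)
    ntarget = int(np.ceil(proportion / 2 * n))
    if ntarget < 1:
        return 0.0
    p = max(ntarget / n, proportion)
    t_abs = np.abs(tstat)
    max_df = np.nanmax(df)
    smaller = df < max_df
    if smaller.any():
        tail = stats.t.logsf(t_abs[smaller], df[smaller])
        t_abs = t_abs.copy()
        t_abs[smaller] = stats.t.isf(np.exp(tail), max_df)
    order = np.argsort(-t_abs)[:ntarget]
    t_top = t_abs[order]
    v1 = unscaled_sd[order] ** 2
    rank = np.arange(1, ntarget + 1)
    p0 = 2 * stats.t.sf(t_top, max_df)
    ptarget = ((rank - 0.5) / n - (1 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2, max_df)
        v0[pos] = v1[pos] * ((t_top[pos] / qtarget) ** 2 - 1)
    return float(np.clip(v0, 0, None).mean())


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j >= p_i of m * p_j / rank_j, clipped to
    [0, 1]; tied p-values share a q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def moderate_and_test(fits: pd.DataFrame, prior_df: float = 4.0,
                      pi0_de: float = 0.01,
                      min_testable: int = 20) -> pd.DataFrame:
    """Moderated t, two-sided p, posterior probability of DE, and BH q.

    ``fits`` is the output of :func:`fit_all_genes` (or rows assembled
    from :func:`fit_gene`).  Variances are shrunk toward the ensemble
    scale with ``prior_df`` pseudo-degrees of freedom; the posterior
    probability is the logistic transform of the B-statistic log-odds
    with prior DE proportion ``pi0_de`` and effect variance estimated
    from the data.
    """
    if not 0 < pi0_de < 1:
        raise ConfigurationError("model.pi0_de", f"{pi0_de} outside (0, 1)")
    if prior_df <= 0:
        raise ConfigurationError("model.prior_df", "must be > 0")
    out = fits.copy()
    testable = out["df"].notna() & (out["df"] > 0) & out["sigma"].notna()
    n_testable = int(testable.sum())
    if n_testable < min_testable:
        raise ModelError(
            f"only {n_testable} testable genes; empirical-Bayes pooling needs "
            f">= {min_testable} (lower min_testable explicitly to override)")

    s2 = out.loc[testable, "sigma"].to_numpy() ** 2
    df = out.loc[testable, "df"].to_numpy(float)
    u = out.loc[testable, "unscaled_sd"].to_numpy(float)
    mu = out.loc[testable, "mu_hat"].to_numpy(float)

    s0_sq = estimate_prior_scale(s2, df, prior_df)
    s2_post = (prior_df * s0_sq + df * s2) / (prior_df + df)
    se_mod = np.maximum(np.sqrt(s2_post) * u, SE_FLOOR)
    df_total = df + prior_df
    t_mod = mu / se_mod
    p = 2 * stats.t.sf(np.abs(t_mod), df_total)

    v0 = _tmixture(t_mod, u, df_total, pi0_de)
    ratio = (u ** 2 + v0) / (u ** 2)
    t2 = t_mod ** 2
    kernel = (1 + df_total) / 2 * np.log((t2 + df_total) / (t2 / ratio + df_total))
    lods = np.log(pi0_de / (1 - pi0_de)) - 0.5 * np.log(ratio) + kernel
    posterior = special.expit(lods)

    for col in ("s2_post", "t_mod", "df_total", "p_value", "posterior_prob",
                "q_value", "lods"):
        out[col] = np.nan
    out.loc[testable, "s2_post"] = s2_post
    out.loc[testable, "t_mod"] = t_mod
    out.loc[testable, "df_total"] = df_total
    out.loc[testable, "p_value"] = p
    out.loc[testable, "posterior_prob"] = posterior
    out.loc[testable, "lods"] = lods
    out.loc[testable, "q_value"] = bh_fdr(p)
    out["fold_change"] = 2.0 ** out["mu_hat"]
    out["direction"] = np.where(out["mu_hat"] > 0, "up", "down")
    out["testable"] = testable
    return out


def consistency_fractions(matrix: RatioMatrix, results: pd.DataFrame,
                          fold: float = 2.0) -> np.ndarray:
    """Fraction of valid arrays showing >= ``fold``-change in the called direction."""
    thr = np.log2(fold)
    M, valid = matrix.M, matrix.valid_mask
    n_valid = np.maximum(valid.sum(axis=1), 1)
    up = ((M >= thr) & valid).sum(axis=1) / n_valid
    down = ((M <= -thr) & valid).sum(axis=1) / n_valid
    is_up = results["direction"].to_numpy() == "up"
    frac = np.where(is_up, up, down)
    frac[valid.sum(axis=1) == 0] = np.nan
    return frac


def analyze(matrix: RatioMatrix, prior_df: float = 4.0, pi0_de: float = 0.01,
            consistency_fold: float = 2.0, min_testable: int = 20) -> pd.DataFrame:
    """Full per-gene analysis of a normalized ratio matrix.

    Convenience wrapper: vectorized fits, moderation/testing, and the
    per-gene consistency fraction, returned as one GeneResult frame.
    """
    fits = fit_all_genes(matrix)
    results = moderate_and_test(fits, prior_df=prior_df, pi0_de=pi0_de,
                                min_testable=min_testable)
    results["consistency_fraction"] = consistency_fractions(
        matrix, results, fold=consistency_fold)
    return results
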