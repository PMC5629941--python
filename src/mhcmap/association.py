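"""Regression engines and the multiallelic omnibus association test.

The central statistic is an omnibus log-likelihood-ratio test for a marker
group: the most common member in the control population is taken as the
reference and excluded, the remaining member dosages enter an additive
logistic model alongside covariates (principal components, optionally age
of psoriasis onset), and the group p-value compares this full model to the
covariate-only null on a chi-square with (members - 1) degrees of freedom.
Conditional tests add previously selected groups' dosage columns to both
models.  P-values are carried as log10(p) throughout: headline MHC signals
(p ~ 1e-66) underflow a double if exponentiated naively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

from .catalog import DosageMatrix, MarkerGroup

LN10 = math.log(10.0)
#: absolute coefficient beyond which a term is flagged as quasi-separated
SEPARATION_BETA = 15.0


@dataclass
class FitResult:
    """Outcome of one regression fit."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    llf: float
    converged: bool
    n_used: int
    dropped: list[str] = field(default_factory=list)
    quasi_separated: list[str] = field(default_factory=list)
    n_iter: int = 0

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])


def _bernoulli_llf(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0.0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > tol * diag[0] * max(X.shape)))
    return np.sort(piv[:rank])


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood additive logistic regression via IRLS.

    Newton/IRLS with step-halving whenever a step would decrease the
    likelihood; convergence when the log-likelihood changes by less than
    ``tol``.  Collinear columns are detected by pivoted QR, dropped with a
    warning and recorded in the result.  ``X`` must already contain an
    intercept column.  Rows with missing values in ``y`` or ``X`` are
    dropped (listwise deletion).

    Raises
    ------
    ValueError
        If the outcome is constant after row deletion.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("one name per column required")

    rows = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[rows], X[rows, :]
    n = int(rows.sum())
    if n == 0:
        raise ValueError("no complete observations")
    if np.all(y == y[0]):
        raise ValueError("outcome is constant; logistic model is undefined")

    kept = _independent_columns(X)
    dropped = [names[j] for j in range(X.shape[1]) if j not in set(kept.tolist())]
    if dropped:
        warnings.warn(
            f"dropping collinear design columns: {', '.join(dropped)}",
            stacklevel=2,
        )
    X = X[:, kept]
    used_names = [names[j] for j in kept]
    p = X.shape[1]

    beta = np.zeros(p)
    eta = X @ beta
    llf = _bernoulli_llf(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        # step-halve if the proposed step lowers the likelihood
        step = beta_new - beta
        for _ in range(30):
            llf_new = _bernoulli_llf(y, X @ (beta + step))
            if llf_new >= llf - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        eta = X @ beta
        if abs(llf_new - llf) < tol:
            llf = llf_new
            converged = True
            break
        llf = llf_new

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    quasi = [nm for nm, b in zip(used_names, beta) if abs(b) > SEPARATION_BETA]
    return FitResult(
        names=used_names,
        params=beta,
        bse=bse,
        llf=llf,
        converged=converged,
        n_used=n,
        dropped=dropped,
        quasi_separated=quasi,
        n_iter=it,
    )


def likelihood_ratio_test(fit_null: FitResult, fit_full: FitResult, df: int) -> float:
    """log10 p of the LRT between nested fits on a chi-square with ``df`` df.

    Small negative deviances (numerical noise) are clamped to zero; a
    deviance below -1e-8 indicates non-nested or unconverged models and
    raises.
    """
    deviance = 2.0 * (fit_full.llf - fit_null.llf)
    if deviance < -1e-8:
        raise ValueError(
            f"negative deviance {deviance:.3g}: models not nested or not converged"
        )
    deviance = max(deviance, 0.0)
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.logsf(deviance, df) / LN10)


def wald_log10_p(beta: float, se: float) -> float:
    """Two-sided Wald log10 p for a single coefficient."""
    if not np.isfinite(se) or se <= 0:
        return float("nan")
    z = abs(beta) / se
    return float((stats.norm.logsf(z) + math.log(2.0)) / LN10)


@dataclass
class AssociationResult:
    """Omnibus (or conditional) test result for one marker group.

    ``per_member`` has one row per group member (reference first) with
    columns label, marker_id, frequency_controls, OR, ci_low, ci_high,
    log10_p — the reference row carries NaN effect columns.
    """

    group_id: str
    p_omnibus_log10: float
    df: int
    reference_label: str
    per_member: pd.DataFrame
    n_used: int
    dropped_members: list[str] = field(default_factory=list)
    self_conditioned: bool = False
    fit_full: FitResult | None = None
    fit_null: FitResult | None = None

    @property
    def p_omnibus(self) -> float:
        return 10.0 ** self.p_omnibus_log10


def _member_table(group, freq, order_ref_first):
    rows = [
        {
            "label": m.label,
            "marker_id": m.marker_id,
            "frequency_controls": freq.get(m.marker_id, np.nan),
            "OR": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "log10_p": np.nan,
        }
        for m in order_ref_first
    ]
    return pd.DataFrame(rows)


def omnibus_association(
    group: MarkerGroup,
    dosages: DosageMatrix,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    control_samples: list[str] | None = None,
    condition_groups: tuple[MarkerGroup, ...] = (),
) -> AssociationResult:
    """Multiallelic omnibus LRT of one marker group.

    Parameters
    ----------
    group
        The tested unit (one SNP, or all residues of an amino-acid position,
        or all alleles of a locus).
    dosages
        Matrix holding every member (and conditioning) column; may contain
        more samples than the analysis set.
    y
        Binary outcome indexed by sample id; its index defines the analysis
        samples.  The reference group of the contrast is coded 0.
    covariates
        Optional numeric covariates indexed like ``y``.
    control_samples
        Samples defining the reference member (the most frequent member in
        the control population) and the reported member frequencies.  When
        None, the ``y == 0`` samples are used.
    condition_groups
        Previously selected groups whose non-reference member dosages are
        added to both the null and the full model.
    """
    samples = list(y.index)
    if control_samples is None:
        control_samples = [s for s, v in y.items() if v == 0]
    freq = dosages.allele_frequencies(control_samples).to_dict()

    members = sorted(
        group.members, key=lambda m: (-freq.get(m.marker_id, 0.0), m.marker_id)
    )
    if group.size > 1:
        reference, tested = members[0], members[1:]
        ref_label = reference.label
    else:
        reference, tested = None, list(members)
        ref_label = "-"

    cond_ids: list[str] = []
    for cg in condition_groups:
        cmembers = sorted(
            cg.members, key=lambda m: (-freq.get(m.marker_id, 0.0), m.marker_id)
        )
        drop_ref = 1 if cg.size > 1 else 0
        cond_ids.extend(m.marker_id for m in cmembers[drop_ref:])

    tested_ids = {m.marker_id for m in group.members}
    conditioned_ids = set()
    for cg in condition_groups:
        conditioned_ids.update(m.marker_id for m in cg.members)
    if tested_ids and tested_ids <= conditioned_ids:
        table = _member_table(group, freq, members)
        return AssociationResult(
            group_id=group.group_id,
            p_omnibus_log10=0.0,
            df=max(len(tested), 1),
            reference_label=ref_label,
            per_member=table,
            n_used=len(samples),
            self_conditioned=True,
        )

    pos = {s: i for i, s in enumerate(dosages.samples)}
    ridx = [pos[s] for s in samples]
    yv = np.asarray(y, dtype=float)

    cols: list[np.ndarray] = [np.ones(len(samples))]
    names: list[str] = ["intercept"]
    if covariates is not None:
        cov = covariates.loc[samples]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    for mid in cond_ids:
        cols.append(dosages.column(mid)[ridx])
        names.append(f"cond:{mid}")
    n_null_cols = len(cols)

    dropped_members: list[str] = []
    member_cols: list[tuple[str, np.ndarray]] = []
    rows_ok = ~np.isnan(yv)
    for c in cols:
        rows_ok &= ~np.isnan(c)
    for m in tested:
        col = dosages.column(m.marker_id)[ridx]
        valid = rows_ok & ~np.isnan(col)
        if np.nanstd(col[valid]) < 1e-12:
            dropped_members.append(m.marker_id)
        else:
            member_cols.append((m.marker_id, col))
    if not member_cols:
        table = _member_table(group, freq, members)
        return AssociationResult(
            group_id=group.group_id,
            p_omnibus_log10=0.0,
            df=1,
            reference_label=ref_label,
            per_member=table,
            n_used=len(samples),
            dropped_members=dropped_members,
        )

    X_null = np.column_stack(cols)
    X_full = np.column_stack(cols + [c for _, c in member_cols])
    full_names = names + [mid for mid, _ in member_cols]
    # shared listwise deletion so the two likelihoods are comparable
    complete = ~(np.isnan(yv) | np.isnan(X_full).any(axis=1))
    fit_null = fit_logistic(yv[complete], X_null[complete], names=list(names))
    fit_full = fit_logistic(yv[complete], X_full[complete], names=full_names)
    df = len(member_cols) - sum(
        1 for mid, _ in member_cols if mid in set(fit_full.dropped)
    )
    df = max(df, 1)
    log10_p = likelihood_ratio_test(fit_null, fit_full, df)

    table = _member_table(group, freq, members)
    for i, m in enumerate(members):
        mid = m.marker_id
        if mid in fit_full.names:
            b, se = fit_full.coef(mid), fit_full.se(mid)
            if mid in fit_full.quasi_separated or not np.isfinite(se) or se == 0:
                lo, hi = 0.0, np.inf
            else:
                lo, hi = math.exp(b - 1.959964 * se), math.exp(b + 1.959964 * se)
            table.loc[i, ["OR", "ci_low", "ci_high", "log10_p"]] = [
                math.exp(b),
                lo,
                hi,
                wald_log10_p(b, se),
            ]
    return AssociationResult(
        group_id=group.group_id,
        p_omnibus_log10=log10_p,
        df=df,
        reference_label=ref_label,
        per_member=table,
        n_used=fit_full.n_used,
        dropped_members=dropped_members,
        fit_full=fit_full,
        fit_null=fit_null,
    )


def conditional_association(
    group: MarkerGroup,
    dosages: DosageMatrix,
    y: pd.Series,
    covariates: pd.DataFrame | None,
    conditioned_groups,
    control_samples: list[str] | None = None,
) -> AssociationResult:
    """Omnibus test of ``group`` conditioning on previously selected groups."""
    return omnibus_association(
        group,
        dosages,
        y,
        covariates=covariates,
        control_samples=control_samples,
        condition_groups=tuple(conditioned_groups),
    )


def compute_pcs(genotypes: np.ndarray | DosageMatrix, k: int = 2) -> np.ndarray:
    """Top-k principal component scores of a column-standardized dosage matrix.

    Missing entries are mean-imputed per marker before standardization;
    zero-variance markers are dropped.  The sign of each component is fixed
    by making its largest-magnitude marker loading positive, so scores are
    reproducible across runs and platforms.
    """
    if isinstance(genotypes, DosageMatrix):
        genotypes = genotypes.dosage
    G = np.array(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (samples x markers)")
    mean = np.nanmean(G, axis=0)
    idx = np.where(np.isnan(G))
    G[idx] = np.take(mean, idx[1])
    sd = G.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("all markers have zero variance; no structure to extract")
    Z = (G[:, keep] - mean[keep]) / sd[keep]
    if not 1 <= k < min(Z.shape):
        raise ValueError(f"k={k} must satisfy 1 <= k < min(n_samples, n_markers)")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] *= -1.0
    return scores


def onset_linear_association(
    onset: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[FitResult, float]:
    """OLS of age of onset on marker dosage; returns the fit and log10 p.

    The p-value is the two-sided t-test on the dosage term.  Onset must be
    non-missing for every included sample (rows with missing dosage or
    covariates are dropped).
    """
    onset = np.asarray(onset, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    cols = [np.ones_like(onset), dosage]
    names = ["intercept", "dosage"]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != onset.shape[0]:
            covariates = covariates.T
        for j in range(covariates.shape[1]):
            cols.append(covariates[:, j])
            names.append(f"covar{j}")
    X = np.column_stack(cols)
    rows = ~(np.isnan(onset) | np.isnan(X).any(axis=1))
    if np.isnan(onset).any():
        raise ValueError("onset must be non-missing for all included samples")
    X, yv = X[rows], onset[rows]
    if np.std(X[:, 1]) < 1e-12:
        raise ValueError("dosage has zero variance")
    import statsmodels.api as sm

    model = sm.OLS(yv, X)
    res = model.fit()
    dfree = res.df_resid
    tval = res.params[1] / res.bse[1]
    log10_p = float(
        (stats.t.logsf(abs(tval), dfree) + math.log(2.0)) / LN10
    )
    fit = FitResult(
        names=names,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        llf=float(res.llf),
        converged=True,
        n_used=int(res.nobs),
    )
    return fit, log10_p


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    Uses the exact null distribution when both samples have n <= 25 and no
    ties, otherwise the normal approximation with continuity correction.
    Returns ``(p, median(b) - median(a))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    p = 1.0 if res.statistic == a.size * b.size / 2.0 else float(min(res.pvalue, 1.0))
    return p, float(np.median(b) - np.median(a))
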