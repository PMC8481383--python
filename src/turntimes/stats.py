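"""Descriptive statistics and mixed models for turn-transition data.

Two models mirror the standard analysis of dyadic vs triadic transition
times:

* a linear mixed model for the signed transition time with an overlap dummy
  and group-size / transition-type sum contrasts (dyad = +0.5, QR = +0.5)
  *nested within* each overlap level, and by-responder random intercepts
  plus overlap and transition-type slopes (with correlations), fitted by
  maximum likelihood through statsmodels' MixedLM;

* a logistic mixed model for the probability of overlap (binomial family,
  logit link) with the group-size x transition-type factorial and a
  by-responder random intercept + transition-type slope, fitted by maximum
  likelihood with a Laplace approximation implemented here (statsmodels has
  no frequentist binomial GLMM).

The interaction is decomposed with marginal contrasts: the group-size
effect within each transition type is a linear combination of coefficients
(main effect +/- half the interaction) with delta-method standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit

import statsmodels.api as sm

from turntimes.transitions import Transition, transitions_to_frame

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Descriptives
# --------------------------------------------------------------------------

@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    mad: float
    modes: list[float]
    sd_defined: bool = True


def kde_modes(
    values: Sequence[float],
    bandwidth_rule: str | float = "silverman",
    max_modes: int = 2,
    rel_prominence: float = 0.10,
    grid_size: int = 512,
) -> list[float]:
    """Local maxima of a Gaussian kernel density estimate.

    The density is evaluated on a fixed grid spanning the data range plus
    three bandwidths on each side; local maxima are ranked by density and a
    secondary mode must reach at least ``rel_prominence`` of the primary
    mode's density (guards against KDE ripple).  Returns up to
    ``max_modes`` mode locations, ordered by density, clipped to the data
    range.  Degenerate (all-equal) input returns the common value.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("kde_modes requires at least 2 values")
    if np.ptp(x) == 0:
        return [float(x[0])]
    kde = sps.gaussian_kde(x, bw_method=bandwidth_rule)
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    idx = np.flatnonzero(interior) + 1
    if len(idx) == 0:
        idx = np.array([int(np.argmax(dens))])
    order = idx[np.argsort(dens[idx])[::-1]]
    peak = dens[order[0]]
    modes = [
        float(np.clip(grid[i], x.min(), x.max()))
        for i in order
        if dens[i] >= rel_prominence * peak
    ]
    return modes[:max_modes]


def describe(values: Sequence[float]) -> SummaryStats:
    """Mean, sample sd, median, unscaled MAD and KDE modes of a sample."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("describe requires at least one value")
    median = float(np.median(x))
    mad = float(np.median(np.abs(x - median)))
    if len(x) == 1:
        return SummaryStats(
            n=1, mean=float(x[0]), sd=0.0, median=median, mad=mad,
            modes=[float(x[0])], sd_defined=False,
        )
    return SummaryStats(
        n=len(x),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=median,
        mad=mad,
        modes=kde_modes(x),
    )


# --------------------------------------------------------------------------
# Model design
# --------------------------------------------------------------------------

LMM_FIXED_TERMS = [
    "const",
    "overlap",
    "gap:group_size",
    "ovl:group_size",
    "gap:type_qr",
    "ovl:type_qr",
    "gap:gs_x_qr",
    "ovl:gs_x_qr",
]
GLMM_FIXED_TERMS = ["const", "group_size", "type_qr", "gs_x_qr"]


@dataclass
class ModelDesign:
    """Contrast-coded design for the transition-time LMM or overlap GLMM.

    Sum-to-zero contrasts: dyad = +0.5 / triad = -0.5 on ``group_size``,
    QR = +0.5 / non-QR = -0.5 on ``type_qr``.  For the LMM the factorial is
    expanded within each level of the overlap dummy (``gap:`` = non-overlap
    level, ``ovl:`` = overlap level).  The grouping factor is the speaker
    taking the turn.
    """

    kind: str  # "lmm" or "glmm"
    endog: np.ndarray
    exog: pd.DataFrame
    exog_re: pd.DataFrame
    groups: np.ndarray
    frame: pd.DataFrame


def build_design(
    kept_transitions: "pd.DataFrame | list[Transition]",
    response: str = "transition",
    include_overlap: bool = True,
) -> ModelDesign:
    """Build the LMM (``response='transition'``) or GLMM (``'overlap'``) design.

    ``include_overlap=False`` builds the reduced transition-time model with
    the plain group-size x transition-type factorial and no overlap dummy,
    random intercept + transition-type slope only — the natural reduced
    model for a likelihood-ratio test of the overlap expansion (7 added
    parameters: 4 fixed, 3 random-effect (co)variances).
    """
    if isinstance(kept_transitions, list):
        frame = transitions_to_frame(kept_transitions)
    else:
        frame = kept_transitions.copy()
    required = {"group_size", "type", "transition_ms", "next_speaker"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"transitions table missing columns {sorted(missing)}")

    gs = np.where(frame["group_size"] == 2, 0.5, -0.5)
    qr = np.where(frame["type"] == "QR", 0.5, -0.5)
    ov = (frame["transition_ms"] < 0).astype(float).to_numpy()
    groups = frame["next_speaker"].to_numpy()

    if response == "transition" and not include_overlap:
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "group_size": gs,
                "type_qr": qr,
                "gs_x_qr": gs * qr,
            }
        )[GLMM_FIXED_TERMS]
        exog_re = pd.DataFrame({"const": 1.0, "type_qr": qr})
        endog = frame["transition_ms"].to_numpy(dtype=float)
        kind = "lmm"
    elif response == "transition":
        gap = 1.0 - ov
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "overlap": ov,
                "gap:group_size": gs * gap,
                "ovl:group_size": gs * ov,
                "gap:type_qr": qr * gap,
                "ovl:type_qr": qr * ov,
                "gap:gs_x_qr": gs * qr * gap,
                "ovl:gs_x_qr": gs * qr * ov,
            }
        )[LMM_FIXED_TERMS]
        exog_re = pd.DataFrame(
            {"const": 1.0, "overlap": ov, "type_qr": qr}
        )
        endog = frame["transition_ms"].to_numpy(dtype=float)
        # flag degenerate grouping levels (no response variation)
        for g, sub in frame.groupby("next_speaker"):
            if len(sub) > 1 and sub["transition_ms"].nunique() == 1:
                logger.warning(
                    "grouping level %r has all-identical response values", g
                )
        kind = "lmm"
    elif response == "overlap":
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "group_size": gs,
                "type_qr": qr,
                "gs_x_qr": gs * qr,
            }
        )[GLMM_FIXED_TERMS]
        exog_re = pd.DataFrame({"const": 1.0, "type_qr": qr})
        endog = ov.astype(int)
        kind = "glmm"
    else:
        raise ValueError("response must be 'transition' or 'overlap'")

    return ModelDesign(
        kind=kind,
        endog=endog,
        exog=exog,
        exog_re=exog_re,
        groups=groups,
        frame=frame,
    )


# --------------------------------------------------------------------------
# Model fits
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Coefficients, likelihood and diagnostics of a fitted mixed model.

    ``params`` rows match design columns; ``stat`` is the normal-
    approximation z (estimate / se) and p-values are two-sided normal.
    ``n_params`` counts fixed effects + random-effect (co)variances
    (+ residual variance for the LMM), so AIC = -2 logLik + 2 n_params.
    """

    kind: str
    params: pd.DataFrame
    cov_params: pd.DataFrame
    cov_re: pd.DataFrame
    loglik: float
    n_obs: int
    n_groups: int
    n_params: int
    scale: float | None = None
    converged: bool = True
    singular: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params


def _params_frame(
    terms: Sequence[str], est: np.ndarray, se: np.ndarray
) -> pd.DataFrame:
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": est, "se": se, "stat": z, "p": p}, index=list(terms)
    )


def fit_transition_lmm(design: ModelDesign) -> ModelFit:
    """ML fit of the nested-contrast linear mixed model for transition time.

    Random structure: by-responder intercept + overlap + transition-type
    slopes with correlations (no slope-interaction terms).  Non-convergence
    and approximate singularity are reported as flags, never raised.
    """
    if design.kind != "lmm":
        raise ValueError("design is not a transition-time (LMM) design")
    n_groups = len(pd.unique(design.groups))
    if n_groups < 2:
        raise ValueError("LMM requires at least 2 grouping-factor levels")

    model = sm.MixedLM(
        design.endog,
        design.exog.to_numpy(),
        groups=design.groups,
        exog_re=design.exog_re.to_numpy(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False, method="lbfgs", maxiter=500)
        fe_params = np.asarray(result.fe_params, dtype=float)
        bse_fe = np.asarray(result.bse_fe, dtype=float)
        cov_all = np.asarray(result.cov_params())

    k_fe = design.exog.shape[1]
    q = design.exog_re.shape[1]
    n_params = k_fe + q * (q + 1) // 2 + 1  # + residual variance

    cov_re = result.cov_re * result.scale
    re_names = list(design.exog_re.columns)
    cov_re = pd.DataFrame(
        np.asarray(cov_re), index=re_names, columns=re_names
    )
    eigvals = np.linalg.eigvalsh(np.asarray(cov_re))
    singular = bool(eigvals.min() < 1e-6 * max(eigvals.max(), 1.0))

    est = fe_params
    se = bse_fe
    terms = list(design.exog.columns)
    cov_params = pd.DataFrame(
        cov_all[:k_fe, :k_fe], index=terms, columns=terms
    )
    fit = ModelFit(
        kind="lmm",
        params=_params_frame(terms, est, se),
        cov_params=cov_params,
        cov_re=cov_re,
        loglik=float(result.llf),
        n_obs=len(design.endog),
        n_groups=n_groups,
        n_params=n_params,
        scale=float(result.scale),
        converged=bool(result.converged),
        singular=singular,
    )
    if not fit.converged:
        fit.notes.append("optimizer did not report convergence")
    if singular:
        fit.notes.append("random-effect covariance is approximately singular")
    if not np.all(np.isfinite(se)):
        fit.notes.append("some fixed-effect standard errors are undefined")
    return fit


def _laplace_nll_factory(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    gcodes: np.ndarray,
    n_groups: int,
):
    """Negative Laplace log-likelihood of a logistic mixed model.

    Random effects b_i = L u_i with u_i ~ N(0, I_2); the inner mode of each
    group's u_i is found by (vectorized) Newton iterations, warm-started
    across outer evaluations.
    """
    n, p = X.shape
    U_warm = {"U": np.zeros((n_groups, 2))}

    def nll(x: np.ndarray) -> float:
        beta = x[:p]
        l11, l21, l22 = x[p], x[p + 1], x[p + 2]
        L = np.array([[l11, 0.0], [l21, l22]])
        A = Z @ L.T  # (n, 2): row j is L' z_j in effect-space
        xb = X @ beta
        U = U_warm["U"].copy()
        for _ in range(100):
            eta = xb + np.einsum("ij,ij->i", A, U[gcodes])
            pr = expit(eta)
            r = y - pr
            g1 = np.bincount(gcodes, A[:, 0] * r, minlength=n_groups) - U[:, 0]
            g2 = np.bincount(gcodes, A[:, 1] * r, minlength=n_groups) - U[:, 1]
            if max(np.abs(g1).max(), np.abs(g2).max()) < 1e-9:
                break
            w = pr * (1.0 - pr)
            h11 = np.bincount(gcodes, w * A[:, 0] ** 2, minlength=n_groups) + 1
            h12 = np.bincount(gcodes, w * A[:, 0] * A[:, 1], minlength=n_groups)
            h22 = np.bincount(gcodes, w * A[:, 1] ** 2, minlength=n_groups) + 1
            det = h11 * h22 - h12**2
            U[:, 0] += (h22 * g1 - h12 * g2) / det
            U[:, 1] += (h11 * g2 - h12 * g1) / det
        U_warm["U"] = U

        eta = xb + np.einsum("ij,ij->i", A, U[gcodes])
        pr = expit(eta)
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        ll -= 0.5 * float(np.sum(U**2))
        w = pr * (1.0 - pr)
        h11 = np.bincount(gcodes, w * A[:, 0] ** 2, minlength=n_groups) + 1
        h12 = np.bincount(gcodes, w * A[:, 0] * A[:, 1], minlength=n_groups)
        h22 = np.bincount(gcodes, w * A[:, 1] ** 2, minlength=n_groups) + 1
        ll -= 0.5 * float(np.sum(np.log(h11 * h22 - h12**2)))
        return -ll

    return nll


def fit_overlap_glmm(design: ModelDesign) -> ModelFit:
    """Laplace-approximation ML fit of the logistic overlap mixed model.

    Binomial family, logit link; by-responder random intercept +
    transition-type slope with correlation, parameterised through the
    Cholesky factor of the random-effect covariance (boundary fits at zero
    variance are allowed and flagged as singular).  Complete separation is
    flagged, not raised.
    """
    if design.kind != "glmm":
        raise ValueError("design is not an overlap (GLMM) design")
    y = design.endog.astype(float)
    X = design.exog.to_numpy(dtype=float)
    Z = design.exog_re.to_numpy(dtype=float)
    levels, gcodes = np.unique(design.groups, return_inverse=True)
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("GLMM requires at least 2 grouping-factor levels")
    if y.min() == y.max():
        raise ValueError("overlap response is constant; nothing to fit")

    p = X.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = (
            sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        )
    x0 = np.concatenate([beta0, [0.3, 0.0, 0.3]])
    bounds = [(None, None)] * p + [(0.0, 10.0), (-10.0, 10.0), (0.0, 10.0)]
    nll = _laplace_nll_factory(y, X, Z, gcodes, n_groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-10},
        )

    beta = opt.x[:p]
    l11, l21, l22 = opt.x[p:]
    Lmat = np.array([[l11, 0.0], [l21, l22]])
    cov_re = pd.DataFrame(
        Lmat @ Lmat.T,
        index=list(design.exog_re.columns),
        columns=list(design.exog_re.columns),
    )

    # observed-information SEs for the fixed effects at the optimum
    # (random-effect parameters held at their estimates, as is conventional)
    def nll_beta(b: np.ndarray) -> float:
        return nll(np.concatenate([b, opt.x[p:]]))

    h = 1e-4 * (1.0 + np.abs(beta))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            bpp = beta.copy(); bpp[i] += h[i]; bpp[j] += h[j]
            bpm = beta.copy(); bpm[i] += h[i]; bpm[j] -= h[j]
            bmp = beta.copy(); bmp[i] -= h[i]; bmp[j] += h[j]
            bmm = beta.copy(); bmm[i] -= h[i]; bmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                nll_beta(bpp) - nll_beta(bpm) - nll_beta(bmp) + nll_beta(bmm)
            ) / (4 * h[i] * h[j])
    try:
        cov_beta = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
        cov_ok = True
    except np.linalg.LinAlgError:
        cov_beta = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
        cov_ok = False

    terms = list(design.exog.columns)
    fit = ModelFit(
        kind="glmm",
        params=_params_frame(terms, beta, se),
        cov_params=pd.DataFrame(cov_beta, index=terms, columns=terms),
        cov_re=cov_re,
        loglik=-float(opt.fun),
        n_obs=len(y),
        n_groups=n_groups,
        n_params=p + 3,
        converged=bool(opt.success),
        singular=bool(min(l11, l22) < 1e-3),
    )
    if not cov_ok:
        fit.notes.append("fixed-effect Hessian was singular; used pseudoinverse")
    if np.abs(beta).max() > 15:
        fit.converged = False
        fit.notes.append("possible complete separation (|beta| > 15)")
    if fit.singular:
        fit.notes.append("random-effect covariance at or near boundary")
    return fit


# --------------------------------------------------------------------------
# Model comparison and contrasts
# --------------------------------------------------------------------------

def lrt(fit_reduced: ModelFit, fit_full: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of two nested ML fits on the same data.

    chi2 = 2 (logLik_full - logLik_reduced); df is the parameter-count
    difference (fixed + random-effect parameters).
    """
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("LRT requires fits on identical data (n_obs differ)")
    if fit_full.n_params < fit_reduced.n_params:
        raise ValueError("fit_full must have at least as many parameters")
    chi2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    df = fit_full.n_params - fit_reduced.n_params
    if df == 0:
        return max(chi2, 0.0), 0, 1.0
    pval = float(sps.chi2.sf(max(chi2, 0.0), df))
    return max(chi2, 0.0), df, pval


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    se: float
    z: float
    p: float


def marginal_contrasts(glmm_fit: ModelFit) -> list[ContrastResult]:
    """Group-size effect within each transition type, from the GLMM fit.

    With +/-0.5 sum contrasts the within-type effect is the group-size main
    effect plus/minus half the interaction; standard errors come from the
    delta method on the fixed-effect covariance.  With dyads coded +0.5 a
    negative estimate means overlap is more probable for triads.
    """
    terms = list(glmm_fit.params.index)
    for needed in ("group_size", "gs_x_qr"):
        if needed not in terms:
            raise ValueError(
                f"GLMM fit lacks the {needed!r} term; cannot decompose"
            )
    beta = glmm_fit.params["estimate"].to_numpy()
    V = glmm_fit.cov_params.to_numpy()
    out = []
    for label, sign in (("group_size within QR", 0.5),
                        ("group_size within nonQR", -0.5)):
        c = np.zeros(len(terms))
        c[terms.index("group_size")] = 1.0
        c[terms.index("gs_x_qr")] = sign
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        z = est / se if se > 0 else np.nan
        out.append(
            ContrastResult(
                label=label,
                estimate=est,
                se=se,
                z=z,
                p=float(2 * sps.norm.sf(abs(z))),
            )
        )
    return out
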