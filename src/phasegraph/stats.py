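"""Association of regional network metrics with PET covariates.

The statistical unit is the brain region.  A metric observed at k wavelet
scales per region forms a repeated-measures design with scale as the within
factor and one or two regional PET values (protein synthesis rCPS, glucose
uptake SUV) as continuous between-unit covariates:

* the covariate main effect tests whether the region-mean metric tracks the
  PET value (F with df (1, n - 1 - p) for p covariates);
* the covariate-by-scale interaction tests whether that association varies
  across scales, with Greenhouse-Geisser epsilon-corrected degrees of
  freedom when Mauchly's test rejects sphericity;
* post-hoc per-scale Pearson (or first-order partial) correlations localize
  the effect, Bonferroni-corrected over the scales-by-metrics family.

Sums of squares are Type III (each covariate adjusted for the other);
covariates are z-scored before fitting, which leaves all F statistics
unchanged but conditions the solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.linalg import null_space

from .io import DimensionError, RegionalPetVector
from .wavelets import ParameterError


class CollinearityError(ValueError):
    """The covariate design is rank deficient."""


class DegenerateControlError(ValueError):
    """A control variable is perfectly correlated with an input."""


def _covariate_matrix(covariates) -> tuple[np.ndarray, tuple]:
    """Stack covariates into a z-scored (n, p) matrix and collect names."""
    cols, names = [], []
    for i, cov in enumerate(covariates):
        if isinstance(cov, RegionalPetVector):
            cols.append(cov.values)
            names.append(cov.tracer)
        else:
            cols.append(np.asarray(cov, dtype=float).ravel())
            names.append(f"covariate_{i}")
    z = np.column_stack(cols)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)
    return z, tuple(names)


def _within_contrasts(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) basis of the space orthogonal to the constant."""
    return null_space(np.ones((1, k)))


@dataclass
class EffectTest:
    f: float
    df1: float
    df2: float
    p: float


@dataclass
class WithinEffectTest:
    """Uncorrected and Greenhouse-Geisser-corrected F test of a within effect."""

    f: float
    df1: float
    df2: float
    p: float
    df1_gg: float
    df2_gg: float
    p_gg: float


@dataclass
class AssociationResult:
    """Output of the repeated-measures GLM for one metric."""

    metric: str
    covariates: tuple
    f_main: dict
    f_interaction: dict
    scale_effect: WithinEffectTest
    gg_epsilon: float
    mauchly_w: float
    mauchly_p: float
    sphericity_rejected: bool
    n_regions: int
    n_scales: int
    posthoc: pd.DataFrame | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [("scale", "within", self.scale_effect.f,
                 self.scale_effect.df1_gg if self.sphericity_rejected
                 else self.scale_effect.df1,
                 self.scale_effect.df2_gg if self.sphericity_rejected
                 else self.scale_effect.df2,
                 self.scale_effect.p_gg if self.sphericity_rejected
                 else self.scale_effect.p)]
        for name, eff in self.f_main.items():
            rows.append((name, "main", eff.f, eff.df1, eff.df2, eff.p))
        for name, eff in self.f_interaction.items():
            rows.append((
                f"{name} x scale", "interaction", eff.f,
                eff.df1_gg if self.sphericity_rejected else eff.df1,
                eff.df2_gg if self.sphericity_rejected else eff.df2,
                eff.p_gg if self.sphericity_rejected else eff.p,
            ))
        df = pd.DataFrame(rows, columns=["effect", "kind", "F", "df1", "df2", "p"])
        df.insert(0, "metric", self.metric)
        return df


def gg_epsilon(metric_by_scale: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of a (n_units, k) repeated-measures matrix.

    epsilon = tr(S)^2 / ((k-1) tr(S^2)) on the covariance S of orthonormal
    within-factor contrasts; equals 1 under sphericity, bounded below by
    1/(k-1).
    """
    y = np.asarray(metric_by_scale, dtype=float)
    k = y.shape[1]
    if k < 2:
        raise ParameterError("need at least 2 within-factor levels")
    if k == 2:
        return 1.0
    s = np.cov(y @ _within_contrasts(k), rowvar=False)
    return _epsilon_from_contrast_cov(s, k)


def _epsilon_from_contrast_cov(s: np.ndarray, k: int) -> float:
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        return 1.0
    return float(tr ** 2 / ((k - 1) * tr2))


def mauchly_sphericity(metric_by_scale: np.ndarray,
                       error_df: int | None = None) -> tuple[float, float]:
    """Mauchly's W and its chi-square p-value.

    W = det(S) / (tr(S)/(k-1))^(k-1) on the orthonormal-contrast covariance
    S; the chi-square approximation uses the standard Box correction factor.
    W = 1 exactly (p = 1) for k = 2.
    """
    y = np.asarray(metric_by_scale, dtype=float)
    n, k = y.shape
    if k == 2:
        return 1.0, 1.0
    s = np.cov(y @ _within_contrasts(k), rowvar=False)
    f_err = (n - 1) if error_df is None else error_df
    return _mauchly_from_contrast_cov(s, k, f_err)


def _mauchly_from_contrast_cov(s: np.ndarray, k: int,
                               f_err: int) -> tuple[float, float]:
    d = k - 1
    if d < 2:
        return 1.0, 1.0
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        return 0.0, 0.0
    log_w = logdet - d * np.log(np.trace(s) / d)
    w = float(np.exp(log_w))
    factor = f_err - (2 * d ** 2 + d + 2) / (6.0 * d)
    chi2 = -factor * log_w
    df = d * (d + 1) // 2 - 1
    p = float(sp_stats.chi2.sf(chi2, df))
    return w, p


def rm_glm(metric_by_scale: np.ndarray, covariates,
           metric: str = "metric", alpha_sphericity: float = 0.05) -> AssociationResult:
    """Repeated-measures GLM of a metric across scales on PET covariates.

    Parameters
    ----------
    metric_by_scale : ndarray, shape (n_regions, n_scales)
        Population-averaged metric values, one column per scale.
    covariates : RegionalPetVector or sequence of one/two of them (or arrays)

    Returns
    -------
    AssociationResult
        Main-effect F per covariate with df (1, n - 1 - p), scale main
        effect, covariate-by-scale interactions with both uncorrected and
        Greenhouse-Geisser-corrected tests, plus epsilon and Mauchly's W.
        The GG-corrected test is the headline one whenever Mauchly rejects
        at ``alpha_sphericity``.
    """
    y = np.asarray(metric_by_scale, dtype=float)
    if y.ndim != 2:
        raise DimensionError("metric_by_scale must be (n_regions, n_scales)")
    n, k = y.shape
    if k < 2:
        raise ParameterError("need at least 2 scales")
    if isinstance(covariates, (RegionalPetVector, np.ndarray)):
        covariates = [covariates]
    z, names = _covariate_matrix(covariates)
    if z.shape[0] != n:
        raise DimensionError("covariate length must match n_regions")
    p = z.shape[1]
    x = np.column_stack([np.ones(n), z])
    xtx = x.T @ x
    if np.linalg.cond(xtx) > 1e10:
        raise CollinearityError("covariates are collinear")
    xtx_inv = np.linalg.inv(xtx)
    df_err = n - 1 - p

    # --- between-unit (covariate main) effects on the region means
    ybar = y.mean(axis=1)
    beta = xtx_inv @ x.T @ ybar
    resid = ybar - x @ beta
    mse = resid @ resid / df_err
    f_main = {}
    for j, name in enumerate(names, start=1):
        fj = beta[j] ** 2 / (mse * xtx_inv[j, j]) if mse > 0 else np.inf
        f_main[name] = EffectTest(
            f=float(fj), df1=1, df2=df_err, p=float(sp_stats.f.sf(fj, 1, df_err)))

    # --- within effects on orthonormal scale contrasts
    c = _within_contrasts(k)
    yc = y @ c                      # (n, k-1)
    # no within-scale variation at all (columns of y identical up to
    # rounding): every within effect is null by construction
    degenerate_within = float(np.sum(yc ** 2)) <= 1e-12 * float(np.sum(y ** 2))
    b = xtx_inv @ x.T @ yc          # (p+1, k-1)
    e = yc.T @ yc - b.T @ xtx @ b   # residual SSCP, df = df_err
    sse = float(np.trace(e))
    d = k - 1
    sigma_c = e / df_err
    if degenerate_within or k == 2:
        eps, w, w_p = 1.0, 1.0, 1.0
    else:
        eps = _epsilon_from_contrast_cov(sigma_c, k)
        w, w_p = _mauchly_from_contrast_cov(sigma_c, k, df_err)

    def within_test(row: int) -> WithinEffectTest:
        ssh = float(b[row] @ b[row]) / xtx_inv[row, row]
        if degenerate_within:
            fv = 0.0
        elif sse > 1e-300:
            fv = (ssh / d) / (sse / (d * df_err))
        elif ssh <= 1e-300:
            fv = 0.0  # perfect fit with no effect: 0/0 read as no evidence
        else:
            fv = np.inf
        df1, df2 = d, d * df_err
        return WithinEffectTest(
            f=float(fv), df1=df1, df2=df2,
            p=float(sp_stats.f.sf(fv, df1, df2)),
            df1_gg=eps * df1, df2_gg=eps * df2,
            p_gg=float(sp_stats.f.sf(fv, eps * df1, eps * df2)),
        )

    scale_effect = within_test(0)
    f_interaction = {name: within_test(j) for j, name in enumerate(names, start=1)}

    return AssociationResult(
        metric=metric, covariates=names, f_main=f_main,
        f_interaction=f_interaction, scale_effect=scale_effect,
        gg_epsilon=float(eps), mauchly_w=float(w), mauchly_p=float(w_p),
        sphericity_rejected=bool(w_p < alpha_sphericity),
        n_regions=n, n_scales=k,
    )


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        z: np.ndarray) -> float:
    """First-order partial Pearson correlation r_xy.z."""
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz ** 2) * (1 - r_yz ** 2)
    if min(1 - r_xz ** 2, 1 - r_yz ** 2) < 1e-12:
        raise DegenerateControlError(
            "control variable perfectly correlated with an input")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def posthoc_correlations(metric_per_scale: np.ndarray,
                         target: RegionalPetVector,
                         control: RegionalPetVector | None = None,
                         n_comparisons: int | None = None,
                         alpha: float = 0.05,
                         scales=None) -> pd.DataFrame:
    """Per-scale (partial) Pearson correlation with Bonferroni flags.

    Parameters
    ----------
    metric_per_scale : ndarray, shape (n_regions, n_scales)
    target : RegionalPetVector
        Variable of interest (e.g. rCPS).
    control : RegionalPetVector, optional
        Covariate of no interest (e.g. SUV); when given, first-order partial
        correlations are reported.
    n_comparisons : int, optional
        Size of the Bonferroni family.  Defaults to the number of scales
        times the four node metrics (the per-figure family).
    """
    y = np.asarray(metric_per_scale, dtype=float)
    n, k = y.shape
    if len(target.values) != n:
        raise DimensionError("target length must match n_regions")
    if scales is None:
        scales = list(range(1, k + 1))
    if n_comparisons is None:
        n_comparisons = k * 4
    g = 0 if control is None else 1
    df = n - 2 - g
    rows = []
    for si in range(k):
        if control is None:
            r = float(np.corrcoef(y[:, si], target.values)[0, 1])
        else:
            r = partial_correlation(y[:, si], target.values, control.values)
        r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r_c * np.sqrt(df / (1 - r_c ** 2))
        p = float(2 * sp_stats.t.sf(abs(t), df))
        p_bonf = min(1.0, p * n_comparisons)
        rows.append((scales[si], r, p, p_bonf, p_bonf < alpha))
    return pd.DataFrame(
        rows, columns=["scale", "r", "p", "p_bonferroni", "significant"])
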