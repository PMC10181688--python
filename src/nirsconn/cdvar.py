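"""Condition-driven vector autoregression (the effective-connectivity model).

The M regional signals G(t) are modelled as a VAR(p),

    G(t) = sum_{l=1..p} Phi(l) G(t-l) + eps(t),      eps ~ WN(0, Sigma_eps)

whose coefficient matrices shift with the experimental condition: with K+1
dichotomic conditions (index 0 the baseline),

    Phi(l) = Phi_0(l) + sum_{k=1..K} Phi_k(l) * C_k,

where C_k is 1 when the run belongs to condition k and 0 otherwise.  Phi_0
is the baseline connectivity; Phi_k (k >= 1) is the *change* relative to
baseline induced by condition k.  Because conditions are recorded in
separate runs, the indicators are constant within a run and the lagged
predictors never straddle a run boundary.

Estimation is equation-by-equation ordinary least squares on one shared
design matrix, which is exact multivariate OLS here and runs in time linear
in the number of observations.  Entry (i, j) of Phi_k(l) is the effect of
region j at lag l on region i under condition k -- a directed
(Granger-causal) edge j -> i.  Inference uses the asymptotic normality of
the vectorised coefficients, vec(Phi_hat) ~ N(vec(Phi), Sigma_eps kron
(X'X)^{-1}): each coefficient divided by its asymptotic standard error is a
z statistic, with two-sided normal p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, SingularDesignError, ValidationError
from .projection import ProjectedSeries

__all__ = [
    "DEFAULT_CONDITIONS",
    "ConditionCoding",
    "CoefIndex",
    "CDVARDesign",
    "CDVARFit",
    "trial_average",
    "extract_task_epochs",
    "build_design",
    "fit_ols",
    "wald_pvalues",
    "significant_edges",
    "companion_spectral_radius",
]

#: Footwear conditions of the walking experiment, baseline first.
DEFAULT_CONDITIONS = (
    "barefoot",
    "flat sole",
    "medial wedge",
    "personal shoes",
    "SGL shoes",
)


@dataclass(frozen=True)
class ConditionCoding:
    """Dummy coding of experimental conditions.

    ``condition_names[0]`` is the baseline (reference) condition: its
    dynamics are Phi_0 alone and it contributes no delta term.  Every run
    maps to exactly one condition.
    """

    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        if len(self.condition_names) < 1:
            raise ValidationError("need at least a baseline condition")
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValidationError("condition names must be unique")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_names)

    @property
    def baseline(self) -> str:
        return self.condition_names[0]

    @property
    def K(self) -> int:
        """Number of non-baseline conditions (delta matrices)."""
        return len(self.condition_names) - 1

    def index(self, name: str) -> int:
        try:
            return self.condition_names.index(name)
        except ValueError as exc:
            raise ValidationError(
                f"unknown condition {name!r}; known: {self.condition_names}"
            ) from exc

    def indicator(self, k: int, run_condition: str) -> int:
        """1 if the run belongs to (non-baseline) condition k, else 0."""
        return int(self.index(run_condition) == k)


class CoefIndex(NamedTuple):
    """Identifies one design-matrix column / coefficient: which condition
    block (0 = baseline, k >= 1 = delta for condition k), which lag, and
    which source cluster the lagged predictor comes from."""

    condition: int
    lag: int
    source: int


@dataclass
class CDVARDesign:
    """Stacked regression problem: response Y (n x M), predictors X (n x q)
    with q = M * p * (K + 1), plus the map from columns to coefficients."""

    Y: np.ndarray
    X: np.ndarray
    index: list[CoefIndex]
    M: int
    p: int
    K: int
    condition_names: tuple[str, ...]
    n_obs_per_condition: dict[str, int]

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]


def trial_average(epochs: Sequence[ProjectedSeries]) -> ProjectedSeries:
    """Pointwise mean of same-length epochs of one condition.

    Averaging across the repeated task blocks boosts the signal-to-noise
    ratio before the (short-sample) VAR fit.
    """
    if len(epochs) == 0:
        raise DataError("trial_average needs at least one epoch")
    first = epochs[0]
    for e in epochs[1:]:
        if e.g.shape != first.g.shape:
            raise DataError(
                f"epoch length mismatch: {e.g.shape} vs {first.g.shape}"
            )
        if e.assignment is not first.assignment and not np.array_equal(
            e.assignment.labels, first.assignment.labels
        ):
            raise DataError("epochs use different cluster assignments")
    mean_g = np.mean([e.g for e in epochs], axis=0)
    return ProjectedSeries(
        g=mean_g,
        fs=first.fs,
        assignment=first.assignment,
        run_condition=first.run_condition,
    )


def extract_task_epochs(
    series: ProjectedSeries, include_rest: bool = False
) -> list[ProjectedSeries]:
    """Cut a run into its task-block epochs using the event markers.

    Epochs are truncated to the shortest block so they can be
    trial-averaged.  With ``include_rest`` the whole run is returned as a
    single epoch (rest periods included in the fit).
    """
    if include_rest or not series.event_markers:
        return [series]
    segments = []
    for m in series.event_markers:
        a = int(round(m.onset * series.fs))
        b = int(round((m.onset + m.duration) * series.fs))
        b = min(b, series.n_samples)
        if b - a < 2:
            continue
        segments.append((a, b))
    if not segments:
        raise DataError("no usable task blocks found in event markers")
    length = min(b - a for a, b in segments)
    return [
        ProjectedSeries(
            g=series.g[:, a : a + length],
            fs=series.fs,
            assignment=series.assignment,
            run_condition=series.run_condition,
        )
        for a, b in segments
    ]


def build_design(
    series_by_condition: Mapping[str, ProjectedSeries | Sequence[ProjectedSeries]],
    coding: ConditionCoding | None = None,
    p: int = 1,
) -> CDVARDesign:
    """Assemble the stacked OLS problem for the condition-driven VAR.

    Each condition may contribute one series or several runs/epochs; lagged
    predictors are built within each run only, so no response row ever uses
    values from a different run.  The predictor row for time t of a run in
    condition k is

        [ G(t-1) ... G(t-p) | 1{k=1} G(t-1)...G(t-p) | ... | 1{k=K} ... ]

    i.e. a baseline lag block that is always active plus one delta block per
    non-baseline condition, active only for that condition's runs.
    """
    if coding is None:
        coding = ConditionCoding(tuple(series_by_condition.keys()))
    if p < 1:
        raise ValidationError("VAR order p must be >= 1")
    unknown = set(series_by_condition) - set(coding.condition_names)
    if unknown:
        raise ValidationError(f"conditions {sorted(unknown)} not in coding")

    K = coding.K
    M = None
    rows_X, rows_Y = [], []
    n_obs_per_condition: dict[str, int] = {}

    for cond in coding.condition_names:
        if cond not in series_by_condition:
            continue
        runs = series_by_condition[cond]
        if isinstance(runs, ProjectedSeries):
            runs = [runs]
        k = coding.index(cond)
        n_cond = 0
        for run in runs:
            g = run.g
            if M is None:
                M = g.shape[0]
            elif g.shape[0] != M:
                raise ValidationError("all series must share the cluster count M")
            T = g.shape[1]
            if T < p + 1:
                raise DataError(
                    f"condition {cond!r}: run of {T} samples cannot support "
                    f"lag order p={p} (need >= {p + 1})"
                )
            # responses: t = p .. T-1; predictors: lags within this run only
            Y = g[:, p:].T                                   # (T-p, M)
            lag_blocks = [g[:, p - l : T - l].T for l in range(1, p + 1)]
            base = np.hstack(lag_blocks)                     # (T-p, M*p)
            blocks = [base]
            for j in range(1, K + 1):
                blocks.append(base * coding.indicator(j, cond))
            rows_Y.append(Y)
            rows_X.append(np.hstack(blocks))
            n_cond += T - p
        n_obs_per_condition[cond] = n_cond

    if not rows_Y:
        raise DataError("no data supplied for any condition")
    index = [
        CoefIndex(condition=k, lag=l, source=j)
        for k in range(K + 1)
        for l in range(1, p + 1)
        for j in range(M)
    ]
    return CDVARDesign(
        Y=np.vstack(rows_Y),
        X=np.vstack(rows_X),
        index=index,
        M=M,
        p=p,
        K=K,
        condition_names=coding.condition_names,
        n_obs_per_condition=n_obs_per_condition,
    )


@dataclass
class CDVARFit:
    """OLS fit of the condition-driven VAR.

    ``phi`` has shape (K+1, p, M, M): ``phi[0]`` is the baseline
    connectivity, ``phi[k]`` (k >= 1) the delta for condition k;
    ``phi[k, l-1, i, j]`` is the lag-l effect of region j on region i.
    ``coef_cov`` is the asymptotic covariance of vec(B) (columns of the
    q x M coefficient matrix stacked, i.e. equation-major ordering):
    Sigma_eps kron (X'X)^{-1}.
    """

    p: int
    M: int
    K: int
    condition_names: tuple[str, ...]
    phi: np.ndarray
    se: np.ndarray
    resid_cov: np.ndarray
    xtx_inv: np.ndarray = field(repr=False)
    index: list[CoefIndex] = field(repr=False, default_factory=list)
    n_obs: int = 0
    dof: int = 0
    n_obs_per_condition: dict[str, int] = field(default_factory=dict)
    zvalues: np.ndarray | None = None
    pvalues: np.ndarray | None = None

    @property
    def coef_cov(self) -> np.ndarray:
        return np.kron(self.resid_cov, self.xtx_inv)

    def phi_total(self, k: int) -> np.ndarray:
        """Per-condition coefficients Phi_0 + Phi_k (shape (p, M, M))."""
        if k == 0:
            return self.phi[0]
        return self.phi[0] + self.phi[k]

    def companion_radii(self) -> dict[str, float]:
        """Companion spectral radius of each condition's total dynamics;
        values >= 1 indicate a non-stationary fitted process."""
        return {
            name: companion_spectral_radius(self.phi_total(k))
            for k, name in enumerate(self.condition_names)
        }


def fit_ols(design: CDVARDesign) -> CDVARFit:
    """Equation-by-equation least squares on the stacked design.

    Equivalent to multivariate OLS because every equation shares the same
    predictors.  The residual covariance uses the degrees-of-freedom
    correction n - q (q predictors per equation); the coefficient covariance
    is the standard asymptotic Kronecker form.
    """
    X, Y = design.X, design.Y
    n, q = X.shape
    if n <= q:
        raise DataError(f"need more observations ({n}) than coefficients ({q})")
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        # identify offending columns via the QR diagonal
        R = np.linalg.qr(X, mode="r")
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        cols = [design.index[c] for c in bad]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {q}); "
            f"collinear columns: {cols} -- a condition with no data or a "
            f"zero-variance predictor is the usual cause",
            collinear_columns=bad,
        )
    if n < 10 * q:
        warnings.warn(
            f"small sample: {n} observations for {q} coefficients per "
            f"equation (< 10x); standard errors will be unreliable",
            stacklevel=2,
        )

    B, *_ = np.linalg.lstsq(X, Y, rcond=None)       # (q, M)
    resid = Y - X @ B
    dof = n - q
    resid_cov = resid.T @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_flat = np.sqrt(np.outer(np.diag(xtx_inv), np.diag(resid_cov)))  # (q, M)

    M, p, K = design.M, design.p, design.K
    phi = np.zeros((K + 1, p, M, M))
    se = np.zeros_like(phi)
    for c, ci in enumerate(design.index):
        phi[ci.condition, ci.lag - 1, :, ci.source] = B[c]
        se[ci.condition, ci.lag - 1, :, ci.source] = se_flat[c]

    fit = CDVARFit(
        p=p,
        M=M,
        K=K,
        condition_names=design.condition_names,
        phi=phi,
        se=se,
        resid_cov=resid_cov,
        xtx_inv=xtx_inv,
        index=list(design.index),
        n_obs=n,
        dof=dof,
        n_obs_per_condition=dict(design.n_obs_per_condition),
    )
    radii = fit.companion_radii()
    unstable = {k: r for k, r in radii.items() if r >= 1.0}
    if unstable:
        warnings.warn(
            f"fitted dynamics non-stationary (companion spectral radius >= 1) "
            f"for conditions: {unstable}",
            stacklevel=2,
        )
    return fit


def wald_pvalues(fit: CDVARFit) -> np.ndarray:
    """Two-sided p-values for H0: phi_{k, j->i}(l) = 0.

    z = estimate / asymptotic SE, referred to the standard normal (the
    limiting law of the vectorised OLS coefficients).  The z map ("t-value
    map") is cached on the fit alongside the p-values.  Coefficients with a
    zero standard error get NaN p-values and a warning rather than a silent
    0 or 1.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.phi / fit.se
    zero_se = fit.se == 0
    if np.any(zero_se):
        warnings.warn(
            f"{int(zero_se.sum())} coefficients have zero standard error; "
            f"their p-values are undefined (NaN)",
            stacklevel=2,
        )
        z = np.where(zero_se, np.nan, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    fit.zvalues = z
    fit.pvalues = p
    return p


def _bh_mask(pflat: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up on a flat vector (NaN never rejected)."""
    finite = np.isfinite(pflat)
    mask = np.zeros(pflat.shape, dtype=bool)
    pv = pflat[finite]
    m = pv.size
    if m == 0:
        return mask
    order = np.argsort(pv)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = pv[order] <= thresh
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        cut = pv[order][kmax]
        mask[finite] = pv <= cut
    return mask


def significant_edges(
    pvalues: np.ndarray, alpha: float = 0.05, correction: str | None = None
) -> np.ndarray:
    """Boolean mask of significant coefficients (p <= alpha).

    ``correction=None`` reproduces plain per-coefficient thresholding;
    ``correction="bh"`` applies Benjamini-Hochberg across all coefficients.
    Self-edges (i == i) are included in the mask; callers that need them
    separated can compare indices.  NaN p-values are never significant.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(pvalues, dtype=float)
    if correction is None or correction == "none":
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(p), p <= alpha, False)
    if correction == "bh":
        return _bh_mask(p.ravel(), alpha).reshape(p.shape)
    raise ValidationError(f"unknown correction {correction!r}; use None or 'bh'")


def companion_spectral_radius(phi) -> float:
    """Spectral radius of the pM x pM companion matrix of a lag-matrix stack
    (p, M, M); < 1 certifies a stable (weakly stationary) VAR."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 2:
        phi = phi[None, :, :]
    p, M, M2 = phi.shape
    if M != M2:
        raise ValidationError("coefficient matrices must be square")
    comp = np.zeros((p * M, p * M))
    comp[:M, :] = np.concatenate(list(phi), axis=1)
    if p > 1:
        comp[M:, : (p - 1) * M] = np.eye((p - 1) * M)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))
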