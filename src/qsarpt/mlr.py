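"""Weighted multilinear regression of clearance indices on scaled descriptors.

Observation weights are 1, 1/Y or 1/Y² (Y = observed CI), the weighting
scheme used to stabilise the variance of replicate clearance measurements.
R² is reported from the unweighted residuals — the validation formulas carry
no weights — and the weighted coefficient of determination is stored
alongside.  Model simplification removes non-significant descriptors one at
a time (two-sided t-test, alpha 0.05), switching to bidirectional stepwise
search by AIC when many descriptors are non-significant; candidate models
are ranked by BIC after filtering on R² and coefficient significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .errors import CollinearityError, InsufficientDataError, UnknownDescriptorError
from .io import ClearanceTable
from .selection import ScaledMatrix

WEIGHTINGS = ("1", "1/Y", "1/Y2")


def _obs_weights(ci: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "1":
        return np.ones_like(ci)
    if weighting == "1/Y":
        return 1.0 / ci
    if weighting in ("1/Y2", "1/Y^2", "1/Y²"):
        return 1.0 / ci**2
    raise ValueError(f"unknown weighting {weighting!r}; use one of {WEIGHTINGS}")


@dataclass
class MLRModel:
    codes: tuple[str, ...]
    intercept: float
    coef: np.ndarray  # per descriptor, scaled space
    weighting: str
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray  # per descriptor (intercept excluded)
    intercept_pvalue: float
    r2: float  # unweighted coefficient of determination
    r2_weighted: float
    aic: float
    bic: float
    leverage: np.ndarray  # per observation, weighted hat diagonal
    obs_compounds: tuple[str, ...]
    training_compounds: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    n_obs: int
    degenerate: bool = False
    unprunable: bool = False

    @property
    def n_descriptors(self) -> int:
        return len(self.codes)

    def predict_scaled(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.n_descriptors == 0:
            return np.full(Z.shape[0], self.intercept)
        return self.intercept + Z @ self.coef

    def predict_raw(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict from raw descriptor values using the training center/scale."""
        X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
        if self.n_descriptors == 0:
            return np.full(X_raw.shape[0], self.intercept)
        return self.predict_scaled((X_raw - self.center) / self.scale)

    def coefficients_raw(self) -> tuple[float, np.ndarray]:
        """Back-transform to raw descriptor units; returns (intercept, betas)."""
        if self.n_descriptors == 0:
            return self.intercept, np.array([])
        betas = self.coef / self.scale
        return float(self.intercept - np.sum(betas * self.center)), betas

    def leverage_by_compound(self) -> pd.Series:
        return (
            pd.Series(self.leverage, index=list(self.obs_compounds))
            .groupby(level=0, sort=False)
            .mean()
        )

    def leverage_share(self) -> pd.Series:
        """Per-compound total hat share (sum over its replicate rows).

        Replicate rows are identical, so each individual row's hat value is
        bounded by 1/r (r replicates); the sum is the replicate-invariant
        leverage of the compound in the design, bounded by 1.
        """
        return (
            pd.Series(self.leverage, index=list(self.obs_compounds))
            .groupby(level=0, sort=False)
            .sum()
        )

    def to_report(self) -> dict:
        b0_raw, b_raw = self.coefficients_raw()
        return {
            "descriptors": list(self.codes),
            "weighting": self.weighting,
            "intercept_scaled": self.intercept,
            "coefficients_scaled": dict(zip(self.codes, map(float, self.coef))),
            "intercept_raw": b0_raw,
            "coefficients_raw": dict(zip(self.codes, map(float, b_raw))),
            "pvalues": dict(zip(self.codes, map(float, self.pvalues))),
            "r2": self.r2,
            "r2_weighted": self.r2_weighted,
            "aic": self.aic,
            "bic": self.bic,
            "leverage_by_compound": {
                k: float(v) for k, v in self.leverage_by_compound().items()
            },
            "degenerate": self.degenerate,
            "unprunable": self.unprunable,
        }


_EXPANSION_CACHE: dict = {}


def _obs_expansion(Xs: ScaledMatrix, y: ClearanceTable):
    """Replicate-expanded (compounds, ci, descriptor rows), memoised.

    Cross-validation and combination search refit the same data thousands of
    times; the expansion is identical across fits, so it is cached per
    (matrix, table) object pair (strong references guard against id reuse).
    """
    key = (id(Xs), id(y))
    hit = _EXPANSION_CACHE.get(key)
    if hit is not None and hit[0] is Xs and hit[1] is y:
        return hit[2]
    row_of = {c: i for i, c in enumerate(Xs.compound_ids)}
    comp = tuple(y.records["compound_id"])
    missing = sorted(set(comp) - set(row_of))
    if missing:
        raise UnknownDescriptorError(f"compounds without descriptor rows: {missing}")
    ci = y.records["ci"].to_numpy(dtype=float)
    V = Xs.values[[row_of[c] for c in comp]]
    if len(_EXPANSION_CACHE) > 16:
        _EXPANSION_CACHE.clear()
    _EXPANSION_CACHE[key] = (Xs, y, (comp, ci, V))
    return comp, ci, V


def _dependent_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Columns involved in exact linear dependences (via QR pivoting)."""
    r = np.linalg.matrix_rank(design)
    _, R = np.linalg.qr(design)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    weak = [names[i] for i in range(len(names)) if i < len(diag) and diag[i] <= tol]
    return weak or names[r:]


def fit_wls(
    Xs: ScaledMatrix,
    y: ClearanceTable,
    descriptors,
    weighting: str = "1/Y",
) -> MLRModel:
    """Weighted least squares of CI on the given scaled descriptors.

    Replicate observations share their compound's descriptor row.  Leverage
    is the diagonal of the weighted hat matrix (sums to the number of fitted
    parameters); AIC/BIC come from the Gaussian weighted log-likelihood.
    """
    descriptors = tuple(descriptors)
    comp, ci, V = _obs_expansion(Xs, y)
    col_idx = {c: j for j, c in enumerate(Xs.codes)}
    for code in descriptors:
        if code not in col_idx:
            raise UnknownDescriptorError(code)
    I = ci.size
    A = len(descriptors)
    if I <= A + 1:
        raise InsufficientDataError(f"{I} observations cannot support {A} descriptors")

    design = np.empty((I, A + 1))
    design[:, 0] = 1.0
    if A > 0:
        design[:, 1:] = V[:, [col_idx[c] for c in descriptors]]
    names = ["const", *descriptors]
    p = design.shape[1]

    # weighted normal equations solved directly; conventions (weighted
    # Gaussian log-likelihood, parameter count, weighted R^2) follow the
    # standard WLS definitions so information criteria are comparable
    w = _obs_weights(ci, weighting)
    sw = np.sqrt(w)
    Xw = design * sw[:, None]
    yw = ci * sw
    XtX = Xw.T @ Xw
    try:
        chol = np.linalg.cholesky(XtX)
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        raise CollinearityError(
            "rank-deficient design", columns=_dependent_columns(Xw, names)
        ) from None
    # guard against numerically singular but Cholesky-passing designs
    if not np.all(np.diag(chol) > np.sqrt(np.finfo(float).eps) * np.sqrt(np.diag(XtX).max())):
        raise CollinearityError(
            "rank-deficient design", columns=_dependent_columns(Xw, names)
        )
    params = XtX_inv @ (Xw.T @ yw)
    resid_w = yw - Xw @ params
    rss_w = float(resid_w @ resid_w)
    df_resid = I - p
    cov = XtX_inv * (rss_w / df_resid)
    se = np.sqrt(np.diag(cov))
    tvals = params / se
    pvals = 2.0 * special.stdtr(df_resid, -np.abs(tvals))

    fitted = design @ params
    resid = ci - fitted
    ss_tot = np.sum((ci - ci.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    ybar_w = float(np.sum(w * ci) / np.sum(w))
    tss_w = float(np.sum(w * (ci - ybar_w) ** 2))
    r2_weighted = 1.0 - rss_w / tss_w if tss_w > 0 else np.nan

    llf = -0.5 * I * (np.log(2 * np.pi) + np.log(rss_w / I) + 1.0) + 0.5 * np.sum(
        np.log(w)
    )
    aic = -2.0 * llf + 2.0 * p
    bic = -2.0 * llf + np.log(I) * p

    h = np.einsum("ij,jk,ik->i", Xw, XtX_inv, Xw)

    center, scale = Xs.center_scale(descriptors) if A else (np.array([]), np.array([]))
    return MLRModel(
        codes=descriptors,
        intercept=float(params[0]),
        coef=params[1:],
        weighting=weighting,
        se=se[1:],
        tvalues=tvals[1:],
        pvalues=pvals[1:],
        intercept_pvalue=float(pvals[0]),
        r2=float(r2),
        r2_weighted=float(r2_weighted),
        aic=float(aic),
        bic=float(bic),
        leverage=h,
        obs_compounds=comp,
        training_compounds=tuple(dict.fromkeys(comp)),
        center=center,
        scale=scale,
        n_obs=I,
    )


def prune_model(
    Xs: ScaledMatrix,
    y: ClearanceTable,
    model: MLRModel,
    alpha: float = 0.05,
    stepwise_trigger: int = 3,
) -> MLRModel:
    """Drop non-significant descriptors until all coefficients have p < alpha.

    One descriptor (the least significant) is removed per refit; when more
    than ``stepwise_trigger`` descriptors are simultaneously non-significant
    the search switches to bidirectional stepwise minimisation of AIC over
    the model's original descriptor pool.  A model pruned down to the
    intercept is returned flagged ``degenerate`` rather than raising.
    """
    pool = model.codes
    current = model
    used_stepwise = False
    while current.n_descriptors > 0:
        nonsig = [c for c, p in zip(current.codes, current.pvalues) if not (p < alpha)]
        if not nonsig:
            return current
        if len(nonsig) > stepwise_trigger and not used_stepwise:
            current = _stepwise_aic(Xs, y, current, pool)
            used_stepwise = True
            continue
        worst = current.codes[int(np.argmax(current.pvalues))]
        keep = tuple(c for c in current.codes if c != worst)
        current = fit_wls(Xs, y, keep, current.weighting)
    degenerate = fit_wls(Xs, y, (), model.weighting)
    return replace(degenerate, degenerate=True)


def _stepwise_aic(Xs, y, model: MLRModel, pool) -> MLRModel:
    """Bidirectional stepwise search minimising AIC within ``pool``."""
    current = model
    improved = True
    while improved:
        improved = False
        best = current
        for code in current.codes:  # backward
            try:
                cand = fit_wls(
                    Xs, y, tuple(c for c in current.codes if c != code), current.weighting
                )
            except (CollinearityError, InsufficientDataError):
                continue
            if cand.aic < best.aic - 1e-9:
                best = cand
        for code in pool:  # forward
            if code in current.codes:
                continue
            try:
                cand = fit_wls(Xs, y, current.codes + (code,), current.weighting)
            except (CollinearityError, InsufficientDataError):
                continue
            if cand.aic < best.aic - 1e-9:
                best = cand
        if best is not current:
            current = best
            improved = True
    return current


def forward_aic(
    Xs: ScaledMatrix,
    y: ClearanceTable,
    candidates,
    weighting: str = "1/Y",
    max_size: int = 8,
) -> MLRModel:
    """Forward selection from the intercept, minimising AIC, capped in size."""
    current = fit_wls(Xs, y, (), weighting)
    while current.n_descriptors < max_size:
        best = current
        for code in candidates:
            if code in current.codes:
                continue
            try:
                cand = fit_wls(Xs, y, current.codes + (code,), weighting)
            except (CollinearityError, InsufficientDataError):
                continue
            if cand.aic < best.aic - 1e-9:
                best = cand
        if best is current:
            break
        current = best
    return current


def rank_models(
    models: list[MLRModel], r2_min: float = 0.7, alpha: float = 0.05
) -> list[MLRModel]:
    """Keep fully-significant models with R² above ``r2_min``, sort by BIC.

    Ties are broken by fewer descriptors, then lexicographic codes.
    """
    survivors = [
        m
        for m in models
        if not m.degenerate
        and m.n_descriptors > 0
        and m.r2 > r2_min
        and bool(np.all(m.pvalues < alpha))
    ]
    return sorted(
        survivors, key=lambda m: (m.bic, m.n_descriptors, tuple(sorted(m.codes)))
    )


def flag_high_leverage(model: MLRModel, rule: float | None = None) -> dict[str, bool]:
    """Flag compounds whose leverage share exceeds a warning cutoff.

    The compound-level hat share h_c (sum over its replicate rows, <= 1) is
    compared to the classic warning leverage 3(A+1)/N (N compounds).  When
    that value is unattainable — it exceeds 1 whenever the parameter count
    approaches N/3, as here — the cutoff falls back to the midpoint between
    the mean share (A+1)/N and the maximum 1.  ``rule`` overrides the cutoff.
    Flagged compounds are pinned to training sets downstream: the model
    extrapolates at them, so they must inform the fit.
    """
    share = model.leverage_share()
    n_comp = share.size
    p = model.n_descriptors + 1
    if rule is not None:
        cutoff = rule
    else:
        cutoff = min(3.0 * p / n_comp, 0.5 * (1.0 + p / n_comp))
    return {comp: bool(h > cutoff) for comp, h in share.items()}
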