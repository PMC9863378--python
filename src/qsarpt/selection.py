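"""Descriptor scaling, neural-network importance weighting and enumeration of
uncorrelated descriptor combinations.

The selection procedure mirrors the modelling workflow: descriptors are
autoscaled (centered, unit SD), a small neural network with sigmoid output is
trained by resilient backpropagation to map descriptors to min-max-rescaled
clearance indices, and descriptors whose mean absolute input weight exceeds
twice the median of all weights are retained.  Correlated pairs (pairwise
R-squared above a threshold, default 0.5) among the retained descriptors are
then split recursively — each branch keeps one endpoint of the pair — until
only mutually uncorrelated sets remain; after deduplication and removal of
nested sets this equals the family of maximal independent sets of the
correlation graph.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, MissingValueError, UnknownDescriptorError
from .io import ClearanceTable, DescriptorMatrix


@dataclass
class ScaledMatrix:
    """Autoscaled descriptor matrix (columns centered, unit sample SD)."""

    compound_ids: list[str]
    codes: tuple[str, ...]
    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    dropped: tuple[str, ...] = ()

    def column(self, code: str) -> np.ndarray:
        try:
            j = self.codes.index(code)
        except ValueError:
            raise UnknownDescriptorError(code) from None
        return self.values[:, j]

    def columns(self, codes) -> np.ndarray:
        return np.column_stack([self.column(c) for c in codes])

    def center_scale(self, codes) -> tuple[np.ndarray, np.ndarray]:
        idx = [self.codes.index(c) for c in codes]
        return self.center[idx], self.scale[idx]


def scale_matrix(X: DescriptorMatrix) -> ScaledMatrix:
    """Center and scale each descriptor to unit sample SD (denominator n-1).

    Zero-variance columns are dropped and recorded; matrices with missing
    values or fewer than two compounds are rejected.
    """
    if X.has_missing:
        raise MissingValueError(
            f"matrix has missing values (columns {X.missing_codes or 'scattered NaNs'})"
        )
    if len(X.compound_ids) < 2:
        raise ValueError("need at least two compounds to estimate an SD")
    center = X.values.mean(axis=0)
    scale = X.values.std(axis=0, ddof=1)
    keep = scale > 0
    dropped = tuple(np.asarray(X.schema.codes)[~keep])
    values = (X.values[:, keep] - center[keep]) / scale[keep]
    return ScaledMatrix(
        compound_ids=list(X.compound_ids),
        codes=tuple(np.asarray(X.schema.codes)[keep]),
        values=values,
        center=center[keep],
        scale=scale[keep],
        dropped=dropped,
    )


@dataclass
class AnnConfig:
    restarts: int = 5
    seed: int = 0
    stepmax: int = 100_000
    threshold: float = 0.005  # stop when max |dE/dw| falls below this
    learning_rate: float = 0.02  # full-batch gradient step size
    hidden: int = 0  # optional single hidden layer size (sensitivity analysis)
    target_margin: float = 0.05  # min-max rescale the outcome into [m, 1-m]


@dataclass
class AnnSelectionResult:
    codes: tuple[str, ...]
    weights: np.ndarray  # mean |input weight| over restarts, per descriptor
    median_weight: float
    threshold: float  # = 2 * median_weight
    selected: tuple[str, ...]
    config: AnnConfig
    converged: tuple[bool, ...] = ()  # per restart

    def weight(self, code: str) -> float:
        return float(self.weights[self.codes.index(code)])


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _init_weights(seed: int, restart: int, codes, n_rows: int) -> np.ndarray:
    """Per-descriptor seeded initialisation keyed by descriptor identity.

    Seeding by a hash of the code (not the column position) makes training
    exactly equivariant under column permutations/relabelings.  The scale is
    kept well below typical trained weights: gradient descent only ever adds
    row-space components, so initial noise persists additively in the final
    weights and would otherwise blur the 2 x median selection threshold.
    """
    sd = 0.05 / np.sqrt(max(len(codes), 1))
    w = np.empty(len(codes) + 1)
    for j, code in enumerate(codes):
        key = zlib.crc32(str(code).encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, restart, key]))
        w[j] = rng.normal(0.0, sd)
    rng = np.random.default_rng(np.random.SeedSequence([seed, restart, zlib.crc32(b"__bias__")]))
    w[-1] = rng.normal(0.0, sd)
    return w


def _gd_train(
    X: np.ndarray,
    t: np.ndarray,
    W0: np.ndarray,
    stepmax: int,
    threshold: float,
    lr: float,
):
    """Full-batch gradient backpropagation, simultaneously for all restarts.

    ``W0`` has one row per restart, last column is the bias.  Updates are
    proportional to the gradient of the squared-error loss, so weights on
    descriptors that carry no outcome information stay near their small
    initial values while informative weights grow — the contrast the
    2 x median selection rule relies on.  Returns the trained weights and a
    per-restart convergence flag (max |gradient| below ``threshold``).
    """
    R, _ = W0.shape
    W = W0.copy()
    active = np.ones(R, dtype=bool)
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    rate = np.full(R, lr)

    def loss_grad(Wa):
        preds = _sigmoid(Xb @ Wa.T)  # (n, r)
        resid = preds - t[:, None]
        E = 0.5 * np.sum(resid**2, axis=0)
        grad = (resid * preds * (1.0 - preds)).T @ Xb
        return E, grad

    E, grad = loss_grad(W)
    for _ in range(stepmax):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        done = np.abs(grad[ia]).max(axis=1) < threshold
        if done.any():
            active[ia[done]] = False
            ia = ia[~done]
            if ia.size == 0:
                continue
        # backtracking step: halve the rate on loss increase (overshoot into
        # sigmoid saturation), grow it gently on success
        W_new = W[ia] - rate[ia, None] * grad[ia]
        E_new, grad_new = loss_grad(W_new)
        ok = E_new <= E[ia]
        W[ia[ok]] = W_new[ok]
        E[ia[ok]] = E_new[ok]
        grad[ia[ok]] = grad_new[ok]
        rate[ia[ok]] = np.minimum(rate[ia[ok]] * 1.1, 1.0)
        rate[ia[~ok]] *= 0.5
    return W, ~active


def ann_weights(
    Xs: ScaledMatrix, y: ClearanceTable, cfg: AnnConfig | None = None
) -> AnnSelectionResult:
    """Importance-weight descriptors with a sigmoid-output network.

    Descriptor rows are repeated for every replicate observation; the outcome
    is min-max rescaled before the sigmoid output.  The per-descriptor weight
    is the mean absolute input weight over random restarts, and descriptors
    with weight strictly greater than twice the median of all weights are
    selected.
    """
    cfg = cfg or AnnConfig()
    if len(Xs.codes) < 3:
        raise ValueError("descriptor weighting needs at least 3 descriptors")
    row_of = {c: i for i, c in enumerate(Xs.compound_ids)}
    comp = y.records["compound_id"].to_numpy()
    X = Xs.values[[row_of[c] for c in comp]]
    ci = y.records["ci"].to_numpy(dtype=float)
    if np.unique(ci).size < 2:
        raise ValueError("outcome must take at least two distinct values")
    m = cfg.target_margin
    t = m + (1 - 2 * m) * (ci - ci.min()) / (ci.max() - ci.min())

    d = len(Xs.codes)
    if cfg.hidden > 0:
        return _ann_weights_hidden(Xs, X, t, cfg)
    W0 = np.stack([_init_weights(cfg.seed, r, Xs.codes, X.shape[0]) for r in range(cfg.restarts)])
    W, converged = _gd_train(X, t, W0, cfg.stepmax, cfg.threshold, cfg.learning_rate)
    if not converged.any():
        partial = _selection_from_weights(Xs.codes, np.abs(W[:, :d]).mean(axis=0), cfg, converged)
        raise ConvergenceError(
            f"no restart reached gradient < {cfg.threshold} in {cfg.stepmax} steps",
            result=partial,
        )
    weights = np.abs(W[converged][:, :d]).mean(axis=0)
    return _selection_from_weights(Xs.codes, weights, cfg, converged)


def _selection_from_weights(codes, weights, cfg, converged) -> AnnSelectionResult:
    median = float(np.median(weights))
    thr = 2.0 * median
    selected = tuple(c for c, w in zip(codes, weights) if w > thr)
    return AnnSelectionResult(
        codes=tuple(codes),
        weights=np.asarray(weights, dtype=float),
        median_weight=median,
        threshold=thr,
        selected=selected,
        config=cfg,
        converged=tuple(bool(b) for b in converged),
    )


def _ann_weights_hidden(Xs: ScaledMatrix, X, t, cfg: AnnConfig) -> AnnSelectionResult:
    """One-hidden-layer variant; importance by connection-weight products."""
    n, d = X.shape
    h = cfg.hidden
    importances = []
    converged = []
    for r in range(cfg.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, r, 7]))
        sd = 0.5 / np.sqrt(d)
        W1 = rng.normal(0, sd, size=(d + 1, h))
        W2 = rng.normal(0, 0.5 / np.sqrt(h), size=h + 1)
        theta = np.concatenate([W1.ravel(), W2])
        Xb = np.hstack([X, np.ones((n, 1))])
        ok = False
        for _ in range(cfg.stepmax):
            W1 = theta[: (d + 1) * h].reshape(d + 1, h)
            W2 = theta[(d + 1) * h :]
            H = _sigmoid(Xb @ W1)
            out = _sigmoid(H @ W2[:-1] + W2[-1])
            dout = (out - t) * out * (1 - out)
            gW2 = np.append(H.T @ dout, dout.sum())
            dH = np.outer(dout, W2[:-1]) * H * (1 - H)
            gW1 = Xb.T @ dH
            g = np.concatenate([gW1.ravel(), gW2])
            if np.abs(g).max() < cfg.threshold:
                ok = True
                break
            theta -= cfg.learning_rate * g
        converged.append(ok)
        W1 = theta[: (d + 1) * h].reshape(d + 1, h)
        W2 = theta[(d + 1) * h :]
        importances.append(np.abs(W1[:d] @ W2[:-1]))
    converged = np.asarray(converged)
    if not converged.any():
        raise ConvergenceError(
            "no restart converged (hidden-layer variant)",
            result=_selection_from_weights(Xs.codes, np.mean(importances, axis=0), cfg, converged),
        )
    weights = np.mean([imp for imp, ok in zip(importances, converged) if ok], axis=0)
    return _selection_from_weights(Xs.codes, weights, cfg, converged)


@dataclass
class CombinationList:
    sets: tuple[frozenset, ...]
    r2_threshold: float

    def __len__(self):
        return len(self.sets)

    def as_sorted_tuples(self) -> list[tuple[str, ...]]:
        return sorted(tuple(sorted(s)) for s in self.sets)


def enumerate_uncorrelated(
    Xs: ScaledMatrix, candidates, r2_threshold: float = 0.5
) -> CombinationList:
    """All maximal mutually-uncorrelated subsets of ``candidates``.

    Pairs with squared Pearson correlation strictly above ``r2_threshold``
    (computed across compounds) are split recursively, dropping one endpoint
    per branch; duplicate and nested leaves are removed, which yields exactly
    the maximal independent sets of the correlation graph.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        return CombinationList(sets=(), r2_threshold=r2_threshold)
    for c in candidates:
        if c not in Xs.codes:
            raise UnknownDescriptorError(c)
    Z = Xs.columns(candidates)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(Z, rowvar=False)
    r2 = np.nan_to_num(np.atleast_2d(r)) ** 2
    k = len(candidates)
    correlated = [
        {j for j in range(k) if j != i and r2[i, j] > r2_threshold} for i in range(k)
    ]
    # Naive pair-splitting revisits exponentially many intermediate subsets;
    # its deduplicated, maximality-filtered leaves are exactly the maximal
    # cliques of the complement ("uncorrelated") graph, enumerated here by
    # Bron-Kerbosch with pivoting.
    uncorr = [frozenset(range(k)) - correlated[i] - {i} for i in range(k)]
    maximal: list[frozenset] = []

    def expand(clique: frozenset, cand: frozenset, excl: frozenset) -> None:
        if not cand and not excl:
            maximal.append(clique)
            return
        pivot = max(cand | excl, key=lambda v: len(uncorr[v] & cand))
        for v in sorted(cand - uncorr[pivot]):
            expand(clique | {v}, cand & uncorr[v], excl & uncorr[v])
            cand = cand - {v}
            excl = excl | {v}

    expand(frozenset(), frozenset(range(k)), frozenset())
    sets = tuple(
        frozenset(candidates[i] for i in s)
        for s in sorted(maximal, key=lambda s: tuple(sorted(s)))
    )
    return CombinationList(sets=sets, r2_threshold=r2_threshold)
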