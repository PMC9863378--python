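"""Train/test split design and the validation metric battery.

The 15-compound, 5-replicate data set is divided into three leave-many-out
(LMO) data sets: each has an 11-compound training set (55 observations) and
a 4-compound test set (20 observations); high-leverage compounds are pinned
to every training set.  Metrics:

* calibration — R² = 1 - RSS/TSS and RMSEC with denominator I - A - 1,
* cross-validation — Q² (same form on leave-one-compound-out predictions)
  and RMSECV with denominator I,
* LMO — QLMO² = 1 - (PRESS_ext/nEXT)/(SS_training/nTR), RMSEP, Lin's
  concordance correlation coefficient (CCC) plus squared Pearson and
  Spearman correlations between observed and predicted values.

Acceptance thresholds: R² > 0.65, Q² > 0.5, QLMO² > 0.65, CCC > 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, SplitConflictError
from .io import ClearanceTable
from .mlr import MLRModel, fit_wls, flag_high_leverage
from .selection import ScaledMatrix

THRESHOLDS = {"r2": 0.65, "q2": 0.5, "qlmo2": 0.65, "ccc": 0.85}


@dataclass(frozen=True)
class SplitPlan:
    """N train/test compound allocations with pinned (never-tested) compounds."""

    sets: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    pinned: tuple[str, ...] = ()

    def __post_init__(self):
        tested: list[str] = []
        for train, test in self.sets:
            for c in test:
                if c in self.pinned:
                    raise SplitConflictError(f"pinned compound {c!r} placed in a test set")
                if c in tested:
                    raise SplitConflictError(f"compound {c!r} appears in two test sets")
                if c in train:
                    raise SplitConflictError(f"compound {c!r} in both train and test")
            tested.extend(test)

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def make_split_plan(
    compounds,
    pinned=(),
    n_sets: int = 3,
    test_size: int = 4,
    seed: int = 0,
) -> SplitPlan:
    """Randomly allocate non-pinned compounds to disjoint test sets.

    Every compound not in a test set (pinned ones always) goes to that set's
    training side, so replicates of a compound never straddle a split.
    """
    compounds = list(dict.fromkeys(compounds))
    pinned = tuple(pinned)
    for p in pinned:
        if p not in compounds:
            raise ValueError(f"pinned compound {p!r} not among compounds")
    eligible = [c for c in compounds if c not in pinned]
    need = n_sets * test_size
    if len(eligible) < need:
        raise ValueError(
            f"{len(eligible)} eligible compounds cannot fill {n_sets} x {test_size} test slots"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(eligible))
    sets = []
    for s in range(n_sets):
        test = tuple(sorted(order[s * test_size : (s + 1) * test_size]))
        train = tuple(c for c in compounds if c not in test)
        sets.append((train, test))
    return SplitPlan(sets=tuple(sets), pinned=pinned)


def concordance_ccc(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (agreement with identity)."""
    y, p = np.asarray(y_obs, float), np.asarray(y_pred, float)
    my, mp = y.mean(), p.mean()
    num = 2.0 * np.sum((y - my) * (p - mp))
    den = np.sum((y - my) ** 2) + np.sum((p - mp) ** 2) + y.size * (my - mp) ** 2
    return float(num / den) if den > 0 else np.nan


def compute_metrics(
    y_obs,
    y_pred,
    context: str,
    I: int | None = None,
    A: int | None = None,
    n_ext: int | None = None,
    n_tr: int | None = None,
    y_train=None,
) -> dict:
    """Validation metrics for one context: calibration, cv or lmo.

    ``y_train`` (the training observations) is required for the lmo context,
    whose denominator is the training-set variance SS/nTR.
    """
    y = np.asarray(y_obs, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    rss = float(np.sum((y - p) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))

    if context == "calibration":
        I = I if I is not None else y.size
        A = 0 if A is None else A
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        return {"r2": r2, "rmsec": float(np.sqrt(rss / (I - A - 1)))}
    if context == "cv":
        I = I if I is not None else y.size
        q2 = 1.0 - rss / tss if tss > 0 else np.nan
        return {"q2": q2, "rmsecv": float(np.sqrt(rss / I))}
    if context == "lmo":
        if y_train is None:
            raise ValueError("lmo context requires y_train")
        yt = np.asarray(y_train, dtype=float)
        n_ext = n_ext if n_ext is not None else y.size
        n_tr = n_tr if n_tr is not None else yt.size
        ss_tr = float(np.sum((yt - yt.mean()) ** 2))
        qlmo2 = 1.0 - (rss / n_ext) / (ss_tr / n_tr) if ss_tr > 0 else np.nan
        pr = stats.pearsonr(y, p).statistic if np.std(p) > 0 and np.std(y) > 0 else np.nan
        sp = stats.spearmanr(y, p).statistic if np.std(p) > 0 and np.std(y) > 0 else np.nan
        return {
            "qlmo2": qlmo2,
            "rmsep": float(np.sqrt(rss / n_ext)),
            "ccc": concordance_ccc(y, p),
            "pearson2": float(pr**2) if pr == pr else np.nan,
            "spearman2": float(sp**2) if sp == sp else np.nan,
        }
    raise ValueError(f"unknown context {context!r}")


def cross_validate(
    Xs: ScaledMatrix,
    y: ClearanceTable,
    descriptors,
    weighting: str = "1/Y",
    grouped: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Cross-validation on the given data, grouped by compound by default.

    With ``grouped=True`` (leave-one-compound-out) all replicates of the
    held-out compound leave together — their descriptor rows are identical,
    so observation-level folds would leak the compound into training.  The
    row-level variant (``grouped=False``) is provided for comparison.
    Returns (Q², RMSECV, per-observation predictions); folds with
    rank-deficient designs are skipped and reported in the prediction frame.
    """
    compounds = y.compounds
    if len(compounds) < 3:
        raise ValueError("cross-validation needs at least 3 compounds")
    rows = []
    row_of = {c: i for i, c in enumerate(Xs.compound_ids)}
    if grouped:
        for held in compounds:
            rest = y.for_compounds([c for c in compounds if c != held])
            try:
                m = fit_wls(Xs, rest, descriptors, weighting)
            except CollinearityError:
                rows.append({"compound_id": held, "skipped": True})
                continue
            z = Xs.values[row_of[held]][[Xs.codes.index(c) for c in descriptors]]
            pred = float(m.predict_scaled(z[None, :])[0])
            for _, rec in y.for_compounds([held]).records.iterrows():
                rows.append(
                    {
                        "compound_id": held,
                        "replicate_id": rec["replicate_id"],
                        "ci": rec["ci"],
                        "ci_pred": pred,
                        "skipped": False,
                    }
                )
    else:
        for k in range(len(y.records)):
            rest = ClearanceTable(y.records.drop(index=k).reset_index(drop=True))
            rec = y.records.iloc[k]
            try:
                m = fit_wls(Xs, rest, descriptors, weighting)
            except CollinearityError:
                rows.append({"compound_id": rec["compound_id"], "skipped": True})
                continue
            z = Xs.values[row_of[rec["compound_id"]]][
                [Xs.codes.index(c) for c in descriptors]
            ]
            rows.append(
                {
                    "compound_id": rec["compound_id"],
                    "replicate_id": rec["replicate_id"],
                    "ci": rec["ci"],
                    "ci_pred": float(m.predict_scaled(z[None, :])[0]),
                    "skipped": False,
                }
            )
    preds = pd.DataFrame(rows)
    ok = preds[~preds["skipped"]]
    if len(ok) < 2:
        return float("nan"), float("nan"), preds
    m = compute_metrics(ok["ci"], ok["ci_pred"], "cv", I=len(ok))
    return m["q2"], m["rmsecv"], preds


@dataclass
class ValidationReport:
    """Table-2-shaped metric set with threshold verdicts."""

    per_set: list[dict]
    aggregate: dict
    pooled: pd.DataFrame  # compound, mean observed CI, predicted CI, set id
    verdicts: dict[str, bool]
    thresholds: dict[str, float] = field(default_factory=lambda: dict(THRESHOLDS))
    unreliable: tuple[str, ...] = ()

    def verdict_strings(self) -> dict[str, str]:
        out = {}
        for key, thr in self.thresholds.items():
            val = self.aggregate.get(key, np.nan)
            out[key] = f"{key}={val:.3f} {'passes' if self.verdicts[key] else 'fails'} >{thr}"
        return out


def lmo_validate(
    Xs: ScaledMatrix,
    y: ClearanceTable,
    descriptors,
    plan: SplitPlan,
    weighting: str = "1/Y",
) -> ValidationReport:
    """Leave-many-out validation of a fixed descriptor set over a split plan.

    Per data set: fit on training observations, report calibration R²/RMSEC
    and leave-one-compound-out Q²/RMSECV, then predict the test compounds
    and score QLMO²/RMSEP against the training-set variance.  CCC and the
    squared Pearson/Spearman correlations are computed on predictions pooled
    across the test sets against per-compound mean observed CI.  R², Q² and
    QLMO² aggregate as means over the data sets; the aggregate RMSEP is
    pooled over all test observations.
    """
    descriptors = tuple(descriptors)
    per_set = []
    pooled_rows = []
    unreliable: list[str] = []
    row_of = {c: i for i, c in enumerate(Xs.compound_ids)}
    press_tot, n_ext_tot = 0.0, 0
    for s, (train, test) in enumerate(plan.sets, start=1):
        y_tr = y.for_compounds(train)
        model = fit_wls(Xs, y_tr, descriptors, weighting)
        cal = compute_metrics(
            y_tr.records["ci"],
            model.predict_scaled(Xs.columns(descriptors)[[row_of[c] for c in y_tr.records["compound_id"]]]),
            "calibration",
            I=len(y_tr),
            A=len(descriptors),
        )
        q2, rmsecv, _ = cross_validate(Xs, y_tr, descriptors, weighting)

        flags = flag_high_leverage(model)
        y_te = y.for_compounds(test)
        Z_te = Xs.columns(descriptors)[[row_of[c] for c in y_te.records["compound_id"]]]
        pred_te = model.predict_scaled(Z_te)
        lmo = compute_metrics(
            y_te.records["ci"], pred_te, "lmo",
            n_ext=len(y_te), n_tr=len(y_tr), y_train=y_tr.records["ci"],
        )
        press_tot += float(np.sum((y_te.records["ci"].to_numpy() - pred_te) ** 2))
        n_ext_tot += len(y_te)

        mean_obs = y_te.mean_by_compound()
        for comp in test:
            z = Xs.values[row_of[comp]][[Xs.codes.index(c) for c in descriptors]]
            pred = float(model.predict_scaled(z[None, :])[0])
            flagged = flags.get(comp, False)
            if flagged:
                unreliable.append(comp)
            pooled_rows.append(
                {
                    "compound_id": comp,
                    "mean_obs_ci": float(mean_obs[comp]),
                    "pred_ci": pred,
                    "data_set": s,
                    "unreliable": flagged,
                }
            )
        per_set.append(
            {
                "data_set": s,
                "r2": cal["r2"],
                "rmsec": cal["rmsec"],
                "q2": q2,
                "rmsecv": rmsecv,
                "qlmo2": lmo["qlmo2"],
                "rmsep": lmo["rmsep"],
                "bic": model.bic,
                "aic": model.aic,
            }
        )

    pooled = pd.DataFrame(pooled_rows)
    ccc = concordance_ccc(pooled["mean_obs_ci"], pooled["pred_ci"])
    pr = stats.pearsonr(pooled["mean_obs_ci"], pooled["pred_ci"]).statistic
    sp = stats.spearmanr(pooled["mean_obs_ci"], pooled["pred_ci"]).statistic
    aggregate = {
        "r2": float(np.mean([d["r2"] for d in per_set])),
        "rmsec": float(np.mean([d["rmsec"] for d in per_set])),
        "q2": float(np.mean([d["q2"] for d in per_set])),
        "rmsecv": float(np.mean([d["rmsecv"] for d in per_set])),
        "qlmo2": float(np.mean([d["qlmo2"] for d in per_set])),
        "rmsep_mean": float(np.mean([d["rmsep"] for d in per_set])),
        "rmsep": float(np.sqrt(press_tot / n_ext_tot)),
        "ccc": ccc,
        "pearson2": float(pr**2),
        "spearman2": float(sp**2),
        "bic": float(np.mean([d["bic"] for d in per_set])),
    }
    verdicts = {k: bool(aggregate[k] > thr) for k, thr in THRESHOLDS.items()}
    return ValidationReport(
        per_set=per_set,
        aggregate=aggregate,
        pooled=pooled,
        verdicts=verdicts,
        unreliable=tuple(dict.fromkeys(unreliable)),
    )
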