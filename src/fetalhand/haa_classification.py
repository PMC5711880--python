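"""Hand-asymmetry advantage (HAA) inference of postnatal handedness.

Per-fetus HAA/rHAA in each (week x target) condition, sign-rule
classification with label-permutation p-values, group HAA separation,
the min-distance silhouette variant, and leave-one-out cross-validated
logistic regression.

Sign conventions (positive metrics):
  * HAA = mean(RH movements) - mean(LH movements), per fetus.
  * MT: the dominant hand is faster, so haa < 0 predicts right-handedness.
  * TPV: the dominant hand decelerates for a shorter time (larger TPV),
    so haa > 0 predicts right-handedness.
Permutation p-values use the literal strictly-greater rule: the fraction of
permuted accuracies strictly exceeding the observed one (an add-one smoothed
variant is available via ``smoothed=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fetalhand.data_model import Cohort
from fetalhand.errors import DegenerateDataError, ValidationError
from fetalhand.robust_stats import TestResult, hodges_lehmann, spearman, welch_u_test

#: Numeric handedness coding used for rank correlations with HAA_MT:
#: right = -1 and left = +1, so that a genuine dominant-hand MT advantage
#: (negative haa for right-handers) yields a positive correlation.
HANDEDNESS_CODING = {"right": -1.0, "left": 1.0}

_TIE = "tie"  # sentinel prediction for haa == 0; scored as incorrect


@dataclass(frozen=True)
class HAAResult:
    """Per-fetus hand-asymmetry advantage in one condition."""

    fetus_id: str
    gw: int | None
    target: str
    metric: str
    haa: float
    rhaa: float
    n_rh: int
    n_lh: int
    rh_mean: float = float("nan")
    lh_mean: float = float("nan")


@dataclass
class HAACollection:
    """HAA results for one condition plus exclusion bookkeeping."""

    metric: str
    results: list[HAAResult]
    n_excluded: int  # fetuses active in the condition but missing a hand

    @property
    def values(self) -> np.ndarray:
        return np.array([r.haa for r in self.results], dtype=float)

    @property
    def rhaa_values(self) -> np.ndarray:
        return np.array([r.rhaa for r in self.results], dtype=float)

    @property
    def per_hand_means(self) -> np.ndarray:
        """(n_fetuses, 2) array of (RH mean, LH mean) features."""
        return np.array([[r.rh_mean, r.lh_mean] for r in self.results], dtype=float)

    def labels(self, cohort: Cohort) -> np.ndarray:
        hmap = cohort.handedness_map
        return np.array([hmap[r.fetus_id] for r in self.results])


@dataclass(frozen=True)
class AccuracyResult:
    """Classification accuracy with an optional permutation p-value."""

    accuracy: float
    n_classified: int
    p_perm: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    diagnostics: tuple[str, ...] = ()


@dataclass(frozen=True)
class SilhouetteResult:
    values: np.ndarray  # per-point silhouette, each in [-1, 1]
    mean: float
    p_perm: float | None
    n_permutations: int
    seed: int | None
    flags: tuple[str, ...] = ()


def compute_haa(cohort: Cohort, metric: str, gw: int, target: str) -> HAACollection:
    """Per-fetus HAA and rHAA for one (metric, week, target) condition.

    A fetus contributes only when it has at least one movement with each
    hand in the condition; fetuses seen with a single hand are excluded and
    counted in ``n_excluded``.
    """
    if metric not in ("mt", "tpv"):
        raise ValidationError(f"unknown metric {metric!r}")
    df = cohort.to_frame()
    sub = df[(df.gw == gw) & (df.target == target)]
    results: list[HAAResult] = []
    n_excluded = 0
    for fid, grp in sub.groupby("fetus_id", sort=True):
        rh = grp.loc[grp.hand == "right", metric].to_numpy()
        lh = grp.loc[grp.hand == "left", metric].to_numpy()
        if rh.size == 0 or lh.size == 0:
            n_excluded += 1
            continue
        haa = float(rh.mean() - lh.mean())
        rhaa = 2.0 * haa / float(rh.mean() + lh.mean())
        results.append(
            HAAResult(str(fid), gw, target, metric, haa, rhaa, rh.size, lh.size,
                      rh_mean=float(rh.mean()), lh_mean=float(lh.mean()))
        )
    return HAACollection(metric=metric, results=results, n_excluded=n_excluded)


def sign_classify(haa_values, metric: str) -> np.ndarray:
    """Predict handedness from the sign of the HAA.

    MT: right iff haa < 0.  TPV: right iff haa > 0.  A zero HAA gives the
    tie sentinel, which never matches a label (scored incorrect).
    """
    v = np.asarray(haa_values, dtype=float)
    if metric == "mt":
        neg, pos = "right", "left"
    elif metric == "tpv":
        neg, pos = "left", "right"
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    out = np.where(v < 0, neg, np.where(v > 0, pos, _TIE))
    return out


def classification_accuracy(predictions, labels) -> AccuracyResult:
    """Exact fraction of predictions matching the labels."""
    preds = np.asarray(predictions)
    labs = np.asarray(labels)
    if preds.size == 0 or preds.shape != labs.shape:
        raise ValidationError("predictions and labels must be equal-length and non-empty")
    return AccuracyResult(accuracy=float(np.mean(preds == labs)), n_classified=int(preds.size))


def permutation_pvalue(
    predictions,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
    smoothed: bool = False,
    rule: str = "greater",
) -> AccuracyResult:
    """Label-permutation p-value for a fixed prediction vector.

    Shuffles the label vector uniformly ``n_perm`` times.  ``rule`` sets the
    tie handling: ``"greater"`` (default) is the literal strictly-greater
    fraction; ``"greater-equal"`` is the conventional valid permutation p;
    ``"mid"`` counts half the tie mass (mid-p), the standard remedy for the
    heavily discrete accuracy distribution at small n.  ``smoothed`` applies
    the add-one estimate (b + 1)/(n_perm + 1).

    The accuracy distribution has few support points (it is hypergeometric
    in the prediction/label overlap), so the literal rule is markedly
    anti-conservative and the greater-equal rule conservative; mid-p is the
    only variant with near-nominal type-I error at alpha = 0.05.
    """
    preds = np.asarray(predictions)
    labs = np.asarray(labels)
    if np.unique(labs).size < 2:
        raise DegenerateDataError("permutation p undefined with a single class")
    observed = float(np.mean(preds == labs))
    rng = np.random.default_rng(seed)
    n = labs.size
    # n_perm x n matrix of permuted label indices.
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_acc = (labs[perm_idx] == preds[None, :]).mean(axis=1)
    greater = float(np.sum(perm_acc > observed + 1e-12))
    ties = float(np.sum(np.abs(perm_acc - observed) <= 1e-12))
    if rule == "greater":
        exceed = greater
    elif rule == "greater-equal":
        exceed = greater + ties
    elif rule == "mid":
        exceed = greater + 0.5 * ties
    else:
        raise ValidationError(f"unknown rule {rule!r}")
    p = (exceed + 1) / (n_perm + 1) if smoothed else exceed / n_perm
    return AccuracyResult(
        accuracy=observed, n_classified=int(n), p_perm=float(p),
        n_permutations=int(n_perm), seed=seed,
    )


def permutation_accuracy_test(
    haa_values,
    labels,
    metric: str,
    n_perm: int = 10_000,
    seed: int | None = None,
    smoothed: bool = False,
    rule: str = "greater",
) -> AccuracyResult:
    """Sign-rule accuracy plus its label-permutation p-value."""
    preds = sign_classify(haa_values, metric)
    return permutation_pvalue(
        preds, labels, n_perm=n_perm, seed=seed, smoothed=smoothed, rule=rule
    )


def group_haa_separation(haa_values, labels) -> TestResult:
    """Location difference of HAA between the handedness groups.

    Hodges-Lehmann estimate oriented left-handed group minus right-handed
    group (positive for MT when the dominant-hand advantage is present),
    with a Welch U-test p-value.
    """
    v = np.asarray(haa_values, dtype=float)
    labs = np.asarray(labels)
    left = v[labs == "left"]
    right = v[labs == "right"]
    if left.size < 2 or right.size < 2:
        raise DegenerateDataError(
            f"need >= 2 fetuses per group, got left={left.size}, right={right.size}"
        )
    res = welch_u_test(left, right)
    return TestResult(
        estimate=hodges_lehmann(left, right),
        statistic=res.statistic,
        df=res.df,
        p_raw=res.p_raw,
        method="hl-welch-u(left-right)",
    )


# ---------------------------------------------------------------------------
# Silhouette (paper variant: b is the MINIMUM distance to the other cluster)


def silhouette_values(values, labels) -> tuple[np.ndarray, list[str]]:
    """Per-point silhouette s = (b - a) / max(a, b) on 1-D data.

    a(i) is the mean absolute difference to same-cluster points (excluding
    the point itself); b(i) is the minimum absolute difference to the other
    cluster.  Points in a singleton cluster get s = 0 and a flag.
    """
    v = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    if v.size != labs.size or v.size < 2:
        raise ValidationError("need >= 2 paired values/labels")
    if np.unique(labs).size != 2:
        raise DegenerateDataError("silhouette needs exactly two clusters")
    flags: list[str] = []
    s = np.zeros(v.size)
    dist = np.abs(v[:, None] - v[None, :])
    for i in range(v.size):
        same = (labs == labs[i])
        same[i] = False
        other = labs != labs[i]
        if not same.any():
            flags.append(f"point {i}: singleton cluster, s set to 0")
            continue
        a = dist[i, same].mean()
        b = dist[i, other].min()
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, flags


def silhouette_analysis(
    values, labels, n_perm: int = 1000, seed: int | None = None
) -> SilhouetteResult:
    """Mean silhouette of the handedness clustering plus a permutation p.

    The p-value shuffles the cluster labels and counts the fraction of
    permutations whose mean silhouette strictly exceeds the observed one.
    """
    v = np.asarray(values, dtype=float)
    labs = np.asarray(labels)
    s, flags = silhouette_values(v, labs)
    observed = float(s.mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labs)
        sp, _ = silhouette_values(v, perm)
        if sp.mean() > observed:
            exceed += 1
    return SilhouetteResult(
        values=s, mean=observed, p_perm=exceed / n_perm,
        n_permutations=n_perm, seed=seed, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# LOOCV logistic regression


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _fit_ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1e-3) -> np.ndarray:
    """Newton-Raphson fit of intercept + coefficients with a small ridge.

    The ridge (not applied to the intercept) is a numerical device that
    keeps the optimum finite under complete separation; at lam = 1e-3 on
    standardized features it does not materially move non-separable fits.
    """
    n, k = X.shape
    Xb = np.column_stack([np.ones(n), X])
    w = np.zeros(k + 1)
    pen = np.full(k + 1, lam)
    pen[0] = 0.0
    for _ in range(100):
        p = _sigmoid(Xb @ w)
        grad = Xb.T @ (p - y) + pen * w
        wdiag = np.maximum(p * (1 - p), 1e-10)
        hess = Xb.T @ (wdiag[:, None] * Xb) + np.diag(np.maximum(pen, 1e-10))
        step = np.linalg.solve(hess, grad)
        w -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    return w


def _loocv_predictions(X: np.ndarray, labs: np.ndarray, lam: float) -> tuple[np.ndarray, int]:
    """Held-out label predictions; returns (predictions, n single-class folds)."""
    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    n_single = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ltr = X[mask], labs[mask]
        classes = np.unique(ltr)
        if classes.size == 1:
            preds[i] = classes[0]  # majority-class fallback
            n_single += 1
            continue
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        ytr = (ltr == "left").astype(float)
        w = _fit_ridge_logistic((Xtr - mu) / sd, ytr, lam=lam)
        z = w[0] + ((X[i] - mu) / sd) @ w[1:]
        preds[i] = "left" if z > 0 else "right"
    return preds, n_single


def loocv_logistic(
    features,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
    lam: float = 1e-3,
    smoothed: bool = False,
    rule: str = "greater",
) -> AccuracyResult:
    """Leave-one-out cross-validated logistic classification of handedness.

    For each fetus a logistic model (intercept + features, features
    standardized on the training fold) is fitted on the remaining fetuses
    and the held-out label predicted at probability threshold 0.5.  The
    permutation p-value relabels the fetuses and repeats the full LOOCV.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labs = np.asarray(labels)
    if X.shape[0] != labs.size:
        raise ValidationError("features and labels must align")
    classes, counts = np.unique(labs, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise DegenerateDataError("need >= 2 fetuses per class")

    preds, n_single = _loocv_predictions(X, labs, lam)
    observed = float(np.mean(preds == labs))
    diagnostics = []
    if n_single:
        diagnostics.append(f"{n_single} single-class training folds (majority fallback)")

    tie_weight = {"greater": 0.0, "greater-equal": 1.0, "mid": 0.5}.get(rule)
    if tie_weight is None:
        raise ValidationError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    exceed = 0.0
    for _ in range(n_perm):
        perm_labs = rng.permutation(labs)
        perm_preds, _ = _loocv_predictions(X, perm_labs, lam)
        acc = np.mean(perm_preds == perm_labs)
        if acc > observed + 1e-12:
            exceed += 1.0
        elif abs(acc - observed) <= 1e-12:
            exceed += tie_weight
    p = (exceed + 1) / (n_perm + 1) if smoothed else exceed / n_perm if n_perm else None
    return AccuracyResult(
        accuracy=observed, n_classified=int(labs.size), p_perm=p,
        n_permutations=int(n_perm), seed=seed, diagnostics=tuple(diagnostics),
    )


# ---------------------------------------------------------------------------
# Pooled-mouth analysis


@dataclass
class PooledMouthResult:
    """Handedness inference from mouth MT pooled over gestational weeks."""

    haa: HAACollection
    sign: AccuracyResult
    loocv: AccuracyResult
    spearman_rho: float
    spearman_p: float
    n_excluded: int = field(init=False)

    def __post_init__(self):
        self.n_excluded = self.haa.n_excluded


def pooled_mouth_haa(cohort: Cohort) -> HAACollection:
    """Per-fetus rHAA of mouth MT pooled across all gestational weeks."""
    df = cohort.to_frame()
    sub = df[df.target == "mouth"]
    results: list[HAAResult] = []
    n_excluded = 0
    for fid, grp in sub.groupby("fetus_id", sort=True):
        rh = grp.loc[grp.hand == "right", "mt"].to_numpy()
        lh = grp.loc[grp.hand == "left", "mt"].to_numpy()
        if rh.size == 0 or lh.size == 0:
            n_excluded += 1
            continue
        haa = float(rh.mean() - lh.mean())
        rhaa = 2.0 * haa / float(rh.mean() + lh.mean())
        results.append(
            HAAResult(str(fid), None, "mouth", "mt", haa, rhaa, rh.size, lh.size,
                      rh_mean=float(rh.mean()), lh_mean=float(lh.mean()))
        )
    return HAACollection(metric="mt", results=results, n_excluded=n_excluded)


def pooled_mouth_analysis(
    cohort: Cohort,
    n_perm_sign: int = 10_000,
    n_perm_loocv: int = 1000,
    seed: int | None = None,
) -> PooledMouthResult:
    """Sign-rule, LOOCV-logistic and rank-correlation inference on pooled mouth MT."""
    coll = pooled_mouth_haa(cohort)
    labs = coll.labels(cohort)
    rhaa = coll.rhaa_values
    ss = np.random.SeedSequence(seed)
    s_sign, s_loocv = ss.spawn(2)
    sign = permutation_pvalue(
        sign_classify(rhaa, "mt"), labs,
        n_perm=n_perm_sign, seed=int(s_sign.generate_state(1)[0]),
    )
    loocv = loocv_logistic(
        rhaa[:, None], labs, n_perm=n_perm_loocv, seed=int(s_loocv.generate_state(1)[0])
    )
    coding = np.array([HANDEDNESS_CODING[l] for l in labs])
    rho, p = spearman(rhaa, coding)
    return PooledMouthResult(haa=coll, sign=sign, loocv=loocv, spearman_rho=rho, spearman_p=p)
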