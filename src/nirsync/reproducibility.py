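"""Single-participant reproducibility: consistency and decoding sensitivity.

Consistency asks whether one participant's ISC pattern resembles the group's.
The score is a normalized dot product ``(1/n) * sum_i a_i * g_i`` between the
participant's ISC vector ``a`` and the leave-one-out group-mean ISC vector
``g``, restricted to the channels of that participant's LOO
Intact > Scrambled mask.  It preserves both magnitude and sign, so a
participant who systematically anti-tracks the group scores negative.  The
null is built by phase-scrambling the entire cohort and recomputing the
score with the original mask held fixed.

Sensitivity asks whether ISC vectors can be decoded into Intact vs Scrambled.
An ensemble of classifier families votes, each vote weighted by the
classifier's tuned median 3-fold cross-validated balanced accuracy on the
training (LOO) data; predictions over all left-out participants are pooled
into one confusion matrix and evaluated against a within-participant
label-swap permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.semi_supervised import LabelPropagation, LabelSpreading
from sklearn.svm import SVC, NuSVC
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, ValidationError
from .isc_stats import FreqCohort, Mask, loo_isc_stack, stack_cohort
from .preprocess import HemoglobinSeries

__all__ = [
    "ConsistencyResult",
    "DecodingResult",
    "LOOISCData",
    "normalized_dot_product",
    "consistency_scores",
    "consistency_analysis",
    "consistency_validation",
    "CLASSIFIER_REGISTRY",
    "train_vote_ensemble",
    "VotingEnsemble",
    "build_loo_isc_data",
    "swap_condition_labels",
    "decode_cohort",
    "per_channel_decoding",
]

SCRAMBLED_LABEL = 0
INTACT_LABEL = 1


# --------------------------------------------------------------------------
# Consistency
# --------------------------------------------------------------------------


def normalized_dot_product(
    a: np.ndarray | Sequence[float],
    g: np.ndarray | Sequence[float],
    mask: Mask | Sequence[int] | None = None,
    channels: Sequence[str] | None = None,
) -> float:
    """``(1/n) * sum_i a_i g_i`` over mask channels; sign-preserving.

    ``a`` and ``g`` are ISC vectors over ``channels``.  ``mask`` may be a
    :class:`Mask` (resolved through ``channels``), an index sequence, or
    None for the full vector.
    """
    a = np.asarray(a, dtype=float)
    g = np.asarray(g, dtype=float)
    if a.shape != g.shape:
        raise ValidationError("a and g must have equal length")
    if isinstance(mask, Mask):
        if channels is None:
            raise ValidationError("resolving a Mask requires the channel list")
        idx = [list(channels).index(c) for c in mask.channels]
    elif mask is None:
        idx = list(range(a.size))
    else:
        idx = list(mask)
    if len(idx) == 0:
        raise ValidationError("mask must be nonempty")
    return float(np.dot(a[idx], g[idx]) / len(idx))


def _loo_group_means_engine(
    eng: FreqCohort, n_p: int, rot: np.ndarray | None = None
) -> np.ndarray:
    """g_p: channel-wise mean ISC of the cohort with participant p removed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(eng.loo_z_drop_one(rot), axis=1)


def _scores_from_stacks(
    a_rows: np.ndarray, g_rows: np.ndarray, masks: Sequence[Mask],
    channels: Sequence[str],
) -> np.ndarray:
    ch_index = {c: i for i, c in enumerate(channels)}
    scores = np.full(a_rows.shape[0], np.nan)
    for p, m in enumerate(masks):
        if len(m) == 0:
            continue
        idx = [ch_index[c] for c in m.channels]
        scores[p] = np.dot(a_rows[p, idx], g_rows[p, idx]) / len(idx)
    return scores


def consistency_scores(
    hb_test: Sequence[HemoglobinSeries],
    hb_group: Sequence[HemoglobinSeries],
    masks: Sequence[Mask],
) -> np.ndarray:
    """Per-participant normalized dot products.

    ``a_p`` is participant p's leave-one-out ISC row within ``hb_test``;
    ``g_p`` is the group-mean ISC of ``hb_group`` with p excluded.  Passing
    the Intact cohort twice gives the Intact consistency scores; passing the
    Scrambled cohort as ``hb_test`` gives the validation scores.  Empty masks
    yield NaN (indeterminate participant).
    """
    if len(hb_test) != len(hb_group) or len(hb_test) != len(masks):
        raise ValidationError("hb_test, hb_group and masks must align per participant")
    ho_t, hr_t = stack_cohort(hb_test)
    a = loo_isc_stack(ho_t, hr_t)
    eng_g = FreqCohort(*stack_cohort(hb_group))
    g = _loo_group_means_engine(eng_g, len(hb_group))
    return _scores_from_stacks(a, g, masks, hb_test[0].channel_ids)


@dataclass
class ConsistencyResult:
    participants: list[str]
    scores: np.ndarray
    p_uncorrected: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    mask_sizes: list[int]
    null_mean: np.ndarray
    null_sd: np.ndarray

    def n_significant(self) -> int:
        return int(np.nansum(self.significant))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participants,
                "score": self.scores,
                "p_uncorrected": self.p_uncorrected,
                "q": self.q,
                "significant": self.significant,
                "mask_size": self.mask_sizes,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
            }
        )


def consistency_analysis(
    cohort_hb: Sequence[HemoglobinSeries],
    masks: Sequence[Mask],
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_null: int | None = None,
    participants: Sequence[str] | None = None,
) -> ConsistencyResult:
    """Consistency of each participant's Intact ISCs against the LOO group.

    The null phase-scrambles the cohort per iteration and recomputes each
    participant's leave-one-out ISC vector, which is then scored against the
    *original* leave-one-out group-mean vector with the original mask held
    fixed.  This models chance-level similarity: what score would a
    participant whose series carry no stimulus alignment obtain against the
    group's actual ISC topography?  (Scrambling the group mean as well
    would shrink the null far below the score fluctuations of a genuinely
    non-tracking participant and flag noise as consistency.)  The one-sided
    p counts null scores at or above the actual score, so small p means the
    participant tracks the group more than chance allows.  Benjamini-
    Hochberg FDR is applied across participants at q < alpha.
    """
    cfg = config or AnalysisConfig()
    B = n_null if n_null is not None else cfg.n_surrogates
    rng = np.random.default_rng(rng)
    n_p = len(cohort_hb)
    if len(masks) != n_p:
        raise ValidationError("need one LOO mask per participant")
    if participants is None:
        participants = [m.left_out_participant for m in masks]

    hbo, hbr = stack_cohort(cohort_hb)
    channels = cohort_hb[0].channel_ids
    eng = FreqCohort(hbo, hbr)
    n_c = hbo.shape[1]
    a = eng.loo_z()
    g = _loo_group_means_engine(eng, n_p)
    scores = _scores_from_stacks(a, g, masks, channels)

    null = np.empty((B, n_p))
    for b in range(B):
        rot = eng.draw_rotation(rng, n_p, n_c)
        a_s = eng.loo_z(rot)
        null[b] = _scores_from_stacks(a_s, g, masks, channels)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_unc = np.where(
            np.isnan(scores), np.nan, (null >= scores[None, :]).mean(axis=0)
        )
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0)

    q = np.full(n_p, np.nan)
    sig = np.zeros(n_p, dtype=bool)
    valid = ~np.isnan(p_unc)
    if valid.any():
        rej, qvals, *_ = multipletests(p_unc[valid], alpha=cfg.alpha, method="fdr_bh")
        q[valid] = qvals
        sig[valid] = rej
    return ConsistencyResult(
        participants=list(participants),
        scores=scores,
        p_uncorrected=p_unc,
        q=q,
        significant=sig,
        mask_sizes=[len(m) for m in masks],
        null_mean=null_mean,
        null_sd=null_sd,
    )


def consistency_validation(
    scores_intact: np.ndarray, scores_scrambled: np.ndarray
) -> tuple[float, float]:
    """Paired t-test of Intact vs Scrambled consistency scores.

    Returns (t, p) with dof = n - 1.  Participants with an indeterminate
    score in either condition are dropped pairwise.
    """
    a = np.asarray(scores_intact, dtype=float)
    b = np.asarray(scores_scrambled, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("score vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValidationError("need at least 3 paired scores")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = sstats.ttest_rel(a, b)
    return float(t), float(p)


# --------------------------------------------------------------------------
# Classifier registry
# --------------------------------------------------------------------------

# 17 families spanning trees, boosting, linear, kernel, Bayesian,
# Gaussian-process, semi-supervised, discriminant and nearest-neighbor
# methods.  Hyperparameter grids are deliberately small: training sets hold
# ~2*(n-1) samples, so a handful of capacity knobs per family is all the
# data supports.


def _registry() -> dict[str, tuple[object, dict]]:
    return {
        "extra_trees": (
            ExtraTreesClassifier(n_estimators=20),
            {"n_estimators": [10, 20, 40], "max_depth": [None, 2, 4],
             "max_features": ["sqrt", None]},
        ),
        "bagging": (
            BaggingClassifier(n_estimators=8),
            {"n_estimators": [4, 8, 15], "max_samples": [0.5, 0.8, 1.0]},
        ),
        "adaboost": (
            AdaBoostClassifier(n_estimators=15),
            {"n_estimators": [5, 15, 30], "learning_rate": [0.1, 0.5, 1.0]},
        ),
        "gradient_boosting": (
            GradientBoostingClassifier(n_estimators=20, max_depth=2),
            {"n_estimators": [10, 20, 40], "learning_rate": [0.05, 0.1, 0.3],
             "max_depth": [1, 2, 3]},
        ),
        "logistic": (
            LogisticRegression(max_iter=1000),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        "ridge": (RidgeClassifier(), {"alpha": [0.1, 1.0, 10.0, 100.0]}),
        "svm": (
            SVC(),
            {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"],
             "gamma": ["scale", "auto"]},
        ),
        "nu_svm": (
            NuSVC(nu=0.3),
            {"nu": [0.2, 0.3, 0.5], "kernel": ["linear", "rbf"]},
        ),
        "bernoulli_nb": (
            BernoulliNB(binarize=0.0),
            {"alpha": [0.1, 0.5, 1.0]},
        ),
        "gaussian_nb": (
            GaussianNB(),
            {"var_smoothing": [1e-9, 1e-6, 1e-3]},
        ),
        "gaussian_process": (
            GaussianProcessClassifier(n_restarts_optimizer=0),
            {"max_iter_predict": [50, 100]},
        ),
        "label_propagation": (
            LabelPropagation(gamma=1.0, max_iter=500),
            {"gamma": [0.1, 1.0, 10.0], "n_neighbors": [3, 5]},
        ),
        "label_spreading": (
            LabelSpreading(gamma=1.0, max_iter=500),
            {"gamma": [0.1, 1.0, 10.0], "alpha": [0.1, 0.2, 0.5]},
        ),
        "lda": (
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
            {"shrinkage": ["auto", 0.1, 0.5]},
        ),
        "qda": (
            QuadraticDiscriminantAnalysis(reg_param=0.1),
            {"reg_param": [0.01, 0.1, 0.5]},
        ),
        "knn": (
            KNeighborsClassifier(n_neighbors=3),
            {"n_neighbors": [1, 3, 5], "weights": ["uniform", "distance"]},
        ),
        "nearest_centroid": (
            NearestCentroid(),
            {"shrink_threshold": [None, 0.1, 0.5]},
        ),
    }


CLASSIFIER_REGISTRY = _registry()


@dataclass
class VotingEnsemble:
    """Fitted classifiers with training-accuracy voting weights.

    Prediction is the class with the larger sum of weights among classifiers
    voting for it; exact ties resolve to Scrambled (the conservative outcome
    for claims of narrative processing).
    """

    names: list[str]
    estimators: list
    weights: np.ndarray  # tuned median CV balanced accuracy per classifier

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        votes = np.stack([est.predict(X) for est in self.estimators])  # (K, n)
        w = self.weights[:, None]
        score_intact = np.sum(w * (votes == INTACT_LABEL), axis=0)
        score_scrambled = np.sum(w * (votes == SCRAMBLED_LABEL), axis=0)
        return np.where(score_intact > score_scrambled, INTACT_LABEL, SCRAMBLED_LABEL)


def _median_cv_balanced_accuracy(
    est, X: np.ndarray, y: np.ndarray, seed: int
) -> float:
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    scores = []
    for tr, te in cv.split(X, y):
        if len(np.unique(y[tr])) < 2:
            scores.append(0.5)
            continue
        m = clone(est)
        _maybe_seed(m, seed)
        m.fit(X[tr], y[tr])
        scores.append(balanced_accuracy_score(y[te], m.predict(X[te])))
    return float(np.median(scores))


def _maybe_seed(est, seed: int) -> None:
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)


def train_vote_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    budget: int | None = None,
) -> VotingEnsemble:
    """Tune, fit and weight every registered classifier on the training set.

    Each classifier's hyperparameters are chosen by a budgeted random search
    maximizing the median balanced accuracy over stratified 3-fold CV; the
    winning score becomes its voting weight.  ``budget`` counts evaluated
    configurations (the defaults always count as one); budget <= 1 skips the
    search but still computes the CV weight.
    """
    cfg = config or AnalysisConfig()
    B = budget if budget is not None else cfg.tuning_budget
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    registry = CLASSIFIER_REGISTRY
    if cfg.classifiers:
        registry = {k: registry[k] for k in cfg.classifiers}

    names, fitted, weights = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, (proto, space) in registry.items():
            seed = int(rng.integers(2**31 - 1))
            candidates = [dict()]
            if B > 1 and space:
                n_extra = min(B - 1, int(np.prod([len(v) for v in space.values()])))
                candidates += list(
                    ParameterSampler(space, n_iter=n_extra, random_state=seed)
                )
            best_score, best_params = -np.inf, {}
            for params in candidates:
                est = clone(proto).set_params(**params)
                try:
                    score = _median_cv_balanced_accuracy(est, X, y, seed)
                except Exception:
                    continue
                if score > best_score:
                    best_score, best_params = score, params
            final = clone(proto).set_params(**best_params)
            _maybe_seed(final, seed)
            try:
                final.fit(X, y)
            except Exception:
                continue
            names.append(name)
            fitted.append(final)
            weights.append(max(best_score, 0.0))
    if not fitted:
        raise ValidationError("no classifier could be trained")
    return VotingEnsemble(names=names, estimators=fitted, weights=np.asarray(weights))


# --------------------------------------------------------------------------
# Cohort decoding
# --------------------------------------------------------------------------


@dataclass
class LOOISCData:
    """ISC feature matrices for leave-one-out decoding.

    ``test_*`` rows come from the full-cohort leave-one-out ISC (the
    "original" ISCs of each participant).  ``train_*[p]`` are ISC matrices
    recomputed entirely within the cohort excluding participant p, so no
    training feature ever saw p's data.
    """

    participants: list[str]
    channels: list[str]
    test_intact: np.ndarray  # (P, C)
    test_scrambled: np.ndarray  # (P, C)
    train_intact: list[np.ndarray]  # per left-out p: (P-1, C)
    train_scrambled: list[np.ndarray]


def build_loo_isc_data(
    hb_intact: Sequence[HemoglobinSeries],
    hb_scrambled: Sequence[HemoglobinSeries],
    participants: Sequence[str] | None = None,
) -> LOOISCData:
    n_p = len(hb_intact)
    if len(hb_scrambled) != n_p:
        raise ValidationError("conditions must cover the same participants")
    if participants is None:
        participants = [f"P{i + 1:02d}" for i in range(n_p)]
    ho_i, hr_i = stack_cohort(hb_intact)
    ho_s, hr_s = stack_cohort(hb_scrambled)
    test_i = loo_isc_stack(ho_i, hr_i)
    test_s = loo_isc_stack(ho_s, hr_s)
    train_i, train_s = [], []
    for p in range(n_p):
        keep = [q for q in range(n_p) if q != p]
        train_i.append(loo_isc_stack(ho_i[keep], hr_i[keep]))
        train_s.append(loo_isc_stack(ho_s[keep], hr_s[keep]))
    return LOOISCData(
        participants=list(participants),
        channels=list(hb_intact[0].channel_ids),
        test_intact=test_i,
        test_scrambled=test_s,
        train_intact=train_i,
        train_scrambled=train_s,
    )


def swap_condition_labels(data: LOOISCData, swap: np.ndarray) -> LOOISCData:
    """Relabel conditions for the flagged participants (ISC-vector level).

    A swapped participant's Intact ISC vector is presented as Scrambled and
    vice versa, in both the test rows and every LOO training matrix —
    the construction behind shuffled-label sanity checks.
    """
    swap = np.asarray(swap, dtype=bool)
    n_p = len(data.participants)
    if swap.shape != (n_p,):
        raise ValidationError("swap must flag each participant")
    ti = np.where(swap[:, None], data.test_scrambled, data.test_intact)
    ts = np.where(swap[:, None], data.test_intact, data.test_scrambled)
    tr_i, tr_s = [], []
    for p in range(n_p):
        keep = [q for q in range(n_p) if q != p]
        sw = swap[keep][:, None]
        tr_i.append(np.where(sw, data.train_scrambled[p], data.train_intact[p]))
        tr_s.append(np.where(sw, data.train_intact[p], data.train_scrambled[p]))
    return LOOISCData(
        participants=list(data.participants), channels=list(data.channels),
        test_intact=ti, test_scrambled=ts,
        train_intact=tr_i, train_scrambled=tr_s,
    )


@dataclass
class DecodingResult:
    """Pooled decoding performance with permutation p-values.

    ``confusion`` rows are actual condition, columns predicted condition,
    ordered (Scrambled, Intact).
    """

    confusion: np.ndarray
    balanced_accuracy: float
    recall: float
    precision: float
    p_balanced_accuracy: float | None = None
    p_recall: float | None = None
    p_precision: float | None = None
    null_balanced_accuracy: np.ndarray | None = None
    classifier_weights: dict[str, float] = field(default_factory=dict)
    per_channel: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "p_balanced_accuracy": self.p_balanced_accuracy,
            "p_recall": self.p_recall,
            "p_precision": self.p_precision,
            "classifier_weights": self.classifier_weights,
            "per_channel": self.per_channel,
        }


def _metrics_from_confusion(conf: np.ndarray) -> tuple[float, float, float]:
    (tn, fp), (fn, tp) = conf
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return (tpr + tnr) / 2.0, tpr, precision


def _feature_indices(
    mask_intact: Mask, mask_scrambled: Mask, channels: Sequence[str]
) -> list[int]:
    union = list(dict.fromkeys(list(mask_intact.channels) + list(mask_scrambled.channels)))
    if not union:
        warnings.warn(
            f"empty feature union for left-out {mask_intact.left_out_participant}; "
            "falling back to all channels"
        )
        return list(range(len(channels)))
    ch_index = {c: i for i, c in enumerate(channels)}
    return [ch_index[c] for c in union]


def _run_loo_decode(
    data: LOOISCData,
    feat_idx: list[list[int]],
    swap: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
    budget: int,
) -> tuple[np.ndarray, dict[str, list[float]]]:
    """One full LOO decoding pass; ``swap`` permutes labels per participant."""
    n_p = len(data.participants)
    conf = np.zeros((2, 2), dtype=int)
    weight_log: dict[str, list[float]] = {}
    for p in range(n_p):
        keep = [q for q in range(n_p) if q != p]
        idx = feat_idx[p]
        Xi = data.train_intact[p][:, idx]
        Xs = data.train_scrambled[p][:, idx]
        # label swap: a swapped participant's intact vector is labelled
        # Scrambled and vice versa (within-participant permutation)
        y_i = np.where(swap[keep], SCRAMBLED_LABEL, INTACT_LABEL)
        y_s = np.where(swap[keep], INTACT_LABEL, SCRAMBLED_LABEL)
        X = np.vstack([Xi, Xs])
        y = np.concatenate([y_i, y_s])
        ens = train_vote_ensemble(X, y, config, rng, budget=budget)
        for name, w in zip(ens.names, ens.weights):
            weight_log.setdefault(name, []).append(float(w))
        x_test = np.vstack([data.test_intact[p, idx], data.test_scrambled[p, idx]])
        pred = ens.predict(x_test)
        truth = (
            [SCRAMBLED_LABEL, INTACT_LABEL] if swap[p] else [INTACT_LABEL, SCRAMBLED_LABEL]
        )
        for yt, yp in zip(truth, pred):
            conf[yt, yp] += 1
    return conf, weight_log


def decode_cohort(
    data: LOOISCData,
    masks_intact: Sequence[Mask],
    masks_scrambled: Sequence[Mask],
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_permutations: int | None = None,
) -> DecodingResult:
    """Ensemble LOO decoding of Intact vs Scrambled ISC vectors.

    Per left-out participant, the ensemble is trained on the 2*(n-1) ISC
    vectors of the remaining participants (features: union of channels
    significant in either single-condition LOO mask) and predicts the two
    held-out vectors.  Predictions pool into one confusion matrix; balanced
    accuracy, recall and precision (Intact positive) are tested against a
    within-participant label-swap permutation null, with p computed as
    ``(1 + #null >= observed) / (B + 1)``.
    """
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    n_p = len(data.participants)
    if n_p < 4:
        raise ValidationError("decoding needs at least 4 participants")
    if len(masks_intact) != n_p or len(masks_scrambled) != n_p:
        raise ValidationError("need one Intact and one Scrambled mask per participant")
    B = n_permutations if n_permutations is not None else cfg.n_permutations
    perm_budget = (
        cfg.permutation_tuning_budget
        if cfg.permutation_tuning_budget is not None
        else cfg.tuning_budget
    )
    feat_idx = [
        _feature_indices(masks_intact[p], masks_scrambled[p], data.channels)
        for p in range(n_p)
    ]

    no_swap = np.zeros(n_p, dtype=bool)
    conf, weight_log = _run_loo_decode(data, feat_idx, no_swap, cfg, rng, cfg.tuning_budget)
    ba, recall, precision = _metrics_from_confusion(conf)

    null = np.empty((B, 3))
    for b in range(B):
        swap = rng.random(n_p) < 0.5
        c, _ = _run_loo_decode(data, feat_idx, swap, cfg, rng, perm_budget)
        null[b] = _metrics_from_confusion(c)

    def _p(observed: float, col: int) -> float:
        return float((1 + np.sum(null[:, col] >= observed - 1e-12)) / (B + 1))

    return DecodingResult(
        confusion=conf,
        balanced_accuracy=ba,
        recall=recall,
        precision=precision,
        p_balanced_accuracy=_p(ba, 0),
        p_recall=_p(recall, 1),
        p_precision=_p(precision, 2),
        null_balanced_accuracy=null[:, 0].copy(),
        classifier_weights={k: float(np.mean(v)) for k, v in weight_log.items()},
    )


def per_channel_decoding(
    data: LOOISCData,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | int | None = None,
    budget: int = 1,
) -> dict[str, float]:
    """Mean LOO balanced accuracy with each channel as the sole feature.

    Each LOO dataset contributes the balanced accuracy of its two held-out
    predictions; per channel, the average over LOO datasets is reported.
    """
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    n_p = len(data.participants)
    if n_p < 4:
        raise ValidationError("decoding needs at least 4 participants")
    no_swap = np.zeros(n_p, dtype=bool)
    out: dict[str, float] = {}
    for j, ch in enumerate(data.channels):
        accs = []
        for p in range(n_p):
            keep = [q for q in range(n_p) if q != p]
            X = np.vstack(
                [data.train_intact[p][:, [j]], data.train_scrambled[p][:, [j]]]
            )
            y = np.concatenate(
                [np.full(len(keep), INTACT_LABEL), np.full(len(keep), SCRAMBLED_LABEL)]
            )
            ens = train_vote_ensemble(X, y, cfg, rng, budget=budget)
            x_test = np.vstack(
                [data.test_intact[p, [j]], data.test_scrambled[p, [j]]]
            )
            pred = ens.predict(x_test)
            acc = (
                int(pred[0] == INTACT_LABEL) + int(pred[1] == SCRAMBLED_LABEL)
            ) / 2.0
            accs.append(acc)
        out[ch] = float(np.mean(accs))
    return out
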