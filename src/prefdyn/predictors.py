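"""Preference predictors and evaluation statistics.

Two predictors operate on video pairs:

* A training-free baseline: compute one dispersion statistic per video
  and predict the preferred image from the comparison.  For cartoons and
  paintings, higher mobility marks the preferred stimulus; for people
  and animals the empirical link is reversed — faces move more when
  viewing the *less* appealing animate stimulus — so the baseline
  predicts the lower-mobility video as preferred in those domains.
* A learned pipeline: per-landmark descriptor differences (132-d pair
  features) fed to feature standardization, PCA fitted on training data
  only, and an RBF-kernel soft-margin SVM whose kernel width gamma and
  margin C are tuned on an internal split of the training data.
  Evaluation uses repeated class-balanced k-fold cross-validation.

Evaluation helpers include the exact one-sided binomial test of an
accuracy against a fair coin and the correlation between per-pair human
accuracy and the algorithmic difference score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import STATISTICS, pair_feature, video_statistic
from .preprocess import preprocess_video
from .types import DOMAINS, LandmarkDataError, VideoPair

#: Domains where greater mobility marks the *less* preferred stimulus.
REVERSED_DOMAINS = frozenset({"people", "animals"})

#: |s1 - s2| at or below this is reported as a tie (slot 1 predicted).
TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# Baseline predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairPrediction:
    pair_key: tuple[str, int, int]
    s1: float
    s2: float
    predicted: int
    tie: bool
    correct: bool


def difference_score(
    pair: VideoPair, statistic: str, *, preprocess: bool = True
) -> float:
    """statistic(video1) minus statistic(video2).

    With ``preprocess=True`` (default) both videos are eye-normalized and
    restricted to their middle third first, identically.
    """
    v1, v2 = pair.video1, pair.video2
    if preprocess:
        v1 = preprocess_video(v1)
        v2 = preprocess_video(v2)
    return video_statistic(v1, statistic) - video_statistic(v2, statistic)


def predict_pair_baseline(
    pair: VideoPair, statistic: str, *, preprocess: bool = True
) -> PairPrediction:
    """Predict the preferred slot of a pair from one dispersion statistic.

    Cartoons/paintings: the slot with the higher statistic is predicted
    preferred.  People/animals: the *lower* slot is predicted (reversal).
    Exact ties predict slot 1 deterministically and are flagged.
    """
    if pair.domain not in DOMAINS:
        raise LandmarkDataError(f"unknown domain {pair.domain!r}")
    v1, v2 = pair.video1, pair.video2
    if preprocess:
        v1 = preprocess_video(v1)
        v2 = preprocess_video(v2)
    s1 = video_statistic(v1, statistic)
    s2 = video_statistic(v2, statistic)
    tie = abs(s1 - s2) <= TIE_TOL
    if tie:
        predicted = 1
    else:
        higher = 1 if s1 > s2 else 2
        if pair.domain in REVERSED_DOMAINS:
            predicted = 3 - higher
        else:
            predicted = higher
    return PairPrediction(
        pair_key=pair.key,
        s1=s1,
        s2=s2,
        predicted=predicted,
        tie=tie,
        correct=(predicted == pair.preferred),
    )


@dataclass
class EvaluationReport:
    """Per-domain and pooled baseline accuracy with binomial p-values."""

    statistic: str
    domain_accuracy: dict[str, float]
    domain_n: dict[str, int]
    domain_p: dict[str, float]
    pooled_accuracy: float
    pooled_n: int
    pooled_p: float
    predictions: list[PairPrediction] = field(default_factory=list)


def binomial_p(successes: int, trials: int) -> float:
    """Exact one-sided tail P(X >= successes) for X ~ Binomial(trials, 1/2).

    The probability that a fair-coin guesser matches or beats the
    observed number of correct pairs.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    return float(stats.binomtest(successes, trials, 0.5, alternative="greater").pvalue)


def evaluate_baseline(
    pairs: Iterable[VideoPair], statistic: str, *, preprocess: bool = True
) -> EvaluationReport:
    """Evaluate the baseline predictor over the non-excluded pairs.

    Reports accuracy per domain and pooled, each with the exact
    one-sided binomial p-value against chance.  Excluded pairs are
    skipped; empty domains are omitted with a warning.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    preds_by_domain: dict[str, list[PairPrediction]] = {}
    for pair in pairs:
        if pair.excluded:
            continue
        preds_by_domain.setdefault(pair.domain, []).append(
            predict_pair_baseline(pair, statistic, preprocess=preprocess)
        )
    for d in DOMAINS:
        if d not in preds_by_domain:
            warnings.warn(f"domain {d!r} has no active pairs; omitted", stacklevel=2)

    domain_accuracy, domain_n, domain_p = {}, {}, {}
    all_preds: list[PairPrediction] = []
    for d, preds in preds_by_domain.items():
        k = sum(p.correct for p in preds)
        n = len(preds)
        domain_accuracy[d] = k / n
        domain_n[d] = n
        domain_p[d] = binomial_p(k, n)
        all_preds.extend(preds)
    if not all_preds:
        raise LandmarkDataError("no active pairs to evaluate")
    k_all = sum(p.correct for p in all_preds)
    n_all = len(all_preds)
    return EvaluationReport(
        statistic=statistic,
        domain_accuracy=domain_accuracy,
        domain_n=domain_n,
        domain_p=domain_p,
        pooled_accuracy=k_all / n_all,
        pooled_n=n_all,
        pooled_p=binomial_p(k_all, n_all),
        predictions=all_preds,
    )


def human_algorithm_correlation(
    human_accuracy: Sequence[float],
    scores: Sequence[float],
    *,
    method: str = "pearson",
) -> float:
    """Correlation between per-pair human accuracy and difference scores.

    ``human_accuracy`` is the fraction of human judges who labelled each
    pair correctly; ``scores`` the algorithmic difference score for the
    same pairs.  Pearson by default; ``method='spearman'`` for the rank
    variant.
    """
    h = np.asarray(human_accuracy, dtype=float)
    s = np.asarray(scores, dtype=float)
    if h.shape != s.shape or h.ndim != 1:
        raise ValueError("inputs must be 1-d sequences of equal length")
    if h.size < 3:
        raise ValueError(f"need >=3 pairs, got {h.size}")
    if np.ptp(h) == 0 or np.ptp(s) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        return float(stats.pearsonr(h, s).statistic)
    if method == "spearman":
        return float(stats.spearmanr(h, s).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Learned pipeline
# ---------------------------------------------------------------------------

@dataclass
class SvmConfig:
    """Configuration of the PCA + RBF-SVM pipeline and its evaluation.

    ``gamma_grid`` and ``c_grid`` are searched on an internal split of
    each training set (``internal_validation_fraction`` held out for
    validation).  ``pca_variance`` is the fraction of training-set
    variance the principal components must retain.
    """

    gamma_grid: tuple[float, ...] = tuple(np.logspace(-4, 2, 7))
    c_grid: tuple[float, ...] = tuple(np.logspace(-2, 4, 7))
    pca_variance: float = 0.95
    folds: int = 10
    repetitions: int = 10
    internal_validation_fraction: float = 0.2
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gamma_grid or not self.c_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must be in (0, 1]")
        if not 0 < self.internal_validation_fraction < 1:
            raise ValueError("internal_validation_fraction must be in (0, 1)")
        if self.folds < 2 or self.repetitions < 1:
            raise ValueError("need folds >= 2 and repetitions >= 1")


def pair_label(pair: VideoPair) -> int:
    """+1 when slot 1 holds the preferred image, -1 otherwise."""
    return 1 if pair.preferred == 1 else -1


def pair_features(
    pairs: Sequence[VideoPair], *, preprocess: bool = True
) -> np.ndarray:
    """Stack the 132-d difference features of the pairs, row per pair."""
    rows = []
    for p in pairs:
        v1, v2 = p.video1, p.video2
        if preprocess:
            v1 = preprocess_video(v1)
            v2 = preprocess_video(v2)
        rows.append(pair_feature(v1, v2))
    return np.asarray(rows)


def _make_pipeline(gamma: float, c: float, pca_variance: float) -> Pipeline:
    return Pipeline(
        [
            ("scaler", StandardScaler()),
            ("pca", PCA(n_components=pca_variance, svd_solver="full")),
            ("svm", SVC(kernel="rbf", gamma=gamma, C=c)),
        ]
    )


@dataclass
class SvmPairModel:
    """A fitted pair classifier plus an audit trail of what it touched.

    ``audit`` records the keys of every pair whose features entered any
    fitting step (standardization, PCA, hyperparameter tuning, final
    fit) so leakage checks can verify disjointness from held-out data.
    """

    pipeline: Pipeline
    gamma: float
    c: float
    config: SvmConfig
    audit: dict

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(X)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(X)

    def predict_slots(self, pairs: Sequence[VideoPair]) -> list[int]:
        X = pair_features(pairs)
        return [1 if y > 0 else 2 for y in self.predict_labels(X)]


def train_svm(
    pairs: Sequence[VideoPair],
    config: SvmConfig,
    *,
    X: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SvmPairModel:
    """Fit the PCA + RBF-SVM pipeline on training pairs.

    Hyperparameters (gamma, C) are chosen by fitting on an internal
    training subset and scoring on an internal validation subset — both
    carved from the given pairs, never from data outside them — then the
    pipeline is refit on all given pairs with the winning values.
    Precomputed features may be passed as ``X`` (rows aligned to
    ``pairs``).
    """
    y = np.array([pair_label(p) for p in pairs])
    if len(np.unique(y)) < 2:
        raise LandmarkDataError("training set must contain both classes")
    if min(np.bincount((y + 1) // 2)) < 2:
        raise LandmarkDataError("need >=2 training pairs per class")
    if X is None:
        X = pair_features(pairs)
    rng = rng or np.random.default_rng(config.seed)
    split_seed = int(rng.integers(0, 2**31 - 1))
    idx = np.arange(len(y))
    tr_idx, val_idx = train_test_split(
        idx,
        test_size=config.internal_validation_fraction,
        stratify=y,
        random_state=split_seed,
    )

    best: tuple[float, float, float] | None = None  # (score, gamma, c)
    grid_scores = []
    for gamma in config.gamma_grid:
        for c in config.c_grid:
            pipe = _make_pipeline(gamma, c, config.pca_variance)
            pipe.fit(X[tr_idx], y[tr_idx])
            score = float(pipe.score(X[val_idx], y[val_idx]))
            grid_scores.append({"gamma": gamma, "C": c, "val_accuracy": score})
            if best is None or score > best[0]:
                best = (score, gamma, c)
    assert best is not None
    _, gamma, c = best

    pipeline = _make_pipeline(gamma, c, config.pca_variance)
    pipeline.fit(X, y)
    keys = [p.key for p in pairs]
    audit = {
        "fitted_pair_keys": keys,
        "internal_train_keys": [keys[i] for i in tr_idx],
        "internal_validation_keys": [keys[i] for i in val_idx],
        "grid_scores": grid_scores,
        "chosen": {"gamma": gamma, "C": c},
    }
    return SvmPairModel(pipeline=pipeline, gamma=gamma, c=c, config=config, audit=audit)


@dataclass
class CVReport:
    """Repeated cross-validation results for one domain."""

    domain: str
    mean_accuracy: float
    ci_half_width: float
    repetition_accuracies: list[float]
    n_pairs: int
    folds: list[dict] = field(default_factory=list)

    @property
    def ci(self) -> tuple[float, float]:
        return (
            self.mean_accuracy - self.ci_half_width,
            self.mean_accuracy + self.ci_half_width,
        )


def cross_validate(
    pairs: Sequence[VideoPair],
    config: SvmConfig,
    *,
    domain: str | None = None,
) -> CVReport:
    """Repeated class-balanced k-fold cross-validation of the SVM pipeline.

    Each repetition shuffles the pairs with seeded randomness, builds
    stratified folds, trains on k-1 folds (all fitting and tuning
    confined to them) and scores the held-out fold.  The report carries
    the mean accuracy over repetitions, a normal-approximation
    confidence interval half-width at ``config.ci_level``, and a fold
    audit (train/test pair keys and chosen hyperparameters per fold).
    """
    pairs = [p for p in pairs if not p.excluded]
    if domain is None:
        domains = {p.domain for p in pairs}
        if len(domains) != 1:
            raise LandmarkDataError(
                "cross_validate expects pairs from a single domain; "
                f"got {sorted(domains)} (pass domain= to select)"
            )
        domain = domains.pop()
    else:
        pairs = [p for p in pairs if p.domain == domain]
    y = np.array([pair_label(p) for p in pairs])
    if len(pairs) < config.folds:
        raise LandmarkDataError(
            f"{len(pairs)} pairs cannot fill {config.folds} folds"
        )
    if min(np.bincount((y + 1) // 2, minlength=2)) < config.folds:
        raise LandmarkDataError(
            f"fold count {config.folds} exceeds the size of a class "
            f"(class counts {np.bincount((y + 1) // 2, minlength=2).tolist()})"
        )

    X = pair_features(pairs)
    keys = [p.key for p in pairs]
    rng = np.random.default_rng(config.seed)
    rep_accs = []
    fold_audits = []
    for rep in range(config.repetitions):
        skf = StratifiedKFold(
            n_splits=config.folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        correct = 0
        for fold_no, (tr, te) in enumerate(skf.split(X, y)):
            model = train_svm(
                [pairs[i] for i in tr], config, X=X[tr], rng=rng
            )
            pred = model.predict_labels(X[te])
            correct += int(np.sum(pred == y[te]))
            fold_audits.append(
                {
                    "repetition": rep,
                    "fold": fold_no,
                    "train_keys": [keys[i] for i in tr],
                    "test_keys": [keys[i] for i in te],
                    "fitted_keys": model.audit["fitted_pair_keys"],
                    "chosen": model.audit["chosen"],
                }
            )
        rep_accs.append(correct / len(y))

    mean_acc = float(np.mean(rep_accs))
    if config.repetitions > 1:
        sem = float(np.std(rep_accs, ddof=1) / np.sqrt(config.repetitions))
    else:
        sem = 0.0
    z = float(stats.norm.ppf(0.5 + config.ci_level / 2))
    return CVReport(
        domain=domain,
        mean_accuracy=mean_acc,
        ci_half_width=z * sem,
        repetition_accuracies=rep_accs,
        n_pairs=len(pairs),
        folds=fold_audits,
    )


def cross_validate_domains(
    pairs: Sequence[VideoPair], config: SvmConfig
) -> dict[str, CVReport]:
    """Run :func:`cross_validate` independently per domain present."""
    out = {}
    for d in DOMAINS:
        sub = [p for p in pairs if p.domain == d and not p.excluded]
        if sub:
            out[d] = cross_validate(sub, config, domain=d)
    return out
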