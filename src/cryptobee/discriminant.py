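"""Two-class Gaussian linear discriminant analysis on the malar ratios.

Implements the classical Fisher/Gaussian LDA with a pooled within-class
covariance: class k scores ``x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k``
and the larger score wins.  Evaluation follows the study protocol:
class-stratified 60/40 train/test split, accuracy against the
DNA-confirmed labels, and a 999-replicate stratified bootstrap reporting
the median and SD of test accuracy.  *B. perplexus* is excluded from
discriminant fitting (it is separable by hair colour); the classifier is
fit on *B. sandersoni* vs *B. vagans*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .morphometrics import RATIO_NAMES, SpecimenRecord, compute_ratios

logger = logging.getLogger(__name__)

LDA_CLASSES = ("sandersoni", "vagans")


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-class covariance is singular (collinear or constant data)."""


def ratio_matrix(records: Sequence[SpecimenRecord],
                 measurements: Sequence[str]) -> np.ndarray:
    """(n, d) matrix of the requested ratios, in record order."""
    bad = [m for m in measurements if m not in RATIO_NAMES]
    if bad:
        raise ValueError(f"unknown measurements {bad}; choose from {RATIO_NAMES}")
    import warnings
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in records:
            ratios = compute_ratios(r).as_dict()
            rows.append([ratios[m] for m in measurements])
    return np.asarray(rows, dtype=float)


@dataclass(frozen=True)
class LDAModel:
    measurements: tuple[str, ...]
    classes: tuple[str, ...]
    means: np.ndarray          # (k, d) class means
    pooled_cov: np.ndarray     # (d, d)
    priors: np.ndarray         # (k,)

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Linear discriminant scores, one column per class."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        try:
            siginv_mu = np.linalg.solve(self.pooled_cov, self.means.T)  # (d, k)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(str(exc)) from None
        const = -0.5 * np.einsum("dk,kd->k", siginv_mu, self.means) + np.log(self.priors)
        return x @ siginv_mu + const


def stratified_split(
    records: Sequence[SpecimenRecord],
    train_frac: float = 0.60,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SpecimenRecord], list[SpecimenRecord]]:
    """Per-class random train/test partition.

    Each DNA-label class contributes ``ceil(train_frac * n)`` records to
    the training set (rounding toward training so small classes always
    keep at least one test member where possible).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.species_dna, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 records")
        perm = rng.permutation(len(idx))
        n_train = math.ceil(train_frac * len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return [records[i] for i in sorted(train_idx)], [records[i] for i in sorted(test_idx)]


def fit_lda(records: Sequence[SpecimenRecord],
            measurements: Sequence[str] = ("mrl",)) -> LDAModel:
    """Fit two-class LDA with pooled within-class covariance.

    Class means are per-class sample means; the pooled covariance is the
    df-weighted within-class covariance; priors are training class
    frequencies (the study cells are unbalanced).
    """
    labels = np.array([r.species_dna for r in records])
    classes = tuple(sorted(set(labels)))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    X = ratio_matrix(records, measurements)
    d = X.shape[1]
    means = np.empty((2, d))
    pooled = np.zeros((d, d))
    n_tot = 0
    for k, c in enumerate(classes):
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} needs >= 2 training records")
        means[k] = Xc.mean(axis=0)
        dev = Xc - means[k]
        pooled += dev.T @ dev
        n_tot += len(Xc)
    pooled /= n_tot - 2
    # reject numerically singular pooled covariance up front
    if np.linalg.matrix_rank(pooled, tol=1e-12 * max(1.0, np.trace(pooled))) < d:
        raise SingularCovarianceError("pooled covariance is singular")
    priors = np.array([(labels == c).mean() for c in classes])
    return LDAModel(tuple(measurements), classes, means, pooled, priors)


def predict_lda(model: LDAModel, records: Sequence[SpecimenRecord]
                ) -> tuple[list[str], float]:
    """Predicted labels plus accuracy against the DNA-confirmed labels."""
    X = ratio_matrix(records, model.measurements)
    winners = np.argmax(model.scores(X), axis=1)
    labels = [model.classes[w] for w in winners]
    truth = [r.species_dna for r in records]
    if any(t == "unknown" for t in truth):
        raise ValueError("predict_lda: records must carry DNA species labels")
    accuracy = float(np.mean([p == t for p, t in zip(labels, truth)]))
    return labels, accuracy


@dataclass(frozen=True)
class AccuracyEstimate:
    """Bootstrap distribution summary of test-set classification accuracy."""

    median: float
    sd: float
    replicates: int
    per_replicate: np.ndarray

    def __post_init__(self) -> None:
        assert 0.0 <= self.median <= 1.0
        assert self.replicates == len(self.per_replicate)


def bootstrap_accuracy(
    records: Sequence[SpecimenRecord],
    measurements: Sequence[str] = ("mrl",),
    B: int = 999,
    train_frac: float = 0.60,
    seed: int = 0,
) -> AccuracyEstimate:
    """Median +- SD of test accuracy over B stratified bootstrap replicates.

    Each replicate resamples the dataset with replacement within each
    class (preserving the class counts), makes a fresh stratified 60/40
    split, fits the LDA and scores the held-out 40%.  Degenerate
    replicates with a singular training covariance are redrawn (logged);
    they occur only on pathological inputs such as constant measurements.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_class.setdefault(r.species_dna, []).append(r)
    # canonical within-class order -> estimates invariant to input order
    for pool in by_class.values():
        pool.sort(key=lambda r: r.id)
    accs = np.empty(B)
    for b in range(B):
        for _attempt in range(100):
            sample: list[SpecimenRecord] = []
            for label in sorted(by_class):
                pool = by_class[label]
                take = rng.integers(len(pool), size=len(pool))
                sample.extend(pool[i] for i in take)
            try:
                train, test = stratified_split(sample, train_frac, seed=rng)
                model = fit_lda(train, measurements)
                _, accs[b] = predict_lda(model, test)
                break
            except (SingularCovarianceError, ValueError):
                logger.info("degenerate bootstrap replicate %d redrawn", b)
        else:
            raise SingularCovarianceError(
                "could not draw a non-degenerate bootstrap replicate in 100 tries"
            )
    return AccuracyEstimate(
        median=float(np.median(accs)),
        sd=float(np.std(accs, ddof=1)) if B > 1 else 0.0,
        replicates=B,
        per_replicate=accs,
    )


def combined_accuracy(records: Sequence[SpecimenRecord], B: int = 999,
                      seed: int = 0) -> AccuracyEstimate:
    """Bootstrap accuracy of the bivariate (MR1, MR3) discriminant."""
    return bootstrap_accuracy(records, measurements=("mr1", "mr3"), B=B, seed=seed)
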