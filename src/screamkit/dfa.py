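"""Permuted, jack-knifed discriminant function analysis (pDFA).

The workflow mirrors standard practice for vocal-individuality studies:
features are de-correlated (pairwise |r| > threshold), transformed toward
symmetry and standardized; Fisher linear discriminants are fitted on a
balanced training subset and applied to held-out calls (classification vs
cross-validation success); the observed success rates are calibrated against
the same procedure on datasets where the test-factor labels are permuted
within levels of a control factor, yielding empirical expected rates and
p-values.

Estimators follow scikit-learn conventions (``fit``/``transform``/
``predict``, fitted attributes with a trailing underscore) and compose with
sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "CorrelationFilter",
    "SymmetrizingScaler",
    "FisherDiscriminant",
    "DFADesign",
    "DFAResult",
    "DesignInfeasibleError",
    "PermutedDFA",
    "balanced_subsets",
    "jackknife_classify",
    "run_pdfa",
]


class DesignInfeasibleError(ValueError):
    """No individual satisfies the balanced crossed-design requirements."""


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Greedy removal of highly correlated features.

    While any pair has |Pearson r| > ``threshold``, the member of the worst
    pair with the larger mean absolute correlation to the remaining features
    is dropped.  Removals are logged in ``dropped_`` as
    ``(dropped_index, kept_index, r)``.
    """

    def __init__(self, threshold: float = 0.80):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        cols = list(range(X.shape[1]))
        dropped: list[tuple[int, int, float]] = []
        while len(cols) >= 2:
            sub = X[:, cols]
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(sub, rowvar=False)
            np.fill_diagonal(r, 0.0)
            r = np.nan_to_num(np.abs(r))
            i, j = np.unravel_index(np.argmax(r), r.shape)
            if r[i, j] <= self.threshold:
                break
            # drop the member more entangled with everything else
            victim, kept = (i, j) if r[i].mean() >= r[j].mean() else (j, i)
            dropped.append((cols[victim], cols[kept], float(np.corrcoef(sub[:, victim], sub[:, kept])[0, 1])))
            cols.pop(victim)
        self.retained_ = np.array(cols, dtype=int)
        self.dropped_ = dropped
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        X = check_array(X)
        return X[:, self.retained_]


class SymmetrizingScaler(TransformerMixin, BaseEstimator):
    """Per-feature symmetry transform followed by standardization.

    For each column the transform among identity, sqrt and log that minimizes
    |sample skewness| is chosen (sqrt/log get an offset when non-positive
    values are present, recorded in ``offsets_``), then the column is scaled
    to mean 0 and sd 1.  Choices are logged in ``transforms_``.
    """

    _CANDIDATES = ("identity", "sqrt", "log")

    def __init__(self, transforms: tuple[str, ...] = _CANDIDATES):
        self.transforms = transforms

    @staticmethod
    def _apply(x: np.ndarray, name: str, offset: float) -> np.ndarray:
        if name == "identity":
            return x
        if name == "sqrt":
            return np.sqrt(x + offset)
        return np.log(x + offset)

    def fit(self, X, y=None):
        X = check_array(X)
        self.transforms_: list[str] = []
        self.offsets_: list[float] = []
        means, sds = [], []
        for j in range(X.shape[1]):
            x = X[:, j]
            best, best_skew, best_off = "identity", abs(stats.skew(x)), 0.0
            for name in self.transforms:
                if name == "identity":
                    continue
                lo = x.min()
                off = 0.0
                if name == "sqrt" and lo < 0:
                    off = -lo
                if name == "log" and lo <= 0:
                    off = -lo + 1e-6 + 0.01 * (x.max() - lo + 1e-12)
                t = self._apply(x, name, off)
                sk = abs(stats.skew(t))
                if np.isfinite(sk) and sk < best_skew:
                    best, best_skew, best_off = name, sk, off
            self.transforms_.append(best)
            self.offsets_.append(best_off)
            t = self._apply(x, best, best_off)
            means.append(t.mean())
            sds.append(t.std(ddof=0) or 1.0)
        self.means_ = np.array(means)
        self.scales_ = np.array(sds)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X)
        out = np.empty_like(X, dtype=float)
        for j in range(X.shape[1]):
            t = self._apply(X[:, j], self.transforms_[j], self.offsets_[j])
            out[:, j] = (t - self.means_[j]) / self.scales_[j]
        return out


class FisherDiscriminant(ClassifierMixin, BaseEstimator):
    """Fisher linear discriminant with nearest-centroid classification.

    Discriminant axes are the leading generalized eigenvectors of the
    between-class scatter against the within-class scatter; samples are
    classified to the nearest class centroid in discriminant space.  A ridge
    is added to a singular within-class scatter (``ridge_used_``).  Ties in
    the centroid distances go to the lowest class label.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        n, p = X.shape
        means = np.stack([X[y_idx == k].mean(axis=0) for k in range(len(classes))])
        grand = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        for k, nk in zip(range(len(classes)), np.bincount(y_idx)):
            d = X[y_idx == k] - means[k]
            Sw += d.T @ d
            m = (means[k] - grand)[:, None]
            Sb += nk * (m @ m.T)
        self.ridge_used_ = False
        lam = self.ridge * (np.trace(Sw) / p if np.trace(Sw) > 0 else 1.0)
        try:
            evals, evecs = linalg.eigh(Sb, Sw + lam * np.eye(p))
        except linalg.LinAlgError:
            self.ridge_used_ = True
            lam = max(lam, 1e-4 * (np.trace(Sw) / p + 1.0))
            evals, evecs = linalg.eigh(Sb, Sw + lam * np.eye(p))
        if not np.all(np.isfinite(evals)):
            self.ridge_used_ = True
            lam = max(lam * 1e4, 1e-3)
            evals, evecs = linalg.eigh(Sb, Sw + lam * np.eye(p))
        order = np.argsort(evals)[::-1]
        n_comp = min(len(classes) - 1, p)
        self.scalings_ = evecs[:, order[:n_comp]]
        self.classes_ = classes
        self.centroids_ = means @ self.scalings_
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "scalings_")
        return check_array(X) @ self.scalings_

    def predict(self, X):
        check_is_fitted(self, "scalings_")
        Z = self.transform(X)
        d2 = ((Z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]  # argmin: first (lowest) tie wins


# ---------------------------------------------------------------------------
# Designs, subsets, the permutation engine


@dataclass(frozen=True)
class DFADesign:
    """Design of a permuted DFA run."""

    test_factor: str
    control_factor: str | list[str] | None = None
    mode: str = "balanced_crossed"  # balanced_crossed | unbalanced_crossed | plain
    train_fraction: float = 0.5
    n_resamples: int = 100
    n_permutations: int = 1000
    correlation_threshold: float = 0.80
    min_per_cell: int = 2
    redraw_per_permutation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1 or self.n_permutations < 1:
            raise ValueError("n_resamples and n_permutations must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("balanced_crossed", "unbalanced_crossed", "plain"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DFAResult:
    """Observed vs permutation-expected classification rates."""

    observed_classification: float
    expected_classification: float
    observed_crossvalidation: float
    expected_crossvalidation: float
    p_classification: float
    p_crossvalidation: float
    n_classes: int
    n_samples: int
    n_individuals: int
    achieved_train_share: float
    resample_trace: list[tuple[float, float]] = field(default_factory=list)
    permutation_trace: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "observed_classification_pct": self.observed_classification,
            "expected_classification_pct": self.expected_classification,
            "p_classification": self.p_classification,
            "observed_crossvalidation_pct": self.observed_crossvalidation,
            "expected_crossvalidation_pct": self.expected_crossvalidation,
            "p_crossvalidation": self.p_crossvalidation,
            "n_classes": self.n_classes,
            "n_samples": self.n_samples,
            "n_individuals": self.n_individuals,
            "achieved_train_share": self.achieved_train_share,
        }


def _control_cells(table: pd.DataFrame, control) -> pd.Series:
    if control is None:
        return pd.Series("all", index=table.index)
    if isinstance(control, str):
        return table[control].astype(str)
    return table[list(control)].astype(str).agg("|".join, axis=1)


def _draw_subset(
    L: np.ndarray,
    C: np.ndarray,
    n_levels: int,
    n_cells: int,
    design: DFADesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Numpy core of the subset drawing: integer-coded labels and cells.

    Returns (train positions, kept mask, kept level codes).
    """
    counts = np.zeros((n_levels, n_cells), dtype=int)
    np.add.at(counts, (L, C), 1)
    # candidate positions per (level, cell) via one stable sort
    key = L * n_cells + C
    order = np.argsort(key, kind="stable")
    sorted_key = key[order]

    def candidates(lev: int, cell: int) -> np.ndarray:
        k = lev * n_cells + cell
        a = np.searchsorted(sorted_key, k, side="left")
        b = np.searchsorted(sorted_key, k, side="right")
        return order[a:b]

    if design.mode == "balanced_crossed":
        ok = np.flatnonzero((counts >= design.min_per_cell).all(axis=1))
        if len(ok) < 2:
            raise DesignInfeasibleError(
                f"balanced crossed design infeasible: only {len(ok)} level(s) of "
                f"{design.test_factor!r} occupy every control cell with >= "
                f"{design.min_per_cell} samples"
            )
        m = int(counts[ok].min())
        n_draw = min(max(1, int(round(design.train_fraction * m))), m - 1)
        train = []
        for lev in ok:
            for cell in range(n_cells):
                train.append(rng.choice(candidates(lev, cell), size=n_draw, replace=False))
        kept = np.isin(L, ok)
        return np.sort(np.concatenate(train)), kept, ok

    if design.mode == "unbalanced_crossed":
        ok = np.flatnonzero(counts.sum(axis=1) >= max(2, design.min_per_cell))
        if len(ok) < 2:
            raise DesignInfeasibleError(
                "unbalanced crossed design infeasible: fewer than 2 usable levels"
            )
        train = []
        for lev in ok:
            for cell in range(n_cells):
                cand = candidates(lev, cell)
                if len(cand) == 0:
                    continue
                k = min(len(cand), max(1, int(round(design.train_fraction * len(cand)))))
                train.append(rng.choice(cand, size=k, replace=False))
        kept = np.isin(L, ok)
        return np.sort(np.concatenate(train)), kept, ok

    # plain
    ok = np.flatnonzero(counts.sum(axis=1) >= 2)
    if len(ok) < 2:
        raise DesignInfeasibleError("plain design infeasible: fewer than 2 usable levels")
    train = []
    for lev in ok:
        cand = np.flatnonzero(L == lev)
        k = max(1, min(len(cand) - 1, int(round(design.train_fraction * len(cand)))))
        train.append(rng.choice(cand, size=k, replace=False))
    kept = np.isin(L, ok)
    return np.sort(np.concatenate(train)), kept, ok


def balanced_subsets(
    table: pd.DataFrame,
    design: DFADesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Positional indices of one balanced training subset.

    ``balanced_crossed``: only test-factor levels present (with at least
    ``min_per_cell`` samples) in *every* control cell are kept; per level and
    cell, ``round(train_fraction * m)`` samples are drawn where ``m`` is the
    minimum cell count over the kept levels — equal training counts per cell.
    ``unbalanced_crossed``: levels need ``min_per_cell`` samples overall; a
    ``train_fraction`` share is drawn within each level-cell it occupies.
    ``plain``: a ``train_fraction`` share per test-factor level.
    """
    labels, level_names = pd.factorize(table[design.test_factor].astype(str))
    cells, _ = pd.factorize(_control_cells(table, design.control_factor))
    train, kept, ok = _draw_subset(
        labels, cells, labels.max() + 1, cells.max() + 1, design, rng
    )
    info = {"levels": [level_names[i] for i in ok], "kept_mask": kept}
    return train, info


def jackknife_classify(
    X: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    holdout_idx: np.ndarray | None = None,
) -> tuple[float, float]:
    """(classification %, cross-validation %) for one training subset.

    Classification success is re-substitution accuracy on the training
    subset; cross-validation success is accuracy on the holdout.  Classes
    absent from the training subset are excluded from the holdout.
    """
    labels = np.asarray(labels)
    if holdout_idx is None:
        mask = np.ones(len(labels), dtype=bool)
        mask[train_idx] = False
        holdout_idx = np.flatnonzero(mask)
    clf = FisherDiscriminant().fit(X[train_idx], labels[train_idx])
    cls = 100.0 * float(np.mean(clf.predict(X[train_idx]) == labels[train_idx]))
    seen = np.isin(labels[holdout_idx], clf.classes_)
    holdout_idx = holdout_idx[seen]
    if len(holdout_idx) == 0:
        return cls, float("nan")
    cv = 100.0 * float(np.mean(clf.predict(X[holdout_idx]) == labels[holdout_idx]))
    return cls, cv


def _permute_within_cells(labels: np.ndarray, cells: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = labels.copy()
    for cell in np.unique(cells):
        idx = np.flatnonzero(cells == cell)
        out[idx] = labels[rng.permutation(idx)]
    return out


def run_pdfa(
    table: pd.DataFrame,
    feature_cols: list[str],
    design: DFADesign,
) -> DFAResult:
    """Run a permuted jack-knifed DFA.

    Features are correlation-filtered and symmetrized/scaled on the full
    dataset.  Observed rates average ``n_resamples`` balanced subset draws;
    each of the ``n_permutations`` permutations shuffles the test-factor
    labels within control cells (preserving cell sizes) and repeats the
    procedure on one fresh subset draw (or the first observed draw when
    ``redraw_per_permutation`` is False).  Empirical p-values use the
    add-one estimator.
    """
    rng = np.random.default_rng(design.seed)
    work = table.reset_index(drop=True)
    complete = work[feature_cols].notna().all(axis=1)
    work = work[complete].reset_index(drop=True)

    raw = work[feature_cols].to_numpy(dtype=float)
    filt = CorrelationFilter(design.correlation_threshold).fit(raw)
    X = SymmetrizingScaler().fit_transform(filt.transform(raw))
    labels_obs, _level_names = pd.factorize(work[design.test_factor].astype(str))
    cells, _ = pd.factorize(_control_cells(work, design.control_factor))
    n_levels, n_cells = labels_obs.max() + 1, cells.max() + 1

    def one_run(labels: np.ndarray, rng_: np.random.Generator) -> tuple[float, float, int, float]:
        train, kept_mask, ok = _draw_subset(labels, cells, n_levels, n_cells, design, rng_)
        kept = np.flatnonzero(kept_mask)
        holdout = np.setdiff1d(kept, train)
        cls, cv = jackknife_classify(X, labels, train, holdout)
        return cls, cv, len(ok), len(train) / max(1, len(kept))

    resamples = []
    shares = []
    n_kept_levels = 0
    for _ in range(design.n_resamples):
        cls, cv, n_ok, share = one_run(labels_obs, rng)
        resamples.append((cls, cv))
        shares.append(share)
        n_kept_levels = n_ok
    obs_cls = float(np.nanmean([r[0] for r in resamples]))
    obs_cv = float(np.nanmean([r[1] for r in resamples]))

    perms = []
    for _ in range(design.n_permutations):
        perm_labels = _permute_within_cells(labels_obs, cells, rng)
        if design.redraw_per_permutation:
            cls, cv, _, _ = one_run(perm_labels, rng)
        else:
            sub_rng = np.random.default_rng(design.seed)  # reuse the first observed draw
            cls, cv, _, _ = one_run(perm_labels, sub_rng)
        perms.append((cls, cv))
    perm_cls = np.array([p[0] for p in perms])
    perm_cv = np.array([p[1] for p in perms])

    def p_of(perm_vals: np.ndarray, obs: float) -> float:
        valid = perm_vals[np.isfinite(perm_vals)]
        return (np.sum(valid >= obs) + 1.0) / (len(valid) + 1.0)

    return DFAResult(
        observed_classification=obs_cls,
        expected_classification=float(np.nanmean(perm_cls)),
        observed_crossvalidation=obs_cv,
        expected_crossvalidation=float(np.nanmean(perm_cv)),
        p_classification=p_of(perm_cls, obs_cls),
        p_crossvalidation=p_of(perm_cv, obs_cv),
        n_classes=n_kept_levels,
        n_samples=len(work),
        n_individuals=work[design.test_factor].nunique(),
        achieved_train_share=float(np.mean(shares)),
        resample_trace=resamples,
        permutation_trace=perms,
    )


class PermutedDFA(BaseEstimator):
    """Estimator-style interface to the permuted jack-knifed DFA.

    Parameters mirror :class:`DFADesign`; ``fit(table)`` runs the analysis on
    a labelled feature table and exposes the outcome as fitted attributes
    (``result_``, ``observed_crossvalidation_``, ``p_crossvalidation_``, ...).
    """

    def __init__(
        self,
        test_factor: str = "caller_id",
        control_factor=None,
        feature_cols: list[str] | None = None,
        mode: str = "balanced_crossed",
        train_fraction: float = 0.5,
        n_resamples: int = 100,
        n_permutations: int = 1000,
        correlation_threshold: float = 0.80,
        min_per_cell: int = 2,
        seed: int = 0,
    ):
        self.test_factor = test_factor
        self.control_factor = control_factor
        self.feature_cols = feature_cols
        self.mode = mode
        self.train_fraction = train_fraction
        self.n_resamples = n_resamples
        self.n_permutations = n_permutations
        self.correlation_threshold = correlation_threshold
        self.min_per_cell = min_per_cell
        self.seed = seed

    def fit(self, table: pd.DataFrame, y=None) -> "PermutedDFA":
        cols = self.feature_cols
        if cols is None:
            cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        design = DFADesign(
            test_factor=self.test_factor,
            control_factor=self.control_factor,
            mode=self.mode,
            train_fraction=self.train_fraction,
            n_resamples=self.n_resamples,
            n_permutations=self.n_permutations,
            correlation_threshold=self.correlation_threshold,
            min_per_cell=self.min_per_cell,
            seed=self.seed,
        )
        self.result_ = run_pdfa(table, cols, design)
        self.observed_classification_ = self.result_.observed_classification
        self.expected_classification_ = self.result_.expected_classification
        self.observed_crossvalidation_ = self.result_.observed_crossvalidation
        self.expected_crossvalidation_ = self.result_.expected_crossvalidation
        self.p_classification_ = self.result_.p_classification
        self.p_crossvalidation_ = self.result_.p_crossvalidation
        return self
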