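"""PLS-DA viability classifier: NIPALS fit, LV selection, threshold shifting.

The class code is fixed — 0 nonviable, 1 viable — and the model is an
ordinary PLS1 regression of that code on the (preprocessed) spectra,
cut at a decision threshold t. t starts at 0.5 and may be shifted
upward on a 0.01 grid until the predicted-viable group reaches a purity
target, which trades viable recall for a cleaner accepted lot.

Includes the Hotelling T-squared outlier screen on the first two
principal components and the stratified calibration/validation split
that keeps both camera sides of a seed in the same split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .prep import PreprocessSpec, SpectraTable, apply_preprocess

__all__ = [
    "NONVIABLE",
    "VIABLE",
    "PLSDAModel",
    "HotellingResult",
    "ThresholdResult",
    "ConfusionMatrix",
    "hotelling_screen",
    "split_calibration_validation",
    "fit_pls",
    "select_lv",
    "predict_scores",
    "classify",
    "shift_threshold",
    "evaluate",
]

# Fixed class coding; never re-coded.
NONVIABLE, VIABLE = 0, 1


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model.

    ``coef`` maps a centered spectrum to the class score; prediction is
    ``(x - x_mean) @ coef + y_mean``. ``weights``/``x_loadings``/
    ``y_loadings`` hold the NIPALS decomposition (bands x k, bands x k,
    k). ``threshold`` is the decision cut in (0, 1).
    """

    n_lv: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    threshold: float = 0.5
    preprocess: PreprocessSpec | None = None
    cv_error: np.ndarray | None = None
    x_variance: np.ndarray | None = None   # explained X variance per LV
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)


@dataclass(frozen=True)
class HotellingResult:
    flags: np.ndarray      # True = outlier
    t_squared: np.ndarray
    limit: float
    confidence: float

    @property
    def flagged_fraction(self) -> float:
        return float(self.flags.mean())


def hotelling_screen(X: np.ndarray, confidence: float = 0.989
                     ) -> HotellingResult:
    """Flag outliers by Hotelling T² on the first two principal components.

    The bound is the F-based ellipse 2(n-1)/(n-2) * F_{2,n-2}(confidence)
    for two estimated components.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[:2].T
    lam = (s[:2] ** 2) / (n - 1)
    lam = np.where(lam > 0, lam, np.inf)  # degenerate direction: no spread
    t2 = np.sum(scores ** 2 / lam, axis=1)
    limit = 2 * (n - 1) / (n - 2) * stats.f.ppf(confidence, 2, n - 2)
    return HotellingResult(t2 > limit, t2, float(limit), confidence)


def split_calibration_validation(table: SpectraTable, cal_fraction: float = 2 / 3,
                                 rng: np.random.Generator | int = 0,
                                 balanced: bool = True) -> SpectraTable:
    """Assign calibration/validation splits, stratified by variety and label.

    Both camera sides of one seed always land in the same split. Per
    stratum, round(cal_fraction * n_seeds) seeds go to calibration.
    With ``balanced`` the viable and nonviable groups must already hold
    the same number of seeds within each variety.
    """
    if not (0.0 < cal_fraction <= 1.0):
        raise ValueError("cal_fraction must lie in (0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    meta = table.meta
    if meta["label"].isna().any():
        raise ValueError("split requires labels on every row")
    split = np.full(len(table), "validation", dtype=object)
    for variety in meta["variety"].unique():
        in_var = meta["variety"] == variety
        counts = {}
        for lab in (NONVIABLE, VIABLE):
            ids = meta.loc[in_var & (meta["label"] == lab), "sample_id"].unique()
            counts[lab] = len(ids)
        if balanced and counts[NONVIABLE] != counts[VIABLE]:
            raise ValueError(
                f"variety {variety} has {counts[VIABLE]} viable vs "
                f"{counts[NONVIABLE]} nonviable seeds; downsample the larger "
                "group before a balanced split"
            )
        for lab in (NONVIABLE, VIABLE):
            ids = meta.loc[in_var & (meta["label"] == lab), "sample_id"].unique()
            ids = np.array(sorted(ids))
            rng.shuffle(ids)
            n_cal = int(round(cal_fraction * len(ids)))
            cal_ids = set(ids[:n_cal])
            rows = in_var & (meta["label"] == lab)
            split[rows & meta["sample_id"].isin(cal_ids)] = "calibration"
    out = replace(table, meta=table.meta.copy())
    out.meta["split"] = split
    return out


# ---------------------------------------------------------------------------
# NIPALS


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, max_lv: int,
                 max_iter: int = 500, tol: float = 1e-8):
    """NIPALS deflation returning the decomposition for 1..max_lv components.

    Returns (W, P, Q, coefs, x_variance) where coefs[k] is the regression
    vector using k+1 components and x_variance[k] the X variance
    captured by component k+1.
    """
    n, p = Xc.shape
    total_var = float(np.sum(Xc ** 2))
    if total_var == 0:
        raise ValueError("X has zero variance; cannot fit")
    X, y = Xc.copy(), yc.copy()
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    Q = np.zeros(max_lv)
    xvar = np.zeros(max_lv)
    for k in range(max_lv):
        u = y.copy()
        w_old = None
        for _ in range(max_iter):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("NIPALS weight collapsed to zero "
                                 f"at component {k + 1}")
            w /= norm
            t = X @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValueError(f"degenerate score at component {k + 1}")
            q = float(y @ t) / tt
            u = y * q
            # sign-invariant: with univariate y the weight direction is
            # fixed after one pass but its sign may alternate with q
            if w_old is not None and min(np.linalg.norm(w - w_old),
                                         np.linalg.norm(w + w_old)) < tol:
                break
            w_old = w
        else:  # pragma: no cover - univariate y converges in 2 iterations
            raise RuntimeError(f"NIPALS failed to converge at component {k + 1}")
        pvec = X.T @ t / tt
        X = X - np.outer(t, pvec)
        y = y - t * q
        W[:, k], P[:, k], Q[k] = w, pvec, q
        xvar[k] = tt * float(pvec @ pvec) / total_var
    coefs = []
    for k in range(1, max_lv + 1):
        # b_k = W (P'W)^{-1} q over the first k components
        pw = P[:, :k].T @ W[:, :k]
        coefs.append(W[:, :k] @ np.linalg.solve(pw, Q[:k]))
    return W, P, Q, coefs, xvar


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            preprocess: PreprocessSpec | None = None,
            metadata: dict | None = None) -> PLSDAModel:
    """Fit a PLS1 model of the 0/1 class code on spectra by NIPALS.

    X and y are centered internally; ``preprocess`` is stored so
    prediction paths can replay the same row transform.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(f"n_lv must lie in [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, Q, coefs, xvar = _nipals_path(X - x_mean, y - y_mean, n_lv)
    return PLSDAModel(
        n_lv=n_lv, coef=coefs[-1], x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=Q,
        preprocess=preprocess, x_variance=xvar,
        metadata=metadata or {},
    )


def predict_scores(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Continuous class scores ŷ = (X - x_mean) @ b + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"band mismatch: model has {model.coef.shape[0]} bands, "
            f"input has {X.shape[1]}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff score strictly exceeds t (ties go nonviable)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(scores) > threshold).astype(int)


def select_lv(X: np.ndarray, y: np.ndarray, max_lv: int, k_folds: int = 10,
              rng: np.random.Generator | int = 0) -> tuple[int, np.ndarray]:
    """Choose the LV count by venetian-blind k-fold cross-validation.

    Rows are shuffled once (seeded), then fold f holds every k-th row.
    The error curve is the misclassification rate at threshold 0.5 per
    component count; ties resolve to the fewest components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if k_folds > n:
        raise ValueError("more folds than rows")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k_folds    # venetian blinds on the shuffle
    errors = np.zeros(max_lv)
    for f in range(k_folds):
        test = folds == f
        Xtr, ytr = X[~test], y[~test]
        lv_cap = min(max_lv, Xtr.shape[0] - 1, Xtr.shape[1])
        xm, ym = Xtr.mean(axis=0), float(ytr.mean())
        _, _, _, coefs, _ = _nipals_path(Xtr - xm, ytr - ym, lv_cap)
        for j in range(max_lv):
            b = coefs[min(j, lv_cap - 1)]
            pred = (X[test] - xm) @ b + ym
            errors[j] += np.sum((pred > 0.5).astype(int) != y[test])
    errors /= n
    best = int(np.argmin(errors)) + 1        # argmin takes the first minimum
    return best, errors


def coefficient_peaks(model: PLSDAModel, wavelengths: np.ndarray,
                      n_peaks: int = 3) -> np.ndarray:
    """Wavelengths of the largest |b| excursions, for chemical reading.

    An excursion is a local maximum of the absolute regression
    coefficient; the ``n_peaks`` tallest are returned in descending
    magnitude. Their positions point at the absorption bands that drive
    the class separation.
    """
    ab = np.abs(np.asarray(model.coef))
    m = ab.size
    is_peak = np.ones(m, dtype=bool)
    is_peak[1:] &= ab[1:] >= ab[:-1]
    is_peak[:-1] &= ab[:-1] >= ab[1:]
    idx = np.flatnonzero(is_peak)
    idx = idx[np.argsort(-ab[idx])][:n_peaks]
    return np.asarray(wavelengths)[idx]


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    reached: bool       # False when the purity target was unattainable
    purity: float       # achieved purity of the predicted-viable group


def shift_threshold(scores: np.ndarray, labels: np.ndarray,
                    purity_target: float, grid_step: float = 0.01,
                    grid_max: float = 0.99) -> ThresholdResult:
    """Smallest t >= 0.5 on a 0.01 grid with a pure-enough viable group.

    Purity is the truly-viable fraction among calibration samples with
    score >= t; the >= is deliberate so a borderline sample sitting
    exactly on the cut still forces the threshold one step higher (the
    tie rule in :func:`classify` sends it nonviable). An empty accepted
    group counts as pure. If no grid value reaches the target the grid
    maximum is returned with ``reached=False``.
    """
    if not (0.0 < purity_target <= 1.0):
        raise ValueError("purity target must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    grid = np.round(np.arange(0.5, grid_max + grid_step / 2, grid_step), 10)
    last_purity = 0.0
    for t in grid:
        accepted = scores >= t
        purity = 1.0 if not accepted.any() else float(labels[accepted].mean())
        last_purity = purity
        if purity >= purity_target:
            return ThresholdResult(float(t), True, purity)
    return ThresholdResult(float(grid[-1]), False, last_purity)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with viable (=1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def acc_viable(self) -> float:
        """Acc.v: correctly accepted viable seeds over all truly viable."""
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def evaluate(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Confusion matrix of predicted vs true 0/1 labels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    for arr, name in ((pred, "prediction"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be 0 or 1")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )
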