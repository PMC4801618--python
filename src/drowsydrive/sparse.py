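"""Sparse-representation vigilance classification with KSVD-learned dictionaries.

A test feature y in R^p is coded against a concatenated dictionary
DIC = [DIC_alert  DIC_drowsy] by orthogonal matching pursuit under an L0
budget q, and assigned to the class whose sub-dictionary reconstructs it with
the smaller residual

    class(y) = argmin_x || y - DIC a'_x ||_2 ,

where a'_x zeroes the other class's coefficients.  Per-class dictionaries are
either w randomly selected training features (stacked dictionary) or learned
with KSVD, which alternates OMP sparse coding with rank-1 SVD updates of each
atom on the residual of the signals that use it.

`SparseRepresentationClassifier` packages this as a scikit-learn estimator;
the lower-level `omp`, `ksvd_train` and `build_dictionary` functions are the
algorithmic surface and are what the estimator calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SparseCode",
    "ClassDictionary",
    "omp",
    "reconstruct",
    "build_dictionary",
    "ksvd",
    "ksvd_train",
    "classify",
    "accuracy",
    "SparseRepresentationClassifier",
]

_EPS = 1e-12


@dataclass
class SparseCode:
    """Result of coding one feature vector against a two-class dictionary."""

    coeffs: np.ndarray
    support: np.ndarray
    residual_alert: float
    residual_drowsy: float


@dataclass
class ClassDictionary:
    """Per-class atom matrices (columns are unit-norm atoms of length p)."""

    atoms_alert: np.ndarray   # p x w
    atoms_drowsy: np.ndarray  # p x w
    trained: bool = False
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.atoms_alert.shape[0] != self.atoms_drowsy.shape[0]:
            raise ValueError("class dictionaries must share the feature length p")

    @property
    def p(self) -> int:
        return self.atoms_alert.shape[0]

    @property
    def w(self) -> int:
        return self.atoms_alert.shape[1]

    @property
    def combined(self) -> np.ndarray:
        """[DIC_alert DIC_drowsy], p x 2w."""
        return np.hstack([self.atoms_alert, self.atoms_drowsy])


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=0)
    norms[norms < _EPS] = 1.0
    return M / norms


def omp(y: np.ndarray, dictionary: np.ndarray, q: int):
    """Orthogonal matching pursuit: greedy L0-constrained least squares.

    Repeatedly picks the atom most correlated with the current residual and
    re-fits y on the selected support by least squares, stopping after q
    atoms or when the residual vanishes.  Returns ``(coeffs, support)`` with
    ``coeffs`` dense of length n_atoms.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(dictionary, dtype=float)
    if y.size != D.shape[0]:
        raise ValueError(f"y has length {y.size}, dictionary atoms have length {D.shape[0]}")
    if q < 0:
        raise ValueError("q must be >= 0")
    if q > D.shape[1]:
        raise ValueError(f"q={q} exceeds the {D.shape[1]} available atoms")
    coeffs = np.zeros(D.shape[1])
    support: list[int] = []
    residual = y.copy()
    for _ in range(q):
        if np.linalg.norm(residual) < _EPS:
            break
        corr = np.abs(D.T @ residual)
        corr[support] = -1.0  # never re-select
        j = int(np.argmax(corr))
        support.append(j)
        sol, *_ = np.linalg.lstsq(D[:, support], y, rcond=None)
        residual = y - D[:, support] @ sol
    if support:
        coeffs[support] = sol
    return coeffs, np.asarray(support, dtype=int)


def reconstruct(coeffs: np.ndarray, dictionary: np.ndarray) -> np.ndarray:
    """y' = DIC a'."""
    D = np.asarray(dictionary, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float).ravel()
    if coeffs.size != D.shape[1]:
        raise ValueError(f"{coeffs.size} coefficients for {D.shape[1]} atoms")
    return D @ coeffs


def build_dictionary(features_per_class: dict, w: int, seed: int | None = None) -> ClassDictionary:
    """Stack w randomly selected, unit-normalized features per class.

    ``features_per_class`` maps ``"alert"``/``"drowsy"`` to arrays of shape
    (n_features_vectors, p).
    """
    rng = np.random.default_rng(seed)
    atoms = {}
    for cls in ("alert", "drowsy"):
        F = np.asarray(features_per_class[cls], dtype=float)
        if F.ndim != 2 or F.shape[0] < w:
            raise ValueError(f"class {cls!r} needs >= {w} feature vectors, has {F.shape[0] if F.ndim == 2 else 0}")
        pick = rng.choice(F.shape[0], size=w, replace=False)
        atoms[cls] = _normalize_columns(F[pick].T.copy())
    return ClassDictionary(atoms["alert"], atoms["drowsy"], trained=False,
                           train_meta={"w": w, "seed": seed, "method": "stacked"})


def ksvd(Y: np.ndarray, w: int, q: int, iterations: int, seed: int | None = None):
    """KSVD dictionary learning on signals Y (p x n).

    Alternates (i) OMP coding of every column at sparsity q and (ii) an
    atom-by-atom rank-1 SVD update of the residual restricted to the signals
    using that atom (their coefficients are updated jointly).  Atoms that no
    signal uses are replaced by the currently worst-represented signal.
    Returns ``(D, objective)`` where ``objective[i]`` is ||Y - D A||_F after
    iteration i's dictionary update.
    """
    Y = np.asarray(Y, dtype=float)
    p, n = Y.shape
    if n == 0:
        raise ValueError("empty training set")
    if n < w:
        raise ValueError(f"need >= {w} training signals to initialize {w} atoms, have {n}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    D = _normalize_columns(Y[:, rng.choice(n, size=w, replace=False)].copy())
    objective = []
    A = np.zeros((w, n))
    first = True
    for _ in range(iterations):
        for i in range(n):
            code, _ = omp(Y[:, i], D, q)
            # keep the previous code when it still explains the signal better:
            # makes the recorded objective non-increasing across iterations
            if first or np.linalg.norm(Y[:, i] - D @ code) <= np.linalg.norm(Y[:, i] - D @ A[:, i]):
                A[:, i] = code
        first = False
        for j in range(w):
            users = np.nonzero(A[j] != 0)[0]
            if users.size == 0:
                # dead atom: re-seed with the worst-represented signal
                resid = np.linalg.norm(Y - D @ A, axis=0)
                worst = int(np.argmax(resid))
                d = Y[:, worst]
                nrm = np.linalg.norm(d)
                D[:, j] = d / nrm if nrm > _EPS else d
                continue
            E = Y[:, users] - D @ A[:, users] + np.outer(D[:, j], A[j, users])
            U, S, Vt = np.linalg.svd(E, full_matrices=False)
            D[:, j] = U[:, 0]
            A[j, users] = S[0] * Vt[0]
        objective.append(float(np.linalg.norm(Y - D @ A)))
    return D, objective


def ksvd_train(features_per_class: dict, w: int, q: int, iterations: int = 30,
               seed: int | None = None, train_fraction: float = 2.0 / 3.0) -> ClassDictionary:
    """Learn one KSVD dictionary per class on the leading two-thirds of its features.

    The split is by contiguous blocks (earliest ``train_fraction`` of each
    class), leaving the remaining third untouched for held-out evaluation;
    history-averaged features are temporally correlated, so a random shuffle
    would leak.
    """
    atoms, meta = {}, {"w": w, "q": q, "iterations": iterations, "seed": seed,
                       "train_fraction": train_fraction, "method": "ksvd", "objective": {}}
    for cls in ("alert", "drowsy"):
        F = np.asarray(features_per_class[cls], dtype=float)
        if F.ndim != 2 or F.shape[0] == 0:
            raise ValueError(f"class {cls!r} has no feature vectors")
        n_train = max(int(round(train_fraction * F.shape[0])), 1)
        D, obj = ksvd(F[:n_train].T, w, q, iterations, seed)
        atoms[cls] = D
        meta["objective"][cls] = obj
    return ClassDictionary(atoms["alert"], atoms["drowsy"], trained=True, train_meta=meta)


def classify(y: np.ndarray, dic: ClassDictionary, q: int) -> tuple[str, SparseCode]:
    """Minimal-residual two-class decision for one feature vector.

    y is scaled to unit norm (residuals are then comparable across samples),
    coded by OMP against [DIC_alert DIC_drowsy], and assigned to the class
    with the smaller class-restricted reconstruction residual.  Ties go to
    "alert" so a borderline sample never triggers an intervention.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != dic.p:
        raise ValueError(f"feature length {y.size} != dictionary atom length {dic.p}")
    nrm = np.linalg.norm(y)
    if nrm > _EPS:
        y = y / nrm
    D = dic.combined
    coeffs, support = omp(y, D, q)
    w = dic.w
    res = {}
    for cls, sl in (("alert", slice(0, w)), ("drowsy", slice(w, 2 * w))):
        restricted = np.zeros_like(coeffs)
        restricted[sl] = coeffs[sl]
        res[cls] = float(np.linalg.norm(y - D @ restricted))
    label = "alert" if res["alert"] <= res["drowsy"] else "drowsy"
    return label, SparseCode(coeffs, support, res["alert"], res["drowsy"])


def accuracy(predictions, labels) -> float:
    """Percentage of correct detections: 100 x correct / total."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    return 100.0 * float(np.mean(predictions == labels))


class SparseRepresentationClassifier(ClassifierMixin, BaseEstimator):
    """Minimal-residual sparse-representation classifier (SRC) with KSVD.

    Fits one sub-dictionary per class from the training features of that
    class and predicts by coding each sample against the concatenated
    dictionary with OMP, choosing the class whose atoms explain it best.

    Parameters
    ----------
    n_atoms : int, default=50
        Atoms per class (w).
    sparsity : int, default=5
        OMP L0 budget (q).
    n_iter : int, default=30
        KSVD iterations; ignored when ``method="stacked"``.
    method : {"ksvd", "stacked"}, default="ksvd"
        Learn atoms with KSVD or stack randomly selected training features.
    random_state : int or None
        Seeds atom selection / initialization.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ties in residual go to ``classes_[0]``.
    dictionary_ : ClassDictionary
        Learned per-class atoms.
    n_features_in_ : int
    """

    def __init__(self, n_atoms: int = 50, sparsity: int = 5, n_iter: int = 30,
                 method: str = "ksvd", random_state: int | None = None):
        self.n_atoms = n_atoms
        self.sparsity = sparsity
        self.n_iter = n_iter
        self.method = method
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"binary vigilance classifier, got classes {self.classes_}")
        if self.method not in ("ksvd", "stacked"):
            raise ValueError(f"method must be 'ksvd' or 'stacked', got {self.method!r}")
        Xn = _normalize_columns(X.T).T  # unit-norm samples, matches `classify`
        per_class = {"alert": Xn[y == self.classes_[0]], "drowsy": Xn[y == self.classes_[1]]}
        if self.method == "stacked":
            self.dictionary_ = build_dictionary(per_class, self.n_atoms, self.random_state)
        else:
            # fit on everything given: the caller owns the train/test split
            self.dictionary_ = ksvd_train(per_class, self.n_atoms, self.sparsity,
                                          self.n_iter, self.random_state, train_fraction=1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_residuals(self, X) -> np.ndarray:
        """Per-class reconstruction residuals, shape (n_samples, 2)."""
        check_is_fitted(self, "dictionary_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], 2))
        for i, row in enumerate(X):
            _, code = classify(row, self.dictionary_, self.sparsity)
            out[i] = (code.residual_alert, code.residual_drowsy)
        return out

    def decision_function(self, X) -> np.ndarray:
        """residual(classes_[0]) - residual(classes_[1]); positive favors classes_[1]."""
        res = self.predict_residuals(X)
        return res[:, 0] - res[:, 1]

    def predict(self, X):
        res = self.predict_residuals(X)
        # tie -> first (sorted) class: "alert" before "drowsy"
        return self.classes_[(res[:, 1] < res[:, 0]).astype(int)]
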