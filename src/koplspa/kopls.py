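"""Kernel-based orthogonal projections to latent structures (K-OPLS).

A two-class kernel classifier: the centered Gaussian kernel is modelled by
one predictive component (the class response is a single +/-1 column) plus
``Ao`` Y-orthogonal components. Each orthogonal component is the leading
eigenvector of the kernel projected off the current predictive score, and
is removed by the symmetric deflation K <- (I - t_o t_o^T) K (I - t_o t_o^T).
The final predictive score of the fully deflated kernel is regressed on the
centered response to give fitted values.

Test samples are handled by the exact feature-space counterpart of the
training deflation: a test row's orthogonal score is recovered as
t_o,te = (k_te . t_o - tp_te c_i) / lambda_i, after which the row is deflated
with the same rank-one transform; predicting the training set therefore
reproduces the fitted values to machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

EIG_TOL = 1e-12  # eigenvalue cutoff for rank decisions


@dataclass
class KernelSpec:
    """Gaussian kernel k(x, z) = exp(-||x - z||^2 / (2 sigma^2))."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gaussian_kernel(X1: np.ndarray, X2: np.ndarray, spec: KernelSpec | float) -> np.ndarray:
    """Pairwise Gaussian kernel matrix between the rows of X1 and X2."""
    sigma = spec.sigma if isinstance(spec, KernelSpec) else KernelSpec(float(spec)).sigma
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    d2 = cdist(X1, X2, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass
class CenteringState:
    """Training-kernel statistics needed to center test kernels."""

    n: int
    column_means: np.ndarray  # (1/n) 1^T K of the raw training kernel


def center_kernel(K: np.ndarray) -> tuple[np.ndarray, CenteringState]:
    """Double-center a training kernel: Kc = (I - 11'/n) K (I - 11'/n)."""
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("training kernel must be square")
    col_means = K.mean(axis=0)
    row_means = K.mean(axis=1)
    grand = K.mean()
    Kc = K - col_means[None, :] - row_means[:, None] + grand
    return Kc, CenteringState(n=n, column_means=col_means)


def center_kernel_test(K_test: np.ndarray, state: CenteringState) -> np.ndarray:
    """Center a test-vs-training kernel with the stored training statistics."""
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    if K_test.shape[1] != state.n:
        raise ValueError(
            f"test kernel has {K_test.shape[1]} columns, expected {state.n}"
        )
    M = K_test - state.column_means[None, :]
    return M - M.mean(axis=1, keepdims=True)


def _leading_eigenpair(M: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and eigenvector of a symmetric matrix.

    Tries the partial (index-subset) solver first; LAPACK's evr driver can
    return an empty subset for heavily degenerate spectra, in which case the
    full deterministic decomposition is used.
    """
    n = M.shape[0]
    try:
        lam, vec = scipy.linalg.eigh(M, subset_by_index=(n - 1, n - 1))
    except scipy.linalg.LinAlgError:
        lam = np.empty(0)
    if lam.size == 0:
        lam, vec = np.linalg.eigh(M)
        return float(lam[-1]), vec[:, -1]
    return float(lam[0]), vec[:, 0]


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: first non-negligible entry > 0."""
    nz = np.flatnonzero(np.abs(v) > 1e-12 * max(1.0, np.abs(v).max()))
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


@dataclass
class KOPLSModel:
    """Fitted K-OPLS model (single predictive component, Ao orthogonal ones).

    Kernel-side quantities are always present; ``sigma``, ``X_train`` and
    ``centering_state`` are attached by :func:`fit_kopls_xy` and are required
    for predicting new samples from raw feature matrices.
    """

    Ao: int
    classes_: np.ndarray          # sorted label values; classes_[1] codes +1
    y_offset: float               # mean of the +/-1 coding (training)
    majority_class: object        # tie-break target for classify()
    cp: float                     # Y-side loading (scalar, +1 by convention)
    sp: float                     # predictive eigenvalue of Y' Kc Y
    u: np.ndarray                 # Y cp sp^(-1/2): predictive weight in sample space
    yc: np.ndarray = field(repr=False, default=None)   # centered +/-1 response
    Tp: np.ndarray = field(repr=False, default=None)   # final predictive scores (n,)
    To: list = field(repr=False, default_factory=list)           # unit t_o vectors
    To_eigenvalues: list = field(default_factory=list)           # lambda_i
    To_c: list = field(default_factory=list)                     # c_i scalars
    To_w: list = field(repr=False, default_factory=list)         # w_i = K_i t_o
    Tp_levels: list = field(repr=False, default_factory=list)    # K_i u per level
    Bt: float = 0.0               # regression weight Tp -> yc
    yhat: np.ndarray = field(repr=False, default=None)  # fitted centered response
    Kc: np.ndarray = field(repr=False, default=None)    # centered training kernel
    sigma: float | None = None
    X_train: np.ndarray = field(repr=False, default=None)
    centering_state: CenteringState | None = None

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "Ao": self.Ao,
            "classes": self.classes_.tolist(),
            "y_offset": self.y_offset,
            "majority_class": getattr(self.majority_class, "item", lambda: self.majority_class)(),
            "cp": self.cp,
            "sp": self.sp,
            "u": self.u.tolist(),
            "yc": self.yc.tolist(),
            "Tp": self.Tp.tolist(),
            "To": [t.tolist() for t in self.To],
            "To_eigenvalues": list(self.To_eigenvalues),
            "To_c": list(self.To_c),
            "To_w": [w.tolist() for w in self.To_w],
            "Bt": self.Bt,
            "sigma": self.sigma,
        }
        if self.X_train is not None:
            d["X_train"] = self.X_train.tolist()
            d["centering_column_means"] = self.centering_state.column_means.tolist()
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "KOPLSModel":
        with open(path) as fh:
            d = json.load(fh)
        model = cls(
            Ao=d["Ao"],
            classes_=np.asarray(d["classes"]),
            y_offset=d["y_offset"],
            majority_class=d["majority_class"],
            cp=d["cp"],
            sp=d["sp"],
            u=np.asarray(d["u"]),
            yc=np.asarray(d["yc"]),
            Tp=np.asarray(d["Tp"]),
            To=[np.asarray(t) for t in d["To"]],
            To_eigenvalues=d["To_eigenvalues"],
            To_c=d["To_c"],
            To_w=[np.asarray(w) for w in d["To_w"]],
            Bt=d["Bt"],
            sigma=d["sigma"],
        )
        if "X_train" in d:
            model.X_train = np.asarray(d["X_train"])
            model.centering_state = CenteringState(
                n=model.X_train.shape[0],
                column_means=np.asarray(d["centering_column_means"]),
            )
        return model


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, object]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    coded = np.where(y == classes[1], 1.0, -1.0)
    counts = [(y == c).sum() for c in classes]
    majority = classes[int(np.argmax(counts))]
    return coded, classes, majority


def fit_kopls(Kc: np.ndarray, y: np.ndarray, Ao: int) -> KOPLSModel:
    """Estimate a K-OPLS model from a centered training kernel.

    Parameters
    ----------
    Kc : ndarray (n, n)
        Centered (double-centered) training kernel.
    y : array-like (n,)
        Binary class labels (any two values).
    Ao : int
        Number of Y-orthogonal components to extract and deflate.
    """
    Kc = np.asarray(Kc, dtype=float)
    n = Kc.shape[0]
    if Ao < 0:
        raise ValueError("Ao must be non-negative")
    if Ao >= n:
        raise ValueError(f"Ao={Ao} must be smaller than the sample count n={n}")
    coded, classes, majority = _encode_labels(y)
    yc = coded - coded.mean()

    sp = float(yc @ Kc @ yc)
    if sp <= EIG_TOL * max(1.0, np.abs(Kc).max()):
        raise ValueError("degenerate response-kernel product Y'KcY (no signal)")
    cp = 1.0  # sign convention: Y-side loading positive
    u = yc * cp / np.sqrt(sp)

    K = Kc.copy()
    To, lams, cs, ws, tp_levels = [], [], [], [], []
    for _ in range(Ao):
        tp = K @ u
        tt = float(tp @ tp)
        if tt <= EIG_TOL:
            raise ValueError("predictive score collapsed during deflation")
        Ktp = K @ tp
        # M = (I - P) K (I - P) with P the projector onto tp
        M = (
            K
            - np.outer(tp, Ktp) / tt
            - np.outer(Ktp, tp) / tt
            + (tp @ Ktp) / tt**2 * np.outer(tp, tp)
        )
        lam, vec = _leading_eigenpair(M)
        if lam <= EIG_TOL * max(1.0, np.abs(Kc).max()):
            raise ValueError("no Y-orthogonal variation left to extract")
        to = _fix_sign(vec)
        to = to / np.linalg.norm(to)
        w = K @ to
        c = float(tp @ w) / tt
        tp_levels.append(tp)
        To.append(to)
        lams.append(lam)
        cs.append(c)
        ws.append(w)
        # symmetric rank-one deflation (I - t t') K (I - t t')
        K = K - np.outer(to, w) - np.outer(w, to) + float(to @ w) * np.outer(to, to)

    Tp = K @ u
    tt = float(Tp @ Tp)
    if tt <= EIG_TOL:
        raise ValueError("final predictive score is degenerate")
    Bt = float(Tp @ yc) / tt
    model = KOPLSModel(
        Ao=Ao,
        classes_=classes,
        y_offset=float(coded.mean()),
        majority_class=majority,
        cp=cp,
        sp=sp,
        u=u,
        yc=yc,
        Tp=Tp,
        To=To,
        To_eigenvalues=lams,
        To_c=cs,
        To_w=ws,
        Tp_levels=tp_levels,
        Bt=Bt,
        yhat=Tp * Bt,
        Kc=Kc,
    )
    return model


def fit_kopls_xy(
    X: np.ndarray, y: np.ndarray, sigma: float, Ao: int
) -> KOPLSModel:
    """Fit from a scaled feature matrix: kernel, centering, then K-OPLS."""
    X = np.asarray(X, dtype=float)
    K = gaussian_kernel(X, X, sigma)
    Kc, state = center_kernel(K)
    model = fit_kopls(Kc, y, Ao)
    model.sigma = float(sigma)
    model.X_train = X
    model.centering_state = state
    return model


def predict_from_kernel(model: KOPLSModel, Kt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict from an already centered test-vs-training kernel (m, n).

    Returns (yhat, tp_test) on the centered-response scale.
    """
    Kt = np.atleast_2d(np.asarray(Kt, dtype=float))
    for i in range(model.Ao):
        to, lam, c, w = model.To[i], model.To_eigenvalues[i], model.To_c[i], model.To_w[i]
        tp_te = Kt @ model.u
        to_te = (Kt @ to - tp_te * c) / lam
        Kt = Kt - np.outer(to_te, w)
        Kt = Kt - np.outer(Kt @ to, to)
    tp_te = Kt @ model.u
    return tp_te * model.Bt, tp_te


def predict_kopls(model: KOPLSModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted (centered-scale) response and predictive scores for new samples."""
    if model.X_train is None or model.sigma is None:
        raise ValueError("model lacks training features; fit with fit_kopls_xy")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError("feature dimension does not match training data")
    K = gaussian_kernel(X_new, model.X_train, model.sigma)
    Kt = center_kernel_test(K, model.centering_state)
    return predict_from_kernel(model, Kt)


def classify(model: KOPLSModel, yhat: np.ndarray) -> np.ndarray:
    """Map predicted responses to class labels.

    The decision value is yhat plus the training coding offset (undoing the
    response centering); its sign selects the class, with exact zeros
    assigned to the majority training class.
    """
    decision = np.asarray(yhat, dtype=float) + model.y_offset
    out = np.where(decision > 0, model.classes_[1], model.classes_[0])
    out = np.where(decision == 0, model.majority_class, out)
    return out


@dataclass
class FitStats:
    """Explained-variation and cross-validated prediction statistics."""

    R2X: float
    R2Y: float
    Q2Y: float = float("nan")


def explained_kernel_fraction(Kc: np.ndarray, basis: np.ndarray) -> float:
    """Fraction of centered-kernel trace captured by the span of ``basis``.

    Computes tr(P Kc P) / tr(Kc) with P the orthogonal projector onto the
    column span of ``basis`` (equal to tr(P Kc) since P is idempotent).
    """
    Q, _ = np.linalg.qr(np.atleast_2d(np.asarray(basis, dtype=float)))
    tr = float(np.trace(Kc))
    if tr <= 0:
        raise ValueError("centered kernel has non-positive trace")
    return float(np.trace(Q.T @ Kc @ Q)) / tr


def fit_stats(
    model: KOPLSModel,
    cv_y: np.ndarray | None = None,
    cv_pred: np.ndarray | None = None,
) -> FitStats:
    """R2X, R2Y and (when CV predictions are supplied) Q2Y.

    ``cv_y`` / ``cv_pred`` are the true +/-1-coded responses and the
    cross-validated predicted responses (uncentered decision values), aligned
    sample by sample; Q2Y = 1 - PRESS / SS around the training mean.
    """
    yc = model.yc
    ss = float(yc @ yc)
    if ss <= 0:
        raise ValueError("zero response variance")
    rss = float(np.sum((yc - model.yhat) ** 2))
    r2y = 1.0 - rss / ss
    basis = np.column_stack([model.Tp] + list(model.To)) if model.To else model.Tp[:, None]
    r2x = explained_kernel_fraction(model.Kc, basis)
    q2y = float("nan")
    if cv_y is not None and cv_pred is not None:
        cv_y = np.asarray(cv_y, dtype=float)
        cv_pred = np.asarray(cv_pred, dtype=float)
        press = float(np.sum((cv_y - cv_pred) ** 2))
        ss_full = float(np.sum((cv_y - cv_y.mean()) ** 2))
        q2y = 1.0 - press / ss_full
    return FitStats(R2X=r2x, R2Y=r2y, Q2Y=q2y)
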