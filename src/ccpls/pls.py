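"""Partial least squares regression of HVG expression on neighbor scores.

The regression couples the two blocks through outer relations
``X = T P' + E`` and ``Y = U Q' + F`` and the inner relation ``U = T D + H``
with diagonal ``D``; predictions use the summed coefficient matrix ``W`` so
that ``Y = X W + G``.  Components are extracted sequentially with deflation
of both blocks.  The weight vector of each component — classically obtained
by the iterative NIPALS power method — is here computed exactly as the
dominant eigenvector of the small ``L x L`` matrix ``X' Y Y' X``, which is
the fixed point of that iteration; the direct eigen-solution is
deterministic and immune to the slow convergence the power method exhibits
when the leading eigenvalues are nearly tied (as on signal-free data).
The number of components is chosen to minimise mean squared error under
k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSFit",
    "CVSelection",
    "fit_pls",
    "select_num_components",
    "closed_form_coefficients",
    "DegenerateComponentError",
]


class DegenerateComponentError(RuntimeError):
    """Component extraction failed: the deflated cross-covariance vanished."""

    def __init__(self, component: int):
        self.component = component
        super().__init__(
            f"cross-covariance vanished while extracting component {component}"
        )


@dataclass
class PLSFit:
    """Fitted PLS model.

    Attributes
    ----------
    n_components:
        Number of extracted components ``C``.
    T, U:
        ``(n, C)`` score matrices for the predictor and response blocks.
    P_load:
        ``(L, C)`` predictor loadings.
    Q:
        ``(H, C)`` response loadings (normalised y-weights).
    D:
        ``(C, C)`` diagonal inner-relation matrix linking U to T.
    W_comp:
        ``(L, H, C)`` per-component rank-one coefficient increments; the
        prediction after the first ``c`` components is
        ``X @ W_comp[..., :c].sum(axis=2)``.
    W_sum:
        ``(L, H)`` summed coefficient matrix, ``W_comp.sum(axis=2)``.
    """

    n_components: int
    T: np.ndarray
    U: np.ndarray
    P_load: np.ndarray
    Q: np.ndarray
    D: np.ndarray
    x_weights: np.ndarray
    y_reg: np.ndarray  # (H, C) regression of deflated Y on t_c
    rotations: np.ndarray  # (L, C) so that T = X @ rotations
    W_comp: np.ndarray
    W_sum: np.ndarray = field(init=False)
    residual_norms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W_sum = self.W_comp.sum(axis=2)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        c = self.n_components if n_components is None else n_components
        return X @ self.W_comp[..., :c].sum(axis=2)


@dataclass
class CVSelection:
    candidates: list[int]
    mean_mse: list[float]
    chosen: int
    folds: int
    seed: int | None


def _center_check(A: np.ndarray, name: str) -> None:
    col_means = A.mean(axis=0)
    scale = max(1.0, float(np.abs(A).max(initial=0.0)))
    if np.any(np.abs(col_means) > 1e-6 * scale):
        raise ValueError(f"{name} must be column-centered before PLS")


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    *,
    check_centered: bool = True,
) -> PLSFit:
    """Fit a PLS2 model by sequential component extraction with deflation.

    Parameters
    ----------
    X:
        ``(n, L)`` column-centered predictor matrix (z-scored neighbor scores).
    Y:
        ``(n, H)`` column-centered response matrix (processed HVG expression).
    n_components:
        Number of components ``C``; must satisfy ``C <= min(L, n - 1)``.

    Raises
    ------
    DegenerateComponentError
        If the deflated blocks carry no remaining cross-covariance, so a
        further component is undefined.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    n, L = X.shape
    H = Y.shape[1]
    if not 1 <= n_components <= min(L, n - 1):
        raise ValueError(
            f"n_components={n_components} outside valid range "
            f"[1, {min(L, n - 1)}]"
        )
    if check_centered:
        _center_check(X, "X")
        _center_check(Y, "Y")

    C = n_components
    Xc = X.copy()
    Yc = Y.copy()
    T = np.empty((n, C))
    U = np.empty((n, C))
    P_load = np.empty((L, C))
    Q = np.empty((H, C))
    Wx = np.empty((L, C))
    y_reg = np.empty((H, C))
    d_diag = np.empty(C)

    eig_first = None
    for c in range(C):
        S = Xc.T @ Yc  # (L, H) cross-covariance of the deflated blocks
        M = S @ S.T
        if not np.any(S):
            raise DegenerateComponentError(c)
        eigvals, eigvecs = np.linalg.eigh(M)
        if eig_first is None:
            eig_first = eigvals[-1]
        # remaining cross-covariance at round-off level: no further component
        if eigvals[-1] <= 0 or eigvals[-1] <= 1e-24 * eig_first:
            raise DegenerateComponentError(c)
        w = eigvecs[:, -1]
        # deterministic sign: the largest-magnitude weight entry is positive
        pivot = int(np.argmax(np.abs(w)))
        if w[pivot] < 0:
            w = -w

        t = Xc @ w
        tt = float(t @ t)
        if tt == 0.0:
            raise DegenerateComponentError(c)
        q = Yc.T @ t
        q_norm = np.linalg.norm(q)
        if q_norm == 0.0:
            raise DegenerateComponentError(c)
        q /= q_norm
        u = Yc @ q

        p = Xc.T @ t / tt
        creg = Yc.T @ t / tt
        d_diag[c] = float(u @ t) / tt
        T[:, c] = t
        U[:, c] = u
        P_load[:, c] = p
        Q[:, c] = q
        Wx[:, c] = w
        y_reg[:, c] = creg
        Xc -= np.outer(t, p)
        Yc -= np.outer(t, creg)

    # rotations map the *original* X to scores: T = X @ R
    R = Wx @ np.linalg.inv(P_load.T @ Wx)
    W_comp = np.einsum("lc,hc->lhc", R, y_reg)

    fit = PLSFit(
        n_components=C,
        T=T,
        U=U,
        P_load=P_load,
        Q=Q,
        D=np.diag(d_diag),
        x_weights=Wx,
        y_reg=y_reg,
        rotations=R,
        W_comp=W_comp,
    )
    fit.residual_norms = {
        "E": float(np.linalg.norm(Xc)),
        "F": float(np.linalg.norm(Yc)),
        "H_res": float(np.linalg.norm(U - T @ fit.D)),
        "G_res": float(np.linalg.norm(Y - fit.predict(X))),
    }
    return fit


def closed_form_coefficients(X: np.ndarray, Y: np.ndarray, fit: PLSFit) -> np.ndarray:
    """Evaluate ``W = X'U (T'X X'U)^-1 T'Y`` from the fitted score matrices.

    Algebraically identical to ``fit.W_sum``; kept as a separate dense
    evaluation path for validation.
    """
    T, U = fit.T, fit.U
    XtU = X.T @ U
    return XtU @ np.linalg.solve(T.T @ X @ XtU, T.T @ Y)


def select_num_components(
    X: np.ndarray,
    Y: np.ndarray,
    *,
    folds: int = 10,
    c_max: int | None = None,
    seed: int | None = None,
) -> CVSelection:
    """Choose the component count minimising mean CV-MSE.

    Folds are assigned by a seeded shuffle; ties are broken toward the
    smallest component count. If ``n < folds`` the fold count is reduced to
    ``n`` with a warning.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if folds > n:
        warnings.warn(
            f"n={n} smaller than folds={folds}; reducing folds to {n}",
            stacklevel=2,
        )
        folds = n
    if c_max is None:
        c_max = min(X.shape[1], 10)
    # largest C trainable in every fold
    min_train = n - int(np.ceil(n / folds))
    c_max = max(1, min(c_max, X.shape[1], min_train - 1))

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    fold_ids[order] = np.arange(n) % folds

    candidates = list(range(1, c_max + 1))
    sse = np.zeros(len(candidates))
    for k in range(folds):
        test = fold_ids == k
        train = ~test
        Xtr, Ytr = X[train], Y[train]
        # refit centering on the training fold
        x_mean = Xtr.mean(axis=0)
        y_mean = Ytr.mean(axis=0)
        Xtr = Xtr - x_mean
        Ytr = Ytr - y_mean
        Xte = X[test] - x_mean
        Yte = Y[test] - y_mean
        # fit at the largest achievable C in this fold (rank may fall short)
        fit = None
        for c_try in range(candidates[-1], 0, -1):
            try:
                fit = fit_pls(Xtr, Ytr, c_try, check_centered=False)
                break
            except DegenerateComponentError:
                continue
        if fit is None:
            raise DegenerateComponentError(0)
        for ci, c in enumerate(candidates):
            resid = Yte - fit.predict(Xte, n_components=min(c, fit.n_components))
            sse[ci] += float(np.sum(resid**2))
    mean_mse = sse / (n * Y.shape[1])
    # smallest C within 1e-12 of the minimum wins
    best = int(np.flatnonzero(mean_mse <= mean_mse.min() + 1e-12)[0])
    return CVSelection(
        candidates=candidates,
        mean_mse=mean_mse.tolist(),
        chosen=candidates[best],
        folds=folds,
        seed=seed,
    )
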