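"""Sparse group lasso feature selection.

Minimizes  (1/2n)‖y − Xβ‖² + λ[(1−α)·Σ_g √p_g ‖β_g‖₂ + α·‖β‖₁]
by proximal gradient descent: a gradient step on the squared loss followed
by elementwise soft-thresholding (the ℓ₁ part) and blockwise group
soft-thresholding (the ℓ₂-of-groups part).  α mixes lasso (α=1) with pure
group lasso (α=0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sgl_select", "sgl_fit"]


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def sgl_fit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    lam: float,
    alpha_mix: float = 0.5,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Proximal-gradient solve; returns the coefficient vector."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError("alpha_mix must lie in [0,1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    L = np.linalg.norm(Xc, 2) ** 2 / n  # Lipschitz constant of the gradient
    step = 1.0 / max(L, 1e-12)
    beta = np.zeros(p)
    group_ids = np.unique(groups)
    blocks = {g: np.flatnonzero(groups == g) for g in group_ids}
    for _ in range(max_iter):
        grad = Xc.T @ (Xc @ beta - yc) / n
        z = beta - step * grad
        z = _soft(z, step * lam * alpha_mix)
        new = np.empty_like(z)
        for g, idx in blocks.items():
            block = z[idx]
            t = step * lam * (1.0 - alpha_mix) * np.sqrt(len(idx))
            norm = np.linalg.norm(block)
            new[idx] = 0.0 if norm <= t else block * (1.0 - t / norm)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def sgl_select(
    X: pd.DataFrame,
    y: pd.Series,
    groups: dict[str, str] | pd.Series,
    lam: float,
    alpha_mix: float = 0.5,
) -> list[str]:
    """Features with nonzero sparse-group-lasso coefficients.

    ``groups`` maps every feature to a group label (e.g. an operon or
    pathway); a missing feature raises.
    """
    groups = pd.Series(groups)
    missing = [c for c in X.columns if c not in groups.index]
    if missing:
        raise ValueError(f"features without group labels: {missing[:5]}")
    gvec = groups.loc[X.columns].to_numpy()
    beta = sgl_fit(X.to_numpy(), y.to_numpy(), gvec, lam, alpha_mix)
    return [c for c, b in zip(X.columns, beta) if b != 0.0]
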