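"""MANOVA-style statistics and t-SNE ordination of image feature spaces.

Group separation in an n x p score matrix is measured by Wilks' lambda
(|E| / |E+H|) and Pillai's trace (tr H(H+E)^-1), where H and E are the
between- and within-group scatter matrices of a one-way layout.  Parametric
F approximations (Rao's for Wilks, the standard Pillai F) are reported with
their degrees of freedom, and nonparametric significance comes from a
label-permutation null distribution (with a within-group resampling
bootstrap available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

__all__ = ["ManovaResult", "TsneConfig", "manova_stats", "permutation_test",
           "tsne_ordination", "plot_feature_space"]


@dataclass
class ManovaResult:
    lambda_wilks: float
    pillai_V: float
    F_wilks: float
    F_pillai: float
    dof_wilks: tuple[int, int]
    dof_pillai: tuple[int, int]
    s: int
    m: float
    n_aux: float
    p_perm_wilks: float | None = None
    p_perm_pillai: float | None = None
    n_perm: int | None = None


def _scatter(scores: np.ndarray, codes: np.ndarray, g: int):
    """Between-group (H) and within-group (E) scatter matrices."""
    p = scores.shape[1]
    grand = scores.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for k in range(g):
        grp = scores[codes == k]
        mk = grp.mean(axis=0)
        dm = (mk - grand)[:, None]
        H += len(grp) * (dm @ dm.T)
        resid = grp - mk
        E += resid.T @ resid
    return H, E


def _wilks_pillai(H: np.ndarray, E: np.ndarray):
    T = H + E
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_e <= 0 or sign_t <= 0:
        warnings.warn("singular within-group scatter; using pseudo-inverse fallback")
        theta = np.linalg.eigvals(np.linalg.pinv(E) @ H).real
        theta = np.maximum(theta, 0.0)
        lam = float(np.prod(1.0 / (1.0 + theta)))
        V = float(np.sum(theta / (1.0 + theta)))
        return lam, V
    lam = float(np.exp(logdet_e - logdet_t))
    V = float(np.trace(np.linalg.solve(T, H)))
    return lam, V


def manova_stats(scores: np.ndarray, groups) -> ManovaResult:
    """One-way MANOVA statistics of an n x p score matrix.

    Rao's F approximation for Wilks' lambda uses

        t = sqrt((p^2 q^2 - 4) / (p^2 + q^2 - 5)),  q = g - 1,
        df1 = p q,  df2 = w t - (p q - 2)/2,  w = (N - g) + q - (p + q + 1)/2,

    and the Pillai F uses df1 = s(2m + s + 1), df2 = s(2n' + s + 1) with
    s = min(p, q), m = (|p - q| - 1)/2, n' = (N - g - p - 1)/2.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.ndim != 2:
        raise ValueError("scores must be an n x p matrix")
    if scores.shape[1] == 1 and scores.shape[0] == 1:
        raise ValueError("need more than one observation")
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    n, p = scores.shape
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= g:
        raise ValueError("need more observations than groups")

    H, E = _scatter(scores, codes, g)
    lam, V = _wilks_pillai(H, E)

    q = g - 1
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n_aux = (n - g - p - 1) / 2.0

    df1_w = p * q
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    w = (n - g) + q - (p + q + 1) / 2.0
    df2_w = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F_w = ((1 - lam_t) / lam_t) * (df2_w / df1_w) if lam_t > 0 else np.inf

    df1_p = s * (2 * m + s + 1)
    df2_p = s * (2 * n_aux + s + 1)
    F_p = (V / (s - V)) * (df2_p / df1_p) if V < s else np.inf

    return ManovaResult(
        lambda_wilks=lam, pillai_V=V, F_wilks=float(F_w), F_pillai=float(F_p),
        dof_wilks=(int(round(df1_w)), int(round(df2_w))),
        dof_pillai=(int(round(df1_p)), int(round(df2_p))),
        s=s, m=m, n_aux=n_aux,
    )


def permutation_test(scores: np.ndarray, groups, n_perm: int = 1000,
                     seed: int = 0, method: str = "permutation") -> ManovaResult:
    """Nonparametric significance of the group separation.

    ``method="permutation"`` permutes group labels; ``"bootstrap"``
    resamples group-centred residuals with replacement (a resampling null
    that preserves within-group dispersion).  p-values use the add-one
    estimator p = (1 + #{null >= observed extremity}) / (n_perm + 1), where
    smaller lambda and larger Pillai V are more extreme.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    g = len(labels)

    result = manova_stats(scores, groups)
    rng = np.random.default_rng(seed)

    centred = scores - np.stack(
        [scores[codes == k].mean(axis=0) for k in range(g)])[codes]
    hits_w = hits_p = 0
    for _ in range(n_perm):
        if method == "permutation":
            perm_codes = rng.permutation(codes)
            H, E = _scatter(scores, perm_codes, g)
        elif method == "bootstrap":
            resampled = centred[rng.integers(0, len(scores), len(scores))]
            H, E = _scatter(resampled, codes, g)
        else:
            raise ValueError(f"unknown resampling method {method!r}")
        lam_b, V_b = _wilks_pillai(H, E)
        hits_w += lam_b <= result.lambda_wilks
        hits_p += V_b >= result.pillai_V
    result.p_perm_wilks = (1 + hits_w) / (n_perm + 1)
    result.p_perm_pillai = (1 + hits_p) / (n_perm + 1)
    result.n_perm = n_perm
    return result


@dataclass(frozen=True)
class TsneConfig:
    perplexities: tuple[float, ...] = (5.0, 15.0, 30.0, 50.0)
    n_iters: tuple[int, ...] = (250, 1000)
    dims: int = 2
    seed: int = 0

    def validate(self, n: int) -> None:
        if self.dims not in (2, 3):
            raise ValueError("output dims must be 2 or 3")
        for perp in self.perplexities:
            if perp >= n:
                raise ValueError(f"perplexity {perp} must be < n ({n})")
            if n < 3 * perp + 1:
                warnings.warn(f"n={n} is small for perplexity {perp}")


def tsne_ordination(data: np.ndarray, config: TsneConfig = TsneConfig()
                    ) -> dict[tuple[float, int], np.ndarray]:
    """Seed-reproducible t-SNE embeddings over a (perplexity, iterations)
    grid, using the exact gradient (sample sizes here are a few hundred).

    ``data`` is an n x d matrix: flattened prepared images for the
    untrained ordination, or trained feature-space scores.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        data = data.reshape(len(data), -1)
    config.validate(len(data))
    out = {}
    for perp in config.perplexities:
        for it in config.n_iters:
            ts = TSNE(n_components=config.dims, perplexity=perp, max_iter=it,
                      method="exact", init="pca", random_state=config.seed)
            out[(perp, it)] = ts.fit_transform(data)
    return out


def plot_feature_space(scores: np.ndarray, groups, path, title: str = "") -> None:
    """Scatter plot of a 2-D/3-D score or ordination space coloured by
    group, written as PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if scores.shape[1] not in (2, 3):
        raise ValueError("plotting expects 2-D or 3-D scores")
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d" if scores.shape[1] == 3 else None)
    for g in np.unique(groups):
        pts = scores[groups == g]
        ax.scatter(*pts.T, s=12, label=str(g))
    ax.legend(fontsize=6, ncol=2, markerscale=1.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
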