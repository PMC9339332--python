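"""Founder allele effects along a chromosome: fixed coefficients and BLUPs.

Fixed effects regress the whitened trait on the 8 founder-dosage columns
plus non-intercept covariates; because the dosages sum to one, the
intercept is absorbed by the founder block, and the coefficients are on
the trait scale.  For display they are centered to sum to zero across the
8 founders.

BLUPs re-estimate the founder block as a random effect with a common
variance.  The variance ratio is estimated per marker by restricted
maximum likelihood (coarse log-grid then Brent refinement) and the
returned effects are the posterior means, which shrink toward zero the
coefficients of rarely observed alleles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .data_model import (
    AlleleEffects,
    CovariateMatrix,
    GenoProbs,
    KinshipLOCO,
    MarkerMap,
    NullFit,
)
from .scan import block_lod, complete_case_mask, fit_null

__all__ = ["estimate_effects_fixed", "estimate_effects_blup"]

RATIO_GRID = np.logspace(-6.0, 6.0, 25)


def _setup(
    genoprobs: GenoProbs,
    chrom: str,
    trait,
    covariates: CovariateMatrix,
    kinship: KinshipLOCO | None,
):
    if isinstance(trait, pd.Series):
        y_full = trait.reindex(genoprobs.individual_ids).to_numpy(dtype=float)
    else:
        y_full = np.asarray(trait, dtype=float)
    X_full = covariates.design(genoprobs.individual_ids)
    mask = complete_case_mask(y_full, X_full)
    y, X = y_full[mask], X_full[mask]
    K = None
    if kinship is not None:
        idx = np.flatnonzero(mask)
        K = kinship.for_chromosome(chrom)[np.ix_(idx, idx)]
    names = [c.name for c in covariates.columns]
    nf = fit_null(y, X, K, names=names)
    probs = genoprobs.probs[chrom][mask]
    # covariates without the intercept: the founder block carries it
    keep = [i for i, nm in enumerate(names) if nm != "intercept"]
    covar_noint = X[:, keep]
    return nf, probs, covar_noint


def _marker_frame(marker_map: MarkerMap, chrom: str) -> pd.DataFrame:
    return marker_map.for_chromosome(chrom)


def estimate_effects_fixed(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    chrom: str,
    trait,
    covariates: CovariateMatrix,
    kinship: KinshipLOCO | None = None,
) -> AlleleEffects:
    """Per-marker fixed founder-effect coefficients with the marker LOD."""
    nf, probs, covar_noint = _setup(genoprobs, chrom, trait, covariates, kinship)
    sub = _marker_frame(marker_map, chrom)
    n, _, n_markers = probs.shape
    n_par = 8 + covar_noint.shape[1]
    eff = np.full((n_markers, 8), np.nan)
    lods = np.full(n_markers, np.nan)
    cov_w = nf.whiten(covar_noint) if covar_noint.shape[1] else np.empty((n, 0))
    for m in range(n_markers):
        G = probs[:, :, m]
        lods[m] = block_lod(nf, G)
        if n <= n_par:
            continue  # effects not estimable; LOD still defined via RSS
        design = np.hstack([nf.whiten(G), cov_w])
        coef, _, _, _ = np.linalg.lstsq(design, nf.y_rot, rcond=None)
        eff[m] = coef[:8]
    return AlleleEffects(
        effects=pd.DataFrame(eff, index=sub["marker_id"], columns=list(genoprobs.founder_labels)),
        lod=pd.Series(lods, index=sub["marker_id"], name="lod"),
        chromosome=str(chrom),
        mode="fixed",
        positions=pd.Series(sub["pos_Mbp"].to_numpy(), index=sub["marker_id"], name="pos_Mbp"),
    )


# ---------------------------------------------------------------------------
# BLUP machinery


def _blup_neg_reml(log10_ratio: float, G: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Negative restricted log-likelihood of y ~ N(Xb, s2*(g*GG^T + I))."""
    g = 10.0**log10_ratio
    n, p = X.shape
    GtG = G.T @ G
    A = g * GtG + np.eye(G.shape[1])  # 8x8
    sign_a, logdet_a = np.linalg.slogdet(A)
    if sign_a <= 0:
        return np.inf
    Ainv_Gt = np.linalg.solve(A, G.T)

    def hinv(M: np.ndarray) -> np.ndarray:  # Woodbury: H^-1 M
        return M - g * (G @ (Ainv_Gt @ M))

    HiX = hinv(X)
    Hiy = hinv(y)
    XtHiX = X.T @ HiX
    sign_x, logdet_x = np.linalg.slogdet(XtHiX)
    if sign_x <= 0:
        return np.inf
    beta = np.linalg.solve(XtHiX, X.T @ Hiy)
    rss = float(y @ Hiy - beta @ (X.T @ Hiy))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_a + logdet_x
    )
    return -ll


def _blup_solve(ratio: float, G: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Posterior mean of the random founder effects at a fixed ratio."""
    if ratio <= 0:
        return np.zeros(G.shape[1])
    k = G.shape[1]
    A = G.T @ G + np.eye(k) / ratio
    Ainv_Gt = np.linalg.solve(A, G.T)

    def hinv(M: np.ndarray) -> np.ndarray:
        return M - G @ (Ainv_Gt @ M)

    XtHiX = X.T @ hinv(X)
    beta = np.linalg.solve(XtHiX, X.T @ hinv(y))
    resid = y - X @ beta
    return np.linalg.solve(G.T @ G + np.eye(k) / ratio, G.T @ resid)


def estimate_effects_blup(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    chrom: str,
    trait,
    covariates: CovariateMatrix,
    kinship: KinshipLOCO | None = None,
    ratio: float | None = None,
) -> AlleleEffects:
    """Per-marker BLUP founder effects (REML variance ratio unless forced).

    ``ratio`` pins the effect-variance to error-variance ratio: 0 gives
    complete shrinkage (all effects zero), a very large value recovers the
    fixed-effect solution.
    """
    nf, probs, covar_noint = _setup(genoprobs, chrom, trait, covariates, kinship)
    sub = _marker_frame(marker_map, chrom)
    n, _, n_markers = probs.shape
    # fixed part: intercept + covariates, all whitened
    ones_w = nf.whiten(np.ones((n, 1)))
    cov_w = nf.whiten(covar_noint) if covar_noint.shape[1] else np.empty((n, 0))
    X = np.hstack([ones_w, cov_w])
    y = nf.y_rot
    eff = np.full((n_markers, 8), np.nan)
    lods = np.full(n_markers, np.nan)
    for m in range(n_markers):
        Graw = probs[:, :, m]
        lods[m] = block_lod(nf, Graw)
        G = nf.whiten(Graw)
        # center the dosage columns so the random effects are deviations
        # from the intercept rather than absolute founder means
        Gc = G - ones_w @ np.linalg.lstsq(ones_w, G, rcond=None)[0]
        if ratio is not None:
            r = ratio
        else:
            grid = [(_blup_neg_reml(np.log10(g), Gc, X, y), g) for g in RATIO_GRID]
            best = min(grid)[1]
            lo, hi = np.log10(best) - 1.0, np.log10(best) + 1.0
            res = minimize_scalar(
                _blup_neg_reml,
                bounds=(lo, hi),
                args=(Gc, X, y),
                method="bounded",
                options={"xatol": 1e-6},
            )
            r = 10.0**float(res.x)
        eff[m] = _blup_solve(r, Gc, X, y)
    return AlleleEffects(
        effects=pd.DataFrame(eff, index=sub["marker_id"], columns=list(genoprobs.founder_labels)),
        lod=pd.Series(lods, index=sub["marker_id"], name="lod"),
        chromosome=str(chrom),
        mode="blup",
        positions=pd.Series(sub["pos_Mbp"].to_numpy(), index=sub["marker_id"], name="pos_Mbp"),
    )
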