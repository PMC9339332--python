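"""Mixed-model genome scans.

The trait model is ``y = QTL_m + covariates + g + e`` with a polygenic
random term ``g ~ N(0, sg2 * K)`` and ``e ~ N(0, se2 * I)``.  Writing
``h2 = sg2 / (sg2 + se2)`` and eigendecomposing ``K = V diag(lam) V^T``,
the rotated model has independent errors with variance weights
``h2 * lam + (1 - h2)``.  The null (no-QTL) h2 is estimated once per
(trait, chromosome) by restricted maximum likelihood and held fixed across
markers, so each marker fit is a single weighted least-squares solve and

    LOD_m = (n / 2) * log10(RSS_null / RSS_m)

in the whitened basis.  With no kinship the scan reduces to ordinary
least-squares (Haley-Knott style) regression on founder dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from scipy.optimize import minimize_scalar

from .data_model import (
    CovariateMatrix,
    GenoProbs,
    KinshipLOCO,
    LODScan,
    MarkerMap,
    NullFit,
)
from .kinship import decompose_kinship

__all__ = ["fit_null", "scan_additive", "scan_interactive", "block_lod"]

H2_MAX = 1.0 - 1e-6
LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# design utilities


def check_design_rank(X: np.ndarray, names: list[str] | None = None) -> None:
    """Raise if columns of X are collinear, naming the offending columns."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    bad = [int(piv[i]) for i in range(len(diag)) if diag[i] <= thresh]
    if diag.size < X.shape[1]:
        bad += [int(p) for p in piv[diag.size :]]
    if bad:
        if names:
            labels = [names[i] for i in sorted(bad)]
        else:
            labels = [f"column {i}" for i in sorted(bad)]
        raise ValueError(f"rank-deficient design: collinear columns {labels}")


def complete_case_mask(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.isfinite(np.asarray(y, dtype=float)) & np.all(
        np.isfinite(np.asarray(X, dtype=float)), axis=1
    )


def _as_design(covariates: CovariateMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, CovariateMatrix):
        return covariates.design(), [c.name for c in covariates.columns]
    X = np.asarray(covariates, dtype=float)
    return X, [f"column {i}" for i in range(X.shape[1])]


# ---------------------------------------------------------------------------
# null model (REML in the rotated basis)


def _reml_neg_loglik(h2: float, lam: np.ndarray, y_r: np.ndarray, x_r: np.ndarray) -> float:
    """Negative restricted log-likelihood (natural log) at a given h2."""
    n, p = x_r.shape
    w = h2 * lam + (1.0 - h2)
    sw = np.sqrt(w)
    yw = y_r / sw
    xw = x_r / sw[:, None]
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + np.sum(np.log(w))
        + logdet_xtx
    )
    return -ll


def fit_null(
    y: np.ndarray,
    covariates: CovariateMatrix | np.ndarray,
    K: np.ndarray | None = None,
    names: list[str] | None = None,
) -> NullFit:
    """REML fit of the no-QTL model; returns whitened working data.

    ``K = None`` forces ``h2 = 0`` (pure linear model).  The response and
    covariates must already be restricted to complete cases.
    """
    y = np.asarray(y, dtype=float)
    X, default_names = _as_design(covariates)
    names = names or default_names
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("response and covariates have different lengths")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("fit_null requires complete cases (no missing values)")
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} complete cases, got {n}")
    check_design_rank(X, names)

    if K is None:
        lam = np.ones(n)
        rotation = None
        y_r, x_r = y, X
        h2 = 0.0
    else:
        lam, V = decompose_kinship(K)
        rotation = V.T
        y_r = rotation @ y
        x_r = rotation @ X
        res = minimize_scalar(
            _reml_neg_loglik,
            bounds=(0.0, H2_MAX),
            args=(lam, y_r, x_r),
            method="bounded",
            options={"xatol": 1e-8},
        )
        h2 = float(res.x)
        # prefer the boundary when it is at least as good (Brent can stall
        # a hair inside the boundary on flat likelihoods)
        if _reml_neg_loglik(0.0, lam, y_r, x_r) <= res.fun:
            h2 = 0.0

    w = h2 * lam + (1.0 - h2)
    sw = np.sqrt(w)
    yw = y_r / sw
    xw = x_r / sw[:, None]
    beta, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ beta
    rss0 = float(resid @ resid)
    ll10 = -_reml_neg_loglik(h2, lam, y_r, x_r) / LN10 if K is not None else (
        -_reml_neg_loglik(0.0, lam, y_r, x_r) / LN10
    )
    return NullFit(
        h2=h2,
        log10_likelihood=ll10,
        y_rot=yw,
        x_rot=xw,
        rotation=rotation,
        weights=w,
        rss0=rss0,
        sigma2=rss0 / (n - p),
        n=n,
    )


# ---------------------------------------------------------------------------
# marker LODs


@dataclass
class _NullBasis:
    """Orthonormal basis of the whitened covariate space plus null residual."""

    Q0: np.ndarray
    y0: np.ndarray
    rss0: float
    n: int


def _null_basis(nf: NullFit) -> _NullBasis:
    Q0, _ = np.linalg.qr(nf.x_rot)
    y0 = nf.y_rot - Q0 @ (Q0.T @ nf.y_rot)
    return _NullBasis(Q0=Q0, y0=y0, rss0=float(y0 @ y0), n=nf.n)


def _lod_given_basis(basis: _NullBasis, block_w: np.ndarray) -> float:
    """LOD for one whitened design block via Frisch-Waugh residualization."""
    G = block_w - basis.Q0 @ (basis.Q0.T @ block_w)
    coef, _, _, _ = np.linalg.lstsq(G, basis.y0, rcond=None)
    resid = basis.y0 - G @ coef
    rss1 = max(float(resid @ resid), 1e-300)
    return (basis.n / 2.0) * np.log10(basis.rss0 / rss1)


def block_lod(nf: NullFit, block: np.ndarray) -> float:
    """LOD of an arbitrary locus design block against the fitted null."""
    return _lod_given_basis(_null_basis(nf), nf.whiten(block))


def _chromosome_lods(
    nf: NullFit,
    probs_chr: np.ndarray,
    factor: np.ndarray | None = None,
) -> np.ndarray:
    """LOD at every marker of one chromosome (additive or full-interactive)."""
    basis = _null_basis(nf)
    n_markers = probs_chr.shape[2]
    lods = np.empty(n_markers)
    for m in range(n_markers):
        block = probs_chr[:, :, m]
        if factor is not None:
            block = np.hstack([block, block * factor[:, None]])
        lods[m] = _lod_given_basis(basis, nf.whiten(block))
    return lods


# ---------------------------------------------------------------------------
# public scans


def _prepare_traits(trait, genoprobs: GenoProbs) -> pd.DataFrame:
    """Coerce trait input to a DataFrame aligned to genoprob individuals."""
    if isinstance(trait, pd.Series):
        frame = trait.to_frame(trait.name or "trait")
    elif isinstance(trait, pd.DataFrame):
        frame = trait
    else:
        arr = np.asarray(trait, dtype=float)
        frame = pd.DataFrame({"trait": arr}, index=genoprobs.individual_ids)
    frame = frame.reindex(genoprobs.individual_ids)
    return frame.astype(float)


def _scan_map(marker_map: MarkerMap, chroms: list[str]) -> pd.DataFrame:
    parts = [marker_map.for_chromosome(c) for c in chroms]
    return pd.concat(parts, ignore_index=True)


def scan_additive(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    trait,
    covariates: CovariateMatrix,
    kinship: KinshipLOCO | None = None,
) -> LODScan:
    """Additive genome scan: LOD per marker for each trait column.

    With ``kinship`` given, each chromosome uses its LOCO matrix (or the
    single overall matrix) and its own null REML fit; markers with zero
    dosage variance get LOD 0.
    """
    traits = _prepare_traits(trait, genoprobs)
    chroms = genoprobs.chromosomes
    scan_map = _scan_map(marker_map, chroms)
    out = {}
    for trait_id in traits.columns:
        y_full = traits[trait_id].to_numpy(dtype=float)
        X_full = covariates.design(genoprobs.individual_ids)
        mask = complete_case_mask(y_full, X_full)
        if mask.sum() < 3:
            raise ValueError(f"trait {trait_id!r} has fewer than 3 complete cases")
        y, X = y_full[mask], X_full[mask]
        names = [c.name for c in covariates.columns]
        pieces = []
        for chrom in chroms:
            K = _kinship_for(kinship, chrom, genoprobs, mask)
            nf = fit_null(y, X, K, names=names)
            pieces.append(_chromosome_lods(nf, genoprobs.probs[chrom][mask]))
        out[str(trait_id)] = np.concatenate(pieces)
    lod = pd.DataFrame(out, index=scan_map["marker_id"].tolist())
    return LODScan(lod=lod, marker_map=scan_map, kind="additive", used_kinship=kinship is not None)


def scan_interactive(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    trait,
    covariates: CovariateMatrix,
    factor: str,
    kinship: KinshipLOCO | None = None,
) -> tuple[LODScan, LODScan]:
    """Locus-by-factor interactive scan.

    Returns ``(full, delta)``: the full-model LOD against the null, and the
    interaction improvement ``full - additive`` at each marker.  The factor
    must be a covariate column (it enters the null additively) with at
    least two observed values.
    """
    names = [c.name for c in covariates.columns]
    if factor not in names:
        raise ValueError(f"factor {factor!r} is not a covariate column")
    traits = _prepare_traits(trait, genoprobs)
    chroms = genoprobs.chromosomes
    scan_map = _scan_map(marker_map, chroms)
    full_out, delta_out = {}, {}
    for trait_id in traits.columns:
        y_full = traits[trait_id].to_numpy(dtype=float)
        X_full = covariates.design(genoprobs.individual_ids)
        mask = complete_case_mask(y_full, X_full)
        y, X = y_full[mask], X_full[mask]
        fvec = covariates.values[factor].to_numpy(dtype=float)[mask]
        if np.allclose(fvec, fvec[0]):
            raise ValueError(f"factor {factor!r} is constant on the analysis subset")
        full_pieces, add_pieces = [], []
        for chrom in chroms:
            K = _kinship_for(kinship, chrom, genoprobs, mask)
            nf = fit_null(y, X, K, names=names)
            probs = genoprobs.probs[chrom][mask]
            add_pieces.append(_chromosome_lods(nf, probs))
            full_pieces.append(_chromosome_lods(nf, probs, factor=fvec))
        full = np.concatenate(full_pieces)
        add = np.concatenate(add_pieces)
        full_out[str(trait_id)] = full
        delta_out[str(trait_id)] = np.maximum(full - add, 0.0)
    idx = scan_map["marker_id"].tolist()
    full_scan = LODScan(
        lod=pd.DataFrame(full_out, index=idx),
        marker_map=scan_map,
        kind="full-interactive",
        used_kinship=kinship is not None,
    )
    delta_scan = LODScan(
        lod=pd.DataFrame(delta_out, index=idx),
        marker_map=scan_map,
        kind="interaction-delta",
        used_kinship=kinship is not None,
    )
    return full_scan, delta_scan


def _kinship_for(
    kinship: KinshipLOCO | None,
    chrom: str,
    genoprobs: GenoProbs,
    mask: np.ndarray,
) -> np.ndarray | None:
    if kinship is None:
        return None
    K = kinship.for_chromosome(chrom)
    if K.shape[0] != genoprobs.n_individuals:
        raise ValueError("kinship and genoprobs cover different individual sets")
    idx = np.flatnonzero(mask)
    return K[np.ix_(idx, idx)]


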