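"""LOD-drop mediation: retest a target QTL conditioning on candidate mediators.

For each candidate mediator the locus is retested with the mediator
appended to the covariates; kinship is excluded from both the null and the
alternative of every conditional fit so drops are comparable within a
scan.  Each mediator uses its own complete-case subset of (target,
mediator, covariates) with the null recomputed on that subset, and the
marginal (unconditioned) LOD on the same subset is reported alongside.
A mediator that renders the conditional fit degenerate (e.g. the target
itself) gets conditional LOD 0 with a degeneracy flag, never a spurious
finite value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (
    CovariateMatrix,
    GenoProbs,
    MarkerMap,
    MediationResult,
    TraitMatrix,
)
from .scan import block_lod, fit_null

__all__ = ["mediation_scan"]


def _column(values, ids: list[str]) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.reindex(ids).to_numpy(dtype=float)
    return np.asarray(values, dtype=float)


def mediation_scan(
    target,
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    chrom: str,
    marker_id: str,
    covariates: CovariateMatrix,
    mediators: TraitMatrix,
    target_id: str = "target",
) -> MediationResult:
    """Conditional LOD of the locus for every candidate mediator.

    ``chrom``/``marker_id`` locate the QTL under test in the marker map;
    mediator genomic positions are taken from the dataset annotations when
    present.
    """
    ids = genoprobs.individual_ids
    map_chr = marker_map.for_chromosome(chrom)
    hits = map_chr.index[map_chr["marker_id"] == marker_id]
    if len(hits) == 0:
        raise KeyError(f"marker {marker_id!r} not on chromosome {chrom}")
    midx = int(hits[0])
    G_full = genoprobs.probs[str(chrom)][:, :, midx]

    y_full = _column(target, ids)
    X_full = covariates.design(ids)
    med_values = mediators.values.reindex(ids)

    records = []
    for med_id in mediators.trait_ids:
        m_full = med_values[med_id].to_numpy(dtype=float)
        mask = (
            np.isfinite(y_full)
            & np.isfinite(m_full)
            & np.all(np.isfinite(X_full), axis=1)
        )
        n_used = int(mask.sum())
        y, X, mvec, G = y_full[mask], X_full[mask], m_full[mask], G_full[mask]

        ann = mediators.annotation_for(med_id)
        med_chrom = str(ann["chromosome"]) if ann is not None else None
        med_pos = float(ann["midpoint_Mbp"]) if ann is not None else np.nan

        # marginal LOD on the same subset, kinship excluded
        nf_marg = fit_null(y, X)
        marginal = block_lod(nf_marg, G)

        degenerate = False
        resid_med = mvec - X @ np.linalg.lstsq(X, mvec, rcond=None)[0]
        resid_y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        med_scale = float(np.abs(mvec).max())
        # mediator already in the covariate span: conditioning is a no-op
        if np.abs(resid_med).max() <= 1e-10 * max(med_scale, 1.0):
            records.append(
                _record(med_id, med_chrom, med_pos, marginal, marginal, n_used, False)
            )
            continue
        # perfect conditioning: mediator explains the target exactly
        if np.allclose(resid_med, resid_y, atol=1e-10) or _affine_equal(resid_med, resid_y):
            records.append(
                _record(med_id, med_chrom, med_pos, 0.0, marginal, n_used, True)
            )
            continue
        Xc = np.hstack([X, mvec[:, None]])
        try:
            nf_cond = fit_null(y, Xc)
        except ValueError:
            records.append(
                _record(med_id, med_chrom, med_pos, 0.0, marginal, n_used, True)
            )
            continue
        if nf_cond.rss0 <= 1e-12 * max(float(resid_y @ resid_y), 1e-300):
            degenerate = True
            conditional = 0.0
        else:
            conditional = max(block_lod(nf_cond, G), 0.0)
        records.append(
            _record(med_id, med_chrom, med_pos, conditional, marginal, n_used, degenerate)
        )

    frame = pd.DataFrame.from_records(
        records,
        columns=[
            "mediator_id",
            "chromosome",
            "midpoint_Mbp",
            "conditional_lod",
            "marginal_lod",
            "n_used",
            "degenerate",
        ],
    )
    return MediationResult(
        frame=frame, target_id=target_id, chromosome=str(chrom), marker_id=marker_id
    )


def _affine_equal(a: np.ndarray, b: np.ndarray, tol: float = 1e-12) -> bool:
    """True when b is (numerically) an affine transform of a."""
    sa, sb = float(np.std(a)), float(np.std(b))
    if sa == 0 or sb == 0:
        return sa == sb == 0
    r = float(np.corrcoef(a, b)[0, 1])
    return 1.0 - abs(r) < tol


def _record(med_id, med_chrom, med_pos, conditional, marginal, n_used, degenerate):
    return {
        "mediator_id": med_id,
        "chromosome": med_chrom,
        "midpoint_Mbp": med_pos,
        "conditional_lod": conditional,
        "marginal_lod": marginal,
        "n_used": n_used,
        "degenerate": degenerate,
    }
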