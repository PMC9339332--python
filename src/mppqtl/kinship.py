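"""Genetic relationship matrices from founder-haplotype probabilities.

The estimator is the average cross-product of founder-dosage probabilities:

    K_ij = (1/M) * sum_m sum_f p_imf * p_jmf

over the M included markers.  In LOCO ("leave one chromosome out") mode one
matrix is produced per chromosome, excluding that chromosome's markers, so
the random term of the scan model never absorbs the locus under test.  The
raw average is kept unnormalized: LOD scores are invariant to rescaling K
jointly with the variance-ratio reparameterization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import GenoProbs, KinshipLOCO

__all__ = ["compute_kinship", "decompose_kinship", "kinship_to_frame"]

EIG_CLIP = 1e-10


def _crossprod_sums(genoprobs: GenoProbs) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Per-chromosome sums over markers of P_m P_m^T and marker counts."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for chrom, arr in genoprobs.probs.items():
        # arr: (n, 8, m) -> sum over markers of the n x n founder cross-product
        n, _, m = arr.shape
        flat = arr.transpose(0, 2, 1).reshape(n, m * 8)  # (n, m*8)
        sums[chrom] = flat @ flat.T
        counts[chrom] = m
    return sums, counts


def compute_kinship(genoprobs: GenoProbs, mode: str = "loco") -> KinshipLOCO:
    """Estimate kinship matrices.

    Parameters
    ----------
    genoprobs
        Founder-haplotype probabilities for >= 1 chromosome and >= 2
        individuals.
    mode
        ``"overall"`` for one matrix over all markers, ``"loco"`` for one
        matrix per chromosome excluding that chromosome.
    """
    if mode not in ("overall", "loco"):
        raise ValueError(f"unknown kinship mode {mode!r}")
    if genoprobs.n_individuals < 2:
        raise ValueError("kinship requires at least 2 individuals")
    chroms = genoprobs.chromosomes
    if not chroms:
        raise ValueError("kinship requires at least 1 chromosome")
    if mode == "loco" and len(chroms) < 2:
        raise ValueError("LOCO kinship needs >= 2 chromosomes (no markers would remain)")

    sums, counts = _crossprod_sums(genoprobs)

    if mode == "overall":
        total = sum(sums[c] for c in chroms)
        matrices = {"overall": _symmetrize(total / sum(counts.values()))}
    else:
        # summed per left-out chromosome (not total-minus) so K_c is
        # bit-for-bit independent of chromosome c's probabilities
        matrices = {}
        for chrom in chroms:
            others = [c for c in chroms if c != chrom]
            part = sums[others[0]].copy()
            for c in others[1:]:
                part += sums[c]
            m = sum(counts[c] for c in others)
            matrices[chrom] = _symmetrize(part / m)
    return KinshipLOCO(matrices, list(genoprobs.individual_ids), mode=mode)


def _symmetrize(K: np.ndarray) -> np.ndarray:
    return (K + K.T) / 2.0


def decompose_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a symmetric kinship matrix, clipping eigenvalues at 0.

    Returns ``(eigenvalues, eigenvectors)`` with ``K ~= V diag(lam) V^T``.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"kinship must be square, got {K.shape}")
    if np.max(np.abs(K - K.T)) > 1e-8:
        raise ValueError("kinship matrix is not symmetric")
    lam, V = np.linalg.eigh(K)
    lam = np.where(lam < EIG_CLIP, np.maximum(lam, 0.0), lam)
    lam[lam < 0] = 0.0
    return lam, V


def kinship_to_frame(kin: KinshipLOCO, chrom: str) -> pd.DataFrame:
    """Dense labeled CSV-ready view of one kinship matrix."""
    K = kin.for_chromosome(chrom) if kin.mode == "loco" else kin.matrices["overall"]
    return pd.DataFrame(K, index=kin.individual_ids, columns=kin.individual_ids)
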