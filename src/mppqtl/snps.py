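"""Variant association via strain-distribution-pattern imputation.

A founder SNP's 8-bit SDP records which founders carry the alternate
allele (bit 0 = A/J ... bit 7 = WSB/EiJ).  Its allele dosage for each
individual is the summed founder-haplotype probability mass on the carrier
founders at the marker nearest the SNP (tie broken toward the lower
position).  The dosage column then replaces the 8-dosage founder block in
the scan model; SNPs sharing (nearest marker, sdp) are fit once and the
LOD broadcast to all members.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CovariateMatrix,
    FounderSNPTable,
    GenoProbs,
    KinshipLOCO,
    MarkerMap,
)
from .scan import block_lod, complete_case_mask, fit_null

__all__ = ["sdp_dosage", "sdp_mask", "scan_snps", "parse_region", "SnpAssocResult"]


def sdp_mask(sdp: int) -> np.ndarray:
    """Boolean carrier mask over the 8 founders for an SDP integer."""
    sdp = int(sdp)
    if not (1 <= sdp <= 254):
        raise ValueError(f"sdp {sdp} is non-segregating (must be 1..254)")
    return np.array([(sdp >> f) & 1 for f in range(8)], dtype=bool)


def nearest_marker_index(map_chr: pd.DataFrame, pos_Mbp: float) -> int:
    """Index of the marker nearest a position; ties go to the lower position."""
    pos = map_chr["pos_Mbp"].to_numpy(dtype=float)
    dist = np.abs(pos - pos_Mbp)
    return int(np.argmin(dist))  # argmin takes the first (= lower position) on ties


def sdp_dosage(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    chrom: str,
    pos_Mbp: float,
    sdp: int,
) -> np.ndarray:
    """Alternate-allele dosage in [0, 1] for every individual."""
    mask = sdp_mask(sdp)
    map_chr = marker_map.for_chromosome(chrom)
    m = nearest_marker_index(map_chr, pos_Mbp)
    probs = genoprobs.probs[str(chrom)][:, :, m]
    return probs[:, mask].sum(axis=1)


REGION_RE = re.compile(r"^([^:]+):([0-9.]+)-([0-9.]+)$")


def parse_region(region: str) -> tuple[str, float, float]:
    """Parse ``chr:lo-hi`` (Mbp) into components."""
    m = REGION_RE.match(region)
    if not m:
        raise ValueError(f"bad region {region!r}; expected chr:lo-hi in Mbp")
    chrom, lo, hi = m.group(1), float(m.group(2)), float(m.group(3))
    if hi < lo:
        raise ValueError(f"empty region {region!r} (hi < lo)")
    return chrom, lo, hi


@dataclass
class SnpAssocResult:
    """SNP association table plus bookkeeping of deduplicated fits."""

    frame: pd.DataFrame  # snp_id, chr, pos_Mbp, sdp, csq, lod
    n_fits: int = 0
    region: str = ""
    meta: dict = field(default_factory=dict)


def scan_snps(
    genoprobs: GenoProbs,
    marker_map: MarkerMap,
    snp_table: FounderSNPTable,
    trait,
    covariates: CovariateMatrix,
    kinship: KinshipLOCO | None = None,
    region: str = "",
    intcovar: str | None = None,
) -> SnpAssocResult:
    """Association scan of all founder SNPs in ``region`` (``chr:lo-hi``).

    Each unique (nearest marker, sdp) dosage pattern is fit once; an empty
    region yields an empty table.
    """
    chrom, lo, hi = parse_region(region)
    snps = snp_table.in_region(chrom, lo, hi)
    if chrom not in genoprobs.probs:
        raise ValueError(f"chromosome {chrom!r} absent from genotype probabilities")

    if isinstance(trait, pd.Series):
        y_full = trait.reindex(genoprobs.individual_ids).to_numpy(dtype=float)
    else:
        y_full = np.asarray(trait, dtype=float)
    X_full = covariates.design(genoprobs.individual_ids)
    cmask = complete_case_mask(y_full, X_full)
    y, X = y_full[cmask], X_full[cmask]
    names = [c.name for c in covariates.columns]
    K = None
    if kinship is not None:
        idx = np.flatnonzero(cmask)
        K = kinship.for_chromosome(chrom)[np.ix_(idx, idx)]
    nf = fit_null(y, X, K, names=names)

    fvec = None
    if intcovar is not None:
        if intcovar not in names:
            raise ValueError(f"interactive covariate {intcovar!r} is not a covariate column")
        fvec = covariates.values[intcovar].to_numpy(dtype=float)[cmask]

    map_chr = marker_map.for_chromosome(chrom)
    probs = genoprobs.probs[chrom][cmask]

    lods = np.full(len(snps), np.nan)
    cache: dict[tuple[int, int], float] = {}
    n_fits = 0
    for i, row in snps.iterrows():
        midx = nearest_marker_index(map_chr, float(row["pos_Mbp"]))
        sdp = int(row["sdp"])
        key = (midx, sdp)
        if key not in cache:
            dosage = probs[:, sdp_mask(sdp), midx].sum(axis=1)
            block = dosage[:, None]
            if fvec is not None:
                block = np.hstack([block, block * fvec[:, None]])
            cache[key] = block_lod(nf, block)
            n_fits += 1
        lods[i] = cache[key]

    out = snps[["snp_id", "chr", "pos_Mbp", "sdp", "csq"]].copy()
    out["lod"] = lods
    return SnpAssocResult(
        frame=out,
        n_fits=n_fits,
        region=region,
        meta={"h2": nf.h2, "n": nf.n, "intcovar": intcovar},
    )
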