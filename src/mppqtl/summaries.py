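"""Result summaries: peak calling, eQTL maps, hotspots, correlations, profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import CovariateMatrix, LODScan, TraitMatrix

__all__ = [
    "find_peaks",
    "transcriptome_map",
    "hotspot_counts",
    "correlate",
    "profile",
    "DEFAULT_LOD_THRESHOLD",
    "DEFAULT_LOCAL_WINDOW_MBP",
]

#: Conventional screening threshold for -omic peak tables (user-adjustable).
DEFAULT_LOD_THRESHOLD = 7.0

#: Same-chromosome distance (Mbp) within which an -omic QTL is "local".
DEFAULT_LOCAL_WINDOW_MBP = 10.0

SUPPORT_DROP = 1.5

PEAK_COLUMNS = [
    "trait_id",
    "chromosome",
    "marker_id",
    "pos_Mbp",
    "lod",
    "ci_lo_Mbp",
    "ci_hi_Mbp",
]


def _support_interval(
    lods: np.ndarray, pos: np.ndarray, peak_idx: int
) -> tuple[float, float]:
    """Contiguous region around the peak within a LOD drop of 1.5."""
    cutoff = lods[peak_idx] - SUPPORT_DROP
    lo = peak_idx
    while lo > 0 and lods[lo - 1] >= cutoff:
        lo -= 1
    hi = peak_idx
    while hi < len(lods) - 1 and lods[hi + 1] >= cutoff:
        hi += 1
    return float(pos[lo]), float(pos[hi])


def _chromosome_peaks(
    lods: np.ndarray, threshold: float, peakdrop: float | None
) -> list[int]:
    """Indices of peaks on one chromosome's LOD vector."""
    top = int(np.argmax(lods))
    if lods[top] < threshold:
        return []
    if peakdrop is None:
        return [top]
    # local maxima above threshold, then merge pairs whose separating valley
    # does not drop >= peakdrop below the smaller peak
    candidates = [
        i
        for i in range(len(lods))
        if lods[i] >= threshold
        and (i == 0 or lods[i] >= lods[i - 1])
        and (i == len(lods) - 1 or lods[i] > lods[i + 1])
    ]
    merged = True
    while merged and len(candidates) > 1:
        merged = False
        for j in range(len(candidates) - 1):
            a, b = candidates[j], candidates[j + 1]
            valley = lods[a : b + 1].min()
            if valley > min(lods[a], lods[b]) - peakdrop:
                keep = a if lods[a] >= lods[b] else b
                candidates = candidates[:j] + [keep] + candidates[j + 2 :]
                merged = True
                break
    return candidates


def find_peaks(
    scan: LODScan, threshold: float, peakdrop: float | None = None
) -> pd.DataFrame:
    """Call QTL peaks per trait per chromosome above a LOD threshold.

    Without ``peakdrop`` at most one peak (the maximum) is reported per
    chromosome; with it, additional local maxima separated by a valley of
    at least ``peakdrop`` are also reported.  Support intervals span the
    contiguous region within a 1.5-LOD drop of each peak.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    records = []
    mm = scan.marker_map
    for trait_id in scan.trait_ids:
        lod_all = scan.lod[trait_id].to_numpy(dtype=float)
        for chrom, sub in mm.groupby("chromosome", sort=False):
            idx = sub.index.to_numpy()
            lods = lod_all[idx]
            pos = sub["pos_Mbp"].to_numpy(dtype=float)
            for p in _chromosome_peaks(lods, threshold, peakdrop):
                lo, hi = _support_interval(lods, pos, p)
                records.append(
                    {
                        "trait_id": trait_id,
                        "chromosome": str(chrom),
                        "marker_id": sub["marker_id"].iloc[p],
                        "pos_Mbp": float(pos[p]),
                        "lod": float(lods[p]),
                        "ci_lo_Mbp": lo,
                        "ci_hi_Mbp": hi,
                    }
                )
    return pd.DataFrame.from_records(records, columns=PEAK_COLUMNS)


def transcriptome_map(
    peaks: pd.DataFrame,
    annotations: pd.DataFrame,
    window_Mbp: float = DEFAULT_LOCAL_WINDOW_MBP,
) -> tuple[pd.DataFrame, int]:
    """Label peaks local/distal relative to the encoding gene position.

    A peak is *local* when it sits on the gene's chromosome within
    ``window_Mbp`` of the gene midpoint, *distal* otherwise.  Returns the
    labeled table and the count of peaks skipped for lack of annotation.
    """
    ann = annotations.set_index("trait_id")
    records = []
    skipped = 0
    for _, row in peaks.iterrows():
        if row["trait_id"] not in ann.index:
            skipped += 1
            continue
        a = ann.loc[row["trait_id"]]
        gene_chrom = str(a["chromosome"])
        gene_pos = float(a["midpoint_Mbp"])
        local = (
            str(row["chromosome"]) == gene_chrom
            and abs(float(row["pos_Mbp"]) - gene_pos) <= window_Mbp
        )
        rec = dict(row)
        rec.update(
            gene_chromosome=gene_chrom,
            gene_midpoint_Mbp=gene_pos,
            kind="local" if local else "distal",
        )
        records.append(rec)
    cols = list(peaks.columns) + ["gene_chromosome", "gene_midpoint_Mbp", "kind"]
    return pd.DataFrame.from_records(records, columns=cols), skipped


def hotspot_counts(tmap: pd.DataFrame, window_Mbp: float) -> pd.DataFrame:
    """Distal-peak counts in half-open [lo, hi) bins from each chromosome start."""
    if window_Mbp <= 0:
        raise ValueError("window must be positive")
    distal = tmap[tmap["kind"] == "distal"] if "kind" in tmap.columns else tmap
    records = []
    for chrom, sub in distal.groupby("chromosome", sort=False):
        pos = sub["pos_Mbp"].to_numpy(dtype=float)
        if len(pos) == 0:
            continue
        n_bins = int(np.floor(pos.max() / window_Mbp)) + 1
        counts = np.zeros(n_bins, dtype=int)
        for p in pos:
            counts[int(np.floor(p / window_Mbp))] += 1
        for b in range(n_bins):
            records.append(
                {
                    "chromosome": str(chrom),
                    "bin_lo_Mbp": b * window_Mbp,
                    "bin_hi_Mbp": (b + 1) * window_Mbp,
                    "n_distal": int(counts[b]),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["chromosome", "bin_lo_Mbp", "bin_hi_Mbp", "n_distal"]
    )


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def correlate(
    focus,
    dataset: TraitMatrix,
    adjust: CovariateMatrix | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Covariate-adjusted Pearson correlation of a focus trait with a dataset.

    Both members of each pair are residualized on the adjustment design
    before correlating; pairs with fewer than ``min_n`` shared complete
    cases are dropped.  Sorted by \\|r\\| descending.
    """
    ids = dataset.individual_ids
    if isinstance(focus, pd.Series):
        yf = focus.reindex(ids).to_numpy(dtype=float)
    else:
        yf = np.asarray(focus, dtype=float)
    X = (
        adjust.design(ids)
        if adjust is not None
        else np.ones((len(ids), 1))
    )
    records = []
    for trait_id in dataset.trait_ids:
        other = dataset.values[trait_id].to_numpy(dtype=float)
        mask = np.isfinite(yf) & np.isfinite(other) & np.all(np.isfinite(X), axis=1)
        n = int(mask.sum())
        if n < min_n:
            continue
        a = _residualize(yf[mask], X[mask])
        b = _residualize(other[mask], X[mask])
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        records.append({"trait_id": trait_id, "r": r, "n": n})
    frame = pd.DataFrame.from_records(records, columns=["trait_id", "r", "n"])
    return frame.reindex(frame["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def profile(trait: pd.Series, factors: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group a trait by factor level combinations with summary statistics.

    With no factors, the whole sample forms a single group.  Missing trait
    values are excluded from group counts.
    """
    values = trait.astype(float)
    if factors is None or factors.shape[1] == 0:
        groups = {("all",): values}
        level_names = ["group"]
    else:
        level_names = list(factors.columns)
        groups = {}
        for key, sub in values.groupby([factors[c] for c in level_names]):
            groups[key if isinstance(key, tuple) else (key,)] = sub
    records = []
    for key, sub in groups.items():
        clean = sub.dropna()
        rec = {name: lvl for name, lvl in zip(level_names, key)}
        rec.update(
            n=int(clean.size),
            median=float(np.median(clean)) if clean.size else np.nan,
            q1=float(np.percentile(clean, 25)) if clean.size else np.nan,
            q3=float(np.percentile(clean, 75)) if clean.size else np.nan,
            values=clean.tolist(),
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)
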