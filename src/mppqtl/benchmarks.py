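"""Self-contained verification benchmarks for the statistical engine.

Each function recomputes one desk-scale check from scratch — simulating
its own inputs from a seed, running the package under test, and measuring
the result — and returns plain numbers.  The brute-force regression oracle
used for equivalence checks is deliberately independent of the scan
engine's QR/residualization path (explicit normal equations via
pseudo-inverse).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (
    CovariateColumn,
    CovariateMatrix,
    FounderSNPTable,
    GenoProbs,
    MarkerMap,
    TraitMatrix,
)
from .effects import estimate_effects_blup, estimate_effects_fixed
from .kinship import compute_kinship
from .mediation import mediation_scan
from .scan import block_lod, fit_null, scan_additive
from .simulate import (
    ChromSpec,
    MediationLink,
    QTLSpec,
    SimConfig,
    TraitSpec,
    simulate_genome,
    simulate_study,
)
from .snps import scan_snps, sdp_mask
from .summaries import find_peaks

__all__ = [
    "ols_oracle_equivalence",
    "qtl_position_recovery",
    "blup_shrinkage",
    "mediation_recovery",
    "sdp_machinery",
    "invariance_suite",
]


def _brute_force_lod(y: np.ndarray, X: np.ndarray, G: np.ndarray) -> float:
    n = len(y)

    def rss(D: np.ndarray) -> float:
        beta = np.linalg.pinv(D.T @ D) @ (D.T @ y)
        r = y - D @ beta
        return float(r @ r)

    return (n / 2.0) * np.log10(rss(X) / rss(np.hstack([X, G])))


def _random_probs(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    raw = rng.gamma(0.5, size=(n, 8, m))
    return raw / raw.sum(axis=1, keepdims=True)


def _map_for(chrom: str, m: int, length: float = 100.0) -> MarkerMap:
    pos = np.linspace(0.0, length, m + 1)[1:]
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"c{chrom}_m{i + 1:04d}" for i in range(m)],
                "chromosome": chrom,
                "pos_cM": pos * 0.5,
                "pos_Mbp": pos,
            }
        )
    )


# ---------------------------------------------------------------------------
# 1. OLS-oracle equivalence


def ols_oracle_equivalence(seed: int, n_instances: int = 100) -> float:
    """Max |scan LOD - brute-force OLS LOD| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(15, 51))
        m = int(rng.integers(1, 21))
        probs = _random_probs(rng, n, m)
        ids = [f"i{k}" for k in range(n)]
        gp = GenoProbs({"1": probs}, ids)
        y = pd.Series(rng.standard_normal(n), index=ids)
        covar = rng.standard_normal(n)
        cov = CovariateMatrix(
            pd.DataFrame({"intercept": 1.0, "x": covar}, index=ids),
            [CovariateColumn("intercept"), CovariateColumn("x")],
        )
        scan = scan_additive(gp, _map_for("1", m), y, cov, kinship=None)
        X = np.column_stack([np.ones(n), covar])
        for j in range(m):
            oracle = _brute_force_lod(y.to_numpy(), X, probs[:, :, j])
            worst = max(worst, abs(float(scan.lod["trait"].iloc[j]) - oracle))
    return worst


# ---------------------------------------------------------------------------
# 2. planted-QTL position recovery


def qtl_position_recovery(
    seed: int,
    n_replicates: int = 50,
    n: int = 200,
    n_markers: int = 101,
    planted_index: int = 50,
    var_frac: float = 0.4,
    tolerance_markers: int = 5,
) -> float:
    """Fraction of replicates whose genome-wide max LOD lands near the truth."""
    hits = 0
    for rep in range(n_replicates):
        cfg = SimConfig(
            seed=seed + 1000 * (rep + 1),
            n_individuals=n,
            chromosomes=(ChromSpec("1", n_markers=n_markers),),
            traits=(
                TraitSpec(
                    "t",
                    qtls=(
                        QTLSpec(
                            "1", planted_index, var_frac,
                            effects=(0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0),
                        ),
                    ),
                ),
            ),
        )
        study, _ = simulate_study(cfg)
        scan = scan_additive(
            study.genoprobs, study.marker_map, study.traits["sim"].trait("t"),
            study.covariates, kinship=None,
        )
        peak_marker, _ = scan.max_marker("t")
        idx = int(scan.marker_map.index[scan.marker_map["marker_id"] == peak_marker][0])
        if abs(idx - planted_index) <= tolerance_markers:
            hits += 1
    return hits / n_replicates


# ---------------------------------------------------------------------------
# 3. BLUP shrinkage


def blup_shrinkage(seed: int, n_instances: int = 50) -> dict[str, float]:
    """Shrinkage violations and the flat-prior deviation from fixed effects."""
    rng = np.random.default_rng(seed)
    violations = 0
    flat_dev = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(40, 80))
        probs = _random_probs(rng, n, 2)
        ids = [f"i{k}" for k in range(n)]
        gp = GenoProbs({"1": probs}, ids)
        mm = _map_for("1", 2)
        y = pd.Series(rng.standard_normal(n), index=ids)
        cov = CovariateMatrix.intercept_only(ids)
        fixed = estimate_effects_fixed(gp, mm, "1", y, cov).centered().to_numpy()
        blup = estimate_effects_blup(gp, mm, "1", y, cov).centered().to_numpy()
        flat = estimate_effects_blup(gp, mm, "1", y, cov, ratio=1e6).centered().to_numpy()
        ss_f = np.sum(fixed**2, axis=1)
        ss_b = np.sum(blup**2, axis=1)
        violations += int(np.sum(ss_b > ss_f + 1e-8))
        flat_dev = max(flat_dev, float(np.abs(flat - fixed).max()))
    return {"violations": float(violations), "flat_prior_max_dev": flat_dev}


# ---------------------------------------------------------------------------
# 4. mediation recovery


def mediation_recovery(
    seed: int, n_replicates: int = 25, n: int = 300, n_mediators: int = 100
) -> dict[str, float]:
    """Planted-chain mediation: min-rank rate and noise-mediator stability."""
    hits = 0
    worst_noise_shift = 0.0
    for rep in range(n_replicates):
        rep_seed = seed + 313 * (rep + 1)
        cfg = SimConfig(
            seed=rep_seed,
            n_individuals=n,
            chromosomes=(ChromSpec("1", n_markers=41), ChromSpec("2", n_markers=41)),
            traits=(
                TraitSpec("med", qtls=(QTLSpec("1", 20, 0.6, sdp=0b01000100),)),
            ),
            mediation=(MediationLink("med", "target", beta_frac=0.6),),
        )
        study, _ = simulate_study(cfg)
        rng = np.random.default_rng(rep_seed + 7)
        tm = study.traits["sim"]
        noise = pd.DataFrame(
            {f"noise{k}": rng.standard_normal(n) for k in range(n_mediators - 1)},
            index=tm.values.index,
        )
        mediators = TraitMatrix(
            pd.concat([tm.values[["med"]], noise], axis=1), name="medset"
        )
        marker = study.marker_map.for_chromosome("1")["marker_id"].iloc[20]
        result = mediation_scan(
            tm.trait("target"), study.genoprobs, study.marker_map, "1", marker,
            study.covariates, mediators,
        )
        frame = result.frame.set_index("mediator_id")
        if frame["conditional_lod"].idxmin() == "med":
            hits += 1
        shift = float(
            (frame["conditional_lod"] - frame["marginal_lod"]).loc["noise0"].__abs__()
        )
        worst_noise_shift = max(worst_noise_shift, shift)
    return {"min_rank_rate": hits / n_replicates, "max_noise_shift": worst_noise_shift}


# ---------------------------------------------------------------------------
# 5. SDP machinery


def sdp_machinery(seed: int) -> dict[str, float]:
    """Complement symmetry, dedup contract, and planted-SDP recovery."""
    cfg = SimConfig(
        seed=seed, n_individuals=150, chromosomes=(ChromSpec("1", n_markers=21),)
    )
    gp, mm = simulate_genome(cfg)
    rng = np.random.default_rng(seed + 1)
    ids = gp.individual_ids
    cov = CovariateMatrix.intercept_only(ids)
    mk = float(mm.for_chromosome("1")["pos_Mbp"].iloc[10])

    # complement symmetry
    y = pd.Series(rng.standard_normal(150), index=ids)
    sdp = 0b00011011
    rows = [
        ("s", "1", mk, "A", "G", sdp, ""),
        ("sc", "1", mk, "G", "A", 255 - sdp, ""),
    ]
    table = FounderSNPTable(
        pd.DataFrame(rows, columns=["snp_id", "chr", "pos_Mbp", "ref", "alt", "sdp", "csq"])
    )
    res = scan_snps(gp, mm, table, y, cov, region=f"1:{mk - 2:.2f}-{mk + 2:.2f}")
    complement_dev = float(abs(res.frame["lod"].iloc[0] - res.frame["lod"].iloc[1]))

    # dedup contract: 3 SNPs, 2 unique (marker, sdp) patterns
    rows = [
        ("d1", "1", mk - 0.2, "A", "G", 37, ""),
        ("d2", "1", mk + 0.2, "A", "G", 37, ""),
        ("d3", "1", mk + 0.1, "A", "G", 41, ""),
    ]
    table = FounderSNPTable(
        pd.DataFrame(rows, columns=["snp_id", "chr", "pos_Mbp", "ref", "alt", "sdp", "csq"])
    )
    res = scan_snps(gp, mm, table, y, cov, region=f"1:{mk - 2:.2f}-{mk + 2:.2f}")
    dedup_ok = res.n_fits == 2 and res.frame["lod"].iloc[0] == res.frame["lod"].iloc[1]

    # planted-SDP recovery among decoys
    planted = 0b00100010
    d = gp.probs["1"][:, sdp_mask(planted), 10].sum(axis=1)
    y2 = pd.Series(2.0 * d + 0.5 * rng.standard_normal(150), index=ids)
    rows = [("true", "1", mk, "A", "G", planted, "")]
    rows += [
        (f"x{i}", "1", float(p), "A", "G", int(s), "")
        for i, (p, s) in enumerate(
            zip(rng.uniform(mk - 15, mk + 15, size=30), rng.integers(1, 255, size=30))
        )
        if int(s) != planted
    ]
    table = FounderSNPTable(
        pd.DataFrame(rows, columns=["snp_id", "chr", "pos_Mbp", "ref", "alt", "sdp", "csq"])
    )
    res = scan_snps(gp, mm, table, y2, cov, region=f"1:{mk - 20:.2f}-{mk + 20:.2f}")
    top_sdp = int(res.frame.loc[res.frame["lod"].idxmax(), "sdp"])
    return {
        "complement_dev": complement_dev,
        "dedup_ok": float(dedup_ok),
        "planted_recovered": float(top_sdp == planted),
    }


# ---------------------------------------------------------------------------
# 6. invariance suite


def invariance_suite(seed: int) -> dict[str, float]:
    """Affine, founder-drop, LOCO-independence and peak-monotonicity checks."""
    rng = np.random.default_rng(seed)
    n, m = 60, 10
    probs = _random_probs(rng, n, m)
    ids = [f"i{k}" for k in range(n)]
    gp = GenoProbs({"1": probs}, ids)
    mm = _map_for("1", m)
    cov = CovariateMatrix.intercept_only(ids)
    y = pd.Series(rng.standard_normal(n), index=ids)

    base = scan_additive(gp, mm, y, cov).lod.to_numpy()
    affine = scan_additive(gp, mm, -3.0 * y + 11.0, cov).lod.to_numpy()
    affine_dev = float(np.abs(base - affine).max())

    nf = fit_null(y.to_numpy(), np.ones((n, 1)))
    G = probs[:, :, 4]
    full = block_lod(nf, G)
    drop_dev = max(
        abs(block_lod(nf, G[:, [f for f in range(8) if f != d]]) - full) for d in range(8)
    )

    # LOCO independence
    probs2 = {"1": _random_probs(rng, 20, 6), "2": _random_probs(rng, 20, 6)}
    ids2 = [f"j{k}" for k in range(20)]
    k1 = compute_kinship(GenoProbs(probs2, ids2), "loco").matrices["1"]
    probs2b = dict(probs2)
    probs2b["1"] = _random_probs(rng, 20, 6)
    k1b = compute_kinship(GenoProbs(probs2b, ids2), "loco").matrices["1"]
    loco_ok = np.array_equal(k1, k1b)

    # threshold-monotone peak calling
    curve = np.abs(rng.normal(scale=4.0, size=120))
    from .data_model import LODScan

    mm2 = _map_for("1", 120)
    scan = LODScan(
        lod=pd.DataFrame({"t": curve}, index=mm2.frame["marker_id"].tolist()),
        marker_map=mm2.frame,
        kind="additive",
    )
    counts = [len(find_peaks(scan, threshold=t, peakdrop=1.5)) for t in (1, 2, 4, 6, 8)]
    monotone_ok = all(a >= b for a, b in zip(counts, counts[1:]))

    return {
        "affine_dev": affine_dev,
        "founder_drop_dev": float(drop_dev),
        "loco_independent": float(loco_ok),
        "peaks_threshold_monotone": float(monotone_ok),
    }
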