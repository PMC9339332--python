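"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mppqtl.data_model import (
    CovariateColumn,
    CovariateMatrix,
    GenoProbs,
    MarkerMap,
)
from mppqtl.simulate import ChromSpec, QTLSpec, SimConfig, TraitSpec, simulate_study


def ols_lod_oracle(y: np.ndarray, X: np.ndarray, G: np.ndarray) -> float:
    """Brute-force LOD via explicit normal equations (pseudo-inverse).

    Deliberately independent of the scan engine's QR/residualization path.
    """
    y = np.asarray(y, float)
    n = len(y)

    def rss(D: np.ndarray) -> float:
        beta = np.linalg.pinv(D.T @ D) @ (D.T @ y)
        r = y - D @ beta
        return float(r @ r)

    return (n / 2.0) * np.log10(rss(X) / rss(np.hstack([X, G])))


def random_probs(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """A valid (n, 8, m) probability array with rows summing to one."""
    raw = rng.gamma(0.5, size=(n, 8, m))
    return raw / raw.sum(axis=1, keepdims=True)


def certain_probs(haplo_pairs: np.ndarray, m: int) -> np.ndarray:
    """Certain founder-dosage calls from (n, 2) founder assignments."""
    n = haplo_pairs.shape[0]
    probs = np.zeros((n, 8, m))
    for i, (a, b) in enumerate(haplo_pairs):
        probs[i, a, :] += 0.5
        probs[i, b, :] += 0.5
    return probs


def make_map(chrom_markers: dict[str, int], length_Mbp: float = 100.0) -> MarkerMap:
    rows = []
    for chrom, m in chrom_markers.items():
        pos = np.linspace(0.0, length_Mbp, m + 1)[1:]
        for i in range(m):
            rows.append(
                {
                    "marker_id": f"c{chrom}_m{i + 1:04d}",
                    "chromosome": chrom,
                    "pos_cM": float(pos[i] * 0.5),
                    "pos_Mbp": float(pos[i]),
                }
            )
    return MarkerMap(pd.DataFrame(rows))


def intercept_covariates(ids: list[str]) -> CovariateMatrix:
    return CovariateMatrix.intercept_only(ids)


def sex_covariates(ids: list[str], sex: np.ndarray) -> CovariateMatrix:
    return CovariateMatrix(
        pd.DataFrame({"intercept": 1.0, "sex": sex.astype(float)}, index=ids),
        [
            CovariateColumn("intercept", "numeric", False),
            CovariateColumn("sex", "factor", True),
        ],
    )


@pytest.fixture(scope="session")
def small_study():
    """A 120-individual, 2-chromosome study with one planted biallelic QTL."""
    cfg = SimConfig(
        seed=11,
        n_individuals=120,
        chromosomes=(ChromSpec("1", n_markers=40), ChromSpec("2", n_markers=40)),
        traits=(
            TraitSpec("t_qtl", qtls=(QTLSpec("1", 20, 0.4, sdp=0b00100010),), h2=0.2),
            TraitSpec("t_null"),
        ),
        snp_density_per_Mbp=0.5,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
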