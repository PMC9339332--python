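"""Null model fitting and genome scans against independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mppqtl.data_model import GenoProbs, KinshipLOCO
from mppqtl.kinship import compute_kinship
from mppqtl.scan import block_lod, fit_null, scan_additive, scan_interactive
from mppqtl.simulate import ChromSpec, QTLSpec, SimConfig, TraitSpec, simulate_genome, simulate_study

from conftest import intercept_covariates, make_map, ols_lod_oracle, random_probs, sex_covariates


def _geno(seed, n=60, markers=(15, 15)):
    cfg = SimConfig(
        seed=seed,
        n_individuals=n,
        chromosomes=tuple(
            ChromSpec(str(i + 1), n_markers=m) for i, m in enumerate(markers)
        ),
    )
    return simulate_genome(cfg)


class TestFitNull:
    def test_h2_zero_trait_estimated_low(self):
        gp, _ = _geno(21, n=500, markers=(40, 40))
        K = compute_kinship(gp, "overall").matrices["overall"]
        rng = np.random.default_rng(22)
        y = rng.standard_normal(500)
        nf = fit_null(y, np.ones((500, 1)), K)
        assert nf.h2 < 0.15

    def test_identity_kinship_matches_no_kinship(self, rng):
        n = 40
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        G = random_probs(rng, n, 1)[:, :, 0]
        nf_none = fit_null(y, X, None)
        nf_id = fit_null(y, X, np.eye(n))
        assert block_lod(nf_none, G) == pytest.approx(block_lod(nf_id, G), abs=1e-8)

    def test_h2_recovery(self):
        n = 400
        gp, _ = _geno(31, n=n, markers=(30, 30))
        K = compute_kinship(gp, "overall").matrices["overall"]
        lam, V = np.linalg.eigh(K)
        rng = np.random.default_rng(33)
        h2_true = 0.5
        cov = h2_true * K + (1 - h2_true) * np.eye(n)
        y = np.linalg.cholesky(cov) @ rng.standard_normal(n)
        nf = fit_null(y, np.ones((n, 1)), K)
        assert nf.h2 == pytest.approx(h2_true, abs=0.15)

    def test_rank_deficient_covariates_named(self, rng):
        n = 30
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2.0 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_null(rng.standard_normal(n), X, None, names=["intercept", "a", "a_twice"])

    def test_too_few_cases(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            fit_null(rng.standard_normal(3), np.ones((3, 2)), None)


class TestAdditiveScan:
    def test_matches_ols_oracle_small_hand_dataset(self):
        rng = np.random.default_rng(41)
        n, m = 25, 6
        probs = random_probs(rng, n, m)
        gp = GenoProbs({"1": probs}, [f"i{k}" for k in range(n)])
        mm = make_map({"1": m})
        y = pd.Series(rng.standard_normal(n), index=gp.individual_ids)
        cov = intercept_covariates(gp.individual_ids)
        scan = scan_additive(gp, mm, y, cov, kinship=None)
        X = np.ones((n, 1))
        for j in range(m):
            oracle = ols_lod_oracle(y.to_numpy(), X, probs[:, :, j])
            assert scan.lod["trait"].iloc[j] == pytest.approx(oracle, abs=1e-8)

    def test_constant_marker_lod_zero(self, rng):
        n = 30
        probs = random_probs(rng, n, 3)
        probs[:, :, 1] = probs[0, :, 1]  # identical slice across individuals
        probs /= probs.sum(axis=1, keepdims=True)
        gp = GenoProbs({"1": probs}, [f"i{k}" for k in range(n)])
        y = pd.Series(rng.standard_normal(n), index=gp.individual_ids)
        scan = scan_additive(gp, make_map({"1": 3}), y, intercept_covariates(gp.individual_ids))
        assert scan.lod["trait"].iloc[1] == pytest.approx(0.0, abs=1e-8)

    def test_planted_qtl_peak_near_truth(self):
        cfg = SimConfig(
            seed=51,
            n_individuals=200,
            chromosomes=(ChromSpec("1", n_markers=101),),
            traits=(TraitSpec("t", qtls=(QTLSpec("1", 50, 0.4, sdp=0b10010001),),),),
        )
        study, truth = simulate_study(cfg)
        scan = scan_additive(
            study.genoprobs, study.marker_map, study.traits["sim"].trait("t"),
            study.covariates, kinship=None,
        )
        peak_marker, peak_lod = scan.max_marker("t")
        peak_idx = scan.marker_map.index[scan.marker_map["marker_id"] == peak_marker][0]
        assert abs(peak_idx - 50) <= 5
        assert peak_lod > 5

    def test_affine_invariance(self, rng):
        n = 50
        gp = GenoProbs({"1": random_probs(rng, n, 8)}, [f"i{k}" for k in range(n)])
        mm = make_map({"1": 8})
        cov = intercept_covariates(gp.individual_ids)
        y = pd.Series(rng.standard_normal(n), index=gp.individual_ids)
        base = scan_additive(gp, mm, y, cov)
        shifted = scan_additive(gp, mm, -2.5 * y + 7.0, cov)
        np.testing.assert_allclose(
            base.lod.to_numpy(), shifted.lod.to_numpy(), atol=1e-6
        )

    def test_founder_column_drop_invariance(self, rng):
        # LOD from RSS is basis-free: dropping any founder column from the
        # locus block leaves it unchanged because dosages sum to 1 (intercept)
        n = 40
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        G = random_probs(rng, n, 1)[:, :, 0]
        nf = fit_null(y, X, None)
        full = block_lod(nf, G)
        for drop in range(8):
            keep = [f for f in range(8) if f != drop]
            assert block_lod(nf, G[:, keep]) == pytest.approx(full, abs=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 50))
        m = int(rng.integers(1, 10))
        probs = random_probs(rng, n, m)
        gp = GenoProbs({"1": probs}, [f"i{k}" for k in range(n)])
        y = pd.Series(rng.standard_normal(n), index=gp.individual_ids)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        cov = sex_covariates(gp.individual_ids, X[:, 1])
        scan = scan_additive(gp, make_map({"1": m}), y, cov, kinship=None)
        j = int(rng.integers(0, m))
        oracle = ols_lod_oracle(y.to_numpy(), X, probs[:, :, j])
        assert scan.lod["trait"].iloc[j] == pytest.approx(oracle, abs=1e-8)

    def test_null_calibration_median_lod(self):
        # no-QTL traits, h2 = 0.3, 100 replicates: the per-marker LOD at a
        # fixed marker should track its null law.  The founder block is an
        # ~8-dof likelihood-ratio test (median ~ chi2_8 / (2 ln 10) ~ 1.6);
        # a single dosage column is ~1-dof with median below 0.5.
        n = 200
        gp, _ = _geno(61, n=n, markers=(100, 100))
        kin = compute_kinship(gp, "loco")
        K = kin.matrices["1"]
        rng = np.random.default_rng(62)
        cov_true = 0.3 * compute_kinship(gp, "overall").matrices["overall"] + 0.7 * np.eye(n)
        L = np.linalg.cholesky(cov_true)
        lods8, lods1 = [], []
        dosage = gp.probs["1"][:, [1, 5], 50].sum(axis=1)[:, None]
        for _ in range(100):
            y = L @ rng.standard_normal(n)
            nf = fit_null(y, np.ones((n, 1)), K)
            lods8.append(block_lod(nf, gp.probs["1"][:, :, 50]))
            lods1.append(block_lod(nf, dosage))
        assert 0.8 < np.median(lods8) < 2.5
        assert np.median(lods1) < 0.5


class TestInteractiveScan:
    def _study_with_sex(self, seed, n=300, interaction=False):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(
            seed=seed,
            n_individuals=n,
            chromosomes=(ChromSpec("1", n_markers=41),),
        )
        gp, mm = simulate_genome(cfg)
        sex = rng.integers(0, 2, size=n).astype(float)
        cov = sex_covariates(gp.individual_ids, sex)
        G = gp.probs["1"][:, :, 20]
        v = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        signal = G @ v
        signal = (signal - signal.mean()) / signal.std()
        if interaction:
            y = np.where(sex > 0, signal, -signal) + 0.5 * rng.standard_normal(n)
        else:
            y = signal + 0.5 * rng.standard_normal(n)
        return gp, mm, pd.Series(y, index=gp.individual_ids), cov

    def test_no_interaction_delta_below_additive(self):
        gp, mm, y, cov = self._study_with_sex(71, interaction=False)
        full, delta = scan_interactive(gp, mm, y, cov, factor="sex")
        additive = scan_additive(gp, mm, y, cov)
        assert delta.lod["trait"].max() < additive.lod["trait"].max()

    def test_planted_interaction_detected(self):
        gp, mm, y, cov = self._study_with_sex(73, interaction=True)
        _, delta = scan_interactive(gp, mm, y, cov, factor="sex")
        peak_marker, peak = delta.max_marker("trait")
        idx = delta.marker_map.index[delta.marker_map["marker_id"] == peak_marker][0]
        assert peak > 3
        assert abs(idx - 20) <= 5

    def test_monotone_nesting(self):
        gp, mm, y, cov = self._study_with_sex(75, interaction=True)
        full, delta = scan_interactive(gp, mm, y, cov, factor="sex")
        additive = scan_additive(gp, mm, y, cov)
        assert np.all(
            full.lod["trait"].to_numpy() >= additive.lod["trait"].to_numpy() - 1e-6
        )
        assert np.all(additive.lod["trait"].to_numpy() >= -1e-8)

    def test_constant_factor_errors(self):
        gp, mm, y, cov = self._study_with_sex(77)
        cov.values["sex"] = 1.0  # degenerate after coding
        with pytest.raises(ValueError, match="constant|identical"):
            scan_interactive(gp, mm, y, cov, factor="sex")

    def test_unknown_factor_errors(self):
        gp, mm, y, cov = self._study_with_sex(79)
        with pytest.raises(ValueError, match="age"):
            scan_interactive(gp, mm, y, cov, factor="age")


class TestLOCOScan:
    def test_loco_scan_runs_and_flags_kinship(self, small_study):
        study, truth = small_study
        kin = compute_kinship(study.genoprobs, "loco")
        scan = scan_additive(
            study.genoprobs, study.marker_map, study.traits["sim"].trait("t_qtl"),
            study.covariates, kin,
        )
        assert scan.used_kinship
        peak_marker, lod = scan.max_marker("t_qtl")
        assert lod > 5
        assert peak_marker.startswith("c1_")

    def test_missing_values_complete_cased(self, small_study):
        study, _ = small_study
        y = study.traits["sim"].trait("t_qtl").copy()
        y.iloc[:10] = np.nan
        scan = scan_additive(study.genoprobs, study.marker_map, y, study.covariates)
        assert np.isfinite(scan.lod.to_numpy()).all()
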