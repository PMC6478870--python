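"""Normalization chain: plate factors, cell regression, filtering, volume, Z."""

import numpy as np
import pandas as pd
import pytest

from trmet import quantify, synthdata
from trmet.config import SimulationConfig
from trmet.types import AbundanceMatrix, IntensityTable


def _pooled_table(values_by_plate: dict[str, np.ndarray], n_ions: int) -> IntensityTable:
    """Minimal table with one pooled composition shared by all plates."""
    cols, meta, data = [], [], []
    for plate, vals in values_by_plate.items():
        sid = f"{plate}_pool1"
        cols.append(sid)
        meta.append((sid, "pooled", None, plate, "poolA", 1, 1, np.nan))
        data.append(vals)
    intensity = pd.DataFrame(
        np.array(data).T, index=[f"ion{i}" for i in range(n_ions)], columns=cols
    )
    sample_meta = pd.DataFrame(
        meta, columns=["sample", "sample_type", "cell_line", "plate", "pool_id",
                       "timepoint", "replicate", "confluence"],
    ).set_index("sample")
    return IntensityTable(intensity, sample_meta)


class TestPlateFactors:
    def test_identical_pools_give_unit_factors(self):
        base = np.array([100.0, 50.0, 10.0])
        table = _pooled_table({"P1": base, "P2": base, "P3": base}, 3)
        factors, corrected = quantify.estimate_plate_factors(table)
        np.testing.assert_allclose(factors.gamma, 1.0, rtol=1e-12)
        pd.testing.assert_frame_equal(corrected.intensity, table.intensity)

    def test_two_plate_closed_form(self):
        """One plate doubled: gauge prod=1 puts gamma at (1/sqrt2, sqrt2) and
        the corrected intensities for both plates coincide."""
        base = np.array([100.0, 50.0, 10.0])
        table = _pooled_table({"P1": base, "P2": 2 * base}, 3)
        factors, corrected = quantify.estimate_plate_factors(table)
        np.testing.assert_allclose(factors.gamma["P1"], 1 / np.sqrt(2), rtol=1e-10)
        np.testing.assert_allclose(factors.gamma["P2"], np.sqrt(2), rtol=1e-10)
        np.testing.assert_allclose(
            corrected.intensity.iloc[:, 0], corrected.intensity.iloc[:, 1], rtol=1e-10
        )

    def test_noiseless_synthetic_recovery(self, noiseless_study):
        factors, _ = quantify.estimate_plate_factors(noiseless_study.intensities)
        truth = noiseless_study.truth.plate_factor_true
        np.testing.assert_allclose(
            factors.gamma.sort_index(), truth.sort_index(), rtol=1e-9
        )

    def test_disconnected_design_rejected(self):
        table = _pooled_table({"P1": np.ones(2)}, 2)
        with pytest.raises(ValueError, match="unidentifiable"):
            quantify.estimate_plate_factors(table)


class TestCellsFromConfluence:
    @pytest.mark.parametrize(
        "conf,cell_area,well_area,expected",
        [
            (0.0, 1600.0, 0.32e8, 0.0),
            (100.0, 0.32e8, 0.32e8, 1.0),
            (50.0, 1600.0, 0.32e8, 10_000.0),
            (25.0, 2000.0, 3.2e7, 4000.0),
        ],
    )
    def test_conversion(self, conf, cell_area, well_area, expected):
        assert quantify.cells_from_confluence(conf, cell_area, well_area) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantify.cells_from_confluence(120.0, 1000.0)


def _cell_table(I: np.ndarray, lines: list[str]) -> tuple[IntensityTable, pd.Series]:
    n_samples = I.shape[1]
    counts = np.tile(np.array([1000.0, 2000.0, 3000.0, 4000.0, 5000.0]), len(lines))
    meta, cols = [], []
    for i in range(n_samples):
        sid = f"s{i}"
        cols.append(sid)
        meta.append((sid, "cell", lines[i // 5], "P1", "", 1 + i % 5, 1, 50.0))
    intensity = pd.DataFrame(I, index=[f"ion{j}" for j in range(I.shape[0])], columns=cols)
    sample_meta = pd.DataFrame(
        meta, columns=["sample", "sample_type", "cell_line", "plate", "pool_id",
                       "timepoint", "replicate", "confluence"],
    ).set_index("sample")
    return IntensityTable(intensity, sample_meta), pd.Series(counts, index=cols)


class TestCellRegression:
    def test_exact_line_recovers_slope_and_intercept(self):
        table, counts = _cell_table(
            (2.0 * np.tile(np.array([1000.0, 2000, 3000, 4000, 5000]), 1) + 5.0)[None, :],
            ["L1"],
        )
        ab = quantify.fit_cell_regression(table, counts)
        assert ab.alpha.iloc[0, 0] == pytest.approx(2.0, rel=1e-12)
        assert ab.beta.iloc[0] == pytest.approx(5.0, rel=1e-9)
        assert ab.alpha_se.iloc[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert ab.alpha_p.iloc[0, 0] < 1e-12

    def test_permutation_invariance(self, noiseless_study):
        table = noiseless_study.intensities
        counts = noiseless_study.counts
        ab1 = quantify.fit_cell_regression(table, counts)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.intensity.columns)
        shuffled = IntensityTable(table.intensity[perm], table.sample_meta.loc[perm])
        ab2 = quantify.fit_cell_regression(shuffled, counts)
        pd.testing.assert_frame_equal(ab1.alpha, ab2.alpha)

    def test_noiseless_alpha_recovery_to_machine_precision(self, noiseless_study):
        _, corrected = quantify.estimate_plate_factors(noiseless_study.intensities)
        ab = quantify.fit_cell_regression(corrected, noiseless_study.counts)
        truth = noiseless_study.truth
        true_mets = truth.alpha_true.index[:40]
        est = ab.alpha.loc[true_mets].to_numpy()
        true = truth.alpha_true.loc[true_mets].to_numpy()
        np.testing.assert_allclose(est, true, rtol=1e-7, atol=1e-9)

    def test_global_rescaling_scales_alpha(self, noiseless_study):
        """A global intensity rescale propagates linearly into alpha and
        cancels in Z-scores downstream."""
        table = noiseless_study.intensities
        scaled = IntensityTable(table.intensity * 7.5, table.sample_meta.copy())
        ab1 = quantify.fit_cell_regression(table, noiseless_study.counts)
        ab2 = quantify.fit_cell_regression(scaled, noiseless_study.counts)
        np.testing.assert_allclose(ab2.alpha.to_numpy(), 7.5 * ab1.alpha.to_numpy(), rtol=1e-9)


class TestFilterIons:
    def test_bonferroni_threshold_matches_study_scale(self):
        """54 lines x 2723 ions put the threshold at 3.4e-7."""
        assert quantify.bonferroni_threshold(54, 2723) == pytest.approx(3.4e-7, rel=0.01)

    def test_retention_rules(self):
        p = pd.DataFrame(
            [[1e-9, 1e-3, 1e-3, 1e-3, 1e-3],   # strong in one line, nominal in all
             [0.5, 0.6, 0.7, 0.5, 0.9],        # never significant
             [1e-9, 0.5, 0.6, 0.7, 0.8]],      # strong once but not broad
            index=["keep", "drop_weak", "drop_narrow"],
            columns=list("abcde"),
        )
        ab = AbundanceMatrix(alpha=p * 0, alpha_se=p * 0, alpha_p=p, beta=pd.Series(0, index=p.index))
        retained = quantify.filter_ions(ab, n_ions_tested=3)
        assert retained["keep"]
        assert not retained["drop_weak"]
        assert not retained["drop_narrow"]


class TestVolumeCorrection:
    def test_rank_one_alpha_fully_corrected(self):
        rng = np.random.default_rng(0)
        scale = np.exp(rng.normal(0, 1, 30))
        volume = np.exp(rng.normal(0, 0.3, 10))
        alpha = pd.DataFrame(np.outer(scale, volume),
                             index=[f"i{j}" for j in range(30)],
                             columns=[f"L{j}" for j in range(10)])
        ab = AbundanceMatrix(alpha=alpha, alpha_se=alpha * 0, alpha_p=alpha * 0,
                             beta=pd.Series(0.0, index=alpha.index),
                             retained=pd.Series(True, index=alpha.index))
        corrected, factor, selected = quantify.volume_correct(ab)
        cv = corrected.std(axis=1) / corrected.mean(axis=1)
        assert (cv.abs() < 1e-9).all()
        np.testing.assert_allclose(factor, volume / volume.mean(), rtol=1e-9)

    def test_equal_volumes_give_unit_factors(self):
        """Lines of (nearly) equal volume get consensus factors of ~1."""
        rng = np.random.default_rng(1)
        scale = np.exp(rng.normal(0, 1, 30))
        v = 1.0 + 0.01 * rng.standard_normal(16)  # vanishing volume wobble
        alpha = pd.DataFrame(
            np.outer(scale, v), index=[f"i{j}" for j in range(30)],
            columns=[f"L{j}" for j in range(16)],
        )
        alpha.iloc[10:] *= np.exp(rng.normal(0, 0.3, (20, 16)))  # biology
        ab = AbundanceMatrix(alpha=alpha, alpha_se=alpha * 0, alpha_p=alpha * 0,
                             beta=pd.Series(0.0, index=alpha.index),
                             retained=pd.Series(True, index=alpha.index))
        _, factor, _ = quantify.volume_correct(ab)
        np.testing.assert_allclose(factor, 1.0, atol=0.05)

    def test_pure_noise_alpha_fails_selection(self):
        rng = np.random.default_rng(2)
        alpha = pd.DataFrame(
            np.exp(rng.normal(0, 1, 30))[:, None] * np.exp(rng.normal(0, 0.3, (30, 16))),
            index=[f"i{j}" for j in range(30)], columns=[f"L{j}" for j in range(16)],
        )
        ab = AbundanceMatrix(alpha=alpha, alpha_se=alpha * 0, alpha_p=alpha * 0,
                             beta=pd.Series(0.0, index=alpha.index),
                             retained=pd.Series(True, index=alpha.index))
        with pytest.raises(ValueError, match="no ion passed"):
            quantify.volume_correct(ab)

    def test_synthetic_volume_recovery(self, quantified, small_study):
        _, zm, _ = quantified
        vol = small_study.truth.cell_volume
        r = np.corrcoef(zm.volume_factor[vol.index], vol)[0, 1]
        assert r > 0.95

    def test_no_selection_fails_loudly(self):
        rng = np.random.default_rng(2)
        alpha = pd.DataFrame(rng.normal(10, 1, (5, 6)) ** 2,
                             index=[f"i{j}" for j in range(5)],
                             columns=[f"L{j}" for j in range(6)])
        ab = AbundanceMatrix(alpha=alpha, alpha_se=alpha * 0, alpha_p=alpha * 0,
                             beta=pd.Series(0.0, index=alpha.index),
                             retained=pd.Series(True, index=alpha.index))
        with pytest.raises(ValueError, match="no ion passed"):
            quantify.volume_correct(ab, r_threshold=0.9999)


class TestZScore:
    def test_hand_computed_example(self):
        alpha = pd.DataFrame([[1.0, 2.0, 3.0]], index=["i"], columns=list("abc"))
        zm = quantify.zscore(alpha)
        np.testing.assert_allclose(
            zm.z.iloc[0], [-1.22474487, 0.0, 1.22474487], rtol=1e-8
        )

    def test_population_moments(self, quantified):
        _, zm, _ = quantified
        z = zm.z.to_numpy()
        np.testing.assert_allclose(np.nanmean(z, axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.sqrt(np.nanmean(z ** 2, axis=1)), 1.0, atol=1e-9)

    def test_constant_ion_flagged(self):
        alpha = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]],
                             index=["const", "ok"], columns=list("abc"))
        zm = quantify.zscore(alpha)
        assert "const" in zm.flagged_constant
        assert zm.z.loc["const"].isna().all()
        assert not zm.z.loc["ok"].isna().any()


class TestEndToEnd:
    def test_noiseless_z_equals_z_of_truth(self, noiseless_study):
        """The whole chain reproduces Z-scored volume-corrected truth to 1e-9
        without noise (the volume component is removed by construction)."""
        ab, zm, _ = quantify.quantify(noiseless_study.intensities, noiseless_study.counts)
        truth = noiseless_study.truth
        rel_volume = truth.cell_volume / truth.cell_volume.mean()
        truth_alpha = truth.alpha_true.loc[zm.z.index].div(rel_volume, axis=1)
        zt = quantify.zscore(truth_alpha)
        np.testing.assert_allclose(zm.z.to_numpy(), zt.z.to_numpy(), atol=1e-9)

    def test_alpha_stable_on_count_spanning_subsets(self, noiseless_study):
        """Refitting on a >= 3-point subset spanning the count range agrees
        within 3 SE — the estimates do not depend on cultivation structure."""
        table = noiseless_study.intensities
        counts = noiseless_study.counts
        _, corrected = quantify.estimate_plate_factors(table)
        full = quantify.fit_cell_regression(corrected, counts)
        meta = corrected.sample_meta
        keep = meta.index[(meta["sample_type"] != "cell") | (meta["timepoint"].isin([1, 3, 5]))]
        sub = IntensityTable(corrected.intensity[keep], meta.loc[keep])
        subset = quantify.fit_cell_regression(sub, counts[sub.subset("cell").samples])
        diff = (subset.alpha - full.alpha).abs().to_numpy()
        tol = 3 * np.maximum(subset.alpha_se.to_numpy(), 1e-9) + 1e-6 * np.abs(full.alpha.to_numpy())
        assert (diff <= tol).all()


class TestAnnotation:
    REF = pd.DataFrame({
        "compound_id": ["glucose", "pyruvate"],
        "formula": ["C6H12O6", "C3H4O3"],
        "monoisotopic_mass": [180.06339, 88.01604],
        "is_alpha_keto": [False, True],
    })

    def test_deprotonated_match(self):
        anns = quantify.annotate_ions(pd.Series({"ionA": 179.0560}), self.REF)
        assert len(anns) == 1
        assert anns[0].compound_id == "glucose" and anns[0].adduct == "[M-H]-"
        assert abs(anns[0].mass_error) <= 0.003

    def test_tolerance_boundary(self):
        target = 180.06339 - quantify.PROTON_MASS
        assert quantify.annotate_ions(pd.Series({"x": target + 0.004}), self.REF) == []

    def test_phenylhydrazone_shift_value(self):
        assert quantify.PHENYLHYDRAZONE_SHIFT == pytest.approx(90.05818, abs=1e-5)

    def test_alpha_keto_gets_derivative_adduct(self):
        mz = 88.01604 + quantify.PHENYLHYDRAZONE_SHIFT - quantify.PROTON_MASS
        anns = quantify.annotate_ions(pd.Series({"ionB": mz}), self.REF)
        assert [a.adduct for a in anns] == ["[M+PH-H]-"]
        assert anns[0].compound_id == "pyruvate"
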