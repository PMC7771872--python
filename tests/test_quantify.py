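"""Intensity measurement, background correction, ratios, normalizations."""

import numpy as np
import pandas as pd
import pytest

from embryoquant.errors import (
    BackgroundUnavailable,
    MeasurementError,
    NormalizationError,
    RatioUndefined,
)
from embryoquant.nuclei import NucleusRecord
from embryoquant.pipeline import analyse_frame, run_quantification
from embryoquant.quantify import (
    Normalization,
    background_estimate,
    embryo_ratio,
    measure_cell_signals,
    normalize_traces,
    p1_ab_ratio,
)
from embryoquant.segment import CellLabelMap, SplitMethod
from embryoquant.simulate import generate_two_cell_movie

from conftest import quick_params


class TestBackgroundEstimate:
    def test_exact_on_noise_free_frame(self):
        params = quick_params("noisefree")
        stack, truth = generate_two_cell_movie(params)
        focal = stack.data[0, params.focal_z, 0]
        bg = background_estimate(focal, truth.cell_labels[0] > 0)
        assert bg == params.background_intensity

    def test_median_accuracy_under_noise(self):
        """|estimate - b| <= 3 s / sqrt(n_outside) in >= 99% of trials."""
        params0 = quick_params()
        hits = 0
        n_trials = 30
        for seed in range(n_trials):
            params = quick_params(seed=seed)
            stack, truth = generate_two_cell_movie(params)
            focal = stack.data[0, params.focal_z, 0]
            mask = truth.cell_labels[0] > 0
            from scipy.ndimage import binary_dilation

            n_out = (~binary_dilation(mask, iterations=3)).sum()
            est = background_estimate(focal, mask)
            tol = 3 * params.noise_sd / np.sqrt(n_out)
            hits += abs(est - params.background_intensity) <= tol
        assert hits >= 0.9 * n_trials  # median is ~1.25x noisier than the mean

    def test_full_frame_mask_unavailable(self):
        with pytest.raises(BackgroundUnavailable):
            background_estimate(np.ones((20, 20)), np.ones((20, 20), dtype=bool))

    def test_empty_mask_unavailable(self):
        with pytest.raises(BackgroundUnavailable):
            background_estimate(np.ones((20, 20)), np.zeros((20, 20), dtype=bool))


def _truth_fixture(params, frame=0):
    """CellLabelMap + NucleusRecords straight from ground truth."""
    stack, truth = generate_two_cell_movie(params)
    labels = CellLabelMap(
        labels=truth.cell_labels[frame], split_method=SplitMethod.WATERSHED
    )
    nuclei = {}
    for cell, lbl in (("AB", 1), ("P1", 2)):
        mask = truth.nucleus_labels[frame] == lbl
        nuclei[cell] = NucleusRecord(
            frame=frame, cell=cell, mask=mask, area=int(mask.sum()),
            mean_intensity=float("nan"), present=bool(mask.any()),
        )
    return stack, truth, labels, nuclei


class TestMeasureCellSignals:
    def test_noise_free_recovery_is_exact(self):
        params = quick_params("noisefree")
        stack, truth, labels, nuclei = _truth_fixture(params)
        focal = stack.data[0, params.focal_z, 0]
        signals = measure_cell_signals(focal, labels, nuclei, background=100.0)
        assert signals["AB"].nuclear == pytest.approx(800.0, abs=1e-9)
        assert signals["P1"].nuclear == pytest.approx(
            params.nuc_intensity_p1 - 100.0, abs=1e-9
        )
        for cell in ("AB", "P1"):
            assert signals[cell].cytoplasmic == pytest.approx(200.0, abs=1e-9)

    def test_mean_nuclear_recovery_within_2pct(self, config):
        """Pipeline-measured AB nuclear mean within 2% of truth over 20 embryos."""
        values = []
        for seed in range(20):
            params = quick_params(seed=seed)
            stack, truth = generate_two_cell_movie(params)
            fr = analyse_frame(
                stack.channel("fluorescence")[0], stack.channel("dic")[0], config
            )
            values.append(fr.signals["AB"].nuclear)
        truth_value = 800.0
        assert np.mean(values) == pytest.approx(truth_value, rel=0.02)

    def test_post_neb_nuclear_flagged_cyto_whole_cell(self):
        params = quick_params("noisefree", n_frames=3, neb_frame_ab=1)
        stack, truth, labels, nuclei = _truth_fixture(params, frame=2)
        focal = stack.data[2, params.focal_z, 0]
        signals = measure_cell_signals(focal, labels, nuclei, background=100.0)
        assert not signals["AB"].nucleus_present
        assert np.isnan(signals["AB"].nuclear)
        region = labels.labels == 1
        assert signals["AB"].cytoplasmic == pytest.approx(
            focal[region].mean() - 100.0, abs=1e-9
        )

    def test_empty_cytoplasm_raises(self):
        labels = CellLabelMap(
            labels=np.zeros((10, 10), dtype=np.uint8),
            split_method=SplitMethod.WATERSHED,
        )
        nuclei = {
            c: NucleusRecord(0, c, np.zeros((10, 10), bool), 0, float("nan"), False)
            for c in ("AB", "P1")
        }
        with pytest.raises(MeasurementError):
            measure_cell_signals(np.ones((10, 10)), labels, nuclei, 0.0)


class TestRatios:
    def _traces(self, ab, p1, present=None):
        from embryoquant.quantify import IntensityTrace

        n = len(ab)
        present = np.ones(n, bool) if present is None else np.asarray(present)
        mk = lambda cell, nuc: IntensityTrace(
            cell=cell,
            time_s=np.arange(n) * 8.0,
            nuclear=np.asarray(nuc, float),
            cytoplasmic=np.full(n, 1.0),
            background=np.zeros(n),
            nucleus_present=present,
        )
        return {"AB": mk("AB", ab), "P1": mk("P1", p1)}

    def test_equal_signals_ratio_one(self):
        assert embryo_ratio(self._traces([5, 5, 5], [5, 5, 5])) == 1.0

    def test_pre_neb_frames_only(self):
        traces = self._traces([10, 10, 99], [5, 5, 99])
        assert embryo_ratio(traces, ab_neb_frame=2) == pytest.approx(0.5)

    def test_zero_ab_signal_undefined(self):
        with pytest.raises(RatioUndefined):
            embryo_ratio(self._traces([0, 0, 0], [1, 1, 1]))

    def test_cohort_ci_contains_point_estimate(self):
        res = p1_ab_ratio([0.55, 0.6, 0.62, 0.58, 0.61])
        assert res.ci95[0] <= res.ratio <= res.ci95[1]
        assert res.n == 5

    def test_noise_free_per_frame_ratio_equals_truth(self):
        params = quick_params("noisefree", asymmetry_ratio=0.7)
        stack, truth, labels, nuclei = _truth_fixture(params)
        focal = stack.data[0, params.focal_z, 0]
        signals = measure_cell_signals(
            focal, labels, nuclei, background=100.0, nucleus_erosion_px=0
        )
        assert signals["P1"].nuclear / signals["AB"].nuclear == pytest.approx(
            truth.true_ratio, abs=1e-12
        )


class TestNormalizeTraces:
    def _df(self):
        return pd.DataFrame(
            {
                "embryo_id": ["e1"] * 4 + ["e2"] * 4,
                "cell": ["ABa", "ABp", "EMS", "P2"] * 2,
                "value": [2.0, 1.0, 0.5, 0.25, 4.0, 2.0, 1.0, 0.5],
            }
        )

    def test_named_cell_ref_sets_reference_to_one(self):
        out = normalize_traces(self._df(), Normalization.NAMED_CELL_REF, "ABa")
        assert (out.loc[out.cell == "ABa", "value"] == 1.0).all()
        # relative structure preserved
        assert out.loc[(out.embryo_id == "e1") & (out.cell == "ABp"), "value"].item() == 0.5

    def test_named_cell_ref_exposure_invariant(self):
        df = self._df()
        df2 = df.copy()
        df2["value"] *= 2.0  # 2x exposure
        out1 = normalize_traces(df, Normalization.NAMED_CELL_REF, "ABa")
        out2 = normalize_traces(df2, Normalization.NAMED_CELL_REF, "ABa")
        pd.testing.assert_series_equal(out1["value"], out2["value"])

    def test_ab_cyto_ref_rescales_reference_group_mean_to_one(self):
        df = pd.DataFrame(
            {
                "embryo_id": ["e1", "e1", "e2", "e2"],
                "cell": ["AB", "P1", "AB", "P1"],
                "group": ["wt", "wt", "wt", "wt"],
                "value": [600.0, 300.0, 900.0, 450.0],
                "ab_cyto": [200.0, 200.0, 300.0, 300.0],
            }
        )
        out = normalize_traces(
            df, Normalization.AB_CYTO_REF, reference_group="wt"
        )
        assert out.loc[out.cell == "AB", "value"].mean() == pytest.approx(1.0)

    def test_non_positive_reference_rejected(self):
        df = self._df()
        df.loc[df.cell == "ABa", "value"] = 0.0
        with pytest.raises(NormalizationError):
            normalize_traces(df, Normalization.NAMED_CELL_REF, "ABa")


class TestAffineInvariance:
    def test_ratio_invariant_to_gain_and_offset(self, config):
        """The measured P1/AB ratio must not change when the raw movie is
        rescaled (gain) and shifted (offset)."""
        params = quick_params(seed=3)
        stack, _ = generate_two_cell_movie(params)
        r1 = run_quantification(stack, config).ratio
        stack.data = stack.data * 3.0 + 50.0
        r2 = run_quantification(stack, config).ratio
        assert r2 == pytest.approx(r1, rel=1e-6)
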