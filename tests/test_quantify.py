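"""TBR quantification, partial-volume recovery and the decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualpet import (
    AcquisitionSpec,
    AnalysisConfig,
    BackgroundEstimate,
    CohortMember,
    Region,
    RegionSpec,
    RoiMask,
    analyze_mouse,
    classify_mouse,
    insert_tumor,
    make_brain_phantom,
    monitor_growth,
    recovered_uptake,
    simulate_member_scans,
    simulate_scan,
    tbr,
)
from dualpet.quantify import MouseRecord, TbrResult

from conftest import fch_tracer


def _roi(mask):
    idx = np.argwhere(mask)
    centroid = tuple((idx.mean(axis=0) * 0.4).tolist()) if idx.size else (0.0, 0.0, 0.0)
    return RoiMask(
        mask=mask,
        centroid_mm=centroid,
        n_voxels=int(mask.sum()),
        mean_counts=0.0,
    )


def _tbr_result(context, ratio):
    return TbrResult(
        tracer_context=context, ratio=ratio, ratio_sd=0.0, roi_id=0, n_roi_voxels=1
    )


class TestTbr:
    def test_matches_constructed_count_ratio(self):
        # ROI at 224 counts/voxel over a 100 counts/voxel background
        counts = np.full((10, 10, 10), 100.0)
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True
        counts[mask] = 224.0
        bg = BackgroundEstimate(100.0, 10.0, 500)
        result = tbr(counts, _roi(mask), bg)
        assert result.ratio == pytest.approx(2.24)

    def test_roi_distributed_like_background_gives_unity(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100.0, size=(16, 16, 16)).astype(float)
        mask = np.zeros((16, 16, 16), bool)
        mask[2:8, 2:8, 2:8] = True
        bg_vox = counts[~mask]
        bg = BackgroundEstimate(bg_vox.mean(), bg_vox.std(ddof=1), bg_vox.size)
        result = tbr(counts, _roi(mask), bg)
        # s.e. of the ROI mean ratio is ~ 0.1/sqrt(216)
        assert result.ratio == pytest.approx(1.0, abs=0.03)

    @given(alpha=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_global_scaling_invariance(self, alpha):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100.0, size=(8, 8, 8)).astype(float)
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True
        bg = BackgroundEstimate(counts[~mask].mean(), 0.0, int((~mask).sum()))
        bg_scaled = BackgroundEstimate(alpha * bg.mean_counts_per_voxel, 0.0, bg.n_voxels)
        r1 = tbr(counts, _roi(mask), bg).ratio
        r2 = tbr(alpha * counts, _roi(mask), bg_scaled).ratio
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_empty_roi_rejected(self):
        counts = np.ones((4, 4, 4))
        with pytest.raises(ValueError):
            _roi(np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError, match="background mean"):
            tbr(counts, _roi(np.ones((4, 4, 4), bool)), BackgroundEstimate(0.0, 0.0, 1))


class TestUptakeRecovery:
    @pytest.mark.parametrize("true_uptake", [1.5, 2.65, 4.0])
    def test_partial_volume_corrected_estimate_within_ten_percent(self, true_uptake):
        """The PVC estimator recovers the true tissue contrast of a 3.5 mm
        focus under the default 2 mm PSF, with the focus ROI delineated as
        drawn (here: known by construction)."""
        ph = insert_tumor(make_brain_phantom(), 3.5)
        roi = ph.labels == Region.TUMOR
        tracer = fch_tracer(tumor_fch=true_uptake)
        estimates = [
            recovered_uptake(
                simulate_scan(ph, tracer, AcquisitionSpec(seed=s)).counts,
                roi,
                ph.brain_mask(),
                2.0,
                ph.spacing_mm,
            )
            for s in range(20)
        ]
        assert np.mean(estimates) == pytest.approx(true_uptake, rel=0.10)

    def test_plain_tbr_bias_negative_and_shrinking_with_diameter(self):
        """PSF spill-out biases the uncorrected ROI-mean TBR low; the bias
        shrinks as the object grows relative to the PSF."""
        biases = {}
        for d in (2.8, 4.2):
            ph = insert_tumor(make_brain_phantom(), d)
            roi_mask = ph.labels == Region.TUMOR
            scan = simulate_scan(ph, fch_tracer(tumor_fch=2.65), AcquisitionSpec(), noise=False)
            brain_vox = scan.counts[ph.labels == Region.BRAIN]
            # interior background: voxels unaffected by edge falloff
            bg_mean = np.median(brain_vox[brain_vox > 90])
            ratio = scan.counts[roi_mask].mean() / bg_mean
            biases[d] = ratio - 2.65
        assert biases[2.8] < 0 and biases[4.2] < 0
        assert biases[4.2] > biases[2.8]


class TestClassification:
    def test_fused_ratio_above_tau_calls_tumor(self):
        roi = _roi(np.ones((4, 4, 4), bool))
        rec = classify_mouse(
            "t1", "tumor_bearing", [roi],
            [_tbr_result("FCH", 2.24)], [_tbr_result("FUSED_FDG", 1.63)],
        )
        assert rec.call == "tumor"
        assert rec.fused_tbr.ratio == 1.63

    def test_fused_ratio_at_background_calls_false_positive(self):
        roi = _roi(np.ones((4, 4, 4), bool))
        rec = classify_mouse(
            "c1", "control", [roi],
            [_tbr_result("FCH", 2.05)], [_tbr_result("FUSED_FDG", 1.03)],
        )
        assert rec.call == "fch_false_positive"

    def test_no_roi_calls_negative(self):
        rec = classify_mouse("c2", "control", [], [], [])
        assert rec.call == "negative"
        assert rec.fch_tbr is None

    def test_mismatched_lists_rejected(self):
        roi = _roi(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="per ROI"):
            classify_mouse("x", "control", [roi], [_tbr_result("FCH", 2.0)], [])

    @pytest.mark.parametrize(
        "archetype,expected_call",
        [("tumor", "tumor"), ("hotspot_control", "fch_false_positive"), ("clean_control", "negative")],
    )
    def test_noise_free_archetypes_classified_correctly(self, archetype, expected_call):
        """End-to-end decision rule on the three noise-free study archetypes."""
        brain_spec = RegionSpec(Region.BRAIN, 1.0, 1.0)
        if archetype == "tumor":
            member = CohortMember(
                "m", "tumor_bearing", 3.5, False,
                {Region.BRAIN: brain_spec, Region.TUMOR: RegionSpec(Region.TUMOR, 2.65, 1.4)},
                (64, 64, 64), 0.4,
            )
        elif archetype == "hotspot_control":
            member = CohortMember(
                "m", "control", None, True,
                {Region.BRAIN: brain_spec, Region.HOTSPOT: RegionSpec(Region.HOTSPOT, 8.0, 1.0)},
                (64, 64, 64), 0.4,
            )
        else:
            member = CohortMember(
                "m", "control", None, False, {Region.BRAIN: brain_spec}, (64, 64, 64), 0.4
            )
        ph = member.build_phantom()
        acq = AcquisitionSpec()
        from dualpet import TracerSpec

        fch = simulate_scan(ph, TracerSpec("FCH", member.region_uptakes), acq, noise=False)
        fdg = simulate_scan(ph, TracerSpec("FDG", member.region_uptakes), acq, noise=False)
        rec = analyze_mouse("m", member.group, fch, fdg, ph.brain_mask())
        assert rec.call == expected_call


class TestGrowthMonitoring:
    def _record(self, day, fused):
        return MouseRecord(
            mouse_id="m1", group="tumor_bearing",
            fch_tbr=_tbr_result("FCH", 2.0),
            fused_tbr=_tbr_result("FUSED_FDG", fused),
            call="tumor", day=day,
        )

    def test_rising_series_flags_monotone_increase(self):
        traj = monitor_growth([self._record(35, 1.2), self._record(42, 1.5), self._record(50, 1.9)])
        assert traj.monotone_increase
        assert [p.fused_ratio for p in traj.points] == [1.2, 1.5, 1.9]

    def test_constant_series_not_flagged(self):
        traj = monitor_growth([self._record(35, 1.4), self._record(50, 1.4)])
        assert not traj.monotone_increase

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError, match="two time points"):
            monitor_growth([self._record(35, 1.2)])

    def test_unordered_days_rejected(self):
        with pytest.raises(ValueError, match="increasing day"):
            monitor_growth([self._record(50, 1.2), self._record(35, 1.5)])
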