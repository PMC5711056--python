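"""The homogeneous-water dose kernel and dose-grid superposition."""

import numpy as np
import pytest

from brachydmf.geometry import (
    DetectorVolume,
    build_phantom,
    default_detector,
    full_scatter_phantom,
    reference_points,
)
from brachydmf.planning import make_symmetric_plan
from brachydmf.tg43 import (
    GRID_NODES,
    compute_dose_grid,
    point_dose,
)
from brachydmf.transport import EngineConfig, simulate


class TestKernel:
    def test_normalization_node_is_exactly_one(self, kernel):
        i1 = int(np.argmin(np.abs(kernel.r_nodes - 1.0)))
        j90 = int(np.argmin(np.abs(kernel.cos_nodes)))
        assert kernel.r_nodes[i1] == pytest.approx(1.0, abs=1e-12)
        assert kernel.values[i1, j90] == 1.0

    def test_positive_everywhere(self, kernel):
        assert np.all(kernel.values > 0)

    def test_noisy_nodes_flagged_in_provenance(self, kernel):
        """Nodes with statistical error above 1% are recorded as a warning
        in the kernel provenance (or none exist)."""
        if np.any(kernel.rse > 0.01):
            assert "warning" in kernel.provenance
        else:
            assert "warning" not in kernel.provenance

    def test_mirror_symmetry_about_transverse_plane(self, kernel_raw):
        """Raw (unsymmetrized) kernel: k(r, theta) = k(r, 180-theta) within
        3 sigma, over nodes with good statistics."""
        v = kernel_raw.values
        rse = kernel_raw.rse
        mirrored = v[:, ::-1]
        rse_m = rse[:, ::-1]
        good = (rse < 0.05) & (rse_m < 0.05)
        diff = np.abs(v - mirrored)[good]
        sigma = np.hypot(v * rse, mirrored * rse_m)[good]
        frac_within = np.mean(diff <= 3 * sigma)
        # ~99.7% expected for Gaussian errors; allow a small margin
        assert frac_within > 0.98

    def test_near_inverse_square_on_transverse_axis(self, kernel):
        j90 = int(np.argmin(np.abs(kernel.cos_nodes)))
        i1 = int(np.argmin(np.abs(kernel.r_nodes - 1.0)))
        i2 = int(np.argmin(np.abs(kernel.r_nodes - 2.0)))
        r1, r2 = kernel.r_nodes[i1], kernel.r_nodes[i2]
        ratio = (kernel.values[i2, j90] * r2**2) / (
            kernel.values[i1, j90] * r1**2
        )
        assert 0.9 <= ratio <= 1.1

    def test_interpolation_exact_at_nodes(self, kernel):
        for i in (5, 15, 25):
            for j in (5, 20, 35):
                assert kernel(kernel.r_nodes[i], kernel.cos_nodes[j]) == (
                    pytest.approx(kernel.values[i, j], rel=1e-12)
                )

    def test_evaluation_below_inner_radius_rejected(self, kernel):
        with pytest.raises(ValueError):
            kernel(0.1, 0.0)

    def test_save_load_round_trip(self, kernel, tmp_path):
        path = tmp_path / "kernel.txt"
        kernel.save(path)
        from brachydmf.tg43 import DoseKernel

        again = DoseKernel.load(path)
        assert np.allclose(again.values, kernel.values, rtol=1e-6)
        assert np.allclose(again.r_nodes, kernel.r_nodes, rtol=1e-5)


class TestPointDose:
    def test_zero_weights_give_zero(self, kernel, applicator):
        assert point_dose(kernel, applicator, np.zeros(35), [0, 3.2, 0]) == 0.0

    def test_superposition_is_exact(self, kernel, applicator):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, 35)
        b = rng.uniform(0, 1, 35)
        p = np.array([1.0, 2.5, 0.5])
        da = point_dose(kernel, applicator, a, p)
        db = point_dose(kernel, applicator, b, p)
        dab = point_dose(kernel, applicator, a + b, p)
        assert dab == pytest.approx(da + db, rel=1e-12)

    def test_cardinal_points_equal_for_symmetric_plan(self, kernel, applicator):
        refs = reference_points(applicator)
        doses = [
            point_dose(kernel, applicator, np.ones(35), p)
            for p in refs.points
        ]
        assert np.ptp(doses) / np.mean(doses) < 0.005

    def test_point_inside_inner_cutoff_rejected(self, kernel, applicator):
        with pytest.raises(ValueError):
            point_dose(kernel, applicator, np.ones(35), [0.0, 0.5, 0.1])

    def test_kernel_is_faithful_tps_surrogate(self, kernel, applicator):
        """Kernel superposition ratio between two points matches a direct
        full-scatter Monte Carlo tally ratio within 3 combined sigma."""
        w = np.ones(35)
        p_near = np.array([0.0, 3.2, 0.0])
        p_far = np.array([0.0, 5.0, 0.0])
        pred = point_dose(kernel, applicator, w, p_near) / point_dose(
            kernel, applicator, w, p_far
        )
        ph = full_scatter_phantom()
        cfg = EngineConfig(n_histories=2_000_000, seed=107)
        r_near = simulate(w, ph, applicator, DetectorVolume(center=p_near), cfg)
        r_far = simulate(w, ph, applicator, DetectorVolume(center=p_far), cfg)
        mc = r_near.dose_per_history / r_far.dose_per_history
        sigma = mc * np.hypot(r_near.rse, r_far.rse)
        # allow kernel node noise on top of the tally noise
        assert abs(mc - pred) < 3 * sigma + 0.02 * pred


class TestDoseGrid:
    def test_grid_axes_161_nodes_quarter_cm(self, kernel, applicator, sym_plan):
        grid = compute_dose_grid(kernel, applicator, sym_plan)
        assert grid.values.shape == (GRID_NODES,) * 3 == (161, 161, 161)
        ax = grid.axes[0]
        assert ax[0] == -20.0 and ax[-1] == 20.0
        assert np.allclose(np.diff(ax), 0.25)

    def test_grid_matches_direct_point_dose_at_reference_point(
        self, kernel, applicator, sym_plan
    ):
        grid = compute_dose_grid(kernel, applicator, sym_plan)
        refs = reference_points(applicator)
        for p in refs.points:
            direct = point_dose(kernel, applicator, sym_plan, p)
            assert grid.interpolate(p) == pytest.approx(direct, rel=0.01)

    def test_doubling_prescription_doubles_grid(self, kernel, applicator):
        p1 = make_symmetric_plan(applicator, kernel, 340.0)
        p2 = make_symmetric_plan(applicator, kernel, 680.0)
        g1 = compute_dose_grid(kernel, applicator, p1)
        g2 = compute_dose_grid(kernel, applicator, p2)
        assert np.allclose(g2.values, 2 * g1.values, rtol=1e-9)

    def test_unnormalized_plan_rejected(self, kernel, applicator):
        from brachydmf.planning import Plan

        plan = Plan(weights=np.ones(35), active_lumens=("central",),
                    normalization=None)
        with pytest.raises(ValueError, match="normalized"):
            compute_dose_grid(kernel, applicator, plan)

    def test_binary_export_round_trip(self, kernel, applicator, sym_plan,
                                      tmp_path):
        grid = compute_dose_grid(kernel, applicator, sym_plan)
        path = tmp_path / "grid.bin"
        grid.save(path)
        from brachydmf.tg43 import DoseGrid

        again = DoseGrid.load(path)
        assert np.array_equal(again.values, grid.values)
        assert again.spacing == grid.spacing
        assert again.prescription == grid.prescription

    def test_quarter_turn_of_plan_permutes_cardinal_doses(
        self, kernel, applicator
    ):
        """Rotating the per-lumen weights one lumen step (90 degrees)
        permutes the cardinal point doses exactly."""
        refs = reference_points(applicator)
        w = np.zeros(35)
        w[applicator.dwell_indices("A")] = 1.0
        w_rot = np.zeros(35)
        w_rot[applicator.dwell_indices("B")] = 1.0
        d_a = point_dose(kernel, applicator, w, refs.points[refs.labels.index("A")])
        d_b = point_dose(kernel, applicator, w_rot, refs.points[refs.labels.index("B")])
        assert d_a == pytest.approx(d_b, rel=1e-9)
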