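"""Cube averaging and the E^99th tissue metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elfdosim import (
    TissueSpec,
    UniformFieldSource,
    VoxelPhantom,
    cns_aggregate,
    cube_average,
    tissue_E99,
)
from elfdosim.metrics import TissueExposure
from elfdosim.solver import FieldSolution


def _uniform_solution(phantom, E_vec):
    """Synthetic FieldSolution with a spatially constant E vector."""
    shape = phantom.shape
    E = np.zeros((3,) + shape)
    mask = phantom.conductive_mask()
    for c in range(3):
        E[c][mask] = E_vec[c]
    mag = np.zeros(shape)
    mag[mask] = np.linalg.norm(E_vec)
    return FieldSolution(np.zeros(shape), E, mag, 0.0, 0, UniformFieldSource())


@pytest.fixture()
def block_phantom():
    labels = np.zeros((12, 12, 12), dtype=np.int16)
    labels[2:10, 2:10, 2:10] = 1
    return VoxelPhantom(
        labels, 0.002,
        [TissueSpec(0, "air", 0.0, group="AIR"), TissueSpec(1, "cube", 0.1, group="CNS")],
    )


class TestCubeAverage:
    def test_uniform_field_unchanged(self, block_phantom):
        sol = _uniform_solution(block_phantom, [3e-3, 4e-3, 0.0])
        avg = cube_average(sol, block_phantom, side_m=0.006)
        mask = block_phantom.conductive_mask()
        assert np.allclose(avg[mask], 5e-3)
        assert np.all(avg[~mask] == 0)

    def test_degenerate_cube_is_identity(self, block_phantom):
        sol = _uniform_solution(block_phantom, [1e-3, 0, 0])
        rng = np.random.default_rng(0)
        sol.E_field[0][block_phantom.conductive_mask()] = rng.uniform(
            1e-4, 1e-3, block_phantom.conductive_mask().sum()
        )
        sol.E_mag_rms = np.abs(sol.E_field[0])
        avg = cube_average(sol, block_phantom, side_m=0.002)
        assert np.array_equal(avg, np.where(block_phantom.conductive_mask(), sol.E_mag_rms, 0.0))

    def test_linear_field_center_preserved(self, block_phantom):
        # mean of a linear-in-x field over a symmetric cube equals its centre value
        sol = _uniform_solution(block_phantom, [0, 0, 0])
        x = np.arange(12, dtype=float)[:, None, None] * np.ones((1, 12, 12))
        mask = block_phantom.conductive_mask()
        sol.E_field[0] = np.where(mask, 2.0 + 0.1 * x, 0.0)
        sol.E_mag_rms = np.abs(sol.E_field[0])
        avg = cube_average(sol, block_phantom, side_m=0.006)
        assert avg[5, 5, 5] == pytest.approx(2.0 + 0.1 * 5, rel=1e-12)

    def test_sub_voxel_side_refused(self, block_phantom):
        sol = _uniform_solution(block_phantom, [1e-3, 0, 0])
        with pytest.raises(ValueError, match="smaller than voxel"):
            cube_average(sol, block_phantom, side_m=0.001)

    def test_averaging_contracts_maximum(self, block_phantom):
        sol = _uniform_solution(block_phantom, [0, 0, 0])
        rng = np.random.default_rng(1)
        mask = block_phantom.conductive_mask()
        sol.E_field[0][mask] = rng.uniform(0, 1e-3, mask.sum())
        sol.E_mag_rms = np.abs(sol.E_field[0])
        avg = cube_average(sol, block_phantom, side_m=0.006)
        assert avg[mask].max() <= sol.E_mag_rms[mask].max() + 1e-18


class TestTissueE99:
    def test_constant_tissue(self, block_phantom):
        avg = np.where(block_phantom.labels == 1, 7e-3, 0.0)
        exp = tissue_E99(avg, block_phantom, 1)
        assert exp.E99th_V_per_m == pytest.approx(7e-3)
        assert exp.n_voxels == 8**3

    def test_linear_interpolation_percentile(self):
        labels = np.zeros((12, 12, 12), dtype=np.int16)
        labels[1:11, 1:11, 1:11] = 1  # 1000 voxels
        p = VoxelPhantom(
            labels, 0.002,
            [TissueSpec(0, "air", 0.0, group="AIR"), TissueSpec(1, "t", 0.1, group="CNS")],
        )
        avg = np.zeros(p.shape)
        avg[p.labels == 1] = np.arange(1, 1001, dtype=float)
        assert tissue_E99(avg, p, 1).E99th_V_per_m == pytest.approx(990.01)

    def test_small_or_missing_tissue_refused(self, block_phantom):
        avg = np.zeros(block_phantom.shape)
        with pytest.raises(ValueError, match="not present"):
            tissue_E99(avg, block_phantom, 9)
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[3:5, 3:5, 3:5] = 1  # 8 voxels only
        tiny = VoxelPhantom(
            labels, 0.002,
            [TissueSpec(0, "air", 0.0, group="AIR"), TissueSpec(1, "t", 0.1, group="CNS")],
        )
        with pytest.raises(ValueError, match="at least 64"):
            tissue_E99(np.zeros(tiny.shape), tiny, 1)

    def test_e99_between_median_and_max(self, sphere_small, sphere_small_solution):
        avg = cube_average(sphere_small_solution, sphere_small, side_m=0.003)
        vals = avg[sphere_small.labels == 1]
        e99 = tissue_E99(avg, sphere_small, 1).E99th_V_per_m
        assert np.median(vals) <= e99 <= vals.max()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scaling_monotonicity(self, scale):
        # E99th is exactly homogeneous of degree 1 in the field amplitude
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[1:7, 1:7, 1:7] = 1
        p = VoxelPhantom(
            labels, 0.002,
            [TissueSpec(0, "air", 0.0, group="AIR"), TissueSpec(1, "t", 0.1, group="CNS")],
        )
        rng = np.random.default_rng(7)
        avg = np.zeros(p.shape)
        avg[p.labels == 1] = rng.uniform(0.5, 2.0, 216)
        a = tissue_E99(avg, p, 1).E99th_V_per_m
        b = tissue_E99(avg * scale, p, 1).E99th_V_per_m
        assert b == pytest.approx(scale * a, rel=1e-12)


class TestCNSAggregate:
    def _phantom_with_groups(self):
        labels = np.zeros((10, 10, 14), dtype=np.int16)
        labels[1:9, 1:9, 1:5] = 1
        labels[1:9, 1:9, 5:9] = 2
        labels[1:9, 1:9, 9:13] = 3
        return VoxelPhantom(
            labels, 0.002,
            [
                TissueSpec(0, "air", 0.0, group="AIR"),
                TissueSpec(1, "grey", 0.1, group="CNS"),
                TissueSpec(2, "white", 0.06, group="CNS"),
                TissueSpec(3, "nerve", 0.03, group="PNS"),
            ],
        )

    def test_max_over_cns_only(self):
        p = self._phantom_with_groups()
        exps = [
            TissueExposure(1, 2.0, 256, 256),
            TissueExposure(2, 2.3, 256, 256),
            TissueExposure(3, 9.9, 256, 256),  # PNS: must be ignored
        ]
        assert cns_aggregate(exps, p) == 2.3

    def test_single_cns_tissue_is_identity(self, block_phantom):
        assert cns_aggregate([TissueExposure(1, 1.1, 512, 512)], block_phantom) == 1.1

    def test_no_cns_tissue_is_error(self):
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[1:7, 1:7, 1:7] = 1
        p = VoxelPhantom(
            labels, 0.002,
            [TissueSpec(0, "air", 0.0, group="AIR"), TissueSpec(1, "muscle", 0.2, group="OTHER")],
        )
        with pytest.raises(ValueError, match="CNS"):
            cns_aggregate([TissueExposure(1, 1.0, 216, 216)], p)
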