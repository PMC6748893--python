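"""Core/shell contour extraction, embedding, and flow-through metrics."""

import numpy as np
import pytest

from clotflow.flow import inlet_profile
from clotflow.geometry import ChannelGeometry, build_mesh
from clotflow.structure import (CoreShellPair, RegionContour,
                                embed_core_in_shell, extract_core,
                                extract_shell, flow_through_measured_shape,
                                occlusivity, region_mask,
                                region_mean_resistance)


@pytest.fixture(scope="module")
def mesh():
    return build_mesh(ChannelGeometry(), 2.0, 2.0)


def half_ellipse_contour(center=300.0, half_len=60.0, height=15.0, n=81):
    """Synthetic shell shape: half-ellipse sitting on the bottom wall.
    n odd puts the apex exactly at the configured height."""
    th = np.linspace(0.0, np.pi, n)
    x = center + half_len * np.cos(th)
    y = height * np.sin(th)
    v = np.column_stack([x, y])
    return RegionContour(vertices=np.vstack([v, [center - half_len, 0.0]]))


class TestExtractRegions:
    def test_subthreshold_field_gives_empty_contour(self, mesh):
        c = extract_core(np.full(mesh.shape, 0.5), mesh, threshold_nM=1.0)
        assert c.is_empty and c.peak_height == 0.0

    def test_rectangle_indicator_recovered(self, mesh):
        f = np.zeros(mesh.shape)
        xs = (mesh.xc >= 290) & (mesh.xc <= 310)
        f[np.ix_(xs, mesh.yc <= 10)] = 2.0
        c = extract_core(f, mesh, threshold_nM=1.0)
        assert c.peak_height == pytest.approx(10.0, abs=mesh.dy)
        assert c.length == pytest.approx(20.0, abs=2 * mesh.dx)

    def test_half_gaussian_level_set_half_width(self, mesh):
        """Peak 10 nM at the wall, sigma 20 µm: the 1-nM contour half-width
        is sigma*sqrt(2 ln 10) ~= 42.9 µm."""
        sigma = 20.0
        xx, yy = np.meshgrid(mesh.xc, mesh.yc, indexing="ij")
        f = 10.0 * np.exp(-((xx - 300.0) ** 2 + yy ** 2) / (2 * sigma ** 2))
        c = extract_core(f, mesh, threshold_nM=1.0)
        expected = sigma * np.sqrt(2 * np.log(10.0))
        assert 0.5 * c.length == pytest.approx(expected, abs=mesh.dx)
        assert c.peak_height == pytest.approx(expected, abs=2 * mesh.dy)

    def test_shell_plateau_and_threshold_nesting(self, mesh):
        phi = np.zeros(mesh.shape)
        xx, yy = np.meshgrid(mesh.xc, mesh.yc, indexing="ij")
        phi = 0.6 * np.exp(-((xx - 300.0) / 50.0) ** 2 - (yy / 12.0) ** 2)
        lo = extract_shell(phi, mesh, threshold_fraction=0.05)
        hi = extract_shell(phi, mesh, threshold_fraction=0.10)
        assert lo.contains(hi, tol=mesh.dx)
        assert np.all(extract_shell(np.zeros(mesh.shape), mesh).vertices
                      == np.empty((0, 2)))

    def test_largest_component_wins(self, mesh):
        f = np.zeros(mesh.shape)
        f[140:160, :8] = 2.0    # main deposit, 40 µm long
        f[250:253, :3] = 2.0    # satellite
        c = extract_core(f, mesh, 1.0)
        assert 270.0 < c.center_x < 330.0
        assert c.length < 60.0


class TestEmbedCoreInShell:
    def make_pair(self, h_ratio=0.5, l_ratio=0.6, offset=0.0):
        shell = half_ellipse_contour(300.0, 50.0, 10.0)
        core = half_ellipse_contour(300.0 + offset, 50.0 * l_ratio,
                                    10.0 * h_ratio)
        return CoreShellPair(core=core, shell=shell, k_core=2e13, k_shell=1e12)

    def test_hand_computed_rescaling(self):
        """Sim ratios (0.5 height, 0.6 length) into a 15 x 120 µm shell
        give a 7.5 x 72 µm core."""
        pair = self.make_pair(0.5, 0.6)
        measured = half_ellipse_contour(300.0, 60.0, 15.0)
        out = embed_core_in_shell(pair, measured)
        assert out.core.peak_height == pytest.approx(7.5, rel=1e-6)
        assert out.core.length == pytest.approx(72.0, rel=1e-6)

    def test_identity_when_shells_match(self):
        pair = self.make_pair(0.5, 0.6, offset=5.0)
        out = embed_core_in_shell(pair, pair.shell)
        assert out.core.peak_height == pytest.approx(pair.core.peak_height)
        assert out.core.center_x == pytest.approx(pair.core.center_x)

    def test_downstream_offset_preserved(self):
        pair = self.make_pair(0.5, 0.5, offset=10.0)   # core downstream
        measured = half_ellipse_contour(300.0, 100.0, 20.0)
        out = embed_core_in_shell(pair, measured)
        rel_sim = (pair.core.center_x - pair.shell.center_x) / pair.shell.length
        rel_out = (out.core.center_x - measured.center_x) / measured.length
        assert rel_out == pytest.approx(rel_sim, rel=1e-6)
        assert out.core.center_x > measured.center_x

    def test_nesting_invariant_on_randomized_shapes(self):
        """Embedded core stays inside the measured shell for 100 random
        shape/ratio/offset combinations."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            h_r = rng.uniform(0.2, 0.9)
            l_r = rng.uniform(0.2, 0.9)
            off = rng.uniform(-0.5, 0.5) * 50.0 * (1 - l_r)
            pair = self.make_pair(h_r, l_r, off)
            measured = half_ellipse_contour(
                rng.uniform(250, 350), rng.uniform(30, 120),
                rng.uniform(5, 25))
            out = embed_core_in_shell(pair, measured)
            assert measured.contains(out.core, tol=1e-6)

    def test_empty_sim_core_gives_empty_output(self):
        shell = half_ellipse_contour()
        pair = CoreShellPair(core=RegionContour(np.empty((0, 2))),
                             shell=shell, k_core=1e13, k_shell=1e12)
        out = embed_core_in_shell(pair, half_ellipse_contour(280, 40, 8))
        assert out.core.is_empty


class TestRegionResistance:
    def test_uniform_field(self, mesh):
        region = half_ellipse_contour(300.0, 40.0, 12.0)
        k = np.full(mesh.shape, 7e12)
        assert region_mean_resistance(k, region, mesh) == pytest.approx(7e12)

    def test_arithmetic_mean_of_two_values(self, mesh):
        region = half_ellipse_contour(300.0, 40.0, 12.0)
        k = np.full(mesh.shape, 1e12)
        k[mesh.xc >= 300.0, :] = 3e12
        mean = region_mean_resistance(k, region, mesh)
        assert mean == pytest.approx(2e12, rel=0.05)

    def test_empty_region_rejected(self, mesh):
        with pytest.raises(ValueError):
            region_mean_resistance(np.ones(mesh.shape),
                                   RegionContour(np.empty((0, 2))), mesh)


class TestOcclusivity:
    @pytest.mark.parametrize("height,expected", [(18.0, 0.30), (60.0, 1.0)])
    def test_ratio(self, height, expected):
        c = half_ellipse_contour(300.0, 50.0, height)
        assert occlusivity(c, 60.0) == pytest.approx(expected, rel=1e-6)

    def test_empty_contour_is_zero(self):
        assert occlusivity(RegionContour(np.empty((0, 2))), 60.0) == 0.0


class TestFlowThroughMeasuredShape:
    def test_zero_resistance_recovers_poiseuille(self, mesh, fluid):
        shell = half_ellipse_contour(300.0, 60.0, 15.0)
        pair = CoreShellPair(core=RegionContour(np.empty((0, 2))),
                             shell=shell, k_core=0.0, k_shell=0.0)
        state, m = flow_through_measured_shape(pair, mesh, fluid)
        exact = inlet_profile(fluid, 60.0, mesh.yc)
        err = np.abs(state.u_center - exact[None, :]).max() / exact.max()
        assert err < 0.01

    def test_velocity_structure_of_porous_clot(self, mesh, fluid):
        """Velocity is maximal at the clot top and minimal at its base,
        horizontal variation is below vertical variation, and the
        low-velocity region extends beyond the shell footprint."""
        shell = half_ellipse_contour(300.0, 60.0, 16.0)
        core = half_ellipse_contour(305.0, 36.0, 8.0)
        pair = CoreShellPair(core=core, shell=shell,
                             k_core=2.5e13, k_shell=1.5e12)
        state, m = flow_through_measured_shape(pair, mesh, fluid)
        assert m.mean_axial < 0.05 * m.lumen_mean_axial
        assert m.horizontal_variation < m.vertical_variation
        # top vs base of the clot's center column
        sm = region_mask(shell, mesh)
        icen = np.argmin(np.abs(mesh.xc - shell.center_x))
        col = state.u_center[icen, sm[icen, :]]
        assert col[-1] > col[0]
        # the low-velocity region extends beyond the shell footprint, and
        # the slow layer over the clot is much thicker than the ordinary
        # near-wall layer upstream
        lo, hi = m.low_velocity_x_range
        assert lo < shell.x_range[0] and hi > shell.x_range[1]
        assert m.low_velocity_thickness_center \
            > 3 * m.low_velocity_thickness_upstream
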