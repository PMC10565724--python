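"""Substrate generators: relaxation, patterned surfaces, packings, spinodal."""

import numpy as np
import pytest
from scipy import ndimage

from phasecell import GridSpec
from phasecell import substrates as S


# --------------------------------------------------------------------------
# relaxation
# --------------------------------------------------------------------------

class TestRelaxation:
    def test_uniform_mask_is_a_fixed_point(self):
        mask = np.ones((10, 10, 10), np.uint8)
        for which in ("phi", "psi"):
            assert np.allclose(S.relax_substrate(mask, which), 1.0)

    def test_mass_conserved(self):
        rng = np.random.default_rng(1)
        mask = (rng.random((12, 12, 12)) < 0.3).astype(np.uint8)
        for which in ("phi", "psi"):
            out = S.relax_substrate(mask, which)
            assert out.sum() == pytest.approx(mask.sum(), rel=1e-10)

    def test_sensing_skirt_wider_than_contact_skirt(self):
        # slab mask: the distance from the surface to the 0.1 contour
        # must be strictly larger for Psi (D*t = 1.0) than Phi (0.075)
        mask = np.zeros((8, 8, 40), np.uint8)
        mask[:, :, :16] = 1
        phi = S.relax_substrate(mask, "phi")[4, 4]
        psi = S.relax_substrate(mask, "psi")[4, 4]
        z = np.arange(40)
        z_phi = np.interp(-0.1, -phi[14:], z[14:])
        z_psi = np.interp(-0.1, -psi[14:], z[14:])
        assert z_psi > z_phi

    def test_bounds_preserved(self):
        rng = np.random.default_rng(2)
        mask = (rng.random((10, 10, 10)) < 0.5).astype(np.uint8)
        out = S.relax_substrate(mask, "psi")
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            S.relax_substrate(np.full((8, 8, 8), 0.5), "phi")

    def test_substrate_field_invariants(self):
        sub = S.make_flat_with_strip(12.0, extent=(24, 24, 16))
        assert sub.phi.min() >= 0 and sub.phi.max() <= 1
        assert np.all(sub.psi >= sub.phi - 1e-6)
        assert np.all(sub.kappa_map > 0)


# --------------------------------------------------------------------------
# patterned surfaces
# --------------------------------------------------------------------------

class TestStrip:
    def test_kappa_values_are_exactly_on_off(self):
        sub = S.make_flat_with_strip(20.0)
        assert set(np.unique(sub.kappa_map)) == {1.0, 5.0}

    def test_strip_area_matches_width(self):
        sub = S.make_flat_with_strip(20.0)
        top = sub.kappa_map[:, :, -1]
        area = top[top == 5.0].size * sub.grid.spacing**2
        ly = sub.grid.extent[1]
        assert area == pytest.approx(20.0 * ly, abs=ly * sub.grid.spacing)

    def test_strip_centered(self):
        sub = S.make_flat_with_strip(20.0)
        on = np.where(sub.kappa_map[:, 0, 0] == 5.0)[0]
        nx = sub.grid.shape[0]
        assert abs((on[0] + on[-1]) / 2.0 - (nx - 1) / 2.0) <= 0.5


class TestHemisphereArray:
    def test_mask_height(self):
        sub = S.make_hemisphere_array(radius=12.0, base_thickness=6.0)
        ztop = np.argwhere(sub.mask)[:, 2].max()
        assert ztop == pytest.approx(6.0 + 12.0 - 1, abs=1.0)

    def test_solid_volume_matches_analytic(self):
        sub = S.make_hemisphere_array(radius=12.0, bump_spacing=32.0,
                                      extent=(64, 64, 48), base_thickness=6.0)
        n_bumps = (64 / 32.0) ** 2  # periodic lattice
        expect = 64 * 64 * 6.0 + n_bumps * (2.0 / 3.0) * np.pi * 12.0**3
        assert sub.mask.sum() == pytest.approx(expect, rel=0.03)

    def test_periodicity_under_lattice_translation(self):
        sub = S.make_hemisphere_array(radius=10.0, bump_spacing=32.0,
                                      extent=(64, 64, 48))
        assert np.array_equal(sub.mask, np.roll(sub.mask, 32, axis=0))
        assert np.array_equal(sub.mask, np.roll(sub.mask, 32, axis=1))


# --------------------------------------------------------------------------
# sphere packing and PTM
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def packing():
    return S.pack_spheres_rcp(35.0, (210.0, 210.0, 210.0), seed=5)


class TestPacking:
    def test_reaches_close_packing_fraction(self, packing):
        assert packing.meta["achieved_fraction"] >= 0.60

    def test_minimum_distance_invariant(self, packing):
        c = packing.centers
        d_min = 2 * 35.0 * (1 - 0.35)
        delta = c[None, :, :] - c[:, None, :]
        for ax in range(2):
            L = packing.box[ax]
            delta[..., ax] -= L * np.round(delta[..., ax] / L)
        dist = np.sqrt((delta**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= d_min - 1e-9

    def test_fraction_estimators_agree(self, packing):
        # reported MC estimate vs an independent voxel-grid estimate
        band = S._analysis_band(packing)
        xs = np.arange(1.0, 210.0, 2.0)
        zs = np.arange(band[0], band[1], 2.0)
        gx, gy, gz = np.meshgrid(xs, xs, zs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        from scipy.spatial import cKDTree
        tree = cKDTree(S._with_lateral_images(packing.centers,
                                              (210.0, 210.0), 35.0))
        dist, _ = tree.query(pts)
        voxel_frac = (dist <= 35.0).mean()
        assert packing.meta["achieved_fraction"] == pytest.approx(
            voxel_frac, abs=0.005)

    def test_determinism(self):
        a = S.pack_spheres_rcp(20.0, (120.0, 120.0, 120.0), seed=9,
                               max_sweeps=40)
        b = S.pack_spheres_rcp(20.0, (120.0, 120.0, 120.0), seed=9,
                               max_sweeps=40)
        assert np.array_equal(a.centers, b.centers)


class TestPTM:
    def test_inversion_identity(self, packing):
        sub = S.make_ptm(packing, extent=(64, 64, 64))
        pore_frac = 1.0 - sub.mask.mean()
        assert sub.mask.mean() == pytest.approx(1.0 - pore_frac)
        assert 0.0 < sub.mask.mean() < 1.0

    def test_two_sphere_window_diameter(self):
        # analytic circle of intersection for overlapping equal spheres
        r, ov = 35.0, 0.325
        d = 2 * r * (1 - ov)
        a_expect = 2 * r * np.sqrt(1 - (1 - ov) ** 2)
        centers = np.array([[60.0, 60.0, 50.0], [60.0, 60.0, 50.0 + d]])
        pk = S.SpherePacking(centers, r, (120.0, 120.0, 160.0), 0)
        sub = S.make_ptm(pk, extent=(120, 120, 160))
        z_win = int(round(50.0 + d / 2.0))
        pore_slice = ~sub.mask[:, :, z_win].astype(bool)
        area = pore_slice.sum() * 1.0
        d_measured = 2 * np.sqrt(area / np.pi)
        assert d_measured == pytest.approx(a_expect, rel=0.05)

    def test_pore_space_connected_to_boundary(self, packing):
        sub = S.make_ptm(packing, extent=(64, 64, 64))
        pore = ~sub.mask.astype(bool)
        lab, _ = ndimage.label(pore, ndimage.generate_binary_structure(3, 1))
        boundary_labels = set()
        for ax in range(3):
            boundary_labels |= set(np.unique(lab.take(0, axis=ax)))
            boundary_labels |= set(np.unique(lab.take(-1, axis=ax)))
        boundary_labels.discard(0)
        reachable = np.isin(lab, sorted(boundary_labels))
        assert reachable[pore].mean() > 0.99


@pytest.fixture(scope="module")
def ptm3_sub():
    return S.make_ptm_interconnect(36.0, 0.325)


class TestPTMInterconnect:
    def test_window_fraction(self, ptm3_sub):
        # construction: the analytic window is the prescribed fraction
        assert ptm3_sub.meta["window_diameter"] / 36.0 == pytest.approx(
            0.325, abs=0.001)
        # voxelized aperture: the knife-edge rim is sub-voxel at the
        # 1 um build lattice, which can only widen the window by ~1 voxel
        cz = ptm3_sub.meta["center"][2]
        s = ptm3_sub.meta["center_spacing"]
        z_win = int(round(cz - s / 2.0))
        pore = ~ptm3_sub.mask.astype(bool)
        area = pore[:, :, z_win].sum() * 1.0
        d_measured = 2 * np.sqrt(area / np.pi)
        assert ptm3_sub.meta["window_diameter"] - 0.5 <= d_measured <= \
            ptm3_sub.meta["window_diameter"] + 3.0

    def test_four_fold_symmetry(self, ptm3_sub):
        assert np.array_equal(ptm3_sub.mask, np.rot90(ptm3_sub.mask, axes=(0, 1)))

    def test_minimum_cross_section_at_window_planes(self, ptm3_sub):
        pore = ~ptm3_sub.mask.astype(bool)
        profile = pore.sum(axis=(0, 1)).astype(float)
        cz = ptm3_sub.meta["center"][2]
        s = ptm3_sub.meta["center_spacing"]
        zs = [int(round(cz - s / 2)), int(round(cz + s / 2))]
        interior = profile[zs[0] - 10:zs[1] + 10]
        for z in zs:
            assert profile[z - 1:z + 2].min() == interior.min()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            S.make_ptm_interconnect(36.0, 0.8)


@pytest.fixture(scope="module")
def hyp_sub():
    return S.make_hyperboloid(d_max=36.0, d_min=11.7, length=40.0)


class TestHyperboloid:
    def test_throat_diameter(self, hyp_sub):
        pore = ~hyp_sub.mask.astype(bool)
        z0 = int(round(hyp_sub.meta["throat_z"]))
        area = pore[:, :, z0].sum() * 1.0
        assert 2 * np.sqrt(area / np.pi) == pytest.approx(11.7, abs=2.0)

    def test_profile_convex_with_min_at_midplane(self, hyp_sub):
        pore = ~hyp_sub.mask.astype(bool)
        profile = pore.sum(axis=(0, 1)).astype(float)
        z0 = int(round(hyp_sub.meta["throat_z"]))
        half = int(40.0 / 2) - 2
        inner = profile[z0 - half:z0 + half + 1]
        assert inner.argmin() == pytest.approx(half, abs=2)
        # analytic slice area: pi * r_min^2 (1 + (z-z0)^2/b^2)
        r_min = 11.7 / 2
        b = 20.0 / np.sqrt((36.0 / 11.7) ** 2 - 1)
        zz = np.arange(-half, half + 1)
        expect = np.pi * r_min**2 * (1 + zz**2 / b**2)
        assert np.allclose(inner, expect, rtol=0.12, atol=12)

    def test_throat_gentler_than_ptm_rim(self, hyp_sub):
        # the model's own level-set curvature of the pore surface: mean
        # |c| in a band around the hyperboloid throat vs around the
        # interconnect rim of a matched-window column
        from phasecell import fields as F

        ptm = S.make_ptm_interconnect(36.0, 0.325)

        def rim_band_curvature(substrate, z_plane):
            # the sensing surface Psi = 0.5 spans several voxels, unlike
            # the near-binary Phi after its 3 relaxation steps
            c = F.interface_curvature(substrate.psi, substrate.grid)
            z = substrate.grid.meshgrid()[2]
            band = (np.abs(substrate.psi - 0.5) < 0.3) \
                & (np.broadcast_to(np.abs(z - z_plane) < 2.5,
                                   substrate.grid.shape))
            return np.abs(c[band]).mean()

        h_throat = rim_band_curvature(hyp_sub, hyp_sub.meta["throat_z"])
        cz = ptm.meta["center"][2]
        h_rim = rim_band_curvature(ptm, cz - ptm.meta["center_spacing"] / 2)
        assert h_throat < h_rim


# --------------------------------------------------------------------------
# Cahn–Hilliard spinodal structure
# --------------------------------------------------------------------------

class TestDomainSize:
    def test_single_mode_wavelength(self):
        grid = GridSpec((64, 16, 16), 1.0)
        x = grid.meshgrid()[0]
        lam = 16.0
        u = np.broadcast_to(np.sin(2 * np.pi * x / lam), grid.shape).copy()
        assert S.characteristic_domain_size(u, grid) == pytest.approx(
            lam, rel=0.05)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        grid = GridSpec((32, 32, 32), 1.0)
        u = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 2.0)
        assert S.characteristic_domain_size(u, grid) == pytest.approx(
            S.characteristic_domain_size(-u, grid))


@pytest.fixture(scope="module")
def ch_run():
    grid = GridSpec((32, 32, 32), 2.0)
    mask, u = S.cahn_hilliard_run(grid, seed=4, stop_size=20.0,
                                  return_field=True)
    return grid, mask, u


class TestCahnHilliard:
    def test_mean_conserved(self, ch_run):
        _, _, u = ch_run
        assert abs(u.mean()) < 1e-8

    def test_symmetric_phase_fractions(self, ch_run):
        _, mask, _ = ch_run
        assert mask.mean() == pytest.approx(0.5, abs=0.05)

    def test_both_phases_percolate(self, ch_run):
        _, mask, _ = ch_run
        for phase in (mask > 0, mask == 0):
            lab, _ = ndimage.label(phase)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            big = lab == sizes.argmax()
            spans = any(
                big.take(0, axis=ax).any() and big.take(-1, axis=ax).any()
                for ax in range(3)
            )
            assert spans

    def test_coarsening_is_monotone_after_transient(self):
        grid = GridSpec((32, 32, 32), 2.0)
        rng = np.random.default_rng(11)
        u = rng.normal(0, 0.1, grid.shape)
        u -= u.mean()
        k2 = S._ch_k2(grid.shape, grid.spacing)
        k4 = k2 * k2
        from scipy.fft import dctn, idctn
        sizes = []
        dt = 0.1
        den = 1 + dt * k4
        for block in range(8):
            for _ in range(300):
                nl = dctn(u * u * u - u, norm="ortho")
                u = idctn((dctn(u, norm="ortho") - dt * k2 * nl) / den,
                          norm="ortho")
            if block >= 2:
                sizes.append(S.characteristic_domain_size(u, grid))
        assert all(b >= a * 0.995 for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] > sizes[0]


class TestBTM:
    def test_btm_meta_and_bicontinuity(self):
        sub = S.make_btm(extent=(64, 64, 64), stop_size=24.0, seed=6)
        assert sub.meta["domain_size"] >= 24.0
        for phase in (sub.mask > 0, sub.mask == 0):
            lab, _ = ndimage.label(phase)
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            big = lab == sizes.argmax()
            assert any(
                big.take(0, axis=ax).any() and big.take(-1, axis=ax).any()
                for ax in range(3)
            )

    def test_internal_surfaces_are_saddle_shaped(self):
        # angle-defect (discrete Gaussian) curvature on the spinodal
        # surface: negative (saddle) on most of the interior area
        import trimesh
        from skimage import measure

        sub = S.make_btm(extent=(64, 64, 64), stop_size=24.0, seed=6)
        verts, faces, _, _ = measure.marching_cubes(
            ndimage.gaussian_filter(sub.mask.astype(float), 2.0), level=0.5)
        mesh = trimesh.Trimesh(verts, faces, process=False)

        # angle defect per vertex: 2*pi - sum of incident face angles
        tri = mesh.vertices[mesh.faces]
        defect = np.full(len(mesh.vertices), 2.0 * np.pi)
        for i in range(3):
            a = tri[:, (i + 1) % 3] - tri[:, i]
            b = tri[:, (i + 2) % 3] - tri[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.subtract.at(defect, mesh.faces[:, i], ang)

        interior = np.all((mesh.vertices > 6) & (mesh.vertices < 58), axis=1)
        vertex_area = np.zeros(len(mesh.vertices))
        np.add.at(vertex_area, mesh.faces.ravel(),
                  np.repeat(mesh.area_faces / 3.0, 3))
        K = defect[interior]
        w = vertex_area[interior]
        assert (w[K <= 0].sum() / w.sum()) >= 0.8
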