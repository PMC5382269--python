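import numpy as np
import pytest

from hydramem.constants import K_B_SI
from hydramem.frame import minimum_image
from hydramem.synth import (
    EXCLUDE_R,
    PLANT_R_DA,
    GroundTruth,
    LamellarSpec,
    PackingError,
    gen_area_series,
    gen_area_vs_temperature,
    gen_bulk_water_frame,
    gen_diffraction,
    gen_fluctuation_series,
    gen_lamellar_frame,
    gen_pd_curve,
    gen_volume_vs_nw,
)


class TestLamellarSpec:
    def test_nominal_dw(self):
        spec = LamellarSpec()
        assert spec.d_w == pytest.approx(2 * 20.0 * 0.030 / 0.78)

    def test_validation(self):
        with pytest.raises(ValueError):
            LamellarSpec(n_lipids_per_leaflet=0)
        with pytest.raises(ValueError):
            LamellarSpec(a_l=-1.0)
        with pytest.raises(ValueError):
            LamellarSpec(orientation_amplitude=1.5)
        with pytest.raises(ValueError):
            LamellarSpec(planted_hb=[("xy", 1)])
        with pytest.raises(ValueError):
            LamellarSpec(n_oh=9)


class TestLamellarFrame:
    def test_counts_and_annotations(self):
        spec = LamellarSpec(n_lipids_per_leaflet=9, n_w=6.0, seed=3)
        frame, truth = gen_lamellar_frame(spec)
        assert truth.n_lipids == 18
        assert truth.n_waters == round(2 * 9 * 6.0)
        n_waters = int(frame.water_oxygen_mask().sum())
        assert n_waters == truth.n_waters
        assert frame.annotated
        leaflets = {a.leaflet for a in frame.atoms if a.molecule_class == "lipid"}
        assert leaflets == {"upper", "lower"}
        # every lipid carries n_oh hydroxyls
        lipid_o = frame.class_mask("lipid") & frame.role_mask("donor")
        assert int(lipid_o.sum()) == truth.n_lipids * spec.n_oh

    def test_planted_counts_match_request(self):
        spec = LamellarSpec(
            n_lipids_per_leaflet=9,
            n_w=6.0,
            planted_hb=[("ll", 2), ("lw", 3), ("ww", 4)],
            seed=5,
        )
        _, truth = gen_lamellar_frame(spec)
        assert truth.counts() == {"ll": 2, "lw": 3, "ww": 4}

    def test_separation_guarantee(self):
        """Non-planted donor-acceptor pairs stay beyond the exclusion radius."""
        spec = LamellarSpec(
            n_lipids_per_leaflet=9,
            n_w=5.0,
            planted_hb=[("ll", 1), ("lw", 2), ("ww", 2)],
            seed=9,
        )
        frame, truth = gen_lamellar_frame(spec)
        planted_pairs = {(b.donor, b.acceptor) for b in truth.bonds}
        da = np.flatnonzero(frame.role_mask("donor") | frame.role_mask("acceptor"))
        pos = frame.wrapped()
        mol = frame.molecule_ids
        for ii, i in enumerate(da):
            d = minimum_image(pos[da[ii + 1 :]] - pos[i], frame.box)
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            for jj, dist in zip(da[ii + 1 :], r):
                if mol[i] == mol[jj]:
                    continue
                pair = {(i, jj), (jj, i)}
                if pair & planted_pairs:
                    assert dist == pytest.approx(PLANT_R_DA, abs=1e-9)
                else:
                    assert dist > EXCLUDE_R

    def test_midplane_centered(self):
        frame, _ = gen_lamellar_frame(LamellarSpec(n_lipids_per_leaflet=4, n_w=4.0))
        assert frame.water_midplane_z() == pytest.approx(frame.box[2] / 2, abs=0.05)

    def test_reproducible_and_seed_sensitive(self):
        spec = LamellarSpec(n_lipids_per_leaflet=4, n_w=4.0, seed=1)
        f1, _ = gen_lamellar_frame(spec)
        f2, _ = gen_lamellar_frame(spec)
        assert np.array_equal(f1.positions, f2.positions)
        f3, _ = gen_lamellar_frame(LamellarSpec(n_lipids_per_leaflet=4, n_w=4.0, seed=2))
        assert not np.array_equal(f1.positions, f3.positions)

    def test_packing_errors(self):
        with pytest.raises(PackingError, match="packing"):
            gen_lamellar_frame(LamellarSpec(a_l=0.3))
        with pytest.raises(PackingError):
            gen_lamellar_frame(
                LamellarSpec(n_lipids_per_leaflet=2, n_w=4.0, planted_hb=[("ll", 9)])
            )
        with pytest.raises(PackingError, match="waters"):
            gen_lamellar_frame(
                LamellarSpec(n_lipids_per_leaflet=4, n_w=1.0, planted_hb=[("ww", 20)])
            )

    def test_ground_truth_json_round_trip(self):
        spec = LamellarSpec(n_lipids_per_leaflet=4, n_w=4.0, planted_hb=[("ww", 1)])
        _, truth = gen_lamellar_frame(spec)
        back = GroundTruth.from_json(truth.to_json())
        assert back == truth


class TestBulkWater:
    def test_count_matches_density(self):
        frame = gen_bulk_water_frame(33.4, 3.0, seed=1)
        n = int(frame.water_oxygen_mask().sum())
        assert n == round(33.4 * 27.0)

    def test_no_overlap(self):
        frame = gen_bulk_water_frame(33.4, 2.0, seed=2)
        o = frame.wrapped()[frame.water_oxygen_mask()]
        d = minimum_image(o[:, None, :] - o[None, :, :], frame.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        np.fill_diagonal(r, np.inf)
        assert r.min() > 0.25

    def test_zero_density_empty(self):
        assert gen_bulk_water_frame(0.0, 2.0).n_atoms == 0

    def test_infeasible_density(self):
        with pytest.raises(PackingError, match="infeasible"):
            gen_bulk_water_frame(60.0, 2.0)


class TestScalarSeries:
    def test_area_series_variance(self):
        k_a = 0.35
        curve = gen_area_series(k_a, 39.0, 300.0, n=40000, seed=4)
        planted_var = K_B_SI * 300.0 * 39.0 * 1e18 / k_a
        assert np.var(curve.y) == pytest.approx(planted_var, rel=0.05)
        assert np.mean(curve.y) == pytest.approx(39.0, rel=0.01)

    def test_volume_series_linear(self):
        curve = gen_volume_vs_nw(0.030, np.arange(100.0, 200.0, 10.0), v0=50.0)
        assert np.allclose(np.diff(curve.y) / 10.0, 0.030)
        assert curve.y[0] == 50.0

    def test_volume_series_callable_vw(self):
        grid = np.linspace(10.0, 20.0, 11)
        curve = gen_volume_vs_nw(lambda n: 0.001 * n, grid)
        # trapezoid of a linear integrand is exact: V = v0 + 0.0005 (n^2 - n0^2)
        assert np.allclose(curve.y, 100.0 + 0.0005 * (grid**2 - grid[0] ** 2))

    def test_area_vs_temperature(self):
        curve = gen_area_vs_temperature(1.1e-3, 39.0, np.arange(290.0, 311.0, 5.0))
        slopes = np.diff(curve.y) / 5.0
        assert np.allclose(slopes, 1.1e-3 * 39.0)

    def test_dispatcher(self):
        c = gen_fluctuation_series(
            "area", {"k_a": 0.3, "mean_area": 40.0, "temperature": 300.0, "n": 10}
        )
        assert len(c) == 10
        with pytest.raises(ValueError, match="kind"):
            gen_fluctuation_series("bogus", {})


class TestPDAndDiffraction:
    def test_pd_curve_noiseless_exact(self):
        grid = np.linspace(0.2, 1.2, 11)
        curve = gen_pd_curve(1e4, 0.12, grid)
        assert np.allclose(curve.pi, 1e4 * np.exp(-grid / 0.12))
        assert curve.pi_err is None

    def test_pd_curve_noise_scale(self):
        grid = np.linspace(0.2, 1.2, 400)
        curve = gen_pd_curve(1e4, 0.12, grid, noise_frac=0.1, seed=7)
        clean = 1e4 * np.exp(-grid / 0.12)
        rel = curve.pi / clean - 1.0
        assert np.std(rel) == pytest.approx(0.1, rel=0.2)
        assert np.allclose(curve.pi_err, 0.1 * clean)

    def test_diffraction_peak_positions(self):
        pattern = gen_diffraction(54.0, [1, 2, 3])
        for h in (1, 2, 3):
            qc = 2 * np.pi * h / 54.0
            sel = np.abs(pattern.q - qc) < 0.02
            top = pattern.q[sel][np.argmax(pattern.intensity[sel])]
            assert top == pytest.approx(qc, abs=2e-3)

    def test_diffraction_offset_and_background(self):
        pattern = gen_diffraction(54.0, [1], background=25.0, q_offset=0.005)
        qc = 2 * np.pi / 54.0 + 0.005
        sel = np.abs(pattern.q - qc) < 0.02
        top = pattern.q[sel][np.argmax(pattern.intensity[sel])]
        assert top == pytest.approx(qc, abs=2e-3)
        assert pattern.intensity.min() == pytest.approx(25.0, abs=0.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            gen_pd_curve(1.0, -0.1, [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            gen_diffraction(-1.0, [1])
        with pytest.raises(ValueError):
            gen_diffraction(54.0, [])
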