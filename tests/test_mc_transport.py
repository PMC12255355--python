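import numpy as np
import pytest

import pafluence as pf
from pafluence.errors import ConfigurationError, ValidationError
from pafluence.optics_core import dominant_attenuation


def log_slope(profile, lo, hi, weight_r=False):
    """OLS log-slope of phi (optionally r*phi) between lo and hi mm."""
    m = (profile.r >= lo) & (profile.r <= hi) & (profile.phi > 0)
    y = np.log(profile.phi[m] * (profile.r[m] if weight_r else 1.0))
    return np.polyfit(profile.r[m], y, 1)[0]


class TestHenyeyGreensteinSampler:
    @pytest.mark.parametrize("g", [0.0, 0.9])
    def test_mean_deflection_cosine_equals_anisotropy(self, g):
        n = 1_000_000
        cost = pf.hg_samples(g, n, seed=123)
        assert cost.min() >= -1.0 and cost.max() <= 1.0
        se = cost.std() / np.sqrt(n)
        assert abs(cost.mean() - g) < 3.0 * se + 1e-12


class TestEnergyLedger:
    def test_balance_within_roulette_tolerance(self, scattering_medium, warm_mc):
        vol = pf.homogeneous_volume(20.0, 0.4, scattering_medium)
        src = pf.SourceSpec(kind="isotropic_point")
        _, ledger = pf.run_mc(vol, src, photons=10_000, seed=4)
        assert abs(ledger.relative_imbalance) <= 0.005
        # exact identity once the roulette book-keeping is included
        assert (
            ledger.absorbed_weight
            + ledger.escaped_weight
            - ledger.rouletted_weight_bias
        ) == pytest.approx(ledger.launched_weight, rel=1e-9)


class TestRefusals:
    def test_too_few_photons_refused(self, scattering_medium):
        vol = pf.homogeneous_volume(10.0, 0.5, scattering_medium)
        with pytest.raises(ConfigurationError):
            pf.run_mc(vol, pf.SourceSpec(kind="isotropic_point"), photons=500, seed=1)

    def test_missing_seed_refused(self, scattering_medium):
        vol = pf.homogeneous_volume(10.0, 0.5, scattering_medium)
        with pytest.raises(ConfigurationError):
            pf.run_mc(vol, pf.SourceSpec(kind="isotropic_point"), photons=2000)

    def test_oversized_aperture_refused(self, scattering_medium):
        vol = pf.homogeneous_volume(10.0, 0.5, scattering_medium)
        src = pf.SourceSpec(kind="rect_aperture", width=30.0, height=2.0)
        with pytest.raises(ConfigurationError):
            pf.run_mc(vol, src, photons=2000, seed=1)


class TestProfileGeometry:
    def test_point_source_axial_profile_samples(self, scattering_medium, warm_mc):
        """Axial ray from a centered point source: one sample per voxel center
        from half a voxel to the volume edge."""
        vol = pf.homogeneous_volume(24.0, 0.5, scattering_medium)  # 48^3 voxels
        src = pf.SourceSpec(kind="isotropic_point")
        fv, _ = pf.run_mc(vol, src, photons=2_000, seed=9)
        prof = pf.extract_profile(fv, src, mode="axial")
        assert prof.r.size == 24
        assert prof.r[0] == pytest.approx(0.25)
        assert prof.r[-1] == pytest.approx(11.75)

    def test_face_source_profile_starts_at_first_interior_voxel(
        self, scattering_medium, warm_mc
    ):
        vol = pf.homogeneous_volume(10.0, 0.5, scattering_medium)
        src = pf.SourceSpec(kind="rect_aperture", width=6.0, height=2.0)
        fv, _ = pf.run_mc(vol, src, photons=5_000, seed=9)
        prof = pf.extract_profile(fv, src, mode="axial")
        assert prof.r[0] == pytest.approx(0.25)

    def test_lateral_offset_shifts_profile_column(self, scattering_medium, warm_mc):
        vol = pf.homogeneous_volume(10.0, 0.5, scattering_medium)
        src = pf.SourceSpec(kind="rect_aperture", width=6.0, height=2.0)
        fv, _ = pf.run_mc(vol, src, photons=20_000, seed=13)
        on_axis = pf.extract_profile(fv, src, mode="axial")
        off_axis = pf.extract_profile(fv, src, mode="axial", lateral_offset_mm=2.0)
        assert on_axis.r.size == off_axis.r.size
        assert not np.array_equal(on_axis.phi, off_axis.phi)
        with pytest.raises(ValidationError):
            pf.extract_profile(fv, src, mode="axial", lateral_offset_mm=50.0)

    def test_multilayer_volume_transports_and_balances(self, warm_mc):
        """Skin-fat-muscle stack: the engine handles per-voxel properties and
        the fluence reaches every layer."""
        palette = {
            "skin": pf.tissue_properties("skin", 700),
            "fat": pf.tissue_properties("fat", 700),
            "muscle": pf.tissue_properties("muscle", 700),
        }
        vol = pf.build_layered_volume(
            (40, 40, 50), 0.4, [(1.2, "skin"), (2.0, "fat"), (None, "muscle")], palette
        )
        src = pf.SourceSpec(kind="rect_aperture", width=10.0, height=2.0)
        fv, ledger = pf.run_mc(vol, src, photons=30_000, seed=17)
        assert abs(ledger.relative_imbalance) <= 0.005
        prof = pf.extract_profile(fv, src, mode="lateral_mean")
        assert np.all(prof.phi[prof.r < 10.0] > 0)

    def test_subsurface_fluence_peak_for_collimated_aperture(self, warm_mc):
        """Backscatter builds the fluence up to a shallow subsurface peak in a
        scattering-dominant medium."""
        props = pf.tissue_properties("muscle", 700)
        vol = pf.homogeneous_volume((40.0, 24.0, 24.0), 0.4, props)
        src = pf.SourceSpec(kind="rect_aperture", width=30.0, height=2.0)
        fv, _ = pf.run_mc(vol, src, photons=100_000, seed=21)
        prof = pf.extract_profile(fv, src, mode="lateral_mean", max_r_mm=10.0)
        peak_depth = prof.r[np.argmax(prof.phi)]
        assert 0.2 <= peak_depth <= 3.0


class TestDiffusionOracleAgreement:
    def test_point_source_log_slope_matches_greens_function(
        self, scattering_medium, warm_mc
    ):
        """r*phi decays at the diffusion rate mueff for 1-10 mm."""
        vol = pf.homogeneous_volume(30.0, 0.3, scattering_medium)
        src = pf.SourceSpec(kind="isotropic_point")
        fv, _ = pf.run_mc(vol, src, photons=300_000, seed=31)
        prof = pf.extract_profile(fv, src, mode="radial", max_r_mm=12.0)
        mueff = pf.effective_attenuation(scattering_medium)
        slope = log_slope(prof, 1.0, 10.0, weight_r=True)
        assert slope == pytest.approx(-mueff, rel=0.05)

    def test_plane_source_log_slope_matches_greens_function(
        self, scattering_medium, warm_mc
    ):
        vol = pf.homogeneous_volume((24.0, 24.0, 18.0), 0.3, scattering_medium)
        src = pf.SourceSpec(kind="infinite_plane")
        fv, _ = pf.run_mc(vol, src, photons=200_000, seed=32)
        prof = pf.extract_profile(fv, src, mode="lateral_mean", max_r_mm=12.0)
        mueff = pf.effective_attenuation(scattering_medium)
        slope = log_slope(prof, 1.0, 10.0)
        assert slope == pytest.approx(-mueff, rel=0.05)


class TestStochasticBehaviour:
    def test_seed_invariance_of_windowed_slopes(self, scattering_medium, warm_mc):
        """Two seeds give statistically overlapping windowed b estimates."""
        vol = pf.homogeneous_volume(24.0, 0.4, scattering_medium)
        src = pf.SourceSpec(kind="isotropic_point")
        mueff = pf.effective_attenuation(scattering_medium)
        values = []
        for seed in (101, 202):
            fv, _ = pf.run_mc(vol, src, photons=150_000, seed=seed)
            prof = pf.extract_profile(fv, src, mode="radial", max_r_mm=11.0)
            fit = pf.estimate_b(prof, mueff, converge_range_mm=(1.0, 8.0))
            mask = (fit.window_centers >= 1.0) & (fit.window_centers <= 8.0)
            vals = fit.b_local[mask]
            values.append((vals.mean(), 3.0 * vals.std() / np.sqrt(vals.size)))
        (m1, e1), (m2, e2) = values
        assert abs(m1 - m2) < e1 + e2

    def test_identical_seed_reproduces_fluence(self, scattering_medium, warm_mc):
        vol = pf.homogeneous_volume(12.0, 0.4, scattering_medium)
        src = pf.SourceSpec(kind="isotropic_point")
        a, _ = pf.run_mc(vol, src, photons=20_000, seed=55)
        b, _ = pf.run_mc(vol, src, photons=20_000, seed=55)
        assert np.array_equal(a.grid, b.grid)

    def test_variance_scales_inversely_with_photon_count(
        self, scattering_medium, warm_mc
    ):
        """Doubling the photons roughly halves the run-to-run profile
        variance (measured from paired independent runs, which isolates the
        Monte Carlo noise from the deterministic profile shape)."""
        vol = pf.homogeneous_volume(24.0, 0.4, scattering_medium)
        src = pf.SourceSpec(kind="isotropic_point")

        def paired_noise_var(photons, seeds):
            profs = []
            for s in seeds:
                fv, _ = pf.run_mc(vol, src, photons=photons, seed=s)
                profs.append(pf.extract_profile(fv, src, mode="axial"))
            m = (
                (profs[0].r >= 2.0)
                & (profs[0].r <= 9.0)
                & (profs[0].phi > 0)
                & (profs[1].phi > 0)
            )
            diff = np.log(profs[0].phi[m]) - np.log(profs[1].phi[m])
            return np.var(diff) / 2.0  # per-profile noise variance

        v1 = paired_noise_var(40_000, (1, 2))
        v2 = paired_noise_var(80_000, (3, 4))
        assert v2 < v1
        assert v1 / v2 == pytest.approx(2.0, rel=0.6)


class TestNumericalAperture:
    def test_na_tilt_keeps_geometry_parameter_near_half(self, warm_mc):
        """A realistic fiber NA (~0.2) perturbs b only slightly."""
        props = pf.reference_medium("mus_mua_100")
        vol = pf.homogeneous_volume((40.0, 24.0, 24.0), 0.4, props)
        mueff = pf.effective_attenuation(props)
        bs = {}
        for na in (0.0, 0.2):
            src = pf.SourceSpec(
                kind="rect_aperture", width=30.0, height=2.0, numerical_aperture=na
            )
            fv, _ = pf.run_mc(vol, src, photons=200_000, seed=61)
            prof = pf.extract_profile(fv, src, mode="lateral_mean", max_r_mm=11.0)
            bs[na] = pf.estimate_b(prof, mueff, converge_range_mm=(1.0, 8.0)).b_converged
        assert abs(bs[0.2] - bs[0.0]) < 0.15
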