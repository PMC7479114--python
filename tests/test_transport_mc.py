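"""Monte-Carlo engine: sampling laws, stepping, estimators, statistics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from shapely.geometry import box as shapely_box

from suburbdose.fixtures import make_wall_scenario
from suburbdose.geometry import Scenario, Solid, SourceRegion, DetectorSphere
from suburbdose.materials import material_library
from suburbdose.transport_mc import (
    MEC2,
    PhotonState,
    TallySpectrum,
    klein_nishina_sample,
    kn_differential,
    kn_total_cross_section,
    next_event_estimate,
    run_transport,
    sample_source,
    statistical_checks,
    step_and_interact,
)

E0 = 0.662


@pytest.fixture(scope="module")
def water_world():
    """Homogeneous water everywhere (solid overlapping the whole world)."""
    return Scenario(
        materials=material_library(),
        solids=[Solid((-60, -60, -60), (60, 60, 60), "water")],
        regions={"R": SourceRegion("R", shapely_box(-1, -1, 1, 1))},
        detectors={},
        world_radius=60.0,
        z_range=(-60.0, 60.0),
    )


class TestSourceSampling:
    def test_isotropy_upward_fraction(self):
        region = SourceRegion("sq", shapely_box(0, 0, 10, 10))
        rng = np.random.default_rng(2)
        up = sum(
            sample_source(region, rng).direction[2] > 0 for _ in range(20_000)
        )
        se = math.sqrt(20_000 * 0.25)
        assert abs(up - 10_000) < 3 * se

    def test_birth_energy_and_plane(self):
        region = SourceRegion("sq", shapely_box(0, 0, 10, 10))
        rng = np.random.default_rng(3)
        for _ in range(100):
            s = sample_source(region, rng)
            assert s.energy == E0
            assert s.position[2] == 0.0
            assert s.weight == 1.0

    def test_seeded_birth_sequence_reproducible(self):
        region = SourceRegion("sq", shapely_box(0, 0, 10, 10))
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        for _ in range(50):
            s1, s2 = sample_source(region, r1), sample_source(region, r2)
            np.testing.assert_array_equal(s1.position, s2.position)
            np.testing.assert_array_equal(s1.direction, s2.direction)


class TestKleinNishina:
    def test_forward_scatter_loses_no_energy(self):
        k = E0 / MEC2
        assert E0 / (1 + k * (1 - math.cos(0.0))) == pytest.approx(E0)

    def test_backscatter_energy_is_0p1844_mev(self):
        """Compton kinematics: 0.662 MeV photons backscatter at 0.1844 MeV."""
        k = E0 / MEC2
        e_back = E0 / (1 + 2 * k)
        assert e_back == pytest.approx(0.1844, abs=5e-4)
        rng = np.random.default_rng(4)
        samples = [klein_nishina_sample(E0, rng)[0] for _ in range(20_000)]
        assert min(samples) >= e_back - 1e-12

    def test_closed_form_total_matches_quadrature(self):
        for e in (0.05, 0.1844, 0.662):
            q, _ = quad(lambda c: 2 * math.pi * kn_differential(e, c), -1, 1)
            assert kn_total_cross_section(e) == pytest.approx(q, rel=1e-9)

    def test_sampled_mean_energy_matches_quadrature(self):
        """Kahn's rejection sampler reproduces the Klein-Nishina mean
        scattered energy within 3 sigma."""
        rng = np.random.default_rng(5)
        n = 100_000
        samples = np.array(
            [klein_nishina_sample(E0, rng)[0] for _ in range(n)]
        )
        k = E0 / MEC2
        num = quad(
            lambda c: 2 * math.pi * kn_differential(E0, c)
            * E0 / (1 + k * (1 - c)),
            -1, 1,
        )[0]
        mean_exact = num / kn_total_cross_section(E0)
        se = samples.std() / math.sqrt(n)
        assert abs(samples.mean() - mean_exact) < 3 * se

    def test_energy_angle_consistency(self):
        rng = np.random.default_rng(6)
        k = E0 / MEC2
        for _ in range(200):
            e, theta = klein_nishina_sample(E0, rng)
            assert e == pytest.approx(
                E0 / (1 + k * (1 - math.cos(theta))), rel=1e-9
            )


class TestStepping:
    def test_mean_free_path_in_homogeneous_water(self, water_world):
        mu = water_world.materials["water"].linear_attenuation(E0)  # 1/cm
        rng = np.random.default_rng(7)
        n = 4000
        dists = []
        for _ in range(n):
            s = PhotonState(np.array([0.0, 0.0, 0.0]),
                            np.array([0.0, 0.0, 1.0]), E0)
            out, event = step_and_interact(s, water_world, rng)
            if event == "escape":
                continue
            pos = out.position if out is not None else None
            if pos is None:
                # absorbed at the collision point: re-run is not possible,
                # but the flight itself happened; skip (photoelectric is
                # rare at 0.662 MeV so statistics are barely affected)
                continue
            dists.append(pos[2] * 100.0)  # cm
        mfp = 1.0 / mu
        se = mfp / math.sqrt(len(dists))
        assert abs(np.mean(dists) - mfp) < 3 * se

    def test_near_vacuum_photon_escapes(self):
        sc = Scenario(
            materials=material_library(),
            solids=[],
            regions={"R": SourceRegion("R", shapely_box(-1, -1, 1, 1))},
            detectors={},
            world_radius=20.0,
            z_range=(-1.0, 20.0),
        )
        rng = np.random.default_rng(8)
        n = 400
        escapes = 0
        for _ in range(n):
            s = PhotonState(np.array([0.0, 0.0, 1.0]),
                            np.array([1.0, 0.0, 0.0]), E0)
            _, event = step_and_interact(s, sc, rng)
            escapes += event == "escape"
        mu = sc.materials["air"].linear_attenuation(E0)  # 1/cm
        p = math.exp(-mu * 20.0 * 100.0)  # 20 m to the world boundary
        se = math.sqrt(n * p * (1 - p))
        assert abs(escapes - n * p) < 3 * se

    def test_photoelectric_dominates_brick_at_50_kev(self):
        lib = material_library()
        sc = Scenario(
            materials=lib,
            solids=[Solid((-60, -60, -60), (60, 60, 60), "brick")],
            regions={"R": SourceRegion("R", shapely_box(-1, -1, 1, 1))},
            detectors={},
            world_radius=60.0,
            z_range=(-60.0, 60.0),
        )
        expect = float(lib["brick"].table.photoelectric_fraction(0.05))
        assert expect > 0.5
        rng = np.random.default_rng(9)
        n = 3000
        photo = 0
        counted = 0
        for _ in range(n):
            s = PhotonState(np.array([0.0, 0.0, 0.0]),
                            np.array([0.0, 0.0, 1.0]), 0.05)
            _, event = step_and_interact(s, sc, rng)
            if event in ("photoelectric", "compton", "cutoff"):
                counted += 1
                photo += event == "photoelectric"
        se = math.sqrt(expect * (1 - expect) * counted)
        assert abs(photo - expect * counted) < 3 * se


class TestNextEvent:
    def test_isotropic_point_inverse_square(self):
        """Birth event at distance r: expected fluence 1/(4 pi r^2) times
        the (near-unity) air transmission."""
        sc = make_wall_scenario("brick", 0.0, distance=10.0)
        det = sc.detectors["DET"]
        mu_air = sc.materials["air"].linear_attenuation(E0)
        r_m = math.sqrt(10.0**2 + 1.0)
        got, e = next_event_estimate((0.0, 0.0, 0.0), det, sc, E0)
        expect = math.exp(-mu_air * r_m * 100.0) / (
            4 * math.pi * (r_m * 100.0) ** 2
        )
        assert e == E0
        assert got == pytest.approx(expect, rel=1e-9)

    def test_slab_attenuates_by_narrow_beam_factor(self):
        thick = make_wall_scenario("brick", 0.25, distance=10.0)
        empty = make_wall_scenario("brick", 0.0, distance=10.0)
        mu_b = thick.materials["brick"].linear_attenuation(E0)
        mu_a = thick.materials["air"].linear_attenuation(E0)
        # the detector line crosses the slab slightly obliquely (dz/dx = 0.1)
        sec = math.sqrt(1.0 + 0.1**2)
        got_t, _ = next_event_estimate((0.0, 0.0, 0.0),
                                       thick.detectors["DET"], thick, E0)
        got_e, _ = next_event_estimate((0.0, 0.0, 0.0),
                                       empty.detectors["DET"], empty, E0)
        expect = math.exp(-(mu_b - mu_a) * 0.25 * sec * 100.0)
        assert got_t / got_e == pytest.approx(expect, rel=1e-9)

    def test_event_inside_sphere_falls_back(self):
        sc = make_wall_scenario("brick", 0.0, distance=10.0)
        det = sc.detectors["DET"]
        assert next_event_estimate((10.0, 0.0, 1.05), det, sc, E0) is None


class TestRunTransport:
    def test_seeded_run_is_bit_identical(self):
        sc = make_wall_scenario("brick", 0.25, distance=5.0)
        a = run_transport(sc, n_histories=1000, seed=13)
        b = run_transport(sc, n_histories=1000, seed=13)
        assert (a["kerma"] == b["kerma"]).all()
        assert (a["rel_err"] == b["rel_err"]).all()

    def test_kerma_linear_in_areal_activity(self):
        sc1 = make_wall_scenario("brick", 0.25, distance=5.0)
        sc2 = make_wall_scenario("brick", 0.25, distance=5.0)
        sc2.regions["CELL"].areal_activity = 2.0
        a = run_transport(sc1, n_histories=1000, seed=13)
        b = run_transport(sc2, n_histories=1000, seed=13)
        assert b["kerma"].iloc[0] == pytest.approx(
            2.0 * a["kerma"].iloc[0], rel=1e-12
        )

    def test_history_floor_enforced(self):
        sc = make_wall_scenario("brick", 0.25, distance=5.0)
        with pytest.raises(ValueError):
            run_transport(sc, n_histories=100, seed=1)

    def test_mirror_symmetric_regions_agree(self):
        """Two source cells mirror-placed about the detector give equal
        kerma within combined statistics."""
        lib = material_library()
        sc = Scenario(
            materials=lib,
            solids=[],
            regions={
                "L": SourceRegion("L", shapely_box(-10.5, -0.5, -9.5, 0.5)),
                "R": SourceRegion("R", shapely_box(9.5, -0.5, 10.5, 0.5)),
            },
            detectors={"DET": DetectorSphere("DET", (0.0, 0.0, 1.0))},
            world_radius=100.0,
        )
        m = run_transport(sc, n_histories=4000, seed=17)
        kl = m[m.region == "L"].kerma.iloc[0]
        kr = m[m.region == "R"].kerma.iloc[0]
        sig = math.hypot(
            kl * m[m.region == "L"].rel_err.iloc[0],
            kr * m[m.region == "R"].rel_err.iloc[0],
        )
        assert abs(kl - kr) < 3 * max(sig, 1e-12 * kl)


def _make_tally(batch_means, total_rel_err=0.02, vov=0.01, max_frac=0.05):
    bm = np.asarray(batch_means, dtype=float)
    return TallySpectrum(
        bin_edges=np.geomspace(0.01, 0.662, 34),
        fluence=np.full(33, bm.mean() / 33),
        bin_rel_err=np.zeros(33),
        total=float(bm.mean()),
        total_rel_err=total_rel_err,
        batch_means=bm,
        n_histories=10_000,
        vov=vov,
        max_history_fraction=max_frac,
    )


class TestStatisticalChecks:
    def test_converged_tally_passes(self):
        rng = np.random.default_rng(21)
        tally = _make_tally(1.0 + 0.01 * rng.standard_normal(20),
                            total_rel_err=0.002)
        assert statistical_checks(tally)["status"] == "pass"

    def test_dominant_history_named(self):
        rng = np.random.default_rng(22)
        tally = _make_tally(1.0 + 0.01 * rng.standard_normal(20),
                            total_rel_err=0.002, max_frac=0.9)
        report = statistical_checks(tally)
        assert report["status"] == "fail"
        assert "history_dominance" in report["failed"]

    def test_non_shrinking_error_fails(self):
        rng = np.random.default_rng(23)
        # batch means whose spread grows: error does not shrink like 1/sqrt N
        drift = np.concatenate(
            [1.0 + 0.001 * rng.standard_normal(10),
             1.0 + 0.8 * rng.standard_normal(10)]
        )
        report = statistical_checks(_make_tally(drift, total_rel_err=0.002))
        assert report["status"] == "fail"

    def test_too_few_batches_inconclusive(self):
        tally = _make_tally(np.ones(5))
        assert statistical_checks(tally)["status"] == "inconclusive"
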