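"""Monte-Carlo photon transport from planar surface sources to detectors.

Histories start uniformly on a source region at z = 0 with isotropic
direction and 0.662 MeV.  Transport is analog: free paths are sampled from
the heterogeneous attenuation along the exact ray-traced path, collisions
branch between photoelectric absorption and Compton scattering with
probabilities from the embedded coefficient tables, and Compton kinematics
follow the free-electron Klein-Nishina law (Kahn's rejection sampling).
Photons are terminated below 0.01 MeV.

Two estimators are available: a track-length fluence tally in the 30 cm
detector spheres ("analog"), and a next-event (point-detector) estimator
("next-event", the default) that scores the analytically attenuated
expected contribution to every detector at each birth and Compton event,
giving desk-scale variance at small history counts.  Fluence is folded
into air kerma with the energy-dependent kerma-per-fluence coefficient at
scoring time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from suburbdose.geometry import DetectorSphere, Scenario, SourceRegion
from suburbdose.materials import SOURCE_ENERGY_MEV
from suburbdose.pointkernel import kerma_per_fluence

__all__ = [
    "PhotonState",
    "TallySpectrum",
    "sample_source",
    "klein_nishina_sample",
    "kn_total_cross_section",
    "kn_differential",
    "step_and_interact",
    "next_event_estimate",
    "run_transport",
    "statistical_checks",
]

MEC2 = 0.51099895  # MeV
R_E2 = 7.940787e-26  # classical electron radius squared, cm^2
ENERGY_CUTOFF = 0.01  # MeV
ROULETTE_WEIGHT = 1e-3
ROULETTE_SURVIVAL = 0.1
N_ENERGY_BINS = 33
M_TO_CM = 100.0


@dataclass
class PhotonState:
    position: np.ndarray  # m
    direction: np.ndarray  # unit
    energy: float  # MeV
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        assert abs(np.linalg.norm(self.direction) - 1.0) < 1e-9
        assert self.weight > 0


@dataclass
class TallySpectrum:
    """Track-length (or next-event) fluence spectrum with batch statistics."""

    bin_edges: np.ndarray  # MeV, len nbins+1
    fluence: np.ndarray  # per source photon, cm^-2, len nbins
    bin_rel_err: np.ndarray
    total: float
    total_rel_err: float
    batch_means: np.ndarray
    n_histories: int
    vov: float
    max_history_fraction: float

    @property
    def total_from_bins(self) -> float:
        return float(self.fluence.sum())


# --------------------------------------------------------------------------
# Klein-Nishina


def kn_total_cross_section(energy_mev: float) -> float:
    """Total Klein-Nishina cross-section per electron, cm^2 (closed form)."""
    k = energy_mev / MEC2
    t = 1.0 + 2.0 * k
    return (
        2.0
        * math.pi
        * R_E2
        * (
            (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - math.log(t) / k)
            + math.log(t) / (2.0 * k)
            - (1.0 + 3.0 * k) / t**2
        )
    )


def kn_differential(energy_mev: float, cos_theta) -> np.ndarray | float:
    """d(sigma)/d(Omega) per electron, cm^2/sr, free-electron Klein-Nishina."""
    k = energy_mev / MEC2
    c = np.asarray(cos_theta, dtype=float)
    ratio = 1.0 / (1.0 + k * (1.0 - c))
    out = 0.5 * R_E2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - c**2))
    return float(out) if np.isscalar(cos_theta) else out


def klein_nishina_sample(
    energy_mev: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Sample (scattered energy MeV, polar angle rad) by Kahn's method."""
    k = energy_mev / MEC2
    branch_p = (1.0 + 2.0 * k) / (9.0 + 2.0 * k)
    while True:
        r1, r2, r3 = rng.random(3)
        if r1 <= branch_p:
            x = 1.0 + 2.0 * k * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / x**2):
                break
        else:
            x = (1.0 + 2.0 * k) / (1.0 + 2.0 * k * r2)
            cos_t = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (cos_t**2 + 1.0 / x):
                break
    cos_t = 1.0 - (x - 1.0) / k
    return energy_mev / x, math.acos(max(-1.0, min(1.0, cos_t)))


def _rotate(direction: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """New unit vector at polar angle theta (azimuth phi) to ``direction``."""
    d = direction
    if abs(d[2]) < 0.99999:
        u = np.cross([0.0, 0.0, 1.0], d)
    else:
        u = np.cross([1.0, 0.0, 0.0], d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    st = math.sin(theta)
    out = (
        math.cos(theta) * d
        + st * math.cos(phi) * u
        + st * math.sin(phi) * v
    )
    return out / np.linalg.norm(out)


# --------------------------------------------------------------------------
# sampling and stepping


def sample_source(region: SourceRegion, rng: np.random.Generator) -> PhotonState:
    """Birth state: uniform on the region at z = 0, isotropic, 0.662 MeV."""
    xy = region.sample_points(1, rng)[0]
    cos_t = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    st = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    direction = np.array([st * math.cos(phi), st * math.sin(phi), cos_t])
    return PhotonState(
        position=np.array([xy[0], xy[1], 0.0]),
        direction=direction,
        energy=SOURCE_ENERGY_MEV,
        weight=1.0,
    )


def _fly(state: PhotonState, scenario: Scenario, rng: np.random.Generator):
    """Sample the next collision along the ray; returns
    (collision position | None, material name | None, flight length m)."""
    segments = scenario.ray_trace(state.position, state.direction)
    if not segments:
        return None, None, 0.0
    xi = rng.exponential()
    travelled = 0.0
    acc = 0.0
    for length, mat in segments:
        mu = float(scenario.materials[mat].linear_attenuation(state.energy))
        seg_tau = mu * length * M_TO_CM
        if acc + seg_tau >= xi:
            s = (xi - acc) / (mu * M_TO_CM)
            travelled += s
            pos = state.position + travelled * state.direction
            return pos, mat, travelled
        acc += seg_tau
        travelled += length
    return None, None, travelled  # escaped the world


def step_and_interact(
    state: PhotonState,
    scenario: Scenario,
    rng: np.random.Generator,
    energy_cutoff: float = ENERGY_CUTOFF,
):
    """Advance one flight + collision; returns (next state | None, event).

    ``event`` is one of "compton", "photoelectric", "escape", "cutoff",
    "roulette"."""
    pos, mat, _ = _fly(state, scenario, rng)
    if pos is None:
        return None, "escape"
    table = scenario.materials[mat].table
    if rng.random() < float(table.photoelectric_fraction(state.energy)):
        return None, "photoelectric"
    e_out, theta = klein_nishina_sample(state.energy, rng)
    if e_out < energy_cutoff:
        return None, "cutoff"
    phi = rng.uniform(0.0, 2.0 * math.pi)
    new = PhotonState(
        position=pos,
        direction=_rotate(state.direction, theta, phi),
        energy=e_out,
        weight=state.weight,
    )
    if new.weight < ROULETTE_WEIGHT:
        if rng.random() < ROULETTE_SURVIVAL:
            new.weight /= ROULETTE_SURVIVAL
        else:
            return None, "roulette"
    return new, "compton"


def next_event_estimate(
    point,
    detector: DetectorSphere,
    scenario: Scenario,
    energy_mev: float,
    weight: float = 1.0,
    incoming_direction=None,
) -> tuple[float, float] | None:
    """Expected fluence contribution (cm^-2 per source photon) at a detector.

    For a birth event pass ``incoming_direction=None`` (isotropic emission);
    for a Compton event pass the pre-collision flight direction, in which
    case the angular density and scattered energy follow the free-electron
    Klein-Nishina law toward the detector.  Returns (contribution, scored
    energy), or None when the event lies inside the detector sphere (the
    caller falls back to analog-only scoring for that event).
    """
    point = np.asarray(point, dtype=float)
    center = np.asarray(detector.center, dtype=float)
    rvec = center - point
    r_m = float(np.linalg.norm(rvec))
    if r_m < detector.radius:
        return None
    u = rvec / r_m
    if incoming_direction is None:
        pdf = 1.0 / (4.0 * math.pi)
        e_out = energy_mev
    else:
        cos_t = float(np.dot(np.asarray(incoming_direction, float), u))
        k = energy_mev / MEC2
        e_out = energy_mev / (1.0 + k * (1.0 - cos_t))
        pdf = kn_differential(energy_mev, cos_t) / kn_total_cross_section(
            energy_mev
        )
    if e_out < ENERGY_CUTOFF:
        return 0.0, e_out
    tau = float(scenario.optical_depth_multi(point, center[None, :],
                                             np.array([e_out]))[0])
    r_cm = r_m * M_TO_CM
    return weight * pdf * math.exp(-tau) / r_cm**2, e_out


def _sphere_chord(p0, direction, s, center, radius) -> float:
    """Chord length (m) of segment [p0, p0 + s*dir] inside a sphere."""
    f = p0 - center
    b = float(np.dot(f, direction))
    c = float(np.dot(f, f)) - radius * radius
    disc = b * b - c
    if disc <= 0:
        return 0.0
    sq = math.sqrt(disc)
    t0, t1 = max(-b - sq, 0.0), min(-b + sq, s)
    return max(t1 - t0, 0.0)


# --------------------------------------------------------------------------
# tallies


class _PairTally:
    """Accumulates per-history kerma and fluence spectrum for one
    (region, detector) pair."""

    __slots__ = ("edges", "bins", "bins_sq", "hist", "n", "s1", "s2", "s3",
                 "s4", "max_hist", "batch_sums", "bin_hist")

    def __init__(self, n_batches: int) -> None:
        self.edges = np.geomspace(ENERGY_CUTOFF, SOURCE_ENERGY_MEV,
                                  N_ENERGY_BINS + 1)
        self.bins = np.zeros(N_ENERGY_BINS)
        self.bins_sq = np.zeros(N_ENERGY_BINS)
        self.bin_hist = np.zeros(N_ENERGY_BINS)
        self.hist = 0.0
        self.n = 0
        self.s1 = self.s2 = self.s3 = self.s4 = 0.0
        self.max_hist = 0.0
        self.batch_sums = np.zeros(n_batches)

    def score(self, fluence: float, energy: float) -> None:
        idx = int(np.clip(np.searchsorted(self.edges, energy, "right") - 1,
                          0, N_ENERGY_BINS - 1))
        self.bin_hist[idx] += fluence
        self.hist += fluence

    def close_history(self, batch: int) -> None:
        x = self.hist
        self.n += 1
        self.s1 += x
        self.s2 += x * x
        self.s3 += x**3
        self.s4 += x**4
        self.max_hist = max(self.max_hist, x)
        self.batch_sums[batch] += x
        self.bins += self.bin_hist
        self.bins_sq += self.bin_hist**2
        self.hist = 0.0
        self.bin_hist[:] = 0.0

    def spectrum(self, histories_per_batch: np.ndarray) -> TallySpectrum:
        n = self.n
        mean = self.s1 / n if n else 0.0
        var = max(self.s2 / n - mean * mean, 0.0) / max(n - 1, 1) * n
        rel = math.sqrt(var / n) / mean if mean > 0 and n > 1 else 0.0
        bmean = self.bins / n if n else self.bins
        bvar = np.maximum(self.bins_sq / n - bmean**2, 0.0)
        brel = np.zeros_like(bmean)
        nz = bmean > 0
        brel[nz] = np.sqrt(bvar[nz] / n) / bmean[nz]
        # variance of the variance (relative), from central moments
        if n > 3 and mean > 0:
            m1 = mean
            c2 = self.s2 / n - m1**2
            c4 = (self.s4 / n - 4 * m1 * self.s3 / n + 6 * m1**2 * self.s2 / n
                  - 3 * m1**4)
            vov = (c4 - c2**2) / (n * c2**2) if c2 > 0 else 0.0
        else:
            vov = 0.0
        batches = self.batch_sums / np.maximum(histories_per_batch, 1)
        return TallySpectrum(
            bin_edges=self.edges,
            fluence=bmean,
            bin_rel_err=brel,
            total=mean,
            total_rel_err=rel,
            batch_means=batches,
            n_histories=n,
            vov=max(vov, 0.0),
            max_history_fraction=(self.max_hist / self.s1) if self.s1 > 0 else 0.0,
        )


def statistical_checks(tally: TallySpectrum) -> dict:
    """Convergence report for one tally, in the spirit of the standard
    battery of Monte-Carlo reliability tests.

    Checks: total relative error < 0.10; relative error shrinking like
    1/sqrt(N) across batches (within a factor of 2); batch-mean drift small
    compared to the statistical error; relative variance-of-variance < 0.10;
    no single history contributing more than half the mean."""
    nb = len(tally.batch_means)
    if nb < 10:
        return {"status": "inconclusive", "reason": f"only {nb} batches"}
    checks: dict[str, bool] = {}
    checks["relative_error"] = tally.total_rel_err < 0.10
    half = tally.batch_means[: nb // 2]
    re_half = (np.std(half, ddof=1) / math.sqrt(len(half)) / np.mean(half)
               if np.mean(half) > 0 else np.inf)
    re_full = (np.std(tally.batch_means, ddof=1) / math.sqrt(nb)
               / np.mean(tally.batch_means)
               if np.mean(tally.batch_means) > 0 else np.inf)
    ratio = re_half / re_full if re_full > 0 else np.inf
    checks["error_decay"] = math.sqrt(2.0) / 2.0 <= ratio <= 2.0 * math.sqrt(2.0)
    mean = np.mean(tally.batch_means)
    drift = (abs(np.mean(tally.batch_means[nb // 2:]) - np.mean(half))
             / mean if mean > 0 else np.inf)
    checks["batch_drift"] = drift < max(4.0 * tally.total_rel_err, 0.02)
    checks["variance_of_variance"] = tally.vov < 0.10
    checks["history_dominance"] = tally.max_history_fraction < 0.50
    status = "pass" if all(checks.values()) else "fail"
    failed = [k for k, v in checks.items() if not v]
    return {"status": status, "checks": checks, "failed": failed}


# --------------------------------------------------------------------------
# driver


def run_transport(
    scenario: Scenario,
    regions: list[str] | None = None,
    detectors: list[str] | None = None,
    n_histories: int = 10_000,
    seed: int = 0,
    engine: str = "next-event",
    n_batches: int = 10,
    uncollided_only: bool = False,
    return_tallies: bool = False,
):
    """Monte-Carlo contribution matrix: air kerma per unit areal activity.

    ``engine`` selects the estimator filling the matrix: "next-event"
    (point-detector, default) or "analog" (track-length in the detector
    spheres).  Results are normalised per photon emitted per m^2 of region
    (one photon per decay), matching the point-kernel engine.  A fixed seed
    gives a bit-identical matrix.
    """
    if n_histories < 1_000:
        raise ValueError("n_histories must be at least 10^3 per region")
    if engine not in ("next-event", "analog"):
        raise ValueError(f"unknown engine {engine!r}")
    region_labels = regions or sorted(scenario.regions)
    det_labels = detectors or sorted(scenario.detectors)
    dets = [scenario.detectors[d] for d in det_labels]
    det_centers = np.array([d.center for d in dets])
    sphere_volumes_cm3 = np.array(
        [4.0 / 3.0 * math.pi * (d.radius * M_TO_CM) ** 3 for d in dets]
    )
    k_air = scenario.materials["air"].table
    gy_per = 1.602176634e-10  # Gy per (MeV * cm^2/g)

    def kerma_coeff(e):
        return e * gy_per * float(k_air.mass_energy_absorption(e))

    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(region_labels))
    batch_size = n_histories // n_batches

    rows = []
    tallies: dict[tuple[str, str], TallySpectrum] = {}
    for ridx, rl in enumerate(region_labels):
        region = scenario.regions[rl]
        rng = np.random.default_rng(streams[ridx])
        pair = [_PairTally(n_batches) for _ in dets]
        hist_per_batch = np.zeros(n_batches)

        for h in range(n_histories):
            batch = min(h // batch_size, n_batches - 1)
            hist_per_batch[batch] += 1
            state = sample_source(region, rng)
            if engine == "next-event":
                self_score = _score_next_event(
                    scenario, state.position, None, state.energy, state.weight,
                    det_centers, dets, pair, kerma_coeff)
            n_coll = 0
            while True:
                pos, mat, flight = _fly(state, scenario, rng)
                if engine == "analog" and flight > 0:
                    for di, det in enumerate(dets):
                        chord = _sphere_chord(
                            state.position, state.direction, flight,
                            np.asarray(det.center), det.radius)
                        if chord > 0:
                            fl = state.weight * chord * M_TO_CM / \
                                sphere_volumes_cm3[di]
                            pair[di].score(fl * kerma_coeff(state.energy),
                                           state.energy)
                if pos is None:
                    break  # escape
                table = scenario.materials[mat].table
                if rng.random() < float(
                    table.photoelectric_fraction(state.energy)
                ):
                    break
                if engine == "next-event" and not uncollided_only:
                    _score_next_event(
                        scenario, pos, state.direction, state.energy,
                        state.weight, det_centers, dets, pair, kerma_coeff)
                e_out, theta = klein_nishina_sample(state.energy, rng)
                if e_out < ENERGY_CUTOFF:
                    break
                phi = rng.uniform(0.0, 2.0 * math.pi)
                state = PhotonState(pos, _rotate(state.direction, theta, phi),
                                    e_out, state.weight)
                n_coll += 1
                if uncollided_only:
                    break
                if state.weight < ROULETTE_WEIGHT:
                    if rng.random() < ROULETTE_SURVIVAL:
                        state.weight /= ROULETTE_SURVIVAL
                    else:
                        break
            for t in pair:
                t.close_history(batch)

        scale = region.area * region.areal_activity  # photons per (1/m^2)
        for di, dl in enumerate(det_labels):
            spec = pair[di].spectrum(hist_per_batch)
            tallies[(rl, dl)] = spec
            report = statistical_checks(spec)
            rows.append(
                (rl, dl, spec.total * scale, spec.total_rel_err,
                 report["status"] != "pass")
            )

    df = pd.DataFrame(rows, columns=["region", "op", "kerma", "rel_err",
                                     "flagged"])
    df.attrs.update(
        engine=engine, seed=seed, n_histories=n_histories,
        scenario_digest=scenario.digest(),
        kerma_units="Gy per (photon m^-2)",
        uncollided_only=uncollided_only,
    )
    if return_tallies:
        return df, tallies
    return df


def _score_next_event(scenario, point, in_dir, energy, weight, det_centers,
                      dets, pair, kerma_coeff):
    """Vectorised next-event scoring of one event to all detectors."""
    point = np.asarray(point, dtype=float)
    rvec = det_centers - point[None, :]
    r_m = np.linalg.norm(rvec, axis=1)
    if in_dir is None:
        pdf = np.full(len(dets), 1.0 / (4.0 * math.pi))
        e_out = np.full(len(dets), energy)
    else:
        u = rvec / r_m[:, None]
        cos_t = u @ np.asarray(in_dir, float)
        k = energy / MEC2
        e_out = energy / (1.0 + k * (1.0 - cos_t))
        pdf = kn_differential(energy, cos_t) / kn_total_cross_section(energy)
    ok = (r_m >= np.array([d.radius for d in dets])) & (e_out >= ENERGY_CUTOFF)
    if not ok.any():
        return
    tau = scenario.optical_depth_multi(point, det_centers[ok], e_out[ok])
    contrib = weight * pdf[ok] * np.exp(-tau) / (r_m[ok] * M_TO_CM) ** 2
    for j, di in enumerate(np.nonzero(ok)[0]):
        pair[di].score(contrib[j] * kerma_coeff(float(e_out[di])),
                       float(e_out[di]))
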