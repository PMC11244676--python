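"""Synthetic thorax phantom with a metal implant and controllable artifacts.

The generator emulates the features the artifact metrics respond to, not CT
physics: a soft-tissue body ellipse with two lung ellipses, a high-HU
cylindrical implant along the slice axis, blooming as a Gaussian blur of the
implant before compositing, streaks as a low-angular-order sinusoidal
bright/dark modulation around the implant with radial decay, and additive
white Gaussian noise.  The implant's true volume is known analytically
(pi r^2 h), which gives every downstream metric a ground truth.

A companion simulator produces ordinal 1-5 reader scores from a latent
per-case quality plus reader noise, discretised through fixed cutpoints, for
testing the tallying / ICC / ordinal-regression layer.

All randomness flows through one explicit integer seed per operation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .tables import QUESTIONS, ReaderScoreTable
from .volume import CTVolume

__all__ = [
    "StreakSpec",
    "PhantomSpec",
    "ReaderSimSpec",
    "PhantomGroundTruth",
    "SyntheticCase",
    "generate_phantom",
    "simulate_reader_scores",
    "generate_case_battery",
]


@dataclass(frozen=True)
class StreakSpec:
    """Sinusoidal streak field A*cos(order*theta + phase)*exp(-d/decay).

    ``theta`` is the polar angle about the implant axis, ``d`` the radial
    distance to the implant surface (mm); the field is added outside the
    implant only.
    """

    amplitude_hu: float = 40.0
    angular_order: int = 2
    phase_rad: float = 0.0
    radial_decay_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.angular_order < 1:
            raise ValueError("angular_order must be >= 1")
        if self.radial_decay_mm <= 0:
            raise ValueError("radial_decay_mm must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, HU levels and artifact strengths of one synthetic scan.

    Defaults emulate a thorax slice stack around an implanted pump: soft
    tissue at +40 HU, lungs at -700 HU, a titanium-like plateau far above the
    soft-tissue range, sub-millimetre in-plane spacing, and mild blur/streak/
    noise levels of a reasonably corrected reconstruction.
    """

    grid_shape: tuple[int, int, int] = (32, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 0.5, 0.5)  # mm
    background_hu: float = 40.0
    lung_hu: float = -700.0
    metal_hu: float = 8000.0
    implant_center: tuple[float, float] | None = None  # (row, col) voxels; None = grid centre
    implant_radius_mm: float = 10.0
    implant_height_mm: float = 24.0
    contrast_hu: float | None = None
    contrast_center: tuple[float, float] | None = None
    contrast_radius_mm: float = 5.0
    bloom_sigma_mm: float = 0.8
    streak: StreakSpec = field(default_factory=StreakSpec)
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metal_hu <= 200.0:
            raise ValueError("metal_hu must sit well above the soft-tissue range")
        if self.implant_radius_mm <= 0 or self.implant_height_mm <= 0:
            raise ValueError("implant radius and height must be > 0")
        if self.bloom_sigma_mm < 0:
            raise ValueError("bloom_sigma_mm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Unblurred implant mask and its analytic volume."""

    implant_mask: np.ndarray
    true_volume_cm3: float
    implant_center: tuple[float, float]
    implant_radius_mm: float
    implant_height_mm: float


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomGroundTruth]:
    """Generate one synthetic volume; deterministic for a fixed seed."""
    ns, nr, nc = spec.grid_shape
    dz, dr, dc = spec.spacing
    center = spec.implant_center if spec.implant_center is not None else ((nr - 1) / 2.0, (nc - 1) / 2.0)
    r_vox_r = spec.implant_radius_mm / dr
    r_vox_c = spec.implant_radius_mm / dc
    half_h_vox = spec.implant_height_mm / (2.0 * dz)
    z_mid = (ns - 1) / 2.0
    if (
        center[0] - r_vox_r < 0 or center[0] + r_vox_r > nr - 1
        or center[1] - r_vox_c < 0 or center[1] + r_vox_c > nc - 1
        or z_mid - half_h_vox < 0 or z_mid + half_h_vox > ns - 1
    ):
        raise ValueError("implant does not fit inside the grid")

    rows, cols = np.mgrid[0:nr, 0:nc].astype(float)
    # physical in-plane coordinates relative to the implant axis, mm
    x_mm = (cols - center[1]) * dc
    y_mm = (rows - center[0]) * dr
    radius_mm = np.hypot(x_mm, y_mm)

    # background layers: air, body ellipse, two lung ellipses, optional contrast
    background = np.full((nr, nc), -1000.0)
    body = ((rows - (nr - 1) / 2) / (0.46 * nr)) ** 2 + ((cols - (nc - 1) / 2) / (0.46 * nc)) ** 2 <= 1.0
    background[body] = spec.background_hu
    # lungs placed laterally, clear of the contour ring around the implant
    for lung_c in (0.17 * nc, 0.83 * nc):
        lung = ((rows - (nr - 1) / 2) / (0.26 * nr)) ** 2 + ((cols - lung_c) / (0.08 * nc)) ** 2 <= 1.0
        background[lung] = spec.lung_hu
    if spec.contrast_hu is not None:
        cc = spec.contrast_center if spec.contrast_center is not None else (center[0], center[1] + 2.5 * r_vox_c)
        contrast = (rows - cc[0]) ** 2 * dr**2 + (cols - cc[1]) ** 2 * dc**2 <= spec.contrast_radius_mm**2
        background[contrast] = spec.contrast_hu

    z = np.arange(ns, dtype=float)
    in_height = np.abs(z - z_mid) <= half_h_vox
    disk = radius_mm <= spec.implant_radius_mm
    implant_mask = in_height[:, None, None] & disk[None, :, :]

    implant_field = implant_mask.astype(float) * spec.metal_hu
    if spec.bloom_sigma_mm > 0:
        sigma_vox = (spec.bloom_sigma_mm / dz, spec.bloom_sigma_mm / dr, spec.bloom_sigma_mm / dc)
        implant_field = gaussian_filter(implant_field, sigma=sigma_vox)

    theta = np.arctan2(y_mm, x_mm)
    dist_mm = np.maximum(radius_mm - spec.implant_radius_mm, 0.0)
    st = spec.streak
    streak_2d = st.amplitude_hu * np.cos(st.angular_order * theta + st.phase_rad) * np.exp(-dist_mm / st.radial_decay_mm)
    streak_2d = np.where(disk, 0.0, streak_2d)

    data = background[None, :, :] + implant_field + streak_2d[None, :, :]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    volume = CTVolume(data=data, spacing=spec.spacing)
    truth = PhantomGroundTruth(
        implant_mask=implant_mask,
        true_volume_cm3=float(np.pi * spec.implant_radius_mm**2 * spec.implant_height_mm / 1000.0),
        implant_center=center,
        implant_radius_mm=spec.implant_radius_mm,
        implant_height_mm=spec.implant_height_mm,
    )
    return volume, truth


@dataclass(frozen=True)
class ReaderSimSpec:
    """Latent-quality model behind simulated ordinal scores.

    Each reader's raw judgement of case *c* is ``latent_quality[c] + eps``
    with ``eps ~ N(0, reader_sd^2)`` independent per (reader, case); the raw
    value is discretised through four ordered cutpoints into scores 1-5.
    """

    latent_quality: tuple[float, ...]
    n_readers: int = 6
    reader_sd: float = 1.0
    cutpoints: tuple[float, float, float, float] = (1.5, 2.5, 3.5, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_readers < 2:
            raise ValueError("need at least 2 readers")
        if self.reader_sd < 0:
            raise ValueError("reader_sd must be >= 0")
        if list(self.cutpoints) != sorted(self.cutpoints) or len(set(self.cutpoints)) != 4:
            raise ValueError("cutpoints must be 4 strictly increasing values")

    @property
    def n_cases(self) -> int:
        return len(self.latent_quality)


def simulate_reader_scores(spec: ReaderSimSpec, question: str = "Q1") -> ReaderScoreTable:
    """Simulate a case x reader score table for one question."""
    if question not in QUESTIONS:
        raise ValueError(f"unknown question {question!r}")
    rng = np.random.default_rng(spec.seed)
    latent = np.asarray(spec.latent_quality, dtype=float)
    raw = latent[:, None] + rng.normal(0.0, spec.reader_sd, size=(spec.n_cases, spec.n_readers))
    scores_arr = 1 + np.searchsorted(np.asarray(spec.cutpoints), raw).astype(int)
    width = max(3, len(str(spec.n_cases)))
    scores = {}
    for i in range(spec.n_cases):
        cid = f"S{i + 1:0{width}d}"
        for j in range(spec.n_readers):
            scores[(cid, f"R{j + 1}", question)] = int(scores_arr[i, j])
    return ReaderScoreTable(scores=scores)


def latent_model_icc(
    spec: ReaderSimSpec, latent_mean: float | None = None, latent_sd: float | None = None
) -> float:
    """Population ICC(C,k) of the score model, by Gauss-Hermite quadrature.

    When ``latent_mean``/``latent_sd`` are given, the per-case latent quality
    is treated as drawn from N(mean, sd^2) (the sampling scheme used by the
    recovery studies); otherwise the empirical distribution of
    ``spec.latent_quality`` is used.  The returned value is the consistency
    average-measures ICC of the *discretised* scores,
    sigma_b^2 / (sigma_b^2 + sigma_w^2 / k), where sigma_b^2 = Var(E[s|q])
    and sigma_w^2 = E[Var(s|q)] over the latent distribution.
    """
    from numpy.polynomial.hermite_e import hermegauss
    from scipy.stats import norm

    cuts = np.asarray(spec.cutpoints)

    def moments_given_q(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # P(s = m | q) for m = 1..5 via Gaussian reader noise through the cutpoints
        if spec.reader_sd == 0:
            s = 1 + np.searchsorted(cuts, q)
            return s.astype(float), np.zeros_like(q, dtype=float)
        z = (cuts[None, :] - q[:, None]) / spec.reader_sd
        cdf = np.concatenate(
            [np.zeros((len(q), 1)), norm.cdf(z), np.ones((len(q), 1))], axis=1
        )
        pmf = np.diff(cdf, axis=1)
        m = np.arange(1, 6)
        mean = pmf @ m
        var = pmf @ (m**2) - mean**2
        return mean, var

    if latent_sd is not None:
        nodes, weights = hermegauss(80)
        q = latent_mean + latent_sd * nodes
        w = weights / weights.sum()
    else:
        q = np.asarray(spec.latent_quality, dtype=float)
        w = np.full(len(q), 1.0 / len(q))
    mean, var = moments_given_q(q)
    sigma_b2 = float(np.sum(w * mean**2) - np.sum(w * mean) ** 2)
    sigma_w2 = float(np.sum(w * var))
    denom = sigma_b2 + sigma_w2 / spec.n_readers
    return sigma_b2 / denom if denom > 0 else 0.0


@dataclass
class SyntheticCase:
    """One battery entry: the volume, its ground truth and swept parameters."""

    volume: CTVolume
    ground_truth: PhantomGroundTruth
    params: dict


def generate_case_battery(
    base: PhantomSpec, sweep: Mapping[str, Sequence]
) -> list[SyntheticCase]:
    """Generate one phantom per point of a parameter grid.

    ``sweep`` maps :class:`PhantomSpec` field names (e.g. ``bloom_sigma_mm``,
    ``streak``, ``noise_sd``) to value sequences; the Cartesian product is
    generated.  Each case gets a distinct seed derived from ``base.seed``.
    """
    if not sweep or any(len(v) == 0 for v in sweep.values()):
        raise ValueError("sweep grid must name at least one field with at least one value")
    names = list(sweep)
    cases = []
    for idx, values in enumerate(itertools.product(*(sweep[n] for n in names))):
        overrides = dict(zip(names, values))
        spec = replace(base, seed=(base.seed + idx) % (2**31 - 1), **overrides)
        volume, truth = generate_phantom(spec)
        params = dict(overrides)
        params["seed"] = spec.seed
        cases.append(SyntheticCase(volume=volume, ground_truth=truth, params=params))
    return cases
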