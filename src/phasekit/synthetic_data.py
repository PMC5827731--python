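"""Seeded generators for every input class the analysis stages consume.

Each generator forward-models one assay — turbidity grids, two-channel
droplet images, photon traces, scattering curves, Stejskal–Tanner decays,
FRAP recoveries — and returns the data *together with the ground truth that
produced it*, so every downstream stage can be scored by parameter recovery
without any external data.

Reproducibility contract: all randomness flows from a single integer seed
per invocation; the RNG stream is derived from ``(seed, stage name)`` so the
output of one stage never changes when another stage is added or re-ordered.
Identical configuration yields bitwise-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .dropletquant import FluorescenceImage, FrapTrace
from .hydro import GAMMA_1H, DiffusionDecay, stejskal_tanner_attenuation
from .phasediagram import TurbidityMeasurement
from .saxs import Conformer, Ensemble, ScatteringCurve, debye_intensity, sphere_intensity
from .smfret import PhotonTrace

__all__ = [
    "stage_rng",
    "gen_turbidity",
    "gen_droplet_images",
    "gen_photon_trace",
    "gen_saxs_sphere",
    "gen_saxs_from_conformer",
    "gen_diffusion_decay",
    "gen_frap",
    "PAPER_GRADIENT_PERCENT",
]

#: The six gradient fractions (percent of maximum) used in the reference
#: PFG-NMR protocol, with the 100% amplitude 0.423 T/m.
PAPER_GRADIENT_PERCENT = (20.0, 24.5, 28.3, 31.6, 34.6, 37.4)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One RNG stream per (seed, stage name) pair."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# turbidity grids
# ---------------------------------------------------------------------------


def gen_turbidity(
    boundary: Callable[[float], float],
    c_x_grid: Sequence[float],
    c_y_grid: Sequence[float],
    noise_sigma: float = 0.01,
    replicates: int = 3,
    a340_demixed: float = 0.3,
    a340_mixed: float = 0.0,
    seed: int = 0,
) -> tuple[list[TurbidityMeasurement], dict]:
    """Turbidity grid from a known phase boundary c_y*(c_x).

    Points with c_y >= boundary(c_x) read ``a340_demixed`` plus Gaussian
    noise, others ``a340_mixed`` plus noise (negatives clip to zero, as after
    blank subtraction).  Truth records the boundary value and true state per
    grid point.
    """
    rng = stage_rng(seed, "turbidity")
    points: list[TurbidityMeasurement] = []
    truth_rows = []
    for cx in c_x_grid:
        cy_star = float(boundary(cx))
        for cy in c_y_grid:
            demixed = cy >= cy_star
            base = a340_demixed if demixed else a340_mixed
            truth_rows.append({"c_x": float(cx), "c_y": float(cy), "demixed": bool(demixed)})
            for rep in range(replicates):
                a = base + (rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0)
                points.append(
                    TurbidityMeasurement(c_x=float(cx), c_y=float(cy), a340=max(a, 0.0), replicate=rep)
                )
    truth = {
        "stage": "turbidity",
        "seed": seed,
        "noise_sigma": noise_sigma,
        "boundary": {float(cx): float(boundary(cx)) for cx in c_x_grid},
        "states": truth_rows,
    }
    return points, truth


# ---------------------------------------------------------------------------
# droplet images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletSpec:
    """One disk-shaped droplet: center (µm) and radius (µm)."""

    y_um: float
    x_um: float
    radius_um: float


def gen_droplet_images(
    droplets: Sequence[DropletSpec],
    channels: Mapping[str, Mapping[str, float]],
    shape_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.2,
    background: float = 10.0,
    light_level: float = 100.0,
    poisson_noise: bool = False,
    seed: int = 0,
) -> tuple[dict[str, FluorescenceImage], FluorescenceImage, dict]:
    """Two-phase images with known partition coefficients per channel.

    ``channels`` maps a channel name to ``{"pc": ..., "c_corr": ...}``.  The
    light phase sits at ``background + light_level``; inside each disk the
    net signal is multiplied by pc·c_corr (the quantum-yield change a real
    dye experiences in the dense phase); the buffer-only image is flat at
    ``background``.  Overlapping or out-of-field droplet layouts are
    rejected.  Returns ``(channel images, buffer image, truth)``.
    """
    h, w = shape_px
    fov_y, fov_x = h * pixel_size_um, w * pixel_size_um
    for d in droplets:
        if d.radius_um <= 0:
            raise ValueError("droplet radii must be positive")
        if not (d.radius_um <= d.y_um <= fov_y - d.radius_um and d.radius_um <= d.x_um <= fov_x - d.radius_um):
            raise ValueError("droplet extends outside the field of view")
    for a_idx in range(len(droplets)):
        for b_idx in range(a_idx + 1, len(droplets)):
            a, b = droplets[a_idx], droplets[b_idx]
            if np.hypot(a.y_um - b.y_um, a.x_um - b.x_um) <= a.radius_um + b.radius_um:
                raise ValueError("overlapping droplet layout rejected")

    rng = stage_rng(seed, "droplets")
    yy, xx = np.indices(shape_px)
    y_um, x_um = (yy + 0.5) * pixel_size_um, (xx + 0.5) * pixel_size_um
    inside = np.zeros(shape_px, dtype=bool)
    for d in droplets:
        inside |= (y_um - d.y_um) ** 2 + (x_um - d.x_um) ** 2 <= d.radius_um**2

    images: dict[str, FluorescenceImage] = {}
    for name, spec in channels.items():
        pc, c_corr = float(spec["pc"]), float(spec.get("c_corr", 1.0))
        img = np.where(inside, background + light_level * pc * c_corr, background + light_level)
        if poisson_noise:
            img = rng.poisson(img).astype(float)
        images[name] = FluorescenceImage(data=img, pixel_size_um=pixel_size_um, channel=name)
    buffer_img = np.full(shape_px, float(background))
    if poisson_noise:
        buffer_img = rng.poisson(buffer_img).astype(float)
    buffer = FluorescenceImage(data=buffer_img, pixel_size_um=pixel_size_um, channel="buffer")

    truth = {
        "stage": "droplets",
        "seed": seed,
        "droplets": [asdict(d) for d in droplets],
        "channels": {k: dict(v) for k, v in channels.items()},
        "background": background,
        "light_level": light_level,
        "poisson_noise": poisson_noise,
    }
    return images, buffer, truth


# ---------------------------------------------------------------------------
# photon traces
# ---------------------------------------------------------------------------


def gen_photon_trace(
    n_bursts: int,
    epsilons: Sequence[float],
    weights: Sequence[float] | None = None,
    burst_size_mean: float = 60.0,
    burst_span_bins: int = 2,
    gap_mean_bins: float = 40.0,
    donor_only_fraction: float = 0.0,
    background_rate: float = 0.05,
    seed: int = 0,
) -> tuple[PhotonTrace, dict]:
    """Photon trace with bursts of known FRET efficiency.

    Burst arrivals follow a Poisson process (exponential gaps of mean
    ``gap_mean_bins`` bins, with a minimum separation of 3 bins so bursts
    stay resolvable); burst sizes are geometric with mean ``burst_size_mean``
    (the shifted-geometric burst-size model); acceptor counts are
    Binomial(N, ε) with ε drawn from ``epsilons`` with the given weights.  A
    ``donor_only_fraction`` of bursts emit on the donor channel only,
    producing the zero peak of molecules lacking an active acceptor.
    Background counts are Poisson per bin and channel.
    """
    for e in epsilons:
        if not (0.0 < e < 1.0):
            raise ValueError("burst efficiencies must lie in (0, 1)")
    if background_rate < 0:
        raise ValueError("background rate must be >= 0")
    rng = stage_rng(seed, "photon_trace")
    w = np.full(len(epsilons), 1.0 / len(epsilons)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()

    gaps = np.maximum(rng.exponential(gap_mean_bins, size=n_bursts).astype(int), 3)
    starts = np.cumsum(gaps) + 5
    n_bins = int(starts[-1] + burst_span_bins + 20)
    donor = np.zeros(n_bins, dtype=np.int64)
    acceptor = np.zeros(n_bins, dtype=np.int64)

    burst_truth = []
    for s in starts:
        n_photons = int(rng.geometric(1.0 / burst_size_mean))
        is_donor_only = bool(rng.random() < donor_only_fraction)
        if is_donor_only:
            eps, n_a = 0.0, 0
        else:
            eps = float(rng.choice(epsilons, p=w))
            n_a = int(rng.binomial(n_photons, eps))
        n_d = n_photons - n_a
        span = min(burst_span_bins, n_bins - s)
        donor[s : s + span] += rng.multinomial(n_d, np.full(span, 1.0 / span))
        acceptor[s : s + span] += rng.multinomial(n_a, np.full(span, 1.0 / span))
        burst_truth.append(
            {"start": int(s), "n": n_photons, "epsilon": eps, "donor_only": is_donor_only}
        )
    if background_rate > 0:
        donor += rng.poisson(background_rate, n_bins)
        acceptor += rng.poisson(background_rate, n_bins)

    trace = PhotonTrace(donor=donor, acceptor=acceptor)
    truth = {
        "stage": "photon_trace",
        "seed": seed,
        "epsilons": [float(e) for e in epsilons],
        "weights": [float(x) for x in w],
        "burst_size_mean": burst_size_mean,
        "donor_only_fraction": donor_only_fraction,
        "background_rate": background_rate,
        "bursts": burst_truth,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# scattering curves
# ---------------------------------------------------------------------------


def _default_q_grid(n: int = 150) -> np.ndarray:
    return np.linspace(0.018, 0.31, n)


def gen_saxs_sphere(
    radius: float,
    relative_noise: float = 0.0,
    q: np.ndarray | None = None,
    i0: float = 1.0,
    seed: int = 0,
) -> tuple[ScatteringCurve, dict]:
    """Sphere form-factor curve with optional multiplicative Gaussian noise.

    With noise, σ(q) = relative_noise · I(q) and the intensity is perturbed
    by one Gaussian deviate per point.  Truth records R and the exact R_g
    (sqrt(3/5)·R).
    """
    q = _default_q_grid() if q is None else np.asarray(q, float)
    i_true = sphere_intensity(q, radius, i0=i0)
    if relative_noise > 0:
        rng = stage_rng(seed, "saxs")
        sigma = relative_noise * i_true
        i_obs = i_true + rng.normal(0.0, 1.0, q.size) * sigma
        curve = ScatteringCurve(q=q, i=i_obs, sigma=sigma)
    else:
        curve = ScatteringCurve(q=q, i=i_true)
    truth = {
        "stage": "saxs",
        "seed": seed,
        "model": "sphere",
        "radius": float(radius),
        "rg": float(np.sqrt(3.0 / 5.0) * radius),
        "relative_noise": relative_noise,
    }
    return curve, truth


def gen_saxs_from_conformer(
    conformer: Conformer | Ensemble,
    relative_noise: float = 0.02,
    q: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ScatteringCurve, dict]:
    """Debye curve of a bead conformer (or ensemble average) with noise.

    σ(q) = relative_noise · I(q); Gaussian perturbation.  Truth records the
    coordinate R_g (ensemble mean when an ensemble is given).
    """
    q = _default_q_grid() if q is None else np.asarray(q, float)
    if isinstance(conformer, Ensemble):
        curves = np.array([debye_intensity(c, q).i for c in conformer.conformers])
        i_true = curves.mean(axis=0)
        rg = float(conformer.rgs().mean())
    else:
        i_true = debye_intensity(conformer, q).i
        rg = conformer.rg
    sigma = np.maximum(relative_noise, 1e-6) * i_true
    rng = stage_rng(seed, "saxs_conformer")
    i_obs = i_true + (rng.normal(0.0, 1.0, q.size) * sigma if relative_noise > 0 else 0.0)
    curve = ScatteringCurve(q=q, i=i_obs, sigma=sigma)
    truth = {"stage": "saxs_conformer", "seed": seed, "model": "beads", "rg": rg,
             "relative_noise": relative_noise}
    return curve, truth


# ---------------------------------------------------------------------------
# diffusion decays and FRAP traces
# ---------------------------------------------------------------------------


def gen_diffusion_decay(
    d_m2_per_s: float,
    gradient_percent: Sequence[float] = PAPER_GRADIENT_PERCENT,
    g_max_t_per_m: float = 0.423,
    delta_s: float = 4e-3,
    big_delta_s: float = 0.1,
    i0: float = 1.0,
    relative_noise: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[DiffusionDecay, dict]:
    """Stejskal–Tanner decay at the given gradient fractions of g_max.

    Multiplicative Gaussian noise of the given relative magnitude is applied
    per replicate point.  Truth records D, g_max and the acquisition
    parameters.
    """
    rng = stage_rng(seed, "diffusion")
    frac = np.asarray(gradient_percent, float)
    g = np.tile(frac, replicates) / 100.0 * g_max_t_per_m
    i_true = i0 * stejskal_tanner_attenuation(d_m2_per_s, g, delta_s, big_delta_s, GAMMA_1H)
    if relative_noise > 0:
        i_obs = i_true * (1.0 + rng.normal(0.0, relative_noise, g.size))
        i_obs = np.maximum(i_obs, 1e-12 * i0)
    else:
        i_obs = i_true
    decay = DiffusionDecay(
        gradients_t_per_m=g, intensity=i_obs, i0=i0, delta_s=delta_s, big_delta_s=big_delta_s
    )
    truth = {
        "stage": "diffusion",
        "seed": seed,
        "d_m2_per_s": d_m2_per_s,
        "g_max_t_per_m": g_max_t_per_m,
        "gradient_percent": [float(x) for x in frac],
        "delta_s": delta_s,
        "big_delta_s": big_delta_s,
        "relative_noise": relative_noise,
        "replicates": replicates,
    }
    return decay, truth


def gen_frap(
    mobile_fraction: float,
    tau_s: float,
    bleach_depth: float = 0.5,
    n_pre: int = 5,
    n_post: int = 60,
    dt_s: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[FrapTrace, dict]:
    """Single-exponential FRAP recovery with known mobile fraction and τ.

    Pre-bleach frames sit at 1; post-bleach
    I(t) = I_b + m·(1 − I_b)·(1 − exp(−t/τ)) with I_b the bleach depth and m
    the mobile fraction.  Additive Gaussian noise.
    """
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile fraction must lie in [0, 1]")
    rng = stage_rng(seed, "frap")
    t = np.arange(n_pre + n_post) * dt_s
    t_post = t[n_pre:] - t[n_pre]
    i_b = 1.0 - bleach_depth
    y = np.concatenate(
        [np.ones(n_pre), i_b + mobile_fraction * (1.0 - i_b) * (1.0 - np.exp(-t_post / tau_s))]
    )
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, y.size)
    trace = FrapTrace(time_s=t, intensity=y, bleach_index=n_pre)
    truth = {
        "stage": "frap",
        "seed": seed,
        "mobile_fraction": mobile_fraction,
        "tau_s": tau_s,
        "half_time_s": tau_s * float(np.log(2.0)),
        "bleach_depth": bleach_depth,
        "noise_sigma": noise_sigma,
    }
    return trace, truth
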