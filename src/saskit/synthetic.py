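"""Ground-truthed synthetic profiles and SEC-SAXS series.

The generator emulates the statistical structure the analysis pipeline
assumes: one or more eluting species with analytic form factors (solid
sphere, Debye Gaussian coil) and Gaussian elution concentration profiles,
over a constant, featureless buffer background (a decaying exponential plus
a constant in q), with Gaussian counting-statistics-like noise
(sigma ~ sqrt(I)) and optional linear or cumulative (capillary-fouling-like)
baseline drift.  Every simulated series carries a machine-readable truth
record so range selections, recovered parameters and baselines can be scored
exactly.

The preset parameters below define the reference study conditions used by
the test suite: a single sphere of R = 40 A eluting at frame 60 of 100 with
an apex signal-to-noise ratio of ~30, an overlapping sphere+coil pair with
apexes 8 frames apart, a drifting variant and one with an early minor
contaminant peak.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .sasdata import Profile, Series

__all__ = [
    "ComponentSpec",
    "DriftSpec",
    "SecSpec",
    "SeriesTruth",
    "sphere_profile",
    "coil_profile",
    "sphere_pr",
    "add_noise",
    "simulate_sec",
    "simulate_preset",
    "preset_spec",
    "inject_drift",
    "DEFAULT_QGRID",
]

DEFAULT_QGRID = np.linspace(0.008, 0.35, 200)


def _sphere_ff(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized sphere form factor amplitude squared, F(0) = 1."""
    x = q * radius
    amp = np.ones_like(x)
    nz = x != 0
    amp[nz] = 3.0 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return amp ** 2


def sphere_profile(radius: float, i0: float, qgrid=None) -> Profile:
    """Noiseless solid-sphere profile: I(q) = i0 [3(sin x - x cos x)/x^3]^2."""
    if radius <= 0:
        raise ValidationError("radius must be positive")
    q = np.asarray(DEFAULT_QGRID if qgrid is None else qgrid, dtype=float)
    i = i0 * _sphere_ff(q, radius)
    return Profile(q, i, np.zeros_like(q), {"model": "sphere", "radius": radius})


def _coil_ff(q: np.ndarray, rg: float) -> np.ndarray:
    """Debye coil form factor, value 1 at q = 0."""
    x = (q * rg) ** 2
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = 2.0 * (np.exp(-x[nz]) - 1.0 + x[nz]) / x[nz] ** 2
    return out


def coil_profile(rg: float, i0: float, qgrid=None) -> Profile:
    """Noiseless Debye Gaussian-coil profile."""
    if rg <= 0:
        raise ValidationError("rg must be positive")
    q = np.asarray(DEFAULT_QGRID if qgrid is None else qgrid, dtype=float)
    i = i0 * _coil_ff(q, rg)
    return Profile(q, i, np.zeros_like(q), {"model": "coil", "rg": rg})


def sphere_pr(rgrid: np.ndarray, radius: float) -> np.ndarray:
    """Analytic sphere pair-distance distribution shape (arbitrary scale).

    P(r) ~ r^2 gamma(r) with gamma(u) = 1 - 3u/2 + u^3/2, u = r/(2R),
    zero beyond Dmax = 2R.
    """
    r = np.asarray(rgrid, dtype=float)
    u = r / (2.0 * radius)
    gamma = np.where(u <= 1.0, 1.0 - 1.5 * u + 0.5 * u ** 3, 0.0)
    return r ** 2 * gamma


def add_noise(profile: Profile, scale: float, seed: int,
              floor: float = 0.0) -> Profile:
    """Counting-statistics-like noise: sigma = scale*sqrt(I + floor).

    The intensity is perturbed by zero-mean Gaussian noise of that sigma
    (Gaussian rather than Poisson, matching the weighted-least-squares
    assumptions of the downstream fits).  scale -> 0 is the noiseless limit.
    """
    if scale < 0:
        raise ValidationError("noise scale must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = scale * np.sqrt(np.clip(profile.intensity + floor, 0.0, None))
    i = profile.intensity + rng.normal(0.0, 1.0, len(profile)) * sigma
    return Profile(profile.q, i, sigma, dict(profile.metadata))


# ---------------------------------------------------------------------------
# SEC-SAXS series
# ---------------------------------------------------------------------------

@dataclass
class ComponentSpec:
    kind: str          # 'sphere' or 'coil'
    size: float        # sphere radius or coil Rg, in A
    i0: float          # forward scattering at unit concentration
    center: float      # elution apex frame
    width: float       # Gaussian elution sigma, frames
    amplitude: float = 1.0

    def form_factor(self, q: np.ndarray) -> np.ndarray:
        if self.kind == "sphere":
            return self.i0 * _sphere_ff(q, self.size)
        if self.kind == "coil":
            return self.i0 * _coil_ff(q, self.size)
        raise ValidationError(f"unknown component kind {self.kind!r}")


@dataclass
class DriftSpec:
    kind: str          # 'linear' or 'integral'
    magnitude: float   # drift amplitude at the last frame, intensity units


@dataclass
class SecSpec:
    components: list
    n_frames: int = 100
    qgrid: np.ndarray = field(default_factory=lambda: DEFAULT_QGRID.copy())
    buffer_level: float = 20.0
    apex_sn: float = 30.0       # mean I/sigma of the strongest component at apex
    noise_floor: float = 0.0
    drift: DriftSpec = None


@dataclass
class SeriesTruth:
    spec: SecSpec
    concentrations: np.ndarray      # (n_components, n_frames)
    buffer_frames: np.ndarray
    pure_sample_frames: np.ndarray  # purity >= 99% and meaningful signal
    noise_scale: float
    buffer_intensity: np.ndarray    # noiseless buffer(q)
    component_intensity: np.ndarray  # (n_components, n_q) noiseless F_s(q)
    drift_surface: np.ndarray = None  # (n_frames, n_q) or None


def _buffer_shape(q: np.ndarray, level: float) -> np.ndarray:
    # featureless: constant plus a smooth decaying exponential
    return level * (0.5 + np.exp(-q / 0.2))


def _drift_surface(spec: SecSpec, conc_total: np.ndarray) -> np.ndarray:
    q = spec.qgrid
    n = spec.n_frames
    g = np.exp(-q / 0.1)  # smooth positive q shape, strongest at low q
    frames = np.arange(n)
    if spec.drift.kind == "linear":
        ramp = frames / max(n - 1, 1)
    elif spec.drift.kind == "integral":
        cum = np.cumsum(conc_total)
        ramp = cum / cum[-1] if cum[-1] > 0 else np.zeros(n)
    else:
        raise ValidationError(f"unknown drift kind {spec.drift.kind!r}")
    return spec.drift.magnitude * np.outer(ramp, g)


def simulate_sec(spec: SecSpec, seed: int = 0):
    """Simulate a SEC-SAXS series; returns (Series, SeriesTruth).

    Frame i measures buffer(q) + sum_s c_s(i) F_s(q) + drift(q, i) plus
    Gaussian noise with sigma = scale*sqrt(I); the noise scale is set so the
    strongest component's apex frame has the requested mean signal-to-noise
    ratio, the condition the reference datasets are defined at.
    """
    if not spec.components:
        raise ValidationError("need at least one component")
    if spec.n_frames < 50:
        raise ValidationError("need at least 50 frames")
    q = np.asarray(spec.qgrid, dtype=float)
    frames = np.arange(spec.n_frames)
    conc = np.vstack([
        c.amplitude * np.exp(-0.5 * ((frames - c.center) / c.width) ** 2)
        for c in spec.components])
    ff = np.vstack([c.form_factor(q) for c in spec.components])
    buffer_i = _buffer_shape(q, spec.buffer_level)
    signal = conc.T @ ff                        # (n_frames, n_q)
    total = signal + buffer_i[None, :]
    drift = None
    if spec.drift is not None:
        drift = _drift_surface(spec, conc.sum(axis=0))
        total = total + drift

    # noise scale from the apex S/N condition
    forward = np.array([c.form_factor(q)[0] for c in spec.components])
    strongest = int(np.argmax(conc.max(axis=1) * forward))
    apex = int(np.argmin(np.abs(frames - spec.components[strongest].center)))
    comp_apex = conc[:, apex] @ ff
    with np.errstate(divide="ignore"):
        ratio = comp_apex / np.sqrt(np.clip(total[apex] + spec.noise_floor,
                                            1e-300, None))
    scale = float(np.mean(ratio)) / spec.apex_sn if spec.apex_sn > 0 else 0.0

    rng = np.random.default_rng(seed)
    sigma = scale * np.sqrt(np.clip(total + spec.noise_floor, 0.0, None))
    noisy = total + rng.normal(0.0, 1.0, total.shape) * sigma

    profiles = [Profile(q, noisy[k], sigma[k]) for k in range(spec.n_frames)]
    series = Series(profiles, analysis={"simulated": True, "seed": seed})

    sig_strength = conc.T @ forward             # forward component signal
    apex_strength = sig_strength.max()
    buffer_frames = frames[sig_strength <= 1e-4 * apex_strength]
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(sig_strength > 0,
                          (conc.T * forward).max(axis=1) / np.where(
                              sig_strength > 0, sig_strength, 1.0), 0.0)
    pure = frames[(purity >= 0.99) & (sig_strength >= 0.01 * apex_strength)]
    truth = SeriesTruth(spec=spec, concentrations=conc,
                        buffer_frames=buffer_frames, pure_sample_frames=pure,
                        noise_scale=scale, buffer_intensity=buffer_i,
                        component_intensity=ff, drift_surface=drift)
    return series, truth


def preset_spec(name: str) -> SecSpec:
    """Reference study conditions for the named preset."""
    if name == "single":
        return SecSpec(components=[
            ComponentSpec("sphere", 40.0, 100.0, center=60, width=5.0)])
    if name == "overlap":
        return SecSpec(components=[
            ComponentSpec("sphere", 40.0, 100.0, center=55, width=5.0),
            ComponentSpec("coil", 25.0, 60.0, center=63, width=5.0)])
    if name == "drifty":
        return SecSpec(components=[
            ComponentSpec("sphere", 40.0, 100.0, center=60, width=5.0)],
            drift=DriftSpec("linear", 10.0))
    if name == "contaminant":
        return SecSpec(components=[
            ComponentSpec("sphere", 40.0, 100.0, center=60, width=5.0),
            ComponentSpec("sphere", 20.0, 10.0, center=25, width=3.0)])
    raise ValidationError(f"unknown preset {name!r}")


def simulate_preset(name: str, seed: int = 0):
    return simulate_sec(preset_spec(name), seed=seed)


def inject_drift(series: Series, kind: str, magnitude: float,
                 seed: int = 0) -> Series:
    """Add a baseline drift to an existing series (new Series returned).

    linear:   adds magnitude * (frame/(n-1)) * g(q)
    integral: adds magnitude * normalized cumulative sum of a non-negative
              fouling increment profile, taken proportional to the series'
              above-median total intensity (deposition tracks elution).
    g(q) = exp(-q/0.1), a smooth positive low-q-weighted shape.  The drift
    surface is deterministic given the series; ``seed`` is accepted for API
    symmetry with the other generators.  magnitude = 0 is the identity.
    """
    if magnitude < 0:
        raise ValidationError("magnitude must be >= 0")
    q = series.q
    n = series.n_frames
    g = np.exp(-q / 0.1)
    if kind == "linear":
        ramp = np.arange(n) / max(n - 1, 1)
    elif kind == "integral":
        tot = series.intensity_matrix().sum(axis=1)
        inc = np.clip(tot - np.median(tot), 0.0, None)
        cum = np.cumsum(inc)
        ramp = cum / cum[-1] if cum[-1] > 0 else np.zeros(n)
    else:
        raise ValidationError(f"unknown drift kind {kind!r}")
    surface = magnitude * np.outer(ramp, g)
    profiles = [Profile(q, p.intensity + surface[k], p.sigma, dict(p.metadata))
                for k, p in enumerate(series.profiles)]
    analysis = dict(series.analysis)
    analysis["injected_drift"] = {"kind": kind, "magnitude": magnitude}
    return Series(profiles, analysis=analysis)
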