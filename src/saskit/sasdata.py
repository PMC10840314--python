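"""Core 1-D small-angle scattering data containers and elementary operations.

The two containers are :class:`Profile`, a single scattering curve I(q) with
1-sigma uncertainties, and :class:`Series`, an ordered stack of profiles on a
shared q grid (one profile per chromatography frame).  Readers/writers cover
the de-facto three-column ``.dat`` text dialect for single profiles and an
HDF5 layout for series.  All operations are pure: inputs are never modified.

Uncertainty propagation follows the standard rules for independent Gaussian
errors: averaging n profiles gives sigma = sqrt(sum sigma_i^2)/n (uncertainty
of the mean), subtraction adds uncertainties in quadrature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .exceptions import FormatError, ValidationError

__all__ = [
    "Profile",
    "Series",
    "FrameRange",
    "read_dat",
    "write_dat",
    "read_series_h5",
    "write_series_h5",
    "average_profiles",
    "subtract_profiles",
    "transform_profile",
    "dimensionless_kratky",
]

#: relative tolerance used when testing whether two q grids are "the same"
Q_GRID_RTOL = 1e-8


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class Profile:
    """One 1-D scattering curve.

    Parameters
    ----------
    q : array
        Scattering-vector magnitudes, strictly increasing.  Unit-agnostic
        (typically 1/A or 1/nm); molecular-weight constants assume 1/A.
    intensity : array
        I(q), arbitrary units.
    sigma : array
        1-sigma uncertainty of I(q); non-negative.
    metadata : dict
        Free-form provenance (sample name, header lines, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.intensity = _as_float_array(self.intensity, "intensity")
        self.sigma = _as_float_array(self.sigma, "sigma")
        n = len(self.q)
        if n < 3:
            raise ValidationError("a profile needs at least 3 points")
        if len(self.intensity) != n or len(self.sigma) != n:
            raise ValidationError("q, intensity and sigma must have equal length")
        if not np.all(np.diff(self.q) > 0):
            raise ValidationError("q must be strictly increasing")
        if np.any(self.sigma < 0):
            raise ValidationError("sigma must be non-negative")

    def __len__(self) -> int:
        return len(self.q)

    def copy(self) -> "Profile":
        return Profile(self.q.copy(), self.intensity.copy(), self.sigma.copy(),
                       dict(self.metadata))


def same_q_grid(a: np.ndarray, b: np.ndarray, rtol: float = Q_GRID_RTOL) -> bool:
    """True when two q grids agree pointwise within relative tolerance."""
    return len(a) == len(b) and bool(np.allclose(a, b, rtol=rtol, atol=0.0))


def _require_same_grid(profiles) -> np.ndarray:
    q0 = profiles[0].q
    for p in profiles[1:]:
        if not same_q_grid(q0, p.q):
            raise ValidationError("profiles do not share a common q grid")
    return q0


@dataclass(frozen=True)
class FrameRange:
    """Inclusive [start, end] frame interval, 0-based."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= int(self.start) <= int(self.end)):
            raise ValidationError(f"bad frame range [{self.start}, {self.end}]")
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))

    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def as_list(self) -> list:
        return [self.start, self.end]


def frames_of(ranges) -> np.ndarray:
    """Sorted unique frame indices covered by a list of FrameRange."""
    if not ranges:
        return np.array([], dtype=int)
    return np.unique(np.concatenate([r.frames() for r in ranges]))


@dataclass
class Series:
    """Ordered stack of profiles sharing one q grid, plus analysis state.

    ``analysis`` holds the serializable analysis parameters (buffer/sample
    ranges, baseline kind and parameters, per-frame traces).  Derived arrays
    (subtracted intensities, baseline surface) live in the private cache
    attributes and are recomputed rather than persisted.
    """

    profiles: list
    frames: np.ndarray = None
    analysis: dict = field(default_factory=dict)
    # runtime caches, not persisted to HDF5 beyond what `analysis` encodes
    subtracted_i: np.ndarray = None
    subtracted_sigma: np.ndarray = None
    buffer_profile: Profile = None
    baseline: object = None  # BaselineResult, set by series_lc

    def __post_init__(self):
        if len(self.profiles) < 2:
            raise ValidationError("a series needs at least 2 frames")
        _require_same_grid(self.profiles)
        if self.frames is None:
            self.frames = np.arange(len(self.profiles))
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if len(self.frames) != len(self.profiles):
            raise ValidationError("frames and profiles length mismatch")
        if not np.array_equal(self.frames, np.arange(len(self.profiles))):
            raise ValidationError("frames must be 0-based and contiguous")

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0].q

    @property
    def n_frames(self) -> int:
        return len(self.profiles)

    def intensity_matrix(self) -> np.ndarray:
        """(n_frames, n_q) stack of unsubtracted intensities."""
        return np.vstack([p.intensity for p in self.profiles])

    def sigma_matrix(self) -> np.ndarray:
        return np.vstack([p.sigma for p in self.profiles])

    def shallow_copy(self) -> "Series":
        s = replace(self)
        s.profiles = list(self.profiles)
        s.analysis = json.loads(json.dumps(self.analysis)) if self.analysis else {}
        return s


# ---------------------------------------------------------------------------
# .dat text format
# ---------------------------------------------------------------------------

def _parse_floats(line: str):
    out = []
    for tok in line.replace(",", " ").split():
        try:
            out.append(float(tok))
        except ValueError:
            return None
    return out if out else None


def read_dat(path) -> Profile:
    """Read a whitespace-delimited q / I / sigma text profile.

    Lines that do not parse as at least three numeric columns are treated as
    header/footer and preserved in ``metadata['header']``.  Files with exactly
    two numeric columns (no uncertainties) are accepted: sigma is set to 1 for
    every point and ``metadata['sigma_fallback']`` is set, so downstream
    weighted fits degrade to unweighted ones.
    """
    rows3, rows2, header = [], [], []
    first_bad = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            vals = None if line.startswith("#") else _parse_floats(line)
            if vals is not None and len(vals) >= 3:
                rows3.append(vals[:3])
            elif vals is not None and len(vals) == 2:
                rows2.append(vals)
            else:
                header.append(line.lstrip("#").strip())
                if first_bad is None and not line.startswith("#"):
                    first_bad = (lineno, line)
    if len(rows3) >= 3:
        data = np.asarray(rows3)
        q, i, s = data.T
        meta = {}
    elif len(rows2) >= 3:
        data = np.asarray(rows2)
        q, i = data.T
        s = np.ones_like(q)
        meta = {"sigma_fallback": True}
    else:
        where = f" (first unparseable line {first_bad[0]}: {first_bad[1]!r})" if first_bad else ""
        raise FormatError(f"{path}: fewer than 3 parseable data rows{where}")
    if header:
        meta["header"] = header
    if not np.all(np.diff(q) > 0):
        raise ValidationError(f"{path}: q column is not strictly increasing")
    return Profile(q, i, s, meta)


def write_dat(profile: Profile, path) -> None:
    """Write a profile as three whitespace-delimited columns with '#' headers."""
    with open(path, "w") as fh:
        for key, val in profile.metadata.items():
            if key == "header":
                for line in val:
                    fh.write(f"# {line}\n")
            elif np.isscalar(val) or isinstance(val, str):
                fh.write(f"# {key}: {val}\n")
        fh.write("#  q  I  sigma\n")
        for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
            fh.write(f"{q:.8e} {i:.8e} {s:.8e}\n")


# ---------------------------------------------------------------------------
# HDF5 series format
# ---------------------------------------------------------------------------

def _json_sanitize(obj):
    """Make analysis state JSON-encodable (NaN -> None, arrays -> lists)."""
    if isinstance(obj, dict):
        return {str(k): _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_json_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if (math.isnan(f) or math.isinf(f)) else f
    if isinstance(obj, FrameRange):
        return obj.as_list()
    return obj


def write_series_h5(series: Series, path) -> None:
    """Write a series to HDF5: /q, /I, /sigma, /frames plus a JSON 'analysis'
    root attribute carrying ranges, baseline parameters and per-frame traces."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("q", data=series.q.astype(np.float64))
        h5.create_dataset("I", data=series.intensity_matrix().astype(np.float64))
        h5.create_dataset("sigma", data=series.sigma_matrix().astype(np.float64))
        h5.create_dataset("frames", data=series.frames.astype(np.int64))
        if series.analysis:
            h5.attrs["analysis"] = json.dumps(_json_sanitize(series.analysis),
                                              allow_nan=False)


def read_series_h5(path) -> Series:
    with h5py.File(path, "r") as h5:
        for name in ("q", "I", "sigma", "frames"):
            if name not in h5:
                raise FormatError(f"{path}: missing required dataset '/{name}'")
        q = h5["q"][:]
        i_mat = h5["I"][:]
        s_mat = h5["sigma"][:]
        frames = h5["frames"][:]
        analysis = json.loads(h5.attrs["analysis"]) if "analysis" in h5.attrs else {}
    if i_mat.shape != s_mat.shape or i_mat.shape[1] != len(q):
        raise FormatError(f"{path}: inconsistent dataset shapes")
    profiles = [Profile(q, i_mat[k], s_mat[k]) for k in range(i_mat.shape[0])]
    return Series(profiles, frames=frames, analysis=analysis)


# ---------------------------------------------------------------------------
# Elementary profile arithmetic
# ---------------------------------------------------------------------------

def average_profiles(profiles) -> Profile:
    """Per-point mean of independent profiles; sigma = sqrt(sum sigma^2)/n."""
    if not profiles:
        raise ValidationError("need at least one profile to average")
    q = _require_same_grid(profiles)
    n = len(profiles)
    i_mean = np.mean([p.intensity for p in profiles], axis=0)
    sig = np.sqrt(np.sum([p.sigma ** 2 for p in profiles], axis=0)) / n
    return Profile(q.copy(), i_mean, sig, {"n_averaged": n})


def subtract_profiles(sample: Profile, background: Profile) -> Profile:
    """sample - background with quadrature uncertainty propagation."""
    q = _require_same_grid([sample, background])
    i = sample.intensity - background.intensity
    sig = np.hypot(sample.sigma, background.sigma)
    return Profile(q.copy(), i, sig, {"subtracted": True})


def transform_profile(profile: Profile, op: str, *, factor=None,
                      qmin=None, qmax=None) -> Profile:
    """Return a transformed copy of a profile.

    op = 'scale'   : multiply I and sigma by ``factor`` (> 0)
    op = 'q-scale' : multiply q by ``factor`` (> 0)
    op = 'trim'    : keep points with qmin <= q <= qmax
    op = 'rebin'   : average non-overlapping blocks of ``factor`` points;
                     a trailing partial block is kept as a smaller block
    """
    if op == "scale":
        k = float(factor)
        if k <= 0:
            raise ValidationError("scale factor must be > 0")
        return Profile(profile.q.copy(), profile.intensity * k,
                       profile.sigma * k, dict(profile.metadata))
    if op == "q-scale":
        k = float(factor)
        if k <= 0:
            raise ValidationError("q-scale factor must be > 0")
        return Profile(profile.q * k, profile.intensity.copy(),
                       profile.sigma.copy(), dict(profile.metadata))
    if op == "trim":
        if qmin is None or qmax is None or not qmin < qmax:
            raise ValidationError("trim needs qmin < qmax")
        mask = (profile.q >= qmin) & (profile.q <= qmax)
        if mask.sum() < 3:
            raise ValidationError("trim would leave fewer than 3 points")
        return Profile(profile.q[mask], profile.intensity[mask],
                       profile.sigma[mask], dict(profile.metadata))
    if op == "rebin":
        m = int(factor)
        if m < 1:
            raise ValidationError("rebin factor must be a positive integer")
        if m == 1:
            return profile.copy()
        n = len(profile)
        q_out, i_out, s_out = [], [], []
        for start in range(0, n, m):
            sl = slice(start, min(start + m, n))
            k = sl.stop - sl.start
            q_out.append(profile.q[sl].mean())
            i_out.append(profile.intensity[sl].mean())
            s_out.append(np.sqrt(np.sum(profile.sigma[sl] ** 2)) / k)
        if len(q_out) < 3:
            raise ValidationError("rebin would leave fewer than 3 points")
        return Profile(np.array(q_out), np.array(i_out), np.array(s_out),
                       dict(profile.metadata))
    raise ValidationError(f"unknown transform op {op!r}")


def dimensionless_kratky(profile: Profile, rg: float, i0: float):
    """Dimensionless Kratky curve: x = q*Rg, y = (q*Rg)^2 * I(q)/I(0).

    For an ideal Guinier-law curve the ordinate peaks at 3/e ~ 1.104 at
    q*Rg = sqrt(3); deviations from that diagnose flexibility/unfolding.
    """
    if not (rg > 0 and i0 > 0):
        raise ValidationError("rg and i0 must be positive")
    x = profile.q * rg
    y = x ** 2 * profile.intensity / i0
    return x, y
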