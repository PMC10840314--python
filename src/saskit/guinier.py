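"""Guinier analysis: weighted fits, automated range search, dual uncertainties.

At low q the scattering of a monodisperse particle follows the Guinier law
I(q) = I(0) exp(-q^2 Rg^2 / 3), so ln I is linear in q^2 with slope -Rg^2/3.
This module performs the weighted linear fit, searches for a good fit window
automatically with progressively relaxed acceptance criteria, and reports two
uncertainty estimates for Rg and I(0):

* the *fit* uncertainty, from the parameter covariance of the weighted
  least-squares fit (valid when the intensity uncertainties are accurate);
* the *range* uncertainty, the standard deviation of Rg and I(0) over a
  family of sub-ranges of the chosen window (manual fits) or over all
  high-scoring candidate windows (automated fits), which captures how much
  the answer depends on the exact choice of end points.

The reported top-level uncertainty is the larger of the two.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .sasdata import Profile

__all__ = [
    "GuinierResult",
    "AutoGuinierConfig",
    "guinier_fit",
    "range_uncertainty",
    "auto_guinier",
]


@dataclass
class GuinierResult:
    i_min: int = -1
    i_max: int = -1
    rg: float = math.nan
    i0: float = math.nan
    rg_fit_err: float = math.nan
    i0_fit_err: float = math.nan
    rg_range_err: float = math.nan
    i0_range_err: float = math.nan
    rg_err: float = math.nan
    i0_err: float = math.nan
    qmin_rg: float = math.nan
    qmax_rg: float = math.nan
    r2: float = math.nan
    success: bool = False
    stage: int | None = None  # relaxation stage used by auto_guinier
    reason: str = ""

    def finalize_errors(self) -> None:
        """Top-level uncertainty = max(fit uncertainty, range uncertainty)."""
        self.rg_err = np.nanmax([self.rg_fit_err, self.rg_range_err])
        self.i0_err = np.nanmax([self.i0_fit_err, self.i0_range_err])


# ---------------------------------------------------------------------------
# weighted linear regression on (x, y) = (q^2, ln I)
# ---------------------------------------------------------------------------

def _wls(x, y, w, scale_by_residuals: bool):
    """Weighted LS of y = a + b x.

    Returns (a, b, var_a, var_b, r2).  When ``scale_by_residuals`` the
    covariance is scaled by ssr/(n-2) (ordinary LS with unknown noise);
    otherwise the weights are taken as true inverse variances.
    """
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    syy = (w * y * y).sum()
    delta = sw * sxx - sx * sx
    if delta <= 0:
        return math.nan, math.nan, math.nan, math.nan, math.nan
    b = (sw * sxy - sx * sy) / delta
    a = (sxx * sy - sx * sxy) / delta
    ssr = max(syy - a * sy - b * sxy, 0.0)
    sstot = syy - sy * sy / sw
    r2 = 1.0 - ssr / sstot if sstot > 0 else 1.0
    var_b = sw / delta
    var_a = sxx / delta
    if scale_by_residuals:
        dof = len(x) - 2
        s2 = ssr / dof if dof > 0 else 0.0
        var_b *= s2
        var_a *= s2
    return a, b, var_a, var_b, r2


class _PrefixWLS:
    """Closed-form weighted linear fits for many contiguous windows at once.

    Prefix sums of the weighted moments let every window [s, e] (inclusive,
    indices into the supplied arrays) be fitted in O(1).
    """

    def __init__(self, x, y, w):
        z = np.zeros(1)
        self.cw = np.concatenate([z, np.cumsum(w)])
        self.cx = np.concatenate([z, np.cumsum(w * x)])
        self.cy = np.concatenate([z, np.cumsum(w * y)])
        self.cxx = np.concatenate([z, np.cumsum(w * x * x)])
        self.cxy = np.concatenate([z, np.cumsum(w * x * y)])
        self.cyy = np.concatenate([z, np.cumsum(w * y * y)])

    def fit(self, s, e):
        s = np.asarray(s)
        e = np.asarray(e) + 1
        sw = self.cw[e] - self.cw[s]
        sx = self.cx[e] - self.cx[s]
        sy = self.cy[e] - self.cy[s]
        sxx = self.cxx[e] - self.cxx[s]
        sxy = self.cxy[e] - self.cxy[s]
        syy = self.cyy[e] - self.cyy[s]
        delta = sw * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (sw * sxy - sx * sy) / delta
            a = (sxx * sy - sx * sxy) / delta
            ssr = np.maximum(syy - a * sy - b * sxy, 0.0)
            sstot = syy - sy * sy / sw
            r2 = np.where(sstot > 0, 1.0 - ssr / sstot, 1.0)
        bad = delta <= 0
        a[bad] = np.nan
        b[bad] = np.nan
        r2[bad] = np.nan
        return a, b, r2


def _guinier_points(profile: Profile, i_min: int, i_max: int):
    """Usable points in [i_min, i_max]: positive intensity; returns x, y, w
    plus a flag for whether the fit is genuinely weighted."""
    q = profile.q[i_min:i_max + 1]
    i = profile.intensity[i_min:i_max + 1]
    s = profile.sigma[i_min:i_max + 1]
    pos = i > 0
    q, i, s = q[pos], i[pos], s[pos]
    if len(q) < 3:
        raise ValidationError("fewer than 3 positive intensities in Guinier range")
    weighted = bool(np.all(s > 0))
    # sigma(ln I) = sigma/I  ->  weight = (I/sigma)^2.  Without stated
    # uncertainties assume counting statistics (sigma ~ sqrt(I)) => w = I,
    # and let the covariance be scaled by the residuals instead.
    w = (i / s) ** 2 if weighted else i.copy()
    return q, np.square(q), np.log(i), w, weighted


def guinier_fit(profile: Profile, i_min: int, i_max: int,
                compute_range_err: bool = True) -> GuinierResult:
    """Weighted Guinier fit over points [i_min, i_max] (inclusive indices).

    A non-negative slope (Rg undefined, e.g. inter-particle repulsion at low
    q) yields a flagged failure result rather than an exception.
    """
    n = len(profile)
    if not (0 <= i_min < i_max < n):
        raise ValidationError(f"bad fit range [{i_min}, {i_max}] for n={n}")
    q, x, y, w, weighted = _guinier_points(profile, i_min, i_max)
    a, b, var_a, var_b, r2 = _wls(x, y, w, scale_by_residuals=not weighted)
    res = GuinierResult(i_min=i_min, i_max=i_max, r2=r2)
    if not np.isfinite(b) or b >= 0:
        res.reason = "non-negative Guinier slope"
        return res
    rg = math.sqrt(-3.0 * b)
    i0 = math.exp(a)
    res.rg = rg
    res.i0 = i0
    # Rg^2 = -3b  =>  dRg = 3 db / (2 Rg);  I0 = exp(a) => dI0 = I0 da
    res.rg_fit_err = 1.5 * math.sqrt(var_b) / rg if var_b >= 0 else math.nan
    res.i0_fit_err = i0 * math.sqrt(var_a) if var_a >= 0 else math.nan
    res.qmin_rg = q[0] * rg
    res.qmax_rg = q[-1] * rg
    res.success = True
    if compute_range_err:
        res.rg_range_err, res.i0_range_err = range_uncertainty(profile, i_min, i_max)
    else:
        res.rg_range_err = 0.0
        res.i0_range_err = 0.0
    res.finalize_errors()
    return res


def _subrange_offsets(window: int):
    """Deterministic sub-range enumeration for the range uncertainty.

    Starts advance by 0..s points and ends retract by 0..e points with
    s = e = min(10, window//4); sub-ranges shorter than max(5, window//2)
    are excluded; at most 500 sub-ranges are kept by uniform subsampling.
    """
    adv = min(10, window // 4)
    min_len = max(5, window // 2)
    pairs = [(ds, de) for ds in range(adv + 1) for de in range(adv + 1)
             if window - ds - de >= min_len]
    if len(pairs) > 500:
        idx = np.linspace(0, len(pairs) - 1, 500).round().astype(int)
        pairs = [pairs[k] for k in np.unique(idx)]
    return pairs


def range_uncertainty(profile: Profile, i_min: int, i_max: int):
    """Std deviation of (Rg, I0) over sub-ranges of [i_min, i_max].

    Sub-ranges never extend beyond the selected window: the end points are
    assumed to already exclude unusable data, so only interior variation is
    probed.  Returns (rg_range_err, i0_range_err); (0, 0) with a warning if
    every sub-range fit fails.
    """
    window = i_max - i_min + 1
    rgs, i0s = [], []
    for ds, de in _subrange_offsets(window):
        try:
            r = guinier_fit(profile, i_min + ds, i_max - de, compute_range_err=False)
        except ValidationError:
            continue
        if r.success:
            rgs.append(r.rg)
            i0s.append(r.i0)
    if not rgs:
        warnings.warn("all sub-range Guinier fits failed; range errors set to 0")
        return 0.0, 0.0
    return float(np.std(rgs)), float(np.std(i0s))


# ---------------------------------------------------------------------------
# automated range search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Stage:
    region_qrg: float
    min_window: int
    min_window_frac: float
    r2_min: float
    qmax_rg_lo: float
    qmax_rg_hi: float
    qmin_rg_max: float


@dataclass
class AutoGuinierConfig:
    """Constants of the progressive-relaxation window search.

    Stage 1 accepts only high-quality windows; stage 2 allows smaller windows
    and poorer fits; stage 3 additionally widens the search region and the
    allowed q*Rg limits.  The composite window score balances fit quality,
    proximity of qmax*Rg to the canonical ~1.3, small qmin*Rg and window size.
    """

    stages: tuple = (
        _Stage(1.35, 10, 0.05, 0.96, 1.00, 1.35, 0.65),
        _Stage(1.35, 7, 0.05, 0.92, 1.00, 1.35, 0.65),
        _Stage(1.60, 7, 0.05, 0.90, 0.00, 1.45, 1.00),
    )
    score_weights: tuple = (0.6, 0.1, 0.1, 0.2)
    quality_frac: float = 0.9   # candidates within this fraction of the best
    # score contribute to the auto range uncertainty
    max_windows: int = 20000
    region_iter: int = 10
    seed_points: int = 20


def _estimate_region(qv, fitter: _PrefixWLS, target_qrg: float,
                     cfg: AutoGuinierConfig) -> int:
    """Index bounding the search region at q*Rg ~ target, found iteratively.

    Rg is unknown a priori, so fit the first few points, bound the region by
    the current Rg, refit over the region and repeat until stable.
    """
    n = len(qv)
    bound = min(cfg.seed_points, n) - 1
    for _ in range(cfg.region_iter):
        a, b, _ = fitter.fit(np.array([0]), np.array([bound]))
        if not np.isfinite(b[0]) or b[0] >= 0:
            break
        rg = math.sqrt(-3.0 * b[0])
        new_bound = int(np.searchsorted(qv, target_qrg / rg, side="right")) - 1
        new_bound = int(np.clip(new_bound, 4, n - 1))
        if new_bound == bound:
            return bound
        bound = new_bound
    return bound


def _candidate_windows(region_len: int, min_window: int, cap: int):
    starts, ends = [], []
    for length in range(min_window, region_len + 1):
        s = np.arange(0, region_len - length + 1)
        starts.append(s)
        ends.append(s + length - 1)
    s = np.concatenate(starts)
    e = np.concatenate(ends)
    if len(s) > cap:
        idx = np.linspace(0, len(s) - 1, cap).round().astype(int)
        s, e = s[np.unique(idx)], e[np.unique(idx)]
    return s, e


def auto_guinier(profile: Profile, config: AutoGuinierConfig | None = None) -> GuinierResult:
    """Automatic Guinier range selection with progressive relaxation.

    Candidate windows inside the low-q search region are fitted and scored;
    the best valid window at the earliest (strictest) stage that yields any
    valid window is returned.  The reported range uncertainty is the standard
    deviation of Rg and I(0) over all valid candidates scoring at least 90%
    of the winner, mirroring the spread the search itself observed.
    """
    cfg = config or AutoGuinierConfig()
    if len(profile) < 20:
        raise ValidationError("auto_guinier needs a profile with >= 20 points")
    pos = profile.intensity > 0
    idx = np.flatnonzero(pos)
    if len(idx) < 10:
        return GuinierResult(reason="too few positive intensities", success=False)
    qv = profile.q[idx]
    iv = profile.intensity[idx]
    sv = profile.sigma[idx]
    weighted = bool(np.all(sv > 0))
    wv = (iv / sv) ** 2 if weighted else iv.copy()
    xv = qv ** 2
    yv = np.log(iv)
    fitter = _PrefixWLS(xv, yv, wv)
    w_r2, w_qmax, w_qmin, w_len = cfg.score_weights

    best_rejected = ""
    for stage_no, st in enumerate(cfg.stages, start=1):
        bound = _estimate_region(qv, fitter, st.region_qrg, cfg)
        region_len = bound + 1
        min_window = max(st.min_window, math.ceil(st.min_window_frac * region_len))
        if region_len < min_window:
            continue
        s, e = _candidate_windows(region_len, min_window, cfg.max_windows)
        a, b, r2 = fitter.fit(s, e)
        ok = np.isfinite(b) & (b < 0)
        rg = np.full_like(a, np.nan)
        rg[ok] = np.sqrt(-3.0 * b[ok])
        qmin_rg = qv[s] * rg
        qmax_rg = qv[e] * rg
        valid = (ok & (r2 >= st.r2_min)
                 & (qmax_rg >= st.qmax_rg_lo) & (qmax_rg <= st.qmax_rg_hi)
                 & (qmin_rg <= st.qmin_rg_max))
        length = (e - s + 1).astype(float)
        score = (w_r2 * r2
                 + w_qmax * (1.0 - np.abs(1.3 - qmax_rg) / 1.3)
                 + w_qmin * np.maximum(0.0, 1.0 - qmin_rg / 0.65)
                 + w_len * length / region_len)
        if not valid.any():
            if ok.any():
                k = int(np.nanargmax(np.where(ok, score, -np.inf)))
                best_rejected = (f"stage {stage_no}: best rejected window "
                                 f"[{idx[s[k]]},{idx[e[k]]}] r2={r2[k]:.4f} "
                                 f"qmaxRg={qmax_rg[k]:.3f} qminRg={qmin_rg[k]:.3f}")
            continue
        vscore = np.where(valid, score, -np.inf)
        best = vscore.max()
        # deterministic tie-break: lower start, then longer window
        cand = np.flatnonzero(vscore >= best - 1e-12)
        order = np.lexsort((-length[cand], s[cand]))
        k = int(cand[order[0]])
        res = guinier_fit(profile, int(idx[s[k]]), int(idx[e[k]]),
                          compute_range_err=False)
        res.stage = stage_no
        good = valid & (score >= cfg.quality_frac * best)
        if good.sum() > 1:
            res.rg_range_err = float(np.std(rg[good]))
            res.i0_range_err = float(np.std(np.exp(a[good])))
        else:
            res.rg_range_err = 0.0
            res.i0_range_err = 0.0
        res.finalize_errors()
        return res
    return GuinierResult(success=False,
                         reason=best_rejected or "no valid Guinier window found")
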