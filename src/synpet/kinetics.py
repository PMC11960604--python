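"""Reference-tissue kinetic models: SRTM, SRTM2 and the reference Logan plot.

The simplified reference tissue model (SRTM) describes a target-tissue
curve as

    CT(t) = R1 * CR(t) + phi * [CR conv exp(-k2a t)](t),

with R1 = K1/K1' the relative delivery, k2a the apparent efflux rate of
the target, and phi = k2 - R1*k2a.  The derived quantities are
k2 = phi + R1*k2a, the binding potential BPnd = k2/k2a - 1, and the
reference clearance k2' = k2/R1.  SRTM2 re-fits with k2' fixed to a
population value, constraining k2 = R1*k2', which stabilizes R1 and k2a
when the reference clearance is known.

Fitting uses the basis-function approach: for each candidate k2a the
convolution basis is precomputed and the remaining parameters are linear,
solved by weighted least squares; the k2a grid minimum is then refined by
bounded scalar minimization in log space.

The reference Logan plot estimates the distribution volume ratio (DVR)
as the late-time slope of

    Y(T) = int_0^T CT / CT(T)   on
    X(T) = (int_0^T CR + CR(T)/k2') / CT(T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .frames import TimeActivityCurve, cumulative_integral

__all__ = [
    "KineticFit",
    "LoganFit",
    "ReferenceBasis",
    "srtm_fit",
    "srtm2_fit",
    "derive_k2p",
    "mean_sse",
    "logan_ref",
    "logan_steady_state_check",
    "cohort_steady_state_test",
    "voxelwise_ratio_image",
]

log = logging.getLogger(__name__)

# 60 log-spaced candidate efflux rates spanning plausible tracer
# kinetics, refined locally after the grid search.
DEFAULT_K2A_GRID = np.geomspace(0.006, 0.6, 60)
FINE_GRID_DT_MIN = 0.05


@dataclass
class KineticFit:
    """Result of an SRTM or SRTM2 fit for one target curve."""

    r1: float
    k2: float
    k2a: float
    bp_nd: float
    k2p: float
    sse: float
    fitted_values: np.ndarray
    at_boundary: bool = False
    model: str = "srtm"
    name: str = ""

    @property
    def dvr(self) -> float:
        """Distribution volume ratio, BPnd + 1 under reference-tissue
        assumptions."""
        return self.bp_nd + 1.0


@dataclass
class LoganFit:
    """Reference Logan regression for one target curve."""

    dvr: float
    intercept: float
    x_points: np.ndarray
    y_points: np.ndarray
    times: np.ndarray  # frame mid-times (min) of the included points
    t_star: float
    window: tuple[float, float]


class ReferenceBasis:
    """Precomputed fine-grid representation of a reference curve.

    The convolution [CR conv exp(-k2a t)] is evaluated on a uniform
    0.05-min grid — CR linearly interpolated from the frame samples,
    anchored at (0, 0) — using the exact linear recurrence for the
    exponential kernel, then sampled back at the frame mid-times.
    Building this once per reference lets the same basis cache serve
    every cortical region fitted against that reference.
    """

    def __init__(self, reference: TimeActivityCurve, dt: float = FINE_GRID_DT_MIN):
        if not np.any(reference.values != 0):
            raise ValueError("reference TAC is identically zero")
        self.reference = reference
        self.mid = reference.mid_times
        self.dt = float(dt)
        self.t_grid = np.arange(0.0, self.mid[-1] + dt / 2, dt)
        self.cr_fine = np.interp(self.t_grid, np.r_[0.0, self.mid],
                                 np.r_[0.0, reference.values])
        self.cr_frames = reference.values
        self._cache: dict[float, np.ndarray] = {}

    def basis(self, k2a: float) -> np.ndarray:
        """[CR conv exp(-k2a t)] at the frame mid-times (min * activity).

        Grid-search k2a values repeat across every region fitted against
        this reference, so results are memoized per k2a.
        """
        k2a = float(k2a)
        cached = self._cache.get(k2a)
        if cached is not None:
            return cached
        out = self._basis_uncached(k2a)
        if len(self._cache) < 4096:
            self._cache[k2a] = out
        return out

    def _basis_uncached(self, k2a: float) -> np.ndarray:
        a = float(np.exp(-k2a * self.dt))
        c = self.cr_fine
        b = np.empty_like(c)
        b[0] = 0.0
        # trapezoid increment of the convolution integral per grid step
        b[1:] = 0.5 * self.dt * (a * c[:-1] + c[1:])
        y = signal.lfilter([1.0], [1.0, -a], b)
        return np.interp(self.mid, self.t_grid, y)


def _check_shared_schedule(target: TimeActivityCurve, reference: TimeActivityCurve) -> None:
    if len(target) != len(reference) or not np.allclose(target.mid_times, reference.mid_times):
        raise ValueError("target and reference TACs must share a frame schedule")


def _weights(target: TimeActivityCurve, weights) -> np.ndarray:
    if weights is None:
        return target.effective_weights()
    w = np.asarray(weights, float)
    if w.shape != target.values.shape or np.any(w < 0):
        raise ValueError("weights must be nonnegative and match the TAC length")
    return w


def _srtm_solve(ct: np.ndarray, cr: np.ndarray, b: np.ndarray, w: np.ndarray):
    """Weighted LS for CT = R1*CR + phi*B; returns (r1, phi, sse)."""
    g00 = np.dot(w * cr, cr)
    g01 = np.dot(w * cr, b)
    g11 = np.dot(w * b, b)
    r0 = np.dot(w * cr, ct)
    r1v = np.dot(w * b, ct)
    det = g00 * g11 - g01 * g01
    if det <= 0 or not np.isfinite(det):
        return np.nan, np.nan, np.inf
    r1 = (g11 * r0 - g01 * r1v) / det
    phi = (g00 * r1v - g01 * r0) / det
    sse = np.dot(w * ct, ct) - (r1 * r0 + phi * r1v)
    return r1, phi, max(sse, 0.0)


def _srtm2_solve(ct: np.ndarray, cr: np.ndarray, b: np.ndarray, w: np.ndarray,
                 k2p: float, k2a: float):
    """Weighted LS for CT = R1*(CR + (k2p - k2a)*B); returns (r1, sse)."""
    z = cr + (k2p - k2a) * b
    denom = np.dot(w * z, z)
    if denom <= 0:
        return np.nan, np.inf
    r1 = np.dot(w * z, ct) / denom
    resid = ct - r1 * z
    return r1, float(np.dot(w * resid, resid))


def _refine_k2a(sse_of, lo: float, hi: float) -> float:
    res = optimize.minimize_scalar(
        lambda x: sse_of(float(np.exp(x))), bounds=(np.log(lo), np.log(hi)),
        method="bounded", options={"xatol": 2e-3})
    return float(np.exp(res.x))


def _validate_grid(k2a_grid) -> np.ndarray:
    grid = np.asarray(k2a_grid, float)
    if grid.ndim != 1 or grid.size < 20:
        raise ValueError("k2a_grid must be a 1-D grid of at least 20 points")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("k2a_grid must be positive and strictly increasing")
    return grid


def srtm_fit(target: TimeActivityCurve, reference: TimeActivityCurve,
             k2a_grid=DEFAULT_K2A_GRID, weights=None,
             basis: ReferenceBasis | None = None) -> KineticFit:
    """Three-parameter SRTM fit of one target curve.

    Grid search over k2a with the linear parameters (R1, phi) solved in
    closed form at each grid point, followed by local refinement of k2a
    between the neighbours of the grid minimum.  A best k2a landing on
    the grid edge is flagged ``at_boundary`` and excluded from k2'
    pooling downstream.
    """
    _check_shared_schedule(target, reference)
    grid = _validate_grid(k2a_grid)
    rb = basis if basis is not None else ReferenceBasis(reference)
    w = _weights(target, weights)
    ct, cr = target.values, rb.cr_frames

    sse_grid = np.empty(grid.size)
    for i, k2a in enumerate(grid):
        sse_grid[i] = _srtm_solve(ct, cr, rb.basis(k2a), w)[2]
    idx = int(np.argmin(sse_grid))
    at_boundary = idx in (0, grid.size - 1)
    if at_boundary:
        k2a = float(grid[idx])
    else:
        k2a = _refine_k2a(lambda x: _srtm_solve(ct, cr, rb.basis(x), w)[2],
                          grid[idx - 1], grid[idx + 1])
    b = rb.basis(k2a)
    r1, phi, sse = _srtm_solve(ct, cr, b, w)
    k2 = phi + r1 * k2a
    return KineticFit(r1=float(r1), k2=float(k2), k2a=float(k2a),
                      bp_nd=float(k2 / k2a - 1.0), k2p=float(k2 / r1),
                      sse=float(sse), fitted_values=r1 * cr + phi * b,
                      at_boundary=at_boundary, model="srtm", name=target.name)


def srtm2_fit(target: TimeActivityCurve, reference: TimeActivityCurve, k2p: float,
              k2a_grid=DEFAULT_K2A_GRID, weights=None,
              basis: ReferenceBasis | None = None) -> KineticFit:
    """Two-parameter SRTM2 fit with the reference clearance k2' fixed.

    With k2 constrained to R1*k2', the model collapses to a single
    linear amplitude per candidate k2a:
    CT = R1 * [CR + (k2' - k2a) * B(k2a)].
    """
    if not k2p > 0:
        raise ValueError(f"k2p must be positive, got {k2p}")
    _check_shared_schedule(target, reference)
    grid = _validate_grid(k2a_grid)
    rb = basis if basis is not None else ReferenceBasis(reference)
    w = _weights(target, weights)
    ct, cr = target.values, rb.cr_frames

    sse_grid = np.empty(grid.size)
    for i, k2a in enumerate(grid):
        sse_grid[i] = _srtm2_solve(ct, cr, rb.basis(k2a), w, k2p, k2a)[1]
    idx = int(np.argmin(sse_grid))
    at_boundary = idx in (0, grid.size - 1)
    if at_boundary:
        k2a = float(grid[idx])
    else:
        k2a = _refine_k2a(lambda x: _srtm2_solve(ct, cr, rb.basis(x), w, k2p, x)[1],
                          grid[idx - 1], grid[idx + 1])
    b = rb.basis(k2a)
    r1, sse = _srtm2_solve(ct, cr, b, w, k2p, k2a)
    k2 = r1 * k2p
    return KineticFit(r1=float(r1), k2=float(k2), k2a=float(k2a),
                      bp_nd=float(k2 / k2a - 1.0), k2p=float(k2p),
                      sse=float(sse), fitted_values=r1 * (cr + (k2p - k2a) * b),
                      at_boundary=at_boundary, model="srtm2", name=target.name)


@dataclass
class K2PrimeEstimate:
    """Subject-level reference clearance pooled over regional SRTM fits."""

    k2p: float
    per_roi: np.ndarray
    n_excluded: int


def derive_k2p(fits: list[KineticFit], min_bp: float = -0.5,
               mad_threshold: float = 5.0) -> K2PrimeEstimate:
    """Pool a subject's reference clearance from regional SRTM fits.

    Implausible fits are dropped first: k2a pinned at the search
    boundary, BPnd <= ``min_bp``, non-finite or non-positive k2/R1, and
    — because the k2/R1 ratio is heavy-tailed under frame noise —
    values farther than ``mad_threshold`` median absolute deviations
    from the regional median.  The estimate is the unweighted mean of
    the surviving per-region k2/R1 values.
    """
    if not fits:
        raise ValueError("derive_k2p requires at least one fit")
    candidates = np.array([f.k2p for f in fits
                           if not f.at_boundary and f.bp_nd > min_bp
                           and np.isfinite(f.k2p) and f.k2p > 0])
    if candidates.size:
        med = np.median(candidates)
        mad = np.median(np.abs(candidates - med))
        tol = mad_threshold * max(mad, 0.02 * med)
        per_roi = candidates[np.abs(candidates - med) <= tol]
    else:
        per_roi = candidates
    if per_roi.size == 0:
        raise ValueError("all regional fits were excluded by plausibility filters")
    return K2PrimeEstimate(k2p=float(per_roi.mean()), per_roi=per_roi,
                           n_excluded=len(fits) - per_roi.size)


def mean_sse(fits: list[KineticFit]) -> float:
    """Arithmetic mean of per-region weighted SSE — the fit-quality
    summary used to compare candidate reference regions."""
    if not fits:
        raise ValueError("mean_sse of an empty fit list")
    return float(np.mean([f.sse for f in fits]))


def _logan_points(target: TimeActivityCurve, reference: TimeActivityCurve,
                  k2p: float, t_star: float, t_end: float):
    _check_shared_schedule(target, reference)
    if not k2p > 0:
        raise ValueError(f"k2p must be positive, got {k2p}")
    mid = target.mid_times
    mask = (mid >= t_star) & (mid <= t_end)
    if mask.sum() < 3:
        raise ValueError(
            f"Logan fit needs >= 3 frames in [{t_star}, {t_end}] min; "
            f"found {int(mask.sum())}")
    ct = target.values
    if np.any(ct[mask] <= 0):
        raise ValueError("target TAC must be positive over the Logan window")
    int_ct = cumulative_integral(target)
    int_cr = cumulative_integral(reference)
    y = int_ct[mask] / ct[mask]
    x = (int_cr[mask] + reference.values[mask] / k2p) / ct[mask]
    return x, y, mid[mask]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient Logan regression (constant X)")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def logan_ref(target: TimeActivityCurve, reference: TimeActivityCurve, k2p: float,
              t_star: float = 35.0, t_end: float = 90.0) -> LoganFit:
    """Reference Logan graphical analysis; the slope estimates DVR.

    Frames are included when their mid-time lies in [t_star, t_end];
    the running integrals always start at injection.  Ordinary least
    squares is used without error-in-variables correction, so noise in
    CT(T) induces the well-known negative bias at high noise.
    """
    x, y, times = _logan_points(target, reference, k2p, t_star, t_end)
    slope, intercept = _ols_slope(x, y)
    return LoganFit(dvr=slope, intercept=intercept, x_points=x, y_points=y,
                    times=times, t_star=float(t_star),
                    window=(float(t_star), float(t_end)))


@dataclass
class SteadyStateCheck:
    slope_a: float
    slope_b: float
    difference: float
    window_a: tuple[float, float]
    window_b: tuple[float, float]


def logan_steady_state_check(fit: LoganFit, window_a=(35.0, 90.0),
                             window_b=(70.0, 90.0)) -> SteadyStateCheck:
    """Compare Logan slopes over an early-onset and a late-only window.

    A nonzero difference indicates the plot is still curving — the
    tracer has not reached the steady-state regime where the graphical
    slope is a valid DVR.

    Each window needs at least 2 points: on the standard 35-frame
    schedule the [70, 90] window contains exactly the two 600-s frames,
    so its slope is the two-point secant.
    """
    out = []
    for w in (window_a, window_b):
        m = (fit.times >= w[0]) & (fit.times <= w[1])
        if m.sum() < 2:
            raise ValueError(f"steady-state check needs >= 2 Logan points in window {list(w)}")
        out.append(_ols_slope(fit.x_points[m], fit.y_points[m])[0])
    return SteadyStateCheck(slope_a=out[0], slope_b=out[1],
                            difference=out[0] - out[1],
                            window_a=tuple(window_a), window_b=tuple(window_b))


def cohort_steady_state_test(checks: list[SteadyStateCheck]):
    """Paired t-test of the per-subject slope differences against zero."""
    diffs = np.array([c.difference for c in checks])
    t, p = stats.ttest_1samp(diffs, 0.0)
    return {"mean_difference": float(diffs.mean()), "t": float(t),
            "p": float(p), "n": len(diffs)}


def voxelwise_ratio_image(image, reference: TimeActivityCurve, method: str,
                          mask: np.ndarray, k2p: float | None = None,
                          t_star: float = 35.0, t_end: float = 90.0,
                          window=(60.0, 80.0)) -> np.ndarray:
    """Whole-brain ratio image: per-voxel reference Logan DVR or SUVR.

    Voxels outside ``mask`` — and voxels where the fit fails (e.g.
    non-positive activity inside the Logan window) — are set to NaN; the
    failure count is logged.
    """
    data = image.data
    mask = np.asarray(mask, bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask must match the image grid")
    out = np.full(data.shape[:3], np.nan)
    ct_mat = data[mask]  # (nvox, nframes)
    mid = image.schedule.mid_times()
    if method == "suvr":
        ref_val = np.asarray(reference.values, float)
        ref_mean = TimeActivityCurve.from_schedule(image.schedule, ref_val)
        from .frames import window_average
        denom = window_average(ref_mean, window)
        if denom <= 0:
            raise ValueError("reference window average must be positive")
        w_mask = (mid >= window[0]) & (mid <= window[1])
        durs = image.schedule.durations[w_mask]
        num = ct_mat[:, w_mask] @ durs / durs.sum()
        out[mask] = num / denom
        return out
    if method != "logan":
        raise ValueError(f"unknown ratio method {method!r}")
    if k2p is None or k2p <= 0:
        raise ValueError("logan method requires positive k2p")

    # vectorized Logan across voxels
    frame_mask = (mid >= t_star) & (mid <= t_end)
    if frame_mask.sum() < 3:
        raise ValueError(f"Logan needs >= 3 frames in [{t_star}, {t_end}] min")
    t_ext = np.r_[0.0, mid]
    v_ext = np.concatenate([np.zeros((ct_mat.shape[0], 1)), ct_mat], axis=1)
    incr = np.diff(t_ext) * (v_ext[:, :-1] + v_ext[:, 1:]) / 2.0
    int_ct = np.cumsum(incr, axis=1)
    int_cr = cumulative_integral(reference)

    ct_w = ct_mat[:, frame_mask]
    ok = np.all(ct_w > 0, axis=1)
    y = int_ct[ok][:, frame_mask] / ct_w[ok]
    x = (int_cr[frame_mask] + reference.values[frame_mask] / k2p) / ct_w[ok]
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    denom = np.sum(xm * xm, axis=1)
    slope = np.where(denom > 0, np.sum(xm * ym, axis=1) / np.where(denom > 0, denom, 1.0),
                     np.nan)
    vals = np.full(ct_mat.shape[0], np.nan)
    vals[ok] = slope
    n_fail = int(np.sum(~np.isfinite(vals)))
    if n_fail:
        log.info("voxelwise Logan: %d/%d masked voxels failed and were set to NaN",
                 n_fail, vals.size)
    out[mask] = vals
    return out
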