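"""Signal-area segmentation of probe tracks (the chipSAD core).

The segmenter walks the genomic coordinate of a probe track and, at every
eligible probe, grows a pair of *correlated probe regions* (CPRs): windows
of consecutive probes with consistent signal immediately left and right of
the anchor.  Each window starts at the initial width ``w`` (the mean
inter-probe distance) and expands probe-by-probe outward while

(a) the gap to the next probe does not exceed ``w``,
(b) once the window holds at least ``m(w)`` probes, the next probe's M
    deviates from the window mean by no more than ``k`` times the window
    scatter (floored by the fudge constant and a robust track-level noise
    scale), and
(c) the window span stays below ``max_window_expansion``.

The two windows are then compared with a generalized t-statistic in the
SAM (significance analysis of microarrays) relative-difference form,

    t(x) = (mean_R - mean_L) / (s + s0),
    s    = sqrt( (1/n_L + 1/n_R) * (SS_L + SS_R) / (n_L + n_R - 2) ),

where SS is the within-window sum of squared deviations and ``s0`` a small
fudge constant that stabilizes t where the local scatter is near zero.
Local extrema of |t(x)| above a threshold are the signal *change points*.

Signal areas (SAS, the putative transcripts) are then assembled between
change points.  On a uniformly tiled layout the t-curve alone fixes the
boundaries; on non-uniform layouts a left-to-right merge pass re-joins
adjacent candidate regions whose pooled pseudomedian intensity exceeds the
absolute difference of their individual pseudomedians.  Per-area intensity
is summarized by the pseudomedian (Hodges-Lehmann estimator): the median of
all Walsh averages (v_i + v_j) / 2, i <= j.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import ProbeTrack, estimate_min_probes, estimate_window_size

logger = logging.getLogger("chipsad")

# CV of inter-probe gaps below which a layout is treated as tiled
_TILING_CV_MAX = 0.2


@dataclass
class SegmentationParams:
    """Tunables of the segmenter; ``None`` means estimate from the track.

    w:        initial window size, bp.
    m_w:      minimum probes per window.
    s0:       t-statistic fudge constant (signal units); default is the 5th
              percentile of pooled s over all anchors, floored at 0.01.
    t_threshold: |t| needed to call a change point.
    k_consistency: CPR expansion gate in window-scatter units.
    gap_factor: largest bridgeable inter-probe gap, in units of w.  With w
              equal to the *mean* gap, skewed non-tiling layouts place a
              large fraction of gaps above w itself; a factor of 2 keeps
              windows alive across ordinary spacing irregularity while a
              3w hole still severs them.
    max_window_expansion: hard cap on CPR span, bp; default 10*w.
    layout_mode: 'tiling', 'nontiling' or 'auto'.
    """

    w: int | None = None
    m_w: int | None = None
    s0: float | None = None
    t_threshold: float = 3.0
    k_consistency: float = 3.0
    gap_factor: float = 2.0
    max_window_expansion: int | None = None
    layout_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.w is not None and self.w <= 0:
            raise ValueError("w must be positive")
        if self.m_w is not None and self.m_w < 2:
            raise ValueError("m_w must be at least 2")
        if self.s0 is not None and self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if self.layout_mode not in ("tiling", "nontiling", "auto"):
            raise ValueError(f"unknown layout_mode {self.layout_mode!r}")

    def resolved(self, track: ProbeTrack) -> "SegmentationParams":
        """Fill data-driven defaults (w, m_w, expansion cap) from the track."""
        w = self.w if self.w is not None else estimate_window_size(track)
        m_w = self.m_w if self.m_w is not None else estimate_min_probes(track, w)
        cap = (
            self.max_window_expansion
            if self.max_window_expansion is not None
            else 10 * w
        )
        return SegmentationParams(
            w=w, m_w=m_w, s0=self.s0, t_threshold=self.t_threshold,
            k_consistency=self.k_consistency, gap_factor=self.gap_factor,
            max_window_expansion=cap, layout_mode=self.layout_mode,
        )


@dataclass
class CPR:
    """A correlated probe region on one side of an anchor coordinate."""

    side: str                 # 'left' or 'right'
    anchor_x: int
    lo: int                   # first probe index (inclusive)
    hi: int                   # last probe index (exclusive)
    n: int
    mean_M: float
    ss_M: float               # within-region sum of squared deviations
    span: int

    @property
    def degenerate(self) -> bool:
        return self.n < 2

    @property
    def sd_M(self) -> float:
        return math.sqrt(self.ss_M / (self.n - 1)) if self.n >= 2 else 0.0


@dataclass
class ChangePoint:
    x: int
    t_value: float


@dataclass
class SignalArea:
    """A contiguous interval of consistent signal — a putative transcript."""

    experiment_id: str
    replicon: str
    strand: str
    start: int
    end: int
    pseudomedian_M: float
    n_probes: int
    probe_lo: int = 0
    probe_hi: int = 0
    probe_Ms: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("SignalArea start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# pseudomedian (Hodges-Lehmann)
# ---------------------------------------------------------------------------

def pseudomedian(values) -> float:
    """Median of all Walsh averages (v_i + v_j) / 2 for i <= j.

    Exact O(n^2) construction; robust to outliers and, unlike the plain
    median, smooth under small perturbations of single values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("pseudomedian of an empty list")
    if v.size == 1:
        return float(v[0])
    i, j = np.triu_indices(v.size)
    return float(np.median((v[i] + v[j]) / 2.0))


# ---------------------------------------------------------------------------
# CPR construction
# ---------------------------------------------------------------------------

def _expand_side(starts, ends, M, lo, hi, direction, params, s0_gate,
                 ignore_gap=False, strict_gate=False):
    """Grow the window [lo, hi) outward one probe at a time.

    direction -1 grows leftward (decreasing lo), +1 rightward (increasing
    hi).  Growth below m_w probes is gated only by the gap and span rules;
    from m_w on, the signal-consistency rule applies as well.  With
    ``ignore_gap`` the window grows by probe count regardless of spacing
    (used by the hole comparison, where the spacing rule cannot hold by
    construction); ``strict_gate`` applies the consistency rule from the
    first probe on instead of waiving it below m_w, so a count-grown window
    cannot swallow a probe across a signal step.
    """
    max_gap = math.inf if ignore_gap else params.gap_factor * params.w
    k = params.k_consistency
    cap = params.max_window_expansion
    m_w = params.m_w

    n = hi - lo
    if n == 0:
        return lo, hi
    vals = M[lo:hi]
    mean = float(vals.mean())
    ss = float(((vals - mean) ** 2).sum())

    while True:
        nxt = lo - 1 if direction < 0 else hi
        if nxt < 0 or nxt >= len(starts):
            break
        gap = starts[lo] - starts[nxt] if direction < 0 else starts[nxt] - starts[hi - 1]
        if gap > max_gap:
            break
        span = (max(ends[hi - 1], ends[nxt]) - min(starts[lo], starts[nxt])) + 1
        if span > cap:
            break
        if n >= m_w or strict_gate:
            sd = math.sqrt(ss / (n - 1)) if n >= 2 else 0.0
            if abs(M[nxt] - mean) > k * max(sd, s0_gate):
                break
        # Welford update
        n += 1
        delta = M[nxt] - mean
        mean += delta / n
        ss += delta * (M[nxt] - mean)
        if direction < 0:
            lo = nxt
        else:
            hi = nxt + 1
    return lo, hi


def build_cpr_pair(
    track: ProbeTrack,
    anchor_index: int,
    params: SegmentationParams,
    s0_gate: float | None = None,
    rescue_holes: bool = False,
) -> tuple[CPR, CPR]:
    """Build the left/right correlated probe regions flanking one anchor.

    The anchor coordinate is the start of the anchor probe; the left window
    initially covers starts in [x - w, x) and the right window [x, x + w),
    then each expands outward under the gap / consistency / span rules.
    A side with fewer than two probes is returned degenerate and yields no
    t value.

    ``rescue_holes`` (the non-tiling path) regrows a degenerate side by
    probe count with the gap rule waived and the consistency rule applied
    from the first probe on: a signal step sitting next to an unbridgeable
    probe hole keeps an eligible anchor instead of going blind.
    """
    params = params.resolved(track)
    if s0_gate is None:
        s0_gate = max(params.s0 or 0.01, _robust_noise_scale(track.M))
    starts, ends, M = track.starts, track.ends, track.M
    x = int(starts[anchor_index])
    w = params.w

    l_lo = int(np.searchsorted(starts, x - w, side="left"))
    l_hi = anchor_index
    r_lo = anchor_index
    r_hi = int(np.searchsorted(starts, x + w, side="left"))
    if l_lo == l_hi and anchor_index > 0:
        # empty left window: seed it from the adjacent probe when the hole
        # is bridgeable, so sparse layouts keep their interior anchors
        if x - starts[anchor_index - 1] <= params.gap_factor * w:
            l_lo = anchor_index - 1

    l_lo, l_hi = _expand_side(starts, ends, M, l_lo, l_hi, -1, params, s0_gate)
    r_lo, r_hi = _expand_side(starts, ends, M, r_lo, r_hi, +1, params, s0_gate)
    if rescue_holes:
        if l_hi - l_lo < 2 and anchor_index > 0:
            l_lo, l_hi = _expand_side(
                starts, ends, M, anchor_index - 1, anchor_index, -1, params,
                s0_gate, ignore_gap=True, strict_gate=True,
            )
        if r_hi - r_lo < 2:
            r_lo, r_hi = _expand_side(
                starts, ends, M, anchor_index, anchor_index + 1, +1, params,
                s0_gate, ignore_gap=True, strict_gate=True,
            )

    def mk(side, lo, hi):
        n = hi - lo
        if n == 0:
            return CPR(side, x, lo, hi, 0, math.nan, 0.0, 0)
        vals = M[lo:hi]
        mean = float(vals.mean())
        ss = float(((vals - mean) ** 2).sum())
        return CPR(side, x, lo, hi, n, mean, ss, int(ends[hi - 1] - starts[lo] + 1))

    return mk("left", l_lo, l_hi), mk("right", r_lo, r_hi)


# ---------------------------------------------------------------------------
# t-statistic and profile
# ---------------------------------------------------------------------------

def sam_t(left: CPR, right: CPR, s0: float) -> float:
    """SAM-style relative difference between the two flanking regions."""
    if left.degenerate or right.degenerate:
        raise ValueError("sam_t needs two non-degenerate CPRs (n >= 2 each)")
    n_l, n_r = left.n, right.n
    s = math.sqrt(
        (1.0 / n_l + 1.0 / n_r) * (left.ss_M + right.ss_M) / (n_l + n_r - 2)
    )
    return (right.mean_M - left.mean_M) / (s + s0)


def _robust_noise_scale(M: np.ndarray) -> float:
    """Probe-to-probe noise sigma from the median absolute first difference.

    For i.i.d. Gaussian noise the successive differences have sd sigma*sqrt(2),
    so sigma = median|diff| / (sqrt(2) * 0.6745); steps between transcripts
    are sparse in the difference sequence and do not move the median.
    """
    if M.size < 3:
        return 0.0
    d = np.abs(np.diff(M))
    return float(np.median(d) / (math.sqrt(2) * 0.6745))


def _pooled_s(left: CPR, right: CPR) -> float:
    return math.sqrt(
        (1.0 / left.n + 1.0 / right.n)
        * (left.ss_M + right.ss_M)
        / (left.n + right.n - 2)
    )


def _anchor_pairs(track: ProbeTrack, params: SegmentationParams, s0_gate: float,
                  rescue_holes: bool = False):
    """CPR pairs at every eligible interior anchor (degenerate sides skipped)."""
    anchors = range(params.m_w, len(track) - params.m_w)
    pairs = []
    for a in anchors:
        left, right = build_cpr_pair(track, a, params, s0_gate=s0_gate,
                                     rescue_holes=rescue_holes)
        if left.degenerate or right.degenerate:
            continue
        pairs.append((a, left, right))
    return pairs


def _resolve_s0(track: ProbeTrack, params: SegmentationParams) -> SegmentationParams:
    """Fill in the fudge constant when unset.

    s0 is the 5th percentile of the pooled-s distribution over all anchors
    (computed with a provisional expansion gate from the robust noise
    scale), floored at 0.01.
    """
    if params.s0 is not None:
        return params
    sigma = _robust_noise_scale(track.M)
    pairs = _anchor_pairs(track, params, max(0.01, sigma))
    if not pairs:
        return replace(params, s0=0.01)
    s_values = [_pooled_s(l, r) for _, l, r in pairs]
    return replace(params, s0=max(0.01, float(np.percentile(s_values, 5))))


def t_profile(
    track: ProbeTrack, params: SegmentationParams, rescue_holes: bool = False
) -> list[tuple[int, float]]:
    """The ordered t(x) curve: one value per interior probe with valid CPRs.

    The first and last m_w probes cannot anchor a change point.  When the
    fudge constant is not given, it is set to the 5th percentile of the
    pooled-s distribution over all anchors (floored at 0.01) and the CPRs
    are rebuilt with the final value.
    """
    if len(track) < 2 * 2 + 1:
        return []
    params = params.resolved(track)
    params = _resolve_s0(track, params)
    sigma = _robust_noise_scale(track.M)
    pairs = _anchor_pairs(track, params, max(params.s0, sigma), rescue_holes)
    starts = track.starts
    return [(int(starts[a]), sam_t(l, r, params.s0)) for a, l, r in pairs]


def _hole_change_points(
    track: ProbeTrack, params: SegmentationParams
) -> list[ChangePoint]:
    """Signal comparison across probe holes too wide for any CPR to bridge.

    The sliding windows never span a gap above gap_factor * w, so a signal
    step coinciding with such a hole leaves no eligible anchor and the
    t-curve is blind there.  For every hole the two flanking windows are
    grown by probe count (same consistency and span rules, gap rule waived
    at the hole itself) and compared with the same t-statistic; a cut is
    placed at the first probe after the hole when |t| passes the threshold.
    Redundant cuts near genuine anchors are harmless: the pseudomedian
    merge pass rejoins consistent neighbours.
    """
    assert params.s0 is not None
    sigma = _robust_noise_scale(track.M)
    s0_gate = max(params.s0, sigma)
    starts, ends, M = track.starts, track.ends, track.M
    max_gap = params.gap_factor * params.w
    out = []
    for i in range(len(track) - 1):
        if starts[i + 1] - starts[i] <= max_gap:
            continue
        l_lo, l_hi = _expand_side(starts, ends, M, i, i + 1, -1, params, s0_gate,
                                  ignore_gap=True, strict_gate=True)
        r_lo, r_hi = _expand_side(starts, ends, M, i + 1, i + 2, +1, params, s0_gate,
                                  ignore_gap=True, strict_gate=True)
        if l_hi - l_lo < 2 or r_hi - r_lo < 2:
            continue
        def _cpr(side, lo, hi):
            vals = M[lo:hi]
            mean = float(vals.mean())
            ss = float(((vals - mean) ** 2).sum())
            return CPR(side, int(starts[i + 1]), lo, hi, hi - lo, mean, ss,
                       int(ends[hi - 1] - starts[lo] + 1))
        t = sam_t(_cpr("left", l_lo, l_hi), _cpr("right", r_lo, r_hi), params.s0)
        if abs(t) >= params.t_threshold:
            out.append(ChangePoint(int(starts[i + 1]), t))
    return out


def detect_change_points(
    profile: list[tuple[int, float]], t_threshold: float
) -> list[ChangePoint]:
    """Collapse above-threshold runs of the t-curve to single change points.

    Within a run of consecutive anchors with |t| >= threshold only the
    anchor with maximal |t| is kept (leftmost on ties).  A sign change of t
    inside a run ends it: a rising and a falling step are two distinct
    change points even when no eligible anchor sits between them (sparse
    layouts can leave the intervening anchors degenerate).
    """
    out: list[ChangePoint] = []
    best: tuple[float, int, float] | None = None  # (|t|, x, t)
    for x, t in profile:
        if abs(t) >= t_threshold:
            if best is not None and t * best[2] < 0:
                out.append(ChangePoint(best[1], best[2]))
                best = None
            if best is None or abs(t) > best[0]:
                best = (abs(t), x, t)
        else:
            if best is not None:
                out.append(ChangePoint(best[1], best[2]))
                best = None
    if best is not None:
        out.append(ChangePoint(best[1], best[2]))
    return out


# ---------------------------------------------------------------------------
# signal-area assembly
# ---------------------------------------------------------------------------

def _candidate_regions(track: ProbeTrack, change_points) -> list[tuple[int, int]]:
    """Probe-index intervals [lo, hi) delimited by the change points.

    A change point at coordinate x opens a new region at the first probe
    whose start is >= x (the anchor probe belongs to the right-hand side of
    the comparison that called it).
    """
    starts = track.starts
    cuts = sorted({int(np.searchsorted(starts, cp.x, side="left"))
                   for cp in change_points})
    cuts = [c for c in cuts if 0 < c < len(track)]
    bounds = [0] + cuts + [len(track)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _make_sas(track: ProbeTrack, lo: int, hi: int) -> SignalArea:
    ms = track.M[lo:hi]
    return SignalArea(
        experiment_id=track.experiment_id,
        replicon=track.replicon,
        strand=track.strand,
        start=int(track.starts[lo]),
        end=int(track.ends[hi - 1]),
        pseudomedian_M=pseudomedian(ms),
        n_probes=hi - lo,
        probe_lo=lo,
        probe_hi=hi,
        probe_Ms=ms,
    )


def segment_tiling(track: ProbeTrack, change_points) -> list[SignalArea]:
    """Tiled layout: signal areas are exactly the inter-change-point runs."""
    if not track.probes:
        return []
    return [_make_sas(track, lo, hi) for lo, hi in _candidate_regions(track, change_points)]


def segment_nontiling(
    track: ProbeTrack, change_points, params: SegmentationParams | None = None
) -> list[SignalArea]:
    """Non-uniform layout: change-point regions plus a pseudomedian merge pass.

    Adjacent candidate regions A, B are joined when the pseudomedian of
    their pooled probe values exceeds, in absolute value, |PM(A) - PM(B)|;
    a join extends the comparison to the next region with the merged region
    as the new left operand, otherwise the boundary between A and B is
    fixed.
    """
    if not track.probes:
        return []
    regions = _candidate_regions(track, change_points)
    M = track.M
    merged: list[tuple[int, int]] = []
    cur_lo, cur_hi = regions[0]
    for lo, hi in regions[1:]:
        pm_left = pseudomedian(M[cur_lo:cur_hi])
        pm_right = pseudomedian(M[lo:hi])
        pm_union = pseudomedian(M[cur_lo:hi])
        if abs(pm_union) > abs(pm_left - pm_right):
            cur_hi = hi
        else:
            merged.append((cur_lo, cur_hi))
            cur_lo, cur_hi = lo, hi
    merged.append((cur_lo, cur_hi))
    return [_make_sas(track, lo, hi) for lo, hi in merged]


def _layout_is_tiled(track: ProbeTrack) -> bool:
    gaps = np.diff(track.starts)
    if gaps.size == 0:
        return True
    mean = float(gaps.mean())
    if mean == 0:
        return True
    return float(gaps.std()) / mean < _TILING_CV_MAX


def chipsad(track: ProbeTrack, params: SegmentationParams | None = None) -> list[SignalArea]:
    """Full single-track segmentation: t-profile, change points, assembly.

    ``layout_mode='auto'`` picks the tiling path when the coefficient of
    variation of the inter-probe gaps is below 0.2, else the non-tiling
    path.  The returned areas are sorted, disjoint, and cover every probe
    of the track exactly once.
    """
    if params is None:
        params = SegmentationParams()
    if not track.probes:
        return []
    if len(track) == 1:
        return [_make_sas(track, 0, 1)]
    params = params.resolved(track)
    params = _resolve_s0(track, params)
    mode = params.layout_mode
    if mode == "auto":
        mode = "tiling" if _layout_is_tiled(track) else "nontiling"
    profile = t_profile(track, params, rescue_holes=(mode == "nontiling"))
    cps = detect_change_points(profile, params.t_threshold)
    if mode == "tiling":
        sas = segment_tiling(track, cps)
    else:
        cps = sorted(cps + _hole_change_points(track, params), key=lambda c: c.x)
        sas = segment_nontiling(track, cps, params)
    logger.info(
        "segmented %s/%s/%s: %d probes -> %d change points -> %d signal areas (%s)",
        track.experiment_id, track.replicon, track.strand,
        len(track), len(cps), len(sas), mode,
    )
    return sas
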