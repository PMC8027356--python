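"""Phase segmentation and curve-parameter extraction for oxygenscan traces.

The four per-sample readouts of oxygen-gradient ektacytometry:

* ``EI_max`` — maximum elongation index at full oxygenation (pO2 100-150
  mmHg), read from the pre-deoxygenation plateau; baseline arterial
  deformability.
* ``EI_min`` — minimum EI at pO2 < 20 mmHg during deoxygenation;
  deformability at venous-like hypoxia.
* ``PoS`` (point of sickling) — the pO2 during deoxygenation at which the EI
  first falls, sustainedly, to 95% of EI_max; the oxygen tension where HbS
  polymerization accelerates.
* ``Recovery`` — the post-reoxygenation EI maximum as a percentage of EI_max.
  Because EI_max is taken from the pre-deoxygenation plateau only, Recovery
  can legitimately exceed 100% (lysis of poorly deformable cells during the
  cycle raises the population average).

All extractors operate on a rolling-median-smoothed EI series (default
window 11 samples; robust to diffraction-readout spikes) and share one phase
segmentation.  A trace with no sustained pO2 decline has no cycle and cannot
be segmented; a curve that never drops 5% below EI_max has an *undefined*
PoS, which is a first-class outcome (normal, non-sickling red cells), not an
error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import median_filter

from .trace_io import OxygenscanTrace

# Flag names
POS_UNDEFINED = "pos_undefined"
NO_HYPOXIC_SAMPLES = "no_hypoxic_samples"
REOX_WINDOW_FALLBACK = "reox_window_fallback"
POS_BELOW_AT_PHASE_START = "pos_below_at_phase_start"


class SegmentationError(ValueError):
    """The trace does not contain a full deoxygenation/reoxygenation cycle."""


class ExtractionError(ValueError):
    """A curve parameter cannot be computed from this trace."""


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction settings.

    The two pO2 windows (normoxic 100-150 mmHg, hypoxic < 20 mmHg) are fixed
    by the assay definition; the remaining knobs are robustness parameters.
    ``seg_smooth_window`` smooths pO2 for phase detection (wider than the EI
    window because the deoxygenation ramp is slow relative to pO2 readout
    noise); ``sustain_k`` consecutive samples are required before a decline,
    rise or threshold crossing counts as sustained; ``seg_min_drop_mmHg`` is
    the minimum smoothed-pO2 change over such a run.
    """

    smooth_window: int = 11
    seg_smooth_window: int = 51
    sustain_k: int = 5
    seg_min_drop_mmHg: float = 0.25
    normoxic_window_mmHg: tuple[float, float] = (100.0, 150.0)
    hypoxic_cutoff_mmHg: float = 20.0
    reox_fallback_samples: int = 20

    def __post_init__(self) -> None:
        for name in ("smooth_window", "seg_smooth_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd count >= 1, got {w}")
        if self.sustain_k < 1:
            raise ValueError("sustain_k must be >= 1")


DEFAULT_CONFIG = ExtractionConfig()


@dataclass(frozen=True)
class PhaseSegmentation:
    """Index boundaries of the three cycle phases.

    ``[0, deox_start)`` is the fully oxygenated plateau, ``[deox_start,
    reox_start)`` the deoxygenation ramp, ``[reox_start, n)`` the
    reoxygenation.  Ranges are contiguous and cover the trace.
    """

    deox_start_idx: int
    reox_start_idx: int
    n_samples: int

    def __post_init__(self) -> None:
        if not 0 <= self.deox_start_idx < self.reox_start_idx < self.n_samples:
            raise ValueError("phase boundaries must be ordered within the trace")


@dataclass(frozen=True)
class CurveParameters:
    """The four extracted scalars, with QC flags.

    ``pos_mmHg`` and ``ei_min`` are NaN when undefined (see flags).
    ``ei_max_idx``/``ei_min_idx`` record which sample supplied each extremum.
    """

    ei_max: float
    ei_min: float
    pos_mmHg: float
    recovery_pct: float
    flags: frozenset[str] = frozenset()
    ei_max_idx: int | None = None
    ei_min_idx: int | None = None


# ---------------------------------------------------------------------------
# Smoothing and run detection
# ---------------------------------------------------------------------------

def rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with edge replication; identity for window 1."""
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    return median_filter(values, size=window, mode="nearest")


def _first_sustained_run(
    sm: np.ndarray, start: int, k: int, min_total: float, sign: int,
    confirm_ahead: int,
) -> int | None:
    """First index i >= start where the smoothed series ``sm`` begins a
    sustained move in direction ``sign``: k consecutive diffs of that sign
    totalling at least ``min_total``, *confirmed* by a move of at least
    2% of the series range ``confirm_ahead`` samples later (rejects runs of
    pure readout noise on a plateau).  Returns None if no such run."""
    diffs = np.diff(sm)
    good = (diffs * sign) > 0
    if len(good) < k:
        return None
    # run_ok[i]: diffs[i:i+k] all of the right sign
    windows = np.lib.stride_tricks.sliding_window_view(good, k)
    totals = np.lib.stride_tricks.sliding_window_view(diffs, k).sum(axis=1)
    ok = windows.all(axis=1) & ((totals * sign) >= min_total)
    ok[:start] = False
    confirm_total = max(min_total, 0.02 * float(np.ptp(sm)))
    last = len(sm) - 1
    for i in np.flatnonzero(ok):
        j = min(i + confirm_ahead, last)
        if (sm[j] - sm[i]) * sign >= confirm_total:
            return int(i)
    return None


def segment_phases(
    trace: OxygenscanTrace,
    smooth_window: int | None = None,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> PhaseSegmentation:
    """Locate the deoxygenation and reoxygenation onsets from the pO2 series.

    The deoxygenation onset is the first index where the rolling-median
    smoothed pO2 begins a sustained decline (``sustain_k`` consecutive
    decreasing samples dropping at least ``seg_min_drop_mmHg`` in total); the
    reoxygenation onset is the first sustained rise after it, snapped to the
    raw-pO2 minimum in its neighbourhood (the ramp corner).
    """
    if smooth_window is not None:
        config = replace(config, seg_smooth_window=smooth_window)
    po2 = np.asarray(trace.pO2_mmHg, dtype=float)
    sm = rolling_median(po2, config.seg_smooth_window)
    k = config.sustain_k
    confirm = config.seg_smooth_window
    deox = _first_sustained_run(sm, 0, k, config.seg_min_drop_mmHg, -1, confirm)
    if deox is None:
        raise SegmentationError("no_deoxygenation_phase")
    rise = _first_sustained_run(sm, deox + 1, k, config.seg_min_drop_mmHg, +1,
                                confirm)
    if rise is None:
        raise SegmentationError("no_reoxygenation_phase")
    # Snap to the raw pO2 minimum near the detected rise: the V-shaped ramp
    # corner is sharp in the raw series but blurred by the wide median.
    lo = max(deox + 1, rise - config.seg_smooth_window)
    hi = min(len(po2), rise + k + 1)
    reox = lo + int(np.argmin(po2[lo:hi]))
    if reox <= deox:
        reox = deox + 1
    return PhaseSegmentation(deox_start_idx=deox, reox_start_idx=reox,
                             n_samples=len(po2))


# ---------------------------------------------------------------------------
# Parameter extractors
# ---------------------------------------------------------------------------

def _smooth_ei(trace: OxygenscanTrace, config: ExtractionConfig) -> np.ndarray:
    return rolling_median(trace.ei, config.smooth_window)


def compute_ei_max(
    trace: OxygenscanTrace,
    seg: PhaseSegmentation,
    window_mmHg: tuple[float, float] | None = None,
    config: ExtractionConfig = DEFAULT_CONFIG,
    _smoothed_ei: np.ndarray | None = None,
) -> tuple[float, int]:
    """Maximum smoothed EI over pre-deoxygenation samples with pO2 in the
    normoxic window (default 100-150 mmHg).  Returns (value, sample index)."""
    lo, hi = window_mmHg if window_mmHg is not None else config.normoxic_window_mmHg
    sm = _smoothed_ei if _smoothed_ei is not None else _smooth_ei(trace, config)
    plateau = slice(0, seg.deox_start_idx + 1)
    po2 = trace.pO2_mmHg[plateau]
    mask = (po2 >= lo) & (po2 <= hi)
    if not mask.any():
        raise ExtractionError("no_normoxic_samples")
    cand = np.flatnonzero(mask)
    idx = cand[int(np.argmax(sm[plateau][cand]))]
    return float(sm[idx]), int(idx)


def compute_ei_min(
    trace: OxygenscanTrace,
    seg: PhaseSegmentation,
    config: ExtractionConfig = DEFAULT_CONFIG,
    _smoothed_ei: np.ndarray | None = None,
) -> tuple[float, int | None, frozenset[str]]:
    """Minimum smoothed EI over deoxygenation samples with pO2 below the
    hypoxic cutoff (default 20 mmHg).

    Returns (value, index, flags); value is NaN with ``no_hypoxic_samples``
    flagged when the trace never reaches the hypoxic window.
    """
    sm = _smoothed_ei if _smoothed_ei is not None else _smooth_ei(trace, config)
    deox = slice(seg.deox_start_idx, seg.reox_start_idx + 1)
    po2 = trace.pO2_mmHg[deox]
    mask = po2 < config.hypoxic_cutoff_mmHg
    if not mask.any():
        return float("nan"), None, frozenset({NO_HYPOXIC_SAMPLES})
    cand = np.flatnonzero(mask) + seg.deox_start_idx
    idx = cand[int(np.argmin(sm[cand]))]
    return float(sm[idx]), int(idx), frozenset()


def compute_pos(
    trace: OxygenscanTrace,
    seg: PhaseSegmentation,
    ei_max: float,
    config: ExtractionConfig = DEFAULT_CONFIG,
    _smoothed_ei: np.ndarray | None = None,
) -> tuple[float, frozenset[str]]:
    """Point of sickling: pO2 of the first sustained drop of the smoothed EI
    to 95% of EI_max during deoxygenation.

    Scans the deoxygenation phase in time order for the first sample at or
    below the threshold that stays below for ``sustain_k`` consecutive
    samples, then linearly interpolates the pO2 at the exact crossing between
    the bracketing samples (using the segmentation-smoothed pO2 for a stable
    abscissa).  Returns NaN with ``pos_undefined`` when the curve never
    sustains a 5% drop — the normal-control outcome.
    """
    if not np.isfinite(ei_max):
        raise ExtractionError("ei_max undefined; cannot compute PoS")
    sm = _smoothed_ei if _smoothed_ei is not None else _smooth_ei(trace, config)
    threshold = 0.95 * ei_max
    k = config.sustain_k
    i0, i1 = seg.deox_start_idx, seg.reox_start_idx
    below = sm[i0:i1] <= threshold
    if len(below) >= k:
        runs = np.lib.stride_tricks.sliding_window_view(below, k).all(axis=1)
        hits = np.flatnonzero(runs)
    elif len(below) and below.all():  # phase shorter than k: require all below
        hits = np.array([0])
    else:
        hits = np.array([], dtype=int)
    if len(hits) == 0:
        return float("nan"), frozenset({POS_UNDEFINED})
    i = int(hits[0]) + i0
    po2 = rolling_median(trace.pO2_mmHg, config.seg_smooth_window)
    if i == i0:
        return float(po2[i]), frozenset({POS_BELOW_AT_PHASE_START})
    e_prev, e_here = sm[i - 1], sm[i]
    if e_prev <= threshold or e_here == e_prev:
        frac = 1.0
    else:
        frac = (e_prev - threshold) / (e_prev - e_here)
    pos = po2[i - 1] + frac * (po2[i] - po2[i - 1])
    return float(pos), frozenset()


def compute_recovery(
    trace: OxygenscanTrace,
    seg: PhaseSegmentation,
    ei_max: float,
    config: ExtractionConfig = DEFAULT_CONFIG,
    _smoothed_ei: np.ndarray | None = None,
) -> tuple[float, frozenset[str]]:
    """Recovery: post-reoxygenation EI maximum as a percentage of EI_max.

    The post-reoxygenation maximum is taken over reoxygenation samples with
    pO2 back in the normoxic window; if pO2 never re-enters the window the
    final ``reox_fallback_samples`` samples are used instead (flagged).
    """
    if not (np.isfinite(ei_max) and ei_max > 0):
        raise ExtractionError("ei_max must be positive to compute recovery")
    sm = _smoothed_ei if _smoothed_ei is not None else _smooth_ei(trace, config)
    lo, hi = config.normoxic_window_mmHg
    reox = slice(seg.reox_start_idx, seg.n_samples)
    po2 = trace.pO2_mmHg[reox]
    mask = (po2 >= lo) & (po2 <= hi)
    flags: frozenset[str] = frozenset()
    if mask.any():
        post = float(np.max(sm[reox][mask]))
    else:
        m = min(config.reox_fallback_samples, seg.n_samples)
        post = float(np.max(sm[-m:]))
        flags = frozenset({REOX_WINDOW_FALLBACK})
    return 100.0 * post / ei_max, flags


def extract_parameters(
    trace: OxygenscanTrace,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> CurveParameters:
    """Segment the trace and extract EI_max, EI_min, PoS and Recovery with a
    shared smoothing pass; all component flags are propagated."""
    seg = segment_phases(trace, config=config)
    sm = _smooth_ei(trace, config)
    ei_max, imax = compute_ei_max(trace, seg, config=config, _smoothed_ei=sm)
    ei_min, imin, f_min = compute_ei_min(trace, seg, config=config, _smoothed_ei=sm)
    pos, f_pos = compute_pos(trace, seg, ei_max, config=config, _smoothed_ei=sm)
    rec, f_rec = compute_recovery(trace, seg, ei_max, config=config, _smoothed_ei=sm)
    return CurveParameters(
        ei_max=ei_max,
        ei_min=ei_min,
        pos_mmHg=pos,
        recovery_pct=rec,
        flags=f_min | f_pos | f_rec,
        ei_max_idx=imax,
        ei_min_idx=imin,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def parameters_to_frame(
    results: Iterable[tuple[str, CurveParameters]],
):
    """Rows of (sample_id, CurveParameters) as a DataFrame in the documented
    CSV column order; flags are semicolon-joined."""
    import pandas as pd

    rows = [
        {
            "sample_id": sid,
            "ei_max": p.ei_max,
            "ei_min": p.ei_min,
            "pos_mmHg": p.pos_mmHg,
            "recovery_pct": p.recovery_pct,
            "flags": ";".join(sorted(p.flags)),
        }
        for sid, p in results
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "ei_max", "ei_min", "pos_mmHg", "recovery_pct", "flags"],
    )
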