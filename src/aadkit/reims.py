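"""REIMS burn-event preprocessing.

Raw iKnife/REIMS acquisitions are continuous scan streams (1 Hz typical) in
which each cauterization of tissue produces a *burn event*: an interval of
10-30 s during which the total ion current (TIC, the sum of all ion
intensities in a scan) rises far above the inter-burn baseline.  Burn
events are irregular ("uneven") in shape, so downstream classification
software expects them re-expressed on a canonical footing: a 35-scan
pseudo-Gaussian TIC trace whose burn covers 12 scans and peaks at scan 18
(1-based).  This module detects events, performs that conversion while
conserving total TIC, applies single-point lockmass recalibration
(leu-enkephalin), and bins the consensus spectrum of each event onto a
fixed m/z grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: [M-H]- monoisotopic mass of leucine-enkephalin, the standard negative-mode
#: lockmass compound.
LEU_ENKEPHALIN_MZ = 554.2615

# Canonical processed-trace geometry.
TRACE_LENGTH = 35
PEAK_SCAN = 18          # 1-based position of the trace maximum
BURN_SPAN = 12          # scans above the burn-level threshold
_TRACE_MU = PEAK_SCAN - 0.2   # slight offset so an even burn span brackets the peak
_TRACE_SIGMA = 3.0
_BURN_HALF_WIDTH = 6.0  # scans within mu +/- 6 are "burn" scans (exactly 12)


@dataclass
class RawRun:
    """An ordered sequence of centroided scans with acquisition times.

    ``scans[i]`` is a ``(mz, intensity)`` pair of 1-D arrays; ``tic[i]`` is
    the sum of intensities of scan ``i``.
    """

    scans: list[tuple[np.ndarray, np.ndarray]]
    scan_times: np.ndarray

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        if len(self.scans) != len(self.scan_times):
            raise ValueError("scans and scan_times must have equal length")
        if len(self.scan_times) > 1 and not np.all(np.diff(self.scan_times) > 0):
            raise ValueError("scan_times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    @property
    def tic(self) -> np.ndarray:
        return np.array([float(np.sum(i)) for _, i in self.scans])


@dataclass(frozen=True)
class BurnEventWindow:
    """Inclusive 0-based scan range of one detected burn event."""

    start_scan: int
    end_scan: int
    peak_scan: int

    def __post_init__(self) -> None:
        if not self.start_scan <= self.peak_scan <= self.end_scan:
            raise ValueError("peak_scan must lie within [start_scan, end_scan]")

    @property
    def n_scans(self) -> int:
        return self.end_scan - self.start_scan + 1


@dataclass
class ProcessedTrace:
    """Canonical 35-scan pseudo-Gaussian representation of one burn event.

    ``tic_trace`` redistributes the source window's total TIC onto the
    canonical shape; ``peak_index`` is 1-based (the trace maximum sits at
    scan 18); exactly ``burn_span`` trace values exceed ``burn_threshold``.
    ``consensus_mz``/``consensus_intensity`` hold the Gaussian-weighted
    average spectrum of the window, scaled to the same total TIC.
    """

    tic_trace: np.ndarray
    burn_threshold: float
    burn_span: int
    peak_index: int
    source_window: BurnEventWindow
    consensus_mz: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    consensus_intensity: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


@dataclass
class SpectrumVector:
    """A spectrum binned onto a fixed m/z grid over [mz_lo, mz_hi)."""

    intensities: np.ndarray
    mz_lo: float
    mz_hi: float
    bin_width: float
    normalization: str = "raw"  # "raw" | "tic"

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.intensities.size
        return self.mz_lo + self.bin_width * (np.arange(n) + 0.5)


def detect_burn_events(
    run: RawRun,
    threshold_factor: float = 5.0,
    min_length: int = 3,
) -> list[BurnEventWindow]:
    """Find maximal contiguous windows where TIC > threshold_factor x baseline.

    The baseline is the median TIC of the whole run (robust: burns occupy a
    minority of scans).  Windows shorter than ``min_length`` scans are
    discarded.  Returns non-overlapping windows in scan order; an event-free
    run yields an empty list.
    """
    if run.n_scans == 0:
        raise ValueError("cannot detect burn events in an empty run")
    if run.n_scans < 3:
        raise ValueError("need at least 3 scans to separate burn from baseline")
    tic = run.tic
    baseline = float(np.median(tic))
    threshold = threshold_factor * baseline
    above = tic > threshold
    windows: list[BurnEventWindow] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_length:
                peak = i + int(np.argmax(tic[i : j + 1]))
                windows.append(BurnEventWindow(i, j, peak))
            i = j + 1
        else:
            i += 1
    return windows


def _canonical_weights() -> np.ndarray:
    pos = np.arange(1, TRACE_LENGTH + 1, dtype=float)
    return np.exp(-((pos - _TRACE_MU) ** 2) / (2.0 * _TRACE_SIGMA**2))


def pseudo_gaussianize(run: RawRun, window: BurnEventWindow) -> ProcessedTrace:
    """Convert one uneven burn event into the canonical pseudo-Gaussian trace.

    The window's total TIC is redistributed onto a 35-scan Gaussian profile
    peaking at scan 18 (1-based) with exactly 12 scans above the burn-level
    threshold; total TIC is conserved exactly.  The same Gaussian weights,
    evaluated at each window scan's position mapped linearly onto the burn
    span, average the window's scans into a single consensus spectrum.
    """
    if not (0 <= window.start_scan <= window.end_scan < run.n_scans):
        raise ValueError("burn-event window lies outside the run")
    tic = run.tic
    total = float(tic[window.start_scan : window.end_scan + 1].sum())

    w = _canonical_weights()
    trace = total * w / w.sum()
    # Burn-level threshold: separates the 12 burn scans (|pos - mu| < 6)
    # from the flanking baseline scans of the canonical shape.
    ordered = np.sort(trace)[::-1]
    burn_threshold = 0.5 * (ordered[BURN_SPAN - 1] + ordered[BURN_SPAN])
    span = int(np.sum(trace > burn_threshold))
    peak_index = int(np.argmax(trace)) + 1

    # Consensus spectrum: window scans mapped onto [mu - 6, mu + 6].
    L = window.n_scans
    if L == 1:
        positions = np.array([_TRACE_MU])
    else:
        positions = _TRACE_MU - _BURN_HALF_WIDTH + 2 * _BURN_HALF_WIDTH * np.arange(L) / (L - 1)
    g = np.exp(-((positions - _TRACE_MU) ** 2) / (2.0 * _TRACE_SIGMA**2))
    mz_parts, int_parts = [], []
    for k, scan_idx in enumerate(range(window.start_scan, window.end_scan + 1)):
        mz, inten = run.scans[scan_idx]
        mz_parts.append(np.asarray(mz, dtype=float))
        int_parts.append(g[k] * np.asarray(inten, dtype=float))
    consensus_mz = np.concatenate(mz_parts) if mz_parts else np.empty(0)
    consensus_int = np.concatenate(int_parts) if int_parts else np.empty(0)
    s = consensus_int.sum()
    if s > 0:
        consensus_int = consensus_int * (total / s)

    return ProcessedTrace(
        tic_trace=trace,
        burn_threshold=burn_threshold,
        burn_span=span,
        peak_index=peak_index,
        source_window=window,
        consensus_mz=consensus_mz,
        consensus_intensity=consensus_int,
    )


def lockmass_correct(
    mz: np.ndarray,
    intensity: np.ndarray,
    reference_mz: float = LEU_ENKEPHALIN_MZ,
    search_window: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Shift all m/z by a constant so the lockmass peak lands on its reference.

    The most intense centroid within ``reference_mz +/- search_window`` is
    taken as the lockmass peak.  If no centroid falls in the window the
    spectrum is returned unshifted with shift ``None`` and a warning is
    logged.  Applying the correction twice is equivalent to applying it once.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    in_window = np.abs(mz - reference_mz) <= search_window
    if not np.any(in_window):
        logger.warning(
            "no lockmass peak within %.3f of m/z %.4f; spectrum left uncorrected",
            search_window,
            reference_mz,
        )
        warnings.warn("no lockmass peak found; spectrum left uncorrected", stacklevel=2)
        return mz, intensity, None
    idx = np.flatnonzero(in_window)
    peak = idx[np.argmax(intensity[idx])]
    shift = reference_mz - mz[peak]
    logger.debug("lockmass shift %+0.5f Da", shift)
    return mz + shift, intensity, float(shift)


def bin_spectrum(
    mz: np.ndarray,
    intensity: np.ndarray,
    mz_lo: float = 50.0,
    mz_hi: float = 1200.0,
    bin_width: float = 1.0,
    normalize: str = "tic",
) -> SpectrumVector:
    """Sum centroid intensities into half-open bins [lo, lo + w) over [mz_lo, mz_hi).

    Ions at or beyond ``mz_hi`` are dropped.  ``normalize="tic"`` divides by
    the vector sum so the result sums to 1 (a zero spectrum stays zero).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mz_lo >= mz_hi:
        raise ValueError("mz_lo must be below mz_hi")
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    n_bins = int(np.ceil((mz_hi - mz_lo) / bin_width))
    vec = np.zeros(n_bins)
    if mz.size:
        keep = (mz >= mz_lo) & (mz < mz_hi)
        idx = np.floor((mz[keep] - mz_lo) / bin_width).astype(int)
        np.add.at(vec, idx, intensity[keep])
    norm = "raw"
    if normalize == "tic":
        total = vec.sum()
        if total > 0:
            vec = vec / total
        norm = "tic"
    elif normalize not in (None, "raw"):
        raise ValueError(f"unknown normalization {normalize!r}")
    return SpectrumVector(vec, mz_lo, mz_hi, bin_width, norm)


def process_run(
    run: RawRun,
    threshold_factor: float = 5.0,
    min_length: int = 3,
    lockmass: bool = False,
    reference_mz: float = LEU_ENKEPHALIN_MZ,
    search_window: float = 0.5,
    mz_lo: float = 50.0,
    mz_hi: float = 1200.0,
    bin_width: float = 1.0,
    normalize: str = "tic",
) -> list[SpectrumVector]:
    """Full per-run pipeline: detect -> pseudo-Gaussianize -> (lockmass) -> bin.

    Returns one binned spectrum vector per detected burn event, in scan
    order; a run with no events yields an empty list.
    """
    vectors = []
    for window in detect_burn_events(run, threshold_factor, min_length):
        trace = pseudo_gaussianize(run, window)
        mz, inten = trace.consensus_mz, trace.consensus_intensity
        if lockmass:
            mz, inten, _ = lockmass_correct(mz, inten, reference_mz, search_window)
        vectors.append(bin_spectrum(mz, inten, mz_lo, mz_hi, bin_width, normalize))
    return vectors


# ---------------------------------------------------------------------------
# run I/O


def write_run_csv(run: RawRun, path) -> None:
    """Write a run as long-format CSV (scan, time_s, mz, intensity)."""
    rows = []
    for i, (mz, inten) in enumerate(run.scans):
        t = run.scan_times[i]
        for m, v in zip(mz, inten):
            rows.append((i, t, m, v))
    pd.DataFrame(rows, columns=["scan", "time_s", "mz", "intensity"]).to_csv(
        path, index=False
    )


def read_run_csv(path) -> RawRun:
    df = pd.read_csv(path)
    scans, times = [], []
    for scan_idx, grp in df.groupby("scan", sort=True):
        scans.append((grp["mz"].to_numpy(float), grp["intensity"].to_numpy(float)))
        times.append(float(grp["time_s"].iloc[0]))
    return RawRun(scans, np.asarray(times))


def read_run_mzml(path) -> RawRun:
    """Read a centroided mzML acquisition into a RawRun."""
    from pyteomics import mzml  # deferred: optional dependency

    scans, times = [], []
    with mzml.read(str(path)) as reader:
        for spec in reader:
            mz = np.asarray(spec["m/z array"], dtype=float)
            inten = np.asarray(spec["intensity array"], dtype=float)
            t = float(spec["scanList"]["scan"][0]["scan start time"])
            scans.append((mz, inten))
            times.append(t)
    order = np.argsort(times)
    return RawRun([scans[i] for i in order], np.asarray(times)[order])
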