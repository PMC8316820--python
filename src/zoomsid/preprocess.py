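"""Raw MALDI-ToF trace -> averaged, deisotoped peak list per specimen.

The processing chain mirrors standard collagen-fingerprinting practice:
baseline correction, light smoothing, S/N-gated peak picking (threshold 3.5
by convention), isotope-envelope collapse to the monoisotopic peak, and a
consensus merge of the triplicate spots acquired per specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import SpectrumError
from .panel import MarkerPanel

ISOTOPE_SPACING = 1.00235  # average Da per added neutron in peptides

#: default processing parameters, all config-exposed
DEFAULT_SNR = 3.5
DEFAULT_BASELINE_WINDOW = 100.0  # Da
DEFAULT_SMOOTH_POINTS = 5
DEFAULT_NOISE_WINDOW = 100.0  # Da
DEFAULT_DEISOTOPE_TOL = 0.15  # Da
DEFAULT_MERGE_TOL = 0.3  # Da
DEFAULT_MIN_PRESENCE = 2

# maximum satellite/monoisotopic height ratio accepted at +k neutrons; wide
# enough for the Poisson envelopes of 1-3.5 kDa peptides, tight enough not
# to chain unrelated peaks
_ENVELOPE_CAPS = (2.2, 2.0, 1.3, 0.7)


@dataclass(frozen=True)
class RawSpectrum:
    """Sampled m/z-intensity trace for one MALDI acquisition."""

    mz: np.ndarray
    intensity: np.ndarray
    specimen_id: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or mz.shape != inten.shape:
            raise SpectrumError("mz and intensity must be equal-length 1-D arrays")
        if mz.size == 0:
            raise SpectrumError("zero-length spectrum")
        if np.any(np.diff(mz) <= 0):
            raise SpectrumError("mz grid must be strictly increasing")

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.mz)))

    def write_xy(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.mz, self.intensity]),
                   fmt=["%.4f", "%.6g"])


def read_xy(path: str | Path, specimen_id: str = "",
            replicate_id: int = 0) -> RawSpectrum:
    """Read a two-column whitespace-separated m/z-intensity text file."""
    arr = np.loadtxt(path, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns (mz, intensity)")
    return RawSpectrum(arr[:, 0], arr[:, 1], specimen_id=specimen_id,
                       replicate_id=replicate_id)


@dataclass(frozen=True)
class PeakList:
    """Discrete (m/z, intensity, S/N) peaks, sorted by m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    specimen_id: str = ""
    n_replicates_present: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        snr = np.asarray(self.snr, dtype=float)
        nrep = np.asarray(self.n_replicates_present)
        if nrep.size == 0:
            nrep = np.ones(mz.size, dtype=int)
        nrep = nrep.astype(int)
        if not (mz.shape == inten.shape == snr.shape == nrep.shape):
            raise SpectrumError("peak arrays must share a common length")
        if mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz)
            mz, inten, snr, nrep = mz[order], inten[order], snr[order], nrep[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "snr", snr)
        object.__setattr__(self, "n_replicates_present", nrep)

    def __len__(self) -> int:
        return int(self.mz.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": self.mz,
                "intensity": self.intensity,
                "snr": self.snr,
                "n_replicates_present": self.n_replicates_present,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_peaklist_csv(path: str | Path, specimen_id: str = "") -> PeakList:
    df = pd.read_csv(path)
    if "mz" not in df or "intensity" not in df:
        raise SpectrumError(f"{path}: need at least mz and intensity columns")
    snr = df["snr"].to_numpy() if "snr" in df else np.full(len(df), np.inf)
    nrep = (
        df["n_replicates_present"].to_numpy()
        if "n_replicates_present" in df
        else np.ones(len(df), dtype=int)
    )
    return PeakList(df["mz"].to_numpy(), df["intensity"].to_numpy(), snr,
                    specimen_id=specimen_id, n_replicates_present=nrep)


# ---------------------------------------------------------------------------
# trace-level operations
# ---------------------------------------------------------------------------

def correct_baseline(s: RawSpectrum,
                     window: float = DEFAULT_BASELINE_WINDOW) -> RawSpectrum:
    """Subtract a slowly varying baseline (morphological opening).

    The baseline is estimated as a grey-scale opening (rolling minimum then
    rolling maximum) with a structuring window of ``window`` Da — exact for
    monotone backgrounds, and blind to peaks much narrower than the window.
    Output is clipped at zero.
    """
    if window <= 0:
        raise SpectrumError("baseline window must be positive")
    span = float(s.mz[-1] - s.mz[0])
    if window > span:
        raise SpectrumError(
            f"baseline window {window} Da exceeds spectrum span {span:.1f} Da"
        )
    size = max(3, int(round(window / s.spacing)))
    # point-reflection padding continues the boundary trend, so a sloping
    # background is estimated without the edge bias of constant padding
    y = s.intensity
    pad = min(size, y.size - 1)
    left = 2 * y[0] - y[pad:0:-1]
    right = 2 * y[-1] - y[-2:-pad - 2:-1]
    ext = np.concatenate([left, y, right])
    base = ndimage.grey_opening(ext, size=size, mode="nearest")[pad:pad + y.size]
    out = np.clip(y - base, 0.0, None)
    return replace(s, intensity=out)


def smooth(s: RawSpectrum, window_points: int = DEFAULT_SMOOTH_POINTS) -> RawSpectrum:
    """Savitzky-Golay (moving polynomial, order 2) smoothing."""
    if window_points < 3 or window_points % 2 == 0:
        raise SpectrumError("window_points must be odd and >= 3")
    if window_points > s.mz.size:
        raise SpectrumError("smoothing window exceeds trace length")
    out = signal.savgol_filter(s.intensity, window_points, polyorder=2)
    return replace(s, intensity=out)


def _blockwise_stats(mz: np.ndarray, intensity: np.ndarray,
                     window: float) -> tuple[np.ndarray, np.ndarray]:
    """Robust local background (median) and noise scale (1.4826*MAD) per
    ~window-Da block, interpolated back onto the full grid."""
    spacing = float(np.median(np.diff(mz))) if mz.size > 1 else 1.0
    block = max(16, int(round(window / spacing)))
    n = intensity.size
    nblocks = max(1, n // block)
    centers = np.empty(nblocks)
    bgs = np.empty(nblocks)
    scales = np.empty(nblocks)
    for i in range(nblocks):
        lo = i * block
        hi = n if i == nblocks - 1 else lo + block
        seg = intensity[lo:hi]
        med = np.median(seg)
        bgs[i] = med
        scales[i] = 1.4826 * np.median(np.abs(seg - med))
        centers[i] = 0.5 * (mz[lo] + mz[hi - 1])
    if nblocks == 1:
        return np.full(n, bgs[0]), np.full(n, scales[0])
    return np.interp(mz, centers, bgs), np.interp(mz, centers, scales)


def pick_peaks(s: RawSpectrum, snr_threshold: float = DEFAULT_SNR,
               noise_window: float = DEFAULT_NOISE_WINDOW,
               min_separation: float = 0.3) -> PeakList:
    """Local maxima with height/noise >= snr_threshold.

    Peak height is measured above the local background (sliding robust
    median), and noise is a sliding robust scale (1.4826*MAD). Maxima
    closer than ``min_separation`` Da collapse to the highest (noise can
    split a broad apex), and the apex m/z is refined with a least-squares
    parabola over the surrounding samples. Expects a baseline-corrected,
    smoothed trace.
    """
    if s.mz.size == 0:
        raise SpectrumError("zero-length spectrum")
    y = s.intensity
    background, noise = _blockwise_stats(s.mz, y, noise_window)
    floor = max(1e-12, 1e-9 * float(y.max(initial=0.0)))
    noise = np.maximum(noise, floor)
    empty = PeakList(np.array([]), np.array([]), np.array([]),
                     specimen_id=s.specimen_id)
    idx, props = signal.find_peaks(y, prominence=0.0)
    if idx.size == 0:
        return empty
    # a genuine peak must stand out from its surroundings as well as from
    # the background: noise bumps riding the flank of a larger peak have
    # large height but negligible prominence
    prom = props["prominences"]
    # cheap prefilter on the raw sample height (an overestimate of the true
    # apex under noise, so no true peak is lost here)
    raw_snr = np.minimum(y[idx] - background[idx], prom) / noise[idx]
    keep = raw_snr >= snr_threshold
    idx, prom = idx[keep], prom[keep]
    if idx.size == 0:
        return empty
    # least-squares parabolic apex over +-3 samples (noise-robust), then
    # the definitive S/N gate on the refined height
    half = 3
    cand: list[tuple[float, float, float]] = []  # (mz, height, snr)
    for i, pr in zip(idx, prom):
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        mz_i, h_i = float(s.mz[i]), float(y[i])
        if hi - lo >= 3:
            x = s.mz[lo:hi] - s.mz[i]
            a, b, c = np.polyfit(x, y[lo:hi], 2)
            if a < 0:
                dx = float(np.clip(-b / (2 * a), x[0], x[-1]))
                mz_i = float(s.mz[i] + dx)
                h_i = float(c - b * b / (4 * a))
        h = h_i - float(background[i])
        snr_i = min(h, float(pr)) / float(noise[i])
        if snr_i >= snr_threshold:
            cand.append((mz_i, h, snr_i))
    if not cand:
        return empty
    # collapse refined apexes closer than min_separation (noise can split a
    # broad apex into twin maxima); keep the strongest
    cand.sort()
    merged: list[tuple[float, float, float]] = []
    for c in cand:
        if merged and c[0] - merged[-1][0] < min_separation:
            if c[1] > merged[-1][1]:
                merged[-1] = c
        else:
            merged.append(c)
    arr = np.array(merged)
    return PeakList(arr[:, 0], np.clip(arr[:, 1], 0.0, None), arr[:, 2],
                    specimen_id=s.specimen_id)


# ---------------------------------------------------------------------------
# peak-list operations
# ---------------------------------------------------------------------------

def deisotope(p: PeakList, spacing: float = ISOTOPE_SPACING,
              tol: float = DEFAULT_DEISOTOPE_TOL) -> PeakList:
    """Collapse isotope envelopes to their monoisotopic (lowest-mass) peak.

    Scanning upward in mass, a peak within ``tol`` of base + k*spacing
    (k = 1..4) is absorbed as a satellite provided its height does not
    exceed a peptide-plausible multiple of the base height. Decisions
    depend only on surviving peaks, so the operation is idempotent.
    """
    if tol <= 0 or tol >= spacing / 2:
        raise SpectrumError("deisotope tol must be in (0, spacing/2)")
    n = len(p)
    if n == 0:
        return p
    consumed = np.zeros(n, dtype=bool)
    keep: list[int] = []
    mz, inten = p.mz, p.intensity
    for i in range(n):
        if consumed[i]:
            continue
        keep.append(i)
        for k, cap in enumerate(_ENVELOPE_CAPS, start=1):
            target = mz[i] + k * spacing
            j = np.searchsorted(mz, target - tol)
            best = -1
            best_d = tol
            while j < n and mz[j] <= target + tol:
                d = abs(mz[j] - target)
                if not consumed[j] and j != i and d <= best_d:
                    if inten[j] <= cap * inten[i]:
                        best, best_d = j, d
                j += 1
            if best >= 0:
                consumed[best] = True
    sel = np.array(keep, dtype=int)
    return PeakList(mz[sel], inten[sel], p.snr[sel],
                    specimen_id=p.specimen_id,
                    n_replicates_present=p.n_replicates_present[sel])


def merge_replicates(lists: Sequence[PeakList],
                     tol: float = DEFAULT_MERGE_TOL,
                     min_presence: int = DEFAULT_MIN_PRESENCE) -> PeakList:
    """Consensus peak list across replicate spots of one specimen.

    Peaks are clustered across replicates within ``tol`` Da; a cluster is
    kept iff it appears in at least ``min_presence`` replicates (clamped to
    the number of replicates supplied). Cluster m/z is the intensity-
    weighted mean; intensity is the mean over the replicates where the peak
    is present.
    """
    if len(lists) < 1:
        raise SpectrumError("merge_replicates needs at least one peak list")
    sids = {pl.specimen_id for pl in lists}
    if len(sids) > 1:
        raise SpectrumError(f"peak lists from different specimens: {sorted(sids)}")
    specimen_id = lists[0].specimen_id
    min_presence = max(1, min(min_presence, len(lists)))

    mz = np.concatenate([pl.mz for pl in lists]) if lists else np.array([])
    if mz.size == 0:
        return PeakList(np.array([]), np.array([]), np.array([]),
                        specimen_id=specimen_id)
    inten = np.concatenate([pl.intensity for pl in lists])
    snr = np.concatenate([pl.snr for pl in lists])
    rep = np.concatenate(
        [np.full(len(pl), i, dtype=int) for i, pl in enumerate(lists)]
    )
    order = np.argsort(mz)
    mz, inten, snr, rep = mz[order], inten[order], snr[order], rep[order]

    # split the pooled, sorted peaks wherever the gap exceeds tol
    breaks = np.flatnonzero(np.diff(mz) > tol) + 1
    out_mz, out_int, out_snr, out_n = [], [], [], []
    for seg in np.split(np.arange(mz.size), breaks):
        reps = set(rep[seg].tolist())
        if len(reps) < min_presence:
            continue
        w = inten[seg]
        out_mz.append(float(np.average(mz[seg], weights=w)))
        # mean over replicates where present (sum within a replicate first)
        per_rep = [float(w[rep[seg] == r].sum()) for r in reps]
        out_int.append(float(np.mean(per_rep)))
        out_snr.append(float(np.mean(snr[seg])))
        out_n.append(len(reps))
    return PeakList(np.array(out_mz), np.array(out_int), np.array(out_snr),
                    specimen_id=specimen_id,
                    n_replicates_present=np.array(out_n, dtype=int))


@dataclass(frozen=True)
class BlankReport:
    """Contamination screen over procedural blanks."""

    passed: bool
    flagged: tuple[tuple[str, float, str], ...]  # (blank id, peak mz, marker)
    warnings: tuple[str, ...]


def check_blanks(blank_lists: Iterable[PeakList], panel: MarkerPanel,
                 tol: float | None = None) -> BlankReport:
    """Flag any blank containing a peak matching a panel mass within tol."""
    if tol is None:
        tol = panel.mass_tolerance_default
    mass_to_marker: dict[float, str] = {}
    for prof in panel.profiles:
        for mid, d in prof.markers.items():
            if d is not None:
                for m in d.masses:
                    mass_to_marker.setdefault(m, mid)
    masses = np.array(sorted(mass_to_marker))
    flagged: list[tuple[str, float, str]] = []
    warnings: list[str] = []
    for i, pl in enumerate(blank_lists):
        bid = pl.specimen_id or f"blank_{i + 1}"
        for x in pl.mz:
            j = int(np.searchsorted(masses, x))
            cands = [masses[k] for k in (j - 1, j) if 0 <= k < masses.size]
            hit = next((m for m in cands if abs(m - x) <= tol), None)
            if hit is not None:
                flagged.append((bid, float(x), mass_to_marker[float(hit)]))
            else:
                warnings.append(f"{bid}: unmatched peak at m/z {x:.2f}")
    return BlankReport(passed=not flagged, flagged=tuple(flagged),
                       warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------

def process_replicate(s: RawSpectrum, *, snr: float = DEFAULT_SNR,
                      baseline_window: float = DEFAULT_BASELINE_WINDOW,
                      smooth_points: int = DEFAULT_SMOOTH_POINTS,
                      deisotope_tol: float = DEFAULT_DEISOTOPE_TOL) -> PeakList:
    """Baseline-correct, smooth, pick and deisotope one replicate trace."""
    t = smooth(correct_baseline(s, baseline_window), smooth_points)
    return deisotope(pick_peaks(t, snr), tol=deisotope_tol)


def process_specimen(replicates: Sequence[RawSpectrum], *,
                     snr: float = DEFAULT_SNR,
                     baseline_window: float = DEFAULT_BASELINE_WINDOW,
                     smooth_points: int = DEFAULT_SMOOTH_POINTS,
                     deisotope_tol: float = DEFAULT_DEISOTOPE_TOL,
                     merge_tol: float = DEFAULT_MERGE_TOL,
                     min_presence: int = DEFAULT_MIN_PRESENCE) -> PeakList:
    """Full per-specimen chain: each replicate processed, then the
    triplicate consensus merge."""
    lists = [
        process_replicate(s, snr=snr, baseline_window=baseline_window,
                          smooth_points=smooth_points,
                          deisotope_tol=deisotope_tol)
        for s in replicates
    ]
    return merge_replicates(lists, tol=merge_tol, min_presence=min_presence)
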