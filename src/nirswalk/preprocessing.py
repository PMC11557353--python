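"""Preprocessing chain for walking-task fNIRS recordings.

The five steps run in this fixed order, each on the output of the last:

1. motion-artifact detection (threshold on moving amplitude/SD against a
   robust scale) and cubic-spline correction, on optical density;
2. zero-phase 0.01-0.2 Hz Butterworth bandpass, on optical density;
3. modified Beer-Lambert conversion to concentration changes (uM);
4. PCA removal of the leading cross-channel component (systemic
   physiology such as scalp blood flow);
5. extraction of the walking block, baseline-corrected against the 5 s
   of standing immediately before walk onset.

Filtering before the Beer-Lambert step means the filter acts on optical
density; since both operations are linear the concentration result is
the same either way, but the printed order is kept and recorded in each
output's provenance.  Pearson connectivity downstream is scale
invariant, so results do not depend on the (configurable) extinction
coefficients and differential pathlength factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .montage import Montage
from .synthetic import (
    DEFAULT_DPF,
    DEFAULT_EXTINCTION,
    RawRecording,
    TaskTimeline,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """All tunable preprocessing parameters.

    ``extinction`` is the 2x2 wavelength-by-chromophore matrix in
    1/(mM cm); ``dpf`` the differential pathlength factor per wavelength.
    Neither is identifiable from correlation-based connectivity (Pearson
    is scale invariant) but both are echoed into provenance.
    """

    band_hz: tuple[float, float] = (0.01, 0.2)
    filter_order: int = 3
    artifact_window_s: float = 1.0
    artifact_z_threshold: float = 5.0
    spline_pad_s: float = 0.5
    dpf: tuple[float, float] = DEFAULT_DPF
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    n_pca_components_removed: int = 1
    baseline_window_s: float = 5.0
    block_s: float = 35.0
    correct_artifacts: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("need 0 < band low < band high")
        if self.artifact_z_threshold <= 0 or self.artifact_window_s <= 0:
            raise ValueError("artifact thresholds must be > 0")
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if np.linalg.cond(ext) > 100:
            raise ValueError(
                "extinction matrix is ill-conditioned (cond > 100); "
                "the chromophore system cannot be solved reliably"
            )

    def validate_against(self, fs: float) -> None:
        if self.band_hz[1] >= fs / 2:
            raise ValueError(
                f"band high {self.band_hz[1]} Hz must be below Nyquist {fs / 2} Hz"
            )


@dataclass
class OpticalDensitySeries:
    """Per-channel, per-wavelength optical-density change at ``fs`` Hz."""

    data: np.ndarray               # (2 wavelengths, channels, samples)
    fs: float
    artifact_mask: np.ndarray | None = None   # (channels, samples) bool
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("optical density contains non-finite values")
        if self.artifact_mask is not None and (
            self.artifact_mask.shape != self.data.shape[1:]
        ):
            raise ValueError("artifact mask shape must match (channels, samples)")


@dataclass
class HbSeries:
    """Concentration changes in uM: oxygenated and deoxygenated haemoglobin."""

    hbo: np.ndarray                # (channels, samples)
    hbr: np.ndarray
    fs: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("concentration series contain non-finite values")


@dataclass
class WalkBlock:
    """Baseline-corrected dHbO over the walking interval of one trial."""

    hbo: np.ndarray                # (channels, block samples)
    fs: float
    trial_index: int = 0
    subject_id: str = ""
    group: str = ""
    provenance: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# Step 0: intensity -> optical density
# --------------------------------------------------------------------------

def intensity_to_od(raw: RawRecording) -> OpticalDensitySeries:
    """dOD = -log10(I / I_ref), I_ref the mean intensity of the recording.

    Raises on nonpositive intensity, naming the first offending channel
    and sample.
    """
    I = raw.intensity
    bad = I <= 0
    if np.any(bad):
        wl, ch, t = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive intensity at wavelength index {wl}, "
            f"channel {ch + 1}, sample {t}"
        )
    i_ref = I.mean(axis=2, keepdims=True)
    od = -np.log10(I / i_ref)
    return OpticalDensitySeries(
        data=od, fs=raw.montage.sampling_rate_hz,
        provenance=["intensity_to_od(i_ref=recording mean)"],
    )


# --------------------------------------------------------------------------
# Step 1: motion artifacts
# --------------------------------------------------------------------------

def detect_motion_artifacts(
    od: OpticalDensitySeries, cfg: PreprocessConfig
) -> np.ndarray:
    """Flag samples whose moving-window amplitude range or moving SD exceeds
    ``artifact_z_threshold`` times a robust scale (1.4826 * MAD of the
    series).  Flags are dilated by ``spline_pad_s`` on both sides and
    unioned over the two wavelengths per channel.  Returns a
    (channels, samples) boolean mask.
    """
    x = od.data
    n = x.shape[-1]
    win = max(int(round(cfg.artifact_window_s * od.fs)), 3)
    if n <= win:
        raise ValueError("series shorter than the artifact window")

    med = np.median(x, axis=-1, keepdims=True)
    scale = 1.4826 * np.median(np.abs(x - med), axis=-1, keepdims=True)
    scale = np.maximum(scale, 1e-12)

    mov_range = maximum_filter1d(x, win, axis=-1) - minimum_filter1d(x, win, axis=-1)
    mean = uniform_filter1d(x, win, axis=-1)
    mean_sq = uniform_filter1d(x * x, win, axis=-1)
    mov_sd = np.sqrt(np.maximum(mean_sq - mean**2, 0.0))

    flagged = (mov_range > cfg.artifact_z_threshold * scale) | (
        mov_sd > cfg.artifact_z_threshold * scale
    )
    mask = flagged.any(axis=0)   # union over wavelengths

    pad = int(round(cfg.spline_pad_s * od.fs))
    if pad > 0:
        mask = maximum_filter1d(mask.astype(np.uint8), 2 * pad + 1, axis=-1) > 0
    if mask.all():
        logger.warning("entire recording flagged as motion artifact")
    return mask


def _segments(mask_1d: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_1d.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _correct_channel(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Cubic-trend subtraction and re-anchoring per flagged segment, with
    re-levelling of subsequent samples to keep the series continuous at the
    segment end (the standard spline motion-correction scheme)."""
    n = x.size
    if mask.all():
        t = np.arange(n)
        coef = np.polyfit(t, x, 3)
        return x - np.polyval(coef, t)
    out = x.copy()
    for start, stop in _segments(mask):
        seg = out[start:stop]
        t = np.arange(seg.size)
        if seg.size >= 8:
            # near-interpolating cubic smoothing spline tracks the artifact
            # excursion (including sharp steps) while ignoring fine noise
            s = seg.size * (0.05 * max(float(seg.std()), 1e-12)) ** 2
            trend = UnivariateSpline(t, seg, k=3, s=s)(t)
        elif seg.size >= 2:
            trend = np.polyval(np.polyfit(t, seg, 1), t)
        else:
            trend = seg.astype(float)
        detrended = seg - trend
        if start > 0:
            anchor = out[start - 1]
        elif stop < n:
            anchor = out[stop]
        else:  # pragma: no cover - full mask handled above
            anchor = 0.0
        corrected = detrended + anchor
        out[start:stop] = corrected
        if stop < n and start > 0:
            # restore continuity at the segment end (removes step artifacts)
            out[stop:] -= out[stop] - corrected[-1]
    return out


def spline_correct(
    od: OpticalDensitySeries, mask: np.ndarray | None = None
) -> OpticalDensitySeries:
    """Replace flagged segments by their spline-detrended, re-anchored
    version.  An empty mask returns the input unchanged."""
    if mask is None:
        mask = od.artifact_mask
    if mask is None or not mask.any():
        return replace(od, artifact_mask=mask,
                       provenance=od.provenance + ["spline_correct(no-op)"])
    if mask.shape != od.data.shape[1:]:
        raise ValueError("mask shape must match (channels, samples)")
    data = od.data.copy()
    for wl in range(data.shape[0]):
        for ch in range(data.shape[1]):
            if mask[ch].any():
                data[wl, ch] = _correct_channel(data[wl, ch], mask[ch])
    return OpticalDensitySeries(
        data=data, fs=od.fs, artifact_mask=mask,
        provenance=od.provenance + ["spline_correct(cubic, re-anchored)"],
    )


# --------------------------------------------------------------------------
# Step 2: bandpass
# --------------------------------------------------------------------------

def bandpass(
    data: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward) along the last
    axis.  Raises with a minimum-length hint when the series is too short
    for stable filtering."""
    cfg = cfg or PreprocessConfig()
    cfg.validate_against(fs)
    sos = signal.butter(cfg.filter_order, list(cfg.band_hz), btype="band",
                        fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if data.shape[-1] <= padlen:
        raise ValueError(
            f"series too short for stable filtering: need > {padlen} samples, "
            f"got {data.shape[-1]}"
        )
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass_od(
    od: OpticalDensitySeries, cfg: PreprocessConfig | None = None
) -> OpticalDensitySeries:
    cfg = cfg or PreprocessConfig()
    return replace(
        od,
        data=bandpass(od.data, od.fs, cfg),
        provenance=od.provenance
        + [f"bandpass(butter order {cfg.filter_order}, "
           f"{cfg.band_hz[0]}-{cfg.band_hz[1]} Hz, zero-phase)"],
    )


# --------------------------------------------------------------------------
# Step 3: modified Beer-Lambert law
# --------------------------------------------------------------------------

def mbll(
    od: OpticalDensitySeries, montage: Montage, cfg: PreprocessConfig | None = None
) -> HbSeries:
    """Solve the 2x2 chromophore system per channel and sample:

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)

    with d the source-detector separation in cm.  Output in uM.
    """
    cfg = cfg or PreprocessConfig()
    seps_cm = np.array([c.separation_mm for c in montage.channels]) / 10.0
    ext = np.asarray(cfg.extinction, dtype=float)
    dpf = np.asarray(cfg.dpf, dtype=float)
    path = ext * dpf[:, None]                     # (wl, chromophore)
    inv = np.linalg.inv(path)                     # (chromophore, wl)
    conc_mm = np.einsum("cl,lnt->cnt", inv, od.data) / seps_cm[None, :, None]
    hbo, hbr = conc_mm * 1000.0                   # mM -> uM
    return HbSeries(
        hbo=hbo, hbr=hbr, fs=od.fs,
        provenance=od.provenance
        + [f"mbll(dpf={tuple(dpf)}, separation_cm={seps_cm[0]:g})"],
    )


# --------------------------------------------------------------------------
# Step 4: PCA systemic removal
# --------------------------------------------------------------------------

def pca_remove_systemic(hb: HbSeries, cfg: PreprocessConfig | None = None) -> HbSeries:
    """Mean-center each channel and project out the first k principal
    components across channels (k = ``n_pca_components_removed``).  k = 0
    returns the mean-centered input."""
    cfg = cfg or PreprocessConfig()
    k = cfg.n_pca_components_removed
    n_ch = hb.hbo.shape[0]
    if n_ch < 2:
        raise ValueError("PCA removal needs at least 2 channels")
    if k >= n_ch:
        raise ValueError(f"cannot remove {k} components from {n_ch} channels")
    X = hb.hbo - hb.hbo.mean(axis=1, keepdims=True)
    if k == 0:
        return replace(hb, hbo=X, provenance=hb.provenance + ["pca_remove(k=0)"])
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)   # samples x channels
    removed = (U[:, :k] * S[:k]) @ Vt[:k]
    ev_frac = float(np.sum(S[:k] ** 2) / np.sum(S**2))
    logger.info("PCA removed %d component(s), explained variance %.1f%%",
                k, 100 * ev_frac)
    return replace(
        hb, hbo=(X.T - removed).T,
        provenance=hb.provenance + [f"pca_remove(k={k}, ev={ev_frac:.3f})"],
    )


# --------------------------------------------------------------------------
# Step 5: walking-block extraction
# --------------------------------------------------------------------------

def extract_walk_block(
    hb: HbSeries,
    timeline: TaskTimeline,
    trial_index: int = 0,
    cfg: PreprocessConfig | None = None,
    *,
    subject_id: str = "",
    group: str = "",
) -> WalkBlock:
    """dHbO over [walk_start, walk_start + block_s), minus the per-channel
    mean of the ``baseline_window_s`` immediately before walk onset.
    Sample indexing is half-open with start = floor(t * fs)."""
    cfg = cfg or PreprocessConfig()
    fs = hb.fs
    start = int(np.floor(timeline.pre_stand_s * fs))
    stop = start + int(np.floor(cfg.block_s * fs))
    base_start = start - int(np.floor(cfg.baseline_window_s * fs))
    n = hb.hbo.shape[1]
    if stop > n or base_start < 0:
        raise ValueError(
            f"recording ({n} samples) does not cover the required interval "
            f"[{base_start}, {stop})"
        )
    baseline = hb.hbo[:, base_start:start].mean(axis=1, keepdims=True)
    return WalkBlock(
        hbo=hb.hbo[:, start:stop] - baseline, fs=fs, trial_index=trial_index,
        subject_id=subject_id, group=group,
        provenance=hb.provenance
        + [f"extract_walk_block(block={cfg.block_s}s, "
           f"baseline={cfg.baseline_window_s}s pre-walk)"],
    )


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------

def preprocess(raw: RawRecording, cfg: PreprocessConfig | None = None) -> WalkBlock:
    """Steps 1-5 composed in order; provenance records each step."""
    cfg = cfg or PreprocessConfig()
    od = intensity_to_od(raw)
    if cfg.correct_artifacts:
        mask = detect_motion_artifacts(od, cfg)
        od = spline_correct(od, mask)
    od = bandpass_od(od, cfg)
    hb = mbll(od, raw.montage, cfg)
    hb = pca_remove_systemic(hb, cfg)
    return extract_walk_block(
        hb, raw.timeline, raw.trial_index, cfg,
        subject_id=raw.subject_id, group=raw.group,
    )
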