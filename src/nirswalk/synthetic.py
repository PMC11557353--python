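"""Synthetic walking-task fNIRS cohorts with planted connectivity.

The generator emulates the study conditions of a two-group walking
experiment: 30 Parkinson's disease (PD) and 22 healthy control (HC)
subjects, three trials each of 30 s standing / 35 s walking / 10 s
standing recorded at 11 Hz over 30 channels and two wavelengths, plus a
per-subject gait-parameter table.

Generative model
----------------
Each subject receives a target ROI-level correlation structure drawn
around the group means (6 within-ROI values, 15 between-ROI values).
Channel oxyhaemoglobin fluctuations are built from six band-limited
latent ROI processes ``g_R`` mixed to a latent correlation matrix ``G``
plus channel-private noise::

    dHbO_c = sd * ( sqrt(w_R) * g_R + sqrt(1 - w_R) * e_c ),  c in ROI R

so the asymptotic channel-pair correlation is ``w_R`` within ROI R and
``sqrt(w_R w_S) G_RS`` between ROIs R and S.  On top of that: a
haemodynamic response (canonical double-gamma HRF convolved with the
walking boxcar), sinusoidal cardiac and respiratory components (above
the analysis band), a Mayer-band global systemic process with zero-mean
channel loadings (what the PCA step removes), optional motion
artifacts, and the forward modified Beer-Lambert map to dual-wavelength
light intensity.

Because the analysis estimates Pearson correlation from 35-s
band-limited blocks (~14 effective samples), the sample correlation is
biased low by roughly ``rho(1-rho^2)/(2 n_eff)``.  The latent
construction inflates correlations by the analytic first-order inverse
of that bias so that the planted targets are the estimand of the
trial-averaged pipeline output; see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gamma as _gamma

from .montage import ROIS, Montage, build_default_montage

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Study conditions: group-level targets (PD group first, HC second).
# The seven pairs marked "unreported" received no published value; defaults
# keep a small PD-HC gap and respect the latent feasibility bound
# between(R,S) <= sqrt(within_R * within_S).
# --------------------------------------------------------------------------

PD_WITHIN_R: dict[str, float] = {
    "LPFC": 0.40, "RPFC": 0.42, "LPMC": 0.48, "RPMC": 0.43,
    "LPSC": 0.52, "RPSC": 0.53,
}
HC_WITHIN_R: dict[str, float] = {
    "LPFC": 0.34, "RPFC": 0.37, "LPMC": 0.42, "RPMC": 0.37,
    "LPSC": 0.44, "RPSC": 0.51,
}
PD_BETWEEN_R: dict[tuple[str, str], float] = {
    ("LPFC", "RPFC"): 0.33,   # unreported
    ("LPFC", "LPMC"): 0.39,
    ("LPFC", "RPMC"): 0.37,
    ("LPFC", "LPSC"): 0.39,
    ("LPFC", "RPSC"): 0.33,   # unreported
    ("RPFC", "LPMC"): 0.38,
    ("RPFC", "RPMC"): 0.34,   # unreported
    ("RPFC", "LPSC"): 0.39,
    ("RPFC", "RPSC"): 0.34,   # unreported
    ("LPMC", "RPMC"): 0.38,   # unreported
    ("LPMC", "LPSC"): 0.48,
    ("LPMC", "RPSC"): 0.44,
    ("RPMC", "LPSC"): 0.36,   # unreported
    ("RPMC", "RPSC"): 0.43,
    ("LPSC", "RPSC"): 0.42,   # unreported
}
HC_BETWEEN_R: dict[tuple[str, str], float] = {
    ("LPFC", "RPFC"): 0.30,   # unreported
    ("LPFC", "LPMC"): 0.30,
    ("LPFC", "RPMC"): 0.29,
    ("LPFC", "LPSC"): 0.30,
    ("LPFC", "RPSC"): 0.30,   # unreported
    ("RPFC", "LPMC"): 0.29,
    ("RPFC", "RPMC"): 0.31,   # unreported
    ("RPFC", "LPSC"): 0.31,
    ("RPFC", "RPSC"): 0.31,   # unreported
    ("LPMC", "RPMC"): 0.35,   # unreported
    ("LPMC", "LPSC"): 0.38,
    ("LPMC", "RPSC"): 0.34,
    ("RPMC", "LPSC"): 0.33,   # unreported
    ("RPMC", "RPSC"): 0.35,
    ("LPSC", "RPSC"): 0.40,   # unreported
}

#: The eight between-ROI contrasts with a published significant PD > HC gap.
SIGNIFICANT_BETWEEN_PAIRS: tuple[tuple[str, str], ...] = (
    ("LPFC", "LPMC"), ("LPFC", "RPMC"), ("LPFC", "LPSC"), ("RPFC", "LPMC"),
    ("RPFC", "LPSC"), ("LPMC", "LPSC"), ("LPMC", "RPSC"), ("RPMC", "RPSC"),
)

# Gait-table generator parameters: (PD mean, PD sd, HC mean, HC sd).
GAIT_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "cadence_L": (113.87, 10.68, 113.01, 7.13),
    "cadence_R": (114.02, 10.72, 113.15, 7.11),
    "double_support_L": (21.36, 4.93, 19.53, 3.06),
    "double_support_R": (21.41, 4.86, 19.57, 3.06),
    "gait_cycle_duration_L": (1.07, 0.10, 1.07, 0.07),
    "gait_cycle_duration_R": (1.06, 0.10, 1.07, 0.07),
    "gait_speed_L": (0.97, 0.22, 1.12, 0.15),
    "gait_speed_R": (0.97, 0.21, 1.12, 0.15),
    "stride_length_L": (1.02, 0.21, 1.19, 0.12),
    "stride_length_R": (1.01, 0.20, 1.18, 0.12),
}
GAIT_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "age": (62.40, 7.16, 60.95, 6.34),
    "mmse": (27.43, 1.97, 27.09, 1.55),
}
#: Male fraction per group (PD 15/30, HC 12/22).
SEX_MALE_FRACTION: dict[str, float] = {"PD": 15 / 30, "HC": 12 / 22}

GAIT_VARIABLES: tuple[str, ...] = tuple(GAIT_PARAMS)


@dataclass(frozen=True)
class TaskTimeline:
    """Stand / walk / stand trial structure, in seconds."""

    pre_stand_s: float = 30.0
    walk_s: float = 35.0
    post_stand_s: float = 10.0
    baseline_window_s: float = 5.0
    n_trials: int = 3
    inter_trial_rest_s: float = 120.0

    def __post_init__(self) -> None:
        for name in ("pre_stand_s", "walk_s", "post_stand_s", "baseline_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_window_s > self.pre_stand_s:
            raise ValueError("baseline_window_s must not exceed pre_stand_s")

    @property
    def total_s(self) -> float:
        return self.pre_stand_s + self.walk_s + self.post_stand_s

    def n_samples(self, fs: float) -> int:
        return int(np.floor(self.total_s * fs))


@dataclass(frozen=True)
class GroupFCSpec:
    """Group-level connectivity targets and their between-subject spread.

    ``between_subject_sd`` is the dispersion of the final per-subject FC
    values (what a study reports next to the group mean).  That observed
    dispersion mixes true between-subject variation with single-subject
    estimation noise of the trial-averaged Pearson estimate
    (``estimation_noise_sd``, ~0.08 for three 35-s blocks in the
    0.01-0.2 Hz band); the generator therefore plants target dispersion
    sqrt(between_subject_sd^2 - estimation_noise_sd^2) so the observed
    values disperse at the stated SD.  ``shared_fraction`` of the target
    SD is a single subject-level offset applied to every target (subjects
    run globally high or low), the remainder is target-specific.
    """

    group: str
    within_roi_r: Mapping[str, float]
    between_roi_r: Mapping[tuple[str, str], float]
    between_subject_sd: float = 0.13
    estimation_noise_sd: float = 0.08
    shared_fraction: float = 0.77

    def __post_init__(self) -> None:
        for v in list(self.within_roi_r.values()) + list(self.between_roi_r.values()):
            if not -1.0 < v < 1.0:
                raise ValueError("target correlations must lie in (-1, 1)")
        if not 0 <= self.estimation_noise_sd <= self.between_subject_sd:
            raise ValueError("need 0 <= estimation_noise_sd <= between_subject_sd")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")

    @property
    def target_sd(self) -> float:
        """Planted SD of subject targets around the group mean."""
        return float(np.sqrt(
            self.between_subject_sd**2 - self.estimation_noise_sd**2))

    @property
    def shared_sd(self) -> float:
        return self.shared_fraction * self.target_sd

    @property
    def specific_sd(self) -> float:
        return float(np.sqrt(self.target_sd**2 - self.shared_sd**2))


PD_SPEC = GroupFCSpec("PD", PD_WITHIN_R, PD_BETWEEN_R)
HC_SPEC = GroupFCSpec("HC", HC_WITHIN_R, HC_BETWEEN_R)


@dataclass(frozen=True)
class NoiseSpec:
    """Nuisance components added to the neural signal.

    Cardiac and respiratory components sit above the 0.2 Hz analysis
    band (removed by the bandpass); the Mayer-band component sits inside
    it and is the confound the PCA step targets.  Amplitudes are in uM
    of apparent dHbO; measurement noise is relative light intensity.
    """

    cardiac_hz: float = 1.1
    respiratory_hz: float = 0.25
    mayer_hz: float = 0.1
    cardiac_amp_um: float = 0.15
    respiratory_amp_um: float = 0.10
    mayer_amp_um: float = 0.8
    measurement_noise_sd: float = 1e-3
    artifact_rate_per_min: float = 2.0
    spike_od_range: tuple[float, float] = (0.05, 0.20)
    shift_od_range: tuple[float, float] = (0.02, 0.10)
    spike_duration_s: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        for name in (
            "cardiac_hz", "respiratory_hz", "mayer_hz", "cardiac_amp_um",
            "respiratory_amp_um", "mayer_amp_um", "measurement_noise_sd",
            "artifact_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cardiac_hz <= 0.2 or self.respiratory_hz <= 0.2:
            raise ValueError(
                "cardiac_hz and respiratory_hz must lie above the 0.2 Hz "
                "analysis band so that filtering is testable"
            )


@dataclass(frozen=True)
class SubjectFCTarget:
    """Planted per-subject ROI correlation targets (the estimand)."""

    within: dict[str, float]                      # 6 values
    between: np.ndarray                           # 6x6, zero diagonal
    latent: np.ndarray                            # 6x6 latent correlation G
    latent_within: np.ndarray                     # per-ROI latent variance share

    def between_of(self, roi_a: str, roi_b: str) -> float:
        i, j = ROIS.index(roi_a), ROIS.index(roi_b)
        return float(self.between[i, j])


@dataclass
class RawRecording:
    """One trial of dual-wavelength intensity data plus planted truth."""

    subject_id: str
    group: str
    trial_index: int
    timeline: TaskTimeline
    montage: Montage
    intensity: np.ndarray        # (2 wavelengths, n_channels, n_samples), > 0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        n = self.timeline.n_samples(self.montage.sampling_rate_hz)
        if self.intensity.shape != (2, self.montage.n_channels, n):
            raise ValueError(
                f"intensity shape {self.intensity.shape} != "
                f"(2, {self.montage.n_channels}, {n})"
            )
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive")


# --------------------------------------------------------------------------
# Target construction
# --------------------------------------------------------------------------

def nearest_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest positive semi-definite correlation matrix
    (negative eigenvalues raised to *eps*, diagonal renormalised to 1)."""
    lam, vec = np.linalg.eigh((mat + mat.T) / 2.0)
    if lam[0] >= 0:
        return mat
    lam = np.clip(lam, eps, None)
    fixed = (vec * lam) @ vec.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _effective_samples(block_s: float = 35.0,
                       band_hz: tuple[float, float] = (0.01, 0.2),
                       fs: float = 11.0) -> float:
    """Effective number of independent samples for correlation estimation.

    For Gaussian series with power spectrum S(f) observed for T seconds,
    var(r) ~ (1-rho^2)^2 / n_eff with n_eff = 2T (int S)^2 / int S^2.
    The analysed signals carry the squared (zero-phase) generation filter
    times the squared analysis filter, i.e. S = |H|^8 for the 3rd-order
    Butterworth band; numerically ~0.163 independent samples per second,
    n_eff ~ 11.4 for a 35-s block (an ideal rectangular 0.19 Hz band
    would give 2BT ~ 13.3).
    """
    f = np.linspace(0.0, fs / 2.0, 20001)
    sos = signal.butter(3, list(band_hz), btype="band", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=f, fs=fs)
    s = np.abs(h) ** 8
    return float(2.0 * block_s * np.trapezoid(s, f) ** 2 / np.trapezoid(s**2, f))


#: Effective samples of one 35-s walking block in the 0.01-0.2 Hz band.
N_EFF_BLOCK: float = _effective_samples()


def _debias(rho: np.ndarray | float, n_eff: float = N_EFF_BLOCK):
    """Latent correlation whose finite-window sample correlation has
    expectation ~rho (first-order inverse of E[r] = rho - rho(1-rho^2)/2n)."""
    rho = np.asarray(rho, dtype=float)
    return rho + rho * (1.0 - rho**2) / (2.0 * n_eff)


def _rebias(rho: np.ndarray | float, n_eff: float = N_EFF_BLOCK):
    """Expected finite-window sample correlation of latent correlation rho."""
    rho = np.asarray(rho, dtype=float)
    return rho - rho * (1.0 - rho**2) / (2.0 * n_eff)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _latent_matrix(
    within: Mapping[str, float], between: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """Latent ROI correlation implied by channel-level targets:
    G_RS = between(R,S) / sqrt(within_R * within_S)."""
    G = np.eye(len(ROIS))
    for i, a in enumerate(ROIS):
        for j in range(i + 1, len(ROIS)):
            b = ROIS[j]
            key = (a, b) if (a, b) in between else (b, a)
            G[i, j] = G[j, i] = between[key] / np.sqrt(within[a] * within[b])
    return G


def validate_fc_spec(spec: GroupFCSpec) -> None:
    """Reject specs whose implied channel-level target matrix cannot be
    positive semi-definite (between target exceeding the geometric mean of
    the within targets forces a latent correlation above 1)."""
    G = _latent_matrix(spec.within_roi_r, spec.between_roi_r)
    off = G[~np.eye(len(ROIS), dtype=bool)]
    if np.any(np.abs(off) > 1.0):
        raise ValueError(
            "infeasible FC spec: some between-ROI target exceeds "
            "sqrt(within_a * within_b); the implied channel-level "
            "correlation matrix is not positive semi-definite"
        )
    repaired = nearest_correlation(G)
    delta = float(np.max(np.abs(repaired - G)))
    if delta > 0.2:
        raise ValueError(
            f"infeasible FC spec: PSD repair moves a latent entry by {delta:.3f} > 0.2"
        )


def _is_feasible(G: np.ndarray, max_offdiag: float = 0.97,
                 min_eig: float = 1e-6) -> bool:
    off = G[~np.eye(G.shape[0], dtype=bool)]
    if np.max(np.abs(off)) > max_offdiag:
        return False
    return float(np.linalg.eigvalsh(G)[0]) >= min_eig


def _shrink_to_feasible(G_draw: np.ndarray, G_anchor: np.ndarray,
                        tol: float = 1e-3) -> np.ndarray:
    """Largest convex combination alpha * G_draw + (1-alpha) * G_anchor that
    is positive definite with off-diagonal entries <= 0.97.  ``G_anchor``
    must itself be feasible."""
    if _is_feasible(G_draw):
        return G_draw
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _is_feasible(mid * G_draw + (1.0 - mid) * G_anchor):
            lo = mid
        else:
            hi = mid
    return lo * G_draw + (1.0 - lo) * G_anchor


def _group_latent(spec: GroupFCSpec) -> np.ndarray:
    """Feasible latent ROI correlation for the group means.

    The raw latent matrix can sit marginally outside the PSD cone or the
    0.97 entry bound; a uniform shrink toward the identity,
    beta G + (1 - beta) I with the largest admissible beta, restores both
    while preserving the correlation structure exactly (entries scale by
    beta, typically > 0.99)."""
    G = _latent_matrix(
        {r: min(_debias(spec.within_roi_r[r]), 0.97) for r in ROIS},
        {k: _debias(v) for k, v in spec.between_roi_r.items()},
    )
    np.fill_diagonal(G, 1.0)
    off_max = float(np.max(np.abs(G[~np.eye(len(ROIS), dtype=bool)])))
    eig_min = float(np.linalg.eigvalsh(G)[0])
    beta = 1.0
    if off_max > 0.97:
        beta = min(beta, 0.97 / off_max)
    if eig_min < 1e-4:
        beta = min(beta, (1.0 - 1e-4) / (1.0 - eig_min))
    return beta * G + (1.0 - beta) * np.eye(len(ROIS))


#: SD of the per-entry Fisher-z perturbation of a subject's latent matrix.
LATENT_Z_SD: float = 0.10

#: Finite-sample distortion of within-ROI values by the PCA systemic-removal
#: step: the leading principal component is estimated from ~800 samples, so
#: its direction tilts slightly from the planted systemic loading toward the
#: dominant shared neural direction, and its removal takes a small slice of
#: the within-region shared variance.  Calibrated once on dedicated
#: calibration cohorts (mechanism verified by a PCA-off ablation, where the
#: distortion vanishes); between-ROI values are unaffected.  The recorded
#: estimand refers to the default preprocessing chain (one component removed).
PCA_WITHIN_DISTORTION: float = 0.006


def generate_subject_fc_target(spec: GroupFCSpec, seed) -> SubjectFCTarget:
    """Draw one subject's connectivity targets around the group means.

    Within-ROI targets are Normal(group mean, between_subject_sd) with a
    shared subject-level component, clipped to (0.05, 0.95).  The subject's
    latent ROI matrix is the group latent structure perturbed on Fisher's z
    scale (so it always stays inside the unit ball) and shrunk back toward
    the group matrix if the perturbation leaves the PSD cone; between-ROI
    targets follow as latent * sqrt(w_a * w_b), inheriting the subject's
    shared variation through the within draws.  This keeps every draw
    feasible without one-sided censoring, so group means of the achieved
    targets stay centred on the spec.  Deterministic given the seed.
    """
    validate_fc_spec(spec)
    rng = _as_rng(seed)
    shared = rng.normal(0.0, spec.shared_sd) if spec.shared_sd > 0 else 0.0
    sd = spec.specific_sd
    within = {
        r: float(np.clip(
            spec.within_roi_r[r] + shared
            + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.05, 0.95))
        for r in ROIS
    }

    G_group = _group_latent(spec)
    if spec.between_subject_sd > 0:
        eps = rng.normal(0.0, LATENT_Z_SD, G_group.shape)
        eps = (eps + eps.T) / 2.0
        np.fill_diagonal(eps, 0.0)
        G_draw = np.tanh(np.arctanh(np.clip(G_group, -0.999, 0.999)) + eps)
        np.fill_diagonal(G_draw, 1.0)
        G_rep = _shrink_to_feasible(G_draw, G_group)
    else:
        G_rep = G_group

    # Latent within-variance shares with the finite-window bias folded in,
    # so the drawn targets are the estimand of the trial-averaged Pearson FC.
    w_lat = np.array([min(_debias(within[r]), 0.97) for r in ROIS])

    achieved_between = _rebias(G_rep * np.sqrt(np.outer(w_lat, w_lat)))
    np.fill_diagonal(achieved_between, 0.0)
    achieved_within = {
        r: float(_rebias(w_lat[i])) - PCA_WITHIN_DISTORTION
        for i, r in enumerate(ROIS)
    }
    return SubjectFCTarget(
        within=achieved_within,
        between=achieved_between,
        latent=G_rep,
        latent_within=w_lat,
    )


# --------------------------------------------------------------------------
# Signal synthesis
# --------------------------------------------------------------------------

_BAND_SOS_CACHE: dict[tuple, np.ndarray] = {}


def _band_sos(fs: float, lo: float = 0.01, hi: float = 0.2) -> np.ndarray:
    key = (fs, lo, hi)
    if key not in _BAND_SOS_CACHE:
        _BAND_SOS_CACHE[key] = signal.butter(3, [lo, hi], btype="band", fs=fs,
                                             output="sos")
    return _BAND_SOS_CACHE[key]


def _band_limited_noise(rng: np.random.Generator, n: int, m: int,
                        fs: float) -> np.ndarray:
    """(m, n) unit-variance Gaussian processes confined to the analysis band."""
    pad = 400
    x = rng.standard_normal((m, n + 2 * pad))
    y = signal.sosfiltfilt(_band_sos(fs), x, axis=1)[:, pad:pad + n]
    return y / y.std(axis=1, keepdims=True)


def canonical_hrf(t: np.ndarray, peak_s: float = 6.0,
                  undershoot_s: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function."""
    return _gamma.pdf(t, peak_s) - _gamma.pdf(t, undershoot_s) / ratio


# Extinction coefficients [1/(mM cm)] at (730, 850) nm for (HbO, HbR);
# standard compiled in-vitro values used across fNIRS toolchains.
DEFAULT_EXTINCTION = np.array([[0.390, 1.1022],
                               [1.058, 0.69132]])
DEFAULT_DPF = (6.0, 5.2)
DEFAULT_I0 = 1.0


def forward_mbll(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    separation_mm: float = 30.0,
    extinction: np.ndarray = DEFAULT_EXTINCTION,
    dpf: Sequence[float] = DEFAULT_DPF,
    i0: float = DEFAULT_I0,
) -> np.ndarray:
    """Map concentration changes (uM) to light intensity at both wavelengths
    via dOD(lambda) = [eps_HbO dHbO + eps_HbR dHbR] * d * DPF(lambda) and
    I = I0 * 10**(-dOD).  Returns (2, channels, samples)."""
    d_cm = separation_mm / 10.0
    conc_mm = np.stack([hbo_um, hbr_um]) / 1000.0   # (2 chromophores, ch, n)
    path = extinction * d_cm * np.asarray(dpf)[:, None]  # (2 wl, 2 chrom)
    dod = np.einsum("lc,cnt->lnt", path, conc_mm)
    return i0 * 10.0 ** (-dod)


def simulate_recording(
    target: SubjectFCTarget,
    timeline: TaskTimeline,
    montage: Montage,
    noise: NoiseSpec,
    seed,
    *,
    subject_id: str = "S00",
    group: str = "PD",
    trial_index: int = 0,
    hbo_sd_um: float = 0.5,
    evoked_amp_um: float = 0.1,
    mayer_loadings: np.ndarray | None = None,
) -> RawRecording:
    """Forward-simulate one trial; inverse of the preprocessing chain.

    ``ground_truth`` records the planted dHbO (neural + evoked, before
    nuisance), the subject target matrices, artifact sample indices, and
    the forward-model constants.
    """
    rng = _as_rng(seed)
    fs = montage.sampling_rate_hz
    n = timeline.n_samples(fs)
    n_ch = montage.n_channels
    roi_idx = np.array([ROIS.index(r) for r in montage.roi_of()])
    t = np.arange(n) / fs

    # (i) latent ROI processes with the subject's latent correlation
    L = np.linalg.cholesky(target.latent + 1e-10 * np.eye(len(ROIS)))
    g = L @ _band_limited_noise(rng, n, len(ROIS), fs)
    # (ii) channel signals: shared latent + private noise
    e = _band_limited_noise(rng, n, n_ch, fs)
    w = target.latent_within[roi_idx][:, None]
    hbo = hbo_sd_um * (np.sqrt(w) * g[roi_idx] + np.sqrt(1.0 - w) * e)

    # (iii) walking-evoked response: HRF (*) boxcar, per-channel gain jitter
    if evoked_amp_um > 0:
        box = ((t >= timeline.pre_stand_s)
               & (t < timeline.pre_stand_s + timeline.walk_s)).astype(float)
        h = canonical_hrf(np.arange(0.0, 30.0, 1.0 / fs))
        evoked = np.convolve(box, h / h.sum())[:n]
        hbo = hbo + evoked_amp_um * np.outer(rng.uniform(0.7, 1.3, n_ch), evoked)

    planted_hbo = hbo.copy()

    # (iv) physiological nuisance
    if noise.cardiac_amp_um > 0:
        ph = rng.uniform(0, 2 * np.pi, n_ch)[:, None]
        hbo = hbo + noise.cardiac_amp_um * np.sin(2 * np.pi * noise.cardiac_hz * t + ph)
    if noise.respiratory_amp_um > 0:
        ph = rng.uniform(0, 2 * np.pi, n_ch)[:, None]
        hbo = hbo + noise.respiratory_amp_um * np.sin(
            2 * np.pi * noise.respiratory_hz * t + ph)
    if noise.mayer_amp_um > 0:
        if mayer_loadings is None:
            mayer_loadings = rng.standard_normal(n_ch)
            mayer_loadings = mayer_loadings - mayer_loadings.mean()
            mayer_loadings = mayer_loadings / np.sqrt((mayer_loadings**2).mean())
        lo = max(noise.mayer_hz - 0.04, 0.01)
        sos = signal.butter(2, [lo, noise.mayer_hz + 0.04], btype="band",
                            fs=fs, output="sos")
        pad = 400
        mw = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
        mw = mw / mw.std()
        hbo = hbo + noise.mayer_amp_um * np.outer(mayer_loadings, mw)

    hbr = -hbo / 3.0 + 0.1 * hbo_sd_um * _band_limited_noise(rng, n, n_ch, fs)

    # (v) forward modified Beer-Lambert to intensity
    intensity = forward_mbll(hbo, hbr,
                             separation_mm=montage.channels[0].separation_mm)
    if noise.measurement_noise_sd > 0:
        intensity = intensity * (
            1.0 + noise.measurement_noise_sd * rng.standard_normal(intensity.shape))

    # (vi) motion artifacts, injected as optical-density excursions
    artifact_samples: dict[int, list[int]] = {}
    n_events = rng.poisson(noise.artifact_rate_per_min * timeline.total_s / 60.0)
    for _ in range(n_events):
        ch = int(rng.integers(n_ch))
        start = int(rng.integers(0, n - 1))
        if rng.random() < 0.5:   # spike
            dur = int(rng.uniform(*noise.spike_duration_s) * fs)
            stop = min(start + max(dur, 2), n)
            amp = rng.uniform(*noise.spike_od_range) * rng.choice([-1.0, 1.0])
            shape = np.hanning(2 * (stop - start))[stop - start:]
            dod_art = np.zeros(n)
            dod_art[start:stop] = amp * shape
            idx = list(range(start, stop))
        else:                    # baseline shift
            amp = rng.uniform(*noise.shift_od_range) * rng.choice([-1.0, 1.0])
            dod_art = np.zeros(n)
            dod_art[start:] = amp
            idx = list(range(start, min(start + int(fs), n)))
        intensity[:, ch, :] = intensity[:, ch, :] * 10.0 ** (-dod_art)
        artifact_samples.setdefault(ch, []).extend(idx)

    if np.any(intensity <= 0):
        raise ValueError("nonpositive intensity generated; amplitudes misconfigured")

    ground_truth = {
        "hbo_um": planted_hbo,
        "target": target,
        "artifact_samples": {k: sorted(set(v)) for k, v in artifact_samples.items()},
        "extinction": DEFAULT_EXTINCTION,
        "dpf": DEFAULT_DPF,
        "i0": DEFAULT_I0,
        "hbo_sd_um": hbo_sd_um,
        "evoked_amp_um": evoked_amp_um,
    }
    return RawRecording(
        subject_id=subject_id, group=group, trial_index=trial_index,
        timeline=timeline, montage=montage, intensity=intensity,
        ground_truth=ground_truth,
    )


# --------------------------------------------------------------------------
# Gait table
# --------------------------------------------------------------------------

def _gait_correlation_matrix() -> tuple[list[str], np.ndarray]:
    """Documented cross-variable structure: left/right of the same variable
    correlate at 0.95; gait speed and stride length at 0.8; everything else
    uncorrelated.  Repaired to the nearest correlation matrix."""
    names = list(GAIT_VARIABLES)
    k = len(names)
    C = np.eye(k)
    base = {n.rsplit("_", 1)[0] for n in names}
    for b in base:
        i, j = names.index(f"{b}_L"), names.index(f"{b}_R")
        C[i, j] = C[j, i] = 0.95
    for a in ("gait_speed_L", "gait_speed_R"):
        for b in ("stride_length_L", "stride_length_R"):
            i, j = names.index(a), names.index(b)
            C[i, j] = C[j, i] = 0.8
    return names, nearest_correlation(C)


def simulate_gait_table(
    n_pd: int = 30,
    n_hc: int = 22,
    seed=0,
    *,
    fc_z: Mapping[str, np.ndarray] | None = None,
    fc_gait_r: float = 0.445,
) -> pd.DataFrame:
    """Per-subject gait parameters plus age, sex and MMSE covariates.

    Each variable is Normal(group mean, group SD) with the documented
    cross-variable correlation, truncated to mean +- 4 SD and physical
    ranges.  If ``fc_z`` supplies per-group standard-normal subject scores
    (the subject's RPMC within-FC deviation), gait speed and stride length
    in the PD group receive a correlated component with loading
    ``fc_gait_r``, planting the connectivity-gait association.
    """
    if n_pd < 2 or n_hc < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = _as_rng(seed)
    names, C = _gait_correlation_matrix()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(names)))
    coupled = ("gait_speed_L", "gait_speed_R", "stride_length_L", "stride_length_R")

    rows = []
    for group, n_sub in (("PD", n_pd), ("HC", n_hc)):
        z = L @ rng.standard_normal((len(names), n_sub))
        if fc_z is not None and group in fc_z and group == "PD" and fc_gait_r != 0:
            rho = fc_gait_r
            zfc = np.asarray(fc_z[group], dtype=float)
            for v in coupled:
                i = names.index(v)
                z[i] = rho * zfc + np.sqrt(1.0 - rho**2) * z[i]
        male = rng.random(n_sub) < SEX_MALE_FRACTION[group]
        cov = {
            name: rng.normal(
                p[0] if group == "PD" else p[2],
                p[1] if group == "PD" else p[3], n_sub)
            for name, p in GAIT_COVARIATES.items()
        }
        for s in range(n_sub):
            row = {"subject_id": f"{group}{s + 1:02d}", "group": group,
                   "sex": "M" if male[s] else "F"}
            for name, p in GAIT_COVARIATES.items():
                row[name] = float(cov[name][s])
            for i, name in enumerate(names):
                mu, sd = (GAIT_PARAMS[name][0], GAIT_PARAMS[name][1]) \
                    if group == "PD" else (GAIT_PARAMS[name][2], GAIT_PARAMS[name][3])
                val = mu + sd * float(np.clip(z[i, s], -4.0, 4.0))
                val = max(val, 1e-6)
                if name.startswith("double_support"):
                    val = float(np.clip(val, 1e-6, 100.0 - 1e-6))
                row[name] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    df["mmse"] = df["mmse"].clip(upper=30.0)
    return df


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """Everything downstream stages need: recordings, gait table, truth."""

    recordings: list[RawRecording]
    gait_table: pd.DataFrame
    targets: dict[str, SubjectFCTarget]
    montage: Montage
    timeline: TaskTimeline

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.recordings:
            if r.subject_id not in seen:
                seen.append(r.subject_id)
        return seen


def simulate_cohort(
    n_pd: int = 30,
    n_hc: int = 22,
    timeline: TaskTimeline | None = None,
    seed=0,
    *,
    montage: Montage | None = None,
    noise: NoiseSpec | None = None,
    pd_spec: GroupFCSpec = PD_SPEC,
    hc_spec: GroupFCSpec = HC_SPEC,
    hbo_sd_um: float = 0.5,
    evoked_amp_um: float = 0.1,
) -> Cohort:
    """Simulate the full two-group cohort: per-subject FC targets, three
    trials of raw recordings per subject, and the gait table with the
    planted RPMC-gait coupling.  Per-subject seeds derive deterministically
    from the master seed (NumPy SeedSequence spawning, PCG64 streams)."""
    timeline = timeline or TaskTimeline()
    montage = montage or build_default_montage()
    noise = noise or NoiseSpec()
    master = np.random.SeedSequence(seed)
    gait_ss, *subject_ss = master.spawn(1 + n_pd + n_hc)

    recordings: list[RawRecording] = []
    targets: dict[str, SubjectFCTarget] = {}
    fc_z: dict[str, list[float]] = {"PD": [], "HC": []}
    k = 0
    for group, n_sub, spec in (("PD", n_pd, pd_spec), ("HC", n_hc, hc_spec)):
        for s in range(n_sub):
            rng = np.random.default_rng(subject_ss[k])
            k += 1
            sid = f"{group}{s + 1:02d}"
            target = generate_subject_fc_target(spec, rng)
            targets[sid] = target
            fc_z[group].append(
                (target.within["RPMC"] - spec.within_roi_r["RPMC"])
                / max(spec.target_sd, 1e-12)
            )
            loadings = rng.standard_normal(montage.n_channels)
            loadings = loadings - loadings.mean()
            loadings = loadings / np.sqrt((loadings**2).mean())
            for trial in range(timeline.n_trials):
                recordings.append(
                    simulate_recording(
                        target, timeline, montage, noise, rng,
                        subject_id=sid, group=group, trial_index=trial,
                        hbo_sd_um=hbo_sd_um, evoked_amp_um=evoked_amp_um,
                        mayer_loadings=loadings,
                    )
                )

    gait = simulate_gait_table(
        n_pd, n_hc, np.random.default_rng(gait_ss),
        fc_z={g: np.array(v) for g, v in fc_z.items()},
    )
    return Cohort(recordings=recordings, gait_table=gait, targets=targets,
                  montage=montage, timeline=timeline)
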