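"""Functional-connectivity feature extraction from realigned time series.

Pipeline per subject: (optional band-pass) -> nuisance regression (6 motion
parameters + gray-matter / white-matter / CSF mean signals) -> motion
scrubbing at a framewise-displacement threshold -> network-level
connectivity: between-network FC is the Pearson correlation of voxel-mean
time courses, within-network FC the mean pairwise voxel correlation inside
each network.  Raw correlations are used as features throughout (no Fisher
z-transform).

Also provides one-way random-effects ICC for test-retest reliability of the
features, with negative values clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .atlas import AtlasSpec

#: Scrubbing threshold on framewise displacement, in mm.
FD_THRESHOLD_MM = 0.5
#: Subjects losing more than this fraction of frames to scrubbing are excluded.
QC_SCRUB_RATIO = 0.40


@dataclass
class TimeSeriesBundle:
    """Realigned voxel x frame signals plus realignment parameters.

    ``motion`` holds the 6 rigid-body parameters per frame: 3 translations in
    mm and 3 rotations in radians.  ``tissue_means`` optionally carries
    per-frame mean signals of gray matter, white matter and CSF (3 x frames).
    """

    signal: np.ndarray  # (n_voxels, n_frames)
    voxel_network: np.ndarray  # (n_voxels,) network id per voxel
    motion: np.ndarray  # (n_frames, 6)
    tr_seconds: float
    tissue_means: np.ndarray | None = None  # (3, n_frames)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.voxel_network = np.asarray(self.voxel_network)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D voxel x frame matrix")
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must be a frames x 6 matrix")
        if self.motion.shape[0] != self.n_frames:
            raise ValueError("motion and signal disagree on frame count")
        if self.voxel_network.shape[0] != self.signal.shape[0]:
            raise ValueError("voxel_network must map every voxel")
        if self.tissue_means is not None:
            self.tissue_means = np.asarray(self.tissue_means, dtype=float)
            if self.tissue_means.shape != (3, self.n_frames):
                raise ValueError("tissue_means must be 3 x n_frames")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]


@dataclass
class FCVector:
    """Per-subject connectivity features in canonical atlas order."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("values and labels disagree in length")


@dataclass
class ICCResult:
    """Per-feature one-way random-effects ICC with its mean-square terms."""

    icc: np.ndarray  # clamped to [0, 1]
    ms_between: np.ndarray
    ms_within: np.ndarray
    k: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.icc))

    @property
    def sd(self) -> float:
        return float(np.std(self.icc, ddof=1))


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement in mm.

    Sum of absolute backward differences of the six realignment parameters,
    with rotations (radians) converted to arc length at ``head_radius_mm``.
    The first frame has FD = 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a frames x 6 matrix")
    diffs = np.abs(np.diff(motion, axis=0))
    diffs[:, 3:] *= head_radius_mm
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    return fd


def scrub(
    bundle: TimeSeriesBundle,
    fd: np.ndarray,
    threshold_mm: float = FD_THRESHOLD_MM,
) -> tuple[TimeSeriesBundle, float]:
    """Drop frames with FD > threshold; neighbors are retained.

    Returns the scrubbed bundle and the scrub ratio (fraction of frames
    removed).  Raises if no frame survives.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != bundle.n_frames:
        raise ValueError("fd length must equal the frame count")
    keep = fd <= threshold_mm
    if not keep.any():
        raise ValueError("scrubbing removed every frame; subject unusable")
    ratio = float(1.0 - keep.mean())
    scrubbed = replace(
        bundle,
        signal=bundle.signal[:, keep],
        motion=bundle.motion[keep],
        tissue_means=None if bundle.tissue_means is None else bundle.tissue_means[:, keep],
    )
    return scrubbed, ratio


def nuisance_regress(bundle: TimeSeriesBundle) -> TimeSeriesBundle:
    """Regress 6 motion parameters + 3 tissue mean signals out of every voxel.

    The regressor matrix carries an intercept, so residual series are
    de-meaned and orthogonal to every regressor.  If ``tissue_means`` is
    absent only motion (plus intercept) is removed.
    """
    n = bundle.n_frames
    cols = [np.ones(n), *bundle.motion.T]
    names = ["intercept"] + [f"motion{i + 1}" for i in range(6)]
    if bundle.tissue_means is not None:
        cols.extend(bundle.tissue_means)
        names.extend(["gm", "wm", "csf"])
    R = np.column_stack(cols)
    # constant regressors are redundant with the intercept; drop them
    keep = np.concatenate([[True], R[:, 1:].std(axis=0) > 0])
    R = R[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    centered = R - R.mean(axis=0)
    centered[:, 0] = 1.0
    rank = np.linalg.matrix_rank(centered)
    if rank < R.shape[1]:
        # identify a collinear column for the error message
        bad = []
        for j in range(1, R.shape[1]):
            sub = np.delete(centered, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j])
        raise ValueError(
            "nuisance regressors are rank deficient; collinear columns: "
            + ", ".join(bad or ["unknown"])
        )
    beta, *_ = np.linalg.lstsq(R, bundle.signal.T, rcond=None)
    resid = bundle.signal.T - R @ beta
    return replace(bundle, signal=resid.T)


def bandpass(
    bundle: TimeSeriesBundle,
    low_hz: float = 0.009,
    high_hz: float = 0.08,
    order: int = 4,
) -> TimeSeriesBundle:
    """Zero-phase Butterworth band-pass of every voxel series.

    Retains slow spontaneous fluctuations and suppresses high-frequency
    physiological noise (e.g. cardiac pulsation near 0.3 Hz).
    """
    if low_hz >= high_hz:
        raise ValueError("band edges inverted: low_hz must be < high_hz")
    fs = 1.0 / bundle.tr_seconds
    if high_hz >= fs / 2:
        raise ValueError("high_hz must be below the Nyquist frequency")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, bundle.signal, axis=1)
    out = replace(bundle, signal=filtered)
    if bundle.tissue_means is not None:
        out.tissue_means = sps.sosfiltfilt(sos, bundle.tissue_means, axis=1)
    return out


def compute_fc(bundle: TimeSeriesBundle, atlas: AtlasSpec) -> FCVector:
    """Network-level connectivity features in canonical order.

    Between-network FC: Pearson correlation between the voxel-mean time
    courses of the two networks.  Within-network FC: mean of all pairwise
    voxel correlations inside the network.
    """
    if bundle.n_frames < 3:
        raise ValueError("need at least 3 frames to estimate correlations")
    n = atlas.n_networks
    X = bundle.signal
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"dropping {int((sd == 0).sum())} zero-variance voxel(s) before "
            "correlation",
            stacklevel=2,
        )
    within = np.full(n, np.nan)
    means = np.empty((n, bundle.n_frames))
    for k in range(n):
        sel = (bundle.voxel_network == k) & (sd > 0)
        if sel.sum() < 2:
            raise ValueError(
                f"network {atlas.network_names[k]!r} has fewer than 2 usable voxels"
            )
        block = X[sel]
        means[k] = block.mean(axis=0)
        C = np.corrcoef(block)
        iu = np.triu_indices_from(C, k=1)
        within[k] = C[iu].mean()
    if np.any(means.std(axis=1) == 0):
        bad = int(np.flatnonzero(means.std(axis=1) == 0)[0])
        raise ValueError(
            f"network {atlas.network_names[bad]!r} has a zero-variance mean series"
        )
    B = np.corrcoef(means)
    iu = np.triu_indices(n, k=1)
    values = np.concatenate([within, B[iu]])
    values = np.clip(values, -1.0, 1.0)
    return FCVector(values=values, labels=atlas.feature_labels())


def icc(test_fc: np.ndarray, retest_fc: np.ndarray) -> ICCResult:
    """One-way random-effects ICC per feature across two (or more) sessions.

    ``test_fc`` and ``retest_fc`` are subjects x features matrices for the
    two sessions.  ICC = (MS_b - MS_w) / (MS_b + (k - 1) MS_w), where MS_b
    and MS_w are the between- and within-subject mean squares and k the
    number of sessions; negative values are clamped to 0.
    """
    test_fc = np.atleast_2d(np.asarray(test_fc, dtype=float))
    retest_fc = np.atleast_2d(np.asarray(retest_fc, dtype=float))
    if test_fc.shape != retest_fc.shape:
        raise ValueError("test and retest matrices must have the same shape")
    n = test_fc.shape[0]
    if n < 2:
        raise ValueError("ICC needs at least 2 subjects")
    data = np.stack([test_fc, retest_fc], axis=2)  # (n, p, k)
    k = data.shape[2]
    subj_mean = data.mean(axis=2)  # (n, p)
    grand = subj_mean.mean(axis=0)  # (p,)
    ms_b = k * ((subj_mean - grand) ** 2).sum(axis=0) / (n - 1)
    ms_w = ((data - subj_mean[:, :, None]) ** 2).sum(axis=(0, 2)) / (n * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    return ICCResult(icc=np.clip(raw, 0.0, 1.0), ms_between=ms_b, ms_within=ms_w, k=k)


def extract_fc(
    bundle: TimeSeriesBundle,
    atlas: AtlasSpec,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    qc_max_scrub_ratio: float = QC_SCRUB_RATIO,
    apply_bandpass: bool = False,
) -> tuple[FCVector, dict]:
    """Full per-subject pipeline: (band-pass) -> nuisance -> scrub -> FC.

    Returns the feature vector and a QC record with the scrub ratio and an
    exclusion flag (scrub ratio above ``qc_max_scrub_ratio``).
    """
    fd = framewise_displacement(bundle.motion)
    work = bandpass(bundle) if apply_bandpass else bundle
    work = nuisance_regress(work)
    work, ratio = scrub(work, fd, fd_threshold_mm)
    fc = compute_fc(work, atlas)
    qc = {
        "scrub_ratio": ratio,
        "excluded": ratio > qc_max_scrub_ratio,
        "n_frames_kept": work.n_frames,
    }
    return fc, qc
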