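"""Ground-truthed synthetic cohorts for the FC -> working-memory pipeline.

The generator plants the exact statistical structure the analysis assumes,
so that every downstream stage can be validated against a known truth:

* a sparse linear FC -> WMA relation (default: 16 of 171 connections carry
  nonzero weight) with additive Gaussian residual noise,
* diagnosis-specific per-connection FC mean shifts whose induced effect on
  true WMA has a controlled Hedges-g effect size relative to controls,
* confounds (fluid intelligence, composite cognition, age, head motion)
  correlated with WMA at magnitudes typical of cognitive cohort studies,
* per-session d-prime learning curves following y = a - b/x plus noise,
* optionally, voxel x frame BOLD-like time series whose network-level
  connectivity approximates a requested FC vector, with motion traces and
  injected motion spikes at known frames.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .atlas import AtlasSpec, make_atlas
from .behavior import LearningCurve
from .features import TimeSeriesBundle

DIAGNOSES = ("HC", "SCZ", "MDD", "OCD", "ASD")

#: Planted WMA impairment effect sizes (Hedges g, patients vs controls) and
#: case/control group sizes for the default multi-diagnosis cohort; the
#: graded severity SCZ < MDD < OCD < ASD mirrors the ordering reported by
#: digit-span meta-analyses of these disorders.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "SCZ": -0.68,
    "MDD": -0.29,
    "OCD": -0.16,
    "ASD": 0.09,
}
DEFAULT_GROUP_SIZES: dict[str, tuple[int, int]] = {
    "SCZ": (58, 60),
    "MDD": (77, 63),
    "OCD": (46, 47),
    "ASD": (69, 71),
}
DEFAULT_SITE_MAP: dict[str, str] = {
    "HC": "site-00",
    "SCZ": "site-01",
    "MDD": "site-02",
    "OCD": "site-03",
    "ASD": "site-04",
}

#: Confound-to-WMA correlations used by the generator (values typical of
#: cognition / motion / age couplings in resting-state cohorts).
DEFAULT_CONFOUND_COUPLING: dict[str, float] = {
    "fluid_iq": 0.46,
    "composite_cog": 0.61,
    "age": -0.36,
    "mean_fd": -0.24,
}


@dataclass
class GroundTruth:
    """Generative parameters of a synthetic cohort."""

    w_true: np.ndarray  # per-feature weight, sparse
    intercept_true: float
    noise_sd: float  # WMA residual SD
    fc_mean: np.ndarray  # population-mean FC per feature (HC baseline)
    fc_subject_sd: float  # per-feature between-subject SD
    delta: dict[str, np.ndarray] = field(default_factory=dict)
    confound_coupling: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUND_COUPLING)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.w_true = np.asarray(self.w_true, dtype=float)
        self.fc_mean = np.asarray(self.fc_mean, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.w_true.shape != self.fc_mean.shape:
            raise ValueError("w_true and fc_mean must have equal length")

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.w_true)

    @property
    def wma_sd(self) -> float:
        """Population SD of true WMA (FC variation plus residual noise)."""
        signal_var = float(np.sum(self.w_true**2)) * self.fc_subject_sd**2
        return float(np.sqrt(signal_var + self.noise_sd**2))

    @property
    def wma_mean(self) -> float:
        """Population mean of true WMA in the control (HC) population."""
        return self.intercept_true + float(self.w_true @ self.fc_mean)


@dataclass
class SubjectRecord:
    """One synthetic participant."""

    subject_id: str
    diagnosis: str
    site: str
    age: float
    sex: str
    fc: np.ndarray
    wma_true: float
    score_3back: float
    score_nback: float
    score_digit: float
    fluid_iq: float
    composite_cog: float
    mean_fd: float
    timeseries: TimeSeriesBundle | None = None


def delta_for_effect_size(
    w_true: np.ndarray, wma_sd: float, g: float
) -> np.ndarray:
    """FC mean-shift vector planting a WMA effect size of ``g``.

    The shift is spread across the true support proportionally to the
    weights, so that w_true . delta = g * wma_sd exactly (patients' mean
    true WMA moves by g control-SDs).
    """
    w_true = np.asarray(w_true, dtype=float)
    nrm2 = float(w_true @ w_true)
    if nrm2 == 0:
        raise ValueError("cannot plant an effect size with an all-zero weight vector")
    return g * wma_sd * w_true / nrm2


def make_ground_truth(
    atlas: AtlasSpec | None = None,
    n_support: int = 16,
    noise_sd: float = 0.2,
    population_mean: float = 2.5,
    fc_subject_sd: float = 0.1,
    effect_sizes: dict[str, float] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a sparse FC -> WMA ground truth.

    Support connections are sampled uniformly over the 171 features; weight
    magnitudes are uniform on [0.75, 1.5] with roughly 3 positive for every
    13 negative weights (positive within-network fronto-parietal style
    connections are the minority).  The defaults emulate a high-precision
    behavioural target: every planted connection is individually detectable
    at n = 100 (per-connection t around 3.8) and the planted explainable
    variance is about 0.84 of total WMA variance.
    """
    if atlas is None:
        atlas = make_atlas()
    if effect_sizes is None:
        effect_sizes = dict(DEFAULT_EFFECT_SIZES)
    rng = np.random.default_rng(seed)
    p = atlas.n_features
    if not 1 <= n_support <= p:
        raise ValueError("n_support out of range")

    support = rng.choice(p, size=n_support, replace=False)
    mags = rng.uniform(0.75, 1.5, size=n_support)
    n_pos = max(1, round(n_support * 3 / 16))
    signs = np.full(n_support, -1.0)
    signs[rng.choice(n_support, size=n_pos, replace=False)] = 1.0
    w = np.zeros(p)
    w[support] = mags * signs

    fc_mean = np.empty(p)
    nw = atlas.n_networks
    fc_mean[:nw] = rng.normal(0.5, 0.05, size=nw)
    fc_mean[nw:] = rng.normal(0.2, 0.1, size=p - nw)
    fc_mean = np.clip(fc_mean, -0.8, 0.9)

    # anchor the HC population mean WMA (d-prime plateau scale) at
    # population_mean by absorbing the weighted mean FC into the intercept
    gt = GroundTruth(
        w_true=w,
        intercept_true=population_mean - float(w @ fc_mean),
        noise_sd=noise_sd,
        fc_mean=fc_mean,
        fc_subject_sd=fc_subject_sd,
        seed=seed,
    )
    gt.delta = {"HC": np.zeros(p)}
    for diag, g in effect_sizes.items():
        gt.delta[diag] = delta_for_effect_size(w, gt.wma_sd, g)
    return gt


def simulate_cohort(
    n_per_group: int | dict[str, int],
    diagnoses: tuple[str, ...] | list[str],
    ground_truth: GroundTruth,
    atlas: AtlasSpec | None = None,
    site_map: dict[str, str] | None = None,
    emit: str = "fc_only",
    seed: int = 0,
    n_frames: int = 200,
    tr_seconds: float = 2.0,
    measurement_noise_sd: float = 0.1,
) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord`.

    Per subject: fc = fc_mean + delta[diagnosis] + N(0, fc_subject_sd) per
    feature; wma_true = intercept + w_true . fc + N(0, noise_sd); behavioural
    scores are noisy linear transforms of wma_true; confounds are correlated
    with wma_true through ``confound_coupling``.  With ``emit='timeseries'``
    each record additionally carries a voxel x frame bundle realising its FC
    vector.
    """
    if atlas is None:
        atlas = make_atlas()
    if site_map is None:
        site_map = dict(DEFAULT_SITE_MAP)
    if emit not in ("fc_only", "timeseries"):
        raise ValueError(f"unknown emit mode {emit!r}")
    gt = ground_truth
    for diag in diagnoses:
        if diag not in gt.delta and diag != "HC":
            raise ValueError(f"unknown diagnosis label {diag!r}")
    rng = np.random.default_rng(seed)
    coup = gt.confound_coupling
    records: list[SubjectRecord] = []
    counter = 0
    for diag in diagnoses:
        n = n_per_group[diag] if isinstance(n_per_group, dict) else n_per_group
        if n < 2:
            raise ValueError("n_per_group must be >= 2")
        delta = gt.delta.get(diag, np.zeros(gt.w_true.shape[0]))
        for _ in range(n):
            counter += 1
            fc = gt.fc_mean + delta + rng.normal(0, gt.fc_subject_sd, gt.w_true.shape[0])
            fc = np.clip(fc, -0.99, 0.99)
            wma = gt.intercept_true + float(gt.w_true @ fc) + rng.normal(0, gt.noise_sd)
            z = (wma - gt.wma_mean) / gt.wma_sd

            def couple(r: float) -> float:
                return r * z + np.sqrt(max(0.0, 1 - r**2)) * rng.normal()

            fluid = 16.5 + 4.8 * couple(coup.get("fluid_iq", 0.0))
            comp = couple(coup.get("composite_cog", 0.0))
            age = float(np.clip(35.0 + 9.0 * couple(coup.get("age", 0.0)), 18, 65))
            fd = float(np.clip(0.12 + 0.05 * couple(coup.get("mean_fd", 0.0)), 0.01, None))
            ts = None
            if emit == "timeseries":
                ts = simulate_subject_timeseries(
                    atlas,
                    fc,
                    n_frames=n_frames,
                    tr_seconds=tr_seconds,
                    seed=int(rng.integers(2**31 - 1)),
                )
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{counter:04d}",
                    diagnosis=diag,
                    site=site_map.get(diag, "site-0"),
                    age=age,
                    sex="M" if rng.random() < 0.5 else "F",
                    fc=fc,
                    wma_true=wma,
                    score_3back=wma + (
                        rng.normal(0, measurement_noise_sd)
                        if measurement_noise_sd > 0
                        else 0.0
                    ),
                    score_nback=float(np.clip(86.0 + 9.5 * z + rng.normal(0, 4.0), 0, 100)),
                    score_digit=22.9 + 4.3 * z + rng.normal(0, 2.0),
                    fluid_iq=fluid,
                    composite_cog=comp,
                    mean_fd=fd,
                    timeseries=ts,
                )
            )
    return records


def simulate_case_control_cohort(
    ground_truth: GroundTruth,
    atlas: AtlasSpec | None = None,
    group_sizes: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Patients plus site-matched controls for each diagnosis.

    ``group_sizes`` maps diagnosis -> (n_patients, n_controls); controls are
    HC subjects assigned the patient group's site.  Defaults reproduce the
    four-diagnosis case/control layout (58/60, 77/63, 46/47, 69/71).
    """
    if group_sizes is None:
        group_sizes = dict(DEFAULT_GROUP_SIZES)
    records: list[SubjectRecord] = []
    rng = np.random.default_rng(seed)
    for diag, (n_pat, n_ctl) in group_sizes.items():
        site = DEFAULT_SITE_MAP.get(diag, f"site-{diag.lower()}")
        sub = simulate_cohort(
            {diag: n_pat, "HC": n_ctl},
            (diag, "HC"),
            ground_truth,
            atlas,
            site_map={diag: site, "HC": site},
            seed=int(rng.integers(2**31 - 1)),
        )
        for i, r in enumerate(sub):
            r.subject_id = f"{site}-{i + 1:04d}"
        records.extend(sub)
    return records


# ----------------------------------------------------------------------
# time-series synthesis


def _network_cov_from_target(
    atlas: AtlasSpec, target_fc: np.ndarray, repair_tol: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Latent factor correlation matrix + per-network voxel-noise SDs.

    Each voxel is latent network factor (unit variance) plus iid noise of
    variance s_k^2; within-network FC is then 1/(1+s_k^2) exactly in
    population, and the factor correlations are inflated to compensate for
    the attenuation of voxel-mean courses by averaged noise.
    """
    n = atlas.n_networks
    target_fc = np.asarray(target_fc, dtype=float)
    if target_fc.shape[0] != atlas.n_features:
        raise ValueError("target_fc length does not match the atlas")
    within = target_fc[:n]
    if np.any(within <= 0) or np.any(within > 1):
        raise ValueError(
            "within-network targets must lie in (0, 1] for the factor model"
        )
    noise_sd = np.sqrt((1.0 - within) / within)
    V = np.asarray(atlas.voxels_per_network, dtype=float)
    atten = np.sqrt(1.0 + noise_sd**2 / V)  # voxel-mean attenuation factor

    R = np.eye(n)
    iu = np.triu_indices(n, k=1)
    R[iu] = target_fc[n:]
    R.T[iu] = target_fc[n:]
    latent = R * np.outer(atten, atten)
    np.fill_diagonal(latent, 1.0)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(latent[off]) > 1.0):
        warnings.warn(
            "between-network targets too strong after attenuation "
            "compensation; clipping latent correlations to +/-1",
            stacklevel=3,
        )
        latent[off] = np.clip(latent[off], -1.0, 1.0)
    vals, vecs = np.linalg.eigh(latent)
    if vals.min() < -repair_tol:
        raise ValueError(
            f"target FC implies an indefinite network covariance "
            f"(eigenvalue {vals.min():.4f}); not repairable"
        )
    if vals.min() < -1e-12:
        warnings.warn(
            "target network covariance not PSD; clipping eigenvalues at 1e-10",
            stacklevel=3,
        )
        vals = np.clip(vals, 1e-10, None)
        latent = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    return latent, noise_sd


def simulate_subject_timeseries(
    atlas: AtlasSpec,
    target_fc: np.ndarray,
    n_frames: int = 200,
    tr_seconds: float = 2.0,
    motion_level: float = 0.02,
    spike_frames: tuple[int, ...] = (),
    spike_amplitude_mm: float = 1.0,
    seed: int = 0,
    repair_tol: float = 0.1,
) -> TimeSeriesBundle:
    """Voxel x frame signals realising ``target_fc``, plus a motion trace.

    Network factors are drawn with the covariance implied by the
    between-network targets (inflated to undo voxel-mean attenuation) and
    voxels add iid noise tuned to the within-network targets, so
    ``compute_fc`` of the output converges to ``target_fc`` as the number of
    frames grows.  Motion is a small random walk in the six realignment
    parameters; at each frame in ``spike_frames`` a translation step of
    ``spike_amplitude_mm`` produces a framewise-displacement spike exactly
    there, and a matching transient artifact is added to the signal.
    """
    if n_frames < 30:
        raise ValueError("n_frames must be >= 30")
    rng = np.random.default_rng(seed)
    latent, noise_sd = _network_cov_from_target(atlas, target_fc, repair_tol)
    n = atlas.n_networks
    L = np.linalg.cholesky(latent + 1e-12 * np.eye(n))
    factors = L @ rng.standard_normal((n, n_frames))

    voxel_net = atlas.voxel_network()
    signal = factors[voxel_net] + noise_sd[voxel_net, None] * rng.standard_normal(
        (voxel_net.shape[0], n_frames)
    )

    steps = rng.normal(0.0, motion_level, size=(n_frames, 6))
    steps[:, 3:] /= 50.0  # rotations in radians, arc-comparable at 50 mm
    steps[0] = 0.0
    for t in spike_frames:
        if not 0 < t < n_frames:
            raise ValueError(f"spike frame {t} out of range")
        steps[t, 0] += spike_amplitude_mm
        signal[:, t] += 3.0 * spike_amplitude_mm  # transient motion artifact
    motion = np.cumsum(steps, axis=0)

    gm = signal.mean(axis=0) * 0.2 + rng.standard_normal(n_frames)
    wm = rng.standard_normal(n_frames)
    csf = rng.standard_normal(n_frames)
    return TimeSeriesBundle(
        signal=signal,
        voxel_network=voxel_net,
        motion=motion,
        tr_seconds=tr_seconds,
        tissue_means=np.vstack([gm, wm, csf]),
    )


# ----------------------------------------------------------------------
# learning curves


def max_attainable_dprime(n_targets: int, n_nontargets: int) -> float:
    """Largest |d'| representable under the 1/(2N) extreme-rate correction."""
    return float(
        norm.ppf(1 - 1 / (2 * n_targets)) - norm.ppf(1 / (2 * n_nontargets))
    )


def simulate_learning_curves(
    plateaus: np.ndarray,
    speeds: np.ndarray,
    n_sessions: int = 25,
    trials_per_session: int = 60,
    noise_sd: float = 0.2,
    seed: int = 0,
    trial_level: bool = False,
    target_fraction: float = 0.25,
) -> list[LearningCurve] | tuple[list[LearningCurve], list[np.ndarray]]:
    """Per-subject d-prime learning curves y_x = a - b/x + noise.

    With ``trial_level=True`` each session's d' is additionally realised as
    binomial hit / false-alarm counts in a ``trials_per_session``-trial
    session with ``target_fraction`` targets, and the returned curves carry
    the realised (binomially noisy) d' values; the count arrays
    (sessions x [hits, misses, FA, CR]) are returned alongside.
    """
    plateaus = np.atleast_1d(np.asarray(plateaus, dtype=float))
    speeds = np.atleast_1d(np.asarray(speeds, dtype=float))
    if plateaus.shape != speeds.shape:
        raise ValueError("plateaus and speeds must have equal length")
    if n_sessions < 3:
        raise ValueError("n_sessions must be >= 3")
    if np.any(speeds < 0):
        raise ValueError("learning-speed parameters must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_sessions + 1, dtype=float)
    n_t = max(1, round(trials_per_session * target_fraction))
    n_n = trials_per_session - n_t
    d_max = max_attainable_dprime(n_t, n_n)

    curves: list[LearningCurve] = []
    counts_all: list[np.ndarray] = []
    for a, b in zip(plateaus, speeds):
        y = a - b / x + rng.normal(0, noise_sd, size=n_sessions)
        if trial_level:
            if np.any(np.abs(a - b / x) > d_max):
                warnings.warn(
                    f"curve (a={a:g}, b={b:g}) exceeds the attainable d' range "
                    f"+/-{d_max:.2f} for this trial design; clipping",
                    stacklevel=2,
                )
            yc = np.clip(y, -d_max, d_max)
            hr = norm.cdf(yc / 2.0)
            fr = norm.cdf(-yc / 2.0)
            hits = rng.binomial(n_t, hr)
            fas = rng.binomial(n_n, fr)
            counts = np.column_stack([hits, n_t - hits, fas, n_n - fas])
            counts_all.append(counts)
            from .behavior import session_dprimes

            y = session_dprimes(counts)
        curves.append(LearningCurve(sessions=x.copy(), dprime=y))
    if trial_level:
        return curves, counts_all
    return curves
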