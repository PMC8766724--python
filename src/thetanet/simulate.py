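"""Synthetic working-memory EEG cohorts with known ground truth.

Simulated subjects come in three groups mirroring a control / patient /
impaired-patient design (labels ``Con``, ``TLE-N``, ``TLE-WM``). Each
subject's EEG is a stable MVAR process:

* every channel carries an oscillatory AR(2) resonance whose peak
  frequency lies inside the theta band (4-8 Hz), so theta is the
  prominent band at rest and during the task;
* during task (encoding) segments, a frontal hub channel (default Fz)
  drives the other frontal and the occipital channels through lag-1
  cross-terms of strength ``coupling_gain`` — a directed, frontal-source
  network that DTF analysis should recover;
* in the impaired group the hub-outflow coefficients are multiplied by
  ``impairment_factor`` (reduced frontal theta outflow);
* a per-subject latent scalar scales frontal task-theta gain and shifts
  behavior, so frontal theta task-minus-rest power and reaction time are
  negatively correlated across subjects.

Because the hub coupling is unidirectional, the coefficient spectrum is
that of the diagonal AR(2) blocks and stability is guaranteed by the pole
radius; a spectral-radius check is still run on every emitted tensor.

Behavior is emitted per trial: correctness is Bernoulli with probability
increasing in the latent scalar (logistic link), reaction time is normal
with mean decreasing in the latent scalar; the impaired group receives an
additional RT shift (in units of the trial RT standard deviation) and an
accuracy deficit so that the 1.5-SD phenotyping rule flags them with high
probability. RT is recorded for correct trials only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import companion_spectral_radius
from .io import (
    Recording,
    write_behavior,
    write_events,
    write_recording_delimited,
    write_recording_edf,
)
from .montage import MONTAGE_34, REDUCED_16, default_region_map

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "simulate_mvar_eeg",
    "build_cohort_generator",
    "simulate_behavior",
    "generate_cohort",
    "write_cohort",
    "GROUP_LABELS",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = ("Con", "TLE-N", "TLE-WM")

def _mvar_loop_py(coeffs_t, noise):
    """Time-major MVAR recursion: x[t] = noise[t] + Σ_r x[t-1-r] @ A_r.

    ``coeffs_t`` holds the transposed lag matrices so the inner product
    runs over contiguous memory; the loop is written allocation-free so
    the JIT-compiled version stays close to the raw flop cost.
    """
    p = coeffs_t.shape[0]
    n, k = noise.shape
    x = noise.copy()
    for t in range(p, n):
        for r in range(p):
            a = coeffs_t[r]
            xl = x[t - 1 - r]
            for i in range(k):
                s = 0.0
                for j in range(k):
                    s += xl[j] * a[j, i]
                x[t, i] += s
    return x


try:  # pragma: no cover - exercised implicitly
    import numba as _numba

    _mvar_loop = _numba.njit(cache=False)(_mvar_loop_py)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _mvar_loop = _mvar_loop_py
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and generator parameters for one synthetic cohort.

    Defaults are a desk-scale profile (fs=256 Hz, 60 s rest); the clinical
    acquisition this emulates ran at 1,024 Hz with a 5-minute eyes-closed
    baseline, available by overriding ``fs`` and ``rest_duration``.
    """

    n_per_group: int = 20
    fs: float = 256.0
    n_channels: int = 34
    rest_duration: float = 60.0          # seconds of eyes-closed baseline
    n_trials: int = 60                   # six blocks x ten trials
    encoding_duration: float = 4.039     # 4 pictures x 1 s + 3 x 0.013 s gaps
    mvar_order: int = 2
    coupling_gain: float = 0.01          # hub-outflow lag-1 coefficient
    impairment_factor: float = 0.5       # multiplies hub outflow, impaired group
    behavior_link: float = 0.6           # latent-factor loading on RT/ACC
    rt_mean_ms: float = 700.0
    rt_sd_ms: float = 150.0
    acc_base: float = 0.9
    seed: int = 0
    # secondary generator knobs
    hub_channel: str = "Fz"
    theta_hz: float = 6.0                # resonance centre
    theta_jitter_hz: float = 0.5         # per-channel resonance jitter
    pole_radius: float = 0.96
    background_gain: float = 0.03        # sd of random pairwise couplings
    background_jitter: float = 0.6       # lognormal sd of per-subject background
    coupling_jitter: float = 0.15        # lognormal sd of per-subject hub gain
    innovation_highpass: bool = False    # optional first-difference shaping
    task_theta_boost: float = 0.5        # frontal innovation gain during task
    latent_gain: float = 0.5             # latent scaling of the task boost
    latent_impaired_shift: float = -1.0  # latent mean shift, impaired group
    rt_impaired_shift_sd: float = 3.0    # x rt_sd_ms, impaired group
    acc_impaired_logit: float = 1.5      # logit-scale ACC deficit, impaired
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.impairment_factor <= 1:
            raise ValueError("impairment_factor must lie in (0, 1]")
        if not 0 < self.acc_base <= 1:
            raise ValueError("acc_base must lie in (0, 1]")
        for name in ("n_per_group", "n_trials", "mvar_order", "n_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fs", "rest_duration", "encoding_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.pole_radius < 1:
            raise ValueError("pole_radius must lie in (0, 1)")
        if self.channels is None:
            if self.n_channels == len(MONTAGE_34):
                object.__setattr__(self, "channels", MONTAGE_34)
            elif self.n_channels == len(REDUCED_16):
                object.__setattr__(self, "channels", REDUCED_16)
            else:
                raise ValueError(
                    "n_channels must be 34 (full montage) or 16 (reduced); "
                    "pass channels= explicitly for other layouts"
                )
        else:
            object.__setattr__(self, "channels", tuple(self.channels))
            object.__setattr__(self, "n_channels", len(self.channels))
        if self.hub_channel not in self.channels:
            raise ValueError(f"hub channel {self.hub_channel!r} not in montage")

    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.fs))

    @property
    def encoding_samples(self) -> int:
        return int(round(self.encoding_duration * self.fs))


@dataclass(frozen=True)
class GroundTruth:
    """Everything downstream recovery tests may score against."""

    config: SimulationConfig
    subjects: tuple[str, ...]
    group_labels: dict[str, str]
    impaired_flags: dict[str, bool]
    latent_theta: dict[str, float]
    coupling: dict[str, dict[str, np.ndarray]]   # subject -> {rest, task}
    noise_scales: dict[str, dict[str, np.ndarray]]
    hub_gains: dict[str, float]                  # pre-impairment outflow gain
    hub_channel: str
    subject_seeds: dict[str, int]

    def __post_init__(self) -> None:
        if sorted(self.subjects) != sorted(self.group_labels):
            raise ValueError("every subject must appear exactly once in group_labels")
        for s, flag in self.impaired_flags.items():
            if flag and self.group_labels[s] != "TLE-WM":
                raise ValueError(f"impaired flag set for non-impaired subject {s}")


@dataclass(frozen=True)
class Cohort:
    """In-memory cohort: ground truth plus per-subject data products."""

    ground_truth: GroundTruth
    recordings: dict[str, Recording]
    events: dict[str, pd.DataFrame]
    behavior: dict[str, pd.DataFrame]


# --------------------------------------------------------------------------
# Core simulator
# --------------------------------------------------------------------------

def simulate_mvar_eeg(
    coeffs: np.ndarray,
    noise_scale: np.ndarray | float,
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator,
    channel_labels: tuple[str, ...] | None = None,
    burn_in: int | None = None,
    subject_id: str = "",
    innovation_filter: np.ndarray | None = None,
) -> Recording:
    """Simulate a stable MVAR process and return it as a Recording.

    ``coeffs`` has shape (order, k, k); ``noise_scale`` gives per-channel
    innovation standard deviations. The first ``burn_in`` samples (default
    10 x order) are generated and discarded. Identical seeds give
    bit-identical output.

    ``innovation_filter``, when given, is an FIR taps vector applied to
    each channel's innovation stream (identically per channel). Because a
    common per-channel filter multiplies every row of the transfer matrix
    by the same scalar gain, it shapes the power spectrum without changing
    the process's directed-transfer-function ground truth.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
        raise ValueError("coeffs must have shape (order, k, k)")
    if not np.isfinite(coeffs).all():
        raise ValueError("coefficients contain non-finite values")
    p, k, _ = coeffs.shape
    if n_samples <= 10 * p:
        raise ValueError("n_samples must exceed 10 x order")
    radius = companion_spectral_radius(coeffs)
    if radius >= 1:
        raise ValueError(
            f"unstable MVAR coefficients (companion spectral radius {radius:.4f})"
        )
    scale = np.broadcast_to(np.asarray(noise_scale, dtype=float), (k,)).copy()
    if not np.isfinite(scale).all() or np.any(scale < 0):
        raise ValueError("noise_scale must be finite and non-negative")
    if burn_in is None:
        burn_in = 10 * p
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noise = rng.standard_normal((n_samples + burn_in, k)) * scale[None, :]
    if innovation_filter is not None:
        from scipy.signal import lfilter

        noise = lfilter(np.asarray(innovation_filter, dtype=float), [1.0], noise, axis=0)
    coeffs_t = np.ascontiguousarray(coeffs.transpose(0, 2, 1))
    x = _mvar_loop(coeffs_t, noise).T
    if channel_labels is None:
        channel_labels = tuple(f"ch{i + 1}" for i in range(k))
    return Recording(
        data=x[:, burn_in:],
        fs=fs,
        channel_labels=channel_labels,
        subject_id=subject_id,
    )


# --------------------------------------------------------------------------
# Cohort construction
# --------------------------------------------------------------------------

def _diagonal_ar2(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Order-2 tensor with theta-resonant AR(2) poles on the diagonal."""
    k = config.n_channels
    f0 = config.theta_hz + rng.uniform(
        -config.theta_jitter_hz, config.theta_jitter_hz, size=k
    )
    r = config.pole_radius
    theta = 2 * np.pi * f0 / config.fs
    coeffs = np.zeros((max(config.mvar_order, 2), k, k))
    coeffs[0][np.diag_indices(k)] = 2 * r * np.cos(theta)
    coeffs[1][np.diag_indices(k)] = -(r ** 2)
    return coeffs


def _lag1(matrix: np.ndarray, like: np.ndarray) -> np.ndarray:
    """Embed a k x k lag-1 coupling matrix into a zero tensor shaped like
    ``like`` (order, k, k)."""
    out = np.zeros_like(like)
    out[0] = matrix
    return out


def _hub_targets(config: SimulationConfig) -> list[int]:
    """Indices of channels receiving hub outflow: frontal + occipital."""
    regions = default_region_map().restricted(config.channels)
    targets = [
        c
        for c in config.channels
        if regions.region_of(c) in ("F", "O") and c != config.hub_channel
    ]
    return [config.channels.index(c) for c in targets]


def build_cohort_generator(
    config: SimulationConfig,
    groups: tuple[str, ...] = GROUP_LABELS,
) -> GroundTruth:
    """Construct per-subject generator tensors and latent factors.

    Rest tensors contain the theta-resonant diagonal plus weak random
    pairwise background couplings (group-independent, shared between rest
    and task segments — the anatomical backbone every real cohort has).
    Task (encoding) tensors add lag-1 outflow from the hub channel to the
    frontal and occipital targets, scaled by a per-subject hub gain
    (``coupling_gain`` with lognormal jitter) and — for the impaired group
    — additionally by ``impairment_factor``. The per-subject latent scalar
    sets the frontal innovation gain during task segments.
    """
    if not set(groups) <= set(GROUP_LABELS):
        raise ValueError(f"groups must be a subset of {GROUP_LABELS}")
    root = np.random.SeedSequence(config.seed)
    hub_idx = config.channels.index(config.hub_channel)
    targets = _hub_targets(config)
    frontal = [
        config.channels.index(c)
        for c in config.channels
        if default_region_map().region_of(c) == "F"
    ]

    subjects: list[str] = []
    group_labels: dict[str, str] = {}
    impaired: dict[str, bool] = {}
    latent: dict[str, float] = {}
    coupling: dict[str, dict[str, np.ndarray]] = {}
    noise_scales: dict[str, dict[str, np.ndarray]] = {}
    hub_gains: dict[str, float] = {}
    subject_seeds: dict[str, int] = {}

    prefixes = {"Con": "con", "TLE-N": "tlen", "TLE-WM": "tlewm"}
    children = root.spawn(len(groups) * config.n_per_group)
    idx = 0
    for group in groups:
        for j in range(config.n_per_group):
            sid = f"{prefixes[group]}{j + 1:02d}"
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            is_impaired = group == "TLE-WM"

            diag = _diagonal_ar2(config, rng)
            k = config.n_channels
            bg_scale = config.background_gain * float(
                np.exp(rng.normal(0.0, config.background_jitter))
            )
            bg = rng.normal(0.0, bg_scale, size=(k, k))
            np.fill_diagonal(bg, 0.0)
            hub_gain = config.coupling_gain * float(
                np.exp(rng.normal(0.0, config.coupling_jitter))
            )
            hub_vec = np.zeros((k, k))
            hub_vec[targets, hub_idx] = hub_gain
            # keep a stability margin by shrinking the background (never the
            # hub outflow, whose scaling is the studied effect); margin is
            # checked against the full (unimpaired) hub gain so construction
            # is identical across groups
            while (
                companion_spectral_radius(diag + _lag1(bg + hub_vec, diag)) >= 0.985
                or companion_spectral_radius(diag + _lag1(bg, diag)) >= 0.985
            ):
                bg *= 0.8
            rest = diag + _lag1(bg, diag)
            task = rest.copy()
            gain = hub_gain * (config.impairment_factor if is_impaired else 1.0)
            task[0, targets, hub_idx] = rest[0, targets, hub_idx] + gain

            z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            if is_impaired:
                z += config.latent_impaired_shift
            boost = config.task_theta_boost * (1.0 + config.latent_gain * z)
            boost = max(boost, 0.0)
            rest_scale = np.ones(config.n_channels)
            task_scale = np.ones(config.n_channels)
            task_scale[frontal] = 1.0 + boost

            for name, tensor in (("rest", rest), ("task", task)):
                radius = companion_spectral_radius(tensor)
                if radius >= 1:
                    raise ValueError(
                        f"unstable {name} coefficients for subject {sid} "
                        f"(spectral radius {radius:.4f})"
                    )

            subjects.append(sid)
            group_labels[sid] = group
            impaired[sid] = is_impaired
            latent[sid] = z
            coupling[sid] = {"rest": rest, "task": task}
            noise_scales[sid] = {"rest": rest_scale, "task": task_scale}
            hub_gains[sid] = hub_gain
            subject_seeds[sid] = int(child.generate_state(1)[0] % (2 ** 31))

    return GroundTruth(
        config=config,
        subjects=tuple(subjects),
        group_labels=group_labels,
        impaired_flags=impaired,
        latent_theta=latent,
        coupling=coupling,
        noise_scales=noise_scales,
        hub_gains=hub_gains,
        hub_channel=config.hub_channel,
        subject_seeds=subject_seeds,
    )


def simulate_subject_recording(
    ground_truth: GroundTruth, subject: str
) -> tuple[Recording, pd.DataFrame]:
    """Continuous recording (rest baseline + concatenated encoding epochs)
    and the matching events table for one subject.

    Only encoding-phase samples are synthesized for the task portion (cue,
    maintenance and retrieval segments are never analyzed); the events
    table accordingly lists encoding rows only.
    """
    config = ground_truth.config
    seed = np.random.SeedSequence(
        [ground_truth.subject_seeds[subject], 7]
    )
    rng = np.random.default_rng(seed)
    burn = max(10 * config.mvar_order, 512)
    hp = np.array([1.0, -1.0]) if config.innovation_highpass else None
    rest = simulate_mvar_eeg(
        ground_truth.coupling[subject]["rest"],
        ground_truth.noise_scales[subject]["rest"],
        config.rest_samples,
        config.fs,
        rng,
        channel_labels=config.channels,
        burn_in=burn,
        subject_id=subject,
        innovation_filter=hp,
    )
    n_task = config.n_trials * config.encoding_samples
    task = simulate_mvar_eeg(
        ground_truth.coupling[subject]["task"],
        ground_truth.noise_scales[subject]["task"],
        n_task,
        config.fs,
        rng,
        channel_labels=config.channels,
        burn_in=burn,
        subject_id=subject,
        innovation_filter=hp,
    )
    data = np.concatenate([rest.data, task.data], axis=1)
    rec = Recording(
        data=data, fs=config.fs, channel_labels=config.channels, subject_id=subject
    )
    onsets = config.rest_samples + np.arange(config.n_trials) * config.encoding_samples
    events = pd.DataFrame(
        {
            "trial": np.arange(1, config.n_trials + 1),
            "phase": "encoding",
            "onset_sample": onsets,
            "duration_samples": config.encoding_samples,
        }
    )
    return rec, events


def simulate_behavior(
    ground_truth: GroundTruth,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-subject trial tables (trial, correct, rt_ms).

    RT is drawn only for correct trials (incorrect trials carry NaN).
    ``seed`` defaults to a behavior substream of the cohort's root seed.
    """
    config = config or ground_truth.config
    root = np.random.SeedSequence([config.seed if seed is None else seed, 11])
    out: dict[str, pd.DataFrame] = {}
    for subject, child in zip(
        ground_truth.subjects, root.spawn(len(ground_truth.subjects))
    ):
        rng = np.random.default_rng(child)
        z = ground_truth.latent_theta[subject]
        impaired = ground_truth.impaired_flags[subject]

        logit = np.log(config.acc_base / (1 - config.acc_base)) if config.acc_base < 1 else 6.0
        logit += config.behavior_link * z
        if impaired:
            logit -= config.acc_impaired_logit
        p = 1.0 / (1.0 + np.exp(-logit))
        if not 0 < p < 1:
            warnings.warn(
                f"accuracy probability clipped for subject {subject}"
            )
            p = float(np.clip(p, 1e-3, 1 - 1e-3))
        correct = rng.random(config.n_trials) < p

        mean_rt = config.rt_mean_ms - config.behavior_link * z * config.rt_sd_ms
        if impaired:
            mean_rt += config.rt_impaired_shift_sd * config.rt_sd_ms
        rt = rng.normal(mean_rt, config.rt_sd_ms, size=config.n_trials)
        rt = np.clip(rt, 150.0, None)  # physiological floor
        rt[~correct] = np.nan
        out[subject] = pd.DataFrame(
            {
                "trial": np.arange(1, config.n_trials + 1),
                "correct": correct,
                "rt_ms": rt,
            }
        )
    return out


def generate_cohort(
    config: SimulationConfig, groups: tuple[str, ...] = GROUP_LABELS
) -> Cohort:
    """Ground truth, recordings, events and behavior for a full cohort."""
    gt = build_cohort_generator(config, groups=groups)
    recordings: dict[str, Recording] = {}
    events: dict[str, pd.DataFrame] = {}
    for subject in gt.subjects:
        rec, ev = simulate_subject_recording(gt, subject)
        recordings[subject] = rec
        events[subject] = ev
    behavior = simulate_behavior(gt)
    return Cohort(
        ground_truth=gt, recordings=recordings, events=events, behavior=behavior
    )


# --------------------------------------------------------------------------
# On-disk cohorts
# --------------------------------------------------------------------------

def write_cohort(
    cohort: Cohort,
    out_dir: str | Path,
    eeg_format: str = "csv",
    overwrite: bool = False,
) -> Path:
    """Write a cohort to ``out_dir`` and return the manifest path.

    Layout: ``<out_dir>/<subject>/eeg.{csv|edf}``, ``events.tsv``,
    ``behavior.tsv`` plus a top-level ``cohort_manifest.json``. Refuses a
    non-empty target directory unless ``overwrite`` is set. Delimited
    output is byte-reproducible for a fixed config.
    """
    if eeg_format not in ("csv", "edf"):
        raise ValueError("eeg_format must be 'csv' or 'edf'")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out_dir} is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gt = cohort.ground_truth
    for subject in gt.subjects:
        sdir = out_dir / subject
        sdir.mkdir()
        rec = cohort.recordings[subject]
        if eeg_format == "csv":
            write_recording_delimited(rec, sdir / "eeg.csv")
        else:
            write_recording_edf(rec, sdir / "eeg.edf")
        write_events(cohort.events[subject], sdir / "events.tsv")
        write_behavior(cohort.behavior[subject], sdir / "behavior.tsv")

    config_echo = dataclasses.asdict(gt.config)
    config_echo["channels"] = list(gt.config.channels)
    manifest = {
        "subjects": list(gt.subjects),
        "group_labels": gt.group_labels,
        "impaired_flags": gt.impaired_flags,
        "latent_theta": gt.latent_theta,
        "subject_seeds": gt.subject_seeds,
        "hub_channel": gt.hub_channel,
        "eeg_format": eeg_format,
        "fs": gt.config.fs,
        "config": config_echo,
    }
    manifest_path = out_dir / "cohort_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
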