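"""Synthetic data generators and the fall-detection demo pipeline.

Two generators feed the test and benchmark harnesses:

* :func:`make_classification_data` builds high-dimensional, few-sample
  classification matrices with a known ground truth — class-conditionally
  shifted Gaussian *informative* columns, *redundant* columns that are noisy
  linear mixes of the informative ones, and class-independent *noise*
  columns — emulating the microarray-style benchmarks wrapper selectors are
  usually judged on.

* :func:`make_imu_recording` synthesizes 10 s, 20 Hz, 9-channel inertial
  recordings (3-axis acceleration in g, angular velocity in deg/s, and
  pitch/yaw/roll in degrees) for 8 activities of daily living and 6 fall
  types.  ADLs are band-limited periodic motion around 1 g vertical; falls
  are a gait prefix, a short high-magnitude impact transient, and a
  sustained post-impact orientation change.

:func:`extract_features` computes 27 features per channel (13 time-domain,
6 frequency-domain, 8 wavelet-packet sub-band energies) for a 243-wide
vector, and :func:`fall_pipeline` runs wrapper selection with an SVM fitness
and reports the fall/ADL confusion matrix, F1 and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_selection import FitnessSpec, FSResult, select_features
from .mswoa import MSWOAConfig

__all__ = [
    "SyntheticSpec",
    "IMURecording",
    "ConfusionCounts",
    "ADL_ACTIVITIES",
    "FALL_ACTIVITIES",
    "ACTIVITIES",
    "CHANNEL_NAMES",
    "FEATURE_NAMES",
    "make_classification_data",
    "make_imu_recording",
    "make_imu_dataset",
    "extract_features",
    "f1_score",
    "fall_pipeline",
]

SAMPLE_RATE = 20.0  # Hz
N_SAMPLES = 200  # 10 s at 20 Hz

CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z",
                 "pitch", "yaw", "roll")

# sensor saturation limits: accel +/-16 g, gyro +/-2000 deg/s,
# pitch +/-90 deg, yaw/roll +/-180 deg
_CHANNEL_LIMITS = ((16.0,) * 3 + (2000.0,) * 3 + (90.0, 180.0, 180.0))

ADL_ACTIVITIES = (
    "walking_slowly",
    "jogging",
    "sit_down_stand_up",
    "bending",
    "squat_stand",
    "lie_down_stand_up",
    "stairs",
    "mixed_adl",
)
FALL_ACTIVITIES = (
    "fall_forward_walking",
    "fall_backward_walking",
    "fall_left_walking",
    "fall_right_walking",
    "fall_vertical_walking",
    "fall_jogging",
)
ACTIVITIES = ADL_ACTIVITIES + FALL_ACTIVITIES


@dataclass
class SyntheticSpec:
    """Recipe for a classification matrix with known informative features."""

    n_samples: int = 200
    n_features: int = 30
    n_informative: int = 3
    n_redundant: int = 0
    effect_size: float = 2.5  # class-mean separation in within-class SDs
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("informative + redundant features exceed n_features")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


def make_classification_data(spec: SyntheticSpec):
    """Generate ``(X, y, informative_mask)`` per the spec, seed-deterministic.

    Informative columns are unit-variance Gaussians whose class means differ
    by ``effect_size``; redundant columns are random linear combinations of
    the informative block plus 20% noise; the rest is pure noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    n_pos = int(round(n * spec.class_balance))
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(y)
    x = rng.standard_normal((n, d))
    info = np.arange(spec.n_informative)
    x[:, info] += spec.effect_size * y[:, None]
    if spec.n_redundant:
        red = np.arange(spec.n_informative, spec.n_informative + spec.n_redundant)
        coef = rng.standard_normal((spec.n_informative, spec.n_redundant))
        x[:, red] = x[:, info] @ coef + 0.2 * rng.standard_normal((n, spec.n_redundant))
    mask = np.zeros(d, bool)
    mask[info] = True
    return x, y, mask


# ---------------------------------------------------------------------------
# IMU recordings
# ---------------------------------------------------------------------------

@dataclass
class IMURecording:
    """One 9-channel, 200-sample inertial recording with its activity label."""

    channels: np.ndarray  # 9 x 200
    label: str
    sample_rate: float = SAMPLE_RATE

    @property
    def is_fall(self) -> bool:
        return self.label in FALL_ACTIVITIES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.channels.T, columns=list(CHANNEL_NAMES))

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _gait(t: np.ndarray, freq: float, amp: float, rng: np.random.Generator):
    """Band-limited periodic gait accelerations around 1 g vertical."""
    phase = rng.uniform(0, 2 * np.pi)
    az = 1.0 + amp * np.sin(2 * np.pi * freq * t + phase) \
        + 0.3 * amp * np.sin(2 * np.pi * 2 * freq * t + 2 * phase)
    ax = 0.5 * amp * np.sin(2 * np.pi * freq * t + phase + 0.7)
    ay = 0.4 * amp * np.cos(2 * np.pi * freq * t + phase)
    return ax, ay, az


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    z = np.clip((t - t0) / width, 0.0, 1.0)
    return z * z * (3 - 2 * z)


def make_imu_recording(activity: str, seed: int = 0) -> IMURecording:
    """Synthesize one recording of the given activity; seed-deterministic.

    ADLs combine a motion template (gait, slow posture transitions) with
    sensor noise.  Falls share the gait prefix of the matching ADL, then an
    impact transient (multi-g acceleration spike, several-hundred-deg/s
    angular-velocity burst) followed by a sustained pitch/roll change whose
    sign encodes the fall direction.  Channels are clipped to the sensor
    ranges.
    """
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    rng = np.random.default_rng(np.random.SeedSequence([hash(activity) & 0x7FFFFFFF, seed]))
    t = np.arange(N_SAMPLES) / SAMPLE_RATE
    ch = np.zeros((9, N_SAMPLES))
    ax = ay = az = np.zeros(N_SAMPLES)
    gx = gy = gz = np.zeros(N_SAMPLES)
    pitch = np.zeros(N_SAMPLES)
    yaw = rng.uniform(-20, 20) * np.ones(N_SAMPLES)
    roll = np.zeros(N_SAMPLES)

    if activity == "walking_slowly":
        ax, ay, az = _gait(t, rng.uniform(1.2, 1.8), 0.3, rng)
        pitch = 5.0 * np.sin(2 * np.pi * 1.5 * t)
        gy = 25.0 * np.sin(2 * np.pi * 1.5 * t + 1.0)
    elif activity == "jogging":
        ax, ay, az = _gait(t, rng.uniform(2.2, 2.8), 0.8, rng)
        pitch = 8.0 * np.sin(2 * np.pi * 2.5 * t)
        gy = 60.0 * np.sin(2 * np.pi * 2.5 * t + 1.0)
    elif activity == "sit_down_stand_up":
        cyc = _smoothstep(t, 2.0, 1.5) - _smoothstep(t, 6.0, 1.5)
        pitch = 20.0 * cyc
        az = 1.0 - 0.25 * np.gradient(cyc, t)
        gy = 15.0 * np.gradient(cyc, t)
    elif activity == "bending":
        cyc = _smoothstep(t, 2.0, 2.0) - _smoothstep(t, 6.5, 2.0)
        pitch = 60.0 * cyc
        az = 1.0 - 0.3 * cyc
        gy = 30.0 * np.gradient(cyc, t)
    elif activity == "squat_stand":
        cyc = _smoothstep(t, 2.0, 1.2) - _smoothstep(t, 6.0, 1.2)
        pitch = 25.0 * cyc
        az = 1.0 - 0.4 * np.gradient(cyc, t)
        gy = 20.0 * np.gradient(cyc, t)
    elif activity == "lie_down_stand_up":
        cyc = _smoothstep(t, 2.0, 2.0) - _smoothstep(t, 7.0, 2.0)
        pitch = 75.0 * cyc
        roll = 20.0 * cyc
        az = 1.0 - 0.8 * cyc
        gy = 40.0 * np.gradient(cyc, t)
    elif activity == "stairs":
        ax, ay, az = _gait(t, rng.uniform(1.0, 1.4), 0.5, rng)
        pitch = 10.0 + 6.0 * np.sin(2 * np.pi * 1.2 * t)
        gy = 35.0 * np.sin(2 * np.pi * 1.2 * t)
    elif activity == "mixed_adl":
        ax, ay, az = _gait(t, 1.5, 0.3, rng)
        cyc = _smoothstep(t, 4.0, 1.0) - _smoothstep(t, 7.0, 1.0)
        pitch = 5.0 * np.sin(2 * np.pi * 1.5 * t) + 25.0 * cyc
        gy = 25.0 * np.sin(2 * np.pi * 1.5 * t) + 20.0 * np.gradient(cyc, t)
    else:  # falls
        prefix_freq, prefix_amp = (2.5, 0.8) if activity == "fall_jogging" else (1.5, 0.3)
        ax, ay, az = _gait(t, prefix_freq, prefix_amp, rng)
        t_imp = rng.uniform(3.5, 6.0)
        imp = np.exp(-0.5 * ((t - t_imp) / 0.08) ** 2)  # ~160 ms impact burst
        spike = rng.uniform(4.0, 8.0)
        after = _smoothstep(t, t_imp, 0.5)
        # post-impact the subject is on the ground: gait dies out
        ax = ax * (1 - after)
        ay = ay * (1 - after)
        az = az * (1 - after) + spike * imp + 0.15 * after
        gyro_burst = rng.uniform(300.0, 800.0)
        direction = {
            "fall_forward_walking": (70.0, 0.0),
            "fall_backward_walking": (-70.0, 0.0),
            "fall_left_walking": (0.0, -70.0),
            "fall_right_walking": (0.0, 70.0),
            "fall_vertical_walking": (40.0, 20.0),
            "fall_jogging": (70.0, 10.0),
        }[activity]
        pitch = direction[0] * after + 5.0 * np.sin(2 * np.pi * prefix_freq * t) * (1 - after)
        roll = direction[1] * after
        gy = gyro_burst * imp * np.sign(direction[0] if direction[0] else 1.0) \
            + 25.0 * np.sin(2 * np.pi * prefix_freq * t) * (1 - after)
        gx = 0.6 * gyro_burst * imp * np.sign(direction[1] if direction[1] else 0.3)

    ch[0], ch[1], ch[2] = ax, ay, az
    ch[3], ch[4], ch[5] = gx, gy, gz
    ch[6], ch[7], ch[8] = pitch, yaw, roll
    noise_scale = np.array([0.05, 0.05, 0.05, 3.0, 3.0, 3.0, 0.5, 0.5, 0.5])
    ch += noise_scale[:, None] * rng.standard_normal((9, N_SAMPLES))
    for i, lim in enumerate(_CHANNEL_LIMITS):
        np.clip(ch[i], -lim, lim, out=ch[i])
    return IMURecording(ch, activity)


def make_imu_dataset(n_per_class: int = 5, seed: int = 0,
                     activities=ACTIVITIES) -> list[IMURecording]:
    """A balanced list of recordings, ``n_per_class`` per activity."""
    recs = []
    for activity in activities:
        for r in range(n_per_class):
            recs.append(make_imu_recording(activity, seed=seed * 10_000 + r))
    return recs


# ---------------------------------------------------------------------------
# Feature extraction: 13 time + 6 frequency + 8 wavelet-packet = 27/channel
# ---------------------------------------------------------------------------

_TIME_NAMES = ("mean", "std", "var", "rms", "min", "max", "range", "median",
               "iqr", "skew", "kurtosis", "mad", "zcr")
_FREQ_NAMES = ("spec_energy", "dom_freq", "spec_centroid", "spec_bandwidth",
               "spec_entropy", "mean_freq")
_WPT_NAMES = tuple(f"wpt_band{i}" for i in range(8))
FEATURE_NAMES = tuple(f"{ch}_{name}" for ch in CHANNEL_NAMES
                      for name in _TIME_NAMES + _FREQ_NAMES + _WPT_NAMES)

# orthonormal Daubechies-4 decomposition filters
_DB4_LO = np.array([
    -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
    -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
    0.7148465705525415, 0.23037781330885523])
_DB4_HI = ((-1.0) ** np.arange(8)) * _DB4_LO[::-1]


def _dwt_periodic(x: np.ndarray):
    """One periodized orthogonal DWT level (even-length input)."""
    n = x.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(8)[None, :]) % n
    window = x[idx]
    return window @ _DB4_LO, window @ _DB4_HI


def _wpt_energies(x: np.ndarray, levels: int = 3) -> np.ndarray:
    """Relative energies of the 2^levels leaf sub-bands of a wavelet packet.

    The periodized orthonormal transform preserves energy, so the relative
    energies sum to one by construction (guarded by explicit normalization
    for the all-zero signal).
    """
    bands = [np.asarray(x, float)]
    for _ in range(levels):
        nxt = []
        for band in bands:
            lo, hi = _dwt_periodic(band)
            nxt.extend([lo, hi])
        bands = nxt
    energies = np.array([float(np.sum(b ** 2)) for b in bands])
    total = energies.sum()
    if total == 0.0:
        return np.full(len(bands), 1.0 / len(bands))
    return energies / total


def _time_features(x: np.ndarray) -> list[float]:
    q75, q25 = np.percentile(x, [75, 25])
    centered = x - x.mean()
    zc = float(np.count_nonzero(centered[:-1] * centered[1:] < 0)) / (x.size - 1)
    std = float(x.std())
    if std > 0:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))
    else:
        skew = kurt = 0.0
    return [float(x.mean()), std, float(x.var()),
            float(np.sqrt(np.mean(x ** 2))), float(x.min()), float(x.max()),
            float(x.max() - x.min()), float(np.median(x)), float(q75 - q25),
            skew, kurt, float(np.mean(np.abs(centered))), zc]


def _freq_features(x: np.ndarray, fs: float) -> list[float]:
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mag = spectrum[1:]  # DC carries the offset, not motion content
    f = freqs[1:]
    power = mag ** 2
    total_energy = float(power.sum())
    if total_energy == 0.0:
        return [0.0] * 6
    dom = float(f[np.argmax(mag)])
    centroid = float(np.sum(f * mag) / np.sum(mag))
    bandwidth = float(np.sqrt(np.sum(((f - centroid) ** 2) * mag) / np.sum(mag)))
    p = power / total_energy
    entropy = float(-np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))
                    / np.log(p.size))
    mean_freq = float(np.sum(f * power) / total_energy)
    return [total_energy, dom, centroid, bandwidth, entropy, mean_freq]


def extract_features(recording: IMURecording) -> np.ndarray:
    """27 features per channel, concatenated channel-major: 243 values.

    Per channel: 13 time-domain statistics, 6 magnitude-spectrum
    descriptors, and the 8 relative sub-band energies of a 3-level
    Daubechies-4 wavelet packet.  Deterministic, and permutation-covariant
    in the channels (column names in :data:`FEATURE_NAMES`).
    """
    ch = np.asarray(recording.channels, float)
    if ch.shape != (9, N_SAMPLES):
        raise ValueError(f"expected 9 x {N_SAMPLES} channels, got {ch.shape}")
    feats: list[float] = []
    for sig in ch:
        feats.extend(_time_features(sig))
        feats.extend(_freq_features(sig, recording.sample_rate))
        feats.extend(_wpt_energies(sig).tolist())
    return np.array(feats)


# ---------------------------------------------------------------------------
# Fall-detection demo pipeline
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Binary confusion counts with falls as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.fp + self.tn
        return (self.tp + self.tn) / total if total else 0.0


def f1_score(tp: int, fn: int, fp: int) -> float:
    """F1 with falls positive: ``2 TP / (2 TP + FP + FN)``."""
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class FallPipelineResult:
    confusion: ConfusionCounts
    f1: float
    test_accuracy: float  # percent
    fs_result: FSResult | None = None


def fall_pipeline(recordings: list[IMURecording], algorithm: str = "mswoa",
                  config: MSWOAConfig | None = None, seed: int = 0) -> FallPipelineResult:
    """Feature extraction + wrapper selection + SVM fall/ADL classification.

    Extracts the 243-wide feature vector per recording, selects features
    with the requested optimizer under an RBF-SVM cross-validation fitness
    on the 80% split, then scores the selected subset once on the 20% split
    and reports the confusion counts, F1 and accuracy.
    """
    labels = np.array([1 if r.is_fall else 0 for r in recordings])
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 fall and 2 ADL recordings")
    x = np.vstack([extract_features(r) for r in recordings])
    spec = FitnessSpec(classifier="svm")
    res = select_features(x, labels, algorithm=algorithm, config=config,
                          spec=spec, seed=seed)

    # rebuild the same split to derive the confusion matrix on the test fifth
    from sklearn.model_selection import train_test_split
    x_tr, x_te, y_tr, y_te = train_test_split(x, labels, test_size=0.2,
                                              stratify=labels, random_state=seed)
    from sklearn.svm import SVC
    mask = res.mask
    lo = x_tr[:, mask].min(axis=0)
    span = x_tr[:, mask].max(axis=0) - lo
    span[span == 0.0] = 1.0
    clf = SVC(kernel="rbf")
    clf.fit((x_tr[:, mask] - lo) / span, y_tr)
    pred = clf.predict((x_te[:, mask] - lo) / span)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    tn = int(np.sum((pred == 0) & (y_te == 0)))
    cm = ConfusionCounts(tp, fn, fp, tn)
    return FallPipelineResult(confusion=cm, f1=cm.f1,
                              test_accuracy=100.0 * cm.accuracy, fs_result=res)
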