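"""Synthetic sharp-wave-ripple (SWR) generator with controlled label noise.

The simulator produces ripple-centered intervals (RCIs): 512-sample windows
at 2 kHz (256 ms) holding a Gaussian-modulated sinusoid in the hippocampal
ripple band (120–200 Hz), superimposed on delta (1–3 Hz) and low-gamma
(20–40 Hz) background oscillations plus Gaussian white noise.  Two classes
of ripples are generated — "learning-unaffected" (Class 1) and
"learning-transformed" (Class 2) — distinguished by class-conditional
multipliers on frequency, amplitude and noise level.  A separate step mixes
the classes into before-learning (BL) / after-learning (AL) observed-label
groups at a controlled noise proportion rho, which is the ground-truth
test bed for label-noise correction experiments.

All stochastic quantities described as "normally distributed between a and
b" are drawn from a normal with mean (a+b)/2 and sd (b-a)/6, truncated to
[a, b], so the stated range is covered at +/-3 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import stats

__all__ = [
    "TrueClass",
    "ObservedLabel",
    "SimConfig",
    "ClassSpec",
    "SWRParams",
    "LabeledDataset",
    "CLASS1_SPEC",
    "CLASS2_SPEC",
    "truncated_normal",
    "sample_class_params",
    "synth_ripple",
    "build_rci",
    "generate_dataset",
    "inject_label_noise",
]


class TrueClass(IntEnum):
    """Ground-truth ripple class: unaffected vs transformed by learning."""

    CLASS1 = 0
    CLASS2 = 1


class ObservedLabel(IntEnum):
    """Observed (possibly noisy) session label: before/after learning."""

    BL = 0
    AL = 1


@dataclass(frozen=True)
class SimConfig:
    """Global simulator settings.

    Parameters
    ----------
    sampling_rate : float
        Samples per second; 2000 Hz so a 512-sample RCI spans 256 ms.
    rci_length : int
        Samples per ripple-centered interval.
    base_frequency : float
        Center of the ripple band in Hz; class multipliers scale it.
    base_amplitude : float
        Ripple half-range; the clean ripple spans [-base, +base].
    base_noise_sd : float
        White-noise standard deviation before the class noise multiplier.
    duration_range : (int, int)
        Ripple duration bounds in samples (truncated-normal draw).
    delta_band, gamma_band : (float, float)
        Background oscillation frequency bounds in Hz.
    delta_amplitude, gamma_amplitude : float
        Background sinusoid amplitudes as fractions of ``base_amplitude``.
    envelope_sd_fraction : float
        Gaussian envelope sd as a fraction of the ripple duration.
    dual_noise : bool
        If True, white noise is added both over the ripple span and over the
        whole window; default adds it once over the whole window.
    """

    sampling_rate: float = 2000.0
    rci_length: int = 512
    base_frequency: float = 160.0
    base_amplitude: float = 1.0
    base_noise_sd: float = 0.1
    duration_range: tuple[int, int] = (150, 200)
    delta_band: tuple[float, float] = (1.0, 3.0)
    gamma_band: tuple[float, float] = (20.0, 40.0)
    delta_amplitude: float = 0.3
    gamma_amplitude: float = 0.3
    envelope_sd_fraction: float = 1.0 / 6.0
    dual_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0 or self.rci_length <= 0:
            raise ValueError("sampling_rate and rci_length must be positive")
        lo, hi = self.duration_range
        if not (0 < lo <= hi < self.rci_length):
            raise ValueError("duration_range must lie inside (0, rci_length)")

    @property
    def window_ms(self) -> float:
        return 1000.0 * self.rci_length / self.sampling_rate


def _check_range(name: str, rng_pair: tuple[float, float]) -> None:
    lo, hi = rng_pair
    if lo > hi:
        raise ValueError(f"{name} is inverted: {rng_pair}")
    if lo <= 0:
        raise ValueError(f"{name} must be positive: {rng_pair}")


@dataclass(frozen=True)
class ClassSpec:
    """Class-conditional multiplier ranges for frequency/amplitude/noise."""

    label: TrueClass
    freq_factor_range: tuple[float, float]
    amp_factor_range: tuple[float, float]
    noise_factor_range: tuple[float, float]

    def __post_init__(self):
        _check_range("freq_factor_range", self.freq_factor_range)
        _check_range("amp_factor_range", self.amp_factor_range)
        _check_range("noise_factor_range", self.noise_factor_range)


#: Learning-unaffected ripples: broad frequency/amplitude spread, high noise.
CLASS1_SPEC = ClassSpec(TrueClass.CLASS1, (0.8, 1.2), (0.8, 1.2), (1.0, 1.5))
#: Learning-transformed ripples: faster, tighter, cleaner.
CLASS2_SPEC = ClassSpec(TrueClass.CLASS2, (1.1, 1.3), (0.95, 1.05), (0.5, 1.0))


@dataclass(frozen=True)
class SWRParams:
    """Sampled parameters of one synthetic ripple."""

    frequency: float
    amplitude: float
    duration: int
    noise_sd: float
    delta_freq: float
    gamma_freq: float
    ripple_phase: float = 0.0
    delta_phase: float = 0.0
    gamma_phase: float = 0.0


def truncated_normal(
    bounds: tuple[float, float], rng: np.random.Generator, size=None
):
    """Draw from N(mean=(a+b)/2, sd=(b-a)/6) truncated to [a, b].

    A degenerate range (a == b) returns the constant.
    """
    lo, hi = bounds
    if lo > hi:
        raise ValueError(f"inverted range {bounds}")
    if lo == hi:
        return lo if size is None else np.full(size, lo)
    mean = 0.5 * (lo + hi)
    sd = (hi - lo) / 6.0
    out = stats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, size=size, random_state=rng)
    return float(out) if size is None else out


def sample_class_params(
    spec: ClassSpec, config: SimConfig, rng: np.random.Generator
) -> SWRParams:
    """Sample one ripple's parameters from a class's multiplier ranges."""
    return SWRParams(
        frequency=config.base_frequency * truncated_normal(spec.freq_factor_range, rng),
        amplitude=config.base_amplitude * truncated_normal(spec.amp_factor_range, rng),
        duration=int(round(truncated_normal(config.duration_range, rng))),
        noise_sd=config.base_noise_sd * truncated_normal(spec.noise_factor_range, rng),
        delta_freq=truncated_normal(config.delta_band, rng),
        gamma_freq=truncated_normal(config.gamma_band, rng),
        ripple_phase=rng.uniform(0.0, 2.0 * np.pi),
        delta_phase=rng.uniform(0.0, 2.0 * np.pi),
        gamma_phase=rng.uniform(0.0, 2.0 * np.pi),
    )


def synth_ripple(params: SWRParams, config: SimConfig) -> np.ndarray:
    """Clean Gaussian-modulated sinusoid of length ``params.duration``.

    The envelope is a Gaussian window centered at duration/2 with unit peak,
    so the output is bounded by ``params.amplitude`` in magnitude.
    """
    d = int(params.duration)
    if d < 2:
        raise ValueError("ripple duration must be at least 2 samples")
    t = np.arange(d)
    center = (d - 1) / 2.0
    sd = config.envelope_sd_fraction * d
    env = np.exp(-0.5 * ((t - center) / sd) ** 2)
    carrier = np.sin(
        2.0 * np.pi * params.frequency * t / config.sampling_rate + params.ripple_phase
    )
    return (params.amplitude * env * carrier).astype(np.float32)


def build_rci(
    ripple: np.ndarray,
    params: SWRParams,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Center a ripple in a full window and add background + white noise.

    Delta and gamma sinusoids run over the entire window; Gaussian white
    noise with sd ``params.noise_sd`` is added over the entire window (and
    once more over the ripple span when ``config.dual_noise`` is set).
    """
    n = config.rci_length
    d = len(ripple)
    if d > n:
        raise ValueError(f"ripple of {d} samples exceeds the {n}-sample window")
    start = (n - d) // 2
    out = np.zeros(n, dtype=np.float32)
    out[start : start + d] = ripple

    t = np.arange(n) / config.sampling_rate
    out += (config.delta_amplitude * config.base_amplitude) * np.sin(
        2.0 * np.pi * params.delta_freq * t + params.delta_phase
    ).astype(np.float32)
    out += (config.gamma_amplitude * config.base_amplitude) * np.sin(
        2.0 * np.pi * params.gamma_freq * t + params.gamma_phase
    ).astype(np.float32)
    if params.noise_sd > 0:
        out += rng.normal(0.0, params.noise_sd, n).astype(np.float32)
        if config.dual_noise:
            out[start : start + d] += rng.normal(0.0, params.noise_sd, d).astype(
                np.float32
            )
    return out


@dataclass
class LabeledDataset:
    """RCIs with ground-truth classes and (possibly noisy) observed labels."""

    signals: np.ndarray  # (n, rci_length) float32
    true_class: np.ndarray  # TrueClass codes
    observed_label: np.ndarray  # ObservedLabel codes
    noise_proportion: float
    config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        n = len(self.signals)
        if not (len(self.true_class) == len(self.observed_label) == n):
            raise ValueError("signals and label vectors must align")

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def n_bl(self) -> int:
        return int(np.sum(self.observed_label == ObservedLabel.BL))

    @property
    def n_al(self) -> int:
        return int(np.sum(self.observed_label == ObservedLabel.AL))


def generate_dataset(
    n_per_class: int,
    specs: tuple[ClassSpec, ClassSpec] = (CLASS1_SPEC, CLASS2_SPEC),
    config: SimConfig = SimConfig(),
) -> LabeledDataset:
    """Generate a balanced two-class dataset with noiseless labels (rho=0).

    Class 1 rows receive the BL observed label and Class 2 rows AL, so with
    no injected noise the observed labels equal the true classes.  The whole
    dataset is a pure function of ``(config, specs, n_per_class)`` through
    ``config.seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_total = 2 * n_per_class
    signals = np.empty((n_total, config.rci_length), dtype=np.float32)
    true_class = np.empty(n_total, dtype=np.int64)
    row = 0
    for spec in specs:
        for _ in range(n_per_class):
            params = sample_class_params(spec, config, rng)
            signals[row] = build_rci(synth_ripple(params, config), params, config, rng)
            true_class[row] = int(spec.label)
            row += 1
    observed = np.where(
        true_class == TrueClass.CLASS1, ObservedLabel.BL, ObservedLabel.AL
    ).astype(np.int64)
    return LabeledDataset(signals, true_class, observed, 0.0, config)


def inject_label_noise(
    dataset: LabeledDataset, rho: float, rng: np.random.Generator
) -> LabeledDataset:
    """Mix the classes across the BL/AL groups at proportion ``rho``.

    Exactly ``round(rho * n_per_class)`` Class 1 rows move from BL to AL and
    the same number of Class 2 rows move from AL to BL (uniformly chosen,
    without replacement), so BL holds (1-rho) Class 1 + rho Class 2 and AL
    the mirror image.  Group sizes and true classes are untouched.
    """
    if not 0.0 <= rho <= 0.5:
        raise ValueError("noise proportion must be in [0, 0.5]")
    bl_c1 = np.flatnonzero(
        (dataset.observed_label == ObservedLabel.BL)
        & (dataset.true_class == TrueClass.CLASS1)
    )
    al_c2 = np.flatnonzero(
        (dataset.observed_label == ObservedLabel.AL)
        & (dataset.true_class == TrueClass.CLASS2)
    )
    if dataset.n_bl != dataset.n_al or len(bl_c1) != dataset.n_bl:
        raise ValueError("inject_label_noise expects a balanced, clean dataset")
    k = int(round(rho * len(bl_c1)))
    observed = dataset.observed_label.copy()
    observed[rng.choice(bl_c1, size=k, replace=False)] = ObservedLabel.AL
    observed[rng.choice(al_c2, size=k, replace=False)] = ObservedLabel.BL
    return replace(dataset, observed_label=observed, noise_proportion=float(rho))
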