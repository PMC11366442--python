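"""Synthetic annotated ECG records and pre-segmented beat tables.

The generator exists so that every pipeline stage — annotation reading,
denoising, segmentation, balancing, training, evaluation — is exercisable
without downloading the benchmark databases.  It emulates the statistical
shape of those inputs, not cardiac electrophysiology:

* beat templates are Gaussian-bump composites (P wave, QRS complex, T wave)
  with class-specific QRS width/amplitude and P/T morphology, giving five
  mutually distinguishable morphologies for the N/L/R/A/V vocabulary and a
  Normal/Abnormal pair for the binary one;
* beats are placed at jittered regular intervals (default mean interval
  0.83 s ≈ 72 bpm, jitter ≤ 10%), annotated at the placed template peak;
* interference mirrors the classic ECG noise sources: baseline wander
  (a < 0.5 Hz sinusoid), powerline interference (a 50/60 Hz sinusoid) and
  additive white noise;
* class imbalance defaults to the heavy skew of the real archive
  (~75% normal beats).

Everything is driven by one integer seed; identical configuration ⇒
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BeatAnnotation, BeatDataset, ClassScheme, EcgRecord
from .errors import ConfigurationError
from .io import MITBIH5, PTB2

#: Class mix of the five-class archive (fraction of beats per class).
DEFAULT_PROPORTIONS = {"N": 0.75, "L": 0.08, "R": 0.07, "A": 0.07, "V": 0.03}


@dataclass(frozen=True)
class BeatTemplate:
    """One class's beat morphology: a fixed waveform whose peak is the R-peak."""

    class_label: str
    waveform: np.ndarray
    r_offset: int

    def __post_init__(self) -> None:
        wf = np.asarray(self.waveform, dtype=np.float64)
        object.__setattr__(self, "waveform", wf)
        if wf.ndim != 1 or wf.size == 0:
            raise ValueError("waveform must be a non-empty 1-D array")
        if int(np.argmax(wf)) != self.r_offset:
            raise ValueError("r_offset must be the argmax of the waveform")

    def __len__(self) -> int:
        return self.waveform.size


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator.

    noise_sd, baseline_wander_amplitude, powerline_amplitude are in mV;
    powerline_frequency in Hz (50 or 60 in the wild); mean_rr_s is the mean
    beat-to-beat interval in seconds.
    """

    sampling_rate: float = 360.0
    n_beats: int = 100
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    noise_sd: float = 0.03
    baseline_wander_amplitude: float = 0.1
    baseline_wander_frequency: float = 0.3
    powerline_frequency: float = 60.0
    powerline_amplitude: float = 0.02
    mean_rr_s: float = 0.83
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.n_beats < 1:
            raise ConfigurationError("n_beats must be at least 1")
        fracs = np.array(list(self.class_proportions.values()), dtype=float)
        if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "class_proportions must be nonnegative and sum to 1"
            )
        if not 0 < self.baseline_wander_frequency < 0.5:
            raise ConfigurationError("baseline wander frequency must be in (0, 0.5) Hz")


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _compose_beat(
    fs: float,
    duration_s: float,
    qrs_amp: float,
    qrs_width_s: float,
    p_amp: float,
    t_amp: float,
    q_amp: float,
    s_amp: float,
    notch_amp: float = 0.0,
) -> np.ndarray:
    """P-QRS-T composite of Gaussian bumps; R-peak lands at the center."""
    n = int(round(duration_s * fs))
    t = (np.arange(n) - n // 2) / fs  # seconds relative to R
    wave = qrs_amp * _gauss(t, 0.0, qrs_width_s)
    wave += q_amp * _gauss(t, -1.8 * qrs_width_s - 0.01, 0.01)
    wave += s_amp * _gauss(t, 1.8 * qrs_width_s + 0.01, 0.012)
    wave += p_amp * _gauss(t, -0.17, 0.022)  # P wave ~170 ms before R
    wave += t_amp * _gauss(t, 0.20, 0.05)  # T wave ~200 ms after R
    if notch_amp:
        wave += notch_amp * _gauss(t, 0.045, 0.012)  # R' (rsR' pattern)
    return wave


def default_templates(
    scheme: ClassScheme = MITBIH5,
    sampling_rate: float = 360.0,
    duration_s: float = 0.66,
) -> list[BeatTemplate]:
    """Morphology bank for a class scheme.

    mitbih5: N narrow QRS; L/R wide QRS (R with an R' notch, L with a
    discordant T); A normal-width QRS with an early peaked P; V very wide
    high-amplitude QRS without a P wave and with an inverted T.
    ptb2: the N morphology vs a wide-QRS inverted-T "ischaemic" composite.
    """
    fs = sampling_rate
    shapes = {
        "N": dict(qrs_amp=1.0, qrs_width_s=0.012, p_amp=0.12, t_amp=0.25,
                  q_amp=-0.08, s_amp=-0.12),
        "L": dict(qrs_amp=0.9, qrs_width_s=0.030, p_amp=0.10, t_amp=-0.22,
                  q_amp=-0.02, s_amp=-0.25),
        "R": dict(qrs_amp=0.85, qrs_width_s=0.016, p_amp=0.11, t_amp=0.18,
                  q_amp=-0.05, s_amp=-0.30, notch_amp=0.55),
        "A": dict(qrs_amp=0.95, qrs_width_s=0.012, p_amp=0.30, t_amp=0.22,
                  q_amp=-0.07, s_amp=-0.11),
        "V": dict(qrs_amp=1.45, qrs_width_s=0.045, p_amp=0.0, t_amp=-0.40,
                  q_amp=-0.30, s_amp=-0.35),
        "Normal": dict(qrs_amp=1.0, qrs_width_s=0.012, p_amp=0.12, t_amp=0.25,
                       q_amp=-0.08, s_amp=-0.12),
        "Abnormal": dict(qrs_amp=1.2, qrs_width_s=0.040, p_amp=0.05, t_amp=-0.35,
                         q_amp=-0.25, s_amp=-0.30),
    }
    templates = []
    for label in scheme.classes:
        if label not in shapes:
            raise ConfigurationError(f"no built-in morphology for class {label!r}")
        wave = _compose_beat(fs, duration_s, **shapes[label])
        templates.append(
            BeatTemplate(class_label=label, waveform=wave, r_offset=int(np.argmax(wave)))
        )
    return templates


def allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n beats to classes."""
    labels = list(proportions)
    exact = np.array([proportions[c] * n for c in labels])
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(labels, base.astype(int)))


def _class_sequence(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[str]:
    counts = allocate_counts(config.n_beats, config.class_proportions)
    seq = [label for label, k in counts.items() for _ in range(k)]
    return [seq[i] for i in rng.permutation(len(seq))]


def _interference(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / config.sampling_rate
    out = np.zeros(n)
    if config.baseline_wander_amplitude:
        out += config.baseline_wander_amplitude * np.sin(
            2 * np.pi * config.baseline_wander_frequency * t
            + rng.uniform(0, 2 * np.pi)
        )
    if config.powerline_amplitude:
        out += config.powerline_amplitude * np.sin(
            2 * np.pi * config.powerline_frequency * t + rng.uniform(0, 2 * np.pi)
        )
    if config.noise_sd:
        out += rng.normal(0.0, config.noise_sd, size=n)
    return out


def generate_record(
    config: SyntheticConfig,
    templates: list[BeatTemplate],
    record_id: str = "synthetic",
) -> EcgRecord:
    """Generate one annotated record.

    Beats are placed at jittered regular intervals; each annotation sits at
    the sample where its template's R-peak was placed.  Beats never overlap:
    the configuration is rejected if the interval cannot accommodate the
    longest template plus jitter.
    """
    by_label = {t.class_label: t for t in templates}
    missing = [c for c in config.class_proportions if c not in by_label]
    if missing:
        raise ConfigurationError(f"no template for class(es) {missing}")
    fs = config.sampling_rate
    interval = int(round(config.mean_rr_s * fs))
    max_len = max(len(by_label[c]) for c in config.class_proportions)
    jitter_max = int(0.1 * interval)
    if interval < max_len + 2 * jitter_max:
        raise ConfigurationError(
            f"beat interval {interval} samples cannot hold templates up to "
            f"{max_len} samples without overlap at jitter ±{jitter_max}"
        )
    margin = interval  # keeps full windows inside the record for edge beats
    n_samples = 2 * margin + config.n_beats * interval
    rng = np.random.default_rng(config.seed)
    sequence = _class_sequence(config, rng)
    jitter = rng.integers(-jitter_max, jitter_max + 1, size=config.n_beats)
    signal = np.zeros(n_samples)
    annotations = []
    for k, label in enumerate(sequence):
        tpl = by_label[label]
        center = margin + k * interval + interval // 2 + int(jitter[k])
        start = center - tpl.r_offset
        signal[start : start + len(tpl)] += tpl.waveform
        annotations.append(BeatAnnotation(sample_index=center, symbol=label))
    signal += _interference(config, n_samples, rng)
    return EcgRecord(
        signal=signal, sampling_rate=fs, record_id=record_id, annotations=annotations
    )


def generate_segment_table(
    config: SyntheticConfig,
    templates: list[BeatTemplate],
    window_length: int,
    scheme: ClassScheme | None = None,
) -> BeatDataset:
    """Generate a pre-segmented beat table (one window per row).

    Each row is its class template centered in a ``window_length`` window
    plus the configured interference, emulating the 187-sample segmented
    beat distribution.  Row count equals ``n_beats``.
    """
    by_label = {t.class_label: t for t in templates}
    missing = [c for c in config.class_proportions if c not in by_label]
    if missing:
        raise ConfigurationError(f"no template for class(es) {missing}")
    too_long = [c for c in config.class_proportions if len(by_label[c]) > window_length]
    if too_long:
        raise ConfigurationError(
            f"window_length {window_length} shorter than template(s) for {too_long}"
        )
    if scheme is None:
        scheme = _infer_scheme(list(config.class_proportions))
    rng = np.random.default_rng(config.seed)
    sequence = _class_sequence(config, rng)
    windows = np.zeros((config.n_beats, window_length))
    labels = np.empty(config.n_beats, dtype=np.int64)
    for i, label in enumerate(sequence):
        tpl = by_label[label]
        start = (window_length - len(tpl)) // 2
        windows[i, start : start + len(tpl)] = tpl.waveform
        windows[i] += _interference(config, window_length, rng)
        labels[i] = scheme.label_index(label)
    return BeatDataset(
        windows=windows,
        labels=labels,
        scheme=scheme,
        provenance=[("synthetic-table", i) for i in range(config.n_beats)],
    )


def _infer_scheme(labels: list[str]) -> ClassScheme:
    for known in (MITBIH5, PTB2):
        if set(labels) <= set(known.classes):
            return known
    return ClassScheme(
        name="synthetic", classes=tuple(labels), symbol_map={c: c for c in labels}
    )


def nearest_template_labels(
    windows: np.ndarray, templates: list[BeatTemplate], scheme: ClassScheme
) -> np.ndarray:
    """Nearest-template classifier (sanity oracle for learning tests).

    Assigns each window the class of the template with minimal Euclidean
    distance after centering both in a window-length frame.
    """
    L = windows.shape[1]
    mats = []
    order = []
    for tpl in templates:
        frame = np.zeros(L)
        start = (L - len(tpl)) // 2
        frame[start : start + len(tpl)] = tpl.waveform
        mats.append(frame)
        order.append(scheme.label_index(tpl.class_label))
    proto = np.stack(mats)  # (n_templates, L)
    d2 = ((windows[:, None, :] - proto[None, :, :]) ** 2).sum(axis=2)
    return np.asarray(order)[np.argmin(d2, axis=1)]
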