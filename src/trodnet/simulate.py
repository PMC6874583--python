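"""Synthetic auditory-oddball ERP generator.

This module produces the single-trial data the rest of the pipeline
consumes: pseudo-random 600-tone oddball sequences (82% standards, 6% per
deviant) and baseline-corrected 64-channel epochs sampled at 512 Hz with
the statistical structure the classifier assumes — stereotyped ERP
components (N1, P2, and the deviance-related N2b and P300) embedded in
1/f background activity, alpha-band oscillation, and white sensor noise.

Group structure is injected through an :class:`EffectSpec`: subjects in the
concussed group have selected components attenuated and delayed, emulating
the reduced and slowed N2b/P300 responses reported after mild traumatic
brain injury. Subjects additionally carry their own component gains and
trial-to-trial variability, so that between-subject differences are larger
than within-subject ones — the regime that makes subject-exclusive
cross-validation meaningful.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .montage import N_CHANNELS, gaussian_topography

SFREQ = 512.0
#: samples per epoch: floor(1.200 s x 512 Hz)
N_SAMPLES = 614
#: sample index of stimulus onset; sample k sits at t = (k - ONSET_INDEX)/512 s,
#: so the first sample lies at -199.2 ms and t = 0 falls exactly on the grid.
ONSET_INDEX = 102

#: conditions that are epoched and classified, in the fixed block order
#: used downstream. The intensity deviant appears in tone sequences only.
CONDITIONS = ("standard", "FDev", "DDev")
ALL_TONES = ("standard", "FDev", "DDev", "IDev")

CONTROL = "control"
CONCUSSED = "concussed"


def epoch_times() -> np.ndarray:
    """Time axis in seconds, one entry per sample."""
    return (np.arange(N_SAMPLES) - ONSET_INDEX) / SFREQ


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class ToneSpec:
    frequency_hz: float
    duration_ms: float
    intensity_db: float


@dataclass(frozen=True)
class ParadigmSpec:
    """The multi-deviant oddball design.

    Defaults: 600 tones per run, 82% standards (1000 Hz, 50 ms, 80 dB SPL)
    and 6% each of a frequency deviant (1200 Hz), a duration deviant
    (100 ms) and an intensity deviant (90 dB SPL), presented pseudo-randomly
    with at least ``min_standards_between_deviants`` standards separating
    consecutive deviants.
    """

    n_tones: int = 600
    p_standard: float = 0.82
    p_deviant: float = 0.06
    deviants: tuple[str, ...] = ("FDev", "DDev", "IDev")
    tones: dict = field(
        default_factory=lambda: {
            "standard": ToneSpec(1000.0, 50.0, 80.0),
            "FDev": ToneSpec(1200.0, 50.0, 80.0),
            "DDev": ToneSpec(1000.0, 100.0, 80.0),
            "IDev": ToneSpec(1000.0, 50.0, 90.0),
        }
    )
    min_standards_between_deviants: int = 1

    def __post_init__(self):
        total = self.p_standard + self.p_deviant * len(self.deviants)
        if not np.isclose(total, 1.0):
            raise ValueError(f"tone proportions sum to {total}, not 1")
        if self.n_tones < 1:
            raise ValueError("n_tones must be >= 1")
        for p, what in ((self.p_standard, "standard"), (self.p_deviant, "deviant")):
            cnt = self.n_tones * p
            if not np.isclose(cnt, round(cnt)):
                raise ValueError(f"n_tones x p_{what} = {cnt} is not an integer")

    @property
    def n_standard(self) -> int:
        return round(self.n_tones * self.p_standard)

    @property
    def n_per_deviant(self) -> int:
        return round(self.n_tones * self.p_deviant)


@dataclass(frozen=True)
class ComponentSpec:
    """One stereotyped ERP component: a Gaussian-in-time waveform with a
    fixed scalp topography.

    ``amplitude_uv`` is signed (negative-going components carry negative
    amplitudes); ``width_ms`` is the temporal standard deviation of the
    Gaussian. ``topography`` holds one weight per channel, normalised to
    unit maximum. ``conditions`` lists the epoched conditions in which the
    component appears.
    """

    name: str
    peak_latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        topo = np.asarray(self.topography, dtype=float)
        object.__setattr__(self, "topography", topo)
        if topo.shape != (N_CHANNELS,):
            raise ValueError("topography must have one weight per channel")
        if not np.any(topo):
            raise ValueError("topography must have at least one nonzero weight")
        if self.width_ms <= 0:
            raise ValueError("temporal width must be positive")


def default_components() -> list[ComponentSpec]:
    """Literature-typical auditory-oddball components.

    Obligatory N1 (fronto-central negativity, 100 ms) and P2 (central
    positivity, 200 ms) in every condition; deviance-related N2b
    (fronto-central negativity, 220 ms) and P300 (centro-parietal
    positivity, 320 ms) in the deviant conditions only. Amplitudes and
    latencies are configurable typical values, not estimates from any
    particular cohort.
    """
    deviants = ("FDev", "DDev")
    return [
        ComponentSpec("N1", 100.0, 18.0, -5.0, gaussian_topography("FCz")),
        ComponentSpec("P2", 200.0, 25.0, 4.0, gaussian_topography("Cz")),
        ComponentSpec("N2b", 220.0, 25.0, -4.0, gaussian_topography("FCz"), deviants),
        ComponentSpec("P300", 320.0, 55.0, 8.0, gaussian_topography("Pz"), deviants),
    ]


@dataclass(frozen=True)
class EffectSpec:
    """Group effect applied to concussed subjects.

    ``attenuation`` maps component names to the fraction of amplitude lost
    (0 = intact, 1 = abolished); ``latency_delay_ms`` maps component names
    to an added peak delay.
    """

    attenuation: dict = field(default_factory=dict)
    latency_delay_ms: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, a in self.attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation for {name} must lie in [0, 1]")

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls()

    @classmethod
    def strong(cls) -> "EffectSpec":
        """A strong, clearly detectable deficit of the deviance responses."""
        return cls(
            attenuation={"N2b": 0.6, "P300": 0.6},
            latency_delay_ms={"N2b": 20.0, "P300": 20.0},
        )


@dataclass(frozen=True)
class NoiseParams:
    """Scales (in µV of per-channel standard deviation) of the three noise
    sources added to every trial: 1/f^beta background activity, a 10 Hz
    alpha oscillation with random phase per trial and posterior weighting,
    and white sensor noise."""

    pink_scale: float = 4.0
    pink_beta: float = 1.0
    alpha_scale: float = 3.0
    alpha_freq_hz: float = 10.0
    white_scale: float = 2.0

    def __post_init__(self):
        for name in ("pink_scale", "alpha_scale", "white_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(pink_scale=0.0, alpha_scale=0.0, white_scale=0.0)


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject simulation parameters.

    ``gains`` multiply each component's amplitude (control subjects have
    unit gain in expectation); ``latency_jitter_ms`` is the SD of
    trial-to-trial latency jitter; ``trial_amplitude_sd`` the SD of
    trial-level multiplicative amplitude variability.
    """

    subject_id: str
    group: str
    gains: dict = field(default_factory=dict)
    latency_jitter_ms: float = 10.0
    trial_amplitude_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.group not in (CONTROL, CONCUSSED):
            raise ValueError(f"unknown group {self.group!r}")
        for name, g in self.gains.items():
            if g < 0:
                raise ValueError(f"gain for {name} must be nonnegative")


@dataclass
class Epoch:
    """One baseline-corrected single trial: channels x samples in µV."""

    data: np.ndarray  # (64, 614) float32
    condition: str
    sfreq: float = SFREQ
    onset_index: int = ONSET_INDEX

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != (N_CHANNELS, N_SAMPLES):
            raise ValueError(
                f"epoch data must be {(N_CHANNELS, N_SAMPLES)}, got {self.data.shape}"
            )

    @property
    def times(self) -> np.ndarray:
        return (np.arange(N_SAMPLES) - self.onset_index) / self.sfreq


# ---------------------------------------------------------------------------
# tone sequences


def generate_tone_sequence(spec: ParadigmSpec, seed) -> np.ndarray:
    """Pseudo-random oddball sequence honouring the spacing constraint.

    Returns an array of ``spec.n_tones`` labels with exact per-type counts
    and at least ``spec.min_standards_between_deviants`` standards between
    consecutive deviants. The arrangement is sampled uniformly over all
    valid gap compositions.
    """
    rng = np.random.default_rng(seed)
    k = spec.n_per_deviant * len(spec.deviants)
    n_std = spec.n_standard
    m = spec.min_standards_between_deviants
    if k > 0 and n_std < (k - 1) * m:
        raise ValueError(
            f"cannot place {k} deviants with >= {m} standards between "
            f"consecutive deviants given only {n_std} standards"
        )
    if k == 0:
        return np.array(["standard"] * n_std)

    # gaps g0..gk of standards around the k deviants; interior gaps >= m.
    # Sample a uniform weak composition of the surplus via stars-and-bars.
    surplus = n_std - (k - 1) * m
    bars = np.sort(rng.choice(surplus + k, size=k, replace=False))
    parts = np.diff(np.concatenate(([0], bars - np.arange(k), [surplus])))
    gaps = np.concatenate(([parts[0]], parts[1:-1] + m, [parts[-1]]))

    deviant_order = rng.permutation(np.repeat(spec.deviants, spec.n_per_deviant))
    seq: list[str] = []
    for i, dev in enumerate(deviant_order):
        seq.extend(["standard"] * gaps[i])
        seq.append(dev)
    seq.extend(["standard"] * gaps[k])
    out = np.array(seq)
    assert out.size == spec.n_tones
    return out


# ---------------------------------------------------------------------------
# epochs


def _component_amplitude_and_latency(
    comp: ComponentSpec, subject: SubjectSpec, effect: EffectSpec
) -> tuple[float, float]:
    gain = subject.gains.get(comp.name, 1.0)
    amp = comp.amplitude_uv * gain
    lat = comp.peak_latency_ms
    if subject.group == CONCUSSED:
        amp *= 1.0 - effect.attenuation.get(comp.name, 0.0)
        lat += effect.latency_delay_ms.get(comp.name, 0.0)
    return amp, lat


def _pink_noise(rng: np.random.Generator, n_trials: int, beta: float) -> np.ndarray:
    """(n_trials, 64, 614) of unit-SD 1/f^beta noise (single precision)."""
    from scipy import fft as sfft

    freqs = np.fft.rfftfreq(N_SAMPLES, d=1.0 / SFREQ)
    shaping = np.zeros(freqs.size, dtype=np.float32)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (
        rng.standard_normal((n_trials, N_CHANNELS, freqs.size), dtype=np.float32)
        + 1j * rng.standard_normal((n_trials, N_CHANNELS, freqs.size), dtype=np.float32)
    ) * shaping
    x = sfft.irfft(spec, n=N_SAMPLES, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _synth_trials(
    subject: SubjectSpec,
    condition: str,
    n_trials: int,
    components: list[ComponentSpec],
    effect: EffectSpec,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised core: (n_trials, 64, 614) baseline-corrected epochs."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = epoch_times()[None, :].astype(np.float32)  # seconds, (1, S)
    data = np.zeros((n_trials, N_CHANNELS, N_SAMPLES), dtype=np.float32)
    for comp in components:
        if condition not in comp.conditions:
            continue
        amp, lat_ms = _component_amplitude_and_latency(comp, subject, effect)
        trial_amp = amp * (
            1.0 + subject.trial_amplitude_sd * rng.standard_normal(n_trials)
        )
        trial_lat = (
            lat_ms + subject.latency_jitter_ms * rng.standard_normal(n_trials)
        ) / 1000.0
        wave = np.exp(
            -((t - trial_lat[:, None].astype(np.float32)) ** 2)
            / np.float32(2.0 * (comp.width_ms / 1000.0) ** 2)
        )  # (n_trials, S)
        data += (
            (trial_amp[:, None].astype(np.float32) * wave)[:, None, :]
            * comp.topography.astype(np.float32)[None, :, None]
        )

    if noise.pink_scale > 0:
        data += np.float32(noise.pink_scale) * _pink_noise(rng, n_trials, noise.pink_beta)
    if noise.alpha_scale > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_trials)[:, None].astype(np.float32)
        topo = gaussian_topography("Oz", spread_m=0.07).astype(np.float32)
        osc = np.sin(2 * np.pi * noise.alpha_freq_hz * t + phase)  # (n_trials, S)
        data += np.float32(noise.alpha_scale) * osc[:, None, :] * topo[None, :, None]
    if noise.white_scale > 0:
        data += np.float32(noise.white_scale) * rng.standard_normal(
            data.shape, dtype=np.float32
        )

    baseline = data[:, :, : ONSET_INDEX + 1].mean(axis=-1, keepdims=True, dtype=np.float64)
    return (data - baseline.astype(np.float32)).astype(np.float32)


def synth_epoch(
    subject: SubjectSpec,
    condition: str,
    components: list[ComponentSpec],
    effect: EffectSpec,
    noise: NoiseParams,
    seed,
) -> Epoch:
    """Generate one baseline-corrected single-trial epoch.

    The epoch is the sum over components present in ``condition`` of
    (gain x amplitude x Gaussian-in-time x topography), plus 1/f
    background, alpha oscillation and white noise, baseline-corrected over
    the prestimulus interval. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    data = _synth_trials(subject, condition, 1, components, effect, noise, rng)[0]
    return Epoch(data=data, condition=condition)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SubjectData:
    """One subject's simulated session: per-condition epoch arrays."""

    spec: SubjectSpec
    epochs: dict  # condition -> (n_trials, 64, 614) float32

    @property
    def subject_id(self) -> str:
        return self.spec.subject_id

    @property
    def group(self) -> str:
        return self.spec.group


@dataclass
class Cohort:
    subjects: list
    paradigm: ParadigmSpec
    effect: EffectSpec

    def labels(self) -> dict:
        return {s.subject_id: s.group for s in self.subjects}


def _draw_subject_spec(
    subject_id: str, group: str, rng: np.random.Generator,
    component_names, gain_sd: float
) -> SubjectSpec:
    gains = {
        name: float(np.exp(gain_sd * rng.standard_normal())) for name in component_names
    }
    return SubjectSpec(
        subject_id=subject_id,
        group=group,
        gains=gains,
        seed=int(rng.integers(2**31)),
    )


def simulate_session(
    subject: SubjectSpec,
    paradigm: ParadigmSpec,
    components: list[ComponentSpec],
    effect: EffectSpec,
    noise: NoiseParams,
    seed,
    rejection_fraction: float = 0.0,
    max_standard_epochs: int = 48,
) -> SubjectData:
    """Simulate one recording session for one subject.

    The tone sequence fixes per-condition trial counts (intensity-deviant
    tones are sequenced but never epoched). Only ``max_standard_epochs``
    of the standard tones are epoched — downstream assembly samples 36
    standards uniformly, so epoching all 492 would only cost memory.
    ``rejection_fraction`` removes that fraction of trials at random per
    deviant condition (and from the surplus standards), emulating artifact
    rejection and exercising the bootstrap path.
    """
    rng = np.random.default_rng(seed)
    seq = generate_tone_sequence(paradigm, rng.integers(2**31))
    counts = {c: int((seq == c).sum()) for c in CONDITIONS}
    counts["standard"] = min(counts["standard"], max_standard_epochs)
    if rejection_fraction:
        if not 0.0 <= rejection_fraction < 1.0:
            raise ValueError("rejection_fraction must lie in [0, 1)")
        for c in counts:
            keep = int(round(counts[c] * (1.0 - rejection_fraction)))
            counts[c] = max(keep, 1)
    epochs = {
        c: _synth_trials(subject, c, counts[c], components, effect, noise, rng)
        for c in CONDITIONS
    }
    return SubjectData(spec=subject, epochs=epochs)


def generate_cohort(
    n_control: int,
    n_concussed: int,
    paradigm: ParadigmSpec | None = None,
    effect: EffectSpec | None = None,
    seed=0,
    components: list[ComponentSpec] | None = None,
    noise: NoiseParams | None = None,
    gain_sd: float = 0.2,
    rejection_fraction: float = 0.0,
    max_standard_epochs: int = 48,
) -> Cohort:
    """Simulate a full cohort (one session per subject).

    Control and concussed subjects are drawn with the same between-subject
    gain variability (log-normal, ``gain_sd`` log-SD); the group effect
    enters only through ``effect``.
    """
    if n_control < 1 or n_concussed < 1:
        raise ValueError("both groups need at least one subject")
    paradigm = paradigm or ParadigmSpec()
    effect = effect if effect is not None else EffectSpec.strong()
    components = components if components is not None else default_components()
    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed)
    names = [c.name for c in components]

    subjects = []
    for group, n in ((CONTROL, n_control), (CONCUSSED, n_concussed)):
        for i in range(n):
            spec = _draw_subject_spec(f"{group[:4]}-{i:03d}", group, rng, names, gain_sd)
            subjects.append(
                simulate_session(
                    spec, paradigm, components, effect, noise,
                    seed=rng.integers(2**31),
                    rejection_fraction=rejection_fraction,
                    max_standard_epochs=max_standard_epochs,
                )
            )
    return Cohort(subjects=subjects, paradigm=paradigm, effect=effect)


def specs_from_yaml(path) -> dict:
    """Load simulator specifications from a YAML file.

    Recognised top-level keys (all optional): ``paradigm`` (ParadigmSpec
    fields; tone entries as ``{frequency_hz, duration_ms, intensity_db}``),
    ``components`` (list of ComponentSpec fields with ``topography`` given
    as ``{center: <electrode>, spread_m: <float>}``), ``effect``
    (EffectSpec fields) and ``noise`` (NoiseParams fields). Returns a dict
    with instantiated specs, using defaults for absent keys.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    par = dict(raw.get("paradigm", {}))
    if "tones" in par:
        par["tones"] = {k: ToneSpec(**v) for k, v in par["tones"].items()}
    if "deviants" in par:
        par["deviants"] = tuple(par["deviants"])
    out["paradigm"] = ParadigmSpec(**par)
    comps = raw.get("components")
    if comps is None:
        out["components"] = default_components()
    else:
        built = []
        for c in comps:
            c = dict(c)
            topo = c.pop("topography")
            c["topography"] = gaussian_topography(
                topo["center"], topo.get("spread_m", 0.045)
            )
            if "conditions" in c:
                c["conditions"] = tuple(c["conditions"])
            built.append(ComponentSpec(**c))
        out["components"] = built
    out["effect"] = EffectSpec(**raw.get("effect", {}))
    out["noise"] = NoiseParams(**raw.get("noise", {}))
    return out


def simulate_followup(
    cohort: Cohort,
    returning_ids: list,
    recovered_ids: list,
    components: list[ComponentSpec] | None = None,
    noise: NoiseParams | None = None,
    seed=0,
    rejection_fraction: float = 0.0,
    max_standard_epochs: int = 48,
) -> Cohort:
    """Second-session data for a subset of subjects.

    ``recovered_ids`` are re-simulated with the group effect removed (their
    deviance responses normalise); other returning subjects keep the
    cohort's effect. Subject-level gains are retained, so the follow-up
    session is the same brain on a different day.
    """
    components = components if components is not None else default_components()
    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed)
    recovered = set(recovered_ids)
    by_id = {s.subject_id: s for s in cohort.subjects}
    out = []
    for sid in returning_ids:
        subj = by_id[sid]
        eff = EffectSpec.null() if sid in recovered else cohort.effect
        out.append(
            simulate_session(
                subj.spec, cohort.paradigm, components, eff, noise,
                seed=rng.integers(2**31),
                rejection_fraction=rejection_fraction,
                max_standard_epochs=max_standard_epochs,
            )
        )
    return Cohort(subjects=out, paradigm=cohort.paradigm, effect=cohort.effect)
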