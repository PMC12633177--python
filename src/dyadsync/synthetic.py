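"""Synthetic dyadic fNIRS recordings, transcripts and behavioral scores.

Every downstream stage of the pipeline is exercised on data from this
module, with ground truth known by construction:

* **Cross-brain coupling** — for each designated long-channel pair a common
  band-limited Gaussian process is mixed into both subjects' hemodynamic
  signals with amplitude ratio ``strength**(1/4)`` against independent
  band-limited residuals filling the remaining variance, so the true
  magnitude-squared coherence inside the coupling band equals ``strength``.
* **Physiology** — cardiac, respiratory and Mayer-wave oscillations plus
  white noise form a superficial (scalp) component shared between a
  subject's short- and long-separation channels; long channels receive it
  scaled by ``scalp_gain``.
* **Optics** — hemoglobin signals are pushed through the forward modified
  Beer-Lambert model and an exponential intensity model
  ``I = I0 * exp(-dOD)``, so optical-density conversion and the inverse
  Beer-Lambert step round-trip exactly.
* **Motion artifacts** — additive spikes (1-3 samples) and step baseline
  shifts at Poisson times, recorded per channel in the ground truth.

Identical spec and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from dyadsync.linguistics import Transcript, Utterance
from dyadsync.preprocessing import DEFAULT_DISTANCE_CM, DEFAULT_DPF, beer_lambert_forward
from dyadsync.types import ChannelInfo, DyadRecording, SubjectRecording, TaskAnnotation

__all__ = [
    "NoiseProfile",
    "DyadSpec",
    "ArtifactEvent",
    "GroundTruth",
    "StudyDataset",
    "generate_dyad",
    "generate_transcript",
    "generate_cohort",
]


@dataclass(frozen=True)
class NoiseProfile:
    """Amplitudes (uM HbO equivalent) and centre frequencies of physiology."""

    cardiac_amp: float = 0.6
    cardiac_freq: float = 1.2
    resp_amp: float = 0.3
    resp_freq: float = 0.3
    mayer_amp: float = 0.25
    mayer_freq: float = 0.1
    white_amp: float = 0.2


@dataclass(frozen=True)
class DyadSpec:
    """Generator parameters for one dyadic recording.

    ``coupling_strength`` is the target magnitude-squared coherence of the
    injected cross-brain signal inside ``coupling_band``; ``scalp_gain`` is
    the amplitude ratio with which the superficial component enters long
    channels; ``artifact_rate`` is the expected number of motion events per
    minute and channel.
    """

    n_channels_long: int = 6
    n_channels_short: int = 2
    fs: float = 7.81
    duration_s: float = 120.0
    coupling_band: tuple[float, float] = (0.05, 0.1)
    coupling_strength: float = 0.3
    #: expected motion events per minute per channel; ~0.1 reproduces the
    #: 10-25% channel-exclusion rates typical of parent-child recordings
    artifact_rate: float = 0.1
    scalp_gain: float = 0.4
    noise_profile: NoiseProfile = field(default_factory=NoiseProfile)
    neural_amp: float = 1.0
    #: broadband (white) hemodynamic background per subject, relative to
    #: neural_amp; resting HbO spectra carry a substantial broadband floor
    #: in addition to the slow band-limited fluctuations
    neural_bg_amp: float = 1.0
    #: HbR/HbO amplitude ratio of the neural component.  Note -0.4 would
    #: nearly cancel the 760 nm extinction combination (1486 - 0.4*3844),
    #: hiding neural content from one wavelength entirely
    hbr_ratio: float = -0.25
    task: str = "tangram"
    seed: int = 0

    def __post_init__(self) -> None:
        f_lo, f_hi = self.coupling_band
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if not 0 < f_lo < f_hi:
            raise ValueError("coupling band must satisfy 0 < f_lo < f_hi")
        if f_hi >= self.fs / 2:
            raise ValueError(
                f"coupling band upper edge {f_hi} Hz is at/beyond the "
                f"Nyquist frequency {self.fs / 2} Hz"
            )
        if self.duration_s * self.fs < 4 * self.fs / f_lo:
            raise ValueError(
                "recording too short: need at least 4 periods of the lower "
                "coupling-band edge"
            )
        if self.n_channels_long < 1 or self.n_channels_short < 1:
            raise ValueError("need at least one long and one short channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class ArtifactEvent:
    subject: str
    channel: int  # index into the subject's channel list
    kind: str  # "spike" | "shift"
    time_s: float
    n_samples: int
    amplitude_od: float


@dataclass
class GroundTruth:
    """What was injected: coupling, artifacts, group and latent traits."""

    coupling: dict[int, tuple[tuple[float, float], float]]
    artifacts: list[ArtifactEvent]
    group: str | None = None
    latent_verbal: float | None = None
    symptom_severity: float | None = None
    neural: dict[str, np.ndarray] | None = None  # injected dHbO per long channel
    #: realised per-subject oscillation frequencies (Hz) per component
    physio_freqs: dict[str, dict[str, float]] = field(default_factory=dict)


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillation(
    rng: np.random.Generator, t: np.ndarray, freq: float, amp: float
) -> np.ndarray:
    phase = rng.uniform(0, 2 * np.pi)
    return amp * np.sin(2 * np.pi * freq * t + phase)


def generate_dyad(
    spec: DyadSpec,
    coupling_strengths: dict[int, float] | None = None,
    keep_neural: bool = False,
) -> tuple[DyadRecording, GroundTruth]:
    """Simulate one dyadic two-wavelength recording.

    ``coupling_strengths`` optionally overrides the per-channel-pair target
    coherence (defaults to ``spec.coupling_strength`` on every long pair).
    With ``keep_neural=True`` the injected neural dHbO of every long
    channel is stored in the ground truth for recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    nl, ns = spec.n_channels_long, spec.n_channels_short
    np_prof = spec.noise_profile

    strengths = {
        k: float(np.clip(spec.coupling_strength, 0.0, 1.0)) for k in range(nl)
    }
    if coupling_strengths:
        for k, v in coupling_strengths.items():
            if not 0 <= k < nl:
                raise ValueError(f"no long channel pair with index {k}")
            strengths[k] = float(np.clip(v, 0.0, 1.0))

    # shared band-limited drivers, one per long-channel pair
    common = [_band_noise(rng, n, spec.fs, spec.coupling_band) for _ in range(nl)]

    neural: dict[str, np.ndarray] = {}
    scalp: dict[str, np.ndarray] = {}
    physio: dict[str, dict[str, float]] = {}
    for subject in ("child", "mother"):
        resid = np.array(
            [_band_noise(rng, n, spec.fs, spec.coupling_band) for _ in range(nl)]
        )
        # amplitude mixing ratio: with unit-variance common and residual
        # processes, magnitude-squared coherence = alpha**4, so alpha is the
        # fourth root of the target squared coherence
        alpha = np.array([strengths[k] for k in range(nl)])[:, None] ** 0.25
        sig = spec.neural_amp * (alpha * np.array(common) + np.sqrt(1 - alpha**2) * resid)
        # broadband hemodynamic background, low-passed to the vascular
        # bandwidth (~0.5 Hz); its spectral density matches white noise of
        # the given amplitude below the cutoff
        bg = rng.standard_normal((nl, n))
        sos_bg = butter(4, 0.5, btype="lowpass", fs=spec.fs, output="sos")
        sig += spec.neural_bg_amp * spec.neural_amp * sosfiltfilt(sos_bg, bg, axis=-1)
        neural[subject] = sig
        # physiological oscillation frequencies vary between individuals;
        # identical frequencies across subjects would be trivially
        # phase-locked and show spurious coherence
        freqs = {
            "cardiac": float(rng.normal(np_prof.cardiac_freq, 0.06 * np_prof.cardiac_freq)),
            "resp": float(rng.normal(np_prof.resp_freq, 0.10 * np_prof.resp_freq)),
            "mayer": float(rng.normal(np_prof.mayer_freq, 0.12 * np_prof.mayer_freq)),
        }
        physio[subject] = freqs
        scalp[subject] = (
            _oscillation(rng, t, freqs["cardiac"], np_prof.cardiac_amp)
            + _oscillation(rng, t, freqs["resp"], np_prof.resp_amp)
            + _oscillation(rng, t, freqs["mayer"], np_prof.mayer_amp)
            + np_prof.white_amp * rng.standard_normal(n)
        )

    artifacts: list[ArtifactEvent] = []
    subjects: dict[str, SubjectRecording] = {}
    for subject in ("child", "mother"):
        channels = [
            ChannelInfo(subject, s + 1, s + 1, "long", region=f"region-{s + 1}")
            for s in range(nl)
        ] + [
            ChannelInfo(subject, 100 + s, 100 + s, "short") for s in range(ns)
        ]
        intensity = np.empty((nl + ns, 2, n))
        for ci, ch in enumerate(channels):
            # neural activity anticorrelates HbO/HbR (hbr_ratio < 0); the
            # superficial component is blood-volume driven, so HbO and HbR
            # move in phase there
            if ch.separation == "long":
                neur = neural[subject][ci]
                sup = spec.scalp_gain * scalp[subject]
            else:
                neur = np.zeros(n)
                sup = scalp[subject] + 0.3 * np_prof.white_amp * rng.standard_normal(n)
            hbo = neur + sup
            hbr = spec.hbr_ratio * neur + 0.3 * sup + 0.03 * rng.standard_normal(n)
            od = beer_lambert_forward(
                hbo, hbr, DEFAULT_DISTANCE_CM[ch.separation], DEFAULT_DPF
            )
            # per-wavelength sensor (shot/electronic) noise; its sample-to-
            # sample magnitude dominates the temporal derivative, which is
            # the regime robust motion correction is designed for
            od += 3e-3 * rng.standard_normal(od.shape)
            od = _inject_artifacts(
                rng, od, spec, subject, ci, artifacts
            )
            baseline = rng.uniform(500.0, 2000.0, size=2)
            intensity[ci] = baseline[:, None] * np.exp(-od)
        subjects[subject] = SubjectRecording(intensity=intensity, channels=channels)

    rec = DyadRecording(
        dyad_id=f"dyad-{spec.seed}",
        fs=spec.fs,
        subjects=subjects,
        annotations=[TaskAnnotation(spec.task, 0.0, n / spec.fs)],
    )
    gt = GroundTruth(
        coupling={k: (spec.coupling_band, strengths[k]) for k in range(nl)},
        artifacts=artifacts,
        neural={s: neural[s].copy() for s in neural} if keep_neural else None,
        physio_freqs=physio,
    )
    return rec, gt


def _inject_artifacts(
    rng: np.random.Generator,
    od: np.ndarray,
    spec: DyadSpec,
    subject: str,
    channel: int,
    artifacts: list[ArtifactEvent],
) -> np.ndarray:
    """Add spike and baseline-shift events at Poisson times (OD domain)."""
    n = od.shape[1]
    expected = spec.artifact_rate * spec.duration_s / 60.0
    n_events = rng.poisson(expected)
    if n_events == 0:
        return od
    od = od.copy()
    sd = od.std(axis=1, keepdims=True)
    for _ in range(n_events):
        start = int(rng.integers(0, n))
        if rng.random() < 0.6:
            width = int(rng.integers(1, 4))
            amp = rng.uniform(5, 20) * rng.choice([-1.0, 1.0])
            od[:, start : start + width] += amp * sd
            kind = "spike"
        else:
            width = n - start
            amp = rng.uniform(3, 10) * rng.choice([-1.0, 1.0])
            od[:, start:] += amp * sd
            kind = "shift"
        artifacts.append(
            ArtifactEvent(
                subject=subject,
                channel=channel,
                kind=kind,
                time_s=start / spec.fs,
                n_samples=min(width, n - start),
                amplitude_od=float(amp * sd[0, 0]),
            )
        )
    return od


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

_NOUNS = ["ball", "dog", "cat", "puzzle", "piece", "picture", "car", "house"]
_VERBS = ["play", "want", "look", "turn", "help", "jump", "walk", "push"]
_MODS = ["big", "red", "little", "funny", "blue", "happy"]
_SUBORDINATE = [
    ("because", "it is {n}"),
    ("when", "we {v}"),
    ("if", "you {v} it"),
    ("that", "we can {v}"),
]
_MOT_PROMPTS = [
    ["what", "do", "you", "see"],
    ["can", "you", "find", "the", "piece"],
    ["tell", "me", "more"],
    ["where", "does", "it", "go"],
    ["good", "job"],
]


def generate_transcript(latent_verbal: float, seed: int = 0) -> Transcript:
    """CHAT-style mother-child conversation driven by a latent verbal score.

    ``latent_verbal`` in [0, 1] monotonically increases the child's expected
    utterance length, inflection use, subordination rate and utterance
    count, so MLU, TNW, WPS and CPS all grow with it in expectation.  At
    the floor (0) the child produces one-to-two-morpheme utterances.
    """
    if not 0.0 <= latent_verbal <= 1.0:
        raise ValueError("latent_verbal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    v = latent_verbal
    n_child = 10 + int(np.floor(8 * v)) + int(rng.poisson(2))
    utterances: list[Utterance] = []
    for _ in range(n_child):
        prompt = int(rng.integers(len(_MOT_PROMPTS)))
        utterances.append(Utterance("mother", list(_MOT_PROMPTS[prompt]), "?"))
        n_words = 1 + int(rng.poisson(0.3 + 5.0 * v))
        tokens: list[str] = []
        for w in range(n_words):
            r = rng.random()
            if r < 0.45:
                word = str(rng.choice(_NOUNS))
                if rng.random() < 0.1 + 0.4 * v:  # plural inflection
                    word += "s"
            elif r < 0.8:
                word = str(rng.choice(_VERBS))
                u = rng.random()
                if u < 0.08 + 0.3 * v:
                    word += "ing" if rng.random() < 0.5 else "ed"
            else:
                word = str(rng.choice(_MODS))
            tokens.append(word)
        if rng.random() < 0.5 * v:  # subordinate clause
            marker, templ = _SUBORDINATE[int(rng.integers(len(_SUBORDINATE)))]
            clause = templ.format(
                n=str(rng.choice(_MODS)), v=str(rng.choice(_VERBS))
            )
            tokens.append(marker)
            tokens.extend(clause.split())
        utterances.append(Utterance("child", tokens, "."))
    return Transcript(utterances=utterances)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """A simulated three-group study: recordings, ground truth, behavior."""

    dyads: list[DyadRecording]
    ground_truth: dict[str, GroundTruth]
    behavioral: pd.DataFrame  # dyad_id, group, symptom_total, task_score
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, str]:
        return {d.dyad_id: self.ground_truth[d.dyad_id].group for d in self.dyads}


def generate_cohort(
    n_per_group: dict[str, int],
    effect_map: dict[str, dict[int, float]] | None = None,
    spec: DyadSpec | None = None,
    seed: int = 0,
    symptom_tau: float = 0.4,
    symptom_pair: int = 0,
    coupling_jitter_sd: float = 0.08,
    with_transcripts: bool = False,
) -> StudyDataset:
    """Simulate a cohort of dyads in groups A/B/C with known group effects.

    ``effect_map[group][pair]`` adds a coupling-strength delta to that
    channel pair for dyads of that group; all other pairs share the base
    coupling distribution.  Per-dyad coupling of ``symptom_pair`` is
    jittered (sd ``coupling_jitter_sd``) and the child's symptom-severity
    score is drawn from a Gaussian copula with Kendall tau
    ``symptom_tau`` against that realised coupling strength, mirroring an
    IBS-symptom association with known effect size.
    """
    effect_map = effect_map or {}
    spec = spec or DyadSpec()
    if not n_per_group:
        raise ValueError("empty cohort")
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs at least 2 dyads, got {n}")
    rng = np.random.default_rng(seed)
    rho = np.sin(np.pi * symptom_tau / 2)  # Kendall tau -> Gaussian correlation

    dyads: list[DyadRecording] = []
    gts: dict[str, GroundTruth] = {}
    rows = []
    transcripts: dict[str, Transcript] = {}
    idx = 0
    for group in sorted(n_per_group):
        deltas = effect_map.get(group, {})
        for _ in range(n_per_group[group]):
            z1 = rng.standard_normal()
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal()
            strengths = {}
            for k in range(spec.n_channels_long):
                base = spec.coupling_strength + deltas.get(k, 0.0)
                jitter = coupling_jitter_sd * (z1 if k == symptom_pair else rng.standard_normal())
                strengths[k] = float(np.clip(base + jitter, 0.02, 0.95))
            dyad_seed = int(rng.integers(0, 2**31 - 1))
            rec, gt = generate_dyad(
                replace(spec, seed=dyad_seed), coupling_strengths=strengths
            )
            rec.dyad_id = f"{group}{idx:03d}"
            gt.group = group
            gt.latent_verbal = float(rng.uniform(0.05, 0.95))
            gt.symptom_severity = float(60 + 10 * z2)
            dyads.append(rec)
            gts[rec.dyad_id] = gt
            rows.append(
                {
                    "dyad_id": rec.dyad_id,
                    "group": group,
                    "symptom_total": gt.symptom_severity,
                    "task_score": float(
                        np.clip(10 + 10 * gt.latent_verbal + rng.normal(0, 2), 0, 30)
                    ),
                }
            )
            if with_transcripts:
                transcripts[rec.dyad_id] = generate_transcript(
                    gt.latent_verbal, seed=dyad_seed + 1
                )
            idx += 1
    return StudyDataset(
        dyads=dyads,
        ground_truth=gts,
        behavioral=pd.DataFrame(rows),
        transcripts=transcripts,
    )
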