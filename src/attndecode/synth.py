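"""Synthetic continuous EEG with a known feature-based attention effect.

The generator implements a deliberately simple linear forward model: each
stimulus presentation evokes, in every channel, the superposition of two
orientation-selective spatial patterns (one for the orientation shown in the
attended colour, one for the ignored colour), each modulated by a smooth
amplitude kernel over time.  Before a configurable divergence latency the two
patterns carry identical gain — attended and ignored orientations are coded
equally — and from that latency on the ignored pattern's gain drops, which is
the ground-truth attention effect downstream stages must recover.  Responses
of successive presentations add linearly, as they do in rapid serial designs
where stimulus-onset asynchronies are far shorter than the evoked response.

Noise is spatially correlated (random factor model plus a diagonal) and
temporally correlated (AR(1)), which makes leave-one-sequence-out
cross-validation necessary rather than decorative: epochs within a sequence
share noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import (
    EVENT_OTHER_ORIENTATIONS,
    FRAME_MS,
    ORIENTATIONS,
    TARGET_ORIENTATIONS,
    EventStimulus,
    SequenceSpec,
    SessionSpec,
    StimulusType,
    generate_session,
    sequence_to_frame,
)

EVENT_PATTERN_ORIENTATIONS: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

#: Default signal amplitude (uV) at the kernel peak for a unit-norm pattern.
DEFAULT_AMPLITUDE: float = 2.5
#: Default between-participant SD of the amplitude (uV).
DEFAULT_BETWEEN_SUBJECT_SD: float = 0.5

_FM_FIELDS = {
    "kernel_onset_ms",
    "kernel_peak_ms",
    "kernel_offset_ms",
    "divergence_ms",
    "attended_gain",
    "unattended_gain",
    "amplitude",
    "ar_phi",
    "noise_sd",
}


@dataclass
class ForwardModel:
    """Linear pattern-superposition model of the evoked response.

    Parameters
    ----------
    orientation_patterns
        One unit-norm, pairwise-orthogonal channel vector per analysable
        orientation (22.5/67.5/112.5/157.5 deg).
    event_patterns
        Unit-norm channel vectors for the target/foil orientations
        (0/45/90/135 deg); targets and foils are excluded from analysis, so
        these patterns only contribute overlap.
    kernel_onset_ms, kernel_peak_ms, kernel_offset_ms
        Support and peak of the evoked amplitude kernel (raised-cosine rise
        and fall); zero outside [onset, offset).
    divergence_ms
        Latency at which attended and unattended gains diverge; both are 1
        before it.
    attended_gain, unattended_gain
        Post-divergence gains for the cued and uncued orientation patterns.
    amplitude
        Peak evoked amplitude in uV for a unit-norm pattern.
    noise_cov, ar_phi, noise_sd
        Spatial covariance of the noise (unit mean diagonal), AR(1)
        coefficient over time, and innovation SD in uV.
    """

    n_channels: int
    orientation_patterns: dict[float, np.ndarray]
    event_patterns: dict[float, np.ndarray]
    noise_cov: np.ndarray
    kernel_onset_ms: float = 80.0
    kernel_peak_ms: float = 170.0
    kernel_offset_ms: float = 400.0
    divergence_ms: float = 230.0
    attended_gain: float = 1.0
    unattended_gain: float = 0.4
    amplitude: float = DEFAULT_AMPLITUDE
    ar_phi: float = 0.95
    noise_sd: float = 1.0
    sampling_rate_hz: int = 1000
    _noise_chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Evoked amplitude envelope at times `t_ms` after stimulus onset."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        t_on, t_pk, t_off = (
            self.kernel_onset_ms,
            self.kernel_peak_ms,
            self.kernel_offset_ms,
        )
        rise = (t >= t_on) & (t < t_pk)
        fall = (t >= t_pk) & (t < t_off)
        out[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - t_on) / (t_pk - t_on))
        out[fall] = 0.5 + 0.5 * np.cos(np.pi * (t[fall] - t_pk) / (t_off - t_pk))
        return out

    def gain(self, t_ms: np.ndarray, attended: bool) -> np.ndarray:
        """Attention gain profile: 1 before divergence, condition gain after."""
        t = np.asarray(t_ms, dtype=float)
        g = self.attended_gain if attended else self.unattended_gain
        return np.where(t < self.divergence_ms, 1.0, g)

    @property
    def noise_chol(self) -> np.ndarray:
        if self._noise_chol is None:
            self._noise_chol = np.linalg.cholesky(self.noise_cov)
        return self._noise_chol


def make_forward_model(
    n_channels: int = 64, seed: int = 0, **overrides
) -> ForwardModel:
    """Build a seeded forward model.

    Orientation patterns are random channel vectors orthogonalised (QR) and
    unit-normalised; event-orientation patterns are independent unit vectors.
    The noise spatial covariance is a rank-8 random factor model plus a
    diagonal, normalised to unit mean diagonal.  Keyword overrides replace
    scalar model parameters.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels to orthogonalise 4 patterns")
    unknown = set(overrides) - _FM_FIELDS
    if unknown:
        raise TypeError(f"unknown forward-model overrides: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n_channels, len(ORIENTATIONS)))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))  # fix sign convention for determinism
    orientation_patterns = {
        ori: q[:, i].copy() for i, ori in enumerate(ORIENTATIONS)
    }
    event_patterns = {}
    for ori in EVENT_PATTERN_ORIENTATIONS:
        v = rng.standard_normal(n_channels)
        event_patterns[ori] = v / np.linalg.norm(v)
    f = rng.standard_normal((n_channels, 8)) / np.sqrt(8)
    cov = f @ f.T + np.diag(rng.uniform(0.5, 1.5, n_channels))
    cov /= np.mean(np.diag(cov))
    return ForwardModel(
        n_channels=n_channels,
        orientation_patterns=orientation_patterns,
        event_patterns=event_patterns,
        noise_cov=cov,
        **overrides,
    )


@dataclass
class ContinuousRecording:
    """Continuous multichannel data with its event table.

    `events` is the sequence's BIDS-style table plus an `onset_sample`
    column giving each presentation's onset in samples of `data`.
    """

    data: np.ndarray  # channels x samples, uV
    sampling_rate_hz: int
    channel_names: list[str]
    events: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _event_pattern_pair(
    fm: ForwardModel, stim, cued_colour: str, uncued_colour: str
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(stim, StimulusType):
        return (
            fm.orientation_patterns[stim.orientation(cued_colour)],
            fm.orientation_patterns[stim.orientation(uncued_colour)],
        )
    return (
        fm.event_patterns[stim.orientation(cued_colour, cued_colour)],
        fm.event_patterns[stim.orientation(uncued_colour, cued_colour)],
    )


def simulate_recording(
    sequence: SequenceSpec,
    fm: ForwardModel,
    rng: np.random.Generator,
    lead_ms: float = 500.0,
    tail_ms: float = 900.0,
) -> ContinuousRecording:
    """Simulate one sequence's continuous recording.

    Every presentation contributes
    ``A * [g_att(dt) * k(dt) * p_cued + g_unatt(dt) * k(dt) * p_uncued]``
    at lag ``dt`` after its onset; contributions of overlapping presentations
    sum linearly.  AR(1) noise with spatial covariance `noise_cov` is added
    when ``noise_sd > 0``.  Deterministic given the generator state.
    """
    sr = fm.sampling_rate_hz
    ms_per_sample = 1000.0 / sr
    lead = int(round(lead_ms / ms_per_sample))
    last_onset = int(round(sequence.events[-1].onset_ms / ms_per_sample))
    n_samples = lead + last_onset + int(round(tail_ms / ms_per_sample))
    data = np.zeros((fm.n_channels, n_samples))

    # Evoked kernel sampled on the recording grid, shared across events.
    i0 = int(np.ceil(fm.kernel_onset_ms / ms_per_sample))
    i1 = int(np.ceil(fm.kernel_offset_ms / ms_per_sample))
    rel_ms = np.arange(i0, i1) * ms_per_sample
    k = fm.kernel(rel_ms)
    g_att = fm.gain(rel_ms, attended=True) * k
    g_unatt = fm.gain(rel_ms, attended=False) * k

    cued, uncued = sequence.cued_colour, sequence.uncued_colour
    onset_samples = []
    if fm.amplitude != 0.0:
        for e in sequence.events:
            t0 = lead + int(round(e.onset_ms / ms_per_sample))
            onset_samples.append(t0)
            p_c, p_u = _event_pattern_pair(fm, e.stimulus, cued, uncued)
            sl = slice(t0 + i0, t0 + i1)
            data[:, sl] += fm.amplitude * (
                np.outer(p_c, g_att) + np.outer(p_u, g_unatt)
            )
    else:
        onset_samples = [
            lead + int(round(e.onset_ms / ms_per_sample)) for e in sequence.events
        ]

    if fm.noise_sd > 0:
        z = rng.standard_normal((n_samples, fm.n_channels))
        ar = lfilter([1.0], [1.0, -fm.ar_phi], z, axis=0)
        data += fm.noise_sd * (ar @ fm.noise_chol.T).T

    events = sequence_to_frame(sequence)
    events["onset_sample"] = onset_samples
    names = [f"CH{i + 1:02d}" for i in range(fm.n_channels)]
    return ContinuousRecording(
        data=data, sampling_rate_hz=sr, channel_names=names, events=events
    )


@dataclass
class ParticipantSimulation:
    """Lazy handle on one simulated participant.

    Recordings are regenerated on demand from the stored noise seed, so two
    passes over `recordings()` (or two handles built from the same base
    seed) yield bit-identical data without holding a session's worth of
    continuous EEG in memory.
    """

    session: SessionSpec
    forward_model: ForwardModel
    noise_seed: int

    def recordings(self) -> Iterator[ContinuousRecording]:
        rng = np.random.default_rng(self.noise_seed)
        for seq in self.session.sequences:
            yield simulate_recording(seq, self.forward_model, rng)


def simulate_participants(
    n_participants: int,
    base_seed: int,
    n_sequences: int = 64,
    n_channels: int = 64,
    fm_overrides: dict | None = None,
    amplitude_mean: float = DEFAULT_AMPLITUDE,
    between_subject_sd: float = DEFAULT_BETWEEN_SUBJECT_SD,
) -> list[ParticipantSimulation]:
    """Simulate a group of participants.

    Each participant gets an independent seeded forward model (fresh
    patterns and noise covariance), an amplitude drawn from a normal with
    mean `amplitude_mean` and SD `between_subject_sd` truncated at 0, and a
    full counterbalanced session.  Fully reproducible from `base_seed`.
    An explicit ``amplitude`` in `fm_overrides` suppresses the draw.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants for group simulation")
    fm_overrides = dict(fm_overrides or {})
    children = np.random.SeedSequence(base_seed).spawn(n_participants)
    out = []
    for p, child in enumerate(children):
        design_seed, fm_seed, noise_seed, amp_seed = (
            int(s) for s in child.generate_state(4)
        )
        overrides = dict(fm_overrides)
        if "amplitude" not in overrides:
            if between_subject_sd == 0:
                amp = max(amplitude_mean, 0.0)
            else:  # normal truncated at 0 by rejection
                amp_rng = np.random.default_rng(amp_seed)
                amp = -1.0
                while amp < 0:
                    amp = (
                        amplitude_mean
                        + between_subject_sd * amp_rng.standard_normal()
                    )
            overrides["amplitude"] = float(amp)
        session = generate_session(f"sim{p + 1:02d}", design_seed, n_sequences)
        fm = make_forward_model(n_channels=n_channels, seed=fm_seed, **overrides)
        out.append(
            ParticipantSimulation(
                session=session, forward_model=fm, noise_seed=noise_seed
            )
        )
    return out
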