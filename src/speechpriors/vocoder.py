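"""Sine-vocoder synthesis and stimulus mixing.

A sine vocoder analyses speech through a bank of contiguous bandpass filters,
extracts each band's amplitude envelope (half-wave rectification followed by
a 30 Hz fourth-order Butterworth low-pass), multiplies the envelope by a tone
carrier at the band centre, re-filters with the same bandpass, restores each
band's RMS to that of the analysis output, and sums across bands.  Spectral
inversion ("flipping") reassigns band envelopes to mirror-image bands
(low <-> high), which destroys intelligibility while preserving spectral
complexity — the control condition.

All filtering is forward-only IIR (as a real-time vocoder would run); this
choice, like the mixing convention, is recorded in the stimulus manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .filterbank import FilterbankSpec, make_filterbank

SNR_GRID_DB = (-6.0, -3.0, 0.0, 3.0, 6.0)
BAND_COUNTS = (8, 16)
#: reference RMS all finished stimuli are normalised to
REFERENCE_RMS = 0.05
#: peak ceiling applied before writing WAV, after RMS equalisation
PEAK_CEILING = 0.9


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform plus its sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("AudioSignal must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2))) if len(self.samples) else 0.0


@dataclass(frozen=True)
class VocoderConfig:
    """Vocoder parameters: filterbank plus envelope-extraction settings."""

    filterbank: FilterbankSpec
    env_cutoff: float = 30.0
    env_order: int = 4
    flip: bool = False
    rms_match: bool = True

    def __post_init__(self) -> None:
        if self.env_order < 1:
            raise ValueError("env_order must be >= 1")
        if self.env_cutoff >= min(self.filterbank.centers):
            raise ValueError("env_cutoff must lie below the lowest band centre")

    def envelope_sos(self) -> np.ndarray:
        """Low-pass filter used for envelope smoothing."""
        return signal.butter(
            self.env_order,
            self.env_cutoff,
            btype="lowpass",
            fs=self.filterbank.sample_rate,
            output="sos",
        )


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the stimulus grid: band count x SNR x intelligibility."""

    n_bands: int
    snr_db: float
    kind: str  # "intelligible" | "unintelligible"

    def __post_init__(self) -> None:
        if self.n_bands not in BAND_COUNTS:
            raise ValueError(f"n_bands must be one of {BAND_COUNTS}")
        if self.snr_db not in SNR_GRID_DB:
            raise ValueError(f"snr_db must be on the grid {SNR_GRID_DB}")
        if self.kind not in ("intelligible", "unintelligible"):
            raise ValueError("kind must be 'intelligible' or 'unintelligible'")


def condition_grid() -> list[StimulusCondition]:
    """All 20 stimulus conditions: 5 SNRs x 2 band counts x 2 kinds."""
    return [
        StimulusCondition(n_bands=nb, snr_db=snr, kind=kind)
        for kind in ("intelligible", "unintelligible")
        for nb in BAND_COUNTS
        for snr in SNR_GRID_DB
    ]


def default_config(n_bands: int = 8, flip: bool = False) -> VocoderConfig:
    return VocoderConfig(filterbank=make_filterbank(n_bands), flip=flip)


# ---------------------------------------------------------------------------
# core DSP


def extract_envelope(band: AudioSignal, cfg: VocoderConfig) -> AudioSignal:
    """Amplitude envelope of one analysis band.

    Half-wave rectify, then low-pass (Butterworth, ``cfg.env_order``,
    ``cfg.env_cutoff`` Hz).  Silence maps to silence.
    """
    if band.sample_rate != cfg.filterbank.sample_rate:
        raise ValueError("band sample rate does not match the vocoder config")
    rectified = np.maximum(band.samples, 0.0)
    env = signal.sosfilt(cfg.envelope_sos(), rectified)
    return AudioSignal(env, band.sample_rate)


def _flip_index(b: int, n_bands: int) -> int:
    """Destination band for envelope ``b`` under spectral inversion (0-based)."""
    return n_bands - 1 - b


def vocode_bands(speech: AudioSignal, cfg: VocoderConfig) -> tuple[list[np.ndarray], list[float]]:
    """Per-band synthesized components and per-band analysis RMS levels.

    Returns (components, analysis_rms) where ``components[b]`` is the
    synthesized signal driven by analysis band b's envelope (rendered in the
    destination band when flipped) and ``analysis_rms[b]`` is the RMS of
    analysis band b's output.  With ``rms_match`` on, each component's RMS is
    restored to its *source* band's analysis RMS, so spectral inversion moves
    energy from high bands into low bands and vice versa — the long-term band
    spectrum of flipped speech mirrors the original's.
    """
    fb = cfg.filterbank
    if speech.sample_rate != fb.sample_rate:
        raise ValueError("speech sample rate does not match the filterbank")
    if len(speech.samples) == 0:
        raise ValueError("empty signal")
    n = fb.n_bands
    t = np.arange(len(speech.samples)) / fb.sample_rate

    components: list[np.ndarray] = []
    analysis_rms: list[float] = []
    for b in range(n):
        band = signal.sosfilt(fb.band_sos(b), speech.samples)
        a_rms = float(np.sqrt(np.mean(band**2)))
        env = extract_envelope(AudioSignal(band, fb.sample_rate), cfg).samples
        dest = _flip_index(b, n) if cfg.flip else b
        carrier = np.sin(2 * np.pi * fb.centers[dest] * t)
        synth = signal.sosfilt(fb.band_sos(dest), env * carrier)
        if cfg.rms_match:
            synth_rms = float(np.sqrt(np.mean(synth**2)))
            synth = synth * (a_rms / synth_rms) if synth_rms > 0 else synth * 0.0
        components.append(synth)
        analysis_rms.append(a_rms)
    return components, analysis_rms


def vocode(speech: AudioSignal, cfg: VocoderConfig) -> AudioSignal:
    """Sine-vocode ``speech``; spectral inversion when ``cfg.flip`` is set.

    Band b's envelope drives the carrier and bandpass of band b (unflipped)
    or band n+1-b (flipped); per-band RMS is restored to the analysis level
    and the bands are summed.  Output duration equals input duration.
    """
    components, _ = vocode_bands(speech, cfg)
    out = np.sum(components, axis=0)
    return AudioSignal(out, cfg.filterbank.sample_rate)


def mix_at_snr(target: AudioSignal, masker: AudioSignal, snr_db: float,
               reference_rms: float = REFERENCE_RMS) -> AudioSignal:
    """Mix ``target`` and ``masker`` at a nominal SNR (RMS ratio, dB).

    The gain is applied to the target: g = 10^(snr/20) * RMS(masker)/RMS(target);
    the sum is then normalised to ``reference_rms`` so every stimulus has the
    same overall level.  The masker is looped or truncated to target length.
    """
    if target.sample_rate != masker.sample_rate:
        raise ValueError("sample-rate mismatch between target and masker")
    if target.rms == 0 or masker.rms == 0:
        raise ValueError("cannot mix: zero-RMS target or masker")
    m = masker.samples
    n = len(target.samples)
    if len(m) < n:
        m = np.tile(m, int(np.ceil(n / len(m))))
    m = m[:n]
    m_rms = float(np.sqrt(np.mean(m**2)))
    g = 10.0 ** (snr_db / 20.0) * m_rms / target.rms
    mixture = g * target.samples + m
    mix_rms = float(np.sqrt(np.mean(mixture**2)))
    if mix_rms > 0:
        mixture = mixture * (reference_rms / mix_rms)
    return AudioSignal(mixture, target.sample_rate)


def make_trial(kind: str, sentence_a: AudioSignal, sentence_b: AudioSignal,
               cond: StimulusCondition, cfg: VocoderConfig) -> AudioSignal:
    """Build one discrimination trial.

    intelligible: unflipped vocoded ``sentence_a`` mixed with flipped vocoded
    ``sentence_b`` at ``cond.snr_db``.  unintelligible: both flipped, same SNR.
    Both kinds are normalised to the same reference RMS so they match in
    overall intensity and spectral complexity.
    """
    if kind not in ("intelligible", "unintelligible"):
        raise ValueError("kind must be 'intelligible' or 'unintelligible'")
    if sentence_a.samples.shape == sentence_b.samples.shape and np.array_equal(
        sentence_a.samples, sentence_b.samples
    ):
        raise ValueError("sentence_a and sentence_b must be distinct sentences")
    flip_a = kind == "unintelligible"
    svs_a = vocode(sentence_a, replace(cfg, flip=flip_a))
    svs_b = vocode(sentence_b, replace(cfg, flip=True))
    return mix_at_snr(svs_a, svs_b, cond.snr_db)


def make_target_sound(sentence_a: AudioSignal, sentence_b: AudioSignal,
                      cfg: VocoderConfig, seed: int = 0) -> AudioSignal:
    """'Scratchy' attention-target sound: flipped sine-vocoded speech that is
    subsequently noise-vocoded on the same filterbank (band envelopes modulate
    band-limited noise carriers), giving a denser spectrum and different
    timbre than the sine-vocoded stimuli."""
    if sentence_a.samples.shape == sentence_b.samples.shape and np.array_equal(
        sentence_a.samples, sentence_b.samples
    ):
        raise ValueError("sentence_a and sentence_b must be distinct sentences")
    svs = vocode(mix_plain(sentence_a, sentence_b), replace(cfg, flip=True))
    return noise_vocode(svs, cfg, seed=seed)


def mix_plain(a: AudioSignal, b: AudioSignal) -> AudioSignal:
    """Sum two signals sample-wise (shorter one looped), no level change."""
    if a.sample_rate != b.sample_rate:
        raise ValueError("sample-rate mismatch")
    n = len(a.samples)
    m = b.samples
    if len(m) < n:
        m = np.tile(m, int(np.ceil(n / len(m))))
    return AudioSignal(a.samples + m[:n], a.sample_rate)


def noise_vocode(speech: AudioSignal, cfg: VocoderConfig, seed: int = 0) -> AudioSignal:
    """Noise vocoder on the same filterbank: band envelopes x band-limited
    white-noise carriers, per-band RMS matched to the analysis output."""
    fb = cfg.filterbank
    if speech.sample_rate != fb.sample_rate:
        raise ValueError("speech sample rate does not match the filterbank")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(speech.samples)
    for b in range(fb.n_bands):
        band = signal.sosfilt(fb.band_sos(b), speech.samples)
        env = extract_envelope(AudioSignal(band, fb.sample_rate), cfg).samples
        carrier = signal.sosfilt(fb.band_sos(b), rng.standard_normal(len(env)))
        synth = signal.sosfilt(fb.band_sos(b), env * carrier)
        band_rms = float(np.sqrt(np.mean(band**2)))
        synth_rms = float(np.sqrt(np.mean(synth**2)))
        synth = synth * (band_rms / synth_rms) if synth_rms > 0 else synth * 0.0
        out += synth
    return AudioSignal(out, fb.sample_rate)


def measure_lowpass_cutoff(sos: np.ndarray, sample_rate: float,
                           f_max: float = 200.0, n_grid: int = 200_001) -> float:
    """Half-power (-3 dB) frequency of a low-pass design, read from its
    computed magnitude response on a fine grid with linear interpolation."""
    freqs = np.linspace(0.0, f_max, n_grid)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * freqs / sample_rate)
    mag = np.abs(h)
    target = 1.0 / np.sqrt(2.0)
    idx = int(np.argmax(mag < target))
    if idx == 0:
        raise ValueError("response never crosses -3 dB on the grid")
    f1, f2 = freqs[idx - 1], freqs[idx]
    m1, m2 = mag[idx - 1], mag[idx]
    return float(f1 + (m1 - target) / (m1 - m2) * (f2 - f1))


# ---------------------------------------------------------------------------
# synthetic speech-like source (fixture generator standing in for recorded
# sentences)


def synth_speechlike(duration: float, seed: int, sample_rate: float = 22050.0) -> AudioSignal:
    """Deterministic synthetic speech-like signal.

    Harmonic source near 110 Hz with slow pitch drift, shaped by three
    time-varying formant resonators (F1/F2/F3 random walks within typical
    male-speech ranges), with syllabic amplitude modulation at a per-seed
    rate in 3–5 Hz.  Bit-for-bit reproducible per seed.
    """
    if not 1.0 <= duration <= 5.0:
        raise ValueError("duration must be in [1, 5] seconds")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    # voiced source: harmonics of a drifting f0, 1/h amplitude roll-off
    f0 = 110.0 * (1.0 + 0.04 * np.sin(2 * np.pi * rng.uniform(0.3, 0.8) * t
                                      + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(f0) / sample_rate
    n_harm = int(5000 // 110)
    source = np.zeros(n)
    for h in range(1, n_harm + 1):
        source += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h

    # piecewise-stationary formant shaping, 50 ms frames with filter-state
    # continuity across frame boundaries
    frame = int(0.05 * sample_rate)
    n_frames = int(np.ceil(n / frame))
    ranges = [(300.0, 800.0), (900.0, 2200.0), (2300.0, 3000.0)]
    bws = [80.0, 120.0, 160.0]
    tracks = []
    for lo, hi in ranges:
        walk = np.cumsum(rng.normal(0, 0.12, n_frames))
        walk = (walk - walk.min()) / max(walk.max() - walk.min(), 1e-12)
        tracks.append(lo + (hi - lo) * (0.15 + 0.7 * walk))
    shaped = np.zeros(n)
    zis = [None, None, None]
    for fi in range(n_frames):
        seg = source[fi * frame: (fi + 1) * frame]
        acc = np.zeros_like(seg)
        for k in range(3):
            r = np.exp(-np.pi * bws[k] / sample_rate)
            theta = 2 * np.pi * tracks[k][fi] / sample_rate
            b = [1.0 - r]
            a = [1.0, -2 * r * np.cos(theta), r * r]
            if zis[k] is None:
                zis[k] = signal.lfilter_zi(b, a) * seg[0]
            y, zis[k] = signal.lfilter(b, a, seg, zi=zis[k])
            acc += y
        shaped[fi * frame: fi * frame + len(seg)] = acc

    am_rate = rng.uniform(3.0, 5.0)
    am = 0.55 + 0.45 * np.cos(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi))
    ramp = np.minimum(1.0, np.minimum(t, t[::-1]) / 0.05)
    out = shaped * am * ramp
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out * (PEAK_CEILING / peak)
    return AudioSignal(out, sample_rate)


# ---------------------------------------------------------------------------
# level handling + WAV I/O


def peak_normalize(sig: AudioSignal, ceiling: float = PEAK_CEILING) -> AudioSignal:
    """Scale down (never up) so that max |sample| <= ceiling."""
    peak = float(np.max(np.abs(sig.samples))) if len(sig.samples) else 0.0
    if peak > ceiling:
        return AudioSignal(sig.samples * (ceiling / peak), sig.sample_rate)
    return sig


def write_wav(path, sig: AudioSignal) -> None:
    """Write mono 16-bit PCM WAV."""
    clipped = peak_normalize(sig)
    pcm = np.clip(np.round(clipped.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(sig.sample_rate)), pcm)


def read_wav(path) -> AudioSignal:
    """Read a mono WAV into float samples in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioSignal(data, float(rate))
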