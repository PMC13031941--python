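"""Spectrogram frontend: 30-s audio frames -> fixed-shape PCEN tensors.

The detector consumes 30-second segments at 200 Hz, transformed into
Hann-windowed magnitude spectrograms (256-point FFT, 75% overlap),
band-limited to 4-80 Hz, normalised with per-channel energy normalisation
(PCEN), bilinearly resized to 97 time frames x 90 frequency bins, min-max
scaled to [0, 1] and replicated into three identical channels — the
97 x 90 x 3 tensor an image-recognition backbone expects.

PCEN adaptively normalises each frequency channel by a smoothed version of
its own recent energy:

    M[t] = (1 - s) * M[t-1] + s * E[t]
    out  = (E / (eps + M)**alpha + delta)**r - delta**r

which suppresses stationary background (including slowly varying ambient
and the tail of repeated airgun shots) while emphasising transient calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly
from scipy.signal.windows import hann
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FrontendConfig",
    "SpectrogramFrame",
    "resample",
    "stft_bandlimit",
    "pcen",
    "to_input",
    "SpectrogramFrontend",
]


@dataclass
class FrontendConfig:
    """Frontend parameters; defaults reproduce the detector input contract."""

    target_rate_hz: float = 200.0
    frame_len_s: float = 30.0
    nfft: int = 256
    overlap_frac: float = 0.75
    band_hz: tuple[float, float] = (4.0, 80.0)
    # PCEN: gain alpha, bias delta, exponent r, smoothing coefficient s, floor eps
    pcen_alpha: float = 0.98
    pcen_delta: float = 2.0
    pcen_r: float = 0.5
    pcen_s: float = 0.025
    pcen_eps: float = 1e-6
    out_shape: tuple[int, int, int] = (97, 90, 3)

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must be in [0, 1)")
        lo, hi = self.band_hz
        if not (0 < lo < hi < self.target_rate_hz / 2):
            raise ValueError("band_hz must lie within (0, target_rate/2)")

    @property
    def hop(self) -> int:
        return int(round(self.nfft * (1.0 - self.overlap_frac)))

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_len_s * self.target_rate_hz))


@dataclass
class SpectrogramFrame:
    """A band-limited (time x frequency) spectrogram with its axis metadata."""

    values: np.ndarray  # shape (n_time, n_freq), non-negative
    freqs_hz: np.ndarray  # ascending, length n_freq
    frame_start: float = 0.0
    instrument_id: str = ""


def resample(waveform: np.ndarray, in_rate_hz: float, target_rate_hz: float = 200.0) -> np.ndarray:
    """Anti-aliased decimation to the target rate; identity if already there.

    Upsampling is refused: instruments record at >= 200 Hz and interpolated
    audio would fabricate band content the detector was never trained on.
    """
    if in_rate_hz < target_rate_hz:
        raise ValueError(
            f"in_rate {in_rate_hz} Hz below target {target_rate_hz} Hz; upsampling unsupported"
        )
    if in_rate_hz == target_rate_hz:
        return waveform
    from fractions import Fraction

    frac = Fraction(target_rate_hz / in_rate_hz).limit_denominator(1000)
    return resample_poly(waveform, frac.numerator, frac.denominator)


def stft_bandlimit(frame: np.ndarray, config: FrontendConfig | None = None) -> SpectrogramFrame:
    """Hann-windowed STFT magnitude of one 30-s frame, band-limited 4-80 Hz.

    The frame must be exactly ``frame_len_s`` at ``target_rate_hz``
    (6000 samples by default).  No boundary padding is applied, so the
    number of time frames is floor((n - nfft)/hop) + 1 = 90 with defaults.
    Output axes are (time, frequency), frequency ascending.
    """
    config = config or FrontendConfig()
    n = config.frame_samples
    if frame.shape != (n,):
        raise ValueError(f"expected a frame of exactly {n} samples, got {frame.shape}")
    win = hann(config.nfft, sym=False)
    # windows slide from sample 0 with no boundary padding (convention pinned
    # here rather than delegated to scipy's centred-window STFT wrappers)
    n_time = (n - config.nfft) // config.hop + 1
    idx = config.hop * np.arange(n_time)[:, None] + np.arange(config.nfft)[None, :]
    segments = frame[idx] * win[None, :]
    spec = np.abs(np.fft.rfft(segments, n=config.nfft, axis=1))  # (time, freq)
    freqs = np.fft.rfftfreq(config.nfft, d=1.0 / config.target_rate_hz)
    lo, hi = config.band_hz
    keep = (freqs >= lo) & (freqs <= hi)
    return SpectrogramFrame(values=spec[:, keep], freqs_hz=freqs[keep])


def pcen(
    spectrogram: np.ndarray,
    alpha: float = 0.98,
    delta: float = 2.0,
    r: float = 0.5,
    s: float = 0.025,
    eps: float = 1e-6,
) -> np.ndarray:
    """Per-channel energy normalisation of a (time x frequency) magnitude array.

    The smoother M is a first-order IIR along time, initialised at the
    first frame (M[0] = E[0]).  All-zero input maps to all-zero output and
    outputs are always >= 0 for non-negative inputs.
    """
    E = np.asarray(spectrogram, dtype=float)
    if np.any(E < 0):
        raise ValueError("PCEN requires non-negative input")
    if E.size == 0:
        raise ValueError("empty spectrogram")
    M = np.empty_like(E)
    M[0] = E[0]
    for t in range(1, E.shape[0]):
        M[t] = (1.0 - s) * M[t - 1] + s * E[t]
    out = (E / (eps + M) ** alpha + delta) ** r - delta**r
    return np.maximum(out, 0.0)


def to_input(spectrogram: np.ndarray, out_shape: tuple[int, int, int] = (97, 90, 3)) -> np.ndarray:
    """Resize a PCEN spectrogram to the detector tensor shape.

    Bilinear resize to (time, freq) = out_shape[:2], min-max scale to
    [0, 1] (a constant input maps to all zeros), replicate into
    ``out_shape[2]`` identical channels.
    """
    spec = np.asarray(spectrogram, dtype=float)
    if spec.size == 0:
        raise ValueError("empty spectrogram")
    resized = _sk_resize(
        spec, out_shape[:2], order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    lo, hi = resized.min(), resized.max()
    scaled = (resized - lo) / (hi - lo) if hi > lo else np.zeros_like(resized)
    return np.repeat(scaled[:, :, None], out_shape[2], axis=2)


class SpectrogramFrontend(TransformerMixin, BaseEstimator):
    """Transformer mapping raw 30-s frames to detector input tensors.

    Stateless (``fit`` only validates parameters); ``transform`` accepts a
    list/array of waveform frames at ``in_rate_hz`` and returns an array of
    shape (n_frames, *out_shape).  Deterministic: same bytes in, same
    tensor out.
    """

    def __init__(self, config: FrontendConfig | None = None, in_rate_hz: float = 200.0):
        self.config = config
        self.in_rate_hz = in_rate_hz

    def fit(self, X=None, y=None):
        self.config_ = self.config or FrontendConfig()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        cfg = self.config_
        out = np.empty((len(X), *cfg.out_shape))
        for i, wave in enumerate(X):
            wave = resample(np.asarray(wave, dtype=float), self.in_rate_hz, cfg.target_rate_hz)
            sf = stft_bandlimit(wave, cfg)
            normalised = pcen(
                sf.values, cfg.pcen_alpha, cfg.pcen_delta, cfg.pcen_r, cfg.pcen_s, cfg.pcen_eps
            )
            out[i] = to_input(normalised, cfg.out_shape)
        return out
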