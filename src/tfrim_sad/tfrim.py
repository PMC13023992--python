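"""Time-Frequency Respiratory Impedance Map (TFRIM) construction.

A two-channel IOS recording (oral pressure, flow) is sliced into 4-s Hamming
windows hopped by 0.4 s.  Within each window the impedance is estimated by
Welch-averaged cross-power spectral densities,

    Z_t[k] = S_PF(t)[k] / S_FF(t)[k],

which is robust to measurement noise because noise uncorrelated with flow
averages out of the cross-spectrum.  The magnitude-squared coherence

    gamma_t^2[k] = |S_PF[k]|^2 / (S_PP[k] * S_FF[k])

serves as quality control: entries below the 0.90 threshold are zeroed, and
the 24 frequency channels with the highest time-mean coherence are retained,
giving a fixed (2, 24, 48) resistance/reactance tensor per recording.

Welch averaging uses half-overlapping Hamming-tapered sub-segments per
window (a single-segment estimate would make the coherence identically 1).
The sub-segment length defaults to 0.8 s -- exactly two periods of the 2.5 Hz
excitation -- so every harmonic lands on an even sub-segment bin, where the
Hamming kernel has exact nulls; inter-harmonic leakage in the Welch
cross-spectra then vanishes by construction.  Sub-segment FFTs are
zero-padded to the full window length so the frequency grid keeps the
0.25 Hz spacing of the 4-s window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, detrend as _detrend, filtfilt, get_window

from .simulate import MIN_SAMPLES, IOSRecording

__all__ = [
    "TFRIMConfig",
    "WindowedSpectra",
    "RawTFRIM",
    "TFRIMTensor",
    "ScalarIOSParams",
    "QualityError",
    "global_impedance",
    "scalar_ios_parameters",
    "stft_windows",
    "window_impedance",
    "coherence_screen",
    "select_channels",
    "build_tfrim",
    "TFRIMTransformer",
]


class QualityError(RuntimeError):
    """Raised when a recording fails coherence-based quality control."""


@dataclass(frozen=True)
class TFRIMConfig:
    window_s: float = 4.0
    hop_s: float = 0.4
    gamma_th: float = 0.90
    n_channels: int = 24
    subsegment_s: float = 0.8
    subsegment_overlap: float = 0.5
    highpass_hz: float = 1.0  # 0 disables; cancels exactly in the Z ratio
    crop_samples: int = MIN_SAMPLES

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma_th <= 1.0):
            raise ValueError("gamma_th must lie in (0, 1]")
        if not (0.0 < self.subsegment_s < self.window_s):
            raise ValueError("subsegment_s must lie in (0, window_s)")
        if self.window_s <= 0 or self.hop_s <= 0 or self.n_channels < 1:
            raise ValueError("window_s, hop_s and n_channels must be positive")


@dataclass
class WindowedSpectra:
    """Per-window spectra and Welch-averaged (cross-)power densities."""

    Pt: np.ndarray  # (T, K) complex full-window spectra, pressure
    Ft: np.ndarray  # (T, K) complex full-window spectra, flow
    S_PF: np.ndarray  # (T, K) complex cross-power density
    S_PP: np.ndarray  # (T, K) real auto-power, pressure
    S_FF: np.ndarray  # (T, K) real auto-power, flow
    gamma2: np.ndarray  # (T, K) coherence in [0, 1]
    window_times: np.ndarray  # (T,) window centres, s
    freqs: np.ndarray  # (K,) Hz


@dataclass
class RawTFRIM:
    R: np.ndarray  # (T, K) kPa/(L/s)
    X: np.ndarray  # (T, K)
    gamma2: np.ndarray  # (T, K)
    mask: np.ndarray  # (T, K) bool, True = retained
    freqs: np.ndarray
    window_times: np.ndarray


@dataclass
class TFRIMTensor:
    values: np.ndarray  # (2, H, W): channel 0 = R, channel 1 = X
    freqs: np.ndarray  # (H,) retained frequencies, ascending
    times: np.ndarray  # (W,) window centres, s
    mean_coherence: np.ndarray  # (H,) time-mean coherence per retained channel
    subject_id: str = ""


@dataclass
class ScalarIOSParams:
    """Classical scalar IOS indices; ``fres`` is None when the reactance does
    not cross zero inside the measured band."""

    R5: float | None
    R20: float | None
    R35: float | None
    X5: float | None
    Z5: float | None
    Fres: float | None


# --------------------------------------------------------------------------

def global_impedance(
    rec: IOSRecording,
    flow_floor_rel: float = 1e-12,
    taper: str = "hamming",
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-recording impedance spectrum Z[k] = P[k]/F[k] over one-sided bins.

    Both channels are linearly detrended and tapered before the DFT; the taper
    cancels in the ratio at excited bins while suppressing leakage from the
    off-bin breathing component.  Bins whose flow power falls below
    ``flow_floor_rel`` of the band maximum are returned as NaN rather than
    divided.

    Returns (Z, freqs).
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if not np.any(rec.flow):
        raise ValueError("flow is identically zero; impedance undefined")
    w = get_window(taper, rec.n_samples) if taper != "boxcar" else np.ones(rec.n_samples)
    p = _detrend(rec.pressure, type="linear") * w
    f = _detrend(rec.flow, type="linear") * w
    P = np.fft.rfft(p)
    F = np.fft.rfft(f)
    power = np.abs(F) ** 2
    ok = power > flow_floor_rel * power.max()
    Z = np.full(P.shape, np.nan + 0j, dtype=complex)
    Z[ok] = P[ok] / F[ok]
    freqs = np.fft.rfftfreq(rec.n_samples, d=1.0 / rec.fs)
    return Z, freqs


def scalar_ios_parameters(Z: np.ndarray, freqs: np.ndarray,
                          band: tuple[float, float] = (5.0, 60.0)) -> ScalarIOSParams:
    """Interpolate R, X at 5/20/35 Hz and locate the reactance zero crossing.

    Only bins with defined (finite) impedance inside ``band`` are used; the
    default band starts at the lowest clinically reported oscillation
    frequency, which also keeps breathing-band bins out of the zero-crossing
    search.  Parameters whose target frequency falls outside the defined band
    come back as None instead of failing.
    """
    Z = np.asarray(Z)
    freqs = np.asarray(freqs, dtype=float)
    ok = np.isfinite(Z) & (freqs >= band[0]) & (freqs <= band[1])
    f = freqs[ok]
    if f.size < 2:
        return ScalarIOSParams(None, None, None, None, None, None)
    r = Z[ok].real
    x = Z[ok].imag
    order = np.argsort(f)
    f, r, x = f[order], r[order], x[order]

    def interp(target: float, y: np.ndarray) -> float | None:
        if not (f[0] <= target <= f[-1]):
            return None
        return float(np.interp(target, f, y))

    r5, r20, r35 = interp(5.0, r), interp(20.0, r), interp(35.0, r)
    x5 = interp(5.0, x)
    z5 = float(np.hypot(r5, x5)) if (r5 is not None and x5 is not None) else None

    fres = None
    sign = np.sign(x)
    crossings = np.nonzero(np.diff(sign) > 0)[0]  # negative -> positive
    if crossings.size:
        i = int(crossings[0])
        fres = float(f[i] - x[i] * (f[i + 1] - f[i]) / (x[i + 1] - x[i]))
    elif np.any(x == 0.0):
        fres = float(f[np.nonzero(x == 0.0)[0][0]])
    return ScalarIOSParams(R5=r5, R20=r20, R35=r35, X5=x5, Z5=z5, Fres=fres)


def ios_scalar_params(rec: IOSRecording, excitation_f0: float = 2.5,
                      n_harmonics: int = 24) -> ScalarIOSParams:
    """Scalar IOS indices from a recording, sampling the whole-recording
    impedance at the excitation harmonics m*f0 (the only frequencies the
    device injects energy at) before interpolating.

    Using the full DFT grid instead would hand the interpolator leakage bins
    whose impedance mirrors the nearest harmonic, biasing the resonant
    frequency.
    """
    Z, freqs = global_impedance(rec)
    targets = excitation_f0 * np.arange(1, n_harmonics + 1)
    idx = np.argmin(np.abs(freqs[None, :] - targets[:, None]), axis=1)
    return scalar_ios_parameters(Z[idx], freqs[idx])


# --------------------------------------------------------------------------

def _segment(rec: IOSRecording, cfg: TFRIMConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nwin = int(round(cfg.window_s * rec.fs))
    hop = int(round(cfg.hop_s * rec.fs))
    if rec.n_samples < nwin:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{nwin}-sample analysis window"
        )
    p_wins = sliding_window_view(rec.pressure, nwin)[::hop]
    f_wins = sliding_window_view(rec.flow, nwin)[::hop]
    starts = np.arange(p_wins.shape[0]) * hop
    times = (starts + nwin / 2.0) / rec.fs
    return p_wins, f_wins, times


def stft_windows(rec: IOSRecording, config: TFRIMConfig = TFRIMConfig()) -> WindowedSpectra:
    """Slice into tapered windows and compute per-window and Welch spectra.

    Window count is floor((N - window)/hop) + 1; per-window linear detrend is
    applied before tapering; the frequency grid has 1/window_s spacing.

    Both channels are first passed through the same zero-phase high-pass
    (default 1 Hz, below the lowest excitation harmonic): an identical filter
    on pressure and flow cancels exactly in the impedance ratio and in the
    coherence, while removing the large breathing-band component whose
    leakage would otherwise bias low-harmonic bins.
    """
    if config.highpass_hz > 0:
        ba = butter(4, config.highpass_hz, btype="highpass", fs=rec.fs)
        # Gustafsson forward-backward initialisation: plain padding leaves
        # second-long transients at the record edges that bias edge windows
        rec = IOSRecording(pressure=filtfilt(*ba, rec.pressure, method="gust"),
                           flow=filtfilt(*ba, rec.flow, method="gust"), fs=rec.fs,
                           subject_id=rec.subject_id)
    p_wins, f_wins, times = _segment(rec, config)
    nwin = p_wins.shape[1]
    if config.highpass_hz > 0:
        # the high-pass already removed trend and breathing band; a further
        # per-window detrend would project the two channels differently and
        # spoil their exact linear relation
        p_d, f_d = p_wins, f_wins
    else:
        p_d = _detrend(p_wins, axis=1, type="linear")
        f_d = _detrend(f_wins, axis=1, type="linear")

    full_taper = get_window("hamming", nwin)
    Pt = np.fft.rfft(p_d * full_taper, axis=1)
    Ft = np.fft.rfft(f_d * full_taper, axis=1)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / rec.fs)

    # Welch sub-segments inside each window (half-overlapping, tapered,
    # zero-padded back to the full-window FFT grid)
    ov = config.subsegment_overlap
    seg_len = int(round(config.subsegment_s * rec.fs))
    step = max(int(round(seg_len * (1 - ov))), 1)
    if seg_len < 8 or seg_len > nwin:
        raise ValueError("sub-segment configuration yields degenerate segments")
    p_sub = sliding_window_view(p_d, seg_len, axis=1)[:, ::step]
    f_sub = sliding_window_view(f_d, seg_len, axis=1)[:, ::step]
    if p_sub.shape[1] < 2:
        raise ValueError(
            "sub-segment configuration yields fewer than 2 averages; "
            "coherence would be undefined"
        )
    if config.highpass_hz <= 0:
        p_sub = _detrend(p_sub, axis=2, type="linear")
        f_sub = _detrend(f_sub, axis=2, type="linear")
    taper = get_window("hamming", seg_len)
    Psub = np.fft.rfft(p_sub * taper, n=nwin, axis=2)
    Fsub = np.fft.rfft(f_sub * taper, n=nwin, axis=2)

    S_PF = np.mean(Psub * np.conj(Fsub), axis=1)
    S_PP = np.mean(np.abs(Psub) ** 2, axis=1)
    S_FF = np.mean(np.abs(Fsub) ** 2, axis=1)
    denom = S_PP * S_FF
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma2 = np.where(denom > 0, np.abs(S_PF) ** 2 / denom, 0.0)
    gamma2 = np.clip(gamma2, 0.0, 1.0)

    return WindowedSpectra(Pt=Pt, Ft=Ft, S_PF=S_PF, S_PP=S_PP, S_FF=S_FF,
                           gamma2=gamma2, window_times=times, freqs=freqs)


def window_impedance(ws: WindowedSpectra, flow_floor_rel: float = 1e-12) -> RawTFRIM:
    """Split the Welch impedance Z_t[k] = S_PF/S_FF into R and X maps.

    Bins whose flow auto-power falls below ``flow_floor_rel`` of the band
    maximum are zeroed and masked out (unexcited bins would otherwise produce
    spurious impedance from a near-zero division).
    """
    floor = flow_floor_rel * ws.S_FF.max()
    ok = ws.S_FF > floor
    Z = np.zeros(ws.S_PF.shape, dtype=complex)
    Z[ok] = ws.S_PF[ok] / ws.S_FF[ok]
    return RawTFRIM(R=Z.real.copy(), X=Z.imag.copy(), gamma2=ws.gamma2.copy(),
                    mask=ok.copy(), freqs=ws.freqs.copy(),
                    window_times=ws.window_times.copy())


def coherence_screen(raw: RawTFRIM, gamma_th: float = 0.90) -> RawTFRIM:
    """Zero and unmask every entry whose coherence falls below the threshold."""
    keep = raw.mask & (raw.gamma2 >= gamma_th)
    R = np.where(keep, raw.R, 0.0)
    X = np.where(keep, raw.X, 0.0)
    return RawTFRIM(R=R, X=X, gamma2=raw.gamma2.copy(), mask=keep,
                    freqs=raw.freqs.copy(), window_times=raw.window_times.copy())


def select_channels(raw: RawTFRIM, n_channels: int = 24, subject_id: str = "") -> TFRIMTensor:
    """Keep the ``n_channels`` frequency bins with the highest time-mean
    coherence (screened-out windows count as zero), re-sorted by frequency.

    Ties at the cutoff are broken toward the lower frequency.  Selection uses
    only this recording's own signals.
    """
    score = np.where(raw.mask, raw.gamma2, 0.0).mean(axis=0)  # (K,)
    eligible = np.nonzero(score > 0.0)[0]
    if eligible.size < n_channels:
        raise QualityError(
            f"only {eligible.size} frequency bins passed coherence screening; "
            f"{n_channels} required"
        )
    # stable sort on (-score, frequency): equal scores fall to lower frequency
    order = np.lexsort((raw.freqs[eligible], -score[eligible]))
    kept = np.sort(eligible[order[:n_channels]])  # ascending frequency
    values = np.stack([raw.R[:, kept].T, raw.X[:, kept].T])  # (2, H, T)
    return TFRIMTensor(values=values, freqs=raw.freqs[kept].copy(),
                       times=raw.window_times.copy(),
                       mean_coherence=score[kept].copy(), subject_id=subject_id)


def build_tfrim(rec: IOSRecording, config: TFRIMConfig = TFRIMConfig()) -> TFRIMTensor:
    """Full pipeline: crop -> STFT -> Welch impedance -> screen -> select.

    The recording is cropped to its first ``crop_samples`` samples; shorter
    recordings are rejected rather than padded.
    """
    if rec.n_samples < config.crop_samples:
        raise ValueError(
            f"recording has {rec.n_samples} samples; map construction requires "
            f"at least {config.crop_samples}"
        )
    if not (np.all(np.isfinite(rec.pressure)) and np.all(np.isfinite(rec.flow))):
        raise ValueError("recording contains non-finite samples")
    cropped = IOSRecording(pressure=rec.pressure[: config.crop_samples],
                           flow=rec.flow[: config.crop_samples],
                           fs=rec.fs, subject_id=rec.subject_id)
    try:
        ws = stft_windows(cropped, config)
        raw = window_impedance(ws)
        screened = coherence_screen(raw, config.gamma_th)
        return select_channels(screened, config.n_channels, subject_id=rec.subject_id)
    except QualityError:
        raise
    except ValueError as exc:
        raise ValueError(f"TFRIM construction failed: {exc}") from exc


# --------------------------------------------------------------------------

class TFRIMTransformer:
    """scikit-learn style transformer: recordings -> stacked TFRIM tensors.

    Stateless (``fit`` is a no-op kept for pipeline compatibility);
    ``transform`` maps a sequence of :class:`IOSRecording` to an array of
    shape (n, 2, n_channels, n_windows).
    """

    def __init__(self, window_s: float = 4.0, hop_s: float = 0.4,
                 gamma_th: float = 0.90, n_channels: int = 24):
        self.window_s = window_s
        self.hop_s = hop_s
        self.gamma_th = gamma_th
        self.n_channels = n_channels

    def get_params(self, deep: bool = True) -> dict:
        return {"window_s": self.window_s, "hop_s": self.hop_s,
                "gamma_th": self.gamma_th, "n_channels": self.n_channels}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> TFRIMConfig:
        return TFRIMConfig(window_s=self.window_s, hop_s=self.hop_s,
                           gamma_th=self.gamma_th, n_channels=self.n_channels)

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.stack([build_tfrim(rec, cfg).values for rec in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
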