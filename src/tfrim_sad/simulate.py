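"""Synthetic impulse-oscillometry cohorts with a known impedance ground truth.

The forward model is a single-compartment resistance--inertance--compliance
(RIC) respiratory system probed, as in clinical IOS, by a weak multi-harmonic
flow oscillation superimposed on tidal breathing:

    Z(f, t) = R(f, t) + j (2*pi*f*I - 1/(2*pi*f*C))

with a resistance that rises during expiration (the within-breath signature of
small airway dysfunction) and falls with frequency,

    R(f, t) = (R0 + dR_exp * 1[expiration]) - fdep * (f - 5),  floored at 0.05.

Pressure is synthesised quasi-statically: the impedance varies on the breathing
timescale (seconds), two orders of magnitude slower than the excitation period,
so each excitation harmonic is simply multiplied by the instantaneous |Z| and
phase-shifted by arg Z.  This keeps the generating impedance available in
closed form for every downstream estimator test.

Group-level parameter distributions are anchored to the published cohort
statistics (SAD vs non-SAD): mean R at 5 Hz 0.47 vs 0.37 kPa/(L/s), X5 -0.16
vs -0.10, resonant frequency 17.6 vs 13.6 Hz, and FEF ratio means 0.43/0.49/
0.35 vs 0.88/0.94/0.77.  A shared latent severity scalar couples a subject's
impedance to its spirometry ratios so that waveforms and labels carry
correlated, but not deterministic, signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SimImpedanceModel",
    "BreathingPattern",
    "ExcitationSpec",
    "SubjectRecord",
    "GroupStats",
    "GROUP_STATS",
    "resistance_at",
    "impedance_at",
    "resonant_frequency",
    "synthesize_recording",
    "sad_phenotype",
    "assign_spirometry_ratios",
    "generate_cohort",
]

MIN_SAMPLES = 9120
R_FLOOR = 0.05
F_REF = 5.0  # Hz at which R(f) equals R0


@dataclass(frozen=True)
class SimImpedanceModel:
    """Ground-truth RIC phenotype for one subject.

    Units: resistances kPa/(L/s); ``fdep`` kPa/(L/s) per Hz; inertance ``I``
    kPa*s^2/L; compliance ``C`` L/kPa; noise standard deviations in the units
    of their channel (kPa, L/s).  ``severity`` is the latent z-score shared
    with the spirometry-ratio draw; it carries no physical unit.
    """

    R0: float
    dR_exp: float = 0.0
    fdep: float = 0.0
    I: float = 5.0e-4
    C: float = 0.25
    noise_sd_p: float = 0.0
    noise_sd_f: float = 0.0
    severity: float = 0.0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.I <= 0 or self.C <= 0:
            raise ValueError("inertance and compliance must be positive")
        if self.dR_exp < 0 or self.fdep < 0:
            raise ValueError("dR_exp and fdep must be non-negative")
        if self.noise_sd_p < 0 or self.noise_sd_f < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class BreathingPattern:
    breath_rate: float = 12.0  # breaths per minute
    tidal_flow_amp: float = 0.5  # L/s
    expiratory_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (6.0 <= self.breath_rate <= 30.0):
            raise ValueError("breath_rate must lie in [6, 30] breaths/min")
        if self.tidal_flow_amp <= 0:
            raise ValueError("tidal_flow_amp must be positive")
        if not (0.0 < self.expiratory_fraction < 1.0):
            raise ValueError("expiratory_fraction must lie in (0, 1)")


def _default_amplitudes(n: int) -> tuple[float, ...]:
    # 1/m decay: pulse-train energy concentrated at the fundamental.
    return tuple(0.3 / m for m in range(1, n + 1))


@dataclass(frozen=True)
class ExcitationSpec:
    """Multi-harmonic flow excitation: first ``n_harmonics`` cosines of a
    2.5 Hz pulse train (2.5 .. n*2.5 Hz)."""

    f0: float = 2.5
    n_harmonics: int = 24
    amplitudes: tuple[float, ...] = field(default=())
    phases: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if not self.amplitudes:
            object.__setattr__(self, "amplitudes", _default_amplitudes(self.n_harmonics))
        if not self.phases:
            object.__setattr__(self, "phases", tuple(0.0 for _ in range(self.n_harmonics)))
        if len(self.amplitudes) != self.n_harmonics or len(self.phases) != self.n_harmonics:
            raise ValueError("amplitudes/phases must have n_harmonics entries")

    @property
    def frequencies(self) -> np.ndarray:
        return self.f0 * np.arange(1, self.n_harmonics + 1)


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: int  # male=1, female=0
    height: float  # cm
    weight: float  # kg
    v1: float  # FEF25-75 measured/predicted
    v2: float  # FEF50
    v3: float  # FEF75
    recording_path: str = ""

    def __post_init__(self) -> None:
        if self.age <= 0 or self.height <= 0 or self.weight <= 0:
            raise ValueError("age, height and weight must be positive")
        if min(self.v1, self.v2, self.v3) <= 0:
            raise ValueError("spirometry ratios must be positive")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (female) or 1 (male)")


# --------------------------------------------------------------------------
# closed-form impedance of the generating model (the test oracle)

def resistance_at(model: SimImpedanceModel, f, expiratory: bool = False):
    """R(f) of the generating model, with the frequency-dependence floor."""
    f = np.asarray(f, dtype=float)
    base = model.R0 + (model.dR_exp if expiratory else 0.0)
    return np.maximum(base - model.fdep * (f - F_REF), R_FLOOR)


def impedance_at(model: SimImpedanceModel, f, expiratory: bool = False):
    """Complex Z(f) = R(f) + j(2*pi*f*I - 1/(2*pi*f*C))."""
    f = np.asarray(f, dtype=float)
    w = 2.0 * np.pi * f
    return resistance_at(model, f, expiratory) + 1j * (w * model.I - 1.0 / (w * model.C))


def resonant_frequency(model: SimImpedanceModel) -> float:
    """Frequency at which reactance crosses zero: 1 / (2*pi*sqrt(I*C))."""
    return 1.0 / (2.0 * np.pi * math.sqrt(model.I * model.C))


# --------------------------------------------------------------------------
# forward synthesis

@dataclass
class IOSRecording:
    """Synchronised oral pressure (kPa) and flow (L/s) at ``fs`` Hz.

    Expiration uses the positive-flow convention: tidal flow > 0 during
    expiration.
    """

    pressure: np.ndarray
    flow: np.ndarray
    fs: float = 400.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        self.flow = np.asarray(self.flow, dtype=np.float64)
        if self.pressure.shape != self.flow.shape or self.pressure.ndim != 1:
            raise ValueError("pressure and flow must be equal-length 1-D arrays")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.pressure.size)


def synthesize_recording(
    model: SimImpedanceModel,
    breathing: BreathingPattern = BreathingPattern(),
    excitation: ExcitationSpec = ExcitationSpec(),
    fs: float = 400.0,
    duration: float = 30.0,
    seed: int = 0,
    subject_id: str = "",
) -> IOSRecording:
    """Synthesise one pressure/flow recording from the RIC ground truth.

    Flow is a tidal sinusoid plus the harmonic excitation; pressure is the
    quasi-static per-harmonic response plus the breathing-band pressure
    R(t) * tidal flow.  Identical seeds give bit-identical output.
    """
    n = int(round(duration * fs))
    if n < MIN_SAMPLES:
        raise ValueError(
            f"duration*fs = {n} samples is below the {MIN_SAMPLES}-sample minimum "
            "required for map construction"
        )
    freqs = excitation.frequencies
    if freqs[-1] > fs / 2.0:
        raise ValueError(
            f"harmonic at {freqs[-1]:.1f} Hz exceeds the Nyquist frequency {fs / 2.0:.1f} Hz"
        )

    t = np.arange(n) / fs
    f_breath = breathing.breath_rate / 60.0
    tidal = breathing.tidal_flow_amp * np.sin(2.0 * np.pi * f_breath * t)
    expiratory = tidal > 0.0  # positive-flow expiration convention

    amps = np.asarray(excitation.amplitudes)
    phases = np.asarray(excitation.phases)
    arg = 2.0 * np.pi * np.outer(freqs, t) + phases[:, None]  # (M, n)
    flow_osc = amps[:, None] * np.cos(arg)

    # instantaneous impedance per harmonic: two states (insp/exp), switched
    z_insp = impedance_at(model, freqs, expiratory=False)[:, None]
    z_exp = impedance_at(model, freqs, expiratory=True)[:, None]
    z_t = np.where(expiratory[None, :], z_exp, z_insp)  # (M, n)
    press_osc = amps[:, None] * np.abs(z_t) * np.cos(arg + np.angle(z_t))

    # breathing-band pressure: low-frequency resistance times tidal flow
    # (frequency dependence is not extrapolated below the excitation band)
    r_breath = np.where(expiratory, model.R0 + model.dR_exp, model.R0)
    flow = tidal + flow_osc.sum(axis=0)
    pressure = r_breath * tidal + press_osc.sum(axis=0)

    rng = np.random.default_rng(seed)
    if model.noise_sd_p > 0:
        pressure = pressure + rng.normal(0.0, model.noise_sd_p, n)
    if model.noise_sd_f > 0:
        flow = flow + rng.normal(0.0, model.noise_sd_f, n)
    return IOSRecording(pressure=pressure, flow=flow, fs=fs, subject_id=subject_id)


# --------------------------------------------------------------------------
# group-conditional phenotypes

@dataclass(frozen=True)
class GroupStats:
    """Cohort anchors per group: (mean, sd) pairs."""

    r5: tuple[float, float]
    x5: tuple[float, float]
    fres: tuple[float, float]
    v: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    dr_exp: tuple[float, float]
    fdep: tuple[float, float]
    age: tuple[float, float]
    height: tuple[float, float]
    weight: tuple[float, float]
    male_fraction: float


GROUP_STATS: dict[str, GroupStats] = {
    "SAD": GroupStats(
        r5=(0.47, 0.20),
        x5=(-0.16, 0.12),
        fres=(17.56, 6.25),
        v=((0.43, 0.17), (0.49, 0.20), (0.35, 0.14)),
        dr_exp=(0.15, 0.06),
        fdep=(0.0060, 0.0025),
        age=(50.42, 18.32),
        height=(163.21, 11.38),
        weight=(66.94, 16.00),
        male_fraction=0.486,
    ),
    "nonSAD": GroupStats(
        r5=(0.37, 0.14),
        x5=(-0.10, 0.05),
        fres=(13.63, 3.96),
        v=((0.88, 0.18), (0.94, 0.19), (0.77, 0.25)),
        dr_exp=(0.03, 0.02),
        fdep=(0.0030, 0.0015),
        age=(41.04, 17.49),
        height=(164.94, 12.38),
        weight=(68.80, 19.30),
        male_fraction=0.480,
    ),
}

# Correlation between the latent severity scalar and each spirometry ratio;
# the remainder of the ratio variance is independent measurement noise.
# Strong coupling keeps the waveform-label link learnable without being
# deterministic (label residual sd = sqrt(1-rho^2) ~ 0.44 of the marginal sd).
SEVERITY_V_COUPLING = 0.9
W5 = 2.0 * np.pi * F_REF


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(min(max(mean, lo + 1e-9), hi - 1e-9))


def _demographic_factor(demographics: SubjectRecord | None) -> float:
    """Multiplicative baseline shift of R0: up with age, down with height.

    Bounded to +/-15% so demographics alone are only weakly predictive.
    """
    if demographics is None:
        return 1.0
    shift = 0.05 * (demographics.age - 45.0) / 17.5 - 0.05 * (demographics.height - 164.0) / 12.0
    return float(np.clip(1.0 + shift, 0.85, 1.15))


def sad_phenotype(
    group: str,
    demographics: SubjectRecord | None = None,
    seed: int = 0,
) -> SimImpedanceModel:
    """Draw a ground-truth impedance model from group-conditional anchors.

    The latent severity z-score drives R0, dR_exp and fdep jointly; X5 and
    resonant frequency are drawn with partial coupling and inverted through
    the RIC closed forms to obtain inertance and compliance.
    """
    if group not in GROUP_STATS:
        raise ValueError(f"group must be one of {sorted(GROUP_STATS)}, got {group!r}")
    gs = GROUP_STATS[group]
    rng = np.random.default_rng(seed)

    z = _truncated_normal(rng, 0.0, 1.0, -2.0, 2.0)
    r0 = max(gs.r5[0] + gs.r5[1] * z, 0.10) * _demographic_factor(demographics)

    half = math.sqrt(0.5)
    x5 = _truncated_normal(rng, gs.x5[0] + gs.x5[1] * (-0.5 * z), gs.x5[1] * half,
                           -0.60, -0.02)
    fres = _truncated_normal(rng, gs.fres[0] + gs.fres[1] * (0.5 * z), gs.fres[1] * half,
                             8.0, 35.0)
    # invert (X5, Fres) through the RIC closed forms
    ic = 1.0 / (2.0 * np.pi * fres) ** 2
    c = (W5 * ic - 1.0 / W5) / x5  # positive because fres > 5 and x5 < 0
    i = ic / c

    dr_exp = max(gs.dr_exp[0] + gs.dr_exp[1] * (0.7 * z + 0.71 * rng.normal()), 0.0)
    fdep = float(np.clip(gs.fdep[0] + gs.fdep[1] * (0.7 * z + 0.71 * rng.normal()),
                         0.0, 0.012))
    return SimImpedanceModel(
        R0=r0, dR_exp=dr_exp, fdep=fdep, I=i, C=c,
        noise_sd_p=0.002, noise_sd_f=0.010, severity=z,
    )


def assign_spirometry_ratios(
    model: SimImpedanceModel,
    group: str,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Draw (v1, v2, v3) coupled to the model's latent severity.

    Each ratio is mean - sd*(rho*z + sqrt(1-rho^2)*eps) so marginals keep the
    group anchors while higher-severity (higher R0) subjects get lower
    ratios.  Draws outside (0.05, 2.0) are resampled.
    """
    if group not in GROUP_STATS:
        raise ValueError(f"group must be one of {sorted(GROUP_STATS)}, got {group!r}")
    gs = GROUP_STATS[group]
    rng = np.random.default_rng(seed)
    rho = SEVERITY_V_COUPLING
    resid = math.sqrt(1.0 - rho * rho)
    out = []
    for mean, sd in gs.v:
        for _ in range(1000):
            v = mean - sd * (rho * model.severity + resid * rng.normal())
            if 0.05 < v < 2.0:
                break
        else:
            v = min(max(mean, 0.05 + 1e-6), 2.0 - 1e-6)
        out.append(float(v))
    return out[0], out[1], out[2]


# --------------------------------------------------------------------------
# cohort generation

def _draw_demographics(gs: GroupStats, subject_id: str,
                       rng: np.random.Generator) -> SubjectRecord:
    age = _truncated_normal(rng, *gs.age, 18.0, 90.0)
    height = _truncated_normal(rng, *gs.height, 140.0, 200.0)
    weight = _truncated_normal(rng, *gs.weight, 35.0, 150.0)
    sex = int(rng.random() < gs.male_fraction)
    return SubjectRecord(subject_id=subject_id, age=age, sex=sex,
                         height=height, weight=weight, v1=1.0, v2=1.0, v3=1.0)


def generate_cohort(
    n: int,
    sad_fraction: float = 0.423,
    fs: float = 400.0,
    duration: float = 30.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    breathing: BreathingPattern = BreathingPattern(),
    excitation: ExcitationSpec = ExcitationSpec(),
) -> tuple[list[SubjectRecord], list[IOSRecording], np.ndarray]:
    """Generate ``n`` subjects; exactly round(n*sad_fraction) SAD phenotypes.

    Returns (records, recordings, y_group) where y_group[i] is 1 for SAD
    phenotype.  When ``out_dir`` is given, recordings and the manifest CSV are
    also written there (see :mod:`tfrim_sad.io`).  The default
    ``sad_fraction`` mirrors the published cohort prevalence 1061/2510.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 subjects")
    if not (0.0 < sad_fraction < 1.0):
        raise ValueError("sad_fraction must lie in (0, 1)")
    n_sad = int(round(n * sad_fraction))
    groups = ["SAD"] * n_sad + ["nonSAD"] * (n - n_sad)

    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(3 * n).reshape(n, 3) >> np.uint32(1)  # < 2**31

    records: list[SubjectRecord] = []
    recordings: list[IOSRecording] = []
    for i, group in enumerate(groups):
        sid = f"S{i:04d}"
        demo_rng = np.random.default_rng(int(subject_seeds[i, 0]))
        rec_subject = _draw_demographics(GROUP_STATS[group], sid, demo_rng)
        model = sad_phenotype(group, rec_subject, seed=int(subject_seeds[i, 1]))
        v1, v2, v3 = assign_spirometry_ratios(model, group, seed=int(subject_seeds[i, 1]))
        rec_subject.v1, rec_subject.v2, rec_subject.v3 = v1, v2, v3
        recording = synthesize_recording(
            model, breathing, excitation, fs=fs, duration=duration,
            seed=int(subject_seeds[i, 2]), subject_id=sid,
        )
        records.append(rec_subject)
        recordings.append(recording)

    y_group = np.array([1] * n_sad + [0] * (n - n_sad), dtype=int)

    if out_dir is not None:
        from . import io as _io  # local import: io depends on this module's types

        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
        for rec_subject, recording in zip(records, recordings):
            path = out_dir / f"{recording.subject_id}.csv"
            _io.write_recording(recording, path)
            rec_subject.recording_path = path.name
        _io.write_manifest(records, out_dir / "manifest.csv")

    return records, recordings, y_group
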