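"""Synthetic resting-state EEG cohorts with planted spectral and
phase-coupling effects.

Each channel is 1/f background noise plus five band-limited oscillatory
components.  A planted coupling effect makes the involved channels share a
common band-limited carrier whose per-channel phase jitter is von-Mises
distributed with concentration kappa (kappa = 0 -> independent phases,
kappa -> inf -> PLV -> 1).  A planted power effect multiplies a channel's
band component variance.  Everything is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .contrast import benjamini_hochberg, group_contrast
from .core.types import STANDARD_32_CHANNELS, Group, Recording, ValidationError
from .features.bands import CANONICAL_BANDS, BandDefinition, get_band
from .features.plv import PLVFeatures, fisher_mean_plv_axis
from .features.psd import PSDFeatures

#: Default oscillator-to-background in-band power ratios.  Alpha sits at 1
#: (realistic resting SNR); the high bands get stronger oscillators so the
#: 1/f tail does not dilute planted multiplicative effects there.
DEFAULT_BAND_SNR = {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 10.0, "gamma": 5.0}


@dataclass(frozen=True)
class PowerEffect:
    """Multiply the band-component variance of some channels in one group."""

    group: str
    band: str
    channels: tuple[str, ...]
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValidationError(f"power factor must be > 0, got {self.factor}")


@dataclass(frozen=True)
class CouplingEffect:
    """Plant phase coupling with concentration kappa among some channels
    of one group, in one band.  All listed channels share one carrier."""

    group: str
    band: str
    channels: tuple[str, ...]
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValidationError(f"kappa must be >= 0, got {self.kappa}")
        if len(self.channels) < 2:
            raise ValidationError("coupling needs at least 2 channels")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        chs = self.channels
        return tuple(
            (chs[i], chs[j]) for i in range(len(chs)) for j in range(i + 1, len(chs))
        )


@dataclass
class CohortSpec:
    groups: tuple[tuple[str, int], ...] = (("HC", 4), ("PD", 4))
    fs: float = 512.0
    duration_s: float = 60.0
    channels: tuple[str, ...] = STANDARD_32_CHANNELS
    background_exponent: float = 1.0
    background_amplitude: float = 10.0  # time-series SD in microvolts
    band_snr: dict = field(default_factory=lambda: dict(DEFAULT_BAND_SNR))
    power_effects: tuple[PowerEffect, ...] = ()
    coupling_effects: tuple[CouplingEffect, ...] = ()
    jitter_hz: float = 20.0  # phase-jitter block rate for coupled carriers
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple((str(g), int(n)) for g, n in self.groups)
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ValidationError("groups must be non-empty with >= 1 subject each")
        known = set(self.channels)
        for eff in tuple(self.power_effects) + tuple(self.coupling_effects):
            get_band(eff.band)  # raises on unknown band
            missing = [c for c in eff.channels if c not in known]
            if missing:
                raise ValidationError(
                    f"effect references unknown channels: {', '.join(missing)}"
                )
            Group(eff.group)

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    """1/f^exponent noise of length n with the given SD; also returns the
    per-rfft-bin expected power fractions (for SNR bookkeeping)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = shape * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    x *= amplitude / sd if sd > 0 else 0.0
    power_frac = shape**2
    total = power_frac.sum()
    return x, power_frac / total if total > 0 else power_frac


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: BandDefinition) -> np.ndarray:
    """Unit-variance band-limited gaussian noise."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _jittered_copy(rng: np.random.Generator, carrier: np.ndarray, fs: float,
                   kappa: float, jitter_hz: float) -> np.ndarray:
    """Re-synthesize a carrier with block-wise von-Mises phase jitter."""
    analytic = signal.hilbert(carrier)
    env = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    n = len(carrier)
    block = max(1, int(round(fs / jitter_hz)))
    n_blocks = int(np.ceil(n / block))
    if kappa == 0.0:
        jumps = rng.uniform(-np.pi, np.pi, size=n_blocks)
    else:
        jumps = rng.vonmises(0.0, kappa, size=n_blocks)
    jitter = np.repeat(jumps, block)[:n]
    out = env * np.cos(phase + jitter)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_recording(
    subject_id: str,
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> Recording:
    """One subject's recording under the cohort spec.

    Coupling carriers are drawn per subject (phase coupling is a
    within-subject, across-channel phenomenon) and shared by every channel
    of the corresponding coupling effect.
    """
    n = int(round(spec.fs * spec.duration_s))
    n_ch = len(spec.channels)
    data = np.empty((n_ch, n))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)

    # per-subject carriers for coupling effects targeting this group
    active_couplings = [
        (ei, eff) for ei, eff in enumerate(spec.coupling_effects) if eff.group == group
    ]
    carriers = {}
    for ei, eff in active_couplings:
        carriers[ei] = _band_noise(rng, n, spec.fs, get_band(eff.band))

    power_by_chan_band: dict[tuple[str, str], float] = {}
    for eff in spec.power_effects:
        if eff.group != group:
            continue
        for ch in eff.channels:
            key = (ch, get_band(eff.band).name)
            power_by_chan_band[key] = power_by_chan_band.get(key, 1.0) * eff.factor

    coupling_by_chan_band: dict[tuple[str, str], tuple[int, float]] = {}
    for ei, eff in active_couplings:
        for ch in eff.channels:
            coupling_by_chan_band[(ch, get_band(eff.band).name)] = (ei, eff.kappa)

    for ci, ch in enumerate(spec.channels):
        bg, power_frac = _pink_noise(
            rng, n, spec.fs, spec.background_exponent, spec.background_amplitude
        )
        x = bg.copy()
        bg_var = spec.background_amplitude**2
        for band in CANONICAL_BANDS:
            mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
            bg_band_power = bg_var * float(power_frac[mask].sum())
            snr = float(spec.band_snr.get(band.name, 1.0))
            target_var = snr * bg_band_power
            target_var *= power_by_chan_band.get((ch, band.name), 1.0)
            if target_var <= 0:
                continue
            key = (ch, band.name)
            if key in coupling_by_chan_band:
                ei, kappa = coupling_by_chan_band[key]
                comp = _jittered_copy(rng, carriers[ei], spec.fs, kappa, spec.jitter_hz)
            else:
                comp = _band_noise(rng, n, spec.fs, band)
            x += np.sqrt(target_var) * comp
        data[ci] = x
    return Recording(
        subject_id=subject_id,
        group=Group(group),
        fs=spec.fs,
        channels=spec.channels,
        data=data,
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """All subjects of the cohort, bit-reproducible from ``spec.seed``."""
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    recordings = []
    si = 0
    for group, n_subjects in spec.groups:
        for k in range(n_subjects):
            rng = np.random.default_rng(seeds[si])
            recordings.append(
                generate_recording(f"{group.lower()}{k + 1:02d}", group, spec, rng)
            )
            si += 1
    return recordings


def _bootstrap_ci(values_a: np.ndarray, values_b: np.ndarray, stat,
                  rng: np.random.Generator, n_boot: int = 1000,
                  level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI over subjects for stat(a, b)."""
    na, nb = len(values_a), len(values_b)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        draws[i] = stat(values_a[ia], values_b[ib])
    lo = (1 - level) / 2
    return float(np.quantile(draws, lo)), float(np.quantile(draws, 1 - lo))


def planted_effect_report(
    spec: CohortSpec,
    psd: Sequence[PSDFeatures],
    plv: Sequence[PLVFeatures],
    alpha: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted vs recovered effect sizes with bootstrap CIs and flags.

    Compares the spec's second group (effect carrier) against its first
    (reference).  PSD rows report the recovered group power ratio per
    channel x band; PLV rows report the Fisher-domain group PLV delta per
    pair x band.  ``flagged`` marks units significant at ``alpha`` after
    Benjamini-Hochberg correction of per-subject-mean t-tests.
    """
    if len(spec.groups) < 2:
        raise ValidationError("report needs at least two groups")
    ref_group, eff_group = spec.groups[0][0], spec.groups[1][0]
    psd_ref = [f for f in psd if f.group == ref_group]
    psd_eff = [f for f in psd if f.group == eff_group]
    plv_ref = [f for f in plv if f.group == ref_group]
    plv_eff = [f for f in plv if f.group == eff_group]
    if len(psd_ref) != spec.groups[0][1] or len(psd_eff) != spec.groups[1][1]:
        raise ValidationError(
            "feature subject counts do not match the cohort spec "
            f"({len(psd_ref)}/{len(psd_eff)} vs {spec.groups[0][1]}/{spec.groups[1][1]})"
        )
    rng = np.random.default_rng(seed)

    planted_power: dict[tuple[str, str], float] = {}
    for eff in spec.power_effects:
        if eff.group == eff_group:
            for ch in eff.channels:
                key = (get_band(eff.band).name, ch)
                planted_power[key] = planted_power.get(key, 1.0) * eff.factor
    planted_kappa: dict[tuple[str, str], float] = {}
    for eff in spec.coupling_effects:
        if eff.group == eff_group:
            for a, b in eff.pairs:
                planted_kappa[(get_band(eff.band).name, f"{a}-{b}")] = eff.kappa

    rows = []
    bands = psd_eff[0].band_defs if psd_eff else ()
    for bi, band in enumerate(bands):
        cmap = group_contrast(psd_eff, psd_ref, band, alpha=alpha,
                              per_subject_mean=True, fdr=False)
        # subject-level band power per channel
        a = np.stack([f.values[:, :, bi].mean(axis=0) for f in psd_eff])
        b = np.stack([f.values[:, :, bi].mean(axis=0) for f in psd_ref])
        for ci, ch in enumerate(psd_eff[0].channels):
            lo, hi = _bootstrap_ci(
                a[:, ci], b[:, ci], lambda x, y: x.mean() / y.mean(), rng, n_boot
            )
            rows.append({
                "kind": "psd", "band": band.name, "unit": ch,
                "planted": planted_power.get((band.name, ch), 1.0),
                "recovered": float(a[:, ci].mean() / b[:, ci].mean()),
                "ci_low": lo, "ci_high": hi,
                "p_value": float(cmap.p_value[ci]),
            })
    bands = plv_eff[0].band_defs if plv_eff else ()
    for bi, band in enumerate(bands):
        cmap = group_contrast(plv_eff, plv_ref, band, alpha=alpha,
                              per_subject_mean=True, fdr=False)
        a = np.stack([fisher_mean_plv_axis(f.values[:, :, bi], axis=0) for f in plv_eff])
        b = np.stack([fisher_mean_plv_axis(f.values[:, :, bi], axis=0) for f in plv_ref])
        for pi, name in enumerate(plv_eff[0].pair_names):
            lo, hi = _bootstrap_ci(
                a[:, pi], b[:, pi],
                lambda x, y: float(fisher_mean_plv_axis(x) - fisher_mean_plv_axis(y)),
                rng, n_boot,
            )
            rows.append({
                "kind": "plv", "band": band.name, "unit": name,
                "planted": planted_kappa.get((band.name, name), 0.0),
                "recovered": float(
                    fisher_mean_plv_axis(a[:, pi]) - fisher_mean_plv_axis(b[:, pi])
                ),
                "ci_low": lo, "ci_high": hi,
                "p_value": float(cmap.p_value[pi]),
            })
    table = pd.DataFrame(rows)
    # FDR across every unit of the report jointly, then threshold at alpha
    table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    table["flagged"] = table["p_adjusted"] <= alpha
    return table
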