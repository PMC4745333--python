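"""Synthetic HRV panels and RR-interval series for end-to-end testing.

Two levels of realism are provided.  ``generate_panel`` draws index-level
panels directly: each subject gets a latent pre-phase profile (log-normal
between-subject variation around configurable means), each week multiplies
it by log-normal within-subject noise, and the post phase applies
multiplicative intervention effects (stress index down, total power up,
HF up).  Log-normal noise is used because all indices are positive and
right-skewed in real recordings.

``generate_rr`` instead synthesises a 5-minute interbeat-interval series as
a base interval plus one narrowband oscillation per spectral band (plus
white jitter), and ``band_powers`` estimates band powers from any RR series
by uniform resampling and Welch periodogram averaging — grounding the
panel-level indices in an explicit signal model.

The stress index (PSI) of the real analyser is proprietary; the synthetic
stand-in used here is a documented surrogate: a fixed, zero-intercept linear
functional of the measured spectrum,

    psi = p * (VLF + LF) - p_h * HF + q * (TP - VLF - LF - HF)  (+ noise),

with positive loadings on the sympathetically-dominated bands and on the
excess (non-band) spectral power, and a negative loading on the vagal HF
band.  The coefficients (p, p_h) are solved from the configured pre-phase
means and post-phase effects so that the functional's expectation equals the
configured PSI mean in both phases; the ``psi_factor`` effect then
multiplies the post phase explicitly.  The zero-intercept spectral form is
deliberate: the grey relational fit regresses accumulated sequences with no
constant column, so an index that is a direct functional of the spectrum —
as a device-computed index is — gives the generator a ground truth the
fit can actually recover.  The surrogate mimics qualitative behaviour only
(PSI falls when vagal power rises) and makes no claim to reproduce the
device's formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.interpolate
import scipy.signal

from .data import HrvMeasurement, HrvPanel, Phase
from .grey import GreyHrvError, InvalidInputError

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "SpectralBands",
    "RrSeries",
    "generate_panel",
    "generate_rr",
    "band_powers",
]

logger = logging.getLogger("greyhrv")


class ConfigError(GreyHrvError, ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the panel generator.

    Defaults emulate the study conditions: 45 subjects over 4 weeks, with
    post-phase effects lowering the stress index (x0.7), raising total power
    (x1.4) and HF power (x2.0), and leaving LF unchanged.  Pre-phase band
    means sit near the middle of the observed pre-intervention range.
    Dispersion
    is moderate (between-subject CV 0.25, week-to-week CV 0.12): a regime in
    which the configured effects are recoverable by the relational fit; real
    cohorts are more dispersed, which visibly destabilises the fitted
    ranking (see the methods note).

    ``pre_cv['psi']`` is the CV of the multiplicative idiosyncratic factor
    on the surrogate stress index (the index's between-subject spread comes
    mainly through its dependence on the band powers); ``psi_noise_sd`` is
    additive device noise in PSI units.  ``excess_loading`` is the
    surrogate's weight q on the non-band excess power TP - (VLF+LF+HF).
    """

    n_subjects: int = 45
    n_weeks: int = 4
    seed: int = 0
    pre_means: Mapping[str, float] = field(
        default_factory=lambda: {"psi": 65.0, "vlf": 450.0, "lf": 400.0, "hf": 300.0}
    )
    pre_cv: Mapping[str, float] = field(
        default_factory=lambda: {"psi": 0.02, "vlf": 0.25, "lf": 0.25, "hf": 0.25}
    )
    post_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "psi_factor": 0.7,
            "tp_factor": 1.4,
            "hf_factor": 2.0,
            "lf_factor": 1.0,
        }
    )
    noise_cv: float = 0.12
    tp_jitter_cv: float = 0.025
    psi_noise_sd: float = 1.5
    excess_loading: float = 0.9
    psi_floor: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 6:
            raise ConfigError(f"n_subjects must be >= 6, got {self.n_subjects}")
        if self.n_weeks < 1:
            raise ConfigError(f"n_weeks must be >= 1, got {self.n_weeks}")
        for key in ("psi", "vlf", "lf", "hf"):
            if key not in self.pre_means or self.pre_means[key] <= 0:
                raise ConfigError(f"pre_means[{key!r}] must be a positive number")
            if key not in self.pre_cv or self.pre_cv[key] < 0:
                raise ConfigError(f"pre_cv[{key!r}] must be >= 0")
        for key in ("psi_factor", "tp_factor", "hf_factor", "lf_factor"):
            if key not in self.post_effects or self.post_effects[key] <= 0:
                raise ConfigError(f"post_effects[{key!r}] must be > 0")
        if min(self.noise_cv, self.tp_jitter_cv, self.psi_noise_sd) < 0:
            raise ConfigError("noise_cv, tp_jitter_cv and psi_noise_sd must be >= 0")
        if self.excess_loading < 0 or self.psi_floor <= 0:
            raise ConfigError("excess_loading must be >= 0 and psi_floor > 0")

    def surrogate_coefficients(self) -> tuple[float, float]:
        """Solve the surrogate loadings (p, p_h) from means and effects.

        Two constraints: the functional's expectation equals the configured
        PSI mean in the pre phase and (before the explicit psi_factor) also
        in the post phase.  When the post phase leaves the bands unchanged
        the system is singular and p_h falls back to p/2.
        """
        m, eff = self.pre_means, self.post_effects
        mv, ml, mh = m["vlf"], m["lf"], m["hf"]
        tp_post = eff["tp_factor"] * (mv + ml + mh)
        ml_post = eff["lf_factor"] * ml
        mh_post = eff["hf_factor"] * mh
        mv_post = tp_post - ml_post - mh_post
        A = np.array([[mv + ml, -mh], [mv_post + ml_post, -mh_post]], dtype=float)
        rhs = np.array([m["psi"], m["psi"]])
        if abs(np.linalg.det(A)) < 1e-9 * np.abs(A).max() ** 2:
            p = m["psi"] / (mv + ml - 0.5 * mh)
            return p, 0.5 * p
        p, p_h = np.linalg.solve(A, rhs)
        if p <= 0 or p_h <= 0:
            p = m["psi"] / (mv + ml - 0.5 * mh)
            return p, 0.5 * p
        return float(p), float(p_h)


@dataclass(frozen=True)
class SpectralBands:
    """Frequency bands in Hz, half-open [low, high); conventional short-term defaults."""

    vlf: tuple[float, float] = (0.0033, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)

    def __post_init__(self):
        edges = [*self.vlf, *self.lf, *self.hf]
        if any(e < 0 for e in edges) or not all(
            a < b for a, b in (self.vlf, self.lf, self.hf)
        ):
            raise ConfigError("band edges must be nonnegative with low < high")
        if not (self.vlf[1] <= self.lf[0] and self.lf[1] <= self.hf[0]):
            raise ConfigError("bands must be disjoint and ordered vlf < lf < hf")


@dataclass(frozen=True)
class RrSeries:
    """Successive interbeat intervals in milliseconds."""

    intervals: tuple[float, ...]
    duration: float  # seconds actually covered

    def __len__(self) -> int:
        return len(self.intervals)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.intervals, dtype=float)

    def beat_times(self) -> np.ndarray:
        """Event times (s) of each beat, starting at the end of the first interval."""
        return np.cumsum(self.as_array()) / 1000.0


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Unit-mean log-normal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_panel(config: SyntheticConfig) -> HrvPanel:
    """Draw a synthetic subject x week x phase panel.

    Per subject: latent pre-phase band powers (VLF, LF, HF) are log-normal
    around the configured means.  Post-phase latents multiply LF and HF by
    their factors and rescale VLF so that total power scales by
    ``tp_factor``.  Per week, each band multiplies its phase latent by
    independent log-normal noise; TP is the band sum times a small jitter
    (so the soft band-additivity invariant holds); LF/HF is the ratio; and
    PSI is the linear spectral surrogate evaluated on the week's values
    (times ``psi_factor`` in the post phase, a subject-level multiplicative
    factor, and additive device noise, floored at ``psi_floor``).  In the
    noise-free limit with unit effects every measurement equals the
    configured pre-phase means exactly.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m = config.pre_means
    eff = config.post_effects
    p, p_h = config.surrogate_coefficients()
    q = config.excess_loading
    records = []
    n_vlf_clipped = n_floored = 0
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        lat = {
            k: m[k] * _lognormal_factor(rng, config.pre_cv[k]) for k in ("vlf", "lf", "hf")
        }
        psi_subject = _lognormal_factor(rng, config.pre_cv["psi"])
        post = {
            "lf": lat["lf"] * eff["lf_factor"],
            "hf": lat["hf"] * eff["hf_factor"],
        }
        # VLF balances so that total power scales by tp_factor
        vlf_post = eff["tp_factor"] * (lat["vlf"] + lat["lf"] + lat["hf"]) - post["lf"] - post["hf"]
        if vlf_post <= 0:
            vlf_post = 0.05 * lat["vlf"]
            n_vlf_clipped += 1
        post["vlf"] = vlf_post
        for phase, latents, pf in (
            (Phase.PRE, lat, 1.0),
            (Phase.POST, post, eff["psi_factor"]),
        ):
            for week in range(1, config.n_weeks + 1):
                vlf = latents["vlf"] * _lognormal_factor(rng, config.noise_cv)
                lf = latents["lf"] * _lognormal_factor(rng, config.noise_cv)
                hf = latents["hf"] * _lognormal_factor(rng, config.noise_cv)
                tp = (vlf + lf + hf) * _lognormal_factor(rng, config.tp_jitter_cv)
                index = (
                    p * (vlf + lf)
                    - p_h * hf
                    + q * (tp - vlf - lf - hf)
                    + (rng.normal(0.0, config.psi_noise_sd) if config.psi_noise_sd else 0.0)
                )
                if index < config.psi_floor:
                    index = config.psi_floor
                    n_floored += 1
                psi = index * pf * psi_subject
                records.append(
                    HrvMeasurement(
                        subject_id=subject,
                        week=week,
                        phase=phase,
                        psi=psi,
                        tp=tp,
                        vlf=vlf,
                        lf=lf,
                        hf=hf,
                        lfhf=lf / hf,
                    )
                )
    if n_vlf_clipped:
        logger.warning(
            "post-phase VLF rebalancing went nonpositive for %d subject(s); clipped",
            n_vlf_clipped,
        )
    if n_floored:
        logger.info("surrogate stress index floored for %d record(s)", n_floored)
    return HrvPanel(records)


def generate_rr(
    band_powers_ms2: Mapping[str, float],
    duration: float = 300.0,
    seed: int = 0,
    base_interval_ms: float = 800.0,
    jitter_ms: float = 2.0,
    bands: SpectralBands = SpectralBands(),
) -> RrSeries:
    """Simulate an RR-interval series with prescribed band powers.

    The instantaneous interval is a base value plus one sinusoid centred in
    each requested band (``{"vlf": P, "lf": P, "hf": P}`` in ms^2; variance
    of a sinusoid of amplitude a is a^2/2) with random phase, plus white
    jitter.  Intervals are clipped to the physiological range 300-2000 ms;
    the clipping rate is logged if nonzero.
    """
    if duration < 60:
        raise InvalidInputError(f"duration must be >= 60 s, got {duration}")
    targets = {k: float(band_powers_ms2.get(k, 0.0)) for k in ("vlf", "lf", "hf")}
    if any(v < 0 for v in targets.values()):
        raise InvalidInputError("band target powers must be >= 0")
    rng = np.random.default_rng(seed)
    centers = {k: 0.5 * sum(getattr(bands, k)) for k in ("vlf", "lf", "hf")}
    amps = {k: math.sqrt(2.0 * p) for k, p in targets.items()}
    if sum(amps.values()) + 5.0 * jitter_ms >= base_interval_ms:
        raise InvalidInputError(
            "modulation amplitude exceeds the base interval; lower the target powers"
        )
    phases = {k: rng.uniform(0, 2 * math.pi) for k in amps}

    intervals = []
    t = 0.0
    n_clipped = 0
    while t < duration:
        ival = base_interval_ms + sum(
            amps[k] * math.sin(2 * math.pi * centers[k] * t + phases[k]) for k in amps
        )
        if jitter_ms > 0:
            ival += rng.normal(0.0, jitter_ms)
        clipped = min(max(ival, 300.0), 2000.0)
        n_clipped += clipped != ival
        intervals.append(clipped)
        t += clipped / 1000.0
    if n_clipped:
        logger.warning(
            "clipped %d of %d intervals to the physiological range", n_clipped, len(intervals)
        )
    return RrSeries(intervals=tuple(intervals), duration=t)


def band_powers(
    rr: RrSeries,
    bands: SpectralBands = SpectralBands(),
    resample_hz: float = 4.0,
) -> dict[str, float]:
    """Estimate TP/VLF/LF/HF (ms^2) from an RR series.

    Intervals are placed at their beat times, cubic-spline interpolated onto
    a uniform grid (default 4 Hz), mean-detrended, and the power spectral
    density is estimated by Welch averaged periodograms (150 s Hann
    segments, 50% overlap); each band power is the integral of the PSD over
    the band, and TP the integral over the union of the three bands.
    """
    if rr.duration < 60:
        raise InvalidInputError(f"series too short: {rr.duration:.1f} s (need >= 60 s)")
    if bands.hf[1] > resample_hz / 2.0:
        raise ConfigError(
            f"hf upper edge {bands.hf[1]} Hz exceeds Nyquist {resample_hz / 2.0} Hz"
        )
    times = rr.beat_times()
    values = rr.as_array()
    grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    # cubic spline: linear interpolation low-passes the HF band noticeably
    # at typical beat rates (~1.25 Hz)
    kind = "cubic" if len(values) >= 4 else "linear"
    interp = scipy.interpolate.interp1d(times, values, kind=kind)
    x = interp(grid)
    x = x - x.mean()
    nperseg = min(len(x), int(150 * resample_hz))
    freqs, psd = scipy.signal.welch(
        x, fs=resample_hz, nperseg=nperseg, detrend="constant", window="hann"
    )
    out: dict[str, float] = {}
    for name in ("vlf", "lf", "hf"):
        lo, hi = getattr(bands, name)
        mask = (freqs >= lo) & (freqs < hi)
        out[name] = float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0
    out["tp"] = out["vlf"] + out["lf"] + out["hf"]
    return out
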