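"""Synthetic dyadic 24-h index series with a planted synchrony–stress link.

No public mother–child 24-h HRV cohort exists, so every pipeline stage is
exercised on simulated data whose ground truth is known:

* a day–night circadian profile (night level over 22:00–06:00, day level
  otherwise, smooth linear transitions),
* AR(1) noise split into a dyad-shared and two individual components — the
  shared weight √ρ makes the mother–child noise correlation exactly ρ,
* a linear link PSI = β0 + β1·ρ + noise, clamped to the questionnaire's
  78–390 range, so higher physiological synchrony maps to higher reported
  stress and the full pipeline (plots → SOM → regression) should recover it.

An R-R-level generator with prescribed Poincaré axes (SD1/SD2) exercises
the HRV extraction end-to-end; it is independent of the index-level
generator.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd

from .dayprep import DAY_START, POINTS_PER_DAY, DaySegment
from .hrv import RRSeries
from .psi import HIGH_RISK_CUTOFF, N_ITEMS

__all__ = [
    "DyadSimConfig",
    "CohortSimConfig",
    "CohortBundle",
    "simulate_dyad_day",
    "simulate_rr",
    "simulate_cohort",
]

_DEFAULT_START = datetime(2023, 1, 1, 22, 0)


@dataclass(frozen=True)
class DyadSimConfig:
    """One dyad-day of a generic normalized HRV index.

    Night (22:00–06:00, i.e. the first 480 slots of a 22:00-aligned day)
    sits at ``night_level``, day at ``day_level``, with linear transitions
    of ``transition_min`` minutes centred on the boundaries.  Both members
    share the circadian profile; their AR(1) noises (lag-1 autocorrelation
    ``phi``, unit marginal variance, scaled by ``sigma``) share a common
    component with weight √ρ so that corr(mother, child | profile) = ρ.
    """

    day_level: float = 3.0
    night_level: float = 5.0
    night_end_slot: int = 480  # 06:00 on the 60 s grid starting 22:00
    transition_min: int = 60
    sigma: float = 0.6
    phi: float = 0.995  # per-minute lag-1: autonomic state persists ~3 h
    rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


#: Per-kind circadian levels (day, night, noise σ) in each index's own units:
#: overall HRV (SDNN, ms) and vagal tone (CVI) rise during sleep, sympathetic
#: tone (CSI) during waking activity.
KIND_PROFILES: dict[str, tuple[float, float, float]] = {
    "SDNN": (40.0, 70.0, 8.0),
    "CSI": (3.5, 2.0, 0.45),
    "CVI": (3.0, 5.0, 0.6),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """A cohort of dyads with per-dyad coupling ρ and a linear ρ→PSI link.

    Defaults mirror the reference cohort's shape: ~32 dyads contributing
    1–3 days each, PSI spanning roughly 105–284.  All index kinds of one
    dyad share the same ρ (it is a property of the dyad, not the index).
    """

    n_dyads: int = 32
    days_per_dyad: tuple[int, ...] | int = 2
    kinds: tuple[str, ...] = ("SDNN", "CSI", "CVI")
    rho_low: float = 0.1
    rho_high: float = 0.9
    beta0: float = 110.0
    beta1: float = 150.0
    sigma_psi: float = 10.0
    seed: int = 0
    dyad: DyadSimConfig = field(default_factory=DyadSimConfig)

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be >= 1")
        if self.sigma_psi < 0:
            raise ValueError("sigma_psi must be >= 0")
        for k in self.kinds:
            if k not in KIND_PROFILES:
                raise ValueError(f"unknown index kind {k!r}")


@dataclass
class CohortBundle:
    """Simulated cohort: raw day segments per dyad member, PSI, ground truth."""

    mother_days: dict[str, dict[str, list[DaySegment]]]  # dyad -> kind -> days
    child_days: dict[str, dict[str, list[DaySegment]]]
    psi: dict[str, int]  # dyad id -> mother's PSI total
    truth: pd.DataFrame  # dyad_id, rho, psi_true (pre-noise link value)
    config: CohortSimConfig


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1), unit marginal variance."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1 - phi**2)
    for t in range(1, n):
        z[t] = phi * z[t - 1] + innov[t - 1]
    return z


def circadian_profile(cfg: DyadSimConfig) -> np.ndarray:
    """The deterministic day–night base curve c(t) on the 1440-slot grid."""
    c = np.full(POINTS_PER_DAY, float(cfg.day_level))
    c[: cfg.night_end_slot] = cfg.night_level
    half = cfg.transition_min // 2
    if half > 0:
        # night -> day ramp centred on the 06:00 boundary
        c[cfg.night_end_slot - half : cfg.night_end_slot + half] = np.linspace(
            cfg.night_level, cfg.day_level, 2 * half
        )
        # day -> night ramp ending at the 22:00 wrap, so the profile is
        # continuous across consecutive days
        c[POINTS_PER_DAY - 2 * half :] = np.linspace(
            cfg.day_level, cfg.night_level, 2 * half
        )
    return c


def simulate_dyad_day(
    cfg: DyadSimConfig,
    subject_prefix: str = "dyad0",
    kind: str = "CVI",
    day_index: int = 0,
    start: datetime = _DEFAULT_START,
) -> tuple[DaySegment, DaySegment]:
    """One (mother, child) pair of raw day segments.

    mother(t) = c(t) + σ·(√ρ·z(t) + √(1−ρ)·z_m(t)) and likewise for the
    child with z_c; z, z_m, z_c are independent unit-variance AR(1)
    processes.  With ρ = 1 mother and child are identical; with ρ = 0
    their fluctuations around c(t) are independent.  Deterministic in
    (config, seed).
    """
    rng = np.random.default_rng(cfg.seed)
    c = circadian_profile(cfg)
    z = _ar1(rng, POINTS_PER_DAY, cfg.phi)
    zm = _ar1(rng, POINTS_PER_DAY, cfg.phi)
    zc = _ar1(rng, POINTS_PER_DAY, cfg.phi)
    w_shared, w_own = np.sqrt(cfg.rho), np.sqrt(1 - cfg.rho)
    mother_vals = c + cfg.sigma * (w_shared * z + w_own * zm)
    child_vals = c + cfg.sigma * (w_shared * z + w_own * zc)
    no_missing = np.zeros(POINTS_PER_DAY, dtype=bool)
    mk = dict(kind=kind, day_index=day_index, start=start, missing=no_missing.copy())
    mother = DaySegment(subject_id=f"{subject_prefix}-m", values=mother_vals, **mk)
    mk["missing"] = no_missing.copy()
    child = DaySegment(subject_id=f"{subject_prefix}-c", values=child_vals, **mk)
    return mother, child


def simulate_rr(
    mean_ms: float,
    sd1: float,
    sd2: float,
    duration_s: float,
    seed: int = 0,
    subject_id: str = "sim",
) -> RRSeries:
    """R-R intervals as a stationary Gaussian AR(1) with prescribed Poincaré axes.

    For an AR(1) with variance σ² and lag-1 autocorrelation φ, the Poincaré
    dispersions satisfy sd1² = σ²(1−φ) and sd2² = σ²(1+φ); inverting gives
    σ² = (sd1² + sd2²)/2 and φ = (sd2² − sd1²)/(sd1² + sd2²), which is
    always inside (−1, 1) for positive sd1, sd2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sd1 and sd2 must be positive")
    var = (sd1**2 + sd2**2) / 2
    phi = (sd2**2 - sd1**2) / (sd1**2 + sd2**2)
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration_s * 1000 / mean_ms * 1.2)) + 10
    intervals = mean_ms + np.sqrt(var) * _ar1(rng, n, phi)
    intervals = np.clip(intervals, 1.0, None)  # intervals must stay positive
    times = np.cumsum(intervals) / 1000.0
    keep = times <= duration_s
    if not keep.any():
        keep[0] = True
    return RRSeries(subject_id=subject_id, times=times[keep], intervals=intervals[keep])


def simulate_cohort(cfg: CohortSimConfig) -> CohortBundle:
    """Simulate a cohort with per-dyad coupling and the planted PSI link.

    Each dyad draws ρ_i ~ Uniform(rho_low, rho_high), simulates its days,
    and the mother's PSI is β0 + β1·ρ_i plus Normal(0, σ_PSI) noise,
    rounded and clamped to the questionnaire range 78–390.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(cfg.days_per_dyad, int):
        days = [cfg.days_per_dyad] * cfg.n_dyads
    else:
        days = list(cfg.days_per_dyad)
        if len(days) != cfg.n_dyads:
            raise ValueError("days_per_dyad must match n_dyads")

    mothers: dict[str, dict[str, list[DaySegment]]] = {}
    children: dict[str, dict[str, list[DaySegment]]] = {}
    psi: dict[str, int] = {}
    rows = []
    for i in range(cfg.n_dyads):
        dyad_id = f"dyad{i:02d}"
        rho = float(rng.uniform(cfg.rho_low, cfg.rho_high))
        mothers[dyad_id] = {k: [] for k in cfg.kinds}
        children[dyad_id] = {k: [] for k in cfg.kinds}
        for d in range(days[i]):
            for kind in cfg.kinds:
                day_lv, night_lv, sig = KIND_PROFILES[kind]
                day_seed = int(rng.integers(0, 2**31 - 1))
                dcfg = replace(
                    cfg.dyad,
                    rho=rho,
                    seed=day_seed,
                    day_level=day_lv,
                    night_level=night_lv,
                    sigma=sig,
                )
                m, c = simulate_dyad_day(
                    dcfg, subject_prefix=dyad_id, kind=kind, day_index=d
                )
                mothers[dyad_id][kind].append(m)
                children[dyad_id][kind].append(c)
        psi_true = cfg.beta0 + cfg.beta1 * rho
        noisy = psi_true + rng.normal(0.0, cfg.sigma_psi)
        psi[dyad_id] = int(np.clip(round(noisy), N_ITEMS, 5 * N_ITEMS))
        rows.append({"dyad_id": dyad_id, "rho": rho, "psi_true": psi_true})

    return CohortBundle(
        mother_days=mothers,
        child_days=children,
        psi=psi,
        truth=pd.DataFrame(rows),
        config=cfg,
    )
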