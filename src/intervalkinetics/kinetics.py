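"""Closed-form kinetics of interval-imaged dissociation measurements.

Interval imaging separates consecutive camera frames (integration time
``tau_int``) by a dark interval, so that the time-lapse time ``tau_tl``
varies while the photobleaching dose per *illuminated* frame stays fixed.
A fluorescently tagged DNA-binding protein observed this way disappears
either because it dissociates (rate ``k_off``) or because its fluorophore
bleaches (rate ``k_b`` per unit illuminated time).  The apparent decay rate
of the dwell-time survival at one time-lapse setting is therefore

    k_eff = k_b * tau_int / tau_tl + k_off

and scanning ``tau_tl`` deconvolves the two contributions: the product
``k_eff * tau_tl`` is affine in ``tau_tl`` with slope ``k_off`` and
intercept ``k_b * tau_int``.

This module holds the kinetic data model (one- or two-population
exponential lifetime mixtures plus a shared bleach rate), the acquisition
geometry, and the closed-form survival/CRTD expressions everything else is
validated against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DEFAULT_TAU_TL_GRID",
    "UV_TAU_TL_GRID",
    "KineticModel",
    "AcquisitionProtocol",
    "EffectiveRate",
    "effective_rate",
    "survival",
    "expected_crtd",
]

#: Standard 8-point time-lapse grid (seconds) used for unperturbed cells.
DEFAULT_TAU_TL_GRID: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0)

#: Compressed 5-point grid (seconds) used after UV irradiation, chosen to
#: keep one full round of interval imaging short.
UV_TAU_TL_GRID: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)

_AMPLITUDE_TOL = 1e-9


@dataclass(frozen=True)
class KineticModel:
    """Exponential lifetime mixture with a shared photobleaching rate.

    Parameters
    ----------
    amplitudes
        Population fractions, one per kinetic population; must sum to 1.
    off_rates
        Dissociation rates in s^-1, sorted descending (fast population
        first, i.e. lifetimes ascending).  Lifetime of population *i* is
        ``1 / off_rates[i]``.
    k_b
        Photobleaching rate in s^-1 of *illuminated* time; the survival
        probability of the fluorophore through one frame is
        ``exp(-k_b * tau_int)``.
    """

    amplitudes: tuple[float, ...]
    off_rates: tuple[float, ...]
    k_b: float

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        rates = tuple(float(k) for k in self.off_rates)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "off_rates", rates)
        object.__setattr__(self, "k_b", float(self.k_b))
        if len(amps) != len(rates):
            raise ValueError("amplitudes and off_rates must have equal length")
        if len(amps) not in (1, 2):
            raise ValueError("model order must be 1 or 2")
        if not all(0.0 < a <= 1.0 for a in amps):
            raise ValueError("amplitudes must lie in (0, 1]")
        if abs(sum(amps) - 1.0) > _AMPLITUDE_TOL:
            raise ValueError(f"amplitudes must sum to 1, got {sum(amps)!r}")
        if not all(k > 0.0 for k in rates):
            raise ValueError("off_rates must be strictly positive")
        if any(rates[i] < rates[i + 1] for i in range(len(rates) - 1)):
            raise ValueError("off_rates must be sorted descending (fast first)")
        if self.k_b < 0.0:
            raise ValueError("k_b must be non-negative")

    @property
    def order(self) -> int:
        return len(self.amplitudes)

    @property
    def lifetimes(self) -> tuple[float, ...]:
        """Lifetimes tau_i = 1/k_off,i in seconds, ascending (fast first)."""
        return tuple(1.0 / k for k in self.off_rates)

    @classmethod
    def from_lifetimes(
        cls,
        amplitudes: Sequence[float],
        lifetimes_s: Sequence[float],
        k_b: float,
    ) -> "KineticModel":
        """Build a model from lifetimes, sorting populations fast-first."""
        pairs = sorted(zip(lifetimes_s, amplitudes), key=lambda p: p[0])
        taus = tuple(float(t) for t, _ in pairs)
        if any(t <= 0 for t in taus):
            raise ValueError("lifetimes must be strictly positive")
        return cls(
            amplitudes=tuple(a for _, a in pairs),
            off_rates=tuple(1.0 / t for t in taus),
            k_b=k_b,
        )

    def to_dict(self) -> dict:
        return {
            "amplitudes": list(self.amplitudes),
            "lifetimes_s": list(self.lifetimes),
            "k_b_per_s": self.k_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls.from_lifetimes(d["amplitudes"], d["lifetimes_s"], d["k_b_per_s"])

    def save(self, path: str | Path) -> None:
        _dump_config(self.to_dict(), Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "KineticModel":
        return cls.from_dict(_load_config(Path(path)))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Two-phase interval-imaging acquisition geometry.

    Phase I (``n_bleach_frames`` continuous frames) thins the fluorophore
    population down to the single-molecule regime; phase II
    (``n_sm_frames`` frames spaced ``tau_tl`` apart) is where individual
    binding events are tracked.
    """

    tau_int: float = 0.1
    tau_tl_grid: tuple[float, ...] = DEFAULT_TAU_TL_GRID
    n_bleach_frames: int = 50
    n_sm_frames: int = 100
    frame_shape: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 106.0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.tau_tl_grid)
        object.__setattr__(self, "tau_tl_grid", grid)
        object.__setattr__(self, "tau_int", float(self.tau_int))
        object.__setattr__(self, "frame_shape", tuple(int(s) for s in self.frame_shape))
        if self.tau_int <= 0:
            raise ValueError("tau_int must be positive")
        if not grid:
            raise ValueError("tau_tl_grid must be non-empty")
        if any(t < self.tau_int for t in grid):
            raise ValueError("every tau_tl must be >= tau_int (dark time >= 0)")
        if self.n_sm_frames <= 0:
            raise ValueError("n_sm_frames must be positive")
        if self.n_bleach_frames < 0:
            raise ValueError("n_bleach_frames must be non-negative")

    def dark_time(self, tau_tl: float) -> float:
        """Dark interval tau_d = tau_tl - tau_int for one grid setting."""
        return float(tau_tl) - self.tau_int

    def to_dict(self) -> dict:
        return {
            "tau_int_s": self.tau_int,
            "tau_tl_s": list(self.tau_tl_grid),
            "n_bleach_frames": self.n_bleach_frames,
            "n_sm_frames": self.n_sm_frames,
            "frame_shape": list(self.frame_shape),
            "pixel_size_nm": self.pixel_size_nm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            tau_int=d.get("tau_int_s", 0.1),
            tau_tl_grid=tuple(d["tau_tl_s"]),
            n_bleach_frames=d.get("n_bleach_frames", 50),
            n_sm_frames=d.get("n_sm_frames", 100),
            frame_shape=tuple(d.get("frame_shape", (512, 512))),
            pixel_size_nm=d.get("pixel_size_nm", 106.0),
        )

    def save(self, path: str | Path) -> None:
        _dump_config(self.to_dict(), Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "AcquisitionProtocol":
        return cls.from_dict(_load_config(Path(path)))


@dataclass(frozen=True)
class EffectiveRate:
    """Apparent single-exponential decay rate of one CRTD."""

    k_eff: float
    tau_tl: float

    def __post_init__(self) -> None:
        if self.k_eff < 0:
            raise ValueError("k_eff must be non-negative")
        if self.tau_tl <= 0:
            raise ValueError("tau_tl must be positive")


def effective_rate(k_off: float, k_b: float, tau_int: float, tau_tl: float) -> float:
    """Effective decay rate ``k_b * tau_int / tau_tl + k_off``.

    The bleach rate is normalised by the illuminated duty fraction
    ``tau_int / tau_tl``: lengthening the dark interval dilutes the bleach
    dose per unit wall-clock time while dissociation proceeds throughout.
    """
    if tau_int <= 0 or tau_tl <= 0:
        raise ValueError("tau_int and tau_tl must be positive")
    if tau_tl < tau_int:
        raise ValueError("tau_tl must be >= tau_int")
    if k_off < 0 or k_b < 0:
        raise ValueError("rates must be non-negative")
    return k_b * tau_int / tau_tl + k_off


def survival(
    model: KineticModel, tau_tl: float, tau_int: float, t: float | np.ndarray
) -> float | np.ndarray:
    """Mixture survival probability at wall-clock time ``t``.

    Returns ``sum_i A_i * exp(-k_eff_i * t)`` where each population decays
    at its own effective rate.  In pipeline use ``t = m * tau_tl`` for
    integer frame counts ``m``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(t_arr)
    for a, k_off in zip(model.amplitudes, model.off_rates):
        k_eff = effective_rate(k_off, model.k_b, tau_int, tau_tl)
        out = out + a * np.exp(-k_eff * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def expected_crtd(
    model: KineticModel,
    protocol: AcquisitionProtocol,
    n_events_per_tau: int,
) -> dict[float, np.ndarray]:
    """Noise-free expected cumulative counts, per time-lapse setting.

    For each ``tau_tl`` in the protocol grid, returns the array
    ``counts[m-1] = n * survival(m * tau_tl)`` for ``m = 1..n_sm_frames``.
    These exact (non-integer) counts serve as fixtures for the global
    fitter, which must recover the generating parameters from them.
    """
    if n_events_per_tau <= 0:
        raise ValueError("n_events_per_tau must be positive")
    m = np.arange(1, protocol.n_sm_frames + 1)
    out: dict[float, np.ndarray] = {}
    for tau_tl in protocol.tau_tl_grid:
        out[tau_tl] = n_events_per_tau * survival(
            model, tau_tl, protocol.tau_int, m * tau_tl
        )
    return out


def _dump_config(d: dict, path: Path) -> None:
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def _load_config(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
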