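"""Synthetic cohort generator for protocol evaluation.

Per patient p and axis: a systematic offset ``S_p ~ N(mu_star, Sigma_star)``
and an optional linear trend slope ``a_p ~ N(0, tau)``; per fraction f the
raw error is ``e_pf = S_p + a_p * f + eps_pf`` with
``eps_pf ~ N(0, sigma_star)``.  Rotational components are kept within
``|e_pf| <= max_abs_rot_deg`` by resampling (not clipping, which would pile
probability mass on the bound).  Everything is reproducible from the seed.

Default rotational parameters follow the clinical cohort the model stands
in for: systematic SDs of 0.9/0.8/0.8 deg (pitch/roll/yaw), maximum
observed rotation 3.2 deg, online-corrected residual scatter ~0.2 deg.
The random-error SD defaults to 0.4 deg (a config field, not a constant).
Translations use the same model shape (2 mm systematic / 1 mm random SD)
purely so the 6DoF plumbing is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .core import AXES, TreatmentCourse

__all__ = ["SimulationConfig", "simulate_population"]

_ROT = slice(3, 6)
_MAX_RESAMPLE = 1000


def _as_axis_vector(name: str, value, n: int = 6) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be a scalar or length-{n} sequence, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {arr.tolist()}")
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population, in AXES order
    (tx, ty, tz in mm; pitch, roll, yaw in deg)."""

    n_patients: int
    n_fractions: int = 30
    mu_star: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    Sigma_star: Sequence[float] = (2.0, 2.0, 2.0, 0.9, 0.8, 0.8)
    sigma_star: Sequence[float] = (1.0, 1.0, 1.0, 0.4, 0.4, 0.4)
    tau: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    max_abs_rot_deg: float = 3.2
    online_sd: Sequence[float] = (0.2, 0.2, 0.2, 0.2, 0.2, 0.2)
    sd_heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")
        for name in ("mu_star", "Sigma_star", "sigma_star", "tau", "online_sd"):
            vec = _as_axis_vector(name, getattr(self, name))
            if name != "mu_star" and np.any(vec < 0):
                raise ValueError(f"{name} must be non-negative, got {vec.tolist()}")
            object.__setattr__(self, name, tuple(vec))
        if not self.max_abs_rot_deg > 0:
            raise ValueError(f"max_abs_rot_deg must be > 0, got {self.max_abs_rot_deg}")
        if self.sd_heterogeneity < 0:
            raise ValueError(
                f"sd_heterogeneity must be >= 0, got {self.sd_heterogeneity}"
            )

    def axis_arrays(self) -> Tuple[np.ndarray, ...]:
        return (
            np.asarray(self.mu_star),
            np.asarray(self.Sigma_star),
            np.asarray(self.sigma_star),
            np.asarray(self.tau),
        )


def _truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, bound: float
) -> np.ndarray:
    """Draw per-axis normals, resampling rotational entries to |x| <= bound."""
    draw = rng.normal(mean, sd)
    for _ in range(_MAX_RESAMPLE):
        bad = np.zeros(6, dtype=bool)
        bad[_ROT] = np.abs(draw[_ROT]) > bound
        if not bad.any():
            return draw
        draw[bad] = rng.normal(mean[bad], sd[bad])
    raise RuntimeError(
        f"truncation to |rotation| <= {bound} failed after {_MAX_RESAMPLE} resamples; "
        "check mu_star/Sigma_star against max_abs_rot_deg"
    )


def simulate_population(config: SimulationConfig) -> List[TreatmentCourse]:
    """Generate one TreatmentCourse per patient from the configured model."""
    mu, Sigma, sigma, tau = config.axis_arrays()
    bound = config.max_abs_rot_deg
    rng = np.random.default_rng(config.seed)

    courses: List[TreatmentCourse] = []
    fr = np.arange(1, config.n_fractions + 1, dtype=float)
    for p in range(config.n_patients):
        S_p = _truncated_normal(rng, mu, Sigma, bound)
        a_p = rng.normal(0.0, tau)
        sigma_p = sigma
        if config.sd_heterogeneity > 0:
            # per-patient scatter drawn half-normal around sigma_star
            sigma_p = np.abs(rng.normal(sigma, config.sd_heterogeneity * sigma))
        base = S_p[None, :] + fr[:, None] * a_p[None, :]  # (n_fractions, 6)
        eps = rng.normal(0.0, sigma_p, size=(config.n_fractions, 6))
        errors = base + eps
        for _ in range(_MAX_RESAMPLE):
            bad = np.zeros_like(errors, dtype=bool)
            bad[:, _ROT] = np.abs(errors[:, _ROT]) > bound
            if not bad.any():
                break
            redraw = rng.normal(0.0, np.broadcast_to(sigma_p, errors.shape)[bad])
            errors[bad] = base[bad] + redraw
        else:
            raise RuntimeError(
                f"per-fraction truncation failed after {_MAX_RESAMPLE} resamples "
                f"for patient sim-{p:04d}"
            )
        courses.append(TreatmentCourse.from_matrix(f"sim-{p:04d}", errors))
    return courses
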