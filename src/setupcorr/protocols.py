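"""Correction policies: none, daily online, NAL, eNAL and eNAL++.

Each policy pairs an imaging schedule with a rule that maps the measured
per-fraction errors to the correction in force at every fraction.  Applying
a policy to a :class:`~setupcorr.core.TreatmentCourse` yields a
:class:`ResidualCourse` (``residual = raw error + correction``) plus
per-fraction imaging / online flags.

Protocol rules
--------------
``none``
    No imaging, no correction.
``online``
    Every fraction is imaged and corrected online; the residual is a draw
    from the online-residual noise model (exactly zero when disabled).
``nal``
    The first ``nal_length`` (default 3) fractions are measured; from the
    next fraction onward the correction is the negated mean of those
    measurements.
``enal``
    Like NAL, plus follow-up measurements at fractions
    ``followup_start, +followup_interval, ...`` (default 8, 13, 18, ...).
    The initial correction equals NAL's (negated mean of the first
    ``nal_length`` measurements).  After each follow-up measurement f_k a
    linear least-squares fit of ALL measurements so far gives intercept
    S_k and slope a_k, and the correction ``C_k = -(S_k + a_k * f_k)``
    takes effect from fraction f_k + 1 until the next update.  A
    measurement never corrects its own fraction off-line.  Set
    ``initial_fit=True`` to use the least-squares fit already for the
    initial correction (slope estimated from the first block too).
``enal_pp``
    Identical correction stream to eNAL, but every imaged fraction
    (including the first ``nal_length``) is corrected online instead, so
    its residual is an online-noise draw.  Off-line corrections are still
    computed from the raw (pre-correction) measurements.

Rotational correction components are clipped per axis to the couch limit
(default +/- 3 deg) when clipping is enabled; translations are never
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import AXES, SetupError6DoF, TreatmentCourse

__all__ = [
    "POLICY_NAMES",
    "CorrectionPolicy",
    "FitResult",
    "ResidualCourse",
    "imaging_schedule",
    "nal_correction",
    "enal_fit",
    "enal_correction",
    "apply_policy",
    "workload",
]

POLICY_NAMES = ("none", "online", "nal", "enal", "enal_pp")

_ROT = slice(3, 6)  # rotational components in AXES order


@dataclass(frozen=True)
class CorrectionPolicy:
    """A protocol definition: imaging schedule plus correction rule."""

    name: str
    nal_length: int = 3
    followup_start: int = 8
    followup_interval: int = 5
    couch_limit_deg: float = 3.0
    clip_enabled: bool = True
    initial_fit: bool = False

    def __post_init__(self) -> None:
        if self.name not in POLICY_NAMES:
            raise ValueError(
                f"unknown policy {self.name!r}; expected one of {POLICY_NAMES}"
            )
        if self.nal_length < 1:
            raise ValueError(f"nal_length must be >= 1, got {self.nal_length}")
        if self.followup_start <= self.nal_length:
            raise ValueError(
                f"followup_start ({self.followup_start}) must exceed "
                f"nal_length ({self.nal_length})"
            )
        if self.followup_interval < 1:
            raise ValueError(
                f"followup_interval must be >= 1, got {self.followup_interval}"
            )
        if not self.couch_limit_deg > 0:
            raise ValueError(
                f"couch_limit_deg must be > 0, got {self.couch_limit_deg}"
            )


@dataclass(frozen=True)
class FitResult:
    """Running least-squares fit of measured errors against fraction index.

    ``S_k`` is the intercept and ``a_k`` the slope per fraction, each a
    6-vector in :data:`~setupcorr.core.AXES` order; ``f_k`` is the most
    recent measured fraction.  With fewer than two distinct fraction
    indices the slope is forced to zero and the intercept is the mean.
    """

    S_k: np.ndarray
    a_k: np.ndarray
    f_k: int
    n_points: int


@dataclass
class ResidualCourse:
    """Per-fraction residual errors after a policy has been applied."""

    patient_id: str
    policy: CorrectionPolicy
    residuals: np.ndarray  # (n_fractions, 6)
    corrections: np.ndarray  # (n_fractions, 6), correction in force
    imaged: np.ndarray  # (n_fractions,) bool
    online_corrected: np.ndarray  # (n_fractions,) bool

    def __post_init__(self) -> None:
        n = self.residuals.shape[0]
        for name in ("corrections", "imaged", "online_corrected"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match residuals")

    @property
    def n_fractions(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_cbct(self) -> int:
        return int(np.count_nonzero(self.imaged))

    def residual_errors(self) -> List[SetupError6DoF]:
        return [SetupError6DoF.from_array(row) for row in self.residuals]


def imaging_schedule(policy: CorrectionPolicy, n_fractions: int) -> Tuple[int, ...]:
    """Fractions at which a CBCT is acquired, as an ordered tuple."""
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    if policy.name == "none":
        return ()
    if policy.name == "online":
        return tuple(range(1, n_fractions + 1))
    initial = list(range(1, min(policy.nal_length, n_fractions) + 1))
    if policy.name == "nal":
        return tuple(initial)
    followups = list(
        range(policy.followup_start, n_fractions + 1, policy.followup_interval)
    )
    return tuple(sorted(set(initial) | set(followups)))


def nal_correction(measured: np.ndarray) -> np.ndarray:
    """Negated mean of the measured errors (rows = fractions)."""
    measured = np.atleast_2d(np.asarray(measured, dtype=float))
    if measured.size == 0:
        raise ValueError("nal_correction requires at least one measurement")
    return -measured.mean(axis=0)


def enal_fit(
    fractions: Sequence[int], values: np.ndarray
) -> FitResult:
    """Least-squares line through measured values vs. fraction index.

    ``values`` has one row per measurement (shape ``(n, 6)`` or ``(n,)``
    for a single axis).  Minimizes ``sum_i (e_i - S - a * f_i)^2`` per axis.
    """
    f = np.asarray(fractions, dtype=float)
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[0] == 1 and f.shape[0] > 1:
        v = v.T  # (n,) input for a single axis
    if f.size == 0:
        raise ValueError("enal_fit requires at least one measurement")
    if f.shape[0] != v.shape[0]:
        raise ValueError("fractions and values must have matching lengths")
    if np.any(np.diff(f) <= 0):
        raise ValueError("fraction indices must be strictly increasing")
    f_k = int(f[-1])
    n = f.shape[0]
    if n < 2 or np.ptp(f) == 0:
        return FitResult(S_k=v.mean(axis=0), a_k=np.zeros(v.shape[1]), f_k=f_k, n_points=n)
    f_bar = f.mean()
    v_bar = v.mean(axis=0)
    denom = float(np.sum((f - f_bar) ** 2))
    a = ((f - f_bar) @ (v - v_bar)) / denom
    S = v_bar - a * f_bar
    return FitResult(S_k=S, a_k=a, f_k=f_k, n_points=n)


def enal_correction(fit: FitResult) -> np.ndarray:
    """Correction ``C_k = -(S_k + a_k * f_k)``, held until the next update."""
    return -(fit.S_k + fit.a_k * fit.f_k)


def _clip(correction: np.ndarray, policy: CorrectionPolicy) -> np.ndarray:
    if not policy.clip_enabled:
        return correction
    clipped = correction.copy()
    limit = policy.couch_limit_deg
    clipped[_ROT] = np.clip(clipped[_ROT], -limit, limit)
    return clipped


def _online_residual(
    online_sd: Optional[np.ndarray], rng: Optional[np.random.Generator]
) -> np.ndarray:
    if online_sd is None:
        return np.zeros(6)
    if rng is None:
        raise ValueError("online noise requires an rng (pass a seeded Generator)")
    return rng.normal(0.0, online_sd)


def _check_online_sd(online_sd) -> Optional[np.ndarray]:
    if online_sd is None:
        return None
    sd = np.asarray(online_sd, dtype=float)
    if sd.ndim == 0:
        sd = np.full(6, float(sd))
    if sd.shape != (6,):
        raise ValueError(f"online_sd must be a scalar or 6-vector, got shape {sd.shape}")
    if np.any(sd < 0):
        raise ValueError(f"online_sd must be non-negative, got {sd.tolist()}")
    return sd


def apply_policy(
    course: TreatmentCourse,
    policy: CorrectionPolicy,
    online_sd=None,
    rng: Optional[np.random.Generator] = None,
) -> ResidualCourse:
    """Apply a correction policy to a course of raw setup errors.

    Parameters
    ----------
    course : TreatmentCourse
        Raw (pre-correction) per-fraction setup errors.
    policy : CorrectionPolicy
    online_sd : float, 6-sequence or None
        Per-axis SD of the residual left by an online correction
        (mm for translations, deg for rotations).  ``None`` disables the
        noise model: online-corrected fractions have exactly zero residual.
    rng : numpy Generator, required when ``online_sd`` is given.

    The result is deterministic given the course, policy and a seeded rng.
    """
    online_sd = _check_online_sd(online_sd)
    n = course.n_fractions
    if policy.name in ("nal", "enal", "enal_pp") and n < policy.nal_length:
        raise ValueError(
            f"course of {n} fractions is shorter than nal_length={policy.nal_length}"
        )
    E = course.error_matrix()
    schedule = set(imaging_schedule(policy, n))

    residuals = np.empty((n, 6))
    corrections = np.zeros((n, 6))
    imaged = np.zeros(n, dtype=bool)
    online = np.zeros(n, dtype=bool)

    current = np.zeros(6)  # correction in force
    meas_f: List[int] = []
    meas_v: List[np.ndarray] = []

    for f in range(1, n + 1):
        raw = E[f - 1]
        is_imaged = f in schedule
        imaged[f - 1] = is_imaged
        corrections[f - 1] = current

        if policy.name == "online" or (policy.name == "enal_pp" and is_imaged):
            online[f - 1] = True
            residuals[f - 1] = _online_residual(online_sd, rng)
        else:
            residuals[f - 1] = raw + current

        if is_imaged and policy.name in ("nal", "enal", "enal_pp"):
            # measurements are the raw, pre-correction errors
            meas_f.append(f)
            meas_v.append(raw)
            if policy.name == "nal":
                if len(meas_f) == policy.nal_length:
                    current = _clip(nal_correction(np.vstack(meas_v)), policy)
            elif len(meas_f) >= policy.nal_length:
                if len(meas_f) == policy.nal_length and not policy.initial_fit:
                    # initial correction matches NAL (plain mean); the
                    # trend fit starts at the first follow-up measurement
                    current = _clip(nal_correction(np.vstack(meas_v)), policy)
                else:
                    fit = enal_fit(meas_f, np.vstack(meas_v))
                    current = _clip(enal_correction(fit), policy)

    return ResidualCourse(
        patient_id=course.patient_id,
        policy=policy,
        residuals=residuals,
        corrections=corrections,
        imaged=imaged,
        online_corrected=online,
    )


def workload(policy: CorrectionPolicy, n_fractions: int) -> Tuple[int, float]:
    """CBCT count and percentage reduction relative to daily online imaging."""
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    n_cbct = len(imaging_schedule(policy, n_fractions))
    reduction = 100.0 * (n_fractions - n_cbct) / n_fractions
    return n_cbct, reduction
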