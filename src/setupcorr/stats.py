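"""Population decomposition of setup errors into systematic and random parts.

Per axis (6 axes, treated independently):

* ``S`` (per patient): mean error over all fractions of that patient.
* ``mu``: mean of ``S`` over patients.
* ``Sigma``: SD over patients of ``S`` — the population systematic error.
* ``sigma``: RMS over patients of the per-patient SDs — the population
  random error.

Sample (n-1) standard deviations are used throughout, both across patients
and within a patient.  Residuals at ALL fractions enter the decomposition,
including the uncorrected first fractions of NAL/eNAL; pass
``fractions="imaged"`` to restrict to imaged fractions instead (mimicking
a clinic that only measures residuals on imaging days).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AXES, TreatmentCourse
from .protocols import (
    CorrectionPolicy,
    ResidualCourse,
    apply_policy,
    workload,
)

__all__ = [
    "PopulationStats",
    "patient_systematic",
    "patient_random_sd",
    "decompose",
    "compare_protocols",
]

Course = Union[TreatmentCourse, ResidualCourse]


@dataclass(frozen=True)
class PopulationStats:
    """Per-axis population statistics (vectors in :data:`AXES` order)."""

    mu: np.ndarray
    Sigma: np.ndarray
    sigma: np.ndarray
    n_patients: int
    mean_n_cbct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"axis": AXES, "mu": self.mu, "Sigma": self.Sigma, "sigma": self.sigma}
        )


def _residual_matrix(course: Course) -> np.ndarray:
    if isinstance(course, ResidualCourse):
        return course.residuals
    if isinstance(course, TreatmentCourse):
        return course.error_matrix()
    matrix = np.asarray(course, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 6:
        raise TypeError(
            "expected TreatmentCourse, ResidualCourse or an (n, 6) array"
        )
    return matrix


def patient_systematic(course: Course) -> np.ndarray:
    """Per-axis mean error over all fractions of one patient (S)."""
    matrix = _residual_matrix(course)
    if matrix.shape[0] < 1:
        raise ValueError("course has no fractions")
    return matrix.mean(axis=0)


def patient_random_sd(course: Course) -> np.ndarray:
    """Per-axis sample SD (n-1) of one patient's errors about their mean."""
    matrix = _residual_matrix(course)
    if matrix.shape[0] < 2:
        raise ValueError("per-patient SD requires >= 2 fractions")
    return matrix.std(axis=0, ddof=1)


def decompose(
    population: Sequence[Course], fractions: str = "all"
) -> PopulationStats:
    """Decompose a population of courses into mu, Sigma and sigma per axis.

    Parameters
    ----------
    population : sequence of TreatmentCourse or ResidualCourse
    fractions : {"all", "imaged"}
        Which fractions enter the statistics.  ``"imaged"`` requires
        ResidualCourse inputs and mimics estimating statistics from
        imaging-day residuals only.
    """
    population = list(population)
    if len(population) < 2:
        raise ValueError(
            f"Sigma requires >= 2 patients, got n_patients={len(population)}"
        )
    if fractions not in ("all", "imaged"):
        raise ValueError(f"fractions must be 'all' or 'imaged', got {fractions!r}")

    means: List[np.ndarray] = []
    sds: List[np.ndarray] = []
    cbct_counts: List[int] = []
    for course in population:
        matrix = _residual_matrix(course)
        if fractions == "imaged":
            if not isinstance(course, ResidualCourse):
                raise ValueError("fractions='imaged' requires ResidualCourse inputs")
            matrix = matrix[course.imaged]
        if matrix.shape[0] < 2:
            pid = getattr(course, "patient_id", "?")
            raise ValueError(
                f"sigma requires >= 2 fractions per patient; patient {pid!r} "
                f"has {matrix.shape[0]}"
            )
        means.append(matrix.mean(axis=0))
        sds.append(matrix.std(axis=0, ddof=1))
        if isinstance(course, ResidualCourse):
            cbct_counts.append(course.n_cbct)

    means_arr = np.vstack(means)
    sds_arr = np.vstack(sds)
    mean_n_cbct = float(np.mean(cbct_counts)) if cbct_counts else float("nan")
    return PopulationStats(
        mu=means_arr.mean(axis=0),
        Sigma=means_arr.std(axis=0, ddof=1),
        sigma=np.sqrt(np.mean(sds_arr**2, axis=0)),
        n_patients=len(population),
        mean_n_cbct=mean_n_cbct,
    )


def compare_protocols(
    population: Sequence[TreatmentCourse],
    policies: Sequence[CorrectionPolicy],
    online_sd=None,
    seed: int = 0,
    fractions: str = "all",
) -> pd.DataFrame:
    """Apply each policy to the population and tabulate Sigma/sigma/workload.

    Returns a long-format frame with one row per (policy, axis) and columns
    ``policy, axis, mu, Sigma, sigma, mean_n_cbct, reduction_pct``.
    Deterministic given ``seed``: each policy draws its online noise from an
    independent child stream of the one seed.
    """
    population = list(population)
    if not population:
        raise ValueError("empty population")
    n_fractions = population[0].n_fractions
    children = np.random.SeedSequence(seed).spawn(len(policies))
    rows = []
    for policy, child in zip(policies, children):
        rng = np.random.default_rng(child)
        residuals = [
            apply_policy(course, policy, online_sd=online_sd, rng=rng)
            for course in population
        ]
        stats = decompose(residuals, fractions=fractions)
        _, reduction = workload(policy, n_fractions)
        for i, axis in enumerate(AXES):
            rows.append(
                {
                    "policy": policy.name,
                    "axis": axis,
                    "mu": stats.mu[i],
                    "Sigma": stats.Sigma[i],
                    "sigma": stats.sigma[i],
                    "mean_n_cbct": stats.mean_n_cbct,
                    "reduction_pct": reduction,
                }
            )
    return pd.DataFrame(rows)
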