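"""Steered-pull analysis: restraint forces, work curves, separation, ensembles.

A constant-velocity steered pull drags a harmonic restraint centre λ(t) =
λ0 + v·t along a collective variable d(t) (here: the distance between the
centres of mass of two monomers, in Å).  The instantaneous restraint force

    F(t) = k · (λ(t) − d(t))        [kJ/mol/nm]

is positive when the restraint leads the collective variable.  The external
work done by the moving restraint is accumulated by trapezoidal integration
of F over the restraint-centre displacement (not over d(t)): this is the
quantity steered-MD engines report as "work applied".  Negative
instantaneous force (the CV ahead of the restraint) contributes negative
work; nothing is clipped.

Separation of a dimer is detected as the first frame at which the
inter-monomer contact count drops to zero and stays there for a persistence
window (default 10 frames), which guards against transient zero-contact
fluctuations.  Ensembles of replicates are compared by their final works:
per-group means, matched-pair orderings and a Wilcoxon rank-sum statistic.

Unit policy: trace distances in Å, time in ns; the force constant k is the
steered-MD convention (kJ/mol per nm of extension); forces in kJ/mol/nm and
work in kJ/mol.  Å→nm conversion happens in exactly one place
(:data:`A_PER_NM`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "A_PER_NM",
    "PullTrace",
    "WorkCurve",
    "EnsembleComparison",
    "restraint_force",
    "work_curve",
    "separation_point",
    "compare_ensembles",
]

A_PER_NM = 10.0  # Å per nm; the single distance-unit conversion


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PullTrace:
    """One steered-pull time series.

    ``time_ns`` strictly increasing; ``cv_A`` the collective variable
    (inter-monomer COM distance, Å); ``lambda_A`` the restraint centre (Å).
    If ``lambda_A`` is omitted it is reconstructed from ``lambda0_A`` and
    ``velocity_A_per_ns``.
    """

    time_ns: np.ndarray
    cv_A: np.ndarray
    lambda_A: np.ndarray | None = None
    force_constant: float = 1000.0  # kJ/mol/nm of extension
    velocity_A_per_ns: float | None = None
    lambda0_A: float | None = None
    label: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.cv_A = np.asarray(self.cv_A, dtype=float)
        if self.time_ns.shape != self.cv_A.shape:
            raise ValueError("time and CV series must have equal length")
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.lambda_A is None:
            if self.lambda0_A is None or self.velocity_A_per_ns is None:
                raise ValueError(
                    "restraint centre missing: provide lambda_A or (lambda0_A, velocity_A_per_ns)"
                )
            self.lambda_A = self.lambda0_A + self.velocity_A_per_ns * self.time_ns
        else:
            self.lambda_A = np.asarray(self.lambda_A, dtype=float)
            if self.lambda_A.shape != self.time_ns.shape:
                raise ValueError("restraint-centre series must match trace length")
            if self.velocity_A_per_ns is not None and self.lambda0_A is not None:
                expected = self.lambda0_A + self.velocity_A_per_ns * self.time_ns
                if not np.allclose(self.lambda_A, expected, atol=1e-6):
                    raise ValueError(
                        "declared constant-velocity schedule is inconsistent with lambda_A"
                    )

    def __len__(self) -> int:
        return self.time_ns.size


@dataclass
class WorkCurve:
    """Cumulative restraint work versus distance pulled.

    ``distance_A`` is the restraint-centre displacement relative to the
    start; ``work_kJmol`` is cumulative with W(0) = 0; ``force_kJmol_nm``
    is the per-sample restraint force.
    """

    distance_A: np.ndarray
    work_kJmol: np.ndarray
    force_kJmol_nm: np.ndarray
    label: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.work_kJmol[0] != 0.0:
            raise ValueError("work must start at zero")

    @property
    def final_work(self) -> float:
        return float(self.work_kJmol[-1])

    def work_at(self, distance_A: float) -> float:
        """Cumulative work interpolated at a given pulled distance."""
        return float(np.interp(distance_A, self.distance_A, self.work_kJmol))


@dataclass
class EnsembleComparison:
    mean_final_work: tuple[float, float]
    final_works: tuple[np.ndarray, np.ndarray]
    pairwise_group1_greater: float
    n_pairs: int
    ranksum_statistic: float
    ranksum_pvalue: float
    common_distance_A: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def restraint_force(trace: PullTrace) -> np.ndarray:
    """Restraint force series F = k (λ − d), in kJ/mol/nm."""
    extension_nm = (trace.lambda_A - trace.cv_A) / A_PER_NM
    return trace.force_constant * extension_nm


def work_curve(trace: PullTrace) -> WorkCurve:
    """Integrate restraint force over restraint-centre displacement.

    Trapezoidal rule on (λ, F); the curve is indexed by distance pulled
    λ(t) − λ(0) in Å and shares the trace's sample grid.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to integrate work")
    force = restraint_force(trace)
    dlam_nm = np.diff(trace.lambda_A) / A_PER_NM
    increments = 0.5 * (force[1:] + force[:-1]) * dlam_nm
    work = np.concatenate([[0.0], np.cumsum(increments)])
    return WorkCurve(
        distance_A=trace.lambda_A - trace.lambda_A[0],
        work_kJmol=work,
        force_kJmol_nm=force,
        label=trace.label,
        condition=trace.condition,
        replicate=trace.replicate,
    )


def separation_point(
    contact_counts: Sequence[int] | np.ndarray,
    persistence: int = 10,
    times: np.ndarray | None = None,
):
    """First frame at which contacts vanish and stay vanished.

    ``contact_counts`` is the per-frame number of inter-monomer residue
    contacts.  Returns the frame index (or the matching entry of ``times``
    when given) of the first zero that begins a run of at least
    ``persistence`` consecutive zero-contact frames; ``None`` if the dimer
    never separates.
    """
    counts = np.asarray(contact_counts)
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if persistence > counts.size:
        raise ValueError(
            f"persistence window ({persistence}) exceeds trace length ({counts.size})"
        )
    zero = counts == 0
    # first index whose following `persistence` frames are all zero
    for i in range(counts.size - persistence + 1):
        if zero[i : i + persistence].all():
            return times[i] if times is not None else i
    return None


def compare_ensembles(
    group_1: Sequence[WorkCurve], group_2: Sequence[WorkCurve]
) -> EnsembleComparison:
    """Compare final pull works of two replicate ensembles.

    Curves are evaluated at the largest pulled distance common to every
    replicate (so length-mismatched curves are compared fairly).  Reports
    per-group mean final work, every replicate's final work, the fraction
    of cross-group pairs in which group 1 exceeds group 2 (ties count 1/2)
    and a two-sided Wilcoxon rank-sum test.
    """
    if not group_1 or not group_2:
        raise ValueError("both ensembles must be non-empty")
    common = min(float(c.distance_A[-1]) for c in [*group_1, *group_2])
    w1 = np.array([c.work_at(common) for c in group_1])
    w2 = np.array([c.work_at(common) for c in group_2])
    diffs = w1[:, None] - w2[None, :]
    greater = (diffs > 0).sum() + 0.5 * (diffs == 0).sum()
    rs = stats.ranksums(w1, w2)
    return EnsembleComparison(
        mean_final_work=(float(w1.mean()), float(w2.mean())),
        final_works=(w1, w2),
        pairwise_group1_greater=float(greater),
        n_pairs=w1.size * w2.size,
        ranksum_statistic=float(rs.statistic),
        ranksum_pvalue=float(rs.pvalue),
        common_distance_A=common,
    )
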