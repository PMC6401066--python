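"""Ideal monomer-dimer self-association: model, titration fitting, fold-change.

The NN interface of SAS-6 dimerises weakly (K_d on the 100 μM scale).  A
fluorophore-labelled protomer reports dimer formation through an increase in
fluorescence polarisation, so a concentration titration traces the
mass-action isotherm

    2M ⇌ D,   K_d = [M]^2 / [D],   C = [M] + 2[D],

where ``C`` is the *total protomer* concentration.  Solving the mass balance
gives the free monomer concentration

    [M] = (-K_d + sqrt(K_d^2 + 8 K_d C)) / 4

and the fraction of protomers sequestered in dimers f = (C - [M]) / C.  The
polarisation observable is an affine function of that fraction,
``P = p_base + dp_max * f``, which is what :func:`fit_self_association`
fits by weighted nonlinear least squares with K_d parameterised on a log
scale (positivity, optimiser stability).  Confidence intervals come from
bootstrap resampling of points within each replicate, respecting the
replicate structure of the experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "DimerModelParams",
    "TitrationSeries",
    "DimerFitResult",
    "dimer_fraction",
    "predict_polarisation",
    "fit_self_association",
    "affinity_fold_change",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimerModelParams:
    """Parameters of the monomer-dimer polarisation model.

    Attributes
    ----------
    kd : float
        Dissociation constant in μM, on the protomer basis.
    p_base : float
        Baseline (monomer) polarisation in mP.
    dp_max : float
        Maximal polarisation change on full dimerisation, in mP.
    """

    kd: float
    p_base: float
    dp_max: float

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.dp_max < 0:
            raise ValueError(f"dp_max must be non-negative, got {self.dp_max}")


@dataclass
class TitrationSeries:
    """One replicate of a polarisation-monitored self-association titration."""

    conc_uM: np.ndarray
    polarisation_mP: np.ndarray
    sigma_mP: np.ndarray | None = None
    replicate: int = 0
    condition: str = "WT"

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.polarisation_mP = np.asarray(self.polarisation_mP, dtype=float)
        if self.conc_uM.shape != self.polarisation_mP.shape:
            raise ValueError("concentration and polarisation must have equal length")
        if np.any(self.conc_uM <= 0):
            raise ValueError("total protomer concentrations must be positive")
        if self.sigma_mP is not None:
            self.sigma_mP = np.asarray(self.sigma_mP, dtype=float)
            if self.sigma_mP.shape != self.conc_uM.shape:
                raise ValueError("sigma must match the number of points")
            if np.any(self.sigma_mP <= 0):
                raise ValueError("per-point sigma must be positive where provided")

    def __len__(self) -> int:
        return self.conc_uM.size

    def to_frame(self) -> pd.DataFrame:
        sigma = self.sigma_mP if self.sigma_mP is not None else np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "condition": self.condition,
                "replicate": self.replicate,
                "conc_uM": self.conc_uM,
                "polarisation_mP": self.polarisation_mP,
                "sigma_mP": sigma,
            }
        )


@dataclass
class DimerFitResult:
    """Result of fitting the ideal self-association model to titrations."""

    kd: float
    p_base: float
    dp_max: float
    kd_ci: tuple[float, float] | None
    dp_max_ci: tuple[float, float] | None
    converged: bool
    associating: bool
    n_boot: int
    redchi: float
    n_points: int
    boot_kd: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kd_ci is not None and self.kd_ci[0] > self.kd_ci[1]:
            raise ValueError("confidence interval bounds must be ordered")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def dimer_fraction(conc_uM, kd: float):
    """Fraction of protomers in dimers at total protomer concentration ``conc_uM``.

    Closed-form root of the mass balance C = [M] + 2 [M]^2 / K_d.  Returns a
    scalar for scalar input, an array otherwise; f(0) = 0 by continuity.
    """
    c = np.asarray(conc_uM, dtype=float)
    if not kd > 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    monomer = (-kd + np.sqrt(kd * kd + 8.0 * kd * c)) / 4.0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(c > 0, (c - monomer) / np.where(c > 0, c, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if np.isscalar(conc_uM) else frac


def predict_polarisation(params: DimerModelParams, conc_uM):
    """Polarisation (mP) predicted by the monomer-dimer model at ``conc_uM``."""
    return params.p_base + params.dp_max * dimer_fraction(conc_uM, params.kd)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _stack(series: Iterable[TitrationSeries]) -> pd.DataFrame:
    frames = [s.to_frame() for s in series]
    if not frames:
        raise ValueError("at least one titration series is required")
    return pd.concat(frames, ignore_index=True)


def _fit_once(
    conc: np.ndarray,
    pol: np.ndarray,
    weights: np.ndarray,
    kd_max: float,
    p0: tuple[float, float, float],
) -> lmfit.minimizer.MinimizerResult:
    params = lmfit.Parameters()
    params.add("log10_kd", value=math.log10(p0[0]), min=-6.0, max=math.log10(kd_max))
    params.add("p_base", value=p0[1])
    params.add("dp_max", value=p0[2], min=0.0)

    def residual(p):
        model = p["p_base"].value + p["dp_max"].value * dimer_fraction(
            conc, 10.0 ** p["log10_kd"].value
        )
        return (model - pol) * weights

    return lmfit.minimize(residual, params, method="leastsq")


def fit_self_association(
    series: TitrationSeries | Sequence[TitrationSeries],
    n_boot: int = 1000,
    boot_seed: int = 0,
    ci_level: float = 0.95,
) -> DimerFitResult:
    """Fit the ideal self-association model jointly to one or more titrations.

    Weighted least squares over (log10 K_d, p_base, dp_max); per-point weights
    are 1/σ where σ is provided, 1 otherwise.  Bootstrap confidence intervals
    resample points *within* each replicate (``n_boot`` resamples, percentile
    interval at ``ci_level``).

    Flat, non-associating data are flagged (``associating=False``) rather than
    reported as a spurious affinity: the flag trips when the fitted K_d hits
    its upper bound (10x the largest concentration), the 95% confidence
    interval on dp_max (asymptotic, from the fit covariance) contains zero,
    or the K_d interval spans more than a decade per side — i.e. the data
    cannot exclude a flat titration or pin down an affinity.
    """
    if isinstance(series, TitrationSeries):
        series = [series]
    data = _stack(series)

    conc = data["conc_uM"].to_numpy()
    pol = data["polarisation_mP"].to_numpy()
    sigma = data["sigma_mP"].to_numpy()
    weights = np.where(np.isfinite(sigma), 1.0 / np.where(np.isfinite(sigma), sigma, 1.0), 1.0)

    warnings: list[str] = []
    n_distinct = np.unique(conc).size
    if n_distinct < 5:
        raise ValueError(
            f"need >= 5 distinct concentrations, got {n_distinct}"
        )
    span = conc.max() / conc.min()
    if span < 10.0:
        warnings.append(
            f"concentration span {span:.2f}x is below one order of magnitude; "
            "the fitted K_d may be poorly constrained"
        )

    kd_max = 10.0 * conc.max()
    p0 = (float(np.median(conc)), float(pol.min()), float(max(pol.max() - pol.min(), 1.0)))
    out = _fit_once(conc, pol, weights, kd_max, p0)
    kd = 10.0 ** out.params["log10_kd"].value
    p_base = out.params["p_base"].value
    dp_max = out.params["dp_max"].value
    converged = bool(out.success)

    at_bound = kd >= 0.999 * kd_max
    dp_stderr = out.params["dp_max"].stderr
    dp_indistinct_from_zero = (
        dp_stderr is not None and np.isfinite(dp_stderr) and dp_max - 1.96 * dp_stderr <= 0.0
    )
    # a K_d whose 95% interval spans more than a decade per side is unbounded
    # for practical purposes — flat data land here even when a tiny spurious
    # amplitude sneaks past the dp_max test
    kd_stderr_log10 = out.params["log10_kd"].stderr
    kd_unbounded = (
        kd_stderr_log10 is None
        or not np.isfinite(kd_stderr_log10)
        or 1.96 * kd_stderr_log10 > 1.0
    )

    # bootstrap: resample point indices within each replicate block
    boot_kd = None
    kd_ci = None
    dp_ci = None
    if n_boot > 0 and converged:
        rng = np.random.default_rng(boot_seed)
        blocks = [
            np.flatnonzero((data["condition"] == c) & (data["replicate"] == r))
            for c, r in data[["condition", "replicate"]].drop_duplicates().itertuples(index=False)
        ]
        kds, dps = [], []
        for _ in range(n_boot):
            idx = np.concatenate([b[rng.integers(0, b.size, b.size)] for b in blocks])
            try:
                bout = _fit_once(conc[idx], pol[idx], weights[idx], kd_max, (kd, p_base, dp_max))
            except Exception:  # pragma: no cover - pathological resample
                continue
            kds.append(10.0 ** bout.params["log10_kd"].value)
            dps.append(bout.params["dp_max"].value)
        if kds:
            boot_kd = np.asarray(kds)
            alpha = 100.0 * (1.0 - ci_level) / 2.0
            kd_ci = tuple(np.percentile(boot_kd, [alpha, 100.0 - alpha]))
            dp_ci = tuple(np.percentile(dps, [alpha, 100.0 - alpha]))

    associating = (
        converged and not at_bound and not dp_indistinct_from_zero and not kd_unbounded
    )
    if dp_ci is not None and dp_ci[0] <= 0.0:
        associating = False
    if dp_indistinct_from_zero:
        warnings.append(
            "dp_max is statistically indistinguishable from zero; "
            "no self-association detected on the sampled range"
        )
    if kd_unbounded and not dp_indistinct_from_zero and not at_bound:
        warnings.append(
            "K_d is unbounded (95% interval wider than a decade per side); "
            "data do not constrain a self-association affinity"
        )
    if at_bound:
        warnings.append(
            "fitted K_d reached the upper bound (10x the largest concentration); "
            "data do not support self-association on the sampled range"
        )

    return DimerFitResult(
        kd=kd,
        p_base=p_base,
        dp_max=dp_max,
        kd_ci=kd_ci,
        dp_max_ci=dp_ci,
        converged=converged,
        associating=associating,
        n_boot=n_boot,
        redchi=float(out.redchi),
        n_points=conc.size,
        boot_kd=boot_kd,
        warnings=warnings,
    )


def plot_dimer_fraction(
    series: TitrationSeries | Sequence[TitrationSeries],
    fit: DimerFitResult,
    ax=None,
):
    """Fraction-of-dimers view of a titration and its fit.

    Converts raw polarisation to protomer dimer fraction using the fitted
    p_base and dp_max, overlays the fitted isotherm on a log concentration
    axis, and returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if isinstance(series, TitrationSeries):
        series = [series]
    if ax is None:
        _, ax = plt.subplots()
    for s in series:
        frac = (s.polarisation_mP - fit.p_base) / fit.dp_max
        ax.semilogx(s.conc_uM, frac, "o", ms=4, alpha=0.7,
                    label=f"{s.condition} rep {s.replicate}")
    grid = np.geomspace(min(s.conc_uM.min() for s in series),
                        max(s.conc_uM.max() for s in series), 200)
    ax.semilogx(grid, dimer_fraction(grid, fit.kd), "-",
                label=f"fit, $K_d$ = {fit.kd:.3g} µM")
    ax.set_xlabel("total protomer concentration (µM)")
    ax.set_ylabel("fraction of protomers in dimers")
    ax.legend(fontsize=8)
    return ax


def affinity_fold_change(
    fit_low_affinity: DimerFitResult, fit_high_affinity: DimerFitResult
) -> tuple[float, tuple[float, float] | None]:
    """Affinity fold-change K_d(low affinity) / K_d(high affinity).

    A ratio above 1 means the second fit binds more tightly.  The interval
    propagates the two bootstrap samples (paired by resample index when both
    carry samples).  Raises on unconverged or non-associating input.
    """
    for name, fit in (("low-affinity", fit_low_affinity), ("high-affinity", fit_high_affinity)):
        if not (fit.converged and fit.associating):
            raise ValueError(f"{name} fit did not converge to an association model")
    ratio = fit_low_affinity.kd / fit_high_affinity.kd
    interval = None
    if fit_low_affinity.boot_kd is not None and fit_high_affinity.boot_kd is not None:
        n = min(fit_low_affinity.boot_kd.size, fit_high_affinity.boot_kd.size)
        samples = fit_low_affinity.boot_kd[:n] / fit_high_affinity.boot_kd[:n]
        interval = tuple(np.percentile(samples, [2.5, 97.5]))
    return ratio, interval
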