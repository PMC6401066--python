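"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its parameters and an explicit integer
seed — identical inputs give bit-identical outputs, and no global random
state is touched.  The generators plant known ground truth so that every
downstream stage can be tested against what was planted:

* :func:`gen_titration` — monomer-dimer polarisation titrations with
  Gaussian noise, replicate-structured like a three-experiment FP series;
* :func:`gen_noe_profile` — hetNOE profiles with a planted flexible span
  (the analogue of the K101–T131 loop);
* :func:`gen_shift_profile` — secondary-shift profiles with planted
  helix/strand/coil layout;
* :func:`gen_loop_trajectory` — a two-chain bead dimer whose loop residues
  make on/off contacts through independent two-state Markov chains with a
  chosen stationary occupancy;
* :func:`gen_pull_trace` — 1-D overdamped Langevin pulls out of a Gaussian
  adhesion well, with an optional extra adhesion term standing in for
  loop-mediated interface contacts;
* :func:`gen_intensity_series` — linear intensity-versus-salt series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sas6flex.binding import DimerModelParams, TitrationSeries, predict_polarisation
from sas6flex.contacts import Trajectory
from sas6flex.nmr import IntensitySeries, NOEProfile, SecondaryShiftProfile
from sas6flex.pulling import A_PER_NM, PullTrace

__all__ = [
    "TitrationDesign",
    "ToyDimerSpec",
    "AdhesionSpec",
    "gen_titration",
    "gen_noe_profile",
    "gen_shift_profile",
    "gen_loop_trajectory",
    "gen_pull_trace",
    "gen_intensity_series",
]

KB_KJ_PER_MOL_K = 0.0083144621


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationDesign:
    """Design of a replicated polarisation titration.

    ``concentrations`` (μM, total protomer) must be strictly positive and
    strictly increasing.  Replicate r draws its noise from seed
    ``seed + r``, so a three-replicate design at seed 1 uses seeds 1-3.
    """

    concentrations: tuple[float, ...]
    n_replicates: int = 3
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size == 0 or np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @staticmethod
    def log_spaced(
        c_min: float = 1.0,
        c_max: float = 1000.0,
        n_points: int = 12,
        n_replicates: int = 3,
        noise_sd: float = 2.0,
        seed: int = 0,
    ) -> "TitrationDesign":
        """Log-spaced design mirroring a typical FP titration (1–1000 μM, 12 points)."""
        conc = tuple(np.geomspace(c_min, c_max, n_points))
        return TitrationDesign(conc, n_replicates, noise_sd, seed)


def gen_titration(
    params: DimerModelParams, design: TitrationDesign, condition: str = "WT"
) -> list[TitrationSeries]:
    """Generate replicate titrations from the monomer-dimer polarisation model.

    Each point is p_base + dp_max·f_dimer(C, K_d) + N(0, noise_sd); the
    per-point σ records the generating noise level (1 mP floor so weights
    stay finite for noiseless data).
    """
    conc = np.asarray(design.concentrations, dtype=float)
    ideal = predict_polarisation(params, conc)
    sigma = np.full_like(conc, max(design.noise_sd, 1.0))
    series = []
    for r in range(design.n_replicates):
        rng = np.random.default_rng(design.seed + r)
        noisy = ideal + rng.normal(0.0, design.noise_sd, size=conc.size)
        series.append(
            TitrationSeries(
                conc_uM=conc,
                polarisation_mP=noisy,
                sigma_mP=sigma.copy(),
                replicate=r,
                condition=condition,
            )
        )
    return series


# ---------------------------------------------------------------------------
# NMR profiles
# ---------------------------------------------------------------------------

def gen_noe_profile(
    n_residues: int,
    flexible_span: tuple[int, int],
    rigid_level: float = 0.82,
    flexible_level: float = 0.35,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> NOEProfile:
    """hetNOE profile with a planted flexible span (inclusive, 1-based).

    Residues inside the span scatter around ``flexible_level``, the rest
    around ``rigid_level``; values are clipped to [-0.5, 1.0].  The levels
    must straddle the 0.6 structured/flexible threshold.
    """
    lo, hi = flexible_span
    if not (1 <= lo <= hi <= n_residues):
        raise ValueError(f"flexible span {flexible_span} outside sequence 1..{n_residues}")
    if not flexible_level < 0.6 < rigid_level:
        raise ValueError("levels must straddle the 0.6 threshold")
    rng = np.random.default_rng(seed)
    idx = np.arange(1, n_residues + 1)
    base = np.where((idx >= lo) & (idx <= hi), flexible_level, rigid_level)
    noe = np.clip(base + rng.normal(0.0, noise_sd, size=n_residues), -0.5, 1.0)
    err = np.full(n_residues, max(noise_sd, 1e-3))
    return NOEProfile(residue_index=idx, noe=noe, noe_err=err)


# generator defaults: planted deviations comfortably beyond CSI thresholds
SHIFT_MAGNITUDES = {
    "helix": (3.0, -0.5),
    "strand": (-1.5, 2.0),
    "coil": (0.0, 0.0),
}


def gen_shift_profile(
    layout: list[tuple[str, tuple[int, int]]],
    n_residues: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    magnitudes: dict[str, tuple[float, float]] | None = None,
) -> SecondaryShiftProfile:
    """Secondary-shift profile with planted helix/strand spans (inclusive, 1-based).

    ``layout`` lists non-overlapping (element_type, (start, end)) entries;
    anything uncovered is coil.  Planted deviations default to
    helix (+3.0, −0.5) and strand (−1.5, +2.0) ppm for (Cα, Cβ).
    """
    mags = dict(SHIFT_MAGNITUDES, **(magnitudes or {}))
    covered = np.zeros(n_residues + 1, dtype=bool)
    d_ca = np.zeros(n_residues)
    d_cb = np.zeros(n_residues)
    for kind, (lo, hi) in layout:
        if kind not in mags:
            raise ValueError(f"unknown element type {kind!r}")
        if not (1 <= lo <= hi <= n_residues):
            raise ValueError(f"span {(lo, hi)} outside sequence 1..{n_residues}")
        if covered[lo : hi + 1].any():
            raise ValueError(f"element {kind} {(lo, hi)} overlaps an earlier element")
        covered[lo : hi + 1] = True
        d_ca[lo - 1 : hi] = mags[kind][0]
        d_cb[lo - 1 : hi] = mags[kind][1]
    rng = np.random.default_rng(seed)
    d_ca = d_ca + rng.normal(0.0, noise_sd, size=n_residues)
    d_cb = d_cb + rng.normal(0.0, noise_sd, size=n_residues)
    frame = pd.DataFrame(
        {
            "residue_index": np.arange(1, n_residues + 1),
            "aa": "X",
            "d_ca": d_ca,
            "d_cb": d_cb,
        }
    )
    return SecondaryShiftProfile(frame, reference_id="synthetic-planted")


# ---------------------------------------------------------------------------
# bead-dimer trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyDimerSpec:
    """Two-chain bead dimer with Markov on/off loop contacts.

    One bead per residue, chains A and B, ``n_core_residues`` residues each.
    Loop residues (``loop_span``, inclusive 1-based) of each chain contact
    residues of the partner chain's ``target_region``; every loop residue
    carries an independent two-state Markov chain with stationary contact
    probability ``p_on`` and contact persistence ``p_stay`` (probability of
    staying in contact).  In contact frames the loop bead sits at half the
    contact cutoff from its partner bead; otherwise it sits at its home
    position, beyond twice the cutoff from the partner chain.
    """

    n_core_residues: int = 30
    loop_span: tuple[int, int] = (10, 20)
    target_region: tuple[int, int] = (2, 8)
    p_on: float = 0.5
    p_stay: float = 0.8
    bead_spacing: float = 3.8
    contact_distance_on: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("loop_span", self.loop_span), ("target_region", self.target_region)):
            if not (1 <= lo <= hi <= self.n_core_residues):
                raise ValueError(f"{name} {(lo, hi)} outside chain bounds")
        if not (
            self.loop_span[1] < self.target_region[0]
            or self.target_region[1] < self.loop_span[0]
        ):
            raise ValueError("loop_span and target_region must be disjoint")
        for name in ("p_on", "p_stay"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bead_spacing <= 0 or self.contact_distance_on <= 0:
            raise ValueError("distances must be positive")


def _markov_states(p_on: float, p_stay: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary two-state chain: P(on) = p_on at every frame, P(on->on) = p_stay."""
    if p_on == 0.0:
        return np.zeros(n, dtype=bool)
    if p_on == 1.0:
        return np.ones(n, dtype=bool)
    p_on_from_off = p_on * (1.0 - p_stay) / (1.0 - p_on)
    if p_on_from_off > 1.0:
        raise ValueError(
            f"infeasible Markov parameters: stationary occupancy {p_on} with "
            f"persistence {p_stay} requires off->on probability {p_on_from_off:.3f} > 1"
        )
    states = np.empty(n, dtype=bool)
    u = rng.random(n)
    states[0] = u[0] < p_on  # start from the stationary distribution
    for t in range(1, n):
        p = p_stay if states[t - 1] else p_on_from_off
        states[t] = u[t] < p
    return states


def gen_loop_trajectory(spec: ToyDimerSpec, n_frames: int) -> Trajectory:
    """Bead-dimer trajectory whose loop contacts realise the planted occupancy."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_core_residues
    cutoff = spec.contact_distance_on
    offset = max(5.0 * cutoff, 20.0)  # inter-chain separation of the rigid cores

    home = np.zeros((2, n, 3))
    home[0, :, 0] = np.arange(n) * spec.bead_spacing
    home[1, :, 0] = np.arange(n) * spec.bead_spacing
    home[1, :, 1] = offset

    loop = list(range(spec.loop_span[0], spec.loop_span[1] + 1))
    target = list(range(spec.target_region[0], spec.target_region[1] + 1))
    partner = {r: target[(r - loop[0]) % len(target)] for r in loop}

    # independent Markov chains: chain index, loop residue -> frame states
    states = {
        (ci, r): _markov_states(spec.p_on, spec.p_stay, n_frames, rng)
        for ci in (0, 1)
        for r in loop
    }

    coords = np.empty((n_frames, 2 * n, 3))
    coords[:] = home.reshape(1, 2 * n, 3)
    for (ci, r), s in states.items():
        other = 1 - ci
        p_pos = home[other, partner[r] - 1]
        # contact frames: half the cutoff from the partner bead, on the line
        # back toward the loop bead's home position
        back = home[ci, r - 1] - p_pos
        contact_pos = p_pos + back / np.linalg.norm(back) * (0.5 * cutoff)
        atom = ci * n + (r - 1)
        coords[s, atom, :] = contact_pos

    atoms = pd.DataFrame(
        {
            "chain": ["A"] * n + ["B"] * n,
            "resid": list(range(1, n + 1)) * 2,
            "resname": "GLY",
            "name": "CA",
            "element": "C",
        }
    )
    return Trajectory(coords=coords, atoms=atoms)


# ---------------------------------------------------------------------------
# Langevin pull traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdhesionSpec:
    """1-D overdamped Langevin particle in a Gaussian adhesion well.

    The collective variable d (nm internally, reported in Å) starts at the
    well centre.  ``well_depth`` models the core dimerisation interface;
    ``extra_adhesion_depth`` adds the loop-mediated contribution (zero for
    the loop-deletion analogue).  ``friction`` is the drag coefficient γ in
    kJ·ns/(mol·nm²); temperature in K; ``dt`` in ns.
    """

    well_depth: float = 30.0
    well_width: float = 0.3
    extra_adhesion_depth: float = 0.0
    friction: float = 100.0
    temperature: float = 300.0
    dt: float = 0.01
    n_steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.well_depth < 0 or self.extra_adhesion_depth < 0:
            raise ValueError("adhesion depths must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.well_width <= 0 or self.friction <= 0 or self.temperature < 0:
            raise ValueError("well_width and friction must be positive, temperature >= 0")


def gen_pull_trace(
    spec: AdhesionSpec,
    k: float = 1000.0,
    v: float = 1.0,
    d0_A: float = 20.0,
    condition: str = "",
    replicate: int = 0,
) -> PullTrace:
    """Constant-velocity steered pull of a Langevin particle out of its well.

    ``k`` is the restraint force constant (kJ/mol per nm of extension) and
    ``v`` the pull velocity in Å/ns, as in a typical steered-MD protocol
    (defaults 1000 kJ/mol/nm, 1 Å/ns).  Euler–Maruyama integration with the
    overdamped stability requirement dt < γ/k enforced up front.
    """
    if k <= 0 or v <= 0:
        raise ValueError("force constant and velocity must be positive")
    bound = spec.friction / k
    if spec.dt >= bound:
        raise ValueError(
            f"dt={spec.dt} ns unstable for k={k}: Euler–Maruyama requires dt < friction/k = {bound:.4g} ns"
        )
    rng = np.random.default_rng(spec.seed)
    d0 = d0_A / A_PER_NM
    v_nm = v / A_PER_NM
    depth = spec.well_depth + spec.extra_adhesion_depth
    w2 = spec.well_width ** 2
    kt = KB_KJ_PER_MOL_K * spec.temperature
    noise_scale = np.sqrt(2.0 * kt * spec.dt / spec.friction)

    d = np.empty(spec.n_steps + 1)
    lam = d0 + v_nm * spec.dt * np.arange(spec.n_steps + 1)
    d[0] = d0
    xi = rng.standard_normal(spec.n_steps)
    for t in range(spec.n_steps):
        x = d[t]
        f_well = -depth * (x - d0) / w2 * np.exp(-((x - d0) ** 2) / (2.0 * w2))
        f_restraint = k * (lam[t] - x)
        d[t + 1] = x + spec.dt / spec.friction * (f_well + f_restraint) + noise_scale * xi[t]

    times = spec.dt * np.arange(spec.n_steps + 1)
    return PullTrace(
        time_ns=times,
        cv_A=d * A_PER_NM,
        lambda_A=lam * A_PER_NM,
        force_constant=k,
        velocity_A_per_ns=v,
        lambda0_A=d0_A,
        label=f"{condition}-{replicate}" if condition else f"pull-{replicate}",
        condition=condition,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# intensity series
# ---------------------------------------------------------------------------

def gen_intensity_series(
    slope: float,
    intercept: float,
    salt_points,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "G120",
) -> IntensitySeries:
    """Normalised-intensity series, linear in salt concentration plus noise."""
    salt = np.asarray(salt_points, dtype=float)
    if np.any(np.diff(salt) <= 0):
        raise ValueError("salt points must be strictly increasing")
    rng = np.random.default_rng(seed)
    y = intercept + slope * salt + rng.normal(0.0, noise_sd, size=salt.size)
    return IntensitySeries(
        label=label,
        condition_mM=salt,
        intensity=np.clip(y, 0.0, None),
        normalisation_labels=("G111", "G128"),
    )
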