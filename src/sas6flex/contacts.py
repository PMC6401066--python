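"""Residue-pair contact occupancy over trajectories and replicate aggregation.

Contact occupancy — the fraction of trajectory frames in which the minimum
interatomic distance between two residues falls (strictly) below a cutoff —
is the statistic that quantifies how often a flexible loop touches the
structured core across a dimerisation interface.  The default cutoff is
3.5 Å and the default atom filter keeps heavy atoms only; ties at exactly
the cutoff count as non-contact.  No periodic-boundary imaging is applied
(a documented limitation for imported periodic MD data; the bead
trajectories this package generates are non-periodic).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "ContactOccupancy",
    "parse_selection",
    "residue_min_distance",
    "contact_occupancy",
    "aggregate_replicates",
]

ResidueKey = tuple[str, int]  # (chain ID, 1-based residue index)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames x atoms coordinate stack with per-atom labels.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``atoms`` is a table
    with columns chain, resid, resname, name, element, constant across
    frames.  ``frame_spacing_ps`` is optional metadata.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_spacing_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        required = {"chain", "resid", "resname", "name", "element"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table length must match coordinate atom count")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def residues(self, chain: str | None = None) -> list[ResidueKey]:
        table = self.atoms if chain is None else self.atoms[self.atoms["chain"] == chain]
        seen = table[["chain", "resid"]].drop_duplicates()
        return [(str(c), int(r)) for c, r in seen.itertuples(index=False)]

    def atom_indices(self, residue: ResidueKey, atom_filter: str | Callable = "heavy") -> np.ndarray:
        chain, resid = residue
        mask = (self.atoms["chain"] == chain) & (self.atoms["resid"] == resid)
        if not mask.any():
            raise KeyError(f"residue {chain}:{resid} not found in trajectory")
        sub = self.atoms[mask]
        keep = _atom_mask(sub, atom_filter)
        idx = sub.index.to_numpy()[keep]
        if idx.size == 0:
            raise ValueError(f"residue {chain}:{resid}: no atoms pass filter {atom_filter!r}")
        return idx


@dataclass
class ContactOccupancy:
    """Pairwise and per-residue contact occupancy for two residue groups.

    ``pairs``: columns chain_a, resid_a, chain_b, resid_b, occupancy.
    ``marginal_a``/``marginal_b``: per residue of each group, the fraction of
    frames in contact with *any* partner residue (occupancy_any) plus the
    max and mean pairwise occupancies against the partner group.
    """

    pairs: pd.DataFrame
    marginal_a: pd.DataFrame
    marginal_b: pd.DataFrame
    cutoff: float
    n_frames: int

    def transposed(self) -> "ContactOccupancy":
        pairs = self.pairs.rename(
            columns={
                "chain_a": "chain_b", "resid_a": "resid_b",
                "chain_b": "chain_a", "resid_b": "resid_a",
            }
        )[["chain_a", "resid_a", "chain_b", "resid_b", "occupancy"]]
        return ContactOccupancy(
            pairs=pairs,
            marginal_a=self.marginal_b,
            marginal_b=self.marginal_a,
            cutoff=self.cutoff,
            n_frames=self.n_frames,
        )


# ---------------------------------------------------------------------------
# selections and atom filters
# ---------------------------------------------------------------------------

_SEL_RE = re.compile(r"^\s*([A-Za-z0-9]+)\s*:\s*(\d+)\s*-\s*(\d+)\s*$")


def parse_selection(selection: str | Sequence[ResidueKey]) -> list[ResidueKey]:
    """Parse a residue group: 'chain:first-last' mini-syntax or explicit keys."""
    if not isinstance(selection, str):
        return [(str(c), int(r)) for c, r in selection]
    m = _SEL_RE.match(selection)
    if m is None:
        raise ValueError(f"cannot parse selection {selection!r}; expected 'chain:first-last'")
    chain, first, last = m.group(1), int(m.group(2)), int(m.group(3))
    if last < first:
        raise ValueError(f"selection {selection!r}: last residue before first")
    return [(chain, r) for r in range(first, last + 1)]


def _atom_mask(sub: pd.DataFrame, atom_filter: str | Callable) -> np.ndarray:
    if callable(atom_filter):
        return sub.apply(atom_filter, axis=1).to_numpy(dtype=bool)
    if atom_filter == "all":
        return np.ones(len(sub), dtype=bool)
    if atom_filter == "heavy":
        return (sub["element"].str.upper() != "H").to_numpy()
    raise ValueError(f"unknown atom filter {atom_filter!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def residue_min_distance(
    traj: Trajectory,
    frame: int,
    residue_a: ResidueKey,
    residue_b: ResidueKey,
    atom_filter: str | Callable = "heavy",
) -> float:
    """Minimum distance (Å) between any selected atom pair of two residues in one frame."""
    ia = traj.atom_indices(residue_a, atom_filter)
    ib = traj.atom_indices(residue_b, atom_filter)
    a = traj.coords[frame, ia]  # (na, 3)
    b = traj.coords[frame, ib]  # (nb, 3)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _pair_min_distances(
    traj: Trajectory, ia: np.ndarray, ib: np.ndarray
) -> np.ndarray:
    """Per-frame minimum distance between two atom index sets, all frames at once."""
    a = traj.coords[:, ia, :]  # (F, na, 3)
    b = traj.coords[:, ib, :]  # (F, nb, 3)
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    return d.reshape(traj.n_frames, -1).min(axis=1)


def contact_occupancy(
    traj: Trajectory,
    group_a: str | Sequence[ResidueKey],
    group_b: str | Sequence[ResidueKey],
    cutoff: float = 3.5,
    atom_filter: str | Callable = "heavy",
) -> ContactOccupancy:
    """Contact occupancy of every residue pair between two disjoint groups.

    occupancy(a, b) = #frames with min-distance(a, b) < cutoff / n_frames
    (strict inequality).  Per-residue marginals additionally report the
    fraction of frames each residue contacts *any* partner-group residue.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    keys_a = parse_selection(group_a)
    keys_b = parse_selection(group_b)
    if not keys_a or not keys_b:
        raise ValueError("residue groups must be non-empty")
    if set(keys_a) & set(keys_b):
        raise ValueError("residue groups must be disjoint")

    idx_a = {k: traj.atom_indices(k, atom_filter) for k in keys_a}
    idx_b = {k: traj.atom_indices(k, atom_filter) for k in keys_b}

    n = traj.n_frames
    rows = []
    contact_any_a = {k: np.zeros(n, dtype=bool) for k in keys_a}
    contact_any_b = {k: np.zeros(n, dtype=bool) for k in keys_b}
    occ_matrix = np.zeros((len(keys_a), len(keys_b)))
    for i, ka in enumerate(keys_a):
        for j, kb in enumerate(keys_b):
            dmin = _pair_min_distances(traj, idx_a[ka], idx_b[kb])
            in_contact = dmin < cutoff
            occ = in_contact.sum() / n
            occ_matrix[i, j] = occ
            contact_any_a[ka] |= in_contact
            contact_any_b[kb] |= in_contact
            rows.append((ka[0], ka[1], kb[0], kb[1], occ))
    pairs = pd.DataFrame(
        rows, columns=["chain_a", "resid_a", "chain_b", "resid_b", "occupancy"]
    )

    def marginal(keys, any_map, axis) -> pd.DataFrame:
        maxes = occ_matrix.max(axis=axis)
        means = occ_matrix.mean(axis=axis)
        return pd.DataFrame(
            {
                "chain": [k[0] for k in keys],
                "resid": [k[1] for k in keys],
                "occupancy_any": [any_map[k].sum() / n for k in keys],
                "max_pair": maxes,
                "mean_pair": means,
            }
        )

    return ContactOccupancy(
        pairs=pairs,
        marginal_a=marginal(keys_a, contact_any_a, 1),
        marginal_b=marginal(keys_b, contact_any_b, 0),
        cutoff=cutoff,
        n_frames=n,
    )


def frame_contact_counts(
    traj: Trajectory,
    group_a: str | Sequence[ResidueKey],
    group_b: str | Sequence[ResidueKey],
    cutoff: float = 3.5,
    atom_filter: str | Callable = "heavy",
) -> np.ndarray:
    """Per-frame number of residue pairs in contact between two groups.

    The input separation-detection expects: counts drop to zero when the
    two groups lose all contacts.
    """
    keys_a = parse_selection(group_a)
    keys_b = parse_selection(group_b)
    counts = np.zeros(traj.n_frames, dtype=int)
    for ka in keys_a:
        ia = traj.atom_indices(ka, atom_filter)
        for kb in keys_b:
            ib = traj.atom_indices(kb, atom_filter)
            counts += _pair_min_distances(traj, ia, ib) < cutoff
    return counts


def aggregate_replicates(
    runs: Sequence[ContactOccupancy],
    side: str = "a",
    report_threshold: float = 0.5,
) -> pd.DataFrame:
    """Aggregate per-residue contact occupancy across replicate runs.

    Collects the ``occupancy_any`` marginal of the chosen side from every
    run, reports the per-run values, their mean, and flags residues whose
    mean occupancy exceeds ``report_threshold`` (default 0.5 — residues in
    contact for over half of the simulation time).
    """
    if not runs:
        raise ValueError("need at least one run")
    cutoffs = {r.cutoff for r in runs}
    if len(cutoffs) != 1:
        raise ValueError(f"runs use different cutoffs: {sorted(cutoffs)}")
    marginals = [r.marginal_a if side == "a" else r.marginal_b for r in runs]
    keys0 = list(zip(marginals[0]["chain"], marginals[0]["resid"]))
    for m in marginals[1:]:
        if list(zip(m["chain"], m["resid"])) != keys0:
            raise ValueError("runs cover different residue universes")
    out = marginals[0][["chain", "resid"]].copy()
    per_run = np.column_stack([m["occupancy_any"].to_numpy() for m in marginals])
    for i in range(per_run.shape[1]):
        out[f"run_{i}"] = per_run[:, i]
    out["mean"] = per_run.mean(axis=1)
    out["flagged"] = out["mean"] > report_threshold
    return out
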