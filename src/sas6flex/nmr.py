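"""Per-residue NMR analyses: secondary shifts, hetNOE segmentation, intensity trends.

Three observables, three operations:

* **Secondary chemical shifts.**  Cα/Cβ chemical shifts deviate from their
  random-coil values in characteristic directions inside stable secondary
  structure (helix: Δδ(Cα) > 0, Δδ(Cβ) < 0; strand: the reverse).
  :func:`secondary_shifts` subtracts a bundled random-coil reference table
  (Wishart-style 1-letter-coded Cα/Cβ values, see ``data/random_coil_shifts.csv``)
  and :func:`classify_css` applies chemical-shift-index style thresholds to
  call helix/strand/coil segments.

* **Heteronuclear {1H}-15N NOE.**  Ratios above ~0.6 indicate structured
  backbone; sustained runs below the threshold mark sub-nanosecond
  flexibility.  :func:`segment_flexible` extracts maximal sub-threshold runs,
  bridging short unassigned gaps (prolines, overlapped peaks) so that a
  contiguous flexible loop is not artificially split.

* **Resonance intensity trends.**  Exchange-broadened resonances recover
  intensity when the interactions that broaden them are screened; a linear
  regression of normalised intensity against salt concentration quantifies
  the trend (:func:`normalized_intensity_trend`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ShiftTable",
    "SecondaryShiftProfile",
    "NOEProfile",
    "FlexSegments",
    "IntensitySeries",
    "LinearFitResult",
    "load_random_coil_table",
    "secondary_shifts",
    "classify_css",
    "segment_flexible",
    "normalized_intensity_trend",
]

_RC_TABLE_ID = "wishart-random-coil-ca-cb"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ShiftTable:
    """Observed Cα/Cβ chemical shifts per residue (1-based numbering).

    ``data`` columns: residue_index, aa (1-letter), dCA, dCB.  Missing
    observations are NaN; glycine carries no Cβ by construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"residue_index", "aa", "dCA", "dCB"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        idx = self.data["residue_index"].to_numpy()
        if len(np.unique(idx)) != len(idx) or np.any(np.diff(idx) <= 0):
            raise ValueError("residue indices must be unique and increasing")
        gly = self.data["aa"].str.upper() == "G"
        if gly.any() and self.data.loc[gly, "dCB"].notna().any():
            raise ValueError("glycine residues must not carry a Cβ shift")


@dataclass
class SecondaryShiftProfile:
    """Δδ = δ_obs − δ_random-coil per residue, per atom type (ppm)."""

    data: pd.DataFrame  # columns: residue_index, aa (optional), d_ca, d_cb
    reference_id: str = _RC_TABLE_ID

    def __post_init__(self) -> None:
        required = {"residue_index", "d_ca", "d_cb"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"profile missing columns: {sorted(missing)}")


@dataclass
class NOEProfile:
    """Per-residue heteronuclear {1H}-15N NOE ratios, optionally with errors."""

    residue_index: np.ndarray
    noe: np.ndarray
    noe_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.noe = np.asarray(self.noe, dtype=float)
        if self.residue_index.shape != self.noe.shape:
            raise ValueError("residue_index and noe must have equal length")
        finite = self.noe[np.isfinite(self.noe)]
        if finite.size and (finite.min() < -1.5 or finite.max() > 1.2):
            raise ValueError("hetNOE ratios outside sanity bound [-1.5, 1.2]")
        if self.noe_err is not None:
            self.noe_err = np.asarray(self.noe_err, dtype=float)


@dataclass
class FlexSegments:
    """Flexible/rigid backbone segments from hetNOE thresholding.

    ``segments`` is a sorted list of (start_residue, end_residue, class)
    with class in {"flexible", "rigid"}; boundaries are inclusive.
    """

    segments: list[tuple[int, int, str]]
    threshold: float
    min_run: int
    max_gap: int

    @property
    def flexible(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, k in self.segments if k == "flexible"]

    @property
    def rigid(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, k in self.segments if k == "rigid"]

    def report(self) -> str:
        lines = [f"hetNOE segmentation (threshold {self.threshold}, "
                 f"min_run {self.min_run}, max_gap {self.max_gap})"]
        for a, b, k in self.segments:
            lines.append(f"  {a:4d} - {b:4d}  {k}")
        return "\n".join(lines)


@dataclass
class IntensitySeries:
    """Normalised resonance intensities of one probe across a condition series."""

    label: str
    condition_mM: np.ndarray
    intensity: np.ndarray
    normalisation_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.condition_mM = np.asarray(self.condition_mM, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.condition_mM.shape != self.intensity.shape:
            raise ValueError("condition and intensity vectors must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("normalised intensities must be non-negative")


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_random_coil_table() -> pd.DataFrame:
    """Bundled random-coil Cα/Cβ reference shifts, indexed by 1-letter code."""
    with resources.files("sas6flex.data").joinpath("random_coil_shifts.csv").open() as fh:
        table = pd.read_csv(fh)
    return table.set_index("aa")


def secondary_shifts(
    obs: ShiftTable, ref: pd.DataFrame | None = None
) -> SecondaryShiftProfile:
    """Secondary chemical shifts Δδ = δ_obs − δ_rc per residue and atom type.

    Missing observations propagate as NaN.  Unknown residue codes raise,
    naming the offending residue.
    """
    if ref is None:
        ref = load_random_coil_table()
        ref_id = _RC_TABLE_ID
    else:
        ref_id = "user-supplied"
    rows = []
    for row in obs.data.itertuples(index=False):
        aa = str(row.aa).upper()
        if aa not in ref.index:
            raise KeyError(
                f"residue {aa}{row.residue_index}: no random-coil reference for '{aa}'"
            )
        rc_ca = ref.loc[aa, "ca_ppm"]
        rc_cb = ref.loc[aa, "cb_ppm"]
        d_ca = row.dCA - rc_ca if np.isfinite(row.dCA) else np.nan
        d_cb = row.dCB - rc_cb if np.isfinite(row.dCB) and np.isfinite(rc_cb) else np.nan
        rows.append((row.residue_index, aa, d_ca, d_cb))
    frame = pd.DataFrame(rows, columns=["residue_index", "aa", "d_ca", "d_cb"])
    return SecondaryShiftProfile(frame, reference_id=ref_id)


def _merge_calls(
    idx: np.ndarray, calls: np.ndarray, min_len: int
) -> list[tuple[int, int, str]]:
    """Merge per-residue calls into segments; demote short helix/strand runs to coil."""
    segments: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, len(calls) + 1):
        if i == len(calls) or calls[i] != calls[start]:
            segments.append((int(idx[start]), int(idx[i - 1]), str(calls[start])))
            start = i
    # demote sub-min_len structured runs, then coalesce adjacent coil
    demoted = [
        (a, b, "coil") if k != "coil" and (b - a + 1) < min_len else (a, b, k)
        for a, b, k in segments
    ]
    merged: list[tuple[int, int, str]] = []
    for seg in demoted:
        if merged and merged[-1][2] == seg[2] and seg[0] == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def classify_css(
    profile: SecondaryShiftProfile,
    tau_ca: float = 0.7,
    tau_cb: float = 1.0,
    min_len: int = 4,
) -> list[tuple[int, int, str]]:
    """Call helix/strand/coil segments from secondary chemical shifts.

    A residue is called helix when Δδ(Cα) > +tau_ca, strand when
    Δδ(Cα) < −tau_ca, coil otherwise; a Cβ deviation pointing firmly the
    wrong way (|Δδ(Cβ)| > tau_cb with the opposite sign signature) vetoes
    the call.  Structured runs shorter than ``min_len`` are demoted to coil.
    Returns inclusive (start, end, class) segments covering the profile.
    """
    if tau_ca <= 0 or tau_cb <= 0:
        raise ValueError("thresholds must be positive")
    data = profile.data.sort_values("residue_index")
    idx = data["residue_index"].to_numpy()
    d_ca = data["d_ca"].to_numpy()
    d_cb = data["d_cb"].to_numpy()
    calls = np.full(len(idx), "coil", dtype=object)
    has_cb = np.isfinite(d_cb)
    helix = (d_ca > tau_ca) & ~(has_cb & (d_cb > tau_cb))
    strand = (d_ca < -tau_ca) & ~(has_cb & (d_cb < -tau_cb))
    calls[helix] = "helix"
    calls[strand] = "strand"
    return _merge_calls(idx, calls, min_len)


def segment_flexible(
    noe: NOEProfile,
    threshold: float = 0.6,
    min_run: int = 3,
    max_gap: int = 2,
) -> FlexSegments:
    """Segment the backbone into flexible and rigid spans from hetNOE ratios.

    Flexible residues satisfy ratio < ``threshold`` (strict).  Runs of
    flexible residues separated only by *unmeasured* gaps of at most
    ``max_gap`` residues are bridged; bridged runs shorter than ``min_run``
    are dropped.  The complement (measured, at/above threshold) is returned
    as rigid segments.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if noe.residue_index.size == 0:
        raise ValueError("empty hetNOE profile")

    lo, hi = int(noe.residue_index.min()), int(noe.residue_index.max())
    n = hi - lo + 1
    measured = np.zeros(n, dtype=bool)
    flex = np.zeros(n, dtype=bool)
    for i, v in zip(noe.residue_index, noe.noe):
        if np.isfinite(v):
            measured[i - lo] = True
            flex[i - lo] = v < threshold

    # maximal flexible runs, bridging unmeasured gaps <= max_gap
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if measured[i] and flex[i]:
            start = i
            end = i
            j = i + 1
            gap = 0
            while j < n:
                if measured[j] and flex[j]:
                    end = j
                    gap = 0
                elif not measured[j]:
                    gap += 1
                    if gap > max_gap:
                        break
                else:  # measured rigid residue terminates the run
                    break
                j += 1
            runs.append((start, end))
            i = end + 1
        else:
            i += 1
    runs = [(a, b) for a, b in runs if (b - a + 1) >= min_run]

    flex_mask = np.zeros(n, dtype=bool)
    for a, b in runs:
        flex_mask[a : b + 1] = True

    segments: list[tuple[int, int, str]] = []
    for a, b in runs:
        segments.append((a + lo, b + lo, "flexible"))
    # rigid complement: measured residues not inside a flexible run
    rigid = measured & ~flex_mask
    i = 0
    while i < n:
        if rigid[i]:
            start = i
            while i + 1 < n and rigid[i + 1]:
                i += 1
            segments.append((start + lo, i + lo, "rigid"))
        i += 1
    segments.sort()
    return FlexSegments(segments, threshold=threshold, min_run=min_run, max_gap=max_gap)


def normalized_intensity_trend(series: IntensitySeries) -> LinearFitResult:
    """Ordinary least-squares linear trend of normalised intensity vs condition."""
    if len(series.condition_mM) < 3:
        raise ValueError("need at least 3 points for a linear trend")
    x, y = series.condition_mM, series.intensity
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = max(len(x) - 2, 1)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        residual_sd=float(np.sqrt(ss_res / dof)),
    )
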