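"""Format I/O, run configuration and the pipeline driver.

Formats handled here, all plain text:

* multi-model PDB (MODEL/ENDMDL records, chains A/B, 1-based residue
  numbering) and XYZ (with a chain/residue sidecar map) for trajectories;
* CSV with a header row for every table (titrations, shift tables, hetNOE
  profiles, pull traces, occupancy tables); floats serialised at 9
  significant digits;
* whitespace-delimited COLVAR-style pull traces via a column mapping;
* key-value run manifests echoing effective parameters and seeds.

:func:`run_pipeline` dispatches one named stage from a :class:`RunConfig`
(unknown keys rejected before any computation) and writes the stage outputs,
a manifest and a log; identical configs and seeds give identical numeric
outputs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from sas6flex import binding, contacts, nmr, pulling, ring, synthetic

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_titrations",
    "write_titrations",
    "read_shift_table",
    "read_noe_profile",
    "read_pull_trace",
    "read_colvar",
    "write_manifest",
    "RunConfig",
    "run_pipeline",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.9g"


# ---------------------------------------------------------------------------
# trajectory formats
# ---------------------------------------------------------------------------

def _validate_pdb_models(path: Path) -> None:
    """Light structural scan: MODEL/ENDMDL nesting and per-model atom counts."""
    open_model = None
    counts: list[int] = []
    current = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if open_model is not None:
                    raise ValueError(
                        f"{path}:{lineno}: MODEL opened inside MODEL (opened at line {open_model})"
                    )
                open_model = lineno
                current = 0
            elif rec == "ENDMDL":
                if open_model is None:
                    raise ValueError(f"{path}:{lineno}: ENDMDL without matching MODEL")
                counts.append(current)
                open_model = None
            elif rec in ("ATOM", "HETATM") and open_model is not None:
                current += 1
    if open_model is not None:
        raise ValueError(f"{path}:{open_model}: MODEL never closed by ENDMDL")
    if counts and len(set(counts)) != 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise ValueError(
            f"{path}: model {bad + 1} has {counts[bad]} atoms, expected {counts[0]}"
        )


def write_trajectory(traj: contacts.Trajectory, path: str | Path, fmt: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or XYZ (+ sidecar map CSV)."""
    path = Path(path)
    if fmt == "pdb":
        template = struc.AtomArray(traj.n_atoms)
        template.chain_id = traj.atoms["chain"].to_numpy(dtype="U4")
        template.res_id = traj.atoms["resid"].to_numpy(dtype=int)
        template.res_name = traj.atoms["resname"].to_numpy(dtype="U5")
        template.atom_name = traj.atoms["name"].to_numpy(dtype="U6")
        template.element = traj.atoms["element"].to_numpy(dtype="U2")
        stack = struc.from_template(template, traj.coords)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(path)
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\nframe {f}\n")
                for el, xyz in zip(traj.atoms["element"], traj.coords[f]):
                    fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
        traj.atoms.assign(atom_index=np.arange(traj.n_atoms)).to_csv(
            path.with_suffix(path.suffix + ".map.csv"), index=False
        )
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path: str | Path, fmt: str = "pdb") -> contacts.Trajectory:
    """Read a trajectory from multi-model PDB or XYZ with its sidecar map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "pdb":
        _validate_pdb_models(path)
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)
        if isinstance(stack, struc.AtomArray):  # single model
            stack = struc.stack([stack])
        atoms = pd.DataFrame(
            {
                "chain": stack.chain_id,
                "resid": stack.res_id,
                "resname": stack.res_name,
                "name": stack.atom_name,
                "element": stack.element,
            }
        )
        return contacts.Trajectory(coords=np.asarray(stack.coord, dtype=float), atoms=atoms)
    if fmt == "xyz":
        frames = []
        with open(path) as fh:
            lines = fh.read().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i])
            block = lines[i + 2 : i + 2 + n]
            frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
            i += 2 + n
        coords = np.asarray(frames, dtype=float)
        atoms = pd.read_csv(path.with_suffix(path.suffix + ".map.csv")).drop(
            columns=["atom_index"], errors="ignore"
        )
        return contacts.Trajectory(coords=coords, atoms=atoms)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def write_titrations(series: Sequence[binding.TitrationSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_titrations(path: str | Path) -> list[binding.TitrationSeries]:
    data = pd.read_csv(path)
    out = []
    for (cond, rep), grp in data.groupby(["condition", "replicate"], sort=True):
        sigma = grp["sigma_mP"].to_numpy() if "sigma_mP" in grp else None
        if sigma is not None and not np.isfinite(sigma).all():
            sigma = None
        out.append(
            binding.TitrationSeries(
                conc_uM=grp["conc_uM"].to_numpy(),
                polarisation_mP=grp["polarisation_mP"].to_numpy(),
                sigma_mP=sigma,
                replicate=int(rep),
                condition=str(cond),
            )
        )
    return out


def read_shift_table(path: str | Path, sep: str | None = None) -> nmr.ShiftTable:
    data = pd.read_csv(path, sep=sep, engine="python")
    data = data.rename(columns={"dCA": "dCA", "dCB": "dCB"})
    return nmr.ShiftTable(data[["residue_index", "aa", "dCA", "dCB"]])


def read_noe_profile(path: str | Path, sep: str | None = None) -> nmr.NOEProfile:
    data = pd.read_csv(path, sep=sep, engine="python")
    err = data["noe_err"].to_numpy() if "noe_err" in data else None
    return nmr.NOEProfile(
        residue_index=data["residue_index"].to_numpy(),
        noe=data["noe"].to_numpy(),
        noe_err=err,
    )


def read_pull_trace(path: str | Path, force_constant: float = 1000.0) -> pulling.PullTrace:
    """CSV pull trace: time_ns, cv_A, and either lambda_A or lambda0_A + v_A_per_ns."""
    data = pd.read_csv(path)
    kwargs: dict = {}
    if "lambda_A" in data:
        kwargs["lambda_A"] = data["lambda_A"].to_numpy()
    else:
        kwargs["lambda0_A"] = float(data["lambda0_A"].iloc[0])
        kwargs["velocity_A_per_ns"] = float(data["v_A_per_ns"].iloc[0])
    if "force_constant" in data:
        force_constant = float(data["force_constant"].iloc[0])
    return pulling.PullTrace(
        time_ns=data["time_ns"].to_numpy(),
        cv_A=data["cv_A"].to_numpy(),
        force_constant=force_constant,
        **kwargs,
    )


def read_colvar(
    path: str | Path,
    time_col: int = 0,
    cv_col: int = 1,
    lambda_col: int = 2,
    force_constant: float = 1000.0,
    time_unit_ns: float = 1.0,
    distance_unit_A: float = 10.0,
) -> pulling.PullTrace:
    """Whitespace-delimited COLVAR-style trace via a column mapping.

    Unit factors are explicit: times are multiplied by ``time_unit_ns`` and
    distances by ``distance_unit_A`` to reach ns and Å (for a file in ns
    and nm, the defaults apply).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows)
    return pulling.PullTrace(
        time_ns=arr[:, time_col] * time_unit_ns,
        cv_A=arr[:, cv_col] * distance_unit_A,
        lambda_A=arr[:, lambda_col] * distance_unit_A,
        force_constant=force_constant,
    )


def write_manifest(path: str | Path, params: dict) -> None:
    """Key-value run manifest (one ``key = value`` pair per line)."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key} = {params[key]}\n")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

_STAGE_PARAMS = {
    "gen-titration": {"kd", "p_base", "dp_max", "c_min", "c_max", "n_points",
                      "n_replicates", "noise_sd", "seed", "condition"},
    "fit-dimer": {"n_boot", "boot_seed"},
    "gen-noe": {"n_residues", "span_start", "span_end", "rigid_level",
                "flexible_level", "noise_sd", "seed"},
    "noe-segment": {"threshold", "min_run", "max_gap"},
    "css": {"tau_ca", "tau_cb", "min_len"},
    "gen-traj": {"n_frames", "n_core_residues", "loop_start", "loop_end",
                 "target_start", "target_end", "p_on", "p_stay", "seed", "fmt"},
    "contacts": {"group_a", "group_b", "cutoff", "atom_filter", "fmt"},
    "gen-pull": {"well_depth", "extra_adhesion_depth", "well_width", "friction",
                 "temperature", "dt", "n_steps", "seed", "k", "v", "condition",
                 "replicate"},
    "pull-work": {},
    "ring-sweep": {"n", "gamma", "topology", "kd_values", "c_values"},
}


@dataclass
class RunConfig:
    """One pipeline stage run: stage name, inputs, parameter overrides, outdir."""

    stage: str
    output_dir: str | Path
    inputs: dict = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_PARAMS:
            raise ValueError(
                f"unknown stage {self.stage!r}; expected one of {sorted(_STAGE_PARAMS)}"
            )
        unknown = set(self.params) - _STAGE_PARAMS[self.stage]
        if unknown:
            raise ValueError(
                f"unknown parameter keys for stage {self.stage!r}: {sorted(unknown)}"
            )
        self.output_dir = Path(self.output_dir)


def _stage_gen_titration(cfg: RunConfig, out: Path, p: dict) -> dict:
    params = binding.DimerModelParams(
        kd=p.get("kd", 100.0), p_base=p.get("p_base", 80.0), dp_max=p.get("dp_max", 60.0)
    )
    design = synthetic.TitrationDesign.log_spaced(
        c_min=p.get("c_min", 1.0), c_max=p.get("c_max", 1000.0),
        n_points=p.get("n_points", 12), n_replicates=p.get("n_replicates", 3),
        noise_sd=p.get("noise_sd", 2.0), seed=p.get("seed", 0),
    )
    series = synthetic.gen_titration(params, design, condition=p.get("condition", "WT"))
    write_titrations(series, out / "titration.csv")
    return {"n_series": len(series), **p}


def _stage_fit_dimer(cfg: RunConfig, out: Path, p: dict) -> dict:
    series = read_titrations(cfg.inputs["titration"])
    fit = binding.fit_self_association(
        series, n_boot=p.get("n_boot", 1000), boot_seed=p.get("boot_seed", 0)
    )
    frame = pd.DataFrame(
        [
            {
                "kd_uM": fit.kd,
                "kd_ci_low": fit.kd_ci[0] if fit.kd_ci else np.nan,
                "kd_ci_high": fit.kd_ci[1] if fit.kd_ci else np.nan,
                "p_base_mP": fit.p_base,
                "dp_max_mP": fit.dp_max,
                "converged": fit.converged,
                "associating": fit.associating,
                "redchi": fit.redchi,
                "n_points": fit.n_points,
            }
        ]
    )
    frame.to_csv(out / "dimer_fit.csv", index=False, float_format=FLOAT_FORMAT)
    (out / "dimer_fit.txt").write_text(
        f"K_d = {fit.kd:.4g} uM"
        + (f" (95% CI {fit.kd_ci[0]:.4g}-{fit.kd_ci[1]:.4g})" if fit.kd_ci else "")
        + f"\np_base = {fit.p_base:.4g} mP\ndp_max = {fit.dp_max:.4g} mP\n"
        f"associating = {fit.associating}\n"
    )
    return {"kd_uM": fit.kd, **p}


def _stage_gen_noe(cfg: RunConfig, out: Path, p: dict) -> dict:
    prof = synthetic.gen_noe_profile(
        n_residues=p.get("n_residues", 168),
        flexible_span=(p.get("span_start", 101), p.get("span_end", 131)),
        rigid_level=p.get("rigid_level", 0.82),
        flexible_level=p.get("flexible_level", 0.35),
        noise_sd=p.get("noise_sd", 0.05),
        seed=p.get("seed", 0),
    )
    pd.DataFrame(
        {"residue_index": prof.residue_index, "noe": prof.noe, "noe_err": prof.noe_err}
    ).to_csv(out / "noe.csv", index=False, float_format=FLOAT_FORMAT)
    return dict(p)


def _stage_noe_segment(cfg: RunConfig, out: Path, p: dict) -> dict:
    prof = read_noe_profile(cfg.inputs["noe"])
    segs = nmr.segment_flexible(
        prof, threshold=p.get("threshold", 0.6),
        min_run=p.get("min_run", 3), max_gap=p.get("max_gap", 2),
    )
    pd.DataFrame(segs.segments, columns=["start", "end", "class"]).to_csv(
        out / "segments.csv", index=False
    )
    (out / "segments.txt").write_text(segs.report() + "\n")
    return {"n_flexible": len(segs.flexible), **p}


def _stage_css(cfg: RunConfig, out: Path, p: dict) -> dict:
    table = read_shift_table(cfg.inputs["shifts"])
    profile = nmr.secondary_shifts(table)
    calls = nmr.classify_css(
        profile, tau_ca=p.get("tau_ca", 0.7), tau_cb=p.get("tau_cb", 1.0),
        min_len=p.get("min_len", 4),
    )
    profile.data.to_csv(out / "secondary_shifts.csv", index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame(calls, columns=["start", "end", "class"]).to_csv(
        out / "css_segments.csv", index=False
    )
    return {"n_segments": len(calls), **p}


def _stage_gen_traj(cfg: RunConfig, out: Path, p: dict) -> dict:
    spec = synthetic.ToyDimerSpec(
        n_core_residues=p.get("n_core_residues", 30),
        loop_span=(p.get("loop_start", 10), p.get("loop_end", 20)),
        target_region=(p.get("target_start", 2), p.get("target_end", 8)),
        p_on=p.get("p_on", 0.5), p_stay=p.get("p_stay", 0.8),
        seed=p.get("seed", 0),
    )
    traj = synthetic.gen_loop_trajectory(spec, n_frames=p.get("n_frames", 100))
    fmt = p.get("fmt", "pdb")
    write_trajectory(traj, out / f"trajectory.{fmt}", fmt=fmt)
    return {"n_frames": traj.n_frames, **p}


def _stage_contacts(cfg: RunConfig, out: Path, p: dict) -> dict:
    traj = read_trajectory(cfg.inputs["trajectory"], fmt=p.get("fmt", "pdb"))
    occ = contacts.contact_occupancy(
        traj, p["group_a"], p["group_b"],
        cutoff=p.get("cutoff", 3.5), atom_filter=p.get("atom_filter", "heavy"),
    )
    occ.pairs.to_csv(out / "pair_occupancy.csv", index=False, float_format=FLOAT_FORMAT)
    occ.marginal_a.to_csv(out / "marginal_a.csv", index=False, float_format=FLOAT_FORMAT)
    occ.marginal_b.to_csv(out / "marginal_b.csv", index=False, float_format=FLOAT_FORMAT)
    return {"n_frames": occ.n_frames, "cutoff": occ.cutoff, **p}


def _stage_gen_pull(cfg: RunConfig, out: Path, p: dict) -> dict:
    spec = synthetic.AdhesionSpec(
        well_depth=p.get("well_depth", 30.0),
        extra_adhesion_depth=p.get("extra_adhesion_depth", 0.0),
        well_width=p.get("well_width", 0.3),
        friction=p.get("friction", 100.0),
        temperature=p.get("temperature", 300.0),
        dt=p.get("dt", 0.01),
        n_steps=p.get("n_steps", 2000),
        seed=p.get("seed", 0),
    )
    trace = synthetic.gen_pull_trace(
        spec, k=p.get("k", 1000.0), v=p.get("v", 1.0),
        condition=p.get("condition", ""), replicate=p.get("replicate", 0),
    )
    pd.DataFrame(
        {
            "time_ns": trace.time_ns,
            "cv_A": trace.cv_A,
            "lambda_A": trace.lambda_A,
            "force_constant": trace.force_constant,
        }
    ).to_csv(out / "pull_trace.csv", index=False, float_format=FLOAT_FORMAT)
    return dict(p)


def _stage_pull_work(cfg: RunConfig, out: Path, p: dict) -> dict:
    trace = read_pull_trace(cfg.inputs["trace"])
    curve = pulling.work_curve(trace)
    pd.DataFrame(
        {
            "distance_A": curve.distance_A,
            "work_kJmol": curve.work_kJmol,
            "force_kJmol_nm": curve.force_kJmol_nm,
        }
    ).to_csv(out / "work_curve.csv", index=False, float_format=FLOAT_FORMAT)
    return {"final_work_kJmol": curve.final_work, **p}


def _stage_ring_sweep(cfg: RunConfig, out: Path, p: dict) -> dict:
    kds = p.get("kd_values", [50.0, 100.0])
    cs = p.get("c_values", [0.1, 1.0, 10.0])
    rows = []
    for c in cs:
        for kd in kds:
            params = ring.AssemblyParams(
                kd_nn=kd, c_total=c, n=p.get("n", 9),
                gamma=p.get("gamma", 1000.0), topology=p.get("topology", "ring"),
            )
            rows.append({"c_total_uM": c, "kd_uM": kd,
                         "ring_likelihood": ring.ring_likelihood(params)})
    table = pd.DataFrame(rows)
    # fold-change of the strongest vs weakest affinity at each concentration
    folds = []
    for c, grp in table.groupby("c_total_uM"):
        weakest = grp.loc[grp["kd_uM"].idxmax()]
        strongest = grp.loc[grp["kd_uM"].idxmin()]
        folds.append({"c_total_uM": c, "kd_from": weakest["kd_uM"],
                      "kd_to": strongest["kd_uM"],
                      "fold_change": strongest["ring_likelihood"] / weakest["ring_likelihood"]})
    table.to_csv(out / "ring_likelihood.csv", index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame(folds).to_csv(out / "ring_fold_change.csv", index=False,
                               float_format=FLOAT_FORMAT)
    return dict(p)


_STAGES = {
    "gen-titration": _stage_gen_titration,
    "fit-dimer": _stage_fit_dimer,
    "gen-noe": _stage_gen_noe,
    "noe-segment": _stage_noe_segment,
    "css": _stage_css,
    "gen-traj": _stage_gen_traj,
    "contacts": _stage_contacts,
    "gen-pull": _stage_gen_pull,
    "pull-work": _stage_pull_work,
    "ring-sweep": _stage_ring_sweep,
}


def run_pipeline(config: RunConfig) -> int:
    """Run one pipeline stage; returns exit status 0 (ok) / 1 (user error) / 2 (internal).

    On failure, partial outputs are retained next to a ``FAILED`` marker
    describing the error.  Every successful run writes ``manifest.txt``
    echoing the effective parameters.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        manifest = _STAGES[config.stage](config, out, dict(config.params))
    except (ValueError, KeyError, FileNotFoundError) as exc:
        (out / "FAILED").write_text(f"{config.stage}: {exc}\n")
        print(f"error: {exc}", file=sys.stderr)
        return 1
    except Exception as exc:  # pragma: no cover - internal error path
        (out / "FAILED").write_text(f"{config.stage}: internal error: {exc}\n")
        print(f"internal error: {exc}", file=sys.stderr)
        return 2
    manifest["stage"] = config.stage
    for key, val in config.inputs.items():
        manifest[f"input.{key}"] = val
    write_manifest(out / "manifest.txt", manifest)
    return 0
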