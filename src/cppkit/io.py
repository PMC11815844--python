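"""Readers and writers for the pipeline's on-disk formats.

Trajectories travel as multi-model PDB or GRO series with bead roles
encoded in atom names, so any standard structure viewer or parser can
open them:

====================  =========  ===========================
role                  atom name  residue name
====================  =========  ===========================
headgroup             HD         lipid species (DPPC, ...)
tail carbon k         Ck         lipid species
sterol ring           ST         sterol species (CHOL)
water                 W          SOL
peptide residue       CA         PEP
====================  =========  ===========================

Work traces are one CSV per replica with columns
``time_ns, lambda_A, x_A, work_kcal_mol``; PMF profiles export as
``z_A, free_energy_kcal_mol`` CSV.  Readers validate and reject rather
than silently coerce.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bilayer import Trajectory
from .membrane import _leaflet_masks
from .pmf import PMFProfile
from .simulate import WorkTrace

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_work_trace",
    "read_work_trace",
    "write_pmf",
    "read_pmf",
    "reaction_coordinate",
]

_TAIL_RE = re.compile(r"^C(\d+)$")


def _pdb_cryst1(path: Path) -> np.ndarray | None:
    """Box lengths from the first CRYST1 record of a PDB file.

    Multi-model PDBs carry a single CRYST1 in the header, which per-frame
    readers may not attach to each model; this recovers it.
    """
    with open(path) as handle:
        for line in handle:
            if line.startswith("CRYST1"):
                return np.array(
                    [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                )
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break
    return None


def _role_for_atom(name: str, resname: str) -> tuple[str, int]:
    if name == "HD":
        return "headgroup", 0
    if name == "ST":
        return "sterol", 0
    if name in ("W", "OW") or resname in ("SOL", "WAT", "HOH", "TIP3"):
        return "water", 0
    if name == "CA" or resname == "PEP":
        return "peptide", 0  # residue index assigned afterwards
    m = _TAIL_RE.match(name)
    if m:
        return "tail", int(m.group(1))
    raise KeyError(name)


def _universe_from_trajectory(traj: Trajectory):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    uniq, first_bead, res_index = np.unique(
        traj.resids, return_index=True, return_inverse=True
    )
    u = mda.Universe.empty(
        n_atoms=traj.n_beads,
        n_residues=len(uniq),
        atom_resindex=res_index,
        trajectory=False,
    )
    names = np.empty(traj.n_beads, dtype="U4")
    for i in range(traj.n_beads):
        role = traj.roles[i]
        if role == "headgroup":
            names[i] = "HD"
        elif role == "tail":
            names[i] = f"C{traj.role_index[i]}"
        elif role == "sterol":
            names[i] = "ST"
        elif role == "water":
            names[i] = "W"
        else:
            names[i] = "CA"
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", traj.resnames[first_bead])
    u.add_TopologyAttr("resids", uniq)
    dims = np.column_stack([traj.boxes, np.full((traj.n_frames, 3), 90.0)])
    u.load_new(
        traj.coords.astype(np.float32), format=MemoryReader, dimensions=dims
    )
    return u


def write_trajectory(
    traj: Trajectory, path: str | Path, fmt: str | None = None
) -> list[Path]:
    """Write a trajectory as multi-model PDB (one file) or a GRO series
    (one numbered file per frame).  Returns the paths written."""
    import MDAnalysis as mda

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "pdb"
    u = _universe_from_trajectory(traj)
    written: list[Path] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            with mda.Writer(str(path), multiframe=True, n_atoms=traj.n_beads) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
            written.append(path)
        elif fmt == "gro":
            for f, _ in enumerate(u.trajectory):
                frame_path = path.with_name(f"{path.stem}_{f:04d}.gro")
                u.atoms.write(str(frame_path))
                written.append(frame_path)
        else:
            raise ValueError(f"unsupported trajectory format {fmt!r}")
    return written


def read_trajectory(
    topology: str | Path, frames: Sequence[str | Path] | None = None
) -> Trajectory:
    """Read a labeled trajectory from multi-model PDB or a GRO series.

    Roles are inferred from the atom/residue naming convention in the
    module docstring; beads that fit no role abort the read with the
    offending names listed.
    """
    import MDAnalysis as mda

    topology = Path(topology)
    if not topology.exists():
        raise FileNotFoundError(topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if frames:
                u = mda.Universe(str(topology), [str(f) for f in frames])
            else:
                u = mda.Universe(str(topology))
        except Exception as exc:  # noqa: BLE001 - surface parser context
            raise ValueError(f"failed to parse trajectory {topology}: {exc}") from exc

        n = len(u.atoms)
        roles = np.empty(n, dtype="U9")
        role_index = np.zeros(n, dtype=int)
        offenders = []
        for i, atom in enumerate(u.atoms):
            try:
                roles[i], role_index[i] = _role_for_atom(atom.name, atom.resname)
            except KeyError:
                offenders.append(f"{atom.resname}:{atom.name}")
        if offenders:
            raise ValueError(
                "beads with no recognised role: " + ", ".join(sorted(set(offenders))[:10])
            )
        resids = u.atoms.resids.astype(int)
        # peptide residue index = rank of the residue among peptide residues
        pep = roles == "peptide"
        if pep.any():
            pep_ids = np.unique(resids[pep])
            rank = {int(r): k + 1 for k, r in enumerate(pep_ids)}
            role_index[pep] = [rank[int(r)] for r in resids[pep]]

        header_box = (
            _pdb_cryst1(topology) if topology.suffix.lower() == ".pdb" else None
        )
        coords = np.empty((len(u.trajectory), n, 3))
        boxes = np.empty((len(u.trajectory), 3))
        for f, ts in enumerate(u.trajectory):
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                boxes[f] = ts.dimensions[:3]
            elif header_box is not None and np.all(header_box > 0):
                boxes[f] = header_box
            else:
                raise ValueError(f"frame {f}: missing or degenerate box dimensions")
            coords[f] = ts.positions
    return Trajectory(
        resids=resids,
        resnames=u.atoms.resnames.astype("U5"),
        roles=roles,
        role_index=role_index,
        coords=coords,
        boxes=boxes,
    )


# --------------------------------------------------------------------------
# work traces and PMF profiles
# --------------------------------------------------------------------------

_WORK_COLUMNS = ["time_ns", "lambda_A", "x_A", "work_kcal_mol"]


def write_work_trace(trace: WorkTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "time_ns": trace.time,
        "lambda_A": trace.lam,
        "x_A": trace.position,
        "work_kcal_mol": trace.work,
    }).to_csv(path, index=False)
    return path


def read_work_trace(
    path: str | Path, stage_id: int = 0, replica_id: int = 0
) -> WorkTrace:
    """Load one replica's work log (e.g. exported from an MD engine)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _WORK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing work-log columns {missing}")
    if not np.all(np.isfinite(df[_WORK_COLUMNS].to_numpy())):
        raise ValueError(f"{path}: non-finite values in work log")
    return WorkTrace(
        stage_id=stage_id,
        replica_id=replica_id,
        time=df["time_ns"].to_numpy(),
        lam=df["lambda_A"].to_numpy(),
        position=df["x_A"].to_numpy(),
        work=df["work_kcal_mol"].to_numpy(),
        seed=-1,
    )


def write_pmf(profile: PMFProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "z_A": profile.grid,
        "free_energy_kcal_mol": profile.free_energy,
    }).to_csv(path, index=False)
    return path


def read_pmf(path: str | Path) -> PMFProfile:
    df = pd.read_csv(path)
    for col in ("z_A", "free_energy_kcal_mol"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing PMF column {col}")
    return PMFProfile(
        grid=df["z_A"].to_numpy(),
        free_energy=df["free_energy_kcal_mol"].to_numpy(),
    )


# --------------------------------------------------------------------------
# reaction coordinate
# --------------------------------------------------------------------------

def reaction_coordinate(
    traj: Trajectory,
    peptide_mask: np.ndarray | None = None,
    headgroup_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame scalar pulling coordinate (A).

    The signed z distance between the peptide center of mass and the
    center of mass of the lower-leaflet headgroups (equal bead masses).
    Custom selections may be passed as bead masks; by default the peptide
    beads and a per-frame lower-leaflet assignment are used.
    """
    if peptide_mask is None:
        peptide_mask = traj.mask(role="peptide")
    if not peptide_mask.any():
        raise ValueError("empty peptide selection")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if headgroup_mask is None:
            _, lower = _leaflet_masks(traj, f)
        else:
            lower = headgroup_mask
        if not lower.any():
            raise ValueError("empty headgroup selection")
        out[f] = traj.coords[f, peptide_mask, 2].mean() - traj.coords[f, lower, 2].mean()
    return out
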