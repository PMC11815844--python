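"""Residue-level peptide-lipid contact occupancy.

Occupancy of a peptide residue is the percentage of analyzed frames in
which any bead of that residue lies within a distance cutoff of any bead
of the selected lipid group (headgroups of one or all species, tails, or
sterol) in the selected leaflet.  Distances are minimum-image under the
orthorhombic box.  The default cutoff is 4 A between bead pairs and the
default analysis window is the trailing 0.8 of the trajectory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import distance_array

from .bilayer import Trajectory
from .membrane import assign_leaflets, trailing_slice

__all__ = [
    "LIPID_GROUPS",
    "group_mask",
    "residue_occupancy",
    "occupancy_table",
    "occupancy_contrast",
]

LIPID_GROUPS = ("headgroup", "tail", "sterol")


def group_mask(traj: Trajectory, group: str, leaflet: str = "both") -> np.ndarray:
    """Bead mask for a lipid group selector.

    ``group`` is ``'headgroup'``, ``'tail'`` or ``'sterol'``, optionally
    suffixed with a species label as in ``'headgroup:DPPS'``.  ``leaflet``
    restricts to ``'upper'`` or ``'lower'`` lipids (assigned on the first
    frame) or ``'both'``.
    """
    role, _, species = group.partition(":")
    if role not in LIPID_GROUPS:
        raise ValueError(f"unknown lipid group {group!r}; roles: {LIPID_GROUPS}")
    mask = traj.mask(role=role, resname=species or None)
    if leaflet not in ("upper", "lower", "both"):
        raise ValueError(f"unknown leaflet {leaflet!r}")
    if leaflet != "both":
        tags = assign_leaflets(traj, frame=0)
        ids = np.array([rid for rid, t in tags.items() if t == leaflet], dtype=int)
        mask = mask & np.isin(traj.resids, ids)
    return mask


def residue_occupancy(
    traj: Trajectory,
    cutoff: float = 4.0,
    group: str = "headgroup",
    leaflet: str = "both",
    trailing_fraction: float = 0.8,
) -> pd.Series:
    """Per-residue occupancy (%) of the peptide against one lipid group.

    Returns a Series indexed by peptide residue index (1-based), each
    value the percentage of analyzed frames with at least one bead pair
    within ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    pep = traj.mask(role="peptide")
    if not pep.any():
        raise ValueError("trajectory has no peptide beads")
    lipids = group_mask(traj, group, leaflet)
    residues = sorted(int(i) for i in np.unique(traj.role_index[pep]))
    window = trailing_slice(traj.n_frames, trailing_fraction)
    frames = range(window.start, window.stop)
    hits = {i: 0 for i in residues}
    res_masks = {i: pep & (traj.role_index == i) for i in residues}
    for f in frames:
        box = np.array([*traj.boxes[f], 90.0, 90.0, 90.0])
        lipid_pos = traj.coords[f, lipids]
        if len(lipid_pos) == 0:
            continue
        for i in residues:
            d = distance_array(traj.coords[f, res_masks[i]], lipid_pos, box=box)
            if d.min() <= cutoff:
                hits[i] += 1
    n = len(list(frames))
    return pd.Series(
        {i: 100.0 * hits[i] / n for i in residues}, name=f"{group}/{leaflet}"
    ).rename_axis("residue")


def occupancy_table(
    traj: Trajectory,
    groups: list[str],
    leaflets: list[str] = ["upper", "lower"],
    cutoff: float = 4.0,
    trailing_fraction: float = 0.8,
) -> pd.DataFrame:
    """Occupancy for every (group, leaflet) pair, residues as rows.

    Columns are a (group, leaflet) MultiIndex; values are percentages in
    [0, 100].
    """
    cols = {}
    for g in groups:
        for l in leaflets:
            cols[(g, l)] = residue_occupancy(
                traj, cutoff=cutoff, group=g, leaflet=l,
                trailing_fraction=trailing_fraction,
            )
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["group", "leaflet"])
    return table


def occupancy_contrast(
    table: pd.DataFrame, group_a: str, group_b: str, leaflet: str = "upper"
) -> pd.Series:
    """Signed per-residue occupancy difference (group_a - group_b), in
    percentage points — e.g. a PS-vs-PC headgroup preference profile."""
    for g in (group_a, group_b):
        if (g, leaflet) not in table.columns:
            raise ValueError(f"group {(g, leaflet)} missing from table")
    return table[(group_a, leaflet)] - table[(group_b, leaflet)]
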