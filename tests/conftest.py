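"""Shared fixtures: small synthetic bilayers and hand-built trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from cppkit import BilayerSpec, ChannelSpec, Trajectory, generate_bilayer_trajectory


def make_traj(
    head_upper_z: float = 19.25,
    head_lower_z: float = -19.25,
    n_heads_per_leaflet: int = 16,
    box_xy: float = 40.0,
    box_z: float = 80.0,
    water_coords: np.ndarray | None = None,
    peptide_coords: np.ndarray | None = None,
    n_frames: int = 1,
) -> Trajectory:
    """Hand-built minimal trajectory: headgroup grids on two planes plus
    optional explicit water/peptide beads (same in every frame unless the
    arrays carry a leading frame axis)."""
    side = int(np.ceil(np.sqrt(n_heads_per_leaflet)))
    xs = (np.arange(n_heads_per_leaflet) % side + 0.5) * (box_xy / side)
    ys = (np.arange(n_heads_per_leaflet) // side + 0.5) * (box_xy / side)
    heads_up = np.column_stack([xs, ys, np.full(n_heads_per_leaflet, head_upper_z)])
    heads_lo = np.column_stack([xs, ys, np.full(n_heads_per_leaflet, head_lower_z)])

    blocks = [heads_up, heads_lo]
    resids = list(range(1, 2 * n_heads_per_leaflet + 1))
    resnames = ["DPPC"] * (2 * n_heads_per_leaflet)
    roles = ["headgroup"] * (2 * n_heads_per_leaflet)
    role_index = [0] * (2 * n_heads_per_leaflet)
    rid = 2 * n_heads_per_leaflet

    def static_part(extra: np.ndarray | None, role: str, resname: str):
        nonlocal rid
        if extra is None:
            return 0
        arr = np.asarray(extra, dtype=float)
        per_frame = arr.ndim == 3
        n = arr.shape[-2]
        for i in range(n):
            rid += 1
            resids.append(rid)
            resnames.append(resname)
            roles.append(role)
            role_index.append(i + 1 if role == "peptide" else 0)
        blocks.append(arr)
        return per_frame

    pep_per_frame = static_part(peptide_coords, "peptide", "PEP")
    wat_per_frame = static_part(water_coords, "water", "SOL")

    n_beads = len(resids)
    coords = np.empty((n_frames, n_beads, 3))
    for f in range(n_frames):
        parts = [heads_up, heads_lo]
        if peptide_coords is not None:
            arr = np.asarray(peptide_coords, dtype=float)
            parts.append(arr[f] if pep_per_frame else arr)
        if water_coords is not None:
            arr = np.asarray(water_coords, dtype=float)
            parts.append(arr[f] if wat_per_frame else arr)
        coords[f] = np.vstack(parts)
    boxes = np.tile([box_xy, box_xy, box_z], (n_frames, 1))
    return Trajectory(
        resids=np.array(resids),
        resnames=np.array(resnames),
        roles=np.array(roles),
        role_index=np.array(role_index),
        coords=coords,
        boxes=boxes,
    )


@pytest.fixture(scope="session")
def small_bilayer() -> Trajectory:
    """60 lipids per leaflet, mild jitter, no channel, no peptide."""
    spec = BilayerSpec(
        lipid_counts={"DPPC": 40, "CHOL": 20},
        box_xy=60.0,
        n_frames=5,
        n_bulk_waters=60,
        seed=42,
    )
    return generate_bilayer_trajectory(spec)


@pytest.fixture(scope="session")
def channel_bilayer() -> Trajectory:
    """Constant 6 A transmembrane water channel."""
    spec = BilayerSpec(
        lipid_counts={"DPPC": 40},
        box_xy=60.0,
        channel=ChannelSpec(radius=6.0),
        n_frames=4,
        n_bulk_waters=40,
        seed=7,
    )
    return generate_bilayer_trajectory(spec)


@pytest.fixture(scope="session")
def peptide_bilayer() -> Trajectory:
    """Peptide chain of 5 residues held at the lower headgroup plane."""
    spec = BilayerSpec(
        lipid_counts={"DPPC": 20, "DPPS": 20},
        box_xy=50.0,
        peptide=(5, -19.0),
        n_frames=5,
        n_bulk_waters=40,
        seed=8,
    )
    return generate_bilayer_trajectory(spec)
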