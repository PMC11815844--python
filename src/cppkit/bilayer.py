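"""Synthetic coarse bilayer trajectories with known ground truth.

Each lipid is a short bead chain: one headgroup bead pinned (up to jitter)
to its leaflet plane and a tail hanging toward the bilayer midplane.
Sterol species carry a single ring bead instead of a tail chain.  Water
fills slabs beyond the membrane and, optionally, a transmembrane channel
whose radius profile r(z) is specified exactly — so the true pore
bottleneck, thickness, lipid counts and area per lipid of every generated
trajectory are known by construction.

Geometry convention: Angstrom everywhere, z is the membrane normal, the
bilayer midplane sits at z = 0, boxes are orthorhombic with x/y the
membrane plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ROLES",
    "MEMBRANE_COMPOSITIONS",
    "ChannelSpec",
    "BilayerSpec",
    "Trajectory",
    "generate_bilayer_trajectory",
]

#: Closed set of bead roles.
ROLES = ("headgroup", "tail", "sterol", "water", "peptide")

#: Lipid counts per leaflet of the three study membranes (species are labels).
MEMBRANE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "DPPC": {"DPPC": 150},
    "DPPC:DOPC:CHOL": {"DPPC": 50, "DOPC": 50, "CHOL": 50},
    "DPPC:DOPC:DPPS:DOPS:CHOL": {
        "DPPC": 30, "DOPC": 30, "DPPS": 30, "DOPS": 30, "CHOL": 30,
    },
}

#: Species rendered as single-bead sterols (no tail chain).
STEROL_SPECIES = frozenset({"CHOL"})

_BOND_LENGTH = 1.5   # A between successive tail beads
_STEROL_DROP = 5.0   # A from sterol headgroup bead to its ring bead
_PEPTIDE_SPACING = 3.5  # A between consecutive peptide CA beads


@dataclass(frozen=True)
class ChannelSpec:
    """Transmembrane water channel with an exactly known radius profile.

    ``radius`` is either a constant (A) or a callable r(z) evaluated over
    the membrane span.  Waters are drawn uniformly in the disk of radius
    r(z) for each 1 A generator sub-slab, with a per-slab count
    proportional to the disk area (``water_density`` waters per A^3), so
    the narrowest slab is the analytically known bottleneck.
    """

    radius: float | Callable[[float], float]
    water_density: float = 0.5  # waters per A^3 of channel volume

    def radius_at(self, z: float) -> float:
        r = self.radius(z) if callable(self.radius) else float(self.radius)
        if not (math.isfinite(r) and r >= 0):
            raise ValueError(f"channel radius must be finite and >= 0, got {r} at z={z}")
        return r

    def min_radius(self, z_lower: float, z_upper: float) -> float:
        zs = np.linspace(z_lower, z_upper, 201)
        return min(self.radius_at(float(z)) for z in zs)


@dataclass(frozen=True)
class BilayerSpec:
    """Recipe for a synthetic bilayer trajectory.

    Defaults emulate the simplest study system: a one-species neutral
    bilayer of 150 lipids per leaflet with headgroup planes 38.5 A apart
    in a 95 A square box (~60 A^2 per lipid).
    """

    lipid_counts: Mapping[str, int] = field(
        default_factory=lambda: {"DPPC": 150}
    )  # per leaflet
    box_xy: float = 95.0
    headgroup_planes: tuple[float, float] = (19.25, -19.25)  # (z_upper, z_lower)
    tail_beads_per_chain: int = 8
    chain_tilt_noise: float = 0.1   # radians, sd of tail tilt away from the normal
    water_slab_margin: float = 2.0  # A gap between headgroups and bulk water
    bulk_water_depth: float = 10.0  # A of bulk water slab on each side
    n_bulk_waters: int = 200        # per side
    channel: ChannelSpec | None = None
    peptide: tuple[int, float] | None = None  # (n_residues, depth z in A)
    n_frames: int = 10
    frame_jitter: float = 0.5       # A, sd of per-frame positional noise
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.lipid_counts.values()):
            raise ValueError("lipid counts must be >= 0")
        z_upper, z_lower = self.headgroup_planes
        if not z_upper > z_lower:
            raise ValueError("z_upper must exceed z_lower")
        if self.box_xy <= 0:
            raise ValueError("box_xy must be > 0")
        if self.tail_beads_per_chain < 1:
            raise ValueError("tail_beads_per_chain must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_jitter < 0 or self.chain_tilt_noise < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.channel is not None:
            zs = np.linspace(z_lower, z_upper, 201)
            rmax = max(self.channel.radius_at(float(z)) for z in zs)
            if rmax > self.box_xy / 2.0:
                raise ValueError(
                    f"channel radius {rmax:.1f} A exceeds half the box width "
                    f"{self.box_xy / 2.0:.1f} A"
                )
        if self.peptide is not None and self.peptide[0] < 1:
            raise ValueError("peptide must have >= 1 residues")

    @property
    def box_z(self) -> float:
        z_upper, z_lower = self.headgroup_planes
        return (z_upper - z_lower) + 2.0 * (
            self.water_slab_margin + self.bulk_water_depth + 2.0
        )


@dataclass
class Trajectory:
    """Labeled-bead trajectory: static topology plus per-frame coordinates.

    ``roles`` draws from :data:`ROLES`; ``role_index`` carries the tail
    carbon index (1..n) or the peptide residue index (1..n) and is 0 for
    the other roles.  ``coords`` has shape (n_frames, n_beads, 3) in A and
    ``boxes`` holds per-frame orthorhombic box lengths (Lx, Ly, Lz).
    """

    resids: np.ndarray
    resnames: np.ndarray
    roles: np.ndarray
    role_index: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype="U5")
        self.roles = np.asarray(self.roles, dtype="U9")
        self.role_index = np.asarray(self.role_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        n = self.resids.shape[0]
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n, 3):
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if self.boxes.shape != (self.coords.shape[0], 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if np.any(self.boxes <= 0):
            raise ValueError("box dimensions must be > 0")
        unknown = set(np.unique(self.roles)) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown bead roles: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def mask(
        self,
        role: str | None = None,
        resname: str | None = None,
        role_index: int | None = None,
    ) -> np.ndarray:
        """Boolean bead selector by role, residue name and/or role index."""
        m = np.ones(self.n_beads, dtype=bool)
        if role is not None:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}; valid roles: {ROLES}")
            m &= self.roles == role
        if resname is not None:
            m &= self.resnames == resname
        if role_index is not None:
            m &= self.role_index == role_index
        return m

    def lipid_resids(self) -> np.ndarray:
        """Residue ids of lipids, i.e. residues owning a headgroup bead."""
        return np.unique(self.resids[self.roles == "headgroup"])


def _sample_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a disk of given radius, shape (n, 2)."""
    r = radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def generate_bilayer_trajectory(spec: BilayerSpec) -> Trajectory:
    """Build a labeled trajectory realising ``spec`` exactly.

    Lipid/water/peptide base positions are drawn once from the seed;
    every frame then adds fresh isotropic Gaussian jitter of sd
    ``frame_jitter`` (channel and bulk waters are resampled per frame so
    pore statistics fluctuate frame to frame).  Identical seeds give
    bit-identical trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    z_upper, z_lower = spec.headgroup_planes
    box = np.array([spec.box_xy, spec.box_xy, spec.box_z])
    cx = cy = spec.box_xy / 2.0

    resids: list[int] = []
    resnames: list[str] = []
    roles: list[str] = []
    role_index: list[int] = []
    base: list[np.ndarray] = []  # static beads only
    resid = 0

    # --- lipids, both leaflets ---------------------------------------------
    for leaflet_sign, plane in ((1.0, z_upper), (-1.0, z_lower)):
        for species, count in spec.lipid_counts.items():
            is_sterol = species in STEROL_SPECIES
            for _ in range(count):
                resid += 1
                hx, hy = rng.random(2) * spec.box_xy
                head = np.array([hx, hy, plane])
                resids.append(resid)
                resnames.append(species)
                roles.append("headgroup")
                role_index.append(0)
                base.append(head)
                if is_sterol:
                    resids.append(resid)
                    resnames.append(species)
                    roles.append("sterol")
                    role_index.append(0)
                    base.append(head + np.array([0.0, 0.0, -leaflet_sign * _STEROL_DROP]))
                else:
                    tilt = rng.normal(0.0, spec.chain_tilt_noise, size=2)
                    direction = np.array([tilt[0], tilt[1], -leaflet_sign])
                    direction /= np.linalg.norm(direction)
                    for k in range(1, spec.tail_beads_per_chain + 1):
                        resids.append(resid)
                        resnames.append(species)
                        roles.append("tail")
                        role_index.append(k)
                        base.append(head + k * _BOND_LENGTH * direction)

    # --- peptide chain ------------------------------------------------------
    if spec.peptide is not None:
        n_res, depth = spec.peptide
        x0 = cx - (n_res - 1) * _PEPTIDE_SPACING / 2.0
        for i in range(1, n_res + 1):
            resid += 1
            resids.append(resid)
            resnames.append("PEP")
            roles.append("peptide")
            role_index.append(i)
            base.append(np.array([x0 + (i - 1) * _PEPTIDE_SPACING, cy, depth]))

    n_static = len(base)
    base_arr = np.array(base) if base else np.empty((0, 3))

    # --- water counts (fixed per frame; positions resampled) ----------------
    slab_lo = z_lower - spec.water_slab_margin
    slab_hi = z_upper + spec.water_slab_margin
    channel_slabs: list[tuple[float, float, float, int]] = []  # (z0, z1, r, n)
    n_channel = 0
    if spec.channel is not None:
        n_sub = max(1, int(round(z_upper - z_lower)))
        edges = np.linspace(z_lower, z_upper, n_sub + 1)
        for z0, z1 in zip(edges[:-1], edges[1:]):
            zc = 0.5 * (z0 + z1)
            r = spec.channel.radius_at(float(zc))
            n = int(round(spec.channel.water_density * np.pi * r**2 * (z1 - z0)))
            if r > 0 and n > 0:
                channel_slabs.append((float(z0), float(z1), r, n))
                n_channel += n
    n_water = 2 * spec.n_bulk_waters + n_channel

    water_resids = resid + 1 + np.arange(n_water)
    resid += n_water
    n_beads = n_static + n_water

    all_resids = np.concatenate([np.array(resids, dtype=int), water_resids]) \
        if n_water else np.array(resids, dtype=int)
    all_resnames = np.array(resnames + ["SOL"] * n_water, dtype="U5")
    all_roles = np.array(roles + ["water"] * n_water, dtype="U9")
    all_role_index = np.array(role_index + [0] * n_water, dtype=int)

    coords = np.empty((spec.n_frames, n_beads, 3))
    for f in range(spec.n_frames):
        frame = np.empty((n_beads, 3))
        frame[:n_static] = base_arr + rng.normal(0.0, spec.frame_jitter, (n_static, 3))
        w = n_static
        # bulk slabs above and below the membrane
        for zmin, zmax in (
            (slab_hi, spec.box_z / 2.0),
            (-spec.box_z / 2.0, slab_lo),
        ):
            pts = np.column_stack([
                rng.random(spec.n_bulk_waters) * spec.box_xy,
                rng.random(spec.n_bulk_waters) * spec.box_xy,
                zmin + rng.random(spec.n_bulk_waters) * (zmax - zmin),
            ])
            frame[w:w + spec.n_bulk_waters] = pts
            w += spec.n_bulk_waters
        # transmembrane channel column
        for z0, z1, r, n in channel_slabs:
            xy = _sample_disk(rng, n, r) + np.array([cx, cy])
            zz = z0 + rng.random(n) * (z1 - z0)
            frame[w:w + n] = np.column_stack([xy, zz])
            w += n
        coords[f] = frame

    boxes = np.tile(box, (spec.n_frames, 1))
    return Trajectory(
        resids=all_resids,
        resnames=all_resnames,
        roles=all_roles,
        role_index=all_role_index,
        coords=coords,
        boxes=boxes,
    )
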