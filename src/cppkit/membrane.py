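"""Bilayer disruption metrics from labeled coarse trajectories.

Implements the analysis battery run on the post-pull relaxation
trajectories: leaflet assignment, acyl-chain order parameter, water-defined
pore radius ladders, membrane thickness, area per lipid and the four-way
classification of the peptide's fate (lower-leaflet equilibrium, pore
formation, insertion, return).

Order parameter convention: S(k) = <(3 cos^2 theta - 1)/2> with theta the
angle between a pseudo C-H/segment vector of tail carbon k and the membrane
normal (z).  1 means aligned with the normal, 0 isotropic, -0.5
perpendicular.

Pore convention: the membrane span is sliced into z slabs; the radius of a
slab is the maximal lateral extent of its water cluster (distance from the
slab water centroid by default, half the maximal pairwise distance behind
the ``method`` flag); a frame's pore radius is the minimum over slabs, i.e.
the bottleneck of the transmembrane water pathway; an empty slab means no
continuous pathway and yields 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .bilayer import Trajectory

__all__ = [
    "Outcome",
    "OrderParameterProfile",
    "PoreSlabProfile",
    "MembraneSummary",
    "assign_leaflets",
    "scd_from_vectors",
    "order_parameter",
    "pore_radius_profile",
    "pore_timeseries",
    "mean_pore_radius",
    "thickness",
    "area_per_lipid",
    "headgroup_planes",
    "classify_outcome",
    "trailing_slice",
]


class Outcome(str, Enum):
    """Peptide fate over the relaxation window."""

    LOWER_LEAFLET_EQUILIBRIUM = "lower_leaflet_equilibrium"
    PORE_FORMATION = "pore_formation"
    INSERTION = "insertion"
    RETURN = "return"


def trailing_slice(n_frames: int, trailing_fraction: float) -> slice:
    """Frames of the trailing analysis window (default elsewhere: 0.8,
    matching an 80-of-100 ns relaxation window)."""
    if not 0.0 < trailing_fraction <= 1.0:
        raise ValueError("trailing_fraction must be in (0, 1]")
    start = n_frames - max(1, int(round(trailing_fraction * n_frames)))
    return slice(start, n_frames)


# --------------------------------------------------------------------------
# leaflets, thickness, area per lipid
# --------------------------------------------------------------------------

def assign_leaflets(traj: Trajectory, frame: int = 0) -> dict[int, str]:
    """Map lipid resid -> 'upper'/'lower' by headgroup z against the median.

    Every lipid must own at least one headgroup bead (multi-bead heads are
    averaged).  The tie rule is z >= median -> upper, so a single lipid or
    a fully planar frame still splits deterministically.
    """
    head = traj.roles == "headgroup"
    if not head.any():
        raise ValueError("trajectory has no headgroup beads")
    rids = traj.resids[head]
    z = traj.coords[frame, head, 2]
    uniq, inverse = np.unique(rids, return_inverse=True)
    mean_z = np.bincount(inverse, weights=z) / np.bincount(inverse)
    median = float(np.median(mean_z))
    return {
        int(rid): ("upper" if hz >= median else "lower")
        for rid, hz in zip(uniq, mean_z)
    }


def _leaflet_masks(traj: Trajectory, frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Headgroup-bead masks of the upper and lower leaflets for one frame."""
    tags = assign_leaflets(traj, frame)
    head = traj.roles == "headgroup"
    upper_ids = np.array([rid for rid, t in tags.items() if t == "upper"], dtype=int)
    in_upper = np.isin(traj.resids, upper_ids)
    return head & in_upper, head & ~in_upper


def headgroup_planes(
    traj: Trajectory, trailing_fraction: float = 1.0
) -> tuple[float, float]:
    """Mean headgroup plane z of the (upper, lower) leaflets over the window."""
    window = trailing_slice(traj.n_frames, trailing_fraction)
    uppers, lowers = [], []
    for f in range(window.start, window.stop):
        up, lo = _leaflet_masks(traj, f)
        if not up.any() or not lo.any():
            raise ValueError(f"frame {f}: a leaflet is empty")
        uppers.append(traj.coords[f, up, 2].mean())
        lowers.append(traj.coords[f, lo, 2].mean())
    return float(np.mean(uppers)), float(np.mean(lowers))


def thickness(traj: Trajectory) -> np.ndarray:
    """Per-frame bilayer thickness: mean upper minus mean lower headgroup z (A)."""
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        up, lo = _leaflet_masks(traj, f)
        if not up.any() or not lo.any():
            raise ValueError(f"frame {f}: a leaflet is empty")
        out[f] = traj.coords[f, up, 2].mean() - traj.coords[f, lo, 2].mean()
    return out


def area_per_lipid(traj: Trajectory) -> dict[str, np.ndarray]:
    """Per-frame area per lipid for each leaflet: Lx*Ly / n_lipids (A^2).

    Box-area method, so APL times the leaflet lipid count equals the box
    cross-section exactly.
    """
    out = {"upper": np.empty(traj.n_frames), "lower": np.empty(traj.n_frames)}
    for f in range(traj.n_frames):
        tags = assign_leaflets(traj, f)
        area = traj.boxes[f, 0] * traj.boxes[f, 1]
        for leaflet in ("upper", "lower"):
            n = sum(1 for t in tags.values() if t == leaflet)
            if n == 0:
                raise ValueError(f"frame {f}: no lipids in {leaflet} leaflet")
            out[leaflet][f] = area / n
    return out


@dataclass
class MembraneSummary:
    """Trailing-window summary of thickness and area per lipid."""

    thickness_series: np.ndarray
    apl_series: dict[str, np.ndarray]
    trailing_fraction: float

    @property
    def mean_thickness(self) -> float:
        w = trailing_slice(len(self.thickness_series), self.trailing_fraction)
        return float(self.thickness_series[w].mean())

    def mean_apl(self, leaflet: str = "upper") -> float:
        series = self.apl_series[leaflet]
        w = trailing_slice(len(series), self.trailing_fraction)
        return float(series[w].mean())


# --------------------------------------------------------------------------
# order parameter
# --------------------------------------------------------------------------

@dataclass
class OrderParameterProfile:
    """Per-carbon order parameter: carbon index -> (mean, sd)."""

    values: dict[int, tuple[float, float]]

    def mean(self, k: int) -> float:
        return self.values[k][0]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ks = np.array(sorted(self.values))
        means = np.array([self.values[k][0] for k in ks])
        sds = np.array([self.values[k][1] for k in ks])
        return ks, means, sds


def scd_from_vectors(vectors: np.ndarray) -> tuple[float, float]:
    """Order parameter of a set of bond vectors against the z axis.

    Returns (mean, sd) of (3 cos^2 theta - 1)/2 over the vectors; the mean
    is bounded in [-0.5, 1] for any input.  Zero-length vectors are
    rejected.
    """
    v = np.asarray(vectors, dtype=float).reshape(-1, 3)
    if v.size == 0:
        raise ValueError("no bond vectors given")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length bond vector")
    cos2 = (v[:, 2] / norms) ** 2
    s = 1.5 * cos2 - 0.5
    return float(s.mean()), float(s.std(ddof=0))


def order_parameter(
    traj: Trajectory,
    bond_vectors: Mapping[int, np.ndarray] | None = None,
) -> OrderParameterProfile:
    """Order parameter profile along the acyl chain.

    With explicit ``bond_vectors`` (carbon index -> (N, 3) array) the
    profile is computed from those directly.  Otherwise pseudo-bond
    vectors are derived from the trajectory: for tail carbon k, the
    segment from bead k-1 (the headgroup for k = 1) to bead k, pooled
    over lipids and frames.
    """
    if bond_vectors is not None:
        return OrderParameterProfile(
            {int(k): scd_from_vectors(v) for k, v in bond_vectors.items()}
        )
    tail = traj.roles == "tail"
    if not tail.any():
        raise ValueError("trajectory has no tail beads")
    ks = sorted(int(k) for k in np.unique(traj.role_index[tail]))
    values: dict[int, tuple[float, float]] = {}
    for k in ks:
        cur = tail & (traj.role_index == k)
        prev = (
            (traj.roles == "headgroup") if k == 1 else (tail & (traj.role_index == k - 1))
        )
        # align beads of the same lipid by resid order
        order_cur = np.argsort(traj.resids[cur], kind="stable")
        order_prev = np.argsort(traj.resids[prev], kind="stable")
        cur_idx = np.flatnonzero(cur)[order_cur]
        prev_idx = np.flatnonzero(prev)[order_prev]
        # restrict to lipids that own both beads
        common = np.intersect1d(traj.resids[cur_idx], traj.resids[prev_idx])
        cur_idx = cur_idx[np.isin(traj.resids[cur_idx], common)]
        prev_idx = prev_idx[np.isin(traj.resids[prev_idx], common)]
        vecs = (traj.coords[:, cur_idx, :] - traj.coords[:, prev_idx, :]).reshape(-1, 3)
        values[k] = scd_from_vectors(vecs)
    return OrderParameterProfile(values)


# --------------------------------------------------------------------------
# pore detection
# --------------------------------------------------------------------------

@dataclass
class PoreSlabProfile:
    """Per-slab water radii of one frame plus the bottleneck value."""

    slab_edges: np.ndarray   # z edges, length n_slabs + 1
    radii: np.ndarray        # per-slab radius, A; 0 for empty slabs
    minimum: float           # bottleneck = min over slabs


def _slab_radius(xy: np.ndarray, method: str) -> float:
    if len(xy) == 0:
        return 0.0
    if method == "centroid":
        centroid = xy.mean(axis=0)
        return float(np.max(np.linalg.norm(xy - centroid, axis=1)))
    if method == "pairwise":
        if len(xy) == 1:
            return 0.0
        return float(pdist(xy).max() / 2.0)
    raise ValueError(f"unknown pore method {method!r}")


def pore_radius_profile(
    traj: Trajectory,
    frame: int,
    slab_width: float = 1.0,
    z_bounds: tuple[float, float] | None = None,
    method: str = "centroid",
) -> PoreSlabProfile:
    """Water-defined pore ladder of one frame.

    The span between ``z_bounds`` (default: the leaflet headgroup planes)
    is sliced into slabs of at most ``slab_width``; each slab's radius is
    the lateral extent of its waters and the frame value is the minimum
    over slabs.  A frame with any empty slab therefore reports 0: no
    continuous water pathway.
    """
    if slab_width <= 0:
        raise ValueError("slab_width must be > 0")
    if z_bounds is None:
        up, lo = _leaflet_masks(traj, frame)
        z_bounds = (float(traj.coords[frame, lo, 2].mean()),
                    float(traj.coords[frame, up, 2].mean()))
    z_lo, z_hi = sorted(z_bounds)
    if z_hi - z_lo <= 0:
        raise ValueError("empty z_bounds span")
    half = traj.boxes[frame, 2] / 2.0
    if z_lo < -half or z_hi > half:
        raise ValueError("z_bounds extend outside the box")
    n_slabs = max(1, int(np.ceil((z_hi - z_lo) / slab_width)))
    edges = np.linspace(z_lo, z_hi, n_slabs + 1)
    water = traj.mask(role="water")
    pos = traj.coords[frame, water]
    radii = np.empty(n_slabs)
    for i in range(n_slabs):
        in_slab = (pos[:, 2] >= edges[i]) & (
            pos[:, 2] < edges[i + 1] if i < n_slabs - 1 else pos[:, 2] <= edges[i + 1]
        )
        radii[i] = _slab_radius(pos[in_slab, :2], method)
    return PoreSlabProfile(slab_edges=edges, radii=radii, minimum=float(radii.min()))


def pore_timeseries(
    traj: Trajectory,
    slab_width: float = 1.0,
    z_bounds: tuple[float, float] | None = None,
    method: str = "centroid",
) -> np.ndarray:
    """Per-frame bottleneck pore radius (A)."""
    return np.array([
        pore_radius_profile(traj, f, slab_width, z_bounds, method).minimum
        for f in range(traj.n_frames)
    ])


def mean_pore_radius(
    traj: Trajectory,
    trailing_fraction: float = 0.8,
    slab_width: float = 1.0,
    z_bounds: tuple[float, float] | None = None,
    method: str = "centroid",
) -> tuple[float, float]:
    """Mean and sd of the per-frame bottleneck radius over the trailing window."""
    series = pore_timeseries(traj, slab_width, z_bounds, method)
    window = series[trailing_slice(len(series), trailing_fraction)]
    return float(window.mean()), float(window.std(ddof=0))


# --------------------------------------------------------------------------
# peptide fate
# --------------------------------------------------------------------------

def classify_outcome(
    peptide_com_z: Sequence[float] | np.ndarray,
    pore_radii: Sequence[float] | np.ndarray,
    planes: tuple[float, float],
    margin: float = 5.0,
    pore_threshold: float = 1.0,
    persistence: float = 0.5,
    trailing_fraction: float = 0.8,
) -> Outcome:
    """Four-way peptide fate over the trailing analysis window.

    Median peptide COM z below the lower headgroup plane plus ``margin``
    -> the peptide settled past the bilayer (lower-leaflet equilibrium);
    above the upper plane minus ``margin`` -> it bounced back (return);
    otherwise it sits in the hydrophobic core and the call splits on
    whether a pore (bottleneck radius > ``pore_threshold``) persists in
    more than ``persistence`` of the window frames: pore formation vs
    insertion.  Total on its domain: every valid input maps to exactly
    one label.
    """
    com = np.asarray(peptide_com_z, dtype=float)
    pores = np.asarray(pore_radii, dtype=float)
    if com.size == 0:
        raise ValueError("empty peptide COM series")
    if com.shape != pores.shape:
        raise ValueError("COM and pore series must be aligned")
    z_upper, z_lower = planes
    if not z_upper > z_lower:
        raise ValueError("planes must be ordered (z_upper, z_lower)")
    window = trailing_slice(com.size, trailing_fraction)
    med = float(np.median(com[window]))
    if med <= z_lower + margin:
        return Outcome.LOWER_LEAFLET_EQUILIBRIUM
    if med >= z_upper - margin:
        return Outcome.RETURN
    pore_frac = float(np.mean(pores[window] > pore_threshold))
    if pore_frac > persistence:
        return Outcome.PORE_FORMATION
    return Outcome.INSERTION
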