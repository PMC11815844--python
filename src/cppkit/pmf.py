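"""Staged steered-pull free-energy estimation via the Jarzynski equality.

The reaction coordinate is split into contiguous stages; each stage runs an
ensemble of pull replicas, the stage free-energy profile is the pointwise
Jarzynski average

    dF(z) = -(1/beta) * ln <exp(-beta * W(z))>,   beta = 1 / (kB * T),

and the replica whose final work lies closest to the stage estimate seeds
the next stage (its final configuration becomes the next initial state).
Stage segments are concatenated with offset matching so the assembled
profile is continuous by construction.

All exponentials are evaluated with a shifted log-sum-exp scheme so that
large work values (hundreds of kT) cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .simulate import BOLTZMANN_KCAL, LangevinConfig, WorkTrace, generate_work_ensemble

__all__ = [
    "ThermoParams",
    "StagePlan",
    "PMFProfile",
    "ProtocolTotals",
    "plan_stages",
    "jarzynski_free_energy",
    "jarzynski_profile",
    "select_representative_replica",
    "run_asmd",
    "hysteresis",
    "protocol_accounting",
    "plan_experiment_matrix",
]


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and Boltzmann constant defining beta = 1/(kB*T)."""

    temperature: float = 310.15
    boltzmann_constant: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")
        if not self.boltzmann_constant > 0:
            raise ValueError("boltzmann_constant must be > 0")

    @property
    def kt(self) -> float:
        """kB*T in kcal/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """1/(kB*T) in mol/kcal."""
        return 1.0 / self.kt


@dataclass(frozen=True)
class StagePlan:
    """Ordered contiguous pulling stages along the reaction coordinate."""

    stages: tuple[tuple[float, float], ...]
    stage_width: float
    n_replicas: int
    velocity: float
    direction: str = "forward"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("plan must contain at least one stage")
        if self.stage_width <= 0:
            raise ValueError("stage_width must be > 0")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        tol = 1e-9
        for start, end in self.stages:
            width = abs(end - start)
            if width <= 0:
                raise ValueError(f"degenerate stage ({start}, {end})")
            if width > self.stage_width + tol:
                raise ValueError(
                    f"stage ({start}, {end}) wider than stage_width {self.stage_width}"
                )
        for (_, e0), (s1, _) in zip(self.stages[:-1], self.stages[1:]):
            if abs(e0 - s1) > tol:
                raise ValueError("stages must be contiguous")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def span(self) -> tuple[float, float]:
        return self.stages[0][0], self.stages[-1][1]


@dataclass
class PMFProfile:
    """Free energy vs reaction coordinate, anchored to 0 at the first point."""

    grid: np.ndarray          # reaction-coordinate values, A
    free_energy: np.ndarray   # kcal/mol
    stage_boundaries: tuple[int, ...] = ()   # grid indices of stage starts
    selected_replicas: tuple[int, ...] = ()  # representative replica per stage

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.shape != self.free_energy.shape or self.grid.ndim != 1:
            raise ValueError("grid and free_energy must be equal-length 1-D arrays")
        if len(self.grid) and abs(self.free_energy[0]) > 1e-12:
            raise ValueError("free_energy must be anchored to 0 at the first point")

    @property
    def barrier(self) -> float:
        """Highest free energy along the profile, kcal/mol."""
        return float(np.max(self.free_energy))

    @property
    def final_value(self) -> float:
        return float(self.free_energy[-1])


def plan_stages(
    span_start: float,
    span_end: float,
    stage_width: float = 5.0,
    n_replicas: int = 25,
    velocity: float = 1.0,
) -> StagePlan:
    """Split ``[span_start, span_end]`` into contiguous stages of
    ``stage_width``; the last stage is truncated when the span is not an
    integer multiple of the width.  Works in either pull direction.
    """
    if stage_width <= 0:
        raise ValueError("stage_width must be > 0")
    if span_end == span_start:
        raise ValueError("zero-length span")
    sign = 1.0 if span_end > span_start else -1.0
    stages: list[tuple[float, float]] = []
    pos = span_start
    while sign * (span_end - pos) > 1e-9:
        nxt = pos + sign * stage_width
        if sign * (nxt - span_end) > 0:
            nxt = span_end
        stages.append((pos, nxt))
        pos = nxt
    return StagePlan(
        stages=tuple(stages),
        stage_width=stage_width,
        n_replicas=n_replicas,
        velocity=velocity,
        direction="forward" if sign > 0 else "backward",
    )


def _check_works(works: np.ndarray) -> np.ndarray:
    works = np.asarray(works, dtype=float).ravel()
    if works.size == 0:
        raise ValueError("empty work ensemble")
    if not np.all(np.isfinite(works)):
        raise ValueError("non-finite work values in ensemble")
    return works


def jarzynski_free_energy(
    final_works: Sequence[float] | np.ndarray,
    thermo: ThermoParams = ThermoParams(),
) -> float:
    """Jarzynski estimate dF = -(1/beta) ln <exp(-beta W)> over replicas.

    Evaluated as a shifted log-sum-exp, so ensembles with works of
    hundreds of kcal/mol are handled without underflow.  Satisfies
    ``dF <= mean(W)`` (Jensen) and ``dF <= min(W) + kT ln N``.
    """
    works = _check_works(final_works)
    beta = thermo.beta
    return float(-(logsumexp(-beta * works) - math.log(works.size)) / beta)


def jarzynski_profile(
    traces: Sequence[WorkTrace],
    grid: np.ndarray,
    thermo: ThermoParams = ThermoParams(),
) -> PMFProfile:
    """Pointwise Jarzynski average along one stage.

    Each replica's accumulated work is linearly interpolated at the guide
    positions in ``grid`` (which must lie within the stage span); the
    estimate is anchored to 0 at the first grid point.
    """
    if not traces:
        raise ValueError("no traces given")
    grid = np.asarray(grid, dtype=float)
    lam0 = traces[0].lam
    lo, hi = min(lam0[0], lam0[-1]), max(lam0[0], lam0[-1])
    if np.any(grid < lo - 1e-9) or np.any(grid > hi + 1e-9):
        raise ValueError("grid extends outside the stage span")
    beta = thermo.beta
    # interpolation requires ascending abscissa; pulls may run either way
    w_grid = np.empty((len(traces), grid.size))
    for i, tr in enumerate(traces):
        lam, work = tr.lam, tr.work
        if lam[0] > lam[-1]:
            lam, work = lam[::-1], work[::-1]
        w_grid[i] = np.interp(grid, lam, work)
    log_n = math.log(len(traces))
    df = -(logsumexp(-beta * w_grid, axis=0) - log_n) / beta
    df = df - df[0]
    df[0] = 0.0
    return PMFProfile(grid=grid, free_energy=df)


def select_representative_replica(
    traces: Sequence[WorkTrace],
    thermo: ThermoParams = ThermoParams(),
) -> int:
    """Replica whose final work is closest to the stage Jarzynski estimate.

    Ties break toward the lowest replica id, so selection is deterministic.
    """
    if not traces:
        raise ValueError("no traces given")
    finals = _check_works([tr.final_work for tr in traces])
    df = jarzynski_free_energy(finals, thermo)
    dist = np.abs(finals - df)
    order = sorted(range(len(traces)), key=lambda i: (dist[i], traces[i].replica_id))
    return traces[order[0]].replica_id


def run_asmd(
    plan: StagePlan,
    simulator_config: LangevinConfig,
    thermo: ThermoParams = ThermoParams(),
    seed: int = 0,
    points_per_stage: int = 50,
) -> PMFProfile:
    """Execute the staged protocol on the Langevin engine.

    Per stage: run ``plan.n_replicas`` pulls, form the pointwise Jarzynski
    segment, pick the representative replica and hand its final particle
    position to the next stage.  Segments are concatenated with offset
    matching, so the assembled profile is continuous at every boundary.
    Stage s of the run draws replica noise from ``(seed, s)`` streams;
    identical seeds reproduce the profile bit for bit.
    """
    cfg = LangevinConfig(
        potential=simulator_config.potential,
        friction=simulator_config.friction,
        temperature=simulator_config.temperature,
        spring_constant=simulator_config.spring_constant,
        velocity=plan.velocity,
        timestep=simulator_config.timestep,
        seed=simulator_config.seed,
    )
    grids: list[np.ndarray] = []
    values: list[np.ndarray] = []
    selected: list[int] = []
    offset = 0.0
    x0: float | None = None
    for s, (start, end) in enumerate(plan.stages):
        stage_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0] % (2**31))
        traces = generate_work_ensemble(
            cfg, start, end, plan.n_replicas, seed=stage_seed, stage_id=s, x0=x0
        )
        grid = np.linspace(start, end, points_per_stage + 1)
        segment = jarzynski_profile(traces, grid, thermo)
        rep = select_representative_replica(traces, thermo)
        selected.append(rep)
        x0 = traces[rep].final_position
        if s == 0:
            grids.append(segment.grid)
            values.append(segment.free_energy + offset)
        else:  # drop the duplicated boundary point
            grids.append(segment.grid[1:])
            values.append(segment.free_energy[1:] + offset)
        offset += segment.final_value
    return PMFProfile(
        grid=np.concatenate(grids),
        free_energy=np.concatenate(values),
        stage_boundaries=tuple(s * points_per_stage for s in range(plan.n_stages)),
        selected_replicas=tuple(selected),
    )


def hysteresis(forward: PMFProfile, backward: PMFProfile) -> tuple[float, float]:
    """Forward/backward calibration discrepancy.

    The backward profile (pulled end -> start) is mapped onto the forward
    grid, both are anchored to 0 at the forward start, and the maximum and
    mean absolute free-energy difference over the overlapping grid are
    returned (kcal/mol).
    """
    fg, fv = forward.grid, forward.free_energy
    bg, bv = backward.grid, backward.free_energy
    if bg[0] > bg[-1]:
        bg, bv = bg[::-1], bv[::-1]
    lo, hi = max(fg.min(), bg.min()), min(fg.max(), bg.max())
    if lo >= hi:
        raise ValueError("profiles have disjoint grids")
    sel = (fg >= lo - 1e-9) & (fg <= hi + 1e-9)
    grid = fg[sel]
    f_on = fv[sel] - np.interp(lo, fg, fv)
    b_on = np.interp(grid, bg, bv) - np.interp(lo, bg, bv)
    diff = np.abs(f_on - b_on)
    return float(diff.max()), float(diff.mean())


@dataclass(frozen=True)
class ProtocolTotals:
    """Simulation-time bookkeeping for a staged pulling campaign (ns)."""

    per_replica_ns: tuple[float, ...]   # per stage
    per_stage_ns: tuple[float, ...]     # per stage, all replicas
    per_simulation_ns: float            # all stages of one pull
    campaign_ns: float                  # all peptide x membrane systems


def protocol_accounting(
    plan: StagePlan, n_peptides: int = 1, n_membranes: int = 1
) -> ProtocolTotals:
    """Aggregate simulated time implied by a stage plan.

    Per-replica time per stage is width/velocity; a stage costs that times
    ``n_replicas``; a simulation sums its stages; a campaign multiplies by
    the number of peptide-membrane systems.
    """
    if n_peptides < 0 or n_membranes < 0:
        raise ValueError("system counts must be >= 0")
    per_replica = tuple(abs(e - s) / plan.velocity for s, e in plan.stages)
    per_stage = tuple(t * plan.n_replicas for t in per_replica)
    per_simulation = float(sum(per_stage))
    return ProtocolTotals(
        per_replica_ns=per_replica,
        per_stage_ns=per_stage,
        per_simulation_ns=per_simulation,
        campaign_ns=per_simulation * n_peptides * n_membranes,
    )


def plan_experiment_matrix(
    peptides: Sequence[str],
    membranes: Sequence[str],
    include_controls: bool = True,
) -> list[dict[str, str | None]]:
    """Enumerate the peptide x membrane systems, plus peptide-free controls.

    Returns one descriptor per system: ``{"peptide": name or None,
    "membrane": name, "control": bool}``.  Three peptides and three
    membranes with controls give the full 12-system study matrix.
    """
    if not membranes:
        raise ValueError("membrane list must be non-empty")
    systems: list[dict[str, str | None]] = []
    if include_controls:
        for m in membranes:
            systems.append({"peptide": None, "membrane": m, "control": True})
    for p in peptides:
        for m in membranes:
            systems.append({"peptide": p, "membrane": m, "control": False})
    return systems
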