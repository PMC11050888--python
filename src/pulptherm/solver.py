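"""Transient heat conduction on labelled voxel phantoms.

Solves ``rho c dT/dt = div(k grad T)`` with a two-point-flux finite-volume
discretization on the voxel grid: face conductances use the harmonic mean of
the two cell conductivities, storage is lumped per cell, convection enters
as a Robin term ``h A (T_amb - T)`` on crown faces, and the finishing-tool
load is a time-varying Dirichlet temperature imposed on composite voxels
that own an exterior source face.

The thermal protocol emulates dry finishing and polishing: the contact
surface ramps linearly from body temperature (37 C) to 140 C over 5 s and
holds there for a further 10 s.  Time stepping is implicit (backward Euler
by default, Crank-Nicolson optional); with backward Euler the scheme
satisfies a discrete maximum principle, so every temperature stays inside
[min(T_initial, T_ambient), T_peak].

Units: geometry in mm, materials in SI; all lengths are converted to metres
inside the assembly so conductances are W/K and capacities J/K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, splu

from .errors import (
    ConfigurationError,
    InvalidParameterError,
    MissingTissueError,
    NumericalFailureError,
    SolverError,
)
from .geometry import (
    BACKGROUND,
    COMPOSITE,
    DENTIN,
    ENAMEL,
    LABEL_NAMES,
    PULP,
    SurfaceSets,
    TissueLabelGrid,
    extract_surfaces,
)
from .materials import MaterialLibrary, interface_conductivity

__all__ = [
    "ThermalProtocol",
    "SimulationConfig",
    "DiscreteOperator",
    "TemperatureHistory",
    "SensorSeries",
    "protocol_temperature",
    "assemble_operator",
    "run_simulation",
    "sample_sensors",
]

# which material record serves each tissue label
MATERIAL_FOR_LABEL = {
    ENAMEL: "Enamel",
    DENTIN: "Dentin",
    PULP: "Pulp",
    COMPOSITE: "Filtek Supreme XT",
}


@dataclass(frozen=True)
class ThermalProtocol:
    """The ramp-and-hold surface temperature schedule of dry finishing."""

    T_initial: float = 37.0
    T_peak: float = 140.0
    ramp_duration: float = 5.0
    hold_duration: float = 10.0

    def __post_init__(self) -> None:
        if self.T_peak < self.T_initial:
            raise InvalidParameterError(
                f"T_peak ({self.T_peak}) must be >= T_initial ({self.T_initial})"
            )
        if not (self.ramp_duration > 0.0 and self.hold_duration > 0.0):
            raise InvalidParameterError("protocol durations must be positive")

    @property
    def total_duration(self) -> float:
        return self.ramp_duration + self.hold_duration

    def temperature(self, t: float) -> float:
        return protocol_temperature(self, t)


def protocol_temperature(protocol: ThermalProtocol, t: float) -> float:
    """Source-surface temperature at time ``t`` (s).

    Linear ramp from ``T_initial`` to ``T_peak`` over ``ramp_duration``,
    then constant ``T_peak`` (clamped beyond the protocol's end).
    """
    if t < 0.0:
        raise InvalidParameterError(f"time must be non-negative, got {t!r}")
    if t <= protocol.ramp_duration:
        frac = t / protocol.ramp_duration
        return protocol.T_initial + (protocol.T_peak - protocol.T_initial) * frac
    return protocol.T_peak


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical parameters of one transient run.

    ``dt`` is the implicit time step (s), ``total_time`` the simulated span
    (s), ``scheme`` one of ``backward_euler`` / ``crank_nicolson``,
    ``convection_coefficient`` the intraoral film coefficient h in
    W/(m^2 K), ``ambient_temperature`` the intraoral air temperature (C).
    ``linear_solver`` selects a direct sparse factorization (``"direct"``,
    default — the system matrix is constant across steps so one
    factorization serves the whole run) or preconditioned conjugate
    gradients (``"cg"``) with ``linear_solver_tolerance`` as relative
    residual.  ``store_fields_every`` keeps a full temperature snapshot
    every that many steps (0 disables snapshots beyond first/last).
    """

    dt: float = 0.05
    total_time: float = 15.0
    scheme: str = "backward_euler"
    convection_coefficient: float = 3.0
    ambient_temperature: float = 37.0
    linear_solver: str = "direct"
    linear_solver_tolerance: float = 1e-8
    store_fields_every: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0.0):
            raise InvalidParameterError(f"dt must be positive, got {self.dt!r}")
        if not (self.total_time > 0.0):
            raise InvalidParameterError("total_time must be positive")
        if self.scheme not in ("backward_euler", "crank_nicolson"):
            raise InvalidParameterError(
                f"unknown scheme {self.scheme!r}; expected 'backward_euler' "
                "or 'crank_nicolson'"
            )
        if self.convection_coefficient < 0.0:
            raise InvalidParameterError("convection_coefficient must be >= 0")
        if not (0.0 < self.linear_solver_tolerance <= 1e-4):
            raise InvalidParameterError(
                "linear_solver_tolerance must lie in (0, 1e-4]"
            )
        if self.linear_solver not in ("direct", "cg"):
            raise InvalidParameterError(
                f"unknown linear_solver {self.linear_solver!r}"
            )

    @property
    def theta(self) -> float:
        return 1.0 if self.scheme == "backward_euler" else 0.5


@dataclass
class DiscreteOperator:
    """Assembled finite-volume system for one phantom.

    ``dof_of_voxel`` maps flat voxel index -> dof (-1 for background).
    ``conduction`` is the symmetric conduction matrix K (W/K) over all
    tissue dofs, ``capacity`` the lumped rho*c*V vector (J/K),
    ``robin_diag``/``robin_rhs`` the convection contributions h*A and
    h*A*T_amb, and ``dirichlet_dofs`` the composite dofs owning an exterior
    source face (where the protocol temperature is imposed).
    """

    dof_of_voxel: np.ndarray
    voxel_of_dof: np.ndarray
    conduction: sparse.csr_matrix
    capacity: np.ndarray
    robin_diag: np.ndarray
    robin_rhs: np.ndarray
    dirichlet_dofs: np.ndarray
    surfaces: SurfaceSets
    labels_of_dof: np.ndarray

    @property
    def n_dof(self) -> int:
        return len(self.capacity)


def assemble_operator(
    grid: TissueLabelGrid,
    library: MaterialLibrary,
    config: SimulationConfig,
    surfaces: SurfaceSets | None = None,
    require_source: bool = True,
) -> DiscreteOperator:
    """Assemble conduction matrix, capacity vector and boundary terms.

    Face conductance between cells i, j is ``k_harm * A / d`` with
    ``k_harm`` the harmonic mean of the two conductivities, ``A`` the face
    area and ``d`` the center spacing (both from ``voxel_size``).  The
    conduction matrix is symmetric with zero row sums (discrete
    conservation) and, with the Robin diagonal added, diagonally dominant.
    """
    lab = grid.labels
    present = sorted(int(c) for c in np.unique(lab) if c != BACKGROUND)
    for code in present:
        name = MATERIAL_FOR_LABEL.get(code)
        if name is None or name not in library:
            raise ConfigurationError(
                f"no material registered for label {LABEL_NAMES[int(code)]!r}"
            )

    solid = lab != BACKGROUND
    n_dof = int(solid.sum())
    dof_of_voxel = np.full(lab.size, -1, dtype=np.intp)
    flat_solid = np.flatnonzero(solid.reshape(-1))
    dof_of_voxel[flat_solid] = np.arange(n_dof)
    labels_of_dof = lab.reshape(-1)[flat_solid]

    h_m = grid.voxel_size * 1e-3  # voxel edge in metres
    area = h_m * h_m

    k_of_label = np.zeros(max(LABEL_NAMES) + 1)
    rhoc_of_label = np.zeros(max(LABEL_NAMES) + 1)
    for code in present:
        props = library[MATERIAL_FOR_LABEL[code]]
        k_of_label[code] = props.conductivity
        rhoc_of_label[code] = props.volumetric_heat_capacity

    capacity = rhoc_of_label[labels_of_dof] * h_m**3

    # internal faces: pairs of solid voxels adjacent along each axis
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        a = lab[tuple(sl_lo)]
        b = lab[tuple(sl_hi)]
        both = (a != BACKGROUND) & (b != BACKGROUND)
        idx_a = np.argwhere(both)
        if not len(idx_a):
            continue
        idx_b = idx_a.copy()
        idx_b[:, axis] += 1
        flat_a = np.ravel_multi_index(idx_a.T, lab.shape)
        flat_b = np.ravel_multi_index(idx_b.T, lab.shape)
        ka = k_of_label[lab.reshape(-1)[flat_a]]
        kb = k_of_label[lab.reshape(-1)[flat_b]]
        k_face = 2.0 * ka * kb / (ka + kb)
        g = k_face * area / h_m  # W/K
        da = dof_of_voxel[flat_a]
        db = dof_of_voxel[flat_b]
        rows.extend([da, db, da, db])
        cols.extend([db, da, da, db])
        vals.extend([-g, -g, g, g])
    if rows:
        conduction = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_dof, n_dof),
        ).tocsr()
    else:
        conduction = sparse.csr_matrix((n_dof, n_dof))

    if surfaces is None:
        surfaces = extract_surfaces(grid)

    robin_diag = np.zeros(n_dof)
    robin_rhs = np.zeros(n_dof)
    h_conv = config.convection_coefficient
    if h_conv > 0.0 and len(surfaces.convection_faces):
        conv_dofs = dof_of_voxel[surfaces.convection_faces[:, 0]]
        np.add.at(robin_diag, conv_dofs, h_conv * area)
        np.add.at(
            robin_rhs, conv_dofs, h_conv * area * config.ambient_temperature
        )

    if len(surfaces.source_faces):
        dirichlet_dofs = np.unique(dof_of_voxel[surfaces.source_faces[:, 0]])
    else:
        dirichlet_dofs = np.empty(0, dtype=np.intp)
    if require_source and len(dirichlet_dofs) == 0:
        raise ConfigurationError(
            "phantom has no source surface: an intact (unrestored) phantom "
            "cannot be used for a finishing simulation"
        )

    return DiscreteOperator(
        dof_of_voxel=dof_of_voxel,
        voxel_of_dof=flat_solid,
        conduction=conduction,
        capacity=capacity,
        robin_diag=robin_diag,
        robin_rhs=robin_rhs,
        dirichlet_dofs=dirichlet_dofs,
        surfaces=surfaces,
        labels_of_dof=labels_of_dof,
    )


@dataclass
class SensorSeries:
    """One virtual sensor trace: (time, temperature) samples for a tissue."""

    times: np.ndarray
    temperatures: np.ndarray
    tissue: str
    mode: str = "max"  # "max" or "probe"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.shape != self.temperatures.shape:
            raise InvalidParameterError("times and temperatures differ in length")
        if len(self.times) and not (np.diff(self.times) > 0).all():
            raise InvalidParameterError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class TemperatureHistory:
    """Result of one transient run.

    ``times`` starts at 0 (the uniform initial state).  ``traces`` maps
    tissue name -> {"max": array, "probe": array}: the tissue-wise maximum
    temperature and the temperature at a fixed probe voxel (the tissue voxel
    nearest the cavity floor).  ``snapshots`` optionally holds (t, field)
    pairs of full per-dof temperature vectors.
    """

    times: np.ndarray
    traces: dict[str, dict[str, np.ndarray]]
    probe_voxels: dict[str, int]
    snapshots: list[tuple[float, np.ndarray]] = field(default_factory=list)
    grid_shape: tuple[int, int, int] | None = None


def _probe_points(grid: TissueLabelGrid, op: DiscreteOperator) -> dict[str, int]:
    """Fixed probe voxel per tissue: the voxel nearest the cavity floor.

    The cavity floor is taken as the centroid of composite faces adjacent
    to dentin (the deepest restoration surface); for an intact phantom the
    pulp-chamber roof centroid is used instead.
    """
    lab = grid.labels.reshape(-1)
    h = grid.voxel_size
    origin = np.asarray(grid.origin)

    comp = np.flatnonzero(lab == COMPOSITE)
    if len(comp):
        # composite voxels with a dentin face-neighbour
        idx = np.array(np.unravel_index(comp, grid.shape)).T
        floor_pts = []
        for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)):
            nb = idx + off
            ok = ((nb >= 0) & (nb < np.asarray(grid.shape))).all(axis=1)
            nb_flat = np.ravel_multi_index(nb[ok].T, grid.shape)
            touching = lab[nb_flat] == DENTIN
            floor_pts.append(idx[ok][touching])
        floor_idx = np.vstack([f for f in floor_pts if len(f)])
        ref = (floor_idx.mean(axis=0) + 0.5) * h + origin
    else:
        pulp_idx = np.array(np.unravel_index(np.flatnonzero(lab == PULP),
                                             grid.shape)).T
        ref = (pulp_idx.mean(axis=0) + 0.5) * h + origin

    probes: dict[str, int] = {}
    for code, name in LABEL_NAMES.items():
        if code == BACKGROUND:
            continue
        flat = np.flatnonzero(lab == code)
        if not len(flat):
            continue
        idx = np.array(np.unravel_index(flat, grid.shape)).T
        centers = (idx + 0.5) * h + origin
        probes[name] = int(flat[np.argmin(((centers - ref) ** 2).sum(axis=1))])
    return probes


def run_simulation(
    grid: TissueLabelGrid,
    library: MaterialLibrary,
    protocol: ThermalProtocol,
    config: SimulationConfig,
    operator: DiscreteOperator | None = None,
) -> TemperatureHistory:
    """Integrate the transient problem and record per-tissue sensor traces.

    The field starts uniformly at ``protocol.T_initial``; at every implicit
    step the source temperature ``protocol_temperature(t_{n+1})`` is imposed
    on the Dirichlet dofs and the reduced symmetric positive-definite system
    is solved for the free dofs.  Deterministic given its inputs.
    """
    if config.total_time + 1e-12 < protocol.total_duration:
        raise InvalidParameterError(
            "total_time must cover the protocol "
            f"({protocol.total_duration} s), got {config.total_time} s"
        )
    op = operator if operator is not None else assemble_operator(
        grid, library, config
    )

    n_steps = int(round(config.total_time / config.dt))
    if abs(n_steps * config.dt - config.total_time) > 1e-9 * config.total_time:
        raise InvalidParameterError(
            f"dt ({config.dt}) must divide total_time ({config.total_time})"
        )

    theta = config.theta
    A = op.conduction + sparse.diags(op.robin_diag)
    free = np.setdiff1d(np.arange(op.n_dof), op.dirichlet_dofs)
    dmask = np.zeros(op.n_dof, dtype=bool)
    dmask[op.dirichlet_dofs] = True

    A_ff = A[free][:, free].tocsc()
    A_fd = A[free][:, op.dirichlet_dofs].tocsr()
    C_f = op.capacity[free]
    M = (sparse.diags(C_f / config.dt) + theta * A_ff).tocsc()

    use_direct = config.linear_solver == "direct"
    lu = splu(M) if use_direct else None
    M_csr = None if use_direct else M.tocsr()
    precond = None
    if not use_direct:
        inv_diag = 1.0 / M.diagonal()
        precond = sparse.linalg.LinearOperator(
            M.shape, matvec=lambda v: inv_diag * v
        )

    T = np.full(op.n_dof, protocol.T_initial)
    times = [0.0]
    probes = _probe_points(grid, op)
    tissue_dofs = {
        name: np.flatnonzero(op.labels_of_dof == code)
        for code, name in LABEL_NAMES.items()
        if code != BACKGROUND and (op.labels_of_dof == code).any()
    }
    probe_dofs = {
        name: int(op.dof_of_voxel[vox]) for name, vox in probes.items()
    }

    traces: dict[str, dict[str, list[float]]] = {
        name: {"max": [float(T[dofs].max())],
               "probe": [float(T[probe_dofs[name]])]}
        for name, dofs in tissue_dofs.items()
    }
    snapshots: list[tuple[float, np.ndarray]] = []
    if config.store_fields_every:
        snapshots.append((0.0, T.copy()))

    T_d_old = protocol_temperature(protocol, 0.0)
    for step in range(1, n_steps + 1):
        t_new = step * config.dt
        T_d_new = protocol_temperature(protocol, t_new)
        rhs = C_f / config.dt * T[free] + op.robin_rhs[free]
        if theta < 1.0:
            rhs -= (1.0 - theta) * (
                A_ff @ T[free] + A_fd @ np.full(len(op.dirichlet_dofs), T_d_old)
            )
        rhs -= theta * (A_fd @ np.full(len(op.dirichlet_dofs), T_d_new))

        if use_direct:
            T_f = lu.solve(rhs)
        else:
            T_f, info = cg(
                M_csr, rhs, x0=T[free], rtol=config.linear_solver_tolerance,
                M=precond,
            )
            if info != 0:
                res = float(np.linalg.norm(M_csr @ T_f - rhs))
                raise SolverError(
                    f"conjugate gradients failed at t={t_new:.4f} s "
                    f"(info={info})", residual=res,
                )
        if not np.isfinite(T_f).all():
            raise NumericalFailureError(
                f"non-finite temperature at t={t_new:.4f} s"
            )
        T[free] = T_f
        T[dmask] = T_d_new
        T_d_old = T_d_new

        times.append(t_new)
        for name, dofs in tissue_dofs.items():
            traces[name]["max"].append(float(T[dofs].max()))
            traces[name]["probe"].append(float(T[probe_dofs[name]]))
        if config.store_fields_every and (
            step % config.store_fields_every == 0 or step == n_steps
        ):
            snapshots.append((t_new, T.copy()))

    return TemperatureHistory(
        times=np.asarray(times),
        traces={
            name: {k: np.asarray(v) for k, v in tr.items()}
            for name, tr in traces.items()
        },
        probe_voxels=probes,
        snapshots=snapshots,
        grid_shape=grid.shape,
    )


def sample_sensors(
    history: TemperatureHistory, grid: TissueLabelGrid
) -> dict[str, dict[str, SensorSeries]]:
    """Per-tissue sensor series from a run's recorded traces.

    Returns ``{tissue: {"max": SensorSeries, "probe": SensorSeries}}`` where
    "max" is the tissue-wise maximum temperature at each sample time and
    "probe" the trace of the fixed voxel nearest the cavity floor.
    """
    present = {
        name for code, name in LABEL_NAMES.items()
        if code != BACKGROUND and (grid.labels == code).any()
    }
    missing = present - set(history.traces)
    if missing:
        raise MissingTissueError(
            f"history lacks traces for tissues present in grid: {sorted(missing)}"
        )
    out: dict[str, dict[str, SensorSeries]] = {}
    for name, tr in history.traces.items():
        if name not in present:
            raise MissingTissueError(f"tissue {name!r} absent from grid")
        out[name] = {
            mode: SensorSeries(
                times=history.times, temperatures=tr[mode], tissue=name,
                mode=mode,
            )
            for mode in ("max", "probe")
        }
    return out
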