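"""Analytic-solution checks for the transient conduction solver.

Two classical configurations with closed-form solutions:

* sudden surface-temperature step on a homogeneous half-space, whose
  solution is ``T(x,t) = T0 + (Ts - T0) * erfc(x / (2 sqrt(alpha t)))``;
* steady conduction between two fixed-temperature faces of a homogeneous
  slab, whose solution is the linear profile.

Both are discretized exactly the way a restored phantom is (the heated
voxel is labelled composite so the standard source-surface machinery
applies; the composite record is overridden with the bulk material's
properties so the bar is homogeneous).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import erfc

from .geometry import COMPOSITE, DENTIN, TissueLabelGrid
from .materials import default_library
from .solver import (
    SimulationConfig,
    ThermalProtocol,
    assemble_operator,
    run_simulation,
)

__all__ = [
    "make_bar_grid",
    "homogeneous_bar_library",
    "transient_slab_error",
    "steady_state_error",
]


def make_bar_grid(n_cells: int, voxel_size: float,
                  heated_end: bool = True) -> TissueLabelGrid:
    """A 1D bar of dentin along x; voxel 0 is labelled composite when
    ``heated_end`` so its exterior faces become the temperature source."""
    labels = np.full((n_cells, 1, 1), DENTIN, dtype=np.int8)
    if heated_end:
        labels[0, 0, 0] = COMPOSITE
    return TissueLabelGrid(
        labels=labels, voxel_size=voxel_size, origin=(0.0, 0.0, 0.0),
        cervical_z=1e9,  # no convective crown faces on a bar
    )


def homogeneous_bar_library(base: str = "Dentin"):
    """Material library whose composite record equals ``base``'s, so a
    composite-tipped bar is thermally homogeneous."""
    lib = default_library()
    return lib.override("Filtek Supreme XT", lib[base])


def transient_slab_error(
    voxel_size: float = 0.05,
    dt: float = 0.005,
    t_end: float = 1.0,
    bar_length_mm: float = 8.0,
    T0: float = 37.0,
    Ts: float = 140.0,
) -> float:
    """Relative L-infinity error of the solver against the half-space
    ``erfc`` solution at ``t_end``.

    The bar must be long enough to stay effectively semi-infinite over
    ``t_end`` (the default 8 mm covers ~1 s of dentin diffusion many times
    over).  The surface step is imposed through a ramp much shorter than
    one time step.  Distance ``x`` is measured from the held voxel's
    center, which is where the discrete Dirichlet plane sits.
    """
    n = int(round(bar_length_mm / voxel_size))
    grid = make_bar_grid(n, voxel_size)
    lib = homogeneous_bar_library()
    ramp = min(1e-9, dt / 100.0)
    protocol = ThermalProtocol(
        T_initial=T0, T_peak=Ts, ramp_duration=ramp,
        hold_duration=t_end - ramp,
    )
    n_steps = int(round(t_end / dt))
    config = SimulationConfig(
        dt=dt, total_time=t_end, convection_coefficient=0.0,
        store_fields_every=n_steps,
    )
    history = run_simulation(grid, lib, protocol, config)
    t_final, field = history.snapshots[-1]
    assert abs(t_final - t_end) < 1e-9

    alpha = lib["Dentin"].diffusivity  # m^2/s
    # dof order equals flat voxel order on a bar; dof 0 is the held voxel
    x = np.arange(n) * voxel_size * 1e-3  # m, from held voxel center
    exact = T0 + (Ts - T0) * erfc(x / (2.0 * np.sqrt(alpha * t_end)))
    return float(np.max(np.abs(field - exact)) / (Ts - T0))


def steady_state_error(
    n_cells: int = 40,
    voxel_size: float = 0.25,
    T_hot: float = 140.0,
    T_cold: float = 37.0,
) -> float:
    """L-infinity deviation (C) of the steady two-face Dirichlet solution
    from the exact linear profile across a homogeneous bar.

    Solves ``K_ff T_f = -K_fd T_d`` directly with the ends held at
    ``T_hot`` / ``T_cold``; the discrete solution of the two-point-flux
    scheme should reproduce the linear profile to solver precision.
    """
    grid = make_bar_grid(n_cells, voxel_size, heated_end=False)
    lib = default_library()
    config = SimulationConfig(convection_coefficient=0.0)
    op = assemble_operator(grid, lib, config, require_source=False)

    K = op.conduction.tocsr()
    dir_dofs = np.array([0, op.n_dof - 1])
    dir_vals = np.array([T_hot, T_cold])
    free = np.arange(1, op.n_dof - 1)
    T_f = spsolve(K[free][:, free].tocsc(),
                  -(K[free][:, dir_dofs] @ dir_vals))
    T = np.empty(op.n_dof)
    T[dir_dofs] = dir_vals
    T[free] = T_f

    x = np.arange(n_cells, dtype=float)
    exact = T_hot + (T_cold - T_hot) * x / (n_cells - 1)
    return float(np.max(np.abs(T - exact)))
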