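"""Synthetic voxel phantoms of a restored molar crown.

The phantom is a smooth parametric stand-in for a scanned tooth: a
superellipsoid crown (enamel shell obtained by an inward offset, dentin
body, ellipsoidal pulp chamber) sampled on a regular millimetre voxel grid.
Four class II cavity designs can be carved into the distal aspect and filled
with composite:

``direct_access``
    a box entered straight through the distal surface, no occlusal
    involvement (the most conservative preparation);
``occlusal_distal``
    a compound preparation joining an occlusal box to the distal box
    (the most invasive);
``vertical_slot``
    a tall, narrow, occlusogingivally oriented channel;
``horizontal_slot``
    a wide, shallow, mesiodistally oriented channel in the middle third.

Default cavity dimensions are calibrated once (see ``scripts`` in the
repository) so the composite volumes land on 12.2 mm^3 for direct access,
29.35 mm^3 for occlusal-distal, and within 1 mm^3 of each other for the two
slots, with the remaining dentin wall over the pulp thinnest for the
occlusal-distal design and thickest for direct access.

Coordinate convention: axis-aligned grid, 0-based integer voxel indices,
voxel centers at ``origin + (i + 0.5) * voxel_size``; x is the mesiodistal
axis with the distal aspect at +x, y is buccolingual, z is occlusogingival
with the (insulated) cervical base at low z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    EmptyCavityError,
    InvalidLabelError,
    InvalidParameterError,
    PulpExposureError,
)

__all__ = [
    "BACKGROUND",
    "ENAMEL",
    "DENTIN",
    "PULP",
    "COMPOSITE",
    "LABEL_NAMES",
    "TISSUE_CODES",
    "DESIGN_KINDS",
    "PhantomParams",
    "CavityDesign",
    "TissueLabelGrid",
    "SurfaceSets",
    "build_phantom",
    "carve_and_fill",
    "region_volume",
    "extract_surfaces",
]

# Tissue label codes.
BACKGROUND = 0
ENAMEL = 1
DENTIN = 2
PULP = 3
COMPOSITE = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    ENAMEL: "enamel",
    DENTIN: "dentin",
    PULP: "pulp",
    COMPOSITE: "composite",
}
TISSUE_CODES = {name: code for code, name in LABEL_NAMES.items()}

DESIGN_KINDS = (
    "direct_access",
    "occlusal_distal",
    "vertical_slot",
    "horizontal_slot",
)


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the intact crown phantom.

    All lengths in millimetres.  ``crown_extent`` is the full width of the
    crown along (mesiodistal x, buccolingual y, occlusogingival z);
    ``pulp_center_offset`` displaces the pulp chamber relative to the crown
    center.  ``crown_exponent`` is the superellipsoid exponent (2 gives an
    ellipsoid, larger values a more box-like crown).  ``cervical_fraction``
    sets the height of the cervical plane as a fraction of crown height;
    exterior enamel faces below it are treated as insulated rather than
    convective.  ``random_seed`` enables a small deterministic surface
    roughness jitter; ``None`` (default) disables it.
    """

    crown_extent: tuple[float, float, float] = (10.0, 11.0, 8.0)
    enamel_thickness: float = 1.0
    pulp_semi_axes: tuple[float, float, float] = (2.0, 2.5, 1.8)
    pulp_center_offset: tuple[float, float, float] = (0.0, 0.0, -0.8)
    voxel_size: float = 0.25
    crown_exponent: float = 3.0
    cervical_fraction: float = 0.25
    roughness_amplitude: float = 0.02
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.voxel_size > 0.0):
            raise InvalidParameterError(
                f"voxel_size must be positive, got {self.voxel_size!r}"
            )
        if any(not (e > 0.0) for e in self.crown_extent):
            raise InvalidParameterError(
                f"crown_extent must be positive, got {self.crown_extent!r}"
            )
        if min(self.crown_extent) < 4.0 * self.voxel_size:
            raise InvalidParameterError(
                "degenerate crown: every extent must be at least "
                f"4*voxel_size = {4 * self.voxel_size} mm, "
                f"got {self.crown_extent!r}"
            )
        if self.enamel_thickness < 2.0 * self.voxel_size:
            raise InvalidParameterError(
                "enamel_thickness must be at least 2*voxel_size "
                f"({2 * self.voxel_size} mm), got {self.enamel_thickness!r}"
            )
        if any(not (s > 0.0) for s in self.pulp_semi_axes):
            raise InvalidParameterError(
                f"pulp_semi_axes must be positive, got {self.pulp_semi_axes!r}"
            )
        if not (self.crown_exponent >= 2.0):
            raise InvalidParameterError(
                f"crown_exponent must be >= 2, got {self.crown_exponent!r}"
            )
        # Conservative analytic nesting pre-check along each axis; the exact
        # 26-connectivity invariant is re-verified on the built grid.
        semi = tuple(e / 2.0 for e in self.crown_extent)
        inner = tuple(s - self.enamel_thickness for s in semi)
        for ax in range(3):
            reach = abs(self.pulp_center_offset[ax]) + self.pulp_semi_axes[ax]
            if reach >= inner[ax]:
                raise InvalidParameterError(
                    "pulp chamber does not fit inside the dentin envelope "
                    f"along axis {ax}: offset+semi-axis {reach} mm >= "
                    f"inner semi-axis {inner[ax]} mm"
                )


# Calibrated default cavity dimensions (mm).  `floor_x` is the mesiodistal
# position of the cavity floor (the carve removes all tooth material distal
# of it inside the stated window); the remaining dentin wall over the pulp
# orders occlusal_distal < vertical_slot < horizontal_slot < direct_access.
_DEFAULT_DIMS: dict[str, dict[str, float]] = {
    "direct_access": {
        "floor_x": 3.5,
        "width_y": 3.0,
        "z_min": 2.25,
        "z_max": 5.0,
    },
    "vertical_slot": {
        "floor_x": 3.0,
        "width_y": 2.0,
        "z_min": 1.75,
        "z_max": 6.0,
    },
    "horizontal_slot": {
        "floor_x": 3.5,
        "width_y": 5.5,
        "z_min": 2.75,
        "z_max": 4.75,
    },
    "occlusal_distal": {
        "floor_x": 2.75,
        "width_y": 2.5,
        "z_min": 2.75,
        "occ_z_min": 6.75,
        "occ_x_min": 1.0,
        "occ_width_y": 2.5,
    },
}


@dataclass(frozen=True)
class CavityDesign:
    """One of the four class II cavity/restoration designs.

    ``dims`` holds the per-kind box/channel dimensions in mm (see
    :data:`_DEFAULT_DIMS` for the schema); ``wall_margin`` is the minimum
    remaining dentin thickness that must separate the carved region from the
    pulp chamber.
    """

    kind: str
    dims: Mapping[str, float] = field(default_factory=dict)
    wall_margin: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise InvalidParameterError(
                f"unknown cavity kind {self.kind!r}; "
                f"expected one of {DESIGN_KINDS}"
            )
        if not self.dims:
            object.__setattr__(self, "dims", dict(_DEFAULT_DIMS[self.kind]))
        if not (self.wall_margin > 0.0):
            raise InvalidParameterError(
                f"wall_margin must be positive, got {self.wall_margin!r}"
            )

    @classmethod
    def default(cls, kind: str, **overrides: float) -> "CavityDesign":
        """The shipped calibrated design for ``kind``, with optional
        dimension overrides."""
        dims = dict(_DEFAULT_DIMS.get(kind, {}))
        dims.update(overrides)
        return cls(kind=kind, dims=dims)


@dataclass
class TissueLabelGrid:
    """Voxelized phantom: a 3D integer label array plus its geometry.

    ``labels`` uses the codes in :data:`LABEL_NAMES`.  ``origin`` is the
    world-coordinate (mm) of the grid's low corner; voxel centers sit at
    ``origin + (index + 0.5) * voxel_size``.
    """

    labels: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float]
    cervical_z: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidParameterError("labels must be a 3D array")
        if not np.isin(self.labels, list(LABEL_NAMES)).all():
            raise InvalidLabelError(
                "labels contain codes outside the five known values"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centers (broadcastable grids)."""
        axes = [
            self.origin[ax] + (np.arange(self.shape[ax]) + 0.5) * self.voxel_size
            for ax in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def copy(self) -> "TissueLabelGrid":
        return TissueLabelGrid(
            labels=self.labels.copy(),
            voxel_size=self.voxel_size,
            origin=self.origin,
            cervical_z=self.cervical_z,
        )

    def counts(self) -> dict[str, int]:
        """Voxel count per label name."""
        return {
            name: int((self.labels == code).sum())
            for code, name in LABEL_NAMES.items()
        }


@dataclass
class SurfaceSets:
    """Partition of the phantom's exterior voxel faces.

    Each face array has shape (n, 5): flat voxel index of the owning tissue
    voxel, its (i, j, k) indices, and the face id 0..5 encoding axis*2 +
    (0 for the -side, 1 for the +side).  ``source_faces`` are exterior
    composite faces (the finishing-tool contact surface), ``convection_faces``
    exterior enamel faces on the anatomic crown above the cervical plane,
    ``insulated_faces`` everything else.
    """

    source_faces: np.ndarray
    convection_faces: np.ndarray
    insulated_faces: np.ndarray

    @property
    def n_exterior(self) -> int:
        return (
            len(self.source_faces)
            + len(self.convection_faces)
            + len(self.insulated_faces)
        )


# --------------------------------------------------------------------------
# phantom construction


def _superellipsoid_field(x, y, z, semi, center, p):
    return (
        np.abs((x - center[0]) / semi[0]) ** p
        + np.abs((y - center[1]) / semi[1]) ** p
        + np.abs((z - center[2]) / semi[2]) ** p
    )


def build_phantom(params: PhantomParams) -> TissueLabelGrid:
    """Construct the intact three-tissue crown phantom.

    The outer crown surface is a superellipsoid; the enamel-dentin junction
    is approximated by the same superellipsoid with every semi-axis reduced
    by ``enamel_thickness`` (an inward offset that is exact on the axes and
    slightly thicker on the diagonals); the pulp chamber is a true ellipsoid.
    Deterministic for a fixed ``random_seed``.
    """
    h = params.voxel_size
    ext = params.crown_extent
    semi = tuple(e / 2.0 for e in ext)
    # one-voxel background margin around the crown bounding box
    n = tuple(int(np.ceil(e / h)) + 2 for e in ext)
    origin = (-semi[0] - h, -semi[1] - h, -h)
    crown_center = (0.0, 0.0, semi[2])

    labels = np.zeros(n, dtype=np.int8)
    grid = TissueLabelGrid(
        labels=labels, voxel_size=h, origin=origin,
        cervical_z=params.cervical_fraction * ext[2],
    )
    x, y, z = grid.voxel_centers()

    p = params.crown_exponent
    outer = _superellipsoid_field(x, y, z, semi, crown_center, p)
    if params.random_seed is not None:
        rng = np.random.default_rng(params.random_seed)
        outer = outer + rng.uniform(
            -params.roughness_amplitude, params.roughness_amplitude, size=outer.shape
        )
    inner_semi = tuple(s - params.enamel_thickness for s in semi)
    inner = _superellipsoid_field(x, y, z, inner_semi, crown_center, p)

    pulp_center = tuple(
        c + o for c, o in zip(crown_center, params.pulp_center_offset)
    )
    pulp = _superellipsoid_field(x, y, z, params.pulp_semi_axes, pulp_center, 2.0)

    labels[outer <= 1.0] = ENAMEL
    labels[inner <= 1.0] = DENTIN
    labels[pulp <= 1.0] = PULP

    _check_pulp_nesting(grid)
    for code in (ENAMEL, DENTIN, PULP):
        if not (labels == code).any():
            raise InvalidParameterError(
                f"degenerate phantom: no {LABEL_NAMES[code]} voxels produced"
            )
    return grid


def _check_pulp_nesting(grid: TissueLabelGrid) -> None:
    """Every pulp voxel's 26-neighbourhood must contain only pulp or dentin."""
    pulp = grid.labels == PULP
    if not pulp.any():
        raise InvalidParameterError("phantom contains no pulp voxels")
    shell = ndimage.binary_dilation(
        pulp, structure=np.ones((3, 3, 3), dtype=bool)
    ) & ~pulp
    bad = np.unique(grid.labels[shell])
    if not np.isin(bad, [DENTIN]).all():
        names = [LABEL_NAMES[int(c)] for c in bad if c != DENTIN]
        raise InvalidParameterError(
            "pulp chamber is not strictly nested in dentin; "
            f"pulp touches: {names}"
        )


# --------------------------------------------------------------------------
# cavity carving


def _design_mask(grid: TissueLabelGrid, design: CavityDesign) -> np.ndarray:
    """Boolean mask of the carve region (in world coordinates)."""
    x, y, z = grid.voxel_centers()
    d = design.dims
    kind = design.kind
    if kind in ("direct_access", "vertical_slot", "horizontal_slot"):
        return (
            (x >= d["floor_x"])
            & (np.abs(y) <= d["width_y"] / 2.0)
            & (z >= d["z_min"])
            & (z <= d["z_max"])
        )
    # occlusal_distal: distal proximal box open to the occlusal surface,
    # plus an occlusal step extending mesially
    prox = (
        (x >= d["floor_x"])
        & (np.abs(y) <= d["width_y"] / 2.0)
        & (z >= d["z_min"])
    )
    occ = (
        (x >= d["occ_x_min"])
        & (np.abs(y) <= d["occ_width_y"] / 2.0)
        & (z >= d["occ_z_min"])
    )
    return prox | occ


def carve_and_fill(grid: TissueLabelGrid, design: CavityDesign) -> TissueLabelGrid:
    """Carve the design's region out of enamel/dentin and fill with composite.

    Only enamel and dentin voxels inside the carve region change label (to
    composite); pulp and background are untouched, so the total voxel count
    and the pulp geometry are bitwise preserved.

    Raises
    ------
    PulpExposureError
        if the region intersects the pulp or comes closer to it than
        ``design.wall_margin``.
    EmptyCavityError
        if the region removes no tooth material.
    """
    mask = _design_mask(grid, design)
    if (mask & (grid.labels == PULP)).any():
        raise PulpExposureError(
            f"{design.kind} cavity intersects the pulp chamber"
        )
    carve = mask & np.isin(grid.labels, (ENAMEL, DENTIN))
    if not carve.any():
        raise EmptyCavityError(
            f"{design.kind} cavity removes no tooth material"
        )
    # Euclidean distance (mm) from each voxel center to the nearest pulp voxel
    dist = ndimage.distance_transform_edt(
        grid.labels != PULP, sampling=grid.voxel_size
    )
    min_wall = float(dist[carve].min())
    if min_wall < design.wall_margin:
        raise PulpExposureError(
            f"{design.kind} cavity floor comes within {min_wall:.3f} mm of "
            f"the pulp (wall_margin is {design.wall_margin} mm)"
        )
    restored = grid.copy()
    restored.labels[carve] = COMPOSITE
    return restored


def region_volume(grid: TissueLabelGrid, label: int | str) -> float:
    """Volume (mm^3) of one labelled region: voxel count times voxel volume."""
    if isinstance(label, str):
        try:
            code = TISSUE_CODES[label]
        except KeyError:
            raise InvalidLabelError(
                f"unknown label {label!r}; known: {sorted(TISSUE_CODES)}"
            ) from None
    else:
        code = int(label)
        if code not in LABEL_NAMES:
            raise InvalidLabelError(
                f"unknown label code {label!r}; known: {sorted(LABEL_NAMES)}"
            )
    return float((grid.labels == code).sum()) * grid.voxel_size**3


# --------------------------------------------------------------------------
# exterior surface extraction

# face id f = 2*axis + (0 for -side, 1 for +side)
_FACE_OFFSETS = [
    (0, (-1, 0, 0)),
    (1, (1, 0, 0)),
    (2, (0, -1, 0)),
    (3, (0, 1, 0)),
    (4, (0, 0, -1)),
    (5, (0, 0, 1)),
]


def exterior_faces(grid: TissueLabelGrid) -> np.ndarray:
    """All exterior faces: (n, 5) array [flat_index, i, j, k, face_id].

    A face is exterior when a non-background voxel abuts background or the
    grid edge across it.
    """
    lab = grid.labels
    solid = lab != BACKGROUND
    rows = []
    for face_id, off in _FACE_OFFSETS:
        padded = np.pad(solid, 1, constant_values=False)
        neigh = padded[
            1 + off[0] : 1 + off[0] + lab.shape[0],
            1 + off[1] : 1 + off[1] + lab.shape[1],
            1 + off[2] : 1 + off[2] + lab.shape[2],
        ]
        mask = solid & ~neigh
        idx = np.argwhere(mask)
        if len(idx):
            flat = np.ravel_multi_index(idx.T, lab.shape)
            rows.append(
                np.column_stack([flat, idx, np.full(len(idx), face_id)])
            )
    if not rows:
        return np.empty((0, 5), dtype=np.intp)
    return np.vstack(rows).astype(np.intp)


def face_centers(grid: TissueLabelGrid, faces: np.ndarray) -> np.ndarray:
    """World coordinates (mm) of face centers, shape (n, 3)."""
    h = grid.voxel_size
    centers = (faces[:, 1:4] + 0.5) * h + np.asarray(grid.origin)
    for axis in range(3):
        minus = faces[:, 4] == 2 * axis
        plus = faces[:, 4] == 2 * axis + 1
        centers[minus, axis] -= h / 2.0
        centers[plus, axis] += h / 2.0
    return centers


def extract_surfaces(grid: TissueLabelGrid) -> SurfaceSets:
    """Partition the exterior boundary into source / convection / insulated.

    Composite exterior faces form the finishing-tool contact (temperature
    source); enamel exterior faces whose center lies at or above the
    cervical plane exchange heat with intraoral air (convection); every
    remaining exterior face — the cervical base and any face below the
    plane — is insulated.

    Raises
    ------
    ConfigurationError
        if the grid contains composite but none of it reaches the exterior
        surface (a buried restoration cannot be finished).
    """
    faces = exterior_faces(grid)
    owner = grid.labels.reshape(-1)[faces[:, 0]]
    centers = face_centers(grid, faces)

    is_source = owner == COMPOSITE
    is_conv = (owner == ENAMEL) & (centers[:, 2] >= grid.cervical_z)
    is_insulated = ~(is_source | is_conv)

    has_composite = (grid.labels == COMPOSITE).any()
    if has_composite and not is_source.any():
        raise ConfigurationError(
            "restored phantom has no exterior composite face: the cavity "
            "does not reach the surface"
        )
    return SurfaceSets(
        source_faces=faces[is_source],
        convection_faces=faces[is_conv],
        insulated_faces=faces[is_insulated],
    )
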