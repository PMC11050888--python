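"""Thermo-physical material properties of the simulated dental tissues.

The default library covers the four materials of a restored tooth crown:
enamel, dentin, pulp and the Filtek Supreme XT nanocomposite used as the
restorative.  Density, thermal conductivity and specific heat drive the
transient conduction solver; Young's modulus and Poisson's ratio are stored
for completeness but enter no computation (the package models heat transfer
only, not thermo-mechanics).

Thermal diffusivity ``alpha = k / (rho * c)`` is exposed as a derived
property; with the default values enamel conducts fastest and pulp, being
essentially water, slowest — which is what makes dentin the pulp's thermal
shield during dry finishing and polishing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import yaml

from .errors import InvalidParameterError, MaterialLookupError

__all__ = [
    "MaterialProperties",
    "MaterialLibrary",
    "default_library",
    "interface_conductivity",
]


@dataclass(frozen=True)
class MaterialProperties:
    """One material's property record.

    Parameters
    ----------
    youngs_modulus : float
        Elastic modulus in GPa.  Stored only; never used by the solver.
    poissons_ratio : float
        Dimensionless.  Stored only; never used by the solver.
    density : float
        rho, in kg/m^3.  Must be positive.
    conductivity : float
        k, in W/(m K).  Must be positive.
    specific_heat : float
        c, in J/(kg K).  Must be positive.
    """

    youngs_modulus: float
    poissons_ratio: float
    density: float
    conductivity: float
    specific_heat: float

    def __post_init__(self) -> None:
        for name in ("density", "conductivity", "specific_heat"):
            value = getattr(self, name)
            if not (value > 0.0):
                raise InvalidParameterError(
                    f"{name} must be positive, got {value!r}"
                )

    @property
    def diffusivity(self) -> float:
        """Thermal diffusivity alpha = k/(rho c), in m^2/s."""
        return self.conductivity / (self.density * self.specific_heat)

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c, in J/(m^3 K)."""
        return self.density * self.specific_heat


class MaterialLibrary(Mapping[str, MaterialProperties]):
    """Mapping of material name -> :class:`MaterialProperties`.

    Behaves like a read-only mapping; :meth:`override` returns a copy with
    one entry replaced, so the shipped defaults are never mutated in place.
    """

    def __init__(self, entries: Mapping[str, MaterialProperties]):
        self._entries = dict(entries)

    def __getitem__(self, name: str) -> MaterialProperties:
        try:
            return self._entries[name]
        except KeyError:
            known = ", ".join(sorted(self._entries))
            raise MaterialLookupError(
                f"unknown material {name!r}; known materials: {known}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def get_material(self, name: str) -> MaterialProperties:
        """Alias for ``library[name]`` with the same lookup error."""
        return self[name]

    def override(self, name: str, props: MaterialProperties) -> "MaterialLibrary":
        """Return a new library with ``name`` replaced (or added)."""
        if not isinstance(props, MaterialProperties):
            raise InvalidParameterError(
                "override value must be a MaterialProperties instance"
            )
        entries = dict(self._entries)
        entries[name] = props
        return MaterialLibrary(entries)

    # ------------------------------------------------------------------ io

    def to_yaml(self, path) -> None:
        """Serialize the library to a human-readable YAML file."""
        payload = {
            name: {
                "youngs_modulus": p.youngs_modulus,
                "poissons_ratio": p.poissons_ratio,
                "density": p.density,
                "conductivity": p.conductivity,
                "specific_heat": p.specific_heat,
            }
            for name, p in self._entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MaterialLibrary":
        """Load a library from a YAML file produced by :meth:`to_yaml`."""
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: Mapping) -> "MaterialLibrary":
        if not isinstance(payload, Mapping) or not payload:
            raise InvalidParameterError("material file holds no mapping")
        entries = {}
        for name, rec in payload.items():
            try:
                entries[name] = MaterialProperties(**rec)
            except TypeError as exc:
                raise InvalidParameterError(
                    f"malformed record for material {name!r}: {exc}"
                ) from exc
        return cls(entries)


def default_library(units_interpretation: str = "normalized") -> MaterialLibrary:
    """The built-in four-material library.

    Parameters
    ----------
    units_interpretation : {"normalized", "literal"}
        ``"normalized"`` (default) reads the source table's periods as
        thousands separators, giving densities of 2800/2000/1000/1500 kg/m^3
        and specific heats of 750/1302/4200/1370 J/(kg K) — the magnitudes
        standard in the dental-materials literature.  ``"literal"`` keeps the
        printed decimal values verbatim; it is retained purely so the
        consequences of the literal reading can be audited, and is not
        physically meaningful.
    """
    ref = resources.files("pulptherm.data").joinpath("materials.yaml")
    payload = yaml.safe_load(ref.read_text())
    lib = MaterialLibrary._from_payload(payload)
    if units_interpretation == "normalized":
        return lib
    if units_interpretation == "literal":
        literal = {}
        for name, p in lib.items():
            literal[name] = MaterialProperties(
                youngs_modulus=p.youngs_modulus,
                poissons_ratio=p.poissons_ratio,
                density=p.density / 1000.0,
                specific_heat=(
                    p.specific_heat
                    if name in ("Enamel", "Pulp")
                    else p.specific_heat / 1000.0
                ),
                conductivity=p.conductivity,
            )
        return MaterialLibrary(literal)
    raise InvalidParameterError(
        "units_interpretation must be 'normalized' or 'literal', "
        f"got {units_interpretation!r}"
    )


def interface_conductivity(k1: float, k2: float) -> float:
    """Effective conductivity of the face between two materials.

    Uses the harmonic mean ``2 k1 k2 / (k1 + k2)``, the exact series
    conductance of two half-cells in a two-point-flux discretization.
    Symmetric in its arguments and never larger than either input's double.
    """
    if not (k1 > 0.0 and k2 > 0.0):
        raise InvalidParameterError(
            f"conductivities must be positive, got ({k1!r}, {k2!r})"
        )
    return 2.0 * k1 * k2 / (k1 + k2)
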