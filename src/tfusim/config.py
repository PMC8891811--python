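"""Declarative run configuration (YAML) for the layered-media simulator."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .materials import Medium, load_materials


@dataclass(frozen=True)
class TransducerSpec:
    """Focused bowl source.

    A spherical cap of ``aperture_diameter`` across, cut from a sphere of
    radius ``curvature_radius``; the geometric focus sits one curvature
    radius beyond the apex.  ``drive_amplitude`` is the pressure amplitude
    imposed on the cap surface; it is usually fixed by calibrating the
    free-water focal peak rather than set directly.
    """

    center_frequency: float = 1.0e6
    aperture_diameter: float = 0.046
    curvature_radius: float = 0.090
    drive_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")
        if self.aperture_diameter <= 0 or self.curvature_radius <= 0:
            raise ValueError("aperture and curvature radius must be > 0")
        if self.aperture_diameter > 2.0 * self.curvature_radius:
            raise ValueError(
                "aperture_diameter exceeds 2*curvature_radius: spherical cap "
                "is not geometrically realizable"
            )

    @property
    def aperture_radius(self) -> float:
        return 0.5 * self.aperture_diameter

    @property
    def cap_height(self) -> float:
        """Axial depth of the spherical cap."""
        R, a = self.curvature_radius, self.aperture_radius
        return R - (R * R - a * a) ** 0.5


@dataclass(frozen=True)
class GridSpec:
    spacing: float = 5.0e-5
    radial_extent: float = 0.030
    axial_extent: float = 0.120


@dataclass(frozen=True)
class PMLSpec:
    thickness: float = 1.5e-3
    target_reflection: float = 1.0e-4
    profile_order: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    pml: PMLSpec = field(default_factory=PMLSpec)
    source_margin: float = 2.0e-3
    standoff: float = 0.010
    peak_margin: float = 1.5e-3
    #: (medium name, thickness in m) slabs, source-to-far-field order.
    layers: tuple[tuple[str, float], ...] = ()
    materials: Mapping[str, Medium] = field(default_factory=load_materials)

    def resolve_layers(self) -> list[tuple[Medium, float]]:
        out = []
        for name, thickness in self.layers:
            if name not in self.materials:
                raise KeyError(
                    f"unknown material {name!r}; have {sorted(self.materials)}"
                )
            out.append((self.materials[name], float(thickness)))
        return out

    def with_layers(self, layers: Sequence[tuple[str, float]]) -> "SimulationConfig":
        return dataclasses.replace(self, layers=tuple((n, float(t)) for n, t in layers))

    def digest(self) -> str:
        """Short stable hash of everything that affects a solve."""
        import hashlib

        parts = [
            repr(self.transducer),
            repr(self.grid),
            repr(self.pml),
            repr((self.source_margin, self.standoff, self.peak_margin)),
            repr(self.layers),
            repr(sorted((m.name, m.speed_of_sound, m.density, m.attenuation)
                        for m in self.materials.values())),
        ]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def default_config_path() -> Path:
    return Path(str(resources.files("tfusim").joinpath("data/default.yaml")))


def load_config(path: str | Path | None = None) -> SimulationConfig:
    """Parse a YAML run config; ``None`` loads the packaged default."""
    if path is None:
        path = default_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    t = raw.get("transducer", {})
    transducer = TransducerSpec(
        center_frequency=float(t.get("center_frequency_hz", 1.0e6)),
        aperture_diameter=float(t.get("aperture_diameter_m", 0.046)),
        curvature_radius=float(t.get("curvature_radius_m", 0.090)),
        drive_amplitude=float(t.get("drive_amplitude_pa", 1.0)),
    )
    g = raw.get("grid", {})
    grid = GridSpec(
        spacing=float(g.get("spacing_m", 5.0e-5)),
        radial_extent=float(g.get("radial_extent_m", 0.030)),
        axial_extent=float(g.get("axial_extent_m", 0.120)),
    )
    p = raw.get("pml", {})
    pml = PMLSpec(
        thickness=float(p.get("thickness_m", 1.5e-3)),
        target_reflection=float(p.get("target_reflection", 1.0e-4)),
        profile_order=int(p.get("profile_order", 2)),
    )
    geo = raw.get("geometry", {})
    materials = load_materials(raw.get("materials"))
    layers = tuple(
        (str(item["material"]), float(item["thickness_m"]))
        for item in (raw.get("layers") or [])
    )
    return SimulationConfig(
        transducer=transducer,
        grid=grid,
        pml=pml,
        source_margin=float(geo.get("source_margin_m", 2.0e-3)),
        standoff=float(geo.get("standoff_m", 0.010)),
        peak_margin=float(geo.get("peak_margin_m", 1.5e-3)),
        layers=layers,
        materials=materials,
    )
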