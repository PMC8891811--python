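"""Acoustic media and their lossy (complex-valued) representation.

A tissue is described by three real constants at the operating frequency:
speed of sound ``c`` (m/s), density ``rho`` (kg/m^3) and the amplitude
attenuation coefficient ``alpha`` (dB/m).  Absorption enters the
time-harmonic wave operator through a complex wavenumber

    k = omega/c - i * alpha_Np,        alpha_Np = alpha_dB * ln(10) / 20,

under the e^{+i omega t} convention, so that an outgoing wave
``exp(-i k z)`` decays like ``exp(-alpha_Np z)``.  The equivalent complex
sound speed is ``c_c = omega / k``; the density is kept real, which is the
standard equivalent-fluid closure when only one loss parameter is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from importlib import resources

#: dB/m -> Np/m conversion factor, ln(10)/20 (about 1/8.6859).
DB_TO_NP = math.log(10.0) / 20.0

#: Reference water at 295.15 K used for every free-field calibration.
#: Attenuation in water is negligible at 1 MHz over centimetre paths and is
#: set to zero so the free-water baseline is purely geometric.
WATER_NAME = "water"


@dataclass(frozen=True)
class Medium:
    """One tissue's real acoustic constants.

    Parameters
    ----------
    name : str
        Text label, e.g. ``"skull"``.
    speed_of_sound : float
        Phase speed in m/s, strictly positive.
    density : float
        Mass density in kg/m^3, strictly positive.
    attenuation : float
        Amplitude attenuation coefficient in dB/m, non-negative.
    """

    name: str
    speed_of_sound: float
    density: float
    attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise ValueError(f"{self.name}: speed_of_sound must be > 0")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if self.attenuation < 0:
            raise ValueError(f"{self.name}: attenuation must be >= 0")

    @property
    def impedance(self) -> float:
        """Characteristic impedance rho*c in Rayl (kg m^-2 s^-1)."""
        return self.density * self.speed_of_sound

    def wavelength(self, frequency: float) -> float:
        return self.speed_of_sound / frequency


@dataclass(frozen=True)
class ComplexMedium:
    """Lossy equivalent-fluid representation of a :class:`Medium` at one frequency."""

    name: str
    frequency: float
    complex_density: complex
    complex_speed: complex
    wavenumber: complex

    @property
    def complex_impedance(self) -> complex:
        return self.complex_density * self.complex_speed


def to_complex_medium(medium: Medium, frequency: float) -> ComplexMedium:
    """Build the complex wavenumber / speed / density triple at ``frequency``.

    ``k = omega/c - i*alpha_Np`` with ``alpha_Np = alpha_dB * ln(10)/20``;
    ``c_c = omega/k`` so that the lossless Helmholtz operator with the
    complex pair reproduces exactly this wavenumber.  Density stays real.

    Raises
    ------
    ValueError
        If ``frequency`` is not positive (the medium itself validates its
        own constants on construction).
    """
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    omega = 2.0 * math.pi * frequency
    alpha_np = medium.attenuation * DB_TO_NP
    k = omega / medium.speed_of_sound - 1j * alpha_np
    return ComplexMedium(
        name=medium.name,
        frequency=frequency,
        complex_density=complex(medium.density),
        complex_speed=omega / k,
        wavenumber=k,
    )


def _materials_path() -> Path:
    return Path(str(resources.files("tfusim").joinpath("data/materials_table1.csv")))


def load_materials(path: str | Path | None = None) -> Mapping[str, Medium]:
    """Load a material table from columnar CSV.

    The file must carry the header
    ``name,speed_of_sound_mps,attenuation_db_per_m,density_kg_per_m3``.
    With ``path=None`` the packaged default head-tissue table is loaded
    (scalp 1450 m/s / 68 dB/m / 955 kg/m^3, skull 4080 / 2000 / 1658,
    brain 1552 / 85 / 1046, water 1482 / 0 / 998).
    """
    if path is None:
        path = _materials_path()
    frame = pd.read_csv(path)
    required = {"name", "speed_of_sound_mps", "attenuation_db_per_m", "density_kg_per_m3"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"material file {path} missing columns: {sorted(missing)}")
    media = {}
    for row in frame.itertuples(index=False):
        media[row.name] = Medium(
            name=str(row.name),
            speed_of_sound=float(row.speed_of_sound_mps),
            density=float(row.density_kg_per_m3),
            attenuation=float(row.attenuation_db_per_m),
        )
    return media
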