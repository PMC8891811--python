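"""Packaged benchmark measurements and the synthetic sample generator.

Every published measurement the package validates against is shipped as a
plain CSV with a citation column, registered here with a SHA-256 checksum
so silent drift fails loudly.  The synthetic generator draws noisy
(thickness, transmission) observations from a known exponential law for
fit-recovery testing.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ThicknessSample

#: name -> (relative path under tfusim/data, sha256 of the file)
REGISTRY: dict[str, tuple[str, str]] = {
    "materials_table1": (
        "fixtures/materials_table1.csv",
        "f8767c886dcebb18f805eab56da3f7f5186e28d47a92ec5d09bd0cc88282b94d",
    ),
    "water_pressures": (
        "fixtures/water_pressures.csv",
        "b03d8e46244b89612be0c9875cb50758abc41f542bcef89c21717120e0c28ece",
    ),
    "multilayer_peaks": (
        "fixtures/multilayer_peaks.csv",
        "34540ffbcb45ce5c0ce07547ff3655f5df5f852e50257cb40f70c6d3236091eb",
    ),
    "single_layer_phantom": (
        "fixtures/single_layer_phantom.csv",
        "61447e18bfdc27bdbbe104a3d78082acbb295fd06c07a3ff2cf502fc358c4622",
    ),
    "single_layer_sim_mixed_thickness": (
        "fixtures/single_layer_sim_mixed_thickness.csv",
        "d168bcc2ee1cd35ac5a9b5e7b556be58fcf93344ba5bddc87a761e84330af947",
    ),
    "single_layer_sim_5mm": (
        "fixtures/single_layer_sim_5mm.csv",
        "05e52719ca379f4dc097f038a60f3ad95d88f1b1173aebebc8861ea5b31424ea",
    ),
    "skull14_sim": (
        "fixtures/skull14_sim.csv",
        "55dceec502cdf810dad35944c27fac81f549223d48bc7292fd39b756b3ad90f8",
    ),
    "skull14_phantom": (
        "fixtures/skull14_phantom.csv",
        "20041e305cd202406745cc438f688d08a1a72607d35a0fd49cd4e997d0dda600",
    ),
    "skull49_errors": (
        "fixtures/skull49_errors.csv",
        "9f74ee761912dd39410303686162516e2f71eb807164eacdccc52becf9b8ba78",
    ),
}

REQUIRED_COLUMNS = (
    "site", "thickness_mm", "quantity", "value", "units", "provenance",
    "citation",
)


@dataclass(frozen=True)
class FixtureTable:
    """A validated table of published measurements."""

    name: str
    source: str
    frame: pd.DataFrame

    def values(self, quantity: str, provenance: str | None = None) -> pd.DataFrame:
        sel = self.frame[self.frame["quantity"] == quantity]
        if provenance is not None:
            sel = sel[sel["provenance"] == provenance]
        return sel.reset_index(drop=True)

    def value(self, site: str, quantity: str) -> float:
        sel = self.frame[
            (self.frame["site"] == site) & (self.frame["quantity"] == quantity)
        ]
        if sel.empty:
            raise KeyError(f"no record for site={site!r} quantity={quantity!r}")
        return float(sel["value"].iloc[0])


def _fixture_path(relpath: str) -> Path:
    return Path(str(resources.files("tfusim").joinpath(f"data/{relpath}")))


def list_fixtures() -> list[str]:
    return sorted(REGISTRY)


def load_fixture(name: str) -> FixtureTable:
    """Load and checksum-verify a packaged fixture table.

    Raises
    ------
    KeyError
        Unknown fixture name; the message lists the registry.
    RuntimeError
        Checksum mismatch (the packaged file was altered).
    """
    if name not in REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        )
    relpath, expected = REGISTRY[name]
    path = _fixture_path(relpath)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise RuntimeError(
            f"fixture {name!r} failed its checksum: the packaged file at "
            f"{path} has drifted from the registered measurements"
        )
    frame = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise RuntimeError(f"fixture {name!r} missing columns {sorted(missing)}")
    return FixtureTable(name=name, source=str(frame["citation"].iloc[0]),
                        frame=frame)


def generate_tau_samples(
    a: float,
    b: float,
    thicknesses_mm: Sequence[float],
    noise_sigma: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> list[ThicknessSample]:
    """Draw noisy transmission observations from a known exponential law.

    ``tau_i = a * exp(-b z_i) * (1 + eps_i)`` with ``eps_i ~ N(0, sigma)``
    — multiplicative noise, emulating hydrophone amplitude error.  Values
    falling outside [0, 100] are clipped and a warning reports how many.
    Reproducible for a fixed integer seed.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be > 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    z = np.asarray(thicknesses_mm, dtype=float)
    if np.any(z < 0):
        raise ValueError("thicknesses must be >= 0")
    tau = a * np.exp(-b * z)
    if noise_sigma > 0:
        tau = tau * (1.0 + rng.normal(0.0, noise_sigma, size=z.shape))
    clipped = int(np.sum((tau < 0) | (tau > 100)))
    if clipped:
        warnings.warn(
            f"{clipped} synthetic transmission value(s) clipped to [0, 100]",
            stacklevel=2,
        )
    tau = np.clip(tau, 0.0, 100.0)
    return [
        ThicknessSample(thickness_mm=float(zi), transmission_percent=float(ti),
                        provenance="synthetic")
        for zi, ti in zip(z, tau)
    ]
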