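"""Loading of the versioned model-constants and source-curve files.

All numeric constants of the network — impedance coefficients, anatomical
dimensions, the bone-wave parameters and the frequency grid — live in
``data/model.yaml``; the stand-in excitation spectra and their calibration
targets live in ``data/sources.yaml``.  Code paths carry no magic numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .elements import ImpedanceElement

__all__ = [
    "load_model_constants",
    "load_source_config",
    "build_impedance_table",
    "frequency_grid",
]


def _load_yaml(name: str, path: str | Path | None) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("innerear").joinpath("data", name)
    return yaml.safe_load(ref.read_text())


def load_model_constants(path: str | Path | None = None) -> dict:
    """Load the model constants file (defaults to the packaged one)."""
    return _load_yaml("model.yaml", path)


def load_source_config(path: str | Path | None = None) -> dict:
    """Load the stand-in source curves and calibration spec."""
    return _load_yaml("sources.yaml", path)


def _leaf(name: str, coeffs: dict) -> ImpedanceElement:
    return ImpedanceElement(
        name=name,
        mass=float(coeffs.get("mass", 0.0)),
        resistance=float(coeffs.get("resistance", 0.0)),
        stiffness=float(coeffs.get("stiffness", 0.0)),
    )


def build_impedance_table(constants: dict) -> dict[str, ImpedanceElement]:
    """Construct the named lumped elements from the constants file."""
    table: dict[str, ImpedanceElement] = {}
    for name, spec in constants["impedances"].items():
        if "parallel" in spec:
            parts = tuple(_leaf(f"{name}[{i}]", c) for i, c in enumerate(spec["parallel"]))
            table[name] = ImpedanceElement(name=name, parts=parts, mode="parallel")
        elif "series" in spec:
            parts = tuple(_leaf(f"{name}[{i}]", c) for i, c in enumerate(spec["series"]))
            table[name] = ImpedanceElement(name=name, parts=parts, mode="series")
        else:
            table[name] = _leaf(name, spec)
    return table


def frequency_grid(constants: dict) -> np.ndarray:
    """Log-spaced analysis grid with the audiometric comparison frequencies on-grid.

    ``n`` log-spaced points between ``f_min_hz`` and ``f_max_hz``; the points
    nearest each required frequency are snapped to it so that 100, 125, 250,
    300, 500 and 1000 Hz are exactly representable.
    """
    g = constants["grid"]
    f = np.logspace(np.log10(g["f_min_hz"]), np.log10(g["f_max_hz"]), int(g["n"]))
    for req in g["required_hz"]:
        idx = int(np.argmin(np.abs(np.log(f) - np.log(req))))
        f[idx] = req
    f = np.sort(f)
    if len(np.unique(f)) != len(f):  # pragma: no cover - guards config edits
        raise ValueError("frequency grid collision while snapping required frequencies")
    return f
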