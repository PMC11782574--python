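"""Axon elongation-rate conversions from published measurements.

The agent model needs the stress sensitivity ``a`` in (mm/day)/Pa.  Published
axon towing experiments report either a growth-rate sensitivity to applied
tension per unit elastic modulus, or a force-rate threshold ``b`` (nN/h) for
an axon of diameter ``D`` (um); both convert to ``a`` in the model units.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "rate_from_modulus",
    "rate_from_force_rate",
    "build_table1",
    "write_table1_csv",
]


def rate_from_modulus(G: float, E: float) -> float:
    """Stress sensitivity a = G / E in (mm/day)/Pa.

    ``G`` is the measured towed-growth rate sensitivity in (mm/day) per unit
    strain and ``E`` the axon elastic modulus in Pa.
    """
    if E <= 0:
        raise ValueError("modulus must be positive")
    return G / E


def rate_from_force_rate(b: float, D: float) -> float:
    """Stress sensitivity a in (mm/day)/Pa from a force-rate measurement.

    ``b`` is the growth sensitivity to force rate in mm/h per nN and ``D``
    the axon diameter in um.  Dividing the applied force by the axon
    cross-section pi D^2 / 4 converts force (nN) to stress; with nN/um^2 =
    kPa the chain of unit conversions collapses to

        a [(mm/day)/Pa] = b * (pi D^2 / 4) * 24 / 1000.
    """
    if D <= 0:
        raise ValueError("diameter must be positive")
    return b * (math.pi * D * D / 4.0) * 24.0 / 1000.0


# measurement rows: (source system, conversion kind, parameters, diameter)
_MEASUREMENTS = (
    {
        "system": "rat DRG",
        "kind": "modulus",
        "G": 2.0,  # mm/day per unit strain
        "E_range": (100.0, 4600.0),  # Pa
        "D_um": None,
    },
    {
        "system": "rat hippocampal",
        "kind": "force_rate",
        "b_range": (0.66, 0.66),  # mm/h per nN
        "D_um": 5.0,
    },
    {
        "system": "chick forebrain",
        "kind": "force_rate",
        "b_range": (0.05, 0.5),
        "D_um": 1.0,
    },
    {
        "system": "chick DRG",
        "kind": "force_rate",
        "b_range": (0.02, 0.55),
        "D_um": 2.0,
    },
)


def build_table1() -> pd.DataFrame:
    """Converted stress sensitivities for the four published measurements.

    Returns a tidy frame with one row per system: the raw lower/upper bounds
    of ``a`` in (mm/day)/Pa (equal when the source reports a single value)
    and the same bounds rounded for display.
    """
    rows = []
    for m in _MEASUREMENTS:
        if m["kind"] == "modulus":
            lo = rate_from_modulus(m["G"], m["E_range"][1])
            hi = rate_from_modulus(m["G"], m["E_range"][0])
        else:
            lo = rate_from_force_rate(m["b_range"][0], m["D_um"])
            hi = rate_from_force_rate(m["b_range"][1], m["D_um"])
        lo, hi = sorted((lo, hi))
        rows.append(
            {
                "system": m["system"],
                "conversion": m["kind"],
                "a_lower": lo,
                "a_upper": hi,
                "a_lower_2dp": round(lo, 2),
                "a_upper_2dp": round(hi, 2),
            }
        )
    return pd.DataFrame(rows)


def write_table1_csv(path) -> pd.DataFrame:
    """Write the converted-rate table to ``path`` and return it."""
    table = build_table1()
    table.to_csv(path, index=False)
    return table
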