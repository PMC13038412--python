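"""Degree of oxidation (OxD) of the ratiometric redox probe roGFP2.

roGFP2 is excited at two wavelengths (400 nm and ~480/488 nm; both
measurement labels refer to the same long-wavelength channel, here called
I480) and read at 510 nm.  With fully reduced (DTT) and fully oxidized
(diamide) controls on the same plate, the probe's degree of oxidation is

    OxD = (I400s * I480red - I400red * I480s)
          / [(I400s * I480red - I400s * I480ox)
             + (I400ox * I480s - I400red * I480s)]

which is 0 when the sample matches the reduced controls, 1 when it matches
the oxidized controls, and invariant under any common rescaling of all six
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateControlsError, InvalidParameterError, SchemaError


@dataclass(frozen=True)
class OxDRecord:
    """Six ratiometric intensities (a.u.), optional time point and condition.

    ``oxd`` is the value clamped to [0, 1]; ``oxd_raw`` keeps the unclamped
    number so that noise-driven excursions remain visible downstream.
    """

    I400_sample: float
    I480_sample: float
    I400_red: float
    I480_red: float
    I400_ox: float
    I480_ox: float
    time_min: float | None = None
    condition: str | None = None
    oxd: float | None = None
    oxd_raw: float | None = None


def compute_oxd(record: OxDRecord) -> OxDRecord:
    """Fill in ``oxd`` / ``oxd_raw`` from the six intensities."""
    for name in ("I400_sample", "I480_sample", "I400_red", "I480_red", "I400_ox", "I480_ox"):
        val = getattr(record, name)
        if val is None:
            raise SchemaError(f"missing intensity field {name}")
        if name != "I400_sample" and name != "I480_sample" and val <= 0:
            raise InvalidParameterError(f"control intensity {name} must be > 0, got {val}")

    num = record.I400_sample * record.I480_red - record.I400_red * record.I480_sample
    den = (
        record.I400_sample * record.I480_red
        - record.I400_sample * record.I480_ox
        + record.I400_ox * record.I480_sample
        - record.I400_red * record.I480_sample
    )
    scale = max(abs(record.I400_sample * record.I480_red), 1e-300)
    if abs(den) <= 1e-12 * scale:
        raise DegenerateControlsError(
            "OxD denominator vanishes for these controls/sample intensities"
        )
    raw = num / den
    return replace(record, oxd_raw=raw, oxd=float(np.clip(raw, 0.0, 1.0)))


def fold_change(series, reference: float | None = None) -> np.ndarray:
    """Element-wise ratio of a fluorescence series to its reference value.

    By default the reference is the first element (time zero); used to
    summarize induction time courses (e.g. a fivefold rise at the plateau).
    """
    arr = np.asarray(series, dtype=float)
    ref = float(arr[0]) if reference is None else float(reference)
    if ref <= 0:
        raise InvalidParameterError(f"reference value must be > 0, got {ref}")
    return arr / ref
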