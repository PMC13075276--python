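"""Reference LAI from destructive field measurements (specific-leaf-weight).

The specific-leaf-weight method scales the dry mass of all leaves sampled
from representative stems through a reference mass-per-area ratio:

    LAI = (W2 / W1) * (S * M) / A

where W1 is the dry mass (g) of the reference leaves, S their total
one-sided area (m^2), W2 the total leaf dry mass (g) of the sampled stems,
M the stem count of the plant, and A the horizontal canopy projection area,
taken as an ellipse: A = pi * (d1/2) * (d2/2) for the major/minor canopy
diameters d1, d2 (m). LAI is homogeneous of degree +1 in W2 and M and of
degree -1 in W1 and A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["FieldRecord", "canopy_area", "slw_lai", "read_field_records"]


@dataclass(frozen=True)
class FieldRecord:
    """Field measurements for one sampled plant (units enforced on parse)."""

    sample_id: str
    w1: float  # reference-leaf dry mass, g
    w2: float  # total sampled-stem leaf dry mass, g
    s: float   # reference-leaf total one-sided area, m^2
    m: int     # stem count per plant
    d1: float  # major canopy diameter, m
    d2: float  # minor canopy diameter, m

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "s", "d1", "d2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.sample_id}: {name} must be > 0, got {v}")
        if not (isinstance(self.m, int) and self.m >= 1):
            raise ValueError(f"{self.sample_id}: stem count m must be >= 1, "
                             f"got {self.m}")


def canopy_area(d1: float, d2: float) -> float:
    """Elliptical canopy projection area A = pi * (d1/2) * (d2/2), m^2."""
    if d1 <= 0 or d2 <= 0:
        raise ValueError(f"canopy diameters must be positive, got {d1}, {d2}")
    return math.pi * (d1 / 2.0) * (d2 / 2.0)


def slw_lai(record: FieldRecord) -> float:
    """Specific-leaf-weight LAI: (W2/W1) * (S*M)/A with elliptical A."""
    a = canopy_area(record.d1, record.d2)
    return (record.w2 / record.w1) * (record.s * record.m) / a


def read_field_records(path) -> list[FieldRecord]:
    """Read field records from CSV.

    Expected headers: sample_id, w1, w2, s, m, d1, d2. Rows violating the
    measurement invariants raise with a row-level message.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "w1", "w2", "s", "m", "d1", "d2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"field-record CSV missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(FieldRecord(
                sample_id=str(row["sample_id"]), w1=float(row["w1"]),
                w2=float(row["w2"]), s=float(row["s"]), m=int(row["m"]),
                d1=float(row["d1"]), d2=float(row["d2"])))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return records


def attach_lai(samples, records: list[FieldRecord]) -> None:
    """Fill ``reference_lai`` on canopy samples from matching field records.

    A sample that already carries a reference LAI keeps it (directly
    provided values win over recomputation).
    """
    by_id = {r.sample_id: r for r in records}
    for s in samples:
        if s.reference_lai is None and s.sample_id in by_id:
            s.reference_lai = slw_lai(by_id[s.sample_id])
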