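"""Circular-chromosome coordinates and the relative-distance-to-oriC metric.

The *E. coli* chromosome is circular and is conventionally drawn as a
100-minute map.  Replication starts at *oriC* and proceeds bidirectionally
along the two arms (replichores) towards the terminus region *terC*, which
sits roughly opposite the origin.  Two derived quantities recur throughout
the package:

* the **relative distance** of a locus to *oriC* -- the shorter circular arc
  between the two positions divided by the total map length, a dimensionless
  number in ``[0, 0.5]``; and
* the **arm position** ``x`` -- the fraction of a replication arm a fork has
  to travel before it duplicates the locus, with ``x = 0`` at the origin and
  ``x = 1`` at the terminus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .errors import ConfigurationError, CoordinateError, ParseError, ValidationError

#: MG1655 genome length in base pairs (RefSeq NC_000913.3).
DEFAULT_LENGTH_BP = 4_641_652

#: Map-minute positions of the origin, terminus, the three DnaA-modulating
#: loci and the Tn10 insertion sites used as relocation targets.
DEFAULT_LOCI: Mapping[str, float] = {
    "datA": 94.6,
    "CAG18488": 93.9,
    "CAG18496": 86.8,
    "oriC": 84.6,
    "CAG18499": 83.5,
    "DARS2": 64.0,
    "CAG12135": 63.6,
    "CAG12173": 62.2,
    "CAG12151": 38.3,
    "terC": 36.0,
    "CAG18461": 33.3,
    "CAG18493": 17.7,
    "DARS1": 17.5,
}

ArmMode = Literal["symmetric", "explicit_ter"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables conventionally do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChromosomeMap:
    """A circular coordinate system with named loci.

    Positions are map minutes on ``[0, length_min)``; base-pair coordinates
    are 0-based, half-open on ``[0, length_bp)``.
    """

    length_min: float = 100.0
    length_bp: int = DEFAULT_LENGTH_BP
    loci: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOCI))
    ori_name: str = "oriC"
    ter_name: str | None = "terC"

    def __post_init__(self):
        if self.length_min <= 0:
            raise ValidationError(f"length_min must be positive, got {self.length_min}")
        if self.length_bp <= 0:
            raise ValidationError(f"length_bp must be positive, got {self.length_bp}")
        for name, pos in self.loci.items():
            if not 0 <= pos < self.length_min:
                raise ValidationError(
                    f"locus {name!r} at {pos} min is outside [0, {self.length_min})"
                )
        if self.ori_name not in self.loci:
            raise ValidationError(f"origin locus {self.ori_name!r} not in loci")
        if self.ter_name is not None and self.ter_name not in self.loci:
            raise ValidationError(f"terminus locus {self.ter_name!r} not in loci")

    @property
    def ori_min(self) -> float:
        return self.loci[self.ori_name]

    @property
    def ter_min(self) -> float | None:
        return None if self.ter_name is None else self.loci[self.ter_name]

    def position(self, name: str) -> float:
        try:
            return self.loci[name]
        except KeyError:
            raise CoordinateError(f"unknown locus {name!r}") from None

    def _check(self, position_min: float) -> float:
        if not 0 <= position_min < self.length_min:
            raise CoordinateError(
                f"position {position_min} min outside [0, {self.length_min})"
            )
        return position_min


def min_to_bp(position_min: float, chrom: ChromosomeMap | None = None) -> int:
    """Convert a map-minute position to the nearest base-pair coordinate."""
    chrom = chrom or ChromosomeMap()
    chrom._check(position_min)
    bp = round(position_min / chrom.length_min * chrom.length_bp)
    return int(bp % chrom.length_bp)


def bp_to_min(position_bp: int, chrom: ChromosomeMap | None = None) -> float:
    """Convert a base-pair coordinate to map minutes."""
    chrom = chrom or ChromosomeMap()
    if not 0 <= position_bp < chrom.length_bp:
        raise CoordinateError(
            f"position {position_bp} bp outside [0, {chrom.length_bp})"
        )
    return position_bp / chrom.length_bp * chrom.length_min


def relative_distance(
    locus_min: float, ori_min: float, chrom: ChromosomeMap | None = None
) -> float:
    """Shorter circular arc between two positions as a fraction of map length.

    Symmetric in its arguments and bounded by 0.5 (the antipode).  This is
    the conserved quantity that places datA at 0.10, DARS2 at 0.21 and DARS1
    at 0.33 from the origin on the wild-type chromosome.
    """
    chrom = chrom or ChromosomeMap()
    chrom._check(locus_min)
    chrom._check(ori_min)
    arc = abs(locus_min - ori_min)
    return min(arc, chrom.length_min - arc) / chrom.length_min


def arm_position(
    locus_min: float,
    chrom: ChromosomeMap | None = None,
    mode: ArmMode = "symmetric",
) -> float:
    """Fraction of the replication arm between the origin and a locus.

    ``symmetric`` assumes the terminus is exactly antipodal to the origin, so
    ``x = 2 * relative_distance`` (clipped to 1).  ``explicit_ter`` measures
    the arc from the origin to the locus along whichever arm carries the
    locus, divided by that arm's origin-to-terminus arc.
    """
    chrom = chrom or ChromosomeMap()
    chrom._check(locus_min)
    ori = chrom.ori_min
    if mode == "symmetric":
        return min(2.0 * relative_distance(locus_min, ori, chrom), 1.0)
    if mode != "explicit_ter":
        raise ValueError(f"unknown arm mode {mode!r}")
    ter = chrom.ter_min
    if ter is None:
        raise ConfigurationError("explicit_ter mode requires a terminus locus")
    L = chrom.length_min
    fwd_locus = (locus_min - ori) % L
    fwd_ter = (ter - ori) % L
    if fwd_ter in (0.0,):
        raise ConfigurationError("terminus coincides with the origin")
    if fwd_locus <= fwd_ter:  # locus on the forward (clockwise) arm
        x = fwd_locus / fwd_ter
    else:  # locus on the counterclockwise arm
        x = ((ori - locus_min) % L) / ((ori - ter) % L)
    return min(max(x, 0.0), 1.0)


def rd_table(chrom: ChromosomeMap, mode: ArmMode = "symmetric") -> pd.DataFrame:
    """Relative distance and arm position for every locus on a map."""
    rows = []
    for name, pos in chrom.loci.items():
        rows.append(
            {
                "name": name,
                "position_min": pos,
                "relative_distance": relative_distance(pos, chrom.ori_min, chrom),
                "arm_position": arm_position(pos, chrom, mode=mode),
            }
        )
    return pd.DataFrame(rows)


def load_loci(
    path: str | Path,
    length_min: float = 100.0,
    length_bp: int = DEFAULT_LENGTH_BP,
    ori_name: str = "oriC",
    ter_name: str | None = None,
) -> ChromosomeMap:
    """Read a locus table (CSV with ``name,position,unit`` header, or BED).

    BED rows (``chrom  start  end  name``) use 0-based half-open base-pair
    coordinates; the locus position is the interval midpoint.  CSV positions
    may be in minutes (``unit=min``) or base pairs (``unit=bp``).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise ParseError("empty locus file")
    loci: dict[str, float] = {}

    def add(name: str, pos_min: float, lineno: int) -> None:
        if name in loci:
            raise ValidationError(f"duplicate locus name {name!r} (line {lineno})")
        if not 0 <= pos_min < length_min:
            raise ValidationError(
                f"locus {name!r} at {pos_min} min outside [0, {length_min}) (line {lineno})"
            )
        loci[name] = pos_min

    header = lines[0].lower().replace(" ", "")
    if header.startswith("name,position"):
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise ParseError("expected name,position,unit", line=lineno)
            name, pos_s, unit = parts[0], parts[1], parts[2].lower()
            try:
                pos = float(pos_s)
            except ValueError:
                raise ParseError(f"bad position {pos_s!r}", line=lineno) from None
            if unit == "min":
                add(name, pos, lineno)
            elif unit == "bp":
                add(name, pos / length_bp * length_min, lineno)
            else:
                raise ParseError(f"unknown unit {unit!r}", line=lineno)
    else:  # BED
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("expected 4 BED columns (chrom start end name)", line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer BED coordinates", line=lineno) from None
            if not 0 <= start < end <= length_bp:
                raise ParseError(
                    f"BED interval [{start}, {end}) outside genome", line=lineno
                )
            mid = (start + end) / 2.0
            add(parts[3].strip(), mid / length_bp * length_min, lineno)

    return ChromosomeMap(
        length_min=length_min,
        length_bp=length_bp,
        loci=loci,
        ori_name=ori_name,
        ter_name=ter_name,
    )
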