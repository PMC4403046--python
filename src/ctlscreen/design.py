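"""Screening-library design: gene universe, 384-well plate geometry, control layout.

The screen is laid out on standard 384-well plates (rows A-P, columns 1-24).
Library siRNA pools occupy a fixed block of *sample* columns; positive and
negative control siRNAs are placed into otherwise empty wells in the outer
columns, one fixed layout shared by every replicate plate of the screen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: Plate rows of a 384-well plate, top to bottom.
PLATE_ROWS = "ABCDEFGHIJKLMNOP"
#: Number of columns of a 384-well plate.
PLATE_COLS = 24
#: Columns holding library (sample) wells in the default layout.
SAMPLE_COLS = tuple(range(3, 23))
#: Outer columns reserved for controls, in fill order.
CONTROL_COLS = (1, 2, 24, 23)

#: Well content classes.
CONTENT_CLASSES = (
    "sample",
    "control_fluc",
    "control_lethal",
    "control_suppressor",
    "control_negative",
    "empty",
)
CONTROL_CLASSES = tuple(c for c in CONTENT_CLASSES if c.startswith("control_"))

#: Default number of control wells per plate, by class.
DEFAULT_CONTROL_COUNTS: Mapping[str, int] = {
    "control_negative": 8,
    "control_fluc": 4,
    "control_lethal": 4,
    "control_suppressor": 4,
}

_WELL_RE = re.compile(r"^([A-P])([0-9]{1,2})$")


class DesignError(ValueError):
    """Raised when a library design cannot be realised on the plate format."""


def parse_well(well: str) -> tuple[int, int]:
    """Parse a well label like ``"B14"`` into (row_index, column).

    Returns a 0-based row index (A=0 .. P=15) and the 1-based column number.
    Raises :class:`DesignError` for labels outside the 16x24 grid.
    """
    m = _WELL_RE.match(str(well))
    if not m:
        raise DesignError(f"malformed well label {well!r} (expected e.g. 'B14')")
    row = PLATE_ROWS.index(m.group(1))
    col = int(m.group(2))
    if not 1 <= col <= PLATE_COLS:
        raise DesignError(f"well {well!r}: column {col} outside 1..{PLATE_COLS}")
    return row, col


def well_label(row_index: int, col: int) -> str:
    return f"{PLATE_ROWS[row_index]}{col}"


@dataclass(frozen=True)
class LibraryDesign:
    """The gene universe and per-plate control layout of one screening library.

    Parameters
    ----------
    genes
        Ordered gene identifiers, one per siRNA pool.
    duplexes_per_pool
        Number of synthetic siRNA duplexes mixed in each pool. Metadata only;
        pools are screened as single wells and never deconvolved.
    plate_capacity
        Number of library wells available per plate (default: the 16x20
        sample-column block, 320 wells).
    control_counts
        Control wells per plate, keyed by content class.
    """

    genes: tuple[str, ...]
    duplexes_per_pool: int = 4
    plate_capacity: int = len(PLATE_ROWS) * len(SAMPLE_COLS)
    control_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_COUNTS)
    )

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise DesignError("library must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise DesignError("duplicate gene identifiers in library")
        if not 0 < self.plate_capacity <= len(PLATE_ROWS) * len(SAMPLE_COLS):
            raise DesignError("plate_capacity outside the sample-column block")
        bad = set(self.control_counts) - set(CONTROL_CLASSES)
        if bad:
            raise DesignError(f"unknown control classes: {sorted(bad)}")
        n_ctrl = sum(self.control_counts.values())
        if n_ctrl > len(CONTROL_COLS) * len(PLATE_ROWS):
            raise DesignError(
                f"{n_ctrl} control wells do not fit in the control columns"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_plates(self) -> int:
        return -(-self.n_genes // self.plate_capacity)

    def plate_ids(self) -> list[str]:
        return [f"p{i + 1}" for i in range(self.n_plates)]

    def plate_layout(self) -> pd.DataFrame:
        """The shared physical layout of every replicate plate set.

        Returns a frame with columns ``plate_id, well, row, col, content,
        gene_id`` covering all occupied (sample and control) wells; empty
        wells are omitted. Sample wells fill the sample-column block
        row-major; control wells fill the outer control columns top-down in a
        fixed class order, identically on every plate.
        """
        records: list[tuple[str, str, int, int, str, object]] = []
        sample_positions = [
            (r, c) for r in range(len(PLATE_ROWS)) for c in SAMPLE_COLS
        ][: self.plate_capacity]
        control_positions = [
            (r, c) for c in CONTROL_COLS for r in range(len(PLATE_ROWS))
        ]
        gene_iter = iter(self.genes)
        done = False
        for plate_id in self.plate_ids():
            for r, c in sample_positions:
                gene = next(gene_iter, None)
                if gene is None:
                    done = True
                    break
                records.append((plate_id, well_label(r, c), r, c, "sample", gene))
            pos = iter(control_positions)
            for cls in CONTROL_CLASSES:
                for _ in range(self.control_counts.get(cls, 0)):
                    r, c = next(pos)
                    records.append((plate_id, well_label(r, c), r, c, cls, None))
            if done and plate_id != self.plate_ids()[-1]:  # pragma: no cover
                break
        return pd.DataFrame(
            records, columns=["plate_id", "well", "row", "col", "content", "gene_id"]
        )


def default_library(n_genes: int = 520) -> LibraryDesign:
    """The default library: 520 siRNA pools of four duplexes each.

    Gene identifiers are synthetic placeholders (``G0001`` ...); the screen's
    analysis never interprets them beyond identity.
    """
    genes = tuple(f"G{i + 1:04d}" for i in range(n_genes))
    return LibraryDesign(genes=genes)
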