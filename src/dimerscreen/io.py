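"""Plate CSV round-trip.

Long-format schema: ``plate_id,row,col,role,value,compound_id`` with 0-based
row/column indices and role in ``{sample,pos,neg,empty}``.  The
``compound_id`` column (blank for controls) carries sample identity through
the triage; readers accept files without it and synthesize positional ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import LayoutError
from .plates import EMPTY, SAMPLE, PlateGrid


def plates_to_frame(plates: list[PlateGrid]) -> pd.DataFrame:
    rows = []
    for plate in plates:
        nr, nc = plate.shape
        for i in range(nr):
            for j in range(nc):
                rows.append(
                    {
                        "plate_id": plate.plate_id,
                        "row": i,
                        "col": j,
                        "role": plate.roles[i, j],
                        "value": plate.values[i, j],
                        "compound_id": plate.compound_ids[i, j],
                    }
                )
    return pd.DataFrame(rows, columns=["plate_id", "row", "col", "role", "value", "compound_id"])


def frame_to_plates(frame: pd.DataFrame) -> list[PlateGrid]:
    if "compound_id" not in frame.columns:
        frame = frame.copy()
        frame["compound_id"] = [
            f"{p}-r{r}c{c}" if role == SAMPLE else ""
            for p, r, c, role in zip(frame["plate_id"], frame["row"], frame["col"], frame["role"])
        ]
    plates = []
    for plate_id, grp in frame.groupby("plate_id", sort=True):
        nr = int(grp["row"].max()) + 1
        nc = int(grp["col"].max()) + 1
        if len(grp) != nr * nc:
            raise LayoutError(f"plate {plate_id!r}: non-rectangular well set")
        values = np.zeros((nr, nc))
        roles = np.full((nr, nc), EMPTY, dtype=object)
        ids = np.full((nr, nc), "", dtype=object)
        for rec in grp.itertuples(index=False):
            i, j = int(rec.row), int(rec.col)
            values[i, j] = float(rec.value)
            roles[i, j] = rec.role
            ids[i, j] = "" if pd.isna(rec.compound_id) else str(rec.compound_id)
        plates.append(PlateGrid(str(plate_id), values, roles, ids))
    return plates


def write_plates_csv(plates: list[PlateGrid], path: str | Path) -> None:
    plates_to_frame(plates).to_csv(path, index=False)


def read_plates_csv(path: str | Path) -> list[PlateGrid]:
    return frame_to_plates(pd.read_csv(path, keep_default_na=False, na_values=[]))
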