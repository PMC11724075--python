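"""Compound library container and SMILES/SDF round-trip.

The container is deliberately thin: a pandas DataFrame of
``(compound_id, smiles, label)`` records plus a provenance tag saying
whether the set is a hit list, a reference collection, or a candidate pool.
RDKit does all structure handling; compounds that fail to parse are skipped
with a logged count rather than silently dropped — every operation that
consumes a library reports how many records it ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

from .exceptions import DataError

logger = logging.getLogger(__name__)

# RDKit is chatty about every parse failure; the skip policy logs its own count
RDLogger.DisableLog("rdApp.error")


@dataclass
class CompoundLibrary:
    """A set of compounds with unique ids and optional activity labels.

    ``records`` columns: ``compound_id`` (str), ``smiles`` (str) and
    optionally ``label`` (0/1 activity).  ``provenance`` is one of
    ``hitlist``, ``reference``, ``candidate`` (free-form accepted).
    """

    records: pd.DataFrame
    provenance: str = "candidate"
    _mols: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"compound_id", "smiles"}
        if not required.issubset(self.records.columns):
            raise DataError(f"library records need columns {sorted(required)}")
        ids = self.records["compound_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DataError(f"duplicate compound id {dup!r}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return self.records["compound_id"].tolist()

    def mols(self) -> list[Chem.Mol | None]:
        """RDKit molecules aligned to rows; ``None`` where parsing failed."""
        if self._mols is None:
            self._mols = [Chem.MolFromSmiles(s) for s in self.records["smiles"]]
            n_bad = sum(m is None for m in self._mols)
            if n_bad:
                logger.warning(
                    "%s library: skipped %d unparsable structures", self.provenance, n_bad
                )
        return self._mols

    def parsed(self) -> tuple[list[str], list[Chem.Mol]]:
        """(ids, molecules) for the parsable subset, input order preserved."""
        out_ids, out_mols = [], []
        for cid, mol in zip(self.ids, self.mols()):
            if mol is not None:
                out_ids.append(cid)
                out_mols.append(mol)
        return out_ids, out_mols

    def subset(self, ids: Iterable[str], provenance: str | None = None) -> "CompoundLibrary":
        keep = set(ids)
        sub = self.records[self.records["compound_id"].isin(keep)]
        return CompoundLibrary(sub.copy(), provenance or self.provenance)

    # ---- I/O ---------------------------------------------------------------

    @classmethod
    def from_smi(cls, path: str | Path, provenance: str = "candidate") -> "CompoundLibrary":
        """Read a ``SMILES<tab>compound_id`` file."""
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            smiles, cid = parts[0], parts[1]
            rows.append({"compound_id": cid, "smiles": smiles})
        return cls(pd.DataFrame(rows, columns=["compound_id", "smiles"]), provenance)

    def to_smi(self, path: str | Path) -> None:
        lines = [
            f"{row.smiles}\t{row.compound_id}"
            for row in self.records.itertuples(index=False)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_sdf(cls, path: str | Path, provenance: str = "candidate") -> "CompoundLibrary":
        rows = []
        for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
            if mol is None:
                logger.warning("SDF record %d unparsable, skipped", i)
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"SDF-{i:06d}"
            rows.append({"compound_id": cid, "smiles": Chem.MolToSmiles(mol)})
        return cls(pd.DataFrame(rows, columns=["compound_id", "smiles"]), provenance)

    def to_sdf(self, path: str | Path) -> None:
        writer = Chem.SDWriter(str(path))
        try:
            for cid, mol in zip(self.ids, self.mols()):
                if mol is None:
                    continue
                mol = Chem.Mol(mol)
                mol.SetProp("_Name", str(cid))
                writer.write(mol)
        finally:
            writer.close()


def library_from_records(
    ids: Sequence[str],
    smiles: Sequence[str],
    labels: Sequence[int] | None = None,
    provenance: str = "candidate",
) -> CompoundLibrary:
    data = {"compound_id": list(ids), "smiles": list(smiles)}
    if labels is not None:
        data["label"] = list(labels)
    return CompoundLibrary(pd.DataFrame(data), provenance)
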