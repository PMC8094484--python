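"""Structure and feature-table I/O.

Reads protein complex structures from PDB files (one record per residue
with a Calpha atom), reads/writes per-residue feature tables (CSV/TSV),
and writes hot-region predictions (JSON plus a flat CSV).

Residues are identified by author numbering exactly as printed in the
ATOM records, so ids line up with the conventional "A16"-style labels
used in the hot-spot literature.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, three-letter codes.
STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_LABEL_RE = re.compile(r"^([A-Za-z0-9])(-?\d+)([A-Za-z]?)$")


class StructureIOError(Exception):
    """Base error for structure/feature I/O problems."""


class EmptyStructureError(StructureIOError):
    """The input contained no usable Calpha atoms."""


class SchemaError(StructureIOError):
    """A table is missing mandatory columns."""


class ConsistencyError(StructureIOError):
    """Residue ids referenced by a table do not exist in the structure."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of a residue: chain, author sequence number, insertion code.

    ``res_type`` (three-letter code) is carried for convenience but does
    not participate in equality/ordering, so ids parsed from bare "A16"
    labels compare equal to ids read from a structure.
    """

    chain: str
    seq_num: int
    icode: str = ""
    res_type: str = field(default="UNK", compare=False)

    @property
    def label(self) -> str:
        """Compact "A16"-style label (chain letter + number [+ icode])."""
        return f"{self.chain}{self.seq_num}{self.icode}"

    @classmethod
    def from_label(cls, label: str, res_type: str = "UNK") -> "ResidueId":
        m = _LABEL_RE.match(label.strip())
        if not m:
            raise ValueError(f"cannot parse residue label {label!r}")
        chain, num, icode = m.groups()
        return cls(chain=chain, seq_num=int(num), icode=icode, res_type=res_type)

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_num, self.icode)


@dataclass(frozen=True)
class ResidueRecord:
    """A residue with its Calpha coordinates (angstrom)."""

    id: ResidueId
    ca: np.ndarray

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.shape != (3,) or not np.all(np.isfinite(ca)):
            raise ValueError(f"invalid Calpha coordinates for {self.id.label}: {self.ca}")
        object.__setattr__(self, "ca", ca)


class ComplexStructure:
    """An ordered collection of Calpha residue records grouped by chain."""

    def __init__(self, name: str, residues: Iterable[ResidueRecord]):
        self.name = name
        recs = list(residues)
        if not recs:
            raise EmptyStructureError(f"structure {name!r} has no residues")
        # within a chain, order by (seq_num, icode); chains keep first-seen order
        chain_order = {r.id.chain: i for i, r in enumerate(recs[::-1])}
        chain_first = {}
        for i, r in enumerate(recs):
            chain_first.setdefault(r.id.chain, i)
        recs.sort(key=lambda r: (chain_first[r.id.chain], r.id.seq_num, r.id.icode))
        self.residues: list[ResidueRecord] = recs
        self._index: dict[tuple[str, int, str], ResidueRecord] = {}
        for r in recs:
            k = r.id.key()
            if k in self._index:
                raise ConsistencyError(f"duplicate residue id {r.id.label} in {name!r}")
            self._index[k] = r
        _ = chain_order  # first-seen order retained via chain_first

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid.key() in self._index

    def get(self, rid: ResidueId) -> ResidueRecord:
        try:
            return self._index[rid.key()]
        except KeyError:
            raise ConsistencyError(
                f"residue {rid.label} not found in structure {self.name!r}"
            ) from None

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.id.chain, None)
        return list(seen)

    def ids(self) -> list[ResidueId]:
        return [r.id for r in self.residues]

    def coords(self) -> np.ndarray:
        """(n, 3) array of Calpha coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)


class FeatureTable:
    """Per-residue named feature values keyed by :class:`ResidueId`.

    Thin wrapper around a pandas DataFrame whose key columns are
    ``chain``, ``seq_num``, ``icode``, ``res_type``; every other column is
    a named real-valued feature.
    """

    KEY_COLUMNS = ("chain", "seq_num", "icode", "res_type")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("chain", "seq_num"):
            if col not in df.columns:
                raise SchemaError(f"feature table missing mandatory column {col!r}")
        if "icode" not in df.columns:
            df["icode"] = ""
        if "res_type" not in df.columns:
            df["res_type"] = "UNK"
        df["chain"] = df["chain"].astype(str)
        df["seq_num"] = df["seq_num"].astype(int)
        df["icode"] = df["icode"].fillna("").astype(str)
        df["res_type"] = df["res_type"].astype(str)
        keys = list(zip(df["chain"], df["seq_num"], df["icode"]))
        if len(set(keys)) != len(keys):
            raise ConsistencyError("duplicate residue ids in feature table")
        self.df = df.reset_index(drop=True)
        self._pos = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid.key() in self._pos

    def ids(self) -> list[ResidueId]:
        return [
            ResidueId(c, int(s), ic, rt)
            for c, s, ic, rt in zip(
                self.df["chain"], self.df["seq_num"], self.df["icode"], self.df["res_type"]
            )
        ]

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.KEY_COLUMNS]

    def value(self, rid: ResidueId, column: str) -> float:
        if column not in self.df.columns:
            raise SchemaError(f"feature table has no column {column!r}")
        try:
            i = self._pos[rid.key()]
        except KeyError:
            raise ConsistencyError(f"residue {rid.label} not in feature table") from None
        return float(self.df.at[i, column])

    def column(self, name: str) -> dict[ResidueId, float]:
        if name not in self.df.columns:
            raise SchemaError(f"feature table has no column {name!r}")
        return {rid: float(v) for rid, v in zip(self.ids(), self.df[name])}

    def require(self, columns: Sequence[str]) -> None:
        missing = [c for c in columns if c not in self.df.columns]
        if missing:
            raise SchemaError(f"feature table missing required columns: {missing}")
        bad = [c for c in columns if self.df[c].isna().any()]
        if bad:
            raise SchemaError(f"feature table has missing values in columns: {bad}")


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_pdb(
    path: str | Path,
    name: str | None = None,
    include_nonstandard: bool = False,
) -> ComplexStructure:
    """Read a PDB file into a Calpha-level :class:`ComplexStructure`.

    One :class:`ResidueRecord` is produced per residue that has a CA atom;
    residues lacking CA are skipped with a logged warning. For alternate
    locations the first-listed conformer is used (occupancy is ignored).
    HETATM/nonstandard residues are excluded unless ``include_nonstandard``.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(name or path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"{path}: no models") from None

    records: list[ResidueRecord] = []
    for chain in model:
        for residue in chain:
            hetfield, seq_num, icode = residue.id
            resname = residue.get_resname().strip()
            if hetfield.strip() and not include_nonstandard:
                continue
            if resname not in STANDARD_RESIDUES and not include_nonstandard:
                continue
            if "CA" not in residue:
                logger.warning(
                    "residue %s%s%s (%s) has no CA atom; skipped",
                    chain.id, seq_num, icode.strip(), resname,
                )
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]  # first-listed altloc
            rid = ResidueId(
                chain=str(chain.id), seq_num=int(seq_num),
                icode=icode.strip(), res_type=resname,
            )
            records.append(ResidueRecord(id=rid, ca=np.asarray(atom.coord, dtype=float)))
    if not records:
        raise EmptyStructureError(f"{path}: no residues with CA atoms")
    return ComplexStructure(name or path.stem, records)


def write_ca_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write a Calpha-only PDB file (deterministic byte output)."""
    path = Path(path)
    lines = []
    serial = 1
    for chain in structure.chains:
        last = None
        for rec in structure.residues:
            if rec.id.chain != chain:
                continue
            x, y, z = rec.ca
            lines.append(
                f"ATOM  {serial:5d}  CA  {rec.id.res_type:>3s} {chain:1s}"
                f"{rec.id.seq_num:4d}{rec.id.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}"
            )
            serial += 1
            last = rec
        if last is not None:
            lines.append(
                f"TER   {serial:5d}      {last.id.res_type:>3s} {chain:1s}"
                f"{last.id.seq_num:4d}{last.id.icode or ' ':1s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_feature_table(
    path: str | Path, structure: ComplexStructure | None = None
) -> FeatureTable:
    """Read a CSV/TSV feature table; optionally check ids against a structure."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = FeatureTable(_read_delimited(path))
    if structure is not None:
        unknown = [rid.label for rid in table.ids() if rid not in structure]
        if unknown:
            raise ConsistencyError(
                f"feature table rows not present in structure {structure.name!r}: "
                + ", ".join(unknown)
            )
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with 6-significant-digit numeric formatting."""
    path = Path(path)
    df = table.df.copy()
    for col in table.feature_columns:
        df[col] = df[col].map(lambda v: f"{float(v):.6g}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(
    regions: Sequence,  # Sequence[HotRegion]; duck-typed to avoid circular import
    path: str | Path,
    structure_name: str = "",
    scores: Mapping[ResidueId, float] | None = None,
) -> None:
    """Write hot-region predictions as JSON plus a flat residue->region CSV.

    The CSV is written next to the JSON file with a ``.csv`` suffix.
    """
    path = Path(path)
    payload = {
        "structure": structure_name,
        "n_regions": len(regions),
        "regions": [
            {
                "index": i,
                "size": len(region.members),
                "mean_cn": region.mean_cn,
                "residues": [rid.label for rid in sorted(region.members)],
            }
            for i, region in enumerate(regions)
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    rows = []
    for i, region in enumerate(regions):
        for rid in sorted(region.members):
            rows.append(
                {
                    "structure": structure_name,
                    "region": i,
                    "residue": rid.label,
                    "chain": rid.chain,
                    "seq_num": rid.seq_num,
                    "score": (
                        f"{float(scores[rid]):.6g}"
                        if scores is not None and rid in scores
                        else ""
                    ),
                }
            )
    pd.DataFrame(
        rows, columns=["structure", "region", "residue", "chain", "seq_num", "score"]
    ).to_csv(path.with_suffix(".csv"), index=False)


def read_predictions(path: str | Path) -> tuple[str, list[set[ResidueId]]]:
    """Read back a predictions JSON file -> (structure name, region member sets)."""
    payload = json.loads(Path(path).read_text())
    regions = [
        {ResidueId.from_label(lbl) for lbl in region["residues"]}
        for region in payload["regions"]
    ]
    return payload.get("structure", ""), regions
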