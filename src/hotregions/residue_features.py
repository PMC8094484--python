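"""Per-residue geometric and physico-chemical features.

Implements the distance-based descriptors used for hot-spot filtering:

* residue-residue contacts: two residues are in contact when their Calpha
  atoms are within 6.5 angstrom and they are not sequence neighbours
  (|i - j| <= 1 on the same chain never counts);
* the coordination number ``CN_i``: the number of contacts of residue i;
* the residue pair potential ``PP(i) = |sum_j potential(i, j)|``, summing
  knowledge-based contact-potential terms over partners within 7 angstrom
  at sequence separation >= 4 (inter-chain partners are always eligible);
* relative complex ASA: ``100 * ASA_complex / maxASA`` where ``maxASA`` is
  the residue's maximal exposure in a Gly-X-Gly tripeptide;
* a rolling-probe (Shrake-Rupley) solvent-accessible-surface computation
  for full-atom inputs, with a chain subset so that monomer and complex
  ASA can be obtained from the same file;
* a greedy Pearson-correlation redundancy filter for feature tables.

Cross-chain residue pairs are treated as sequence-distant for both the
contact rule and the pair-potential separation rule: sequence adjacency is
undefined across chains and interface contacts are inherently inter-chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import (
    ComplexStructure,
    ConsistencyError,
    FeatureTable,
    ResidueId,
    ResidueRecord,
    STANDARD_RESIDUES,
)

logger = logging.getLogger(__name__)

#: Default Calpha distance cutoff for a residue-residue contact (angstrom).
CONTACT_CUTOFF = 6.5
#: Default distance cutoff for a pair-potential term (angstrom).
POTENTIAL_CUTOFF = 7.0
#: Default minimum same-chain sequence separation for a pair-potential term.
MIN_SEPARATION = 4


class MatrixCoverageError(Exception):
    """A residue type is not covered by the contact-potential matrix."""


class CaOnlyStructureError(Exception):
    """ASA computation requested on a structure without full-atom coordinates."""


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(filename: str) -> Path:
    return Path(resources.files("hotregions").joinpath("data", filename))  # type: ignore[arg-type]


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Maximum ASA of each residue type in a Gly-X-Gly tripeptide (angstrom^2).

    The packaged default holds the theoretical values of Tien et al. (2013).
    """
    df = pd.read_csv(path or _data_path("max_asa_tien2013.csv"))
    return {str(r): float(v) for r, v in zip(df["res"], df["max_asa"])}


@dataclass(frozen=True)
class PairPotentialMatrix:
    """A symmetric 20x20 residue contact-potential table.

    The packaged default (``pair_potential_synthetic.csv``) is a synthetic
    hydrophobicity-derived matrix constructed for this package: published
    knowledge-based tables are not redistributable here, so the default is
    labelled synthetic and any user matrix with the same CSV layout (row
    label column ``res`` plus one column per residue type) can be loaded
    via :meth:`from_csv`.
    """

    values: Mapping[tuple[str, str], float]
    residue_types: tuple[str, ...]
    provenance: str = "synthetic-hydrophobicity"

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None) -> "PairPotentialMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        types = tuple(str(c) for c in df.columns)
        vals: dict[tuple[str, str], float] = {}
        for a in types:
            for b in types:
                vals[(a, b)] = float(df.at[a, b])
        for a in types:
            for b in types:
                if not np.isclose(vals[(a, b)], vals[(b, a)]):
                    raise ValueError(f"matrix not symmetric at ({a}, {b})")
                if not np.isfinite(vals[(a, b)]):
                    raise ValueError(f"non-finite matrix entry at ({a}, {b})")
        return cls(values=vals, residue_types=types, provenance=provenance or path.stem)

    @classmethod
    def default(cls) -> "PairPotentialMatrix":
        return cls.from_csv(
            _data_path("pair_potential_synthetic.csv"),
            provenance="synthetic-hydrophobicity",
        )

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return self.values[(a, b)]
        except KeyError:
            raise MatrixCoverageError(
                f"residue pair ({a}, {b}) not covered by matrix {self.provenance!r}"
            ) from None

    def covers(self, res_type: str) -> bool:
        return res_type in self.residue_types


# ---------------------------------------------------------------------------
# Distances, contacts, coordination numbers
# ---------------------------------------------------------------------------

def ca_distance(a: ResidueRecord, b: ResidueRecord) -> float:
    """Euclidean distance between the Calpha atoms of two residues (angstrom)."""
    return float(np.linalg.norm(a.ca - b.ca))


def sequence_eligible(i: ResidueId, j: ResidueId, min_sep: int = 2) -> bool:
    """True when the pair may count as a spatial neighbour.

    Same-chain pairs require ``|seq_num_i - seq_num_j| >= min_sep`` (author
    numbering); pairs on different chains are always eligible.
    """
    if i.chain != j.chain:
        return True
    return abs(i.seq_num - j.seq_num) >= min_sep


def contact_indicator(
    i: ResidueId,
    j: ResidueId,
    structure: ComplexStructure,
    cutoff: float = CONTACT_CUTOFF,
    inclusive: bool = True,
) -> int:
    """Contact indicator for a residue pair.

    1 iff the pair is sequence-eligible (separation > 1 or inter-chain) and
    the Calpha distance is <= cutoff (``inclusive=False`` switches to a
    strict inequality at the boundary).
    """
    if i == j:
        return 0
    d = ca_distance(structure.get(i), structure.get(j))
    if not sequence_eligible(i, j, min_sep=2):
        return 0
    if inclusive:
        return int(d <= cutoff)
    return int(d < cutoff)


@dataclass
class ContactMap:
    """Symmetric binary contact relation over the residues of a structure."""

    ids: list[ResidueId]
    matrix: np.ndarray  # (n, n) bool
    cutoff: float

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(int)


def contact_map(
    structure: ComplexStructure,
    cutoff: float = CONTACT_CUTOFF,
    inclusive: bool = True,
) -> ContactMap:
    """All-pairs contact map (vectorized)."""
    ids = structure.ids()
    coords = structure.coords()
    d = cdist(coords, coords)
    within = d <= cutoff if inclusive else d < cutoff
    chains = np.array([rid.chain for rid in ids])
    nums = np.array([rid.seq_num for rid in ids])
    same_chain = chains[:, None] == chains[None, :]
    near_seq = np.abs(nums[:, None] - nums[None, :]) <= 1
    eligible = ~(same_chain & near_seq)
    m = within & eligible
    np.fill_diagonal(m, False)
    return ContactMap(ids=ids, matrix=m, cutoff=cutoff)


@dataclass
class CoordinationProfile:
    """Coordination number CN_i per residue; RN = total residue count."""

    cn: dict[ResidueId, int]
    rn: int

    def __getitem__(self, rid: ResidueId) -> int:
        return self.cn[rid]

    def mean(self, subset: Iterable[ResidueId] | None = None) -> float:
        vals = (
            [self.cn[r] for r in subset] if subset is not None else list(self.cn.values())
        )
        if not vals:
            return 0.0
        return float(np.mean(vals))


def coordination_numbers(
    structure: ComplexStructure, cutoff: float = CONTACT_CUTOFF, inclusive: bool = True
) -> CoordinationProfile:
    """Coordination number of every residue: CN_i = sum_j Contact(i, j)."""
    cm = contact_map(structure, cutoff=cutoff, inclusive=inclusive)
    sums = cm.row_sums()
    return CoordinationProfile(
        cn={rid: int(s) for rid, s in zip(cm.ids, sums)}, rn=len(cm.ids)
    )


# ---------------------------------------------------------------------------
# Pair potentials
# ---------------------------------------------------------------------------

@dataclass
class PairPotentialProfile:
    """PP(i) per residue: absolute sum of contact-potential terms."""

    pp: dict[ResidueId, float]
    cutoff: float = POTENTIAL_CUTOFF
    min_sep: int = MIN_SEPARATION

    def __getitem__(self, rid: ResidueId) -> float:
        return self.pp[rid]


def pair_potentials(
    structure: ComplexStructure,
    matrix: PairPotentialMatrix | None = None,
    cutoff: float = POTENTIAL_CUTOFF,
    min_sep: int = MIN_SEPARATION,
) -> PairPotentialProfile:
    """Pair potential PP(i) = |sum_j potential(i, j)| for every residue.

    A partner j contributes matrix[type_i, type_j] when the Calpha distance
    is <= ``cutoff`` and the pair is sequence-eligible at separation
    >= ``min_sep`` (inter-chain partners always eligible). The sum runs over
    all residues of the complex.
    """
    matrix = matrix or PairPotentialMatrix.default()
    ids = structure.ids()
    uncovered = sorted({r.res_type for r in ids if not matrix.covers(r.res_type)})
    if uncovered:
        raise MatrixCoverageError(
            f"residue types not covered by matrix {matrix.provenance!r}: {uncovered}"
        )
    coords = structure.coords()
    d = cdist(coords, coords)
    chains = np.array([rid.chain for rid in ids])
    nums = np.array([rid.seq_num for rid in ids])
    same_chain = chains[:, None] == chains[None, :]
    far_seq = np.abs(nums[:, None] - nums[None, :]) >= min_sep
    eligible = (~same_chain) | far_seq
    near = d <= cutoff
    np.fill_diagonal(near, False)
    types = [r.res_type for r in ids]
    tmat = np.array([[matrix[(a, b)] for b in types] for a in types])
    contrib = np.where(near & eligible, tmat, 0.0)
    pp = np.abs(contrib.sum(axis=1))
    return PairPotentialProfile(
        pp={rid: float(v) for rid, v in zip(ids, pp)}, cutoff=cutoff, min_sep=min_sep
    )


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccessibilityRecord:
    """ASA bookkeeping for one residue (angstrom^2; relative value in %)."""

    asa_complex: float
    asa_monomer: float
    max_asa: float
    rel_complex_asa: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.asa_complex, self.asa_monomer) < 0 or self.max_asa <= 0:
            raise ValueError("ASA values must be >= 0 and max_asa > 0")
        object.__setattr__(
            self, "rel_complex_asa", relative_complex_asa(self.asa_complex, self.max_asa)
        )


def relative_complex_asa(asa_complex: float, max_asa: float) -> float:
    """Relative complex ASA in percent: 100 * ASA_complex / maxASA."""
    if max_asa <= 0:
        raise ValueError(f"max_asa must be positive, got {max_asa}")
    if asa_complex < 0:
        raise ValueError(f"asa_complex must be >= 0, got {asa_complex}")
    return 100.0 * asa_complex / max_asa


def compute_asa(
    source,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chains: Sequence[str] | None = None,
) -> dict[ResidueId, float]:
    """Per-residue solvent-accessible surface area by the rolling-probe method.

    ``source`` is a PDB file path or a Biopython model/structure with
    full-atom coordinates. ``chains`` restricts the computation to a chain
    subset *in isolation*, which is how monomer ASA is obtained for
    comparison with the complex value. Shrake-Rupley sphere sampling with a
    fixed point count keeps the result deterministic.

    Raises :class:`CaOnlyStructureError` when only Calpha atoms are present
    (ASA is undefined without side-chain/backbone atoms; supply a feature
    table instead).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    if isinstance(source, (str, Path)):
        parser = PDBParser(QUIET=True)
        entity = parser.get_structure(Path(source).stem, str(source))
        model = next(entity.get_models())
    else:
        model = source
        if hasattr(model, "get_models"):  # a Structure
            model = next(model.get_models())

    atom_names = {a.get_name() for a in model.get_atoms()}
    if atom_names <= {"CA"}:
        raise CaOnlyStructureError(
            "structure contains only Calpha atoms; ASA cannot be computed - "
            "provide full-atom coordinates or a precomputed feature table"
        )

    if chains is not None:
        import copy

        model = copy.deepcopy(model)
        for chain in list(model):
            if chain.id not in set(chains):
                model.detach_child(chain.id)
        if len(list(model)) == 0:
            raise ValueError(f"no chains left after restricting to {chains}")

    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(model, level="R")
    out: dict[ResidueId, float] = {}
    for chain in model:
        for residue in chain:
            hetfield, seq_num, icode = residue.id
            if hetfield.strip():
                continue
            rid = ResidueId(
                chain=str(chain.id), seq_num=int(seq_num),
                icode=icode.strip(), res_type=residue.get_resname().strip(),
            )
            out[rid] = float(residue.sasa)
    return out


# ---------------------------------------------------------------------------
# Feature redundancy pruning
# ---------------------------------------------------------------------------

def pearson_redundancy_filter(
    features: FeatureTable | pd.DataFrame,
    threshold: float = 0.9,
    columns: Sequence[str] | None = None,
) -> list[str]:
    """Greedy correlation-based redundancy pruning of feature columns.

    Columns are scanned in header order; a column is dropped when its
    absolute Pearson correlation with any already-retained column is
    >= ``threshold``. Constant (zero-variance) columns are excluded with a
    warning. Returns the retained column names.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    df = features.df if isinstance(features, FeatureTable) else features
    cols = list(
        columns
        if columns is not None
        else (
            features.feature_columns
            if isinstance(features, FeatureTable)
            else [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        )
    )
    if len(cols) < 2:
        raise ValueError("need at least 2 numeric columns")
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    retained: list[str] = []
    for col in cols:
        x = df[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.warning("column %r is constant; excluded from redundancy filter", col)
            continue
        redundant = False
        for kept in retained:
            r = np.corrcoef(x, df[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) >= threshold:
                redundant = True
                break
        if not redundant:
            retained.append(col)
    return retained


def accessibility_table(
    structure: ComplexStructure,
    asa_complex: Mapping[ResidueId, float],
    asa_monomer: Mapping[ResidueId, float],
    max_asa: Mapping[str, float] | None = None,
) -> FeatureTable:
    """Assemble an accessibility feature table from per-residue ASA mappings."""
    max_asa = max_asa or load_max_asa()
    rows = []
    for rec in structure:
        rid = rec.id
        if rid not in asa_complex or rid not in asa_monomer:
            raise ConsistencyError(f"missing ASA value for {rid.label}")
        if rid.res_type not in max_asa:
            raise MatrixCoverageError(f"no max-ASA reference for type {rid.res_type}")
        rows.append(
            {
                "chain": rid.chain,
                "seq_num": rid.seq_num,
                "icode": rid.icode,
                "res_type": rid.res_type,
                "asa_complex": float(asa_complex[rid]),
                "asa_monomer": float(asa_monomer[rid]),
                "rel_asa_complex": relative_complex_asa(
                    float(asa_complex[rid]), max_asa[rid.res_type]
                ),
            }
        )
    return FeatureTable(pd.DataFrame(rows))
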