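"""Self-contained synthetic fixtures: toy complexes with planted hot regions.

The generator emulates the statistical structure the detection pipeline
assumes of real interface data:

* two chains whose non-interface-like bulk ("strand decoys") lies far from
  the partner chain, carrying low coordination numbers;
* ``n_regions`` planted hot regions at the inter-chain interface, each a
  compact cross-chain motif of 3-6 residues that is pairwise
  community-adjacent and tightly packed (all member pairs within the
  contact cutoff);
* hot-spot features drawn from a truncated model that respects the PPRA
  bounds exactly (pair potential >= threshold, relative ASA <= threshold),
  and decoy features guaranteed to violate at least one bound;
* every residue buries surface upon complexation (``asa_monomer`` >
  ``asa_complex``), mirroring interface-residue tables.

Planted members are arranged from sequence-adjacent pairs and triples (one
group per chain), with a "balancer" decoy residue packed against each
triple's middle member, so that all members of a region end up with the
same coordination number - the uniform tight packing that makes the
mean-coordination-number optimization a no-op on genuine hot spots. A
post-generation validator recomputes contacts and rejects any layout
(after jitter) that breaks pairwise adjacency or coordination uniformity;
generation retries with fresh jitter and fails after a bounded number of
attempts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .hotregion_pipeline import HotSpotLabel, PipelineConfig, assemble_hot_regions
from .residue_features import coordination_numbers, load_max_asa
from .structure_io import (
    STANDARD_RESIDUES,
    ComplexStructure,
    FeatureTable,
    ResidueId,
    ResidueRecord,
    write_ca_pdb,
    write_feature_table,
)

logger = logging.getLogger(__name__)

_CHAIN_LABELS = ("A", "B")
_REGION_GAP = 30.0  # angstrom between planted region centers
_STRAND_OFFSET = 12.0  # |y| of the strand far from the interface
_GROUP_OFFSET = 2.0  # |y| of a planted group from the interface midplane
_STEP = 3.8  # consecutive Calpha spacing along a strand
_MAX_ATTEMPTS = 25


class GenerationError(Exception):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic complex.

    ``decoy_count`` is the total number of non-hot residues (window
    entry/exit/balancer residues included); alternatively fix
    ``residues_per_chain`` and the decoy count is derived. Hot features:
    pair potential ~ Normal(mu_hot, sigma_hot) truncated at >= pp_threshold
    and relative ASA ~ Uniform(0, rasa_threshold). Decoy features fail at
    least one PPRA bound: pair potential truncated below the threshold, or
    relative ASA drawn above it.
    """

    n_chains: int = 2
    residues_per_chain: int | None = None
    n_regions: int = 2
    region_size: int = 5
    region_spread: float = 0.15  # jitter sigma on member coordinates (angstrom)
    decoy_count: int = 50
    mu_hot: float = 25.0
    sigma_hot: float = 4.0
    mu_decoy: float = 8.0
    sigma_decoy: float = 4.0
    pp_threshold: float = 18.0
    rasa_threshold: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains != 2:
            raise GenerationError("generator supports exactly 2 chains")
        if self.region_size < 3:
            raise GenerationError("region_size must be >= 3")
        if self.region_size > 6:
            raise GenerationError(
                "region_size > 6 cannot keep all members pairwise adjacent "
                "with two chains; use more regions instead"
            )
        if self.n_regions < 1:
            raise GenerationError("need at least one region")
        if self.region_spread < 0:
            raise GenerationError("region_spread must be >= 0")

    @property
    def n_hot(self) -> int:
        return self.n_regions * self.region_size


@dataclass
class SyntheticComplex:
    structure: ComplexStructure
    features: FeatureTable
    truth: list[HotSpotLabel]
    planted_regions: list[set[ResidueId]]
    spec: SyntheticSpec

    @property
    def hot_ids(self) -> set[ResidueId]:
        return {t.id for t in self.truth if t.is_hot}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit PDB + features CSV + truth CSV + planted-regions JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pdb": out / "complex.pdb",
            "features": out / "features.csv",
            "truth": out / "truth.csv",
            "regions": out / "regions.json",
        }
        write_ca_pdb(self.structure, paths["pdb"])
        write_feature_table(self.features, paths["features"])
        rows = [
            {
                "chain": t.id.chain,
                "seq_num": t.id.seq_num,
                "icode": t.id.icode,
                "res_type": t.id.res_type,
                "is_hot": int(t.is_hot),
                "ddg": f"{t.ddg:.6g}" if t.ddg is not None else "",
            }
            for t in self.truth
        ]
        pd.DataFrame(rows).to_csv(paths["truth"], index=False)
        paths["regions"].write_text(
            json.dumps(
                {
                    "n_regions": len(self.planted_regions),
                    "regions": [
                        sorted(r.label for r in region) for region in self.planted_regions
                    ],
                },
                indent=2,
            )
            + "\n"
        )
        return paths


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _direction_set() -> np.ndarray:
    dirs = []
    rng = range(-2, 3)
    for i in rng:
        for j in rng:
            for k in rng:
                if i == j == k == 0:
                    continue
                v = np.array([i, j, k], dtype=float)
                dirs.append(v / np.linalg.norm(v))
    uniq = np.unique(np.round(np.array(dirs), 6), axis=0)
    return uniq


_DIRS = _direction_set()


def _place_away(
    anchor: np.ndarray, r: float, avoid: list[np.ndarray], prefer: np.ndarray | None = None
) -> np.ndarray:
    """Point at distance r from anchor maximising the min distance to avoid."""
    best_pt, best_score = None, -np.inf
    for v in _DIRS:
        pt = anchor + r * v
        score = min((float(np.linalg.norm(pt - a)) for a in avoid), default=np.inf)
        if prefer is not None:
            score += 1e-3 * float(np.dot(v, prefer))  # deterministic tie-break
        if score > best_score:
            best_score, best_pt = score, pt
    assert best_pt is not None
    return best_pt


def _region_composition(size: int) -> list[tuple[int, str]]:
    """(chain index, kind) groups per region; at most one group per chain."""
    return {
        3: [(0, "triple")],
        4: [(0, "pair"), (1, "pair")],
        5: [(0, "triple"), (1, "pair")],
        6: [(0, "triple"), (1, "triple")],
    }[size]


def _group_geometry(kind: str, side: int, center: np.ndarray, rng, sigma: float):
    """Member and helper coordinates for one group.

    Returns (member_positions, window_builder) where window_builder
    produces the full sequence window [entry, members..., exit-or-balancer]
    once all members of the region are known (entry/balancer placement must
    avoid the other chain's members too).
    """
    y = side * _GROUP_OFFSET
    if kind == "pair":
        members = [
            center + np.array([-1.9, y, 0.0]),
            center + np.array([+1.9, y, 0.0]),
        ]
    else:  # triple
        members = [
            center + np.array([-1.9, y, 0.0]),
            center + np.array([0.0, y, 3.29]),
            center + np.array([+1.9, y, 0.0]),
        ]
    members = [m + rng.normal(0.0, sigma, size=3) for m in members]
    outward = np.array([0.0, float(side), 0.0])

    def build(all_members: list[np.ndarray]) -> list[np.ndarray]:
        others_first = [p for p in all_members if p is not members[0]]
        entry = _place_away(members[0], _STEP, others_first, prefer=outward)
        if kind == "pair":
            others_last = [p for p in all_members if p is not members[-1]]
            tail = _place_away(members[-1], _STEP, others_last, prefer=outward)
        else:
            # balancer: within the contact cutoff of the triple middle only
            avoid = [p for p in all_members if p is not members[1] and p is not members[2]]
            tail = _place_away(members[1], 6.0, avoid, prefer=outward + np.array([0, 0, 1.0]))
        return [entry, *members, tail]

    return members, build


def _random_restype(rng) -> str:
    return STANDARD_RESIDUES[int(rng.integers(len(STANDARD_RESIDUES)))]


def _truncated_normal(rng, mu: float, sigma: float, low=None, high=None) -> float:
    for _ in range(10_000):
        v = float(rng.normal(mu, sigma))
        if (low is None or v >= low) and (high is None or v < high):
            return v
    raise GenerationError("truncated-normal rejection sampling failed")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _build_geometry(spec: SyntheticSpec, rng):
    """Per-chain lists of (coordinate, role) plus planted member bookkeeping.

    role is "hot" for planted members, "decoy" otherwise.
    """
    comp = _region_composition(spec.region_size)
    # windows[chain] = list of (region index, [positions of window residues], member slice)
    windows: dict[int, list[tuple[int, list[np.ndarray], slice]]] = {0: [], 1: []}
    region_members: list[list[np.ndarray]] = []
    for r in range(spec.n_regions):
        center = np.array([r * _REGION_GAP, 0.0, 0.0])
        groups = []
        all_members: list[np.ndarray] = []
        for chain_idx, kind in comp:
            side = +1 if chain_idx == 0 else -1
            members, build = _group_geometry(kind, side, center, rng, spec.region_spread)
            groups.append((chain_idx, members, build))
            all_members.extend(members)
        region_members.append(all_members)
        for chain_idx, members, build in groups:
            window = build(all_members)
            windows[chain_idx].append((r, window, slice(1, 1 + len(members))))

    overhead = sum(
        len(w) - (sl.stop - sl.start) for ws in windows.values() for _, w, sl in ws
    )
    if spec.residues_per_chain is not None:
        total = spec.residues_per_chain * spec.n_chains
        strand_total = total - spec.n_hot - overhead
        if strand_total < 2:
            raise GenerationError(
                f"residues_per_chain={spec.residues_per_chain} too small for "
                f"{spec.n_hot} hot spots plus {overhead} window residues"
            )
    else:
        strand_total = spec.decoy_count - overhead
        if strand_total < 2:
            raise GenerationError(
                f"decoy_count={spec.decoy_count} too small: windows alone need "
                f"{overhead} decoy residues"
            )

    chains: list[list[tuple[np.ndarray, str]]] = []
    for chain_idx in range(spec.n_chains):
        share = strand_total // spec.n_chains + (
            1 if chain_idx < strand_total % spec.n_chains else 0
        )
        wins = windows[chain_idx]
        n_seg = len(wins) + 1
        seg = [share // n_seg] * n_seg
        for i in range(share % n_seg):
            seg[i] += 1
        y = _STRAND_OFFSET if chain_idx == 0 else -_STRAND_OFFSET
        residues: list[tuple[np.ndarray, str]] = []
        x_counter = 0

        def strand_run(count: int):
            nonlocal x_counter
            for _ in range(count):
                residues.append(
                    (np.array([x_counter * _STEP, y, 0.0]), "decoy")
                )
                x_counter += 1

        for i, (_, window, member_slice) in enumerate(wins):
            strand_run(seg[i])
            for j, pos in enumerate(window):
                role = "hot" if member_slice.start <= j < member_slice.stop else "decoy"
                residues.append((pos, role))
        strand_run(seg[-1])
        chains.append(residues)
    return chains, region_members


def _assemble(spec: SyntheticSpec, rng, name: str):
    chains, _ = _build_geometry(spec, rng)
    records: list[ResidueRecord] = []
    roles: dict[ResidueId, str] = {}
    for chain_idx, residues in enumerate(chains):
        chain = _CHAIN_LABELS[chain_idx]
        for i, (pos, role) in enumerate(residues, start=1):
            rid = ResidueId(
                chain=chain, seq_num=i, icode="", res_type=_random_restype(rng)
            )
            records.append(ResidueRecord(id=rid, ca=pos))
            roles[rid] = role
    structure = ComplexStructure(name, records)
    return structure, roles


def _planted_sets(structure: ComplexStructure, roles, spec: SyntheticSpec):
    """Recover planted region id sets from geometry (by x proximity to centers)."""
    regions: list[set[ResidueId]] = [set() for _ in range(spec.n_regions)]
    for rec in structure:
        if roles[rec.id] != "hot":
            continue
        r = int(np.argmin([abs(rec.ca[0] - i * _REGION_GAP) for i in range(spec.n_regions)]))
        regions[r].add(rec.id)
    return regions


def _validate(structure: ComplexStructure, regions, config: PipelineConfig) -> bool:
    coords = {rec.id: rec.ca for rec in structure}
    for region in regions:
        members = sorted(region)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if np.linalg.norm(coords[a] - coords[b]) > config.contact_cutoff:
                    return False
    cn = coordination_numbers(structure, cutoff=config.contact_cutoff)
    for region in regions:
        vals = {cn[m] for m in region}
        if len(vals) != 1:
            return False
    assembled = assemble_hot_regions(
        set().union(*regions), structure, config
    )
    if {frozenset(r) for r in regions} != {r.members for r in assembled}:
        return False
    return True


def generate_complex(spec: SyntheticSpec, name: str | None = None) -> SyntheticComplex:
    """Generate a synthetic complex with planted hot regions (deterministic).

    Layout attempts are validated by recomputing contacts and coordination
    numbers on the generated structure; jitter is resampled on failure and
    a :class:`GenerationError` is raised after a bounded number of retries.
    """
    config = PipelineConfig()
    name = name or f"synthetic-seed{spec.seed}"
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng((spec.seed, attempt))
        structure, roles = _assemble(spec, rng, name)
        regions = _planted_sets(structure, roles, spec)
        if all(len(r) == spec.region_size for r in regions) and _validate(
            structure, regions, config
        ):
            break
    else:
        raise GenerationError(
            f"could not realise a valid geometry in {_MAX_ATTEMPTS} attempts "
            f"(region_spread={spec.region_spread} too large?)"
        )

    max_asa = load_max_asa()
    rows = []
    truth: list[HotSpotLabel] = []
    for rec in structure:
        rid = rec.id
        hot = roles[rid] == "hot"
        if hot:
            pp = _truncated_normal(rng, spec.mu_hot, spec.sigma_hot, low=spec.pp_threshold)
            rasa = float(rng.uniform(0.0, spec.rasa_threshold))
            ddg = float(rng.uniform(2.0, 6.0))
        else:
            if rng.uniform() < 0.5:
                pp = _truncated_normal(
                    rng, spec.mu_decoy, spec.sigma_decoy, high=spec.pp_threshold
                )
                rasa = float(rng.uniform(0.0, 100.0))
            else:
                pp = float(rng.normal(spec.mu_decoy, spec.sigma_decoy))
                rasa = float(rng.uniform(spec.rasa_threshold, 100.0))
                if rasa <= spec.rasa_threshold:  # guard the open bound
                    rasa = np.nextafter(spec.rasa_threshold, 100.0)
            ddg = float(rng.uniform(0.0, 1.9))
        asa_complex = rasa / 100.0 * max_asa[rid.res_type]
        asa_monomer = asa_complex + float(rng.uniform(5.0, 30.0))
        rows.append(
            {
                "chain": rid.chain,
                "seq_num": rid.seq_num,
                "icode": rid.icode,
                "res_type": rid.res_type,
                "asa_monomer": asa_monomer,
                "asa_complex": asa_complex,
                "rel_asa_complex": rasa,
                "pair_potential": max(pp, 0.0) if hot else abs(pp),
            }
        )
        truth.append(HotSpotLabel(id=rid, is_hot=hot, ddg=ddg))

    features = FeatureTable(pd.DataFrame(rows))
    return SyntheticComplex(
        structure=structure,
        features=features,
        truth=truth,
        planted_regions=regions,
        spec=spec,
    )


def class_balance(obj, nonhot: int | None = None) -> str:
    """Hot:non-hot class ratio in "x.xx:1" form.

    Accepts either a :class:`SyntheticComplex` / iterable of
    :class:`HotSpotLabel`, or raw ``(hot, nonhot)`` counts.
    """
    if nonhot is not None:
        hot = int(obj)
        non = int(nonhot)
    else:
        labels = obj.truth if isinstance(obj, SyntheticComplex) else list(obj)
        hot = sum(1 for t in labels if t.is_hot)
        non = sum(1 for t in labels if not t.is_hot)
    if non == 0:
        raise ValueError("class balance needs at least one non-hot residue")
    return f"{hot / non:.2f}:1"


def class_ratio(hot: int, nonhot: int) -> float:
    """Numeric hot/non-hot ratio rounded to 2 decimals."""
    if nonhot == 0:
        raise ValueError("class ratio needs at least one non-hot residue")
    return round(hot / nonhot, 2)
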