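"""Hot-region detection pipeline.

Stages, in order:

1. interface residue selection (ASA drop upon complexation when monomer and
   complex ASA are available; otherwise a cross-chain Calpha proximity
   fallback);
2. silhouette-guided K-means over the interface residues' Calpha
   coordinates (or standardized feature vectors); clusters of at least
   ``min_region_size`` members form the first candidate set (RH1);
3. PPRA filtering: candidates are kept when their pair potential is
   >= 18.0 and their relative complex ASA is <= 20.0 % (both boundaries
   inclusive); interface residues outside the candidate set that satisfy
   both conditions and sit next to a surviving candidate are recovered
   (RH2);
4. coordination-number optimization (RCNO): candidates whose coordination
   number falls strictly below the candidate mean are removed;
5. spatial hot-region assembly: treating each residue as a ball, two hot
   spots belong to the same community when their Calpha distance is less
   than the sum of their radii plus a 2 angstrom harmonic distance;
   connected communities of three or more hot spots form hot regions.

Every stage records its membership in a :class:`StageTrace` so a run can
be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .clustering import ClusteringConfig, ClusteringError, PointSet, select_k
from .residue_features import CoordinationProfile, coordination_numbers
from .structure_io import ComplexStructure, FeatureTable, ResidueId, ResidueRecord, SchemaError

logger = logging.getLogger(__name__)

#: Default per-residue ball radius (angstrom) for the community rule.
DEFAULT_RESIDUE_RADIUS = 3.25


class PipelineError(Exception):
    pass


@dataclass
class PipelineConfig:
    """All tunable thresholds of the detection pipeline.

    ``ddg_hotspot_threshold`` (kcal/mol) defines a hot spot from alanine
    scanning energies; ``pp_threshold`` / ``rasa_threshold`` are the PPRA
    retention bounds; ``contact_cutoff`` and ``potential_cutoff`` are the
    Calpha distance cutoffs for contacts and pair-potential terms;
    ``harmonic_distance`` and the residue radii define community adjacency.
    """

    ddg_hotspot_threshold: float = 2.0
    pp_threshold: float = 18.0
    rasa_threshold: float = 20.0
    contact_cutoff: float = 6.5
    potential_cutoff: float = 7.0
    harmonic_distance: float = 2.0
    residue_radius: float = DEFAULT_RESIDUE_RADIUS
    residue_radius_table: dict[str, float] = field(default_factory=dict)
    min_region_size: int = 3
    rcno_factor: float = 1.0
    rcno_iterate: bool = False
    rcno_over_interface: bool = False
    ppra_recovery: bool = True
    cluster_space: str = "coords"  # "coords" | "features"
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)

    def __post_init__(self) -> None:
        for name in (
            "ddg_hotspot_threshold", "pp_threshold", "rasa_threshold",
            "contact_cutoff", "potential_cutoff", "harmonic_distance",
            "residue_radius",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")
        if self.min_region_size < 3:
            raise PipelineError("min_region_size must be >= 3")
        if self.cluster_space not in ("coords", "features"):
            raise PipelineError(f"unknown cluster_space {self.cluster_space!r}")

    def radius(self, res_type: str) -> float:
        return self.residue_radius_table.get(res_type, self.residue_radius)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "clustering" in d and isinstance(d["clustering"], Mapping):
            d["clustering"] = ClusteringConfig(**d["clustering"])
        return cls(**d)


@dataclass(frozen=True)
class HotSpotLabel:
    """Ground-truth annotation: hot iff ddg >= threshold when ddg is known."""

    id: ResidueId
    is_hot: bool
    ddg: float | None = None

    @classmethod
    def from_ddg(cls, rid: ResidueId, ddg: float, threshold: float = 2.0) -> "HotSpotLabel":
        return cls(id=rid, is_hot=ddg >= threshold, ddg=ddg)


@dataclass
class CandidateInfo:
    cluster: int | None = None
    pp: float | None = None
    rasa: float | None = None
    cn: int | None = None
    recovered: bool = False


@dataclass
class CandidateSet:
    """A stage's candidate hot spots with per-residue diagnostics."""

    stage: str
    members: dict[ResidueId, CandidateInfo]

    def ids(self) -> set[ResidueId]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self.members


@dataclass(frozen=True)
class HotRegion:
    """A connected community of >= min_region_size predicted hot spots."""

    members: frozenset
    mean_cn: float
    size: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "size", len(self.members))


@dataclass
class StageTrace:
    """Residue membership after every pipeline stage, for auditability."""

    stages: list[tuple[str, list[str]]] = field(default_factory=list)

    def record(self, stage: str, ids: Iterable[ResidueId]) -> None:
        self.stages.append((stage, sorted(r.label for r in ids)))

    def counts(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in self.stages}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {name: ids for name, ids in self.stages}, indent=2
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


# ---------------------------------------------------------------------------
# Community adjacency and hot-region assembly
# ---------------------------------------------------------------------------

def community_adjacent(
    a: ResidueRecord, b: ResidueRecord, config: PipelineConfig | None = None
) -> bool:
    """True when two residues' balls overlap within the harmonic distance.

    Strictly: dist(a, b) < radius(a) + radius(b) + harmonic_distance.
    """
    cfg = config or PipelineConfig()
    limit = cfg.radius(a.id.res_type) + cfg.radius(b.id.res_type) + cfg.harmonic_distance
    return float(np.linalg.norm(a.ca - b.ca)) < limit


def _adjacency_matrix(
    records: Sequence[ResidueRecord], config: PipelineConfig
) -> np.ndarray:
    coords = np.array([r.ca for r in records])
    radii = np.array([config.radius(r.id.res_type) for r in records])
    d = cdist(coords, coords)
    limit = radii[:, None] + radii[None, :] + config.harmonic_distance
    adj = d < limit
    np.fill_diagonal(adj, False)
    return adj


def assemble_hot_regions(
    hot_spots: Iterable[ResidueId],
    structure: ComplexStructure,
    config: PipelineConfig | None = None,
    cn_profile: CoordinationProfile | None = None,
) -> list[HotRegion]:
    """Group predicted hot spots into hot regions by community connectivity.

    Connected components of the community-adjacency graph restricted to the
    hot spots; components smaller than ``min_region_size`` are discarded.
    Regions are ordered by size descending, then by their lexicographically
    smallest member.
    """
    cfg = config or PipelineConfig()
    ids = sorted(set(hot_spots))
    if not ids:
        return []
    records = [structure.get(r) for r in ids]
    adj = _adjacency_matrix(records, cfg)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    regions: list[HotRegion] = []
    for comp in range(n_comp):
        members = [ids[i] for i in range(len(ids)) if labels[i] == comp]
        if len(members) < cfg.min_region_size:
            continue
        mean_cn = (
            float(np.mean([cn_profile[m] for m in members])) if cn_profile else float("nan")
        )
        regions.append(HotRegion(members=frozenset(members), mean_cn=mean_cn))
    regions.sort(key=lambda r: (-r.size, min(r.members)))
    return regions


# ---------------------------------------------------------------------------
# Interface residues
# ---------------------------------------------------------------------------

def interface_residues(
    structure: ComplexStructure,
    features: FeatureTable | None = None,
    config: PipelineConfig | None = None,
) -> list[ResidueId]:
    """Residues taking part in the interface.

    Default definition: residues whose ASA decreases upon complexation
    (``asa_monomer - asa_complex > 0``) when both columns are available.
    Fallback: residues within ``contact_cutoff`` of any residue on another
    chain. Single-chain structures return all residues.
    """
    cfg = config or PipelineConfig()
    if features is not None and {"asa_monomer", "asa_complex"} <= set(features.df.columns):
        out = []
        for rid in features.ids():
            if features.value(rid, "asa_monomer") - features.value(rid, "asa_complex") > 0:
                out.append(structure.get(rid).id)
        return out
    chains = structure.chains
    if len(chains) < 2:
        return structure.ids()
    coords = structure.coords()
    ids = structure.ids()
    chain_arr = np.array([r.chain for r in ids])
    d = cdist(coords, coords)
    cross = chain_arr[:, None] != chain_arr[None, :]
    near = (d <= cfg.contact_cutoff) & cross
    return [ids[i] for i in range(len(ids)) if near[i].any()]


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def cluster_candidates(
    structure: ComplexStructure,
    features: FeatureTable,
    config: PipelineConfig | None = None,
    interface: Sequence[ResidueId] | None = None,
):
    """Cluster interface residues and keep clusters of viable region size (RH1).

    Returns ``(candidates, diagnostics)`` where diagnostics is the per-k
    (k, wcss, asw) table from the silhouette scan (``None`` on the
    degenerate three-residue path, which skips k selection and treats all
    residues as a single candidate cluster).
    """
    cfg = config or PipelineConfig()
    iface = list(interface) if interface is not None else interface_residues(structure, features, cfg)
    if len(iface) < 3:
        raise PipelineError(
            f"need at least 3 interface residues to cluster, got {len(iface)}"
        )
    iface = sorted(iface)  # canonical order: invariant to input shuffling
    if len(iface) == 3:
        members = {rid: CandidateInfo(cluster=0) for rid in iface}
        return CandidateSet(stage="RH1", members=members), None

    if cfg.cluster_space == "coords":
        pts = np.array([structure.get(r).ca for r in iface])
    else:
        cols = [
            c for c in features.feature_columns
            if c not in ("asa_monomer", "asa_complex")
        ]
        if not cols:
            raise SchemaError("no feature columns available for feature-space clustering")
        mat = np.array([[features.value(r, c) for c in cols] for r in iface])
        std = mat.std(axis=0)
        std[std == 0] = 1.0
        pts = (mat - mat.mean(axis=0)) / std

    cfg_clu = cfg.clustering
    if cfg_clu.k_max >= len(iface):
        from dataclasses import replace

        cfg_clu = replace(cfg_clu, k_max=len(iface) - 1)
    result, _, diagnostics = select_k(PointSet(pts, ids=iface), cfg_clu)
    members: dict[ResidueId, CandidateInfo] = {}
    for cluster_idx in range(result.k):
        cluster_ids = [iface[i] for i in np.flatnonzero(result.assignments == cluster_idx)]
        if len(cluster_ids) < cfg.min_region_size:
            continue
        for rid in cluster_ids:
            members[rid] = CandidateInfo(cluster=int(cluster_idx))
    return CandidateSet(stage="RH1", members=members), diagnostics


def _passes_ppra(pp: float, rasa: float, cfg: PipelineConfig) -> bool:
    return pp >= cfg.pp_threshold and rasa <= cfg.rasa_threshold


def ppra_filter(
    candidates: CandidateSet,
    features: FeatureTable,
    structure: ComplexStructure,
    config: PipelineConfig | None = None,
    interface: Sequence[ResidueId] | None = None,
) -> CandidateSet:
    """Pair-potential / relative-ASA filtering with neighbour recovery (RH2).

    Removal: candidates with PP < pp_threshold or relative complex ASA >
    rasa_threshold are dropped (both retention boundaries inclusive).
    Recovery: interface residues outside the candidate set that satisfy
    both conditions and are community-adjacent to a surviving candidate are
    added; recovery is closed transitively (a recovered residue can carry
    recovery onward), which makes the filter idempotent.
    """
    cfg = config or PipelineConfig()
    features.require(["pair_potential", "rel_asa_complex"])
    iface = list(interface) if interface is not None else interface_residues(structure, features, cfg)

    def pp_of(rid: ResidueId) -> float:
        return features.value(rid, "pair_potential")

    def rasa_of(rid: ResidueId) -> float:
        return features.value(rid, "rel_asa_complex")

    survivors: dict[ResidueId, CandidateInfo] = {}
    for rid, info in candidates.members.items():
        pp, rasa = pp_of(rid), rasa_of(rid)
        if _passes_ppra(pp, rasa, cfg):
            survivors[rid] = CandidateInfo(
                cluster=info.cluster, pp=pp, rasa=rasa, recovered=info.recovered
            )

    if cfg.ppra_recovery and survivors:
        eligible = {
            rid for rid in iface
            if rid not in survivors and _passes_ppra(pp_of(rid), rasa_of(rid), cfg)
        }
        frontier = list(survivors)
        recs = {rid: structure.get(rid) for rid in set(eligible) | set(survivors)}
        while frontier:
            nxt = []
            for cand in list(eligible):
                if any(
                    community_adjacent(recs[cand], recs[s], cfg) for s in frontier
                ):
                    survivors[cand] = CandidateInfo(
                        pp=pp_of(cand), rasa=rasa_of(cand), recovered=True
                    )
                    eligible.discard(cand)
                    nxt.append(cand)
            frontier = nxt

    return CandidateSet(stage="RH2", members=survivors)


def rcno_filter(
    candidates: CandidateSet,
    cn: CoordinationProfile,
    config: PipelineConfig | None = None,
    interface: Sequence[ResidueId] | None = None,
) -> CandidateSet:
    """Residue coordination-number optimization.

    Removes candidates whose coordination number is strictly below
    ``rcno_factor`` times the mean coordination number of the current
    candidates (or of all interface residues with ``rcno_over_interface``).
    Single pass by default; ``rcno_iterate`` repeats to a fixed point.
    """
    cfg = config or PipelineConfig()
    if not candidates.members:
        logger.warning("rcno_filter called with an empty candidate set")
        return CandidateSet(stage="RCNO", members={})
    missing = [r.label for r in candidates.members if r not in cn.cn]
    if missing:
        raise PipelineError(f"coordination profile missing candidates: {missing}")

    members = dict(candidates.members)
    while True:
        pool = list(interface) if cfg.rcno_over_interface and interface else list(members)
        mean_cn = cn.mean(pool)
        threshold = cfg.rcno_factor * mean_cn
        kept = {rid: info for rid, info in members.items() if cn[rid] >= threshold}
        removed = len(members) - len(kept)
        members = kept
        if not cfg.rcno_iterate or removed == 0 or not members:
            break
    for rid, info in members.items():
        info.cn = cn[rid]
    return CandidateSet(stage="RCNO", members=members)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_rcnoik(
    structure: ComplexStructure,
    features: FeatureTable,
    config: PipelineConfig | None = None,
    use_ppra: bool = True,
    use_rcno: bool = True,
) -> tuple[list[HotRegion], StageTrace, "pd.DataFrame | None"]:
    """Run the full detection pipeline.

    Stage order: interface selection -> silhouette-guided clustering (RH1)
    -> PPRA filter with recovery (RH2) -> coordination-number optimization
    -> spatial hot-region assembly. Returns the hot regions, the per-stage
    membership trace, and the per-k clustering diagnostic table.
    """
    cfg = config or PipelineConfig()
    trace = StageTrace()
    iface = interface_residues(structure, features, cfg)
    trace.record("interface", iface)

    candidates, diagnostics = cluster_candidates(
        structure, features, cfg, interface=iface
    )
    trace.record("RH1", candidates.ids())

    if use_ppra:
        candidates = ppra_filter(candidates, features, structure, cfg, interface=iface)
        trace.record("RH2", candidates.ids())

    cn = coordination_numbers(structure, cutoff=cfg.contact_cutoff)
    if use_rcno:
        candidates = rcno_filter(candidates, cn, cfg, interface=iface)
        trace.record("RCNO", candidates.ids())

    regions = assemble_hot_regions(candidates.ids(), structure, cfg, cn_profile=cn)
    trace.record("final", [rid for reg in regions for rid in reg.members])
    logger.info("pipeline stage counts: %s", trace.counts())
    return regions, trace, diagnostics
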