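"""Population-graph construction from pairwise clinical similarity.

Each patient is a node carrying an image-derived feature vector; an edge
connects two patients when a clinical similarity score — combined from four
component scores over demographics (sex + age), tumour lobe, histology and
pTNM sub-stage — reaches a connection threshold, and the score becomes the
edge weight.

Default scheme (all component weights 1):

* demographics = 1[same sex] + age kernel (1 for a gap <= 5 years, 0.5 for
  a gap <= 10 years, 0 beyond), so its maximum is 2;
* location / histology / stage = 1[same category];
* combination rule ``sum`` (range [0, 5], default threshold 2.0) or
  ``product`` (range [0, 2]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .records import PatientRecord, SPLITS, STAGE_ORDINAL

COMBINE_RULES = ("sum", "product")


class SimilarityConfigError(ValueError):
    pass


class GraphBuildError(ValueError):
    pass


@dataclass
class SimilarityConfig:
    w_sex: float = 1.0
    w_age: float = 1.0
    w_location: float = 1.0
    w_histology: float = 1.0
    w_stage: float = 1.0
    age_full_credit: float = 5.0   # years; full age credit at or below this gap
    age_half_credit: float = 10.0  # years; half credit at or below this gap
    rule: str = "sum"
    threshold: float = 2.0

    def validate(self) -> "SimilarityConfig":
        if self.rule not in COMBINE_RULES:
            raise SimilarityConfigError(f"unknown rule {self.rule!r}; use one of {COMBINE_RULES}")
        if not 0 < self.age_full_credit <= self.age_half_credit:
            raise SimilarityConfigError("need 0 < age_full_credit <= age_half_credit")
        return self


@dataclass(frozen=True)
class ComponentScores:
    demographics: float
    location: float
    histology: float
    stage: float

    def combine(self, rule: str = "sum") -> float:
        v = (self.demographics, self.location, self.histology, self.stage)
        if rule == "sum":
            return float(sum(v))
        if rule == "product":
            return float(np.prod(v))
        raise SimilarityConfigError(f"unknown rule {rule!r}")


def _age_kernel(gap: float, cfg: SimilarityConfig) -> float:
    if gap <= cfg.age_full_credit:
        return 1.0
    if gap <= cfg.age_half_credit:
        return 0.5
    return 0.0


def component_scores(a: PatientRecord, b: PatientRecord,
                     cfg: Optional[SimilarityConfig] = None) -> ComponentScores:
    """The four clinical agreement scores for one unordered patient pair."""
    cfg = (cfg or SimilarityConfig()).validate()
    demo = cfg.w_sex * (a.sex == b.sex) + cfg.w_age * _age_kernel(abs(a.age - b.age), cfg)
    return ComponentScores(
        demographics=float(demo),
        location=float(cfg.w_location * (a.lobe == b.lobe)),
        histology=float(cfg.w_histology * (a.histology == b.histology)),
        stage=float(cfg.w_stage * (a.stage == b.stage)),
    )


def similarity(a: PatientRecord, b: PatientRecord,
               cfg: Optional[SimilarityConfig] = None) -> float:
    cfg = (cfg or SimilarityConfig()).validate()
    return component_scores(a, b, cfg).combine(cfg.rule)


@dataclass
class PopulationGraph:
    """Patients as nodes (canonically ordered by id), clinical-similarity edges.

    ``edges`` holds each undirected edge once as (i, j, weight) with i < j.
    Survival endpoint arrays are carried along so transductive training can
    take the graph as its single input.
    """

    node_ids: List[str]
    features: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_weight: np.ndarray
    masks: Dict[str, np.ndarray]
    os_time: np.ndarray
    os_event: np.ndarray
    rfs_time: np.ndarray
    rfs_event: np.ndarray
    records: List[PatientRecord] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return self.edge_i.size

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise GraphBuildError(f"unknown node id {node_id!r}") from None

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency (no self-loops), CSR."""
        n = self.n_nodes
        i = np.concatenate([self.edge_i, self.edge_j])
        j = np.concatenate([self.edge_j, self.edge_i])
        w = np.concatenate([self.edge_weight, self.edge_weight])
        return sp.csr_matrix((w, (i, j)), shape=(n, n))

    def normalized_adjacency(self) -> sp.csr_matrix:
        """Row-normalized adjacency: row v sums to 1 (all-zero for isolated v)."""
        a = self.adjacency()
        deg = np.asarray(a.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        return sp.diags(inv) @ a

    def neighbours(self, idx: int) -> Tuple[np.ndarray, np.ndarray]:
        """(neighbour indices, edge weights) of node ``idx``."""
        sel_i = self.edge_i == idx
        sel_j = self.edge_j == idx
        nbr = np.concatenate([self.edge_j[sel_i], self.edge_i[sel_j]])
        w = np.concatenate([self.edge_weight[sel_i], self.edge_weight[sel_j]])
        return nbr, w

    def survival(self, endpoint: str) -> Tuple[np.ndarray, np.ndarray]:
        if endpoint == "OS":
            return self.os_time, self.os_event
        if endpoint == "RFS":
            return self.rfs_time, self.rfs_event
        raise GraphBuildError(f"unknown endpoint {endpoint!r}")


def _pairwise_similarity_matrix(records: Sequence[PatientRecord],
                                cfg: SimilarityConfig) -> np.ndarray:
    """Vectorized all-pairs similarity (n x n, diagonal meaningless)."""
    age = np.array([r.age for r in records])
    sex = np.array([r.sex for r in records])
    lobe = np.array([r.lobe for r in records])
    hist = np.array([r.histology for r in records])
    stage = np.array([r.stage for r in records])

    gap = np.abs(age[:, None] - age[None, :])
    age_k = np.where(gap <= cfg.age_full_credit, 1.0,
                     np.where(gap <= cfg.age_half_credit, 0.5, 0.0))
    demo = cfg.w_sex * (sex[:, None] == sex[None, :]) + cfg.w_age * age_k
    loc = cfg.w_location * (lobe[:, None] == lobe[None, :])
    his = cfg.w_histology * (hist[:, None] == hist[None, :])
    stg = cfg.w_stage * (stage[:, None] == stage[None, :])

    if cfg.rule == "sum":
        return demo + loc + his + stg
    return demo * loc * his * stg


def build_graph(records: Sequence[PatientRecord], features: np.ndarray,
                cfg: Optional[SimilarityConfig] = None) -> PopulationGraph:
    """Score all pairs and connect those at or above ``cfg.threshold``.

    Nodes are ordered canonically by id, so the graph is invariant to the
    order in which records arrive.
    """
    cfg = (cfg or SimilarityConfig()).validate()
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != len(records):
        raise GraphBuildError(
            f"feature matrix rows ({features.shape}) do not align with {len(records)} records"
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GraphBuildError(f"duplicated patient ids: {dupes}")

    order = np.argsort(np.array(ids))
    records = [records[k] for k in order]
    features = features[order]
    ids = [r.id for r in records]

    sim = _pairwise_similarity_matrix(records, cfg)
    iu, ju = np.triu_indices(len(records), k=1)
    keep = sim[iu, ju] >= cfg.threshold
    edge_i, edge_j, w = iu[keep], ju[keep], sim[iu, ju][keep]

    splits = [r.split for r in records]
    if all(s is not None for s in splits):
        masks = {s: np.array([r.split == s for r in records]) for s in SPLITS}
    else:
        masks = {}

    return PopulationGraph(
        node_ids=ids,
        features=features,
        edge_i=edge_i.astype(np.int64),
        edge_j=edge_j.astype(np.int64),
        edge_weight=w.astype(float),
        masks=masks,
        os_time=np.array([r.os_time for r in records]),
        os_event=np.array([r.os_event for r in records]),
        rfs_time=np.array([r.rfs_time for r in records]),
        rfs_event=np.array([r.rfs_event for r in records]),
        records=list(records),
    )


@dataclass(frozen=True)
class NeighbourProfile:
    """Edge-weight summary of one node's neighbourhood by risk class.

    Medians are None (flagged undefined) when the class is absent among
    the neighbours.
    """

    node_id: str
    n_neighbours: int
    median_weight_high: Optional[float]
    median_weight_low: Optional[float]


def neighbour_profile(g: PopulationGraph, node_id: str,
                      risk_labels: Sequence[str]) -> NeighbourProfile:
    """Median edge weight to high- vs low-risk neighbours of one node.

    ``risk_labels`` gives 'high'/'low' per node in graph order.
    """
    idx = g.index_of(node_id)
    labels = np.asarray(risk_labels)
    if labels.shape != (g.n_nodes,):
        raise GraphBuildError("risk_labels must have one label per node")
    nbr, w = g.neighbours(idx)
    med = {}
    for cls in ("high", "low"):
        sel = labels[nbr] == cls
        med[cls] = float(np.median(w[sel])) if sel.any() else None
    return NeighbourProfile(node_id, int(nbr.size), med["high"], med["low"])


# --------------------------------------------------------------------------
# Edge-list / feature-matrix serialization

def write_graph(g: PopulationGraph, edges_path, features_path=None) -> None:
    with open(edges_path, "w") as fh:
        fh.write("id_a\tid_b\tweight\n")
        for i, j, w in zip(g.edge_i, g.edge_j, g.edge_weight):
            fh.write(f"{g.node_ids[i]}\t{g.node_ids[j]}\t{w:.10g}\n")
    if features_path is not None:
        header = "\t".join(g.node_ids)
        np.savetxt(features_path, g.features, delimiter="\t", header=header)


def read_edge_list(path) -> List[Tuple[str, str, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "id_a\tid_b\tweight":
            raise GraphBuildError(f"unexpected edge-list header: {header!r}")
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            out.append((a, b, float(w)))
    return out
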