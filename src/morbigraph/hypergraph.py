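"""Weighted multimorbidity hypergraphs.

Nodes are diseases; hyperedges are the *observed exact multimorbidity
profiles* of size >= 2 — the unique combinations of study diseases carried by
at least one person and no others under consideration.  This edge universe
keeps the exact-profile strata non-overlapping (each multimorbid person
feeds exactly one edge), which is what the exact-set HRU weighting needs,
and avoids the exponential blow-up of enumerating all co-occurring subsets.

Three weighting schemes:

``prevalence_overlap``
    node weight  w^N_i = |X_i| / P   (disease prevalence),
    edge weight  w^E_a = |X_i ∩ X_j ∩ ... ∩ X_l| / min(|X_i|, ..., |X_l|)
    (the generalised overlap coefficient; the numerator counts persons
    carrying *all* members, other diseases permitted).
``outpatient_hru`` / ``inpatient_hru``
    node and edge weights are directly age-standardised event rates per
    100,000 people over exact-profile strata (singleton profiles for nodes,
    by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agestd import AgeStandard, esp2013, standardized_rate
from .catalogue import DiseaseCatalogue, DiseaseSet
from .cohort import Cohort, OUTCOME_COLS

__all__ = [
    "SCHEMES", "WeightedHypergraph",
    "enumerate_edges", "prevalence_node_weights", "overlap_coefficient",
    "hru_weights", "build_hypergraph", "write_hypergraph", "read_hypergraph",
]

logger = logging.getLogger(__name__)

SCHEMES = ("prevalence_overlap", "outpatient_hru", "inpatient_hru")
SCHEME_OUTCOME = {"outpatient_hru": OUTCOME_COLS[0], "inpatient_hru": OUTCOME_COLS[1]}


def _profile_keys(flags: np.ndarray) -> np.ndarray:
    """Bit-pack each person's flag row into one int64 key."""
    d = flags.shape[1]
    if d > 62:
        raise ValueError("more than 62 diseases not supported by the bit-packed keys")
    powers = (np.int64(1) << np.arange(d, dtype=np.int64))
    return flags.astype(np.int64) @ powers


def _key_to_set(key: int, catalogue: DiseaseCatalogue) -> DiseaseSet:
    members = tuple(catalogue.names[j] for j in range(len(catalogue)) if key >> j & 1)
    return DiseaseSet(members)


def _set_to_key(ds: DiseaseSet, catalogue: DiseaseCatalogue) -> int:
    return int(sum(1 << catalogue.index(m) for m in ds.members))


@dataclass
class WeightedHypergraph:
    """Nodes, exact-profile edges, weights and per-edge support counts.

    ``n_exact`` counts persons whose exact profile equals the edge;
    ``n_all`` counts persons carrying every member (supersets included),
    the numerator of the overlap coefficient.  Edges are sorted by
    (size, canonical label) so construction is order-deterministic.
    """

    catalogue: DiseaseCatalogue
    edges: tuple[DiseaseSet, ...]
    node_weights: np.ndarray
    edge_weights: np.ndarray
    n_exact: np.ndarray
    n_all: np.ndarray
    scheme: str
    node_support: np.ndarray = field(default=None)  # persons per node stratum

    def __post_init__(self) -> None:
        E, d = len(self.edges), len(self.catalogue)
        self.node_weights = np.asarray(self.node_weights, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        self.n_exact = np.asarray(self.n_exact, dtype=np.int64)
        self.n_all = np.asarray(self.n_all, dtype=np.int64)
        if self.node_weights.shape != (d,) or self.edge_weights.shape != (E,):
            raise ValueError("weight vectors misaligned with nodes/edges")
        if any(e.size < 2 for e in self.edges):
            raise ValueError("every hyperedge needs >= 2 members")
        if len(set(self.edges)) != E:
            raise ValueError("duplicate edges")
        if not (np.all(np.isfinite(self.node_weights)) and np.all(self.node_weights >= 0)
                and np.all(np.isfinite(self.edge_weights)) and np.all(self.edge_weights >= 0)):
            raise ValueError("weights must be finite and non-negative")
        if np.any(self.n_exact > self.n_all):
            raise ValueError("n_exact cannot exceed n_all")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_labels(self) -> list[str]:
        return [e.label for e in self.edges]

    def edge_sizes(self) -> np.ndarray:
        return np.array([e.size for e in self.edges], dtype=np.int64)

    def incidence(self) -> np.ndarray:
        """Binary node x edge incidence matrix M."""
        M = np.zeros((len(self.catalogue), self.n_edges), dtype=np.int8)
        for a, e in enumerate(self.edges):
            for m in e.members:
                M[self.catalogue.index(m), a] = 1
        return M

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "disease": list(self.catalogue.names),
            "node_weight": self.node_weights,
            "stratum_persons": (self.node_support if self.node_support is not None
                                else np.full(len(self.catalogue), -1)),
        })

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "disease_set": self.edge_labels(),
            "size": self.edge_sizes(),
            "n_exact": self.n_exact,
            "n_all": self.n_all,
            "edge_weight": self.edge_weights,
        })


def enumerate_edges(cohort: Cohort):
    """Unique exact profiles of size >= 2 with their support counts.

    Returns ``(edges, n_exact, n_all, keys)`` with edges sorted by
    (size, canonical label).  ``n_all`` is computed by a bitwise subset
    scan over the unique observed profiles.
    """
    keys = _profile_keys(cohort.flags)
    ukeys, counts = np.unique(keys, return_counts=True)
    sizes = np.bitwise_count(ukeys.astype(np.uint64)).astype(np.int64)
    edge_mask = sizes >= 2
    ekeys = ukeys[edge_mask]
    n_exact = counts[edge_mask]
    if ekeys.size == 0:
        logger.warning("no person carries >= 2 study diseases; edge list is empty")
        return (), np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.int64)
    # n_all: total count over unique profiles that are supersets of the edge
    n_all = np.zeros(ekeys.size, dtype=np.int64)
    chunk = 256
    for s in range(0, ekeys.size, chunk):
        ek = ekeys[s:s + chunk]
        superset = (ukeys[:, None] & ek[None, :]) == ek[None, :]
        n_all[s:s + chunk] = counts @ superset
    edges = [_key_to_set(int(k), cohort.catalogue) for k in ekeys]
    order = sorted(range(len(edges)), key=lambda i: (edges[i].size, edges[i].label))
    edges = tuple(edges[i] for i in order)
    return edges, n_exact[order], n_all[order], ekeys[order]


def prevalence_node_weights(cohort: Cohort) -> np.ndarray:
    """w^N_i = |X_i| / P: fraction of the whole cohort carrying disease i."""
    if cohort.n == 0:
        raise ValueError("prevalence weights of an empty cohort are undefined")
    return cohort.carriers() / cohort.n


def overlap_coefficient(edge, cohort: Cohort) -> float:
    """Generalised overlap coefficient of a disease set.

    Fraction of the rarest member's carriers who carry every member;
    errors when any member has no carrier (undefined denominator).
    """
    ds = cohort.catalogue.validate_set(edge)
    idx = [cohort.catalogue.index(m) for m in ds.members]
    carriers = cohort.flags[:, idx]
    per = carriers.sum(axis=0, dtype=np.int64)
    if np.any(per == 0):
        zero = [ds.members[j] for j in np.flatnonzero(per == 0)]
        raise ValueError(f"overlap coefficient undefined: no carriers of {zero}")
    inter = int(np.all(carriers == 1, axis=1).sum())
    return inter / int(per.min())


def hru_weights(cohort: Cohort, outcome_column: str, edge_keys: np.ndarray,
                standard: AgeStandard | None = None,
                node_stratum: str = "exact_singleton"):
    """Age-standardised rates per 100,000 over exact-profile strata.

    Edge weight for set S: rate over persons whose exact profile equals S.
    Node weight for disease i: rate over exact-singleton carriers of i
    (default), or over all carriers with ``node_stratum='all_carriers'``.
    An empty stratum gets weight 0 with a logged warning.
    """
    standard = standard or esp2013(min_age=20)
    counts = cohort.outcome(outcome_column)
    keys = _profile_keys(cohort.flags)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]

    def stratum_indices(key: int) -> np.ndarray:
        lo = np.searchsorted(sorted_keys, key, side="left")
        hi = np.searchsorted(sorted_keys, key, side="right")
        return order[lo:hi]

    def rate_of(idx: np.ndarray, what: str) -> float:
        if idx.size == 0:
            logger.warning("empty stratum for %s; weight set to 0", what)
            return 0.0
        return standardized_rate(counts[idx], cohort.ages[idx], standard)

    edge_w = np.array([
        rate_of(stratum_indices(int(k)), f"edge key {int(k)}") for k in edge_keys
    ])
    d = cohort.n_diseases
    node_w = np.empty(d)
    node_support = np.empty(d, dtype=np.int64)
    for j, name in enumerate(cohort.catalogue.names):
        if node_stratum == "exact_singleton":
            idx = stratum_indices(1 << j)
        elif node_stratum == "all_carriers":
            idx = np.flatnonzero(cohort.flags[:, j] == 1)
        else:
            raise ValueError(f"unknown node_stratum {node_stratum!r}")
        node_support[j] = idx.size
        node_w[j] = rate_of(idx, f"disease {name!r}")
    return node_w, edge_w, node_support


def build_hypergraph(cohort: Cohort, scheme: str,
                     standard: AgeStandard | None = None,
                     node_stratum: str = "exact_singleton") -> WeightedHypergraph:
    """Build one weighted hypergraph; the edge list depends only on profiles,
    so the three schemes share it on a given cohort."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    edges, n_exact, n_all, ekeys = enumerate_edges(cohort)
    node_support = None
    if scheme == "prevalence_overlap":
        node_w = prevalence_node_weights(cohort)
        carriers = cohort.carriers()
        edge_w = np.empty(len(edges))
        for a, e in enumerate(edges):
            idx = [cohort.catalogue.index(m) for m in e.members]
            edge_w[a] = n_all[a] / carriers[idx].min() if len(edges) else 0.0
        node_support = carriers
    else:
        node_w, edge_w, node_support = hru_weights(
            cohort, SCHEME_OUTCOME[scheme], ekeys, standard, node_stratum
        )
    return WeightedHypergraph(cohort.catalogue, edges, node_w, edge_w,
                              n_exact, n_all, scheme, node_support=node_support)


def write_hypergraph(h: WeightedHypergraph, nodes_path, edges_path) -> None:
    h.node_frame().to_csv(nodes_path, index=False, float_format="%.12g")
    h.edge_frame().to_csv(edges_path, index=False, float_format="%.12g")


def read_hypergraph(nodes_path, edges_path, scheme: str) -> WeightedHypergraph:
    """Round-trip reader for the two-CSV serialisation."""
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    cat = DiseaseCatalogue(tuple(nodes["disease"]))
    edge_sets = tuple(DiseaseSet.from_label(s) for s in edges["disease_set"])
    return WeightedHypergraph(
        cat, edge_sets,
        nodes["node_weight"].to_numpy(float),
        edges["edge_weight"].to_numpy(float),
        edges["n_exact"].to_numpy(np.int64),
        edges["n_all"].to_numpy(np.int64),
        scheme,
        node_support=nodes["stratum_persons"].to_numpy(np.int64),
    )
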