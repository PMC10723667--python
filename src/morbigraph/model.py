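"""Model / Results interface for disease-set centrality with bootstrap CIs.

`HypergraphCentrality` is the statsmodels-style entry point: construct it
from a cohort (or a raw dataframe) and a weighting scheme, call
:meth:`~HypergraphCentrality.fit` and get a :class:`CentralityResults`
holding the full-cohort ("point") centralities together with bootstrap
means and percentile confidence intervals.

The bootstrap resamples *persons* with replacement, cohort-sized, and
reruns the whole cohort -> hypergraph -> dual-centrality pipeline per
replicate.  Replicates are aligned by canonical disease-set string; a set
absent from a replicate's edge list contributes centrality 0 there, which
makes the zero-crossing discard rule behave correctly for rare sets: a set
carried by very few people misses enough replicates that its 2.5th
percentile hits zero and the set is dropped.  Per-replicate seeds derive
from the master seed and the replicate counter, so any replicate is
reproducible in isolation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .agestd import AgeStandard, esp2013
from .catalogue import DiseaseCatalogue
from .cohort import Cohort, merge_disease_pairs
from .centrality import PowerIterationError, dual_adjacency, eigenvector_centrality
from .hypergraph import SCHEMES, WeightedHypergraph, build_hypergraph

__all__ = ["HypergraphCentrality", "CentralityResults",
           "bootstrap_centrality", "filter_zero_ci"]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["disease_set", "size", "n_exact", "n_all", "edge_weight",
                 "point_centrality", "boot_mean", "ci_lower", "ci_upper",
                 "n_replicates_present", "retained"]


def _edge_centrality(h: WeightedHypergraph, tol: float, max_iter: int,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Dual centrality of a built hypergraph; one perturbed-start retry on
    non-convergence (then the error propagates)."""
    adj = dual_adjacency(h)
    try:
        return eigenvector_centrality(adj, tol=tol, max_iter=max_iter).values
    except PowerIterationError:
        start = 1.0 + (rng.random(adj.n) if rng is not None else
                       np.linspace(0.0, 0.5, adj.n))
        logger.warning("power iteration did not converge; retrying with perturbed start")
        return eigenvector_centrality(adj, tol=tol, max_iter=max_iter, start=start).values


class HypergraphCentrality:
    """Disease-set importance model for one weighting scheme.

    Parameters
    ----------
    cohort : Cohort
        Merged, validated cohort (apply :func:`merge_disease_pairs` first if
        the catalogue carries a merge map; :meth:`from_dataframe` does both).
    scheme : str
        One of ``prevalence_overlap``, ``outpatient_hru``, ``inpatient_hru``.
    age_standard : AgeStandard, optional
        Standard population for the HRU schemes; ESP 2013 restricted to ages
        20+ by default.
    node_stratum : str
        ``"exact_singleton"`` (default) or ``"all_carriers"`` — the stratum
        used for HRU node weights.

    Examples
    --------
    >>> model = HypergraphCentrality(cohort, scheme="outpatient_hru")
    >>> res = model.fit(n_boot=50, seed=7)
    >>> res.retained.head()
    """

    def __init__(self, cohort: Cohort, scheme: str = "prevalence_overlap",
                 age_standard: AgeStandard | None = None,
                 node_stratum: str = "exact_singleton"):
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
        self.cohort = cohort
        self.scheme = scheme
        self.age_standard = age_standard or esp2013(min_age=20)
        self.node_stratum = node_stratum
        self._hypergraph: WeightedHypergraph | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, catalogue: DiseaseCatalogue,
                       scheme: str = "prevalence_overlap", **kwargs) -> "HypergraphCentrality":
        """Validate a raw person-level table, apply the catalogue's disease-pair
        merge, and build the model."""
        cohort = merge_disease_pairs(Cohort.from_dataframe(df, catalogue), catalogue)
        return cls(cohort, scheme=scheme, **kwargs)

    @property
    def hypergraph(self) -> WeightedHypergraph:
        if self._hypergraph is None:
            self._hypergraph = build_hypergraph(
                self.cohort, self.scheme, self.age_standard, self.node_stratum
            )
        return self._hypergraph

    def fit(self, n_boot: int = 100, seed: int | None = None,
            tol: float = 1e-10, max_iter: int = 10_000) -> "CentralityResults":
        """Point centralities plus an ``n_boot``-replicate percentile bootstrap.

        ``n_boot`` must be >= 2.  ``seed`` drives the person resampling;
        identical (cohort, scheme, n_boot, seed) reproduce the table exactly.
        """
        table = bootstrap_centrality(
            self.cohort, self.scheme, n_boot, seed,
            age_standard=self.age_standard, node_stratum=self.node_stratum,
            tol=tol, max_iter=max_iter, hypergraph=self.hypergraph,
        )
        return CentralityResults(self, table, n_boot=n_boot, seed=seed)


class CentralityResults:
    """Bootstrap centrality table plus convenience views.

    ``table`` columns: disease_set, size, n_exact, n_all, edge_weight,
    point_centrality, boot_mean, ci_lower (2.5th percentile), ci_upper
    (97.5th), n_replicates_present, retained.  Rows sorted by descending
    boot_mean.  ``retained`` is True where ci_lower > 0; the study's
    discard rule drops everything else.
    """

    def __init__(self, model: HypergraphCentrality, table: pd.DataFrame,
                 n_boot: int, seed: int | None):
        self.model = model
        self.scheme = model.scheme
        self.table = table
        self.n_boot = n_boot
        self.seed = seed

    @property
    def retained(self) -> pd.DataFrame:
        return filter_zero_ci(self.table)

    @property
    def n_discarded(self) -> int:
        return int((~self.table["retained"]).sum())

    def scatter_data(self) -> pd.DataFrame:
        """(disease_set, size, boot_mean) triples for centrality scatters."""
        return self.table[["disease_set", "size", "boot_mean"]].copy()

    def summary(self, top: int = 10) -> str:
        t = self.table
        lines = [
            "Disease-set dual eigenvector centrality",
            "=" * 55,
            f"scheme:               {self.scheme}",
            f"cohort size:          {self.model.cohort.n}",
            f"disease sets (edges): {len(t)}",
            f"bootstrap replicates: {self.n_boot}  (seed {self.seed})",
            f"retained (CI > 0):    {int(t['retained'].sum())}"
            f"  discarded: {self.n_discarded}",
            "",
            f"Top {min(top, len(t))} retained sets by bootstrap mean centrality:",
        ]
        view = self.retained.head(top)[
            ["disease_set", "size", "n_exact", "boot_mean", "ci_lower", "ci_upper"]
        ]
        lines.append(view.to_string(index=False,
                                    float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<CentralityResults scheme={self.scheme!r} sets={len(self.table)} "
                f"n_boot={self.n_boot}>")


def bootstrap_centrality(cohort: Cohort, scheme: str, n_boot: int,
                         seed: int | None = None, *,
                         age_standard: AgeStandard | None = None,
                         node_stratum: str = "exact_singleton",
                         tol: float = 1e-10, max_iter: int = 10_000,
                         hypergraph: WeightedHypergraph | None = None) -> pd.DataFrame:
    """Whole-pipeline percentile bootstrap of disease-set centrality.

    Returns the CentralityResults table (see :class:`CentralityResults`).
    Every set appearing in the full cohort or any replicate gets a row.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    seed = 0 if seed is None else int(seed)
    h0 = hypergraph or build_hypergraph(cohort, scheme, age_standard, node_stratum)
    if h0.n_edges >= 2:
        point = _edge_centrality(h0, tol, max_iter)
    else:
        point = np.zeros(h0.n_edges)

    index: dict[str, int] = {lab: i for i, lab in enumerate(h0.edge_labels())}
    sizes: dict[str, int] = {e.label: e.size for e in h0.edges}
    rows: list[np.ndarray] = []        # per-replicate centralities, aligned
    present: list[np.ndarray] = []     # per-replicate presence indicators

    def grow(n_new: int) -> None:
        for k in range(len(rows)):
            rows[k] = np.pad(rows[k], (0, n_new))
            present[k] = np.pad(present[k], (0, n_new))

    for r in range(n_boot):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, cohort.n, size=cohort.n)
        sub = cohort.take(idx)
        h = build_hypergraph(sub, scheme, age_standard, node_stratum)
        vals = np.zeros(len(index))
        pres = np.zeros(len(index), dtype=bool)
        if h.n_edges >= 2:
            cent = _edge_centrality(h, tol, max_iter, rng=rng)
        else:
            cent = np.zeros(h.n_edges)
        new = [e.label for e in h.edges if e.label not in index]
        if new:
            grow(len(new))
            vals = np.pad(vals, (0, len(new)))
            pres = np.pad(pres, (0, len(new)))
            for lab in new:
                index[lab] = len(index)
            for e in h.edges:
                sizes.setdefault(e.label, e.size)
        for a, e in enumerate(h.edges):
            i = index[e.label]
            vals[i] = cent[a]
            pres[i] = True
        rows.append(vals)
        present.append(pres)

    K = len(index)
    mat = np.vstack([np.pad(v, (0, K - v.size)) for v in rows])
    pres_mat = np.vstack([np.pad(p, (0, K - p.size)) for p in present])
    boot_mean = mat.mean(axis=0)
    ci_lower = np.percentile(mat, 2.5, axis=0)
    ci_upper = np.percentile(mat, 97.5, axis=0)

    labels = [None] * K
    for lab, i in index.items():
        labels[i] = lab
    n0 = h0.n_edges
    point_full = np.zeros(K)
    point_full[:n0] = point
    n_exact = np.zeros(K, dtype=np.int64)
    n_all = np.zeros(K, dtype=np.int64)
    edge_w = np.zeros(K)
    n_exact[:n0] = h0.n_exact
    n_all[:n0] = h0.n_all
    edge_w[:n0] = h0.edge_weights

    table = pd.DataFrame({
        "disease_set": labels,
        "size": [sizes[lab] for lab in labels],
        "n_exact": n_exact,
        "n_all": n_all,
        "edge_weight": edge_w,
        "point_centrality": point_full,
        "boot_mean": boot_mean,
        "ci_lower": ci_lower,
        "ci_upper": ci_upper,
        "n_replicates_present": pres_mat.sum(axis=0),
        "retained": ci_lower > 0,
    })
    table = table.sort_values(["boot_mean", "disease_set"],
                              ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


def filter_zero_ci(table: pd.DataFrame) -> pd.DataFrame:
    """Discard sets whose lower 95% confidence bound touches zero.

    A set whose 2.5th-percentile centrality is <= 0 (including exactly 0)
    is indistinguishable from unimportant; in practice this removes sets
    carried by small numbers of individuals.
    """
    kept = table[table["ci_lower"] > 0].reset_index(drop=True)
    logger.info("discarded %d of %d sets with CI touching zero",
                len(table) - len(kept), len(table))
    return kept
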