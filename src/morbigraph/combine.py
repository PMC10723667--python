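"""Composite importance across hypergraphs.

Sets that matter both for prevalence and for resource use are found by (i)
keeping the sets whose centrality is strictly above the median in *every*
component hypergraph, then (ii) scoring survivors by the Euclidean
combination sqrt(sum of squared component centralities), with each component
max-normalised first so the combination is scale-free.  Components are
weighted equally by default; an optional weight vector is exposed for
tailoring (weights scale components before squaring).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .catalogue import DiseaseSet

__all__ = [
    "median_filter", "euclidean_combine", "top_sets",
    "disease_appearance_summary", "ImportanceResults", "combine_importance",
]

logger = logging.getLogger(__name__)


def _as_retained_series(table) -> pd.Series:
    """boot_mean indexed by disease_set, retained rows only."""
    if hasattr(table, "retained") and not isinstance(table, pd.DataFrame):
        table = table.retained  # CentralityResults
    elif isinstance(table, pd.DataFrame) and "retained" in table.columns:
        table = table[table["retained"]]
    return table.set_index("disease_set")["boot_mean"]


def median_filter(tables: list) -> list[str]:
    """Sets strictly above the median retained centrality in every table.

    Accepts CentralityResults or their tables; a set missing from any table
    is excluded regardless of the others.  Empty intersections warn.
    """
    if len(tables) < 2:
        raise ValueError("median filter needs at least two centrality tables")
    survivor_sets = []
    for t in tables:
        s = _as_retained_series(t)
        med = s.median()
        survivor_sets.append(set(s.index[s > med]))
    common = set.intersection(*survivor_sets)
    if not common:
        warnings.warn("median filter left no common disease set", stacklevel=2)
    return sorted(common)


def euclidean_combine(components: pd.DataFrame,
                      weights: np.ndarray | None = None) -> pd.DataFrame:
    """Composite = sqrt(sum of squared (optionally weighted) components).

    ``components``: one row per disease set (index = canonical label), one
    column per scheme; all rows must be present for every column (mismatched
    set lists error).  Returns the table with ``size``, ``composite`` and
    deterministic ``rank`` columns, sorted by rank.
    """
    if components.isna().any().any():
        bad = components.index[components.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"mismatched set lists; missing components for {bad}")
    X = components.to_numpy(dtype=float)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (X.shape[1],):
            raise ValueError("one weight per component column required")
        X = X * weights[None, :]
    out = components.copy()
    out["size"] = [DiseaseSet.from_label(lab).size for lab in out.index]
    out["composite"] = np.sqrt((X**2).sum(axis=1))
    # deterministic order: descending composite, ties to smaller set then label
    order = sorted(range(len(out)),
                   key=lambda i: (-out["composite"].iloc[i], out["size"].iloc[i],
                                  out.index[i]))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_sets(table: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """First ``k`` rows by composite rank; warns when k exceeds the table."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(table):
        warnings.warn(f"requested top {k} of only {len(table)} sets", stacklevel=2)
    return table.head(k).copy()


def disease_appearance_summary(top: pd.DataFrame, catalogue=None) -> pd.DataFrame:
    """How often each single disease appears among the listed sets.

    Returns (disease, count, percent) with percentages relative to the
    number of listed sets; catalogue diseases absent from every set get 0.
    """
    if len(top) == 0:
        raise ValueError("appearance summary of an empty slice")
    labels = list(top.index if top.index.dtype == object else top["disease_set"])
    counts: dict[str, int] = {}
    if catalogue is not None:
        counts = {name: 0 for name in catalogue.names}
    for lab in labels:
        for m in DiseaseSet.from_label(lab).members:
            counts[m] = counts.get(m, 0) + 1
    out = pd.DataFrame({
        "disease": list(counts),
        "count": list(counts.values()),
    })
    out["percent"] = 100.0 * out["count"] / len(labels)
    return out.sort_values(["count", "disease"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)


class ImportanceResults:
    """Composite importance table over median-filter survivors.

    ``table``: index = canonical disease-set label; one max-normalised
    centrality column per component scheme, plus size, composite, rank.
    """

    def __init__(self, table: pd.DataFrame, component_labels: tuple[str, ...],
                 catalogue=None):
        self.table = table
        self.component_labels = component_labels
        self.catalogue = catalogue

    def top(self, k: int = 100) -> pd.DataFrame:
        return top_sets(self.table, k)

    def appearance_summary(self, k: int | None = None) -> pd.DataFrame:
        """Single-disease appearance counts; over the whole retained table by
        default, or over the top-``k`` slice."""
        view = self.table if k is None else self.top(k)
        return disease_appearance_summary(view, self.catalogue)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Composite disease-set importance (Euclidean combination)",
            "=" * 58,
            f"components: {', '.join(self.component_labels)}",
            f"sets above median in all components: {len(self.table)}",
            "",
            f"Top {min(top, len(self.table))} sets:",
            self.table.head(top).to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<ImportanceResults components={self.component_labels} "
                f"sets={len(self.table)}>")


def combine_importance(results: dict, weights=None) -> ImportanceResults:
    """Median-filter + Euclidean-combine a mapping of scheme -> results.

    ``results`` maps scheme label to a CentralityResults (or its table).
    Each component is restricted to the common above-median survivors and
    max-normalised before combination.
    """
    labels = tuple(results)
    if len(labels) < 2:
        raise ValueError("need at least two component hypergraphs")
    survivors = median_filter(list(results.values()))
    catalogue = None
    for r in results.values():
        if hasattr(r, "model"):
            catalogue = r.model.cohort.catalogue
            break
    comp = pd.DataFrame(index=pd.Index(survivors, name="disease_set"))
    for lab, r in results.items():
        s = _as_retained_series(r).reindex(survivors)
        peak = s.max()
        comp[lab] = s / peak if peak and peak > 0 else s
    table = euclidean_combine(comp, weights=weights)
    return ImportanceResults(table, labels, catalogue)
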