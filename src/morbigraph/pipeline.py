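"""End-to-end pipeline: simulate/ingest -> build -> bootstrap -> combine -> report.

All randomness flows from a single master seed; rerunning with the same
configuration and seed produces byte-identical CSVs, recorded in a manifest
with per-file content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalogue import DiseaseCatalogue
from .cohort import Cohort, merge_disease_pairs, read_cohort, write_cohort
from .combine import combine_importance
from .hypergraph import SCHEMES, build_hypergraph, write_hypergraph
from .model import HypergraphCentrality
from .simulate import SimulationConfig, default_config, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "FIXTURES"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML-loadable."""

    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    catalogue: DiseaseCatalogue | None = None  # required with cohort_path
    schemes: tuple[str, ...] = SCHEMES
    n_boot: int = 100
    seed: int = 0
    top_k: int = 100
    outdir: str = "morbigraph_out"
    log_level: str = "INFO"
    composites: tuple[tuple[str, ...], ...] = field(default=None)

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one scheme required")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.simulation is None and self.cohort_path is None:
            raise ValueError("either a simulation config or a cohort path is required")
        if self.composites is None:
            hru = [s for s in self.schemes if s != "prevalence_overlap"]
            pairs = [("prevalence_overlap", h) for h in hru
                     if "prevalence_overlap" in self.schemes]
            self.composites = tuple(pairs) + (
                (tuple(self.schemes),) if len(self.schemes) > 2 else ()
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.get("simulation")
        cat = d.get("catalogue")
        return cls(
            simulation=None if sim is None else SimulationConfig.from_dict(sim),
            cohort_path=d.get("cohort_path"),
            catalogue=None if cat is None else DiseaseCatalogue(
                tuple(cat["names"]),
                tuple(tuple(m) for m in cat.get("merge_map", ())),
            ),
            schemes=tuple(d.get("schemes", SCHEMES)),
            n_boot=int(d.get("n_boot", 100)),
            seed=int(d.get("seed", 0)),
            top_k=int(d.get("top_k", 100)),
            outdir=d.get("outdir", "morbigraph_out"),
            log_level=d.get("log_level", "INFO"),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        _write(df, path, index=index)
        written.append(path)
        counts[name] = len(df)

    # stage 1: cohort
    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": config.seed})
            cohort = generate_cohort(sim)
            write_cohort(cohort, outdir / "cohort.csv")
            written.append(outdir / "cohort.csv")
            counts["cohort.csv"] = cohort.n
        else:
            if config.catalogue is None:
                raise ValueError("a catalogue is required to read a cohort file")
            cohort = read_cohort(config.cohort_path, config.catalogue)
            cohort = merge_disease_pairs(cohort, config.catalogue)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cohort' failed: {exc}") from exc

    # stages 2-4: build, bootstrap, filter — per scheme
    results = {}
    for scheme in config.schemes:
        try:
            model = HypergraphCentrality(cohort, scheme=scheme)
            h = model.hypergraph
            write_hypergraph(h, outdir / f"nodes_{scheme}.csv",
                             outdir / f"edges_{scheme}.csv")
            written += [outdir / f"nodes_{scheme}.csv", outdir / f"edges_{scheme}.csv"]
            counts[f"edges_{scheme}.csv"] = h.n_edges
            res = model.fit(n_boot=config.n_boot, seed=config.seed)
            results[scheme] = res
            emit(res.table, f"bootstrap_{scheme}.csv")
            emit(res.retained, f"centrality_{scheme}.csv")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'bootstrap[{scheme}]' failed: {exc}") from exc

    # stage 5: combine + report
    for combo in config.composites:
        if not all(s in results for s in combo):
            continue
        tag = "_".join(_short(s) for s in combo)
        try:
            imp = combine_importance({s: results[s] for s in combo})
        except ValueError as exc:
            logger.warning("composite %s skipped: %s", tag, exc)
            continue
        emit(imp.table.reset_index(), f"importance_{tag}.csv")
        if len(imp.table):
            app = imp.appearance_summary()
            topk = imp.top(min(config.top_k, len(imp.table))).reset_index()
        else:  # keep the schema stable even when nothing survives the filter
            app = pd.DataFrame(columns=["disease", "count", "percent"])
            topk = imp.table.reset_index()
        emit(app, f"appearances_{tag}.csv")
        emit(topk, f"top{config.top_k}_{tag}.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "schemes": list(config.schemes),
        "n_boot": config.n_boot,
        "row_counts": counts,
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _short(scheme: str) -> str:
    return {"prevalence_overlap": "prev", "outpatient_hru": "outp",
            "inpatient_hru": "inp"}[scheme]


# ---------------------------------------------------------------------------
# Hand-checkable fixtures


def _fixture_cohort(profiles: list[tuple[str, ...]], diseases: tuple[str, ...]) -> Cohort:
    cat = DiseaseCatalogue(diseases)
    flags = np.zeros((len(profiles), len(diseases)), dtype=np.int8)
    for i, prof in enumerate(profiles):
        for m in prof:
            flags[i, cat.index(m)] = 1
    ages = np.full(len(profiles), 50)
    ones = np.ones(len(profiles), dtype=np.int64)
    return Cohort(flags, ages, ones, ones, cat,
                  person_id=np.array([f"F{i}" for i in range(len(profiles))]))


def _toy5():
    cohort = _fixture_cohort(
        [("A", "B"), ("A", "B"), ("A", "B", "C"), ("A",), ("C",)],
        ("A", "B", "C"),
    )
    expected = {
        "edges": {"A&B": {"n_exact": 2, "n_all": 3}, "A&B&C": {"n_exact": 1, "n_all": 1}},
        "overlap": {"A&B": 1.0, "A&B&C": 0.5},  # |A|=4,|B|=3,|C|=2
        "prevalence": {"A": 0.8, "B": 0.6, "C": 0.4},
    }
    return cohort, expected


def _path():
    # 2x{A,B}, 2x{B,C}, 2x{C,D}: symmetric counts make the dual adjacency a
    # uniformly weighted 3-edge path, whose leading eigenvector is
    # (1/sqrt(2), 1, 1/sqrt(2)).
    cohort = _fixture_cohort(
        [("A", "B")] * 2 + [("B", "C")] * 2 + [("C", "D")] * 2,
        ("A", "B", "C", "D"),
    )
    s = 1.0 / np.sqrt(2.0)
    expected = {"centrality": {"A&B": s, "B&C": 1.0, "C&D": s}}
    return cohort, expected


def _empty_multimorbidity():
    cohort = _fixture_cohort([("A",), ("B",), (), ()], ("A", "B", "C"))
    return cohort, {"edges": {}}


FIXTURES = {
    "toy5": _toy5,
    "path": _path,
    "empty-multimorbidity": _empty_multimorbidity,
}


def make_fixture(name: str):
    """A tiny hand-checkable cohort plus its expected outputs."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
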