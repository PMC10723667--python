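"""Disease catalogues and canonical disease sets.

Nodes of every hypergraph are diseases drawn from a fixed, ordered catalogue
(by default the Elixhauser chronic-condition categories).  Hyperedges are
*disease sets*: sorted, duplicate-free tuples of catalogue labels with a
canonical ``"&"``-joined string form, e.g. ``"Diabetes&Hypertension"``.

Closely related condition pairs (a condition and its "with complication"
variant, cancer and metastatic cancer) would co-occur almost by construction
and induce spurious clustering, so the catalogue carries a merge map that
collapses each pair into a single flag via logical OR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DiseaseSet",
    "DiseaseCatalogue",
    "elixhauser_catalogue",
    "ELIXHAUSER_MERGE_MAP",
]

SET_SEPARATOR = "&"


@dataclass(frozen=True, order=True)
class DiseaseSet:
    """A non-empty, canonically sorted set of disease labels."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("a disease set needs at least one member")
        canon = tuple(sorted(self.members))
        if len(set(canon)) != len(canon):
            raise ValueError(f"duplicate members in disease set: {self.members}")
        object.__setattr__(self, "members", canon)

    @classmethod
    def from_label(cls, label: str) -> "DiseaseSet":
        return cls(tuple(label.split(SET_SEPARATOR)))

    @property
    def label(self) -> str:
        return SET_SEPARATOR.join(self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, disease: str) -> bool:
        return disease in self.members

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class DiseaseCatalogue:
    """Ordered disease labels plus the pair-merge map.

    Parameters
    ----------
    names
        Ordered, unique disease labels (the flag columns of a cohort table).
    merge_map
        Triples ``(source_a, source_b, merged_name)``.  Applying the map
        replaces the two source flags by their logical OR under
        ``merged_name``.  Sources must be disjoint across pairs.
    """

    names: tuple[str, ...]
    merge_map: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "merge_map", tuple(tuple(m) for m in self.merge_map))
        if len(set(names)) != len(names):
            raise ValueError("catalogue names must be unique")
        sources: list[str] = []
        for a, b, merged in self.merge_map:
            if a not in names or b not in names:
                raise ValueError(f"merge sources {a!r}/{b!r} not in catalogue")
            sources += [a, b]
            survivors = [n for n in names if n not in (a, b)]
            if merged in survivors:
                raise ValueError(f"merged name {merged!r} collides with an existing disease")
        if len(set(sources)) != len(sources):
            raise ValueError("merge sources must be disjoint")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def merged(self) -> "DiseaseCatalogue":
        """Catalogue after applying the merge map (empty map on the result)."""
        names = list(self.names)
        for a, b, merged in self.merge_map:
            names[names.index(a)] = merged
            names.remove(b)
        return DiseaseCatalogue(tuple(names))

    def validate_set(self, members) -> DiseaseSet:
        ds = members if isinstance(members, DiseaseSet) else DiseaseSet(tuple(members))
        unknown = [m for m in ds.members if m not in self.names]
        if unknown:
            raise ValueError(f"diseases not in catalogue: {unknown}")
        return ds


# Elixhauser-derived study catalogue.  The three merge pairs collapse
# condition/complication variants that would otherwise pseudocluster.
_ELIXHAUSER_PREMERGE = (
    "Hypertension",
    "Hypertension with Complication",
    "Diabetes",
    "Diabetes with Complication",
    "Depression",
    "COPD",
    "Cancer",
    "Metastatic Cancer",
    "Renal Disease",
    "Obesity",
    "Arrythmia",
    "Other Neurological Disorders",
    "Hypothyroidism",
    "Deficiency Anaemia",
    "Congestive heart failure",
    "Fluid & Electrolyte Disorders",
    "Weight Loss",
    "Valvular Disease",
    "Peripheral Vascular Disease",
    "Rheumatoid Arthritis",
    "Peptic Ulcer",
    "Liver Disease",
    "Pulmonary Circulation Disorder",
    "Paralysis",
    "Drug Abuse",
    "Psychosis",
    "Coagulopathy",
    "Lymphoma",
    "Blood loss anaemia",
)

ELIXHAUSER_MERGE_MAP = (
    ("Cancer", "Metastatic Cancer", "Any Cancer"),
    ("Diabetes", "Diabetes with Complication", "Diabetes"),
    ("Hypertension", "Hypertension with Complication", "Hypertension"),
)


def elixhauser_catalogue(merged: bool = True) -> DiseaseCatalogue:
    """The Elixhauser-derived study catalogue.

    With ``merged=True`` (default) returns the 26-disease post-merge
    catalogue; otherwise the 29-flag pre-merge catalogue carrying the
    three-pair merge map.
    """
    pre = DiseaseCatalogue(_ELIXHAUSER_PREMERGE, ELIXHAUSER_MERGE_MAP)
    return pre.merged() if merged else pre
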