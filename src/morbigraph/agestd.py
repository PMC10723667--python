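"""Direct age standardisation against a standard population.

Healthcare-resource-use weights are expressed as age-standardised rates per
100,000 people: within a stratum (the people carrying an exact disease set),
age-band-specific crude rates are averaged with the standard population's
band weights.  Bands are half-open ``[lower, upper)`` with an open-ended top
band, so band membership is unambiguous at the boundaries.

The shipped standard is the European Standard Population 2013 (Eurostat,
revision of the 1976 ESP; weights per 5-year band summing to 100,000).
Adult analyses use :func:`esp2013` with ``min_age=20``, which keeps the
published band weights and renormalises over occupied bands at computation
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgeStandard", "ESP_2013", "esp2013", "assign_age_band", "standardized_rate"]

PER = 100_000.0


@dataclass(frozen=True)
class AgeStandard:
    """Contiguous half-open age bands with positive standard weights.

    ``lowers`` are the ascending band lower bounds; each band ends where the
    next begins and the last band is open-ended.
    """

    name: str
    lowers: tuple[int, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        lowers = tuple(int(x) for x in self.lowers)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "lowers", lowers)
        object.__setattr__(self, "weights", weights)
        if len(lowers) != len(weights) or not lowers:
            raise ValueError("lowers and weights must be equal-length, non-empty")
        if any(b <= a for a, b in zip(lowers, lowers[1:])):
            raise ValueError("band lower bounds must be strictly increasing")
        if any(w <= 0 for w in weights):
            raise ValueError("standard weights must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.lowers)

    @property
    def bands(self) -> tuple[tuple[int, int | None, float], ...]:
        """(lower, upper-or-None, weight) triples; upper is exclusive."""
        uppers = self.lowers[1:] + (None,)
        return tuple(zip(self.lowers, uppers, self.weights))

    def labels(self) -> list[str]:
        return [
            f"{lo}-{hi - 1}" if hi is not None else f"{lo}+"
            for lo, hi, _ in self.bands
        ]

    def band_index(self, ages) -> np.ndarray:
        """Vectorised band assignment; errors on ages below the first band."""
        ages = np.asarray(ages)
        if ages.size and ages.min() < self.lowers[0]:
            bad = int(ages.min())
            raise ValueError(
                f"age {bad} below the lowest band (starts at {self.lowers[0]})"
            )
        return np.searchsorted(np.asarray(self.lowers), ages, side="right") - 1

    def restricted(self, min_age: int) -> "AgeStandard":
        keep = [i for i, lo in enumerate(self.lowers) if lo >= min_age]
        if not keep:
            raise ValueError("no bands at or above min_age")
        return AgeStandard(
            f"{self.name}[{min_age}+]",
            tuple(self.lowers[i] for i in keep),
            tuple(self.weights[i] for i in keep),
        )


# European Standard Population 2013, 5-year bands, weights sum to 100,000.
ESP_2013 = AgeStandard(
    name="ESP2013",
    lowers=tuple(range(0, 95, 5)),
    weights=(
        5000, 5500, 5500, 5500, 6000, 6000, 6500, 7000, 7000, 7000,
        7000, 6500, 6000, 5500, 5000, 4000, 2500, 1500, 1000,
    ),
)


def esp2013(min_age: int | None = None) -> AgeStandard:
    """ESP 2013, optionally restricted to bands starting at ``min_age``."""
    return ESP_2013 if min_age is None else ESP_2013.restricted(min_age)


def assign_age_band(age_years: int, standard: AgeStandard) -> int:
    """Index of the half-open band containing ``age_years``."""
    return int(standard.band_index(np.asarray([age_years]))[0])


def standardized_rate(outcome_counts, ages, standard: AgeStandard,
                      renormalise: bool = True) -> float:
    """Directly age-standardised event rate per 100,000 people.

    Band-specific crude rates (events per person) are averaged with the
    standard weights.  By default the weights are renormalised over the
    bands actually occupied by the stratum, so a small stratum is not
    penalised for empty age bands; ``renormalise=False`` divides by the
    full weight total instead.

    Raises ``ValueError`` on an empty stratum (the rate is undefined).
    """
    counts = np.asarray(outcome_counts, dtype=float)
    ages = np.asarray(ages)
    if counts.size == 0:
        raise ValueError("standardized_rate is undefined for an empty stratum")
    if counts.shape != ages.shape:
        raise ValueError("outcome_counts and ages must have equal length")
    band = standard.band_index(ages)
    nb = standard.n_bands
    persons = np.bincount(band, minlength=nb).astype(float)
    events = np.bincount(band, weights=counts, minlength=nb)
    occupied = persons > 0
    w = np.asarray(standard.weights, dtype=float)
    rates = np.zeros(nb)
    rates[occupied] = events[occupied] / persons[occupied]
    denom = w[occupied].sum() if renormalise else w.sum()
    return float(PER * (w[occupied] @ rates[occupied]) / denom)
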