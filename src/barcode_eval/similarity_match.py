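"""Best Match / Best Close Match species identification.

Leave-one-out over every sequence in a distance matrix: each query is
classified by the species of the samples attaining its minimum defined
distance (the query itself is never a candidate):

* CORRECT    — all best matches are conspecific with the query,
* AMBIGUOUS  — the best-match set contains the query's species and others,
* INCORRECT  — the best-match set excludes the query's species,
* NO_MATCH   — (Best Close Match only) the best distance exceeds the
  threshold.

The Best Close Match threshold is the empirical 95th percentile of all
defined intraspecific distances: the smallest observed distance v such that
at least 95% of intraspecific distances are <= v (no interpolation).

Singleton species must be deleted beforehand (every query needs at least one
conspecific candidate); queries with no defined distance to any candidate
are excluded from the percentage denominator and listed in the report.
Distances are compared exactly: they are deterministic functions of site
counts, so exact ties are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .errors import StageError

__all__ = [
    "Category",
    "MatchVerdict",
    "BCMThreshold",
    "MatchReport",
    "bcm_threshold",
    "best_match",
    "best_close_match",
]


class Category(str, Enum):
    CORRECT = "CORRECT"
    AMBIGUOUS = "AMBIGUOUS"
    INCORRECT = "INCORRECT"
    NO_MATCH = "NO_MATCH"


@dataclass(frozen=True)
class MatchVerdict:
    query: str
    species: str
    best_distance: float
    best_match_species: frozenset[str]
    category: Category


@dataclass(frozen=True)
class BCMThreshold:
    value: float
    n_intra_pairs: int


@dataclass
class MatchReport:
    method: str  # "BM" | "BCM"
    verdicts: list[MatchVerdict]
    excluded: list[str] = field(default_factory=list)  # queries w/o defined distances

    def count(self, category: Category) -> int:
        return sum(v.category is category for v in self.verdicts)

    def pct(self, category: Category) -> float:
        if not self.verdicts:
            raise StageError("match report has no classified queries")
        return 100.0 * self.count(category) / len(self.verdicts)

    @property
    def pct_correct(self) -> float:
        return self.pct(Category.CORRECT)

    @property
    def pct_ambiguous(self) -> float:
        return self.pct(Category.AMBIGUOUS)

    @property
    def pct_incorrect(self) -> float:
        return self.pct(Category.INCORRECT)

    @property
    def pct_no_match(self) -> float:
        return self.pct(Category.NO_MATCH)

    def summary(self) -> dict[str, float]:
        out = {
            "method": self.method,
            "n_queries": len(self.verdicts),
            "n_excluded": len(self.excluded),
            "pct_correct": self.pct_correct,
            "pct_ambiguous": self.pct_ambiguous,
            "pct_incorrect": self.pct_incorrect,
        }
        if self.method == "BCM":
            out["pct_no_match"] = self.pct_no_match
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    v.query,
                    v.species,
                    v.best_distance,
                    ";".join(sorted(v.best_match_species)),
                    v.category.value,
                )
                for v in self.verdicts
            ],
            columns=["query", "species", "best_distance", "best_species_set", "category"],
        )


def bcm_threshold(dm: DistanceMatrix) -> BCMThreshold:
    """Empirical 95th percentile of defined intraspecific distances.

    Smallest observed value covering at least 95% of the intraspecific
    distances, computed by rank (no interpolation).
    """
    intra = np.sort(dm.intra_distances())
    if intra.size == 0:
        raise StageError("BCM threshold needs at least one intraspecific pair")
    rank = math.ceil(0.95 * intra.size)
    return BCMThreshold(value=float(intra[rank - 1]), n_intra_pairs=int(intra.size))


def _check_no_singletons(dm: DistanceMatrix) -> None:
    counts: dict[str, int] = {}
    for sp in dm.species:
        counts[sp] = counts.get(sp, 0) + 1
    singles = sorted(sp for sp, n in counts.items() if n < 2)
    if singles:
        raise StageError(
            "singleton species must be deleted before BM/BCM: "
            + ", ".join(singles)
        )


def _classify(dm: DistanceMatrix, threshold: float | None) -> MatchReport:
    if dm.n < 2:
        raise StageError("matching needs at least 2 records")
    _check_no_singletons(dm)
    method = "BM" if threshold is None else "BCM"
    verdicts: list[MatchVerdict] = []
    excluded: list[str] = []
    species = np.asarray(dm.species, dtype=object)
    for i in range(dm.n):
        row = dm.values[i].copy()
        row[i] = np.nan  # leave-one-out
        defined = ~np.isnan(row)
        if not defined.any():
            excluded.append(dm.labels[i])
            continue
        best = float(np.nanmin(row))
        if threshold is not None and best > threshold:
            verdicts.append(
                MatchVerdict(
                    query=dm.labels[i],
                    species=dm.species[i],
                    best_distance=best,
                    best_match_species=frozenset(),
                    category=Category.NO_MATCH,
                )
            )
            continue
        best_set = frozenset(species[defined & (row == best)])
        if best_set == {dm.species[i]}:
            cat = Category.CORRECT
        elif dm.species[i] in best_set:
            cat = Category.AMBIGUOUS
        else:
            cat = Category.INCORRECT
        verdicts.append(
            MatchVerdict(
                query=dm.labels[i],
                species=dm.species[i],
                best_distance=best,
                best_match_species=best_set,
                category=cat,
            )
        )
    if not verdicts:
        raise StageError("every query lacked defined distances")
    return MatchReport(method=method, verdicts=verdicts, excluded=excluded)


def best_match(dm: DistanceMatrix) -> MatchReport:
    """Best Match: classify each query by its nearest neighbours' species."""
    return _classify(dm, threshold=None)


def best_close_match(
    dm: DistanceMatrix, threshold: BCMThreshold | float
) -> MatchReport:
    """Best Close Match: Best Match restricted to candidates within the
    intraspecific 95th-percentile threshold; distant queries get NO_MATCH."""
    value = threshold.value if isinstance(threshold, BCMThreshold) else float(threshold)
    return _classify(dm, threshold=value)
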