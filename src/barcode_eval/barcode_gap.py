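"""Per-species barcoding-gap analysis.

Two complementary views of the same distance matrix:

* scatter method — for every species with >= 2 individuals, compare its
  maximum intraspecific distance against its minimum distance to any
  heterospecific individual. The species has a barcoding gap when the
  minimum interspecific distance strictly exceeds the maximum intraspecific
  one (a dot strictly above the 1:1 line in a scatter plot).
* histogram method — pooled distributions of all intra- and interspecific
  distances; a gap appears as a gap between the two supports, overlap as
  overlapping histograms.

Singleton species have no intraspecific distance and are excluded from the
scatter records (their individuals still contribute to other species'
minimum interspecific distances). Undefined (NaN) distances are excluded
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .errors import StageError

__all__ = [
    "SpeciesGapRecord",
    "GapReport",
    "DistanceHistogram",
    "species_gap_records",
    "gap_percentage",
    "gap_report",
    "scatter_table",
    "distance_histograms",
]


@dataclass(frozen=True)
class SpeciesGapRecord:
    species: str
    n_individuals: int
    max_intra: float
    min_inter: float

    @property
    def has_gap(self) -> bool:
        """Strict inequality: a dot on the 1:1 line is not a gap."""
        return self.min_inter > self.max_intra


@dataclass
class GapReport:
    locus: str
    records: list[SpeciesGapRecord]
    skipped_species: list[str] = field(default_factory=list)

    @property
    def pct_with_gap(self) -> float:
        return gap_percentage(self.records)


@dataclass
class DistanceHistogram:
    bin_width: float
    bin_edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "intra_count": self.intra_counts,
                "inter_count": self.inter_counts,
            }
        )


def species_gap_records(dm: DistanceMatrix) -> list[SpeciesGapRecord]:
    """One record per species with >= 2 individuals and defined distances.

    max_intra is the maximum defined conspecific distance; min_inter the
    minimum defined distance from any member to any non-member. Species
    whose intra or inter distances are all undefined are skipped (use
    :func:`gap_report` to see which).
    """
    return gap_report(dm).records


def gap_report(dm: DistanceMatrix, locus: str = "") -> GapReport:
    species = np.asarray(dm.species, dtype=object)
    uniq = sorted(set(dm.species))
    if len(uniq) < 2:
        raise StageError("gap analysis needs at least 2 species")
    records: list[SpeciesGapRecord] = []
    skipped: list[str] = []
    vals = dm.values
    for sp in uniq:
        member = species == sp
        n_ind = int(member.sum())
        if n_ind < 2:
            continue  # singleton: no intraspecific distance
        intra = vals[np.ix_(member, member)]
        intra = intra[np.triu_indices_from(intra, k=1)]
        intra = intra[~np.isnan(intra)]
        inter = vals[np.ix_(member, ~member)].ravel()
        inter = inter[~np.isnan(inter)]
        if intra.size == 0 or inter.size == 0:
            skipped.append(sp)
            continue
        records.append(
            SpeciesGapRecord(
                species=sp,
                n_individuals=n_ind,
                max_intra=float(intra.max()),
                min_inter=float(inter.min()),
            )
        )
    return GapReport(locus=locus or "", records=records, skipped_species=skipped)


def gap_percentage(records: list[SpeciesGapRecord]) -> float:
    """Percentage of assessed species whose gap criterion holds."""
    if not records:
        raise StageError("gap percentage of zero species is undefined")
    return 100.0 * sum(r.has_gap for r in records) / len(records)


def scatter_table(records: list[SpeciesGapRecord]) -> pd.DataFrame:
    """Plot-ready table: x = max_intra, y = min_inter, 1:1 reference line."""
    return pd.DataFrame(
        [
            (r.species, r.n_individuals, r.max_intra, r.min_inter, r.has_gap)
            for r in records
        ],
        columns=["species", "n_individuals", "max_intra", "min_inter", "has_gap"],
    )


def distance_histograms(
    dm: DistanceMatrix, bin_width: float = 0.01
) -> DistanceHistogram:
    """Bin all defined intra- and interspecific distances on a shared grid.

    Bins cover [0, max distance] with the final edge rounded up to a whole
    bin; counts conserve the number of defined pairs.
    """
    if bin_width <= 0:
        raise StageError("bin_width must be positive")
    intra = dm.intra_distances()
    inter = dm.inter_distances()
    if intra.size == 0 and inter.size == 0:
        raise StageError("no defined pairwise distances to bin")
    top = float(max(intra.max() if intra.size else 0.0,
                    inter.max() if inter.size else 0.0))
    n_bins = max(1, int(np.ceil(top / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    intra_counts, _ = np.histogram(intra, bins=edges)
    inter_counts, _ = np.histogram(inter, bins=edges)
    return DistanceHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
    )
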