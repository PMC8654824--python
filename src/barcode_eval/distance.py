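"""Pairwise genetic distances with pairwise deletion.

Two models:

* Kimura 2-parameter (K2P): separates transitions (A<->G, C<->T, proportion
  P) from transversions (proportion Q) among the sites comparable for the
  pair, and corrects for multiple hits::

      d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

* p-distance: uncorrected mismatch proportion over comparable sites.

Pairwise deletion: for each pair, any column where either member is not a
plain A/C/G/T (gap, N, IUPAC ambiguity) is ignored. A pair with zero
comparable sites, or whose K2P log arguments are non-positive (saturation),
gets an UNDEFINED distance, represented as NaN and carried explicitly so
downstream summaries can exclude rather than zero it.

Base encoding used throughout the package: A=0, G=1, C=2, T=3 (so a
transition flips the low bit, a transversion flips the group bit), 4 =
missing/ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import InputError
from .seqio import ConcatAlignment, LocusAlignment

__all__ = [
    "K2P",
    "P_DIST",
    "UNDEFINED",
    "DistanceMatrix",
    "DistanceRanges",
    "encode",
    "decode",
    "pairwise_k2p",
    "pairwise_pdist",
    "distance_matrix",
    "summarize_ranges",
]

K2P = "k2p"
P_DIST = "p"
UNDEFINED = float("nan")

_BASES = "AGCT"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as uint8 (A=0,G=1,C=2,T=3, 4=missing)."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, comparable sites) for one encoded pair."""
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    diff = valid & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, n


def _k2p_from_counts(ts: int, tv: int, n: int) -> float:
    if n == 0:
        return UNDEFINED
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0


def pairwise_k2p(seq_a: str, seq_b: str) -> tuple[float, int]:
    """K2P distance and comparable-site count for one aligned pair.

    Returns (NaN, sites) when no sites are comparable or the correction is
    saturated (log argument <= 0).
    """
    if len(seq_a) != len(seq_b):
        raise InputError(
            f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}"
        )
    ts, tv, n = _pair_counts(encode(seq_a), encode(seq_b))
    return _k2p_from_counts(ts, tv, n), n


def pairwise_pdist(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance and comparable-site count for one pair."""
    if len(seq_a) != len(seq_b):
        raise InputError(
            f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}"
        )
    ts, tv, n = _pair_counts(encode(seq_a), encode(seq_b))
    if n == 0:
        return UNDEFINED, 0
    return (ts + tv) / n, n


@dataclass(frozen=True)
class DistanceRanges:
    """Extrema of inter- and intraspecific distances; None when absent."""

    min_inter: float | None
    max_inter: float | None
    min_intra: float | None
    max_intra: float | None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix with species labels.

    ``values`` holds NaN for UNDEFINED entries; ``sites`` the number of
    comparable sites per pair (diagonal: determinate sites per sequence).
    """

    labels: list[str]
    species: list[str]
    values: np.ndarray
    sites: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.sites.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if len(self.species) != n:
            raise InputError("species list does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.labels, self.species))

    def _pair_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(intra, inter) boolean masks over the strict upper triangle."""
        sp = np.asarray(self.species, dtype=object)
        same = sp[:, None] == sp[None, :]
        upper = np.triu(np.ones((self.n, self.n), dtype=bool), k=1)
        return same & upper, (~same) & upper

    def intra_distances(self) -> np.ndarray:
        """Defined intraspecific pairwise distances (1-D array)."""
        intra, _ = self._pair_masks()
        vals = self.values[intra]
        return vals[~np.isnan(vals)]

    def inter_distances(self) -> np.ndarray:
        """Defined interspecific pairwise distances (1-D array)."""
        _, inter = self._pair_masks()
        vals = self.values[inter]
        return vals[~np.isnan(vals)]

    def subset(self, keep: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lbl) for lbl in keep]
        ix = np.ix_(idx, idx)
        return DistanceMatrix(
            labels=[self.labels[i] for i in idx],
            species=[self.species[i] for i in idx],
            values=self.values[ix].copy(),
            sites=self.sites[ix].copy(),
            model=self.model,
        )

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    (
                        self.labels[i],
                        self.labels[j],
                        self.values[i, j],
                        int(self.sites[i, j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["sample_a", "sample_b", "distance", "sites"]
        )

    def write_square_tsv(self, path: str | Path) -> None:
        self.to_square_frame().to_csv(path, sep="\t", index_label="sample_id")

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)


def distance_matrix(
    aln: Union[LocusAlignment, ConcatAlignment], model: str = K2P
) -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` ("k2p" or "p").

    Pair counting is done with one-hot matrix products so large alignments
    stay fast; per-pair results are identical to :func:`pairwise_k2p` /
    :func:`pairwise_pdist`.
    """
    if model not in (K2P, P_DIST):
        raise InputError(f"unknown distance model {model!r}")
    if len(aln.records) < 2:
        raise InputError("distance matrix needs at least 2 records")
    codes = np.vstack([encode(rec.residues) for rec in aln.records])
    onehot = [(codes == b).astype(np.float32) for b in range(4)]
    valid = (codes < 4).astype(np.float32)

    sites = valid @ valid.T
    match = sum(h @ h.T for h in onehot)
    # transitions: A<->G (codes 0,1) and C<->T (codes 2,3)
    ts = (
        onehot[0] @ onehot[1].T
        + onehot[1] @ onehot[0].T
        + onehot[2] @ onehot[3].T
        + onehot[3] @ onehot[2].T
    )
    sites_i = np.rint(sites).astype(np.int64)
    ts_i = np.rint(ts).astype(np.int64)
    diff_i = sites_i - np.rint(match).astype(np.int64)
    tv_i = diff_i - ts_i

    with np.errstate(divide="ignore", invalid="ignore"):
        if model == P_DIST:
            values = np.where(sites_i > 0, diff_i / np.maximum(sites_i, 1), np.nan)
        else:
            p = ts_i / np.maximum(sites_i, 1)
            q = tv_i / np.maximum(sites_i, 1)
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            ok = (sites_i > 0) & (w1 > 0) & (w2 > 0)
            values = np.where(
                ok,
                -0.5 * np.log(np.where(ok, w1, 1.0))
                - 0.25 * np.log(np.where(ok, w2, 1.0)),
                np.nan,
            )
    values = np.asarray(values, dtype=float) + 0.0  # normalise -0.0
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(
        labels=[rec.sample_id for rec in aln.records],
        species=[rec.species for rec in aln.records],
        values=values,
        sites=sites_i,
        model=model,
    )


def summarize_ranges(dm: DistanceMatrix) -> DistanceRanges:
    """Extrema of defined intra- and interspecific distances.

    A range with no defined pairs is reported as absent (None), never as 0.
    """
    intra = dm.intra_distances()
    inter = dm.inter_distances()
    return DistanceRanges(
        min_inter=float(inter.min()) if inter.size else None,
        max_inter=float(inter.max()) if inter.size else None,
        min_intra=float(intra.min()) if intra.size else None,
        max_intra=float(intra.max()) if intra.size else None,
    )
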