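"""Full barcode-evaluation pipeline over loci and their combinations.

For every requested barcode (single locus or concatenation) the pipeline

1. applies the sampling filters (minimum ungapped length, per-species cap),
2. computes a K2P distance matrix: distance ranges, per-species barcoding-gap
   records and intra/inter histograms,
3. deletes singleton species and runs Best Match / Best Close Match with the
   95th-percentile intraspecific threshold,
4. computes a p-distance matrix, builds the neighbour-joining tree and scores
   per-species monophyly,

then assembles three summary tables: sequence characteristics and distance
ranges; gap and NJ-discrimination percentages; BM/BCM category percentages.
Defaults mirror the standard published protocol (K2P for distance-based
analyses, p-distance for trees, 300-bp filter with ITS2 exempt, 20-individual
cap, singleton deletion before matching); everything is overridable.

All randomness-free: identical inputs and configuration give byte-identical
outputs. When ``out_dir`` is set, every intermediate artifact (long-format
distances, scatter and histogram tables, verdicts, Newick tree, monophyly
table) is written along with a JSON manifest, so each summary number can be
re-derived from the files on disk.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from itertools import combinations as iter_combinations
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from . import __version__
from .barcode_gap import (
    DistanceHistogram,
    GapReport,
    distance_histograms,
    gap_report,
    scatter_table,
)
from .distance import (
    K2P,
    P_DIST,
    DistanceMatrix,
    DistanceRanges,
    distance_matrix,
    summarize_ranges,
)
from .errors import InputError, StageError
from .njtree import (
    MonophylyReport,
    UnrootedTree,
    nj_build,
    species_monophyly,
    write_newick,
)
from .seqio import (
    ConcatAlignment,
    FilterLog,
    LocusAlignment,
    apply_sampling_filters,
    concatenate,
    drop_singleton_species,
    read_alignment,
)
from .similarity_match import (
    BCMThreshold,
    MatchReport,
    bcm_threshold,
    best_close_match,
    best_match,
)

__all__ = [
    "RunConfig",
    "BarcodeResult",
    "EvaluationReport",
    "default_combinations",
    "evaluate",
    "evaluate_alignments",
    "report_tables",
]

logger = logging.getLogger(__name__)

Alignment = Union[LocusAlignment, ConcatAlignment]

#: loci excluded from default concatenations (alignment pathologies create
#: heavy missing data when combined)
NO_CONCAT_LOCI = frozenset({"trnH-psbA"})
#: locus pairs never combined by default (one is a sub-region of the other)
NESTED_LOCI = frozenset({frozenset({"ITS", "ITS2"})})


@dataclass
class RunConfig:
    """Configuration of one evaluation run."""

    min_len: int = 300
    max_per_species: int = 20
    exempt_min_len: tuple[str, ...] = ("ITS2",)
    apply_filters: bool = True
    dist_model: str = K2P  # gap analysis + BM/BCM
    tree_model: str = P_DIST  # NJ
    bin_width: float = 0.01
    out_dir: str | None = None


@dataclass
class BarcodeResult:
    """Everything computed for one barcode (locus or combination)."""

    name: str
    n_sequences: int
    n_species: int
    len_min: int
    len_max: int
    ranges: DistanceRanges
    gap: GapReport
    histogram: DistanceHistogram | None
    threshold: BCMThreshold | None
    bm: MatchReport | None
    bcm: MatchReport | None
    monophyly: MonophylyReport | None
    tree: UnrootedTree | None
    filter_log: FilterLog = field(default_factory=FilterLog)
    singleton_species_removed: list[str] = field(default_factory=list)
    nj_excluded_samples: list[str] = field(default_factory=list)


@dataclass
class EvaluationReport:
    barcodes: list[BarcodeResult]
    config: RunConfig

    def barcode(self, name: str) -> BarcodeResult:
        for b in self.barcodes:
            if b.name == name:
                return b
        raise KeyError(name)


def default_combinations(loci: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2- and 3-locus combinations, skipping loci unsuited to
    concatenation and nested locus pairs."""
    usable = [lc for lc in loci if lc not in NO_CONCAT_LOCI]
    combos: list[tuple[str, ...]] = []
    for size in (2, 3):
        for combo in iter_combinations(usable, size):
            if any(
                nested <= set(combo) for nested in NESTED_LOCI
            ):
                continue
            combos.append(combo)
    return combos


def _drop_undefined_samples(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Greedily remove samples with undefined distances until none remain."""
    import numpy as np

    removed: list[str] = []
    while True:
        undef = np.isnan(dm.values)
        if not undef.any():
            return dm, removed
        counts = undef.sum(axis=1)
        worst = int(counts.argmax())
        removed.append(dm.labels[worst])
        keep = [lbl for k, lbl in enumerate(dm.labels) if k != worst]
        if len(keep) < 3:
            raise StageError(
                "too few samples with fully defined distances for NJ"
            )
        dm = dm.subset(keep)


def _evaluate_one(name: str, aln: Alignment, cfg: RunConfig) -> BarcodeResult:
    if cfg.apply_filters and isinstance(aln, LocusAlignment):
        aln, flog = apply_sampling_filters(
            aln,
            min_len=cfg.min_len,
            max_per_species=cfg.max_per_species,
            exempt_min_len=cfg.exempt_min_len,
        )
    else:
        flog = FilterLog()
    if len(aln) < 2:
        raise StageError(f"barcode {name}: fewer than 2 sequences after filtering")

    dm = distance_matrix(aln, model=cfg.dist_model)
    ranges = summarize_ranges(dm)
    gap = gap_report(dm, locus=name)
    try:
        hist = distance_histograms(dm, bin_width=cfg.bin_width)
    except StageError:
        hist = None

    # similarity-based identification on the singleton-free alignment
    bm_report: MatchReport | None = None
    bcm_report: MatchReport | None = None
    threshold: BCMThreshold | None = None
    if isinstance(aln, ConcatAlignment):
        reduced_records = [
            r for r in aln.records if aln.species_counts()[r.species] >= 2
        ]
        removed = sorted(
            sp for sp, k in aln.species_counts().items() if k < 2
        )
        reduced = LocusAlignment(locus=name, records=reduced_records)
    else:
        reduced, removed = drop_singleton_species(aln)
    if len(reduced) >= 2 and len(set(r.species for r in reduced.records)) >= 1:
        dm_match = distance_matrix(reduced, model=cfg.dist_model)
        try:
            threshold = bcm_threshold(dm_match)
            bm_report = best_match(dm_match)
            bcm_report = best_close_match(dm_match, threshold)
        except StageError as exc:
            logger.warning("barcode %s: matching skipped (%s)", name, exc)

    # tree-based identification
    tree: UnrootedTree | None = None
    mono: MonophylyReport | None = None
    nj_excluded: list[str] = []
    if len(aln) >= 3:
        dm_tree = distance_matrix(aln, model=cfg.tree_model)
        try:
            dm_tree, nj_excluded = _drop_undefined_samples(dm_tree)
            if nj_excluded:
                logger.warning(
                    "barcode %s: %d samples dropped for NJ (undefined distances)",
                    name,
                    len(nj_excluded),
                )
            tree = nj_build(dm_tree)
            mono = species_monophyly(tree)
        except StageError as exc:
            logger.warning("barcode %s: NJ skipped (%s)", name, exc)

    lengths = [rec.ungapped_length for rec in aln.records]
    return BarcodeResult(
        name=name,
        n_sequences=len(aln),
        n_species=len(set(r.species for r in aln.records)),
        len_min=min(lengths),
        len_max=max(lengths),
        ranges=ranges,
        gap=gap,
        histogram=hist,
        threshold=threshold,
        bm=bm_report,
        bcm=bcm_report,
        monophyly=mono,
        tree=tree,
        filter_log=flog,
        singleton_species_removed=removed,
        nj_excluded_samples=nj_excluded,
    )


def evaluate_alignments(
    loci: dict[str, LocusAlignment],
    combinations: Sequence[Sequence[str]] | None = None,
    cfg: RunConfig | None = None,
) -> EvaluationReport:
    """Evaluate already-loaded alignments (library entry point)."""
    cfg = cfg or RunConfig()
    if not loci:
        raise InputError("no loci provided")
    combos = (
        [tuple(c) for c in combinations]
        if combinations is not None
        else default_combinations(list(loci))
    )
    for combo in combos:
        missing = [lc for lc in combo if lc not in loci]
        if missing:
            raise InputError(
                f"combination {'+'.join(combo)} references missing loci: {missing}"
            )

    results: list[BarcodeResult] = []
    filtered: dict[str, LocusAlignment] = {}
    for name, aln in loci.items():
        try:
            res = _evaluate_one(name, aln, cfg)
        except (InputError, StageError) as exc:
            raise StageError(f"stage '{name}': {exc}") from exc
        results.append(res)
        if cfg.apply_filters:
            filtered[name], _ = apply_sampling_filters(
                aln,
                min_len=cfg.min_len,
                max_per_species=cfg.max_per_species,
                exempt_min_len=cfg.exempt_min_len,
            )
        else:
            filtered[name] = aln
    combo_cfg = RunConfig(**{**cfg.__dict__, "apply_filters": False})
    for combo in combos:
        name = "+".join(combo)
        try:
            concat = concatenate([filtered[lc] for lc in combo])
            results.append(_evaluate_one(name, concat, combo_cfg))
        except (InputError, StageError) as exc:
            raise StageError(f"stage '{name}': {exc}") from exc

    report = EvaluationReport(barcodes=results, config=cfg)
    if cfg.out_dir:
        _write_artifacts(report, loci, combos, Path(cfg.out_dir))
    return report


def evaluate(
    locus_paths: dict[str, str | Path],
    combinations: Sequence[Sequence[str]] | None = None,
    cfg: RunConfig | None = None,
) -> EvaluationReport:
    """Evaluate FASTA files: {locus_name: path}."""
    loci = {
        name: read_alignment(path, locus=name)
        for name, path in locus_paths.items()
    }
    return evaluate_alignments(loci, combinations=combinations, cfg=cfg)


def _fmt_range(lo: float | None, hi: float | None) -> str:
    if lo is None or hi is None:
        return "NA"
    return f"{lo:.4g}-{hi:.4g}"


def report_tables(
    report: EvaluationReport,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three summary tables: sequence/distance characteristics, gap and NJ
    percentages, BM/BCM category percentages."""
    rows2, rows3, rows4 = [], [], []
    for b in report.barcodes:
        rows2.append(
            (
                b.name,
                b.n_sequences,
                b.len_max,
                b.len_min,
                _fmt_range(b.ranges.min_inter, b.ranges.max_inter),
                _fmt_range(b.ranges.min_intra, b.ranges.max_intra),
            )
        )
        rows3.append(
            (
                b.name,
                b.gap.pct_with_gap if b.gap.records else float("nan"),
                b.monophyly.pct_discriminated
                if b.monophyly and b.monophyly.records
                else float("nan"),
            )
        )
        rows4.append(
            (
                b.name,
                b.bm.pct_correct if b.bm else float("nan"),
                b.bm.pct_ambiguous if b.bm else float("nan"),
                b.bm.pct_incorrect if b.bm else float("nan"),
                b.bcm.pct_correct if b.bcm else float("nan"),
                b.bcm.pct_ambiguous if b.bcm else float("nan"),
                b.bcm.pct_incorrect if b.bcm else float("nan"),
                b.bcm.pct_no_match if b.bcm else float("nan"),
            )
        )
    t2 = pd.DataFrame(
        rows2,
        columns=["marker", "n_seq", "len_max", "len_min", "inter_range", "intra_range"],
    )
    t3 = pd.DataFrame(rows3, columns=["marker", "gap_pct", "nj_pct"])
    t4 = pd.DataFrame(
        rows4,
        columns=[
            "marker",
            "bm_correct",
            "bm_ambiguous",
            "bm_incorrect",
            "bcm_correct",
            "bcm_ambiguous",
            "bcm_incorrect",
            "bcm_no_match",
        ],
    )
    if t2.empty:
        raise StageError("no barcodes evaluated")
    return t2, t3, t4


def _write_artifacts(
    report: EvaluationReport,
    loci: dict[str, LocusAlignment],
    combos: Sequence[tuple[str, ...]],
    out: Path,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for b in report.barcodes:
        bdir = out / b.name.replace("+", "_")
        bdir.mkdir(exist_ok=True)
        scatter_table(b.gap.records).to_csv(bdir / "scatter.csv", index=False)
        if b.histogram is not None:
            b.histogram.to_frame().to_csv(bdir / "histogram.csv", index=False)
        if b.bm:
            b.bm.to_frame().to_csv(bdir / "verdicts_bm.tsv", sep="\t", index=False)
        if b.bcm:
            b.bcm.to_frame().to_csv(bdir / "verdicts_bcm.tsv", sep="\t", index=False)
        if b.tree:
            write_newick(b.tree, bdir / "tree.nwk")
        if b.monophyly:
            b.monophyly.to_frame().to_csv(
                bdir / "monophyly.tsv", sep="\t", index=False
            )
        if b.filter_log.entries:
            pd.DataFrame(
                [
                    (e.sample_id, e.species, e.locus, e.reason, e.detail)
                    for e in b.filter_log.entries
                ],
                columns=["sample_id", "species", "locus", "reason", "detail"],
            ).to_csv(bdir / "filter_log.tsv", sep="\t", index=False)
    t2, t3, t4 = report_tables(report)
    t2.to_csv(out / "table_characteristics.tsv", sep="\t", index=False)
    t3.to_csv(out / "table_gap_nj.tsv", sep="\t", index=False)
    t4.to_csv(out / "table_bm_bcm.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "loci": {name: len(aln) for name, aln in loci.items()},
        "combinations": ["+".join(c) for c in combos],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in report.config.__dict__.items()
            if k != "out_dir"  # location, not an analysis parameter
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
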