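"""Species-structured alignment simulator.

Generates gap-free aligned datasets with controlled within- and
between-species divergence so every pipeline stage can be verified end to
end:

1. a pure-birth (Yule) species tree, ultrametric, rescaled so the
   root-to-tip height equals ``inter_scale`` (expected substitutions/site
   between the most divergent species pair is ~2x that);
2. each species tip replaced by a star of individuals whose pendant branches
   are uniform on [0, intra_scale] — a deliberately simple stand-in for a
   within-species genealogy that directly controls the maximum intraspecific
   distance;
3. sequences evolved along the resulting tree under the Kimura 2-parameter
   substitution process (exact transition probabilities, no site
   discretisation, no indels), with ``kappa`` = expected transitions per
   transversion (R = alpha / 2 beta).

``n_confusable_pairs`` species pairs are generated with zero species-level
divergence (the second member's individuals radiate from the first member's
tip), emulating cryptic or over-split species: their members are expected to
break the barcoding gap, mislead best-match identification and destroy NJ
monophyly.

``min_split_frac`` keeps every speciation at least that fraction of the tree
height away from the tips, so a "clean" dataset has its interspecific floor
strictly above the intraspecific ceiling by construction.

Everything is driven by one ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``: output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .njtree import Node, UnrootedTree
from .seqio import LocusAlignment, SeqRecord

__all__ = [
    "SimulationConfig",
    "simulate_species_tree",
    "simulate_individuals",
    "evolve_sequences",
    "simulate_alignment",
    "BenchmarkSuite",
    "make_benchmark_suite",
]

_BASES = "AGCT"  # matches the distance-module encoding


@dataclass(frozen=True)
class SimulationConfig:
    """Study-like simulation conditions.

    individuals_per_species: fixed int, or (lo, hi) sampled uniformly per
    species. inter_scale / intra_scale are expected substitutions per site
    (species-tree height, individual pendant ceiling). missing_fraction is
    the per-locus sample dropout probability in multi-locus datasets.
    """

    n_species: int = 30
    individuals_per_species: int | tuple[int, int] = (1, 20)
    seq_length: int = 800
    kappa: float = 2.0
    inter_scale: float = 0.2
    intra_scale: float = 0.005
    n_confusable_pairs: int = 0
    missing_fraction: float = 0.1
    min_split_frac: float = 0.2
    seed: int = 0
    locus: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InputError("need at least 2 species")
        if self.seq_length <= 0:
            raise InputError("seq_length must be positive")
        if self.inter_scale < 0 or self.intra_scale < 0:
            raise InputError("divergence scales must be non-negative")
        if self.kappa < 0:
            raise InputError("kappa must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise InputError("missing_fraction must be in [0, 1)")
        if not 0 <= self.min_split_frac < 1:
            raise InputError("min_split_frac must be in [0, 1)")
        if 2 * self.n_confusable_pairs > self.n_species:
            raise InputError("too many confusable pairs for n_species")


def _species_name(i: int) -> str:
    return f"Simulorchis_sp{i + 1:03d}"


def simulate_species_tree(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> UnrootedTree:
    """Yule (pure-birth) species tree, ultrametric with height inter_scale.

    Internal split times are compressed by (1 - min_split_frac) so the
    shallowest split is at least min_split_frac * inter_scale above the tips.
    Deterministic under the config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    root = Node()
    birth = {id(root): 0.0}
    tips = [root]
    t = 0.0
    while len(tips) < cfg.n_species:
        t += rng.exponential(1.0 / len(tips))
        idx = int(rng.integers(len(tips)))
        parent = tips[idx]
        kids = [Node(), Node()]
        parent.children = kids
        birth[id(kids[0])] = birth[id(kids[1])] = t
        tips[idx : idx + 1] = kids
    t_final = t + rng.exponential(1.0 / cfg.n_species)
    if t_final <= 0.0:  # n_species == 2 could give t == 0 only if exp drew 0
        t_final = 1.0
    squeeze = 1.0 - cfg.min_split_frac
    scale = cfg.inter_scale / t_final

    def assign(node: Node, parent_time: float) -> None:
        own = birth[id(node)] * squeeze
        node.length = (own - parent_time) * scale
        if node.is_leaf:
            node.length = (t_final - parent_time) * scale
            return
        for ch in node.children:
            assign(ch, own)

    for i, tip in enumerate(tips):
        tip.name = _species_name(i)
        tip.species = _species_name(i)
    for ch in root.children:
        assign(ch, 0.0)
    root.length = 0.0
    return UnrootedTree(root=root)


def _draw_k(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    if isinstance(cfg.individuals_per_species, int):
        return cfg.individuals_per_species
    lo, hi = cfg.individuals_per_species
    return int(rng.integers(lo, hi + 1))


def simulate_individuals(
    species_tree: UnrootedTree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[UnrootedTree, list[tuple[str, str]]]:
    """Replace species tips by stars of individuals; apply confusable pairs.

    Returns the per-individual tree and the list of confusable species pairs
    (second member's individuals grafted onto the first member's tip, i.e.
    zero species-level divergence). The input tree is modified in place.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    tips = {leaf.species: leaf for leaf in species_tree.leaves()}
    names = sorted(tips)
    pairs: list[tuple[str, str]] = []
    if cfg.n_confusable_pairs:
        chosen = rng.choice(
            len(names), size=2 * cfg.n_confusable_pairs, replace=False
        )
        chosen = np.sort(chosen)
        pairs = [
            (names[int(chosen[2 * i])], names[int(chosen[2 * i + 1])])
            for i in range(cfg.n_confusable_pairs)
        ]
    host = {b: a for a, b in pairs}

    def attach(tip: Node, species: str) -> None:
        k = _draw_k(cfg, rng)
        for j in range(k):
            tip.children.append(
                Node(
                    name=f"{species.lower()}_i{j + 1:02d}",
                    species=species,
                    length=float(rng.uniform(0.0, cfg.intra_scale)),
                )
            )

    for sp in names:  # fixed iteration order keeps the RNG stream stable
        target = tips[host.get(sp, sp)]
        attach(target, sp)
    for _, b in pairs:
        _prune_leaf(species_tree, tips[b])
    return species_tree, pairs


def _prune_leaf(tree: UnrootedTree, leaf: Node) -> None:
    """Remove a (now childless) tip and suppress the resulting unary node.

    Suppression relinks the remaining child (summing branch lengths) so
    other node objects keep their identity.
    """

    def remove(node: Node, parent: Node | None) -> bool:
        for ch in list(node.children):
            if ch is leaf:
                node.children.remove(ch)
                if parent is not None and len(node.children) == 1:
                    only = node.children[0]
                    only.length += node.length
                    parent.children[parent.children.index(node)] = only
                return True
            if remove(ch, node):
                return True
        return False

    remove(tree.root, None)


def _k2p_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after branch length t.

    Rates normalised to one expected substitution per site per unit t:
    alpha = R/(R+1), beta = 1/(2(R+1)) with R = kappa = alpha/(2 beta).
    """
    r = kappa
    alpha = r / (r + 1.0)
    beta = 0.5 / (r + 1.0)
    e1 = np.exp(-2.0 * (alpha + beta) * t)
    e2 = np.exp(-4.0 * beta * t)
    p_ts = 0.25 + 0.25 * e2 - 0.5 * e1
    p_tv = 0.25 - 0.25 * e2
    return float(p_ts), float(p_tv)


def _mutate(
    seq: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if t <= 0.0:
        return seq.copy()
    p_ts, p_tv = _k2p_probs(t, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    out[u < p_ts] ^= 1  # transition: flip within purines / pyrimidines
    out[(u >= p_ts) & (u < p_ts + p_tv)] ^= 2
    out[(u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)] ^= 3
    return out


def evolve_sequences(
    tree: UnrootedTree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> LocusAlignment:
    """Evolve one gap-free alignment along a per-individual tree.

    Root sequence uniform over ACGT; K2P substitution process per branch.
    Records appear in tree traversal order.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    root_seq = rng.integers(0, 4, size=cfg.seq_length, dtype=np.uint8)
    records: list[SeqRecord] = []

    def walk(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            records.append(
                SeqRecord(
                    sample_id=node.name,
                    species=node.species,
                    locus=cfg.locus,
                    residues="".join(_BASES[c] for c in seq),
                )
            )
            return
        for ch in node.children:
            walk(ch, _mutate(seq, ch.length, cfg.kappa, rng))

    walk(tree.root, root_seq)
    return LocusAlignment(locus=cfg.locus, records=records)


def simulate_alignment(
    cfg: SimulationConfig,
) -> tuple[LocusAlignment, UnrootedTree, list[tuple[str, str]]]:
    """Full single-locus simulation: (alignment, individual tree, pairs)."""
    rng = np.random.default_rng(cfg.seed)
    sp_tree = simulate_species_tree(cfg, rng)
    ind_tree, pairs = simulate_individuals(sp_tree, cfg, rng)
    aln = evolve_sequences(ind_tree, cfg, rng)
    return aln, ind_tree, pairs


@dataclass
class BenchmarkSuite:
    """Clean, confusable and multi-locus-with-dropout datasets plus truth."""

    clean: LocusAlignment
    confusable: LocusAlignment
    multilocus: dict[str, LocusAlignment]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        from .seqio import write_alignment

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(self.clean, out / "clean.fasta")
        write_alignment(self.confusable, out / "confusable.fasta")
        for locus, aln in self.multilocus.items():
            write_alignment(aln, out / f"multilocus_{locus}.fasta")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def make_benchmark_suite(cfg: SimulationConfig) -> BenchmarkSuite:
    """Three datasets exercising every pipeline stage, with ground truth.

    * clean — no confusable pairs, no dropout: every species has a gap, is
      monophyletic and best-match identifiable by construction;
    * confusable — max(1, cfg.n_confusable_pairs) zero-divergence species
      pairs: their members are expected to lose the gap, mislead BM/BCM and
      break monophyly;
    * multilocus — three independent loci on the same individuals with
      per-locus sample dropout, for concatenation tests.
    """
    n_conf = max(1, cfg.n_confusable_pairs)
    clean_cfg = dataclasses.replace(
        cfg, n_confusable_pairs=0, missing_fraction=0.0
    )
    conf_cfg = dataclasses.replace(
        cfg, n_confusable_pairs=n_conf, missing_fraction=0.0, seed=cfg.seed + 101
    )
    clean_aln, _, _ = simulate_alignment(clean_cfg)
    conf_aln, _, conf_pairs = simulate_alignment(conf_cfg)

    loci = ["LOC1", "LOC2", "LOC3"]
    rng = np.random.default_rng(cfg.seed + 202)
    ml_cfg = dataclasses.replace(cfg, n_confusable_pairs=0)
    sp_tree = simulate_species_tree(ml_cfg, rng)
    ind_tree, _ = simulate_individuals(sp_tree, ml_cfg, rng)
    multilocus: dict[str, LocusAlignment] = {}
    for locus in loci:
        full = evolve_sequences(
            ind_tree, dataclasses.replace(ml_cfg, locus=locus), rng
        )
        keep = [
            rec
            for rec in full.records
            if rng.random() >= ml_cfg.missing_fraction
        ]
        multilocus[locus] = LocusAlignment(
            locus=locus,
            records=[dataclasses.replace(r, locus=locus) for r in keep],
        )

    conf_members = sorted({sp for pair in conf_pairs for sp in pair})
    truth = {
        "seed": cfg.seed,
        "n_species": cfg.n_species,
        "clean": {
            "species_with_gap": sorted(
                {r.species for r in clean_aln.records}
            ),
            "expected_gap_pct": 100.0,
            "expected_bm_correct_pct": 100.0,
            "expected_nj_monophyly_pct": 100.0,
        },
        "confusable": {
            "pairs": [list(p) for p in conf_pairs],
            "species_expected_nonmonophyletic": conf_members,
            "expected_nj_monophyly_pct": 100.0
            * (cfg.n_species - 2 * n_conf)
            / cfg.n_species,
            "expected_bm_noncorrect_species": conf_members,
        },
        "multilocus": {
            "loci": loci,
            "missing_fraction": ml_cfg.missing_fraction,
            "n_samples_per_locus": {
                locus: len(aln) for locus, aln in multilocus.items()
            },
        },
    }
    return BenchmarkSuite(
        clean=clean_aln,
        confusable=conf_aln,
        multilocus=multilocus,
        truth=truth,
    )
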