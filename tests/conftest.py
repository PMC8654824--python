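import random

import pytest

from barcode_eval import LocusAlignment, SeqRecord, SimulationConfig, simulate_alignment


def make_aln(locus: str, rows: list[tuple[str, str, str]]) -> LocusAlignment:
    """rows: (sample_id, species, residues)."""
    return LocusAlignment(
        locus=locus,
        records=[SeqRecord(sid, sp, locus, seq) for sid, sp, seq in rows],
    )


@pytest.fixture
def toy_alignment() -> LocusAlignment:
    """Two 2-individual species, clearly separated."""
    return make_aln(
        "ITS",
        [
            ("a1", "Dendrobium_nobile", "ACGTACGTAC"),
            ("a2", "Dendrobium_nobile", "ACGTACGTAT"),
            ("b1", "Coelogyne_ovalis", "TGCATGCATG"),
            ("b2", "Coelogyne_ovalis", "TGCATGCATC"),
        ],
    )


@pytest.fixture
def clean_sim():
    """Small clean simulated dataset shared by several test modules."""
    cfg = SimulationConfig(
        n_species=10,
        individuals_per_species=4,
        seq_length=500,
        inter_scale=0.2,
        intra_scale=0.005,
        n_confusable_pairs=0,
        missing_fraction=0.0,
        seed=42,
    )
    aln, tree, pairs = simulate_alignment(cfg)
    return cfg, aln


def random_sequences(rng: random.Random, length: int, n: int, gap_rate=0.1):
    """Random gapped DNA strings for property-style checks."""
    alphabet = "ACGT" * 9 + "-N"
    return [
        "".join(rng.choice(alphabet) for _ in range(length)) for _ in range(n)
    ]
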