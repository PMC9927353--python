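import numpy as np
import pytest

from aidmap import (GeneFeature, GenomeModel, SimParams, SNPRecord, SNPSet,
                    generate_genome, plant_boxes, simulate_experiment)


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    """Deterministic 100-kb genome with 50 genes."""
    return generate_genome(100_000, 50, seed=11)


@pytest.fixture(scope="session")
def planted_scenario():
    """Genome + planted boxes + three simulated replicates (fixed seeds)."""
    genome = generate_genome(100_000, 50, seed=11)
    boxes = plant_boxes(genome, 10, seed=12)
    params = SimParams(seed=13)
    replicates = simulate_experiment(genome, boxes, params, n_replicates=3)
    return genome, boxes, params, replicates


@pytest.fixture
def toy_genome() -> GenomeModel:
    """Tiny hand-laid genome: ←g1 .. g2→ .. g3→ .. ←g4 (divergent and
    convergent intergenic regions plus gene bodies)."""
    seq = "".join("ACGT"[(i * 7) % 4] for i in range(3000))
    genes = [
        GeneFeature("g1", "c1", 200, 500, "-"),
        GeneFeature("g2", "c1", 800, 1100, "+"),   # (500,800) divergent: up of g1+g2
        GeneFeature("g3", "c1", 1400, 1700, "+"),  # (1100,1400) up of g3 only
        GeneFeature("g4", "c1", 2000, 2300, "-"),  # (1700,2000) convergent: g3-> <-g4
    ]
    return GenomeModel({"c1": seq}, genes)


def make_snp(pos: int, contig: str = "c1", ref: str = "C", alt: str = "T",
             ref_depth: int | None = 70, alt_depth: int | None = 30) -> SNPRecord:
    return SNPRecord(contig=contig, pos=pos, ref=ref, alt=alt,
                     ref_depth=ref_depth, alt_depth=alt_depth)


def random_snpset(rng: np.random.Generator, n: int, span: int = 1_000_000,
                  label: str = "s") -> SNPSet:
    """n distinct random SNPs over [0, span) with random alleles and depths."""
    positions = rng.choice(span, size=n, replace=False)
    out = SNPSet(label=label)
    for pos in positions:
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        alt_depth = int(rng.integers(5, 95))
        out.add(SNPRecord(contig="c1", pos=int(pos), ref=str(ref), alt=str(alt),
                          ref_depth=100 - alt_depth, alt_depth=alt_depth))
    return out
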