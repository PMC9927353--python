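"""Synthetic deaminase-mutagenesis experiments with known ground truth.

Emulates the full experimental readout: a random bacterial-style genome
with annotated genes, TF-binding boxes planted in promoter-like
intergenic regions, TF-directed cytidine deamination whose per-site
rate decays with distance from the box, stochastic background
mutations, allele-frequency build-up over serial-passage generations,
and binomial read sampling with caller-style detection thresholds.
Every replicate is reproducible bit-for-bit from its seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .genome_io import GeneFeature, GenomeModel, SNPRecord, SNPSet, revcomp
from .stats import distance_to_box

BASES = "ACGT"

#: Default planted binding-box consensus: 16 bp with CTGT...ACAG ends and
#: an AT-rich core, the reverse-symmetric shape typical of LuxR-family
#: operator boxes.
DEFAULT_CONSENSUS = "CTGTAAATTTTTACAG"


@dataclass(frozen=True, slots=True)
class TFBox:
    """A TF-binding box interval with its occupancy.

    ``occupancy`` is the probability that the box is TF-bound, i.e. the
    first-order binding isotherm [TF]/([TF]+Kd); it scales the directed
    deamination rate at and around the box.
    """

    contig: str
    start: int
    end: int
    strand: str = "+"
    occupancy: float = 1.0
    promoter_gene: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if not self.start < self.end:
            raise ValueError("empty box interval")


@dataclass(frozen=True, slots=True)
class SimParams:
    """Parameters of the simulated mutagenesis experiment.

    mu0
        Per-generation deamination probability of a C at distance 0 from
        a fully occupied box.
    window_scale
        Exponential decay length (bp) of editability with distance from
        the box; with the 15-bp default most directed events fall within
        ~40 bp of the box.
    window_max
        Hard cutoff (bp) beyond which the directed rate is zero.
    p_bg
        Per-generation, per-bp stochastic background mutation
        probability; the default compounds over 24 generations to a
        per-experiment rate just under 1e-4 per bp.
    generations
        Number of generations under induction; 24 corresponds to two
        12-h culture rounds with 5x dilution between them.
    s
        Selection coefficient against mutants (0 = neutral).
    depth
        Sequencing depth per site.
    detect_min_frac / detect_min_alt
        Caller emulation: a variant is reported only if the alt read
        fraction and alt read count reach these thresholds.
    """

    mu0: float = 0.015
    window_scale: float = 15.0
    window_max: int = 100
    p_bg: float = 4e-6
    generations: int = 24
    s: float = 0.0
    depth: int = 100
    detect_min_frac: float = 0.1
    detect_min_alt: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu0", "p_bg", "detect_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.window_scale <= 0:
            raise ValueError("window_scale must be positive")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.s < 1.0:
            raise ValueError("s must be in [0, 1)")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(length: int, n_genes: int, seed: int,
                    contig: str = "sim1",
                    gene_length_range: tuple[int, int] = (300, 900),
                    min_gap: int = 150) -> GenomeModel:
    """Random genome with non-overlapping gene bodies and random strands.

    Gene lengths are drawn uniformly from ``gene_length_range`` and the
    leftover sequence is distributed over the ``n_genes + 1`` intergenic
    gaps (each at least ``min_gap`` bp so binding boxes fit).  The same
    seed reproduces the genome byte-for-byte.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), size=length))
    if n_genes == 0:
        return GenomeModel({contig: seq}, [])
    lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1,
                           size=n_genes)
    slack = length - int(lengths.sum()) - (n_genes + 1) * min_gap
    if slack < 0:
        raise ValueError(
            f"cannot pack {n_genes} genes of total {int(lengths.sum())} bp plus "
            f"{(n_genes + 1) * min_gap} bp of gaps into {length} bp")
    extra = rng.multinomial(slack, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    genes: list[GeneFeature] = []
    cursor = 0
    for i in range(n_genes):
        cursor += min_gap + int(extra[i])
        start = cursor
        end = start + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(gene_id=f"g{i + 1:04d}", contig=contig,
                                 start=start, end=end, strand=strand))
        cursor = end
    return GenomeModel({contig: seq}, genes)


# ---------------------------------------------------------------------------
# Box planting
# ---------------------------------------------------------------------------

OccupancyDist = float | tuple[float, float] | Callable[[np.random.Generator], float]


def _draw_occupancy(dist: OccupancyDist, rng: np.random.Generator) -> float:
    if callable(dist):
        return float(dist(rng))
    if isinstance(dist, tuple):
        lo, hi = dist
        return float(rng.uniform(lo, hi))
    return float(dist)


def _promoter_gaps(genome: GenomeModel, contig: str) -> list[tuple[int, int, GeneFeature]]:
    """Intergenic gaps that are 5'-adjacent to at least one gene.

    Returns (gap_start, gap_end, downstream_gene) with the downstream
    gene being the one whose 5' end faces the gap (the right neighbour
    on '+', else the left neighbour on '-').
    """
    genes = genome.genes_on(contig)
    out = []
    for gs, ge in genome.intergenic[contig]:
        right = next((g for g in genes if g.start >= ge), None)
        left = next((g for g in reversed(genes) if g.end <= gs), None)
        if right is not None and right.strand == "+":
            out.append((gs, ge, right))
        elif left is not None and left.strand == "-":
            out.append((gs, ge, left))
    return out


def plant_boxes(genome: GenomeModel, n_boxes: int, seed: int,
                consensus: str = DEFAULT_CONSENSUS,
                occupancy_dist: OccupancyDist = (0.5, 1.0),
                margin: int = 10) -> list[TFBox]:
    """Write binding-box consensus copies into promoter-like intergenic DNA.

    Each box goes into a distinct intergenic gap that lies 5' of a gene,
    at least ``margin`` bp clear of the flanking gene bodies; the box is
    recorded with that downstream gene and an occupancy drawn from
    ``occupancy_dist``.  Minus-strand boxes carry the reverse complement
    of the consensus.  The genome sequence is modified in place.
    """
    rng = np.random.default_rng(seed)
    boxes: list[TFBox] = []
    w = len(consensus)
    for contig in genome.contigs:
        candidates = [(gs, ge, g) for gs, ge, g in _promoter_gaps(genome, contig)
                      if ge - gs >= w + 2 * margin]
        if len(candidates) < n_boxes:
            raise ValueError(
                f"only {len(candidates)} promoter-like gaps can hold a "
                f"{w}-bp box with {margin}-bp margins; need {n_boxes}")
        chosen = rng.choice(len(candidates), size=n_boxes, replace=False)
        seq = genome.contigs[contig]
        for idx in sorted(int(i) for i in chosen):
            gs, ge, gene = candidates[idx]
            start = int(rng.integers(gs + margin, ge - margin - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = consensus if strand == "+" else revcomp(consensus)
            seq = seq[:start] + inserted + seq[start + w:]
            boxes.append(TFBox(contig=contig, start=start, end=start + w,
                               strand=strand,
                               occupancy=_draw_occupancy(occupancy_dist, rng),
                               promoter_gene=gene.gene_id))
        genome.set_sequence(contig, seq)
        break  # single-contig genomes at test scale
    return boxes


# ---------------------------------------------------------------------------
# Editing and frequency dynamics
# ---------------------------------------------------------------------------

def site_edit_prob(box: TFBox, pos: int, params: SimParams,
                   base: str | None = None, genome: GenomeModel | None = None) -> float:
    """Per-generation directed deamination probability at one site.

    mu0 · occupancy · exp(-d / window_scale), with the distance d
    clipped to 0 inside the box, and exactly 0 beyond ``window_max`` or
    when the reference base is not a C or G (no deaminatable C on
    either strand).
    """
    if base is None:
        if genome is None:
            raise ValueError("need the reference base or the genome")
        base = genome.contigs[box.contig][pos]
    if base not in ("C", "G"):
        return 0.0
    d = max(distance_to_box(pos, box), 0)
    if d > params.window_max:
        return 0.0
    return params.mu0 * box.occupancy * math.exp(-d / params.window_scale)


def freq_after_generations(mu_site: float, G: int, s: float = 0.0) -> float:
    """Population mutant frequency after G generations of editing + selection.

    Each generation the unmutated fraction converts with probability
    ``mu_site`` (f ← f + (1-f)·mu), then selection at coefficient ``s``
    rescales mutant growth (f ← f(1-s) / (1 - f·s)).  With s = 0 this
    telescopes to the closed form 1 - (1 - mu_site)^G.
    """
    if not 0.0 <= mu_site <= 1.0:
        raise ValueError("mu_site must be a probability")
    if s == 0.0:
        return 1.0 - (1.0 - mu_site) ** G
    f = 0.0
    for _ in range(G):
        f = f + (1.0 - f) * mu_site
        f = f * (1.0 - s) / (1.0 - f * s)
    return f


# ---------------------------------------------------------------------------
# Replicate simulation
# ---------------------------------------------------------------------------

def simulate_replicate(genome: GenomeModel, boxes: Sequence[TFBox],
                       params: SimParams, replicate_seed: int,
                       label: str | None = None) -> SNPSet:
    """One sequenced replicate of the mutagenesis experiment.

    Directed events: every C/G within ``window_max`` of a box reaches
    population frequency ``freq_after_generations(site_edit_prob(...))``
    deterministically; a reference C yields a C→T record and a reference
    G a G→A record (the C on the minus strand was edited).  Background
    events: each position mutates with the compounded per-experiment
    probability 1-(1-p_bg)^G to a random different base; its frequency
    is 2^-g for a uniformly drawn generation of origin g, the jackpot
    profile of a mutation arising early versus late in the expansion.
    Sequencing: alt reads ~ Binomial(depth, f); a record is emitted only
    if it passes the caller-emulation thresholds.  Output is a pure
    function of (params.seed, replicate_seed).
    """
    rng = np.random.default_rng([params.seed, replicate_seed])
    label = label or f"rep{replicate_seed}"
    snps = SNPSet(label=label)
    G, D = params.generations, params.depth

    # Per-position directed rate: overlapping box windows take the max.
    directed: dict[tuple[str, int], float] = {}
    for box in boxes:
        seq = genome.contigs[box.contig]
        lo = max(0, box.start - params.window_max)
        hi = min(len(seq), box.end + params.window_max)
        for pos in range(lo, hi):
            mu = site_edit_prob(box, pos, params, base=seq[pos])
            if mu > 0.0:
                key = (box.contig, pos)
                if mu > directed.get(key, 0.0):
                    directed[key] = mu

    for (contig, pos), mu in sorted(directed.items()):
        f = freq_after_generations(mu, G, params.s)
        alt = int(rng.binomial(D, f))
        if alt >= params.detect_min_alt and alt / D >= params.detect_min_frac:
            ref = genome.contigs[contig][pos]
            alt_base = "T" if ref == "C" else "A"
            snps.add(SNPRecord(contig=contig, pos=pos, ref=ref, alt=alt_base,
                               ref_depth=D - alt, alt_depth=alt))

    p_exp = 1.0 - (1.0 - params.p_bg) ** G
    for contig, seq in genome.contigs.items():
        n_mut = int(rng.binomial(len(seq), p_exp))
        if n_mut == 0:
            continue
        positions = rng.choice(len(seq), size=n_mut, replace=False)
        for pos in sorted(int(p) for p in positions):
            if (contig, pos) in directed:
                continue  # directed signal dominates at these sites
            ref = seq[pos]
            if ref == "N":
                continue
            alt_base = BASES.replace(ref, "")[int(rng.integers(0, 3))]
            g_origin = int(rng.integers(1, G + 1))
            f = min(1.0, 2.0 ** -g_origin)
            if params.s > 0.0:
                f = f * (1.0 - params.s) ** (G - g_origin)
            alt = int(rng.binomial(D, f))
            if alt >= params.detect_min_alt and alt / D >= params.detect_min_frac:
                key = (contig, pos, ref, alt_base)
                if key not in snps:
                    snps.add(SNPRecord(contig=contig, pos=pos, ref=ref,
                                       alt=alt_base, ref_depth=D - alt,
                                       alt_depth=alt))
    return snps


def simulate_experiment(genome: GenomeModel, boxes: Sequence[TFBox],
                        params: SimParams, n_replicates: int = 3,
                        label: str = "tf") -> list[SNPSet]:
    """Parallel replicates of one experiment (distinct replicate seeds)."""
    return [simulate_replicate(genome, boxes, params, replicate_seed=i + 1,
                               label=f"{label}_r{i + 1}")
            for i in range(n_replicates)]


def population_mc_frequency(mu_site: float, G: int, s: float, n_cells: int,
                            rng: np.random.Generator) -> float:
    """Agent-free Monte-Carlo oracle for :func:`freq_after_generations`.

    Tracks mutant/wild-type counts in a population of ``n_cells``: each
    generation wild-type cells convert Binomial(n_wt, mu), then the next
    generation is resampled with mutant fitness (1-s).  Used to validate
    the deterministic recursion, not as the default engine.
    """
    n_mut = 0
    for _ in range(G):
        n_mut += int(rng.binomial(n_cells - n_mut, mu_site))
        if s > 0.0 and 0 < n_mut < n_cells:
            w_mut = n_mut * (1.0 - s)
            p = w_mut / (w_mut + (n_cells - n_mut))
            n_mut = int(rng.binomial(n_cells, p))
    return n_mut / n_cells
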