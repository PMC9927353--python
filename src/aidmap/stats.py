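"""Summary statistics for deaminase-directed TF-target mapping.

Covers the quantities used to judge a run: the expected number of
replicate-shared stochastic mutations (N·p0^k), SNP-to-binding-box
distances, template/coding strand classification of C deamination,
per-promoter peak mutation frequency, pairwise replicate R², and
benchmarking of detected promoter targets against a reference list.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .genome_io import GeneFeature, SNPRecord, SNPSet

if TYPE_CHECKING:  # pragma: no cover
    from .profiler import AttributedSNP
    from .simulate import TFBox


# ---------------------------------------------------------------------------
# Stochastic replicate sharing
# ---------------------------------------------------------------------------

def expected_shared_stochastic(N: float, p0: float, k: int = 3) -> float:
    """Expected count of background SNP positions shared by k replicates.

    If stochastic (non-TF-directed) mutations hit each of N positions
    independently with probability ``p0`` per experiment, a position is
    mutated in all ``k`` independent replicates with probability
    ``p0**k``, so the expected replicate-shared count is ``N * p0**k``.
    For a bacterial genome (N ~ 1e6–1e7) at p0 ≤ 1e-4 and k = 3 this is
    far below one, which is what makes replicate intersection an
    effective background filter.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    if k < 1:
        raise ValueError("k must be >= 1")
    return N * p0 ** k


def simulate_shared_count(N: int, p0: float, k: int, n_seeds: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo counterpart of :func:`expected_shared_stochastic`.

    Draws k independent Bernoulli(p0) mutation masks over N positions
    per seed and counts positions mutated in all k replicates.  Returns
    the per-seed shared counts (length ``n_seeds``).
    """
    counts = np.empty(n_seeds, dtype=np.int64)
    for i in range(n_seeds):
        shared = np.ones(N, dtype=bool)
        for _ in range(k):
            shared &= rng.random(N) < p0
        counts[i] = int(shared.sum())
    return counts


# ---------------------------------------------------------------------------
# Distance to binding box
# ---------------------------------------------------------------------------

def distance_to_box(pos: int, box: "TFBox | Sequence[TFBox]",
                    contig: str | None = None) -> int:
    """Signed distance (bp) from a SNP position to the nearest box base.

    Outside the box the value is the gap to the nearest box base, with
    the immediately adjacent base at distance 1.  A negative value means
    the SNP sits inside the box: -(1 + bases to the nearest box edge),
    so the first/last box base is -1.  Given a list of boxes the nearest
    one wins; ties break toward the lower-coordinate box.  If ``contig``
    is given it must match the box's contig.
    """
    boxes = box if isinstance(box, (list, tuple)) else [box]
    if not boxes:
        raise ValueError("no boxes given")
    if contig is not None:
        mismatched = [b for b in boxes if b.contig != contig]
        if mismatched:
            raise ValueError(f"box on contig {mismatched[0].contig}, SNP on {contig}")
    best: int | None = None
    for b in sorted(boxes, key=lambda b: b.start):
        d = _distance_one(pos, b)
        if best is None or abs(d) < abs(best):
            best = d
    return best  # type: ignore[return-value]


def _distance_one(pos: int, box: "TFBox") -> int:
    if pos < box.start:
        return box.start - pos
    if pos >= box.end:
        return pos - (box.end - 1)
    return -(1 + min(pos - box.start, box.end - 1 - pos))


def distance_table(snps: Iterable[SNPRecord], boxes: "Sequence[TFBox]") -> "DistanceStat":
    """Per-SNP signed distances to the nearest box, with mean and median."""
    per_snp: list[tuple[SNPRecord, int]] = []
    for snp in snps:
        same = [b for b in boxes if b.contig == snp.contig]
        if not same:
            raise ValueError(f"no box on contig {snp.contig}")
        per_snp.append((snp, distance_to_box(snp.pos, same)))
    dists = np.array([d for _, d in per_snp], dtype=float)
    return DistanceStat(
        distances=per_snp,
        mean=float(dists.mean()) if len(dists) else float("nan"),
        median=float(np.median(dists)) if len(dists) else float("nan"),
    )


@dataclass(frozen=True)
class DistanceStat:
    distances: list[tuple[SNPRecord, int]]
    mean: float
    median: float


# ---------------------------------------------------------------------------
# Strand classification of deamination events
# ---------------------------------------------------------------------------

def strand_class(snp: SNPRecord, gene: GeneFeature) -> str:
    """Which strand of a gene carried the deaminated C: ``TS`` or ``CS``.

    A C→T on the reference strand means the deaminated C was on the
    plus strand; for a plus-strand gene that is the coding strand (CS),
    for a minus-strand gene the template strand (TS).  A G→A on the
    reference strand is a C→T on the minus strand, so the classes swap.
    Any other substitution is not a deaminase signature and is rejected.
    """
    if (snp.ref, snp.alt) == ("C", "T"):
        edited_plus = True
    elif (snp.ref, snp.alt) == ("G", "A"):
        edited_plus = False
    else:
        raise ValueError(
            f"{snp.ref}>{snp.alt} is not a C>T/G>A deamination signature")
    if gene.strand == "+":
        return "CS" if edited_plus else "TS"
    return "TS" if edited_plus else "CS"


def strand_class_counts(pairs: Iterable[tuple[SNPRecord, GeneFeature]]) -> Counter:
    counts: Counter = Counter()
    for snp, gene in pairs:
        counts[strand_class(snp, gene)] += 1
    return counts


# ---------------------------------------------------------------------------
# Per-promoter peak frequency
# ---------------------------------------------------------------------------

def promoter_peak_frequency(attributed: "Iterable[AttributedSNP]") -> dict[str, float]:
    """Per promoter, the maximum SNP mutation frequency.

    When one promoter region holds several mutation sites, the site with
    the highest frequency represents the promoter's degree of mutation.
    Promoters are keyed by downstream gene id; a divergent intergenic
    region upstream of two genes contributes to both keys.  SNPs with
    unknown frequency are ignored.
    """
    peaks: dict[str, float] = {}
    for a in attributed:
        if a.region_class != "promoter_like":
            continue
        freq = a.snp.frequency
        if freq is None and a.snp.rep_freqs:
            known = [f for f in a.snp.rep_freqs if f is not None]
            freq = max(known) if known else None
        if freq is None:
            continue
        for gid in a.upstream_of:
            if gid not in peaks or freq > peaks[gid]:
                peaks[gid] = freq
    return peaks


# ---------------------------------------------------------------------------
# Replicate reproducibility
# ---------------------------------------------------------------------------

def replicate_r2(consensus: SNPSet) -> dict[tuple[int, int], float | None]:
    """Pairwise R² of per-replicate mutation frequencies over shared SNPs.

    ``consensus`` must come from replicate intersection so that each
    record carries ``rep_freqs``.  For every replicate pair (i, j), i<j,
    an ordinary least-squares regression of replicate j's frequencies on
    replicate i's gives the coefficient of determination.  Three
    replicates yield the three printed values.  A pair with a constant
    frequency vector has no defined R² and is reported as ``None``.
    """
    freqs = [r.rep_freqs for r in consensus]
    if not freqs or any(f is None for f in freqs):
        raise ValueError("records lack per-replicate frequencies; run replicate "
                         "intersection first")
    n_rep = len(freqs[0])
    out: dict[tuple[int, int], float | None] = {}
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            x, y = [], []
            for f in freqs:
                if f[i] is not None and f[j] is not None:
                    x.append(f[i])
                    y.append(f[j])
            if len(x) < 2:
                raise ValueError(f"fewer than 2 shared SNPs with known frequencies "
                                 f"for replicate pair ({i}, {j})")
            xa, ya = np.asarray(x), np.asarray(y)
            if np.ptp(xa) == 0 or np.ptp(ya) == 0:
                out[(i, j)] = None
                continue
            res = sps.linregress(xa, ya)
            out[(i, j)] = float(res.rvalue ** 2)
    return out


# ---------------------------------------------------------------------------
# Benchmarking against reference target lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkResult:
    """Three-way comparison of detected vs previously reported targets."""

    overlap: int
    new_targets: int
    not_detected: int
    overlap_ids: frozenset[str]
    new_ids: frozenset[str]
    missed_ids: frozenset[str]

    def __post_init__(self) -> None:
        assert self.overlap == len(self.overlap_ids)
        assert self.new_targets == len(self.new_ids)
        assert self.not_detected == len(self.missed_ids)


def venn_compare(detected: Iterable[str], reference: Iterable[str]) -> BenchmarkResult:
    """Overlap / new-target / not-detected counts for promoter-target sets.

    ``overlap`` counts detected targets that were previously reported,
    ``new_targets`` those that were not, and ``not_detected`` reported
    targets the screen missed; ids must share one namespace.
    """
    det, ref = set(detected), set(reference)
    return BenchmarkResult(
        overlap=len(det & ref),
        new_targets=len(det - ref),
        not_detected=len(ref - det),
        overlap_ids=frozenset(det & ref),
        new_ids=frozenset(det - ref),
        missed_ids=frozenset(ref - det),
    )


def detected_promoter_ids(attributed: "Iterable[AttributedSNP]") -> set[str]:
    """Promoter-target ids from an attributed SNP table.

    Uses the downstream gene id of each promoter-like region; a
    divergent region upstream of two genes emits both ids, and a match
    on either counts as overlap downstream.
    """
    ids: set[str] = set()
    for a in attributed:
        if a.region_class == "promoter_like":
            ids.update(a.upstream_of)
    return ids


# ---------------------------------------------------------------------------
# SNPs per box
# ---------------------------------------------------------------------------

def snps_per_box(snps: Iterable[SNPRecord], boxes: "Sequence[TFBox]",
                 window: int = 100) -> tuple[dict[int, int], Counter]:
    """Count SNPs within ``window`` bp of each box; histogram the counts.

    Returns ``(per_box, histogram)`` where ``per_box[i]`` is the SNP
    count for ``boxes[i]`` (in-box SNPs count, distance ≤ window) and
    ``histogram`` maps a per-box count to the number of boxes with it.
    """
    snp_list = list(snps)
    per_box: dict[int, int] = {}
    for i, box in enumerate(boxes):
        n = 0
        for snp in snp_list:
            if snp.contig != box.contig:
                continue
            if distance_to_box(snp.pos, box) <= window:
                n += 1
        per_box[i] = n
    return per_box, Counter(per_box.values())
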