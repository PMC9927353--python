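"""Summary statistics: sharing bound, distances, strands, R², benchmarking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aidmap import (SNPSet, distance_to_box, expected_shared_stochastic,
                    promoter_peak_frequency, replicate_r2, simulate_shared_count,
                    snps_per_box, strand_class, venn_compare)
from aidmap.genome_io import GeneFeature, SNPRecord
from aidmap.profiler import AttributedSNP
from aidmap.simulate import TFBox

from conftest import make_snp


# ---------------------------------------------------------------------------
# expected_shared_stochastic
# ---------------------------------------------------------------------------

def test_expected_shared_arithmetic():
    assert expected_shared_stochastic(6.3e6, 1e-4, 3) == pytest.approx(6.3e-6)
    assert expected_shared_stochastic(1e6, 0.0, 3) == 0.0
    assert expected_shared_stochastic(1e6, 2e-4, 1) == pytest.approx(200.0)


@pytest.mark.parametrize("p0", [1e-5, 1e-4, 1e-3])
@pytest.mark.parametrize("k", [2, 3])
def test_expected_shared_matches_bernoulli_monte_carlo(p0, k):
    """N·p0^k vs direct Bernoulli simulation, within 3 standard errors.

    N is scaled so the expectation is resolvable at every (p0, k)
    without genome-scale arrays; the prediction is linear in N.
    """
    rng = np.random.default_rng(17)
    N = 200_000 if p0 >= 1e-4 else 400_000
    n_seeds = 200
    counts = simulate_shared_count(N, p0, k, n_seeds, rng)
    predicted = expected_shared_stochastic(N, p0, k)
    se = counts.std(ddof=1) / math.sqrt(n_seeds)
    assert abs(counts.mean() - predicted) <= max(3 * se, 3 / n_seeds)


# ---------------------------------------------------------------------------
# distance_to_box
# ---------------------------------------------------------------------------

BOX = TFBox(contig="c1", start=100, end=116)


def test_distance_sign_convention():
    assert distance_to_box(116 - 1 + 25, BOX) == 25  # 25 bp right of last base
    assert distance_to_box(100, BOX) == -1           # first box base
    assert distance_to_box(115, BOX) == -1           # last box base
    assert distance_to_box(107, BOX) == -8           # deepest interior
    assert distance_to_box(99, BOX) == 1             # adjacent base
    assert distance_to_box(116, BOX) == 1


def test_distance_requires_matching_contig():
    with pytest.raises(ValueError, match="contig"):
        distance_to_box(50, BOX, contig="c2")


def _brute_force_distance(pos: int, box: TFBox) -> int:
    gaps = [abs(pos - b) for b in range(box.start, box.end)]
    if box.start <= pos < box.end:
        return -(1 + min(pos - box.start, box.end - 1 - pos))
    return min(gaps) # nearest box base, adjacent base = 1


@given(pos=st.integers(0, 500), start=st.integers(0, 480),
       width=st.integers(1, 20))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_distance_matches_per_base_scan_oracle(pos, start, width):
    box = TFBox(contig="c1", start=start, end=start + width)
    assert distance_to_box(pos, box) == _brute_force_distance(pos, box)


@given(pos=st.integers(0, 500), start=st.integers(0, 480),
       width=st.integers(1, 20))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_distance_symmetric_under_coordinate_reflection(pos, start, width):
    L = 1000
    box = TFBox(contig="c1", start=start, end=start + width)
    mirrored = TFBox(contig="c1", start=L - (start + width), end=L - start)
    assert distance_to_box(pos, box) == distance_to_box(L - 1 - pos, mirrored)


def test_nearest_box_wins_with_low_coordinate_tiebreak():
    near = TFBox(contig="c1", start=0, end=10)
    far = TFBox(contig="c1", start=100, end=110)
    assert distance_to_box(30, [near, far]) == 21
    # equidistant: 55 is 46 bp from each; value is the same either way
    assert distance_to_box(54, [near, far]) == 45


# ---------------------------------------------------------------------------
# strand_class
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ref,alt,strand,expected", [
    ("C", "T", "+", "CS"),
    ("G", "A", "+", "TS"),
    ("C", "T", "-", "TS"),
    ("G", "A", "-", "CS"),
])
def test_strand_class_convention(ref, alt, strand, expected):
    gene = GeneFeature("g", "c1", 0, 100, strand)
    snp = make_snp(150, ref=ref, alt=alt)
    assert strand_class(snp, gene) == expected


def test_strand_class_rejects_non_deamination_substitutions():
    gene = GeneFeature("g", "c1", 0, 100, "+")
    with pytest.raises(ValueError, match="signature"):
        strand_class(make_snp(10, ref="A", alt="G"), gene)


def test_symmetric_editing_gives_balanced_strand_classes(planted_scenario):
    """With strand-symmetric editing, TS:CS ≈ 1 (binomial test not rejecting)."""
    from scipy.stats import binomtest

    from aidmap import run_profile

    genome, boxes, params, reps = planted_scenario
    res = run_profile(reps, genome)
    counts = {"TS": 0, "CS": 0}
    gene_by_id = {g.gene_id: g for g in genome.genes}
    for a in res.promoter_snps:
        gene = gene_by_id[a.upstream_of[0]]
        counts[strand_class(a.snp, gene)] += 1
    n = counts["TS"] + counts["CS"]
    assert n > 30
    assert binomtest(counts["TS"], n, 0.5).pvalue > 0.01


# ---------------------------------------------------------------------------
# promoter_peak_frequency
# ---------------------------------------------------------------------------

def _attr(pos, freq_pair, upstream):
    rec = SNPRecord(contig="c1", pos=pos, ref="C", alt="T",
                    ref_depth=int(round(100 * (1 - freq_pair))),
                    alt_depth=int(round(100 * freq_pair)))
    return AttributedSNP(snp=rec, region_class="promoter_like",
                         upstream_of=upstream)


def test_peak_frequency_takes_group_maximum():
    attributed = [_attr(10, 0.1, ("gA",)), _attr(20, 0.4, ("gA",)),
                  _attr(30, 0.2, ("gA",)), _attr(40, 0.3, ("gB", "gC"))]
    peaks = promoter_peak_frequency(attributed)
    assert peaks["gA"] == pytest.approx(0.4)
    assert peaks["gB"] == peaks["gC"] == pytest.approx(0.3)
    assert "gD" not in peaks  # empty group → absent key


def test_peak_frequency_matches_max_oracle():
    rng = np.random.default_rng(5)
    attributed, oracle = [], {}
    for i, pos in enumerate(rng.choice(10_000, 200, replace=False)):
        gid = f"g{int(rng.integers(0, 20))}"
        f = round(float(rng.uniform(0.05, 0.95)), 2)
        attributed.append(_attr(int(pos), f, (gid,)))
        oracle[gid] = max(oracle.get(gid, 0.0), f)
    peaks = promoter_peak_frequency(attributed)
    assert set(peaks) == set(oracle)
    for gid in oracle:
        assert peaks[gid] == pytest.approx(oracle[gid], abs=5e-3)


# ---------------------------------------------------------------------------
# replicate_r2
# ---------------------------------------------------------------------------

def _consensus_with_freqs(freq_triples):
    out = SNPSet(label="consensus")
    for i, triple in enumerate(freq_triples):
        out.add(SNPRecord(contig="c1", pos=i, ref="C", alt="T",
                          rep_freqs=tuple(triple)))
    return out


def test_identical_and_exactly_linear_frequencies_give_r2_of_one():
    vals = [0.1, 0.25, 0.4, 0.7]
    identical = _consensus_with_freqs([(v, v, v) for v in vals])
    assert all(r == pytest.approx(1.0) for r in replicate_r2(identical).values())
    linear = _consensus_with_freqs([(v, min(2 * v, 1.0), v) for v in [0.1, 0.2, 0.3, 0.4]])
    assert replicate_r2(linear)[(0, 1)] == pytest.approx(1.0)


def test_r2_matches_textbook_formula_oracle():
    rng = np.random.default_rng(6)
    x = rng.uniform(0.05, 0.95, 50)
    y = np.clip(0.8 * x + rng.normal(0, 0.05, 50), 0, 1)
    z = rng.uniform(0.05, 0.95, 50)
    consensus = _consensus_with_freqs(zip(x, y, z))
    r2 = replicate_r2(consensus)

    def oracle(a, b):  # squared Pearson correlation == OLS R² with intercept
        a, b = np.asarray(a), np.asarray(b)
        cov = ((a - a.mean()) * (b - b.mean())).sum()
        return cov ** 2 / (((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())

    assert r2[(0, 1)] == pytest.approx(oracle(x, y), abs=1e-12)
    assert r2[(0, 2)] == pytest.approx(oracle(x, z), abs=1e-12)
    assert r2[(1, 2)] == pytest.approx(oracle(y, z), abs=1e-12)


def test_constant_vector_reports_undefined_not_zero():
    consensus = _consensus_with_freqs([(0.3, 0.1, 0.5), (0.3, 0.6, 0.2),
                                       (0.3, 0.4, 0.9)])
    r2 = replicate_r2(consensus)
    assert r2[(0, 1)] is None and r2[(0, 2)] is None
    assert r2[(1, 2)] is not None


# ---------------------------------------------------------------------------
# venn_compare
# ---------------------------------------------------------------------------

def test_venn_identity_cases():
    same = venn_compare({"a", "b", "c"}, {"a", "b", "c"})
    assert (same.overlap, same.new_targets, same.not_detected) == (3, 0, 0)
    disjoint = venn_compare({"a", "b"}, {"c", "d", "e"})
    assert (disjoint.overlap, disjoint.new_targets, disjoint.not_detected) == (0, 2, 3)


@given(det=st.sets(st.integers(0, 50)), ref=st.sets(st.integers(0, 50)))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_venn_count_identities_hold_on_every_input(det, ref):
    """overlap + new = |detected| and overlap + not_detected = |reference|."""
    r = venn_compare({str(i) for i in det}, {str(i) for i in ref})
    assert r.overlap + r.new_targets == len(det)
    assert r.overlap + r.not_detected == len(ref)


def test_venn_reproduces_reported_target_partition():
    """32 detected promoters of which 21 previously known, against a
    36-promoter reference, must give (21, 11, 15)."""
    known = {f"known{i}" for i in range(21)}
    detected = known | {f"new{i}" for i in range(11)}
    reference = known | {f"missed{i}" for i in range(15)}
    r = venn_compare(detected, reference)
    assert (r.overlap, r.new_targets, r.not_detected) == (21, 11, 15)


# ---------------------------------------------------------------------------
# snps_per_box
# ---------------------------------------------------------------------------

def test_no_snps_gives_all_zero_boxes():
    boxes = [TFBox(contig="c1", start=i * 1000, end=i * 1000 + 16)
             for i in range(5)]
    per_box, hist = snps_per_box([], boxes, window=100)
    assert per_box == {i: 0 for i in range(5)}
    assert hist == {0: 5}


def test_snps_per_box_consistent_with_distance_oracle(planted_scenario):
    from aidmap import run_profile

    genome, boxes, params, reps = planted_scenario
    res = run_profile(reps, genome)
    snps = [a.snp for a in res.attributed]
    per_box, hist = snps_per_box(snps, boxes, window=100)
    for i, box in enumerate(boxes):
        oracle = sum(1 for s in snps if s.contig == box.contig
                     and distance_to_box(s.pos, box) <= 100)
        assert per_box[i] == oracle
    assert sum(hist.values()) == len(boxes)
    assert min(per_box.values()) >= 1  # every planted box recovered
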