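"""Replicate-consensus SNP profiling and promoter attribution.

The screening cascade that turns per-replicate variant call sets into
TF-guided SNPs:

1. remove wild-type stock SNPs from every replicate,
2. intersect the replicates (stochastic mutations almost never recur:
   the expected replicate-shared background count is N·p0^k << 1),
3. subtract the background union SNP^negative (empty-vector and
   deaminase-only controls plus the wild-type stock),
4. drop SNPs in excluded hypermutable regions (e.g. the pf4 prophage),
5. drop SNPs recurring across too many different-TF experiments,
6. classify each survivor as promoter-like or not and attach the flank
   sequence used for motif discovery.

Every stage only ever removes records, so per-stage counts are
monotone non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genome_io import (GenomeModel, SNPRecord, SNPSet, extract_flanks,
                        write_flank_fasta)

log = logging.getLogger("aidmap")

Region = tuple[str, int, int]  # (contig, start, end), 0-based half-open

#: Approximate span of the pf4 prophage (locus tags PA0715-PA0729) on the
#: P. aeruginosa PAO1 chromosome, a hypermutable region excluded from
#: profiling.  Coordinates are approximate; supply exact ones from the
#: annotation when available.
PAO1_PF4_REGION: Region = ("NC_002516.2", 784_000, 798_000)


@dataclass(frozen=True)
class ProfilerConfig:
    """Tunables of the screening cascade.

    ``cross_tf_max_occurrences`` is the largest number of distinct TF
    experiments a SNP may appear in before it is deemed a weak-binding
    artifact (a promoter regulated by three different TFs is considered
    implausible, so the default keeps SNPs seen at most twice).
    ``count_focal_tf`` controls whether the focal experiment itself
    counts toward that number.  ``min_frequency`` optionally gates
    records below a mutation frequency; the default trusts the caller.
    """

    n_replicates: int = 3
    exclusion_regions: tuple[Region, ...] = ()
    cross_tf_max_occurrences: int = 2
    count_focal_tf: bool = True
    min_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.cross_tf_max_occurrences < 1:
            raise ValueError("cross_tf_max_occurrences must be >= 1")
        if not 0.0 <= self.min_frequency <= 1.0:
            raise ValueError("min_frequency must be in [0, 1]")


@dataclass(frozen=True)
class AttributedSNP:
    """A TF-guided SNP decorated with its genomic context.

    ``region_class`` is ``promoter_like`` for intergenic SNPs upstream
    of at least one gene (the operational promoter definition), else
    ``nonpromoter``.  Promoter-like implies ``within_gene`` is None and
    ``upstream_of`` is non-empty (two ids for divergent gene pairs).
    """

    snp: SNPRecord
    region_class: str
    upstream_of: tuple[str, ...] = ()
    within_gene: str | None = None
    flank_seq: str = ""
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in ("promoter_like", "nonpromoter"):
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.region_class == "promoter_like":
            if self.within_gene is not None or not self.upstream_of:
                raise ValueError("promoter_like requires upstream genes and no "
                                 "containing gene")


# ---------------------------------------------------------------------------
# Set-algebra stages
# ---------------------------------------------------------------------------

def intersect_replicates(sets: Sequence[SNPSet], label: str = "SNP^ori") -> SNPSet:
    """SNPs called in every replicate, with per-replicate frequencies kept.

    Identity (contig, pos, ref, alt) is the unit of agreement; depths
    may differ between replicates and are preserved per replicate in
    ``rep_freqs`` for downstream reproducibility statistics.
    """
    if len(sets) < 2:
        raise ValueError("replicate intersection needs at least 2 sets")
    shared = set.intersection(*(s.keys() for s in sets))
    out = SNPSet(label=label)
    for key in shared:
        rec = sets[0].get(key)
        out.add(rec.with_rep_freqs(s.get(key).frequency for s in sets))
    return out


def build_background(pjn_common: SNPSet, aid_common: SNPSet,
                     wt_snps: SNPSet | None = None) -> SNPSet:
    """Union of control SNP sets: the background set SNP^negative.

    Combines the replicate-consensus SNPs of the empty-vector control
    and the unfused-deaminase control, plus any wild-type stock SNPs.
    """
    out = SNPSet(label="SNP^negative")
    for source in (pjn_common, aid_common, wt_snps or SNPSet()):
        for rec in source:
            if rec.key not in out:
                out.add(rec)
    return out


def subtract_background(snp_ori: SNPSet, snp_negative: SNPSet,
                        label: str = "SNP^TF") -> SNPSet:
    """Records of SNP^ori whose identity is absent from SNP^negative."""
    out = SNPSet(label=label)
    for rec in snp_ori:
        if rec.key not in snp_negative:
            out.add(rec)
    return out


def filter_excluded_regions(snps: SNPSet, cfg: ProfilerConfig) -> SNPSet:
    """Drop SNPs falling in configured exclusion intervals."""
    trees: dict[str, IntervalTree] = {}
    for contig, start, end in cfg.exclusion_regions:
        trees.setdefault(contig, IntervalTree()).addi(start, end)
    out = SNPSet(label=snps.label)
    dropped = 0
    for rec in snps:
        tree = trees.get(rec.contig)
        if tree is not None and tree.overlaps_point(rec.pos):
            dropped += 1
            continue
        out.add(rec)
    if dropped:
        log.info("excluded-region filter dropped %d of %d SNPs", dropped, len(snps))
    return out


def filter_recurrent_cross_tf(snps: SNPSet, all_tf_sets: Mapping[str, SNPSet],
                              cfg: ProfilerConfig,
                              focal_tf: str | None = None) -> SNPSet:
    """Drop SNPs recurring in too many different-TF experiments.

    A SNP occurring in more than ``cfg.cross_tf_max_occurrences``
    distinct TF experiments is attributed to weak nonspecific binding
    and removed.  With ``cfg.count_focal_tf`` (default) the focal
    experiment counts toward the occurrence number; ``focal_tf`` names
    the focal entry of ``all_tf_sets`` so it can be excluded from the
    count in the alternative mode.
    """
    out = SNPSet(label=snps.label)
    removed: list = []
    for rec in snps:
        n = sum(1 for name, tf_set in all_tf_sets.items()
                if rec.key in tf_set and (cfg.count_focal_tf or name != focal_tf))
        if cfg.count_focal_tf and focal_tf is not None and focal_tf not in all_tf_sets:
            n += 1  # focal set not listed among the experiments
        if n > cfg.cross_tf_max_occurrences:
            removed.append(rec.key)
            continue
        out.add(rec)
    if removed:
        log.info("cross-TF recurrence filter removed %d SNPs: %s",
                 len(removed), removed)
    return out


# ---------------------------------------------------------------------------
# Promoter attribution
# ---------------------------------------------------------------------------

def classify_region(snp: SNPRecord, genome: GenomeModel,
                    flank: int = 100) -> AttributedSNP:
    """Attribute a SNP to a promoter-like or nonpromoter region.

    Promoter-like means intergenic and upstream of at least one gene:
    the nearer flanking gene on the right is on '+' (its 5' end faces
    the SNP) and/or the one on the left is on '-'.  A SNP inside any
    gene body is nonpromoter even if also upstream of another gene, and
    an intergenic SNP between two convergent 3' ends is nonpromoter.
    """
    genes = genome.genes_on(snp.contig)
    win = extract_flanks(snp, genome, flank=flank)
    if not genes:
        log.warning("contig %s has no genes; %s:%d classified nonpromoter",
                    snp.contig, snp.contig, snp.pos)
        return AttributedSNP(snp=snp, region_class="nonpromoter",
                             flank_seq=win.seq, flank_truncated=win.truncated)
    containing = next((g for g in genes if g.start <= snp.pos < g.end), None)
    if containing is not None:
        return AttributedSNP(snp=snp, region_class="nonpromoter",
                             within_gene=containing.gene_id,
                             flank_seq=win.seq, flank_truncated=win.truncated)
    left = max((g for g in genes if g.end <= snp.pos),
               key=lambda g: g.end, default=None)
    right = min((g for g in genes if g.start > snp.pos),
                key=lambda g: g.start, default=None)
    upstream = []
    if right is not None and right.strand == "+":
        upstream.append(right.gene_id)
    if left is not None and left.strand == "-":
        upstream.append(left.gene_id)
    if upstream:
        return AttributedSNP(snp=snp, region_class="promoter_like",
                             upstream_of=tuple(upstream),
                             flank_seq=win.seq, flank_truncated=win.truncated)
    return AttributedSNP(snp=snp, region_class="nonpromoter",
                         flank_seq=win.seq, flank_truncated=win.truncated)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    attributed: list[AttributedSNP]
    stage_counts: dict[str, int] = field(default_factory=dict)
    consensus: SNPSet | None = None  # post-intersection set, for R² statistics

    @property
    def promoter_snps(self) -> list[AttributedSNP]:
        return [a for a in self.attributed if a.region_class == "promoter_like"]

    @property
    def nonpromoter_snps(self) -> list[AttributedSNP]:
        return [a for a in self.attributed if a.region_class == "nonpromoter"]


def _apply_min_frequency(snps: SNPSet, min_frequency: float) -> SNPSet:
    if min_frequency <= 0.0:
        return snps
    out = SNPSet(label=snps.label)
    for rec in snps:
        freq = rec.frequency
        if freq is None or freq >= min_frequency:  # unknown depth: trust the call
            out.add(rec)
    return out


def run_profile(tf_replicates: Sequence[SNPSet],
                genome: GenomeModel,
                cfg: ProfilerConfig | None = None,
                pjn_common: SNPSet | None = None,
                aid_common: SNPSet | None = None,
                wt_snps: SNPSet | None = None,
                other_tf_sets: Mapping[str, SNPSet] | None = None,
                focal_tf: str = "focal",
                flank: int = 100) -> ProfileResult:
    """Run the whole screening cascade on one TF's replicate call sets.

    Stage order: wild-type pre-exclusion → replicate intersection →
    background subtraction → excluded-region filter → cross-TF
    recurrence filter → region classification + flank extraction.
    An empty final set is a valid outcome and is logged prominently.
    """
    cfg = cfg or ProfilerConfig()
    wt = wt_snps or SNPSet(label="wt")
    counts: dict[str, int] = {}
    counts["input_per_replicate"] = max((len(s) for s in tf_replicates), default=0)

    reps = [subtract_background(_apply_min_frequency(s, cfg.min_frequency), wt,
                                label=s.label)
            for s in tf_replicates]
    consensus = intersect_replicates(reps)
    counts["replicate_consensus"] = len(consensus)

    negative = build_background(pjn_common or SNPSet(), aid_common or SNPSet(), wt)
    counts["background_size"] = len(negative)
    snp_tf = subtract_background(consensus, negative)
    counts["after_background_subtraction"] = len(snp_tf)

    snp_tf = filter_excluded_regions(snp_tf, cfg)
    counts["after_region_exclusion"] = len(snp_tf)

    snp_tf = filter_recurrent_cross_tf(snp_tf, other_tf_sets or {}, cfg,
                                       focal_tf=focal_tf)
    counts["after_cross_tf_filter"] = len(snp_tf)

    attributed = [classify_region(rec, genome, flank=flank) for rec in snp_tf]
    counts["promoter_like"] = sum(a.region_class == "promoter_like"
                                  for a in attributed)
    counts["nonpromoter"] = len(attributed) - counts["promoter_like"]
    if not attributed:
        log.warning("profiling produced an empty TF-guided SNP set")
    return ProfileResult(attributed=attributed, stage_counts=counts,
                         consensus=consensus)


def write_profile_outputs(result: ProfileResult, genome: GenomeModel,
                          outdir, flank: int = 100) -> dict[str, str]:
    """Write the attributed TSV and the promoter/nonpromoter flank FASTAs."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in result.attributed:
        rows.append({
            "contig": a.snp.contig,
            "pos": a.snp.pos + 1,  # 1-based in reports
            "ref": a.snp.ref,
            "alt": a.snp.alt,
            "rep_freqs": ";".join("NA" if f is None else f"{f:.4f}"
                                  for f in (a.snp.rep_freqs or ())),
            "region_class": a.region_class,
            "upstream_of": ",".join(a.upstream_of),
            "within_gene": a.within_gene or "",
        })
    tsv = outdir / "attributed_snps.tsv"
    pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "rep_freqs",
                                "region_class", "upstream_of", "within_gene"]
                 ).to_csv(tsv, sep="\t", index=False)
    prom = outdir / "promoter.fasta"
    nonprom = outdir / "nonpromoter.fasta"
    write_flank_fasta((a.snp for a in result.promoter_snps), genome, prom,
                      flank=flank)
    write_flank_fasta((a.snp for a in result.nonpromoter_snps), genome, nonprom,
                      flank=flank)
    summary = outdir / "summary.json"
    summary.write_text(json.dumps({"stage_counts": result.stage_counts},
                                  indent=2) + "\n")
    return {"tsv": str(tsv), "promoter_fasta": str(prom),
            "nonpromoter_fasta": str(nonprom), "summary": str(summary)}
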