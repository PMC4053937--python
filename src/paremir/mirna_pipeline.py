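"""The two miRNA discovery routes: stringent de novo and homology-based.

The stringent route takes distinct small-RNA tags through an abundance /
size / genome-hit filter, folds candidate precursor windows around each
genome hit, places the miRNA* and demands near-perfect duplex statistics,
a strand bias >= 0.9 and an abundance bias >= 0.7.  The homology route
rescues known-miRNA loci that fail those criteria, with looser duplex
(<= 8 defects) and abundance-bias (>= 0.4) thresholds on +/-150-nt windows
anchored at known-miRNA positions, merging anchors within 100 nt.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import hairpin as hp
from .config import PipelineConfig
from .mapping import GenomeHit, TagHits, map_tags
from .normalization import TP2M, normalize
from .sequence_io import GenomeSeq, TagTable, revcomp

# rejection reasons, in evaluation order
REASONS = (
    "loop-spanning",
    "strand_bias",
    "abundance_bias",
    "not_most_abundant",
    "duplex",
    "bulge_size",
)


@dataclass(frozen=True)
class Rejection:
    reason: str
    detail: str = ""


@dataclass
class PrecursorCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # precursor-strand orientation
    structure: hp.HairpinStructure
    mir_interval: tuple[int, int]  # offsets within `sequence`
    star_interval: tuple[int, int]
    stats: hp.DuplexStats
    strand_bias: float
    abundance_bias: float


@dataclass
class MirnaCall:
    name: str
    mature_seq: str
    precursors: list[PrecursorCandidate] = field(default_factory=list)
    route: str = "stringent"  # stringent | homology | manual-family
    conservation: str = "non-conserved"


def _tp2m_values(table: TagTable, tag: str, config: PipelineConfig) -> list[float]:
    if config.tp2m_basis == "raw" or not table.genome_matched_totals:
        totals = {lib: int(table.counts[lib].sum()) for lib in table.library_ids}
    else:
        totals = table.genome_matched_totals
    return [
        normalize(table.raw(tag, lib), totals[lib], TP2M)
        for lib in table.library_ids
        if totals[lib] > 0
    ]


def tag_abundance_tp2m(table: TagTable, tag: str, config: PipelineConfig) -> float:
    """Summed per-library TP2M abundance of a tag (the locus-weight measure)."""
    return sum(_tp2m_values(table, tag, config))


def filter1_stringent(
    table: TagTable, hits: Mapping[str, TagHits], config: PipelineConfig | None = None
) -> list[str]:
    """First stringent filter: size 20-24 nt, >= 10 TP2M in >= 1 library,
    1-20 total genome hits."""
    config = config or PipelineConfig()
    out = []
    for tag in table.tags:
        if not (config.mirna_min_len <= len(tag) <= config.mirna_max_len):
            continue
        th = hits.get(tag)
        if th is None or th.exceeded or not (1 <= th.n_hits <= config.max_genome_hits):
            continue
        if max(_tp2m_values(table, tag, config), default=0.0) >= config.stringent_min_tp2m:
            out.append(tag)
    return out


def _locus_tags(
    table: TagTable,
    hits: Mapping[str, TagHits],
    chrom: str,
    lo: int,
    hi: int,
    sense_strand: str,
    config: PipelineConfig,
) -> list[hp.LocusTag]:
    """All mapped tags whose hit overlaps [lo, hi) on either strand.

    Abundance is the tag's summed TP2M; strands are reported relative to the
    precursor (sense) strand.
    """
    out = []
    for tag, th in hits.items():
        if tag not in table.counts.index:
            continue
        ab = None
        for h in th.hits:
            if h.chrom != chrom:
                continue
            if h.start < hi and h.start + len(tag) > lo:
                if ab is None:
                    ab = tag_abundance_tp2m(table, tag, config)
                rel_strand = "+" if h.strand == sense_strand else "-"
                rel_start = (
                    h.start - lo if sense_strand == "+" else hi - (h.start + len(tag))
                )
                out.append(hp.LocusTag(tag, rel_start, rel_strand, ab))
    return out


def _orient_window(genome_seq: str, lo: int, hi: int, strand: str) -> str:
    window = genome_seq[lo:hi]
    return window if strand == "+" else revcomp(window)


def _mir_offset(lo: int, hi: int, hit: GenomeHit, taglen: int) -> int:
    """Offset of the miRNA within the oriented window."""
    if hit.strand == "+":
        return hit.start - lo
    return hi - (hit.start + taglen)


def evaluate_candidate(
    tag: str,
    hit: GenomeHit,
    genome: Mapping[str, str],
    table: TagTable,
    hits: Mapping[str, TagHits],
    config: PipelineConfig,
    windows: Sequence[tuple[int, int]] | None = None,
    route: str = "stringent",
    external_structure: hp.HairpinStructure | None = None,
) -> PrecursorCandidate | Rejection:
    """Fold candidate windows around one genome hit and apply the criteria.

    Returns the passing :class:`PrecursorCandidate` or a :class:`Rejection`
    carrying the first failed criterion.  The stringent route folds two
    asymmetric windows, (hit-150, hit_end+30) and (hit-30, hit_end+150),
    covering 5'-arm and 3'-arm placements, and keeps the better hairpin.
    """
    chrom_seq = genome[hit.chrom]
    L = len(tag)
    if windows is None:
        up, down = config.homology_window_upstream, config.homology_window_downstream
        windows = [
            (hit.start - up, hit.start + L + 30),
            (hit.start - 30, hit.start + L + down),
        ]

    if route == "stringent":
        bias_min = config.abundance_bias_min_stringent
        max_defects = config.max_defects_stringent
        max_bulge = config.max_bulge_len_stringent
        min_paired = None  # locate_star default: mir_len - 4
    else:
        bias_min = config.abundance_bias_min_homology
        max_defects = config.max_defects_homology
        max_bulge = config.max_bulge_len_homology
        min_paired = L - config.max_defects_homology

    # bias criteria are evaluated first, over the union of candidate windows
    union_lo = max(0, min(lo for lo, _ in windows))
    union_hi = min(len(chrom_seq), max(hi for _, hi in windows))
    locus = _locus_tags(table, hits, hit.chrom, union_lo, union_hi, hit.strand, config)
    if not locus:
        return Rejection("strand_bias", "no mapped tags at locus")
    sb = hp.strand_bias(locus)
    if sb < config.strand_bias_min:
        return Rejection("strand_bias", f"{sb:.3f}")
    ab = hp.abundance_bias(locus)
    if ab < bias_min:
        return Rejection("abundance_bias", f"{ab:.3f}")

    # the predicted miRNA must be the most abundant overlapping sense variant
    my_ab = tag_abundance_tp2m(table, tag, config)
    mir_lo = hit.start - union_lo if hit.strand == "+" else union_hi - (hit.start + L)
    for lt in locus:
        if (
            lt.strand == "+"
            and lt.tag != tag
            and lt.start < mir_lo + L
            and lt.start + len(lt.tag) > mir_lo
            and lt.abundance > my_ab
        ):
            return Rejection("not_most_abundant", lt.tag)

    best = None
    last_error = Rejection("loop-spanning")
    for lo, hi in windows:
        lo, hi = max(0, lo), min(len(chrom_seq), hi)
        if hi - lo < L + hp.MIN_LOOP + 2:
            continue
        seq = _orient_window(chrom_seq, lo, hi, hit.strand)
        m0 = _mir_offset(lo, hi, hit, L)
        if m0 < 0 or m0 + L > len(seq):
            continue
        structure = external_structure or hp.fold_hairpin(seq)
        try:
            star_start, star_len = hp.locate_star(structure, m0, L, min_paired=min_paired)
        except hp.NoStarError as exc:
            last_error = Rejection("loop-spanning", str(exc))
            continue
        paired = sum(1 for i in range(m0, m0 + L) if structure.pair_map[i] >= 0)
        cand = (paired, structure.n_pairs, lo, hi, seq, structure, m0, star_start, star_len)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return last_error
    paired, _, lo, hi, seq, structure, m0, star_start, star_len = best

    stats = hp.duplex_stats(structure, (m0, m0 + L), (star_start, star_start + star_len))
    if stats.total_defects > max_defects:
        return Rejection("duplex", f"{stats.total_defects} defects")
    if max_bulge is not None and stats.max_bulge_len > max_bulge:
        return Rejection("bulge_size", f"max bulge {stats.max_bulge_len}")

    return PrecursorCandidate(
        chrom=hit.chrom,
        start=lo,
        end=hi,
        strand=hit.strand,
        sequence=seq,
        structure=structure,
        mir_interval=(m0, m0 + L),
        star_interval=(star_start, star_start + star_len),
        stats=stats,
        strand_bias=sb,
        abundance_bias=ab,
    )


def run_stringent_pipeline(
    table: TagTable,
    hits: Mapping[str, TagHits],
    genome: Mapping[str, str],
    config: PipelineConfig | None = None,
) -> tuple[list[MirnaCall], dict[str, list[Rejection]]]:
    """Full stringent route: filter, evaluate every hit, collect calls."""
    config = config or PipelineConfig()
    calls: list[MirnaCall] = []
    rejections: dict[str, list[Rejection]] = {}
    for tag in filter1_stringent(table, hits, config):
        precursors = []
        rejs = []
        for hit in hits[tag].hits:
            res = evaluate_candidate(tag, hit, genome, table, hits, config, route="stringent")
            if isinstance(res, Rejection):
                rejs.append(res)
            else:
                precursors.append(res)
        if precursors:
            calls.append(MirnaCall(name="", mature_seq=tag, precursors=precursors))
        if rejs:
            rejections[tag] = rejs
    return calls, rejections


def homology_pipeline(
    table: TagTable,
    hits: Mapping[str, TagHits],
    genome_seqs: Sequence[GenomeSeq],
    known: Mapping[str, str],
    config: PipelineConfig | None = None,
    exclude_tags: set[str] | None = None,
) -> tuple[list[MirnaCall], dict[str, list[Rejection]]]:
    """Homology route: rescue known-miRNA loci with relaxed criteria.

    ``known`` maps family/miRNA names to sequences; they are mapped to the
    genome with zero mismatches (20-24 nt, <= 20 hits) and small-RNA tags
    with >= 1 TP2M whose hits coincide become candidate anchors.  Anchors
    within 100 nt keep only the most abundant tag.
    """
    config = config or PipelineConfig()
    exclude_tags = exclude_tags or set()
    genome = {g.name: g.sequence for g in genome_seqs}

    known_sizes = {
        name: seq
        for name, seq in known.items()
        if config.mirna_min_len <= len(seq) <= config.mirna_max_len
    }
    known_hits = map_tags(genome_seqs, known_sizes.values(), config.max_genome_hits)
    anchor_regions: list[tuple[str, int, int, str]] = []
    for seq, th in known_hits.items():
        if th.exceeded:
            continue
        for h in th.hits:
            anchor_regions.append((h.chrom, h.start, h.start + len(seq), h.strand))

    # candidate tags: >= 1 TP2M, right size, overlapping a known-miRNA position
    anchors: list[tuple[str, GenomeHit, float]] = []
    for tag in table.tags:
        if tag in exclude_tags:
            continue
        if not (config.mirna_min_len <= len(tag) <= config.mirna_max_len):
            continue
        th = hits.get(tag)
        if th is None or th.exceeded or th.n_hits == 0 or th.n_hits > config.max_genome_hits:
            continue
        if max(_tp2m_values(table, tag, config), default=0.0) < config.homology_min_tp2m:
            continue
        ab = tag_abundance_tp2m(table, tag, config)
        for h in th.hits:
            for chrom, lo, hi, strand in anchor_regions:
                if (
                    h.chrom == chrom
                    and h.strand == strand
                    and h.start < hi
                    and h.start + len(tag) > lo
                ):
                    anchors.append((tag, h, ab))
                    break

    # same genome position: keep the most abundant tag
    by_pos: dict[tuple[str, int, str], tuple[str, GenomeHit, float]] = {}
    for tag, h, ab in anchors:
        key = (h.chrom, h.start, h.strand)
        if key not in by_pos or ab > by_pos[key][2]:
            by_pos[key] = (tag, h, ab)

    # merge anchors within merge_distance, keeping the most abundant
    merged: list[tuple[str, GenomeHit, float]] = []
    for (chrom, strand), group in itertools.groupby(
        sorted(by_pos.values(), key=lambda a: (a[1].chrom, a[1].strand, a[1].start)),
        key=lambda a: (a[1].chrom, a[1].strand),
    ):
        cluster: list[tuple[str, GenomeHit, float]] = []
        for item in group:
            if cluster and item[1].start - cluster[-1][1].start > config.merge_distance:
                merged.append(max(cluster, key=lambda a: a[2]))
                cluster = []
            cluster.append(item)
        if cluster:
            merged.append(max(cluster, key=lambda a: a[2]))

    calls: list[MirnaCall] = []
    rejections: dict[str, list[Rejection]] = {}
    up, down = config.homology_window_upstream, config.homology_window_downstream
    for tag, hit, _ in merged:
        window = (hit.start - up, hit.start + len(tag) + down)
        res = evaluate_candidate(
            tag, hit, genome, table, hits, config, windows=[window], route="homology"
        )
        if isinstance(res, Rejection):
            rejections.setdefault(tag, []).append(res)
        else:
            existing = next((c for c in calls if c.mature_seq == tag), None)
            if existing is None:
                calls.append(MirnaCall(name="", mature_seq=tag, precursors=[res], route="homology"))
            else:
                existing.precursors.append(res)
    return calls, rejections


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(1 for x, y in zip(a, b) if x != y)


def _best_family(seq: str, catalog: Mapping[str, str], max_mm: int) -> str | None:
    best_name, best_d = None, max_mm + 1
    for name, cat_seq in sorted(catalog.items()):
        d = _hamming(seq, cat_seq)
        if d is not None and d < best_d:
            best_name, best_d = name, d
    return best_name


def assign_names(
    calls: Sequence[MirnaCall],
    known: Mapping[str, str],
    other_species: Mapping[str, str] | None = None,
    config: PipelineConfig | None = None,
    novel_prefix: str = "candidate-miR",
) -> list[MirnaCall]:
    """Name calls against a known catalog (<= 2 mismatches for a family name).

    Sequences with no catalog match are named as novel candidates; calls on
    the manual-family route may match with up to 3 mismatches.  Conservation
    is set by presence (<= 2 mismatches) in a second, other-species catalog.
    """
    config = config or PipelineConfig()
    other_species = other_species or {}
    counter = itertools.count(1)
    for call in calls:
        max_mm = (
            config.manual_family_max_mismatches
            if call.route == "manual-family"
            else config.naming_max_mismatches
        )
        family = _best_family(call.mature_seq, known, max_mm)
        if family is not None:
            call.name = family
        else:
            call.name = f"{novel_prefix}-{next(counter):03d}"
        in_other = _best_family(
            call.mature_seq, other_species, config.naming_max_mismatches
        )
        call.conservation = "conserved" if in_other is not None else "non-conserved"
    return list(calls)
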