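"""Phased-siRNA locus detection and PARE-based trigger identification.

Phased loci are genomic intervals where small-RNA 5' ends recur in a fixed
21- or 24-nt register downstream of a trigger-miRNA cleavage.  The phasing
score used here is a 9-cycle log-odds statistic:

    score(pos) = (k - 2) * ln(1 + 10 * P / (1 + U))

evaluated over a window of nine phase cycles centered on ``pos``, where P is
the total abundance at in-register positions, U the total at out-of-register
positions and k the number of distinct occupied in-register positions; the
score is 0 when k < 3.  The study this package models does not print its
phasing formula; this one is the package's declared substitute and any score
increasing in P and k and decreasing in U can be swapped in.

Trigger identification pulls PARE tags within five phase cycles of a locus,
reconstructs the 24-nt miRNA-complementary window around each PARE 5' end
(13 nt upstream + first 11 nt of the fragment, +/-1), and scores candidate
miRNAs with mismatch 1 / G:U 0.5; calls need a score <= 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import PipelineConfig
from .target_scoring import duplex_score

WINDOW_CYCLES = 9  # phasing-score window: focal cycle +/- 4


@dataclass
class PhasedLocus:
    chrom: str
    start: int
    end: int
    period: int
    max_score: float
    max_score_pos: int
    register: int
    libraries_supporting: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TriggerCall:
    locus: PhasedLocus
    mirna_name: str
    pare_pos: int
    duplex_score: float
    register_offset: int  # cleavage position minus dominant register, signed


def fold_strand_positions(
    tag_hits: Iterable[tuple[int, str, int, float]],
) -> dict[int, float]:
    """Combine stranded 5'-end positions into one top-strand register profile.

    Input items are (start, strand, tag_length, abundance) with ``start`` the
    leftmost genome coordinate of the hit.  A top-strand tag's 5' end is
    ``start``; a bottom-strand tag's 5' end is ``start + length - 1`` and is
    folded into the top-strand register with the 2-nt duplex-overhang shift
    (position p maps to p + 2).
    """
    profile: dict[int, float] = {}
    for start, strand, length, abundance in tag_hits:
        pos = start if strand == "+" else start + length - 1 + 2
        profile[pos] = profile.get(pos, 0.0) + abundance
    return profile


def phasing_score(
    abundances: Mapping[int, float], period: int, focal_pos: int
) -> float:
    """The 9-cycle phasing score at ``focal_pos`` (see module docstring)."""
    lo = focal_pos - 4 * period
    hi = focal_pos + 5 * period  # half-open
    P = 0.0
    U = 0.0
    k = 0
    for pos, ab in abundances.items():
        if ab <= 0 or not (lo <= pos < hi):
            continue
        if (pos - focal_pos) % period == 0:
            P += ab
            k += 1
        else:
            U += ab
    if k < 3 or P <= 0:
        return 0.0
    return (k - 2) * math.log(1 + 10.0 * P / (1 + U))


def score_profile(abundances: Mapping[int, float], period: int) -> dict[int, float]:
    """Phasing score at every occupied position."""
    return {
        pos: phasing_score(abundances, period, pos)
        for pos, ab in abundances.items()
        if ab > 0
    }


def find_phased_loci(
    abundances: Mapping[int, float],
    period: int,
    min_score: float = 25.0,
    edge_score: float = 20.0,
    max_gap_cycles: int = 2,
    chrom: str = "genome",
    per_library: Mapping[str, Mapping[int, float]] | None = None,
) -> list[PhasedLocus]:
    """Maximal intervals holding a position with score >= ``min_score``,
    extended outward to the first/last position scoring >= ``edge_score``.

    ``abundances`` is the strand-folded combined profile (see
    :func:`fold_strand_positions`).  Scored positions further apart than
    ``max_gap_cycles`` phase cycles start a new locus.  The dominant register
    is the residue (mod period) of the maximum-score position (5'-most on
    ties); locus end extends one period past the last scored position so the
    final tag is covered.
    """
    scores = score_profile(abundances, period)
    edge_positions = sorted(p for p, s in scores.items() if s >= edge_score)
    if not edge_positions:
        return []
    max_gap = max_gap_cycles * period
    clusters: list[list[int]] = [[edge_positions[0]]]
    for pos in edge_positions[1:]:
        if pos - clusters[-1][-1] > max_gap:
            clusters.append([])
        clusters[-1].append(pos)
    loci = []
    for cluster in clusters:
        peak_pos = max(cluster, key=lambda p: (scores[p], -p))
        if scores[peak_pos] < min_score:
            continue
        locus = PhasedLocus(
            chrom=chrom,
            start=cluster[0],
            end=cluster[-1] + period,
            period=period,
            max_score=scores[peak_pos],
            max_score_pos=peak_pos,
            register=peak_pos % period,
        )
        if per_library is not None:
            locus.libraries_supporting = [
                lib
                for lib, prof in per_library.items()
                if any(
                    locus.start <= p < locus.end and (p - peak_pos) % period == 0
                    for p, a in prof.items()
                    if a > 0
                )
            ]
        loci.append(locus)
    return loci


def dominant_register(
    abundances: Mapping[int, float], locus: PhasedLocus
) -> int:
    """Register (mod period) holding the largest summed abundance in the locus."""
    sums: dict[int, float] = {}
    for pos, ab in abundances.items():
        if locus.start <= pos < locus.end and ab > 0:
            r = pos % locus.period
            sums[r] = sums.get(r, 0.0) + ab
    if not sums:
        return locus.register
    return max(sorted(sums), key=lambda r: sums[r])


def complementary_window(
    sequence: str, pare_pos: int, shifts: Sequence[int] = (0, -1, 1)
) -> list[tuple[int, str]]:
    """The 24-nt miRNA-complementary windows around a PARE 5' end.

    The canonical window is the 13 nt upstream of the PARE start plus the
    first 11 nt of the fragment, [pare_pos - 13, pare_pos + 11); shifted
    variants cover off-by-one cleavage.  Windows that do not fit inside the
    sequence are skipped.
    """
    out = []
    for shift in shifts:
        lo = pare_pos - 13 + shift
        hi = pare_pos + 11 + shift
        if lo < 0 or hi > len(sequence):
            continue
        out.append((lo, sequence[lo:hi]))
    return out


def _register_offset(pos: int, register: int, period: int) -> int:
    d = (pos - register) % period
    if d > period // 2:
        d -= period
    return d


def identify_triggers(
    locus: PhasedLocus,
    pare_abundances: Mapping[int, float],
    mirnas: Mapping[str, str],
    sequence: str,
    config: PipelineConfig | None = None,
) -> list[TriggerCall]:
    """Score candidate trigger miRNAs against PARE ends near a phased locus.

    PARE positions within ``trigger_window_cycles`` phase cycles of the locus
    are considered.  For each, the miRNA is 3'-aligned in each complementary
    window so that miRNA position 10 pairs the PARE 5' base (the +/-1 windows
    cover off-by-one cleavage); the best window's score must be <= 5.
    Duplicate PARE entries cannot duplicate calls (one call per miRNA and
    position); results are sorted and carry the signed register offset.
    """
    config = config or PipelineConfig()
    pad = config.trigger_window_cycles * locus.period
    lo, hi = locus.start - pad, locus.end + pad
    calls: dict[tuple[str, int], TriggerCall] = {}
    for pos in sorted(pare_abundances):
        if pare_abundances[pos] <= 0 or not (lo <= pos < hi):
            continue
        windows = complementary_window(sequence, pos)
        if not windows:
            continue
        for name in sorted(mirnas):
            mir = mirnas[name]
            L = len(mir)
            if L > 23:
                continue
            best = None
            for _, win in windows:
                site = win[23 - L : 23]
                score, _states = duplex_score(
                    mir,
                    site,
                    "uniform",
                    mismatch_penalty=config.mismatch_penalty,
                    gu_penalty=config.gu_penalty,
                )
                if best is None or score < best:
                    best = score
            if best is not None and best <= config.trigger_max_score:
                offset = _register_offset(pos, locus.register, locus.period)
                if config.strict_register and abs(offset) > 1:
                    continue
                calls[(name, pos)] = TriggerCall(locus, name, pos, best, offset)
    return sorted(calls.values(), key=lambda c: (c.pare_pos, c.mirna_name))


def write_locus_gff3(loci: Sequence[PhasedLocus], path) -> None:
    """Phased loci as GFF3 (1-based inclusive; score = max phasing score)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci, start=1):
            fh.write(
                f"{locus.chrom}\tparemir\tphased_siRNA_locus\t{locus.start + 1}\t"
                f"{locus.end}\t{locus.max_score:.2f}\t+\t.\t"
                f"ID=phased{i:04d};period={locus.period};register={locus.register}\n"
            )


def write_trigger_table(calls: Sequence[TriggerCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlocus_start_1based\tlocus_end_1based\tperiod\tmirna\t"
                 "pare_pos_1based\tscore\tregister_offset\n")
        for c in calls:
            fh.write(
                f"{c.locus.chrom}\t{c.locus.start + 1}\t{c.locus.end}\t{c.locus.period}\t"
                f"{c.mirna_name}\t{c.pare_pos + 1}\t{c.duplex_score:g}\t{c.register_offset}\n"
            )
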