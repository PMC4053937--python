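"""PARE degradome profiles and the three-criterion prominence classifier.

Each miRNA target site with degradome support is scored on three criteria in
the library where its exact cleavage signature is strongest:

* abundance — the TP10M abundance of the PARE tag starting exactly at the
  predicted cleavage position is at least 10;
* rank — that position is among the top two most abundant positions of its
  transcript;
* peak — the peak percentage of the transcript is at least 20%.

A site passing none of the criteria is Level 1 and one passing all three is
Level 4 (level = 1 + number passed).  Two peak-percentage variants exist in
the literature this package follows: the default "top2" variant (100 x the
sum of the transcript's two largest position abundances over its total) and
the "site" variant (100 x the exact-site abundance over the total); both are
computed and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .mapping import TagHits, map_tags
from .normalization import TP10M, normalize
from .sequence_io import GenomeSeq, TagTable
from .target_scoring import TargetSite


@dataclass
class PareProfile:
    """Per-transcript, per-library degradome profile (position -> TP10M)."""

    transcript_id: str
    library_id: str
    abundance_by_position: dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.abundance_by_position.values())


@dataclass
class SiteMetrics:
    abundance: float
    rank: int
    peak_percentage_site: float
    peak_percentage_top2: float


@dataclass
class ProminenceResult:
    site: TargetSite
    library_id: str
    metrics: SiteMetrics
    criteria_passed: tuple[str, ...]
    level: int


def build_profiles(
    pare_table: TagTable,
    transcripts: dict[str, str],
    hits: Mapping[str, TagHits] | None = None,
) -> list[PareProfile]:
    """Map PARE tags onto transcripts and build sense-strand TP10M profiles.

    Tags are expected to be pre-filtered (trimmed to 20 nt, <= 20 genome
    hits, low-complexity and structural-RNA removed).  A tag matching a
    transcript at several positions contributes at each; antisense matches
    are excluded (the degradome is sense-only).
    """
    if not pare_table.genome_matched_totals:
        raise ValueError("PARE table lacks genome-matched totals for TP10M")
    if hits is None:
        seqs = [GenomeSeq(tid, seq) for tid, seq in transcripts.items()]
        hits = map_tags(seqs, pare_table.tags, max_hits=10_000)
    profiles: dict[tuple[str, str], PareProfile] = {}
    for tag, th in hits.items():
        if tag not in pare_table.counts.index:
            continue
        for h in th.hits:
            if h.strand != "+":
                continue
            for lib in pare_table.library_ids:
                raw = pare_table.raw(tag, lib)
                if raw == 0:
                    continue
                tp10m = normalize(raw, pare_table.genome_matched_totals[lib], TP10M)
                key = (h.chrom, lib)
                prof = profiles.setdefault(key, PareProfile(h.chrom, lib))
                prof.abundance_by_position[h.start] = (
                    prof.abundance_by_position.get(h.start, 0.0) + tp10m
                )
    return list(profiles.values())


def site_metrics(profile: PareProfile, cleavage_pos: int) -> SiteMetrics:
    """Abundance, competition rank and both peak-percentage variants.

    Ties share the better rank.  A site position absent from the profile has
    abundance 0 and rank = number of occupied positions + 1.  The top-two
    peak uses the two largest position abundances; when more than two
    positions tie, the 5'-most two are the reported peak positions (the
    percentage itself is tie-invariant).
    """
    abunds = profile.abundance_by_position
    total = sum(abunds.values())
    site_ab = abunds.get(cleavage_pos, 0.0)
    if cleavage_pos in abunds:
        rank = 1 + sum(1 for v in abunds.values() if v > site_ab)
    else:
        rank = len(abunds) + 1
    if total > 0:
        top2 = sum(sorted(abunds.values(), reverse=True)[:2])
        peak_top2 = 100.0 * top2 / total
        peak_site = 100.0 * site_ab / total
    else:
        peak_top2 = peak_site = 0.0
    return SiteMetrics(site_ab, rank, peak_site, peak_top2)


def assign_level(
    metrics: SiteMetrics, site: TargetSite, library_id: str, config: PipelineConfig | None = None
) -> ProminenceResult:
    """Count the inclusive prominence criteria and set level = 1 + passed."""
    config = config or PipelineConfig()
    peak = (
        metrics.peak_percentage_top2
        if config.peak_variant == "top2"
        else metrics.peak_percentage_site
    )
    passed = []
    if metrics.abundance >= config.abundance_cutoff_tp10m:
        passed.append("abundance")
    if metrics.rank <= config.rank_cutoff:
        passed.append("rank")
    if peak >= config.peak_cutoff_percent:
        passed.append("peak")
    return ProminenceResult(site, library_id, metrics, tuple(passed), 1 + len(passed))


def choose_best_library(
    cleavage_pos: int,
    profiles_by_library: Mapping[str, PareProfile],
    library_order: Sequence[str],
) -> str:
    """Library with the highest exact-site abundance; ties keep config order."""
    ordered = [lib for lib in library_order if lib in profiles_by_library]
    if not ordered:
        raise ValueError("no library has a profile for this transcript")
    return max(
        ordered,
        key=lambda lib: (
            profiles_by_library[lib].abundance_by_position.get(cleavage_pos, 0.0),
            -ordered.index(lib),
        ),
    )


def evaluate_all(
    sites: Sequence[TargetSite],
    profiles: Sequence[PareProfile],
    library_order: Sequence[str],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One row per predicted site: precise-PARE flag, best library, level.

    Sites on transcripts without any degradome signal get ``precise`` False
    and no level (they are outside the classifiable set).
    """
    config = config or PipelineConfig()
    by_transcript: dict[str, dict[str, PareProfile]] = {}
    for p in profiles:
        by_transcript.setdefault(p.transcript_id, {})[p.library_id] = p
    rows = []
    for site in sites:
        libs = by_transcript.get(site.transcript_id, {})
        precise = any(
            site.cleavage_pos in p.abundance_by_position for p in libs.values()
        )
        row = {
            "mirna": site.mirna_name,
            "transcript": site.transcript_id,
            "cleavage_pos_1based": site.cleavage_pos + 1,
            "scheme": site.scheme,
            "score": site.score,
            "precise": precise,
        }
        if libs:
            best = choose_best_library(site.cleavage_pos, libs, library_order)
            metrics = site_metrics(libs[best], site.cleavage_pos)
            result = assign_level(metrics, site, best, config)
            row.update(
                best_library=best,
                abundance_tp10m=metrics.abundance,
                rank=metrics.rank,
                peak_percent_top2=metrics.peak_percentage_top2,
                peak_percent_site=metrics.peak_percentage_site,
                passes_abundance="abundance" in result.criteria_passed,
                passes_rank="rank" in result.criteria_passed,
                passes_peak="peak" in result.criteria_passed,
                level=result.level if precise else pd.NA,
            )
        else:
            row.update(
                best_library=pd.NA,
                abundance_tp10m=0.0,
                rank=pd.NA,
                peak_percent_top2=pd.NA,
                peak_percent_site=pd.NA,
                passes_abundance=False,
                passes_rank=False,
                passes_peak=False,
                level=pd.NA,
            )
        rows.append(row)
    return pd.DataFrame(rows)
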