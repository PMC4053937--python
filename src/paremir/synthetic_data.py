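"""Seeded generators for a toy genome with planted small-RNA biology.

The generators emulate the structure of deep plant small-RNA/PARE sequencing
experiments at desk scale: hairpin precursors whose loci are dominated by a
mature miRNA and its star, double-stranded siRNA loci, degradome libraries
with a cleavage peak over uniform background decay, and trigger-initiated
phased siRNA loci.  Everything is a pure function of a
:class:`SimulationConfig` (bitwise-reproducible per seed) and carries its
ground truth, so every pipeline stage is testable without downloads.

Design notes: background tag sequences are drawn from the genome (real
positions), so genome-hit filters are meaningfully exercised; library depths
are orders of magnitude below real experiments but chosen so every abundance
threshold still binds (a singleton background read normalizes below the
10 TP2M candidate cut-off).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hairpin import DuplexStats
from .sequence_io import GenomeSeq, TagTable, revcomp

BASES = "ACGT"

# a base that neither Watson-Crick pairs nor wobbles with the key
_NONPAIRING = {"A": "C", "C": "A", "G": "A", "T": "C"}

# default trigger miRNAs (22 nt, the size class that initiates phasing)
TRIGGER_21 = "TAGATATTTCAGGTTGTGTGGA"
TRIGGER_24 = "TTGCAGTCCTCAAGGTAGTCAA"


@dataclass(frozen=True)
class Defect:
    """A planted duplex defect at a 1-based miRNA position.

    ``mismatch``: the star base facing ``mir_pos`` is made non-pairing.
    ``bulge`` with arm ``star``: ``length`` unpairable bases inserted in the
    star arm opposite ``mir_pos``; with arm ``mir``: ``length`` star bases
    deleted so the miRNA bases at ``mir_pos`` .. are unopposed.
    """

    kind: str  # "mismatch" | "bulge"
    mir_pos: int
    length: int = 1
    arm: str = "star"


@dataclass
class PlantedPrecursor:
    sequence: str
    mir_start: int
    mir_len: int
    star_start: int
    star_len: int
    expected_stats: DuplexStats
    mature_seq: str
    star_seq: str


@dataclass
class PhasedLocusSpec:
    period: int = 21
    cycles: int = 5
    occupancy: float = 1.0
    trigger_name: str = "trigger-21"
    trigger_seq: str = TRIGGER_21
    site_defects: int = 0  # planted mismatches in the trigger binding site


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 20_000
    chrom_name: str = "chr1"

    # small-RNA side
    n_precursors: int = 3
    n_bulgy_precursors: int = 1  # homology-route plants (6 duplex defects)
    n_sirna_loci: int = 2
    n_background_tags: int = 40
    mature_len: int = 21
    mature_fraction: float = 0.85
    star_fraction: float = 0.10
    n_jitter_variants: int = 2
    precursor_locus_reads: int = 400
    sirna_locus_reads: int = 200
    smallrna_libraries: tuple[str, ...] = ("leaf", "panicle")
    smallrna_library_depth: int = 400_000  # bulked to this genome-matched total

    # PARE side
    transcript_length: int = 300
    pare_reads_per_transcript: int = 2_000
    pare_background_positions: int = 40
    pare_peak_fraction: float = 0.6
    pare_libraries: tuple[str, ...] = ("root", "panicle")

    # phased loci
    phased_locus_specs: tuple[PhasedLocusSpec, ...] = (
        PhasedLocusSpec(21, 5, 1.0, "trigger-21", TRIGGER_21),
        PhasedLocusSpec(24, 5, 1.0, "trigger-24", TRIGGER_24),
    )
    phased_cycle_reads: int = 400
    phased_pare_reads: int = 60

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Planted coordinates and sequences, all 0-based on the emitted genome."""

    precursors: list[dict] = field(default_factory=list)
    sirna_loci: list[dict] = field(default_factory=list)
    transcripts: dict[str, str] = field(default_factory=dict)
    cleavage_sites: dict[str, dict] = field(default_factory=dict)
    phased_loci: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def validate(self, genome: str) -> None:
        """Every planted element must index validly into the emitted genome."""
        for p in self.precursors:
            assert 0 <= p["start"] < p["end"] <= len(genome)
            assert genome[p["start"] : p["end"]] == p["sequence"]
        for locus in self.phased_loci:
            assert 0 <= locus["cleavage_pos"] < len(genome)
        for tid, site in self.cleavage_sites.items():
            assert 0 <= site["cleavage_pos"] < len(self.transcripts[tid])


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# precursor construction
# ---------------------------------------------------------------------------


def build_precursor(
    mature_seq: str,
    loop_len: int = 8,
    defects: tuple[Defect, ...] | list[Defect] = (),
    rng: np.random.Generator | None = None,
    flank: int = 30,
) -> PlantedPrecursor:
    """Assemble a hairpin precursor around a mature miRNA.

    Layout: 5' flank + mature + loop + star + 3' flank, where the star is the
    reverse complement of the mature with the requested defects applied.  The
    returned star interval follows the canonical 2-nt 3' overhang geometry
    (it starts at the partner of the mature's last duplex base and extends
    two bases past the partner of the mature's first base).
    """
    mature = mature_seq.upper().replace("U", "T")
    L = len(mature)
    if not 20 <= L <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if loop_len < 3:
        raise ValueError("loop length must be >= 3")
    rng = rng if rng is not None else np.random.default_rng(0)

    # star entries ordered 5'->3' along the precursor; entry i pairs the
    # mature position it was built from unless defected
    entries: list[tuple[str, int | None]] = [
        (_complement(mature[q - 1]), q) for q in range(L, 0, -1)
    ]
    mism = 0
    bulges = 0
    max_bulge = 0
    for d in defects:
        if not 3 <= d.mir_pos <= L - 3:
            raise ValueError("defect positions must lie within the duplex core")
        idx = next(
            (i for i, (_, q) in enumerate(entries) if q == d.mir_pos), None
        )
        if idx is None:
            raise ValueError(f"no duplex column left at miRNA position {d.mir_pos}")
        if d.kind == "mismatch":
            if d.length != 1:
                raise ValueError("mismatch defects have length 1; plant several")
            entries[idx] = (_NONPAIRING[mature[d.mir_pos - 1]], None)
            mism += 1
        elif d.kind == "bulge":
            if d.arm == "star":
                filler = [(_NONPAIRING[mature[d.mir_pos - 1]], None)] * d.length
                entries[idx:idx] = filler
            else:  # unopposed miRNA bases: delete the facing star columns
                for q in range(d.mir_pos, d.mir_pos - d.length, -1):
                    entries = [(b, qq) for b, qq in entries if qq != q]
            bulges += 1
            max_bulge = max(max_bulge, d.length)
        else:
            raise ValueError(f"unknown defect kind {d.kind!r}")

    star = "".join(b for b, _ in entries)
    # complementary flanks extend the stem below the duplex, the geometry of
    # real pri-miRNA hairpins; a single fully stacked helix also makes the
    # planted structure the unique folding optimum
    flank5 = _random_seq(rng, flank)
    loop = _random_seq(rng, loop_len)
    flank3 = revcomp(flank5)
    seq = flank5 + mature + loop + star + flank3

    t0 = flank + L + loop_len  # star block offset in the precursor
    pos_of = {q: t0 + i for i, (_, q) in enumerate(entries) if q is not None}
    j_hi = pos_of[min(pos_of)]  # partner of the mature's 5'-most paired base
    anchor = max(q for q in pos_of if q <= L - 2)
    j_lo = pos_of[anchor]
    star_start = j_lo
    star_end = min(j_hi + 3, len(seq))
    return PlantedPrecursor(
        sequence=seq,
        mir_start=flank,
        mir_len=L,
        star_start=star_start,
        star_len=star_end - star_start,
        expected_stats=DuplexStats(mism, bulges, max_bulge),
        mature_seq=mature,
        star_seq=star,
    )


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}[base]


# ---------------------------------------------------------------------------
# phased locus construction
# ---------------------------------------------------------------------------


@dataclass
class PlantedPhasedLocus:
    insert: str
    cleavage_rel: int  # relative to insert start
    period: int
    cycles: int
    trigger_name: str
    trigger_seq: str
    tag_positions: list[int]  # relative 5' ends of phased tags
    tag_count: int
    pare_count: int
    site_score_defects: int


def simulate_phased_locus(
    spec: PhasedLocusSpec,
    rng: np.random.Generator,
    cycle_reads: int = 150,
    pare_reads: int = 60,
    pad5: int = 120,
    pad3: int = 60,
) -> PlantedPhasedLocus:
    """A genome insert with a trigger site and in-register siRNAs downstream.

    The trigger's complementary site is embedded so that cleavage (opposite
    miRNA positions 10/11) falls at the phase origin; phased tags of length
    ``period`` start at the origin and every ``period`` nt after it.
    ``site_defects`` mismatches can be planted into the site to push the
    trigger score above the calling threshold (designed negatives).
    """
    if spec.period not in (21, 24):
        raise ValueError("period must be 21 or 24")
    if spec.cycles < 3:
        raise ValueError("need >= 3 cycles for a scoreable locus")
    trig = spec.trigger_seq.upper().replace("U", "T")
    L = len(trig)
    site = list(revcomp(trig))
    for i in range(spec.site_defects):
        # mutate site bases facing miRNA positions 3, 5, 7, ... (core side)
        mir_pos = 3 + 2 * i
        if mir_pos > L - 2:
            raise ValueError("too many site defects for this trigger length")
        site[L - mir_pos] = _NONPAIRING[trig[mir_pos - 1]]
    site_seq = "".join(site)

    site_start = pad5
    cleavage_rel = site_start + L - 10
    phased_len = spec.cycles * spec.period
    downstream_needed = cleavage_rel + phased_len + pad3

    insert = list(_random_seq(rng, downstream_needed))
    insert[site_start : site_start + L] = site_seq
    insert_seq = "".join(insert)

    n_occupied = max(3, int(round(spec.occupancy * spec.cycles)))
    occupied = sorted(
        rng.choice(spec.cycles, size=min(n_occupied, spec.cycles), replace=False)
    )
    if 0 not in occupied:  # cleavage-adjacent cycle is always produced
        occupied[0] = 0
    tag_positions = [cleavage_rel + int(c) * spec.period for c in sorted(set(occupied))]
    return PlantedPhasedLocus(
        insert=insert_seq,
        cleavage_rel=cleavage_rel,
        period=spec.period,
        cycles=spec.cycles,
        trigger_name=spec.trigger_name,
        trigger_seq=trig,
        tag_positions=tag_positions,
        tag_count=cycle_reads,
        pare_count=pare_reads,
        site_score_defects=spec.site_defects,
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    config: SimulationConfig
    genome: list[GenomeSeq]
    smallrna: TagTable
    pare: TagTable
    truth: GroundTruth

    @property
    def genome_map(self) -> dict[str, str]:
        return {g.name: g.sequence for g in self.genome}


def _split_counts(
    rng: np.random.Generator, total: int, libraries: tuple[str, ...]
) -> dict[str, int]:
    probs = np.full(len(libraries), 1.0 / len(libraries))
    counts = rng.multinomial(total, probs)
    return {lib: int(c) for lib, c in zip(libraries, counts)}


class _TagAccumulator:
    def __init__(self, libraries: tuple[str, ...]):
        self.libraries = libraries
        self.rows: dict[str, dict[str, int]] = {}

    def add(self, tag: str, counts: dict[str, int]) -> None:
        if not tag or "N" in tag:
            return
        row = self.rows.setdefault(tag, {lib: 0 for lib in self.libraries})
        for lib, c in counts.items():
            row[lib] += c

    def table(self) -> TagTable:
        df = pd.DataFrame.from_dict(self.rows, orient="index", columns=list(self.libraries))
        df = df.fillna(0).astype("int64")
        df.index.name = "tag"
        return TagTable(df)


def simulate_dataset(config: SimulationConfig | None = None) -> Dataset:
    """Generate the full synthetic study: genome, libraries, ground truth."""
    config = config or SimulationConfig()
    rng = config.rng()
    chrom = config.chrom_name

    genome = list(_random_seq(rng, config.genome_length))
    truth = GroundTruth()
    cursor = 300  # left margin
    gap = 250

    def plant(insert: str) -> int:
        nonlocal cursor
        start = cursor
        if start + len(insert) + 300 > config.genome_length:
            raise ValueError("genome_length too small for the requested elements")
        genome[start : start + len(insert)] = insert
        cursor = start + len(insert) + gap
        return start

    sm = _TagAccumulator(config.smallrna_libraries)

    # --- hairpin precursors -------------------------------------------------
    def draw_mature(defects: tuple[Defect, ...]) -> str:
        while True:
            mature = list(_random_seq(rng, config.mature_len))
            for d in defects:
                if d.kind == "mismatch":
                    # freed duplex bases are kept mutually non-pairing (A/C)
                    # so planted internal loops cannot chance-pair shut
                    mature[d.mir_pos - 1] = str(rng.choice(["A", "C"]))
            m = "".join(mature)
            # internally repetitive matures (rare in real catalogs) allow
            # register-slipped co-optimal folds; resample until 5-mer-unique
            kmers = [m[i : i + 5] for i in range(len(m) - 4)]
            if len(set(kmers)) == len(kmers):
                return m

    def plant_precursor(defects: tuple[Defect, ...], compliant: bool) -> None:
        mature = draw_mature(defects)
        prec = build_precursor(mature, loop_len=8, defects=defects, rng=rng)
        start = plant(prec.sequence)
        reads = config.precursor_locus_reads
        n_mat = int(round(config.mature_fraction * reads))
        n_star = int(round(config.star_fraction * reads))
        rest = max(0, reads - n_mat - n_star)
        sm.add(prec.mature_seq, _split_counts(rng, n_mat, config.smallrna_libraries))
        sm.add(prec.star_seq, _split_counts(rng, n_star, config.smallrna_libraries))
        jitters = []
        for j in range(1, config.n_jitter_variants + 1):
            v = prec.sequence[prec.mir_start + j : prec.mir_start + j + prec.mir_len]
            jitters.append(v)
        for v in jitters:
            share = rest // max(1, len(jitters))
            sm.add(v, _split_counts(rng, share, config.smallrna_libraries))
        truth.precursors.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + len(prec.sequence),
                "strand": "+",
                "sequence": prec.sequence,
                "mature_seq": prec.mature_seq,
                "star_seq": prec.star_seq,
                "mir_start": start + prec.mir_start,
                "star_start": start + prec.star_start,
                "star_len": prec.star_len,
                "expected_defects": prec.expected_stats.total_defects,
                "expected_max_bulge": prec.expected_stats.max_bulge_len,
                "compliant": compliant,
            }
        )

    # compliant plants carry one interior mismatch: real miRNA duplexes are
    # imperfect, and a perfect duplex would make mature and star exact
    # reverse complements, mapping each to both strands of its own hairpin
    for _ in range(config.n_precursors):
        plant_precursor((Defect("mismatch", 12),), compliant=True)
    # homology-route plants: a 2-nt star-arm bulge folds stably but violates
    # the stringent bulge-size limit (<= 1 nt); the relaxed route accepts it
    bulgy = (Defect("bulge", 11, 2, "star"),)
    for _ in range(config.n_bulgy_precursors):
        plant_precursor(bulgy, compliant=False)

    # --- double-stranded siRNA loci -----------------------------------------
    for _ in range(config.n_sirna_loci):
        start = plant(_random_seq(rng, 150))
        n_tags = 12
        per = max(1, config.sirna_locus_reads // n_tags)
        positions = sorted(rng.choice(120, size=n_tags, replace=False))
        for i, p in enumerate(positions):
            length = int(rng.integers(21, 25))
            tag = "".join(genome[start + p : start + p + length])
            if i % 2 == 1:
                tag = revcomp(tag)
            sm.add(tag, _split_counts(rng, per, config.smallrna_libraries))
        truth.sirna_loci.append({"chrom": chrom, "start": start, "end": start + 150})

    # --- phased loci ---------------------------------------------------------
    pare = _TagAccumulator(config.pare_libraries)
    for spec in config.phased_locus_specs:
        planted = simulate_phased_locus(
            spec, rng, config.phased_cycle_reads, config.phased_pare_reads
        )
        start = plant(planted.insert)
        for rel in planted.tag_positions:
            tag = "".join(genome[start + rel : start + rel + planted.period])
            sm.add(tag, _split_counts(rng, planted.tag_count, config.smallrna_libraries))
        pare_tag = "".join(genome[start + planted.cleavage_rel : start + planted.cleavage_rel + 20])
        pare.add(pare_tag, _split_counts(rng, planted.pare_count, config.pare_libraries))
        truth.phased_loci.append(
            {
                "chrom": chrom,
                "start": start + planted.tag_positions[0],
                "end": start + planted.cleavage_rel + planted.cycles * planted.period,
                "period": planted.period,
                "cleavage_pos": start + planted.cleavage_rel,
                "register": (start + planted.cleavage_rel) % planted.period,
                "trigger_name": planted.trigger_name,
                "trigger_seq": planted.trigger_seq,
                "site_defects": planted.site_score_defects,
            }
        )

    # --- background tags ------------------------------------------------------
    for _ in range(config.n_background_tags):
        length = int(rng.integers(20, 25))
        p = int(rng.integers(0, config.genome_length - length))
        tag = "".join(genome[p : p + length])
        if rng.random() < 0.5:
            tag = revcomp(tag)
        sm.add(tag, _split_counts(rng, 1, config.smallrna_libraries))

    # --- depth filler ---------------------------------------------------------
    # long (30 nt) highly abundant tags emulate the bulk of the library
    # (size-excluded from miRNA discovery) so per-library genome-matched
    # totals reach the configured depth and TP2M thresholds bind
    smallrna = sm.table()
    current = {lib: int(smallrna.counts[lib].sum()) for lib in config.smallrna_libraries}
    for i, lib in enumerate(config.smallrna_libraries):
        need = config.smallrna_library_depth - current[lib]
        if need > 0:
            p = 50 + 35 * i
            tag = "".join(genome[p : p + 30])
            sm.add(tag, {lib: need})
    smallrna = sm.table()

    # --- transcripts and PARE -------------------------------------------------
    genome_str = "".join(genome)
    for idx, p in enumerate(truth.precursors):
        if not p["compliant"]:
            continue
        tid = f"target{idx + 1:02d}"
        mat = p["mature_seq"]
        L = len(mat)
        t_seq = list(_random_seq(rng, config.transcript_length))
        site_start = config.transcript_length // 2 - L
        t_seq[site_start : site_start + L] = revcomp(mat)
        t_seq = "".join(t_seq)
        cleavage = site_start + L - 10
        truth.transcripts[tid] = t_seq
        truth.cleavage_sites[tid] = {
            "mirna": mat,
            "site_start": site_start,
            "cleavage_pos": cleavage,
            "peak_fraction": config.pare_peak_fraction,
        }
        _emit_pare_for_transcript(
            pare, rng, tid, t_seq, cleavage, config
        )

    dataset = Dataset(
        config=config,
        genome=[GenomeSeq(chrom, genome_str)],
        smallrna=smallrna,
        pare=pare.table(),
        truth=truth,
    )
    # normalization bases: all emitted tags are genome/transcript-derived
    dataset.smallrna.genome_matched_totals = {
        lib: int(dataset.smallrna.counts[lib].sum()) for lib in config.smallrna_libraries
    }
    dataset.pare.genome_matched_totals = {
        lib: int(dataset.pare.counts[lib].sum()) for lib in config.pare_libraries
    }
    return dataset


def _emit_pare_for_transcript(
    pare: "_TagAccumulator",
    rng: np.random.Generator,
    tid: str,
    t_seq: str,
    cleavage: int,
    config: SimulationConfig,
) -> None:
    """Background decay at uniform positions plus a point mass at the site."""
    n = len(t_seq)
    total = config.pare_reads_per_transcript
    peak = int(round(config.pare_peak_fraction * total))
    background = total - peak
    valid = [p for p in range(0, n - 20) if p != cleavage]
    positions = rng.choice(len(valid), size=config.pare_background_positions, replace=False)
    counts = rng.multinomial(background, np.full(len(positions), 1.0 / len(positions)))
    if peak > 0:
        pare.add(t_seq[cleavage : cleavage + 20], _split_counts(rng, peak, config.pare_libraries))
    for pi, c in zip(positions, counts):
        if c > 0:
            p = valid[int(pi)]
            pare.add(t_seq[p : p + 20], _split_counts(rng, int(c), config.pare_libraries))


def simulate_smallrna_library(config: SimulationConfig | None = None):
    """Convenience wrapper returning (genome, small-RNA TagTable, truth)."""
    ds = simulate_dataset(config)
    return ds.genome, ds.smallrna, ds.truth


def simulate_pare_library(config: SimulationConfig | None = None):
    """Convenience wrapper returning (transcripts, PARE TagTable, truth)."""
    ds = simulate_dataset(config)
    return ds.truth.transcripts, ds.pare, ds.truth
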