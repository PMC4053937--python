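"""Readers/writers for the on-disk formats used throughout the pipeline.

Conventions enforced here and relied on everywhere else:

* the internal nucleotide alphabet is DNA over ``{A, C, G, T, N}``; ``U`` is
  converted to ``T`` on input and RNA display (``T`` -> ``U``) happens only at
  output boundaries;
* all internal coordinates are 0-based half-open; coordinates written to
  files (GFF3, D-plot tables, hit dumps) are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement over the DNA alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Display form of a sequence (T -> U); used only when writing output."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class GenomeSeq:
    """A named nucleotide sequence (genome contig, transcript, miRNA...)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        if not seq:
            raise FormatError(f"record {self.name!r}: empty sequence")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.name!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeSeq]:
    """Read a FASTA file into :class:`GenomeSeq` records (U->T, upper-cased)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        records.append(GenomeSeq(rec.id, str(rec.seq)))
    return records


def write_fasta(seqs: Iterable[GenomeSeq], path: str | Path, as_rna: bool = False) -> None:
    """Write records to FASTA. ``as_rna`` displays T as U (e.g. miRNA catalogs)."""
    recs = [
        SeqRecord(Seq(to_rna(s.sequence) if as_rna else s.sequence), id=s.name, description="")
        for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# tag tables
# ---------------------------------------------------------------------------


@dataclass
class TagTable:
    """Distinct small-RNA or PARE tags with per-library raw counts.

    ``counts`` is a DataFrame indexed by tag sequence (distinct, DNA alphabet)
    with one integer column per library.  ``genome_matched_totals`` holds the
    per-library normalization basis once mapping has been performed.
    """

    counts: pd.DataFrame
    genome_matched_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("tag table index contains duplicate tags")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("tag table contains negative counts")

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def raw(self, tag: str, library: str) -> int:
        return int(self.counts.at[tag, library])

    def total_abundance(self, tag: str) -> int:
        """Raw count summed over libraries."""
        return int(self.counts.loc[tag].sum())

    def subset(self, tags: Iterable[str]) -> "TagTable":
        wanted = set(tags)
        keep = [t for t in self.counts.index if t in wanted]
        return TagTable(self.counts.loc[keep].copy(), dict(self.genome_matched_totals))


def read_tag_table(path: str | Path, library_ids: Sequence[str] | None = None) -> TagTable:
    """Read a TSV tag table (columns: ``tag`` then one count column per library).

    Duplicate tag rows are summed with a logged warning; non-integer counts
    raise :class:`FormatError` with the offending 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "tag" not in df.columns:
        raise FormatError(f"{path}: missing 'tag' column")
    libs = list(library_ids) if library_ids is not None else [c for c in df.columns if c != "tag"]
    missing = set(libs) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing library columns {sorted(missing)}")
    for col in libs:
        for row_num, value in enumerate(df[col], start=1):
            try:
                int(value)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {value!r} in column {col!r}, row {row_num}"
                ) from None
        df[col] = df[col].astype("int64")
    df["tag"] = df["tag"].map(normalize_sequence)
    if df["tag"].duplicated().any():
        ndup = int(df["tag"].duplicated().sum())
        logger.warning("%s: %d duplicate tag rows summed", path, ndup)
    counts = df.groupby("tag", sort=False)[libs].sum()
    return TagTable(counts)


def write_tag_table(table: TagTable, path: str | Path) -> None:
    out = table.counts.reset_index()
    out = out.rename(columns={out.columns[0]: "tag"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcript models and GFF3
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """A spliced transcript: exon intervals on the genome plus orientation.

    Exons are 0-based half-open genome intervals stored sorted in transcript
    (5'->3') order: ascending genome start for ``+`` transcripts, descending
    for ``-``.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (a1, b1), (a2, b2) in zip(genomic, genomic[1:]):
            if b1 > a2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        parts = []
        for a, b in sorted(self.exons):
            parts.append(chrom_seq[a:b])
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


def read_transcript_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GFF3 file, grouped by Parent (or ID).

    Only ``exon`` features are consumed; coordinates converted from 1-based
    inclusive to internal 0-based half-open.
    """
    groups: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "exon":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attr.get("Parent") or attr.get("ID")
            if parent is None:
                raise FormatError(f"{path}:{lineno}: exon without Parent/ID")
            g = groups.setdefault(parent, {"chrom": chrom, "strand": strand, "exons": []})
            g["exons"].append((int(start) - 1, int(end)))
    return [
        TranscriptModel(tid, g["chrom"], g["strand"], g["exons"])
        for tid, g in groups.items()
    ]


def write_transcript_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            genomic = sorted(m.exons)
            lo, hi = genomic[0][0], genomic[-1][1]
            fh.write(
                f"{m.chrom}\t.\ttranscript\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id}\n"
            )
            for a, b in genomic:
                fh.write(
                    f"{m.chrom}\t.\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# packaged study tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaperTables:
    """Transcribed summary tables shipped with the package.

    ``smallrna_libraries`` and ``pare_libraries`` each carry the per-library
    rows plus a printed total row (``code`` empty).  ``new_mirnas`` exposes
    (family, name, sequence, length, abundance); the abundance column stores
    the printed numbers without interpreting their normalization basis.
    """

    smallrna_libraries: pd.DataFrame
    new_mirnas: pd.DataFrame
    pare_libraries: pd.DataFrame
    phased_triggers: pd.DataFrame

    def smallrna_rows(self) -> pd.DataFrame:
        """Per-library rows of the small-RNA summary (total row excluded)."""
        df = self.smallrna_libraries
        return df[df["code"].notna() & (df["code"] != "")].reset_index(drop=True)

    def smallrna_total(self) -> pd.Series:
        df = self.smallrna_libraries
        return df[df["code"].isna() | (df["code"] == "")].iloc[0]

    def pare_rows(self) -> pd.DataFrame:
        df = self.pare_libraries
        return df[df["code"].notna() & (df["code"] != "")].reset_index(drop=True)

    def pare_total(self) -> pd.Series:
        df = self.pare_libraries
        return df[df["code"].isna() | (df["code"] == "")].iloc[0]


def load_paper_tables() -> PaperTables:
    """Load the packaged study summary tables."""
    base = resources.files("paremir").joinpath("data")

    def _read(name: str) -> pd.DataFrame:
        with resources.as_file(base.joinpath(name)) as p:
            return pd.read_csv(p, sep="\t")

    return PaperTables(
        smallrna_libraries=_read("table1_smallrna_libraries.tsv"),
        new_mirnas=_read("table2_new_mirnas.tsv"),
        pare_libraries=_read("table3_pare_libraries.tsv"),
        phased_triggers=_read("table5_phased_triggers.tsv"),
    )


# ---------------------------------------------------------------------------
# D-plot tables
# ---------------------------------------------------------------------------


def write_dplot_table(profile, site: int | None, path: str | Path, transcript_length: int | None = None) -> None:
    """Write a degradation-plot table: one row per occupied transcript position.

    Columns: 1-based position, TP10M abundance, and a flag marking the
    miRNA cleavage site (true on at most one row).
    """
    positions = sorted(profile.abundance_by_position)
    if site is not None:
        limit = transcript_length
        if limit is None and positions:
            limit = max(positions) + 1
        if site < 0 or (limit is not None and site >= limit):
            raise ValueError(f"cleavage site {site} outside transcript")
    with open(path, "w") as fh:
        fh.write("position\tabundance_tp10m\tis_cleavage_site\n")
        for pos in positions:
            flag = "true" if site is not None and pos == site else "false"
            fh.write(f"{pos + 1}\t{profile.abundance_by_position[pos]:.4f}\t{flag}\n")
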