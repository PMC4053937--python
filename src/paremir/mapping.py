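"""Exact-match placement of tags on genome or transcript sequences.

The mapper reports every perfect occurrence of a tag on the forward strand
and of its reverse complement on the reverse strand.  Hit counting is exact
up to ``max_hits + 1`` occurrences, after which the tag is flagged as
exceeding the cap (the downstream pipelines only ever ask "<= 20 hits?").

Multi-mapping abundance is never apportioned across hits: each hit carries
the tag's full abundance, and the hit count is used only for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_io import GenomeSeq, revcomp

PARE_TAG_LENGTH = 20


@dataclass(frozen=True)
class GenomeHit:
    """One perfect match: 0-based offset of the tag's 5'-most genome base.

    Reverse-strand hits are recorded at the position of the reverse-complement
    match, i.e. ``start`` is the leftmost genome coordinate of the matched
    window on either strand.
    """

    chrom: str
    start: int
    strand: str


@dataclass
class TagHits:
    """Hit list for one tag, possibly truncated at the hit cap."""

    hits: list[GenomeHit] = field(default_factory=list)
    exceeded: bool = False

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def _find_all(haystack: str, needle: str, out: list[int], cap: int) -> None:
    """Append all occurrence starts of needle, stopping once len(out) > cap."""
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        if len(out) > cap:
            return
        pos = haystack.find(needle, pos + 1)


def map_tags(
    seqs: Sequence[GenomeSeq],
    tags: Iterable[str],
    max_hits: int = 20,
) -> dict[str, TagHits]:
    """Map each tag to its perfect-match hits across ``seqs``.

    Tags containing N get zero hits (N never matches).  When a tag has more
    than ``max_hits`` occurrences, enumeration stops at ``max_hits + 1`` and
    the result is flagged ``exceeded``.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    result: dict[str, TagHits] = {}
    for tag in tags:
        if tag in result:
            continue
        th = TagHits()
        result[tag] = th
        if not tag or "N" in tag:
            continue
        rc = revcomp(tag)
        palindrome = rc == tag
        done = False
        for rec in seqs:
            starts: list[int] = []
            _find_all(rec.sequence, tag, starts, max_hits)
            for s in starts:
                th.hits.append(GenomeHit(rec.name, s, "+"))
                if palindrome:
                    th.hits.append(GenomeHit(rec.name, s, "-"))
                if len(th.hits) > max_hits:
                    done = True
                    break
            if not done and not palindrome:
                starts = []
                _find_all(rec.sequence, rc, starts, max_hits)
                for s in starts:
                    th.hits.append(GenomeHit(rec.name, s, "-"))
                    if len(th.hits) > max_hits:
                        done = True
                        break
            if done:
                break
        if len(th.hits) > max_hits:
            th.exceeded = True
            del th.hits[max_hits + 1:]
    return result


def trim_pare_tag(tag: str, length: int = PARE_TAG_LENGTH) -> str:
    """PARE tags are mapped by their 5'-most 20 nucleotides."""
    return tag[:length]


def mask_low_complexity(tag: str, max_run: int = 12) -> bool:
    """True when the tag should be removed as low complexity.

    A tag is masked when it contains a tandem run of a 1-, 2- or
    3-nucleotide motif whose total length exceeds ``max_run`` nucleotides
    (strictly greater; a 12-nt homopolymer inside a 20-mer survives).
    """
    n = len(tag)
    for k in (1, 2, 3):
        if n <= max_run:
            continue
        run = k  # current tandem run length ending at position i
        best = k
        for i in range(k, n):
            if tag[i] == tag[i - k]:
                run += 1
            else:
                run = k  # reset: a fresh motif occupies k bases
            if run > best:
                best = run
        if best > max_run:
            return True
    return False


def structural_rna_filter(tags: Iterable[str], blacklist: Iterable[str]) -> list[str]:
    """Drop tags exactly matching a blacklist sequence or its reverse complement.

    Stands in for the removal of rRNA/tRNA/snRNA/snoRNA-derived tags; the
    blacklist is supplied as plain sequences (e.g. read from a FASTA).
    """
    banned: set[str] = set()
    for b in blacklist:
        banned.add(b)
        banned.add(revcomp(b))
    return [t for t in tags if t not in banned]


def write_hit_table(hits: Mapping[str, TagHits], path) -> None:
    """Dump hits as TSV with 1-based start coordinates."""
    with open(path, "w") as fh:
        fh.write("tag\tchrom\tstart_1based\tstrand\n")
        for tag, th in hits.items():
            for h in th.hits:
                fh.write(f"{tag}\t{h.chrom}\t{h.start + 1}\t{h.strand}\n")
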