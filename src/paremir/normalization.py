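"""Library-size normalization of tag counts.

Abundances are expressed as transcripts per 2 million (TP2M, small-RNA
libraries) or transcripts per 10 million (TP10M, PARE libraries).  The
normalization basis is the library's genome-matched abundance: a raw count
is multiplied by ``scale / genome_matched_total``.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .mapping import TagHits
from .sequence_io import TagTable

TP2M = 2_000_000
TP10M = 10_000_000


class UndefinedBasisError(ValueError):
    """Normalization requested against a zero genome-matched total."""


def normalize(raw: int, genome_matched_total: int, scale: int) -> float:
    """raw * scale / genome_matched_total (the TPxM transform)."""
    if genome_matched_total <= 0:
        raise UndefinedBasisError(
            f"genome-matched total must be positive, got {genome_matched_total}"
        )
    if raw < 0:
        raise ValueError("raw count must be >= 0")
    return raw * scale / genome_matched_total


def normalize_table(table: TagTable, scale: int) -> pd.DataFrame:
    """Per-library normalized abundances for every tag in the table."""
    if not table.genome_matched_totals:
        raise UndefinedBasisError("tag table has no genome-matched totals")
    out = table.counts.astype(float).copy()
    for lib in table.library_ids:
        total = table.genome_matched_totals.get(lib, 0)
        if total <= 0:
            raise UndefinedBasisError(f"library {lib!r} has zero genome-matched total")
        out[lib] = out[lib] * (scale / total)
    return out


def attach_genome_matched_totals(table: TagTable, hits: Mapping[str, TagHits]) -> None:
    """Compute and store per-library genome-matched totals from a hit map.

    A tag counts toward the basis when it has at least one genome hit
    (tags flagged as exceeding the hit cap still matched the genome).
    """
    matched = [t for t in table.tags if t in hits and (hits[t].n_hits > 0 or hits[t].exceeded)]
    totals = table.counts.loc[matched].sum()
    table.genome_matched_totals = {lib: int(totals[lib]) for lib in table.library_ids}


def summarize(table: TagTable, hits: Mapping[str, TagHits] | None = None) -> pd.DataFrame:
    """Per-library summary: raw total, distinct, genome-matched total/distinct.

    Mirrors the bookkeeping columns of the study's library summary tables;
    the returned frame carries one row per library plus a ``Total`` row whose
    entries are the column sums.
    """
    rows = []
    for lib in table.library_ids:
        col = table.counts[lib]
        present = col > 0
        raw_total = int(col.sum())
        distinct = int(present.sum())
        if hits is not None:
            is_matched = table.counts.index.map(
                lambda t: t in hits and (hits[t].n_hits > 0 or hits[t].exceeded)
            )
            gm_total = int(col[present & is_matched].sum())
            gm_distinct = int((present & is_matched).sum())
        else:
            gm_total, gm_distinct = raw_total, distinct
        rows.append(
            {
                "library": lib,
                "raw_total": raw_total,
                "distinct": distinct,
                "genome_matched_total": gm_total,
                "genome_matched_distinct": gm_distinct,
            }
        )
    df = pd.DataFrame(rows)
    total = df.drop(columns="library").sum()
    total["library"] = "Total"
    return pd.concat([df, total.to_frame().T], ignore_index=True)[df.columns]
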