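"""miRNA-transcript complementarity scoring and cleavage-site prediction.

A site is a transcript window the same length as the miRNA, read 5'->3' on
the transcript sense strand; the miRNA binds antisense, so miRNA position
``p`` (1-based from its 5' end) pairs the site base ``L - p`` (0-based).
Penalties: mismatch 1, G:U wobble 0.5 (G:T in the DNA alphabet); gapless.

Two schemes are provided.  ``uniform`` applies the base penalties at every
position.  ``core-weighted`` doubles them at miRNA positions 2-13, the
pairing core whose disruption is most deleterious for cleavage; it stands in
for scoring systems that weight the 5' core and is labeled as such in
outputs.  Slicing occurs opposite miRNA positions 10-11: the downstream
fragment's 5' base is the one pairing miRNA position 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import normalize_sequence

SCHEMES = ("uniform", "core-weighted")
CORE_RANGE = (2, 13)  # inclusive miRNA positions with doubled penalties

MATCH, GU, MISMATCH = "match", "GU", "mismatch"

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TargetSite:
    """One scored miRNA binding site on a transcript."""

    transcript_id: str
    mirna_name: str
    start: int  # 0-based half-open site interval on the transcript
    end: int
    alignment: tuple[str, ...]  # per miRNA position (5'->3'): match/GU/mismatch
    score: float
    cleavage_pos: int  # transcript coordinate pairing miRNA position 10
    scheme: str = "uniform"


def _pair_state(mir_base: str, site_base: str) -> str:
    if _COMP.get(mir_base) == site_base:
        return MATCH
    if (mir_base, site_base) in (("G", "T"), ("T", "G")):
        return GU
    return MISMATCH


def _position_weight(pos_1based: int, scheme: str) -> float:
    if scheme == "core-weighted" and CORE_RANGE[0] <= pos_1based <= CORE_RANGE[1]:
        return 2.0
    return 1.0


def duplex_score(
    mirna: str,
    site: str,
    scheme: str = "uniform",
    mismatch_penalty: float = 1.0,
    gu_penalty: float = 0.5,
) -> tuple[float, tuple[str, ...]]:
    """Score a gapless miRNA:site duplex; returns (score, per-position states).

    ``site`` is the transcript sense-strand window, same length as the miRNA.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    m = normalize_sequence(mirna)
    s = normalize_sequence(site)
    if len(m) != len(s):
        raise ValueError(f"miRNA ({len(m)} nt) and site ({len(s)} nt) lengths differ")
    L = len(m)
    states = []
    score = 0.0
    for p in range(1, L + 1):
        state = _pair_state(m[p - 1], s[L - p])
        states.append(state)
        w = _position_weight(p, scheme)
        if state == MISMATCH:
            score += mismatch_penalty * w
        elif state == GU:
            score += gu_penalty * w
    return score, tuple(states)


def cleavage_coordinate(site_start: int, site_len: int) -> int:
    """Transcript coordinate of the downstream fragment's 5' base.

    For a site [s, s+L) with the miRNA 5' end pairing the site's 3'-most
    base, miRNA position 10 pairs s + (L - 10).
    """
    if site_len < 11:
        raise ValueError(f"site of {site_len} nt has no position-10/11 boundary")
    return site_start + site_len - 10


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.int8, count=len(seq))


def predict_targets(
    mirna_name: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    scheme: str = "uniform",
    max_score: float = 7.0,
    mismatch_penalty: float = 1.0,
    gu_penalty: float = 0.5,
) -> list[TargetSite]:
    """All sites with score <= max_score, sorted by (transcript, position).

    Scans every window of miRNA length with a vectorized penalty profile;
    N bases never pair (they always incur the mismatch penalty).
    """
    m = normalize_sequence(mirna_seq)
    L = len(m)
    mir_codes = _encode(m)

    # penalty[mir_code, site_code] under unit weights
    pen = np.full((5, 5), mismatch_penalty, dtype=np.float64)
    for a, b in ((0, 3), (3, 0), (2, 1), (1, 2)):
        pen[a, b] = 0.0
    pen[2, 3] = gu_penalty  # G:U
    pen[3, 2] = gu_penalty  # U:G
    pen[4, :] = mismatch_penalty
    pen[:, 4] = mismatch_penalty

    sites: list[TargetSite] = []
    for tid in sorted(transcripts):
        seq = normalize_sequence(transcripts[tid])
        n = len(seq)
        if n < L:
            continue
        codes = _encode(seq)
        n_win = n - L + 1
        scores = np.zeros(n_win, dtype=np.float64)
        for offset in range(L):
            p = L - offset  # miRNA position pairing site offset (0-based)
            w = _position_weight(p, scheme)
            scores += w * pen[mir_codes[p - 1], codes[offset : offset + n_win]]
        for s in np.nonzero(scores <= max_score + 1e-9)[0]:
            s = int(s)
            score, states = duplex_score(
                m, seq[s : s + L], scheme, mismatch_penalty, gu_penalty
            )
            sites.append(
                TargetSite(
                    transcript_id=tid,
                    mirna_name=mirna_name,
                    start=s,
                    end=s + L,
                    alignment=states,
                    score=score,
                    cleavage_pos=cleavage_coordinate(s, L),
                    scheme=scheme,
                )
            )
    return sites


def predict_targets_presets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    presets: dict[str, tuple[str, float]],
    mismatch_penalty: float = 1.0,
    gu_penalty: float = 0.5,
) -> list[TargetSite]:
    """Union of sites over (scheme, threshold) presets, deduplicated.

    A site found by several presets is reported once, keeping the preset
    order of ``presets`` for attribution via the ``scheme`` field.
    """
    seen: dict[tuple[str, str, int], TargetSite] = {}
    for preset_name, (scheme, max_score) in presets.items():
        for name, seq in mirnas.items():
            for site in predict_targets(
                name, seq, transcripts, scheme, max_score, mismatch_penalty, gu_penalty
            ):
                key = (site.mirna_name, site.transcript_id, site.start)
                if key not in seen:
                    seen[key] = site
    return sorted(seen.values(), key=lambda s: (s.transcript_id, s.start, s.mirna_name))


def write_target_table(sites, path) -> None:
    """Target TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "mirna\ttranscript\tstart_1based\tend_1based\tscheme\tscore\tcleavage_pos_1based\n"
        )
        for s in sites:
            fh.write(
                f"{s.mirna_name}\t{s.transcript_id}\t{s.start + 1}\t{s.end}\t"
                f"{s.scheme}\t{s.score:g}\t{s.cleavage_pos + 1}\n"
            )
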