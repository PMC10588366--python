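"""Tiling Cas9 guide design on a target transcript.

Scans both strands for 23-base protospacer+PAM sites (SpCas9 NGG),
greedily selects a non-overlapping tiling, and emits T7 in-vitro
transcription templates.  Also provides the sequence diagnostics used to
reason about why a transcript escapes poly(A) depletion: IUPAC motif
scanning (e.g. the AATAAA-family polyadenylation signal) and maximal
poly(A)-stretch detection.

Coordinates are 0-based half-open internally and 1-based in reports.
No on/off-target scoring is attempted: the designer guarantees count and
non-overlap of cut sites, not activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd

__all__ = [
    "Protospacer", "GuideSet", "find_protospacers", "select_nonoverlapping",
    "emit_t7_templates", "scan_motifs", "find_polya_stretches",
    "T7_PROMOTER", "SCAFFOLD_OVERLAP",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Minimal T7 promoter used to drive in vitro transcription of each guide.
T7_PROMOTER = "TAATACGACTCACTATAG"
#: 5' end of the invariant sgRNA scaffold, appended after the spacer so the
#: template can be completed by overlap-extension PCR.
SCAFFOLD_OVERLAP = "GTTTTAGAGCTAGAAATAGCAAG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SITE_LEN = 23  # 20-base spacer + 3-base PAM


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_nt(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Protospacer:
    """One candidate Cas9 site: 23 bases on the plus-sequence coordinate
    ``[start, start+23)``; the spacer is strand-oriented 5'→3' and
    excludes the PAM."""

    start: int
    strand: str           # "+" or "-"
    spacer: str           # 20 bases
    pam: str              # 3 bases, NGG on its strand

    @property
    def end(self) -> int:
        return self.start + SITE_LEN


@dataclass
class GuideSet:
    """Ordered non-overlapping guide selection on one target."""

    target_id: str
    guides: List[Protospacer]

    def __len__(self) -> int:
        return len(self.guides)

    def starts(self) -> List[int]:
        return [g.start for g in self.guides]


def find_protospacers(seq: str) -> List[Protospacer]:
    """Every 23-base window carrying an NGG PAM on either strand, in
    ascending start order (plus strand first on ties).

    Plus-strand sites have the PAM at window positions 20..22 (N,G,G);
    minus-strand sites show C,C,N at window positions 0..2 on the plus
    sequence, and their spacer is the reverse complement of plus positions
    3..22.  Sequences shorter than 23 bases yield an empty list.
    """
    seq = _check_nt(seq)
    sites: List[Protospacer] = []
    for start in range(len(seq) - SITE_LEN + 1):
        window = seq[start:start + SITE_LEN]
        if window[21] == "G" and window[22] == "G":
            sites.append(Protospacer(start, "+", window[:20], window[20:]))
        if window[0] == "C" and window[1] == "C":
            sites.append(Protospacer(start, "-", revcomp(window[3:]),
                                     revcomp(window[:3])))
    return sites


def select_nonoverlapping(candidates: List[Protospacer],
                          max_guides: Optional[int] = None,
                          min_gap: int = 0,
                          target_id: str = "target") -> GuideSet:
    """Greedy left-to-right tiling: accept a candidate iff its 23-base
    interval (plus ``min_gap``) does not intersect any accepted interval;
    stop once ``max_guides`` are selected.

    Greedy maximality: with no guide cap, no rejected candidate fits in a
    remaining gap.
    """
    selected: List[Protospacer] = []
    last_end = -10**9
    for cand in candidates:
        if max_guides is not None and len(selected) >= max_guides:
            break
        if cand.start >= last_end + min_gap:
            selected.append(cand)
            last_end = cand.end
    return GuideSet(target_id, selected)


def emit_t7_templates(gs: GuideSet, promoter: str = T7_PROMOTER,
                      scaffold_overlap: str = SCAFFOLD_OVERLAP) -> pd.DataFrame:
    """Per-guide template: promoter + spacer + scaffold overlap, with a G
    prepended when the spacer does not already start with one (T7
    initiates transcription on G).

    Returns a table with name, strand, start (1-based), spacer, template,
    in coordinate order.
    """
    if not promoter or not scaffold_overlap:
        raise ValueError("promoter and scaffold_overlap must be non-empty")
    rows = []
    for i, g in enumerate(gs.guides, 1):
        spacer = g.spacer if g.spacer.startswith("G") else "G" + g.spacer
        rows.append({
            "name": f"{gs.target_id}_sg{i:02d}",
            "strand": g.strand,
            "start": g.start + 1,
            "spacer": g.spacer,
            "pam": g.pam,
            "template": promoter + spacer + scaffold_overlap,
        })
    return pd.DataFrame(rows, columns=["name", "strand", "start", "spacer",
                                       "pam", "template"])


def scan_motifs(seq: str, motif: str) -> List[int]:
    """All 1-based start positions where the IUPAC ``motif`` matches
    (U treated as T on both arguments, overlaps allowed)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = _check_nt(seq)
    motif = motif.upper().replace("U", "T")
    try:
        allowed = [IUPAC[c] for c in motif]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in motif") from exc
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(seq[i + j] in allowed[j] for j in range(len(motif))):
            hits.append(i + 1)
    return hits


def find_polya_stretches(seq: str, min_len: int = 5) -> List[Tuple[int, int]]:
    """Maximal runs of A of length >= ``min_len`` as (1-based start, length)."""
    seq = _check_nt(seq)
    out = []
    i = 0
    while i < len(seq):
        if seq[i] == "A":
            j = i
            while j < len(seq) and seq[j] == "A":
                j += 1
            if j - i >= min_len:
                out.append((i + 1, j - i))
            i = j
        else:
            i += 1
    return out
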