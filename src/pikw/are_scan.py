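"""Degenerate-consensus motif scanning for antioxidant response elements.

NRF2 binds AREs whose human de novo consensus is TGASWMAKCN in IUPAC code
(S = G/C, W = A/T, M = A/C, K = G/T, N = any base). The scanner matches any
IUPAC pattern against promoter windows upstream of gene loci, on both strands
by default (AREs act orientation-independently), reporting every overlapping
hit in forward-strand, 0-based half-open coordinates. An ambiguous 'N' in the
scanned sequence matches only pattern positions that are themselves 'N' — an
unknown base is never credited with satisfying a constrained position.

Loci come from BED records; the scanned window is the ~1000 bp immediately
upstream of the annotated locus start (strand-aware), truncated — not
discarded — at contig edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ARE_CONSENSUS",
    "IUPAC_SETS",
    "IUPACPattern",
    "MotifHit",
    "UpstreamWindow",
    "compile_pattern",
    "scan",
    "extract_upstream",
    "count_ares",
    "read_bed",
]

ARE_CONSENSUS = "TGASWMAKCN"

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class IUPACPattern:
    pattern: str
    degeneracy: int

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One match, in forward-strand 0-based half-open coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    matched_text: str  # forward-strand slice


@dataclass(frozen=True)
class UpstreamWindow:
    locus_id: str
    sequence_id: str
    start: int  # forward-strand half-open interval of the window
    end: int
    sequence: str  # oriented 5'->3' relative to the gene
    strand: str
    truncated: bool


def compile_pattern(text: str) -> IUPACPattern:
    """Validate an IUPAC pattern and compute its degeneracy."""
    text = text.upper()
    if not text:
        raise ValueError("empty pattern")
    degeneracy = 1
    for ch in text:
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern")
        degeneracy *= len(IUPAC_SETS[ch])
    return IUPACPattern(text, degeneracy)


def _regex(pattern: IUPACPattern) -> re.Pattern:
    # sequence 'N' may only satisfy pattern 'N'; constrained positions
    # therefore exclude it from their character class
    parts = []
    for ch in pattern.pattern:
        allowed = IUPAC_SETS[ch]
        if ch == "N":
            allowed += "N"
        parts.append(f"[{allowed}]" if len(allowed) > 1 else allowed)
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    return seq


def scan(
    sequence: str,
    pattern: IUPACPattern | str,
    strands: str = "both",
    sequence_id: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """All (overlapping) pattern occurrences in ``sequence``.

    With ``strands="both"`` the reverse complement is scanned too and its
    hits are reported in forward-strand coordinates with strand "-".
    ``offset`` shifts reported coordinates (used when the sequence is a
    window cut out of a larger contig). A sequence shorter than the pattern
    yields an empty list.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    seq = _validate_sequence(sequence)
    m = len(pattern)
    rx = _regex(pattern)
    hits = [
        MotifHit(sequence_id, offset + mo.start(), offset + mo.start() + m,
                 "+", mo.group(1))
        for mo in rx.finditer(seq)
    ]
    if strands == "both":
        rc = str(Seq(seq).reverse_complement())
        L = len(seq)
        for mo in rx.finditer(rc):
            start = L - mo.start() - m
            hits.append(
                MotifHit(sequence_id, offset + start, offset + start + m,
                         "-", seq[start:start + m])
            )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def extract_upstream(
    sequence: str,
    locus_id: str,
    sequence_id: str,
    start: int,
    end: int,
    strand: str,
    window: int = 1000,
) -> UpstreamWindow:
    """The ``window`` bp immediately upstream of a locus, gene-oriented.

    Plus-strand locus [s, e): window [max(0, s - window), s), sequence as-is.
    Minus-strand locus: window [e, min(L, e + window)), reverse-complemented
    so it reads 5'->3' toward the gene. Windows are truncated at contig
    edges and the truncation recorded.
    """
    seq = _validate_sequence(sequence)
    L = len(seq)
    if not (0 <= start < end <= L):
        raise ValueError(
            f"locus {locus_id!r} [{start},{end}) outside sequence of length {L}"
        )
    if strand == "+":
        w_start, w_end = max(0, start - window), start
        truncated = (start - window) < 0
        text = seq[w_start:w_end]
    elif strand == "-":
        w_start, w_end = end, min(L, end + window)
        truncated = (end + window) > L
        text = str(Seq(seq[w_start:w_end]).reverse_complement())
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return UpstreamWindow(locus_id, sequence_id, w_start, w_end, text,
                          strand, truncated)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end, name, score, strand."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "name": str,
               "score": str, "strand": str},
    )
    return df


def count_ares(
    fasta: str | Path | dict[str, str],
    loci: pd.DataFrame | str | Path,
    pattern: IUPACPattern | str = ARE_CONSENSUS,
    window: int = 1000,
    strands: str = "both",
) -> pd.DataFrame:
    """Per-locus ARE counts in upstream windows.

    ``fasta`` may be a path or an id -> sequence mapping; ``loci`` a BED path
    or an equivalent DataFrame. Every locus is reported, including those with
    zero hits — motif absence is itself a finding. Hit coordinates are
    forward-strand positions on the source sequence, 0-based half-open.
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    if isinstance(fasta, (str, Path)):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    else:
        seqs = dict(fasta)
    if isinstance(loci, (str, Path)):
        loci = read_bed(loci)
    missing = sorted(set(loci["chrom"]) - set(seqs))
    if missing:
        raise ValueError(f"BED sequence ids missing from FASTA: {missing}")

    rows = []
    for _, rec in loci.iterrows():
        win = extract_upstream(
            seqs[rec["chrom"]], rec["name"], rec["chrom"],
            int(rec["start"]), int(rec["end"]), rec["strand"], window,
        )
        # scan in source-forward coordinates regardless of gene orientation
        forward_window = seqs[rec["chrom"]][win.start:win.end]
        hits = scan(forward_window, pattern, strands=strands,
                    sequence_id=rec["chrom"], offset=win.start)
        rows.append({
            "locus_id": rec["name"],
            "sequence_id": rec["chrom"],
            "window_start": win.start,
            "window_end": win.end,
            "truncated": win.truncated,
            "n_hits": len(hits),
            "hits": hits,
        })
    return pd.DataFrame(rows)
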