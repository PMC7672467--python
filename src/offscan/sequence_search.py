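"""Core sequence types and PAM-constrained, mismatch-tolerant off-target search.

The SpCas9 query is a guide RNA: a 20-nt protospacer read 5'->3' followed by a
3-nt protospacer-adjacent motif (PAM), canonically NGG.  A candidate off-target
site (OTS) is any 23-nt genomic window, on either strand, whose last 3 nt match
the PAM pattern and whose first 20 nt lie within a mismatch budget of the
protospacer.  Position indexing throughout the package: position 1 is the
PAM-distal (5') end of the protospacer, position 20 is adjacent to the PAM, and
the PAM occupies positions 21-23.

Coordinates are 0-based half-open on the forward strand of the reference (BED
convention).  Minus-strand hits report ``site_seq`` as the reverse complement
of the reference window, so ``site_seq`` always reads protospacer-then-PAM
5'->3' on the matching strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlphabetError",
    "GuideRNA",
    "PamPattern",
    "CandidateSite",
    "revcomp",
    "gc_content",
    "mismatch_profile",
    "pam_match",
    "enumerate_candidates",
    "read_fasta",
    "read_guides_tsv",
    "write_candidates_tsv",
    "read_candidates_tsv",
]

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN  # 23
DEFAULT_MAX_MISMATCH = 6

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes -> set of unambiguous bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class AlphabetError(ValueError):
    """A sequence contains a character outside the expected alphabet."""


def _check_alphabet(seq: str, allowed: str, what: str = "sequence") -> None:
    bad = set(seq) - set(allowed)
    if bad:
        raise AlphabetError(
            f"{what} contains characters outside {{{allowed}}}: {sorted(bad)}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    _check_alphabet(seq, "ACGTN")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G/C bases in ``seq``; raises on an empty string."""
    if not seq:
        raise ValueError("gc_content is undefined for an empty sequence")
    _check_alphabet(seq, "ACGT")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class GuideRNA:
    """A named SpCas9 guide: 20-nt protospacer plus 3-nt PAM.

    ``cell_type`` records where the guide's validated off-targets were
    detected; it is optional metadata, not part of identity.
    """

    name: str
    protospacer: str
    pam: str
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"protospacer must be {PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if len(self.pam) != PAM_LEN:
            raise ValueError(f"PAM must be {PAM_LEN} nt, got {len(self.pam)}")
        _check_alphabet(self.protospacer, "ACGT", "protospacer")
        _check_alphabet(self.pam, "ACGT", "PAM")

    @property
    def sequence(self) -> str:
        """Full 23-nt target sequence (protospacer + PAM)."""
        return self.protospacer + self.pam


@dataclass(frozen=True)
class PamPattern:
    """A 3-symbol IUPAC PAM pattern.  NGG is canonical; NRG is also common."""

    pattern: str = "NGG"

    def __post_init__(self) -> None:
        if len(self.pattern) != PAM_LEN:
            raise ValueError(f"PAM pattern must be {PAM_LEN} symbols")
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise AlphabetError(f"non-IUPAC symbols in PAM pattern: {sorted(bad)}")

    def allowed(self, i: int) -> frozenset[str]:
        return IUPAC_CODES[self.pattern[i]]


def pam_match(seq3: str, pattern: PamPattern | str) -> bool:
    """True iff each base of a 3-nt sequence is in the matching IUPAC set."""
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    if len(seq3) != PAM_LEN:
        raise ValueError(f"PAM sequence must be {PAM_LEN} nt, got {len(seq3)}")
    _check_alphabet(seq3, "ACGT", "PAM sequence")
    return all(seq3[i] in pattern.allowed(i) for i in range(PAM_LEN))


def mismatch_profile(
    guide: "GuideRNA | str", site20: str
) -> tuple[int, list[int]]:
    """Mismatch count and 1-based positions between a protospacer and a 20-mer.

    Position 1 is PAM-distal; position 20 abuts the PAM.
    """
    proto = guide.protospacer if isinstance(guide, GuideRNA) else guide
    if len(proto) != PROTOSPACER_LEN or len(site20) != PROTOSPACER_LEN:
        raise ValueError(
            f"mismatch_profile requires two {PROTOSPACER_LEN}-nt sequences"
        )
    positions = [i + 1 for i in range(PROTOSPACER_LEN) if proto[i] != site20[i]]
    return len(positions), positions


@dataclass
class CandidateSite:
    """One candidate cleavage locus with its mismatch profile vs. its guide.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``site_seq`` is the 23-nt sequence on the matching strand (reverse
    complement of the reference window for minus-strand hits).  ``label`` is
    the validation status (1 = experimentally validated OTS) once assigned.
    """

    guide_name: str
    chrom: str
    start: int
    end: int
    strand: str
    site_seq: str
    n_mismatch: int
    mismatch_positions: tuple[int, ...]
    label: int | None = None
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LEN:
            raise ValueError(f"site must span {SITE_LEN} bp (end - start)")
        if len(self.site_seq) != SITE_LEN:
            raise ValueError(f"site_seq must be {SITE_LEN} nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.n_mismatch != len(self.mismatch_positions):
            raise ValueError("n_mismatch must equal len(mismatch_positions)")
        if self.label not in (None, 0, 1):
            raise ValueError("label must be 0, 1 or None")

    @property
    def protospacer_seq(self) -> str:
        return self.site_seq[:PROTOSPACER_LEN]

    @property
    def pam_seq(self) -> str:
        return self.site_seq[PROTOSPACER_LEN:]

    @property
    def locus(self) -> tuple[str, int, int, str]:
        """Locus key used for labeling, merging and set intersection."""
        return (self.chrom, self.start, self.end, self.strand)

    def validate_against(self, guide: GuideRNA, pattern: PamPattern) -> None:
        """Check the full type invariants that need the guide and PAM pattern."""
        n, pos = mismatch_profile(guide, self.protospacer_seq)
        if (n, tuple(pos)) != (self.n_mismatch, tuple(self.mismatch_positions)):
            raise ValueError("stored mismatch profile disagrees with site_seq")
        if not pam_match(self.pam_seq, pattern):
            raise ValueError(f"PAM {self.pam_seq!r} does not match {pattern.pattern}")


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

_BASE_ORD = np.frombuffer(b"ACGT", dtype=np.uint8)


def _iupac_lut(code: str) -> np.ndarray:
    lut = np.zeros(256, dtype=bool)
    for b in IUPAC_CODES[code]:
        lut[ord(b)] = True
    return lut


def _scan_one_strand(
    seq: str, proto: str, pattern: PamPattern, max_mm: int
) -> list[tuple[int, int, list[int]]]:
    """All (window_start, n_mm, positions) hits of ``proto``+PAM in ``seq``.

    Vectorized over every 23-nt window: byte-compare the 20-mer against the
    protospacer, check the PAM with per-symbol IUPAC lookup tables, and skip
    any window containing a base outside {A,C,G,T}.
    """
    L = len(seq)
    if L < SITE_LEN:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)

    acgt = np.zeros(256, dtype=bool)
    acgt[_BASE_ORD] = True
    valid = acgt[win].all(axis=1)

    proto_arr = np.frombuffer(proto.encode("ascii"), dtype=np.uint8)
    mm = (win[:, :PROTOSPACER_LEN] != proto_arr).sum(axis=1)

    pam_ok = np.ones(win.shape[0], dtype=bool)
    for j in range(PAM_LEN):
        pam_ok &= _iupac_lut(pattern.pattern[j])[win[:, PROTOSPACER_LEN + j]]

    hit_idx = np.flatnonzero(valid & pam_ok & (mm <= max_mm))
    out = []
    for i in hit_idx:
        diffs = np.flatnonzero(win[i, :PROTOSPACER_LEN] != proto_arr)
        out.append((int(i), int(mm[i]), [int(d) + 1 for d in diffs]))
    return out


def enumerate_candidates(
    genome: Mapping[str, str],
    guide: GuideRNA,
    max_mm: int = DEFAULT_MAX_MISMATCH,
    pattern: PamPattern | str = PamPattern("NGG"),
) -> list[CandidateSite]:
    """Enumerate every candidate OTS of ``guide`` in ``genome``.

    Both strands are scanned; minus-strand hits are found by scanning the
    reverse complement of each contig and mapping window offsets back to
    forward-strand coordinates.  Windows containing non-ACGT bases are skipped
    entirely.  Chromosome-end windows shorter than 23 nt are dropped.  Output
    order is deterministic: (chrom, start, strand).
    """
    if isinstance(pattern, str):
        pattern = PamPattern(pattern)
    if max_mm < 0:
        raise ValueError("max_mm must be non-negative")

    sites: list[CandidateSite] = []
    for chrom in genome:
        # ambiguity codes other than N also disqualify a window; fold them to N
        seq = "".join(
            c if c in "ACGT" else "N" for c in genome[chrom].upper()
        )
        L = len(seq)
        for start, n_mm, pos in _scan_one_strand(seq, guide.protospacer, pattern, max_mm):
            sites.append(
                CandidateSite(
                    guide_name=guide.name,
                    chrom=chrom,
                    start=start,
                    end=start + SITE_LEN,
                    strand="+",
                    site_seq=seq[start : start + SITE_LEN],
                    n_mismatch=n_mm,
                    mismatch_positions=tuple(pos),
                    cell_type=guide.cell_type,
                )
            )
        rc = revcomp(seq)
        for rstart, n_mm, pos in _scan_one_strand(rc, guide.protospacer, pattern, max_mm):
            fstart = L - SITE_LEN - rstart
            sites.append(
                CandidateSite(
                    guide_name=guide.name,
                    chrom=chrom,
                    start=fstart,
                    end=fstart + SITE_LEN,
                    strand="-",
                    site_seq=rc[rstart : rstart + SITE_LEN],
                    n_mismatch=n_mm,
                    mismatch_positions=tuple(pos),
                    cell_type=guide.cell_type,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-contig, line-wrapped) FASTA into a dict.

    Sequences are uppercased; contig order follows the file.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    return genome


def read_guides_tsv(path: str | Path) -> list[GuideRNA]:
    """Read guides from TSV: name, 23-nt sequence (protospacer+PAM), [cell_type].

    A header line starting with ``name`` is tolerated.
    """
    guides: list[GuideRNA] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "name":
                continue
            if len(parts) < 2:
                raise ValueError(f"malformed guide line: {line!r}")
            name, seq = parts[0], parts[1].upper()
            cell = parts[2] if len(parts) > 2 and parts[2] else None
            if len(seq) != SITE_LEN:
                raise ValueError(
                    f"guide {name!r}: expected {SITE_LEN}-nt protospacer+PAM, got {len(seq)}"
                )
            guides.append(
                GuideRNA(name, seq[:PROTOSPACER_LEN], seq[PROTOSPACER_LEN:], cell)
            )
    return guides


_CAND_COLS = [
    "guide_name",
    "chrom",
    "start",
    "end",
    "strand",
    "site_seq",
    "n_mismatch",
    "mismatch_positions",
]


def write_candidates_tsv(candidates: Iterable[CandidateSite], path: str | Path) -> None:
    cols = list(_CAND_COLS)
    cands = list(candidates)
    labeled = any(c.label is not None for c in cands)
    if labeled:
        cols.append("label")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in cands:
            row = [
                c.guide_name,
                c.chrom,
                str(c.start),
                str(c.end),
                c.strand,
                c.site_seq,
                str(c.n_mismatch),
                ",".join(map(str, c.mismatch_positions)),
            ]
            if labeled:
                row.append("" if c.label is None else str(c.label))
            fh.write("\t".join(row) + "\n")


def read_candidates_tsv(path: str | Path) -> list[CandidateSite]:
    out: list[CandidateSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            mmpos = parts[idx["mismatch_positions"]]
            label: int | None = None
            if "label" in idx and parts[idx["label"]] != "":
                label = int(parts[idx["label"]])
            out.append(
                CandidateSite(
                    guide_name=parts[idx["guide_name"]],
                    chrom=parts[idx["chrom"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    strand=parts[idx["strand"]],
                    site_seq=parts[idx["site_seq"]],
                    n_mismatch=int(parts[idx["n_mismatch"]]),
                    mismatch_positions=tuple(
                        int(p) for p in mmpos.split(",") if p
                    ),
                    label=label,
                )
            )
    return out
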