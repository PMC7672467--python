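"""Dataset curation, labeling and set intersection for validated off-targets.

Validated off-target records come from heterogeneous detection assays (in
vitro, cell-based, in vivo) and must be reduced to a uniform population before
benchmarking: fixed 23-nt span, canonical NGG PAM, at most 6 mismatches, and
guides with protospacer GC content at or below 75% (GC-rich guides are
promiscuous and would dominate the positive class).  Rejection rules are
applied in a fixed order — length, PAM, mismatch, guide GC — and each record
is charged to its first failing rule, so the filter log is conservative:
kept + per-rule rejections + orphans == input size.

Locus identity everywhere is exact coordinate equality on
(chrom, start, end, strand) under one declared genome build; a ``tolerance``
option (±k bp on start/end, same strand) exists for noisy sources, default 0.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sequence_search import (
    DEFAULT_MAX_MISMATCH,
    PAM_LEN,
    PROTOSPACER_LEN,
    SITE_LEN,
    CandidateSite,
    GuideRNA,
    PamPattern,
    gc_content,
    mismatch_profile,
    pam_match,
)

__all__ = [
    "OtsRecord",
    "CuratedDataset",
    "LabelResult",
    "filter_guides_gc",
    "curate_records",
    "merge_by_celltype",
    "label_candidates",
    "intersect_sets",
    "membership_counts",
    "read_records_tsv",
    "write_records_tsv",
    "write_records_bed",
    "write_filter_log",
]

DEFAULT_MAX_GC = 0.75

#: Fixed application order of the curation rules.
RULE_ORDER = ("length", "pam", "mismatch", "guide_gc")

Locus = tuple[str, int, int, str]


@dataclass(frozen=True)
class OtsRecord:
    """One validated off-target locus as read from a source dataset."""

    guide_name: str
    chrom: str
    start: int
    end: int
    strand: str
    site_seq: str
    technique: str
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("coordinates must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def locus(self) -> Locus:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class CuratedDataset:
    """Records surviving curation, the guides they reference, and the log."""

    guides: list[GuideRNA]
    records: list[OtsRecord]
    provenance: dict = field(default_factory=dict)
    filter_log: dict = field(default_factory=dict)

    @property
    def loci(self) -> set[Locus]:
        return {r.locus for r in self.records}


def filter_guides_gc(
    guides: Sequence[GuideRNA], max_gc: float = DEFAULT_MAX_GC
) -> tuple[list[GuideRNA], list[GuideRNA]]:
    """Partition guides by protospacer GC content (strict cutoff, PAM excluded).

    A guide is rejected iff GC > ``max_gc``; a guide at exactly the cutoff is
    kept.
    """
    kept, rejected = [], []
    for g in guides:
        (rejected if gc_content(g.protospacer) > max_gc else kept).append(g)
    return kept, rejected


def curate_records(
    records: Sequence[OtsRecord],
    guides: Sequence[GuideRNA],
    max_mm: int = DEFAULT_MAX_MISMATCH,
    pam_pattern: PamPattern | str = PamPattern("NGG"),
    max_gc: float = DEFAULT_MAX_GC,
) -> CuratedDataset:
    """Apply the four curation rules in fixed order and log every rejection.

    Rules (first failure charged): site length == 23 nt; PAM (last 3 nt)
    matches the canonical pattern; mismatch count vs. the guide <= ``max_mm``;
    guide not GC-rejected.  Records naming an unknown guide are counted as
    orphans, never silently dropped.
    """
    if isinstance(pam_pattern, str):
        pam_pattern = PamPattern(pam_pattern)
    guide_map = {g.name: g for g in guides}
    kept_guides, gc_rejected = filter_guides_gc(list(guide_map.values()), max_gc)
    gc_rejected_names = {g.name for g in gc_rejected}

    log = Counter({rule: 0 for rule in RULE_ORDER})
    log["orphan"] = 0
    orphans: list[str] = []
    kept: list[OtsRecord] = []

    for rec in records:
        guide = guide_map.get(rec.guide_name)
        if guide is None:
            log["orphan"] += 1
            orphans.append(rec.guide_name)
            continue
        seq = rec.site_seq.upper()
        if len(seq) != SITE_LEN:
            log["length"] += 1
            continue
        if not pam_match(seq[PROTOSPACER_LEN:], pam_pattern):
            log["pam"] += 1
            continue
        n_mm, _ = mismatch_profile(guide, seq[:PROTOSPACER_LEN])
        if n_mm > max_mm:
            log["mismatch"] += 1
            continue
        if rec.guide_name in gc_rejected_names:
            log["guide_gc"] += 1
            continue
        kept.append(rec)

    referenced = {r.guide_name for r in kept}
    return CuratedDataset(
        guides=[g for g in kept_guides if g.name in referenced],
        records=kept,
        provenance={
            "techniques": sorted({r.technique for r in kept}),
            "cell_types": sorted({r.cell_type for r in kept if r.cell_type}),
            "orphan_guides": sorted(set(orphans)),
        },
        filter_log={
            "input": len(records),
            "kept": len(kept),
            "rejected": {rule: log[rule] for rule in RULE_ORDER},
            "orphan": log["orphan"],
        },
    )


def merge_by_celltype(
    datasets: Iterable[CuratedDataset],
) -> dict[str, CuratedDataset]:
    """Group curated records by cell type, merging duplicate loci per guide.

    Within one (guide, cell_type) group, records at the identical locus
    reported by different assays collapse to a single record whose
    ``technique`` field is the comma-joined sorted union of sources.
    """
    by_cell: dict[str, dict[tuple[str, Locus], list[OtsRecord]]] = {}
    guides_by_cell: dict[str, dict[str, GuideRNA]] = {}
    for ds in datasets:
        guide_map = {g.name: g for g in ds.guides}
        for rec in ds.records:
            if rec.cell_type is None:
                raise ValueError(
                    f"record at {rec.locus} (guide {rec.guide_name!r}) has no cell_type"
                )
            key = (rec.guide_name, rec.locus)
            by_cell.setdefault(rec.cell_type, {}).setdefault(key, []).append(rec)
            if rec.guide_name in guide_map:
                guides_by_cell.setdefault(rec.cell_type, {})[rec.guide_name] = (
                    guide_map[rec.guide_name]
                )

    out: dict[str, CuratedDataset] = {}
    for cell in sorted(by_cell):
        merged: list[OtsRecord] = []
        for (gname, locus), group in sorted(by_cell[cell].items()):
            techniques = sorted({t for r in group for t in r.technique.split(",")})
            merged.append(replace(group[0], technique=",".join(techniques)))
        out[cell] = CuratedDataset(
            guides=sorted(guides_by_cell.get(cell, {}).values(), key=lambda g: g.name),
            records=merged,
            provenance={"cell_type": cell},
            filter_log={},
        )
    return out


@dataclass
class LabelResult:
    """Labeled candidates plus the reconciliation log of unmatched positives."""

    candidates: list[CandidateSite]
    unmatched_validated: list[OtsRecord]

    @property
    def n_positive(self) -> int:
        return sum(c.label == 1 for c in self.candidates)


def label_candidates(
    candidates: Sequence[CandidateSite],
    validated: CuratedDataset,
    tolerance: int = 0,
) -> LabelResult:
    """Label each candidate 1 iff a validated record shares its locus and guide.

    A validated record matching no candidate signals disagreement between the
    search and the curation (different build, convention or mismatch budget);
    such records are returned in the reconciliation log rather than ignored.
    With ``tolerance`` k > 0, loci on the same strand whose start and end each
    differ by at most k bp are treated as equal.
    """
    validated_keys = {(r.guide_name, r.locus) for r in validated.records}
    matched: set[tuple[str, Locus]] = set()
    labeled: list[CandidateSite] = []
    for c in candidates:
        key = (c.guide_name, c.locus)
        hit = key in validated_keys
        if not hit and tolerance > 0:
            for gname, (chrom, start, end, strand) in validated_keys:
                if (
                    gname == c.guide_name
                    and chrom == c.chrom
                    and strand == c.strand
                    and abs(start - c.start) <= tolerance
                    and abs(end - c.end) <= tolerance
                ):
                    hit = True
                    key = (gname, (chrom, start, end, strand))
                    break
        if hit:
            matched.add(key)
        labeled.append(replace_label(c, 1 if hit else 0))
    unmatched = [
        r for r in validated.records if (r.guide_name, r.locus) not in matched
    ]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} validated record(s) matched no candidate; "
            "search and curation disagree (see LabelResult.unmatched_validated)",
            stacklevel=2,
        )
    return LabelResult(candidates=labeled, unmatched_validated=unmatched)


def replace_label(site: CandidateSite, label: int) -> CandidateSite:
    """Copy a candidate with its validation label set."""
    return CandidateSite(
        guide_name=site.guide_name,
        chrom=site.chrom,
        start=site.start,
        end=site.end,
        strand=site.strand,
        site_seq=site.site_seq,
        n_mismatch=site.n_mismatch,
        mismatch_positions=site.mismatch_positions,
        label=label,
        cell_type=site.cell_type,
    )


def intersect_sets(*named_sets: tuple[str, set[Locus]]) -> dict:
    """Exact set algebra over locus sets from different assays or cell types.

    Returns pairwise intersection sizes plus the full membership-pattern
    counts (UpSet-style): for every non-empty subset of set names, how many
    loci belong to exactly those sets.
    """
    names = [n for n, _ in named_sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    sets = dict(named_sets)
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    return {
        "sizes": {n: len(s) for n, s in sets.items()},
        "pairwise": pairwise,
        "patterns": membership_counts(sets),
        "union": len(set().union(*sets.values())) if sets else 0,
    }


def membership_counts(sets: Mapping[str, set[Locus]]) -> dict[tuple[str, ...], int]:
    """Exclusive membership-pattern counts over a family of locus sets."""
    names = sorted(sets)
    counts: Counter[tuple[str, ...]] = Counter()
    for locus in set().union(*sets.values()) if sets else set():
        pattern = tuple(n for n in names if locus in sets[n])
        counts[pattern] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REC_COLS = [
    "guide_name",
    "chrom",
    "start",
    "end",
    "strand",
    "site_seq",
    "technique",
    "cell_type",
]


def read_records_tsv(path: str | Path) -> list[OtsRecord]:
    out: list[OtsRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = set(_REC_COLS[:-1]) - set(idx)
        if missing:
            raise ValueError(f"records TSV missing columns: {sorted(missing)}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cell = (
                parts[idx["cell_type"]]
                if "cell_type" in idx and parts[idx["cell_type"]]
                else None
            )
            out.append(
                OtsRecord(
                    guide_name=parts[idx["guide_name"]],
                    chrom=parts[idx["chrom"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    strand=parts[idx["strand"]],
                    site_seq=parts[idx["site_seq"]],
                    technique=parts[idx["technique"]],
                    cell_type=cell,
                )
            )
    return out


def write_records_tsv(records: Iterable[OtsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REC_COLS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.guide_name,
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.site_seq,
                        r.technique,
                        r.cell_type or "",
                    ]
                )
                + "\n"
            )


def write_records_bed(records: Iterable[OtsRecord], path: str | Path) -> None:
    """BED6 + sidecar columns (site_seq, technique, cell_type)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.guide_name,
                        ".",
                        r.strand,
                        r.site_seq,
                        r.technique,
                        r.cell_type or "",
                    ]
                )
                + "\n"
            )


def write_filter_log(dataset: CuratedDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataset.filter_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
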