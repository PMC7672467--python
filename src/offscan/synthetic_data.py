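"""Synthetic fixtures: random genomes with planted off-targets, and labeled
feature tables with controllable signal and class imbalance.

The generators emulate the structure of real off-target benchmarks — a
genome-wide candidate population with a handful of validated positives (a
fraction of a percent), grouped by cell type, with several tool-score columns
of varying informativeness — so every other module is testable without
reference genomes or external datasets.  Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_search import (
    PAM_LEN,
    PROTOSPACER_LEN,
    SITE_LEN,
    CandidateSite,
    GuideRNA,
    mismatch_profile,
    revcomp,
)

__all__ = [
    "PlantSpec",
    "SimFeatureSpec",
    "make_genome",
    "write_genome_fasta",
    "plant_sites",
    "simulate_feature_table",
    "random_guide",
]

_BASES = np.array(list("ACGT"))


def random_guide(
    seed: int, name: str = "guide", cell_type: str | None = None
) -> GuideRNA:
    """A uniformly random guide with canonical xGG PAM."""
    rng = np.random.default_rng(seed)
    proto = "".join(rng.choice(_BASES, PROTOSPACER_LEN))
    pam = "".join(rng.choice(_BASES, 1)) + "GG"
    return GuideRNA(name, proto, pam, cell_type)


def make_genome(
    length: int,
    gc: float = 0.41,
    seed: int = 0,
    n_contigs: int = 1,
) -> dict[str, str]:
    """i.i.d. random contigs with P(G or C) = ``gc`` (default human-like 41%)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0,1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    sizes = [length // n_contigs] * n_contigs
    sizes[-1] += length - sum(sizes)
    return {
        f"contig{i + 1}": "".join(rng.choice(_BASES, size, p=probs))
        for i, size in enumerate(sizes)
    }


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class PlantSpec:
    """What to plant: per-site (mismatch count, strand, 2-nt PAM tail).

    Planted loci are chosen non-overlapping; mismatch positions are drawn
    without replacement from 1..20 and mutated to a different base, so each
    planted window carries exactly the requested profile.
    """

    guide: GuideRNA
    sites: Sequence[tuple[int, str, str]] = field(
        default_factory=lambda: [(0, "+", "GG"), (2, "-", "GG"), (4, "+", "GG")]
    )
    genome_length: int = 10_000
    gc: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        for n_mm, strand, tail in self.sites:
            if not 0 <= n_mm <= PROTOSPACER_LEN:
                raise ValueError("mismatch count must lie in 0..20")
            if strand not in "+-":
                raise ValueError("strand must be '+' or '-'")
            if len(tail) != 2:
                raise ValueError("pam_tail must be 2 nt")


def plant_sites(
    genome: Mapping[str, str],
    spec: PlantSpec,
    max_tries: int = 1000,
) -> tuple[dict[str, str], list[CandidateSite]]:
    """Write mismatched copies of the guide target into a genome.

    Returns the modified genome and the truth table: one label-1
    CandidateSite per planted locus with its exact mismatch profile.  Each
    written window is re-read from the modified genome and its profile
    recomputed as a post-hoc guarantee that the plant is faithful.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = list(genome)
    seqs = {c: list(genome[c].upper()) for c in chroms}
    lengths = {c: len(genome[c]) for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth: list[CandidateSite] = []

    for n_mm, strand, tail in spec.sites:
        proto = list(spec.guide.protospacer)
        positions = sorted(rng.choice(np.arange(1, PROTOSPACER_LEN + 1), n_mm, replace=False).tolist())
        for p in positions:
            alternatives = [b for b in "ACGT" if b != proto[p - 1]]
            proto[p - 1] = alternatives[rng.integers(len(alternatives))]
        pam = str(_BASES[rng.integers(4)]) + tail
        site23 = "".join(proto) + pam
        written = site23 if strand == "+" else revcomp(site23)

        placed = False
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            if lengths[chrom] < SITE_LEN:
                continue
            start = int(rng.integers(0, lengths[chrom] - SITE_LEN + 1))
            if any(start < e and s < start + SITE_LEN for s, e in occupied[chrom]):
                continue
            seqs[chrom][start : start + SITE_LEN] = list(written)
            occupied[chrom].append((start, start + SITE_LEN))
            truth.append(
                CandidateSite(
                    guide_name=spec.guide.name,
                    chrom=chrom,
                    start=start,
                    end=start + SITE_LEN,
                    strand=strand,
                    site_seq=site23,
                    n_mismatch=n_mm,
                    mismatch_positions=tuple(positions),
                    label=1,
                    cell_type=spec.guide.cell_type,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place a non-overlapping planted site; "
                "genome too small or too crowded"
            )

    modified = {c: "".join(seqs[c]) for c in chroms}
    for site in truth:  # post-hoc faithfulness check on the written windows
        window = modified[site.chrom][site.start : site.end]
        observed = window if site.strand == "+" else revcomp(window)
        n, pos = mismatch_profile(spec.guide, observed[:PROTOSPACER_LEN])
        assert (n, tuple(pos)) == (site.n_mismatch, site.mismatch_positions), (
            "planted window does not carry the requested mismatch profile"
        )
    return modified, truth


@dataclass
class SimFeatureSpec:
    """Controls for a simulated candidate x tool-score table.

    Each row has a latent cleavage propensity z ~ N(0,1); within every cell
    type, the rows with the largest z are labeled 1 so the positive count is
    exactly round(prevalence * n) (quantile thresholding; set
    ``bernoulli=True`` for random positive counts instead).  Column j is
    ``tool_signal[j] * z + noise_sd * N(0,1)``, so a larger signal means a
    larger expected single-column AUC.
    """

    n_rows: int = 20_000
    prevalence: float = 0.004
    tool_signal: Mapping[str, float] = field(
        default_factory=lambda: {
            "CFD": 1.0,
            "MIT": 0.8,
            "CCTop": 0.6,
            "CROP-IT": 0.5,
            "DeepCRISPR": 0.7,
            "CRISPRoff": 1.2,
            "uCRISPR": 1.1,
        }
    )
    noise_sd: float = 1.0
    cell_types: Sequence[tuple[str, float, float]] | None = None  # (name, row fraction, prevalence)
    seed: int = 0
    bernoulli: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0,1)")
        if any(not np.isfinite(v) for v in self.tool_signal.values()):
            raise ValueError("tool signals must be finite")


def simulate_feature_table(spec: SimFeatureSpec) -> pd.DataFrame:
    """Simulated labeled feature table; columns as in ``build_feature_matrix``."""
    rng = np.random.default_rng(spec.seed)
    cells = spec.cell_types or [("cellA", 1.0, spec.prevalence)]
    frames = []
    for name, frac, prev in cells:
        n = int(round(spec.n_rows * frac))
        z = rng.standard_normal(n)
        if spec.bernoulli:
            # propensity-linked Bernoulli labels with expected rate ~ prev
            p = prev * np.exp(z) / np.mean(np.exp(z))
            labels = (rng.random(n) < np.clip(p, 0, 1)).astype(int)
        else:
            n_pos = max(1, int(round(prev * n)))
            labels = np.zeros(n, dtype=int)
            labels[np.argsort(-z, kind="stable")[:n_pos]] = 1
        cols = {
            col: sig * z + spec.noise_sd * rng.standard_normal(n)
            for col, sig in spec.tool_signal.items()
        }
        df = pd.DataFrame(cols)
        df.insert(0, "guide_name", f"sim_{name}")
        df.insert(1, "chrom", "simchr")
        df["label"] = labels
        df["cell_type"] = name
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(2, "start", np.arange(len(out)) * (SITE_LEN + 1))
    out.insert(3, "end", out["start"] + SITE_LEN)
    out.insert(4, "strand", "+")
    return out
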