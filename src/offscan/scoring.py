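"""Hypothesis-driven off-target scores and feature-matrix assembly.

Four position-weighted specificity scores are computed natively from the
mismatch profile of a candidate site against its guide; they share the
package-wide position convention (1 = PAM-distal, 20 = PAM-proximal):

* CFD-style score — product over mismatched positions of per-(position,
  guide base, site base) activity factors, times a factor for the 2-nt PAM
  tail; 1 at a perfect match with canonical NGG.
* MIT/Hsu score — product of (1 - W[p]) over mismatches, a penalty growing as
  mismatches cluster (mean pairwise gap d_bar), and a 1/n^2 count penalty:
  score = prod(1 - W[p]) * 1 / (((19 - d_bar)/19)*4 + 1) * 1/n^2.
* CCTop feature — the published quantity is a penalty sum(base^p) with base
  1.2; the negated value is exposed so that, like every other column, larger
  means more cleavage-prone (perfect match = 0 is the maximum).
* CROP-IT-style score — sum of segment weights over *matched* positions
  normalized by the total weight, so perfect match = 1 and all-mismatch = 0.

Numeric constants live in versioned JSON config files; the loader validates
completeness (all 20 positions x 12 mismatch pairs for CFD, exact segment
coverage of 1..20 for CROP-IT) so a missing key is a configuration error at
load time, never a silent zero at scoring time.

Energy-based and learning-based tool scores are ingested from TSVs keyed by
(guide_name, chrom, start, end, strand) — their models are not re-implemented.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_search import PROTOSPACER_LEN, CandidateSite, GuideRNA

__all__ = [
    "ConfigError",
    "ScoreTables",
    "NATIVE_SCORERS",
    "cfd_score",
    "mit_score",
    "cctop_score",
    "cropit_score",
    "ingest_external_scores",
    "build_feature_matrix",
    "feature_columns",
    "write_feature_table",
    "read_feature_table",
]

LOCUS_COLS = ["guide_name", "chrom", "start", "end", "strand"]
META_COLS = LOCUS_COLS + ["label", "cell_type"]

_BASES = "ACGT"


class ConfigError(ValueError):
    """A score-table config file is incomplete or inconsistent."""


@dataclass(frozen=True)
class ScoreTables:
    """The constant lookup tables parameterizing the four native scores."""

    cfd_mm: Mapping[tuple[int, str, str], float]
    cfd_pam: Mapping[str, float]
    mit_w: tuple[float, ...]
    cctop_base: float
    cropit_segments: tuple[tuple[int, int, float], ...]
    versions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        for p in range(1, PROTOSPACER_LEN + 1):
            for g in _BASES:
                for d in _BASES:
                    if g != d and (p, g, d) not in self.cfd_mm:
                        raise ConfigError(f"CFD table missing key ({p},{g},{d})")
        for tail in (a + b for a in _BASES for b in _BASES):
            if tail not in self.cfd_pam:
                raise ConfigError(f"CFD PAM table missing tail {tail!r}")
        if any(not (0 <= v) or not math.isfinite(v) for v in self.cfd_mm.values()):
            raise ConfigError("CFD factors must be finite and non-negative")
        if len(self.mit_w) != PROTOSPACER_LEN:
            raise ConfigError("MIT weight vector must have 20 entries")
        if any(not (0 <= w <= 1) for w in self.mit_w):
            raise ConfigError("MIT weights must lie in [0,1]")
        covered = []
        for start, end, weight in self.cropit_segments:
            if weight < 0 or not math.isfinite(weight):
                raise ConfigError("segment weights must be finite and >= 0")
            covered.extend(range(start, end + 1))
        if sorted(covered) != list(range(1, PROTOSPACER_LEN + 1)):
            raise ConfigError("CROP-IT segments must cover positions 1..20 exactly once")

    @classmethod
    def from_files(
        cls,
        cfd_path: str | Path,
        mit_path: str | Path,
        cctop_path: str | Path,
        cropit_path: str | Path,
    ) -> "ScoreTables":
        with open(cfd_path) as fh:
            cfd = json.load(fh)
        with open(mit_path) as fh:
            mit = json.load(fh)
        with open(cctop_path) as fh:
            cctop = json.load(fh)
        with open(cropit_path) as fh:
            cropit = json.load(fh)
        return cls._from_objs(cfd, mit, cctop, cropit, {
            "cfd": str(cfd_path), "mit": str(mit_path),
            "cctop": str(cctop_path), "cropit": str(cropit_path),
        })

    @classmethod
    def load_default(cls) -> "ScoreTables":
        """Load the config files shipped with the package."""
        pkg = resources.files("offscan.data")
        objs = {}
        names = {
            "cfd": "cfd_factors.synthetic.json",
            "mit": "mit_weights.json",
            "cctop": "cctop.json",
            "cropit": "cropit_segments.synthetic.json",
        }
        for key, fname in names.items():
            objs[key] = json.loads(pkg.joinpath(fname).read_text())
        return cls._from_objs(
            objs["cfd"], objs["mit"], objs["cctop"], objs["cropit"],
            {k: f"builtin:{v}" for k, v in names.items()},
        )

    @classmethod
    def _from_objs(cls, cfd, mit, cctop, cropit, versions) -> "ScoreTables":
        try:
            cfd_mm = {}
            for key, v in cfd["mismatch"].items():
                p, g, d = key.split(":")
                cfd_mm[(int(p), g, d)] = float(v)
            return cls(
                cfd_mm=cfd_mm,
                cfd_pam={k: float(v) for k, v in cfd["pam"].items()},
                mit_w=tuple(float(w) for w in mit["weights"]),
                cctop_base=float(cctop["base"]),
                cropit_segments=tuple(
                    (int(s["start"]), int(s["end"]), float(s["weight"]))
                    for s in cropit["segments"]
                ),
                versions=versions,
            )
        except (KeyError, ValueError, TypeError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(f"malformed score-table config: {exc}") from exc


def _site_mismatches(
    guide: GuideRNA, site: CandidateSite
) -> list[tuple[int, str, str]]:
    """(position, guide base, site base) for each mismatched position."""
    return [
        (p, guide.protospacer[p - 1], site.site_seq[p - 1])
        for p in site.mismatch_positions
    ]


def cfd_score(guide: GuideRNA, site: CandidateSite, tables: ScoreTables) -> float:
    """Product of per-mismatch activity factors times the PAM-tail factor."""
    score = 1.0
    for p, g, d in _site_mismatches(guide, site):
        try:
            score *= tables.cfd_mm[(p, g, d)]
        except KeyError:
            raise ConfigError(f"CFD table missing key ({p},{g},{d})") from None
    tail = site.pam_seq[1:]
    try:
        score *= tables.cfd_pam[tail]
    except KeyError:
        raise ConfigError(f"CFD PAM table missing tail {tail!r}") from None
    return score


def mit_score(guide: GuideRNA, site: CandidateSite, tables: ScoreTables) -> float:
    """Hsu-lab specificity score in [0,1]; 1 at a perfect match.

    The pairwise-distance term is undefined for a single mismatch; by the
    convention of the original webtool family its factor is taken as 1.
    """
    pos = sorted(site.mismatch_positions)
    n = len(pos)
    if n == 0:
        return 1.0
    score = 1.0
    for p in pos:
        score *= 1.0 - tables.mit_w[p - 1]
    if n > 1:
        d_bar = (pos[-1] - pos[0]) / (n - 1)  # mean gap between consecutive mismatches
        score *= 1.0 / (((19.0 - d_bar) / 19.0) * 4.0 + 1.0)
    score *= 1.0 / (n * n)
    return score


def cctop_score(guide: GuideRNA, site: CandidateSite, tables: ScoreTables) -> float:
    """Negated exponential position penalty; 0 (the maximum) at perfect match."""
    return -sum(tables.cctop_base ** p for p in site.mismatch_positions)


def cropit_score(guide: GuideRNA, site: CandidateSite, tables: ScoreTables) -> float:
    """Matched-position segment-weight mass, normalized to [0,1]."""
    weight_at = {}
    for start, end, w in tables.cropit_segments:
        for p in range(start, end + 1):
            weight_at[p] = w
    total = sum(weight_at.values())
    mismatched = set(site.mismatch_positions)
    matched_mass = sum(
        w for p, w in weight_at.items() if p not in mismatched
    )
    return matched_mass / total


#: name -> scorer, in the fixed feature order of the native columns.
NATIVE_SCORERS: dict[str, Callable[[GuideRNA, CandidateSite, ScoreTables], float]] = {
    "CFD": cfd_score,
    "MIT": mit_score,
    "CCTop": cctop_score,
    "CROP-IT": cropit_score,
}


def ingest_external_scores(
    table: pd.DataFrame | str | Path,
    candidates: pd.DataFrame,
    column: str,
    impute: str = "min",
) -> tuple[pd.Series, pd.Series, float]:
    """Join one external tool's scores onto the candidate locus keys.

    ``table`` must carry the five locus key columns plus ``column`` (or a
    single ``score`` column to be renamed).  Returns the aligned score
    series, a 0/1 missingness indicator, and the coverage fraction.
    Candidates absent from the table are imputed with the column minimum
    (the most benign assumption) and flagged in the indicator.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    table = table.copy()
    if column not in table.columns and "score" in table.columns:
        table = table.rename(columns={"score": column})
    missing_cols = set(LOCUS_COLS + [column]) - set(table.columns)
    if missing_cols:
        raise ValueError(f"external score table missing columns: {sorted(missing_cols)}")
    if table.duplicated(LOCUS_COLS).any():
        dups = table[table.duplicated(LOCUS_COLS, keep=False)]
        raise ValueError(
            f"external score table has {len(dups)} duplicate locus keys"
        )
    merged = candidates[LOCUS_COLS].merge(
        table[LOCUS_COLS + [column]], on=LOCUS_COLS, how="left"
    )
    scores = merged[column]
    flag = scores.isna()
    coverage = 1.0 - flag.mean() if len(flag) else 1.0
    fill = scores.dropna().min() if scores.notna().any() else 0.0
    scores = scores.fillna(fill)
    scores.index = candidates.index
    indicator = flag.astype(int)
    indicator.index = candidates.index
    return scores, indicator, float(coverage)


def _candidate_frame(candidates: Sequence[CandidateSite]) -> pd.DataFrame:
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            candidates[i].chrom,
            candidates[i].start,
            candidates[i].strand,
            candidates[i].guide_name,
        ),
    )
    rows = []
    for i in order:
        c = candidates[i]
        rows.append(
            {
                "guide_name": c.guide_name,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "site_seq": c.site_seq,
                "n_mismatch": c.n_mismatch,
                "label": c.label,
                "cell_type": c.cell_type,
            }
        )
    return pd.DataFrame(rows).reset_index(drop=True)


def build_feature_matrix(
    candidates: Sequence[CandidateSite],
    guides: Sequence[GuideRNA],
    tables: ScoreTables | None = None,
    native: Sequence[str] = tuple(NATIVE_SCORERS),
    external: Mapping[str, pd.DataFrame | str | Path] | None = None,
    require_labels: bool = True,
) -> pd.DataFrame:
    """Assemble the candidate x tool-score matrix with labels and grouping.

    One row per candidate in deterministic (chrom, start, strand, guide)
    order; native score columns computed in place, external columns joined by
    locus key (with a companion ``<name>_missing`` indicator when coverage is
    incomplete).  Assembly fails on any remaining missing value.
    """
    if tables is None and native:
        tables = ScoreTables.load_default()
    guide_map = {g.name: g for g in guides}
    df = _candidate_frame(candidates)
    ordered = sorted(
        candidates,
        key=lambda c: (c.chrom, c.start, c.strand, c.guide_name),
    )
    for name in native:
        scorer = NATIVE_SCORERS[name]
        df[name] = [
            scorer(guide_map[c.guide_name], c, tables) for c in ordered
        ]
    coverages: dict[str, float] = {}
    for name, tab in (external or {}).items():
        if name in df.columns:
            raise ValueError(f"duplicate feature column {name!r}")
        scores, indicator, cov = ingest_external_scores(tab, df, name)
        df[name] = scores
        coverages[name] = cov
        if cov < 1.0:
            df[f"{name}_missing"] = indicator
    if require_labels and df["label"].isna().any():
        raise ValueError("candidates must be labeled before feature assembly")
    feat = feature_columns(df)
    if df[feat].isna().any().any():
        bad = [c for c in feat if df[c].isna().any()]
        raise ValueError(f"missing values remain in feature columns: {bad}")
    df.attrs["external_coverage"] = coverages
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Score columns of a feature table (everything but locus/label/meta)."""
    skip = set(META_COLS) | {"site_seq", "n_mismatch"}
    return [c for c in table.columns if c not in skip]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
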