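"""Benchmarking predicted exon sets against reference annotations.

The benchmark has two modes.  Sequence mode classifies predictions against
annotated exon *sequences* using exact ungapped matching (a predicted exon
hits an annotated one when they share a 100%-identity stretch of at least
``min_match`` nucleotides, the analogue of retaining only perfect-identity
local alignment hits) and summarises the outcome in a weighted match score:

    total = 0.7 * recovered + 0.1 * perfect + 0.2 * extraneous

where *recovered* is the fraction of annotated exons hit at all, *perfect*
the fraction of recovered exons whose best hit is sequence-identical over
the full annotated length, and the *extraneous* component decays linearly
from 1 to 0 as the number of matchless predictions grows to 100.

Coordinate mode applies overlap rules to interval annotations from other
tools: a tool exon overlapping at least half of a reference exon is a match,
and one spanning several reference exons still counts once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scan import ExonSet, ScanParams, find_pevk_exons
from .sequence_io import GenomicSequence

__all__ = [
    "AnnotatedExon",
    "AnnotatedExonSet",
    "ExonMatchReport",
    "MatchScore",
    "ParamGridSpec",
    "longest_common_substring",
    "match_exons",
    "match_score",
    "grid_search",
    "compare_coordinates",
]


@dataclass(frozen=True)
class AnnotatedExon:
    """One reference exon: a sequence, coordinates, or both."""

    name: str
    nt_seq: str | None = None
    start: int | None = None
    end: int | None = None


@dataclass
class AnnotatedExonSet:
    origin: str
    exons: list[AnnotatedExon]
    source: str = "cDNA"

    def __post_init__(self) -> None:
        if all(x.start is not None for x in self.exons):
            self.exons.sort(key=lambda x: x.start)

    def __len__(self) -> int:
        return len(self.exons)

    @classmethod
    def from_sequences(
        cls, origin: str, seqs: Iterable[tuple[str, str]], source: str = "cDNA"
    ) -> "AnnotatedExonSet":
        return cls(origin, [AnnotatedExon(n, s) for n, s in seqs], source)


@dataclass
class ExonMatchReport:
    """Per-exon match flags plus the counts feeding the match score."""

    recovered: list[bool]
    perfect: list[bool]
    matchless: list[bool]
    n_annotated: int
    n_predicted: int

    @property
    def n_recovered(self) -> int:
        return sum(self.recovered)

    @property
    def n_perfect(self) -> int:
        return sum(self.perfect)

    @property
    def n_matchless(self) -> int:
        return sum(self.matchless)


@dataclass(frozen=True)
class MatchScore:
    recovered_component: float
    perfect_component: float
    extraneous_component: float

    @property
    def total(self) -> float:
        return (
            0.7 * self.recovered_component
            + 0.1 * self.perfect_component
            + 0.2 * self.extraneous_component
        )


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring of ``a`` and ``b``."""
    if not a or not b:
        return 0
    if len(a) > len(b):
        a, b = b, a
    A = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(len(B), dtype=np.int32)
    best = 0
    for i in range(len(A)):
        cur = np.zeros(len(B), dtype=np.int32)
        eq = B == A[i]
        cur[0] = 1 if eq[0] else 0
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def match_exons(
    predicted: ExonSet | Sequence, annotated: AnnotatedExonSet, min_match: int = 12
) -> ExonMatchReport:
    """Classify annotated exons as recovered/perfect and predictions as matchless.

    A hit is a shared 100%-identity ungapped stretch of at least ``min_match``
    nt.  Each annotated exon keeps its highest-scoring hit (score = shared
    stretch length; ties go to the longer predicted exon, then the smaller
    start coordinate).
    """
    if not all(x.nt_seq for x in annotated.exons):
        raise ValueError(
            "annotated exons lack sequences; use compare_coordinates for "
            "coordinate-only references"
        )
    pred_list = list(predicted)
    pred_seqs = [getattr(p, "nt_seq", p if isinstance(p, str) else None) for p in pred_list]
    if any(s is None for s in pred_seqs):
        raise ValueError("predicted exons must carry nt sequences")
    pred_starts = [getattr(p, "start", i) for i, p in enumerate(pred_list)]

    pred_kmers = [_kmer_set(s, min_match) for s in pred_seqs]
    ann_kmers = [_kmer_set(x.nt_seq, min_match) for x in annotated.exons]

    n_ann = len(annotated.exons)
    n_pred = len(pred_list)
    recovered = [False] * n_ann
    perfect = [False] * n_ann
    pred_hit = [False] * n_pred

    for ia, ann in enumerate(annotated.exons):
        best_key = None
        best_j = None
        for j in range(n_pred):
            if not (ann_kmers[ia] & pred_kmers[j]):
                continue  # no shared min_match-mer => no qualifying hit
            score = longest_common_substring(ann.nt_seq, pred_seqs[j])
            if score < min_match:
                continue
            pred_hit[j] = True
            key = (score, len(pred_seqs[j]), -pred_starts[j])
            if best_key is None or key > best_key:
                best_key = key
                best_j = j
        if best_j is not None:
            recovered[ia] = True
            perfect[ia] = pred_seqs[best_j] == ann.nt_seq
    matchless = [not h for h in pred_hit]
    return ExonMatchReport(recovered, perfect, matchless, n_ann, n_pred)


def match_score(report: ExonMatchReport) -> MatchScore:
    """Weighted benchmark score in [0, 1] from a match report."""
    if report.n_annotated == 0:
        raise ValueError("benchmark undefined: no annotated exons")
    r = report.n_recovered / report.n_annotated
    p = report.n_perfect / report.n_recovered if report.n_recovered else 0.0
    x = max(0.0, (100 - report.n_matchless) / 100)
    return MatchScore(r, p, x)


def score_from_counts(
    n_annotated: int, n_recovered: int, n_perfect: int, n_matchless: int
) -> MatchScore:
    """Match score directly from the four counts (no per-exon flags)."""
    report = ExonMatchReport(
        recovered=[True] * n_recovered + [False] * (n_annotated - n_recovered),
        perfect=[True] * n_perfect + [False] * (n_annotated - n_perfect),
        matchless=[True] * n_matchless,
        n_annotated=n_annotated,
        n_predicted=n_matchless,
    )
    return match_score(report)


@dataclass(frozen=True)
class ParamGridSpec:
    """Parameter grid: (min, max, step) per criterion, ranges inclusive."""

    min_exon_len: tuple[int, int, int] = (10, 30, 1)
    min_ratio: tuple[float, float, float] = (0.45, 0.83, 0.01)
    window_len: tuple[int, int, int] = (10, 30, 1)

    def __post_init__(self) -> None:
        for lo, hi, step in (self.min_exon_len, self.min_ratio, self.window_len):
            if step <= 0:
                raise ValueError("grid step must be > 0")
            if hi < lo:
                raise ValueError("empty grid range")

    def _values(self, rng: tuple[float, float, float], as_int: bool) -> list:
        lo, hi, step = rng
        n = int(round((hi - lo) / step)) + 1
        vals = [round(lo + i * step, 10) for i in range(n) if lo + i * step <= hi + 1e-9]
        return [int(v) for v in vals] if as_int else vals

    def combinations(self) -> list[tuple[int, float, int]]:
        """All (min_exon_len, min_ratio, window_len) combinations."""
        return list(
            itertools.product(
                self._values(self.min_exon_len, True),
                self._values(self.min_ratio, False),
                self._values(self.window_len, True),
            )
        )

    def __len__(self) -> int:
        return (
            len(self._values(self.min_exon_len, True))
            * len(self._values(self.min_ratio, False))
            * len(self._values(self.window_len, True))
        )


@dataclass
class GridSearchResult:
    table: pd.DataFrame
    argmax: pd.DataFrame


def grid_search(
    genome: GenomicSequence,
    annotated: AnnotatedExonSet,
    grid: ParamGridSpec | None = None,
    base_params: ScanParams | None = None,
    min_match: int = 12,
) -> GridSearchResult:
    """Evaluate the match score over every parameter combination.

    Rows are sorted by total score descending (ties: smaller window, smaller
    minimum exon length, larger ratio); ``argmax`` holds every combination
    within 1e-9 of the maximum.
    """
    if grid is None:
        grid = ParamGridSpec()
    if base_params is None:
        base_params = ScanParams()
    rows = []
    for mel, ratio, win in grid.combinations():
        params = ScanParams(
            window_len=win,
            min_ratio=ratio,
            min_exon_len=mel,
            splice_flank=base_params.splice_flank,
            landmark_min_identity=base_params.landmark_min_identity,
        )
        exons = find_pevk_exons(genome, params)
        score = match_score(match_exons(exons, annotated, min_match=min_match))
        rows.append(
            {
                "min_exon_len": mel,
                "min_ratio": ratio,
                "window_len": win,
                "n_predicted": len(exons),
                "recovered": score.recovered_component,
                "perfect": score.perfect_component,
                "extraneous": score.extraneous_component,
                "total": score.total,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["total", "window_len", "min_exon_len", "min_ratio"],
        ascending=[False, True, True, False],
        kind="mergesort",
    ).reset_index(drop=True)
    best = df["total"].max()
    argmax = df[df["total"] >= best - 1e-9].reset_index(drop=True)
    return GridSearchResult(df, argmax)


def _check_disjoint(intervals: Sequence[tuple[int, int]], label: str) -> None:
    prev_end = None
    for s, e in intervals:
        if e <= s:
            raise ValueError(f"{label}: invalid interval [{s}, {e})")
        if prev_end is not None and s < prev_end:
            raise ValueError(f"{label}: overlapping intervals (malformed annotation)")
        prev_end = e


def compare_coordinates(
    tool_exons: Sequence[tuple[int, int]], ref_exons: Sequence[tuple[int, int]]
) -> dict[str, int]:
    """Coordinate-overlap validation against a reference exon list.

    A tool exon matches when it covers at least 50% of the length of some
    reference exon; covering several reference exons still counts as one
    match.  Reference exons with zero overlap from any tool exon are
    missing; tool exons with zero overlap to any reference exon are novel.
    """
    tool = sorted(tool_exons)
    ref = sorted(ref_exons)
    _check_disjoint(tool, "tool")
    _check_disjoint(ref, "reference")

    def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
        return max(0, min(a[1], b[1]) - max(a[0], b[0]))

    n_match = 0
    ref_touched = [False] * len(ref)
    n_novel = 0
    for t in tool:
        touched_any = False
        is_match = False
        for j, r in enumerate(ref):
            ov = overlap(t, r)
            if ov > 0:
                touched_any = True
                ref_touched[j] = True
                if ov >= 0.5 * (r[1] - r[0]):
                    is_match = True
        if is_match:
            n_match += 1
        if not touched_any:
            n_novel += 1
    n_missing = ref_touched.count(False)
    return {"n_match": n_match, "n_missing": n_missing, "n_novel": n_novel}
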