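"""Cross-species exon comparison: orthology, substitutions, dot plots.

Exon-level orthologs are called by reciprocal best hit: a reference exon
and a target exon are orthologs when each is the other's top-scoring hit.
Hits are scored by glocal alignment (the query aligned end to end, target
ends free) under a fixed scheme (match +1, mismatch -1, gap -2), so the
e-value/bit-score ordering of a database search collapses to a plain
alignment-score ordering.  Within-species repetitiveness is quantified by
globally aligning every exon pair and counting substitutions (mismatched
columns, gaps excluded), summarised by region quadrant (N:N, N:C, C:C) and
ninth (N/CA/CB x N/CA/CB).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .sequence_io import write_fasta
from .structure import RegionPartition

__all__ = [
    "AlignScoring",
    "OrthologCall",
    "SubstitutionMatrix",
    "best_hit",
    "reciprocal_best_hits",
    "confident_orthologs",
    "pairwise_substitutions",
    "aggregate_substitutions",
    "dotplot",
    "export_codon_fasta",
]


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    min_score: float = 10.0


def _aligner(scoring: AlignScoring, glocal: bool) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap
    al.extend_gap_score = scoring.gap
    if glocal:
        # free target end gaps: query fully aligned, target ends free
        # (the target is always passed as the first sequence)
        if hasattr(al, "end_deletion_score"):
            al.end_deletion_score = 0.0
        else:  # older attribute name
            al.target_end_gap_score = 0.0
    return al


@dataclass(frozen=True)
class OrthologCall:
    query_id: str
    target_species: str
    target_id: str
    forward_score: float
    reciprocal_confirmed: bool


def best_hit(
    query_seq: str,
    targets: Sequence[tuple[str, str]],
    scoring: AlignScoring | None = None,
) -> tuple[str, float] | None:
    """Top-scoring target for a query exon, or None below ``min_score``.

    Ties go to the longer target sequence, then the smaller target index.
    """
    if not targets:
        raise ValueError("empty target set")
    if scoring is None:
        scoring = AlignScoring()
    al = _aligner(scoring, glocal=True)
    best: tuple[float, int, int] | None = None  # (score, len, -index) max
    best_name = None
    for idx, (name, seq) in enumerate(targets):
        score = al.score(seq, query_seq)  # target first: its end gaps are free
        key = (score, len(seq), -idx)
        if best is None or key > best:
            best = key
            best_name = name
    assert best is not None
    if best[0] < scoring.min_score:
        return None
    return best_name, float(best[0])


def reciprocal_best_hits(
    ref_set: Sequence[tuple[str, str]],
    other_set: Sequence[tuple[str, str]],
    other_species: str = "other",
    scoring: AlignScoring | None = None,
) -> list[OrthologCall]:
    """Reciprocally confirmed best hits from ``ref_set`` into ``other_set``."""
    if not ref_set or not other_set:
        raise ValueError("both exon sets must be non-empty")
    if scoring is None:
        scoring = AlignScoring()
    calls = []
    for name, seq in ref_set:
        fwd = best_hit(seq, other_set, scoring)
        if fwd is None:
            continue
        target_name, fwd_score = fwd
        target_seq = dict(other_set)[target_name]
        back = best_hit(target_seq, ref_set, scoring)
        if back is not None and back[0] is not None and back[0] == name:
            calls.append(OrthologCall(name, other_species, target_name, fwd_score, True))
    return calls


def confident_orthologs(
    call_tables: Mapping[str, Sequence[OrthologCall]], min_species: int = 11
) -> dict[str, dict[str, str]]:
    """Ortholog groups present in at least ``min_species`` species.

    ``call_tables`` maps species name to its reciprocal-best-hit calls
    against the reference.  The species count includes the reference
    itself, so the default 11 implements "more than 10 species including
    the reference".
    """
    if len(call_tables) < 2:
        raise ValueError("need call tables for at least 2 species")
    groups: dict[str, dict[str, str]] = {}
    for species, calls in call_tables.items():
        for c in calls:
            if not c.reciprocal_confirmed:
                continue
            groups.setdefault(c.query_id, {})[species] = c.target_id
    return {
        q: members
        for q, members in groups.items()
        if len(members) + 1 >= min_species  # +1 for the reference species
    }


@dataclass
class SubstitutionMatrix:
    """Symmetric substitutions-per-exon-pair matrix with region summaries."""

    matrix: np.ndarray
    labels: list[str]
    partition: RegionPartition | None
    quadrant_means: dict[str, float]
    ninth_means: dict[str, float]


def _count_substitutions(al: Align.PairwiseAligner, a: str, b: str) -> int:
    aln = al.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    return sum(1 for x, y in zip(s1, s2) if x != y and x != "-" and y != "-")


def pairwise_substitutions(
    exons: Sequence[tuple[str, str]],
    partition: RegionPartition | None = None,
    scoring: AlignScoring | None = None,
) -> SubstitutionMatrix:
    """Globally align every exon pair and count substitutions.

    Gap columns are excluded from the count; the matrix is symmetric with a
    zero diagonal.  When a partition is supplied, per-quadrant (NN, NC, CC)
    and per-ninth (N/CA/CB crossed) means are attached.
    """
    n = len(exons)
    if n < 2:
        raise ValueError("need at least 2 exons")
    if scoring is None:
        scoring = AlignScoring()
    al = _aligner(scoring, glocal=False)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            subs = _count_substitutions(al, exons[i][1], exons[j][1])
            mat[i, j] = mat[j, i] = subs

    quadrants: dict[str, float] = {}
    ninths: dict[str, float] = {}
    if partition is not None:
        if len(partition.labels) != n:
            raise ValueError("partition inconsistent with exon list")
        coarse = ["N" if l == "N" else "C" for l in partition.labels]
        for pair_label, sel in _region_pairs(coarse):
            quadrants[pair_label] = _mean_over(mat, sel)
        for pair_label, sel in _region_pairs(partition.labels):
            ninths[pair_label] = _mean_over(mat, sel)
    return SubstitutionMatrix(mat, [e[0] for e in exons], partition, quadrants, ninths)


def _region_pairs(labels: Sequence[str]):
    regions = sorted(set(labels), key=lambda r: ("N", "CA", "CB", "C").index(r))
    idx = {r: [i for i, l in enumerate(labels) if l == r] for r in regions}
    for a in regions:
        for b in regions:
            if regions.index(b) < regions.index(a):
                continue
            yield f"{a}:{b}", (idx[a], idx[b])


def _mean_over(mat: np.ndarray, sel: tuple[list[int], list[int]]) -> float:
    rows, cols = sel
    vals = []
    for i in rows:
        for j in cols:
            if i == j:
                continue
            vals.append(mat[i, j])
    return float(np.mean(vals)) if vals else float("nan")


def aggregate_substitutions(per_species: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Cross-species quadrant/ninth summary with an all-pairs comparison.

    Input maps species to its per-quadrant (or per-ninth) mean
    substitutions.  Returns group means +/- SE per quadrant together with a
    one-way F statistic and Tukey-HSD adjusted p-values for all pairwise
    quadrant contrasts.
    """
    long = [
        {"species": sp, "group": g, "value": v}
        for sp, d in per_species.items()
        for g, v in d.items()
        if np.isfinite(v)
    ]
    df = pd.DataFrame(long)
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    summary = df.groupby("group")["value"].agg(mean="mean", se="sem", n="count")
    samples = [g["value"].to_numpy() for _, g in df.groupby("group")]
    f_stat, p = stats.f_oneway(*samples)
    summary.attrs["F"] = float(f_stat)
    summary.attrs["p"] = float(p)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(df["value"], df["group"])
    contrasts = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    summary.attrs["tukey"] = contrasts
    return summary


def dotplot(
    seq_a: str, seq_b: str, window: int = 11, min_identity: float = 0.8
) -> np.ndarray:
    """Binary window-identity matrix between two nucleotide sequences.

    Cell (i, j) is True when the ``window``-nt windows starting at i in A
    and j in B agree at >= ``min_identity`` of positions.
    """
    if window > min(len(seq_a), len(seq_b)):
        raise ValueError("window longer than the shorter sequence")
    A = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    B = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    na, nb = len(A) - window + 1, len(B) - window + 1
    eq = (A[:, None] == B[None, :]).astype(np.int16)
    counts = np.zeros((na, nb), dtype=np.int16)
    for k in range(window):
        counts += eq[k : k + na, k : k + nb]
    return counts >= min_identity * window - 1e-9


def export_codon_fasta(
    group: Mapping[str, str], path: str | Path
) -> dict[str, str]:
    """Write an ortholog group as alignment-ready multi-FASTA.

    Sequences are trimmed to a multiple of 3 (incomplete terminal codons
    dropped); headers are the species ids.  Returns the written sequences.
    """
    if not group:
        raise ValueError("empty ortholog group")
    trimmed = {}
    for species, seq in group.items():
        if len(seq) < 3:
            raise ValueError(f"sequence for {species!r} shorter than one codon")
        trimmed[species] = seq[: len(seq) - len(seq) % 3]
    write_fasta(path, trimmed.items())
    return trimmed
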