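"""PEVK region architecture: N/CA/CB partitioning, composition, gaps.

The PEVK region splits into a structurally conserved N-terminal block
(PEVK-N) and a variable C-terminal block (PEVK-C), itself divided into a
dense, highly repetitive head (PEVK-CA) and a sparser, more variable tail
(PEVK-CB).  Boundaries are properly a manual call based on exon spacing and
ratio patterns; the heuristic offered here is an explicit convenience whose
provenance is always recorded and which emits a warning when used.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ExonSet, PevkExon

AA20 = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "RegionPartition",
    "CompositionTable",
    "partition_regions",
    "composition_stats",
    "diagram_table",
    "gap_report",
]


@dataclass
class RegionPartition:
    """Contiguous N / CA / CB labels over an ordered exon set."""

    labels: list[str]
    last_n: int
    last_ca: int
    provenance: str  # "manual" | "heuristic"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not 0 <= self.last_n < self.last_ca < n:
            raise ValueError(
                f"boundaries ({self.last_n}, {self.last_ca}) out of range for {n} exons"
            )
        expected = (
            ["N"] * (self.last_n + 1)
            + ["CA"] * (self.last_ca - self.last_n)
            + ["CB"] * (n - 1 - self.last_ca)
        )
        if self.labels != expected:
            raise ValueError("labels must be contiguous blocks N..., CA..., CB...")


def _two_group_threshold(values: np.ndarray) -> float:
    """Split 1-D values into two groups minimizing within-group variance.

    Returns the midpoint between the group means (falls back to the median
    when the values are effectively constant).
    """
    v = np.sort(values)
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return float(np.median(v)) if n else 0.0
    best_cost, best_k = np.inf, 1
    for k in range(1, n):
        lo, hi = v[:k], v[k:]
        cost = lo.var() * len(lo) + hi.var() * len(hi)
        if cost < best_cost:
            best_cost, best_k = cost, k
    return float((v[: best_k].mean() + v[best_k:].mean()) / 2)


def _labels_from_bounds(n: int, last_n: int, last_ca: int) -> list[str]:
    return ["N"] * (last_n + 1) + ["CA"] * (last_ca - last_n) + ["CB"] * (n - 1 - last_ca)


def partition_regions(
    exons: ExonSet,
    manual_bounds: tuple[int, int] | None = None,
    local_window: int = 7,
) -> RegionPartition:
    """Partition an exon set into PEVK-N, PEVK-CA and PEVK-CB blocks.

    ``manual_bounds = (last_n_index, last_ca_index)`` applies user-supplied
    boundaries verbatim.  Without them a heuristic picks the N/C boundary as
    the index maximizing downstream exon density (exons per kb) times
    downstream mean ratio minus the mean ratio over a centered window of
    ``local_window`` exons, and ends PEVK-CA at the last exon of the densest
    run of closely spaced C-region exons.  Heuristic output is advisory.
    """
    n = len(exons)
    if n < 10:
        raise ValueError(f"need >= 10 exons to partition, got {n}")
    if manual_bounds is not None:
        last_n, last_ca = manual_bounds
        if not 0 <= last_n < last_ca < n:
            raise ValueError(f"manual bounds {manual_bounds} out of range for {n} exons")
        return RegionPartition(_labels_from_bounds(n, last_n, last_ca), last_n, last_ca, "manual")

    ratios = np.array([x.ratio for x in exons])
    starts = np.array([x.start for x in exons])
    ends = np.array([x.end for x in exons])
    half = local_window // 2

    best_score, last_n = -np.inf, half
    # leave at least a handful of exons on each side
    for i in range(half, n - 4):
        down = slice(i + 1, n)
        span_kb = (ends[-1] - starts[i + 1]) / 1000.0
        density = (n - i - 1) / span_kb if span_kb > 0 else 0.0
        local = ratios[max(0, i - half) : i + half + 1].mean()
        score = density * ratios[down].mean() - local
        if score > best_score:
            best_score, last_n = score, i

    # densest run of C exons: consecutive gaps in the short-gap cluster of
    # a two-group split of the inter-exon gaps (short = within-CA spacing,
    # long = CB/desert spacing)
    c_start = last_n + 1
    gaps = starts[c_start + 1 :] - ends[c_start:-1]
    if len(gaps) == 0:
        raise ValueError("heuristic found no C region; supply manual bounds")
    thr = _two_group_threshold(gaps.astype(float))
    runs: list[tuple[int, int]] = []  # (first_exon, last_exon) in global indices
    run_start = c_start
    for k, g in enumerate(gaps):
        if g > thr:
            runs.append((run_start, c_start + k))
            run_start = c_start + k + 1
    runs.append((run_start, n - 1))
    dens_run = max(runs, key=lambda r: r[1] - r[0])
    last_ca = dens_run[1]
    if last_ca >= n - 1:  # keep a non-empty CB tail
        last_ca = n - 2
    if last_ca <= last_n:
        last_ca = last_n + 1

    warnings.warn(
        "region boundaries determined heuristically; treat as advisory",
        stacklevel=2,
    )
    return RegionPartition(_labels_from_bounds(n, last_n, last_ca), last_n, last_ca, "heuristic")


@dataclass
class CompositionTable:
    """Per-exon residue composition with per-region summaries and tests.

    ``per_exon`` has one row per exon (lengths, ratio, the 20 residue
    counts, the glutamate-per-residue track); ``per_region`` holds mean and
    standard error per region; ``tests`` reports Welch two-sample
    comparisons (N vs C) for each residue count plus length and ratio.
    """

    per_exon: pd.DataFrame
    per_region: pd.DataFrame
    tests: pd.DataFrame


def composition_stats(exons: ExonSet, partition: RegionPartition) -> CompositionTable:
    if len(partition.labels) != len(exons):
        raise ValueError("partition inconsistent with exon set")
    rows = []
    for i, x in enumerate(exons):
        counts = {aa: x.aa_seq.count(aa) for aa in AA20}
        rows.append(
            {
                "exon": i,
                "region": partition.labels[i],
                "start": x.start,
                "end": x.end,
                "length_nt": x.length_nt,
                "length_aa": x.length_aa,
                "ratio": x.ratio,
                "E_per_residue": counts["E"] / x.length_aa if x.length_aa else 0.0,
                **counts,
            }
        )
    per_exon = pd.DataFrame(rows)

    metrics = ["length_nt", "length_aa", "ratio", "E_per_residue", *AA20]
    grouped = per_exon.groupby("region")[metrics]
    per_region = pd.concat(
        {"mean": grouped.mean(), "se": grouped.sem(ddof=1)}, axis=1
    )

    # two-group (N vs C = CA+CB) unequal-variance comparisons
    is_n = per_exon["region"] == "N"
    test_rows = []
    for m in metrics:
        a = per_exon.loc[is_n, m].to_numpy(dtype=float)
        b = per_exon.loc[~is_n, m].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2 or (a.std() == 0 and b.std() == 0):
            t, p = np.nan, np.nan
            if len(a) and len(b) and a.mean() == b.mean():
                t, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                # near-constant residue columns trip scipy's precision
                # warning; the resulting t is still well-defined for us
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(a, b, equal_var=False)
        mean_n = a.mean() if len(a) else np.nan
        mean_c = b.mean() if len(b) else np.nan
        test_rows.append(
            {
                "metric": m,
                "mean_N": mean_n,
                "mean_C": mean_c,
                "fold_N_over_C": mean_n / mean_c if mean_c else np.nan,
                "t": t,
                "p": p,
            }
        )
    tests = pd.DataFrame(test_rows)
    return CompositionTable(per_exon, per_region, tests)


def diagram_table(exons: ExonSet, partition: RegionPartition | None = None) -> pd.DataFrame:
    """Rows (start, end, ratio, region) in genomic order for track rendering."""
    if len(exons) == 0:
        raise ValueError("empty exon set")
    labels = partition.labels if partition is not None else ["."] * len(exons)
    return pd.DataFrame(
        {
            "start": [x.start for x in exons],
            "end": [x.end for x in exons],
            "ratio": [x.ratio for x in exons],
            "region": labels,
        }
    )


def gap_report(
    genome, interval: tuple[int, int] | None = None, min_len: int = 10
) -> list[dict]:
    """Maximal runs of 'N' of length >= ``min_len`` within ``interval``.

    Coordinates are genomic (0-based half-open), sorted by start.  The
    default threshold mirrors the smallest assembly-gap class worth
    reporting (runs of 10 bases and up).
    """
    residues = genome.residues if hasattr(genome, "residues") else str(genome)
    lo, hi = interval if interval is not None else (0, len(residues))
    if not 0 <= lo <= hi <= len(residues):
        raise ValueError(f"interval [{lo}, {hi}) outside sequence")
    out = []
    for m in re.finditer(r"N+", residues[lo:hi]):
        if m.end() - m.start() >= min_len:
            out.append(
                {"start": lo + m.start(), "end": lo + m.end(), "length": m.end() - m.start()}
            )
    return out
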