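"""Core PEVK exon scanner.

The algorithm annotates the PEVK region of a titin-like gene directly from
genomic DNA, exploiting the region's compositional signature instead of
splice-model gene finding:

1. translate the genome in the three forward reading frames;
2. slide a window over each translation and keep windows whose PEVK ratio
   (fraction of P/E/V/K/A residues) meets a minimum threshold;
3. combine overlapping windows into candidate regions;
4. resolve each candidate's exon boundaries by searching for the canonical
   acceptor (AG, immediately 5' of the exon) / donor (GT, immediately 3')
   dinucleotide pair with the minimum distance between them — candidates
   without an admissible pair are discarded;
5. collapse exons reported by more than one frame into a single call.

Optionally the exon set is trimmed to the PEVK region proper using the two
conserved landmark exon peptides that open and close the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import (
    FrameTranslation,
    GenomicSequence,
    aa_to_nt,
    translate_frame,
    translate_three_frames,
)

PEVK_RESIDUES = frozenset("PEVKA")

#: Amino-acid sequence of the first exon of the PEVK region, conserved
#: across mammals; used as the 5' trimming landmark.
FIRST_LANDMARK = "EIPPVVAPPIPLLLPTPEEKKPPPKRI"
#: Amino-acid sequence of the last exclusively-PEVK exon (3' landmark).
LAST_LANDMARK = "AKAPKEEAAKPKGPI"

__all__ = [
    "ScanParams",
    "CandidateRegion",
    "PevkExon",
    "ExonSet",
    "FIRST_LANDMARK",
    "LAST_LANDMARK",
    "pevk_ratio",
    "scan_windows",
    "merge_windows",
    "resolve_splice_bounds",
    "resolve_frames",
    "find_pevk_exons",
    "trim_to_region",
    "landmark_identity",
]


@dataclass(frozen=True)
class ScanParams:
    """The scanner's tunable criteria.

    window_len and min_exon_len are measured in amino-acid residues; the
    splice-search flank is in nucleotides on each side of a candidate.
    Defaults are the consensus optima from benchmarking against cDNA
    annotation: window 10, minimum ratio 0.54, minimum exon length 12.
    """

    window_len: int = 10
    min_ratio: float = 0.54
    min_exon_len: int = 12
    splice_flank: int = 60
    landmark_min_identity: float = 0.8

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 0.0 <= self.min_ratio <= 1.0:
            raise ValueError("min_ratio must be in [0, 1]")
        if self.min_exon_len < 1:
            raise ValueError("min_exon_len must be >= 1")
        if self.splice_flank < 0:
            raise ValueError("splice_flank must be >= 0")


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal union of overlapping above-threshold windows in one frame."""

    frame: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int


@dataclass(frozen=True)
class PevkExon:
    """A predicted exon, bounded by an upstream AG and a downstream GT."""

    start: int
    end: int
    frame: int
    nt_seq: str
    aa_seq: str
    ratio: float
    source_candidate: CandidateRegion | None = None

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)


@dataclass
class ExonSet:
    """Ordered, non-overlapping exon calls for one genomic sequence."""

    origin: str
    params: ScanParams
    exons: list[PevkExon]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self):
        return iter(self.exons)

    def __getitem__(self, i):
        return self.exons[i]


def pevk_ratio(aa_seq: str) -> float:
    """Fraction of residues in {P, E, V, K, A}; 'X' and '*' are non-PEVK.

    Alanine is included because of the PPAK motifs characteristic of the
    region.
    """
    if not aa_seq:
        raise ValueError("empty amino-acid sequence")
    return sum(c in PEVK_RESIDUES for c in aa_seq) / len(aa_seq)


def scan_windows(ft: FrameTranslation, params: ScanParams) -> list[tuple[int, int]]:
    """All windows ``[i, i + window_len)`` with PEVK ratio >= min_ratio.

    Step is one residue; the threshold is inclusive so the default optimum
    0.54 admits windows at exactly 0.54.  Returns an empty list when the
    translation is shorter than the window.
    """
    aa = ft.aa_seq
    w = params.window_len
    n = len(aa)
    if n < w:
        return []
    member = np.frombuffer(aa.encode("ascii"), dtype=np.uint8)
    is_pevk = np.isin(member, np.frombuffer(b"PEVKA", dtype=np.uint8)).astype(np.int32)
    counts = np.convolve(is_pevk, np.ones(w, dtype=np.int32), mode="valid")
    # integer threshold avoids float round-off at the boundary
    need = params.min_ratio * w
    hits = np.nonzero(counts >= need - 1e-9)[0]
    # guard against floating error admitting counts strictly below need
    hits = [int(i) for i in hits if counts[i] / w >= params.min_ratio - 1e-12]
    return [(i, i + w) for i in hits]


def merge_windows(
    windows: list[tuple[int, int]], ft: FrameTranslation
) -> list[CandidateRegion]:
    """Union overlapping windows (sharing >= 1 residue) into candidates.

    Abutting-but-disjoint windows stay separate.
    """
    out: list[CandidateRegion] = []
    if not windows:
        return out
    cur_start, cur_end = windows[0]
    merged: list[tuple[int, int]] = []
    for s, e in windows[1:]:
        if s < cur_end:  # strict overlap
            cur_end = max(cur_end, e)
        else:
            merged.append((cur_start, cur_end))
            cur_start, cur_end = s, e
    merged.append((cur_start, cur_end))
    for s, e in merged:
        nt_s, nt_e = aa_to_nt(ft.frame, s, e)
        out.append(CandidateRegion(ft.frame, s, e, nt_s, nt_e))
    return out


def _exon_from_pair(
    genome: GenomicSequence, s: int, e: int, cand: CandidateRegion
) -> PevkExon:
    nt_seq = genome.residues[s:e]
    # translate in the phase of the seeding frame so exon residues line up
    # with the windows that seeded the candidate
    offset = (cand.frame - s) % 3
    coding = nt_seq[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = translate_frame(GenomicSequence("tmp", coding), 0).aa_seq if len(coding) >= 3 else ""
    ratio = pevk_ratio(aa) if aa else 0.0
    return PevkExon(s, e, cand.frame, nt_seq, aa, ratio, cand)


def resolve_splice_bounds(
    cand: CandidateRegion, genome: GenomicSequence, params: ScanParams
) -> PevkExon | None:
    """Resolve a candidate to exact exon boundaries via its AG/GT pair.

    Acceptor candidates are every AG whose implied exon start lies within
    ``splice_flank`` nt of the candidate start; donor candidates every GT
    whose implied exon end lies within the flank of the candidate end.
    Admissible pairs must span at least ``3 * min_exon_len`` nt and overlap
    the candidate; among them the shortest wins (ties: smaller start).
    Returns None when no admissible pair exists (candidate discarded).
    """
    g = genome.residues
    n = len(g)
    flank = params.splice_flank

    lo_s = max(2, cand.nt_start - flank)
    hi_s = min(n, cand.nt_start + flank)
    acceptors = [s for s in range(lo_s, hi_s + 1) if g[s - 2 : s] == "AG"]

    lo_e = max(0, cand.nt_end - flank)
    hi_e = min(n - 2, cand.nt_end + flank)
    donors = [e for e in range(lo_e, hi_e + 1) if g[e : e + 2] == "GT"]

    min_len = 3 * params.min_exon_len
    best: tuple[int, int] | None = None
    for s in acceptors:
        for e in donors:
            if e - s < min_len:
                continue
            if s >= cand.nt_end or e <= cand.nt_start:
                continue  # must overlap the seed candidate
            if best is None or (e - s, s) < (best[1] - best[0], best[0]):
                best = (s, e)
    if best is None:
        return None
    return _exon_from_pair(genome, best[0], best[1], cand)


def resolve_frames(exons: list[PevkExon]) -> list[PevkExon]:
    """Collapse exons whose nt intervals overlap into one representative.

    Within a group of transitively overlapping calls the winner has the
    highest PEVK ratio; ties go to the longer exon, then the lower frame.
    """
    if not exons:
        return []
    exons = sorted(exons, key=lambda x: (x.start, x.end))
    groups: list[list[PevkExon]] = [[exons[0]]]
    cur_end = exons[0].end
    for x in exons[1:]:
        if x.start < cur_end:
            groups[-1].append(x)
            cur_end = max(cur_end, x.end)
        else:
            groups.append([x])
            cur_end = x.end
    out = [
        max(g, key=lambda x: (x.ratio, x.length_nt, -x.frame)) for g in groups
    ]
    return sorted(out, key=lambda x: x.start)


def find_pevk_exons(
    genome: GenomicSequence, params: ScanParams | None = None
) -> ExonSet:
    """Full pipeline: translate, scan, merge, resolve boundaries and frames."""
    if params is None:
        params = ScanParams()
    per_frame: list[PevkExon] = []
    for ft in translate_three_frames(genome):
        windows = scan_windows(ft, params)
        for cand in merge_windows(windows, ft):
            exon = resolve_splice_bounds(cand, genome, params)
            if exon is not None:
                per_frame.append(exon)
    return ExonSet(genome.id, params, resolve_frames(per_frame))


def landmark_identity(aa_seq: str, landmark: str) -> float:
    """Best ungapped identity of ``landmark`` against ``aa_seq``.

    The landmark slides over the sequence (partial overlaps allowed);
    identity is matches divided by the landmark length.
    """
    if not aa_seq or not landmark:
        return 0.0
    best = 0
    la, ll = len(aa_seq), len(landmark)
    for off in range(-(ll - 1), la):
        matches = 0
        for j in range(ll):
            i = off + j
            if 0 <= i < la and aa_seq[i] == landmark[j]:
                matches += 1
        best = max(best, matches)
    return best / ll


def trim_to_region(
    exons: ExonSet,
    first_landmark: str = FIRST_LANDMARK,
    last_landmark: str = LAST_LANDMARK,
    params: ScanParams | None = None,
) -> ExonSet:
    """Trim an exon set to the PEVK region between the two landmark exons.

    The exon best matching each landmark peptide (ungapped identity) bounds
    the retained range, inclusive.  If either landmark cannot be located at
    ``landmark_min_identity`` the set is returned untrimmed with a warning
    recorded in ``ExonSet.warnings``.
    """
    if params is None:
        params = exons.params
    if not exons.exons:
        raise ValueError("cannot trim an empty exon set")
    idents_first = [landmark_identity(x.aa_seq, first_landmark) for x in exons]
    idents_last = [landmark_identity(x.aa_seq, last_landmark) for x in exons]
    i_first = int(np.argmax(idents_first))
    i_last = int(np.argmax(idents_last))
    thr = params.landmark_min_identity
    if idents_first[i_first] < thr or idents_last[i_last] < thr or i_first > i_last:
        missing = []
        if idents_first[i_first] < thr:
            missing.append("first")
        if idents_last[i_last] < thr:
            missing.append("last")
        if i_first > i_last and not missing:
            missing.append("ordering")
        return ExonSet(
            exons.origin,
            exons.params,
            list(exons.exons),
            warnings=exons.warnings
            + [f"landmark(s) not located ({', '.join(missing)}); set untrimmed"],
        )
    return ExonSet(
        exons.origin,
        exons.params,
        list(exons.exons[i_first : i_last + 1]),
        warnings=list(exons.warnings),
    )
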