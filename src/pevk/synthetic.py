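"""Truth-labelled synthetic titin-like genomes.

The generator emits a multi-exon gene whose architecture mimics a mammalian
titin PEVK region: a conserved-style PEVK-N block of longer, moderately
PEVK-rich exons separated by long introns; a dense PEVK-CA block of short,
very PEVK-rich exons with short introns; and a sparse PEVK-CB tail.  Every
exon is bounded by a canonical acceptor (AG) immediately 5' and donor (GT)
immediately 3'; optional decoys are PEVK-rich stretches with no splice
sites, and optional N-runs emulate assembly gaps inside introns.

Two structural guarantees make planted truth exactly recoverable:

* exon interiors are free of AG and GT dinucleotides — valine is excluded
  from sampled exon residues (all Val codons contain GT) and codons are
  chosen, with a small adjacency rule, so no codon junction forms AG/GT;
* intron interiors are sampled over {A, C, T} with AA and CC forbidden, so
  they contain no G at all (hence no AG/GT) and no codon of P/E/V/K/A in
  any frame — their translations have PEVK ratio 0.

The planted (AG, GT) pair is therefore the unique admissible splice pair
for each seeded candidate, and the scanner's minimum-distance rule must
return the planted boundaries.  The two landmark exons are an exception:
their fixed peptides force a few interior AG/GT (e.g. the Val codons of the
first landmark), placed where no admissible competing pair can form; the
terminal landmark is planted as its nearly-identical K2->P variant for the
same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .scan import FIRST_LANDMARK, LAST_LANDMARK, pevk_ratio
from .sequence_io import GenomicSequence

#: One codon per amino acid, none containing AG or GT, none ending in G.
CODON = {
    "P": "CCT", "E": "GAA", "K": "AAA", "A": "GCC",
    "L": "CTT", "I": "ATT", "S": "TCC", "T": "ACC",
    "R": "CGC", "G": "GGA", "V": "GTT",  # V only used in landmark exons
}

#: Terminal landmark planted as a nearly-identical variant (K2 -> P): any
#: reverse translation of the exact peptide puts an AG within 9 nt of the
#: exon start, which would admit a shorter competing splice pair.
PLANTED_LAST_LANDMARK = "A" + "P" + LAST_LANDMARK[2:]

PEVK_CHOICES = "PEKA"  # sampled PEVK residues (no V: Val codons contain GT)
FILLER_CHOICES = "LIST"

__all__ = [
    "SyntheticTitinSpec",
    "PlantedExon",
    "GroundTruth",
    "generate_titin",
    "mutate_species",
    "write_truth",
]


@dataclass(frozen=True)
class SyntheticTitinSpec:
    """Generative parameters for one synthetic titin locus.

    Defaults emulate the observed mammalian architecture: ~50 PEVK-N exons
    (longer, mean ratio ~0.75, long introns), ~40 dense PEVK-CA exons
    (short, ratio ~0.85, short introns) and ~9 sparse PEVK-CB exons.
    Intron lengths stay above the splice-search flank so spurious sites
    near one exon can never be paired by the scanner with another exon's
    candidate.
    """

    n_exons: tuple[int, int, int] = (50, 40, 9)  # N, CA, CB
    exon_len_aa: dict = field(
        default_factory=lambda: {"N": (15, 40), "CA": (12, 28), "CB": (12, 28)}
    )
    target_ratio: dict = field(
        default_factory=lambda: {"N": 0.75, "CA": 0.85, "CB": 0.80}
    )
    intron_len: dict = field(
        default_factory=lambda: {"N": (300, 900), "CA": (100, 260), "CB": (600, 1400)}
    )
    n_decoys: int = 3
    decoy_len_aa: tuple[int, int] = (15, 25)
    n_runs: int = 2
    n_run_len: tuple[int, int] = (10, 150)
    landmarks: bool = True
    flank_len: int = 200  # leading/trailing intronic sequence
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.n_exons) or self.n_decoys < 0 or self.n_runs < 0:
            raise ValueError("counts must be >= 0")
        for r in self.target_ratio.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("target ratios must be in [0, 1]")
        for lo, hi in self.intron_len.values():
            if lo < 70:
                raise ValueError("introns must be at least 70 nt (> splice flank)")


@dataclass(frozen=True)
class PlantedExon:
    start: int
    end: int
    frame: int
    region: str
    aa_seq: str
    ratio: float


@dataclass
class GroundTruth:
    genome_id: str
    seed: int
    exons: list[PlantedExon]

    def intervals(self) -> list[tuple[int, int]]:
        return [(x.start, x.end) for x in self.exons]

    def __len__(self) -> int:
        return len(self.exons)


def _intron(rng: np.random.Generator, length: int) -> str:
    """Intron interior over {A,C,T} with AA and CC forbidden.

    No G means no AG/GT anywhere; forbidding AA and CC excludes every
    codon of K (AAR) and P (CCN), and absent G excludes E/V/A codons, so
    every window of the translation has PEVK ratio 0 in all frames.
    """
    allowed = {"A": "CT", "C": "AT", "T": "ACT", "": "ACT"}
    out = []
    prev = ""
    for _ in range(length):
        choices = allowed[prev]
        c = choices[rng.integers(len(choices))]
        out.append(c)
        prev = c
    return "".join(out)


def _exon_aa(rng: np.random.Generator, length: int, target_ratio: float) -> str:
    """Amino-acid sequence hitting the nearest achievable PEVK count.

    The adjacency rule (no E/A after E/K) keeps codon junctions free of AG.
    """
    n_pevk = int(round(target_ratio * length))
    n_pevk = min(max(n_pevk, 0), length)
    flags = np.zeros(length, dtype=bool)
    if n_pevk:
        # even spacing keeps every window's ratio within ~1/window of the
        # exon ratio, so threshold behaviour tracks the planted ratio
        idx = np.floor(np.arange(n_pevk) * length / n_pevk).astype(int)
        flags[np.clip(idx, 0, length - 1)] = True
    out = []
    prev = ""
    for is_pevk in flags:
        if is_pevk:
            pool = "PK" if prev in "EK" else PEVK_CHOICES
        else:
            pool = FILLER_CHOICES
        c = pool[rng.integers(len(pool))]
        out.append(c)
        prev = c
    return "".join(out)


def _decoy_aa(rng: np.random.Generator, length: int) -> str:
    """All-PEVK decoy over {P,K,A}; starts and ends with P (clean junctions)."""
    out = ["P"]
    prev = "P"
    for _ in range(length - 2):
        pool = "PK" if prev in "EK" else "PKA"
        c = pool[rng.integers(len(pool))]
        out.append(c)
        prev = c
    out.append("P")
    return "".join(out)


def _reverse_translate(aa: str) -> str:
    return "".join(CODON[c] for c in aa)


def generate_titin(spec: SyntheticTitinSpec) -> tuple[GenomicSequence, GroundTruth]:
    """Emit a genome and its planted-exon truth, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    regions = (
        ["N"] * spec.n_exons[0] + ["CA"] * spec.n_exons[1] + ["CB"] * spec.n_exons[2]
    )
    if not regions:
        raise ValueError("spec plants no exons")

    # choose amino-acid sequences per exon
    aa_seqs: list[str] = []
    for i, region in enumerate(regions):
        lo, hi = spec.exon_len_aa[region]
        length = int(rng.integers(lo, hi + 1))
        aa_seqs.append(_exon_aa(rng, length, spec.target_ratio[region]))
    if spec.landmarks:
        aa_seqs[0] = FIRST_LANDMARK
        aa_seqs[-1] = PLANTED_LAST_LANDMARK

    # decide decoy and N-run placements (inside intron interiors); prefer
    # the long N/CB introns so the insert plus safety margins always fits
    n_introns = len(regions) + 1
    eligible = [i for i in range(1, n_introns - 1) if regions[i] in ("N", "CB")]
    if not eligible:
        eligible = list(range(1, n_introns - 1))

    def _pick(count: int) -> set[int]:
        if count <= 0 or not eligible:
            return set()
        k = min(count, len(eligible))
        return set(rng.choice(np.array(eligible), size=k, replace=False).tolist())

    decoy_introns = _pick(spec.n_decoys)
    nrun_introns = _pick(spec.n_runs)

    parts: list[str] = []
    exons: list[PlantedExon] = []
    pos = 0

    def emit_intron(idx: int, region: str) -> None:
        nonlocal pos
        if idx == 0 or idx == n_introns - 1:
            length = spec.flank_len
        else:
            lo, hi = spec.intron_len[region]
            length = int(rng.integers(lo, hi + 1))
        seq = _intron(rng, length)
        margin = 65  # keep inserts clear of splice-search windows
        if idx in decoy_introns:
            lo_d, hi_d = spec.decoy_len_aa
            decoy_nt = _reverse_translate(_decoy_aa(rng, int(rng.integers(lo_d, hi_d + 1))))
            if length >= len(decoy_nt) + 2 * margin:
                at = int(rng.integers(margin, length - margin - len(decoy_nt) + 1))
                seq = seq[:at] + decoy_nt + seq[at + len(decoy_nt):]
        if idx in nrun_introns:
            run = int(rng.integers(spec.n_run_len[0], spec.n_run_len[1] + 1))
            if length >= run + 2 * margin:
                at = int(rng.integers(margin, length - margin - run + 1))
                seq = seq[:at] + "N" * run + seq[at + run:]
        parts.append(seq)
        pos += len(seq)

    for i, region in enumerate(regions):
        emit_intron(i, region)
        nt = _reverse_translate(aa_seqs[i])
        parts.append("AG")
        pos += 2
        start = pos
        parts.append(nt)
        pos += len(nt)
        exons.append(
            PlantedExon(start, pos, start % 3, region, aa_seqs[i], pevk_ratio(aa_seqs[i]))
        )
        parts.append("GT")
        pos += 2
    emit_intron(n_introns - 1, regions[-1])

    genome = GenomicSequence(f"synthetic_titin_seed{spec.seed}", "".join(parts))
    truth = GroundTruth(genome.id, spec.seed, exons)
    # construction invariants
    for x in exons:
        assert genome.residues[x.start - 2 : x.start] == "AG"
        assert genome.residues[x.end : x.end + 2] == "GT"
    return genome, truth


def mutate_species(
    genome: GenomicSequence,
    truth: GroundTruth,
    substitution_rate: float = 0.0,
    duplication_prob: float = 0.0,
    loss_prob: float = 0.0,
    seed: int = 0,
    duplication_block: tuple[int, int] = (2, 5),
    spacer_len: int = 150,
) -> tuple[GenomicSequence, GroundTruth]:
    """Derive a new "species" by exon loss, CA-block duplication, substitution.

    Losses delete whole exons with their AG/GT flanks; a duplication copies
    a contiguous run of PEVK-CA exons (with intervening introns) in tandem,
    separated by a fresh clean spacer; point substitutions avoid the AG/GT
    dinucleotides of retained exons and never touch N bases.  The returned
    truth reflects all edits.
    """
    for r in (substitution_rate, duplication_prob, loss_prob):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = genome.residues
    exons = list(truth.exons)

    # --- exon loss -------------------------------------------------------
    if loss_prob > 0 and len(exons) > 1:
        keep = [rng.random() >= loss_prob for _ in exons]
        if not any(keep):
            keep[0] = True
        new_seq_parts = []
        new_exons = []
        cursor = 0
        shift = 0
        for x, k in zip(exons, keep):
            if k:
                new_exons.append(replace(x, start=x.start - shift, end=x.end - shift))
                continue
            cut_lo, cut_hi = x.start - 2, x.end + 2
            new_seq_parts.append(seq[cursor:cut_lo])
            cursor = cut_hi
            shift += cut_hi - cut_lo
        new_seq_parts.append(seq[cursor:])
        seq = "".join(new_seq_parts)
        exons = new_exons

    # --- tandem duplication of a CA block --------------------------------
    if duplication_prob > 0 and rng.random() < duplication_prob:
        ca_idx = [i for i, x in enumerate(exons) if x.region == "CA"]
        if len(ca_idx) >= duplication_block[0]:
            size = int(
                rng.integers(duplication_block[0], min(duplication_block[1], len(ca_idx)) + 1)
            )
            first = int(rng.choice(ca_idx[: len(ca_idx) - size + 1]))
            last = first + size - 1
            blk_lo = exons[first].start - 2
            blk_hi = exons[last].end + 2
            spacer = _intron(rng, spacer_len)
            insert = spacer + seq[blk_lo:blk_hi]
            seq = seq[:blk_hi] + insert + seq[blk_hi:]
            offset = len(insert)
            # duplicated copies sit offset nt downstream of the originals
            dup = [
                replace(x, start=x.start + offset, end=x.end + offset)
                for x in exons[first : last + 1]
            ]
            shifted_tail = [
                replace(x, start=x.start + offset, end=x.end + offset)
                for x in exons[last + 1 :]
            ]
            exons = exons[: last + 1] + dup + shifted_tail

    # --- point substitutions ---------------------------------------------
    if substitution_rate > 0:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        protected = np.zeros(len(arr), dtype=bool)
        for x in exons:
            protected[max(0, x.start - 2) : x.start] = True
            protected[x.end : min(len(arr), x.end + 2)] = True
        is_n = arr == ord("N")
        hit = (rng.random(len(arr)) < substitution_rate) & ~protected & ~is_n
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in np.nonzero(hit)[0]:
            alt = bases[bases != arr[i]]
            arr[i] = alt[rng.integers(3)]
        seq = arr.tobytes().decode("ascii")

    new_id = f"{genome.id}_mut{seed}"
    out_genome = GenomicSequence(new_id, seq)
    # refresh exon sequences/ratios from the edited genome
    from .sequence_io import translate_frame  # local import to avoid cycle

    refreshed = []
    for x in exons:
        nt = seq[x.start : x.end]
        coding = nt[: len(nt) - len(nt) % 3]
        aa = (
            translate_frame(GenomicSequence("tmp", coding), 0).aa_seq
            if len(coding) >= 3
            else ""
        )
        refreshed.append(
            replace(x, frame=x.start % 3, aa_seq=aa, ratio=pevk_ratio(aa) if aa else 0.0)
        )
    return out_genome, GroundTruth(new_id, seed, refreshed)


def write_truth(truth: GroundTruth, bed_path: str | Path, json_path: str | Path) -> None:
    """Dump truth as BED6 (score = 1000*ratio) and JSON."""
    with open(bed_path, "w") as fh:
        for i, x in enumerate(truth.exons):
            fh.write(
                f"{truth.genome_id}\t{x.start}\t{x.end}\texon{i}\t"
                f"{int(round(1000 * x.ratio))}\t+\n"
            )
    payload = {
        "genome_id": truth.genome_id,
        "seed": truth.seed,
        "exons": [
            {
                "start": x.start,
                "end": x.end,
                "frame": x.frame,
                "region": x.region,
                "aa_seq": x.aa_seq,
                "ratio": x.ratio,
            }
            for x in truth.exons
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
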