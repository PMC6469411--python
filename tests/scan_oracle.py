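"""Brute-force reference for the exon scanner, kept deliberately naive.

Re-derives exon calls from first principles: enumerate every window by
direct residue counting, form candidate stretches, enumerate every (AG, GT)
span near each candidate by string scanning, and pick the shortest
admissible span.  Shares no code with pevk.scan beyond the translation
utilities it is checking against.
"""

from collections import Counter

from pevk.sequence_io import GenomicSequence, translate_frame


def ratio_of(aa: str) -> float:
    c = Counter(aa)
    return sum(c[x] for x in "PEVKA") / len(aa)


def oracle_exons(genome: GenomicSequence, params):
    g = genome.residues
    n = len(g)
    calls = []
    for frame in (0, 1, 2):
        aa = translate_frame(genome, frame).aa_seq
        w = params.window_len
        passing = [
            i for i in range(len(aa) - w + 1) if ratio_of(aa[i : i + w]) >= params.min_ratio
        ]
        # group strictly-overlapping windows into candidate aa stretches
        cands = []
        for i in passing:
            if cands and i < cands[-1][1]:
                cands[-1][1] = max(cands[-1][1], i + w)
            else:
                cands.append([i, i + w])
        for a_lo, a_hi in cands:
            c_lo = frame + 3 * a_lo
            c_hi = frame + 3 * a_hi
            accs = [
                s
                for s in range(max(2, c_lo - params.splice_flank), min(n, c_lo + params.splice_flank) + 1)
                if g[s - 2 : s] == "AG"
            ]
            dons = [
                e
                for e in range(max(0, c_hi - params.splice_flank), min(n - 2, c_hi + params.splice_flank) + 1)
                if g[e : e + 2] == "GT"
            ]
            spans = [
                (s, e)
                for s in accs
                for e in dons
                if e - s >= 3 * params.min_exon_len and s < c_hi and e > c_lo
            ]
            if not spans:
                continue
            s, e = min(spans, key=lambda p: (p[1] - p[0], p[0]))
            off = (frame - s) % 3
            coding = g[s:e][off:]
            coding = coding[: len(coding) - len(coding) % 3]
            aa_seq = translate_frame(GenomicSequence("o", coding), 0).aa_seq if len(coding) >= 3 else ""
            r = ratio_of(aa_seq) if aa_seq else 0.0
            calls.append((s, e, frame, r))
    # collapse transitively overlapping calls: best ratio, then longer, then lower frame
    calls.sort()
    groups = []
    for c in calls:
        if groups and c[0] < max(x[1] for x in groups[-1]):
            groups[-1].append(c)
        else:
            groups.append([c])
    out = []
    for grp in groups:
        best = max(grp, key=lambda c: (c[3], c[1] - c[0], -c[2]))
        out.append((best[0], best[1]))
    return sorted(out)
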