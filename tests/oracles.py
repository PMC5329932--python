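"""Independent brute-force oracles shared by the test modules."""

import re

from coldacc.ssr import DEFAULT_MIN_REPEATS


def bruteforce_scan(seq, min_repeats=None, compound_max_gap=100):
    """Regex-based SSR oracle: maximal runs per unit size with a
    primitivity check, longest-span overlap resolution, compound merge.
    Returns (motif, start, end, repeats, kind) tuples, 1-based."""
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    seq = seq.upper()
    cands = []
    for k, min_rep in min_repeats.items():
        for m in re.finditer(rf"([ACGT]{{{k}}})\1{{{min_rep - 1},}}", seq):
            unit = m.group(1)
            if any(
                len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d)
                for d in range(1, len(unit))
            ):
                continue
            span = m.end() - m.start()
            reps = span // k
            cands.append((m.start() + 1, m.start() + reps * k, unit, reps))
    cands.sort(key=lambda c: (-(c[1] - c[0] + 1), len(c[2]), c[0]))
    kept = []
    for c in cands:
        if all(c[1] < k[0] or c[0] > k[1] for k in kept):
            kept.append(c)
    kept.sort()
    out, i = [], 0
    while i < len(kept):
        j = i
        while j + 1 < len(kept) and kept[j + 1][0] - kept[j][1] - 1 <= compound_max_gap:
            j += 1
        if j == i:
            s, e, u, r = kept[i]
            out.append((u, s, e, r, "perfect"))
        else:
            out.append(("", kept[i][0], kept[j][1], 0, "compound"))
        i = j + 1
    return out


def records_as_tuples(records):
    return [
        (r.motif if r.kind == "perfect" else "", r.start, r.end, r.repeat_number, r.kind)
        for r in records
    ]


IUPAC_PAIRS = {
    ("A", "G"): "R", ("C", "T"): "Y", ("C", "G"): "S",
    ("A", "T"): "W", ("G", "T"): "K", ("A", "C"): "M",
}


def true_iupac(genotype: tuple[str, str]) -> str:
    a, b = sorted(genotype)
    return a if a == b else IUPAC_PAIRS[(a, b)]
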