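"""Simple-sequence-repeat (microsatellite) detection and marker selection.

Perfect SSRs are maximal tandem runs of a 1-6 base unit meeting a
per-unit-size minimum repeat number (defaults: mono 10, di 6, tri/tetra/
penta/hexa 5).  Nearby SSRs separated by at most ``compound_max_gap``
bases are merged into compound records.  Marker candidates keep only
perfect SSRs with unit size >= 2, since mononucleotide runs and compound
repeats genotype poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SSRRecord:
    """One detected SSR; coordinates are 1-based inclusive."""

    seq_id: str
    motif: str
    unit_size: int
    repeat_number: int
    start: int
    end: int
    kind: str = "perfect"  # perfect | compound
    components: list["SSRRecord"] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class MarkerCandidate:
    marker_id: str
    seq_id: str
    start: int
    end: int
    flank_start: int
    flank_end: int
    rationale: str


def _is_primitive(unit: str) -> bool:
    """True if the unit is not itself a repetition of a shorter unit."""
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def _candidate_runs(seq: str, min_repeats: dict[int, int]) -> list[tuple[int, int, str, int]]:
    """All maximal primitive-unit runs meeting the repeat minimum.

    Returns (start0, span, unit, repeats) tuples with 0-based starts.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    out: list[tuple[int, int, str, int]] = []
    for k, min_rep in sorted(min_repeats.items()):
        if n < k * min_rep:
            continue
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        # maximal runs of consecutive True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive
        for i, j in zip(starts, ends):
            run_len = j - i  # periodic region is seq[i : j + k]
            repeats = (run_len + k) // k
            if repeats < min_rep:
                continue
            unit = seq[i : i + k]
            if not _is_primitive(unit):
                continue
            out.append((int(i), repeats * k, unit, repeats))
    return out


def _resolve_overlaps(cands: list[tuple[int, int, str, int]]) -> list[tuple[int, int, str, int]]:
    """Longest span wins; ties by smaller unit, then leftmost start."""
    ranked = sorted(cands, key=lambda c: (-c[1], len(c[2]), c[0]))
    kept: list[tuple[int, int, str, int]] = []
    for c in ranked:
        s, span = c[0], c[1]
        e = s + span - 1
        if all(e < k[0] or s > k[0] + k[1] - 1 for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return kept


def find_ssrs(
    seq: str,
    seq_id: str = "seq",
    min_repeats: dict[int, int] | None = None,
    compound_max_gap: int = 100,
) -> list[SSRRecord]:
    """Scan one sequence for perfect and compound SSRs.

    Parameters
    ----------
    seq : str
        Nucleotide sequence over A/C/G/T/N (case-insensitive; N breaks runs).
    min_repeats : dict
        Minimum repeat number per unit size (1-6).
    compound_max_gap : int
        Adjacent SSRs separated by at most this many bases are merged
        into a single compound record.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    seq = seq.upper()
    kept = _resolve_overlaps(_candidate_runs(seq, min_repeats))
    perfect = [
        SSRRecord(
            seq_id=seq_id,
            motif=unit,
            unit_size=len(unit),
            repeat_number=reps,
            start=s + 1,
            end=s + span,
        )
        for s, span, unit, reps in kept
    ]
    # merge neighbours into compound records
    records: list[SSRRecord] = []
    i = 0
    while i < len(perfect):
        block = [perfect[i]]
        while (
            i + 1 < len(perfect)
            and perfect[i + 1].start - block[-1].end - 1 <= compound_max_gap
        ):
            i += 1
            block.append(perfect[i])
        if len(block) == 1:
            records.append(block[0])
        else:
            records.append(
                SSRRecord(
                    seq_id=seq_id,
                    motif="-".join(f"({b.motif}){b.repeat_number}" for b in block),
                    unit_size=0,
                    repeat_number=0,
                    start=block[0].start,
                    end=block[-1].end,
                    kind="compound",
                    components=block,
                )
            )
        i += 1
    return records


def canonical_motif(unit: str) -> str:
    """Canonical class of a repeat unit.

    The class label is the lexicographically smallest string among all
    rotations of the unit and all rotations of its reverse complement,
    so e.g. AG, GA, CT and TC all map to "AG".
    """
    unit = unit.upper()
    if not unit or any(b not in "ACGT" for b in unit):
        raise ValueError(f"invalid repeat unit: {unit!r}")
    rc = unit.translate(_COMPLEMENT)[::-1]
    variants = [u[i:] + u[:i] for u in (unit, rc) for i in range(len(u))]
    return min(variants)


def ssr_marker_filter(ssrs: list[SSRRecord], flank: int = 100) -> list[MarkerCandidate]:
    """Marker candidates: perfect SSRs with unit size of at least two bases."""
    out = []
    for i, r in enumerate(ssrs):
        if r.kind != "perfect" or r.unit_size < 2:
            continue
        out.append(
            MarkerCandidate(
                marker_id=f"SSR_{r.seq_id}_{r.start}",
                seq_id=r.seq_id,
                start=r.start,
                end=r.end,
                flank_start=max(1, r.start - flank),
                flank_end=r.end + flank,
                rationale=f"perfect ({r.motif}){r.repeat_number}",
            )
        )
    return out


def indel_marker_filter(indels: pd.DataFrame, flank: int = 100) -> list[MarkerCandidate]:
    """InDel marker candidates: genes carrying exactly one biallelic InDel.

    ``indels`` needs columns gene_id, pos, ref, alt where ``alt`` is a
    comma-separated list of alternate alleles.
    """
    out: list[MarkerCandidate] = []
    for gene, grp in indels.groupby("gene_id", sort=True):
        if len(grp) != 1:
            continue
        row = grp.iloc[0]
        n_alleles = 1 + len(str(row["alt"]).split(","))
        if n_alleles != 2:
            continue
        pos = int(row["pos"])
        out.append(
            MarkerCandidate(
                marker_id=f"InDel_{gene}_{pos}",
                seq_id=str(gene),
                start=pos,
                end=pos + max(len(str(row["ref"])) - 1, 0),
                flank_start=max(1, pos - flank),
                flank_end=pos + flank,
                rationale="single biallelic InDel in gene",
            )
        )
    return out


#: repeat-number bins used for the distribution summary
REPEAT_BINS = [(5, 7), (8, 11), (12, 15), (16, None)]


def ssr_summary(ssrs: list[SSRRecord]) -> dict[str, pd.DataFrame]:
    """Contingency summaries of detected SSRs.

    Returns ``by_class`` (unit size x repeat-number bin counts, percent
    of all detected SSRs) and ``by_motif`` (canonical motif class counts).
    Compound records are summarised through their perfect components.
    """
    units: list[SSRRecord] = []
    for r in ssrs:
        units.extend(r.components if r.kind == "compound" else [r])
    if not units:
        empty = pd.DataFrame()
        return {"by_class": empty, "by_motif": empty}

    def _bin(reps: int) -> str:
        for lo, hi in REPEAT_BINS:
            if hi is None and reps >= lo:
                return f">={lo}"
            if hi is not None and lo <= reps <= hi:
                return f"{lo}-{hi}"
        return f"<{REPEAT_BINS[0][0]}"

    df = pd.DataFrame(
        {
            "unit_size": [r.unit_size for r in units],
            "repeat_bin": [_bin(r.repeat_number) for r in units],
            "canonical": [canonical_motif(r.motif) for r in units],
        }
    )
    by_class = df.groupby(["unit_size", "repeat_bin"]).size().rename("count").reset_index()
    by_class["percent"] = 100.0 * by_class["count"] / len(units)
    by_motif = df.groupby("canonical").size().rename("count").reset_index()
    by_motif["percent"] = 100.0 * by_motif["count"] / len(units)
    return {"by_class": by_class, "by_motif": by_motif}


def records_to_frame(ssrs: list[SSRRecord]) -> pd.DataFrame:
    rows = []
    for r in ssrs:
        rows.append(
            {
                "seq_id": r.seq_id,
                "motif": r.motif,
                "canonical_class": canonical_motif(r.motif) if r.kind == "perfect" else "",
                "unit_size": r.unit_size,
                "repeats": r.repeat_number,
                "start": r.start,
                "end": r.end,
                "kind": r.kind,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["seq_id", "motif", "canonical_class", "unit_size", "repeats", "start", "end", "kind"],
    )
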