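"""Small sequence and interval helpers shared across modules."""

from __future__ import annotations

from typing import Iterable, Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings (unequal lengths -> inf-like)."""
    if len(a) != len(b):
        return max(len(a), len(b)) + 1
    return sum(x != y for x, y in zip(a, b))


def get_chrom_seq(reference: Mapping[str, object], chrom: str) -> str:
    """Fetch a full chromosome as an upper-case string.

    Accepts either a plain dict of strings or a pyfaidx.Fasta object.
    """
    rec = reference[chrom]
    return str(rec[:]).upper() if not isinstance(rec, str) else rec.upper()


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    target: tuple[int, int], covered: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Maximal disjoint sub-intervals of `target` not covered by `covered`."""
    ts, te = target
    gaps: list[tuple[int, int]] = []
    pos = ts
    for s, e in merge_intervals(covered):
        if e <= pos:
            continue
        if s >= te:
            break
        if s > pos:
            gaps.append((pos, min(s, te)))
        pos = max(pos, e)
        if pos >= te:
            break
    if pos < te:
        gaps.append((pos, te))
    return gaps
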