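"""Control-region and spacer feature scanning.

Insect control regions carry short replication/transcription signals: a
poly(T) stretch near the 5' end, a [TA(A)]n-like stretch after it, a
G+A-rich block upstream, exact tandem repeats, and sequences whose
counterparts recur inside the CR. All scanners here are exact and
combinatorial (no thermodynamic folding, no mismatch-tolerant repeat
scoring); they operate on the J-strand sequence, scan both strands where a
motif is strand-symmetric, and report 1-based inclusive coordinates on the
J strand. Passing ``origin`` (the genome coordinate of the first character
of the scanned slice) lifts hit coordinates into genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import reverse_complement

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class MotifHit:
    """A located motif; ``score`` is run length, unit count, purine fraction
    or stem length depending on ``kind``."""

    kind: str  # polyT | TAAlike | GArich | hairpin
    start: int  # 1-based inclusive
    end: int
    strand: str  # J or N
    score: float


@dataclass(frozen=True)
class TandemRepeat:
    """An exact tandem array; ``copies`` may be fractional (partial last copy)."""

    unit: str
    start: int  # 1-based inclusive
    end: int

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def copies(self) -> float:
        return self.span / self.unit_length


@dataclass(frozen=True)
class CounterpartMatch:
    """Best ungapped local match of a query (spacer) window inside a subject (CR)."""

    query_start: int  # 1-based inclusive, query coordinates
    query_end: int
    subject_start: int  # 1-based inclusive, subject J-strand coordinates
    subject_end: int
    strand: str  # subject strand carrying the match
    length: int
    identities: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identities / self.length


def _runs(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length), 0-based."""
    runs = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def find_polyt(seq: str, min_run: int = 5, origin: int = 1) -> list[MotifHit]:
    """Maximal T runs of length >= min_run, on both strands.

    An N-strand poly(T) appears as a poly(A) run on the J-strand slice;
    coordinates are always reported on the J strand.
    """
    if min_run < 3:
        raise ValueError("min_run must be >= 3")
    s = seq.upper()
    hits = []
    for strand, base in (("J", "T"), ("N", "A")):
        for start, length in _runs([c == base for c in s]):
            if length >= min_run:
                hits.append(
                    MotifHit("polyT", origin + start, origin + start + length - 1, strand, length)
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _taa_decompose(s: str) -> int:
    """Greedy left-to-right unit count over {TA, TAA}, preferring TAA."""
    i = units = 0
    while i < len(s):
        if s.startswith("TAA", i):
            i += 3
        elif s.startswith("TA", i):
            i += 2
        else:
            break
        units += 1
    return units


def find_taa_stretch(
    seq: str,
    polyt_hits: Sequence[MotifHit] | None = None,
    window_after: int = 50,
    min_units: int = 3,
    min_run: int = 5,
    origin: int = 1,
) -> list[MotifHit]:
    """The longest [TA(A)]n-like stretch downstream of each J-strand poly(T) hit.

    Within ``window_after`` bp after a poly(T) run, every start position is
    tried; a stretch is the greedy TA/TAA decomposition from that start
    (ties between unit boundaries broken toward the longer TAA unit). The
    longest stretch with >= ``min_units`` units is reported per poly(T) hit;
    ``score`` is the unit count.
    """
    s = seq.upper()
    if polyt_hits is None:
        polyt_hits = find_polyt(s, min_run=min_run, origin=origin)
    hits = []
    for pt in polyt_hits:
        if pt.strand != "J":
            continue
        lo = pt.end - origin + 1  # 0-based first position after the run
        hi = min(len(s), lo + window_after)
        best = None  # (span, -start, units, start)
        for start in range(lo, hi):
            units = _taa_decompose(s[start:])
            if units < min_units:
                continue
            span = _taa_span(s, start)
            cand = (span, -start, units, start)
            if best is None or cand > best:
                best = cand
        if best is not None:
            span, _, units, start = best
            hits.append(MotifHit("TAAlike", origin + start, origin + start + span - 1, "J", units))
    return hits


def _taa_span(s: str, start: int) -> int:
    i = start
    while i < len(s):
        if s.startswith("TAA", i):
            i += 3
        elif s.startswith("TA", i):
            i += 2
        else:
            break
    return i - start


def find_ga_rich_block(
    seq: str,
    polyt_hits: Sequence[MotifHit] | None = None,
    window: int = 10,
    min_frac: float = 0.8,
    origin: int = 1,
) -> list[MotifHit]:
    """Maximal G+A-rich blocks upstream of a poly(T) stretch.

    Every window of ``window`` bp with purine (G+A) fraction >= ``min_frac``
    qualifies; overlapping qualifying windows are merged into maximal
    blocks, reported with the purine fraction of the merged block as score.
    With ``polyt_hits=None`` the whole sequence is scanned.
    """
    if not 0.5 < min_frac <= 1:
        raise ValueError("min_frac must be in (0.5, 1]")
    s = seq.upper()
    if polyt_hits is None:
        region_end = len(s)
    else:
        j_hits = [h for h in polyt_hits if h.strand == "J"]
        if not j_hits:
            return []
        region_end = min(h.start for h in j_hits) - origin  # 0-based exclusive
    if region_end < window:
        return []
    purine = np.frombuffer(s[:region_end].encode(), dtype=np.uint8)
    is_pur = (purine == ord("G")) | (purine == ord("A"))
    csum = np.concatenate([[0], np.cumsum(is_pur)])
    qualifying = [
        i
        for i in range(region_end - window + 1)
        if (csum[i + window] - csum[i]) / window >= min_frac
    ]
    if not qualifying:
        return []
    # merge overlapping/adjacent qualifying windows into maximal blocks
    blocks = []
    block_start = prev = qualifying[0]
    for i in qualifying[1:]:
        if i <= prev + window:
            prev = i
        else:
            blocks.append((block_start, prev + window))
            block_start = prev = i
    blocks.append((block_start, prev + window))
    hits = []
    for b0, b1 in blocks:
        frac = float(csum[b1] - csum[b0]) / (b1 - b0)
        hits.append(MotifHit("GArich", origin + b0, origin + b1 - 1, "J", frac))
    return hits


def tandem_repeats(
    seq: str,
    min_unit: int = 2,
    max_unit: int | None = None,
    min_copies: float = 2.0,
    origin: int = 1,
) -> list[TandemRepeat]:
    """Exact tandem arrays, maximally extended, collapsed to best representatives.

    An array with unit length u is a maximal stretch over which
    ``seq[i] == seq[i-u]`` holds; its copy number span/u may be fractional
    (a partial trailing copy). Arrays with >= ``min_copies`` copies are
    candidates; overlapping candidates are collapsed by keeping the
    highest-copy-number representative first (ties: shorter unit, then
    leftmost), greedily discarding candidates that overlap an accepted one.
    """
    s = seq.upper()
    n = len(s)
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    if max_unit is None:
        max_unit = n // 2
    max_unit = min(max_unit, n // 2)
    candidates = []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    for u in range(min_unit, max_unit + 1):
        match = arr[u:] == arr[:-u]
        for m0, mlen in _runs(match.tolist()):
            span = mlen + u
            if span / u >= min_copies:
                start = m0  # 0-based array start (match index i means s[i+u]==s[i])
                candidates.append((span / u, u, start, span))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[tuple[int, int]] = []  # (start, end) 0-based inclusive
    out = []
    for copies, u, start, span in candidates:
        end = start + span - 1
        if any(not (end < a0 or start > a1) for a0, a1 in accepted):
            continue
        accepted.append((start, end))
        out.append(TandemRepeat(unit=s[start : start + u], start=origin + start, end=origin + end))
    out.sort(key=lambda t: t.start)
    return out


def _best_window_on_diagonal(
    match: Sequence[int], min_len: int, min_identity: float
) -> tuple[int, int, int] | None:
    """Longest window with identity >= threshold (ties: more identities, leftmost).

    Returns (start, length, identities) within the diagonal, or None.
    """
    m = len(match)
    if m < min_len:
        return None
    csum = [0]
    for v in match:
        csum.append(csum[-1] + v)
    for length in range(m, min_len - 1, -1):
        best = None
        for start in range(m - length + 1):
            ident = csum[start + length] - csum[start]
            if ident / length >= min_identity:
                if best is None or ident > best[2]:
                    best = (start, length, ident)
        if best is not None:
            return best
    return None


def counterpart_search(
    query: str,
    subject: str,
    min_len: int = 10,
    min_identity: float = 0.70,
    query_origin: int = 1,
    subject_origin: int = 1,
) -> list[CounterpartMatch]:
    """Ungapped search of a spacer against both strands of a CR.

    Each alignment diagonal (fixed offset of query against subject, either
    strand) is scanned for its best window: the longest stretch of length
    >= ``min_len`` with identity >= ``min_identity``, ties broken toward
    more identities then leftmost. One match per qualifying diagonal is
    reported, best first (percent identity, then length). Subject
    coordinates are always on the given (J) strand; ``strand == "N"`` means
    the match is to the reverse complement.
    """
    q = query.upper()
    if min_len > len(q):
        raise ValueError("min_len exceeds query length")
    matches = []
    for strand in ("J", "N"):
        subj = subject.upper() if strand == "J" else reverse_complement(subject.upper())
        ns, nq = len(subj), len(q)
        for offset in range(-(nq - min_len), ns - min_len + 1):
            # query position i aligns to subject position i + offset
            q_lo = max(0, -offset)
            q_hi = min(nq, ns - offset)
            if q_hi - q_lo < min_len:
                continue
            match = [1 if q[i] == subj[i + offset] else 0 for i in range(q_lo, q_hi)]
            best = _best_window_on_diagonal(match, min_len, min_identity)
            if best is None:
                continue
            w0, length, ident = best
            qs = q_lo + w0
            ss = qs + offset
            if strand == "J":
                s_start, s_end = ss, ss + length - 1
            else:
                # map back from the reverse complement to J-strand coordinates
                s_end = len(subject) - 1 - ss
                s_start = s_end - length + 1
            matches.append(
                CounterpartMatch(
                    query_start=query_origin + qs,
                    query_end=query_origin + qs + length - 1,
                    subject_start=subject_origin + s_start,
                    subject_end=subject_origin + s_end,
                    strand=strand,
                    length=length,
                    identities=ident,
                )
            )
    matches.sort(
        key=lambda m: (-m.percent_identity, -m.length, m.subject_start, m.strand)
    )
    return matches


def hairpin_scan(
    seq: str,
    min_stem: int = 3,
    loop_range: tuple[int, int] = (3, 8),
    origin: int = 1,
) -> list[MotifHit]:
    """Perfect inverted repeats that can close into a stem-loop.

    For every candidate loop interval with length inside ``loop_range``,
    the stem is grown outward while bases pair Watson-Crick (no G.T
    wobble); a hairpin is reported when the maximal stem reaches
    ``min_stem``. ``score`` is the stem length; ``start``/``end`` delimit
    the whole hairpin (5' stem arm through 3' stem arm).
    """
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    lo, hi = loop_range
    if not (3 <= lo <= hi <= 12):
        raise ValueError("loop range must lie within 3..12")
    s = seq.upper()
    n = len(s)
    hits = []
    for a in range(n):
        for loop_len in range(lo, hi + 1):
            b = a + loop_len - 1  # loop occupies s[a..b]
            if b >= n:
                break
            k = 0
            while (
                a - k - 1 >= 0
                and b + k + 1 < n
                and (s[a - k - 1], s[b + k + 1]) in WC_PAIRS
            ):
                k += 1
            if k >= min_stem:
                hits.append(
                    MotifHit("hairpin", origin + a - k, origin + b + k, "J", k)
                )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def motif_hits_to_bed(
    hits: Sequence[MotifHit | TandemRepeat | CounterpartMatch],
    zero_based: bool = False,
) -> str:
    """BED-like TSV export (1-based inclusive by default, 0-based half-open on request)."""
    lines = ["#start\tend\tname\tscore\tstrand"]
    for h in hits:
        if isinstance(h, TandemRepeat):
            start, end, name, score, strand = h.start, h.end, f"tandem:{h.unit}", h.copies, "J"
        elif isinstance(h, CounterpartMatch):
            start, end = h.subject_start, h.subject_end
            name, score, strand = "counterpart", round(h.percent_identity, 1), h.strand
        else:
            start, end, name, score, strand = h.start, h.end, h.kind, h.score, h.strand
        if zero_based:
            start, end = start - 1, end
        lines.append(f"{start}\t{end}\t{name}\t{score}\t{strand}")
    return "\n".join(lines) + "\n"
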