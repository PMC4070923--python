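"""Independent brute-force reference implementations for the motif scanners.

These enumerate candidates directly from the definitions (all starts, all
unit lengths, all windows, all loop intervals) and are kept deliberately
separate from the package's scanning code paths.
"""

from mitocomp.genome import reverse_complement

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def brute_tandem(s: str, min_unit: int, max_unit: int | None, min_copies: float):
    """All maximal exact tandem arrays, collapsed exactly as the scanner collapses.

    Returns a list of (start0, end0, unit) tuples, sorted by start.
    """
    s = s.upper()
    n = len(s)
    if max_unit is None:
        max_unit = n // 2
    max_unit = min(max_unit, n // 2)
    candidates = []
    for u in range(min_unit, max_unit + 1):
        for start in range(n - u):
            if s[start] != s[start + u]:
                continue  # no repetition begins here
            if start >= 1 and s[start - 1] == s[start - 1 + u]:
                continue  # extendable left: not maximal
            span = u + 1
            while start + span < n and s[start + span] == s[start + span - u]:
                span += 1
            if span / u >= min_copies:
                candidates.append((span / u, u, start, span))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted = []
    out = []
    for copies, u, start, span in candidates:
        end = start + span - 1
        if any(not (end < a0 or start > a1) for a0, a1 in accepted):
            continue
        accepted.append((start, end))
        out.append((start, end, s[start : start + u]))
    return sorted(out)


def brute_counterpart(query: str, subject: str, min_len: int, min_identity: float):
    """Per-diagonal best windows by direct enumeration of every window.

    Returns a set of (qstart0, sstart0_J, length, identities, strand).
    """
    q = query.upper()
    out = set()
    for strand in ("J", "N"):
        subj = subject.upper() if strand == "J" else reverse_complement(subject.upper())
        nq, ns = len(q), len(subj)
        for offset in range(-(nq - min_len), ns - min_len + 1):
            lo = max(0, -offset)
            hi = min(nq, ns - offset)
            if hi - lo < min_len:
                continue
            m = [q[i] == subj[i + offset] for i in range(lo, hi)]
            csum = [0]
            for v in m:
                csum.append(csum[-1] + v)
            best = None
            for length in range(len(m), min_len - 1, -1):
                for w0 in range(len(m) - length + 1):
                    ident = csum[w0 + length] - csum[w0]
                    if ident / length >= min_identity and (
                        best is None or ident > best[2]
                    ):
                        best = (w0, length, ident)
                if best is not None:
                    break
            if best is None:
                continue
            w0, length, ident = best
            qs = lo + w0
            ss = qs + offset
            if strand == "N":
                ss = len(subject) - 1 - (ss + length - 1)
            out.add((qs, ss, length, ident, strand))
    return out


def brute_hairpin(s: str, min_stem: int, loop_range: tuple[int, int]):
    """All outward-maximal perfect stem-loops: set of (start0, end0, stem)."""
    s = s.upper()
    n = len(s)
    lo, hi = loop_range
    out = set()
    for i in range(n):
        for loop in range(lo, hi + 1):
            for k in range(min_stem, n):
                end = i + 2 * k + loop - 1
                if end >= n:
                    break
                arm5 = s[i : i + k]
                arm3 = s[i + k + loop : end + 1]
                if not all((a, b) in WC for a, b in zip(arm5, reversed(arm3))):
                    continue
                # outward-maximal: the next enclosing pair must fail or run off
                if i >= 1 and end + 1 < n and (s[i - 1], s[end + 1]) in WC:
                    continue
                out.add((i, end, k))
    return out
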