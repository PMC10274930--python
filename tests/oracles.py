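"""Independent brute-force oracles used by the test suite.

These deliberately share no code path with the package implementations:
overlap detection is exhaustive over all pairs, strands and diagonals using
symbol-wise correlation; transitive-reduction checking is a path search;
integer overlaps try all shifts.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def _indicator(seq: str, c: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), np.uint8) == ord(c)


def _match_counts(a: str, b: str) -> np.ndarray:
    """matches[d + len(b) - 1] = #{i : a[i] == b[i-d]}, exact integers."""
    total = np.zeros(len(a) + len(b) - 1)
    for c in "ACGT":
        ai = _indicator(a, c).astype(np.float64)
        bi = _indicator(b, c).astype(np.float64)
        total += fftconvolve(ai, bi[::-1])
    return np.rint(total).astype(np.int64)


def _classify(a_lo, a_hi, la, r_lo, r_hi, lb):
    a_full = a_lo == 0 and a_hi == la
    b_full = r_lo == 0 and r_hi == lb
    if b_full and (la > lb or (la == lb and a_full)):
        return "a_contains_b"
    if a_full:
        return "b_contains_a"
    if a_hi == la and r_lo == 0:
        return "dovetail"
    if a_lo == 0 and r_hi == lb:
        return "dovetail"
    return None


def oracle_overlaps(reads, k=None, min_ovlp=250, max_div=0.0):
    """All pairs, both strands, every diagonal, by direct counting.

    Returns the same tuples find_overlaps reports, with the same per-pair
    tie-break (longest, then smaller a_start, then same strand first).
    """
    out = []
    n = len(reads)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i].seq, reads[j].seq
            la, lb = len(a), len(b)
            best = None
            for strand, ob in (("same", b), ("opposite", rc(b))):
                counts = _match_counts(a, ob)
                for d in range(-(lb - 1), la):
                    lo, hi = max(0, d), min(la, lb + d)
                    length = hi - lo
                    if length < min_ovlp:
                        continue
                    mism = length - int(counts[d + lb - 1])
                    if mism > max_div * length:
                        continue
                    kind = _classify(lo, hi, la, lo - d, hi - d, lb)
                    if kind is None:
                        continue
                    rank = (-length, lo, 0 if strand == "same" else 1)
                    if best is None or rank < best[0]:
                        best = (rank, strand, d, lo, hi, mism, kind)
            if best is None:
                continue
            rank, strand, d, lo, hi, mism, kind = best
            r_lo, r_hi = lo - d, hi - d
            if strand == "same":
                b_lo, b_hi = r_lo, r_hi
            else:
                b_lo, b_hi = lb - r_hi, lb - r_lo
            out.append((reads[i].id, reads[j].id, strand, lo, hi, b_lo, b_hi,
                        kind, round(1.0 - mism / (hi - lo), 9)))
    return sorted(out)


def overlap_tuples(overlaps):
    return sorted((o.a_id, o.b_id, o.strand, o.a_start, o.a_end,
                   o.b_start, o.b_end, o.kind, round(o.identity, 9))
                  for o in overlaps)


def arc_set(graph):
    return {(str(a), ao, str(b), bo, ov) for a, ao, b, bo, ov in graph.edges()}


def check_reduction(before, after, fuzz, max_depth=12):
    """Every removed edge must be realised by a surviving directed walk of
    consistent total extension; every surviving edge must be irreducible
    (no surviving two-edge witness within fuzz)."""
    kept = arc_set(after)
    removed = arc_set(before) - kept

    def ext(g, w, ov):
        return g.nodes[w].length - ov

    for a, ao, b, bo, ov in removed:
        # breadth-limited search in `after` for a path (a,ao) ->* (b,bo)
        target = before.nodes[_orig(before, b)].length - ov
        found = False
        stack = [((_orig(after, a), ao), 0, 0)]
        while stack:
            (v, vo), tot, depth = stack.pop()
            if depth > max_depth or tot > target + fuzz * max(depth, 1):
                continue
            for w, wo, ovw in after.out_edges(v, vo):
                t2 = tot + ext(after, w, ovw)
                if (str(w), wo) == (str(b), bo) and abs(t2 - target) <= fuzz * (depth + 1):
                    found = True
                    stack = []
                    break
                stack.append(((w, wo), t2, depth + 1))
        assert found, f"removed edge {(a, ao, b, bo)} not implied by surviving walk"

    for a, ao, b, bo, ov in kept:
        target = after.nodes[_orig(after, b)].length - ov
        for w, wo, ovw in after.out_edges(_orig(after, a), ao):
            if (str(w), wo) == (str(b), bo):
                continue
            e1 = after.nodes[w].length - ovw
            for x, xo, ovx in after.out_edges(w, wo):
                if (str(x), xo) == (str(b), bo):
                    e2 = after.nodes[x].length - ovx
                    assert abs(e1 + e2 - target) > fuzz, \
                        f"kept edge {(a, ao, b, bo)} is reducible via {(w, wo)}"


def _orig(graph, sid):
    """Map a stringified node id back to the graph's real id."""
    for nid in graph.nodes:
        if str(nid) == sid:
            return nid
    raise KeyError(sid)


def oracle_integer_overlaps(iseqs, min_iov=1):
    """All pairs, both orientations, all shifts, on plain Python tuples."""
    def rev(els):
        return tuple((n, "-" if o == "+" else "+") for n, o in reversed(els))

    def is_run(hay, needle):
        m = len(needle)
        return any(hay[i : i + m] == needle for i in range(len(hay) - m + 1))

    out = []
    n = len(iseqs)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = iseqs[i].elements, iseqs[j].elements
            br = rev(b)
            cont = None
            if len(b) <= len(a):
                if is_run(a, b):
                    cont = ("same", len(b), "a_contains_b")
                elif is_run(a, br):
                    cont = ("opposite", len(b), "a_contains_b")
            if cont is None and len(a) < len(b):
                if is_run(b, a):
                    cont = ("same", len(a), "b_contains_a")
                elif is_run(br, a):
                    cont = ("opposite", len(a), "b_contains_a")
            if cont is not None:
                strand, length, kind = cont
                out.append((iseqs[i].ul_id, iseqs[j].ul_id, strand, length,
                            kind, True))
                continue
            for strand, ob in (("same", b), ("opposite", br)):
                for a_suffix, (x, y) in ((True, (a, ob)), (False, (ob, a))):
                    best = 0
                    for m in range(min(len(x), len(y)) - 1, min_iov - 1, -1):
                        if x[-m:] == y[:m]:
                            best = m
                            break
                    if best:
                        out.append((iseqs[i].ul_id, iseqs[j].ul_id, strand,
                                    best, "dovetail", a_suffix))
    return sorted(out)


def integer_overlap_tuples(overlaps):
    return sorted((o.a_id, o.b_id, o.strand, o.length, o.kind,
                   o.a_suffix if o.kind == "dovetail" else True)
                  for o in overlaps)


def oracle_n50(lengths):
    """Definition-based: the largest length L in the set such that contigs of
    length >= L together hold at least half the assembly."""
    total = sum(lengths)
    return max(L for L in lengths
               if sum(x for x in lengths if x >= L) >= total / 2)
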