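"""Affine-gap glocal alignment of a fragment against a minimal reference.

The fragment must align end-to-end (every fragment base is accounted for)
while the 2*l_f-long minimal reference may have free unaligned ends: the
fragment is contained in the minimal reference, not vice versa.  Internal
gaps follow an affine model in which a gap of length g costs
``gap_open + gap_extend * g`` (so a single-base gap costs 10.5 with the
defaults, cheaper than two mismatches at 18).

The dynamic program is the standard three-state formulation (match state M,
fragment-consuming gap I = gap in the reference row, reference-consuming gap
D = gap in the fragment row).  All score increments are multiples of 0.5, so
optimality ties are exact in floating point and the traceback can enumerate
every co-optimal path; distinct gap placements of equal score are exactly the
equivalent breakpoint placements the caller must consider (e.g. the n+1 ways
of placing a single-base insertion inside a homopolymer of length n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

NEG = -1e18

# traceback op codes: align / insert (consume fragment) / delete (consume reference)
OP_ALIGN = "M"
OP_INS = "I"
OP_DEL = "D"


@dataclass
class AlignmentPath:
    """One optimal (or tolerated) traceback: ops over fragment/reference."""

    ops: list[tuple[str, int, int]]  # (op, fragment index, reference index), 0-based
    score: float

    def aligned_strings(self, fragment: str, reference: str) -> tuple[str, str]:
        top, bottom = [], []
        for op, i, j in self.ops:
            if op == OP_ALIGN:
                top.append(fragment[i])
                bottom.append(reference[j])
            elif op == OP_INS:
                top.append(fragment[i])
                bottom.append("-")
            else:
                top.append("-")
                bottom.append(reference[j])
        return "".join(top), "".join(bottom)

    def gap_runs(self) -> list[tuple[str, int, int]]:
        """Maximal internal gap runs as (row, start_op_index, end_op_index).

        ``row`` is "reference" for OP_INS runs (gap symbols in the reference
        row; extra fragment sequence) and "fragment" for OP_DEL runs (gap in
        the fragment row; skipped reference sequence).
        """
        runs = []
        k = 0
        ops = self.ops
        while k < len(ops):
            op = ops[k][0]
            if op == OP_ALIGN:
                k += 1
                continue
            start = k
            while k < len(ops) and ops[k][0] == op:
                k += 1
            row = "reference" if op == OP_INS else "fragment"
            runs.append((row, start, k))
        return runs

    def identity_outside_gaps(self, fragment: str, reference: str) -> float:
        aligned = [(i, j) for op, i, j in self.ops if op == OP_ALIGN]
        if not aligned:
            return 0.0
        matches = sum(1 for i, j in aligned if fragment[i] == reference[j] != "N")
        return matches / len(aligned)


@dataclass
class GappedAlignment:
    """Optimal glocal alignment with its co-optimal alternatives."""

    fragment: str
    reference: str
    score: float
    paths: list[AlignmentPath]  # deterministic order; paths[0] is the primary

    @property
    def primary(self) -> AlignmentPath:
        return self.paths[0]


def _substitution_row(frag_codes: np.ndarray, ref_codes: np.ndarray,
                      i: int, match: float, mismatch: float) -> np.ndarray:
    eq = ref_codes == frag_codes[i]
    valid = (ref_codes >= 0) & (frag_codes[i] >= 0)  # N never matches
    return np.where(eq & valid, match, mismatch)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq], dtype=np.int8)


def global_align_affine(
    fragment: str,
    reference: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    max_paths: int = 64,
    tolerance_score: float = 0.0,
) -> GappedAlignment:
    """Glocal affine-gap alignment (fragment global, reference ends free).

    Enumerates up to ``max_paths`` tracebacks whose score is within
    ``tolerance_score`` of the optimum (0 keeps exact co-optima only).
    """
    n, m = len(fragment), len(reference)
    if n == 0 or m == 0:
        raise ValueError("alignment requires non-empty sequences")
    fc, rc = _encode(fragment), _encode(reference)
    open_cost = gap_open + gap_extend

    M = np.full((n + 1, m + 1), NEG)
    I = np.full((n + 1, m + 1), NEG)
    D = np.full((n + 1, m + 1), NEG)
    # virtual row 0: free leading reference skip of any length
    M[0, :] = 0.0

    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], I[i - 1]), D[i - 1])
        sub = _substitution_row(fc, rc, i - 1, match, mismatch)
        M[i, 1:] = prev_best[:-1] + sub
        I[i, :] = np.maximum(
            np.maximum(M[i - 1], D[i - 1]) - open_cost, I[i - 1] - gap_extend
        )
        # D[i, j] = max_{k < j} (best(M,I)[i, k] - gap_open - gap_extend*(j-k))
        base = np.maximum(M[i], I[i]) - gap_open
        shifted = base + gap_extend * np.arange(m + 1)
        run = np.maximum.accumulate(shifted[:-1])
        D[i, 1:] = run - gap_extend * np.arange(1, m + 1)

    # free trailing reference: best over all columns, ending aligned or inserted
    final = np.maximum(M[n], I[n])
    opt = float(final.max())

    paths = _enumerate_paths(
        M, I, D, fc, rc, match, mismatch, open_cost, gap_extend,
        opt, tolerance_score, max_paths,
    )
    return GappedAlignment(fragment, reference, opt, paths)


def _enumerate_paths(M, I, D, fc, rc, match, mismatch, open_cost, gap_extend,
                     opt, tol, max_paths) -> list[AlignmentPath]:
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    need = opt - tol - 1e-9
    mats = {"M": M, "I": I, "D": D}
    out: list[AlignmentPath] = []

    # Backward DFS.  Invariant: ``suffix`` is the summed score of the ops
    # already emitted, so suffix + value[state][i, j] bounds every completion
    # of the partial path; branches below ``need`` are pruned, which makes the
    # search visit co-optimal (or tolerated) paths only.
    def recurse(state: str, i: int, j: int, suffix: float, ops: list) -> None:
        if len(out) >= max_paths:
            return
        val = mats[state][i, j]
        if suffix + val < need:
            return
        if i == 0:
            # virtual start row (M[0, j] == 0): leading reference skip is free
            if state == "M":
                out.append(AlignmentPath(ops[::-1], suffix))
            return
        if state == "M":
            sub = match if (fc[i - 1] >= 0 and fc[i - 1] == rc[j - 1]) else mismatch
            if j == 0:
                return
            ops.append((OP_ALIGN, i - 1, j - 1))
            for prev in ("M", "D", "I"):
                pv = mats[prev][i - 1, j - 1]
                if abs(val - (pv + sub)) < 1e-9:
                    recurse(prev, i - 1, j - 1, suffix + sub, ops)
            ops.pop()
        elif state == "I":
            ops.append((OP_INS, i - 1, j))
            for prev, cost in (("M", open_cost), ("D", open_cost), ("I", gap_extend)):
                pv = mats[prev][i - 1, j]
                if abs(val - (pv - cost)) < 1e-9:
                    recurse(prev, i - 1, j, suffix - cost, ops)
            ops.pop()
        else:  # D
            if j == 0:
                return
            ops.append((OP_DEL, i, j - 1))
            for prev, cost in (("M", open_cost), ("I", open_cost), ("D", gap_extend)):
                pv = mats[prev][i, j - 1]
                if abs(val - (pv - cost)) < 1e-9:
                    recurse(prev, i, j - 1, suffix - cost, ops)
            ops.pop()

    # deterministic start order: rightmost end column first, M before I
    for j in range(m, -1, -1):
        for st in ("M", "I"):
            if len(out) >= max_paths:
                break
            if mats[st][n, j] >= need:
                recurse(st, n, j, 0.0, [])

    seen = set()
    uniq = []
    for p in out:
        key = tuple(p.ops)
        if key not in seen:
            seen.add(key)
            uniq.append(p)
    return uniq
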