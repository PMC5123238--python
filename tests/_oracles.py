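"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

NEG = -(10**9)


def full_affine_sw(
    query: str,
    target: str,
    match: int = 2,
    mismatch: int = 2,
    gap_open: int = 4,
    gap_extend: int = 1,
):
    """Unbanded affine-gap Smith–Waterman, plain O(nm) dynamic program.

    Returns (score, query_start, target_start, ops) where ops is a merged
    list of (op, length) with op in {M, I, D}, or (0, None, None, []) when
    no positive-scoring alignment exists.  Traceback prefers the diagonal
    move, then gap-in-target (I), then gap-in-query (D); the best cell is
    the first maximum in row-major order.
    """
    n, m = len(query), len(target)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, cell = 0, None
    for i in range(1, n + 1):
        qc = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            s = match if qc == target[j - 1] else -mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, cell = H[i][j], (i, j)
    if cell is None:
        return 0, None, None, []
    ops: list[tuple[str, int]] = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    i, j = cell
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            val = H[i][j]
            if val == 0:
                break
            s = match if query[i - 1] == target[j - 1] else -mismatch
            if val == H[i - 1][j - 1] + s:
                push("M")
                i, j = i - 1, j - 1
            elif val == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            push("I")
            if E[i][j] != E[i - 1][j] - gap_extend:
                state = "H"
            i -= 1
        else:
            push("D")
            if F[i][j] != F[i][j - 1] - gap_extend:
                state = "H"
            j -= 1
    ops.reverse()
    return best, i, j, ops


def brute_force_assign(pair, panel, max_mismatches: int = 1):
    """Exhaustive primer-pair matcher: all amplicons, plain Hamming counts."""

    def hamming_prefix(seq, primer):
        if len(seq) < len(primer):
            return None
        return sum(
            1
            for a, b in zip(primer, seq)
            if a != b and a != "N" and b != "N"
        )

    hits = []
    for idx, amp in enumerate(panel.amplicons):
        mm1 = hamming_prefix(pair.seq1, amp.ulso)
        mm2 = hamming_prefix(pair.seq2, amp.dlso)
        if mm1 is None or mm2 is None:
            continue
        if mm1 <= max_mismatches and mm2 <= max_mismatches:
            hits.append((mm1 + mm2, idx, amp.id))
    if not hits:
        return None
    hits.sort()
    return hits[0][2]
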