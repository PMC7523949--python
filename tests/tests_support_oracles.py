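"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive results from first principles (plain DP,
per-window recounting) and must stay independent of the implementations
they check.
"""

from shoreline.landscape import CpGIsland, IslandParams


def bruteforce_align_score(ref: str, clone: str) -> float:
    """End-gap-free global alignment score by plain dynamic programming.

    Match +1 (including the bisulfite asymmetry ref C vs clone T),
    mismatch -1, gap -2; leading and trailing gaps in either sequence free.
    """

    def sub(a: str, b: str) -> float:
        return 1.0 if (a == b or (a == "C" and b == "T")) else -1.0

    n, m = len(ref), len(clone)
    D = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = max(
                D[i - 1][j - 1] + sub(ref[i - 1], clone[j - 1]),
                D[i - 1][j] - 2.0,
                D[i][j - 1] - 2.0,
            )
    return max(
        max(D[n][j] for j in range(m + 1)),
        max(D[i][m] for i in range(n + 1)),
    )


def _stats(sub: str):
    n, c, g, cpg = len(sub), sub.count("C"), sub.count("G"), sub.count("CG")
    gc = (c + g) / n if n else 0.0
    oe = cpg * n / (c * g) if c and g else 0.0
    return gc, oe, cpg


def exhaustive_islands(seq: str, p: IslandParams):
    """Recount every window from scratch, merge qualifying spans, filter."""
    spans = []
    for i in range(len(seq) - p.window + 1):
        gc, oe, _ = _stats(seq[i : i + p.window])
        if gc >= p.min_gc and oe >= p.min_obs_exp:
            if spans and i <= spans[-1][1]:
                spans[-1][1] = i + p.window
            else:
                spans.append([i, i + p.window])
    out = []
    for s, e in spans:
        if e - s >= p.min_length:
            gc, oe, n = _stats(seq[s:e])
            out.append(CpGIsland(s, e, gc, oe, n))
    return out
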