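"""Independent brute-force oracles used by the test suite.

The chain oracle enumerates every gap-valid chain by depth-first search over
anchor successors, independent of the production dynamic program.
"""

from __future__ import annotations


def brute_force_max_chain(
    anchors: list[tuple[int, int]], max_diff: int
) -> int:
    """Length of the longest gap-valid chain, either orientation, by
    exhaustive depth-first enumeration."""
    if not anchors:
        return 0
    best = 0
    for sign in (1, -1):
        pts = sorted((ra, sign * rb) for ra, rb in anchors)
        n = len(pts)

        def dfs(i: int, depth: int) -> None:
            nonlocal best
            best = max(best, depth)
            ra, rb = pts[i]
            for j in range(i + 1, n):
                xa, xb = pts[j]
                da, db = xa - ra, xb - rb
                if 1 <= da <= max_diff and 1 <= db <= max_diff:
                    dfs(j, depth + 1)

        for i in range(n):
            dfs(i, 1)
    return best
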