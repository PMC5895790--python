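"""Independent brute-force oracles used only by the test suite.

Written deliberately as plain, slow, textbook dynamic programming with no
shared code with the package, so agreement with the package's scorers is a
genuine two-route check.
"""

NEG = float("-inf")


def sw_affine_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> int:
    """Smith-Waterman local score; a gap of length k costs gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming b
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            if a[i - 1] == b[j - 1] and a[i - 1] in "ACGT":
                s = match
            else:
                s = mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


def gamma_literal(seq: str) -> dict[str, float]:
    """Trinucleotide relative abundance recomputed literally from raw
    circular, strand-summed string counts (dict arithmetic, no numpy)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(seq))

    def circ_counts(s: str, k: int) -> dict[str, int]:
        ext = s + s[: k - 1]
        out: dict[str, int] = {}
        for i in range(len(s)):
            mer = ext[i : i + k]
            out[mer] = out.get(mer, 0) + 1
        return out

    def gapped_counts(s: str) -> dict[str, int]:
        ext = s + s[:2]
        out: dict[str, int] = {}
        for i in range(len(s)):
            mer = ext[i] + ext[i + 2]
            out[mer] = out.get(mer, 0) + 1
        return out

    def merge(c1: dict, c2: dict) -> dict:
        out = dict(c1)
        for k, v in c2.items():
            out[k] = out.get(k, 0) + v
        return out

    c1 = merge(circ_counts(seq, 1), circ_counts(rc, 1))
    c2 = merge(circ_counts(seq, 2), circ_counts(rc, 2))
    c3 = merge(circ_counts(seq, 3), circ_counts(rc, 3))
    cg = merge(gapped_counts(seq), gapped_counts(rc))

    def freq(counts: dict) -> dict:
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}

    f1, f2, f3, fg = freq(c1), freq(c2), freq(c3), freq(cg)
    out = {}
    for x in "ACGT":
        for y in "ACGT":
            for z in "ACGT":
                mer = x + y + z
                if mer not in f3:
                    out[mer] = 0.0
                    continue
                out[mer] = (
                    f3[mer]
                    * f1.get(x, 0.0)
                    * f1.get(y, 0.0)
                    * f1.get(z, 0.0)
                    / (f2[x + y] * f2[y + z] * fg[x + z])
                )
    return out
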