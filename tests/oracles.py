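"""Independent brute-force oracles used to check the optimized paths.

These are deliberately plain-Python, unoptimized implementations kept
separate from the package so they share no code with what they verify.
"""

NEG = float("-inf")


def gotoh_local_score(query, ref, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Affine-gap local alignment score by the textbook Gotoh recurrence.

    A gap of length L costs ``gap_open + L * gap_extend``.  Returns
    ``(best_score, end_cells)`` where end_cells is the set of (ref_end,
    query_end) positions (1-based cell indices) achieving the best score.
    """
    n, m = len(ref), len(query)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (ref consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (query consumed)
    best, ends = 0.0, set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open + gap_extend, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open + gap_extend, F[i][j - 1] + gap_extend)
            s = match if ref[i - 1] == query[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, ends = H[i][j], {(i, j)}
            elif H[i][j] == best and best > 0:
                ends.add((i, j))
    return best, ends


def local_score_both_strands(query, ref, **kw):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(query))
    return max(gotoh_local_score(query, ref, **kw)[0], gotoh_local_score(rc, ref, **kw)[0])


def microhomology_oracle(host_terminus, vector_terminus):
    """All-overlaps scan: largest k with host suffix == vector prefix."""
    best = 0
    for k in range(1, min(len(host_terminus), len(vector_terminus)) + 1):
        ok = True
        for i in range(k):
            if host_terminus[len(host_terminus) - k + i] != vector_terminus[i]:
                ok = False
                break
        if ok:
            best = k
    return best


def category_oracle(host, chrom, pos):
    """Exhaustive interval-membership annotation, precedence
    exonic > promoter > downstream > intronic > intergenic."""
    in_exon = in_gene = in_prom = in_down = False
    n = len(host.sequences[chrom])
    for g in host.genes:
        if g.chrom != chrom:
            continue
        for lo, hi in g.exons:
            if lo <= pos < hi:
                in_exon = True
        if g.start <= pos < g.end:
            in_gene = True
        if max(0, g.start - host.promoter_extent) <= pos < g.start:
            in_prom = True
        if g.end <= pos < min(n, g.end + host.downstream_extent):
            in_down = True
    if in_exon:
        return "exonic"
    if in_prom:
        return "promoter"
    if in_down:
        return "downstream"
    if in_gene:
        return "intronic"
    return "intergenic"
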