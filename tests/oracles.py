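"""Independently coded brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions, in plain
Python, sharing no code with the package internals.
"""

import math
from bisect import bisect_right

# same documented definition as the package: below this dispersion the NB
# mass is the Poisson limit (part of the test's probability model)
ALPHA_POISSON = 1e-5
LOG_TIE_TOL = 1e-10


def nb_logpmf_scalar(k: int, mu: float, alpha: float) -> float:
    if mu <= 0:
        return 0.0 if k == 0 else float("-inf")
    if alpha < ALPHA_POISSON:
        return k * math.log(mu) - mu - math.lgamma(k + 1)
    r = 1.0 / alpha
    return (math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(r / (r + mu)) + k * math.log(mu / (r + mu)))


def exact_test_split_logprobs(N: int, s_a: float, s_b: float, alpha: float):
    mu_a = N * s_a / (s_a + s_b)
    mu_b = N * s_b / (s_a + s_b)
    return [nb_logpmf_scalar(a, mu_a, alpha)
            + nb_logpmf_scalar(N - a, mu_b, alpha) for a in range(N + 1)]


def exact_test_pvalues_for_total(N: int, s_a: float, s_b: float,
                                 alpha: float) -> list[float]:
    """p-value of every split (k, N - k), k = 0..N, by direct enumeration."""
    if N == 0:
        return [1.0]
    lp = exact_test_split_logprobs(N, s_a, s_b, alpha)
    m = max(lp)
    probs = [math.exp(v - m) for v in lp]
    order = sorted(range(N + 1), key=lambda a: lp[a])
    sorted_lp = [lp[a] for a in order]
    prefix = [0.0]
    for a in order:
        prefix.append(prefix[-1] + probs[a])
    total = prefix[-1]
    out = []
    for k in range(N + 1):
        cut = bisect_right(sorted_lp, lp[k] + LOG_TIE_TOL)
        out.append(min(1.0, prefix[cut] / total))
    return out


def exact_test_pvalue(k_a: int, k_b: int, s_a: float, s_b: float,
                      alpha: float) -> float:
    return exact_test_pvalues_for_total(k_a + k_b, s_a, s_b, alpha)[k_a]


def size_factors_by_definition(matrix) -> list[float]:
    """Median-of-ratios looped per definition; geometric mean rescaled to 1."""
    rows = [list(map(float, row)) for row in matrix]
    usable = [r for r in rows if all(v > 0 for v in r)]
    n = len(rows[0])
    factors = []
    for j in range(n):
        ratios = []
        for r in usable:
            gm = math.exp(sum(math.log(v) for v in r) / n)
            ratios.append(r[j] / gm)
        ratios.sort()
        mid = len(ratios) // 2
        med = (ratios[mid] if len(ratios) % 2
               else 0.5 * (ratios[mid - 1] + ratios[mid]))
        factors.append(med)
    gm_f = math.exp(sum(math.log(f) for f in factors) / n)
    return [f / gm_f for f in factors]


def merge_by_union_find(windows, max_gap: int = 0):
    """Partition significant windows into regions via union-find.

    ``windows``: list of (chrom, start, end, strand, direction).  Two windows
    join when same chrom/strand/direction and gap <= max_gap.  Returns the
    set of merged regions as tuples (chrom, start, end, strand, direction,
    n_windows).
    """
    n = len(windows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = windows[i], windows[j]
            if a[0] != b[0] or a[3] != b[3] or a[4] != b[4]:
                continue
            gap = max(a[1], b[1]) - min(a[2], b[2])
            if gap <= max_gap:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(windows[i])
    regions = set()
    for members in groups.values():
        chrom, _, _, strand, direction = members[0]
        regions.add((
            chrom, min(m[1] for m in members), max(m[2] for m in members),
            strand, direction, len(members),
        ))
    return regions


def classify_by_per_base(region, genes, stranded=True, tolerance=0):
    """Per-base membership classification.

    ``region``: (chrom, start, end, strand); ``genes``: mapping gene_id ->
    (chrom, start, end, strand, [exon (start, end), ...]).  Returns
    (class, host_gene or None) by counting exonic vs non-exonic bases of the
    region within the host (the gene sharing most bases with the region).
    """
    chrom, start, end, strand = region
    bases = set(range(start, end))
    best_host, best_ov = None, 0
    for gid in sorted(genes):
        gchrom, gstart, gend, gstrand, exons = genes[gid]
        if gchrom != chrom:
            continue
        if stranded and strand in "+-" and gstrand != strand:
            continue
        ov = len(bases & set(range(gstart, gend)))
        if ov > best_ov:
            best_host, best_ov = gid, ov
    if best_host is None or best_ov == 0:
        return "intergene", None
    exon_bases = set()
    for s, e in genes[best_host][4]:
        exon_bases |= set(range(s, e))
    e_count = len(bases & exon_bases)
    x_count = len(bases) - e_count
    e_eff = 0 if e_count <= tolerance else e_count
    x_eff = 0 if x_count <= tolerance else x_count
    if e_eff > 0 and x_eff > 0:
        cls = "exon_intron"
    elif x_eff == 0 and e_count > 0:
        cls = "complete_exon"
    elif e_eff == 0 and x_count > 0:
        cls = "intron"
    else:
        cls = "complete_exon" if e_count >= x_count else "intron"
    return cls, best_host
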