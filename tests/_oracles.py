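"""Independent brute-force reference implementations used as test oracles.

Everything here applies the decision clauses literally with plain loops
and no shared code with the package, so agreement is evidence the
package implements the stated rules.
"""

import math

import numpy as np


def brute_filter(counts, groups, min_reads, min_samples):
    """counts: feature->sample->int dict-of-dicts; groups: sample->group."""
    kept = set()
    all_groups = set(groups.values())
    for f, row in counts.items():
        for g in all_groups:
            n = sum(1 for s, c in row.items() if groups[s] == g and c > min_reads)
            if n >= min_samples:
                kept.add(f)
                break
    return kept


def brute_cv(values):
    vals = list(values)
    m = sum(vals) / len(vals)
    if m == 0:
        return math.inf
    var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
    return math.sqrt(var) / m


def brute_housekeeping(mean_expr, cv_max=1.0):
    """mean_expr: feature -> list of tissue means."""
    overall = {f: sum(v) / len(v) for f, v in mean_expr.items()}
    med = float(np.median(sorted(overall.values())))
    return {
        f
        for f in mean_expr
        if overall[f] > med and brute_cv(mean_expr[f]) < cv_max
    }


def brute_tissue_specific(mean_expr, rank_top=0.25, share_min=0.5, ratio_min=3.0):
    """Literal three-clause scan; mean_expr: feature -> list of tissue means."""
    features = list(mean_expr)
    n = len(features)
    n_tissues = len(next(iter(mean_expr.values())))
    out = {}
    for f in features:
        row = mean_expr[f]
        total = sum(row)
        for t in range(n_tissues):
            # clause (ii): share strictly above 0.5
            if total == 0 or row[t] / total <= share_min:
                continue
            # clause (i): top 25% by within-tissue rank of the mean
            smaller = sum(1 for g in features if mean_expr[g][t] < row[t])
            rank_q = smaller / (n - 1) if n > 1 else 1.0
            if rank_q < 1 - rank_top:
                continue
            # clause (iii): at least ratio_min times any other tissue
            other = max(row[:t] + row[t + 1:])
            if (other == 0 and row[t] > 0) or (other > 0 and row[t] >= ratio_min * other):
                out[f] = t
    return out


def brute_context(lnc_exons, lnc_strand, genes, window):
    """Literal precedence classifier.

    lnc_exons: list of (start, end); genes: list of
    (gene_id, strand, exons[(start, end)]) all on one chromosome.
    Returns (category, orientation, partner_gene).
    """
    span = (min(s for s, _ in lnc_exons), max(e for _, e in lnc_exons))

    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    def gspan(g):
        return (min(s for s, _ in g[2]), max(e for _, e in g[2]))

    def dist(a, b):
        if overlaps(a, b):
            return 0
        return b[0] - a[1] if a[1] <= b[0] else a[0] - b[1]

    def pick(cands):
        return min(cands, key=lambda g: (dist(span, gspan(g)), g[0]))

    def label(cat, g):
        if lnc_strand == "." or g[1] == ".":
            ori = "unassigned"
        else:
            ori = "sense" if lnc_strand == g[1] else "antisense"
        return cat, ori, g[0]

    exonic = [
        g for g in genes
        if any(overlaps(le, ce) for le in lnc_exons for ce in g[2])
    ]
    if exonic:
        return label("exonic", pick(exonic))
    intronic = [
        g for g in genes if gspan(g)[0] <= span[0] and span[1] <= gspan(g)[1]
    ]
    if intronic:
        return label("intronic", pick(intronic))

    def region_5p(g):
        s = gspan(g)
        if g[1] == "-":
            return (s[1], s[1] + window)
        return (max(0, s[0] - window), s[0])

    def region_3p(g):
        s = gspan(g)
        if g[1] == "-":
            return (max(0, s[0] - window), s[0])
        return (s[1], s[1] + window)

    up = [g for g in genes if region_5p(g)[0] < region_5p(g)[1]
          and overlaps(span, region_5p(g))]
    if up:
        return label("upstream", pick(up))
    down = [g for g in genes if region_3p(g)[0] < region_3p(g)[1]
            and overlaps(span, region_3p(g))]
    if down:
        return label("downstream", pick(down))
    return "intergenic", "unassigned", None


def brute_conserved(lifted, pig_spans, min_overlap=1):
    """lifted: list of (chrom, start, end, name); pig_spans: list of
    (chrom, start, end, id). Returns set of conserved names."""
    out = set()
    for chrom, s, e, name in lifted:
        for pc, ps, pe, _ in pig_spans:
            if pc == chrom and min(e, pe) - max(s, ps) >= min_overlap:
                out.add(name)
                break
    return out


def brute_cis(lnc_span, gene_spans, window):
    """gene_spans: gene_id -> (chrom, start, end); lnc_span likewise."""
    lc, ls, le = lnc_span
    out = []
    for gid, (gc, gs, ge) in gene_spans.items():
        if gc != lc:
            continue
        if ls < ge and gs < le:
            d = 0
        elif le <= gs:
            d = gs - le
        else:
            d = ls - ge
        if d <= window:
            out.append((gid, d))
    return sorted(out, key=lambda x: (x[1], x[0]))


def brute_hubs(stats, mm_min=0.8, gs_min=0.2):
    out = set()
    for feature, mm, gs in stats:
        if mm is None or gs is None:
            continue
        if abs(mm) > mm_min and abs(gs) > gs_min:
            out.add(feature)
    return out


def brute_de(rows, fdr=0.05, lfc=1.0):
    """rows: list of (feature, contrast, log2fc, p_adj). Returns DE keys."""
    return {
        (f, c)
        for f, c, l, p in rows
        if p < fdr and abs(l) >= lfc
    }


def brute_edge_filter(edges, score_min=140.0, energy_max=-20.0):
    return {
        (s, t)
        for s, t, score, energy in edges
        if score > score_min and energy < energy_max
    }


def brute_cerna(sponge_mirna, mirna_mrna):
    out = set()
    for s, m in sponge_mirna:
        for m2, g in mirna_mrna:
            if m == m2:
                out.add((s, m, g))
    return out


def brute_bh(p):
    """Quadratic min-over-suffix BH step-up, returned in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos, i in enumerate(order, start=1):
        candidates = [
            p[j] * m / k
            for k, j in enumerate(order, start=1)
            if k >= pos
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def brute_welch(a, b):
    """Textbook Welch t statistic and two-sided p from the t distribution."""
    from scipy.stats import t as tdist

    a, b = list(a), list(b)
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * tdist.sf(abs(t), df)


def brute_spearman(x, y):
    """Rank-transform (average ranks) then the Pearson formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
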