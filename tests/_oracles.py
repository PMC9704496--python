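"""Brute-force reference implementations of every repertoire metric.

Each function is a literal, loop-based transcription of the metric's
defining formula, operating on plain Python lists — no numpy, no pandas,
and no imports from the package under test. They are deliberately naive
(quadratic scans, explicit products) so they stay independent of the
optimized implementations they are used to check.
"""

import math


# ---------------------------------------------------------------- basic

def o_mean_freq(freqs):
    return sum(freqs) / len(freqs)


def o_geo_mean_freq(freqs):
    prod = 1.0
    for p in freqs:
        prod *= p
    return prod ** (1.0 / len(freqs))


def o_weighted_cdr3_len(lengths, freqs):
    return sum(l * p for l, p in zip(lengths, freqs))


def o_convergence(cdr3nts, cdr3aas):
    groups = {}
    for nt, aa in zip(cdr3nts, cdr3aas):
        groups.setdefault(aa, set()).add(nt)
    return sum(len(s) for s in groups.values()) / len(groups)


def o_spectratype(lengths, freqs):
    bins = {}
    for l, p in zip(lengths, freqs):
        bins[l] = bins.get(l, 0.0) + p
    return bins


# ------------------------------------------------------------ clonality

def o_pielou_clonality(freqs):
    n = len(freqs)
    if n == 1:
        return 1.0
    return 1.0 + sum(p * math.log(p) for p in freqs) / math.log(n)


def o_clonal_proportion(counts, percent):
    total = sum(counts)
    threshold = percent * total / 100.0
    cum = 0
    for k, c in enumerate(sorted(counts, reverse=True), start=1):
        cum += c
        if cum >= threshold - 1e-9:
            return k
    return len(counts)


def o_abundance_decomposition(freqs, bands):
    out = {label: 0.0 for label, _, _ in bands}
    for p in freqs:
        for label, lo, hi in bands:
            if lo < p <= hi:
                out[label] += p
                break
    return out


# ------------------------------------------------------------ diversity

def o_exp_shannon(freqs):
    return math.exp(sum(-(p * math.log(p)) for p in freqs))


def o_normalized_shannon(freqs):
    return o_exp_shannon(freqs) / math.log(len(freqs))


def o_inv_simpson(freqs):
    return 1.0 / sum(p * p for p in freqs)


def o_gini_simpson(freqs):
    return 1.0 - sum(p * p for p in freqs)


def o_d50(counts):
    n = len(counts)
    total = sum(counts)
    cum = 0
    for k, c in enumerate(sorted(counts, reverse=True), start=1):
        cum += c
        if 2 * cum >= total:
            return 100.0 * k / n
    return 100.0


def o_chao1(counts):
    s = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    estimate = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return estimate, float("nan")
    r = f1 / f2
    return estimate, f2 * (0.5 * r**2 + r**3 + 0.25 * r**4)


def o_gini_coefficient(freqs):
    n = len(freqs)
    ordered = sorted(freqs)
    area = 0.0
    y = 0.0
    for p in ordered:
        y_next = y + p
        area += (1.0 / n) * (y + y_next) / 2.0
        y = y_next
    return (0.5 - area) / 0.5


# ----------------------------------------------------------- gene usage

def o_segment_usage(labels, freqs, weighted):
    out = {}
    if weighted:
        for g, p in zip(labels, freqs):
            out[g] = out.get(g, 0.0) + p
    else:
        n = len(labels)
        for g in labels:
            out[g] = out.get(g, 0.0) + 1.0 / n
    return out


def o_vj_matrix(vs, js, freqs, weighted):
    out = {}
    n = len(vs)
    for v, j, p in zip(vs, js, freqs):
        w = p if weighted else 1.0 / n
        out[(v, j)] = out.get((v, j), 0.0) + w
    return out


# -------------------------------------------------------------- overlap
# Records are dicts with keys count/freq/cdr3nt/cdr3aa/v/d/j. Everything
# below is a naive quadratic scan over the record lists.

def _scan_aggregate(records, key_fields):
    """Aggregate records by key with a linear-search (no hashing) scan."""
    keys, counts, freqs = [], [], []
    for r in records:
        k = tuple(r[f] for f in key_fields)
        for i, existing in enumerate(keys):
            if existing == k:
                counts[i] += r["count"]
                freqs[i] += r["freq"]
                break
        else:
            keys.append(k)
            counts.append(r["count"])
            freqs.append(r["freq"])
    return keys, counts, freqs


def o_overlap_metrics(a_records, b_records, key_fields, alpha=0.5, beta=0.5):
    """All ten pairwise metrics by brute force; JSD handled separately."""
    a_keys, a_counts, a_freqs = _scan_aggregate(a_records, key_fields)
    b_keys, b_counts, b_freqs = _scan_aggregate(b_records, key_fields)
    X = sum(r["count"] for r in a_records)
    Y = sum(r["count"] for r in b_records)

    shared = []  # (x_count, y_count, x_freq, y_freq) in a-order
    for i, k in enumerate(a_keys):
        for j, k2 in enumerate(b_keys):
            if k == k2:
                shared.append((a_counts[i], b_counts[j], a_freqs[i], b_freqs[j]))
                break
    d_i, d_j, d_ij = len(a_keys), len(b_keys), len(shared)

    out = {
        "jaccard": d_ij / (d_i + d_j - d_ij),
        "overlap_coeff": d_ij / min(d_i, d_j),
        "tversky": d_ij / (alpha * (d_i - d_ij) + beta * (d_j - d_ij) + d_ij)
        if d_ij or (d_i - d_ij) or (d_j - d_ij) else float("nan"),
        "rel_overlap_div": d_ij / (d_i * d_j),
    }

    if d_ij == 0:
        out.update(morisita_horn=0.0, cosine=0.0, pearson=float("nan"),
                   geo_mean_overlap_freq=0.0, clonewise_geo_sum=0.0)
        return out

    xs = [t[0] for t in shared]
    ys = [t[1] for t in shared]
    pf = [t[2] for t in shared]
    qf = [t[3] for t in shared]

    num = 2 * sum(x * y for x, y in zip(xs, ys))
    den = (sum(x * x for x in xs) / (X * X) + sum(y * y for y in ys) / (Y * Y)) * X * Y
    out["morisita_horn"] = num / den

    out["cosine"] = sum(p * q for p, q in zip(pf, qf)) / math.sqrt(
        sum(p * p for p in pf) * sum(q * q for q in qf))

    if d_ij < 2:
        out["pearson"] = float("nan")
    else:
        mp = sum(pf) / d_ij
        mq = sum(qf) / d_ij
        sp = sum((p - mp) ** 2 for p in pf)
        sq = sum((q - mq) ** 2 for q in qf)
        if sp == 0.0 or sq == 0.0:
            out["pearson"] = float("nan")
        else:
            cov = sum((p - mp) * (q - mq) for p, q in zip(pf, qf))
            out["pearson"] = cov / math.sqrt(sp * sq)

    f_ij = sum(pf)
    f_ji = sum(qf)
    out["geo_mean_overlap_freq"] = math.sqrt(f_ij * f_ji)
    out["clonewise_geo_sum"] = sum(math.sqrt(p * q) for p, q in zip(pf, qf))
    return out


def o_jsd(p_vec, q_vec):
    """Jensen-Shannon divergence in bits over aligned vectors."""
    def kl(p, m):
        return sum(pi * math.log2(pi / mi) for pi, mi in zip(p, m) if pi > 0)
    m_vec = [(pi + qi) / 2.0 for pi, qi in zip(p_vec, q_vec)]
    return 0.5 * kl(p_vec, m_vec) + 0.5 * kl(q_vec, m_vec)


def o_jsd_v_usage(a_records, b_records):
    p_usage = {}
    for r in a_records:
        p_usage[r["v"]] = p_usage.get(r["v"], 0.0) + r["freq"]
    q_usage = {}
    for r in b_records:
        q_usage[r["v"]] = q_usage.get(r["v"], 0.0) + r["freq"]
    support = sorted(set(p_usage) | set(q_usage))
    return o_jsd([p_usage.get(g, 0.0) for g in support],
                 [q_usage.get(g, 0.0) for g in support])


# ---------------------------------------------------------------- motif

def o_kmer_counts(seqs, counts, k, weighted):
    out = {}
    for seq, c in zip(seqs, counts):
        for i in range(len(seq) - k + 1):
            motif = seq[i:i + k]
            out[motif] = out.get(motif, 0) + (c if weighted else 1)
    return out


# ---------------------------------------------------------------- stats

def o_bonferroni(p_values):
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
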