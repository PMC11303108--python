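"""Independent brute-force oracles used only by the test suite.

Each function recomputes a pipeline quantity by the most transparent method
available (all-pairs scans, per-element enumeration, bp-resolution masks,
full permutation enumeration) so the package implementation is checked
against logic that shares none of its code paths.
"""

from itertools import combinations

import numpy as np


def brute_force_gene_peak_overlap(genes, peaks, halfwidth):
    """All-pairs promoter-window/peak overlap: gene_ids with >= 1 bp overlap."""
    hits = set()
    for gene in genes:
        w_start = max(0, gene.tss - halfwidth)
        w_end = gene.tss + halfwidth + 1
        for p in peaks:
            if p.chrom == gene.interval.chrom and p.start < w_end and w_start < p.end:
                hits.add(gene.gene_id)
                break
    return frozenset(hits)


def brute_force_gate(per_mark_sets, activation_marks, repression_mark, universe):
    """Evaluate the gate formula per gene over an explicit universe."""
    out = set()
    for g in universe:
        if all(g in per_mark_sets[m] for m in activation_marks) and g not in per_mark_sets[repression_mark]:
            out.add(g)
    return frozenset(out)


def brute_force_exclusive(named_sets, target):
    """Per-element membership counting for condition-exclusive sets."""
    out = set()
    for g in named_sets[target]:
        n_memberships = sum(1 for members in named_sets.values() if g in members)
        if n_memberships == 1:
            out.add(g)
    return frozenset(out)


def brute_force_venn(named_sets):
    """Exact-region counts via per-element membership signatures."""
    from collections import Counter

    signature = Counter()
    universe = set().union(*named_sets.values()) if named_sets else set()
    for g in universe:
        members = tuple(sorted(n for n, s in named_sets.items() if g in s))
        signature[members] += 1
    counts = {}
    names = list(named_sets)
    for k in range(1, len(names) + 1):
        for combo in combinations(sorted(names), k):
            counts["&".join(combo)] = signature.get(tuple(sorted(combo)), 0)
    return counts


def bh_stepup(pvalues):
    """Benjamini-Hochberg step-up q-values, written from the definition:
    q_(i) = min_{j >= i} p_(j) * n / j on the p-sorted order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        running_min = min(running_min, p[order[rank - 1]] * n / rank)
        q_sorted[rank - 1] = running_min
    q = np.empty(n)
    q[order] = q_sorted
    return q


def mannwhitney_permutation_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group labelings,
    computing U by direct pairwise comparison (ties count 0.5)."""
    pooled = list(a) + list(b)
    n1 = len(a)
    n = len(pooled)

    def u_of(indices):
        group_a = [pooled[i] for i in indices]
        group_b = [pooled[i] for i in range(n) if i not in set(indices)]
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    mu = n1 * (n - n1) / 2
    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def scan_word_via_revcomp(sequence, word):
    """Positions of a word found by scanning the forward strand and by
    scanning the reverse complement and mapping positions back."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    seq = sequence.upper()
    rc = "".join(comp[c] for c in reversed(seq))
    fwd = {i for i in range(len(seq) - len(word) + 1) if seq[i : i + len(word)] == word}
    rev = {
        len(seq) - len(word) - i
        for i in range(len(rc) - len(word) + 1)
        if rc[i : i + len(word)] == word
    }
    return fwd, rev


def interval_set_to_mask(intervals, lo, hi):
    """bp-resolution boolean mask of an interval set over [lo, hi)."""
    mask = np.zeros(hi - lo, dtype=bool)
    for a, b in intervals:
        mask[max(a, lo) - lo : min(b, hi) - lo] = True
    return mask


def mask_to_interval_set(mask, lo):
    """Inverse of interval_set_to_mask: sorted disjoint intervals."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((lo + i, lo + j))
            i = j
        else:
            i += 1
    return tuple(out)
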