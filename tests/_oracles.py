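"""Independent brute-force oracles used to validate the package's algorithms.

Everything here is deliberately written from first principles (plain Python,
math.lgamma / math.comb) and never calls into the code paths it checks.
"""

import itertools
import math

import numpy as np


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def _lbeta(a, b):
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def dpm_partition_score(reads, blocks, alpha=1.0, a0=1.0, b0=1.0):
    """Collapsed Beta-Bernoulli DPM log score of a partition given as blocks."""
    reads = np.asarray(reads)
    n = reads.shape[1]
    score = len(blocks) * math.log(alpha)
    for block in blocks:
        sub = reads[list(block)]
        mc = len(block)
        score += math.lgamma(mc)  # log (mc-1)!
        for site in range(n):
            s = int(sub[:, site].sum())
            score += _lbeta(a0 + s, b0 + mc - s) - _lbeta(a0, b0)
    return score


def dpm_exhaustive_map(reads, alpha=1.0, a0=1.0, b0=1.0):
    """Best score over ALL set partitions of the reads."""
    m = np.asarray(reads).shape[0]
    return max(
        dpm_partition_score(reads, part, alpha, a0, b0)
        for part in set_partitions(list(range(m)))
    )


def db_statistic(g1, g2, tau=0.0, eps=1e-8, require_margin=False):
    """Plain-Python tau-adjusted inverse Davies-Bouldin separation score."""
    g1 = [list(map(float, r)) for r in g1]
    g2 = [list(map(float, r)) for r in g2]
    n = len(g1[0])
    p1 = [sum(r[l] for r in g1) / len(g1) for l in range(n)]
    p2 = [sum(r[l] for r in g2) / len(g2) for l in range(n)]
    diff = [p1[l] - p2[l] for l in range(n)]
    if require_margin and min(diff) <= tau:
        return 0.0
    dstar = math.sqrt(sum(max(d - tau, 0.0) ** 2 for d in diff))
    s1 = sum(
        math.sqrt(sum((r[l] - p1[l]) ** 2 for l in range(n))) for r in g1
    ) / len(g1)
    s2 = sum(
        math.sqrt(sum((r[l] - p2[l]) ** 2 for l in range(n))) for r in g2
    ) / len(g2)
    return dstar / (s1 + s2 + eps)


def exact_permutation_pvalue(reads, g1_indices, tau=0.0, require_margin=False):
    """Enumerate every same-size group assignment and rank the observed one."""
    reads = [list(r) for r in np.asarray(reads)]
    m = len(reads)
    n1 = len(g1_indices)
    obs = db_statistic(
        [reads[i] for i in g1_indices],
        [reads[i] for i in range(m) if i not in set(g1_indices)],
        tau,
        require_margin=require_margin,
    )
    count = total = 0
    for combo in itertools.combinations(range(m), n1):
        chosen = set(combo)
        stat = db_statistic(
            [reads[i] for i in combo],
            [reads[i] for i in range(m) if i not in chosen],
            tau,
            require_margin=require_margin,
        )
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p for [[a, b], [c, d]] by hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    total = row1 + row2

    def prob(k):
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(total, col1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


def best_bipartition_within_ss(points):
    """Minimum total within-cluster sum of squares over all 2-partitions."""
    points = np.asarray(points, dtype=float)
    m = len(points)
    best = math.inf
    # point 0 stays in cluster A, so both blocks are always nonempty
    for bits in range(1, 2 ** (m - 1)):
        mask = np.array(
            [False] + [(bits >> i) & 1 == 1 for i in range(m - 1)], dtype=bool
        )
        ss = 0.0
        for group in (points[mask], points[~mask]):
            center = group.mean(axis=0)
            ss += float(((group - center) ** 2).sum())
        best = min(best, ss)
    return best


def misclassification_bruteforce(labels, truth):
    """Min error over relabelings, by exhaustive mapping enumeration.

    One-to-one mappings when the prediction has at most as many labels as the
    truth, arbitrary (many-to-one) mappings when it has more.
    """
    labels = list(labels)
    truth = list(truth)
    pred_vals = sorted(set(labels))
    true_vals = sorted(set(truth))
    if len(pred_vals) <= len(true_vals):
        mappings = itertools.permutations(true_vals, len(pred_vals))
    else:
        mappings = itertools.product(true_vals, repeat=len(pred_vals))
    best = 1.0
    for assigned in mappings:
        mapping = dict(zip(pred_vals, assigned))
        err = sum(mapping[l] != t for l, t in zip(labels, truth)) / len(labels)
        best = min(best, err)
    return best
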