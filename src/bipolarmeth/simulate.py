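"""Simulation suite for validating the bipolar detector.

Three studies mirror the detector's validation design:

* Simulation I — type-I error and power.  Null segments draw one per-site
  methylation-probability vector from Beta(8, 8) (mean 0.5, SD 0.12) and all
  reads from it; alternative segments mix a hyper-methylated origin with
  site probabilities from Beta(5.96, 0.89) (mean 0.87) and a hypo-methylated
  origin from Beta(0.72, 4.42) (mean 0.14), each read choosing the hyper
  origin with probability ``w`` (the minority cell-type proportion).
* Simulation II — average p-values on a 16-read, 4-CpG segment containing
  ``i`` all-unmethylated and ``j`` all-methylated reads plus uniform filler
  over the 14 non-constant patterns.
* Simulation III — read-assignment accuracy of DPM MAP search versus plain
  k-means on the binary vectors and a collapsed-Gibbs finite Bernoulli
  mixture, measured by permutation-minimized misclassification rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import betaln, gammaln
from sklearn.cluster import KMeans

from .detect import detect_bipolar
from .dpm import ClusterPartition, DpmConfig, _as_reads
from .io import OriginModel, SegmentReadMatrix

__all__ = [
    "SimDesign",
    "PowerTableCell",
    "beta_mean_sd",
    "simulate_segment",
    "simulate_labeled_segment",
    "estimate_rates",
    "simulate_pattern_counts",
    "average_pvalue_grid",
    "kmeans_binary",
    "bernoulli_mixture_cluster",
    "misclassification_rate",
    "clustering_comparison",
]


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulation cell.

    ``w`` is the proportion of the hyper-methylated origin under the
    alternative; the Beta hyperparameters are the study conditions for the
    null and the two bipolar origins.
    """

    m: int = 16
    n: int = 4
    w: float = 0.5
    null_beta: tuple[float, float] = (8.0, 8.0)
    hyper_beta: tuple[float, float] = (5.96, 0.89)
    hypo_beta: tuple[float, float] = (0.72, 4.42)
    delta: float = 0.35
    tau: float = 0.32
    reps: int = 500
    alpha_level: float = 0.05
    permutations: int = 199
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.w <= 0.5):
            raise ValueError("w must lie in (0, 0.5]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        for a, b in (self.null_beta, self.hyper_beta, self.hypo_beta):
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be positive")


@dataclass
class PowerTableCell:
    """Empirical rejection rate (type-I error or power) for one design cell."""

    design: SimDesign
    hypothesis: str  # "null" | "alternative"
    rate: float
    se: float
    reps: int


def beta_mean_sd(a: float, b: float) -> tuple[float, float]:
    """Mean and standard deviation of a Beta(a, b) distribution."""
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    return mean, float(np.sqrt(var))


def _origin_model(design: SimDesign, hypothesis: str, rng: np.random.Generator) -> OriginModel:
    if hypothesis == "null":
        p = rng.beta(*design.null_beta, size=design.n)
        return OriginModel(P=p[:, None], q=np.array([1.0]))
    if hypothesis == "alternative":
        p_hyper = rng.beta(*design.hyper_beta, size=design.n)
        p_hypo = rng.beta(*design.hypo_beta, size=design.n)
        return OriginModel(
            P=np.column_stack([p_hyper, p_hypo]),
            q=np.array([design.w, 1.0 - design.w]),
        )
    raise ValueError("hypothesis must be 'null' or 'alternative'")


def _segment_from_reads(reads: np.ndarray) -> SegmentReadMatrix:
    n = reads.shape[1]
    return SegmentReadMatrix(
        chrom="sim", cpg_positions=np.arange(n) * 2, reads=reads
    )


def simulate_segment(
    design: SimDesign, hypothesis: str, rng: np.random.Generator
) -> SegmentReadMatrix:
    """Draw one segment from the hierarchical origin model.

    Probability vectors are redrawn fresh for every call, so replicates are
    exchangeable draws from the stated priors.
    """
    model = _origin_model(design, hypothesis, rng)
    reads, _ = model.sample(design.m, rng)
    return _segment_from_reads(reads)


def simulate_labeled_segment(
    design: SimDesign, rng: np.random.Generator
) -> tuple[SegmentReadMatrix, np.ndarray]:
    """Alternative-hypothesis segment together with true origin labels."""
    model = _origin_model(design, "alternative", rng)
    reads, origins = model.sample(design.m, rng)
    return _segment_from_reads(reads), origins


def _default_detector(design: SimDesign):
    def detector(segment, rng):
        return detect_bipolar(
            segment,
            delta=design.delta,
            tau=design.tau,
            permutations=design.permutations,
            significance_level=design.alpha_level,
            rng=rng,
        ).p_value

    return detector


def estimate_rates(
    design: SimDesign, hypothesis: str, detector=None
) -> PowerTableCell:
    """Empirical rejection rate of the detector over ``design.reps`` segments.

    ``detector(segment, rng) -> p-value`` defaults to the full two-step
    pipeline with the design's delta/tau/permutations.  Per-replicate RNG
    streams are spawned deterministically from ``design.seed``.
    """
    detector = detector or _default_detector(design)
    children = np.random.SeedSequence(design.seed).spawn(design.reps)
    hits = 0
    for child in children:
        rng = np.random.default_rng(child)
        segment = simulate_segment(design, hypothesis, rng)
        if detector(segment, rng) <= design.alpha_level:
            hits += 1
    rate = hits / design.reps
    se = float(np.sqrt(rate * (1 - rate) / design.reps))
    return PowerTableCell(
        design=design, hypothesis=hypothesis, rate=rate, se=se, reps=design.reps
    )


# ---------------------------------------------------------------------------
# Simulation II: (i, j) pattern grids
# ---------------------------------------------------------------------------

_NONCONSTANT_PATTERNS = np.array(
    [p for p in itertools.product((0, 1), repeat=4) if 0 < sum(p) < 4], dtype=np.int8
)  # the 14 4-bit patterns that are neither 0000 nor 1111


def simulate_pattern_counts(
    i: int, j: int, total: int = 16, rng: np.random.Generator | None = None
) -> SegmentReadMatrix:
    """Segment with ``i`` all-zero reads, ``j`` all-one reads and uniform filler.

    The remaining ``total - i - j`` reads are drawn uniformly from the 14
    non-constant 4-bit methylation patterns.
    """
    if i < 0 or j < 0 or i + j > total:
        raise ValueError("need i, j >= 0 and i + j <= total")
    rng = np.random.default_rng(rng)
    rows = [np.zeros((i, 4), dtype=np.int8), np.ones((j, 4), dtype=np.int8)]
    n_fill = total - i - j
    if n_fill:
        rows.append(_NONCONSTANT_PATTERNS[rng.integers(0, 14, size=n_fill)])
    return _segment_from_reads(np.vstack(rows))


def average_pvalue_grid(
    cells: list[tuple[int, int]],
    deltas=(0.2, 0.25, 0.3, 0.35, 0.4),
    tau: float = 0.32,
    reps: int = 100,
    total: int = 16,
    permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean detector p-value per (i, j, delta) over ``reps`` replicates.

    Returns a tidy DataFrame with columns i, j, delta, mean_p, reps.  The same
    simulated segments are reused across delta values within one (i, j) cell.
    """
    records = []
    root = np.random.SeedSequence(seed)
    for (i, j), cell_ss in zip(cells, root.spawn(len(cells))):
        rep_children = cell_ss.spawn(reps)
        mean_p = {d: 0.0 for d in deltas}
        for child in rep_children:
            seg_rng = np.random.default_rng(child)
            segment = simulate_pattern_counts(i, j, total=total, rng=seg_rng)
            for d in deltas:
                p = detect_bipolar(
                    segment,
                    delta=d,
                    tau=tau,
                    permutations=permutations,
                    rng=np.random.default_rng(child.spawn(1)[0]),
                ).p_value
                mean_p[d] += p
        for d in deltas:
            records.append(
                {"i": i, "j": j, "delta": d, "mean_p": mean_p[d] / reps, "reps": reps}
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Simulation III: competing clustering methods
# ---------------------------------------------------------------------------

def kmeans_binary(
    segment, k: int = 2, restarts: int = 10, seed: int = 0
) -> ClusterPartition:
    """Lloyd's k-means on the raw binary read vectors (best of ``restarts``).

    Degenerate duplicate centers are compacted away, so fewer than k clusters
    may be returned on ties (e.g. all-identical reads give one cluster).
    """
    reads = _as_reads(segment)
    if reads.shape[0] < k:
        raise ValueError("need at least k reads")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(reads.astype(float))
    return _partition_from_labels(reads, labels)


def _partition_from_labels(reads: np.ndarray, labels: np.ndarray) -> ClusterPartition:
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=np.int64)
    for idx, lab in enumerate(labels):
        if int(lab) not in mapping:
            mapping[int(lab)] = len(mapping)
        out[idx] = mapping[int(lab)]
    k = len(mapping)
    means = np.vstack([reads[out == c].mean(axis=0) for c in range(k)])
    sizes = np.bincount(out, minlength=k)
    return ClusterPartition(labels=out, cluster_means=means, cluster_sizes=sizes)


def _bmm_joint_score(reads, labels, k, a0, b0, dir_alpha):
    """Collapsed log joint P(X, z) of a finite Bernoulli mixture (up to const)."""
    m, n = reads.shape
    score = 0.0
    for c in range(k):
        sub = reads[labels == c]
        score += float(gammaln(sub.shape[0] + dir_alpha))
        if sub.shape[0]:
            s = sub.sum(axis=0)
            score += float(
                np.sum(betaln(a0 + s, b0 + sub.shape[0] - s)) - n * betaln(a0, b0)
            )
    return score


def bernoulli_mixture_cluster(
    segment,
    k: int = 2,
    n_iters: int = 80,
    burn_in: int = 20,
    a0: float = 1.0,
    b0: float = 1.0,
    dir_alpha: float = 1.0,
    seed: int | None = 0,
) -> ClusterPartition:
    """Finite product-Bernoulli mixture fit by collapsed Gibbs sampling.

    Sites carry Beta(a0, b0) priors and the mixture weights a symmetric
    Dirichlet(dir_alpha) prior; components are integrated out so only the
    label vector is sampled.  The labeling with the highest collapsed joint
    posterior among the post-burn-in sweeps is returned (empty components are
    compacted away).
    """
    reads = _as_reads(segment).astype(float)
    m, n = reads.shape
    if m < 2:
        raise ValueError("need at least two reads")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, k, size=m)
    S = np.vstack([reads[labels == c].sum(axis=0) for c in range(k)])
    sizes = np.bincount(labels, minlength=k).astype(float)

    best_labels = labels.copy()
    best_score = _bmm_joint_score(reads, labels, k, a0, b0, dir_alpha)
    for sweep in range(n_iters):
        for i in range(m):
            c = labels[i]
            x = reads[i]
            S[c] -= x
            sizes[c] -= 1
            # predictive log-prob of read i under each component's posterior
            with np.errstate(divide="ignore"):
                logp = (
                    np.log(sizes + dir_alpha)
                    + (
                        x * np.log(a0 + S)
                        + (1 - x) * np.log(b0 + (sizes[:, None] - S))
                        - np.log(a0 + b0 + sizes[:, None])
                    ).sum(axis=1)
                )
            logp -= logp.max()
            prob = np.exp(logp)
            c_new = rng.choice(k, p=prob / prob.sum())
            labels[i] = c_new
            S[c_new] += x
            sizes[c_new] += 1
        if sweep >= burn_in:
            score = _bmm_joint_score(reads, labels, k, a0, b0, dir_alpha)
            if score > best_score:
                best_score = score
                best_labels = labels.copy()
    return _partition_from_labels(reads, best_labels)


def misclassification_rate(labels, truth) -> float:
    """Label-permutation-minimized fraction of misassigned reads.

    When predicted and true label sets have the same cardinality the optimal
    one-to-one relabeling is used (for two classes this is min(err, 1 - err));
    when the prediction has more clusters than the truth, each predicted
    cluster is mapped to its majority true class (many-to-one), the natural
    extension for methods free to open extra clusters.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    m = labels.size
    pred_vals = np.unique(labels)
    true_vals = np.unique(truth)
    conf = np.zeros((pred_vals.size, true_vals.size))
    for a, pv in enumerate(pred_vals):
        for b, tv in enumerate(true_vals):
            conf[a, b] = np.sum((labels == pv) & (truth == tv))
    if pred_vals.size <= true_vals.size:
        rows, cols = linear_sum_assignment(conf, maximize=True)
        matched = conf[rows, cols].sum()
    else:
        matched = conf.max(axis=1).sum()
    return float(1.0 - matched / m)


def clustering_comparison(
    ms=(10, 20, 100),
    ws=(0.1, 0.2, 0.3, 0.4, 0.5),
    reps: int = 200,
    methods=("dpm", "kmeans", "bayes_mixture"),
    design: SimDesign | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean misclassification rate per (m, w, method) under the alternative.

    Every method sees the same simulated segments; truth is the origin
    indicator of each read.  Returns a tidy DataFrame with columns m, w,
    method, mean_misclassification, reps.
    """
    base = design or SimDesign()
    records = []
    root = np.random.SeedSequence(seed)
    cells = [(m, w) for m in ms for w in ws]
    for (m, w), cell_ss in zip(cells, root.spawn(len(cells))):
        cell_design = replace(base, m=m, w=w)
        sums = {meth: 0.0 for meth in methods}
        for child in cell_ss.spawn(reps):
            rng = np.random.default_rng(child)
            segment, truth = simulate_labeled_segment(cell_design, rng)
            seeds = {meth: int(rng.integers(2**31)) for meth in methods}
            for meth in methods:
                if meth == "dpm":
                    from .dpm import dpm_map_search

                    part = dpm_map_search(segment, DpmConfig(seed=seeds[meth]))
                elif meth == "kmeans":
                    part = kmeans_binary(segment, seed=seeds[meth])
                elif meth == "bayes_mixture":
                    part = bernoulli_mixture_cluster(segment, seed=seeds[meth])
                else:
                    raise ValueError(f"unknown method {meth!r}")
                sums[meth] += misclassification_rate(part.labels, truth)
        for meth in methods:
            records.append(
                {
                    "m": m,
                    "w": w,
                    "method": meth,
                    "mean_misclassification": sums[meth] / reps,
                    "reps": reps,
                }
            )
    return pd.DataFrame.from_records(records)
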