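"""Per-segment two-step bipolar methylation detector.

Step 1: cluster the segment's reads with DPM MAP search and reduce the
clusters to a hyper and a hypo group (delta candidate rule, with a 2-means
fallback at low coverage or when no cluster passes the delta criterion).
Step 2: calibrate the separation of the two groups with the tau-adjusted
permutation test.  Segments whose reads form a single cluster (or whose
cluster means are indistinguishable) are trivially non-bipolar (p = 1).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .dpm import DpmConfig, _as_reads, dpm_map_search
from .grouping import (
    form_candidate_groups,
    kmeans_fallback_groups,
    reduce_to_bipolar_groups,
)
from .permtest import BipolarTestResult, permutation_pvalue, shortcut_result

__all__ = ["detect_bipolar"]


def detect_bipolar(
    segment,
    delta: float = 0.35,
    tau: float = 0.32,
    permutations: int = 999,
    dpm_config: DpmConfig | None = None,
    fallback_min_reads: int = 10,
    significance_level: float = 0.05,
    rng: np.random.Generator | int | None = None,
    return_details: bool = False,
):
    """Test one segment for bipolar methylation.

    Parameters
    ----------
    segment
        A :class:`~bipolarmeth.io.SegmentReadMatrix` or raw (m, n) 0/1 array.
    delta
        Candidate-group threshold: cluster means site-wise <= delta are hypo
        candidates, >= 1 - delta hyper candidates.
    tau
        Separation margin of the alternative hypothesis (per-site mean
        difference must exceed tau); larger tau is more conservative.
    permutations
        Monte-Carlo permutation count (exact enumeration replaces it when
        feasible).
    fallback_min_reads
        Below this read count the 2-means-on-cluster-means fallback is used
        instead of the delta candidate rule; at or above it the fallback
        still engages when the delta rule finds no candidates.  Fallback
        groups are tested with the all-site tau margin required
        (``require_margin`` in the permutation test), delta candidates
        without it.
    rng
        Seed or Generator driving the DPM restarts, the fallback k-means and
        the permutations; results are reproducible given it.
    return_details
        If true, return ``(result, partition, groups)`` instead of just the
        :class:`~bipolarmeth.permtest.BipolarTestResult`.
    """
    reads = _as_reads(segment)
    rng = np.random.default_rng(rng)
    cfg = dpm_config or DpmConfig()
    cfg = replace(cfg, seed=int(rng.integers(2**31)))
    kmeans_seed = int(rng.integers(2**31))

    partition = dpm_map_search(reads, cfg)

    groups = None
    require_margin = True
    if partition.k >= 2:
        if reads.shape[0] >= fallback_min_reads:
            hyper_idx, hypo_idx = form_candidate_groups(partition, delta)
            if hyper_idx.size and hypo_idx.size:
                groups = reduce_to_bipolar_groups(reads, hyper_idx, hypo_idx, delta)
                # delta-rule candidates certify >= 1 - 2*delta separation at
                # every site, so no additional margin check is imposed
                require_margin = False
        if groups is None:
            # 2-means fallback groups carry no separation certificate; the
            # test additionally demands the all-site tau margin (the literal
            # alternative hypothesis), which keeps spurious splits of
            # homogeneous segments from registering as bipolar
            groups = kmeans_fallback_groups(reads, partition, seed=kmeans_seed)

    if groups is None:
        result: BipolarTestResult = shortcut_result(tau, significance_level)
    else:
        result = permutation_pvalue(
            reads,
            groups,
            tau=tau,
            n_permutations=permutations,
            rng=rng,
            significance_level=significance_level,
            require_margin=require_margin,
        )
    if return_details:
        return result, partition, groups
    return result
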