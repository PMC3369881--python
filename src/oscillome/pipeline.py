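"""End-to-end workflow: simulate -> DFT -> cluster -> consensus.

Glue used by the command-line interface, the examples and the acceptance
checks.  Each step is a thin call into the corresponding module; the only
policy encoded here is the order of operations and the pre-clustering
filter (genes must be significantly periodic in an experiment to enter its
clustering; the rest are background for that experiment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cluster as cl
from . import fourier
from .synthgen import OscillomeSpec, generate_oscillome

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    features: tuple            # per-experiment feature tables
    assignments: tuple         # per-experiment sorted ClusterAssignments
    consensus: cl.OverlapConsensus
    truth: pd.DataFrame | None = None


def cluster_experiment(
    features: pd.DataFrame,
    k_osc: int,
    K_range,
    p_filter: float = 0.05,
    seed: int = 0,
    restarts: int = 8,
    lam: float | None = None,
    nu: float = 4.0,
) -> cl.ClusterAssignment:
    """Cluster one experiment's Fourier features and phase-sort the labels.

    Genes with permutation p-value above ``p_filter`` are treated as
    non-periodic background for this experiment and excluded from the EM
    fit.  K is selected by BIC over ``K_range`` (periodic genes that leak
    through the filter — e.g. via shared array artifacts — tend to claim a
    mixture component of their own, so the range should extend past the
    expected cohort count).  The fitted clusters are sorted by their
    circular phase-density peaks, anchored at the largest cluster.
    """
    periodic = features.index[features["p_perm"] <= p_filter]
    feats = fourier.clustering_features(features.loc[periodic])
    K, fits = cl.select_K_bic(feats, K_range, nu=nu, lam=lam, seed=seed,
                              restarts=restarts)
    model, assign = fits[K]
    phases = pd.Series(np.rad2deg(features.loc[periodic, f"phi_{k_osc}"]) % 360.0,
                       index=periodic)
    anchor = assign.sizes.idxmax()
    sorted_assign = cl.sort_and_relabel(assign, phases, anchor_label=anchor)
    logger.info("experiment clustering: %d periodic genes, K=%d (BIC), lambda=%.3f, peaks=%s",
                len(periodic), K, model.lam, sorted_assign.peaks)
    return sorted_assign


def run_synthetic_pipeline(
    spec: OscillomeSpec | None = None,
    K_range=None,
    n_permutations: int = 199,
    p_filter: float = 0.05,
    p_threshold: float = 1e-3,
    seed: int = 0,
    restarts: int = 8,
    lam: float | None = None,
) -> PipelineResult:
    """Simulate the two experiments and recover consensus co-expression cohorts.

    Each experiment is clustered on the scaled real/imaginary parts of its
    phenotypic DFT component, with K chosen by BIC over ``K_range``
    (default: planted cohort count -1 .. +2) and the Box-Cox exponent free.
    The consensus label map is derived automatically from mutually-best
    significant overlap cells.
    """
    spec = spec or OscillomeSpec(seed=seed)
    exp1, exp2, truth = generate_oscillome(spec)
    if K_range is None:
        k0 = len(spec.cluster_phases)
        K_range = range(max(2, k0 - 1), k0 + 3)
    feats, assigns = [], []
    for i, exp in enumerate((exp1, exp2)):
        f = fourier.fourier_features(exp.matrix, k_osc=exp.k_osc,
                                     components=[exp.k_osc],
                                     n_permutations=n_permutations,
                                     seed=seed + 17 * (i + 1))
        feats.append(f)
        assigns.append(cluster_experiment(f, k_osc=exp.k_osc, K_range=K_range,
                                          p_filter=p_filter,
                                          seed=seed + 101 * (i + 1),
                                          restarts=restarts, lam=lam))
    labels_a, labels_b = assigns[0].labels, assigns[1].labels
    label_map = cl.auto_label_map(labels_a, labels_b, p_threshold=p_threshold)
    consensus = cl.overlap_consensus(labels_a, labels_b, label_map,
                                     p_threshold=p_threshold,
                                     universe=truth.index)
    return PipelineResult(features=tuple(feats), assignments=tuple(assigns),
                          consensus=consensus, truth=truth)


def consensus_recovery_score(result: PipelineResult) -> float:
    """Adjusted Rand index between consensus labels and the planted cohorts.

    Background genes count as their own class on both sides, so spurious
    cluster labels on planted background genes lower the score.
    """
    truth = result.truth["cohort"]
    pred = result.consensus.consensus.loc[truth.index]
    return adjusted_rand_index(truth.to_numpy(), pred.to_numpy())


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    from scipy.special import comb
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    n = ct.sum()
    sum_cells = comb(ct, 2).sum()
    sum_rows = comb(ct.sum(axis=1), 2).sum()
    sum_cols = comb(ct.sum(axis=0), 2).sum()
    expected = sum_rows * sum_cols / comb(n, 2)
    max_index = (sum_rows + sum_cols) / 2
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))
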