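"""Cluster-based permutation tests on sensor topographies and SOI selection.

The multiple-comparisons control is the standard nonparametric construction
for sensor-level electrophysiology: compute a paired t statistic per
chipset, keep chipsets whose t exceeds the unilateral t(n-1) quantile at the
cluster-forming alpha, group them into spatially connected clusters over the
sensor neighbour graph, score each cluster by the sum of its t values
("maxsum" mass), and compare observed masses against the Monte-Carlo null of
the maximum cluster mass under random within-subject sign flips.

Sensor-of-interest (SOI) rules — per-chipset one-sample permutation tests
against the SNR baseline of 1 (uncorrected), and plain SNR thresholding —
live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "ClusterResult",
    "paired_cluster_test",
    "one_sample_soi_test",
    "threshold_soi",
]


@dataclass
class Cluster:
    chipsets: tuple[int, ...]
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_perm: int
    cluster_alpha: float
    t_threshold: float
    t_obs: np.ndarray
    tail: str = "greater"

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "cluster_alpha": self.cluster_alpha,
            "t_threshold": self.t_threshold,
            "tail": self.tail,
            "clusters": [
                {"chipsets": list(c.chipsets), "mass": c.mass, "p": c.p}
                for c in self.clusters
            ],
        }


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Per-column one-sample t of paired differences; 0/0 defined as 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    # degenerate zero-variance, nonzero-mean columns: large finite t
    t[np.isinf(t)] = np.sign(mean[np.isinf(t)]) * 1e9
    return t


def _perm_t(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for all sign-flip permutations, vectorised.

    Sign flips leave the per-column mean square invariant, so the permuted
    variance follows from the permuted mean alone.
    """
    n = diff.shape[0]
    m2 = np.mean(diff**2, axis=0)  # (n_sensors,)
    mp = signs @ diff / n  # (n_perm, n_sensors)
    var = np.clip((m2 - mp**2) * n / (n - 1), 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mp / np.sqrt(var / n)
    bad = ~np.isfinite(t)
    t[bad] = np.sign(mp[bad]) * 1e9
    return t


def _clusters_from_mask(mask: np.ndarray, graph: nx.Graph, t: np.ndarray):
    nodes = np.flatnonzero(mask)
    if nodes.size == 0:
        return []
    sub = graph.subgraph(nodes.tolist())
    return [tuple(sorted(c)) for c in nx.connected_components(sub)]


def _max_cluster_mass(t_row: np.ndarray, thresh: float, graph: nx.Graph) -> float:
    comps = _clusters_from_mask(t_row > thresh, graph, t_row)
    if not comps:
        return 0.0
    return max(float(t_row[list(c)].sum()) for c in comps)


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator, exact_limit: int = 12):
    """Random +/-1 matrix, or the full 2^n enumeration when n is small enough
    and the caller asked for at least that many permutations."""
    if n <= exact_limit and n_perm >= 2**n:
        grid = np.indices((2,) * n).reshape(n, -1).T
        return 2 * grid - 1, True
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def paired_cluster_test(
    topo_a: np.ndarray,
    topo_b: np.ndarray,
    graph: nx.Graph,
    n_perm: int = 10_000,
    cluster_alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Paired cluster permutation test of condition A > condition B.

    ``topo_a``/``topo_b`` are (n_subjects, n_chipsets) per-subject
    topographies with matched rows. The test is unilateral (A > B, the
    direction of an SNR increase). Cluster p-values use the plus-one
    Monte-Carlo estimator, so p is never exactly 0; when 2^n <= n_perm the
    sign-flip null is enumerated exhaustively instead of sampled.
    """
    topo_a = np.asarray(topo_a, dtype=np.float64)
    topo_b = np.asarray(topo_b, dtype=np.float64)
    if topo_a.shape != topo_b.shape:
        raise ValueError("condition topographies must have matching shape")
    n = topo_a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if topo_a.shape[1] != graph.number_of_nodes():
        raise ValueError("topography length does not match the sensor graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    diff = topo_a - topo_b
    t_obs = _paired_t(diff)
    thresh = float(stats.t.ppf(1.0 - cluster_alpha, df=n - 1))
    comps = _clusters_from_mask(t_obs > thresh, graph, t_obs)
    masses = [float(t_obs[list(c)].sum()) for c in comps]

    signs, exact = _sign_matrix(n, n_perm, rng)
    t_perm = _perm_t(diff, signs)
    null_max = np.fromiter(
        (_max_cluster_mass(row, thresh, graph) for row in t_perm),
        dtype=np.float64,
        count=t_perm.shape[0],
    )
    n_eff = len(null_max)
    clusters = []
    for c, m in sorted(zip(comps, masses), key=lambda cm: -cm[1]):
        # the identity flip reproduces the observed mass only up to
        # round-off, so compare with a relative tolerance
        tol = 1e-9 * max(1.0, abs(m))
        if exact:
            p = float(np.mean(null_max >= m - tol))
        else:
            p = float((1 + np.sum(null_max >= m - tol)) / (1 + n_eff))
        clusters.append(Cluster(chipsets=c, mass=m, p=p))
    return ClusterResult(
        clusters=clusters,
        n_perm=n_eff,
        cluster_alpha=cluster_alpha,
        t_threshold=thresh,
        t_obs=t_obs,
    )


def one_sample_soi_test(
    topos: np.ndarray,
    baseline: float = 1.0,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    return_p: bool = False,
) -> np.ndarray:
    """Per-chipset sign-flip test of mean(SNR - baseline) > 0, uncorrected.

    Returns the boolean mask of chipsets significant at ``alpha`` (or the
    per-chipset p-values when ``return_p``); used to pick tritone-response
    sensors of interest.
    """
    topos = np.asarray(topos, dtype=np.float64)
    if topos.ndim != 2 or topos.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_chipsets) array")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diff = topos - baseline
    t_obs = _paired_t(diff)
    signs, exact = _sign_matrix(topos.shape[0], n_perm, rng)
    t_perm = _perm_t(diff, signs)
    tol = 1e-9 * np.maximum(1.0, np.abs(t_obs))
    if exact:
        p = np.mean(t_perm >= t_obs - tol, axis=0)
    else:
        p = (1 + np.sum(t_perm >= t_obs - tol, axis=0)) / (1 + t_perm.shape[0])
    if return_p:
        return p
    return p < alpha


def threshold_soi(topo: np.ndarray, threshold: float) -> np.ndarray:
    """Plain SNR-threshold sensor selection on a group-mean topography."""
    return np.asarray(topo) > threshold
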