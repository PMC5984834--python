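"""Strain x GCF presence/absence profiling.

Strains are clustered on their family repertoires with the Dice
coefficient and UPGMA (distance = 1 - Dice), and family richness per
phylogenetic group is summarised by sample-based rarefaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .families import GcfPartition
from .model import ValidationError


def presence_absence(
    partition: GcfPartition, strains: Sequence[str]
) -> pd.DataFrame:
    """Binary strain-by-family matrix.

    Entry (s, f) is 1 iff family f has at least one member BGC in strain
    s (copy number is not recorded).  Columns are ordered by consensus
    class and then by descending abundance, the layout of a
    presence/absence map sorted per class.
    """
    strains = list(strains)
    fam_ids = partition.family_ids
    data = np.zeros((len(strains), len(fam_ids)), dtype=int)
    for j, fid in enumerate(fam_ids):
        for i, s in enumerate(strains):
            if s in partition.strains[fid]:
                data[i, j] = 1
    df = pd.DataFrame(data, index=strains, columns=fam_ids)
    order = sorted(
        fam_ids,
        key=lambda f: (
            partition.consensus_class[f],
            -int(df[f].sum()),
            f,
        ),
    )
    return df[order]


def dice_similarity(row_a: Sequence[int], row_b: Sequence[int]) -> float:
    """Dice coefficient 2|A&B| / (|A|+|B|) over present families.

    Two strains sharing nothing — including the degenerate case of two
    all-zero rows — score 0.
    """
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(
            f"row length mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def dice_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-vs-all 1 - Dice distances between the rows of a binary matrix."""
    n = matrix.shape[0]
    vals = matrix.to_numpy(dtype=bool)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - dice_similarity(vals[i], vals[j])
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ------------------------------------------------------------------ UPGMA


@dataclass
class UpgmaTree:
    """Result of a UPGMA agglomeration over n leaves.

    ``merges`` lists (i, j, height, new_index) in merge order, with
    cluster indices 0..n-1 for leaves and n.. for internal nodes; node
    height is half the merge distance so the tree is ultrametric.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def newick(self) -> str:
        return _to_newick(self.labels, self.merges)

    def cut(self, k: int) -> list[set[str]]:
        """Partition the leaves into k groups by undoing the last k-1
        merges."""
        n = len(self.labels)
        if not (1 <= k <= n):
            raise ValidationError(f"cannot cut {n}-leaf tree into {k} groups")
        groups: dict[int, set[str]] = {i: {lab} for i, lab in enumerate(self.labels)}
        for i, j, _, new in self.merges[: n - k]:
            groups[new] = groups.pop(i) | groups.pop(j)
        return sorted(groups.values(), key=lambda s: sorted(s)[0])

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (all equal for an ultrametric tree)."""
        if not self.merges:
            return {lab: 0.0 for lab in self.labels}
        root_h = self.merges[-1][2]
        return {lab: root_h for lab in self.labels}


def upgma(distance: pd.DataFrame | np.ndarray,
          labels: Optional[Sequence[str]] = None) -> UpgmaTree:
    """Average-linkage agglomeration of a symmetric distance matrix.

    At every step the pair of clusters with the smallest size-weighted
    average distance is merged; ties go to the lowest-index pair.  The
    merge height is half the merge distance, so leaves sit at height 0
    and the tree is ultrametric by construction.
    """
    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
        d0 = distance.to_numpy(dtype=float)
    else:
        d0 = np.asarray(distance, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(d0.shape[0])]
        labels = list(labels)
    n = d0.shape[0]
    if d0.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if np.isnan(d0).any():
        raise ValidationError("distance matrix contains NaN")
    if not np.allclose(d0, d0.T):
        raise ValidationError("distance matrix must be symmetric")

    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d0[i, j]
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_idx = n
    while len(active) > 1:
        best = min(
            ((dist[(i, j)], i, j)
             for k, i in enumerate(active) for j in active[k + 1:]),
        )
        dmin, i, j = best
        # Lance-Williams update for unweighted average linkage
        for k in active:
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            new_d = (size[i] * dist[a] + size[j] * dist[b]) / (size[i] + size[j])
            dist[(k, next_idx)] = new_d
        size[next_idx] = size[i] + size[j]
        active = [k for k in active if k not in (i, j)] + [next_idx]
        merges.append((i, j, dmin / 2.0, next_idx))
        next_idx += 1
    return UpgmaTree(labels=labels, merges=merges)


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _to_newick(labels: list[str], merges: list[tuple[int, int, float, int]]) -> str:
    n = len(labels)
    if n == 1:
        return f"{labels[0]};"
    node_str = {i: labels[i] for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    for i, j, h, new in merges:
        # order children by the smallest original leaf index they contain
        first, second = (i, j) if min_leaf[i] <= min_leaf[j] else (j, i)
        parts = []
        for c in (first, second):
            parts.append(f"{node_str[c]}:{_fmt(h - height[c])}")
        node_str[new] = "(" + ",".join(parts) + ")"
        height[new] = h
        min_leaf[new] = min(min_leaf[i], min_leaf[j])
    return node_str[merges[-1][3]] + ";"


# ------------------------------------------------------------- rarefaction


@dataclass
class RarefactionCurve:
    group: str
    k: np.ndarray                      # 1..n
    expected: np.ndarray               # analytic expected richness
    resample_mean: Optional[np.ndarray] = None
    resample_se: Optional[np.ndarray] = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"group": self.group, "k": self.k, "S": self.expected})
        if self.resample_mean is not None:
            df["resample_mean"] = self.resample_mean
            df["resample_se"] = self.resample_se
        return df


def rarefaction(
    matrix: pd.DataFrame,
    group: str = "",
    n_resamples: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> RarefactionCurve:
    """Sample-based rarefaction of family richness over strains.

    The analytic expectation for k sampled strains is
    S(k) = S_obs - sum_j C(n - n_j, k) / C(n, k), where n_j is the
    number of strains containing family j.  With ``n_resamples`` a
    Monte-Carlo mean and standard error over random k-subsets are
    attached as a cross-check.
    """
    if matrix.shape[0] < 1:
        raise ValidationError("rarefaction requires at least one strain")
    inc = matrix.to_numpy(dtype=bool)
    n = inc.shape[0]
    n_j = inc.sum(axis=0)
    n_j = n_j[n_j > 0]
    s_obs = len(n_j)
    ks = np.arange(1, n + 1)
    expected = np.array([
        s_obs - sum(comb(n - nj, k, exact=True) for nj in n_j) / comb(n, k, exact=True)
        for k in ks
    ])
    curve = RarefactionCurve(group=group, k=ks, expected=expected)
    if n_resamples > 0:
        rng = rng or np.random.default_rng()
        means = np.empty(n)
        ses = np.empty(n)
        for idx, k in enumerate(ks):
            rich = np.empty(n_resamples)
            for r in range(n_resamples):
                rows = rng.choice(n, size=k, replace=False)
                rich[r] = int(inc[rows].any(axis=0).sum())
            means[idx] = rich.mean()
            ses[idx] = rich.std(ddof=1) / np.sqrt(n_resamples) if n_resamples > 1 else 0.0
        curve.resample_mean = means
        curve.resample_se = ses
    return curve
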