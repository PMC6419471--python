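"""Distance-threshold MOTU delimiters.

Three delimiters operate on a :class:`~motu_concord.distances.DistanceMatrix`:

* :func:`threshold_partition` — plain single-linkage clustering at a
  fixed cutoff, either a K2P proportion or an absolute mismatch count
  (bp) on each pair's retained sites;
* :func:`gap_partition` — recursive barcode-gap partitioning in the
  spirit of automatic barcode-gap discovery: find the first significant
  gap in the sorted distance distribution above a prior on maximum
  intraspecific divergence, split by single linkage at the gap
  midpoint, recurse into the subgroups;
* :func:`refined_single_linkage` — a two-stage approximation of the
  refined-single-linkage procedure behind barcode index numbers: seed
  clusters by single linkage at a 2.2% p-distance threshold, then split
  a seed cluster only where an internal gap separates subclusters by at
  least ``split_ratio`` times their internal linkage depth.

MOTU ids are opaque strings assigned deterministically in order of each
cluster's first specimen in the matrix ordering.  Missing distance
cells never link (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .datasets import Partition
from .distances import DistanceMatrix


def _components_to_partition(
    ids: list[str], labels: np.ndarray, method_name: str, parameters: dict
) -> Partition:
    """Relabel components as M0001... in order of first appearance."""
    remap: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for sid, lab in zip(ids, labels):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = f"M{len(remap) + 1:04d}"
        assignment[sid] = remap[lab]
    return Partition(assignment, method_name=method_name, parameters=parameters)


def _single_linkage_labels(adjacency: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    return labels


def threshold_partition(
    dm: DistanceMatrix, cutoff: float, units: str = "prop"
) -> Partition:
    """Single-linkage MOTUs: connected components of pairs within cutoff.

    ``units="prop"`` compares the K2P distance to ``cutoff``;
    ``units="bp"`` compares each pair's raw differing-site count on its
    retained sites (the convention of bp-valued cutoff sweeps).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    if units == "prop":
        with np.errstate(invalid="ignore"):
            adj = np.nan_to_num(dm.d, nan=np.inf) <= cutoff
    elif units == "bp":
        adj = (dm.diffs <= cutoff) & (dm.sites > 0)
    else:
        raise ValueError(f"unknown units: {units!r}")
    np.fill_diagonal(adj, False)
    labels = _single_linkage_labels(adj)
    return _components_to_partition(
        dm.ids, labels, "threshold", {"cutoff": cutoff, "units": units}
    )


@dataclass
class SweepCurve:
    """MOTU counts across a sweep of cutoffs (or gap priors)."""

    points: list[tuple[float, int]]

    @property
    def cutoffs(self) -> list[float]:
        return [c for c, _ in self.points]

    @property
    def counts(self) -> list[int]:
        return [n for _, n in self.points]

    def widest_plateau(self) -> tuple[int, int]:
        """(MOTU count, run length) of the longest constant run."""
        best_count, best_len = self.points[0][1], 1
        cur_count, cur_len = best_count, 0
        for _, n in self.points:
            if n == cur_count:
                cur_len += 1
            else:
                cur_count, cur_len = n, 1
            if cur_len > best_len:
                best_count, best_len = cur_count, cur_len
        return best_count, best_len


def threshold_sweep(
    dm: DistanceMatrix, cutoffs: list[float], units: str = "prop"
) -> SweepCurve:
    """One single-linkage partition per cutoff; non-increasing counts."""
    if not cutoffs:
        raise ValueError("empty cutoff list")
    points = [
        (c, threshold_partition(dm, c, units=units).n_motus) for c in sorted(cutoffs)
    ]
    return SweepCurve(points)


# ---------------------------------------------------------------------------
# Recursive barcode-gap partitioning


def _find_gap_threshold(
    values: np.ndarray, prior_max_intra: float, sigma: float, min_gap_width: float
) -> float | None:
    """First significant gap in the sorted distance distribution.

    Scans consecutive differences of the ascending distances; a gap is
    the first difference, ending at or above the prior, that exceeds
    ``max(min_gap_width, sigma * mean of the preceding differences)``.
    When no differences precede the candidate (it is the very first
    step) the mean over *all* consecutive differences is the baseline,
    so a uniformly spaced distance ladder never yields a spurious gap.
    Returns the gap's midpoint or None.
    """
    d = np.sort(values[~np.isnan(values)])
    if len(d) < 2:
        return None
    gaps = np.diff(d)
    overall_mean = float(gaps.mean())
    for i, g in enumerate(gaps):
        if d[i + 1] < prior_max_intra:
            continue
        preceding = gaps[:i]
        baseline = float(preceding.mean()) if len(preceding) else overall_mean
        if g > max(min_gap_width, sigma * baseline):
            return float((d[i] + d[i + 1]) / 2.0)
    return None


def gap_partition(
    dm: DistanceMatrix,
    prior_max_intra: float,
    sigma: float = 1.5,
    min_gap_width: float = 0.001,
) -> Partition:
    """Recursive barcode-gap partitioning of a distance matrix.

    At each level the group's pairwise distances are scanned for the
    first significant gap at or above ``prior_max_intra`` (see
    :func:`_find_gap_threshold`); the group is split by single linkage
    at the gap midpoint and the procedure recurses into each subgroup.
    Recursion stops when no gap is found or a group has fewer than 3
    members.  A group in which no gap is ever found is one MOTU.
    """
    if not 0.0 < prior_max_intra < 1.0:
        raise ValueError("prior_max_intra must be in (0, 1)")
    n = len(dm)
    labels = np.zeros(n, dtype=np.int64)
    next_label = 1

    def recurse(indices: np.ndarray) -> None:
        nonlocal next_label
        if len(indices) < 3:
            return
        sub = dm.d[np.ix_(indices, indices)]
        iu = np.triu_indices(len(indices), k=1)
        threshold = _find_gap_threshold(sub[iu], prior_max_intra, sigma, min_gap_width)
        if threshold is None:
            return
        adj = np.nan_to_num(sub, nan=np.inf) <= threshold
        np.fill_diagonal(adj, False)
        comp = _single_linkage_labels(adj)
        if len(set(comp)) < 2:
            return  # chaining bridged the gap: treat as one group
        for c in sorted(set(comp)):
            members = indices[comp == c]
            if c != comp[0]:
                labels[members] = next_label
                next_label += 1
            recurse(members)

    # each connected start group gets relabelled as recursion splits it
    recurse(np.arange(n))
    return _components_to_partition(
        dm.ids,
        labels,
        "gap",
        {"prior_max_intra": prior_max_intra, "sigma": sigma, "min_gap_width": min_gap_width},
    )


def gap_sweep(dm: DistanceMatrix, priors: list[float], sigma: float = 1.5) -> SweepCurve:
    """Gap partition across a list of priors on maximum intraspecific distance."""
    if not priors:
        raise ValueError("empty prior list")
    points = [(p, gap_partition(dm, p, sigma=sigma).n_motus) for p in sorted(priors)]
    return SweepCurve(points)


# ---------------------------------------------------------------------------
# Refined single linkage (seed + refinement)


def _max_linkage_distance(d: np.ndarray) -> float:
    """Largest single-linkage merge height within a group.

    Equals the largest edge of a minimum spanning tree of the complete
    distance graph; 0 for singletons.
    """
    n = d.shape[0]
    if n < 2:
        return 0.0
    filled = np.nan_to_num(d, nan=float(np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0) * 10 + 1.0)
    # shift so zero distances survive sparse MST construction
    mst = minimum_spanning_tree(csr_matrix(filled + 1.0))
    edges = mst.toarray()
    return float(edges.max() - 1.0) if edges.max() > 0 else 0.0


def refined_single_linkage(
    dm: DistanceMatrix, seed_threshold: float = 0.022, split_ratio: float = 3.0
) -> Partition:
    """Seed single-linkage clusters, then split only across strong gaps.

    Stage 1 links pairs with p-distance <= ``seed_threshold`` (default
    2.2%).  Stage 2 re-examines each seed cluster with
    :func:`gap_partition` (prior = the cluster's median internal
    distance, sigma = ``split_ratio``) and accepts a proposed split only
    if every pair of resulting subclusters is separated by at least
    ``split_ratio`` times the deeper subcluster's internal linkage
    depth; accepted splits are refined recursively.
    """
    p = dm.p
    adj = np.nan_to_num(p, nan=np.inf) <= seed_threshold
    np.fill_diagonal(adj, False)
    seed_labels = _single_linkage_labels(adj)

    final_groups: list[np.ndarray] = []

    def refine(indices: np.ndarray) -> None:
        if len(indices) < 3:
            final_groups.append(indices)
            return
        sub = dm.d[np.ix_(indices, indices)]
        iu = np.triu_indices(len(indices), k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            final_groups.append(indices)
            return
        prior = max(float(np.median(vals)), 1e-4)
        # inside a seed cluster a split-worthy gap must be wide relative to
        # the cluster's own divergence scale, not just the global floor
        proposal = gap_partition(
            dm.submatrix([dm.ids[i] for i in indices]),
            prior,
            sigma=split_ratio,
            min_gap_width=max(0.001, 0.5 * prior),
        )
        groups = list(proposal.motus().values())
        if len(groups) < 2:
            final_groups.append(indices)
            return
        id_to_local = {dm.ids[g]: k for k, g in enumerate(indices)}
        member_idx = [np.array(sorted(id_to_local[s] for s in g)) for g in groups]
        # acceptance: between-subcluster separation must dominate
        # within-subcluster linkage depth for every pair of subclusters
        for a in range(len(member_idx)):
            for b in range(a + 1, len(member_idx)):
                between = np.nanmin(sub[np.ix_(member_idx[a], member_idx[b])])
                depth = max(
                    _max_linkage_distance(sub[np.ix_(member_idx[a], member_idx[a])]),
                    _max_linkage_distance(sub[np.ix_(member_idx[b], member_idx[b])]),
                )
                if np.isnan(between) or (depth > 0 and between / depth < split_ratio):
                    final_groups.append(indices)
                    return
        for g in member_idx:
            refine(indices[g])

    for lab in sorted(set(seed_labels)):
        refine(np.flatnonzero(seed_labels == lab))

    labels = np.zeros(len(dm), dtype=np.int64)
    for k, g in enumerate(final_groups):
        labels[g] = k
    return _components_to_partition(
        dm.ids,
        labels,
        "resl",
        {"seed_threshold": seed_threshold, "split_ratio": split_ratio},
    )
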