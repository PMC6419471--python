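"""Concordance between reference species labels and MOTU partitions.

This module carries the study's bespoke statistics:

* four-way classification of each reference species against a MOTU
  partition — MATCH (one MOTU, no other species), MERGE (one MOTU
  shared with other species), SPLIT (several MOTUs, all pure), MIXTURE
  (several MOTUs, at least one shared);
* summaries over two denominators (all species; multi-specimen species
  only), since singletons can never SPLIT;
* >=k-of-m consensus MOTUs: specimen sets recovered identically by at
  least k of m delimitation methods, with deterministic overlap
  resolution;
* the adjusted Wallace coefficient, a chance-corrected probability that
  a specimen pair co-clustered under partition A is also co-clustered
  under partition B, with a seeded bootstrap confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Partition

CATEGORIES = ("MATCH", "MERGE", "SPLIT", "MIXTURE")


@dataclass
class ConcordanceReport:
    """Per-species four-way classification against one MOTU partition."""

    category: dict[str, str]  # species -> MATCH|MERGE|SPLIT|MIXTURE
    motus_of_species: dict[str, frozenset[str]]  # species -> MOTU ids
    singleton_species: list[str]
    method_name: str = ""

    @property
    def n_species(self) -> int:
        return len(self.category)

    def counts(self, exclude_singletons: bool = False) -> dict[str, int]:
        skip = set(self.singleton_species) if exclude_singletons else set()
        out = {c: 0 for c in CATEGORIES}
        for sp, cat in self.category.items():
            if sp not in skip:
                out[cat] += 1
        return out


def classify_concordance(ref: Partition, motus: Partition) -> ConcordanceReport:
    """Classify every reference species as MATCH/MERGE/SPLIT/MIXTURE.

    ``ref`` maps specimens to species labels, ``motus`` to MOTU ids;
    both must cover the same specimens.  For species S with MOTU set
    M(S): MATCH iff |M(S)| = 1 and that MOTU holds only S; MERGE iff
    |M(S)| = 1 and it holds other species too; SPLIT iff |M(S)| > 1 and
    every MOTU of S is pure; MIXTURE iff |M(S)| > 1 and at least one
    MOTU of S holds another species.
    """
    ua, ub = set(ref.assignment), set(motus.assignment)
    if ua != ub:
        diff = sorted(ua.symmetric_difference(ub))
        raise ValueError(f"specimen universes differ: {diff}")

    species_of = ref.assignment
    motu_members = motus.motus()
    motu_species = {
        m: {species_of[s] for s in members} for m, members in motu_members.items()
    }
    species_sizes: dict[str, int] = {}
    species_motus: dict[str, set[str]] = {}
    for sid, sp in species_of.items():
        species_sizes[sp] = species_sizes.get(sp, 0) + 1
        species_motus.setdefault(sp, set()).add(motus.assignment[sid])

    category: dict[str, str] = {}
    for sp, mset in species_motus.items():
        shared = [m for m in mset if motu_species[m] != {sp}]
        if len(mset) == 1:
            category[sp] = "MERGE" if shared else "MATCH"
        else:
            category[sp] = "MIXTURE" if shared else "SPLIT"
    return ConcordanceReport(
        category=category,
        motus_of_species={sp: frozenset(m) for sp, m in species_motus.items()},
        singleton_species=sorted(sp for sp, n in species_sizes.items() if n == 1),
        method_name=motus.method_name,
    )


def concordance_summary(report: ConcordanceReport) -> pd.DataFrame:
    """Category counts and percentages over both denominators.

    Percentages are rendered with two decimals (half-up).  The two
    denominators are all species and multi-specimen species only.
    """
    rows = []
    for exclude in (False, True):
        counts = report.counts(exclude_singletons=exclude)
        denom = report.n_species - (len(report.singleton_species) if exclude else 0)
        for cat in CATEGORIES:
            pct = 100.0 * counts[cat] / denom if denom else math.nan
            rows.append(
                {
                    "denominator": "multi_specimen" if exclude else "all_species",
                    "category": cat,
                    "count": counts[cat],
                    "denom": denom,
                    "percent": float(f"{pct:.2f}") if denom else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus MOTUs


@dataclass
class ConsensusResult:
    """Specimen sets recovered by at least k of m delimitation methods."""

    motus: list[frozenset[str]]
    support: list[int]
    unassigned: list[str]
    k: int
    m: int

    def to_partition(self) -> Partition:
        assignment = {}
        for idx, group in enumerate(self.motus):
            for sid in group:
                assignment[sid] = f"C{idx + 1:04d}"
        return Partition(assignment, method_name=f"consensus_{self.k}of{self.m}")


def consensus_motus(partitions: list[Partition], k: int = 4) -> ConsensusResult:
    """Keep specimen sets identical across >= k of the m partitions.

    Candidate sets are every MOTU of every partition; support is the
    number of partitions containing *exactly* that set.  Overlaps are
    resolved deterministically: higher support first, then larger set,
    then lexicographically smallest member; losers' uncovered specimens
    are reported unassigned.
    """
    m = len(partitions)
    if not 1 <= k <= m:
        raise ValueError(f"need 1 <= k <= m, got k={k}, m={m}")
    universe = set(partitions[0].assignment)
    for p in partitions[1:]:
        if set(p.assignment) != universe:
            raise ValueError("partitions cover different specimen universes")

    support: dict[frozenset[str], int] = {}
    for p in partitions:
        for group in p.sets():
            support[group] = support.get(group, 0) + 1

    candidates = [(g, s) for g, s in support.items() if s >= k]
    candidates.sort(key=lambda gs: (-gs[1], -len(gs[0]), min(gs[0])))
    kept: list[frozenset[str]] = []
    kept_support: list[int] = []
    covered: set[str] = set()
    for group, s in candidates:
        if group & covered:
            continue
        kept.append(group)
        kept_support.append(s)
        covered |= group
    order = sorted(range(len(kept)), key=lambda i: min(kept[i]))
    return ConsensusResult(
        motus=[kept[i] for i in order],
        support=[kept_support[i] for i in order],
        unassigned=sorted(universe - covered),
        k=k,
        m=m,
    )


# ---------------------------------------------------------------------------
# Adjusted Wallace


@dataclass
class WallaceResult:
    """Directional partition agreement A -> B.

    ``W`` is the raw Wallace coefficient: of the specimen pairs
    co-clustered in A, the fraction also co-clustered in B.  Correcting
    for the agreement expected by chance given B's cluster-size
    distribution (1 - SID(B), with SID Simpson's index of diversity)
    gives the adjusted coefficient AW = (W - (1 - SID)) / SID.
    """

    W: float
    sid_B: float
    AW: float  # NaN when undefined
    ci_low: float
    ci_high: float
    a: int  # pairs together in both
    b: int  # pairs together in A, apart in B
    n: int
    reason_missing: str = ""


def _pair_counts(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[int, int]:
    """(together in both, together in A only), via the contingency table."""
    ct = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b)).to_numpy()
    a_both = int((ct * (ct - 1) // 2).sum())
    rows = ct.sum(axis=1)
    together_a = int((rows * (rows - 1) // 2).sum())
    return a_both, together_a - a_both


def _simpson_diversity(labels: np.ndarray) -> float:
    n = len(labels)
    if n < 2:
        return math.nan
    _, sizes = np.unique(labels, return_counts=True)
    return 1.0 - float((sizes * (sizes - 1)).sum()) / (n * (n - 1))


def _aw_from_labels(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    a, b = _pair_counts(labels_a, labels_b)
    sid = _simpson_diversity(labels_b)
    if a + b == 0 or sid == 0 or math.isnan(sid):
        return math.nan
    w = a / (a + b)
    return (w - (1.0 - sid)) / sid


def adjusted_wallace(
    A: Partition,
    B: Partition,
    exclude_singletons: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> WallaceResult:
    """Adjusted Wallace coefficient A -> B with a bootstrap 95% CI.

    With ``exclude_singletons`` (default), specimens whose A-cluster is
    a singleton are removed first — pairs cannot be formed within
    singletons, and published usage restricts the comparison to
    multi-specimen clusters.  The CI is a seeded percentile bootstrap
    over specimens; ``n_boot=0`` skips it.
    """
    if set(A.assignment) != set(B.assignment):
        raise ValueError("partitions cover different specimen universes")
    ids = sorted(A.assignment)
    if exclude_singletons:
        sizes: dict[str, int] = {}
        for sid in ids:
            sizes[A.assignment[sid]] = sizes.get(A.assignment[sid], 0) + 1
        ids = [sid for sid in ids if sizes[A.assignment[sid]] > 1]

    la = np.array([A.assignment[s] for s in ids])
    lb = np.array([B.assignment[s] for s in ids])
    n = len(ids)
    if n < 2:
        return WallaceResult(
            math.nan, math.nan, math.nan, math.nan, math.nan, 0, 0, n,
            reason_missing="fewer than 2 specimens after singleton exclusion",
        )
    a, b = _pair_counts(la, lb)
    sid_b = _simpson_diversity(lb)
    w = a / (a + b) if a + b else math.nan
    if a + b == 0:
        return WallaceResult(
            w, sid_b, math.nan, math.nan, math.nan, a, b, n,
            reason_missing="no co-clustered pairs in A",
        )
    if sid_b == 0:
        return WallaceResult(
            w, sid_b, math.nan, math.nan, math.nan, a, b, n,
            reason_missing="B is a single cluster: chance agreement is 1",
        )
    aw = (w - (1.0 - sid_b)) / sid_b

    ci_low = ci_high = math.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            take = rng.integers(0, n, size=n)
            reps.append(_aw_from_labels(la[take], lb[take]))
        reps = np.asarray(reps)
        reps = reps[~np.isnan(reps)]
        if len(reps):
            ci_low, ci_high = (float(v) for v in np.percentile(reps, [2.5, 97.5]))
    return WallaceResult(w, sid_b, aw, ci_low, ci_high, a, b, n)


def wallace_matrix(
    partitions: dict[str, Partition],
    exclude_singletons: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Directional AW for every ordered pair of named partitions.

    Row method -> column method; cells formatted ``AW (lo-hi)``.
    """
    names = list(partitions)
    rows = {}
    for i, na in enumerate(names):
        row = {}
        for j, nb in enumerate(names):
            if na == nb:
                row[nb] = ""
                continue
            res = adjusted_wallace(
                partitions[na],
                partitions[nb],
                exclude_singletons=exclude_singletons,
                n_boot=n_boot,
                seed=seed + 1000 * i + j,
            )
            if math.isnan(res.AW):
                row[nb] = "NA"
            else:
                row[nb] = f"{res.AW:.3f} ({res.ci_low:.3f}-{res.ci_high:.3f})"
        rows[na] = row
    return pd.DataFrame.from_dict(rows, orient="index")[names]
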