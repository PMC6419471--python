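"""Kimura two-parameter (K2P) distance analytics.

The K2P model corrects observed sequence differences separately for
transitions (A<->G, C<->T; proportion P) and transversions (proportion
Q):

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a non-ACGT character (N, gap, ?,
IUPAC ambiguity) are deleted pairwise before P and Q are computed.
Distances are stored as proportions; report writers render percent with
two decimals.  A pair is *missing* when fewer than ``min_overlap`` sites
survive pairwise deletion or when the logarithm's argument is
non-positive (saturated pair).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import Dataset, SpecimenRecord

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

# base encoding: A=0, C=1, G=2, T=3, everything else = 4 (missing)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseComparison:
    """Site counts and K2P distance for one pair of aligned sequences."""

    sites_compared: int
    n_transitions: int
    n_transversions: int
    P: float
    Q: float
    K: float  # NaN when undefined (short overlap or saturation)

    @property
    def n_differences(self) -> int:
        return self.n_transitions + self.n_transversions

    @property
    def p_distance(self) -> float:
        if self.sites_compared == 0:
            return math.nan
        return self.n_differences / self.sites_compared

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.K)


def k2p_from_proportions(P: float, Q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return max(0.0, -0.5 * math.log(w1 * math.sqrt(w2)))


def k2p_distance(seq_a: str, seq_b: str, min_overlap: int = 100) -> PairwiseComparison:
    """K2P distance between two equal-length sequences, pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"unequal sequence lengths: {len(seq_a)} vs {len(seq_b)}")
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    return _k2p_encoded(a, b, min_overlap)


def _k2p_encoded(a: np.ndarray, b: np.ndarray, min_overlap: int) -> PairwiseComparison:
    valid = (a < 4) & (b < 4)
    sites = int(valid.sum())
    if sites == 0:
        return PairwiseComparison(0, 0, 0, math.nan, math.nan, math.nan)
    av, bv = a[valid], b[valid]
    diff = av != bv
    # transitions stay within a purine (A,G -> even codes) or pyrimidine pair
    transition = diff & ((av % 2) == (bv % 2))
    ts = int(transition.sum())
    tv = int(diff.sum()) - ts
    P = ts / sites
    Q = tv / sites
    K = math.nan if sites < min_overlap else k2p_from_proportions(P, Q)
    return PairwiseComparison(sites, ts, tv, P, Q, K)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances plus per-pair site and mismatch counts.

    ``d`` holds K2P proportions with NaN for missing pairs; ``sites``
    and ``diffs`` hold the pairwise-deletion site count and the raw
    differing-site count (used for bp-valued cutoffs and p-distances).
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray
    diffs: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for arr in (self.d, self.sites, self.diffs):
            if arr.shape != (n, n):
                raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> np.ndarray:
        """p-distance matrix (differences / retained sites)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.sites > 0, self.diffs / np.maximum(self.sites, 1), np.nan)

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.d[iu]).sum())

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def submatrix(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        sel = np.ix_(idx, idx)
        return DistanceMatrix(
            list(keep_ids), self.d[sel].copy(), self.sites[sel].copy(), self.diffs[sel].copy()
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.d, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.6f", na_rep="NA", index_label="specimen_id")


def distance_matrix(ds: Dataset, min_overlap: int = 100) -> DistanceMatrix:
    """All-pairs K2P distances for an aligned dataset."""
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    lengths = {len(r.sequence) for r in ds.records}
    if len(lengths) > 1:
        raise ValueError("sequences must be aligned to equal length")
    enc = np.vstack([encode_sequence(r.sequence) for r in ds.records])
    valid = enc < 4
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    diffs = np.zeros((n, n), dtype=np.int64)
    n_saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            pc = _k2p_encoded(enc[i], enc[j], min_overlap)
            d[i, j] = d[j, i] = pc.K
            sites[i, j] = sites[j, i] = pc.sites_compared
            diffs[i, j] = diffs[j, i] = pc.n_differences
            if pc.sites_compared >= min_overlap and math.isnan(pc.K):
                n_saturated += 1
    np.fill_diagonal(sites, [int(v.sum()) for v in valid])
    if n_saturated:
        logger.warning("%d saturated pairs excluded (K2P log-argument <= 0)", n_saturated)
    return DistanceMatrix(ds.ids, d, sites, diffs)


def collapse_haplotypes(ds: Dataset) -> tuple[Dataset, dict[str, list[str]]]:
    """Collapse byte-identical sequences to one representative each.

    The representative is the first record (input order) bearing each
    distinct sequence; the returned map sends each representative id to
    all member ids (itself included).  Exact string identity only —
    sequences differing at an ambiguous site are *not* merged.
    """
    reps: list[SpecimenRecord] = []
    by_seq: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for rec in ds.records:
        rep = by_seq.get(rec.sequence)
        if rep is None:
            by_seq[rec.sequence] = rec.specimen_id
            members[rec.specimen_id] = [rec.specimen_id]
            reps.append(rec)
        else:
            members[rep].append(rec.specimen_id)
    return Dataset(reps, alignment_length=ds.alignment_length), members


# ---------------------------------------------------------------------------
# Divergence summaries (pooled and normalized)


@dataclass
class DivergenceSummary:
    """Pooled within-group distance summary at one taxonomic level."""

    level: str
    n_taxa: int
    n_comparisons: int
    min: float
    mean: float
    max: float
    se: float


def _group_label(rec: SpecimenRecord, level: str) -> str:
    if level == "species":
        return rec.species
    if level == "genus":
        return rec.genus
    if level == "family":
        return "__family__"  # single family: pool everything
    raise ValueError(f"unknown level: {level}")


def _within_pairs(dm: DistanceMatrix, ds: Dataset, level: str) -> tuple[list[float], set[str]]:
    """Distances pooled at a level, with the contributing record ids.

    Species level pools conspecific pairs; genus level pools congeneric
    *heterospecific* pairs; family level pools *intergeneric* pairs —
    each level measures divergence between units of the rank below, as
    in standard barcode distance summaries.
    """
    recs = ds.records
    values: list[float] = []
    contributing: set[str] = set()
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            ga, gb = _group_label(a, level), _group_label(b, level)
            if not ga or not gb or ga != gb:
                continue
            if level == "genus" and (a.species == b.species and a.species):
                continue
            if level == "family" and (a.genus == b.genus and a.genus):
                continue
            v = dm.d[i, j]
            if not math.isnan(v):
                values.append(v)
                contributing.add(a.specimen_id)
                contributing.add(b.specimen_id)
    return values, contributing


def divergence_summary(dm: DistanceMatrix, ds: Dataset, level: str) -> DivergenceSummary:
    """Pooled min/mean/max/SE of within-group distances at a rank.

    Groups with a single member contribute no pairs (singletons are
    excluded); ``n_taxa`` counts the records that contribute at least
    one comparison.
    """
    if dm.ids != ds.ids:
        raise ValueError("distance matrix and dataset ids differ")
    values, contributing = _within_pairs(dm, ds, level)
    if not values:
        raise ValueError(f"no comparisons at level {level!r}")
    arr = np.asarray(values)
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return DivergenceSummary(
        level=level,
        n_taxa=len(contributing),
        n_comparisons=len(arr),
        min=float(arr.min()),
        mean=float(arr.mean()),
        max=float(arr.max()),
        se=se,
    )


@dataclass
class NormalizedSummary:
    """Per-species-weighted intraspecific statistics.

    The mean is the unweighted average over species of each species'
    mean intraspecific distance, removing the bias from unequal
    sampling; the SE is over the per-species means.
    """

    n_species: int
    mean_within: float
    se_within: float
    min_between: float


def species_mean_intra(dm: DistanceMatrix, ds: Dataset) -> dict[str, float]:
    """Mean intraspecific distance per multi-specimen species."""
    out: dict[str, list[float]] = {}
    recs = ds.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if recs[i].species and recs[i].species == recs[j].species:
                v = dm.d[i, j]
                if not math.isnan(v):
                    out.setdefault(recs[i].species, []).append(v)
    return {sp: float(np.mean(vals)) for sp, vals in out.items()}


def normalized_summary(dm: DistanceMatrix, ds: Dataset) -> NormalizedSummary:
    per_species = species_mean_intra(dm, ds)
    if not per_species:
        raise ValueError("no multi-specimen species: no comparisons")
    means = np.asarray(list(per_species.values()))
    se = float(means.std(ddof=1) / math.sqrt(len(means))) if len(means) > 1 else 0.0
    # global minimum heterospecific distance
    min_between = math.inf
    recs = ds.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.species and b.species and a.species != b.species:
                v = dm.d[i, j]
                if not math.isnan(v):
                    min_between = min(min_between, v)
    return NormalizedSummary(
        n_species=len(means),
        mean_within=float(means.mean()),
        se_within=se,
        min_between=float(min_between) if math.isfinite(min_between) else math.nan,
    )


# ---------------------------------------------------------------------------
# Geography and sampling-effort regression


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_extent(records: list[SpecimenRecord]) -> float:
    """Maximum pairwise great-circle distance (km) among located records."""
    located = [r for r in records if r.has_coordinates]
    if len(located) < 2:
        return math.nan
    best = 0.0
    for i in range(len(located)):
        for j in range(i + 1, len(located)):
            a, b = located[i], located[j]
            best = max(best, haversine_km(a.latitude, a.longitude, b.latitude, b.longitude))
    return best


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2_adjusted: float
    p_value: float
    n: int


def regress_max_intra(xs: list[float], ys: list[float]) -> RegressionResult:
    """OLS of maximum intraspecific distance on a sampling covariate.

    ``xs`` is record count or geographic extent per species, ``ys`` the
    species' maximum intraspecific K2P distance.  Adjusted R-squared is
    1 - (1-R^2)(n-1)/(n-2); the p-value is the two-sided slope t-test.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect fits trigger a harmless runtime warning
        res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2_adjusted=float(r2_adj),
        p_value=float(res.pvalue),
        n=n,
    )
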