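"""Synthetic barcode datasets with a known (planted) species structure.

The generator emulates the statistical structure a single-locus
delimitation analysis assumes: tight within-species divergence (~1-2%
K2P), much larger between-species divergence (~15%), optional
singletons, cryptic deep splits (one label spanning two lineages
separated by more than 2%) and label merges (two labels sharing one
lineage).  Every dataset comes with its *truth partition* — the lineage
membership of each specimen — so each downstream stage can be tested
against a known answer.

Lineage history is a two-level star phylogeny: lineage ancestors evolve
independently from a single root, specimens independently from their
lineage ancestor.  Substitutions follow the two-rate (K2P) process with
transition/transversion rate ratio ``kappa``, so realized distances are
calibrated against the closed-form expectation
(:func:`expected_divergence`) by numeric inversion.  A star history
realizes the target intra/inter separation but has no rank-dependent
depth structure and no coalescent variance in split times; see the
methods note for what that does and does not exercise.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import Dataset, Partition, SpecimenRecord

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults follow the divergence structure of large katydid barcode
    surveys: normalized mean within-species K2P near 1.4%, congeneric
    between-species divergence near 15%, 658-bp COI-5P barcodes.
    ``kappa`` is the transition/transversion *rate* ratio (4.0, a
    typical insect mitochondrial value).  ``specimens_per_species`` is
    either a fixed count or a (lo, hi) range sampled uniformly;
    ``singleton_fraction`` of species are forced to one specimen.
    """

    seed: int
    n_species: int = 20
    specimens_per_species: int | tuple[int, int] = 5
    singleton_fraction: float = 0.0
    seq_length: int = 658
    kappa: float = 4.0
    target_intra: float = 0.014
    target_inter: float = 0.15
    cryptic_fraction: float = 0.0
    deep_split: float = 0.08
    merge_pairs: int = 0
    geo_spread_km: float = 800.0
    geo_jitter_km: float = 50.0
    ambiguous_fraction: float = 0.0
    ambiguous_run_length: int = 20
    short_fraction: float = 0.0
    base_lat: float = 30.0
    base_lon: float = 110.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.target_intra < self.target_inter:
            raise ValueError("need 0 < target_intra < target_inter")
        for name in ("singleton_fraction", "cryptic_fraction", "ambiguous_fraction", "short_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")
        if self.merge_pairs < 0 or 2 * self.merge_pairs > self.n_species:
            raise ValueError("merge_pairs out of range")
        if self.deep_split <= 0.02:
            raise ValueError("deep_split must exceed 0.02 to count as a deep split")


# ---------------------------------------------------------------------------
# The substitution process and its closed-form expectation


def _rate_components(kappa: float) -> tuple[float, float]:
    """(alpha, beta): transition and per-transversion rates, total rate 1."""
    beta = 1.0 / (kappa + 2.0)
    return kappa * beta, beta


def _event_probabilities(d: float, kappa: float) -> tuple[float, float, float]:
    """(stay, transition, each transversion) after expected d subs/site."""
    alpha, beta = _rate_components(kappa)
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return 1.0 - p_ts - 2.0 * p_tv_each, p_ts, p_tv_each


def expected_divergence(branch_rate_time: float, kappa: float = 4.0) -> float:
    """Expected K2P distance between two tips, each ``branch_rate_time``
    (expected substitutions per site) from their common ancestor.

    The two-rate process composes over the 2t separation, giving
    expected transition/transversion proportions in closed form; the
    K2P estimator applied to those expectations is returned.
    """
    if branch_rate_time < 0:
        raise ValueError("branch_rate_time must be nonnegative")
    if branch_rate_time == 0:
        return 0.0
    _, p_ts, p_tv_each = _event_probabilities(2.0 * branch_rate_time, kappa)
    w1 = 1.0 - 2.0 * p_ts - 2.0 * p_tv_each
    w2 = 1.0 - 4.0 * p_tv_each
    if w1 <= 0 or w2 <= 0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def branch_length_for_target(target_k2p: float, kappa: float = 4.0) -> float:
    """Per-branch length whose tip pair realizes a target K2P distance.

    Numeric inversion of :func:`expected_divergence` (bracketed root
    find); used to calibrate the simulator's branches.
    """
    if target_k2p <= 0:
        return 0.0
    return float(brentq(lambda t: expected_divergence(t, kappa) - target_k2p, 0.0, 10.0))


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve encoded bases (0..3) for expected d substitutions/site."""
    if d <= 0:
        return seq.copy()
    p_stay, p_ts, p_tv_each = _event_probabilities(d, kappa)
    u = rng.random(len(seq))
    out = seq.copy()
    ts_mask = (u >= p_stay) & (u < p_stay + p_ts)
    out[ts_mask] = seq[ts_mask] ^ 2  # A<->G, C<->T
    tv1 = (u >= p_stay + p_ts) & (u < p_stay + p_ts + p_tv_each)
    tv2 = u >= p_stay + p_ts + p_tv_each
    low = 1 - (seq % 2)  # first transversion partner by parity
    out[tv1] = low[tv1]
    out[tv2] = low[tv2] + 2
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[c] for c in seq)


# stop codons of the invertebrate mitochondrial code (table 5): TAA, TAG
_T, _A, _G, _C = 3, 0, 2, 1


def _repair_stops(seq: np.ndarray) -> np.ndarray:
    """Keep reading frame 0 free of stop codons.

    Barcodes are protein-coding, so a stop created by the substitution
    process would be purged by selection; the third codon position of
    any TAA/TAG is rewritten to C (TAC, tyrosine).  Stops are rare at
    the simulated divergences, so the distance calibration is barely
    perturbed.
    """
    out = seq.copy()
    n_codons = len(out) // 3
    codons = out[: 3 * n_codons].reshape(n_codons, 3)
    is_stop = (codons[:, 0] == _T) & (codons[:, 1] == _A) & (
        (codons[:, 2] == _A) | (codons[:, 2] == _G)
    )
    codons[is_stop, 2] = _C
    return out


# ---------------------------------------------------------------------------
# Dataset assembly


def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, Partition, pd.DataFrame]:
    """Generate (dataset, truth partition, lineage table) from a config.

    The truth partition maps every specimen to its generating lineage:
    cryptic species contribute two lineages under one label, merged
    label pairs share a single lineage.  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    root = _repair_stops(rng.integers(0, 4, size=L).astype(np.int64))
    # branch_length_for_target returns the per-branch length whose *pair*
    # of tips realizes the target.  Between-species and deep-split targets
    # are what a pair of SPECIMENS should realize, so the ancestor branches
    # are shortened by the specimen-branch contribution.
    t_intra = branch_length_for_target(cfg.target_intra, cfg.kappa)
    t_inter = max(branch_length_for_target(cfg.target_inter, cfg.kappa) - t_intra, 0.0)
    t_deep = max(branch_length_for_target(cfg.deep_split, cfg.kappa) - t_intra, 0.0)

    species_names = [f"Species_{i + 1:03d}" for i in range(cfg.n_species)]
    genus_of = {
        sp: f"Genus_{i // 4 + 1:02d}" for i, sp in enumerate(species_names)
    }
    subfamily_of = {
        sp: f"Subfamily_{i // 20 + 1:02d}" for i, sp in enumerate(species_names)
    }

    # specimen counts per label
    def draw_count() -> int:
        if cfg.singleton_fraction > 0 and rng.random() < cfg.singleton_fraction:
            return 1
        if isinstance(cfg.specimens_per_species, int):
            return cfg.specimens_per_species
        lo, hi = cfg.specimens_per_species
        return int(rng.integers(lo, hi + 1))

    counts = {sp: draw_count() for sp in species_names}

    # merged labels: the first 2*merge_pairs labels share lineages pairwise
    lineage_of_label: dict[str, str] = {}
    lineage_kind: dict[str, str] = {}
    n_lineage = 0
    for p in range(cfg.merge_pairs):
        n_lineage += 1
        lid = f"LIN{n_lineage:04d}"
        for sp in species_names[2 * p : 2 * p + 2]:
            lineage_of_label[sp] = lid
        lineage_kind[lid] = "merged"
    remaining = species_names[2 * cfg.merge_pairs :]
    for sp in remaining:
        n_lineage += 1
        lineage_of_label[sp] = f"LIN{n_lineage:04d}"
        lineage_kind[lineage_of_label[sp]] = "normal"

    # cryptic labels (multi-specimen, unmerged): label spans two lineages
    n_cryptic = int(round(cfg.cryptic_fraction * cfg.n_species))
    eligible = [sp for sp in remaining if counts[sp] >= 2]
    cryptic_labels = set(eligible[:n_cryptic])
    if len(cryptic_labels) < n_cryptic:
        raise ValueError("not enough multi-specimen unmerged species for cryptic_fraction")

    # ancestors per lineage (merged pairs share; cryptic get two sub-lineages)
    ancestor: dict[str, np.ndarray] = {}
    for lid in sorted(set(lineage_of_label.values())):
        ancestor[lid] = _repair_stops(_evolve(root, t_inter, cfg.kappa, rng))
    sublineages: dict[str, tuple[str, str]] = {}
    for sp in species_names:
        if sp in cryptic_labels:
            base = ancestor[lineage_of_label[sp]]
            n_lineage += 1
            lid_a = f"LIN{n_lineage:04d}"
            n_lineage += 1
            lid_b = f"LIN{n_lineage:04d}"
            ancestor[lid_a] = _repair_stops(_evolve(base, t_deep, cfg.kappa, rng))
            ancestor[lid_b] = _repair_stops(_evolve(base, t_deep, cfg.kappa, rng))
            lineage_kind[lid_a] = lineage_kind[lid_b] = "cryptic"
            sublineages[sp] = (lid_a, lid_b)

    records: list[SpecimenRecord] = []
    truth: dict[str, str] = {}
    table_rows = []
    sid_counter = 0
    deg_per_km = 1.0 / 111.32
    for sp in species_names:
        n_sp = counts[sp]
        cen_lat = cfg.base_lat + rng.normal(0, cfg.geo_spread_km * deg_per_km)
        cen_lon = cfg.base_lon + rng.normal(
            0, cfg.geo_spread_km * deg_per_km / max(math.cos(math.radians(cfg.base_lat)), 0.1)
        )
        if sp in sublineages:
            lid_a, lid_b = sublineages[sp]
            n_a = n_sp // 2 if n_sp // 2 >= 1 else 1
            member_lineages = [lid_a] * n_a + [lid_b] * (n_sp - n_a)
        else:
            member_lineages = [lineage_of_label[sp]] * n_sp
        for lid in member_lineages:
            sid_counter += 1
            sid = f"SP{sid_counter:05d}"
            seq = _repair_stops(_evolve(ancestor[lid], t_intra, cfg.kappa, rng))
            text = _decode(seq)
            if cfg.ambiguous_fraction > 0 and rng.random() < cfg.ambiguous_fraction:
                run = min(cfg.ambiguous_run_length, L)
                start = int(rng.integers(0, L - run + 1))
                text = text[:start] + "N" * run + text[start + run :]
            if cfg.short_fraction > 0 and rng.random() < cfg.short_fraction:
                keep = min(599, L)  # pad with gaps: alignment length preserved
                text = text[:keep] + "-" * (L - keep)
            lat = float(np.clip(cen_lat + rng.normal(0, cfg.geo_jitter_km * deg_per_km), -90, 90))
            lon = float(np.clip(cen_lon + rng.normal(0, cfg.geo_jitter_km * deg_per_km), -180, 180))
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    sequence=text,
                    species=sp,
                    genus=genus_of[sp],
                    subfamily=subfamily_of[sp],
                    bin_id=lid,
                    latitude=lat,
                    longitude=lon,
                    site=f"site_{int(rng.integers(1, 6))}",
                )
            )
            truth[sid] = lid
        for lid in dict.fromkeys(member_lineages):
            table_rows.append(
                {
                    "species": sp,
                    "lineage_id": lid,
                    "n_specimens": member_lineages.count(lid),
                    "kind": lineage_kind[lid],
                }
            )

    ds = Dataset(records, alignment_length=L)
    truth_partition = Partition(truth, method_name="truth", parameters={"seed": cfg.seed})
    return ds, truth_partition, pd.DataFrame(table_rows)


def write_simulation(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[Dataset, Partition, pd.DataFrame]:
    """Run the generator and write FASTA, metadata TSV, truth TSV, config JSON."""
    from .datasets import write_dataset, write_partition

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth, table = simulate_dataset(cfg)
    write_dataset(ds, out / "barcodes.fasta", out / "metadata.tsv")
    write_partition(truth, out / "truth_partition.tsv")
    table.to_csv(out / "lineage_table.tsv", sep="\t", index=False)
    with open(out / "sim_config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=list)
    return ds, truth, table
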