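"""Per-species barcode-gap audit.

For each reference species the audit reports its intraspecific distance
statistics and the distance to its nearest neighbor (NN) — the smallest
K2P distance from any of its specimens to any heterospecific specimen —
and flags the diagnostic conditions: NN closer than 2%, NN overlapping
the species' own maximum intraspecific distance (no local barcode gap),
and deep intraspecific divergence (> 2%, a cryptic-split signal).

The NN scope is configurable: ``all`` considers every heterospecific
specimen (matching how published NN tables pair species across genera),
``congeneric`` restricts the search to the same genus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset
from .distances import DistanceMatrix

DEEP_INTRA_THRESHOLD = 0.02
NN_CLOSE_THRESHOLD = 0.02


@dataclass
class GapRecord:
    """Barcode-gap audit row for one species."""

    species: str
    n: int
    mean_intra: float  # NaN for singletons
    max_intra: float  # NaN for singletons
    nn_species: str
    nn_specimen: str
    nn_dist: float

    @property
    def flag_nn_lt_2pct(self) -> bool:
        return not math.isnan(self.nn_dist) and self.nn_dist < NN_CLOSE_THRESHOLD

    @property
    def flag_overlap(self) -> bool:
        """NN distance does not exceed the species' own maximum depth."""
        if math.isnan(self.max_intra) or math.isnan(self.nn_dist):
            return False
        return self.nn_dist <= self.max_intra

    @property
    def flag_deep_intra(self) -> bool:
        return not math.isnan(self.max_intra) and self.max_intra > DEEP_INTRA_THRESHOLD


def species_gap_report(
    dm: DistanceMatrix, ds: Dataset, nn_scope: str = "all"
) -> list[GapRecord]:
    """Barcode-gap audit for every labelled species, sorted by name."""
    if nn_scope not in ("all", "congeneric"):
        raise ValueError(f"unknown nn_scope: {nn_scope!r}")
    if dm.ids != ds.ids:
        raise ValueError("distance matrix and dataset ids differ")
    species = sorted({r.species for r in ds.records if r.species})
    if len(species) < 2:
        raise ValueError("need at least 2 species for a gap report")
    idx_by_species = {
        sp: [i for i, r in enumerate(ds.records) if r.species == sp] for sp in species
    }
    genus_of = {sp: ds.records[idx_by_species[sp][0]].genus for sp in species}

    out: list[GapRecord] = []
    for sp in species:
        own = idx_by_species[sp]
        intra = [
            dm.d[i, j]
            for a, i in enumerate(own)
            for j in own[a + 1 :]
            if not math.isnan(dm.d[i, j])
        ]
        mean_intra = float(np.mean(intra)) if intra else math.nan
        max_intra = float(np.max(intra)) if intra else math.nan

        nn_dist, nn_specimen, nn_species = math.inf, "", ""
        for other_sp in species:
            if other_sp == sp:
                continue
            if nn_scope == "congeneric" and (
                not genus_of[sp] or genus_of[other_sp] != genus_of[sp]
            ):
                continue
            for j in idx_by_species[other_sp]:
                for i in own:
                    v = dm.d[i, j]
                    if not math.isnan(v) and v < nn_dist:
                        nn_dist = v
                        nn_specimen = ds.records[j].specimen_id
                        nn_species = other_sp
        out.append(
            GapRecord(
                species=sp,
                n=len(own),
                mean_intra=mean_intra,
                max_intra=max_intra,
                nn_species=nn_species,
                nn_specimen=nn_specimen,
                nn_dist=nn_dist if math.isfinite(nn_dist) else math.nan,
            )
        )
    return out


def gap_histogram(dm: DistanceMatrix, ds: Dataset) -> tuple[list[float], list[float]]:
    """(all intraspecific distances, all per-species NN distances).

    The two multisets are the raw material for barcode-gap histograms:
    a gap exists when max(intra) < min(NN).
    """
    recs = ds.records
    intra: list[float] = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if recs[i].species and recs[i].species == recs[j].species:
                v = dm.d[i, j]
                if not math.isnan(v):
                    intra.append(v)
    try:
        report = species_gap_report(dm, ds, nn_scope="all")
        nn = [r.nn_dist for r in report if not math.isnan(r.nn_dist)]
    except ValueError:
        nn = []
    return intra, nn


def gap_report_frame(report: list[GapRecord]) -> pd.DataFrame:
    """Audit table with distances rendered as percent (2 decimals)."""

    def pct(v: float) -> str:
        return "N/A" if math.isnan(v) else f"{100 * v:.2f}"

    rows = [
        {
            "species": r.species,
            "n": r.n,
            "mean_intra_pct": pct(r.mean_intra),
            "max_intra_pct": pct(r.max_intra),
            "nn_species": r.nn_species,
            "nn_specimen": r.nn_specimen,
            "nn_dist_pct": pct(r.nn_dist),
            "flag_nn_lt_2pct": r.flag_nn_lt_2pct,
            "flag_overlap": r.flag_overlap,
            "flag_deep_intra": r.flag_deep_intra,
        }
        for r in report
    ]
    return pd.DataFrame(rows)


def write_gap_report(report: list[GapRecord], path: str | Path) -> None:
    gap_report_frame(report).to_csv(path, sep="\t", index=False)
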