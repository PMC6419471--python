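"""End-to-end orchestration of the delimitation pathway.

``run_pipeline`` executes, in order: record filters -> haplotype
collapse -> K2P distances -> NJ tree (midpoint rooted, newick) -> the
three internal delimiters plus any imported partitions -> barcode-gap
audit -> per-method concordance against the species labels -> >=k-of-m
consensus -> pairwise adjusted-Wallace matrix.  Every artifact it
writes is recomputable by calling the underlying module functions; the
pipeline adds no arithmetic of its own.

Outputs land in ``out_dir``: ``summary.tsv``, ``gap_report.tsv``,
``motu_counts.tsv``, ``concordance.tsv``, ``wallace.tsv``,
``tree.nwk``, ``partitions/``, ``run.log`` and a ``MANIFEST`` listing
each artifact with its completion state.
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .concord import classify_concordance, concordance_summary, consensus_motus, wallace_matrix
from .datasets import Dataset, Partition, filter_records, load_dataset, write_partition
from .delimit import gap_partition, refined_single_linkage, threshold_partition
from .distances import (
    DistanceMatrix,
    collapse_haplotypes,
    distance_matrix,
    divergence_summary,
    normalized_summary,
)
from .gaps import species_gap_report, write_gap_report
from .trees import midpoint_root, nj_tree, write_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    fasta_path: str
    metadata_path: str
    out_dir: str
    min_len: int = 600
    translation_table: int = 5
    threshold_cutoff: float = 0.02
    gap_prior: float = 0.0215
    resl_seed_threshold: float = 0.022
    external_partitions: list[str] = field(default_factory=list)
    consensus_k: int = 4
    wallace_n_boot: int = 200
    seed: int = 0
    subset_by: str = ""  # optional metadata column to analyse per-subset
    min_overlap: int = 100


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


ARTIFACTS = [
    "summary.tsv",
    "gap_report.tsv",
    "motu_counts.tsv",
    "concordance.tsv",
    "wallace.tsv",
    "tree.nwk",
    "partitions",
    "run.log",
]


def _summary_frame(dm: DistanceMatrix, ds: Dataset) -> pd.DataFrame:
    rows = []
    for level in ("species", "genus", "family"):
        try:
            s = divergence_summary(dm, ds, level)
        except ValueError:
            continue
        rows.append(
            {
                "statistic": f"within_{level}",
                "n_taxa": s.n_taxa,
                "n_comparisons": s.n_comparisons,
                "min_pct": f"{100 * s.min:.2f}",
                "mean_pct": f"{100 * s.mean:.2f}",
                "max_pct": f"{100 * s.max:.2f}",
                "se_pct": f"{100 * s.se:.2f}",
            }
        )
    try:
        ns = normalized_summary(dm, ds)
        rows.append(
            {
                "statistic": "normalized_within_species",
                "n_taxa": ns.n_species,
                "n_comparisons": ns.n_species,
                "min_pct": "" if math.isnan(ns.min_between) else f"{100 * ns.min_between:.2f}",
                "mean_pct": f"{100 * ns.mean_within:.2f}",
                "max_pct": "",
                "se_pct": f"{100 * ns.se_within:.2f}",
            }
        )
    except ValueError:
        pass
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run the full pathway; returns a result dict with key artifacts.

    Any stage error aborts with the stage name; artifacts already
    written stay on disk and the MANIFEST records which are complete.
    """
    if cfg.subset_by:
        return _run_per_subset(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "partitions").mkdir(exist_ok=True)
    manifest: dict[str, str] = {a: "pending" for a in ARTIFACTS}

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("motu_concord")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    results: dict[str, object] = {}

    def stage(name: str):
        logger.info("stage: %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _write_manifest(out, manifest)
                    root_logger.removeHandler(handler)
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    try:
        logger.info(
            "motu-concord %s on python %s; seed=%d",
            __version__,
            platform.python_version(),
            cfg.seed,
        )
        logger.info("config: %s", json.dumps(cfg.__dict__, default=str))

        with stage("load"):
            ds = load_dataset(cfg.fasta_path, cfg.metadata_path)
            logger.info("loaded %d records", len(ds))

        with stage("filter"):
            ds, filter_report = filter_records(
                ds, min_len=cfg.min_len, translation_table=cfg.translation_table
            )
            results["filter_report"] = filter_report
            logger.info(
                "filter: kept %d of %d (short %d, stop %d, flagged %d)",
                filter_report.n_kept,
                filter_report.n_input,
                filter_report.n_removed_short,
                filter_report.n_removed_stop,
                filter_report.n_removed_flagged,
            )

        with stage("collapse_haplotypes"):
            haps, hap_map = collapse_haplotypes(ds)
            results["n_haplotypes"] = len(haps)
            logger.info("%d distinct haplotypes from %d records", len(haps), len(ds))

        with stage("distances"):
            dm = distance_matrix(ds, min_overlap=cfg.min_overlap)
            dm.write_tsv(out / "distance_matrix.tsv")

        with stage("summary"):
            _summary_frame(dm, ds).to_csv(out / "summary.tsv", sep="\t", index=False)
            manifest["summary.tsv"] = "complete"

        with stage("tree"):
            hap_dm = distance_matrix(haps, min_overlap=cfg.min_overlap)
            tree = midpoint_root(nj_tree(hap_dm))
            write_newick(tree, out / "tree.nwk")
            results["tree"] = tree
            manifest["tree.nwk"] = "complete"

        with stage("delimit"):
            partitions: dict[str, Partition] = {}
            partitions["threshold"] = threshold_partition(dm, cfg.threshold_cutoff)
            partitions["gap"] = gap_partition(dm, cfg.gap_prior)
            partitions["resl"] = refined_single_linkage(dm, cfg.resl_seed_threshold)
            if any(r.bin_id for r in ds.records) and all(r.bin_id for r in ds.records):
                partitions["bin"] = Partition(
                    {r.specimen_id: r.bin_id for r in ds.records}, method_name="bin"
                )
            from .datasets import read_partition

            for path in cfg.external_partitions:
                p = read_partition(path)
                p = p.restrict(ds.ids)
                partitions[p.method_name] = p
            for name, p in partitions.items():
                write_partition(p, out / "partitions" / f"{name}.tsv")
            results["partitions"] = partitions
            manifest["partitions"] = "complete"
            pd.DataFrame(
                [{"method": n, "n_motus": p.n_motus} for n, p in partitions.items()]
            ).to_csv(out / "motu_counts.tsv", sep="\t", index=False)
            manifest["motu_counts.tsv"] = "complete"

        with stage("gap_report"):
            report = species_gap_report(dm, ds)
            write_gap_report(report, out / "gap_report.tsv")
            results["gap_report"] = report
            manifest["gap_report.tsv"] = "complete"

        with stage("concordance"):
            species_partition = Partition(
                {r.specimen_id: r.species for r in ds.records if r.species},
                method_name="species",
            )
            results["species_partition"] = species_partition
            frames = []
            for name, p in results["partitions"].items():
                rep = classify_concordance(
                    species_partition, p.restrict(species_partition.assignment)
                )
                summ = concordance_summary(rep)
                summ.insert(0, "method", name)
                frames.append(summ)
                results.setdefault("concordance", {})[name] = rep
            pd.concat(frames, ignore_index=True).to_csv(
                out / "concordance.tsv", sep="\t", index=False
            )
            manifest["concordance.tsv"] = "complete"

        with stage("consensus"):
            plist = list(results["partitions"].values())
            k = min(cfg.consensus_k, len(plist))
            cons = consensus_motus(plist, k=k)
            results["consensus"] = cons
            write_partition(cons.to_partition(), out / "partitions" / "consensus.tsv")
            with open(out / "unassigned.txt", "w") as fh:
                fh.write("\n".join(cons.unassigned) + ("\n" if cons.unassigned else ""))

        with stage("wallace"):
            named = {"species": results["species_partition"]}
            for name, p in results["partitions"].items():
                named[name] = p.restrict(results["species_partition"].assignment)
            wm = wallace_matrix(named, n_boot=cfg.wallace_n_boot, seed=cfg.seed)
            wm.to_csv(out / "wallace.tsv", sep="\t", index_label="method")
            results["wallace"] = wm
            manifest["wallace.tsv"] = "complete"

        manifest["run.log"] = "complete"
        _write_manifest(out, manifest)
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict[str, str]) -> None:
    with open(out / "MANIFEST", "w") as fh:
        for name, state in manifest.items():
            fh.write(f"{name}\t{state}\n")


def _run_per_subset(cfg: RunConfig) -> dict[str, object]:
    """Split the input on a metadata column, run each subset, sum counts.

    Each subset gets a full report bundle under
    ``out_dir/subsets/<value>/``; the top level gets an aggregated
    ``motu_counts.tsv`` whose ``Total`` row is the sum over subsets.
    """
    from dataclasses import replace as _replace

    from .datasets import write_dataset

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(cfg.fasta_path, cfg.metadata_path)
    if cfg.subset_by not in ("genus", "subfamily", "site"):
        raise ValueError(f"subset_by must be a grouping column, got {cfg.subset_by!r}")
    groups: dict[str, list] = {}
    for rec in ds.records:
        groups.setdefault(getattr(rec, cfg.subset_by) or "unassigned", []).append(rec)

    count_frames = []
    sub_results: dict[str, dict] = {}
    for value in sorted(groups):
        sub_dir = out / "subsets" / value
        sub_dir.mkdir(parents=True, exist_ok=True)
        sub_ds = Dataset(groups[value], alignment_length=ds.alignment_length)
        write_dataset(sub_ds, sub_dir / "input.fasta", sub_dir / "input.tsv")
        sub_cfg = _replace(
            cfg,
            fasta_path=str(sub_dir / "input.fasta"),
            metadata_path=str(sub_dir / "input.tsv"),
            out_dir=str(sub_dir),
            subset_by="",
        )
        sub_results[value] = run_pipeline(sub_cfg)
        counts = pd.read_csv(sub_dir / "motu_counts.tsv", sep="\t")
        counts = counts.rename(columns={"n_motus": value}).set_index("method")
        count_frames.append(counts)

    merged = pd.concat(count_frames, axis=1)
    merged["Total"] = merged.sum(axis=1)
    merged.to_csv(out / "motu_counts.tsv", sep="\t")
    return {"subsets": sub_results, "motu_counts": merged}
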