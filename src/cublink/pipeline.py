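"""End-to-end pipeline orchestration: indices -> adaptation -> screen ->
expression response, from a single config, with a deterministic manifest.

The pipeline is a pure function of (inputs, config): rerunning the same
config over the same files reproduces every output byte for byte, and the
manifest records sha256 checksums and record counts per stage so that can
be verified cheaply.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import adaptation_table, organism_usage, sid
from .cds_io import CodonCountTable, count_codons, read_and_qc
from .expression import (
    DEFAULT_GROUPS,
    ddct_fold_change,
    merge_degs,
    profile_report,
    rescue_profile_id,
    assign_and_test_profiles,
    stem_profiles,
)
from .indices import gene_index_table, genome_rscu_table, index_summary_and_correlations
from .screen import build_rscu_matrix, organism_profile, screen_genes, screen_summary

log = logging.getLogger("cublink")

ALL_STAGES = ("indices", "adapt", "screen", "expression")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    ``query_fasta`` is the organism screened gene by gene (the plant side of
    the study design); ``partner_fasta`` is the organism whose profile the
    query is screened against and whose genes get CAI/RCDI relative to the
    query reference (the bacterium side).
    """

    out_dir: str
    query_fasta: str | None = None
    partner_fasta: str | None = None
    counts_tsv: str | None = None
    groups_tsv: str | None = None
    deg_a_tsv: str | None = None
    deg_b_tsv: str | None = None
    ct_tsv: str | None = None
    stages: Sequence[str] = ALL_STAGES
    # thresholds
    min_codons: int = 30
    r_min: float = 0.5
    p_max: float = 0.05
    fdr: str | None = None
    alpha: float = 0.05
    lfc_min: float = 1.0
    profile_c: int = 2
    profile_m: int = 50
    baseline: str = "Control"
    group_order: Sequence[str] = DEFAULT_GROUPS
    reference_gene: str = "GAPDH"
    sid_basis: str = "rscu"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        needs = {
            "indices": ["query_fasta", "partner_fasta"],
            "adapt": ["query_fasta", "partner_fasta"],
            "screen": ["query_fasta", "partner_fasta"],
            "expression": ["counts_tsv", "groups_tsv"],
        }
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
            for fld in needs[stage]:
                value = getattr(self, fld)
                if value is None:
                    raise ConfigError(f"stage {stage!r} requires config field {fld!r}")
                if not Path(value).exists():
                    raise ConfigError(f"{fld}: no such file: {value}")
        if not 0 < self.p_max <= 1 or not 0 < self.alpha <= 1:
            raise ConfigError("p_max and alpha must be in (0, 1]")
        if not -1 <= self.r_min <= 1:
            raise ConfigError("r_min must be in [-1, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data: dict = {
            "package": {"name": "cublink", "version": __version__},
            "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
            "inputs": {},
            "stages": {},
        }

    def add_input(self, name: str, path: str | None) -> None:
        if path is not None:
            self.data["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    def add_stage(self, stage: str, outputs: dict[str, Path], counts: dict[str, int], seconds: float) -> None:
        self.data["stages"][stage] = {
            "outputs": {
                name: {"path": p.name, "sha256": _sha256(p)} for name, p in outputs.items()
            },
            "record_counts": counts,
            "seconds": round(seconds, 3),
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _read_counts(config: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
    gmap = pd.read_csv(config.groups_tsv, sep="\t")
    if not {"sample", "group"} <= set(gmap.columns):
        raise ConfigError("groups_tsv needs columns: sample, group")
    groups = gmap.set_index("sample")["group"]
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise ConfigError(f"samples without group label: {sorted(missing)}")
    return counts, groups.loc[list(counts.columns)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write all outputs plus a
    manifest (``manifest.json``) into ``config.out_dir``.

    Stages read prior outputs from the same directory, so a stage subset can
    extend an earlier partial run.  Returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    for name in ("query_fasta", "partner_fasta", "counts_tsv", "groups_tsv",
                 "deg_a_tsv", "deg_b_tsv", "ct_tsv"):
        manifest.add_input(name, getattr(config, name))

    query = partner = None
    if any(s in config.stages for s in ("indices", "adapt", "screen")):
        query, query_qc = read_and_qc(config.query_fasta, min_codons=config.min_codons)
        partner, partner_qc = read_and_qc(config.partner_fasta, min_codons=config.min_codons)
        log.info("QC: query %d pass / %d fail; partner %d pass / %d fail",
                 query_qc.n_pass, query_qc.n_fail, partner_qc.n_pass, partner_qc.n_fail)
        query_counts = count_codons(query)
        partner_counts = count_codons(partner)

    if "indices" in config.stages:
        t0 = time.perf_counter()
        outputs, counts = {}, {}
        for label, seqs, qc in (("query", query, query_qc), ("partner", partner, partner_qc)):
            table = gene_index_table(seqs)
            p = out / f"{label}_indices.tsv"
            _write_tsv(table.reset_index(), p)
            outputs[f"{label}_indices"] = p
            counts[f"{label}_genes"] = len(table)
            qc_path = out / f"{label}_qc.tsv"
            qc.to_tsv(qc_path)
            outputs[f"{label}_qc"] = qc_path
            summary, r, pmat = index_summary_and_correlations(table)
            sp = out / f"{label}_index_summary.tsv"
            _write_tsv(summary.rename_axis("index").reset_index(), sp)
            outputs[f"{label}_index_summary"] = sp
            rp = out / f"{label}_index_correlations.tsv"
            _write_tsv(r.rename_axis("index").reset_index(), rp)
            outputs[f"{label}_index_correlations"] = rp
        rscu_tab = genome_rscu_table({"query": query_counts, "partner": partner_counts})
        p = out / "genome_rscu.tsv"
        _write_tsv(rscu_tab, p)
        outputs["genome_rscu"] = p
        counts["rscu_rows"] = len(rscu_tab)
        manifest.add_stage("indices", outputs, counts, time.perf_counter() - t0)

    if "adapt" in config.stages:
        t0 = time.perf_counter()
        adapt = adaptation_table(partner_counts, query_counts)
        p = out / "partner_adaptation.tsv"
        _write_tsv(adapt.reset_index(), p)
        sid_values = {
            basis: sid(organism_usage(query_counts, basis), organism_usage(partner_counts, basis))
            for basis in ("rscu", "frequency")
        }
        sp = out / "sid.json"
        with open(sp, "w") as fh:
            json.dump({"sid": sid_values[config.sid_basis], "by_basis": sid_values},
                      fh, indent=1, sort_keys=True)
        manifest.add_stage(
            "adapt",
            {"partner_adaptation": p, "sid": sp},
            {"partner_genes": len(adapt)},
            time.perf_counter() - t0,
        )

    screen_df = None
    if "screen" in config.stages:
        t0 = time.perf_counter()
        matrix = build_rscu_matrix(query_counts)
        profile = organism_profile(partner_counts)
        screen_df = screen_genes(
            matrix, profile, r_min=config.r_min, p_max=config.p_max, fdr=config.fdr
        )
        p = out / "screen.tsv"
        _write_tsv(screen_df, p)
        sp = out / "screen_summary.json"
        with open(sp, "w") as fh:
            json.dump(screen_summary(screen_df), fh, indent=1, sort_keys=True)
        manifest.add_stage(
            "screen",
            {"screen": p, "screen_summary": sp},
            {"query_genes": len(screen_df), "selected": int(screen_df["selected"].sum())},
            time.perf_counter() - t0,
        )

    if "expression" in config.stages:
        t0 = time.perf_counter()
        outputs, rc = {}, {}
        counts_df, groups = _read_counts(config)
        library_sizes = counts_df.sum(axis=0)  # before any subsetting
        if screen_df is None and (out / "screen.tsv").exists():
            screen_df = pd.read_csv(out / "screen.tsv", sep="\t")
        if screen_df is not None:
            selected = set(screen_df.loc[screen_df["selected"], "gene_id"])
            subset = counts_df.loc[counts_df.index.intersection(selected)]
            if len(subset):
                counts_df = subset
            p = out / "selected_counts.tsv"
            _write_tsv(counts_df.rename_axis("gene_id").reset_index(), p)
            outputs["selected_counts"] = p
            rc["selected_count_genes"] = len(counts_df)
        if config.deg_a_tsv and config.deg_b_tsv:
            merged = merge_degs(
                pd.read_csv(config.deg_a_tsv, sep="\t"),
                pd.read_csv(config.deg_b_tsv, sep="\t"),
                alpha=config.alpha,
                lfc_min=config.lfc_min,
            )
            p = out / "merged_degs.json"
            with open(p, "w") as fh:
                json.dump(
                    {
                        "common_up": list(merged.common_up),
                        "common_down": list(merged.common_down),
                        "conflicts": list(merged.conflicts),
                        "n_up": merged.n_up,
                        "n_down": merged.n_down,
                    },
                    fh, indent=1, sort_keys=True,
                )
            outputs["merged_degs"] = p
            rc["common_up"] = merged.n_up
            rc["common_down"] = merged.n_down
        profiles = stem_profiles(
            T=len(config.group_order), c=config.profile_c, m=config.profile_m
        )
        tested, assignment = assign_and_test_profiles(
            counts_df, groups, profiles,
            group_order=config.group_order, baseline=config.baseline,
            alpha=config.alpha, library_sizes=library_sizes,
        )
        report = profile_report(tested)
        report["is_rescue"] = report["profile_id"] == rescue_profile_id(tested)
        p = out / "profile_report.tsv"
        _write_tsv(report, p)
        outputs["profile_report"] = p
        ap = out / "profile_assignments.tsv"
        _write_tsv(assignment.rename_axis("gene_id").reset_index(), ap)
        outputs["profile_assignments"] = ap
        rc["profiles"] = len(report)
        rc["significant_profiles"] = int(report["significant"].sum())
        if config.ct_tsv:
            folds = ddct_fold_change(
                pd.read_csv(config.ct_tsv, sep="\t"),
                control_group=config.baseline,
                reference_gene=config.reference_gene,
            )
            p = out / "ddct_folds.tsv"
            _write_tsv(folds, p)
            outputs["ddct_folds"] = p
            rc["ct_measurements"] = len(folds)
        manifest.add_stage("expression", outputs, rc, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest.data
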