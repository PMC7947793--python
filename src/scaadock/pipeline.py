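"""End-to-end screening pipeline: enumerate -> build -> restrain -> dock ->
aggregate -> window -> heatmap -> reduction proposal, with reproducible
seeding and file outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .alphabet import TranslationTable, default_table, default_template
from .analysis import (
    aggregate_poses,
    flag_reference,
    positional_heatmap,
    propose_exclusions,
    records_to_dataframe,
    select_best_binders,
)
from .builder import DihedralTable, build_library_peptide, default_dihedrals
from .docking import MCSchedule, ScoringParams, annotate_charges, dock_peptide
from .library import LibrarySpec, enumerate_library, library_size, reduction_factor
from .metrics import ContactSpec
from .restraints import LoopRange, ReceptorAnnotation, make_default_airs
from .structure import Structure, read_structure

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one screening run."""

    seed: int
    receptor_path: str = "fixture"  # "fixture" -> built-in mock receptor
    receptor_chains: list[str] | None = None
    cdr3a: tuple[str, int, int] | None = None  # (chain, first, last)
    cdr3b: tuple[str, int, int] | None = None
    dihedral_csv: str | None = None
    alphabet_csv: str | None = None
    reference_triad: str | None = None  # natural codes, e.g. "NVR"
    exclusions: dict[int, list[str]] = field(default_factory=dict)
    restraint_lower: float = 4.0
    restraint_upper: float = 8.0
    restraint_force_constant: float = 50.0
    restraint_split: bool = False
    n_poses: int = 100
    mc_steps: int = 600
    contact_cutoff: float = 6.0
    sigma_mode: str = "sd"  # or "sem"
    heatmap_scope: str = "window"  # or "all"
    auto_reduce: bool = False
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        if "cdr3a" in data and data["cdr3a"] is not None:
            data["cdr3a"] = tuple(data["cdr3a"])
        if "cdr3b" in data and data["cdr3b"] is not None:
            data["cdr3b"] = tuple(data["cdr3b"])
        if "exclusions" in data and data["exclusions"]:
            data["exclusions"] = {int(k): list(v) for k, v in data["exclusions"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cdr3a"] = list(self.cdr3a) if self.cdr3a else None
        d["cdr3b"] = list(self.cdr3b) if self.cdr3b else None
        return d

    def config_hash(self) -> str:
        """Hash of the scientifically relevant settings (output path excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_receptor(config: RunConfig) -> tuple[Structure, ReceptorAnnotation]:
    if config.receptor_path == "fixture":
        from .fixtures import make_mock_receptor

        return make_mock_receptor(config.seed)
    if config.cdr3a is None or config.cdr3b is None:
        raise ValueError("cdr3a and cdr3b residue ranges are required for a PDB receptor")
    receptor = read_structure(config.receptor_path, config.receptor_chains)
    annotation = ReceptorAnnotation(
        cdr3a=LoopRange(*config.cdr3a), cdr3b=LoopRange(*config.cdr3b)
    )
    for loop, tag in ((annotation.cdr3a, "CDR3a"), (annotation.cdr3b, "CDR3b")):
        missing = []
        for resseq in range(loop.first, loop.last + 1):
            try:
                res = receptor.get_residue(loop.chain, resseq)
            except KeyError:
                missing.append(resseq)
                continue
            if any(res.atom(n) is None for n in ("N", "CA", "C")):
                missing.append(resseq)
        if missing:
            raise ValueError(f"{tag} range has missing backbone atoms at residues {missing}")
    annotate_charges(receptor)
    return receptor, annotation


def _header_lines(config: RunConfig) -> list[str]:
    return [
        f"# config_hash: {config.config_hash()}",
        f"# seed: {config.seed}",
    ]


def _write_csv(df, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full screening pipeline and write its report files.

    Returns a bundle with the records, window, heatmap, proposed and
    applied exclusions, and the paths of all written artifacts.  Every
    peptide is docked with seed ``config.seed + index`` so a run over k
    peptides equals k independent docking calls.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("scaadock")
    root.addHandler(handler)
    try:
        return _run_pipeline_inner(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(config: RunConfig, out_dir: Path) -> dict:
    t_all = time.perf_counter()
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    table = (
        TranslationTable.from_csv(config.alphabet_csv)
        if config.alphabet_csv
        else default_table()
    )
    template = default_template()
    dihedrals = (
        DihedralTable.from_csv(config.dihedral_csv)
        if config.dihedral_csv
        else default_dihedrals()
    )

    stage = "load-receptor"
    try:
        receptor, annotation = _load_receptor(config)
        logger.info("[%s] receptor with %d residues", stage, len(receptor.residues))

        stage = "enumerate"
        spec = LibrarySpec(
            template=template,
            exclusions={k: frozenset(v) for k, v in config.exclusions.items()},
        )
        peptides = enumerate_library(spec)
        logger.info("[%s] %d peptides", stage, len(peptides))

        stage = "dock"
        schedule = MCSchedule(steps=config.mc_steps)
        params = ScoringParams()
        contact_spec = ContactSpec(cutoff=config.contact_cutoff)
        records = []
        restraints = None
        t0 = time.perf_counter()
        for index, (triad, _sequence) in enumerate(peptides):
            ligand = annotate_charges(build_library_peptide(triad, template, dihedrals))
            if restraints is None:
                restraints = make_default_airs(
                    ligand, annotation,
                    lower=config.restraint_lower, upper=config.restraint_upper,
                    force_constant=config.restraint_force_constant,
                    split=config.restraint_split,
                )
            pose_set = dock_peptide(
                receptor, ligand, restraints, params,
                n_poses=config.n_poses, seed=config.seed + index,
                schedule=schedule, contact_spec=contact_spec,
            )
            records.append(aggregate_poses(pose_set, triad))
        logger.info(
            "[%s] %d peptides x %d poses in %.1f s",
            stage, len(records), config.n_poses, time.perf_counter() - t0,
        )

        stage = "window"
        window = select_best_binders(records, sigma_mode=config.sigma_mode)
        logger.info("[%s] %d of %d records in the ±σ window",
                    stage, len(window.member_ids), len(records))

        reference = None
        if config.reference_triad:
            stage = "flag-reference"
            reference = flag_reference(records, tuple(config.reference_triad), table)
            logger.info("[%s] translated reference %s in window: %s",
                        stage, reference.sequence, reference.in_window)

        stage = "heatmap"
        subset = None if config.heatmap_scope == "window" else list(records)
        heatmap = positional_heatmap(records, subset=subset, template=template)

        stage = "reduce"
        proposals = propose_exclusions(heatmap)
        reduced_sizes = [
            len(a) for a in LibrarySpec(
                template=template,
                exclusions={k: v for k, v in proposals.items()},
            ).effective_alphabets()
        ]
        logger.info("[%s] proposed exclusions %s -> %d peptides",
                    stage, {k: sorted(v) for k, v in proposals.items()},
                    library_size(reduced_sizes))

        stage = "report"
        results_csv = out_dir / "results.csv"
        _write_csv(records_to_dataframe(records), results_csv, config)
        heatmap_csv = out_dir / "heatmap.csv"
        hm_long = heatmap.mean_energy.reset_index(names="scaa_class").melt(
            id_vars="scaa_class", var_name="position", value_name="mean_E"
        )
        hm_long["n"] = heatmap.counts.reset_index(drop=True).melt()["value"].values
        _write_csv(hm_long, heatmap_csv, config)
        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "library_size": len(records),
            "window": {
                "E_center": window.e_center, "E_sigma": window.e_sigma,
                "C_center": window.c_center, "C_sigma": window.c_sigma,
                "sigma_mode": window.sigma_mode,
                "members": list(window.member_ids),
            },
            "reference": None if reference is None else {
                "triad": "".join(reference.triad),
                "sequence": reference.sequence,
                "in_window": reference.in_window,
            },
            "proposed_exclusions": {str(k): sorted(v) for k, v in proposals.items()},
            "reduced_library_size": library_size(reduced_sizes),
            "reduction_factor_vs_natural": reduction_factor(
                library_size([20] * len(template.triad_positions)), len(records)
            ) if records else None,
        }
        report_json = out_dir / "report.json"
        report_json.write_text(json.dumps(report, indent=2))
        logger.info("pipeline finished in %.1f s", time.perf_counter() - t_all)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "records": records,
        "window": window,
        "heatmap": heatmap,
        "reference": reference,
        "proposed_exclusions": proposals,
        "report": report,
        "paths": {
            "results_csv": results_csv,
            "heatmap_csv": heatmap_csv,
            "report_json": report_json,
            "config_yaml": out_dir / "config.yaml",
            "run_log": out_dir / "run.log",
        },
    }
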