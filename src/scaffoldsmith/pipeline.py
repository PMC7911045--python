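"""End-to-end orchestration: structure -> profiles -> patches -> library.

Stage order mirrors the scaffold-selection workflow: candidate filter, solvent
accessibility, MSA conservation, ΔΔG mutability, mutable-residue selection,
patch detection/completion, and (optionally) NNK library design over the
top-ranked patch.  Every stage writes its table before the next starts, so a
failure leaves prior outputs intact, and all outputs are pure functions of the
inputs plus the config (re-runs are byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .conservation import (column_conservation, dedupe, map_to_structure,
                           read_alignment, write_conservation_table)
from .errors import ConfigError
from .libdesign import LibraryDesign, DegenerateCodon, library_diversity, write_design_json
from .mutability import (build_residue_profiles, mutability_profile,
                         read_positionscan, select_mutable, surrogate_ddg,
                         write_mutability_table, write_profile_table)
from .patchfinder import (build_contact_graph, complete_patch, find_patches,
                          patch_independence, write_patch_report)
from .structure_model import (FilterCriteria, candidate_filter, compute_sasa,
                              read_structure, relative_sasa,
                              write_annotated_structure, write_exposure_table)

log = logging.getLogger("scaffoldsmith")


@dataclass
class PipelineConfig:
    structure: str = ""
    msa: str = ""
    ddg: str | None = None  # positionscan file; None -> surrogate model
    chain: str | None = None
    msa_ref_id: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0

    # thresholds (printed defaults of the selection procedure where one exists)
    cons_max: float = 90.0
    mut_min: float = 50.0
    ddg_threshold: float = 0.5
    rsasa_threshold: float = 0.25
    contact_cutoff: float = 8.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    patch_min: int = 10
    patch_max: int = 12

    library_codon: str = "NNK"
    design_library: bool = True
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        crit = raw.pop("filter_criteria", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if crit:
            cfg.filter_criteria = FilterCriteria(**crit)
        return cfg

    def validate(self) -> None:
        problems = []
        if not self.structure or not Path(self.structure).exists():
            problems.append(f"structure file not found: {self.structure!r}")
        if not self.msa or not Path(self.msa).exists():
            problems.append(f"msa file not found: {self.msa!r}")
        if self.ddg is not None and not Path(self.ddg).exists():
            problems.append(f"ddg file not found: {self.ddg!r}")
        for name, value, lo, hi in [
            ("cons_max", self.cons_max, 0, 100),
            ("mut_min", self.mut_min, 0, 100),
            ("rsasa_threshold", self.rsasa_threshold, 0, 2),
            ("contact_cutoff", self.contact_cutoff, 0.1, 100),
            ("probe_radius", self.probe_radius, 0.0, 10),
        ]:
            if not (lo <= value <= hi):
                problems.append(f"{name}={value} outside [{lo}, {hi}]")
        if self.sasa_points < 24:
            problems.append("sasa_points must be >= 24")
        if not (1 <= self.patch_min <= self.patch_max):
            problems.append("patch window must satisfy 1 <= patch_min <= patch_max")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class PipelineResult:
    verdict: Any
    exposure: dict
    conservation_mapped: dict
    mutability: Any
    selection: Any
    patches: list
    completed: list
    library: LibraryDesign | None
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = read_structure(config.structure)
    chain = config.chain or next(iter(model.chains))

    verdict = candidate_filter(model, config.filter_criteria)
    (out / "filter_verdict.json").write_text(json.dumps({
        "passed": verdict.passed, "reasons": verdict.reasons,
        "metrics": verdict.metrics}, indent=2) + "\n")
    log.info("filter: passed=%s reasons=%s", verdict.passed, verdict.reasons)

    sasa = compute_sasa(model, probe_radius=config.probe_radius,
                        n_points=config.sasa_points)
    exposure = relative_sasa(model, sasa.per_residue(),
                             surface_threshold=config.rsasa_threshold)
    write_exposure_table(model, exposure, out / "sasa.tsv")
    n_surface = sum(e.surface for e in exposure.values())
    log.info("sasa: %d residues, %d surface", len(exposure), n_surface)

    aln = dedupe(read_alignment(config.msa, ref_id=config.msa_ref_id))
    profile = column_conservation(aln)
    write_conservation_table(profile, out / "conservation.tsv")
    mapping = map_to_structure(profile, model, chain)
    log.info("conservation: %d positions, mapped %d residues (identity %.1f%%)",
             len(profile.values), len(mapping.values), mapping.identity_pct)

    if config.ddg is not None:
        matrix = read_positionscan(config.ddg)
    else:
        matrix = surrogate_ddg(model, exposure)
    mut = mutability_profile(matrix, threshold=config.ddg_threshold)
    write_mutability_table(mut, matrix, out / "mutability.tsv")
    log.info("mutability: %d positions scored (source=%s)", len(mut.values), mut.source)

    profiles = build_residue_profiles(model, mapping.values, mut.values, exposure)
    write_profile_table(profiles, out / "profiles.tsv")
    selection = select_mutable(profiles, cons_max=config.cons_max,
                               mut_min=config.mut_min)
    (out / "selected.tsv").write_text(
        "chain\tseq_num\n"
        + "".join(f"{k[0]}\t{k[1]}\n" for k in sorted(selection.selected)))
    if selection.excluded_missing:
        (out / "selection_diagnostics.tsv").write_text(
            "chain\tseq_num\tmissing\n"
            + "".join(f"{k[0]}\t{k[1]}\t{why}\n"
                      for k, why in selection.excluded_missing))
    log.info("select: %d mutable residues (%d lacked scores)",
             len(selection.selected), len(selection.excluded_missing))

    graph = build_contact_graph(model, selection.selected, cutoff=config.contact_cutoff)
    patches = find_patches(graph, mut.values)
    completed = [complete_patch(p, model, profiles, target_min=config.patch_min,
                                target_max=config.patch_max,
                                cutoff=config.contact_cutoff)
                 for p in patches]
    write_patch_report(completed, profiles, out / "patches.tsv")
    membership = {k: float(i + 1) for i, p in enumerate(completed) for k in p.members}
    write_annotated_structure(model, membership, out / "patches_annotated.pdb")
    if len(completed) >= 2:
        records = patch_independence(completed, model,
                                     min_separation=config.contact_cutoff)
        (out / "patch_independence.tsv").write_text(
            "patch_a\tpatch_b\tdisjoint\tmin_distance\tindependent\n"
            + "".join(f"{r.patch_a + 1}\t{r.patch_b + 1}\t{int(r.disjoint)}"
                      f"\t{r.min_distance:.2f}\t{int(r.independent)}\n"
                      for r in records))
    log.info("patches: %d found, top size %d",
             len(completed), completed[0].size if completed else 0)

    library = None
    if config.design_library and completed:
        top = completed[0]
        chain_residues = model.residues(chain)
        index = {r.key: i + 1 for i, r in enumerate(chain_residues)}
        positions = sorted(index[k] for k in top.members if k in index)
        library = LibraryDesign(
            scaffold_protein=model.sequence(chain),
            randomized_positions=tuple(positions),
            codons={p: DegenerateCodon(config.library_codon) for p in positions},
        )
        write_design_json(library, out / "library.json")
        div = library_diversity(library)
        log.info("library: %d positions, protein diversity %.3e",
                 len(positions), float(div["protein_diversity"]))

    (out / "run_log.json").write_text(json.dumps({
        "version": __version__,
        "parameters": {k: v for k, v in vars(config).items()
                       if not isinstance(v, FilterCriteria)},
        "counts": {
            "residues": len(model.residues()),
            "surface": n_surface,
            "selected": len(selection.selected),
            "patches": len(completed),
        },
    }, indent=2, default=str) + "\n")

    return PipelineResult(verdict=verdict, exposure=exposure,
                          conservation_mapped=mapping.values, mutability=mut,
                          selection=selection, patches=patches,
                          completed=completed, library=library, out_dir=out)
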