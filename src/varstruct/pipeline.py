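"""End-to-end variant-impact pipeline.

For each missense variant: verify the wild-type residue, build the mutant
model, compute both structural profiles, diff them, attach the consensus
stability call, conservation grade and fold region, then aggregate the
cohort summary and render reports.  Fully deterministic: identical inputs
and configuration give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .compare import ImpactReport, attach_stability, diff_profiles
from .conserve import (ConservationProfile, conservation_grades,
                       is_highly_conserved, read_grades)
from .core import ProteinStructure, VariantSpec, VarstructError
from .io import (PredictorTable, parse_variant_table, read_alignment,
                 read_pdb, read_predictor_table, write_pdb)
from .mutate import build_mutant
from .regions import (RegionAnnotation, cohort_summary, derive_regions,
                      summary_to_markdown)
from .structops import StructuralProfile, build_profile

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    structure_path: str = ""
    numbering_offset: int = 0
    variant_table_path: str = ""
    predictor_table_path: str = ""
    msa_path: str = ""
    msa_reference: str = ""
    grades_path: str = ""
    region_overrides: dict = field(default_factory=dict)
    salt_bridge_cutoff: float = 4.0
    consensus_cutoffs: dict = field(default_factory=dict)
    signal_peptide_length: int = 23
    sasa_points: int = 960
    seed: int = 0
    output_dir: str = "varstruct_out"

    def digest(self) -> str:
        # the output directory does not influence results, so it is not
        # part of the configuration identity
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def header(self) -> dict:
        return {"package": "varstruct", "version": __version__,
                "config_hash": self.digest(),
                "config": dataclasses.asdict(self)}


@dataclass
class PipelineResult:
    reports: list[ImpactReport]
    summary: dict
    wt_profile: StructuralProfile
    annotation: RegionAnnotation
    failures: list[tuple[str, str]] = field(default_factory=list)


def analyze_variants(structure: ProteinStructure, variants: list[VariantSpec],
                     predictor_table: PredictorTable | None = None,
                     conservation: ConservationProfile | None = None,
                     annotation: RegionAnnotation | None = None,
                     sasa_points: int = 960, seed: int = 0,
                     signal_peptide_length: int = 23,
                     region_overrides: dict | None = None,
                     write_mutants_to: str | None = None
                     ) -> PipelineResult:
    """Run the full comparison for a list of variants against one model."""
    wt_profile = build_profile(structure, n_points=sasa_points)
    if annotation is None:
        annotation = derive_regions(wt_profile.ss,
                                    signal_len=signal_peptide_length,
                                    overrides=region_overrides)
    reports: list[ImpactReport] = []
    failures: list[tuple[str, str]] = []
    for v in variants:
        try:
            mutant, info = build_mutant(structure, v, seed=seed)
            mut_profile = build_profile(mutant, n_points=sasa_points)
            rep = diff_profiles(wt_profile, mut_profile, v)
            if write_mutants_to:
                write_pdb(mutant, os.path.join(write_mutants_to,
                                               f"{v.label}.pdb"),
                          remarks=[f"variant {v.label} seed {info['seed']} "
                                   f"rotamers {info['library_version']}"])
        except VarstructError as exc:
            rep = ImpactReport(variant=v, error=str(exc))
            failures.append((v.label, str(exc)))
            logger.warning("variant %s failed: %s", v.label, exc)
        rep.region = annotation.region_of(v.position)
        attach_stability(rep, predictor_table)
        if conservation is not None and v.position in conservation.grades:
            rep.conservation_grade = conservation.grade(v.position)
            rep.conserved_flag = is_highly_conserved(conservation, v.position)
        reports.append(rep)
    summary = cohort_summary(reports, annotation) if reports else {
        "n_variants": 0}
    return PipelineResult(reports, summary, wt_profile, annotation, failures)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven entry point; writes TSV/JSON/HTML outputs to the
    configured directory and returns the in-memory result."""
    structure = read_pdb(config.structure_path, offset=config.numbering_offset)
    variants = parse_variant_table(config.variant_table_path)
    predictor_table = None
    if config.predictor_table_path:
        predictor_table = read_predictor_table(config.predictor_table_path,
                                               cutoffs=config.consensus_cutoffs)
    conservation = None
    if config.grades_path:
        conservation = read_grades(config.grades_path)
    elif config.msa_path:
        msa = read_alignment(config.msa_path)
        ref = config.msa_reference or msa.ids[0]
        conservation = conservation_grades(msa, ref)

    os.makedirs(config.output_dir, exist_ok=True)
    result = analyze_variants(
        structure, variants, predictor_table, conservation,
        sasa_points=config.sasa_points, seed=config.seed,
        signal_peptide_length=config.signal_peptide_length,
        region_overrides={k: tuple(v) for k, v in
                          config.region_overrides.items()} or None)

    header = config.header()
    if variants and all(e for _, e in result.failures) and \
            len(result.failures) == len(variants):
        raise VarstructError("every variant failed the wild-type check")

    out = config.output_dir
    rows = [r.to_dict() for r in result.reports]
    df = pd.DataFrame(rows)
    with open(os.path.join(out, "impact_reports.tsv"), "w") as fh:
        fh.write(f"# varstruct {__version__} config {header['config_hash']}\n")
        df.to_csv(fh, sep="\t", index=False)
    with open(os.path.join(out, "impact_reports.json"), "w") as fh:
        json.dump({**header, "reports": rows}, fh, indent=1, default=str)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump({**header, "summary": result.summary}, fh, indent=1)
    result.wt_profile.to_tsv(os.path.join(out, "wildtype_profile.tsv"))
    result.annotation.to_tsv(os.path.join(out, "regions.tsv"))
    from .report import render_html
    with open(os.path.join(out, "report.html"), "w") as fh:
        fh.write(render_html(result, header))
    with open(os.path.join(out, "summary.md"), "w") as fh:
        fh.write(summary_to_markdown(result.summary) + "\n")
    return result
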