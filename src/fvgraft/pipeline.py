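"""End-to-end humanization pipeline orchestration.

``run_pipeline`` chains the stages — numbering, germline selection, CDR
grafting, structural contact analysis (when an Fv model is supplied),
back-mutation recommendation, reversion, and optionally interface/affinity
profiling of an antibody-antigen complex — and writes each stage's report
into an output directory.  Outputs are deterministic for identical inputs
and configuration; no timestamps enter report bodies.  Stage failures are
re-raised with the stage name attached.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from pathlib import Path
from typing import Mapping, Sequence

from . import germline as germline_mod
from . import grafting, kabat, structure
from .affinity import format_profile_text, profile_complex, write_profile_tsv
from .config import PipelineConfig
from .errors import FvGraftError, InputError

log = logging.getLogger("fvgraft")


@contextmanager
def _stage(name: str):
    try:
        yield
    except FvGraftError as exc:
        if not str(exc).startswith(f"[{name}]"):
            exc.args = (f"[{name}] {exc}",) + exc.args[1:]
        raise


def run_pipeline(
    donors: Mapping[str, str],
    outdir: str | Path,
    libraries: Mapping[str, Sequence[germline_mod.GermlineRecord]] | None = None,
    fv_structures: Mapping[str, str | Path] | None = None,
    support_maps: Mapping[str, structure.SupportMap] | None = None,
    complex_structure: tuple[str | Path, Sequence[str], Sequence[str]] | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full humanization pipeline.

    Parameters
    ----------
    donors:
        Chain type -> donor (nonhuman) amino-acid sequence.
    libraries:
        Chain type -> germline records; packaged libraries by default.
    fv_structures:
        Optional chain type -> PDB path of the donor Fv model, used to derive
        the framework-CDR support map.
    support_maps:
        Optional pre-computed support maps (e.g. transcribed narratives);
        merged over structure-derived maps per chain.
    complex_structure:
        Optional (PDB path, side A chain ids, side B chain ids) for the
        affinity stage.
    """
    config = (config or PipelineConfig()).validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not donors:
        raise InputError("no donor sequences given")
    libraries = dict(libraries or {})
    fv_structures = dict(fv_structures or {})
    support_maps = dict(support_maps or {})
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed, "chains": {}}
    log.info("pipeline start: config %s, seed %d", config.config_hash(), config.seed)

    for chain_type, sequence in sorted(donors.items()):
        tag = "h" if chain_type == "heavy" else "l"
        chain_summary: dict = {}

        with _stage(f"numbering/{chain_type}"):
            donor = kabat.assign_kabat_numbering(sequence, chain_type, source_id=f"donor_{chain_type}")
            with open(outdir / f"numbering_{tag}.tsv", "w") as fh:
                kabat.write_numbering_tsv(donor, fh)

        with _stage(f"germline/{chain_type}"):
            library = libraries.get(chain_type) or germline_mod.default_library(chain_type)
            core = config.upper_core_set(chain_type)
            ranked = germline_mod.select_germline(donor, library, core, config.germline_priors)
            best = ranked[0]
            acceptor = next(r for r in library if r.allele_name == best.allele_name)
            with open(outdir / f"germline_ranking_{tag}.tsv", "w") as fh:
                germline_mod.write_ranking_tsv(ranked, fh)
            with open(outdir / f"germline_positions_{tag}.tsv", "w") as fh:
                germline_mod.write_position_report_tsv(best, fh)
            fr4 = germline_mod.score_fr4(donor)
            chain_summary["acceptor"] = best.allele_name
            chain_summary["framework_identity"] = best.framework_identity
            chain_summary["upper_core_preserved"] = f"{best.upper_core_preserved}/{best.upper_core_total}"
            chain_summary["fr4_best"] = fr4[0][0] if fr4 else None

        with _stage(f"grafting/{chain_type}"):
            grafted = grafting.graft_cdrs(donor, acceptor)
            for w in grafted.warnings:
                log.warning("graft %s: %s", chain_type, w)

        with _stage(f"contacts/{chain_type}"):
            support = support_maps.get(chain_type, structure.SupportMap({}))
            if chain_type in fv_structures:
                model = structure.read_structure(fv_structures[chain_type])
                chain_id = next(iter(model.chains)) if len(model.chains) == 1 else chain_type[0].upper()
                mapping = structure.map_structure_to_kabat(model, donor, chain_id)
                derived = structure.find_fr_cdr_contacts(
                    model, mapping, donor, chain_id, cutoff=config.analysis_cutoff
                )
                merged = dict(derived.positions)
                merged.update(support.positions)
                support = structure.SupportMap(merged)
            with open(outdir / f"contacts_{tag}.tsv", "w") as fh:
                structure.write_contacts_tsv(support, fh)

        with _stage(f"recommend/{chain_type}"):
            recs = structure.recommend_back_mutations(
                donor, acceptor, support, config.upper_core_set(chain_type),
                config.swap_class_sets(), config.contact_weight_threshold,
            )
            with open(outdir / f"recommendations_{tag}.tsv", "w") as fh:
                structure.write_recommendations_tsv(recs, fh)
            chain_summary["back_mutations"] = [
                r.kabat_position for r in recs if r.decision == structure.BACK_MUTATE
            ]

        with _stage(f"humanize/{chain_type}"):
            plan = grafting.plan_from_recommendations(
                donor, acceptor, chain_summary["back_mutations"]
            )
            humanized = grafting.apply_back_mutations(grafted, plan)
            with open(outdir / f"humanized_{tag}.fasta", "w") as fh:
                fh.write(f">humanized_{chain_type} acceptor={best.allele_name}\n")
                fh.write(humanized.sequence + "\n")
            with open(outdir / f"provenance_{tag}.tsv", "w") as fh:
                grafting.write_provenance_tsv(humanized, fh)
            chain_summary["humanized_sequence"] = humanized.sequence

        summary["chains"][chain_type] = chain_summary

    if complex_structure is not None:
        with _stage("affinity"):
            path, side_a, side_b = complex_structure
            if not Path(path).exists():
                raise InputError(f"complex structure file not found: {path}")
            model = structure.read_structure(path)
            profile = profile_complex(
                model, side_a, side_b,
                classes=config.residue_classes,
                coefficients=config.dg_coefficients,
                cutoff=config.ic_cutoff,
                temperature=config.temperature,
            )
            with open(outdir / "affinity_profile.tsv", "w") as fh:
                write_profile_tsv({"complex": profile}, fh)
            (outdir / "affinity_profile.txt").write_text(
                format_profile_text("complex", profile) + "\n"
            )
            summary["affinity"] = {
                "delta_g_kcal_mol": profile.delta_g,
                "kd_molar": profile.kd,
                "ic_counts": profile.ic_counts,
            }

    (outdir / "run_summary.yaml").write_text(_summary_yaml(summary))
    log.info("pipeline done: %s", outdir)
    return summary


def _summary_yaml(summary: dict) -> str:
    import yaml

    return yaml.safe_dump(summary, sort_keys=True)
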