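"""End-to-end orchestration of the stabilization protocol.

Stages, in order: N-terminal truncation → PSSM scan → curated-table merge →
ΔΔG scoring (surrogate or external table) → ΔΔG cutoff filter → structural
filter battery → combinatorial variant design → RMSD/energy selection.
A JSON manifest records the configuration hash, seed, per-stage pool counts
and output paths; re-running with the same configuration and seed
reproduces byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .conservation import (compute_pssm, merge_candidate_pool,
                           positive_mutations, read_alignment, write_pool_tsv)
from .design import DesignConfig, generate_variants
from .energy import EnergyModel, default_rotamer_library, total_energy
from .errors import ConfigurationError, PipelineError
from .filters import (FilterConfig, apply_filter_battery, summarize_verdicts,
                      write_verdicts_tsv)
from .selection import ca_rmsd, rank_and_select
from .stability import (filter_by_ddg, read_ddg_table, surrogate_ddg,
                        write_ddg_tsv)
from .structures import read_pdb, truncate_n_terminus, write_model

logger = logging.getLogger(__name__)


class PssmConfig(BaseModel):
    reference_id: str = "ref"
    pseudocount: float = 1.0
    threshold: float = 0.0


class RunConfig(BaseModel):
    """Validated run configuration (YAML-serializable)."""

    structure_path: str
    alignment_path: str
    curated_path: str | None = None
    ddg_table_path: str | None = None
    chain_id: str | None = None
    truncate_n: int = 11
    ddg_mc_steps: int = 400
    pssm: PssmConfig = Field(default_factory=PssmConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    output_dir: str = "prostab_out"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.filters.catalytic_residues:
            raise ValueError("filters.catalytic_residues must not be empty")
        if self.truncate_n < 0:
            raise ValueError("truncate_n must be non-negative")
        return self

    def validate_paths(self):
        for p in (self.structure_path, self.alignment_path,
                  self.curated_path, self.ddg_table_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_fasta(variants, path: Path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            muts = ",".join(m.label for m in v.mutations)
            fh.write(f">{v.variant_id} n_mutations={len(v.mutations)} "
                     f"energy={v.total_energy:.4f} mutations={muts}\n")
            for i in range(0, len(v.sequence), 60):
                fh.write(v.sequence[i:i + 60] + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full protocol; returns (and writes) the run manifest."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "counts": {},
        "outputs": {},
    }
    stage = "setup"
    t0 = time.time()
    try:
        stage = "truncate"
        structure = read_pdb(config.structure_path)
        chain = config.chain_id or structure.default_chain()
        structure = truncate_n_terminus(structure, config.truncate_n, chain)
        region = structure.polymer_residues(chain)
        logger.info("stage %s: design region %d residues (chain %s)",
                    stage, len(region), chain)
        write_model(structure, out / "wt_model.pdb")
        manifest["outputs"]["wt_model"] = str(out / "wt_model.pdb")

        stage = "pssm_scan"
        alignment = read_alignment(config.alignment_path)
        pssm = compute_pssm(alignment, config.pssm.reference_id,
                            pseudocount=config.pssm.pseudocount)
        wt_seq = "".join(r.one_letter for r in region)
        if len(pssm.positions) != len(region):
            raise ConfigurationError(
                f"alignment reference has {len(pssm.positions)} positions but the "
                f"design region has {len(region)} residues")
        if pssm.reference_sequence != wt_seq:
            logger.warning("alignment reference differs from the structure sequence")
        position_keys = [r.key for r in region]
        pool = positive_mutations(pssm, wt_seq, chain_id=chain,
                                  position_keys=position_keys,
                                  threshold=config.pssm.threshold)
        pssm.to_tsv(out / "pssm.tsv")
        manifest["outputs"]["pssm"] = str(out / "pssm.tsv")

        stage = "curated_merge"
        rejected: list[str] = []
        if config.curated_path:
            wt_lookup = {(r.chain_id, r.seq_number): r.one_letter for r in region}
            merged = merge_candidate_pool(pool, config.curated_path,
                                          wt_lookup=wt_lookup)
            pool, rejected = merged.candidates, merged.rejected
            # curated rows can reference truncated-away positions; drop them
            keep = {r.key for r in region}
            pool = [c for c in pool
                    if (c.mutation.chain_id, c.mutation.position, "") in keep]
        manifest["counts"]["pool_initial_mutations"] = len(pool)
        manifest["counts"]["pool_initial_positions"] = len(
            {(c.mutation.chain_id, c.mutation.position) for c in pool})
        manifest["curated_rejected"] = rejected
        write_pool_tsv(pool, out / "pool_initial.tsv")
        manifest["outputs"]["pool_initial"] = str(out / "pool_initial.tsv")
        logger.info("stage %s: %d candidate mutations", stage, len(pool))

        stage = "ddg"
        energy_model = EnergyModel()
        rotlib = default_rotamer_library()
        if config.ddg_table_path:
            table = {(r.mutation.chain_id, r.mutation.position, r.mutation.mut_aa): r
                     for r in read_ddg_table(config.ddg_table_path)}
            records, missing = [], 0
            for c in pool:
                key = (c.mutation.chain_id, c.mutation.position, c.mutation.mut_aa)
                if key in table:
                    records.append(table[key])
                else:
                    missing += 1
            if missing:
                logger.warning("%d pool mutations missing from the ΔΔG table", missing)
        else:
            records = [surrogate_ddg(structure, c.mutation, energy_model, rotlib,
                                     seed=config.seed, mc_steps=config.ddg_mc_steps)
                       for c in pool]
        write_ddg_tsv(records, out / "ddg.tsv")
        manifest["outputs"]["ddg"] = str(out / "ddg.tsv")

        stage = "ddg_filter"
        records = filter_by_ddg(records, cutoff=config.design.ddg_cutoff)
        manifest["counts"]["pool_post_ddg"] = len(records)
        write_ddg_tsv(records, out / "pool_post_ddg.tsv")
        manifest["outputs"]["pool_post_ddg"] = str(out / "pool_post_ddg.tsv")
        logger.info("stage %s: %d mutations below %.2f", stage, len(records),
                    config.design.ddg_cutoff)

        stage = "structural_filters"
        fconf = config.filters.model_copy(
            update={"active_site_radius": config.design.active_site_radius})
        survivors, verdicts = apply_filter_battery(records, structure, fconf)
        manifest["counts"]["pool_post_filter"] = len(survivors)
        manifest["counts"]["pool_post_filter_positions"] = len(
            {(s.mutation.chain_id, s.mutation.position) for s in survivors})
        manifest["filter_failures"] = summarize_verdicts(verdicts)
        write_verdicts_tsv(verdicts, out / "verdicts.tsv")
        write_ddg_tsv(survivors, out / "pool_post_filter.tsv")
        manifest["outputs"]["pool_post_filter"] = str(out / "pool_post_filter.tsv")
        logger.info("stage %s: %d mutations survive the battery", stage,
                    len(survivors))

        stage = "design"
        pssm_scores = {key: {aa: pssm.score(pssm.positions[i], aa)
                             for aa in pssm.alphabet}
                       for i, key in enumerate(
                           (r.chain_id, r.seq_number) for r in region)}
        dconf = config.design.model_copy(update={"seed": config.seed})
        variants = generate_variants(structure, survivors, dconf, energy_model,
                                     rotlib, pssm_scores=pssm_scores,
                                     chain_id=chain)
        manifest["counts"]["variants_generated"] = len(variants)
        wt_energy = total_energy(structure, energy_model, pssm_scores)
        manifest["wt_energy_full_atom"] = wt_energy

        stage = "selection"
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for v in variants:
            ca_rmsd(v, structure)
            write_model(v.structure, models_dir / f"{v.variant_id}.pdb")
        report = rank_and_select(variants, wt_energy, dconf)
        manifest["counts"]["variants_selected"] = len(report.entries)
        selected_ids = {e.variant_id for e in report.entries}
        _write_fasta([v for v in variants if v.variant_id in selected_ids],
                     out / "variants.fasta")
        report.to_json(out / "selection.json")
        report.to_tsv(out / "selection.tsv")
        report.overlap_to_tsv(out / "overlap.tsv")
        manifest["outputs"].update({
            "variants_fasta": str(out / "variants.fasta"),
            "selection": str(out / "selection.json"),
            "models_dir": str(models_dir),
        })
        logger.info("selected %d variants in %.1f s", len(report.entries),
                    time.time() - t0)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc), manifest) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
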