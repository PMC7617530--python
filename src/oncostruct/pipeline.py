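"""End-to-end orchestration: config, input discovery, output tables.

A run consumes a directory of structure files, a stability CSV, one or
more mutation tables and an optional gene-role table, and produces
plain-TSV outputs: per-residue structural context, ranked stability
landscapes, the gene-level damage-enrichment volcano, EDC values,
group comparisons and the two top-candidate tables. All thresholds are
carried in a single config object and echoed into a run manifest so
every output is auditable; a fixed seed makes synthetic runs
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import context as _context
from .edc import EdcResult, compute_edc, edc_to_frame, recurrent_edc
from .enrichment import (
    gene_damage_enrichment,
    mark_significance,
    rank_candidates,
)
from .mutations import (
    assign_roles,
    deduplicate,
    mutations_to_frame,
    read_mutations,
)
from .stability import StabilityTable, VariantKey, ddg_rank, read_stability_csv
from .structure import StructureModel, plddt_mask, read_structure
from .synthetic import SyntheticSpec, generate_mutation_cohort, write_bundle

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_bundle", "recovery_scores"]


@dataclass
class RunConfig:
    """Inputs, thresholds and switches of one pipeline run.

    Threshold defaults are the ones used throughout the analyses: RSA
    bands at 0.3/0.5, recurrence ≥7, at least 5 mutated residues for an
    EDC value, pLDDT ≥70 for predicted models, chain mapping at >90%
    identity over ≥50 residues, and α = 0.05 with Bonferroni correction
    over the genes tested.
    """

    structures_dir: str | None = None
    stability_csv: str | None = None
    mutations_tsv: str | None = None
    roles_tsv: str | None = None
    dssp_dir: str | None = None
    output_dir: str = "oncostruct_out"
    dataset: str = "cancer_all"
    structure_source: str = "predicted"

    rsa_interior: float = 0.3
    rsa_surface: float = 0.5
    min_recurrence: int = 7
    min_disease_residues: int = 5
    plddt_threshold: float = 70.0
    min_identity: float = 90.0
    min_length: int = 50
    alpha: float = 0.05
    top_n: int = 50
    interface_mode: str = "rsa_bands"
    exact_test_limit: int = 16
    sasa_points: int = 960
    seed: int = 0

    # simulate-subcommand knobs
    n_genes: int = 200
    n_residues: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _header(config: RunConfig) -> str:
    pairs = " ".join(f"{k}={v}" for k, v in sorted(config.to_dict().items()))
    return f"# oncostruct run: {pairs}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", index=False)


def _load_structures(config: RunConfig) -> dict[str, tuple[StructureModel, str]]:
    out: dict[str, tuple[StructureModel, str]] = {}
    if not config.structures_dir:
        return out
    for path in sorted(Path(config.structures_dir).glob("*")):
        if path.suffix.lower() not in {".pdb", ".ent", ".cif", ".mmcif"}:
            continue
        try:
            model = read_structure(path, source=config.structure_source)
        except Exception as exc:
            logger.warning("skipping unreadable structure %s: %s", path, exc)
            continue
        chain_id = next(iter(model.chains))
        out[model.structure_id] = (model, chain_id)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage the available inputs allow; log and skip the rest.

    Returns a map from output name to file path. Missing optional
    inputs degrade gracefully: without stability tables the volcano and
    ranking stages are skipped with a logged reason, without structures
    the context and EDC stages are skipped, and a coverage report
    records what was dropped where.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    coverage: list[dict] = []

    structures = _load_structures(config)

    records = []
    if config.mutations_tsv:
        records = deduplicate(
            read_mutations(config.mutations_tsv, dataset=config.dataset)
        )
        frame = mutations_to_frame(records)
        path = outdir / "mutations_deduplicated.tsv"
        _write_tsv(frame, path, config)
        outputs["mutations"] = path
        coverage.append({"stage": "mutations", "n": len(records)})

    # --- per-residue structural context ---------------------------------
    if structures:
        frames = []
        for protein_id, (model, _chain) in sorted(structures.items()):
            dssp_frame = None
            if config.dssp_dir:
                dssp_path = Path(config.dssp_dir) / f"{protein_id}.dssp"
                if dssp_path.is_file():
                    dssp_frame = _context.read_dssp(dssp_path)
            frames.append(
                _context.residue_context_table(
                    model,
                    n_points=config.sasa_points,
                    dssp=dssp_frame,
                    interface_mode=config.interface_mode,  # type: ignore[arg-type]
                )
            )
        path = outdir / "residue_context.tsv"
        _write_tsv(pd.concat(frames, ignore_index=True), path, config)
        outputs["residue_context"] = path
    else:
        logger.info("no structures: residue context skipped")

    # --- stability ranks and volcano ------------------------------------
    tables: dict[str, StabilityTable] = {}
    if config.stability_csv:
        raw_maps = read_stability_csv(config.stability_csv)
        for protein_id, raw in raw_maps.items():
            if len(raw) < 2:
                coverage.append({"stage": "ddg_rank", "protein": protein_id, "n": len(raw)})
                continue
            tables[protein_id] = ddg_rank(raw, protein_id=protein_id)
        rank_frame = pd.concat(
            [t.to_frame() for t in tables.values()], ignore_index=True
        )
        path = outdir / "stability_ranks.tsv"
        _write_tsv(rank_frame, path, config)
        outputs["stability_ranks"] = path
    else:
        logger.info("no stability tables: ΔΔG_rank and volcano skipped")

    enrichment_results = []
    if tables and records:
        by_protein: dict[str, set[VariantKey]] = {}
        for r in records:
            by_protein.setdefault(r.protein_id, set()).add(
                VariantKey(r.protein_id, r.position, r.ref_aa, r.alt_aa)
            )
        for protein_id, table in sorted(tables.items()):
            observed = by_protein.get(protein_id, set())
            if not observed:
                continue
            result = gene_damage_enrichment(
                table,
                observed,
                structure_source=config.structure_source,  # type: ignore[arg-type]
                exact_limit=config.exact_test_limit,
            )
            if result is not None:
                enrichment_results.append(result)
        enrichment_results, threshold = mark_significance(
            enrichment_results, alpha=config.alpha
        )
        volcano = pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "ddg_rank_diff": r.ddg_rank_diff,
                    "p_value": r.p_value,
                    "n_observed": r.n_observed,
                    "n_unobserved": r.n_unobserved,
                    "structure_source": r.structure_source,
                    "significant": r.significant,
                }
            for r in enrichment_results
            ]
        )
        path = outdir / "volcano.tsv"
        _write_tsv(volcano, path, config)
        outputs["volcano"] = path
        coverage.append(
            {
                "stage": "volcano",
                "n_genes": len(enrichment_results),
                "bonferroni_threshold": threshold,
            }
        )

    # --- EDC -------------------------------------------------------------
    edc_results: list[EdcResult] = []
    recurrent_results: list[EdcResult] = []
    if structures and records:
        for protein_id, (model, chain_id) in sorted(structures.items()):
            residues = {
                r.position for r in records if r.protein_id == protein_id
            }
            coords = model.ca_coordinates(chain_id)
            residues = {r for r in residues if 1 <= r <= len(coords)}
            mask = (
                plddt_mask(model, chain_id, threshold=config.plddt_threshold)
                if model.source == "predicted"
                else None
            )
            result = compute_edc(
                coords,
                residues,
                mask=mask,
                min_disease_residues=config.min_disease_residues,
                protein_id=protein_id,
                dataset=config.dataset,
            )
            if result is not None:
                edc_results.append(result)
        recurrent_results = recurrent_edc(
            records,
            structures,
            min_recurrence=config.min_recurrence,
            min_disease_residues=config.min_disease_residues,
            plddt_threshold=config.plddt_threshold,
            dataset=config.dataset,
        )
        path = outdir / "edc.tsv"
        _write_tsv(
            edc_to_frame(edc_results + recurrent_results), path, config
        )
        outputs["edc"] = path

    # --- group comparisons (by gene role, when roles are available) ------
    if config.roles_tsv and enrichment_results:
        genes = [r.protein_id for r in enrichment_results]
        roles = assign_roles(genes, config.roles_tsv)
        role_frame = pd.DataFrame(
            [
                {
                    "protein_id": r.protein_id,
                    "role": roles[r.protein_id].role,
                    "ddg_rank_diff": r.ddg_rank_diff,
                    "p_value": r.p_value,
                }
                for r in enrichment_results
            ]
        )
        path = outdir / "role_enrichment.tsv"
        _write_tsv(role_frame, path, config)
        outputs["role_enrichment"] = path

    # --- candidate rankings ----------------------------------------------
    if enrichment_results or recurrent_results:
        damage, clustering, overlap = rank_candidates(
            {config.structure_source: enrichment_results},
            recurrent_results,
            top_n=config.top_n,
        )
        path = outdir / "top_damage.tsv"
        _write_tsv(damage, path, config)
        outputs["top_damage"] = path
        path = outdir / "top_clustering.tsv"
        _write_tsv(clustering, path, config)
        outputs["top_clustering"] = path
        path = outdir / "overlap.tsv"
        _write_tsv(
            pd.DataFrame({"protein_id": sorted(overlap)}), path, config
        )
        outputs["overlap"] = path

    manifest = {
        "config": config.to_dict(),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "coverage": coverage,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = manifest_path
    return outputs


def simulate_bundle(config: RunConfig) -> dict[str, Path]:
    """Write a self-contained synthetic input bundle for :func:`run_pipeline`."""
    outdir = Path(config.output_dir)
    if config.n_genes == 0:
        logger.warning("n_genes=0: writing an empty bundle")
        outdir.mkdir(parents=True, exist_ok=True)
        from .synthetic import Cohort

        return write_bundle(Cohort(genes=[]), outdir)
    cohort = generate_mutation_cohort(
        n_genes=config.n_genes,
        base_spec=SyntheticSpec(n_residues=config.n_residues),
        seed=config.seed,
    )
    return write_bundle(cohort, outdir)


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney identity (ties → 0.5)."""
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both positive and negative labels")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (float(gt) + 0.5 * float(eq)) / (len(pos) * len(neg))


def recovery_scores(
    cohort,
    min_recurrence: int = 7,
    min_disease_residues: int = 5,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Score how well the pipeline recovers a synthetic cohort's truth.

    Runs damage enrichment and recurrent EDC over the cohort and
    returns the AUC for recognising TSG-like genes from the signed
    damage score (-log10 p, negated for mild-shifted genes) and
    oncogene-like genes from recurrent EDC (genes skipped by the
    residue threshold count as unclustered, EDC = 1).
    """
    damage_score: dict[str, float] = {}
    for sim in cohort.genes:
        table = ddg_rank(sim.ddg, protein_id=sim.gene)
        observed = {
            VariantKey(r.protein_id, r.position, r.ref_aa, r.alt_aa)
            for r in sim.records
        }
        result = gene_damage_enrichment(table, observed)
        if result is not None:
            logp = -np.log10(max(result.p_value, 1e-300))
            damage_score[sim.gene] = float(np.sign(result.ddg_rank_diff) * logp)

    edc_results = recurrent_edc(
        cohort.records,
        cohort.structures,
        min_recurrence=min_recurrence,
        min_disease_residues=min_disease_residues,
    )
    edc_by_gene = {r.protein_id: r.edc for r in edc_results}

    genes = [g.gene for g in cohort.genes]
    labels = {g.gene: g.label for g in cohort.genes}
    d_scores = np.array([damage_score.get(g, 0.0) for g in genes])
    e_scores = np.array([edc_by_gene.get(g, 1.0) for g in genes])
    is_tsg = np.array([labels[g] == "tsg_like" for g in genes])
    is_onc = np.array([labels[g] == "oncogene_like" for g in genes])
    return {
        "tsg_damage_auc": _auc(d_scores, is_tsg),
        "oncogene_edc_auc": _auc(e_scores, is_onc),
        "n_genes": len(genes),
        "n_edc_reported": len(edc_by_gene),
    }
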