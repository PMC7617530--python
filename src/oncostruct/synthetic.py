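"""Synthetic structures, stability landscapes and mutation cohorts.

Every pipeline stage can be exercised without external downloads by
generating inputs with controlled statistical structure:

* Cα chains — a straight line, an ideal α-helix, or a compact
  self-avoiding random walk emulating a globular fold (3.8 Å consecutive
  spacing, ≥3.5 Å between non-consecutive residues).
* ΔΔG landscapes — one value per possible substitution per residue,
  |ΔΔG| log-normal so that the bulk of values sits below ~3 kcal/mol
  with occasional extreme outliers, as stability predictors produce.
* Mutation cohorts — genes whose observed mutations are drawn uniformly
  (neutral), preferentially from the most destabilizing quantile of the
  landscape (tumor-suppressor-like, loss-of-function selection), or
  from a spatial cluster of neighbouring residues (oncogene-like,
  gain-of-function hotspots), with zero-truncated geometric recurrence
  counts so that a recurrence filter retains a realistic minority.

All generators are deterministic given the spec's seed and emit the
truth labels needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist

from .mutations import MutationRecord
from .stability import VariantKey
from .structure import ResidueRecord, StructureModel

__all__ = [
    "SyntheticSpec",
    "GeneSimulation",
    "Cohort",
    "generate_chain",
    "generate_ddg_landscape",
    "generate_mutation_cohort",
    "write_bundle",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic gene/protein.

    Defaults describe a mid-sized globular protein: 200 residues on a
    compact self-avoiding walk, a log-normal |ΔΔG| landscape with median
    1 kcal/mol (well under the ~3 kcal/mol bulk), 120 observed missense
    variants and recurrence counts with mean 3 so that a ≥7 filter
    keeps roughly the top decile. Damage-enriched genes draw 75% of
    their observed variants from above the 0.7 |ΔΔG| quantile; clustered
    genes confine theirs to the 5% of residues nearest a random center.
    """

    n_residues: int = 200
    chain_geometry: Literal["line", "ideal_helix", "compact_random_walk"] = (
        "compact_random_walk"
    )
    ca_spacing: float = 3.8
    ddg_mu: float = 0.0
    ddg_sigma: float = 1.0
    ddg_negative_fraction: float = 0.2
    mutation_model: Literal["uniform", "clustered", "damage_enriched"] = "uniform"
    cluster_fraction: float = 0.05
    enrich_quantile: float = 0.7
    enrich_fraction: float = 0.75
    n_observed: int = 120
    recurrence_mean: float = 3.0
    plddt: float = 92.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")
        if self.ca_spacing <= 0:
            raise ValueError("ca_spacing must be positive")


@dataclass
class GeneSimulation:
    gene: str
    label: Literal["tsg_like", "oncogene_like", "neutral"]
    spec: SyntheticSpec
    model: StructureModel
    ddg: dict[VariantKey, float]
    records: list[MutationRecord]


@dataclass
class Cohort:
    genes: list[GeneSimulation]

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": g.gene, "label": g.label} for g in self.genes]
        )

    @property
    def structures(self) -> dict[str, tuple[StructureModel, str]]:
        return {g.gene: (g.model, "A") for g in self.genes}

    @property
    def records(self) -> list[MutationRecord]:
        return [r for g in self.genes for r in g.records]


# --- chain generation -----------------------------------------------------

_MIN_NONCONSECUTIVE = 3.5
_CANDIDATES_PER_STEP = 40
_MAX_RESTARTS = 50


def _line(n: int, spacing: float) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return coords


def _ideal_helix(n: int, spacing: float) -> np.ndarray:
    # canonical α-helix: rise 1.5 Å, 100°/residue, radius 2.3 Å; scaled
    # uniformly so consecutive Cα spacing matches the requested value
    rise, radius = 1.5, 2.3
    theta = np.deg2rad(100.0) * np.arange(n)
    coords = np.c_[radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    natural = float(np.linalg.norm(coords[1] - coords[0]))
    return coords * (spacing / natural)


def _random_unit_vectors(rng: np.random.Generator, k: int) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _compact_walk(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding walk biased toward its own centroid (compact globule)."""
    for _ in range(_MAX_RESTARTS):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            dirs = _random_unit_vectors(rng, _CANDIDATES_PER_STEP)
            cands = coords[i - 1] + spacing * dirs
            if i >= 2:
                dists = cdist(cands, coords[: i - 1])
                valid = cands[dists.min(axis=1) >= _MIN_NONCONSECUTIVE]
            else:
                valid = cands
            if len(valid) == 0:
                ok = False
                break
            centroid = coords[:i].mean(axis=0)
            pull = np.linalg.norm(valid - centroid, axis=1)
            if rng.random() < 0.8:
                coords[i] = valid[int(np.argmin(pull))]
            else:
                coords[i] = valid[int(rng.integers(len(valid)))]
        if ok:
            return coords
    raise RuntimeError(f"could not pack a self-avoiding chain of {n} residues")


def _model_from_coords(
    coords: np.ndarray, sequence: str, plddt: float, structure_id: str
) -> StructureModel:
    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(aa) for aa in sequence]
    )
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("b_factor", np.full(n, float(plddt)))

    residues = [
        ResidueRecord(
            chain_id="A",
            residue_index=i + 1,
            author_number=i + 1,
            aa=sequence[i],
            ca_xyz=np.asarray(coords[i], dtype=float),
            bfactor_or_plddt=float(plddt),
            has_ca=True,
        )
        for i in range(n)
    ]
    return StructureModel(
        structure_id=structure_id,
        source="predicted",
        chains={"A": residues},
        resolution=None,
        atoms=atoms,
    )


def generate_chain(spec: SyntheticSpec, structure_id: str = "synthetic") -> StructureModel:
    """Generate a Cα-trace structure model according to the spec.

    Consecutive Cα distances equal ``ca_spacing`` to within 1e-6 Å; the
    compact random walk additionally keeps non-consecutive residues at
    least 3.5 Å apart. The residue sequence is drawn uniformly from the
    20 standard amino acids and the B-factor column carries the spec's
    pLDDT value.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.chain_geometry == "line":
        coords = _line(spec.n_residues, spec.ca_spacing)
    elif spec.chain_geometry == "ideal_helix":
        coords = _ideal_helix(spec.n_residues, spec.ca_spacing)
    elif spec.chain_geometry == "compact_random_walk":
        coords = _compact_walk(spec.n_residues, spec.ca_spacing, rng)
    else:
        raise ValueError(f"unknown chain geometry {spec.chain_geometry!r}")
    sequence = "".join(rng.choice(list(_AA20), size=spec.n_residues))
    return _model_from_coords(coords, sequence, spec.plddt, structure_id)


def generate_ddg_landscape(
    spec: SyntheticSpec, model: StructureModel, protein_id: str | None = None
) -> dict[VariantKey, float]:
    """One ΔΔG per possible substitution per residue of the model.

    |ΔΔG| is log-normal (``ddg_mu``, ``ddg_sigma`` on the log scale; the
    defaults give a median of 1 kcal/mol) and a configurable fraction of
    values is flipped to stabilizing (negative) sign. Deterministic in
    the spec seed (offset so the landscape differs from the chain draw).
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    protein_id = protein_id or model.structure_id
    sequence = [r.aa for r in model.chain("A")]
    out: dict[VariantKey, float] = {}
    for pos, ref in enumerate(sequence, start=1):
        for alt in _AA20:
            if alt == ref:
                continue
            magnitude = rng.lognormal(mean=spec.ddg_mu, sigma=spec.ddg_sigma)
            sign = -1.0 if rng.random() < spec.ddg_negative_fraction else 1.0
            out[VariantKey(protein_id, pos, ref, alt)] = sign * magnitude
    return out


def _draw_variants(
    spec: SyntheticSpec,
    model: StructureModel,
    ddg: dict[VariantKey, float],
    rng: np.random.Generator,
) -> list[VariantKey]:
    keys = sorted(ddg)
    n_obs = min(spec.n_observed, len(keys))
    if spec.mutation_model == "uniform":
        idx = rng.choice(len(keys), size=n_obs, replace=False)
        return [keys[i] for i in idx]
    if spec.mutation_model == "damage_enriched":
        mags = np.array([abs(ddg[k]) for k in keys])
        cut = np.quantile(mags, spec.enrich_quantile)
        top = [i for i, m in enumerate(mags) if m >= cut]
        chosen: set[int] = set()
        while len(chosen) < n_obs:
            if rng.random() < spec.enrich_fraction:
                chosen.add(int(rng.choice(top)))
            else:
                chosen.add(int(rng.integers(len(keys))))
        return [keys[i] for i in sorted(chosen)]
    if spec.mutation_model == "clustered":
        coords = model.ca_coordinates("A")
        center = int(rng.integers(len(coords)))
        k = max(5, round(spec.cluster_fraction * len(coords)))
        dist = np.linalg.norm(coords - coords[center], axis=1)
        cluster_residues = set((np.argsort(dist)[:k] + 1).tolist())
        pool = [i for i, key in enumerate(keys) if key.position in cluster_residues]
        size = min(n_obs, len(pool))
        idx = rng.choice(pool, size=size, replace=False)
        return [keys[i] for i in idx]
    raise ValueError(f"unknown mutation model {spec.mutation_model!r}")


def _zero_truncated_geometric(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    if mean < 1.0:
        raise ValueError("recurrence_mean must be >= 1")
    return rng.geometric(p=1.0 / mean, size=size)


_LABEL_TO_MODEL = {
    "tsg_like": "damage_enriched",
    "oncogene_like": "clustered",
    "neutral": "uniform",
}


def generate_mutation_cohort(
    n_genes: int = 200,
    fractions: tuple[float, float, float] = (0.25, 0.25, 0.5),
    base_spec: SyntheticSpec = SyntheticSpec(),
    seed: int = 0,
    dataset: str = "cancer_all",
) -> Cohort:
    """Simulate a cohort of genes with known TSG-like / oncogene-like truth.

    ``fractions`` gives the (tsg_like, oncogene_like, neutral) shares of
    the ``n_genes`` genes. Each gene gets its own chain, landscape and
    observed mutation set under the mutation model its label implies,
    with recurrence counts drawn from the zero-truncated geometric
    distribution. Deterministic in ``seed``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n_tsg = round(n_genes * fractions[0])
    n_onc = round(n_genes * fractions[1])
    labels = (
        ["tsg_like"] * n_tsg
        + ["oncogene_like"] * n_onc
        + ["neutral"] * (n_genes - n_tsg - n_onc)
    )
    master = np.random.default_rng(seed)
    genes: list[GeneSimulation] = []
    for i, label in enumerate(labels):
        gene = f"G{i:04d}"
        gene_seed = int(master.integers(2**31 - 1))
        spec = replace(
            base_spec, seed=gene_seed, mutation_model=_LABEL_TO_MODEL[label]
        )
        model = generate_chain(spec, structure_id=gene)
        ddg = generate_ddg_landscape(spec, model, protein_id=gene)
        rng = np.random.default_rng(gene_seed + 7)
        variants = _draw_variants(spec, model, ddg, rng)
        recurrences = _zero_truncated_geometric(
            rng, spec.recurrence_mean, len(variants)
        )
        records = [
            MutationRecord(
                gene=gene,
                protein_id=gene,
                position=v.position,
                ref_aa=v.ref_aa,
                alt_aa=v.alt_aa,
                recurrence=int(r),
                dataset=dataset,
            )
            for v, r in zip(variants, recurrences)
        ]
        genes.append(
            GeneSimulation(
                gene=gene, label=label, spec=spec, model=model, ddg=ddg,
                records=records,
            )
        )
    return Cohort(genes=genes)


def write_bundle(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as the same file formats the real pipeline reads.

    Produces per-gene PDB files (Cα traces, pLDDT in the B-factor
    column), one stability CSV, one mutation TSV and a gene-role TSV in
    which TSG-like genes are labelled "TSG", oncogene-like "oncogene"
    and neutral genes are absent — plus the truth table itself.
    """
    outdir = Path(outdir)
    structures_dir = outdir / "structures"
    structures_dir.mkdir(parents=True, exist_ok=True)

    stability_rows = []
    mutation_rows = []
    role_rows = []
    for sim in cohort.genes:
        pdb = PDBFile()
        pdb.set_structure(sim.model.atoms)
        pdb.write(structures_dir / f"{sim.gene}.pdb")
        for key, value in sorted(sim.ddg.items()):
            stability_rows.append(
                {
                    "protein_id": key.protein_id,
                    "position": key.position,
                    "ref_aa": key.ref_aa,
                    "alt_aa": key.alt_aa,
                    "ddg": value,
                }
            )
        for record in sim.records:
            mutation_rows.append(
                {
                    "gene": record.gene,
                    "protein_id": record.protein_id,
                    "position": record.position,
                    "ref_aa": record.ref_aa,
                    "alt_aa": record.alt_aa,
                    "recurrence": record.recurrence,
                }
            )
        if sim.label == "tsg_like":
            role_rows.append({"gene": sim.gene, "role_string": "TSG"})
        elif sim.label == "oncogene_like":
            role_rows.append({"gene": sim.gene, "role_string": "oncogene"})

    paths = {
        "structures": structures_dir,
        "stability": outdir / "stability.csv",
        "mutations": outdir / "mutations.tsv",
        "roles": outdir / "roles.tsv",
        "truth": outdir / "truth.tsv",
    }
    pd.DataFrame(stability_rows).to_csv(paths["stability"], index=False)
    pd.DataFrame(mutation_rows).to_csv(paths["mutations"], sep="\t", index=False)
    pd.DataFrame(role_rows, columns=["gene", "role_string"]).to_csv(
        paths["roles"], sep="\t", index=False
    )
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def radius_of_gyration(coords: np.ndarray) -> float:
    coords = np.asarray(coords, dtype=float)
    return float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum(axis=1).mean()))
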