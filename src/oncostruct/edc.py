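"""Extent of Disease Clustering (EDC) of mutations on a protein structure.

For every residue of a protein subunit, take the Cα:Cα distance to each
residue carrying a disease mutation (other than itself) and keep the
nearest one, D_min. Averaging log(D_min) separately over mutated and
non-mutated residues gives D̄_disease and D̄_non-disease, and

    EDC = D̄_non-disease / D̄_disease

EDC > 1 means mutated residues sit closer to each other than the rest
of the structure does to them — i.e. the mutations cluster in space —
while randomly scattered mutations give EDC ≈ 1. The ratio is invariant
to the logarithm base (the base constant cancels) and to rigid motions
of the coordinates.

Only proteins with mutations at five or more (kept) residues are
scored; low-confidence residues of predicted models (pLDDT < 70) are
excluded from both sides of the ratio before any distance is measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .mutations import MutationRecord, filter_recurrent
from .structure import StructureModel, plddt_mask

logger = logging.getLogger(__name__)

__all__ = ["EdcResult", "compute_edc", "recurrent_edc"]


@dataclass(frozen=True)
class EdcResult:
    protein_id: str
    edc: float
    n_disease: int
    n_nondisease: int
    dataset: str = "custom"
    recurrent: bool = False
    excluded_low_confidence: int = 0


def compute_edc(
    ca_coords: np.ndarray,
    disease_residues: Iterable[int],
    mask: np.ndarray | None = None,
    min_disease_residues: int = 5,
    protein_id: str = "protein",
    dataset: str = "custom",
    recurrent: bool = False,
) -> EdcResult | None:
    """EDC of a mutated-residue set on one subunit's Cα trace.

    Parameters
    ----------
    ca_coords
        (n, 3) Cα coordinates on the subunit's 1-based residue axis;
        rows with NaN (missing Cα) are excluded from the calculation.
    disease_residues
        1-based residue indices carrying mutations.
    mask
        Optional boolean keep-mask of length n (e.g. a pLDDT mask);
        masked-out residues appear on neither side of the ratio.
    min_disease_residues
        Minimum number of kept mutated residues for the value to be
        reported; below it the protein is skipped (returns None).

    Returns None when the protein does not meet the residue threshold;
    raises on degenerate geometry (zero distances) or when no unmutated
    residue remains.
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("ca_coords must be (n, 3)")
    n = len(coords)
    keep = ~np.isnan(coords).any(axis=1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n,):
            raise ValueError("mask length must match number of residues")
        keep &= mask
    n_excluded = int(n - keep.sum())

    disease = np.zeros(n, dtype=bool)
    for idx in disease_residues:
        if not 1 <= idx <= n:
            raise ValueError(f"disease residue index {idx} outside 1..{n}")
        disease[idx - 1] = True

    kept_idx = np.flatnonzero(keep)
    kept_disease = np.flatnonzero(keep & disease)
    kept_nondisease = np.flatnonzero(keep & ~disease)

    if len(kept_disease) < min_disease_residues:
        logger.info(
            "%s/%s: %d mutated residues kept (< %d) — EDC not reported",
            protein_id, dataset, len(kept_disease), min_disease_residues,
        )
        return None
    if len(kept_nondisease) == 0:
        raise ValueError(f"{protein_id}: no unmutated residues left; EDC undefined")

    # D_min per kept residue: nearest kept disease residue other than itself
    dist = cdist(coords[kept_idx], coords[kept_disease])
    self_cols = {g: c for c, g in enumerate(kept_disease)}
    for r, g in enumerate(kept_idx):
        if g in self_cols:
            dist[r, self_cols[g]] = np.inf
    d_min = dist.min(axis=1)
    if np.any(d_min <= 0.0):
        raise ValueError(f"{protein_id}: duplicate Cα coordinates give D_min = 0")

    log_dmin = np.log(d_min)
    is_disease_row = np.isin(kept_idx, kept_disease)
    dbar_disease = float(log_dmin[is_disease_row].mean())
    dbar_nondisease = float(log_dmin[~is_disease_row].mean())
    return EdcResult(
        protein_id=protein_id,
        edc=dbar_nondisease / dbar_disease,
        n_disease=int(len(kept_disease)),
        n_nondisease=int(len(kept_nondisease)),
        dataset=dataset,
        recurrent=recurrent,
        excluded_low_confidence=n_excluded,
    )


def recurrent_edc(
    records: Sequence[MutationRecord],
    structures: Mapping[str, tuple[StructureModel, str]],
    min_recurrence: int = 7,
    min_disease_residues: int = 5,
    plddt_threshold: float = 70.0,
    dataset: str = "cancer_all",
) -> list[EdcResult]:
    """Recurrent-mutation EDC per protein.

    ``structures`` maps protein_id → (model, chain_id), with the chain
    chosen by the structure-selection step. Mutations are first filtered
    to those seen at least ``min_recurrence`` times, collapsed to
    distinct residues, and scored with :func:`compute_edc`; for
    predicted models low-confidence residues are masked first, while
    experimental structures use all residues. Proteins below the residue
    threshold are skipped (and logged), not errors.
    """
    kept = filter_recurrent(records, min_recurrence=min_recurrence)
    by_protein: dict[str, set[int]] = {}
    for record in kept:
        by_protein.setdefault(record.protein_id, set()).add(record.position)

    results: list[EdcResult] = []
    for protein_id, residues in sorted(by_protein.items()):
        if protein_id not in structures:
            logger.info("%s: no structure available — skipped", protein_id)
            continue
        model, chain_id = structures[protein_id]
        coords = model.ca_coordinates(chain_id)
        n = len(coords)
        if any(not 1 <= r <= n for r in residues):
            logger.warning(
                "%s: mutated residues outside structure axis dropped", protein_id
            )
            residues = {r for r in residues if 1 <= r <= n}
        mask = None
        if model.source == "predicted":
            mask = plddt_mask(model, chain_id, threshold=plddt_threshold)
        result = compute_edc(
            coords,
            residues,
            mask=mask,
            min_disease_residues=min_disease_residues,
            protein_id=protein_id,
            dataset=dataset,
            recurrent=True,
        )
        if result is not None:
            results.append(result)
    return results


def edc_to_frame(results: Iterable[EdcResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "dataset": r.dataset,
                "recurrent": r.recurrent,
                "edc": r.edc,
                "n_disease": r.n_disease,
                "n_nondisease": r.n_nondisease,
                "excluded_low_confidence": r.excluded_low_confidence,
            }
            for r in results
        ],
        columns=[
            "protein_id", "dataset", "recurrent", "edc",
            "n_disease", "n_nondisease", "excluded_low_confidence",
        ],
    )
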