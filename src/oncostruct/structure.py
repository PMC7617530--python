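"""Residue-level protein structure models and sequence-to-structure mapping.

Structures are read from PDB or mmCIF files into a light residue-level
model that keeps, for every standard amino-acid residue, its chain, a
1-based sequential index, the Cα coordinates and the B-factor column.
For computationally predicted models the B-factor column carries the
per-residue pLDDT confidence score (0-100), which downstream analyses
use to mask out low-confidence regions.

The mapping of a protein sequence onto a structure chain follows the
criteria used when mapping human proteins onto experimental structures:
a chain is accepted only when it shares >90% sequence identity with the
protein over an aligned region of at least 50 residues.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.structure import filter_amino_acids, get_residues
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure

__all__ = [
    "ResidueRecord",
    "StructureModel",
    "SequenceStructureMapping",
    "MappingRejection",
    "EmptyStructureError",
    "read_structure",
    "map_sequence_to_chain",
    "select_best_chain",
    "plddt_mask",
    "chain_sequence",
]

#: Three-letter codes accepted as standard residues (biotite handles the
#: 3→1 conversion; anything mapping outside the 20 letters becomes 'X').
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class EmptyStructureError(ValueError):
    """Raised when a structure file contains no polypeptide chain."""


@dataclass(frozen=True)
class ResidueRecord:
    """One standard residue in a structure chain.

    ``residue_index`` is the 1-based sequential position of the residue
    among the standard residues of its chain — the axis on which protein
    mutation positions are interpreted. ``author_number`` is the residue
    number printed in the structure file, kept for traceability.
    """

    chain_id: str
    residue_index: int
    author_number: int
    aa: str
    ca_xyz: np.ndarray | None
    bfactor_or_plddt: float
    has_ca: bool


@dataclass
class StructureModel:
    """A structure as an ordered collection of chains of residues."""

    structure_id: str
    source: Literal["experimental", "predicted"]
    chains: dict[str, list[ResidueRecord]]
    resolution: float | None = None
    atoms: object | None = field(default=None, repr=False)  # biotite AtomArray

    @property
    def assembly_size(self) -> int:
        return len(self.chains)

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not present in {self.structure_id}; "
                f"available: {sorted(self.chains)}"
            ) from None

    def ca_coordinates(self, chain_id: str) -> np.ndarray:
        """(n, 3) Cα coordinates of a chain; NaN rows where Cα is missing."""
        residues = self.chain(chain_id)
        out = np.full((len(residues), 3), np.nan)
        for i, res in enumerate(residues):
            if res.has_ca:
                out[i] = res.ca_xyz
        return out


@dataclass(frozen=True)
class SequenceStructureMapping:
    """Accepted alignment between a protein sequence and a structure chain."""

    protein_id: str
    chain_id: str
    aligned_pairs: tuple[tuple[int, int], ...]  # (sequence pos, residue_index)
    percent_identity: float
    aligned_length: int


@dataclass(frozen=True)
class MappingRejection:
    """Explicit refusal to map a sequence onto a chain, with the reason."""

    protein_id: str
    chain_id: str
    reason: Literal["identity", "length"]
    percent_identity: float
    aligned_length: int


def _parse_resolution_pdb(text: str) -> float | None:
    m = re.search(r"^REMARK   2 RESOLUTION\.\s+([0-9.]+)\s+ANGSTROM", text, re.M)
    return float(m.group(1)) if m else None


def _parse_resolution_cif(cif: CIFFile) -> float | None:
    block = cif.block
    for cat, key in (("refine", "ls_d_res_high"), ("reflns", "d_resolution_high")):
        try:
            val = block[cat][key].as_item()
            return float(val)
        except Exception:
            continue
    return None


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
    source: Literal["experimental", "predicted"] = "experimental",
    structure_id: str | None = None,
) -> StructureModel:
    """Read a PDB/mmCIF file into a residue-level :class:`StructureModel`.

    Only standard amino-acid residues are retained; hetero compounds,
    waters and modified residues are excluded from the residue axis.
    Multi-model files (e.g. NMR ensembles) contribute their first model
    only. Residues without a Cα atom are kept in the model but flagged
    ``has_ca=False`` so that distance-based analyses can skip them.

    Parameters
    ----------
    path
        Structure file. With ``format="auto"`` the extension decides
        (``.cif``/``.mmcif`` → mmCIF, anything else → PDB).
    source
        ``"predicted"`` marks the B-factor column as pLDDT.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"

    resolution: float | None = None
    try:
        if format == "pdb":
            pdb = PDBFile.read(str(path))
            atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
            resolution = _parse_resolution_pdb("\n".join(pdb.lines))
        elif format == "mmcif":
            cif = CIFFile.read(str(path))
            atoms = _cif_get_structure(cif, model=1, extra_fields=["b_factor"])
            resolution = _parse_resolution_cif(cif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (FileNotFoundError, ValueError):
        raise
    except Exception as exc:
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc

    aa_mask = filter_amino_acids(atoms)
    atoms = atoms[aa_mask]
    chains: dict[str, list[ResidueRecord]] = {}
    if atoms.array_length() > 0:
        for chain_id in np.unique(atoms.chain_id):
            chain_atoms = atoms[atoms.chain_id == chain_id]
            res_starts, res_names = get_residues(chain_atoms)
            records: list[ResidueRecord] = []
            index = 0
            for author_number, res_name in zip(res_starts, res_names):
                try:
                    one = ProteinSequence.convert_letter_3to1(res_name.item())
                except Exception:
                    one = "X"
                one = one.upper()
                if one not in _STANDARD_AA:
                    # modified / non-standard residues are excluded from the
                    # mapped residue axis entirely
                    continue
                res_atoms = chain_atoms[chain_atoms.res_id == author_number]
                ca = res_atoms[res_atoms.atom_name == "CA"]
                has_ca = ca.array_length() > 0
                index += 1
                records.append(
                    ResidueRecord(
                        chain_id=str(chain_id),
                        residue_index=index,
                        author_number=int(author_number),
                        aa=one,
                        ca_xyz=np.asarray(ca.coord[0], dtype=float) if has_ca else None,
                        bfactor_or_plddt=float(res_atoms.b_factor[0]),
                        has_ca=has_ca,
                    )
                )
            if records:
                chains[str(chain_id)] = records
    if not chains:
        raise EmptyStructureError(f"{path} contains no polypeptide chain")

    return StructureModel(
        structure_id=structure_id or path.stem,
        source=source,
        chains=chains,
        resolution=resolution if source == "experimental" else None,
        atoms=atoms,
    )


def chain_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of the standard residues of a chain."""
    return "".join(res.aa for res in model.chain(chain_id))


def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # free end gaps: partial chains should not be penalised for covering
    # only part of the protein
    aligner.end_gap_score = 0.0
    return aligner


def map_sequence_to_chain(
    protein_seq: str,
    model: StructureModel,
    chain_id: str,
    min_identity: float = 90.0,
    min_length: int = 50,
    protein_id: str = "protein",
) -> SequenceStructureMapping | MappingRejection:
    """Align a protein sequence to a structure chain and accept or reject.

    The alignment is global with free end gaps. Percent identity is
    computed over aligned (non-gap) columns. The mapping is accepted only
    when identity is strictly greater than ``min_identity`` (percent) and
    the number of aligned columns is at least ``min_length``; otherwise a
    :class:`MappingRejection` naming the first failed criterion is
    returned.
    """
    if not protein_seq:
        raise ValueError("protein_seq must be non-empty")
    residues = model.chain(chain_id)
    chain_seq = "".join(res.aa for res in residues)

    aligner = _make_aligner()
    alignment = aligner.align(protein_seq, chain_seq)[0]
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            seq_pos = t0 + offset  # 0-based in protein_seq
            chain_pos = q0 + offset  # 0-based in chain residue list
            pairs.append((seq_pos + 1, residues[chain_pos].residue_index))
            if protein_seq[seq_pos] == chain_seq[chain_pos]:
                n_ident += 1
    aligned_length = len(pairs)
    identity = 100.0 * n_ident / aligned_length if aligned_length else 0.0

    if aligned_length < min_length:
        return MappingRejection(protein_id, chain_id, "length", identity, aligned_length)
    if not identity > min_identity:
        return MappingRejection(protein_id, chain_id, "identity", identity, aligned_length)
    return SequenceStructureMapping(
        protein_id=protein_id,
        chain_id=chain_id,
        aligned_pairs=tuple(pairs),
        percent_identity=identity,
        aligned_length=aligned_length,
    )


def select_best_chain(
    candidates: Sequence[tuple[StructureModel, SequenceStructureMapping]],
) -> tuple[StructureModel, SequenceStructureMapping]:
    """Pick one structure/chain among candidates covering the same protein.

    Highest resolution (numerically lowest) wins; ties are broken by the
    largest assembly (number of polypeptide chains), then by structure id
    so the choice is deterministic. Models without a resolution (e.g.
    predicted ones) sort after any resolved experimental structure.
    """
    if not candidates:
        raise ValueError("no candidates to select from")

    def key(item: tuple[StructureModel, SequenceStructureMapping]):
        model, mapping = item
        res = model.resolution if model.resolution is not None else np.inf
        return (res, -model.assembly_size, model.structure_id, mapping.chain_id)

    return min(candidates, key=key)


def plddt_mask(model: StructureModel, chain_id: str, threshold: float = 70.0) -> np.ndarray:
    """Boolean keep-mask over a chain's residues from pLDDT confidence.

    Residues with pLDDT below ``threshold`` are masked out; a residue at
    exactly the threshold is retained. For experimental structures every
    residue is kept and a warning is emitted, since their B-factor column
    is not a confidence score.
    """
    residues = model.chain(chain_id)
    if model.source != "predicted":
        warnings.warn(
            f"{model.structure_id} is experimental; pLDDT mask keeps all residues",
            stacklevel=2,
        )
        return np.ones(len(residues), dtype=bool)
    return np.array([res.bfactor_or_plddt >= threshold for res in residues], dtype=bool)


def residue_table(model: StructureModel):
    """Residue-level view of a model as a :class:`pandas.DataFrame`."""
    import pandas as pd

    rows = []
    for chain_id, residues in model.chains.items():
        for res in residues:
            x, y, z = (res.ca_xyz if res.has_ca else (np.nan, np.nan, np.nan))
            rows.append(
                {
                    "structure_id": model.structure_id,
                    "chain_id": chain_id,
                    "residue_index": res.residue_index,
                    "author_number": res.author_number,
                    "aa": res.aa,
                    "ca_x": x,
                    "ca_y": y,
                    "ca_z": z,
                    "bfactor_or_plddt": res.bfactor_or_plddt,
                    "has_ca": res.has_ca,
                }
            )
    return pd.DataFrame(rows)
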