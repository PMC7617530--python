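"""Solvent accessibility, residue location classes and secondary structure.

Residues are placed into three location classes from their relative
solvent accessibility (RSA = SASA / reference maximum ASA):

* interior:  RSA ≤ 0.3
* interface: 0.3 < RSA < 0.5
* surface:   RSA ≥ 0.5

Secondary structure comes from DSSP output files when available,
collapsed from the 8-state alphabet to helix (H, G, I), strand (E, B)
and other. A purely geometric Cα-based assigner is provided as an
approximate fallback for models without DSSP output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from biotite.structure import sasa as _shrake_rupley_sasa

from .structure import StructureModel

__all__ = [
    "MAX_ASA_SCALES",
    "compute_sasa",
    "relative_accessibility",
    "classify_location",
    "read_dssp",
    "collapse_ss8",
    "assign_ss_fallback",
    "residue_context_table",
]

# Reference maximum accessible surface areas (Å²), theoretical values of
# Tien et al. (2013) as the default, with the empirical Miller (1987)
# scale available as an alternative.
MAX_ASA_SCALES: dict[str, dict[str, float]] = {
    "tien2013": {
        "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
        "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
        "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
        "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    },
    "miller1987": {
        "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
        "E": 183.0, "Q": 189.0, "G": 85.0, "H": 194.0, "I": 182.0,
        "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
        "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
    },
}


def _per_residue_sasa(atoms, probe_radius: float, n_points: int) -> dict[tuple[str, int], float]:
    """Shrake-Rupley SASA of an AtomArray, aggregated per residue."""
    per_atom = _shrake_rupley_sasa(
        atoms, probe_radius=probe_radius, point_number=n_points, vdw_radii="Single"
    )
    per_atom = np.nan_to_num(per_atom)
    out: dict[tuple[str, int], float] = {}
    keys = list(zip(atoms.chain_id, atoms.res_id))
    for key, value in zip(keys, per_atom):
        k = (str(key[0]), int(key[1]))
        out[k] = out.get(k, 0.0) + float(value)
    return out


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    isolated_chain: str | None = None,
) -> dict[str, np.ndarray]:
    """Per-residue solvent-accessible surface area (Å²).

    Uses sphere-sampling (Shrake-Rupley) over the model's atoms with a
    water-sized probe. Returns one array per chain, aligned with the
    chain's residue list. With ``isolated_chain`` the calculation is
    restricted to that chain's atoms alone, which is what an RSA change
    upon complex formation needs.
    """
    atoms = model.atoms
    if atoms is None or atoms.array_length() == 0:
        raise ValueError(f"{model.structure_id} has no atomic coordinates")
    if isolated_chain is not None:
        atoms = atoms[atoms.chain_id == isolated_chain]
        if atoms.array_length() == 0:
            raise ValueError(f"chain {isolated_chain!r} has no atoms")
    residue_sasa = _per_residue_sasa(atoms, probe_radius, n_points)

    out: dict[str, np.ndarray] = {}
    chain_ids = [isolated_chain] if isolated_chain is not None else list(model.chains)
    for chain_id in chain_ids:
        residues = model.chain(chain_id)
        out[chain_id] = np.array(
            [residue_sasa.get((chain_id, res.author_number), 0.0) for res in residues]
        )
    return out


def relative_accessibility(
    model: StructureModel,
    sasa: dict[str, np.ndarray],
    scale: str = "tien2013",
) -> dict[str, np.ndarray]:
    """RSA per residue: SASA divided by the reference maximum ASA."""
    max_asa = MAX_ASA_SCALES[scale]
    out = {}
    for chain_id, values in sasa.items():
        residues = model.chain(chain_id)
        out[chain_id] = np.array(
            [v / max_asa.get(res.aa, np.mean(list(max_asa.values())))
             for res, v in zip(residues, values)]
        )
    return out


def classify_location(rsa: float) -> Literal["interior", "interface", "surface"]:
    """Location class of a residue from its RSA.

    Boundary semantics: RSA of exactly 0.3 is interior and exactly 0.5
    is surface; the open interval between them is interface.
    """
    if rsa < 0:
        raise ValueError(f"RSA must be non-negative, got {rsa}")
    if rsa <= 0.3:
        return "interior"
    if rsa < 0.5:
        return "interface"
    return "surface"


_SS8_TO_3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
}


def collapse_ss8(code: str) -> str:
    """Collapse an 8-state DSSP code to helix / strand / other."""
    return _SS8_TO_3.get(code.strip().upper() or "-", "other")


def read_dssp(path: str | Path) -> pd.DataFrame:
    """Parse a classic-format DSSP output file.

    Returns a frame with chain, author residue number, amino acid, the
    raw 8-state code (``ss8``) and the collapsed 3-state ``ss_class``.
    Chain-break records are skipped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path} does not look like DSSP output (no residue header)")
    rows = []
    for line in lines[start:]:
        if len(line) < 17:
            continue
        aa = line[13]
        if aa == "!":  # chain break
            continue
        try:
            resnum = int(line[5:10])
        except ValueError as exc:
            raise ValueError(f"malformed DSSP residue line: {line!r}") from exc
        ss8 = line[16].strip() or "-"
        rows.append(
            {
                "chain_id": line[11].strip(),
                "author_number": resnum,
                "aa": aa.upper(),
                "ss8": ss8,
                "ss_class": collapse_ss8(ss8),
            }
        )
    return pd.DataFrame(rows, columns=["chain_id", "author_number", "aa", "ss8", "ss_class"])


def assign_ss_fallback(model: StructureModel, chain_id: str) -> list[str]:
    """Approximate 3-state secondary structure from Cα geometry alone.

    Uses the characteristic Cα(i)-Cα(i+3) and Cα(i)-Cα(i+4) distance
    signature of α-helices (≈5.1 Å and ≈6.2 Å) and the long i→i+3
    separation of extended strands. Windows of four/five consecutive
    residues vote for the residues they cover; ties and uncovered
    residues default to "other". This assigner is approximate — use
    DSSP output when available.
    """
    coords = model.ca_coordinates(chain_id)
    n = len(coords)
    votes: list[dict[str, int]] = [dict() for _ in range(n)]

    def _vote(i: int, j: int, label: str) -> None:
        for k in range(i, j + 1):
            votes[k][label] = votes[k].get(label, 0) + 1

    for i in range(n - 4):
        window = coords[i : i + 5]
        if np.isnan(window).any():
            continue
        d13 = float(np.linalg.norm(window[3] - window[0]))
        d14 = float(np.linalg.norm(window[4] - window[0]))
        if d13 < 6.0 and d14 < 7.2:
            _vote(i, i + 4, "helix")
        elif d13 > 9.0 and d14 > 12.0:
            _vote(i, i + 4, "strand")
        else:
            _vote(i, i + 4, "other")

    out = []
    for v in votes:
        if not v:
            out.append("other")
        else:
            best = max(v.values())
            winners = sorted(label for label, count in v.items() if count == best)
            out.append(winners[0] if len(winners) == 1 else "other")
    return out


def residue_context_table(
    model: StructureModel,
    scale: str = "tien2013",
    probe_radius: float = 1.4,
    n_points: int = 960,
    dssp: pd.DataFrame | None = None,
    interface_mode: Literal["rsa_bands", "delta_rsa"] = "rsa_bands",
) -> pd.DataFrame:
    """Per-residue structural context for every chain of a model.

    ``interface_mode="rsa_bands"`` applies the three-band RSA rule
    directly. ``"delta_rsa"`` instead calls a residue interface when its
    RSA computed on the isolated chain exceeds its RSA in the full
    assembly (i.e. it is buried upon complex formation); the remaining
    residues fall back to interior (RSA ≤ 0.3) or surface. The columns
    record which mode and reference scale produced them.
    """
    sasa = compute_sasa(model, probe_radius=probe_radius, n_points=n_points)
    rsa = relative_accessibility(model, sasa, scale=scale)

    delta: dict[str, np.ndarray] = {}
    if interface_mode == "delta_rsa":
        for chain_id in model.chains:
            iso = compute_sasa(
                model, probe_radius=probe_radius, n_points=n_points,
                isolated_chain=chain_id,
            )
            iso_rsa = relative_accessibility(model, iso, scale=scale)
            delta[chain_id] = iso_rsa[chain_id] - rsa[chain_id]

    ss_by_key: dict[tuple[str, int], str] = {}
    ss8_by_key: dict[tuple[str, int], str] = {}
    if dssp is not None:
        for row in dssp.itertuples(index=False):
            ss_by_key[(row.chain_id, row.author_number)] = row.ss_class
            ss8_by_key[(row.chain_id, row.author_number)] = row.ss8
    ss_provenance = "dssp" if dssp is not None else "ca_geometry_approximate"

    rows = []
    for chain_id, residues in model.chains.items():
        fallback = None
        for i, res in enumerate(residues):
            r = float(rsa[chain_id][i])
            if interface_mode == "delta_rsa" and delta[chain_id][i] > 1e-6:
                location = "interface"
            elif interface_mode == "delta_rsa":
                location = "interior" if r <= 0.3 else "surface"
            else:
                location = classify_location(r)
            key = (chain_id, res.author_number)
            if key in ss_by_key:
                ss = ss_by_key[key]
                ss8 = ss8_by_key[key]
            else:
                if fallback is None:
                    fallback = assign_ss_fallback(model, chain_id)
                ss = fallback[i]
                ss8 = "-"
            rows.append(
                {
                    "structure_id": model.structure_id,
                    "chain_id": chain_id,
                    "residue_index": res.residue_index,
                    "aa": res.aa,
                    "sasa": float(sasa[chain_id][i]),
                    "rsa": r,
                    "location": location,
                    "ss_class": ss,
                    "ss8": ss8,
                    "ss_provenance": ss_provenance,
                    "rsa_scale": scale,
                    "interface_mode": interface_mode,
                }
            )
    return pd.DataFrame(rows)
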