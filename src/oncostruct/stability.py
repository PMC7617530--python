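"""Per-protein stability landscapes and the rank-normalized ΔΔG metric.

Predicted folding free-energy changes (ΔΔG, kcal/mol) for all possible
missense substitutions of a protein form a heavily skewed distribution:
most values fall below ~3 kcal/mol but occasional extreme outliers
dominate any linear scale, and different proteins have very different
intrinsic propensities for destabilizing mutations. Both problems are
removed by rank-normalizing the absolute ΔΔG values within each protein
onto [0, 1]:

    ddg_rank = (rank(|ΔΔG|) - 1) / (n - 1)

with average ranks for ties. 0 is the mildest possible substitution in
the protein, 1 the most destabilizing, and the mean over the complete
substitution landscape is exactly 0.5 (tied or not), so a random draw
of mutations is expected to average 0.5 in the absence of selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "VariantKey",
    "StabilityTable",
    "read_foldx_output",
    "read_stability_csv",
    "average_over_models",
    "enumerate_snv_reachable",
    "ddg_rank",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class VariantKey(NamedTuple):
    """One missense substitution on a protein's own 1-based residue axis."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def validate(self) -> "VariantKey":
        if self.ref_aa not in _AA or self.alt_aa not in _AA:
            raise ValueError(f"non-standard amino acid in {self}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt identical in {self}")
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive in {self}")
        return self


@dataclass
class StabilityTable:
    """Ranked stability landscape of one protein.

    ``entries`` maps each variant to ``(ddg, abs_ddg, ddg_rank)``.
    """

    protein_id: str
    entries: dict[VariantKey, tuple[float, float, float]]
    provenance: Literal["experimental-complex", "predicted-monomer"] = "predicted-monomer"
    n_models_averaged: int = 1
    replicate_counts: dict[VariantKey, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def ranks(self) -> dict[VariantKey, float]:
        return {k: v[2] for k, v in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": k.protein_id,
                "position": k.position,
                "ref_aa": k.ref_aa,
                "alt_aa": k.alt_aa,
                "ddg": ddg,
                "abs_ddg": abs_ddg,
                "ddg_rank": rank,
            }
            for k, (ddg, abs_ddg, rank) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


# FoldX individual-list token, e.g. "KA12G": ref aa, chain, position, alt aa
_FOLDX_TOKEN = re.compile(r"^([A-Y])([A-Za-z0-9])(\d+)([A-Y])$")


def _parse_foldx_lines(path: Path, protein_id: str) -> Iterable[tuple[VariantKey, float]]:
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        m = _FOLDX_TOKEN.match(parts[0].rstrip(";"))
        if m is None:
            continue
        ref, _chain, pos, alt = m.groups()
        yield VariantKey(protein_id, int(pos), ref, alt).validate(), float(parts[1])


def read_foldx_output(
    paths: str | Path | Iterable[str | Path],
    protein_id: str | None = None,
) -> dict[VariantKey, float]:
    """Read FoldX-style output into a variant → ΔΔG map.

    Two dialects are accepted per file: the FoldX individual-list style
    (variant token like ``KA12G`` plus an energy column, one line per
    replicate) and a generic delimited table with columns ``protein_id,
    position, ref_aa, alt_aa, ddg[, replicate]``. Replicate energies of
    the same variant are averaged arithmetically; a variant whose
    replicates disagree on the reference amino acid is a consistency
    error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    acc: dict[VariantKey, list[float]] = {}
    ref_seen: dict[tuple[str, int], str] = {}

    def _add(key: VariantKey, value: float) -> None:
        prev = ref_seen.setdefault((key.protein_id, key.position), key.ref_aa)
        if prev != key.ref_aa:
            raise ValueError(
                f"inconsistent reference amino acid at {key.protein_id} position "
                f"{key.position}: {prev!r} vs {key.ref_aa!r}"
            )
        acc.setdefault(key, []).append(value)

    for raw in paths:
        path = Path(raw)
        header = path.read_text().splitlines()[0] if path.stat().st_size else ""
        if "position" in header and "ddg" in header:
            frame = pd.read_csv(path, sep=None, engine="python")
            for row in frame.itertuples(index=False):
                key = VariantKey(
                    str(row.protein_id), int(row.position),
                    str(row.ref_aa), str(row.alt_aa),
                ).validate()
                _add(key, float(row.ddg))
        else:
            pid = protein_id if protein_id is not None else path.stem
            for key, value in _parse_foldx_lines(path, pid):
                _add(key, value)
    if not acc:
        raise ValueError(f"no variants parsed from {list(map(str, paths))}")
    return {k: float(np.mean(v)) for k, v in acc.items()}


def read_stability_csv(path: str | Path) -> dict[str, dict[VariantKey, float]]:
    """Read a generic stability CSV covering one or more proteins."""
    frame = pd.read_csv(path, sep=None, engine="python")
    required = {"protein_id", "position", "ref_aa", "alt_aa", "ddg"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path} is missing required columns: {sorted(missing)}")
    out: dict[str, dict[VariantKey, list[float]]] = {}
    for row in frame.itertuples(index=False):
        key = VariantKey(
            str(row.protein_id), int(row.position), str(row.ref_aa), str(row.alt_aa)
        ).validate()
        out.setdefault(key.protein_id, {}).setdefault(key, []).append(float(row.ddg))
    return {
        pid: {k: float(np.mean(v)) for k, v in entries.items()}
        for pid, entries in out.items()
    }


def average_over_models(
    tables: Iterable[Mapping[VariantKey, float]],
) -> tuple[dict[VariantKey, float], dict[VariantKey, int]]:
    """Average ΔΔG per variant over overlapping structural models.

    Large proteins are often covered by several overlapping models; a
    variant's ΔΔG is the mean over the models in which it appears. The
    per-variant model count is returned alongside the averaged map.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no stability maps to average")
    protein_ids = {key.protein_id for t in tables for key in t}
    if len(protein_ids) > 1:
        raise ValueError(f"maps span multiple proteins: {sorted(protein_ids)}")
    acc: dict[VariantKey, list[float]] = {}
    for table in tables:
        for key, value in table.items():
            acc.setdefault(key, []).append(float(value))
    averaged = {k: float(np.mean(v)) for k, v in acc.items()}
    counts = {k: len(v) for k, v in acc.items()}
    return averaged, counts


# --- single-nucleotide reachability --------------------------------------

_BASES = "ACGT"


def _codon_table():
    from Bio.Data import CodonTable

    return CodonTable.unambiguous_dna_by_id[1]


def enumerate_snv_reachable(aa_or_codon: str) -> set[str]:
    """Amino acids reachable from a codon (or amino acid) by one SNV.

    Given a codon, enumerates its nine single-nucleotide neighbours under
    the standard genetic code and returns the distinct encoded amino
    acids, excluding the reference amino acid itself and stop codons.
    Given a one-letter amino acid instead, returns the union over all
    codons encoding it (codon-agnostic reachability, used when the
    actual coding sequence is unknown).
    """
    table = _codon_table()
    token = aa_or_codon.upper()
    if len(token) == 1:
        if token not in _AA:
            raise ValueError(f"invalid amino acid {aa_or_codon!r}")
        codons = [c for c, aa in table.forward_table.items() if aa == token]
        out: set[str] = set()
        for codon in codons:
            out |= enumerate_snv_reachable(codon)
        return out
    if len(token) != 3 or any(b not in _BASES for b in token):
        raise ValueError(f"invalid codon {aa_or_codon!r}")
    ref_aa = table.forward_table.get(token)
    if ref_aa is None:
        raise ValueError(f"{aa_or_codon!r} is a stop codon")
    reachable: set[str] = set()
    for i in range(3):
        for base in _BASES:
            if base == token[i]:
                continue
            neighbour = token[:i] + base + token[i + 1 :]
            aa = table.forward_table.get(neighbour)
            if aa is not None and aa != ref_aa:
                reachable.add(aa)
    return reachable


def ddg_rank(
    raw: Mapping[VariantKey, float],
    protein_id: str | None = None,
    provenance: Literal["experimental-complex", "predicted-monomer"] = "predicted-monomer",
    n_models_averaged: int = 1,
    snv_reachable_only: bool = False,
) -> StabilityTable:
    """Rank-normalize a raw ΔΔG map into a :class:`StabilityTable`.

    Ranks are computed on |ΔΔG| ascending with average ranks for ties
    and normalized as ``(rank - 1) / (n - 1)``, which pins the mildest
    untied substitution at 0, the most destabilizing untied one at 1,
    and the mean over the whole landscape at exactly 0.5. With
    ``snv_reachable_only`` the landscape is first restricted to
    substitutions reachable by a single nucleotide change
    (codon-agnostic, since no coding sequence is given here).
    """
    entries = dict(raw)
    if snv_reachable_only:
        entries = {
            k: v for k, v in entries.items()
            if k.alt_aa in enumerate_snv_reachable(k.ref_aa)
        }
    if len(entries) < 2:
        raise ValueError("need at least two variants to rank")
    pids = {k.protein_id for k in entries}
    if protein_id is None:
        if len(pids) > 1:
            raise ValueError(f"map spans multiple proteins: {sorted(pids)}")
        protein_id = next(iter(pids))

    keys = list(entries)
    ddg = np.array([entries[k] for k in keys], dtype=float)
    abs_ddg = np.abs(ddg)
    ranks = (rankdata(abs_ddg, method="average") - 1.0) / (len(keys) - 1.0)
    return StabilityTable(
        protein_id=protein_id,
        entries={
            k: (float(d), float(a), float(r))
            for k, d, a, r in zip(keys, ddg, abs_ddg, ranks)
        },
        provenance=provenance,
        n_models_averaged=n_models_averaged,
    )
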