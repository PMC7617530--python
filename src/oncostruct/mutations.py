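"""Reading, deduplicating, filtering and role-labelling mutation datasets.

Mutation tables are delimited text with one protein-level missense
variant per row: gene, protein id, 1-based position, reference and
alternate amino acid, a recurrence count (number of samples the variant
was seen in) and a dataset label. Gene roles (oncogene / tumor
suppressor) come from a separate two-column table; a "fusion"
classification is ignored since it reflects a different class of
genomic change than missense variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "GeneRole",
    "DATASET_LABELS",
    "read_mutations",
    "deduplicate",
    "filter_recurrent",
    "assign_roles",
    "mutations_to_frame",
]

DATASET_LABELS = {
    "cancer_all",
    "cancer_recurrent",
    "cancer_driver",
    "pathogenic",
    "putatively_benign",
    "custom",
}

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationRecord:
    gene: str
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    recurrence: int
    dataset: str

    def key(self) -> tuple[str, int, str, str, str]:
        return (self.protein_id, self.position, self.ref_aa, self.alt_aa, self.dataset)


@dataclass(frozen=True)
class GeneRole:
    gene: str
    role: Literal["oncogene", "tsg", "oncogene_and_tsg", "none"]


_REQUIRED_COLUMNS = {"gene", "protein_id", "position", "ref_aa", "alt_aa"}


def read_mutations(path: str | Path, dataset: str = "custom") -> list[MutationRecord]:
    """Read a delimited mutation table into records.

    Rows with a missing or invalid field (non-standard amino acid,
    identical ref/alt — i.e. not missense — non-positive position, bad
    recurrence) are dropped and counted in the log rather than aborting
    the run. A missing required column is a schema error. The
    ``recurrence`` column is optional and defaults to 1.
    """
    if dataset not in DATASET_LABELS:
        raise ValueError(f"unknown dataset label {dataset!r}")
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = _REQUIRED_COLUMNS - set(frame.columns)
    if missing:
        raise ValueError(f"{path} is missing required columns: {sorted(missing)}")
    records: list[MutationRecord] = []
    n_dropped = 0
    for row in frame.itertuples(index=False):
        try:
            ref = str(row.ref_aa).upper()
            alt = str(row.alt_aa).upper()
            pos = int(row.position)
            rec = int(getattr(row, "recurrence", 1))
            if ref not in _AA or alt not in _AA or ref == alt or pos < 1 or rec < 1:
                raise ValueError
            records.append(
                MutationRecord(
                    gene=str(row.gene),
                    protein_id=str(row.protein_id),
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    recurrence=rec,
                    dataset=dataset,
                )
            )
        except (ValueError, TypeError):
            n_dropped += 1
    if n_dropped:
        logger.info("read_mutations(%s): dropped %d invalid rows", path, n_dropped)
    return records


def deduplicate(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Keep one record per unique missense variant (within a dataset).

    Duplicate rows of the same variant merge their recurrence by max:
    the recurrence column is a per-variant sample count, so duplicated
    rows are repeated observations of the same count rather than
    additive tallies.
    """
    merged: dict[tuple, MutationRecord] = {}
    for record in records:
        key = record.key()
        prev = merged.get(key)
        if prev is None or record.recurrence > prev.recurrence:
            merged[key] = record
    return list(merged.values())


def filter_recurrent(
    records: Iterable[MutationRecord], min_recurrence: int = 7
) -> list[MutationRecord]:
    """Keep variants seen at least ``min_recurrence`` times (inclusive)."""
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")
    return [r for r in records if r.recurrence >= min_recurrence]


def assign_roles(
    genes: Iterable[str], role_table: str | Path | pd.DataFrame
) -> dict[str, GeneRole]:
    """Resolve gene roles from a (gene, role_string) table.

    Role strings are tokenized on commas/semicolons; only "oncogene" and
    "TSG" tokens count, a "fusion" token is ignored, and genes absent
    from the table (or with no recognised token) get role "none".
    """
    if isinstance(role_table, pd.DataFrame):
        frame = role_table
    else:
        frame = pd.read_csv(role_table, sep=None, engine="python")
    if not {"gene", "role_string"} <= set(frame.columns):
        raise ValueError("role table needs columns: gene, role_string")
    raw = {str(r.gene): str(r.role_string) for r in frame.itertuples(index=False)}

    out: dict[str, GeneRole] = {}
    for gene in genes:
        role_string = raw.get(gene, "")
        tokens = {
            t.strip().lower()
            for t in role_string.replace(";", ",").split(",")
            if t.strip()
        }
        known = {"oncogene", "tsg", "fusion"}
        if tokens - known:
            logger.warning(
                "unrecognised role tokens %s for gene %s; treating as none",
                sorted(tokens - known), gene,
            )
            tokens &= known
        has_onc = "oncogene" in tokens
        has_tsg = "tsg" in tokens
        if has_onc and has_tsg:
            role = "oncogene_and_tsg"
        elif has_onc:
            role = "oncogene"
        elif has_tsg:
            role = "tsg"
        else:
            role = "none"
        out[gene] = GeneRole(gene=gene, role=role)
    return out


def mutations_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "protein_id": r.protein_id,
                "position": r.position,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "recurrence": r.recurrence,
                "dataset": r.dataset,
            }
            for r in records
        ],
        columns=[
            "gene", "protein_id", "position", "ref_aa", "alt_aa",
            "recurrence", "dataset",
        ],
    )
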