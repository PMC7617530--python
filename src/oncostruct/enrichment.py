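"""Gene-level damage enrichment, nonparametric tests and candidate ranking.

The gene-level statistic is the ΔΔG_rank difference: the mean
rank-normalized stability perturbation of the missense mutations
observed in a gene minus the mean over all possible but unobserved
substitutions of the same protein. Positive values mean the observed
mutations are more structurally damaging than random draws from the
protein's own landscape — the signature of selection for damaging
(loss-of-function) mutations, typical of tumor suppressors. The
significance of the difference is a two-sided two-sample Wilcoxon
(Mann-Whitney) test, Bonferroni-corrected across the genes tested.

Candidate driver genes are ranked two ways: by damage enrichment
(smallest p among structure sources, positive differences only) and by
the clustering of recurrent mutations (recurrent EDC, descending).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .edc import EdcResult
from .stability import StabilityTable, VariantKey

__all__ = [
    "GeneEnrichmentResult",
    "GroupComparison",
    "gene_damage_enrichment",
    "wilcoxon_two_sample",
    "fisher_2x2",
    "bonferroni_threshold",
    "rank_candidates",
    "compare_groups",
]

#: Largest pooled sample size for which the Wilcoxon null distribution is
#: enumerated exactly; beyond it the tie-corrected normal approximation
#: is used. C(16, 8) = 12,870 assignments at most.
EXACT_LIMIT_DEFAULT = 16


@dataclass(frozen=True)
class GeneEnrichmentResult:
    protein_id: str
    ddg_rank_diff: float
    p_value: float
    n_observed: int
    n_unobserved: int
    structure_source: Literal["experimental", "predicted"] = "predicted"
    significant: bool = False


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    statistic: Literal["wilcoxon", "fisher"]
    estimate: float
    p_value: float
    n_a: int
    n_b: int


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a: pairs where a > b, ties counting half."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def wilcoxon_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> tuple[float, float]:
    """Two-sample Wilcoxon (Mann-Whitney) test, two-sided.

    For pooled sizes up to ``exact_limit`` the null distribution of U is
    enumerated exactly over all assignments of the pooled values to the
    two groups (valid with ties), with the two-sided p as twice the
    smaller tail, capped at 1. Larger samples use the tie-corrected
    normal approximation with continuity correction.

    Returns ``(U, p)`` with U counted for the first sample.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _mann_whitney_u(a, b)
    n_total = len(a) + len(b)
    if n_total <= exact_limit:
        pooled = np.concatenate([a, b])
        idx = range(n_total)
        n_a = len(a)
        count_le = 0
        count_ge = 0
        total = 0
        for chosen in combinations(idx, n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(chosen)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            total += 1
            if u <= u_obs + 1e-9:
                count_le += 1
            if u >= u_obs - 1e-9:
                count_ge += 1
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return u_obs, p
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def fisher_2x2(counts: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2×2 table, two-sided.

    Returns the sample (cross-product) odds ratio — infinite when a
    zero cell makes it so — and the exact conditional p-value obtained
    by summing hypergeometric probabilities no larger than that of the
    observed table. Both margins must be positive.
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("counts must be a non-negative 2×2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("both margins of the 2×2 table must be positive")
    (a, b), (c, d) = table
    odds_ratio = math.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return odds_ratio, float(p)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def gene_damage_enrichment(
    table: StabilityTable,
    observed: Iterable[VariantKey],
    structure_source: Literal["experimental", "predicted"] = "predicted",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> GeneEnrichmentResult | None:
    """ΔΔG_rank difference of observed vs possible-but-unobserved mutations.

    Observed variants not present in the stability landscape are
    dropped (they could not be scored). Returns None when either side
    of the comparison is empty. The ``significant`` flag is left False
    here; it is set against the Bonferroni threshold once the number of
    genes tested is known (see :func:`mark_significance`).
    """
    ranks = table.ranks()
    observed_keys = {k for k in observed if k in ranks}
    obs = np.array([ranks[k] for k in observed_keys], dtype=float)
    unobs = np.array([v for k, v in ranks.items() if k not in observed_keys], dtype=float)
    if len(obs) == 0 or len(unobs) == 0:
        return None
    diff = float(obs.mean() - unobs.mean())
    _, p = wilcoxon_two_sample(obs, unobs, exact_limit=exact_limit)
    return GeneEnrichmentResult(
        protein_id=table.protein_id,
        ddg_rank_diff=diff,
        p_value=p,
        n_observed=len(obs),
        n_unobserved=len(unobs),
        structure_source=structure_source,
    )


def mark_significance(
    results: Sequence[GeneEnrichmentResult], alpha: float = 0.05
) -> tuple[list[GeneEnrichmentResult], float]:
    """Set the ``significant`` flag at the Bonferroni threshold α/N.

    N is the number of genes actually tested for the given structure
    source, computed from the results at hand.
    """
    if not results:
        return [], float("nan")
    threshold = bonferroni_threshold(alpha, len(results))
    flagged = [
        GeneEnrichmentResult(
            protein_id=r.protein_id,
            ddg_rank_diff=r.ddg_rank_diff,
            p_value=r.p_value,
            n_observed=r.n_observed,
            n_unobserved=r.n_unobserved,
            structure_source=r.structure_source,
            significant=r.p_value <= threshold,
        )
        for r in results
    ]
    return flagged, threshold


def compare_groups(
    values: Mapping[str, Sequence[float]] | None = None,
    categories: Mapping[str, tuple[int, int]] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Pairwise comparisons between mutation groups.

    Continuous per-group values (e.g. ΔΔG_rank) are compared with the
    two-sample Wilcoxon test; category counts (e.g. interior+interface
    vs surface) as 2×2 tables with Fisher's exact test. ``pairs``
    restricts which comparisons run; default is all unordered pairs.
    """
    out: list[GroupComparison] = []
    if values:
        names = sorted(values)
        todo = pairs or list(combinations(names, 2))
        for g1, g2 in todo:
            a, b = np.asarray(values[g1]), np.asarray(values[g2])
            _, p = wilcoxon_two_sample(a, b)
            out.append(
                GroupComparison(
                    group_a=g1, group_b=g2, statistic="wilcoxon",
                    estimate=float(np.mean(a) - np.mean(b)), p_value=p,
                    n_a=len(a), n_b=len(b),
                )
            )
    if categories:
        names = sorted(categories)
        todo = pairs or list(combinations(names, 2))
        for g1, g2 in todo:
            table = [list(categories[g1]), list(categories[g2])]
            odds_ratio, p = fisher_2x2(table)
            out.append(
                GroupComparison(
                    group_a=g1, group_b=g2, statistic="fisher",
                    estimate=odds_ratio, p_value=p,
                    n_a=sum(categories[g1]), n_b=sum(categories[g2]),
                )
            )
    return out


def rank_candidates(
    enrichments: Mapping[str, Sequence[GeneEnrichmentResult]],
    edcs: Sequence[EdcResult],
    top_n: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Candidate tumor-suppressor and oncogene tables.

    The damage table keeps genes with a positive ΔΔG_rank difference and
    ranks them by the most significant p-value across structure sources
    (experimental / predicted), breaking ties by larger |difference|
    then gene name. The clustering table ranks proteins by recurrent
    EDC, descending. The overlap of the two top-``top_n`` lists — genes
    both damage-enriched and spatially clustered — is returned as well.
    """
    best: dict[str, GeneEnrichmentResult] = {}
    for source, results in enrichments.items():
        for r in results:
            prev = best.get(r.protein_id)
            if prev is None or r.p_value < prev.p_value:
                best[r.protein_id] = r
    damage_rows = [
        {
            "protein_id": r.protein_id,
            "ddg_rank_diff": r.ddg_rank_diff,
            "p_value": r.p_value,
            "structure_source": r.structure_source,
            "n_observed": r.n_observed,
            "significant": r.significant,
        }
        for r in best.values()
        if r.ddg_rank_diff > 0
    ]
    damage = pd.DataFrame(
        damage_rows,
        columns=[
            "protein_id", "ddg_rank_diff", "p_value",
            "structure_source", "n_observed", "significant",
        ],
    )
    if len(damage):
        damage["abs_diff"] = damage["ddg_rank_diff"].abs()
        damage = (
            damage.sort_values(
                ["p_value", "abs_diff", "protein_id"],
                ascending=[True, False, True],
            )
            .drop(columns="abs_diff")
            .head(top_n)
            .reset_index(drop=True)
        )

    clustering = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "edc": r.edc,
                "n_disease": r.n_disease,
                "dataset": r.dataset,
            }
            for r in edcs
        ],
        columns=["protein_id", "edc", "n_disease", "dataset"],
    )
    if len(clustering):
        clustering = (
            clustering.sort_values(["edc", "protein_id"], ascending=[False, True])
            .head(top_n)
            .reset_index(drop=True)
        )

    overlap = set(damage["protein_id"]) & set(clustering["protein_id"])
    return damage, clustering, overlap
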