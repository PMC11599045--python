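"""Cross-contrast concordance: Pearson correlation and preranked
gene-set enrichment with a gene-set permutation null.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum:
genes are ordered by a ranking metric r (here the log2 AUC ratio,
descending), and for a gene set S of size N_H inside a universe of N genes
the two cumulative distributions

    P_hit(i)  = sum_{g_j in S, j <= i} |r_j|^p / N_R,   N_R = sum_{g_j in S} |r_j|^p
    P_miss(i) = sum_{g_j not in S, j <= i} 1 / (N - N_H)

are walked down the list; the enrichment score ES is the maximum deviation
from zero of P_hit - P_miss, keeping its sign. The weight exponent defaults
to p = 1. The null distribution is built by gene-set permutation: ES of
random same-size sets drawn without replacement from the universe. The
nominal p-value uses the add-one convention restricted to null scores of
the observed sign; NES divides ES by the mean |null ES| of that sign, and
FDR q-values compare |NES| against the pooled sign-matched null NES.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .auc import AUCContrast
from .io import GeneSetCollection

__all__ = [
    "RankedList",
    "ESProfile",
    "EnrichmentResult",
    "pearson_r",
    "rank_genes",
    "enrichment_score",
    "permutation_test",
    "fdr_across_sets",
    "run_gsea",
]


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Requires equal lengths >= 3 and non-zero variance in both inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance")
    return float(scipy.stats.pearsonr(x, y).statistic)


@dataclass
class RankedList:
    """Genes ordered by ranking metric, descending; ties broken by gene_id."""

    genes: np.ndarray  # object array of gene ids
    scores: np.ndarray  # float metric, aligned with genes

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(contrast: AUCContrast) -> RankedList:
    """Order a contrast's genes by log2 AUC ratio, descending.

    Ties are broken by lexicographic gene_id so the ordering is
    deterministic.
    """
    r = contrast.log2_ratio
    if not np.isfinite(r.to_numpy()).all():
        raise ValueError("ranking metric contains non-finite values")
    df = pd.DataFrame({"gene": r.index.astype(str), "score": r.to_numpy()})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(
        genes=df["gene"].to_numpy(dtype=object), scores=df["score"].to_numpy()
    )


@dataclass
class ESProfile:
    es: float
    running: np.ndarray  # P_hit - P_miss after each rank
    leading_edge: list[str]
    extremum_index: int


def _es_from_hits(hit: np.ndarray, scores: np.ndarray, weight_p: float) -> tuple[float, np.ndarray, int]:
    """Running-sum ES given a boolean hit indicator along the ranking."""
    n = hit.size
    n_hit = int(hit.sum())
    w = np.abs(scores) ** weight_p
    w_hit = np.where(hit, w, 0.0)
    n_r = w_hit.sum()
    if n_r == 0:
        # all member weights are zero (metric exactly 0 with p > 0): fall
        # back to uniform hit weights, the p = 0 limit
        w_hit = hit.astype(float)
        n_r = float(n_hit)
    p_hit = np.cumsum(w_hit) / n_r
    p_miss = np.cumsum(~hit) / (n - n_hit)
    dev = p_hit - p_miss
    imax = int(np.argmax(dev))
    imin = int(np.argmin(dev))
    # sign tie |max| == |min|: choose positive (small tolerance so the
    # tie-break does not depend on summation rounding order)
    if dev[imax] >= -dev[imin] - 1e-12:
        return float(dev[imax]), dev, imax
    return float(dev[imin]), dev, imin


def enrichment_score(
    ranked: RankedList, members, weight_p: float = 1.0
) -> ESProfile:
    """Weighted KS enrichment score of a gene set against a ranking.

    Members outside the ranked universe are dropped with a warning; a set
    that is empty after intersection or equal to the whole universe is an
    error (the miss distribution is undefined).

    Returns the signed ES, the full running profile (which always ends at
    0), and the leading edge: members ranked at or before the extremum for
    positive ES, at or after it for negative ES.
    """
    if weight_p < 0:
        raise ValueError("weight exponent must be >= 0")
    member_set = set(members)
    hit = np.isin(ranked.genes, list(member_set))
    n_hit = int(hit.sum())
    if n_hit < len(member_set):
        import warnings

        dropped = member_set - set(ranked.genes[hit])
        warnings.warn(f"{len(dropped)} set member(s) outside the ranked universe dropped")
    if n_hit == 0:
        raise ValueError("gene set empty after intersecting with the universe")
    if n_hit == len(ranked):
        raise ValueError("gene set equals the universe; P_miss undefined")
    es, dev, iext = _es_from_hits(hit, ranked.scores, weight_p)
    if es >= 0:
        lead_mask = hit & (np.arange(len(ranked)) <= iext)
    else:
        lead_mask = hit & (np.arange(len(ranked)) >= iext)
    return ESProfile(
        es=es,
        running=dev,
        leading_edge=list(ranked.genes[lead_mask]),
        extremum_index=iext,
    )


@dataclass
class EnrichmentResult:
    set_name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float | None
    leading_edge: list[str]
    n_permutations: int
    seed: int
    degenerate: bool = False
    null_es: np.ndarray = field(default=None, repr=False)

    def null_nes(self) -> np.ndarray:
        """Per-set null ES normalized by the sign-matched null means."""
        null = self.null_es
        pos = null[null > 0]
        neg = null[null < 0]
        out = np.zeros_like(null)
        if pos.size:
            out[null > 0] = null[null > 0] / pos.mean()
        if neg.size:
            out[null < 0] = null[null < 0] / np.abs(neg).mean()
        return out[null != 0]


def permutation_test(
    ranked: RankedList,
    members,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    set_name: str = "set",
) -> EnrichmentResult:
    """Gene-set-permutation significance of an enrichment score.

    The null is the ES of ``n_perm`` random same-size gene sets drawn
    without replacement from the universe. With s = sign(observed ES),

        p_nominal = (1 + #{null: sign matches, |null| >= |ES|})
                    / (1 + #{null: sign matches})
        NES       = ES / mean(|null ES with matching sign|)

    Deterministic given ``seed``. If no null score shares the observed
    sign, p = 1 is reported with ``degenerate=True`` and NES is NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    profile = enrichment_score(ranked, members, weight_p)
    hit = np.isin(ranked.genes, list(set(members)))
    k = int(hit.sum())
    n = len(ranked)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(n)
    for i in range(n_perm):
        pick = rng.choice(idx, size=k, replace=False)
        h = np.zeros(n, dtype=bool)
        h[pick] = True
        null[i], _, _ = _es_from_hits(h, ranked.scores, weight_p)

    es = profile.es
    if es > 0:
        same = null[null > 0]
    elif es < 0:
        same = null[null < 0]
    else:
        same = np.empty(0)
    degenerate = same.size == 0
    p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + same.size)
    nes = es / np.abs(same).mean() if not degenerate else float("nan")
    return EnrichmentResult(
        set_name=set_name,
        size=k,
        es=es,
        nes=nes,
        p_nominal=p,
        fdr_q=None,
        leading_edge=profile.leading_edge,
        n_permutations=n_perm,
        seed=seed,
        degenerate=degenerate,
        null_es=null,
    )


def fdr_across_sets(
    results: list[EnrichmentResult], pooled_null_nes: np.ndarray | None = None
) -> list[float]:
    """FDR q-values across a batch of enrichment results.

    For each result, q is the ratio of the fraction of pooled same-sign
    null NES at least as extreme as |NES| to the fraction of observed
    same-sign NES at least as extreme, clipped to [0, 1] and
    monotone-adjusted (suffix minimum over results ordered by descending
    |NES| within each sign) so q never decreases as |NES| decreases.
    The q-values are also written back onto the results.
    """
    if not results:
        raise ValueError("need at least one result")
    if pooled_null_nes is None:
        pooled_null_nes = np.concatenate([r.null_nes() for r in results])
    pooled_null_nes = np.asarray(pooled_null_nes, dtype=float)
    if pooled_null_nes.size == 0:
        raise ValueError("empty pooled null")

    obs = np.array([r.nes for r in results])
    raw = np.empty(len(results))
    for i, r in enumerate(results):
        if not np.isfinite(r.nes):
            raw[i] = 1.0
            continue
        if r.nes >= 0:
            null_same = pooled_null_nes[pooled_null_nes >= 0]
            obs_same = obs[np.isfinite(obs) & (obs >= 0)]
        else:
            null_same = pooled_null_nes[pooled_null_nes < 0]
            obs_same = obs[np.isfinite(obs) & (obs < 0)]
        if null_same.size == 0:
            raw[i] = 1.0
            continue
        num = np.mean(np.abs(null_same) >= abs(r.nes))
        den = np.mean(np.abs(obs_same) >= abs(r.nes))
        raw[i] = min(1.0, num / den) if den > 0 else 1.0

    q = raw.copy()
    for sign in (1, -1):
        grp = [
            i
            for i in range(len(results))
            if np.isfinite(obs[i]) and (obs[i] >= 0 if sign > 0 else obs[i] < 0)
        ]
        grp.sort(key=lambda i: -abs(obs[i]))  # strongest first
        # BH-style suffix min: q of a stronger set never exceeds a weaker one's
        for pos in range(len(grp) - 2, -1, -1):
            q[grp[pos]] = min(q[grp[pos]], q[grp[pos + 1]])
    for r, qi in zip(results, q):
        r.fdr_q = float(qi)
    return [float(v) for v in q]


def run_gsea(
    contrast: AUCContrast,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[EnrichmentResult]:
    """Score every gene set in a collection against one contrast's ranking.

    Each set gets its own seed derived from the base seed and the set's
    position among the sorted set names, so results do not depend on
    collection order; q-values are filled in across the batch.
    """
    ranked = rank_genes(contrast)
    order = {name: i for i, name in enumerate(sorted(collection.names))}
    results = []
    for gs in collection:
        results.append(
            permutation_test(
                ranked,
                gs.members,
                n_perm=n_perm,
                seed=int(np.random.SeedSequence([seed, order[gs.name]]).generate_state(1)[0] % 2**31),
                weight_p=weight_p,
                set_name=gs.name,
            )
        )
    fdr_across_sets(results)
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results for TSV output."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "size": [r.size for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
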