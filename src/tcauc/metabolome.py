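"""Metabolome volcano stage: per-metabolite Welch's t-test with
fold-change annotation.

Each metabolite is compared between two sample groups with a two-sided
Welch (unequal-variance) t-test,

    t  = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    df = (s_a^2/n_a + s_b^2/n_b)^2
         / ((s_a^2/n_a)^2/(n_a-1) + (s_b^2/n_b)^2/(n_b-1))

and annotated with log2 fold change log2((mean_t + c)/(mean_r + c)) for a
pseudocount c (default: half the smallest positive abundance in the
table). The ``significant`` flag uses the raw p-value only (default
threshold P = 0.01) — no multiple-testing correction, matching a volcano
read against a horizontal significance line; a Benjamini-Hochberg column
is emitted alongside for users who want it, but never drives the flags.
``large_change`` marks |log2 FC| strictly above log2 of the fold
threshold (default twofold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .io import MetaboliteTable

__all__ = ["welch_t", "volcano"]


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-sided Welch's t-test for two independent samples.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Both groups need >= 2 observations. If both groups have zero variance
    the test is undefined unless the means are equal, in which case
    ``(0, df, 1)`` is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("degenerate variances: both groups constant with unequal means")
    se2_a = va / na
    se2_b = vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2_a + se2_b)
    df = (se2_a + se2_b) ** 2 / (
        se2_a**2 / (na - 1) + se2_b**2 / (nb - 1)
    )
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def volcano(
    table: MetaboliteTable,
    treatment: str,
    reference: str,
    p_thr: float = 0.01,
    fc_thr: float = 2.0,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-metabolite volcano records for treatment vs reference.

    Returns a DataFrame sorted by p ascending with columns
    ``metabolite_id, log2_fc, t, df, p, q_bh, significant, large_change``.
    ``significant`` is ``p < p_thr``; ``large_change`` is
    ``|log2_fc| > log2(fc_thr)``.
    """
    if fc_thr <= 1:
        raise ValueError("fold-change threshold must be > 1")
    cols_t = table.group_samples(treatment)
    cols_r = table.group_samples(reference)
    if len(cols_t) < 2 or len(cols_r) < 2:
        raise ValueError("each group needs >= 2 samples")
    if pseudocount is None:
        arr = table.values.to_numpy()
        positive = arr[arr > 0]
        pseudocount = 0.5 * positive.min() if positive.size else 1.0
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")

    records = []
    for mid, row in table.values.iterrows():
        a = row[cols_t].to_numpy(dtype=float)
        b = row[cols_r].to_numpy(dtype=float)
        t, df, p = welch_t(a, b)
        lfc = float(np.log2((a.mean() + pseudocount) / (b.mean() + pseudocount)))
        records.append((mid, lfc, t, df, p))
    out = pd.DataFrame(
        records, columns=["metabolite_id", "log2_fc", "t", "df", "p"]
    )
    out["q_bh"] = scipy.stats.false_discovery_control(out["p"], method="bh")
    out["significant"] = out["p"] < p_thr
    out["large_change"] = out["log2_fc"].abs() > np.log2(fc_thr)
    out = out.sort_values(["p", "metabolite_id"], kind="mergesort").reset_index(drop=True)
    return out
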