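"""Count-based differential eccDNA analysis between two groups.

Read counts are pooled within each group and each eccDNA is tested with
a pooled two-proportion z-test (the same binomial sampling null that
MA-plot random-sampling methods such as DEGseq target for grouped
libraries). Significance requires both an absolute fold change of at
least the threshold (default 2, i.e. |log2FC| >= 1) and a
Benjamini-Hochberg q-value below the q threshold (default 0.001).
"Up" means a higher normalized proportion in the first group of the
sample sheet's group order.

Pooling treats replicates as one library per group; biological
overdispersion between replicates is therefore not modeled (a known
limitation of this family of tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SampleSheet


def pool_counts(
    counts: pd.DataFrame, sheet: SampleSheet
) -> tuple[pd.Series, pd.Series, int, int]:
    """Pool per-sample counts within each group.

    Returns (k1, k2, n1, n2): per-eccDNA pooled counts and the pooled
    library totals for the two groups in the sheet's group order.
    """
    if counts.empty:
        raise ValueError("empty counts matrix")
    g1, g2 = sheet.group_order
    s1 = [s for s in sheet.samples_in(g1) if s in counts.columns]
    s2 = [s for s in sheet.samples_in(g2) if s in counts.columns]
    if not s1 or not s2:
        raise ValueError("counts matrix is missing all samples of one group")
    k1 = counts[s1].sum(axis=1)
    k2 = counts[s2].sum(axis=1)
    n1, n2 = int(k1.sum()), int(k2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("a group has zero total reads")
    return k1, k2, n1, n2


def proportion_test(k1, n1, k2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Pooled two-proportion z-test, vectorized over k1/k2.

    z = (k1/n1 - k2/n2) / sqrt(phat (1-phat) (1/n1 + 1/n2)) with
    phat = (k1+k2)/(n1+n2); two-sided p from the standard normal.
    A degenerate pooled proportion (0 or 1) carries no information and
    yields z = 0, p = 1.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if np.any(k1 > n1) or np.any(k2 > n2):
        raise ValueError("counts exceed library totals")
    phat = (k1 + k2) / (n1 + n2)
    var = phat * (1 - phat) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (k1 / n1 - k2 / n2) / np.sqrt(var), 0.0)
    p = np.where(var > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return z, np.minimum(p, 1.0)


def log2_fold_change(k1, n1, k2, n2, pseudocount: float = 0.5) -> np.ndarray:
    """log2 of the normalized group proportions, pseudocount-stabilized.

    The pseudocount applies only here, never to the test statistic.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    return np.log2(((k1 + pseudocount) / n1) / ((k2 + pseudocount) / n2))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_differential(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.001,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Full differential table plus a summary of significant calls.

    eccDNAs with zero total count are excluded before testing. An eccDNA
    is significant iff |log2FC| >= log2(fc_threshold) and q < q_threshold;
    direction is "up" (higher in the first group), "down", or "ns".
    """
    k1, k2, n1, n2 = pool_counts(counts, sheet)
    keep = (k1 + k2) > 0
    k1, k2 = k1[keep], k2[keep]
    z, p = proportion_test(k1.to_numpy(), n1, k2.to_numpy(), n2)
    lfc = log2_fold_change(k1.to_numpy(), n1, k2.to_numpy(), n2, pseudocount)
    q = bh_adjust(p)
    lfc_cut = np.log2(fc_threshold)
    significant = (np.abs(lfc) >= lfc_cut) & (q < q_threshold)
    direction = np.where(significant, np.where(lfc > 0, "up", "down"), "ns")
    table = pd.DataFrame(
        {
            "k1": k1.astype(int),
            "k2": k2.astype(int),
            "n1": n1,
            "n2": n2,
            "log2fc": lfc,
            "z": z,
            "p": p,
            "q": q,
            "significant": significant,
            "direction": direction,
        },
        index=k1.index,
    )
    table.index.name = "eccdna_id"
    g1, g2 = sheet.group_order
    summary = {
        "group1": g1,
        "group2": g2,
        "n_tested": int(len(table)),
        "n_significant": int(significant.sum()),
        "n_up": int((direction == "up").sum()),
        "n_down": int((direction == "down").sum()),
        "fc_threshold": fc_threshold,
        "q_threshold": q_threshold,
    }
    return table, summary
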