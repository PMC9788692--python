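"""Gene-context frequency tables and exact enrichment tests.

The downstream gene of a candidate riboswitch is a proxy for the pathway it
regulates and hence for its ligand.  This module builds side-by-side
frequency tables of the conserved protein domains encoded downstream of two
motifs, and tests 2x2 contingency tables (e.g. motif occurrences in gut vs
non-gut metagenomes against a background) with Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MotifAlignment


def _labels(aln: MotifAlignment, sid: str) -> list[str]:
    raw = aln.meta(sid, "gene_domain")
    if raw is None:
        return []
    return sorted({lab.strip() for lab in raw.split(";") if lab.strip()})


def gene_frequency_table(
    aln_a: MotifAlignment,
    aln_b: MotifAlignment,
    top_k: int = 6,
) -> pd.DataFrame:
    """Most frequent downstream-gene domains of two motifs, side by side.

    Counts RNAs per domain per motif (semicolon-separated multi-labels count
    once per label).  Rows are the union of each motif's ``top_k`` domains,
    sorted by max(pct_a, pct_b) descending.  Percentages are relative to the
    total row count of each motif, including unlabelled RNAs, so columns
    generally sum to less than 100 %.
    """
    counts: dict[str, list[int]] = {}
    totals = (aln_a.n_rows, aln_b.n_rows)
    any_label = False
    for idx, aln in enumerate((aln_a, aln_b)):
        for sid in aln.ids:
            for lab in _labels(aln, sid):
                any_label = True
                counts.setdefault(lab, [0, 0])[idx] += 1
    if not any_label:
        raise ValueError("no gene_domain labels in either alignment")
    top: set[str] = set()
    for idx in (0, 1):
        ranked = sorted(counts, key=lambda d: (-counts[d][idx], d))
        top.update(d for d in ranked[:top_k] if counts[d][idx] > 0)
    rows = []
    for dom in top:
        ca, cb = counts[dom]
        rows.append(
            {
                "domain": dom,
                "count_a": ca,
                "pct_a": 100.0 * ca / totals[0],
                "count_b": cb,
                "pct_b": 100.0 * cb / totals[1],
            }
        )
    df = pd.DataFrame(rows)
    df["_sort"] = df[["pct_a", "pct_b"]].max(axis=1)
    df = df.sort_values(["_sort", "domain"], ascending=[False, True])
    df = df.drop(columns="_sort").reset_index(drop=True)
    df.attrs["n_a"] = totals[0]
    df.attrs["n_b"] = totals[1]
    return df


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 exact-test result: counts, odds ratio, two-sided p-value."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # may be inf; nan when 0/0 (see `undefined`)
    p_two_sided: float
    degenerate: bool = False

    @property
    def undefined(self) -> bool:
        return math.isnan(self.odds_ratio)


def fisher_exact_2x2(table, yates_chisq: bool = False) -> ContingencyResult:
    """Exact two-sided test of association for a 2x2 table.

    The two-sided p-value follows the 'sum of all tables with probability not
    exceeding that of the observed table' convention of the exact
    hypergeometric test.  The odds ratio is the sample estimate a*d / (b*c)
    (inf when only b*c is zero; undefined/NaN when both products vanish).
    With ``yates_chisq=True`` a chi-square test with Yates continuity
    correction replaces the exact p-value.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        odds = float("nan")
    elif bc == 0:
        odds = float("inf")
    else:
        odds = ad / bc
    margins = (a + b, c + d, a + c, b + d)
    if 0 in margins:
        return ContingencyResult(((a, b), (c, d)), odds, 1.0, degenerate=True)
    if yates_chisq:
        _, p, _, _ = stats.chi2_contingency(arr, correction=True)
    else:
        _, p = stats.fisher_exact(arr, alternative="two-sided")
    return ContingencyResult(((a, b), (c, d)), odds, float(min(p, 1.0)))


def environment_enrichment(
    aln: MotifAlignment,
    background: tuple[int, int],
    yates_chisq: bool = False,
) -> ContingencyResult:
    """Gut vs non-gut enrichment of a motif against a metagenome background.

    Counts motif rows labelled gut / non_gut (rows with environment unknown
    or unlabelled are excluded) and tests the 2x2 table
    [[motif_gut, motif_non_gut], [background_gut, background_non_gut]].
    """
    gut = sum(1 for sid in aln.ids if aln.meta(sid, "environment") == "gut")
    non_gut = sum(
        1 for sid in aln.ids if aln.meta(sid, "environment") == "non_gut"
    )
    if gut + non_gut == 0:
        raise ValueError("no rows with a known gut/non_gut environment label")
    bg_gut, bg_non = background
    return fisher_exact_2x2(
        [[gut, non_gut], [int(bg_gut), int(bg_non)]], yates_chisq=yates_chisq
    )
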