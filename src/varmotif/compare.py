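"""Comparison of two homologous motif consensus models.

Homologous riboswitch motifs share most of their conserved columns but can be
told apart by a handful of discriminating features: alignment columns where a
nucleotide identity is near-universal in one motif and (nearly) absent in the
other, or a structural element (typically a hairpin) carried by only one of
the motifs.  This module maps columns between two consensus models by
profile-profile dynamic programming, then scans the mapping for both kinds of
contrast and grades them *strict* (>= 97 % vs <= 3 %) or *high*
(>= 90 % vs <= 10 %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .consensus import ColumnProfile, ConsensusModel
from .io import RESIDUES, MotifAlignment

logger = logging.getLogger(__name__)

GAP_OPEN = -1.0
GAP_EXTEND = -0.2
PAIR_BONUS = 0.5

TAU_HI = 0.97
TAU_LO = 0.03
TAU_HI2 = 0.90
TAU_LO2 = 0.10

MIN_ELEMENT_RUN = 4
MIN_ELEMENT_RESIDUES = 6  # minimal hairpin: 2 bp stem + 2 nt loop
MIN_PRESENT_FOR_IDENTITY = 0.5

_NEG = float("-inf")


@dataclass(frozen=True)
class ColumnMap:
    """Monotone correspondence between the columns of two models.

    ``matches`` is strictly increasing in both coordinates; every column of
    each model appears exactly once across matches and unmatched lists.
    """

    matches: tuple[tuple[int, int], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]

    def __post_init__(self) -> None:
        last = (0, 0)
        for a, b in self.matches:
            if not (a > last[0] and b > last[1]):
                raise ValueError("matches are not strictly increasing")
            last = (a, b)

    def swapped(self) -> "ColumnMap":
        return ColumnMap(
            tuple((b, a) for a, b in self.matches),
            self.unmatched_b,
            self.unmatched_a,
        )


def profile_match_score(
    prof_a: ColumnProfile,
    prof_b: ColumnProfile,
    paired_a: bool,
    paired_b: bool,
    pair_bonus: float = PAIR_BONUS,
) -> float:
    """Dot product of residue frequencies plus a structure-agreement bonus."""
    fa = prof_a.identity_fractions
    fb = prof_b.identity_fractions
    score = sum(fa[x] * fb[x] for x in RESIDUES)
    if paired_a == paired_b:
        score += pair_bonus
    return score


def map_columns(
    model_a: ConsensusModel,
    model_b: ConsensusModel,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    pair_bonus: float = PAIR_BONUS,
) -> ColumnMap:
    """Global profile-profile alignment of two consensus models.

    Gotoh dynamic programming with affine gaps; a gap run of length k costs
    ``gap_open + (k-1) * gap_extend``.  Deterministic: ties are broken toward
    the diagonal (match state preferred, then a-side gap).
    """
    n, m = model_a.n_cols, model_b.n_cols
    if n == 0 or m == 0:
        raise ValueError("both models must be non-empty")
    s = [
        [
            profile_match_score(
                model_a.profile(i), model_b.profile(j),
                model_a.is_paired(i), model_b.is_paired(j),
                pair_bonus,
            )
            for j in range(1, m + 1)
        ]
        for i in range(1, n + 1)
    ]
    # state 0 = M (match), 1 = X (gap in B, column of A unmatched),
    # 2 = Y (gap in A, column of B unmatched)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    ptr: dict[tuple[int, int, int], int] = {}
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
        ptr[(i, 0, 1)] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
        ptr[(0, j, 2)] = 0 if j == 1 else 2

    def argmax(cands: list[tuple[float, int]]) -> tuple[float, int]:
        best = cands[0]
        for c in cands[1:]:
            if c[0] > best[0]:
                best = c
        return best

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best, state = argmax(
                [(M[i - 1][j - 1], 0), (X[i - 1][j - 1], 1), (Y[i - 1][j - 1], 2)]
            )
            M[i][j] = best + s[i - 1][j - 1]
            ptr[(i, j, 0)] = state
            best, state = argmax(
                [
                    (M[i - 1][j] + gap_open, 0),
                    (X[i - 1][j] + gap_extend, 1),
                    (Y[i - 1][j] + gap_open, 2),
                ]
            )
            X[i][j] = best
            ptr[(i, j, 1)] = state
            best, state = argmax(
                [
                    (M[i][j - 1] + gap_open, 0),
                    (X[i][j - 1] + gap_open, 1),
                    (Y[i][j - 1] + gap_extend, 2),
                ]
            )
            Y[i][j] = best
            ptr[(i, j, 2)] = state

    _, state = argmax([(M[n][m], 0), (X[n][m], 1), (Y[n][m], 2)])
    i, j = n, m
    matches: list[tuple[int, int]] = []
    un_a: list[int] = []
    un_b: list[int] = []
    while i > 0 or j > 0:
        prev = ptr[(i, j, state)]
        if state == 0:
            matches.append((i, j))
            i, j = i - 1, j - 1
        elif state == 1:
            un_a.append(i)
            i -= 1
        else:
            un_b.append(j)
            j -= 1
        state = prev
    return ColumnMap(
        tuple(reversed(matches)),
        tuple(reversed(un_a)),
        tuple(reversed(un_b)),
    )


def mapping_score(
    model_a: ConsensusModel,
    model_b: ConsensusModel,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    pair_bonus: float = PAIR_BONUS,
) -> float:
    """Optimal global profile-profile alignment score (same DP objective as
    :func:`map_columns`); used for cross-checking against an independent
    oracle."""
    n, m = model_a.n_cols, model_b.n_cols
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = profile_match_score(
                model_a.profile(i), model_b.profile(j),
                model_a.is_paired(i), model_b.is_paired(j),
                pair_bonus,
            )
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                X[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


@dataclass(frozen=True)
class Thresholds:
    """Contrast-grading thresholds; defaults operationalise 'close to 100 %
    conserved in one motif, never or rarely the same in the other'."""

    tau_hi: float = TAU_HI
    tau_lo: float = TAU_LO
    tau_hi2: float = TAU_HI2
    tau_lo2: float = TAU_LO2


@dataclass(frozen=True)
class DiscriminatingFeature:
    """One contrast between two motifs.

    ``kind`` is ``identity_contrast`` (location = matched column pair) or
    ``element_presence`` (location = ("A"|"B", start, end) span in the motif
    carrying the element).  ``freq_a``/``freq_b`` are the per-motif
    frequencies of the contrasted property.
    """

    kind: str
    location: tuple
    nt: str | None
    freq_a: float
    freq_b: float
    grade: str

    @property
    def contrast(self) -> float:
        return abs(self.freq_a - self.freq_b)

    def mirrored(self) -> "DiscriminatingFeature":
        loc = self.location
        if self.kind == "identity_contrast":
            loc = (loc[1], loc[0])
        else:
            loc = ({"A": "B", "B": "A"}[loc[0]], loc[1], loc[2])
        return DiscriminatingFeature(
            self.kind, loc, self.nt, self.freq_b, self.freq_a, self.grade
        )


def _grade(fa: float, fb: float, th: Thresholds) -> str | None:
    if (fa >= th.tau_hi and fb <= th.tau_lo) or (fb >= th.tau_hi and fa <= th.tau_lo):
        return "strict"
    if (fa >= th.tau_hi2 and fb <= th.tau_lo2) or (
        fb >= th.tau_hi2 and fa <= th.tau_lo2
    ):
        return "high"
    return None


def identity_contrast(
    prof_a: ColumnProfile,
    prof_b: ColumnProfile,
    location: tuple[int, int] = (0, 0),
    thresholds: Thresholds = Thresholds(),
) -> DiscriminatingFeature | None:
    """Best graded nucleotide-identity contrast at a matched column pair.

    Each nucleotide is evaluated on its frequency among non-gap residues in
    the two motifs; the maximal-contrast nucleotide reaching at least the
    *high* grade is returned, else None.
    """
    fa = prof_a.identity_fractions
    fb = prof_b.identity_fractions
    best: DiscriminatingFeature | None = None
    for x in RESIDUES:
        grade = _grade(fa[x], fb[x], thresholds)
        if grade is None:
            continue
        feat = DiscriminatingFeature(
            "identity_contrast", location, x, fa[x], fb[x], grade
        )
        if best is None or feat.contrast > best.contrast:
            best = feat
    return best


def element_presence(
    aln: MotifAlignment,
    span: tuple[int, int],
    min_residues: int = MIN_ELEMENT_RESIDUES,
) -> float:
    """Fraction of rows carrying a structural element within a column span.

    A row carries the element when it has at least ``min_residues`` non-gap
    characters inside the (1-based, inclusive) span; the default of 6 is the
    minimal hairpin (2 bp stem + 2 nt loop).
    """
    lo, hi = span
    if not (1 <= lo <= hi <= aln.n_cols):
        raise IndexError(f"span {span} outside 1..{aln.n_cols}")
    hits = sum(
        1
        for seq in aln.seqs
        if sum(ch != "-" for ch in seq[lo - 1: hi]) >= min_residues
    )
    return hits / aln.n_rows if aln.n_rows else 0.0


def _runs(cols: tuple[int, ...], min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of consecutive column indices with length >= min_len."""
    runs = []
    start = prev = None
    for c in cols:
        if start is None:
            start = prev = c
        elif c == prev + 1:
            prev = c
        else:
            if prev - start + 1 >= min_len:
                runs.append((start, prev))
            start = prev = c
    if start is not None and prev - start + 1 >= min_len:
        runs.append((start, prev))
    return runs


def find_discriminating_features(
    aln_a: MotifAlignment,
    aln_b: MotifAlignment,
    model_a: ConsensusModel,
    model_b: ConsensusModel,
    cmap: ColumnMap,
    thresholds: Thresholds = Thresholds(),
    min_element_run: int = MIN_ELEMENT_RUN,
    min_residues: int = MIN_ELEMENT_RESIDUES,
) -> list[DiscriminatingFeature]:
    """Scan a column mapping for all graded discriminating features.

    Matched column pairs are tested for identity contrasts; columns present
    in fewer than half the rows of either motif are excluded from identity
    testing (absence must not be confounded with identity change).  Maximal
    runs of >= ``min_element_run`` unmatched columns in either motif are
    tested as presence/absence elements against the motif lacking them
    (whose occupancy of a non-existent span is 0 by construction).  Output is
    sorted by contrast, descending, with a deterministic tie-break.
    """
    feats: list[DiscriminatingFeature] = []
    for a, b in cmap.matches:
        pa, pb = model_a.profile(a), model_b.profile(b)
        if (
            pa.present_fraction < MIN_PRESENT_FOR_IDENTITY
            or pb.present_fraction < MIN_PRESENT_FOR_IDENTITY
        ):
            continue
        feat = identity_contrast(pa, pb, (a, b), thresholds)
        if feat is not None:
            feats.append(feat)
    for motif, aln, unmatched in (
        ("A", aln_a, cmap.unmatched_a),
        ("B", aln_b, cmap.unmatched_b),
    ):
        for lo, hi in _runs(unmatched, min_element_run):
            occ = element_presence(aln, (lo, hi), min_residues)
            fa, fb = (occ, 0.0) if motif == "A" else (0.0, occ)
            grade = _grade(fa, fb, thresholds)
            if grade is None:
                continue
            feats.append(
                DiscriminatingFeature(
                    "element_presence", (motif, lo, hi), None, fa, fb, grade
                )
            )
    feats.sort(key=lambda f: (-f.contrast, f.kind, str(f.location)))
    return feats


def subset_by_gene(aln: MotifAlignment, domain: str) -> MotifAlignment:
    """Rows whose downstream-gene domain label matches ``domain``.

    Matching is exact after case folding; semicolon-separated multi-labels
    match if any label matches.  Requires at least one labelled row; an empty
    result is returned with a warning.
    """
    if not any(
        aln.meta(sid, "gene_domain") is not None for sid in aln.ids
    ):
        raise ValueError("no gene_domain metadata in alignment")
    query = domain.casefold()
    keep = [
        sid
        for sid in aln.ids
        if any(
            lab.strip().casefold() == query
            for lab in (aln.meta(sid, "gene_domain") or "").split(";")
        )
    ]
    if not keep:
        logger.warning("subset_by_gene: no rows match domain %r", domain)
    else:
        logger.info("subset_by_gene: %d rows match %r", len(keep), domain)
    return aln.subset(keep, name=f"{aln.name}|{domain}")


def features_table(features: list[DiscriminatingFeature]):
    """Feature list as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "kind": f.kind,
                "location": ":".join(str(x) for x in f.location),
                "nt": f.nt,
                "freq_a": round(f.freq_a, 4),
                "freq_b": round(f.freq_b, 4),
                "contrast": round(f.contrast, 4),
                "grade": f.grade,
            }
            for f in features
        ]
    )
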