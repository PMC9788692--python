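"""Consensus conservation models for structured-RNA motif alignments.

For each alignment column this module computes a nucleotide profile
(frequencies among non-gap residues and a present/absent fraction) and
assigns the conservation tiers conventionally used to annotate riboswitch
consensus diagrams: nucleotide identity at 97/90/75 % and presence at
97/90/75/50 %.

For each base pair in the consensus structure a covariation statistic is
computed: mutual information (in bits) of the joint residue distribution,
corrected with the average product correction (APC) against the MI background
of all column pairs, plus the fraction of rows forming a canonical
(Watson-Crick or G:U) pair.  A pair is called covarying when the corrected MI
exceeds a threshold, at least 90 % of jointly present rows pair canonically,
and at least two distinct canonical pair types each reach 5 % frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GAP, RESIDUES, MotifAlignment, PairTable, parse_ss_cons

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, GAP: 4}
_GAP_CODE = 4

#: canonical pair types, as (code_i, code_j): WC plus G:U wobble
_CANONICAL = {
    (0, 3), (3, 0),  # A:U / U:A
    (2, 1), (1, 2),  # G:C / C:G
    (2, 3), (3, 2),  # G:U / U:G
}

IDENTITY_TIERS = (97, 90, 75)
PRESENT_TIERS = (97, 90, 75, 50)

DEFAULT_TAU_MI = 0.3
MIN_JOINT_ROWS = 5


def encode(aln: MotifAlignment) -> np.ndarray:
    """Integer-encode the alignment: shape (n_rows, n_cols), A,C,G,U,- -> 0..4."""
    lut = np.full(128, -1, dtype=np.int8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    mat = np.frombuffer(
        "".join(aln.seqs).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_rows, aln.n_cols)
    return lut[mat].astype(np.int8)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue/gap counts for one alignment column."""

    counts: dict[str, int]  # keys A, C, G, U, '-'
    n_rows: int

    @property
    def present_fraction(self) -> float:
        return 1.0 - self.counts[GAP] / self.n_rows

    @property
    def n_present(self) -> int:
        return self.n_rows - self.counts[GAP]

    @property
    def identity_fractions(self) -> dict[str, float]:
        """Residue frequencies among non-gap rows (all zero if column empty)."""
        n = self.n_present
        if n == 0:
            return {x: 0.0 for x in RESIDUES}
        return {x: self.counts[x] / n for x in RESIDUES}

    @property
    def gap_fraction(self) -> float:
        return self.counts[GAP] / self.n_rows

    @property
    def majority(self) -> tuple[str | None, float]:
        """(most frequent residue, its identity fraction); (None, 0) if empty."""
        fr = self.identity_fractions
        if self.n_present == 0:
            return None, 0.0
        nt = max(RESIDUES, key=lambda x: fr[x])
        return nt, fr[nt]


def column_profile(aln: MotifAlignment, col: int) -> ColumnProfile:
    """Profile of 1-based column ``col``; raises on out-of-range indices."""
    if not 1 <= col <= aln.n_cols:
        raise IndexError(f"column {col} out of range 1..{aln.n_cols}")
    counts = {x: 0 for x in (*RESIDUES, GAP)}
    for seq in aln.seqs:
        counts[seq[col - 1]] += 1
    return ColumnProfile(counts, aln.n_rows)


def conservation_tiers(
    profile: ColumnProfile,
) -> tuple[tuple[int | None, str | None], int | None]:
    """Identity and presence tiers for a column profile.

    Returns ``((identity_tier, majority_nt), present_tier)`` where
    identity_tier is the largest of 97/90/75 met by the majority-residue
    frequency (None below 75 %) and present_tier is the largest of
    97/90/75/50 met by the non-gap fraction (None below 50 %).
    """
    nt, frac = profile.majority
    identity = next((t for t in IDENTITY_TIERS if frac >= t / 100), None)
    if identity is None:
        nt = None
    pf = profile.present_fraction
    present = next((t for t in PRESENT_TIERS if pf >= t / 100), None)
    return (identity, nt), present


@dataclass(frozen=True)
class CovariationStat:
    """Covariation evidence for one structure pair."""

    mi_bits: float
    mi_apc_bits: float
    canonical_fraction: float
    n_pair_types: int
    covarying: bool
    n_joint: int
    low_support: bool


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI in bits from a 4x4 residue joint-count table (both non-gap)."""
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / outer[mask])))


def mi_matrix(aln: MotifAlignment) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs mutual information over jointly non-gap rows.

    Returns ``(mi, n_joint)``, both (C, C) symmetric arrays; diagonal is 0.
    Computed via a one-hot matrix product, so it is fast even for thousands
    of rows.
    """
    X = encode(aln)
    n, c = X.shape
    onehot = (X[:, :, None] == np.arange(5)).astype(np.float64)  # (n, C, 5)
    flat = onehot.reshape(n, c * 5)
    joint_all = (flat.T @ flat).reshape(c, 5, c, 5)
    mi = np.zeros((c, c))
    n_joint = np.zeros((c, c), dtype=int)
    for i in range(c):
        for j in range(i + 1, c):
            joint = joint_all[i, :4, j, :4]
            nj = int(joint.sum())
            n_joint[i, j] = n_joint[j, i] = nj
            m = _mi_from_joint(joint)
            mi[i, j] = mi[j, i] = m
    return mi, n_joint


def apc_matrix(mi: np.ndarray, n_joint: np.ndarray,
               min_joint: int = MIN_JOINT_ROWS) -> np.ndarray:
    """Average product correction: APC(i,j) = MI_i * MI_j / MI_mean.

    Column means are taken over all pairs with at least ``min_joint`` jointly
    present rows; pairs below that support are excluded from the background.
    """
    c = mi.shape[0]
    work = mi.copy()
    mask = (n_joint >= min_joint)
    np.fill_diagonal(mask, False)
    if not mask.any():
        return np.zeros_like(mi)
    work[~mask] = np.nan
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(work, axis=1)
        overall = np.nanmean(work[np.triu_indices(c, 1)])
    col_mean = np.nan_to_num(col_mean)
    if not np.isfinite(overall) or overall <= 0:
        return np.zeros_like(mi)
    return np.outer(col_mean, col_mean) / overall


def covariation_score(
    aln: MotifAlignment,
    pair: tuple[int, int],
    tau_mi: float = DEFAULT_TAU_MI,
    _background: tuple[np.ndarray, np.ndarray] | None = None,
) -> CovariationStat:
    """Covariation statistic for one (i, j) column pair (1-based).

    ``mi_bits`` is the mutual information of the joint residue distribution
    over rows where both columns are non-gap; ``mi_apc_bits`` subtracts the
    APC background computed over all column pairs.  Pairs with fewer than
    5 jointly present rows carry a low-support flag.
    """
    i, j = pair
    if _background is None:
        mi, n_joint = mi_matrix(aln)
    else:
        mi, n_joint = _background
    apc = apc_matrix(mi, n_joint)
    mi_bits = float(mi[i - 1, j - 1])
    mi_apc = mi_bits - float(apc[i - 1, j - 1])
    X = encode(aln)
    xi, xj = X[:, i - 1], X[:, j - 1]
    both = (xi != _GAP_CODE) & (xj != _GAP_CODE)
    nj = int(both.sum())
    if nj == 0:
        canonical_fraction = 0.0
        n_types = 0
    else:
        combos = xi[both] * 5 + xj[both]
        canon_codes = np.array([a * 5 + b for a, b in _CANONICAL])
        canon_mask = np.isin(combos, canon_codes)
        canonical_fraction = float(canon_mask.mean())
        counts = np.bincount(combos[canon_mask], minlength=25)
        n_types = int(np.sum(counts[canon_codes] / nj >= 0.05))
    low_support = nj < MIN_JOINT_ROWS
    covarying = (
        not low_support
        and mi_apc > tau_mi
        and canonical_fraction >= 0.9
        and n_types >= 2
    )
    return CovariationStat(
        mi_bits=mi_bits,
        mi_apc_bits=mi_apc,
        canonical_fraction=canonical_fraction,
        n_pair_types=n_types,
        covarying=covarying,
        n_joint=nj,
        low_support=low_support,
    )


@dataclass(frozen=True)
class ConsensusModel:
    """Per-column conservation profile plus per-pair covariation statistics."""

    name: str
    n_rows: int
    columns: tuple[ColumnProfile, ...]
    pair_table: PairTable
    identity_tier: tuple[tuple[int | None, str | None], ...]
    present_tier: tuple[int | None, ...]
    covariation: dict[tuple[int, int], CovariationStat]
    tau_mi: float = DEFAULT_TAU_MI

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    def is_paired(self, col: int) -> bool:
        return col in self.pair_table.paired_columns

    def profile(self, col: int) -> ColumnProfile:
        return self.columns[col - 1]

    def majority_consensus(self, min_present: float = 0.5) -> tuple[str, list[int]]:
        """Majority-residue consensus over columns present in >= ``min_present``
        of rows.  Returns the consensus string and the 1-based columns used."""
        chars, cols = [], []
        for c, prof in enumerate(self.columns, start=1):
            if prof.present_fraction >= min_present and prof.n_present > 0:
                nt, _ = prof.majority
                chars.append(nt)
                cols.append(c)
        return "".join(chars), cols

    @property
    def mean_gap_fraction(self) -> float:
        return float(np.mean([p.gap_fraction for p in self.columns]))


def build_consensus(
    aln: MotifAlignment, tau_mi: float = DEFAULT_TAU_MI
) -> ConsensusModel:
    """Build the full consensus model for an alignment.

    Profiles every column, assigns tiers, and scores every SS_cons pair for
    covariation (MI + APC against the all-pairs background).  Deterministic
    given the alignment.  Raises on an empty alignment.
    """
    if aln.n_rows == 0:
        raise ValueError("cannot build a consensus from an empty alignment")
    pt = aln.pair_table()
    profiles = tuple(column_profile(aln, c) for c in range(1, aln.n_cols + 1))
    tiers = [conservation_tiers(p) for p in profiles]
    background = mi_matrix(aln)
    covar = {
        (i, j): covariation_score(aln, (i, j), tau_mi, _background=background)
        for i, j, _layer in pt.pairs
    }
    return ConsensusModel(
        name=aln.name,
        n_rows=aln.n_rows,
        columns=profiles,
        pair_table=pt,
        identity_tier=tuple(t[0] for t in tiers),
        present_tier=tuple(t[1] for t in tiers),
        covariation=covar,
        tau_mi=tau_mi,
    )


def consensus_table(model: ConsensusModel):
    """Per-column consensus summary as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for c in range(1, model.n_cols + 1):
        prof = model.profile(c)
        nt, frac = prof.majority
        (id_tier, id_nt), pres_tier = model.identity_tier[c - 1], model.present_tier[c - 1]
        partner = model.pair_table.partner(c)
        stat = None
        if partner is not None:
            key = (min(c, partner), max(c, partner))
            stat = model.covariation.get(key)
        rows.append(
            {
                "column": c,
                "majority_nt": nt,
                "identity_fraction": round(frac, 4),
                "present_fraction": round(prof.present_fraction, 4),
                "identity_tier": id_tier,
                "identity_tier_nt": id_nt,
                "present_tier": pres_tier,
                "pair_partner": partner,
                "mi_bits": round(stat.mi_bits, 4) if stat else None,
                "mi_apc_bits": round(stat.mi_apc_bits, 4) if stat else None,
                "canonical_fraction": round(stat.canonical_fraction, 4) if stat else None,
                "covarying": stat.covarying if stat else None,
            }
        )
    return pd.DataFrame(rows)
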