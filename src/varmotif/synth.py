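"""Synthetic data with the statistical structure the analyses assume.

The motif-pair generator emits two homologous structured-RNA alignments in
the package's Stockholm dialect.  Both motifs share a common base model —
two hairpins connected by a pseudoknot followed by a U-rich tail, the
architecture of guanidine-IV-like riboswitches — and differ only at planted
positions: a configurable set of identity contrasts (a nucleotide
near-universal in one motif and absent in the other) and one inserted
hairpin element carried by a single motif.  Gene-context labels, phyla and
gut/non-gut environment labels are sampled per motif from configurable
association probabilities.  Assay generators emit probing band tables from a
Hill isotherm and termination band records.

All generators are pure functions of (parameters, seed): reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import BandTable
from .io import GAP, RESIDUES, MotifAlignment

#: canonical base-pair sampling distribution for stems (5' base, 3' base)
CANONICAL_PAIR_DIST = {
    ("G", "C"): 0.35,
    ("C", "G"): 0.25,
    ("A", "U"): 0.15,
    ("U", "A"): 0.10,
    ("G", "U"): 0.10,
    ("U", "G"): 0.05,
}

PHYLA = ("Actinobacteria", "Bacteroidetes", "Firmicutes")


def _conserved(nt: str, level: float) -> dict[str, float]:
    rest = (1.0 - level) / 3
    return {x: (level if x == nt else rest) for x in RESIDUES}


#: a loosely constrained column
VARIABLE = {"A": 0.35, "C": 0.25, "G": 0.25, "U": 0.15}


@dataclass(frozen=True)
class ColumnSpec:
    """Per-column sampling rule: residue distribution + presence probability."""

    dist: dict[str, float]
    present: float = 1.0


@dataclass(frozen=True)
class PlantedContrast:
    """Identity contrast planted at one base-model column.

    Motif A draws ``nt_a`` with probability ``freq_hi`` and ``nt_b`` with
    ``freq_lo`` (remaining mass spread over the other residues); motif B is
    mirrored.
    """

    col: int  # base-model coordinate, 1-based
    nt_a: str
    nt_b: str
    freq_hi: float = 1.0
    freq_lo: float = 0.0

    def dist(self, motif: str) -> dict[str, float]:
        hi, lo = (self.nt_a, self.nt_b) if motif == "A" else (self.nt_b, self.nt_a)
        others = [x for x in RESIDUES if x not in (hi, lo)]
        rest = (1.0 - self.freq_hi - self.freq_lo) / len(others)
        d = {x: rest for x in others}
        d[hi] = self.freq_hi
        d[lo] = self.freq_lo
        return d


@dataclass(frozen=True)
class ElementSpec:
    """Hairpin element carried by one motif only.

    Inserted after base column ``insert_after``; ``ss`` is its local
    structure, ``stem_pairs`` are 1-based positions within the element
    sampled jointly as canonical pairs, remaining positions draw from
    ``loop_dist``.  Each carrier row realises the element with probability
    ``occupancy`` (non-realising rows are gapped across the span).
    """

    insert_after: int = 32
    ss: str = "<<<..>>>"
    stem_pairs: tuple[tuple[int, int], ...] = ((1, 8), (2, 7), (3, 6))
    loop_dist: dict[str, float] = field(
        default_factory=lambda: _conserved("G", 0.7)
    )
    carrier: str = "A"
    occupancy: float = 1.0

    @property
    def length(self) -> int:
        return len(self.ss)


@dataclass(frozen=True)
class GeneratorProfile:
    """Full specification of the synthetic motif pair."""

    base_columns: tuple[ColumnSpec, ...]
    ss_base: str
    stem_pairs: tuple[tuple[int, int], ...]
    planted_contrasts: tuple[PlantedContrast, ...]
    element: ElementSpec | None
    gene_assoc: dict[str, dict[str | None, float]]
    env_gut: dict[str, float]
    env_unknown: float = 0.05
    phyla: dict[str, float] = field(
        default_factory=lambda: {
            "Actinobacteria": 0.2,
            "Bacteroidetes": 0.3,
            "Firmicutes": 0.5,
        }
    )
    star_tree_rate: float = 0.0  # per-position mutation rate from an ancestor

    def __post_init__(self) -> None:
        if len(self.ss_base) != len(self.base_columns):
            raise ValueError("ss_base length != number of base columns")
        ncol = len(self.base_columns)
        cols = [pc.col for pc in self.planted_contrasts]
        if len(set(cols)) != len(cols):
            raise ValueError("planted contrast columns must be distinct")
        for c in cols:
            if not 1 <= c <= ncol:
                raise ValueError(f"planted column {c} outside base model 1..{ncol}")
        if self.element is not None and not (
            0 <= self.element.insert_after <= ncol
        ):
            raise ValueError("element insertion point outside base model")


def default_profile() -> GeneratorProfile:
    """The default study conditions: a 51-column two-hairpin + pseudoknot
    base model, three strict identity contrasts, one 8-column hairpin element
    carried by motif A, transaminase-dominated gene context for motif A
    (55 %), exporter-dominated context for motif B, and five-fold gut
    enrichment of motif A over an even background."""
    C = _conserved
    specs: list[ColumnSpec] = [ColumnSpec(VARIABLE)] * 51
    ss = (
        "<<<<<"      # 1-5   hairpin 1, 5' strand
        ".."         # 6-7   loop
        "AAAA"       # 8-11  pseudoknot, left
        ".."         # 12-13 loop
        ">>>>>"      # 14-18 hairpin 1, 3' strand
        "......"     # 19-24 linker
        "<<<<<<"     # 25-30 terminator hairpin, 5' strand
        "...."       # 31-34 terminator loop (binding-pocket analog)
        ">>>>>>"     # 35-40 terminator hairpin, 3' strand
        "aaaa"       # 41-44 pseudoknot, right
        "......."    # 45-51 U-rich tail
    )
    stem_pairs = tuple(
        [(i, 19 - i) for i in range(1, 6)]          # hairpin 1
        + [(i + 24, 65 - i - 24) for i in range(1, 7)]  # terminator: (25,40)..(30,35)
        + [(7 + k, 45 - k) for k in range(1, 5)]    # pseudoknot: (8,44)..(11,41)
    )
    overrides = {
        7: ColumnSpec(VARIABLE, present=0.9),
        24: ColumnSpec(VARIABLE, present=0.6),
        31: ColumnSpec(C("A", 0.99)),
        32: ColumnSpec(C("G", 0.85)),
        33: ColumnSpec(C("C", 0.99)),
        34: ColumnSpec(C("U", 0.99)),
    }
    for c in range(45, 52):
        overrides[c] = ColumnSpec(C("U", 0.98), present=0.97)
    for c, spec in overrides.items():
        specs[c - 1] = spec
    contrasts = (
        PlantedContrast(6, "C", "A"),
        PlantedContrast(20, "U", "G"),  # G always in motif B, never in A
        PlantedContrast(22, "G", "U"),
    )
    gene_assoc = {
        "A": {
            "PRK07324": 0.55,  # transaminase, motif A hallmark
            "GNAT": 0.16,
            "MATE": 0.12,
            "COG2423": 0.07,
            None: 0.10,
        },
        "B": {
            "COG2076": 0.41,  # sugE-like exporter, motif B hallmark
            "GNAT": 0.20,
            "MATE": 0.13,
            "CarA": 0.08,
            None: 0.18,
        },
    }
    return GeneratorProfile(
        base_columns=tuple(specs),
        ss_base=ss,
        stem_pairs=stem_pairs,
        planted_contrasts=contrasts,
        element=ElementSpec(),
        gene_assoc=gene_assoc,
        env_gut={"A": 5.0 / 6.0, "B": 0.5},
    )


def _sample_categorical(rng, n, dist: dict) -> list:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return [keys[i] for i in idx]


def _motif_layout(profile: GeneratorProfile, motif: str):
    """(ss_cons, base->motif column map, element span) for one motif."""
    ncol = len(profile.base_columns)
    elem = profile.element
    if elem is None or elem.carrier != motif:
        mapping = {c: c for c in range(1, ncol + 1)}
        return profile.ss_base, mapping, None
    k = elem.insert_after
    ss = profile.ss_base[:k] + elem.ss + profile.ss_base[k:]
    mapping = {c: (c if c <= k else c + elem.length) for c in range(1, ncol + 1)}
    span = (k + 1, k + elem.length)
    return ss, mapping, span


def _sample_motif(
    profile: GeneratorProfile, motif: str, n: int, rng: np.random.Generator
) -> MotifAlignment:
    ss, mapping, span = _motif_layout(profile, motif)
    ncols = len(ss)
    mat = np.full((n, ncols), GAP, dtype="<U1")
    planted = {pc.col: pc for pc in profile.planted_contrasts}
    stem_cols = {c for pair in profile.stem_pairs for c in pair}
    # unpaired / planted base columns
    for base_col, spec in enumerate(profile.base_columns, start=1):
        if base_col in stem_cols:
            continue
        col = mapping[base_col] - 1
        dist = planted[base_col].dist(motif) if base_col in planted else spec.dist
        residues = _sample_categorical(rng, n, dist)
        mat[:, col] = residues
        if spec.present < 1.0:
            gaps = rng.random(n) >= spec.present
            mat[gaps, col] = GAP
    # stems: joint canonical sampling preserves complementarity per row
    for i, j in profile.stem_pairs:
        pairs = _sample_categorical(rng, n, CANONICAL_PAIR_DIST)
        mat[:, mapping[i] - 1] = [p[0] for p in pairs]
        mat[:, mapping[j] - 1] = [p[1] for p in pairs]
    # optional star-tree correlation: rows mutate away from a shared ancestor
    if profile.star_tree_rate > 0:
        anc = mat[0].copy()
        rate = profile.star_tree_rate
        for r in range(n):
            keep = rng.random(ncols) >= rate
            mat[r, keep] = anc[keep]
    # planted element (carrier motif only)
    elem = profile.element
    if span is not None and elem is not None:
        lo, _hi = span
        have = rng.random(n) < elem.occupancy
        elem_stem = {c for pair in elem.stem_pairs for c in pair}
        for rel in range(1, elem.length + 1):
            if rel in elem_stem:
                continue
            mat[:, lo - 1 + rel - 1] = _sample_categorical(rng, n, elem.loop_dist)
        for i, j in elem.stem_pairs:
            pairs = _sample_categorical(rng, n, CANONICAL_PAIR_DIST)
            mat[:, lo - 1 + i - 1] = [p[0] for p in pairs]
            mat[:, lo - 1 + j - 1] = [p[1] for p in pairs]
        mat[~have, lo - 1: lo - 1 + elem.length] = GAP

    ids = [f"{motif}_{k:05d}" for k in range(1, n + 1)]
    genes = _sample_categorical(rng, n, profile.gene_assoc[motif])
    phyla = _sample_categorical(rng, n, profile.phyla)
    unknown = rng.random(n) < profile.env_unknown
    gut = rng.random(n) < profile.env_gut[motif]
    metadata = {}
    for k, sid in enumerate(ids):
        meta = {"phylum": phyla[k]}
        if genes[k] is not None:
            meta["gene_domain"] = genes[k]
        meta["environment"] = (
            "unknown" if unknown[k] else ("gut" if gut[k] else "non_gut")
        )
        metadata[sid] = meta
    seqs = ["".join(row) for row in mat]
    return MotifAlignment(f"motif_{motif}", ids, seqs, ss, metadata)


def generate_motif_pair(
    profile: GeneratorProfile, n_a: int, n_b: int, seed: int
) -> tuple[MotifAlignment, MotifAlignment, dict]:
    """Sample the two homologous motif alignments plus a truth record.

    Rows are sampled independently; within a row, residues are drawn per
    column from the motif-specific distributions, with stems (including the
    pseudoknot) drawn jointly from a canonical pair distribution and the
    planted element emitted only for its carrier motif.  Fully reproducible
    from ``seed``.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be >= 1")
    rng = np.random.default_rng(seed)
    aln_a = _sample_motif(profile, "A", n_a, rng)
    aln_b = _sample_motif(profile, "B", n_b, rng)
    _, map_a, span_a = _motif_layout(profile, "A")
    _, map_b, span_b = _motif_layout(profile, "B")
    truth = {
        "seed": seed,
        "n_a": n_a,
        "n_b": n_b,
        "contrasts": [
            {
                "col_base": pc.col,
                "col_a": map_a[pc.col],
                "col_b": map_b[pc.col],
                "nt_a": pc.nt_a,
                "nt_b": pc.nt_b,
                "freq_hi": pc.freq_hi,
                "freq_lo": pc.freq_lo,
            }
            for pc in profile.planted_contrasts
        ],
        "element": (
            None
            if profile.element is None
            else {
                "carrier": profile.element.carrier,
                "span": span_a if profile.element.carrier == "A" else span_b,
                "length": profile.element.length,
                "occupancy": profile.element.occupancy,
            }
        ),
        "gene_assoc": {
            m: {(k if k is not None else "<none>"): v for k, v in d.items()}
            for m, d in profile.gene_assoc.items()
        },
        "env_gut": dict(profile.env_gut),
    }
    return aln_a, aln_b, truth


def add_duplicate_rows(
    aln: MotifAlignment, n_dups: int, seed: int
) -> MotifAlignment:
    """Append ``n_dups`` duplicated rows (fresh ids, same gapped sequences);
    used to exercise deduplication."""
    rng = np.random.default_rng(seed)
    picks = rng.choice(aln.n_rows, size=n_dups, replace=False)
    ids = list(aln.ids)
    seqs = list(aln.seqs)
    meta = {sid: dict(m) for sid, m in aln.metadata.items()}
    for k, idx in enumerate(picks, start=1):
        sid = f"dup_{k:04d}"
        ids.append(sid)
        seqs.append(aln.seqs[int(idx)])
        src = aln.metadata.get(aln.ids[int(idx)])
        if src:
            meta[sid] = dict(src)
    return MotifAlignment(aln.name, ids, seqs, aln.ss_cons, meta)


def occupancy(conc, kd: float, hill_n: float = 1.0):
    """Hill-isotherm fractional occupancy; kd = inf means no binding."""
    c = np.asarray(conc, dtype=float)
    if np.isinf(kd):
        return np.zeros_like(c)
    return c ** hill_n / (kd ** hill_n + c ** hill_n)


def generate_probing_table(
    kd: float,
    hill_n: float,
    f_max: float,
    concs,
    noise_sd: float,
    seed: int,
    baseline: float = 1000.0,
) -> BandTable:
    """In-line probing band table from a Hill isotherm.

    The modulated band decreases with occupancy,
    ``baseline * (1 - f_max * occupancy(c))``, the constant band stays at
    ``baseline``; both carry independent multiplicative lognormal noise with
    log-sd ``noise_sd``.  A no-ligand lane is included first.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    c = np.asarray(concs, dtype=float)
    occ = np.concatenate([[0.0], occupancy(c, kd, hill_n)])
    n = len(occ)
    mod_noise = np.exp(rng.normal(0.0, noise_sd, size=n))
    const_noise = np.exp(rng.normal(0.0, noise_sd, size=n))
    modulated = baseline * (1.0 - f_max * occ) * mod_noise
    constant = baseline * const_noise
    lane_ids = ["no_ligand"] + [f"lane_{k:02d}" for k in range(1, n)]
    conc_col: list[float | None] = [None] + [float(x) for x in c]
    return BandTable(lane_ids, conc_col, list(modulated), list(constant))


def generate_termination_data(
    readthrough: float,
    a_counts: tuple[int, int] = (30, 60),
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1000.0,
) -> dict:
    """Terminated / full-length band record for one transcription reaction.

    ``readthrough`` is the expected full-length product fraction; band
    intensities are distorted by the adenosine counts (body labelling) and
    multiplicative lognormal noise, so running the record through
    terminated-fraction quantification with A-count correction recovers
    ``1 - readthrough``.
    """
    if not 0.0 <= readthrough <= 1.0:
        raise ValueError("readthrough must be in [0, 1]")
    a_term, a_full = a_counts
    rng = np.random.default_rng(seed)
    noise = np.exp(rng.normal(0.0, noise_sd, size=2))
    term = scale * (1.0 - readthrough) * a_term * noise[0]
    full = scale * readthrough * a_full * noise[1]
    return {
        "term": float(term),
        "full": float(full),
        "a_term": int(a_term),
        "a_full": int(a_full),
    }
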