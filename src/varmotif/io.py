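"""Stockholm and FASTA input/output for structured-RNA motif alignments.

The central container is :class:`MotifAlignment`: a gapped RNA alignment with a
consensus secondary structure line (``#=GC SS_cons``, pseudoknot layers
included) and per-sequence metadata carried as ``#=GS`` tags.  Because no
standard Stockholm tags exist for downstream-gene, phylum or environment
labels, this package defines a small dialect:

    #=GS <seq_id> GENE   <conserved-domain label>
    #=GS <seq_id> PHYLUM <phylum name>
    #=GS <seq_id> ENV    <gut|non_gut|unknown>

Unknown ``#=GS`` tags are preserved verbatim through read/write round trips.
Sequences are normalised to uppercase RNA (T -> U); IUPAC degeneracy codes
other than A/C/G/U are treated as gaps for profiling purposes and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RESIDUES = ("A", "C", "G", "U")
GAP = "-"

#: mapping from dialect #=GS tags to metadata keys
_GS_TAGS = {"GENE": "gene_domain", "PHYLUM": "phylum", "ENV": "environment"}
_GS_KEYS = {v: k for k, v in _GS_TAGS.items()}
ENV_VALUES = ("gut", "non_gut", "unknown")

_OPENERS = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}
_UNPAIRED = set(".,_-:~")


class StockholmFormatError(ValueError):
    """Raised for malformed Stockholm input or inconsistent alignments."""


def _normalize_seq(seq: str, seq_id: str) -> str:
    """Uppercase, T->U, '.'/'~' -> '-', degenerate IUPAC codes -> gap."""
    out = []
    degenerate = 0
    for ch in seq.upper().replace("T", "U"):
        if ch in RESIDUES:
            out.append(ch)
        elif ch in ".-~_":
            out.append(GAP)
        elif ch in "RYSWKMBDHVNX":
            degenerate += 1
            out.append(GAP)
        else:
            raise StockholmFormatError(
                f"sequence {seq_id!r}: unexpected character {ch!r}"
            )
    if degenerate:
        logger.warning(
            "sequence %s: %d degenerate IUPAC residues treated as gaps",
            seq_id, degenerate,
        )
    return "".join(out)


@dataclass(frozen=True)
class PairTable:
    """Base-pair table extracted from an SS_cons line.

    ``pairs`` holds ``(i, j, layer)`` with 1-based column indices, ``i < j``
    and ``layer`` either ``"nested"`` (bracket characters) or ``"pseudoknot"``
    (letter layers Aa, Bb, ...).  Each column participates in at most one pair.
    """

    pairs: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j, layer in self.pairs:
            if not (1 <= i < j):
                raise ValueError(f"invalid pair ({i},{j})")
            if layer not in ("nested", "pseudoknot"):
                raise ValueError(f"unknown layer {layer!r}")
            if i in seen or j in seen:
                raise ValueError(f"column in more than one pair: ({i},{j})")
            seen.update((i, j))
        nested = sorted((i, j) for i, j, lay in self.pairs if lay == "nested")
        for a, b in nested:
            for c, d in nested:
                if a < c < b < d:
                    raise ValueError(
                        f"nested-layer pairs cross: ({a},{b}) vs ({c},{d})"
                    )

    @property
    def paired_columns(self) -> frozenset[int]:
        return frozenset(c for i, j, _ in self.pairs for c in (i, j))

    def partner(self, col: int) -> int | None:
        for i, j, _ in self.pairs:
            if col == i:
                return j
            if col == j:
                return i
        return None

    def as_set(self) -> set[tuple[int, int, str]]:
        return set(self.pairs)


def parse_ss_cons(ss: str) -> PairTable:
    """Parse a consensus-structure line into a :class:`PairTable`.

    Bracket characters (``<> () [] {}``) form the nested layer; matched
    uppercase/lowercase letters (``A``...``a``) form pseudoknot layers.
    Raises :class:`StockholmFormatError` on unbalanced layers, reporting the
    offending symbol and column.
    """
    stacks: dict[str, list[int]] = {}
    pairs: list[tuple[int, int, str]] = []
    for col, ch in enumerate(ss, start=1):
        if ch in _UNPAIRED:
            continue
        if ch in _OPENERS:
            stacks.setdefault(ch, []).append(col)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            stack = stacks.get(opener, [])
            if not stack:
                raise StockholmFormatError(
                    f"unbalanced {ch!r} at column {col}: no open {opener!r}"
                )
            pairs.append((stack.pop(), col, "nested"))
        elif ch.isalpha() and ch.isupper():
            stacks.setdefault(ch, []).append(col)
        elif ch.isalpha() and ch.islower():
            upper = ch.upper()
            stack = stacks.get(upper, [])
            if not stack:
                raise StockholmFormatError(
                    f"unbalanced pseudoknot layer {upper!r} at column {col}"
                )
            pairs.append((stack.pop(), col, "pseudoknot"))
        else:
            raise StockholmFormatError(
                f"unexpected SS_cons character {ch!r} at column {col}"
            )
    for sym, stack in stacks.items():
        if stack:
            raise StockholmFormatError(
                f"unbalanced {sym!r}: unclosed at column {stack[-1]}"
            )
    return PairTable(tuple(sorted(pairs)))


@dataclass
class MotifAlignment:
    """A gapped RNA motif alignment with consensus structure and metadata.

    rows are ``(seq_id, gapped_seq)`` over the alphabet ``{A,C,G,U,-}``;
    ``ss_cons`` has the same length as every gapped sequence; ``metadata`` maps
    seq_id to a dict that may hold ``gene_domain``, ``phylum``,
    ``environment`` and any further Stockholm ``#=GS`` tags verbatim.
    """

    name: str
    ids: list[str]
    seqs: list[str]
    ss_cons: str
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise StockholmFormatError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise StockholmFormatError(f"duplicate seq_ids: {dup}")
        ncol = len(self.ss_cons)
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != ncol:
                raise StockholmFormatError(
                    f"sequence {sid!r} has length {len(seq)}, "
                    f"expected {ncol} (SS_cons length)"
                )
        parse_ss_cons(self.ss_cons)  # validates bracket balance
        for sid, meta in self.metadata.items():
            env = meta.get("environment")
            if env is not None and env not in ENV_VALUES:
                raise StockholmFormatError(
                    f"sequence {sid!r}: invalid environment {env!r}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.ss_cons)

    def row(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def meta(self, seq_id: str, key: str) -> str | None:
        return self.metadata.get(seq_id, {}).get(key)

    def subset(self, keep_ids: list[str], name: str | None = None) -> "MotifAlignment":
        """New alignment restricted to ``keep_ids`` (order preserved)."""
        keep = set(keep_ids)
        ids = [i for i in self.ids if i in keep]
        seqs = [s for i, s in zip(self.ids, self.seqs) if i in keep]
        meta = {i: dict(self.metadata[i]) for i in ids if i in self.metadata}
        return MotifAlignment(name or self.name, ids, seqs, self.ss_cons, meta)

    def pair_table(self) -> PairTable:
        return parse_ss_cons(self.ss_cons)


def read_stockholm(path) -> MotifAlignment:
    """Read a single-alignment Stockholm 1.0 file into a MotifAlignment.

    All ``#=GS`` tags are captured: the dialect tags GENE/PHYLUM/ENV land on
    the metadata keys ``gene_domain``/``phylum``/``environment``; anything
    else is preserved under its raw tag name.
    """
    seqs: dict[str, list[str]] = {}
    order: list[str] = []
    ss_parts: list[str] = []
    metadata: dict[str, dict[str, str]] = {}
    name = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# STOCKHOLM"):
            raise StockholmFormatError(f"{path}: missing '# STOCKHOLM 1.0' header")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("//"):
                continue
            if line.startswith("#=GF"):
                parts = line.split(None, 2)
                if len(parts) == 3 and parts[1] == "ID":
                    name = parts[2]
                continue
            if line.startswith("#=GS"):
                parts = line.split(None, 3)
                if len(parts) < 4:
                    raise StockholmFormatError(f"malformed #=GS line: {line!r}")
                _, sid, tag, value = parts
                key = _GS_TAGS.get(tag, tag)
                metadata.setdefault(sid, {})[key] = value
                continue
            if line.startswith("#=GC"):
                parts = line.split()
                if len(parts) == 3 and parts[1] == "SS_cons":
                    ss_parts.append(parts[2])
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise StockholmFormatError(f"malformed sequence line: {line!r}")
            sid, chunk = parts
            if sid not in seqs:
                seqs[sid] = []
                order.append(sid)
            seqs[sid].append(chunk)
    if not ss_parts:
        raise StockholmFormatError(f"{path}: no '#=GC SS_cons' line found")
    ss_cons = "".join(ss_parts)
    ids, rows = [], []
    for sid in order:
        seq = _normalize_seq("".join(seqs[sid]), sid)
        if len(seq) != len(ss_cons):
            raise StockholmFormatError(
                f"sequence {sid!r} has length {len(seq)}, "
                f"expected {len(ss_cons)} (SS_cons length)"
            )
        ids.append(sid)
        rows.append(seq)
    metadata = {sid: m for sid, m in metadata.items() if sid in seqs}
    return MotifAlignment(name or "alignment", ids, rows, ss_cons, metadata)


def write_stockholm(aln: MotifAlignment, path) -> None:
    """Write a MotifAlignment as single-block Stockholm 1.0."""
    width = max([len(i) for i in aln.ids] + [len("#=GC SS_cons")])
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF ID {aln.name}\n")
        for sid in aln.ids:
            meta = aln.metadata.get(sid, {})
            for key, value in meta.items():
                tag = _GS_KEYS.get(key, key)
                fh.write(f"#=GS {sid} {tag} {value}\n")
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f"{sid:<{width}} {seq}\n")
        fh.write(f"{'#=GC SS_cons':<{width}} {aln.ss_cons}\n")
        fh.write("//\n")


def deduplicate(aln: MotifAlignment) -> tuple[MotifAlignment, int]:
    """Drop rows whose ungapped sequence duplicates an earlier row.

    Keeps the first occurrence of each distinct ungapped sequence string; the
    column set is unchanged.  Returns the reduced alignment and the number of
    rows removed.
    """
    seen: set[str] = set()
    keep: list[str] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        key = seq.replace(GAP, "")
        if key in seen:
            continue
        seen.add(key)
        keep.append(sid)
    removed = aln.n_rows - len(keep)
    if removed:
        logger.info("deduplicate: removed %d duplicate rows", removed)
    return aln.subset(keep), removed


def remove_overlap(
    aln: MotifAlignment, other_ids: set[str]
) -> tuple[MotifAlignment, int]:
    """Remove rows whose seq_id appears in ``other_ids`` (e.g. sequences
    already claimed by a homologous motif's alignment).  Returns the reduced
    alignment and the removal count."""
    keep = [sid for sid in aln.ids if sid not in other_ids]
    removed = aln.n_rows - len(keep)
    if removed:
        logger.info("remove_overlap: removed %d overlapping rows", removed)
    return aln.subset(keep), removed


def write_fasta(aln: MotifAlignment, path) -> None:
    """Export ungapped sequences as FASTA."""
    records = [
        SeqRecord(Seq(aln.ungapped(sid)), id=sid, description="")
        for sid in aln.ids
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA sequences, normalised to ungapped uppercase RNA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_seq(str(rec.seq), rec.id).replace(GAP, "")
        out.append((rec.id, seq))
    return out
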