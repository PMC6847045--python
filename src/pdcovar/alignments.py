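"""Concatenated protein-DNA alignments for meganuclease covariation analysis.

A family of LAGLIDADG homing endonucleases is represented as a gapped protein
multiple sequence alignment plus one DNA target site per member.  Target sites
are anchored on the two strand-specific cut positions that flank the central
4 bases (where cleavage leaves 4-nt overhangs), trimmed to a fixed flank on
each side, and appended to the end of each member's protein row.  Downstream
covariation statistics treat protein and nucleotide columns uniformly.

Nucleotide columns carry signed position labels (no position 0).  By default
the first central-4 base is labeled +2, the I-OnuI convention in which the
wild-type central four read CAAC at +2..+5; the start label is a parameter so
other family conventions (including a symmetric scheme centered on the cut
sites) can be used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    PairingError,
    TrimmingError,
)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_SYMBOLS = AMINO_ACIDS | {"-", "X"}
NUCLEOTIDES = ("A", "C", "G", "T")
GAP = "-"

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"


@dataclass(frozen=True, order=True)
class ColumnLabel:
    """Label of one alignment column.

    ``kind`` is ``"protein"`` or ``"nucleotide"``.  For protein columns
    ``index`` is the residue number in the family's reference-structure
    numbering; for nucleotide columns it is the signed target-site position
    (negative upstream, positive downstream, no zero).
    """

    kind: str
    index: int

    def __post_init__(self) -> None:
        if self.kind not in (PROTEIN, NUCLEOTIDE):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == NUCLEOTIDE and self.index == 0:
            raise ValueError("nucleotide positions are signed and skip 0")

    def __str__(self) -> str:
        if self.kind == NUCLEOTIDE:
            return f"{self.index:+d}"
        return str(self.index)


def parse_label(text: str) -> ColumnLabel:
    """Parse ``"227"`` as protein residue 227 and ``"+3"``/``"-9"`` as DNA."""
    text = text.strip()
    if text.startswith(("+", "-")):
        return ColumnLabel(NUCLEOTIDE, int(text))
    return ColumnLabel(PROTEIN, int(text))


def _next_signed(pos: int) -> int:
    nxt = pos + 1
    return nxt if nxt != 0 else 1


def _prev_signed(pos: int) -> int:
    prv = pos - 1
    return prv if prv != 0 else -1


def signed_positions(start: int, n: int) -> list[int]:
    """``n`` consecutive signed positions beginning at ``start``, skipping 0."""
    if start == 0:
        raise ValueError("signed positions skip 0")
    out = [start]
    while len(out) < n:
        out.append(_next_signed(out[-1]))
    return out


@dataclass(frozen=True)
class TargetSite:
    """One member's DNA target site with mapped cleavage positions.

    ``sequence`` is the top strand, 5'->3'.  ``top_cut`` is the 0-based offset
    of the first central-4 base: the top-strand scissile phosphate lies 5' of
    that base.  ``bottom_cut`` is the offset of the base just 3' of the
    central four (in top-strand coordinates); the bottom-strand scissile
    phosphate sits opposite it.  The central 4 bases are therefore
    ``sequence[top_cut:bottom_cut]`` and ``bottom_cut - top_cut == 4``.
    """

    member_id: str
    sequence: str
    top_cut: int
    bottom_cut: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set(NUCLEOTIDES)
        if bad:
            raise AlphabetError(
                f"site {self.member_id!r}: non-ACGT symbols {sorted(bad)!r} "
                "(ambiguity codes are rejected)"
            )
        if self.bottom_cut - self.top_cut != 4:
            raise ValueError(
                f"site {self.member_id!r}: cut positions must flank exactly "
                f"4 central bases (got span {self.bottom_cut - self.top_cut})"
            )
        if self.top_cut < 0 or self.bottom_cut > len(seq):
            raise ValueError(f"site {self.member_id!r}: central 4 outside sequence")

    @property
    def central4(self) -> str:
        return self.sequence[self.top_cut : self.bottom_cut]


@dataclass
class ConcatenatedAlignment:
    """Protein rows with each member's trimmed DNA site appended.

    ``matrix`` is an (n_members, n_columns) array of single characters.
    Protein columns always precede nucleotide columns, nucleotide columns
    contain no gaps, and column labels are unique.
    """

    member_ids: list[str]
    columns: list[ColumnLabel]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        n, m = self.matrix.shape
        if n != len(self.member_ids) or m != len(self.columns):
            raise AlignmentShapeError("matrix shape does not match labels")
        if len(set(map(str, self.columns))) != m:
            raise ValueError("column labels must be unique")
        kinds = [c.kind for c in self.columns]
        first_nt = kinds.index(NUCLEOTIDE) if NUCLEOTIDE in kinds else m
        if PROTEIN in kinds[first_nt:]:
            raise ValueError("protein columns must precede nucleotide columns")
        nt_block = self.matrix[:, first_nt:]
        if nt_block.size and (nt_block == GAP).any():
            raise AlphabetError("nucleotide columns may not contain gaps")

    @property
    def n_members(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def protein_column_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.columns) if c.kind == PROTEIN], dtype=int)

    @property
    def nucleotide_column_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.columns) if c.kind == NUCLEOTIDE], dtype=int
        )

    def column(self, label: ColumnLabel | str) -> np.ndarray:
        """Symbols of the column with the given label."""
        if isinstance(label, str):
            label = parse_label(label)
        for i, c in enumerate(self.columns):
            if c == label:
                return self.matrix[:, i]
        raise KeyError(f"no column labeled {label}")

    def column_index(self, label: ColumnLabel | str) -> int:
        if isinstance(label, str):
            label = parse_label(label)
        for i, c in enumerate(self.columns):
            if c == label:
                return i
        raise KeyError(f"no column labeled {label}")

    def split(self) -> tuple[dict[str, str], dict[str, str]]:
        """Inverse of :func:`concatenate`: (protein rows, site rows) by member."""
        p_idx = self.protein_column_indices
        n_idx = self.nucleotide_column_indices
        prot = {
            mid: "".join(self.matrix[r, p_idx]) for r, mid in enumerate(self.member_ids)
        }
        sites = {
            mid: "".join(self.matrix[r, n_idx]) for r, mid in enumerate(self.member_ids)
        }
        return prot, sites


def read_protein_alignment(path: str | Path) -> dict[str, str]:
    """Read a gapped protein alignment from FASTA.

    Rows are case-normalized to upper; the gap character is ``-`` (``.`` is
    accepted on input and converted).  Unknown residues may be coded ``X``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    rows: dict[str, str] = {}
    length = None
    for rec in records:
        seq = str(rec.seq).upper().replace(".", GAP)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentShapeError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        bad = set(seq) - PROTEIN_SYMBOLS
        if bad:
            raise AlphabetError(f"record {rec.id!r}: unexpected symbols {sorted(bad)!r}")
        if rec.id in rows:
            raise PairingError(f"duplicate member id {rec.id!r} in alignment")
        rows[rec.id] = seq
    return rows


def anchor_and_trim(
    site: TargetSite,
    flank: int = 9,
    central4_start_label: int = 2,
) -> tuple[str, list[ColumnLabel]]:
    """Trim a site to ``flank`` bases on each side of the central 4.

    Returns the ``2*flank + 4``-base top-strand window and its signed
    position labels.  The central four bases receive labels starting at
    ``central4_start_label`` (default +2, placing the I-OnuI wild-type CAAC
    at +2..+5); flanking labels continue contiguously in both directions,
    skipping 0.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    lo = site.top_cut - flank
    hi = site.bottom_cut + flank
    if lo < 0 or hi > len(site.sequence):
        raise TrimmingError(
            f"site {site.member_id!r}: needs {flank} bases on each side of the "
            f"central 4 (has {site.top_cut} upstream, "
            f"{len(site.sequence) - site.bottom_cut} downstream)"
        )
    window = site.sequence[lo:hi]
    positions = signed_positions(central4_start_label, 4 + flank)
    # walk upstream from the central-4 start label
    up: list[int] = []
    pos = central4_start_label
    for _ in range(flank):
        pos = _prev_signed(pos)
        up.append(pos)
    labels = [ColumnLabel(NUCLEOTIDE, p) for p in reversed(up)] + [
        ColumnLabel(NUCLEOTIDE, p) for p in positions
    ]
    return window, labels


def concatenate(
    protein_alignment: Mapping[str, str],
    sites: Iterable[TargetSite],
    flank: int = 9,
    central4_start_label: int = 2,
    protein_labels: Sequence[int] | None = None,
) -> ConcatenatedAlignment:
    """Append each member's trimmed DNA site to its protein row.

    Sites are matched to protein rows by ``member_id``; every member must
    have exactly one site.  Protein columns are labeled ``1..L`` unless
    reference-structure numbering is supplied via ``protein_labels``.
    """
    site_map: dict[str, TargetSite] = {}
    for site in sites:
        if site.member_id in site_map:
            raise PairingError(f"duplicate site for member {site.member_id!r}")
        site_map[site.member_id] = site
    missing = set(protein_alignment) - set(site_map)
    if missing:
        raise PairingError(f"members without a target site: {sorted(missing)!r}")
    extra = set(site_map) - set(protein_alignment)
    if extra:
        raise PairingError(f"sites without a protein row: {sorted(extra)!r}")

    member_ids = list(protein_alignment)
    if not member_ids:
        raise AlignmentShapeError("empty protein alignment")
    lengths = {len(r) for r in protein_alignment.values()}
    if len(lengths) > 1:
        raise AlignmentShapeError(f"ragged protein rows: lengths {sorted(lengths)}")
    plen = lengths.pop()

    if protein_labels is None:
        protein_labels = range(1, plen + 1)
    protein_labels = list(protein_labels)
    if len(protein_labels) != plen:
        raise ValueError("protein_labels length must equal alignment width")
    if any(b <= a for a, b in zip(protein_labels, protein_labels[1:])):
        raise ValueError("protein labels must be strictly increasing")

    nt_labels = None
    rows = []
    for mid in member_ids:
        window, labels = anchor_and_trim(site_map[mid], flank, central4_start_label)
        if nt_labels is None:
            nt_labels = labels
        rows.append(list(protein_alignment[mid].upper()) + list(window))
    columns = [ColumnLabel(PROTEIN, i) for i in protein_labels] + (nt_labels or [])
    matrix = np.array(rows, dtype="<U1") if rows else np.empty((0, 0), dtype="<U1")
    return ConcatenatedAlignment(member_ids=member_ids, columns=columns, matrix=matrix)


def filter_columns(
    aln: ConcatenatedAlignment, max_gap_fraction: float = 0.5
) -> tuple[ConcatenatedAlignment, list[ColumnLabel]]:
    """Drop protein columns whose gap fraction exceeds ``max_gap_fraction``.

    Nucleotide columns are never removed.  Returns the filtered alignment and
    the labels of excluded columns.  Poorly conserved, gap-rich loop columns
    otherwise dominate the pair-score pool with noise.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be within [0, 1]")
    keep: list[int] = []
    excluded: list[ColumnLabel] = []
    n = max(aln.n_members, 1)
    for i, col in enumerate(aln.columns):
        if col.kind == PROTEIN:
            gap_frac = float((aln.matrix[:, i] == GAP).sum()) / n
            if gap_frac > max_gap_fraction:
                excluded.append(col)
                continue
        keep.append(i)
    filtered = ConcatenatedAlignment(
        member_ids=list(aln.member_ids),
        columns=[aln.columns[i] for i in keep],
        matrix=aln.matrix[:, keep],
    )
    return filtered, excluded


# ---------------------------------------------------------------------------
# serialization

def read_sites_table(path: str | Path) -> list[TargetSite]:
    """Read a tab-separated site table: member_id, sequence, top_cut, bottom_cut.

    Cut coordinates are 0-based offsets as documented on :class:`TargetSite`.
    A header line starting with ``member_id`` is permitted.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "member_id":
                continue
            if len(parts) != 4:
                raise ValueError(f"expected 4 tab-separated fields, got {len(parts)}")
            sites.append(
                TargetSite(parts[0], parts[1], int(parts[2]), int(parts[3]))
            )
    return sites


def write_concatenated(
    aln: ConcatenatedAlignment, fasta_path: str | Path, labels_path: str | Path
) -> None:
    """Serialize as FASTA plus a JSON sidecar of column labels."""
    with open(fasta_path, "w") as fh:
        for r, mid in enumerate(aln.member_ids):
            fh.write(f">{mid}\n{''.join(aln.matrix[r])}\n")
    labels = [{"kind": c.kind, "index": c.index} for c in aln.columns]
    Path(labels_path).write_text(json.dumps(labels))


def read_concatenated(
    fasta_path: str | Path, labels_path: str | Path
) -> ConcatenatedAlignment:
    labels = [
        ColumnLabel(d["kind"], d["index"])
        for d in json.loads(Path(labels_path).read_text())
    ]
    member_ids = []
    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        member_ids.append(rec.id)
        rows.append(list(str(rec.seq).upper()))
    if not rows:
        raise AlignmentShapeError(f"no FASTA records in {fasta_path}")
    return ConcatenatedAlignment(member_ids, labels, np.array(rows, dtype="<U1"))
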