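"""From substrate-depletion sequencing reads to a substrate count table.

The depletion assay incubates an endonuclease with a plasmid library whose
target site is randomized at the central four positions (256 substrates for
a 4-base core).  Surviving (uncleaved) substrate is amplified with
sample-specific barcodes and sequenced; reads are demultiplexed by exact
barcode match, the invariant flanks around the randomized core are matched
positionally allowing up to one mismatch per flank, and the core is counted.

Reads are assumed already oriented (amplicon sequencing with a fixed
layout); reverse-complement rescue is available as an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError

NUCLEOTIDES = "ACGT"

# rejection reasons
OK = "ok"
TOO_SHORT = "too_short"
FLANK_MISMATCH = "flank_mismatch"
AMBIGUOUS_CORE = "ambiguous_core"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlankSpec:
    """Invariant sequence context around the randomized core.

    ``upstream`` and ``downstream`` are matched at fixed offsets with at most
    ``max_mismatch_per_flank`` mismatches each (Hamming distance; the
    allowance applies to each flank independently).
    """

    upstream: str
    downstream: str
    core_length: int = 4
    max_mismatch_per_flank: int = 1

    def __post_init__(self) -> None:
        for name in ("upstream", "downstream"):
            seq = getattr(self, name).upper()
            object.__setattr__(self, name, seq)
            if not seq or set(seq) - set(NUCLEOTIDES):
                raise ConfigurationError(f"{name} flank must be non-empty ACGT")
        if self.core_length < 1:
            raise ConfigurationError("core_length must be >= 1")
        if self.max_mismatch_per_flank < 0:
            raise ConfigurationError("max_mismatch_per_flank must be >= 0")

    @property
    def span(self) -> int:
        return len(self.upstream) + self.core_length + len(self.downstream)


def enumerate_substrates(core_length: int = 4) -> list[str]:
    """All 4^core_length core sequences in lexicographic (A<C<G<T) order."""
    if core_length < 1:
        raise ValueError("core_length must be >= 1")
    subs = [""]
    for _ in range(core_length):
        subs = [s + b for s in subs for b in NUCLEOTIDES]
    return subs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_core(
    read: str, spec: FlankSpec, offset: int = 0, try_reverse_complement: bool = False
) -> tuple[str | None, str]:
    """Extract the randomized core from an oriented read.

    The upstream flank is expected at ``offset`` (bases after any barcode),
    followed by the core and the downstream flank.  Returns ``(core, "ok")``
    on success, else ``(None, reason)`` with reason in
    {too_short, flank_mismatch, ambiguous_core}.
    """
    read = read.upper()
    if len(read) < offset + spec.span:
        return None, TOO_SHORT
    up_start = offset
    core_start = up_start + len(spec.upstream)
    down_start = core_start + spec.core_length
    up = read[up_start:core_start]
    core = read[core_start:down_start]
    down = read[down_start : down_start + len(spec.downstream)]
    if (
        _hamming(up, spec.upstream) <= spec.max_mismatch_per_flank
        and _hamming(down, spec.downstream) <= spec.max_mismatch_per_flank
    ):
        if set(core) - set(NUCLEOTIDES):
            return None, AMBIGUOUS_CORE
        return core, OK
    if try_reverse_complement:
        return extract_core(reverse_complement(read), spec, offset, False)
    return None, FLANK_MISMATCH


def _read_seq(read) -> str:
    """Sequence string from a str or a Bio SeqRecord."""
    return str(getattr(read, "seq", read)).upper()


def deconvolute_barcodes(
    reads: Iterable,
    barcode_map: Mapping[str, object] | Sequence[tuple[str, object]],
    offset: int = 0,
):
    """Assign reads to samples by exact barcode match at a fixed offset.

    ``barcode_map`` maps barcode sequence -> sample key; barcodes must be
    equal-length and mutually distinct.  Reads that do not match any barcode
    exactly land in the ``unassigned`` bin, so that
    ``sum(len(assigned)) + len(unassigned) == total``.
    """
    if not isinstance(barcode_map, Mapping):
        pairs = list(barcode_map)
        barcodes = [b for b, _ in pairs]
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("duplicate barcode in map")
        barcode_map = dict(pairs)
    if not barcode_map:
        raise ConfigurationError("empty barcode map")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ConfigurationError("barcodes must be equal-length")
    bc_len = lengths.pop()
    lut = {b.upper(): s for b, s in barcode_map.items()}
    if len(lut) != len(barcode_map):
        raise ConfigurationError("duplicate barcode in map")

    assigned: dict[object, list] = {s: [] for s in lut.values()}
    unassigned: list = []
    for read in reads:
        seq = _read_seq(read)
        sample = lut.get(seq[offset : offset + bc_len])
        if sample is None:
            unassigned.append(read)
        else:
            assigned[sample].append(read)
    return assigned, unassigned


def build_count_table(
    cores_by_sample: Mapping[object, Iterable[str]], core_length: int = 4
) -> pd.DataFrame:
    """Zero-filled substrate x sample count table.

    Rows are the full lexicographic substrate enumeration; columns are the
    sample keys in their given order.  Column sums equal the number of
    accepted cores per sample.
    """
    substrates = enumerate_substrates(core_length)
    index = pd.Index(substrates, name="substrate")
    table = pd.DataFrame(0, index=index, columns=list(cores_by_sample.keys()))
    pos = {s: i for i, s in enumerate(substrates)}
    for sample, cores in cores_by_sample.items():
        col = np.zeros(len(substrates), dtype=np.int64)
        for core in cores:
            col[pos[core]] += 1
        table[sample] = col
    return table


def count_reads(
    reads: Iterable,
    barcode_map: Mapping[str, object],
    spec: FlankSpec,
    barcode_offset: int = 0,
    try_reverse_complement: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: demultiplex, extract cores, tabulate.

    Returns the count table plus a run report with per-stage tallies
    (``assigned + unassigned == total`` and, within assigned reads,
    ``accepted + rejected == assigned``; rejections broken down by reason).
    """
    reads = list(reads)
    assigned, unassigned = deconvolute_barcodes(reads, barcode_map, barcode_offset)
    bc_len = len(next(iter(barcode_map)))
    core_offset = barcode_offset + bc_len

    cores_by_sample: dict[object, list[str]] = {}
    rejected_by_reason: dict[str, int] = {}
    n_accepted = 0
    for sample, sample_reads in assigned.items():
        cores: list[str] = []
        for read in sample_reads:
            core, reason = extract_core(
                _read_seq(read), spec, core_offset, try_reverse_complement
            )
            if core is None:
                rejected_by_reason[reason] = rejected_by_reason.get(reason, 0) + 1
            else:
                cores.append(core)
        n_accepted += len(cores)
        cores_by_sample[sample] = cores

    table = build_count_table(cores_by_sample, spec.core_length)
    n_assigned = sum(len(v) for v in assigned.values())
    report = {
        "total_reads": len(reads),
        "assigned": n_assigned,
        "unassigned": len(unassigned),
        "accepted": n_accepted,
        "rejected": n_assigned - n_accepted,
        "rejected_by_reason": rejected_by_reason,
        "all_zero": bool(table.values.sum() == 0),
    }
    return table, report


def count_fastq(
    fastq_path: str | Path,
    barcode_map: Mapping[str, object],
    spec: FlankSpec,
    barcode_offset: int = 0,
    try_reverse_complement: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """As :func:`count_reads`, reading single-end reads from a FASTQ file."""
    reads: Iterator = SeqIO.parse(str(fastq_path), "fastq")
    return count_reads(reads, barcode_map, spec, barcode_offset, try_reverse_complement)
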