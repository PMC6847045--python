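"""Synthetic data with known ground truth for the two analysis arms.

``simulate_family`` builds a coevolving protein-DNA family: a star-phylogeny
alignment of ``n_members`` proteins with a 22-nt target site each, every
column drawn independently from a two-symbol background of configurable
entropy, and selected residue-base pairs planted with tunable coupling
(coupling 1 makes the residue a deterministic image of the base through a
fixed injective base->residue map; coupling 0 is independence).  An optional
two-clade mode adds shared-ancestry signal to every column so that the
average-product correction's ability to absorb clade structure can be
exercised.

``simulate_depletion`` builds a substrate-depletion sequencing experiment:
256 four-base cores depleted exponentially with per-substrate rates (per
minute, <= 0), sampled multinomially at a configured depth for each
(replicate, timepoint), and optionally emitted as barcoded FASTQ reads with
per-base sequencing errors.  Defaults mirror the assay design: timepoints
0, 5, 10, 15, 30, 60 and 120 minutes, five replicates, and error rate 0.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .alignments import ConcatenatedAlignment, TargetSite, concatenate
from .depletion_counts import FlankSpec, enumerate_substrates
from .errors import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# fixed injective base -> residue map used for planted couplings
BASE_TO_RESIDUE = {"A": "K", "C": "Y", "G": "R", "T": "E"}

# invariant flanks of the I-OnuI target around the randomized central four
DEFAULT_UPSTREAM_FLANK = "CCACTTATT"
DEFAULT_DOWNSTREAM_FLANK = "CTTTTACCC"


@dataclass(frozen=True)
class PlantedPair:
    """A protein position coupled to a nucleotide position."""

    protein_pos: int  # protein column label (1-based)
    dna_pos: int  # signed nucleotide position label
    coupling: float  # in [0, 1]


@dataclass(frozen=True)
class FamilyConfig:
    n_members: int = 28
    protein_length: int = 64
    site_length: int = 22
    planted_pairs: tuple[PlantedPair, ...] = ()
    background_entropy: float = 1.0  # bits per column, in [0, 1]
    gap_rate: float = 0.0  # protein columns only
    n_clades: int = 1
    clade_coupling: float = 0.0
    central4_start_label: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2 or self.protein_length < 1:
            raise ConfigurationError("need >=2 members and >=1 protein column")
        if self.site_length < 4 or (self.site_length - 4) % 2:
            raise ConfigurationError("site_length must be 4 + an even flank total")
        if not 0.0 <= self.background_entropy <= 1.0:
            raise ConfigurationError("background_entropy must be in [0, 1] bits")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ConfigurationError("gap_rate must be in [0, 1)")
        seen: set[tuple[str, int]] = set()
        for pp in self.planted_pairs:
            if not 0.0 <= pp.coupling <= 1.0:
                raise ConfigurationError("coupling must be in [0, 1]")
            if not 1 <= pp.protein_pos <= self.protein_length:
                raise ConfigurationError(f"planted protein position {pp.protein_pos} outside alignment")
            if pp.dna_pos not in self.nucleotide_labels:
                raise ConfigurationError(f"planted DNA position {pp.dna_pos} outside site labels")
            for key in (("p", pp.protein_pos), ("d", pp.dna_pos)):
                if key in seen:
                    raise ConfigurationError("planted positions must be distinct")
                seen.add(key)

    @property
    def flank(self) -> int:
        return (self.site_length - 4) // 2

    @property
    def nucleotide_labels(self) -> tuple[int, ...]:
        from .alignments import signed_positions

        start = self.central4_start_label
        labels = signed_positions(start, 4 + self.flank)
        pos = start
        up = []
        for _ in range(self.flank):
            pos = pos - 1 if pos - 1 != 0 else -1
            up.append(pos)
        return tuple(reversed(up)) + tuple(labels)


@dataclass
class SimulatedFamily:
    alignment: ConcatenatedAlignment
    protein_rows: dict[str, str]
    sites: list[TargetSite]
    truth: dict


def _two_state_p(entropy_bits: float) -> float:
    """Majority probability p with binary entropy equal to ``entropy_bits``."""
    if entropy_bits >= 1.0:
        return 0.5
    if entropy_bits <= 0.0:
        return 1.0

    def h2(p: float) -> float:
        return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))

    return float(brentq(lambda p: h2(p) - entropy_bits, 0.5, 1 - 1e-12))


def simulate_family(cfg: FamilyConfig) -> SimulatedFamily:
    """Draw one family; returns the concatenated alignment plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_members, cfg.protein_length
    p_major = _two_state_p(cfg.background_entropy)
    clades = np.arange(n) % max(cfg.n_clades, 1)

    def draw_column(alphabet: str) -> tuple[np.ndarray, tuple[str, str]]:
        s1, s2 = rng.choice(list(alphabet), size=2, replace=False)
        use_major = rng.random(n) < p_major
        col = np.where(use_major, s1, s2)
        if cfg.n_clades > 1 and cfg.clade_coupling > 0:
            clade_symbol = rng.choice([s1, s2], size=cfg.n_clades)
            follow = rng.random(n) < cfg.clade_coupling
            col = np.where(follow, clade_symbol[clades], col)
        return col.astype("<U1"), (s1, s2)

    # DNA block first so planted protein columns can condition on it
    site_cols = []
    for _ in range(cfg.site_length):
        col, _syms = draw_column(NUCLEOTIDES)
        site_cols.append(col)
    site_matrix = np.column_stack(site_cols)
    nt_labels = cfg.nucleotide_labels
    dna_col_by_label = {lab: j for j, lab in enumerate(nt_labels)}

    planted_by_protein = {pp.protein_pos: pp for pp in cfg.planted_pairs}
    prot_cols = []
    for pos in range(1, L + 1):
        col, (s1, s2) = draw_column(AMINO_ACIDS)
        pp = planted_by_protein.get(pos)
        if pp is not None:
            bases = site_matrix[:, dna_col_by_label[pp.dna_pos]]
            follow = rng.random(n) < pp.coupling
            mapped = np.array([BASE_TO_RESIDUE[b] for b in bases], dtype="<U1")
            col = np.where(follow, mapped, col)
        prot_cols.append(col)
    prot_matrix = np.column_stack(prot_cols)
    if cfg.gap_rate > 0:
        gaps = rng.random(prot_matrix.shape) < cfg.gap_rate
        prot_matrix = np.where(gaps, "-", prot_matrix)

    member_ids = [f"m{i:02d}" for i in range(n)]
    protein_rows = {mid: "".join(prot_matrix[i]) for i, mid in enumerate(member_ids)}
    sites = [
        TargetSite(mid, "".join(site_matrix[i]), cfg.flank, cfg.flank + 4)
        for i, mid in enumerate(member_ids)
    ]
    aln = concatenate(
        protein_rows,
        sites,
        flank=cfg.flank,
        central4_start_label=cfg.central4_start_label,
    )
    truth = {
        "planted_pairs": [
            {"protein": str(pp.protein_pos), "dna": f"{pp.dna_pos:+d}", "coupling": pp.coupling}
            for pp in cfg.planted_pairs
        ],
        "base_to_residue": dict(BASE_TO_RESIDUE),
        "clades": clades.tolist(),
        "config": asdict(cfg),
    }
    return SimulatedFamily(alignment=aln, protein_rows=protein_rows, sites=sites, truth=truth)


# ---------------------------------------------------------------------------
# depletion simulator

@dataclass(frozen=True)
class DepletionConfig:
    enzyme: str = "WT"
    core_length: int = 4
    true_rates: Mapping[str, float] | None = None  # None: uniform(-0.08, 0)
    timepoints: tuple[float, ...] = (0, 5, 10, 15, 30, 60, 120)
    replicates: int = 5
    depth: int = 100_000
    error_rate: float = 0.0
    upstream_flank: str = DEFAULT_UPSTREAM_FLANK
    downstream_flank: str = DEFAULT_DOWNSTREAM_FLANK
    barcode_length: int = 6
    initial_abundance: Mapping[str, float] | None = None  # None: uniform
    sampling: str = "multinomial"  # or "expected": depth * p, no sampling noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling not in ("multinomial", "expected"):
            raise ConfigurationError("sampling must be 'multinomial' or 'expected'")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.replicates < 1 or len(self.timepoints) < 2:
            raise ConfigurationError("need >=1 replicate and >=2 timepoints")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in [0, 1)")
        if self.true_rates is not None:
            subs = set(enumerate_substrates(self.core_length))
            if set(self.true_rates) != subs:
                raise ConfigurationError("true_rates must cover every substrate exactly")
            if any(r > 0 for r in self.true_rates.values()):
                raise ConfigurationError("depletion rates must be <= 0")


@dataclass
class SimulatedDepletion:
    config: DepletionConfig
    count_table: pd.DataFrame  # substrates x (enzyme, replicate, time_min)
    true_rates: pd.Series
    barcode_map: dict[str, tuple]
    flank_spec: FlankSpec
    _read_rng_seed: tuple = field(repr=False, default=())

    @property
    def samples(self) -> list[tuple]:
        return list(self.count_table.columns)

    def to_fastq(self, path: str | Path | None = None) -> list[str] | None:
        """Emit the counted molecules as barcoded single-end reads.

        Read layout: barcode + upstream flank + core + downstream flank.
        Per-base substitution errors are applied at the configured rate with
        a seed-derived generator, so output is reproducible.  With
        ``path=None`` the FASTQ text is returned as a list of lines.
        """
        rng = np.random.default_rng(list(self._read_rng_seed))
        bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
        lines: list[str] = []
        bc_by_sample = {s: b for b, s in self.barcode_map.items()}
        counter = 0
        for sample in self.samples:
            barcode = bc_by_sample[sample]
            col = self.count_table[sample]
            for substrate, count in col.items():
                if count == 0:
                    continue
                template = (
                    barcode
                    + self.config.upstream_flank
                    + substrate
                    + self.config.downstream_flank
                )
                for _ in range(int(count)):
                    seq = template
                    if self.config.error_rate > 0:
                        arr = np.array(list(seq), dtype="<U1")
                        hit = rng.random(arr.size) < self.config.error_rate
                        for pos in np.nonzero(hit)[0]:
                            choices = [b for b in bases if b != arr[pos]]
                            arr[pos] = rng.choice(choices)
                        seq = "".join(arr)
                    lines.append(f"@read{counter}")
                    lines.append(seq)
                    lines.append("+")
                    lines.append("I" * len(seq))
                    counter += 1
        if path is None:
            return lines
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
        return None


def simulate_depletion(cfg: DepletionConfig) -> SimulatedDepletion:
    """Draw multinomial substrate counts from an exponential depletion model.

    Relative abundance of substrate s at time t is proportional to
    ``init_s * 2**(rate_s * t)``; each (replicate, timepoint) sample is an
    independent multinomial draw of ``depth`` reads.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    substrates = enumerate_substrates(cfg.core_length)
    if cfg.true_rates is None:
        rates = pd.Series(
            rng.uniform(-0.08, 0.0, size=len(substrates)), index=substrates
        )
    else:
        rates = pd.Series({s: float(cfg.true_rates[s]) for s in substrates})
    if cfg.initial_abundance is None:
        init = np.full(len(substrates), 1.0 / len(substrates))
    else:
        init = np.array([cfg.initial_abundance[s] for s in substrates], dtype=float)
        init = init / init.sum()

    samples = [
        (cfg.enzyme, rep, float(t))
        for rep in range(1, cfg.replicates + 1)
        for t in cfg.timepoints
    ]
    counts = {}
    r = rates.to_numpy()
    for sample in samples:
        t = sample[2]
        weights = init * np.exp2(r * t)
        p = weights / weights.sum()
        if cfg.sampling == "expected":
            counts[sample] = cfg.depth * p
        else:
            counts[sample] = rng.multinomial(cfg.depth, p)
    table = pd.DataFrame(counts, index=pd.Index(substrates, name="substrate"))

    all_barcodes = enumerate_substrates(cfg.barcode_length)
    stride = max(len(all_barcodes) // len(samples), 1)
    barcode_map = {all_barcodes[i * stride]: s for i, s in enumerate(samples)}
    spec = FlankSpec(cfg.upstream_flank, cfg.downstream_flank, cfg.core_length)
    rates.name = "true_rate"
    return SimulatedDepletion(
        config=cfg,
        count_table=table,
        true_rates=rates,
        barcode_map=barcode_map,
        flank_spec=spec,
        _read_rng_seed=(cfg.seed, 1),
    )


def centered_rates(true_rates: pd.Series) -> pd.Series:
    """True CLR slopes implied by absolute rates: rate minus the mean rate."""
    return true_rates - true_rates.mean()
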