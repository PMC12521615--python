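"""Synthetic libraries and multi-round selection with known ground truth.

The generative process mirrors the modeled one: an NNS-encoded random
library with log-normally skewed abundances is sequenced (multinomial) each
round before and after an affinity-proportional selection step whose
enrichment function is exactly the truth model's kappa — specific binding
plus a non-specific carry-over floor.  Re-amplification sets the next
round's composition to the expected bound law (a ``resample`` flag switches
to resampling from the finite bound reads instead).

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .errors import ConfigurationError
from .library import AA_INDEX, ALPHABET, CountTable, LibraryDesign, IUPAC_DNA
from .model import (
    N_AA,
    BindingMode,
    EnergyModel,
    RoundParams,
    batch_nonspecific_sum,
    encode_peptides,
    extend_with_flanks,
    _window_scores,
)


def degenerate_codons(pattern: str) -> list[str]:
    """All codons matching a 3-letter IUPAC pattern (e.g. 32 for NNS)."""
    return [
        "".join(bases)
        for bases in itertools.product(*(IUPAC_DNA[p] for p in pattern))
    ]


def codon_table(pattern: str = "NNS") -> dict[str, list[str]]:
    """Map amino acid -> codons under the pattern; stops excluded."""
    table: dict[str, list[str]] = {}
    for codon in degenerate_codons(pattern):
        aa = str(Seq(codon).translate())
        if aa == "*":
            continue
        table.setdefault(aa, []).append(codon)
    return table


def aa_distribution(pattern: str = "NNS") -> np.ndarray:
    """Per-residue probabilities induced by the codon pattern (stops dropped)."""
    table = codon_table(pattern)
    counts = np.array([len(table.get(aa, [])) for aa in ALPHABET], dtype=float)
    if counts.sum() == 0:
        raise ConfigurationError(
            f"codon pattern {pattern!r} encodes no amino acids"
        )
    return counts / counts.sum()


@dataclass
class SimConfig:
    """Settings for :func:`simulate_experiment`; ``seed`` is mandatory."""

    design: LibraryDesign
    seed: int
    truth: EnergyModel | None = None
    truth_sigma: float = 1.0
    n_unique: int = 100_000
    abundance_lognormal_sigma: float = 1.0
    rounds: int = 3
    reads_per_round_input: int = 500_000
    reads_per_round_bound: int = 500_000
    capture_fraction: float = 1.0
    phospho_efficiency: float = 1.0
    resample: bool = False

    def __post_init__(self) -> None:
        if self.n_unique < 1 or self.rounds < 1:
            raise ConfigurationError("n_unique and rounds must be >= 1")
        if min(self.reads_per_round_input, self.reads_per_round_bound) < 1:
            raise ConfigurationError("read depths must be >= 1")
        if not 0 < self.capture_fraction <= 1:
            raise ConfigurationError("capture_fraction must be in (0, 1]")
        if not 0 <= self.phospho_efficiency <= 1:
            raise ConfigurationError("phospho_efficiency must be in [0, 1]")


@dataclass
class SimResult:
    """Simulated tables plus the ground truth used to generate them."""

    tables: list[CountTable]
    truth: EnergyModel
    compositions: list[np.ndarray]  # initial + after each round
    peptides: list[str]
    config: SimConfig


def random_truth(
    design: LibraryDesign,
    rounds: int,
    sigma: float = 1.0,
    seed: int = 0,
    ns_width: int = 3,
    flank_depth: int = 5,
    constrained: bool = True,
    constrained_value: float = -10.0,
    log_alpha_ns: float = 2.0,
    log_alpha_s: float = 0.0,
) -> EnergyModel:
    """Random ground-truth model: N(0, sigma) specific cells, flat NS mode.

    The default non-specific activity makes round-one bound reads mostly
    carry-over, so single-round inference is signal-starved while repeated
    selection progressively purifies the specific binders — the regime that
    motivates joint multi-round fitting.
    """
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(0.0, sigma, size=(design.length, N_AA))
    frozen: dict[tuple[int, int], float] = {}
    if constrained:
        center = design.central_position() - 1
        y = AA_INDEX["Y"]
        for a in range(N_AA):
            frozen[(center, a)] = 0.0 if a == y else constrained_value
    flank_depth = min(
        flank_depth, len(design.protein_flank_left), len(design.protein_flank_right)
    )
    specific = BindingMode(
        width=design.length,
        coeffs=coeffs,
        flank_depth=flank_depth,
        constrained_cells=frozen,
    )
    nonspecific = BindingMode(
        width=ns_width,
        coeffs=np.zeros((ns_width, N_AA)),
        position_bias=np.zeros(design.length - ns_width + 1),
    )
    per_round = [
        RoundParams(log_alpha_ns, log_alpha_s, 0.0) for _ in range(rounds)
    ]
    return EnergyModel(
        design=design,
        specific=specific,
        nonspecific=nonspecific,
        per_round=per_round,
        metadata={"truth": True, "sigma": sigma, "seed": seed},
    )


def gen_library(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[str], np.ndarray]:
    """Sample unique peptides and log-normal abundances (normalized)."""
    rng = rng or np.random.default_rng(config.seed)
    design = config.design
    probs = aa_distribution(design.codon_pattern)
    peptides: list[str] = []
    seen: set[str] = set()
    fixed = sorted(design.fixed_positions.items())
    while len(peptides) < config.n_unique:
        need = config.n_unique - len(peptides)
        idx = rng.choice(N_AA, size=(need, design.length), p=probs)
        for pos, res in fixed:
            idx[:, pos - 1] = AA_INDEX[res]
        chars = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)[idx]
        for row in chars:
            pep = row.tobytes().decode()
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
    if config.abundance_lognormal_sigma == 0:
        abundance = np.full(config.n_unique, 1.0 / config.n_unique)
    else:
        abundance = rng.lognormal(
            0.0, config.abundance_lognormal_sigma, size=config.n_unique
        )
        abundance = abundance / abundance.sum()
    return peptides, abundance


def truth_kappa(
    pep_idx: np.ndarray,
    truth: EnergyModel,
    round_index: int = 0,
    phospho_efficiency: float = 1.0,
) -> np.ndarray:
    """Ground-truth enrichment; tyrosine-containing specific windows are
    attenuated by ``phospho_efficiency`` when it is below one."""
    rp = truth.per_round[min(round_index, len(truth.per_round) - 1)]
    ns = batch_nonspecific_sum(pep_idx, truth.nonspecific)
    mode = truth.specific
    ext = extend_with_flanks(pep_idx, truth.design, mode.flank_depth)
    weights = np.exp(_window_scores(ext, mode.coeffs))
    if phospho_efficiency < 1.0:
        w = mode.width
        n_off = ext.shape[1] - w + 1
        has_y = np.zeros((ext.shape[0], n_off), dtype=bool)
        y = AA_INDEX["Y"]
        for j in range(w):
            has_y |= ext[:, j : j + n_off] == y
        weights = np.where(has_y, weights * phospho_efficiency, weights)
    sp = weights.sum(axis=1)
    return np.exp(rp.log_alpha_ns) * ns + np.exp(rp.log_alpha_s) * sp


def simulate_round(
    peptides: list[str],
    composition: np.ndarray,
    truth: EnergyModel,
    reads_input: int,
    reads_bound: int,
    rng: np.random.Generator,
    round_id: int = 1,
    capture_fraction: float = 1.0,
    phospho_efficiency: float = 1.0,
    resample: bool = False,
    pep_idx: np.ndarray | None = None,
) -> tuple[CountTable, np.ndarray]:
    """One selection round: sequence input, select, sequence bound.

    Input counts are multinomial in the current composition; bound counts are
    multinomial in the kappa-weighted law.  Returns the count table (rows
    observed in at least one column) and the next-round composition.
    """
    composition = np.asarray(composition, dtype=float)
    if composition.min() < 0 or not composition.sum() > 0:
        raise ConfigurationError("degenerate composition")
    composition = composition / composition.sum()
    if pep_idx is None:
        pep_idx = encode_peptides(peptides)
    kappa = truth_kappa(
        pep_idx, truth, round_id - 1, phospho_efficiency
    ) * capture_fraction
    bound_law = composition * kappa
    total = bound_law.sum()
    if not np.isfinite(total) or total <= 0:
        raise ConfigurationError("degenerate bound law (check truth model)")
    bound_law = bound_law / total

    k_in = rng.multinomial(reads_input, composition)
    k_bd = rng.multinomial(reads_bound, bound_law)

    keep = (k_in + k_bd) > 0
    table = CountTable(
        round_id=round_id,
        design=truth.design,
        sequences=[p for p, k in zip(peptides, keep) if k],
        counts_input=k_in[keep],
        counts_bound=k_bd[keep],
    )
    if resample:
        new_comp = k_bd / k_bd.sum()
    else:
        new_comp = bound_law
    return table, new_comp


def simulate_experiment(config: SimConfig) -> SimResult:
    """Chain :func:`simulate_round` over ``config.rounds`` rounds."""
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    if truth is None:
        truth = random_truth(
            config.design,
            rounds=config.rounds,
            sigma=config.truth_sigma,
            seed=config.seed,
            constrained=True,
        )
    peptides, composition = gen_library(config, rng)
    pep_idx = encode_peptides(peptides)
    tables: list[CountTable] = []
    compositions = [composition.copy()]
    for r in range(1, config.rounds + 1):
        table, composition = simulate_round(
            peptides,
            composition,
            truth,
            config.reads_per_round_input,
            config.reads_per_round_bound,
            rng,
            round_id=r,
            capture_fraction=config.capture_fraction,
            phospho_efficiency=config.phospho_efficiency,
            resample=config.resample,
            pep_idx=pep_idx,
        )
        tables.append(table)
        compositions.append(composition.copy())
    return SimResult(
        tables=tables,
        truth=truth,
        compositions=compositions,
        peptides=peptides,
        config=config,
    )


#: Corruption labels planted by :func:`gen_reads`, mapped to the processing
#: stage expected to discard them.
CORRUPT_KINDS = ("anchor", "quality", "stop", "codon")


def _back_translate(
    peptide: str, table: dict[str, list[str]], rng: np.random.Generator
) -> str:
    return "".join(
        table[aa][rng.integers(len(table[aa]))] for aa in peptide
    )


def gen_reads(
    table: CountTable,
    out_input: str | Path,
    out_bound: str | Path,
    seed: int,
    error_rate: float = 0.0,
    corrupt_fraction: float = 0.0,
    phred: int = 38,
    pad: int = 4,
) -> dict[str, dict[str, int]]:
    """Write FASTQ files that reproduce ``table`` under read processing.

    Each peptide is back-translated through random pattern codons, wrapped in
    the design's DNA anchors plus short random pads, and emitted once per
    count.  A ``corrupt_fraction`` of reads is deliberately broken (cycling
    through 6-mismatch anchors, a sub-threshold quality base, an amber stop
    codon, and a pattern-violating codon); the returned dict holds the
    planted label counts per column, which :func:`~pepfer.library.build_count_table`
    reports must match exactly when ``error_rate`` is zero.
    """
    if not 0 <= error_rate <= 0.1:
        raise ConfigurationError("error_rate must be in [0, 0.1]")
    from .library import ReadRecord, write_fastq

    design = table.design
    rng = np.random.default_rng(seed)
    codons = codon_table(design.codon_pattern)
    bases = "ACGT"
    planted = {
        "input": {"clean": 0, "anchor": 0, "quality": 0, "design": 0},
        "bound": {"clean": 0, "anchor": 0, "quality": 0, "design": 0},
    }

    def make_reads(counts: np.ndarray, label_bin: dict[str, int]):
        records = []
        kind_cycle = 0
        for pep, count in zip(table.sequences, counts):
            for _ in range(int(count)):
                dna = _back_translate(pep, codons, rng)
                left_pad = "".join(
                    bases[i] for i in rng.integers(4, size=pad)
                )
                right_pad = "".join(
                    bases[i] for i in rng.integers(4, size=pad)
                )
                left_anchor = design.dna_left_anchor
                region = dna
                qual = np.full(
                    len(left_pad)
                    + len(left_anchor)
                    + len(region)
                    + len(design.dna_right_anchor)
                    + len(right_pad),
                    phred,
                    dtype=int,
                )
                region_start = len(left_pad) + len(left_anchor)
                kind = None
                if corrupt_fraction > 0 and rng.random() < corrupt_fraction:
                    kind = CORRUPT_KINDS[kind_cycle % len(CORRUPT_KINDS)]
                    kind_cycle += 1
                if kind == "anchor":
                    positions = rng.choice(
                        len(left_anchor), size=6, replace=False
                    )
                    chars = list(left_anchor)
                    for p in positions:
                        chars[p] = bases[(bases.index(chars[p]) + 1) % 4]
                    left_anchor = "".join(chars)
                    label_bin["anchor"] += 1
                elif kind == "quality":
                    qual[region_start + int(rng.integers(len(region)))] = 10
                    label_bin["quality"] += 1
                elif kind == "stop":
                    c = int(rng.integers(design.length))
                    region = region[: 3 * c] + "TAG" + region[3 * c + 3 :]
                    label_bin["design"] += 1
                elif kind == "codon":
                    c = int(rng.integers(design.length))
                    region = region[: 3 * c + 2] + "A" + region[3 * c + 3 :]
                    label_bin["design"] += 1
                else:
                    label_bin["clean"] += 1
                seq = (
                    left_pad
                    + left_anchor
                    + region
                    + design.dna_right_anchor
                    + right_pad
                )
                if error_rate > 0:
                    n_err = rng.binomial(len(seq), error_rate)
                    for p in rng.choice(len(seq), size=n_err, replace=False):
                        seq = (
                            seq[:p]
                            + bases[(bases.index(seq[p]) + 1) % 4]
                            + seq[p + 1 :]
                        )
                records.append(ReadRecord(sequence=seq, quality=tuple(qual)))
        return records

    write_fastq(make_reads(table.counts_input, planted["input"]), out_input)
    write_fastq(make_reads(table.counts_bound, planted["bound"]), out_bound)
    return planted
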