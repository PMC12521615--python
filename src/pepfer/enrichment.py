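"""Position-wise amino-acid log-enrichment baseline and count utilities.

This is the simple analysis that energy-model regression is compared
against: read-weighted positional residue frequencies are computed before
and after selection and their log-ratio reported per (position, residue)
cell.  Fixed design positions are masked, not dropped, so matrices from
different library designs stay comparable cell-wise.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyTableError, MalformedInputError
from .library import ALPHABET, CountTable
from .model import N_AA, encode_peptides


@dataclass
class EnrichmentMatrix:
    """L x 20 table of log-enrichment values with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # True where the cell is informative
    pseudocount: float
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ConfigurationError("values/mask shape mismatch")
        if not np.isfinite(self.values).all():
            raise ConfigurationError("enrichment values must be finite")


def _positional_frequencies(
    pep_idx: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Read-weighted residue frequencies per position, shape (L, 20)."""
    L = pep_idx.shape[1]
    total = weights.sum()
    freqs = np.empty((L, N_AA))
    for p in range(L):
        freqs[p] = np.bincount(pep_idx[:, p], weights=weights, minlength=N_AA)[
            :N_AA
        ]
    return freqs / total


def aa_log_enrichment(
    table: CountTable, pseudocount: float = 0.5
) -> EnrichmentMatrix:
    """Log-ratio of bound vs input positional residue frequencies.

    The pseudocount is applied as a frequency floor ``pseudocount / column
    read total`` on each side of the ratio.  Cells for non-fixed residues at
    fixed design positions are reported as 0 and masked.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    if table.n_unique == 0:
        raise EmptyTableError("empty count table")
    total_in = table.counts_input.sum()
    total_bd = table.counts_bound.sum()
    if total_in == 0 or total_bd == 0:
        raise EmptyTableError("a column has zero reads")
    pep_idx = encode_peptides(table.sequences)
    f_in = _positional_frequencies(pep_idx, table.counts_input.astype(float))
    f_bd = _positional_frequencies(pep_idx, table.counts_bound.astype(float))
    eps_in = pseudocount / total_in
    eps_bd = pseudocount / total_bd
    values = np.log((f_bd + eps_bd) / (f_in + eps_in))
    mask = np.ones_like(values, dtype=bool)
    for pos, res in table.design.fixed_positions.items():
        row = pos - 1
        keep = ALPHABET.index(res)
        mask[row, :] = False
        mask[row, keep] = True
        values[row, ~mask[row]] = 0.0
    return EnrichmentMatrix(
        values=values,
        mask=mask,
        pseudocount=pseudocount,
        source=f"{table.design.name}:round{table.round_id}",
    )


def downsample(table: CountTable, n_reads: int, seed: int) -> CountTable:
    """Without-replacement subsample of each column to exactly n_reads."""
    rng = np.random.default_rng(seed)
    new_cols = []
    for counts in (table.counts_input, table.counts_bound):
        total = int(counts.sum())
        if n_reads > total:
            raise ConfigurationError(
                f"n_reads {n_reads} exceeds column total {total}"
            )
        if n_reads == total:
            new_cols.append(counts.copy())
        else:
            new_cols.append(
                rng.multivariate_hypergeometric(
                    counts.astype(np.int64), n_reads, method="marginals"
                )
            )
    keep = (new_cols[0] + new_cols[1]) > 0
    return CountTable(
        round_id=table.round_id,
        design=table.design,
        sequences=[s for s, k in zip(table.sequences, keep) if k],
        counts_input=new_cols[0][keep],
        counts_bound=new_cols[1][keep],
    )


def count_distribution(table: CountTable, column: str) -> dict[int, int]:
    """Histogram: reads-per-unique-sequence -> number of sequences."""
    if column == "input":
        counts = table.counts_input
    elif column == "bound":
        counts = table.counts_bound
    else:
        raise ConfigurationError(f"unknown column {column!r}")
    hist = Counter(int(c) for c in counts if c > 0)
    return dict(sorted(hist.items()))


def _as_values_mask(m) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, EnrichmentMatrix):
        return m.values, m.mask
    arr = np.asarray(m, dtype=np.float64)
    return arr, np.ones_like(arr, dtype=bool)


def compare_matrices(m1, m2) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation over jointly unmasked cells.

    Accepts :class:`EnrichmentMatrix` objects or plain (L, 20) arrays (e.g.
    specific-mode coefficient tables).  Returns (r^2, scatter pairs with
    position/residue labels).
    """
    v1, k1 = _as_values_mask(m1)
    v2, k2 = _as_values_mask(m2)
    if v1.shape != v2.shape:
        raise MalformedInputError(
            f"matrix shapes differ: {v1.shape} vs {v2.shape}"
        )
    mask = k1 & k2
    if mask.sum() < 2:
        raise MalformedInputError("fewer than two unmasked cells to compare")
    rows, cols = np.nonzero(mask)
    pairs = pd.DataFrame(
        {
            "position": rows + 1,
            "residue": [ALPHABET[c] for c in cols],
            "value1": v1[mask],
            "value2": v2[mask],
        }
    )
    r = np.corrcoef(v1[mask], v2[mask])[0, 1]
    return float(r * r), pairs


def write_enrichment_tsv(matrix: EnrichmentMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["position"] + list(ALPHABET))
        for p in range(matrix.values.shape[0]):
            writer.writerow(
                [p + 1]
                + [
                    repr(float(v)) if m else "NA"
                    for v, m in zip(matrix.values[p], matrix.mask[p])
                ]
            )


def read_enrichment_tsv(path: str | Path, pseudocount: float = 0.5) -> EnrichmentMatrix:
    rows = []
    masks = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["position"] + list(ALPHABET):
            raise MalformedInputError(f"{path}: unexpected header")
        for row in reader:
            vals = [0.0 if v == "NA" else float(v) for v in row[1:]]
            mask = [v != "NA" for v in row[1:]]
            rows.append(vals)
            masks.append(mask)
    return EnrichmentMatrix(
        values=np.array(rows), mask=np.array(masks), pseudocount=pseudocount
    )
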