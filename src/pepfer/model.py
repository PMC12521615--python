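"""Additive binding free-energy models and their likelihood.

An :class:`EnergyModel` combines two log-linear binding modes — a
sequence-specific mode whose coefficient matrix holds the entries of
-ddG/RT, and a short non-specific mode with an optional per-offset bias —
with per-round activity and depth parameters.  Predicted enrichment for a
peptide is

    kappa = alpha_NS * nonspecific_sum + alpha_S * specific_sum

where each sum runs over all binding offsets (the specific mode may overlap
up to ``flank_depth`` residues of the constant protein flanks).  Observed
input/bound counts are scored with a scaled binomial log-likelihood in which
the odds of a read landing in the bound column are ``rho * kappa`` with
``rho = exp(depth_log_ratio)`` per count table.

All energies are dimensionless (units of RT).  After gauge normalization
(see :func:`pepfer.fitting.normalize`) the per-position-argmax peptide has
ddG/RT = 0 and relative affinity exactly 1.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    MalformedInputError,
    NotNormalizedError,
)
from .library import AA_INDEX, ALPHABET, PAD_CHAR, PAD_INDEX, CountTable, LibraryDesign

N_AA = len(ALPHABET)

_ENCODE_LUT = np.full(256, -1, dtype=np.int16)
for _aa, _i in AA_INDEX.items():
    _ENCODE_LUT[ord(_aa)] = _i
_ENCODE_LUT[ord(PAD_CHAR)] = PAD_INDEX


def encode_peptides(
    sequences: Sequence[str], allow_pad: bool = False
) -> np.ndarray:
    """Encode equal-length peptides as an (n, L) array of alphabet indices."""
    if isinstance(sequences, str):
        sequences = [sequences]
    n = len(sequences)
    if n == 0:
        raise MalformedInputError("no sequences to encode")
    L = len(sequences[0])
    joined = "".join(sequences)
    if len(joined) != n * L:
        raise MalformedInputError("sequences have unequal lengths")
    arr = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    idx = _ENCODE_LUT[arr].reshape(n, L)
    bad = idx < 0
    if not allow_pad:
        bad = bad | (idx == PAD_INDEX)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MalformedInputError(
            f"letter {sequences[i][j]!r} at position {j + 1} of "
            f"{sequences[i]!r} is outside the alphabet"
        )
    return idx.astype(np.intp)


@dataclass
class BindingMode:
    """A fixed-width additive scoring component over the alphabet.

    ``coeffs`` is a (width, 20) table of log-scale contributions.  The
    non-specific mode carries a per-offset additive bias (``position_bias``)
    and no flank overlap; the specific mode may overlap ``flank_depth``
    residues of the constant protein flanks and holds the frozen
    ``constrained_cells`` used for the central-residue constraint.
    """

    width: int
    coeffs: np.ndarray
    position_bias: np.ndarray | None = None
    flank_depth: int = 0
    constrained_cells: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.shape != (self.width, N_AA):
            raise ConfigurationError(
                f"coeffs shape {self.coeffs.shape} != ({self.width}, {N_AA})"
            )
        if not np.isfinite(self.coeffs).all():
            raise ConfigurationError("coeffs must be finite")
        if self.position_bias is not None:
            self.position_bias = np.asarray(self.position_bias, dtype=np.float64)
            if not np.isfinite(self.position_bias).all():
                raise ConfigurationError("position_bias must be finite")
        if self.flank_depth < 0:
            raise ConfigurationError("flank_depth must be >= 0")
        for (row, col), value in self.constrained_cells.items():
            if not (0 <= row < self.width and 0 <= col < N_AA):
                raise ConfigurationError(f"constrained cell ({row}, {col}) out of range")
            self.coeffs[row, col] = value

    def free_mask(self) -> np.ndarray:
        """Boolean (width, 20) mask of cells that are free to vary."""
        mask = np.ones((self.width, N_AA), dtype=bool)
        for row, col in self.constrained_cells:
            mask[row, col] = False
        return mask

    def apply_frozen(self) -> None:
        for (row, col), value in self.constrained_cells.items():
            self.coeffs[row, col] = value

    def copy(self) -> "BindingMode":
        return BindingMode(
            width=self.width,
            coeffs=self.coeffs.copy(),
            position_bias=None
            if self.position_bias is None
            else self.position_bias.copy(),
            flank_depth=self.flank_depth,
            constrained_cells=dict(self.constrained_cells),
        )


@dataclass
class RoundParams:
    """Per-count-table activity weights and depth ratio (all log scale)."""

    log_alpha_ns: float = 0.0
    log_alpha_s: float = 0.0
    depth_log_ratio: float = 0.0

    def copy(self) -> "RoundParams":
        return RoundParams(self.log_alpha_ns, self.log_alpha_s, self.depth_log_ratio)


@dataclass
class RegularizationConfig:
    lambda_l2: float = 1e-6
    barrier_cap: float = 8.0
    barrier_weight: float = 1e-6
    dirichlet_count: float = 5.0

    def __post_init__(self) -> None:
        if min(self.lambda_l2, self.barrier_weight, self.dirichlet_count) < 0:
            raise ConfigurationError("regularization weights must be >= 0")


@dataclass
class EnergyModel:
    """Specific + non-specific binding modes with per-round parameters."""

    design: LibraryDesign
    specific: BindingMode
    nonspecific: BindingMode
    per_round: list[RoundParams]
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "EnergyModel":
        return EnergyModel(
            design=self.design,
            specific=self.specific.copy(),
            nonspecific=self.nonspecific.copy(),
            per_round=[rp.copy() for rp in self.per_round],
            metadata=dict(self.metadata),
        )

    @property
    def is_normalized(self) -> bool:
        return bool(self.metadata.get("normalized", False))


def _window_scores(ext: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Sum coefficient contributions over every width-w window of ``ext``.

    ``ext`` is (n, m) of alphabet indices; returns (n, m - w + 1).
    """
    w = coeffs.shape[0]
    n, m = ext.shape
    n_off = m - w + 1
    if n_off < 1:
        raise ConfigurationError(
            f"mode width {w} exceeds scored sequence length {m}"
        )
    s = np.zeros((n, n_off))
    for j in range(w):
        s += coeffs[j, ext[:, j : j + n_off]]
    return s


def extend_with_flanks(
    pep_idx: np.ndarray, design: LibraryDesign, flank_depth: int
) -> np.ndarray:
    """Concatenate encoded flank tails/heads around encoded peptides."""
    if flank_depth == 0:
        return pep_idx
    if flank_depth > len(design.protein_flank_left) or flank_depth > len(
        design.protein_flank_right
    ):
        raise ConfigurationError(
            f"flank_depth {flank_depth} exceeds protein flank length"
        )
    n = pep_idx.shape[0]
    left = encode_peptides(design.protein_flank_left)[0, -flank_depth:]
    right = encode_peptides(design.protein_flank_right)[0, :flank_depth]
    return np.concatenate(
        [np.tile(left, (n, 1)), pep_idx, np.tile(right, (n, 1))], axis=1
    )


def batch_specific_sum(
    pep_idx: np.ndarray, mode: BindingMode, design: LibraryDesign
) -> np.ndarray:
    """Specific-mode offset sum exp-window-scores for encoded peptides."""
    ext = extend_with_flanks(pep_idx, design, mode.flank_depth)
    return np.exp(_window_scores(ext, mode.coeffs)).sum(axis=1)


def batch_nonspecific_sum(pep_idx: np.ndarray, mode: BindingMode) -> np.ndarray:
    s = _window_scores(pep_idx, mode.coeffs)
    if mode.position_bias is not None:
        if mode.position_bias.shape != (s.shape[1],):
            raise ConfigurationError(
                f"position_bias length {mode.position_bias.shape} does not "
                f"match offset count {s.shape[1]}"
            )
        s = s + mode.position_bias[None, :]
    return np.exp(s).sum(axis=1)


def specific_sum(
    peptide: str, mode: BindingMode, design: LibraryDesign
) -> float:
    """Sum over all offsets (including flank-overlapping ones) of exp(score)."""
    idx = encode_peptides([peptide])
    return float(batch_specific_sum(idx, mode, design)[0])


def nonspecific_sum(peptide: str, mode: BindingMode) -> float:
    idx = encode_peptides([peptide])
    return float(batch_nonspecific_sum(idx, mode)[0])


def batch_enrichment(
    pep_idx: np.ndarray, model: EnergyModel, round_index: int
) -> np.ndarray:
    if not 0 <= round_index < len(model.per_round):
        raise ConfigurationError(
            f"round_index {round_index} outside 0..{len(model.per_round) - 1}"
        )
    rp = model.per_round[round_index]
    ns = batch_nonspecific_sum(pep_idx, model.nonspecific)
    sp = batch_specific_sum(pep_idx, model.specific, model.design)
    return np.exp(rp.log_alpha_ns) * ns + np.exp(rp.log_alpha_s) * sp


def enrichment(peptide: str, model: EnergyModel, round_index: int) -> float:
    """Predicted enrichment kappa of a peptide in the bound library."""
    idx = encode_peptides([peptide])
    return float(batch_enrichment(idx, model, round_index)[0])


def log_likelihood(tables: Sequence[CountTable], model: EnergyModel) -> float:
    """Scaled binomial log-likelihood of the count tables under the model.

    Each table c contributes (1/k_c) * sum_i [ k_I ln(1/(1+rho kappa)) +
    k_B ln(rho kappa/(1+rho kappa)) ]; table contributions are summed.
    """
    if len(tables) != len(model.per_round):
        raise ConfigurationError(
            f"{len(tables)} tables but model has {len(model.per_round)} "
            "per-round parameter sets"
        )
    total = 0.0
    for c, table in enumerate(tables):
        pep_idx = encode_peptides(table.sequences)
        kappa = batch_enrichment(pep_idx, model, c)
        q = np.exp(model.per_round[c].depth_log_ratio) * kappa
        log1pq = np.log1p(q)
        contrib = (
            table.counts_bound @ (np.log(q) - log1pq)
            - table.counts_input @ log1pq
        )
        total += contrib / table.k_total
    return float(total)


def _free_coefficients(model: EnergyModel) -> np.ndarray:
    parts = [
        model.specific.coeffs[model.specific.free_mask()],
        model.nonspecific.coeffs[model.nonspecific.free_mask()],
    ]
    if model.nonspecific.position_bias is not None:
        parts.append(model.nonspecific.position_bias)
    return np.concatenate(parts)


def penalty(
    model: EnergyModel,
    config: RegularizationConfig,
    tables: Sequence[CountTable] | None = None,
) -> float:
    """Regularization value: L2 + exponential barrier + Dirichlet term.

    The Dirichlet term acts as a pseudo-count on the predicted per-row column
    probabilities and therefore needs the count tables; it is skipped when
    ``tables`` is None.
    """
    beta = _free_coefficients(model)
    value = config.lambda_l2 * float(beta @ beta)
    cap = config.barrier_cap
    value += config.barrier_weight * float(
        np.exp(beta - cap).sum() + np.exp(-beta - cap).sum()
    )
    if tables is not None and config.dirichlet_count > 0:
        for c, table in enumerate(tables):
            pep_idx = encode_peptides(table.sequences)
            kappa = batch_enrichment(pep_idx, model, c)
            q = np.exp(model.per_round[c].depth_log_ratio) * kappa
            # ln p_I + ln p_B = ln q - 2 ln(1+q)
            value -= (
                config.dirichlet_count
                / table.n_unique
                * float((np.log(q) - 2.0 * np.log1p(q)).sum())
            )
    return value


def _require_normalized(model: EnergyModel) -> None:
    if not model.is_normalized:
        raise NotNormalizedError(
            "model is not gauge-normalized; call pepfer.fitting.normalize first"
        )


def _central_register_scores(
    windows: Sequence[str] | np.ndarray, model: EnergyModel
) -> np.ndarray:
    """Signed specific-mode score of the centrally aligned window.

    Pad residues ('X') are scored at the column mean over the 20 residues.
    After normalization every column max is 0, so the result is <= 0 and the
    per-position-argmax window scores exactly 0.
    """
    coeffs = model.specific.coeffs
    if isinstance(windows, np.ndarray) and windows.dtype != object:
        idx = windows
    else:
        idx = encode_peptides(list(windows), allow_pad=True)
    if idx.shape[1] != model.specific.width:
        raise MalformedInputError(
            f"window length {idx.shape[1]} != model width {model.specific.width}"
        )
    lookup = np.concatenate(
        [coeffs, coeffs.mean(axis=1, keepdims=True)], axis=1
    )
    return lookup[np.arange(model.specific.width), idx].sum(axis=1)


def batch_relative_affinity(
    windows: Sequence[str] | np.ndarray, model: EnergyModel
) -> np.ndarray:
    """exp(-ddG/RT) for each window; 1 for the optimal sequence."""
    _require_normalized(model)
    return np.exp(_central_register_scores(windows, model))


def ddg(peptide: str, model: EnergyModel) -> float:
    """ddG/RT of the centrally aligned window; >= 0, 0 for the optimum."""
    _require_normalized(model)
    return float(-_central_register_scores([peptide], model)[0])


def relative_affinity(peptide: str, model: EnergyModel) -> float:
    return float(np.exp(-ddg(peptide, model)))


# ---------------------------------------------------------------------------
# JSON serialization

FORMAT_VERSION = 1


def model_to_dict(model: EnergyModel) -> dict:
    d = model.design
    return {
        "format_version": FORMAT_VERSION,
        "alphabet": ALPHABET,
        "design": {
            "name": d.name,
            "L": d.length,
            "fixed_positions": {str(k): v for k, v in d.fixed_positions.items()},
            "protein_flank_left": d.protein_flank_left,
            "protein_flank_right": d.protein_flank_right,
            "dna_left_anchor": d.dna_left_anchor,
            "dna_right_anchor": d.dna_right_anchor,
            "codon_pattern": d.codon_pattern,
        },
        "specific": {
            "width": model.specific.width,
            "flank_depth": model.specific.flank_depth,
            "coeffs": model.specific.coeffs.tolist(),
            "constrained_cells": [
                [int(r), ALPHABET[c], v]
                for (r, c), v in sorted(model.specific.constrained_cells.items())
            ],
        },
        "nonspecific": {
            "width": model.nonspecific.width,
            "coeffs": model.nonspecific.coeffs.tolist(),
            "gamma": None
            if model.nonspecific.position_bias is None
            else model.nonspecific.position_bias.tolist(),
        },
        "per_round": [
            {
                "alpha_ns": rp.log_alpha_ns,
                "alpha_s": rp.log_alpha_s,
                "depth_log_ratio": rp.depth_log_ratio,
            }
            for rp in model.per_round
        ],
        "metadata": model.metadata,
    }


def model_from_dict(data: dict) -> EnergyModel:
    if data.get("format_version") != FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported model format_version {data.get('format_version')}"
        )
    if data.get("alphabet") != ALPHABET:
        raise ConfigurationError("model alphabet does not match package alphabet")
    dd = data["design"]
    design = LibraryDesign(
        name=dd["name"],
        length=dd["L"],
        fixed_positions={int(k): v for k, v in dd["fixed_positions"].items()},
        protein_flank_left=dd["protein_flank_left"],
        protein_flank_right=dd["protein_flank_right"],
        dna_left_anchor=dd["dna_left_anchor"],
        dna_right_anchor=dd["dna_right_anchor"],
        codon_pattern=dd["codon_pattern"],
    )
    sp = data["specific"]
    specific = BindingMode(
        width=sp["width"],
        coeffs=np.array(sp["coeffs"]),
        flank_depth=sp["flank_depth"],
        constrained_cells={
            (int(r), AA_INDEX[aa]): float(v)
            for r, aa, v in sp["constrained_cells"]
        },
    )
    ns = data["nonspecific"]
    nonspecific = BindingMode(
        width=ns["width"],
        coeffs=np.array(ns["coeffs"]),
        position_bias=None if ns["gamma"] is None else np.array(ns["gamma"]),
    )
    per_round = [
        RoundParams(rp["alpha_ns"], rp["alpha_s"], rp["depth_log_ratio"])
        for rp in data["per_round"]
    ]
    return EnergyModel(
        design=design,
        specific=specific,
        nonspecific=nonspecific,
        per_round=per_round,
        metadata=data.get("metadata", {}),
    )


def save_model(model: EnergyModel, path: str | Path) -> None:
    # json's float repr round-trips exactly, preserving values bit-for-bit
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> EnergyModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
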