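"""Downstream use of fitted models.

Relative-affinity scoring of phosphosite windows, variant-effect ratios,
model truncation for shorter arrays, regression validation against measured
dissociation constants, an exact sign test, energy-logo rendering, and
hierarchical clustering of models.

Scoring uses the single centrally aligned register (the phosphosite-aligned
window), matching how validation peptides are scored; the all-offsets sum is
used only inside the enrichment function during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import linregress

from .errors import ConfigurationError, MalformedInputError
from .fitting import normalize
from .library import ALPHABET, PAD_CHAR
from .model import (
    BindingMode,
    EnergyModel,
    batch_relative_affinity,
    relative_affinity,
)


@dataclass
class PhosphositeRecord:
    """A tyrosine phosphosite with its model-width sequence window."""

    protein_id: str
    site_position: int  # 1-based residue index of the Tyr
    window: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        center = len(self.window) // 2
        if self.window[center] != "Y":
            raise MalformedInputError(
                f"window {self.window!r} does not have Y at its center"
            )


@dataclass
class VariantPair:
    """Two windows differing at exactly one non-central position."""

    wt_window: str
    var_window: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.wt_window) != len(self.var_window):
            raise MalformedInputError("variant windows differ in length")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.wt_window, self.var_window))
            if a != b
        ]
        center = len(self.wt_window) // 2
        if center in diffs:
            raise MalformedInputError(
                "variant substitutes the central (phosphorylated) tyrosine"
            )
        if len(diffs) > 1:
            raise MalformedInputError(
                f"windows differ at {len(diffs)} positions; expected at most 1"
            )
        self.diff_position = diffs[0] if diffs else None


def extract_window(
    protein_sequence: str,
    site_position: int,
    model: EnergyModel,
    protein_id: str = "",
    skip_padded: bool = False,
) -> PhosphositeRecord | None:
    """Model-width window centered on a tyrosine site; None if not a Tyr.

    Sites close to a terminus are padded with a neutral placeholder that is
    scored at the column mean (or skipped entirely if ``skip_padded``).
    """
    width = model.specific.width
    half = width // 2
    if not 1 <= site_position <= len(protein_sequence):
        raise MalformedInputError(
            f"site position {site_position} outside 1..{len(protein_sequence)}"
        )
    if protein_sequence[site_position - 1] != "Y":
        return None
    start = site_position - 1 - half
    end = site_position - 1 + half + 1
    pad_left = max(0, -start)
    pad_right = max(0, end - len(protein_sequence))
    if skip_padded and (pad_left or pad_right):
        return None
    window = (
        PAD_CHAR * pad_left
        + protein_sequence[max(0, start) : min(end, len(protein_sequence))]
        + PAD_CHAR * pad_right
    )
    return PhosphositeRecord(
        protein_id=protein_id, site_position=site_position, window=window
    )


def score_sites(
    records: Sequence[PhosphositeRecord],
    model: EnergyModel,
    allow_pairs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Relative affinity per record, ranked descending (stable order).

    ``allow_pairs`` is an optional allow-list of protein ids (e.g. proteins
    co-expressed with the profiled domain); records outside it are dropped.
    An empty allow-list therefore yields an empty output.
    """
    if allow_pairs is not None:
        allowed = set(allow_pairs)
        records = [r for r in records if r.protein_id in allowed]
    if not records:
        return pd.DataFrame(
            columns=["protein_id", "site_position", "window", "relative_affinity"]
        )
    scores = batch_relative_affinity([r.window for r in records], model)
    frame = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "site_position": [r.site_position for r in records],
            "window": [r.window for r in records],
            "relative_affinity": scores,
        }
    )
    frame = frame.sort_values(
        "relative_affinity", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return frame


def variant_ratio(
    pair: VariantPair, model: EnergyModel
) -> tuple[float, float]:
    """(variant affinity / wild-type affinity, max of the two affinities)."""
    aff_wt = relative_affinity(pair.wt_window, model)
    aff_var = relative_affinity(pair.var_window, model)
    return aff_var / aff_wt, max(aff_wt, aff_var)


def truncate_model(
    model: EnergyModel, keep_left: int, keep_right: int
) -> EnergyModel:
    """Drop outer specific-mode columns, keeping the central one.

    ``keep_left``/``keep_right`` are the numbers of positions retained on
    each side of the central column; the result is renormalized.
    """
    width = model.specific.width
    center = width // 2
    if keep_left < 0 or keep_right < 0:
        raise ConfigurationError("keep counts must be >= 0")
    if keep_left > center or keep_right > width - center - 1:
        raise ConfigurationError(
            f"cannot keep {keep_left}+1+{keep_right} columns of a "
            f"width-{width} mode"
        )
    start = center - keep_left
    stop = center + keep_right + 1
    new_cells = {
        (row - start, col): value
        for (row, col), value in model.specific.constrained_cells.items()
        if start <= row < stop
    }
    out = model.copy()
    out.specific = BindingMode(
        width=stop - start,
        coeffs=model.specific.coeffs[start:stop].copy(),
        flank_depth=model.specific.flank_depth,
        constrained_cells=new_cells,
    )
    out.metadata["normalized"] = False
    out.metadata["truncated_from"] = width
    return normalize(out) if model.is_normalized else out


def validate_against_kd(
    predictions: Sequence[float], measured_kd: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of ln(K_D) on predicted ddG/RT: (slope, intercept, r^2)."""
    pred = np.asarray(predictions, dtype=float)
    kd = np.asarray(measured_kd, dtype=float)
    if pred.shape != kd.shape or pred.size < 3:
        raise MalformedInputError("need matched prediction/K_D lists of size >= 3")
    if (kd <= 0).any():
        raise MalformedInputError("K_D values must be > 0")
    result = linregress(pred, np.log(kd))
    return float(result.slope), float(result.intercept), float(result.rvalue**2)


def sign_test(n_concordant: int, n_total: int) -> float:
    """One-sided exact binomial p-value P(X >= n_concordant), p0 = 1/2."""
    if not 0 <= n_concordant <= n_total:
        raise MalformedInputError("need 0 <= n_concordant <= n_total")
    if n_total == 0:
        return 1.0
    tail = sum(comb(n_total, k) for k in range(n_concordant, n_total + 1))
    return tail / 2**n_total


def centered_matrix(model_or_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-position letter heights (value minus column mean) and a mask.

    Frozen cells of an energy model are excluded from the mean and masked
    (rendered as gray rectangles, matching how constrained columns are
    displayed).
    """
    from .enrichment import EnrichmentMatrix

    if isinstance(model_or_matrix, EnergyModel):
        values = model_or_matrix.specific.coeffs.copy()
        mask = model_or_matrix.specific.free_mask()
    elif isinstance(model_or_matrix, EnrichmentMatrix):
        values = model_or_matrix.values.copy()
        mask = model_or_matrix.mask.copy()
    else:
        values = np.asarray(model_or_matrix, dtype=float).copy()
        mask = np.ones_like(values, dtype=bool)
    heights = np.zeros_like(values)
    for p in range(values.shape[0]):
        row_mask = mask[p]
        if row_mask.any():
            mean = values[p, row_mask].mean()
            heights[p, row_mask] = values[p, row_mask] - mean
    return heights, mask


_LETTER_COLORS = {
    **{aa: "#2c7fb8" for aa in "AVLIMFWPG"},  # hydrophobic / special
    **{aa: "#35a06c" for aa in "STNQCY"},  # polar
    **{aa: "#d95f52" for aa in "DE"},  # acidic
    **{aa: "#7b4fa6" for aa in "KRH"},  # basic
}


def energy_logo(
    model_or_matrix,
    out_path: str | Path,
    tsv_path: str | Path | None = None,
) -> np.ndarray:
    """Render an energy logo; returns (and optionally writes) the heights.

    Letters are drawn with signed heights equal to the coefficient minus the
    per-position mean; positive letters stack upward, negative downward.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch, Rectangle
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    heights, mask = centered_matrix(model_or_matrix)
    L = heights.shape[0]

    fig, ax = plt.subplots(figsize=(max(4, 0.7 * L), 3.2))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    span = max(np.abs(heights).max(), 1e-9)
    for p in range(L):
        pos_items = sorted(
            (
                (h, aa)
                for h, aa, m in zip(heights[p], ALPHABET, mask[p])
                if m and h > 0
            ),
        )
        neg_items = sorted(
            (
                (h, aa)
                for h, aa, m in zip(heights[p], ALPHABET, mask[p])
                if m and h < 0
            ),
            reverse=True,
        )
        y = 0.0
        for h, aa in pos_items:
            _draw_letter(ax, aa, p, y, h, font, PathPatch, TextPath, Affine2D)
            y += h
        y = 0.0
        for h, aa in neg_items:
            _draw_letter(ax, aa, p, y + h, -h, font, PathPatch, TextPath, Affine2D)
            y += h
        if not mask[p].all():
            ax.add_patch(
                Rectangle(
                    (p + 0.05, -0.12 * span),
                    0.9,
                    0.24 * span,
                    facecolor="0.6",
                    edgecolor="none",
                    zorder=0,
                )
            )
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlim(0, L)
    ax.set_xticks(np.arange(L) + 0.5)
    ax.set_xticklabels([str(i + 1) for i in range(L)])
    ax.set_ylabel("contribution - position mean")
    ax.set_xlabel("position")
    lim = 1.1 * span
    ax.set_ylim(-lim, lim)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    if tsv_path is not None:
        frame = pd.DataFrame(heights, columns=list(ALPHABET))
        frame.insert(0, "position", np.arange(1, L + 1))
        frame.to_csv(tsv_path, sep="\t", index=False)
    return heights


def _draw_letter(ax, aa, x, y, height, font, PathPatch, TextPath, Affine2D):
    tp = TextPath((0, 0), aa, size=1.0, prop=font)
    bbox = tp.get_extents()
    scale_x = 0.9 / bbox.width
    scale_y = height / bbox.height
    transform = (
        Affine2D()
        .translate(-bbox.x0, -bbox.y0)
        .scale(scale_x, scale_y)
        .translate(x + 0.05, y)
    )
    ax.add_patch(
        PathPatch(
            transform.transform_path(tp),
            facecolor=_LETTER_COLORS.get(aa, "black"),
            edgecolor="none",
        )
    )


def model_distance(m1: EnergyModel, m2: EnergyModel) -> float:
    """1 - Pearson r over jointly unfrozen specific-mode cells."""
    if m1.specific.coeffs.shape != m2.specific.coeffs.shape:
        raise MalformedInputError("models have different specific-mode shapes")
    mask = m1.specific.free_mask() & m2.specific.free_mask()
    a = m1.specific.coeffs[mask]
    b = m2.specific.coeffs[mask]
    r = np.corrcoef(a, b)[0, 1]
    return float(1.0 - r)


def _truncate_to_common_width(models: Sequence[EnergyModel]) -> list[EnergyModel]:
    widths = [m.specific.width for m in models]
    target = min(widths)
    out = []
    for m, w in zip(models, widths):
        if w == target:
            out.append(m)
        else:
            if (w - target) % 2:
                raise MalformedInputError(
                    f"cannot symmetrically truncate width {w} to {target}"
                )
            half = target // 2
            out.append(truncate_model(m, half, half))
    return out


def cluster_models(
    models: Sequence[EnergyModel], labels: Sequence[str] | None = None
) -> dict:
    """Average-linkage clustering of models on distance 1 - Pearson r.

    Returns a dict with the condensed distance matrix, the scipy linkage
    matrix, labels, and the (deterministic) leaf order.
    """
    if len(models) < 2:
        raise ConfigurationError("need at least two models to cluster")
    models = _truncate_to_common_width(models)
    if labels is None:
        labels = [
            m.metadata.get("name", f"model{i}") for i, m in enumerate(models)
        ]
    n = len(models)
    condensed = np.array(
        [
            model_distance(models[i], models[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = [int(i) for i in hierarchy.leaves_list(linkage)]
    return {
        "distances": condensed,
        "linkage": linkage,
        "labels": list(labels),
        "leaf_order": leaves,
    }
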