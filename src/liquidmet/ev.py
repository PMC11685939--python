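"""Multiplex EV bead-panel analysis: blank correction, group statistics, ROC, NTA summaries.

The bead assay captures extracellular vesicles on 39 bead subsets — 37
surface epitopes plus two isotype controls — and reports the median APC
fluorescence (MFI) per subset. Analysis subtracts the buffer-only blank MFI
from every marker, compares groups marker-by-marker with a two-sided
rank-sum test, and evaluates single-marker discrimination (AML vs healthy
donor) with an empirical ROC.

The AUC is computed from the rank-statistic (Mann-Whitney) formulation with
ties counted half; the operating cutoff maximizes Youden's J.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: the 37 capture epitopes of the multiplex EV kit, plus two isotype controls.
MARKERS_37 = (
    "CD1c", "CD2", "CD3", "CD4", "CD8", "CD9", "CD11c", "CD14", "CD19",
    "CD20", "CD24", "CD25", "CD29", "CD31", "CD40", "CD41b", "CD42a",
    "CD44", "CD45", "CD49e", "CD56", "CD62P", "CD63", "CD69", "CD81",
    "CD86", "CD105", "CD133/1", "CD142", "CD146", "CD209", "CD326",
    "HLA-ABC", "HLA-DRDPDQ", "MCSP", "ROR1", "SSEA-4",
)
ISOTYPES = ("mIgG1", "REA")


class EvPanelError(ValueError):
    """Raised for vocabulary violations or degenerate statistical requests."""


@dataclass(frozen=True)
class BeadPanel:
    """One sample's raw bead MFIs: 37 markers, 2 isotype controls, blank."""

    sample_id: str
    marker_mfi: Mapping[str, float]
    isotype_mfi: Mapping[str, float]
    blank_mfi: float
    group: str = "NA"

    def __post_init__(self) -> None:
        if set(self.marker_mfi) != set(MARKERS_37):
            extra = sorted(set(self.marker_mfi) - set(MARKERS_37))
            missing = sorted(set(MARKERS_37) - set(self.marker_mfi))
            raise EvPanelError(
                f"panel {self.sample_id}: marker vocabulary mismatch "
                f"(extra={extra}, missing={missing})"
            )
        if set(self.isotype_mfi) != set(ISOTYPES):
            raise EvPanelError(f"panel {self.sample_id}: isotype controls must be {ISOTYPES}")
        vals = list(self.marker_mfi.values()) + list(self.isotype_mfi.values()) + [self.blank_mfi]
        if not np.all(np.isfinite(vals)):
            raise EvPanelError(f"panel {self.sample_id}: non-finite MFI")


@dataclass(frozen=True)
class CorrectedPanel:
    """Blank-corrected marker MFIs; flags mark values clamped at zero."""

    sample_id: str
    corrected_mfi: Mapping[str, float]
    clamped: Mapping[str, bool]
    group: str = "NA"


def background_correct(panel: BeadPanel, clamp: bool = True) -> CorrectedPanel:
    """Subtract the blank-control MFI from every marker MFI.

    Negative corrected values are clamped to 0 when ``clamp`` is set (the
    flag records which markers were clamped); with ``clamp=False`` the raw
    difference is kept.
    """
    corrected, flags = {}, {}
    for m, v in panel.marker_mfi.items():
        d = v - panel.blank_mfi
        if clamp and d < 0:
            corrected[m], flags[m] = 0.0, True
        else:
            corrected[m], flags[m] = d, False
    return CorrectedPanel(sample_id=panel.sample_id, corrected_mfi=corrected,
                          clamped=flags, group=panel.group)


def isotype_gate(corrected: CorrectedPanel, panel: BeadPanel) -> dict:
    """Optional detection gate: marker called detected only if its corrected
    MFI exceeds the mean corrected isotype MFI. Off by default in the pipeline."""
    iso = np.mean([v - panel.blank_mfi for v in panel.isotype_mfi.values()])
    iso = max(iso, 0.0)
    return {m: v > iso for m, v in corrected.corrected_mfi.items()}


def panels_to_frame(panels: Sequence[CorrectedPanel]) -> pd.DataFrame:
    """Wide per-sample matrix of corrected MFIs with a ``group`` column."""
    rows = [{"sample_id": p.sample_id, "group": p.group, **p.corrected_mfi} for p in panels]
    return pd.DataFrame(rows).set_index("sample_id")


# --------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocResult:
    auc: float
    threshold_best: float
    sensitivity: float
    specificity: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC via the rank-sum (Mann-Whitney) formulation, ties counted half."""
    ranks = stats.rankdata(scores)  # average ranks on ties
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_analysis(scores: Sequence[float], labels: Sequence[int],
                 n_boot: int = 2000, seed: int = 0) -> RocResult:
    """Single-marker ROC: rank-formulation AUC, Youden-J cutoff, bootstrap CI.

    ``labels`` are binary with 1 = case (AML). The cutoff maximizing
    sensitivity + specificity - 1 is chosen from the empirical ROC curve;
    the AUC CI is a stratified percentile bootstrap (cases and controls
    resampled separately, seeded).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise EvPanelError(f"labels must contain both classes 0 and 1; got {classes}")
    auc = rank_auc(scores, labels)

    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))

    rng = np.random.default_rng(seed)
    pos, neg = scores[labels == 1], scores[labels == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[b] = rank_auc(np.concatenate([bp, bn]),
                            np.concatenate([np.ones(bp.size, int), np.zeros(bn.size, int)]))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return RocResult(auc=float(auc), threshold_best=float(thresholds[best]),
                     sensitivity=float(tpr[best]), specificity=float(1.0 - fpr[best]),
                     ci=ci, n_pos=int(pos.size), n_neg=int(neg.size))


# --------------------------------------------------------------------------
# Group comparison


def marker_group_compare(panels: Sequence[CorrectedPanel], grouping: Mapping[str, str] | None = None,
                         adjust: bool = True) -> pd.DataFrame:
    """Per-marker two-sided rank-sum comparison between two groups.

    Returns a tidy table (marker, median per group, U statistic, p, and an
    optional Holm-adjusted column — an analysis-layer addition, not part of
    the assay readout). Groups come from each panel's ``group`` attribute
    unless ``grouping`` overrides them by sample id.
    """
    df = panels_to_frame(panels)
    if grouping is not None:
        df["group"] = [grouping[s] for s in df.index]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise EvPanelError(f"need exactly two groups; got {groups}")
    g_a, g_b = groups
    a_df, b_df = df[df["group"] == g_a], df[df["group"] == g_b]
    if len(a_df) < 2 or len(b_df) < 2:
        raise EvPanelError("each group needs >= 2 samples")
    rows = []
    for m in MARKERS_37:
        a, b = a_df[m].to_numpy(float), b_df[m].to_numpy(float)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append({"marker": m, f"median_{g_a}": float(np.median(a)),
                     f"median_{g_b}": float(np.median(b)),
                     "U": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


# --------------------------------------------------------------------------
# Nanoparticle tracking summaries


@dataclass(frozen=True)
class NtaSummary:
    """Particle-size distribution summary in nm (D10/D50/D90 percentiles)."""

    mean: float
    mode: float
    d10: float
    d50: float
    d90: float
    concentration: float  # particles / mL

    def __post_init__(self) -> None:
        if not self.d10 <= self.d50 <= self.d90:
            raise EvPanelError("percentiles must be ordered d10 <= d50 <= d90")


def nta_summary(sizes: Sequence[float], concentration: float,
                bin_width: float = 5.0) -> NtaSummary:
    """Summarize a particle-diameter sample.

    The mode is the center of the tallest histogram bin (``bin_width`` nm);
    D10/D50/D90 use linear interpolation between order statistics.
    """
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0:
        raise EvPanelError("empty size sample")
    if np.any(arr <= 0):
        raise EvPanelError("particle diameters must be positive")
    if np.ptp(arr) == 0:
        mode = float(arr[0])
    else:
        edges = np.arange(arr.min(), arr.max() + bin_width, bin_width)
        counts, edges = np.histogram(arr, bins=edges)
        i = int(np.argmax(counts))
        mode = float((edges[i] + edges[i + 1]) / 2.0)
    d10, d50, d90 = (float(np.quantile(arr, q, method="linear")) for q in (0.1, 0.5, 0.9))
    return NtaSummary(mean=float(arr.mean()), mode=mode, d10=d10, d50=d50, d90=d90,
                      concentration=float(concentration))
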