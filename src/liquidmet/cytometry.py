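"""Event-level flow-cytometry model: reference-anchored thresholds and quadrant gating.

The analysis profiles redox metabolism of CD34+ blasts in whole blood by
co-staining for reactive oxygen species (ROS), reduced glutathione (GSH) and
mitochondrial membrane potential (MITO), and classifying each cell hi/lo on a
channel pair relative to cutpoints anchored on the CD3+ lymphocytes of the
same sample (an internal reference population present in every draw).

Conventions, fixed here for reproducibility:

* cutpoint = a configurable quantile (default 0.5) of the reference
  population's intensity distribution, linear interpolation between order
  statistics (numpy ``quantile`` with ``method="linear"``);
* a cell exactly at the cutpoint is classified **lo** (hi requires a strict
  ``>``);
* geometric-mean MFI (gMFI) is taken over strictly positive intensities;
  nonpositive values are excluded and counted, never shifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: population labels understood by default; EventTable accepts extensions.
POPULATIONS = ("CD3", "CD34", "CD34_CD38low", "other")

QUADRANT_KEYS = ("hi_hi", "hi_lo", "lo_hi", "lo_lo")


class CytometryError(ValueError):
    """Raised for invalid event tables, thresholds or gating requests."""


@dataclass
class EventTable:
    """Per-cell fluorescence intensities with population labels.

    Parameters
    ----------
    sample_id : str
    channels : sequence of str
        Unique channel names, order defines the column order of `intensities`.
    intensities : (n_cells, n_channels) float array
        Fluorescence in arbitrary units; must be finite.
    population : (n_cells,) array of str
        Per-cell label, e.g. ``CD3``, ``CD34``, ``CD34_CD38low``.
    """

    sample_id: str
    channels: tuple[str, ...]
    intensities: np.ndarray
    population: np.ndarray
    vocabulary: tuple[str, ...] = POPULATIONS

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise CytometryError(f"duplicate channel names: {self.channels}")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != len(self.channels):
            raise CytometryError(
                f"intensities must be (cells, {len(self.channels)}); got {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise CytometryError("intensities must be finite")
        self.population = np.asarray(self.population, dtype=object)
        if self.population.shape != (self.intensities.shape[0],):
            raise CytometryError("population labels must align with rows of intensities")
        unknown = set(self.population) - set(self.vocabulary)
        if unknown:
            raise CytometryError(f"population labels outside vocabulary: {sorted(unknown)}")

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise CytometryError(f"channel {name!r} not in table (has {self.channels})") from None

    def values(self, channel: str, population: str | None = None) -> np.ndarray:
        """Intensity vector for one channel, optionally restricted to a population."""
        col = self.intensities[:, self.channel_index(channel)]
        if population is None:
            return col
        return col[self.population == population]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=list(self.channels))
        df.insert(0, "population", self.population)
        df.insert(0, "sample_id", self.sample_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str | None = None,
                   vocabulary: Sequence[str] = POPULATIONS) -> "EventTable":
        """Build from the tidy CSV dialect written by the cohort simulator."""
        if sample_id is None:
            ids = df["sample_id"].unique()
            if len(ids) != 1:
                raise CytometryError(f"frame holds {len(ids)} samples; pass sample_id")
            sample_id = str(ids[0])
        else:
            df = df[df["sample_id"] == sample_id]
        channels = [c for c in df.columns if c not in ("sample_id", "population")]
        return cls(sample_id=str(sample_id), channels=tuple(channels),
                   intensities=df[channels].to_numpy(dtype=float),
                   population=df["population"].to_numpy(),
                   vocabulary=tuple(vocabulary))


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel hi/lo cutpoints derived from a reference population."""

    cutpoints: Mapping[str, float]
    reference_population: str
    quantile_used: float


@dataclass(frozen=True)
class QuadrantFrequencies:
    """Four-way hi/lo counts and percentages for one channel pair.

    Keys follow ``(first channel state)_(second channel state)``.
    """

    channel_pair: tuple[str, str]
    counts: Mapping[str, int]
    percentages: Mapping[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if self.percentages is None:
            pct = {k: 100.0 * v / total for k, v in self.counts.items()}
            object.__setattr__(self, "percentages", pct)
        if abs(sum(self.percentages.values()) - 100.0) > 1e-9:
            raise CytometryError("quadrant percentages must sum to 100")

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def gmfi(values: Iterable[float]) -> tuple[float, int]:
    """Geometric mean fluorescence intensity over strictly positive values.

    Returns ``(gmfi, n_excluded)`` where ``n_excluded`` counts nonpositive
    values dropped before the geometric mean. Raises if nothing positive
    remains.
    """
    arr = np.asarray(list(values), dtype=float)
    pos = arr[arr > 0]
    n_excluded = arr.size - pos.size
    if pos.size == 0:
        raise CytometryError("gMFI undefined: no strictly positive intensities")
    if n_excluded:
        logger.info("gMFI: excluded %d nonpositive of %d values", n_excluded, arr.size)
    return float(stats.gmean(pos)), int(n_excluded)


def derive_thresholds(table: EventTable, reference: str, channels: Sequence[str],
                      quantile: float = 0.5) -> ThresholdSet:
    """Cutpoint per channel = `quantile` of the reference population's intensities.

    The reference is CD3+ lymphocytes in this study's design; the quantile is a
    modelling choice (the anchoring population is the documented part).
    """
    if not 0.0 < quantile < 1.0:
        raise CytometryError(f"quantile must lie in (0, 1); got {quantile}")
    cut: dict[str, float] = {}
    for ch in channels:
        ref = table.values(ch, reference)
        if ref.size == 0:
            raise CytometryError(
                f"reference population {reference!r} empty in sample {table.sample_id}"
            )
        cut[ch] = float(np.quantile(ref, quantile, method="linear"))
    return ThresholdSet(cutpoints=cut, reference_population=reference, quantile_used=quantile)


def classify_quadrants(table: EventTable, thresholds: ThresholdSet,
                       pair: tuple[str, str], target: str) -> QuadrantFrequencies:
    """Assign each target cell hi/lo on two channels; hi means strictly above cutpoint."""
    ch_a, ch_b = pair
    a = table.values(ch_a, target)
    b = table.values(ch_b, target)
    if a.size == 0:
        raise CytometryError(f"target population {target!r} empty in sample {table.sample_id}")
    try:
        cut_a = thresholds.cutpoints[ch_a]
        cut_b = thresholds.cutpoints[ch_b]
    except KeyError as exc:
        raise CytometryError(f"no cutpoint for channel {exc.args[0]!r}") from None
    hi_a = a > cut_a
    hi_b = b > cut_b
    counts = {
        "hi_hi": int(np.sum(hi_a & hi_b)),
        "hi_lo": int(np.sum(hi_a & ~hi_b)),
        "lo_hi": int(np.sum(~hi_a & hi_b)),
        "lo_lo": int(np.sum(~hi_a & ~hi_b)),
    }
    return QuadrantFrequencies(channel_pair=(ch_a, ch_b), counts=counts, percentages=None)


def mfi_fold_change(treated, control, channel: str | None = None,
                    statistic: str = "gMFI") -> float:
    """Treated / control MFI ratio (MFI fold change relative to untreated control).

    `treated` and `control` may be EventTables (then `channel` is required) or
    precomputed scalar summaries. ``statistic`` is ``"gMFI"`` or ``"median"``.
    """
    def _summarize(x) -> float:
        if isinstance(x, EventTable):
            if channel is None:
                raise CytometryError("channel required when passing EventTables")
            vals = x.values(channel)
            if statistic == "gMFI":
                return gmfi(vals)[0]
            if statistic == "median":
                return float(np.median(vals))
            raise CytometryError(f"unknown statistic {statistic!r}")
        return float(x)

    t, c = _summarize(treated), _summarize(control)
    if c <= 0:
        raise CytometryError(f"control statistic must be positive; got {c}")
    return t / c


def quadrant_table(freqs: Mapping[str, QuadrantFrequencies], sample_id: str) -> pd.DataFrame:
    """Tidy quadrant output: one row per (sample, pair, quadrant)."""
    rows = []
    for name, q in freqs.items():
        for key in QUADRANT_KEYS:
            rows.append({
                "sample_id": sample_id,
                "pair": name,
                "quadrant": key,
                "count": q.counts[key],
                "percent": q.percentages[key],
            })
    return pd.DataFrame(rows)
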