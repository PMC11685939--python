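"""Seeded synthetic cohorts for every assay layer of the liquid-biopsy study.

The generators emulate the study's inputs — per-cell redox cytometry events,
SCENITH inhibitor-condition gMFIs, multiplex EV bead panels, EV lipidomes,
particle-size samples and Mito-Stress OCR traces — for an AML cohort and a
healthy-donor (HD) control group, with known ground truth so every
downstream estimate has a recoverable target.

Modelling choices (the observed data give group summaries, not generative
parameters, so magnitudes here are illustrative and configurable):

* fluorescence intensities are log-normal (flow data are right-skewed);
  group effects are log2-scale shifts applied to the AML group;
* the CD3+ lymphocyte reference is *not* shifted by disease effects, and
  per-sample batch offsets apply to all populations of a sample equally, so
  CD3-anchored thresholds cancel them;
* the SCENITH generative model decomposes the translation signal additively
  into glucose-derived and mitochondrial ATP contributions, making the
  published derived-parameter formulas exact inverses at zero noise;
* one global seed fans out to per-sample substreams through
  ``numpy.random.SeedSequence(seed, spawn_key=(domain, index))`` — adding
  samples never perturbs existing ones.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cytometry import EventTable
from .ev import ISOTYPES, MARKERS_37, BeadPanel
from .lipidomics import LipidMatrix
from .scenith import OcrTrace, ScenithGmfiSet

logger = logging.getLogger(__name__)

_RISKS = ("favorable", "intermediate", "adverse")

# substream domains for SeedSequence spawn keys
_DOMAINS = {"cytometry": 0, "scenith": 1, "beads": 2, "lipids": 3, "nta": 4, "ocr": 5}


class ConfigError(ValueError):
    """Invalid cohort configuration."""


#: default AML-vs-HD effects, log2 shifts; directions follow the study's
#: group summaries (GSH/MITO up and ROS down in AML blasts; CD44 and other
#: stem/immune markers up on AML EVs, platelet markers down; DG and FA lipid
#: classes raised in AML EVs).
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "cytometry": {"GSH": 1.0, "MITO": 1.0, "ROS": -0.5},
    "beads": {
        "CD44": 1.5, "CD133/1": 1.0, "CD4": 1.0, "HLA-DRDPDQ": 1.0,
        "CD105": 1.0, "CD14": 0.75, "CD40": 0.75,
        "CD62P": -1.0, "CD41b": -1.0, "CD42a": -0.75, "CD209": -0.75, "ROR1": -0.75,
    },
    "lipids": {"DG": 0.8, "FA": 0.6},
}


class CohortConfig(BaseModel):
    """Cohort sizes, effect sizes and noise levels for all generators."""

    n_aml: int = 40
    n_hd: int = 12
    risk_proportions: dict[str, float] = Field(
        default_factory=lambda: {"favorable": 0.25, "intermediate": 0.40, "adverse": 0.35})
    effect_map: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()})
    noise_cv: float = 0.20  # between-sample coefficient of variation
    events_per_sample: int = 2000
    seed: int = 0

    @field_validator("n_aml", "n_hd")
    @classmethod
    def _counts(cls, v: int) -> int:
        if v < 1:
            raise ConfigError("cohort counts must be >= 1")
        return v

    @field_validator("events_per_sample")
    @classmethod
    def _events(cls, v: int) -> int:
        if v < 1:
            raise ConfigError("events_per_sample must be >= 1")
        return v

    @field_validator("noise_cv")
    @classmethod
    def _cv(cls, v: float) -> float:
        if v < 0:
            raise ConfigError("noise_cv must be >= 0")
        return v

    @model_validator(mode="after")
    def _risks(self) -> "CohortConfig":
        if set(self.risk_proportions) != set(_RISKS):
            raise ConfigError(f"risk_proportions must cover {_RISKS}")
        if abs(sum(self.risk_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("risk_proportions must sum to 1")
        return self

    def zero_effects(self) -> "CohortConfig":
        """Copy with every effect removed (null cohort)."""
        return self.model_copy(update={"effect_map": {k: {} for k in self.effect_map}})


def _rng(config_seed: int, domain: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config_seed, spawn_key=(_DOMAINS[domain], index)))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit median and the stated CV on the log-normal."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def cohort_metadata(config: CohortConfig) -> pd.DataFrame:
    """Sample sheet: ids, cohort, ELN risk (AML only), sex, source.

    Risk labels are allocated deterministically to match the requested
    proportions (quantile positions of the cumulative distribution), so the
    stratification is identical across seeds of the same shape.
    """
    cum = np.cumsum([config.risk_proportions[r] for r in _RISKS])
    rows = []
    for i in range(config.n_aml):
        pos = (i + 0.5) / config.n_aml
        risk = _RISKS[int(np.searchsorted(cum, pos))]
        rows.append({"sample_id": f"AML_{i + 1:03d}", "cohort": "AML", "eln_risk": risk,
                     "sex": "F" if i % 2 == 0 else "M", "source": "PB"})
    for i in range(config.n_hd):
        rows.append({"sample_id": f"HD_{i + 1:03d}", "cohort": "HD", "eln_risk": "NA",
                     "sex": "F" if i % 2 == 0 else "M", "source": "PB"})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Redox cytometry events


_CHANNELS = ("ROS", "GSH", "MITO")
_POP_FRACTIONS = {"CD3": 0.30, "CD34": 0.50, "CD34_CD38low": 0.15, "other": 0.05}
_LN_BASE = np.log(100.0)  # reference median fluorescence, a.u.
_CELL_SIGMA = 0.8  # per-cell ln-scale spread


def simulate_redox_cytometry(config: CohortConfig) -> dict[str, EventTable]:
    """One event table per synthetic patient (ROS/GSH/MITO channels).

    Every table carries a CD3+ reference population plus CD34+ and
    CD34+CD38low/- target populations. Disease effects shift the CD34
    compartments only; a per-sample batch offset shifts all populations of
    the sample alike.
    """
    meta = cohort_metadata(config)
    effects = config.effect_map.get("cytometry", {})
    sigma_batch = np.sqrt(np.log1p(config.noise_cv ** 2))
    tables: dict[str, EventTable] = {}
    for idx, row in meta.iterrows():
        rng = _rng(config.seed, "cytometry", idx)
        n = config.events_per_sample
        counts = {p: int(round(f * n)) for p, f in _POP_FRACTIONS.items()}
        counts["CD34"] += n - sum(counts.values())  # absorb rounding
        pops = np.concatenate([np.full(c, p, dtype=object) for p, c in counts.items()])
        batch = rng.normal(0.0, sigma_batch, size=len(_CHANNELS))
        cols = []
        for j, ch in enumerate(_CHANNELS):
            mu = np.full(n, _LN_BASE + batch[j])
            if row["cohort"] == "AML":
                shift = effects.get(ch, 0.0) * np.log(2.0)
                target = np.isin(pops, ("CD34", "CD34_CD38low"))
                mu = mu + np.where(target, shift, 0.0)
            cols.append(np.exp(mu + rng.normal(0.0, _CELL_SIGMA, size=n)))
        tables[row["sample_id"]] = EventTable(
            sample_id=row["sample_id"], channels=_CHANNELS,
            intensities=np.column_stack(cols), population=pops)
    return tables


# --------------------------------------------------------------------------
# SCENITH


class ScenithTruth(BaseModel):
    """Ground-truth energetic parameters behind one simulated gMFI set."""

    gluco_dep_true: float = 83.77
    mito_dep_true: float = 21.42
    signal: float = 200.0
    background: float = 50.0

    @model_validator(mode="after")
    def _check(self) -> "ScenithTruth":
        for name in ("gluco_dep_true", "mito_dep_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ConfigError(f"{name} must lie in [0, 100]")
        if self.signal <= 0:
            raise ConfigError("signal must be > 0")
        if self.background < 0:
            raise ConfigError("background must be >= 0")
        return self


def scenith_condition_means(truth: ScenithTruth) -> dict[str, float]:
    """Noise-free condition gMFIs under the additive two-pathway model.

    Translation signal S splits into a glucose-driven share (gluco_dep_true%)
    blocked by 2DG and a mitochondrial share (mito_dep_true%) blocked by
    oligomycin; the double inhibition (DGO) and harringtonine (H) leave only
    background. The published formulas invert this model exactly.
    """
    s, b = truth.signal, truth.background
    return {
        "Co": b + s,
        "twoDG": b + s * (1.0 - truth.gluco_dep_true / 100.0),
        "O": b + s * (1.0 - truth.mito_dep_true / 100.0),
        "DGO": b,
        "H": b,
    }


def simulate_scenith_gmfi(truth: ScenithTruth, noise_cv: float = 0.0,
                          seed: int = 0) -> ScenithGmfiSet:
    """Draw one gMFI set: condition means times independent log-normal noise."""
    means = scenith_condition_means(truth)
    rng = np.random.default_rng(seed)
    noisy = {c: means[c] * _lognormal_factor(rng, noise_cv)
             for c in ("Co", "twoDG", "O", "DGO", "H")}
    return ScenithGmfiSet(Co=noisy["Co"], twoDG=noisy["twoDG"], O=noisy["O"],
                          DGO=noisy["DGO"], H=noisy["H"])


def simulate_percell_puromycin(truth: ScenithTruth, n_cells: int = 500,
                               cell_cv: float = 0.5, seed: int = 0) -> dict[str, np.ndarray]:
    """Per-cell anti-puromycin intensities per condition (for the bootstrap layer).

    Cells are log-normal around the condition mean with unit-median noise, so
    the population gMFI is an unbiased estimate of the condition mean.
    """
    means = scenith_condition_means(truth)
    rng = np.random.default_rng(seed)
    return {c: means[c] * _lognormal_factor(rng, cell_cv, size=n_cells)
            for c in ("Co", "twoDG", "O", "DGO", "H")}


def simulate_scenith_cohort(config: CohortConfig) -> pd.DataFrame:
    """Per-sample gMFI sets for the whole cohort (AML truth vs a more
    mitochondrial HD truth), as a tidy frame of conditions."""
    meta = cohort_metadata(config)
    rows = []
    for idx, row in meta.iterrows():
        rng = _rng(config.seed, "scenith", idx)
        if row["cohort"] == "AML":
            truth = ScenithTruth()  # high glucose dependence, low mito dependence
        else:
            truth = ScenithTruth(gluco_dep_true=60.0, mito_dep_true=45.0)
        jitter = rng.normal(0.0, 4.0, size=2)  # between-patient spread, percentage points
        truth = ScenithTruth(
            gluco_dep_true=float(np.clip(truth.gluco_dep_true + jitter[0], 0, 100)),
            mito_dep_true=float(np.clip(truth.mito_dep_true + jitter[1], 0, 100)),
            signal=truth.signal, background=truth.background)
        g = simulate_scenith_gmfi(truth, noise_cv=0.05,
                                  seed=int(rng.integers(2 ** 31)))
        rows.append({"sample_id": row["sample_id"], "cohort": row["cohort"],
                     "eln_risk": row["eln_risk"],
                     "Co": g.Co, "twoDG": g.twoDG, "O": g.O, "DGO": g.DGO, "H": g.H,
                     "gluco_dep_true": truth.gluco_dep_true,
                     "mito_dep_true": truth.mito_dep_true})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Bead panels

# baseline corrected signal per marker class, a.u.
_TETRASPANINS = {"CD9": 500.0, "CD63": 450.0, "CD81": 480.0}
_BEAD_BASE_DEFAULT = 60.0
_BEAD_BLANK = 40.0
_BEAD_SIGMA_LN = 0.5  # between-sample spread of ln signal


def simulate_bead_panels(config: CohortConfig) -> list[BeadPanel]:
    """Per-sample multiplex bead panels: 37 markers + 2 isotypes + blank.

    Raw marker MFI = blank + log-normal signal; AML samples shift the signal
    by the configured log2 effects. Raw MFIs are clamped at 0 (logged) —
    negative medians cannot leave the cytometer.
    """
    meta = cohort_metadata(config)
    effects = config.effect_map.get("beads", {})
    panels = []
    for idx, row in meta.iterrows():
        rng = _rng(config.seed, "beads", idx)
        is_aml = row["cohort"] == "AML"
        blank = _BEAD_BLANK * _lognormal_factor(rng, 0.1)
        marker_mfi = {}
        for m in MARKERS_37:
            base = _TETRASPANINS.get(m, _BEAD_BASE_DEFAULT)
            mu = np.log(base)
            if is_aml:
                mu += effects.get(m, 0.0) * np.log(2.0)
            signal = np.exp(rng.normal(mu, _BEAD_SIGMA_LN))
            raw = blank + signal - rng.normal(0.0, 2.0)  # small additive read noise
            if raw < 0:
                logger.info("clamped negative raw MFI for %s / %s", row["sample_id"], m)
                raw = 0.0
            marker_mfi[m] = float(raw)
        isotype = {iso: float(blank + np.exp(rng.normal(np.log(5.0), 0.3)))
                   for iso in ISOTYPES}
        panels.append(BeadPanel(sample_id=row["sample_id"], marker_mfi=marker_mfi,
                                isotype_mfi=isotype, blank_mfi=float(blank),
                                group=row["cohort"]))
    return panels


# --------------------------------------------------------------------------
# Lipidome

# default class composition (% of total lipid); the five published
# percentages plus an illustrative split of the remaining 5.86%.
DEFAULT_CLASS_PCT = {
    "PC": 44.69, "FA": 15.85, "DG": 11.61, "Cer": 11.37, "SM": 10.62,
    "LPC": 2.00, "PC-O": 1.50, "PE": 1.50, "PI": 0.86,
}

# species registry: within-class relative weights; includes the species the
# study reports individually and a few odd-chain species at low weight.
SPECIES_REGISTRY: dict[str, dict[str, float]] = {
    "PC": {"PC 16:0_18:1": 0.30, "PC 16:0_18:2": 0.22, "PC 18:0_18:1": 0.16,
           "PC 18:1_18:2": 0.12, "PC 16:0_20:4": 0.10, "PC 18:0_20:4": 0.06,
           "PC 15:0_18:1": 0.02, "PC 17:0_18:1": 0.02},
    "FA": {"FA 16:0": 0.35, "FA 18:1": 0.30, "FA 18:0": 0.15, "FA 18:2": 0.10,
           "FA 21:0": 0.05, "FA 17:1": 0.05},
    "DG": {"DG 16:0_18:1": 0.28, "DG 16:0_18:2": 0.22, "DG 18:0_18:1": 0.18,
           "DG 18:1_18:2": 0.17, "DG 18:1_20:4": 0.15},
    "Cer": {"Cer 18:1;2O/24": 0.40, "Cer 18:1;2O/16:0": 0.30, "Cer 18:1;2O/24:1": 0.20,
            "Cer 18:1;2O/23": 0.10},
    "SM": {"SM 18:2;2O/24:3": 0.30, "SM 18:1;2O/16:0": 0.40, "SM 18:1;2O/24:1": 0.30},
    "LPC": {"LPC 16:0": 0.45, "LPC 18:1": 0.35, "LPC 18:3": 0.20},
    "PC-O": {"PC O-18:1_20:4": 0.50, "PC O-16:0_18:1": 0.50},
    "PE": {"PE 18:0_22:5": 0.40, "PE 16:0_18:1": 0.60},
    "PI": {"PI 18:0_20:4": 0.70, "PI 16:0_18:1": 0.30},
}

_TOTAL_NMOL = 100.0  # total lipid per sample, nmol/mL


def simulate_lipidome(config: CohortConfig) -> LipidMatrix:
    """Species x samples concentration matrix over the nine-class registry.

    Per sample, each class total is its default composition share of 100
    nmol/mL times log-normal noise (AML shifts the configured classes by
    their log2 effect); class totals are split over species by the fixed
    registry weights with mild species-level noise.
    """
    meta = cohort_metadata(config)
    effects = config.effect_map.get("lipids", {})
    names = [n for cls in SPECIES_REGISTRY for n in SPECIES_REGISTRY[cls]]
    data = {}
    for idx, row in meta.iterrows():
        rng = _rng(config.seed, "lipids", idx)
        is_aml = row["cohort"] == "AML"
        conc = []
        for cls, members in SPECIES_REGISTRY.items():
            total = _TOTAL_NMOL * DEFAULT_CLASS_PCT[cls] / 100.0
            if is_aml:
                total *= 2.0 ** effects.get(cls, 0.0)
            total *= _lognormal_factor(rng, config.noise_cv)
            weights = np.array(list(members.values()))
            noise = _lognormal_factor(rng, 0.15, size=weights.size)
            w = weights * noise
            conc.extend(total * w / w.sum())
        data[row["sample_id"]] = conc
    df = pd.DataFrame(data, index=names)
    groups = dict(zip(meta["sample_id"], meta["cohort"]))
    return LipidMatrix(concentrations=df, groups=groups)


# --------------------------------------------------------------------------
# Particle sizes and OCR traces


def simulate_nta(config: CohortConfig, n_particles: int = 2000) -> dict[str, np.ndarray]:
    """Per-sample particle-diameter samples (nm); AML particles run larger."""
    meta = cohort_metadata(config)
    out = {}
    for idx, row in meta.iterrows():
        rng = _rng(config.seed, "nta", idx)
        mu = np.log(140.0 if row["cohort"] == "AML" else 115.0)
        mu += rng.normal(0.0, np.sqrt(np.log1p(config.noise_cv ** 2)) / 2.0)
        out[row["sample_id"]] = np.exp(rng.normal(mu, 0.25, size=n_particles))
    return out


def simulate_ocr_trace(seed: int = 0, basal: float = 100.0, atp_fraction: float = 0.6,
                       max_fold: float = 1.6, non_mito: float = 10.0,
                       noise_cv: float = 0.02, points_per_phase: int = 3) -> OcrTrace:
    """Four-phase Mito-Stress OCR trace with mild measurement noise."""
    rng = np.random.default_rng(seed)
    pre = np.full(points_per_phase, non_mito + basal)
    oligo = np.full(points_per_phase, non_mito + basal * (1.0 - atp_fraction))
    fccp = np.full(points_per_phase, non_mito + basal * max_fold)
    rot = np.full(points_per_phase, non_mito)
    ocr = np.concatenate([pre, oligo, fccp, rot])
    ocr = ocr * _lognormal_factor(rng, noise_cv, size=ocr.size)
    n = points_per_phase
    t = np.arange(ocr.size, dtype=float) * 6.5
    return OcrTrace(timepoints=t, ocr=ocr, injection_marks=(n, 2 * n, 3 * n))


def simulate_ocr_cohort(config: CohortConfig) -> dict[str, OcrTrace]:
    """Per-sample traces; AML samples get a higher maximal-respiration fold."""
    meta = cohort_metadata(config)
    out = {}
    for idx, row in meta.iterrows():
        rng = _rng(config.seed, "ocr", idx)
        fold = 2.0 if row["cohort"] == "AML" else 1.5
        out[row["sample_id"]] = simulate_ocr_trace(
            seed=int(rng.integers(2 ** 31)),
            basal=float(100.0 * _lognormal_factor(rng, config.noise_cv)),
            max_fold=float(fold * _lognormal_factor(rng, 0.1)),
            noise_cv=0.02)
    return out


# --------------------------------------------------------------------------
# Serialization helpers


def events_to_csv(tables: Mapping[str, EventTable], path) -> None:
    pd.concat([t.to_frame() for t in tables.values()]).to_csv(path, index=False)


def panels_to_csv(panels: Sequence[BeadPanel], path) -> None:
    rows = []
    for p in panels:
        row = {"sample_id": p.sample_id, "group": p.group, "blank": p.blank_mfi,
               **{f"iso_{k}": v for k, v in p.isotype_mfi.items()}, **p.marker_mfi}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def panels_from_csv(path) -> list[BeadPanel]:
    df = pd.read_csv(path)
    panels = []
    for _, row in df.iterrows():
        panels.append(BeadPanel(
            sample_id=str(row["sample_id"]), group=str(row["group"]),
            blank_mfi=float(row["blank"]),
            isotype_mfi={iso: float(row[f"iso_{iso}"]) for iso in ISOTYPES},
            marker_mfi={m: float(row[m]) for m in MARKERS_37}))
    return panels


def lipidome_to_csv(matrix: LipidMatrix, path, group_path=None) -> None:
    matrix.concentrations.to_csv(path, index_label="species")
    if group_path is not None and matrix.groups is not None:
        pd.Series(matrix.groups, name="group").rename_axis("sample_id").to_csv(group_path)


def lipidome_from_csv(path, group_path=None) -> LipidMatrix:
    df = pd.read_csv(path, index_col="species")
    groups = None
    if group_path is not None:
        groups = pd.read_csv(group_path, index_col="sample_id")["group"].to_dict()
    return LipidMatrix(concentrations=df, groups=groups)
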