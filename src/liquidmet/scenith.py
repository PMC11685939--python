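"""SCENITH energetic-metabolism parameters and Mito-Stress bioenergetics.

SCENITH infers single-cell energetic metabolism from protein synthesis
(puromycin incorporation, read out as anti-puromycin gMFI) measured under
four inhibitor conditions: vehicle control (Co), 2-deoxy-D-glucose (2DG),
oligomycin (O), and their combination (DGO). The derived parameters are

    gluco_dep = 100 * (Co - 2DG) / (Co - DGO)     glucose dependence
    mito_dep  = 100 * (Co - O)   / (Co - DGO)     mitochondrial dependence
    glyco_cap = 100 - mito_dep                    glycolytic capacity
    faao_cap  = 100 - gluco_dep                   fatty-acid / AA oxidation capacity

Harringtonine (H) is a full translation block and estimates the staining
background; subtracting it before applying the formulas is offered as an
option (``background="subtract_H"``) but the default follows the formulas
verbatim (``background="none"``).

Mito-Stress extraction reduces a Seahorse oxygen-consumption trace
(oligomycin -> FCCP -> rotenone/antimycin A injections) to basal, maximal,
spare (SRC) and ATP-linked respiration using the vendor phase conventions
(last pre-oligomycin point, minima/maxima after each injection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cytometry import gmfi


class ScenithError(ValueError):
    """Degenerate gMFI sets (e.g. Co <= DGO) or malformed OCR traces."""


@dataclass(frozen=True)
class ScenithGmfiSet:
    """anti-Puro gMFI under the four inhibitor conditions (+ optional harringtonine)."""

    Co: float
    twoDG: float
    O: float
    DGO: float
    H: float | None = None

    def __post_init__(self) -> None:
        for name in ("Co", "twoDG", "O", "DGO"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ScenithError(f"gMFI {name} must be finite and > 0; got {v}")
        if self.H is not None and not (self.H > 0 and np.isfinite(self.H)):
            raise ScenithError(f"gMFI H must be finite and > 0; got {self.H}")


def _clamp01(x: float) -> tuple[float, bool]:
    if x < 0.0:
        return 0.0, True
    if x > 100.0:
        return 100.0, True
    return x, False


@dataclass(frozen=True)
class ScenithProfile:
    """Derived SCENITH percentages.

    ``*_raw`` keep the unclamped formula output (noise can push it outside
    [0, 100]); the plain attributes are clamped when the profile was computed
    with ``clamp=True``. Complement identities hold exactly on both layers:
    ``glyco_cap == 100 - mito_dep`` and ``faao_cap == 100 - gluco_dep``.
    """

    gluco_dep: float
    mito_dep: float
    glyco_cap: float
    faao_cap: float
    gluco_dep_raw: float
    mito_dep_raw: float
    clamped: dict = field(default_factory=dict)

    @property
    def glyco_cap_raw(self) -> float:
        return 100.0 - self.mito_dep_raw

    @property
    def faao_cap_raw(self) -> float:
        return 100.0 - self.gluco_dep_raw


def compute_scenith(g: ScenithGmfiSet, clamp: bool = True,
                    background: str = "none", sample_id: str | None = None) -> ScenithProfile:
    """Apply the SCENITH formulas to one gMFI set.

    Parameters
    ----------
    g : ScenithGmfiSet
    clamp : bool
        Clamp the reported percentages into [0, 100] (raw values are always
        kept alongside).
    background : {"none", "subtract_H"}
        ``subtract_H`` removes the harringtonine (full translation arrest)
        signal from every condition before applying the formulas.
    """
    if background not in ("none", "subtract_H"):
        raise ScenithError(f"unknown background mode {background!r}")
    co, dg, o, dgo = g.Co, g.twoDG, g.O, g.DGO
    if background == "subtract_H":
        if g.H is None:
            raise ScenithError("background='subtract_H' requires an H gMFI")
        co, dg, o, dgo = co - g.H, dg - g.H, o - g.H, dgo - g.H
    denom = co - dgo
    if denom <= 0:
        who = f" (sample {sample_id})" if sample_id else ""
        raise ScenithError(
            f"degenerate denominator Co - DGO = {denom:.6g} <= 0{who}: "
            "translation signal does not exceed the double-inhibition floor"
        )
    gluco_raw = 100.0 * (co - dg) / denom
    mito_raw = 100.0 * (co - o) / denom
    if clamp:
        gluco, cg = _clamp01(gluco_raw)
        mito, cm = _clamp01(mito_raw)
        flags = {"gluco_dep": cg, "mito_dep": cm}
    else:
        gluco, mito, flags = gluco_raw, mito_raw, {"gluco_dep": False, "mito_dep": False}
    return ScenithProfile(
        gluco_dep=gluco, mito_dep=mito,
        glyco_cap=100.0 - mito, faao_cap=100.0 - gluco,
        gluco_dep_raw=gluco_raw, mito_dep_raw=mito_raw,
        clamped=flags,
    )


@dataclass(frozen=True)
class ScenithBootstrap:
    """Point profile plus percentile confidence intervals from cell resampling."""

    profile: ScenithProfile
    ci: dict  # parameter -> (lo, hi), 2.5/97.5 percentiles
    n_replicates: int
    n_degenerate: int


def bootstrap_scenith(per_cell_puromycin: dict, B: int = 2000, seed: int = 0,
                      clamp: bool = False) -> ScenithBootstrap:
    """Percentile-bootstrap CIs for the SCENITH parameters.

    ``per_cell_puromycin`` maps condition names {"Co", "twoDG", "O", "DGO"}
    (optionally "H") to per-cell anti-puromycin intensities. Cells are
    resampled with replacement independently within each condition — the
    conditions come from separate tubes, so no pairing across conditions
    exists. Replicates with a degenerate denominator are dropped; more than
    50% degenerate is an error.
    """
    conditions = {"Co", "twoDG", "O", "DGO"}
    missing = conditions - per_cell_puromycin.keys()
    if missing:
        raise ScenithError(f"missing conditions: {sorted(missing)}")
    if B < 1:
        raise ScenithError("B must be >= 1")
    arrays = {}
    for cond, vals in per_cell_puromycin.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[arr > 0]
        if arr.size < 2:
            raise ScenithError(f"condition {cond!r} needs >= 2 positive intensities")
        arrays[cond] = arr

    point = compute_scenith(_gmfi_set(arrays), clamp=clamp)

    rng = np.random.default_rng(seed)
    reps = {"gluco_dep": [], "mito_dep": [], "glyco_cap": [], "faao_cap": []}
    n_degenerate = 0
    for _ in range(B):
        resampled = {c: rng.choice(a, size=a.size, replace=True) for c, a in arrays.items()}
        try:
            prof = compute_scenith(_gmfi_set(resampled), clamp=clamp)
        except ScenithError:
            n_degenerate += 1
            continue
        for k in reps:
            reps[k].append(getattr(prof, k))
    if n_degenerate > B / 2:
        raise ScenithError(
            f"{n_degenerate}/{B} bootstrap replicates had degenerate denominators; "
            "the translation signal is too close to the DGO floor for a stable CI"
        )
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
          for k, v in reps.items()}
    return ScenithBootstrap(profile=point, ci=ci,
                            n_replicates=B - n_degenerate, n_degenerate=n_degenerate)


def _gmfi_set(arrays: dict) -> ScenithGmfiSet:
    g = {c: gmfi(a)[0] for c, a in arrays.items()}
    return ScenithGmfiSet(Co=g["Co"], twoDG=g["twoDG"], O=g["O"], DGO=g["DGO"],
                          H=g.get("H"))


# --------------------------------------------------------------------------
# Mito-Stress (Seahorse) extraction


@dataclass
class OcrTrace:
    """Oxygen-consumption trace with the three Mito-Stress injections.

    ``injection_marks`` are indices of the first measurement *after* each
    injection, in assay order: oligomycin, FCCP, rotenone + antimycin A.
    """

    timepoints: np.ndarray  # minutes, strictly increasing
    ocr: np.ndarray  # pmol O2 / min
    injection_marks: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.timepoints.shape != self.ocr.shape or self.timepoints.ndim != 1:
            raise ScenithError("timepoints and ocr must be 1-D and aligned")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ScenithError("timepoints must be strictly increasing")
        o, f, r = self.injection_marks
        if not (0 < o < f < r <= self.ocr.size):
            raise ScenithError(
                f"injection marks must satisfy 0 < oligo < FCCP < Rot/AA <= n; got {self.injection_marks}"
            )

    def phase(self, name: str) -> np.ndarray:
        o, f, r = self.injection_marks
        sl = {"basal": slice(0, o), "oligomycin": slice(o, f),
              "fccp": slice(f, r), "rot_aa": slice(r, None)}[name]
        return self.ocr[sl]


@dataclass(frozen=True)
class BioenergeticParams:
    """Mito-Stress summary, all in pmol O2/min, non-mito background subtracted."""

    basal: float
    max_resp: float
    src: float
    atp_linked: float
    non_mito: float
    negative_src: bool = False


def mito_stress_parameters(trace: OcrTrace) -> BioenergeticParams:
    """Extract basal / maximal / spare / ATP-linked respiration from one trace.

    Phase statistics follow the standard Mito-Stress conventions:

    * non-mitochondrial OCR = minimum after rotenone/antimycin A;
    * basal = last pre-oligomycin OCR - non-mito;
    * ATP-linked = basal - (minimum post-oligomycin - non-mito);
    * maximal = maximum post-FCCP - non-mito;
    * SRC = maximal - basal (may be negative; flagged, never clamped).
    """
    for name in ("basal", "oligomycin", "fccp", "rot_aa"):
        if trace.phase(name).size == 0:
            raise ScenithError(f"no measurements in phase {name!r}")
    non_mito = float(np.min(trace.phase("rot_aa")))
    basal = float(trace.phase("basal")[-1]) - non_mito
    atp_linked = basal - (float(np.min(trace.phase("oligomycin"))) - non_mito)
    max_resp = float(np.max(trace.phase("fccp"))) - non_mito
    src = max_resp - basal
    return BioenergeticParams(basal=basal, max_resp=max_resp, src=src,
                              atp_linked=atp_linked, non_mito=non_mito,
                              negative_src=src < 0)


def trace_from_phases(pre: Sequence[float], post_oligo: Sequence[float],
                      post_fccp: Sequence[float], post_rot_aa: Sequence[float],
                      dt: float = 6.5) -> OcrTrace:
    """Convenience constructor from per-phase OCR values on a uniform time grid."""
    ocr = np.concatenate([pre, post_oligo, post_fccp, post_rot_aa]).astype(float)
    n1, n2, n3 = len(pre), len(pre) + len(post_oligo), len(pre) + len(post_oligo) + len(post_fccp)
    t = np.arange(ocr.size, dtype=float) * dt
    return OcrTrace(timepoints=t, ocr=ocr, injection_marks=(n1, n2, n3))
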