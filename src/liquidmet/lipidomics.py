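"""EV lipidomics: shorthand parsing, class composition, QC rules, normalization,
and the lipid-class transformation network.

Species are named in the compact lipidomics shorthand, e.g. ``FA 16:0``,
``DG 18:1_20:4``, ``PC O-18:1_20:4``, ``SM 18:2;2O/24:3``: a class code, an
optional ether prefix (O-/P-), and one or more ``carbons:double_bonds``
chains joined by ``_`` (unknown sn-position) or ``/`` (known), each chain
optionally carrying an extra-oxygen modifier after ``;``. Sphingoid bases in
printed tables sometimes spell ``;2O`` with a digit zero (``;20``); the
parser accepts both, flags the ambiguous spelling, and reproduces the
original text on formatting so names round-trip byte-identically.

The class registry defaults to the nine classes observed in the EV dataset:
PC, LPC, ether-PC (``PC-O``), PE, PI, DG, FA, Cer and SM. Ether species are
their own class by default; a single registry flag folds them into the
diacyl class instead (never both).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_CODES = ("PC", "LPC", "PE", "PI", "DG", "FA", "Cer", "SM")
#: classes whose shorthand carries exactly one chain
SINGLE_CHAIN_CLASSES = ("FA", "LPC")
#: default nine-class registry labels (ether-PC distinct)
NINE_CLASSES = ("PC", "LPC", "PC-O", "PE", "PI", "DG", "FA", "Cer", "SM")

#: directed reactant -> product lipid-class conversions probed by the network
DEFAULT_ADJACENCY = (
    ("SM", "Cer"),
    ("PC", "DG"),
    ("PC", "LPC"),
    ("PC", "FA"),
    ("PI", "FA"),
)


class LipidParseError(ValueError):
    """Malformed shorthand; carries the offending name and position."""

    def __init__(self, name: str, pos: int, msg: str):
        self.name, self.pos = name, pos
        super().__init__(f"cannot parse {name!r} at position {pos}: {msg}")


@dataclass(frozen=True)
class Chain:
    """One acyl/alkyl chain: carbons, double bonds, extra oxygens.

    ``raw`` preserves the exact source spelling (``24`` vs ``24:0``,
    ``;2O`` vs ``;20``) so formatting reproduces the input; it never takes
    part in equality.
    """

    carbons: int
    double_bonds: int
    extra_oxygens: int = 0
    raw: str | None = field(default=None, compare=False)
    ambiguous_oxygen: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain carbons must be >= 1; got {self.carbons}")
        if self.double_bonds < 0 or self.extra_oxygens < 0:
            raise ValueError("double bonds and extra oxygens must be >= 0")

    def format(self) -> str:
        if self.raw is not None:
            return self.raw
        s = f"{self.carbons}:{self.double_bonds}"
        if self.extra_oxygens == 1:
            s += ";O"
        elif self.extra_oxygens > 1:
            s += f";{self.extra_oxygens}O"
        return s


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed shorthand lipid identity."""

    class_code: str
    ether_prefix: str = ""  # "", "O" or "P"
    chains: tuple[Chain, ...] = ()
    separators: tuple[str, ...] = ()  # "_" or "/", between consecutive chains
    annotation_level: str = "molecular_species"

    def __post_init__(self) -> None:
        if self.class_code not in CLASS_CODES:
            raise ValueError(f"unknown lipid class {self.class_code!r}")
        if self.ether_prefix not in ("", "O", "P"):
            raise ValueError(f"ether prefix must be '', 'O' or 'P'; got {self.ether_prefix!r}")
        if not self.chains:
            raise ValueError("a species needs at least one chain")
        if len(self.separators) != len(self.chains) - 1:
            raise ValueError("need exactly one separator between consecutive chains")
        if self.class_code in SINGLE_CHAIN_CLASSES and len(self.chains) != 1:
            raise ValueError(f"{self.class_code} carries exactly one chain")

    @property
    def class_key(self) -> str:
        """Registry label; ether species get a distinct ``-O``/``-P`` class."""
        return f"{self.class_code}-{self.ether_prefix}" if self.ether_prefix else self.class_code

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def has_odd_chain(self) -> bool:
        return any(c.carbons % 2 == 1 for c in self.chains)

    def format(self) -> str:
        prefix = f"{self.ether_prefix}-" if self.ether_prefix else ""
        parts = [self.chains[0].format()]
        for sep, ch in zip(self.separators, self.chains[1:]):
            parts.append(sep + ch.format())
        return f"{self.class_code} {prefix}{''.join(parts)}"


_CHAIN_RE = re.compile(r"^(\d+)(?::(\d+))?(?:;(.+))?$")


def _parse_oxygen_token(token: str, name: str, pos: int) -> tuple[int, bool]:
    """Interpret the token after ';' as an extra-oxygen count.

    ``O`` and ``nO`` are unambiguous. A pure number <= 3 is an oxygen count;
    a number like ``20`` (digit zero where tables print the letter O) is read
    as its leading digit with an ambiguity flag. Anything else is an error.
    """
    m = re.fullmatch(r"(\d*)O", token)
    if m:
        return (int(m.group(1)) if m.group(1) else 1), False
    if token.isdigit():
        v = int(token)
        if v <= 3:
            return v, False
        if len(token) == 2 and token[1] == "0" and 1 <= v // 10 <= 3:
            logger.debug("ambiguous oxygen token %r in %r read as %d oxygens",
                         token, name, v // 10)
            return v // 10, True
    raise LipidParseError(name, pos, f"uninterpretable oxygen modifier {token!r}")


def _parse_chain(token: str, name: str, pos: int) -> Chain:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidParseError(name, pos, f"bad chain token {token!r}")
    carbons = int(m.group(1))
    db = int(m.group(2)) if m.group(2) is not None else 0
    oxy, ambiguous = (0, False)
    if m.group(3) is not None:
        oxy, ambiguous = _parse_oxygen_token(m.group(3), name, pos + token.index(";"))
    try:
        return Chain(carbons=carbons, double_bonds=db, extra_oxygens=oxy,
                     raw=token, ambiguous_oxygen=ambiguous)
    except ValueError as exc:
        raise LipidParseError(name, pos, str(exc)) from None


def parse_lipid_shorthand(name: str) -> LipidSpecies:
    """Parse one shorthand species name.

    Grammar: ``CLASS [O-|P-] chain ((_|/) chain)*`` with
    ``chain = C[:D][;ox]``. Raises :class:`LipidParseError` with the
    character position of the first offending token.
    """
    stripped = name.strip()
    m = re.match(r"^(\S+)\s+(\S.*)$", stripped)
    if not m:
        raise LipidParseError(name, 0, "expected 'CLASS chains'")
    cls, rest = m.group(1), m.group(2)
    if cls not in CLASS_CODES:
        raise LipidParseError(name, 0, f"unknown class code {cls!r}")
    prefix = ""
    body_pos = stripped.index(rest)
    if rest[:2] in ("O-", "P-"):
        prefix = rest[0]
        rest = rest[2:]
        body_pos += 2
    tokens = re.split(r"([_/])", rest)
    chains, seps = [], []
    pos = body_pos
    for i, tok in enumerate(tokens):
        if i % 2:  # separator slot
            seps.append(tok)
            pos += len(tok)
        else:
            if not tok:
                raise LipidParseError(name, pos, "empty chain token")
            chains.append(_parse_chain(tok, name, pos))
            pos += len(tok)
    level = ("molecular_species"
             if len(chains) > 1 or cls in SINGLE_CHAIN_CLASSES
             else "species")
    try:
        return LipidSpecies(class_code=cls, ether_prefix=prefix, chains=tuple(chains),
                            separators=tuple(seps), annotation_level=level)
    except ValueError as exc:
        raise LipidParseError(name, 0, str(exc)) from None


def format_lipid(species: LipidSpecies) -> str:
    return species.format()


# --------------------------------------------------------------------------
# Concentration matrix


@dataclass
class LipidMatrix:
    """Species x samples concentration matrix (nmol/mL) with group labels."""

    concentrations: pd.DataFrame  # index = shorthand names, columns = sample ids
    groups: Mapping[str, str] | None = None
    fold_ether: bool = False  # fold O-/P- species into their diacyl class

    def __post_init__(self) -> None:
        if self.concentrations.index.duplicated().any():
            dups = self.concentrations.index[self.concentrations.index.duplicated()]
            raise ValueError(f"duplicate species names: {list(dups)}")
        vals = self.concentrations.to_numpy(float)
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("concentrations must be finite and nonnegative")
        self.species = {n: parse_lipid_shorthand(n) for n in self.concentrations.index}

    @property
    def n_species(self) -> int:
        return len(self.concentrations)

    def class_of(self, name: str) -> str:
        sp = self.species[name]
        return sp.class_code if self.fold_ether else sp.class_key

    def class_totals(self) -> pd.DataFrame:
        """Per-sample class totals (classes x samples); conserves the species sum."""
        keys = pd.Series({n: self.class_of(n) for n in self.concentrations.index})
        return self.concentrations.groupby(keys).sum()

    def sample_groups(self) -> pd.Series:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return pd.Series({s: self.groups[s] for s in self.concentrations.columns})


@dataclass(frozen=True)
class ClassComposition:
    totals: pd.DataFrame        # classes x samples, nmol/mL
    composition: pd.DataFrame   # classes x samples, percent (each column sums to 100)
    overall: pd.Series          # percent of the grand total, per class
    group_composition: pd.DataFrame | None  # classes x groups, percent of group total


def aggregate_classes(matrix: LipidMatrix) -> ClassComposition:
    """Class totals and percent composition per sample, overall and per group."""
    if matrix.n_species == 0 or matrix.concentrations.shape[1] == 0:
        raise ValueError("empty lipid matrix")
    totals = matrix.class_totals()
    composition = 100.0 * totals / totals.sum(axis=0)
    overall = 100.0 * totals.sum(axis=1) / totals.values.sum()
    group_comp = None
    if matrix.groups is not None:
        g = matrix.sample_groups()
        by_group = totals.T.groupby(g).sum().T
        group_comp = 100.0 * by_group / by_group.sum(axis=0)
    return ClassComposition(totals=totals, composition=composition,
                            overall=overall, group_composition=group_comp)


def odd_even_ratio(matrix: LipidMatrix, weighting: str = "concentration") -> float:
    """Percent of the lipidome carried by species with >= 1 odd-carbon chain.

    ``weighting="concentration"`` (default) weights by total concentration;
    ``"species_count"`` weights every species equally. The published ratios
    are small single-digit percentages; the definition itself is fixed here.
    """
    if matrix.n_species == 0:
        raise ValueError("empty lipid matrix")
    odd = np.array([matrix.species[n].has_odd_chain for n in matrix.concentrations.index])
    if weighting == "species_count":
        return 100.0 * float(odd.mean())
    if weighting == "concentration":
        per_species = matrix.concentrations.sum(axis=1).to_numpy(float)
        total = per_species.sum()
        if total == 0:
            return 0.0
        return 100.0 * float(per_species[odd].sum() / total)
    raise ValueError(f"unknown weighting {weighting!r}")


def odd_even_by_group(matrix: LipidMatrix, weighting: str = "concentration") -> dict:
    """Odd/even ratio computed separately within each sample group."""
    g = matrix.sample_groups()
    out = {}
    for grp in sorted(g.unique()):
        sub = LipidMatrix(matrix.concentrations.loc[:, g[g == grp].index],
                          groups=None, fold_ether=matrix.fold_ether)
        out[grp] = odd_even_ratio(sub, weighting=weighting)
    return out


# --------------------------------------------------------------------------
# Annotation QC


@dataclass(frozen=True)
class AnnotationRecord:
    """MS1 annotation evidence for one species."""

    name: str
    theoretical_mz: float
    observed_mz: float
    annotation_score: float  # percent, 0..100

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0 or self.observed_mz <= 0:
            raise ValueError(f"{self.name}: masses must be positive")
        if not 0.0 <= self.annotation_score <= 100.0:
            raise ValueError(f"{self.name}: score must be in [0, 100]")

    @property
    def ppm_error(self) -> float:
        return abs(self.observed_mz - self.theoretical_mz) / self.theoretical_mz * 1e6


def annotation_qc(records: Sequence[AnnotationRecord],
                  max_ppm: float = 25.0, min_score: float = 80.0):
    """Apply the MS1 acceptance rules: ppm error < 25 AND score > 80 (both strict).

    Returns ``(accepted_records, mean_abs_ppm_over_accepted)``; the mean is
    ``nan`` when nothing passes.
    """
    if not records:
        raise ValueError("no annotation records")
    accepted = [r for r in records if r.ppm_error < max_ppm and r.annotation_score > min_score]
    mean_ppm = float(np.mean([r.ppm_error for r in accepted])) if accepted else math.nan
    return accepted, mean_ppm


# --------------------------------------------------------------------------
# Normalization


def normalize_median_autoscale(matrix: LipidMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Median-normalize per sample, then autoscale per species.

    Each sample (column) is divided by its own median concentration; each
    species (row) is then centered to mean 0 and scaled to unit standard
    deviation (ddof=1). Zero-variance rows are left centered-only and
    returned in the flagged list.
    """
    df = matrix.concentrations
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples to autoscale")
    medians = df.median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])
        raise ValueError(f"nonpositive per-sample medians for {bad}")
    norm = df / medians
    centered = norm.sub(norm.mean(axis=1), axis=0)
    sd = norm.std(axis=1, ddof=1)
    degenerate = list(sd.index[sd == 0])
    scale = sd.replace(0, 1.0)
    out = centered.div(scale, axis=0)
    if degenerate:
        logger.info("autoscale: %d zero-variance species left centered-only", len(degenerate))
    return out, degenerate


# --------------------------------------------------------------------------
# Transformation network


@dataclass(frozen=True)
class NetworkEdge:
    reactant: str
    product: str
    z: float
    mean_log_ratio: Mapping[str, float]  # group -> mean per-sample log(product/reactant)
    n_samples: Mapping[str, int]


@dataclass(frozen=True)
class TransformationNetwork:
    """Directed lipid-class conversions scored by a standardized between-group
    difference of per-sample log(product total / reactant total)."""

    edges: tuple[NetworkEdge, ...]
    group_order: tuple[str, str]  # z > 0 means higher ratio in group_order[0]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.reactant, e.product, z=e.z,
                       **{f"mean_log_ratio_{k}": v for k, v in e.mean_log_ratio.items()})
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            row = {"reactant": e.reactant, "product": e.product, "z": e.z}
            for grp, v in e.mean_log_ratio.items():
                row[f"mean_log_ratio_{grp}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def class_network_zscores(matrix: LipidMatrix, groups: Mapping[str, str] | None = None,
                          adjacency: Sequence[tuple[str, str]] = DEFAULT_ADJACENCY,
                          group_order: tuple[str, str] | None = None) -> TransformationNetwork:
    """Score each reactant -> product class conversion between two groups.

    Per sample and edge, ``r = log(product class total / reactant class
    total)``; the edge score is the two-sample standardized mean difference

        z = (mean_A(r) - mean_B(r)) / (s_p * sqrt(1/n_A + 1/n_B))

    with the pooled standard deviation ``s_p``. Samples with a zero reactant
    or product total are excluded per edge (logged); an edge whose group
    empties is an error. Swapping the two group labels negates every z.
    """
    if groups is None:
        g = matrix.sample_groups()
    else:
        g = pd.Series({s: groups[s] for s in matrix.concentrations.columns})
    labels = sorted(g.unique()) if group_order is None else list(group_order)
    if len(set(g)) != 2 or len(labels) != 2:
        raise ValueError(f"need exactly two groups; got {sorted(set(g))}")
    a_label, b_label = labels
    totals = matrix.class_totals()
    edges = []
    for reactant, product in adjacency:
        if reactant not in totals.index or product not in totals.index:
            raise ValueError(f"edge {reactant}->{product}: class absent from matrix")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log(totals.loc[product] / totals.loc[reactant])
        ok = np.isfinite(r)
        if (~ok).any():
            logger.info("edge %s->%s: excluded %d samples with zero class totals",
                        reactant, product, int((~ok).sum()))
        ra = r[ok & (g == a_label)].to_numpy(float)
        rb = r[ok & (g == b_label)].to_numpy(float)
        if ra.size < 2 or rb.size < 2:
            raise ValueError(f"edge {reactant}->{product}: a group has < 2 usable samples")
        diff = ra.mean() - rb.mean()
        sp2 = (((ra.size - 1) * ra.var(ddof=1) + (rb.size - 1) * rb.var(ddof=1))
               / (ra.size + rb.size - 2))
        se = math.sqrt(sp2 * (1.0 / ra.size + 1.0 / rb.size))
        z = 0.0 if diff == 0 else (math.inf if se == 0 else diff / se)
        edges.append(NetworkEdge(
            reactant=reactant, product=product, z=float(z),
            mean_log_ratio={a_label: float(ra.mean()), b_label: float(rb.mean())},
            n_samples={a_label: int(ra.size), b_label: int(rb.size)},
        ))
    return TransformationNetwork(edges=tuple(edges), group_order=(a_label, b_label))
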