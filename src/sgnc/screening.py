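"""Post-generation filter cascade for drug-likeness.

Candidates that leave the generator pass through, in any order (the filters
commute):

* an affinity filter — predicted ΔG < −9.54 kcal/mol on each of the three
  transporter targets (DAT, NET, SERT) and ΔG > −8.18 kcal/mol on hERG, so
  leads bind the therapeutic targets tightly but the cardiotoxicity-linked
  potassium channel weakly;
* Lipinski's rule of five — MW ≤ 500 Da, logP ≤ 5, nHD ≤ 5, nHA ≤ 10
  (all inclusive);
* a novelty filter — cosine similarity to every reference compound below
  0.5, so leads are not trivial re-discoveries of the references;
* range classification of ten ADMET / physicochemical / medicinal-chemistry
  properties against an excellent/medium range table. Property values are
  inputs (typically exported from an external ADMET predictor); this module
  never predicts them.

Each candidate receives a per-property class (excellent / medium / fail),
an overall pass (no property may fail, i.e. at least medium everywhere) and
a percent-excellent score used to rank the surviving leads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sgnc.codec import MoleculeRecord
from sgnc.exceptions import DataError, DomainError

#: ΔG threshold (kcal/mol) below which a transporter binder counts as active.
TRANSPORTER_MAX_DELTA_G = -9.54
#: ΔG threshold (kcal/mol) above which hERG binding counts as safely weak.
HERG_MIN_DELTA_G = -8.18

TRANSPORTER_TARGETS = ("DAT", "NET", "SERT")

#: Lipinski rule-of-five bounds, all inclusive.
LIPINSKI_BOUNDS = {"mw": 500.0, "logp": 5.0, "nhd": 5, "nha": 10}

PROPERTY_NAMES = (
    "caco2", "f20", "pgp_sub", "pgp_inh", "vd", "t_half", "fdamdd", "sas", "logp", "logs",
)
#: Probability-like predictor scores constrained to [0, 1].
SCORE_PROPERTIES = ("f20", "pgp_sub", "pgp_inh", "t_half", "fdamdd")


@dataclass(frozen=True)
class Interval:
    """A numeric interval with per-end closedness; infinite ends are open."""

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = True

    def contains(self, x: float) -> bool:
        above = x >= self.lo if self.lo_closed else x > self.lo
        below = x <= self.hi if self.hi_closed else x < self.hi
        return above and below


def _score_ranges() -> tuple[Interval, Interval]:
    # excellent 0–0.3 closed; medium (0.3, 0.7] excludes the shared boundary
    return Interval(0.0, 0.3), Interval(0.3, 0.7, lo_closed=False)


def default_range_table() -> dict[str, tuple[Interval, Interval | None]]:
    """The built-in excellent/medium ranges for the ten screened properties.

    Caco-2 permeability is excellent above −5.15 (strict); the bioavailability,
    P-gp substrate/inhibitor, half-life and FDA maximum-daily-dose scores are
    excellent in 0–0.3 with a medium band up to 0.7; volume of distribution is
    excellent in 0.04–20 L/kg; synthetic accessibility is excellent below 6
    (strict); logP in 0–3 and logS in −4–0.5 log mol/L. Properties without a
    medium band fail outright outside their excellent range.
    """
    inf = math.inf
    table: dict[str, tuple[Interval, Interval | None]] = {
        "caco2": (Interval(-5.15, inf, lo_closed=False, hi_closed=False), None),
        "f20": _score_ranges(),
        "pgp_sub": _score_ranges(),
        "pgp_inh": _score_ranges(),
        "vd": (Interval(0.04, 20.0), None),
        "t_half": _score_ranges(),
        "fdamdd": _score_ranges(),
        "sas": (Interval(-inf, 6.0, lo_closed=False, hi_closed=False), None),
        "logp": (Interval(0.0, 3.0), None),
        "logs": (Interval(-4.0, 0.5), None),
    }
    return table


@dataclass
class RangeTable:
    """Excellent and optional medium interval per screened property."""

    ranges: dict[str, tuple[Interval, Interval | None]] = field(
        default_factory=default_range_table
    )

    def classify(self, name: str, value: float) -> str:
        try:
            excellent, medium = self.ranges[name]
        except KeyError:
            raise DataError(f"no range defined for property {name!r}") from None
        if excellent.contains(value):
            return "excellent"
        if medium is not None and medium.contains(value):
            return "medium"
        return "fail"


@dataclass
class PropertyProfile:
    """The ten screened property values of one candidate.

    caco2: log cm/s permeability; f20, pgp_sub, pgp_inh, t_half, fdamdd:
    unitless predictor scores in [0, 1]; vd: L/kg; sas: synthetic
    accessibility score; logp, logs: log mol/L.
    """

    id: str
    caco2: float
    f20: float
    pgp_sub: float
    pgp_inh: float
    vd: float
    t_half: float
    fdamdd: float
    sas: float
    logp: float
    logs: float

    def __post_init__(self) -> None:
        for name in PROPERTY_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"profile {self.id!r}: property {name} is not finite")
        for name in SCORE_PROPERTIES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(
                    f"profile {self.id!r}: score property {name} must lie in [0, 1], got {v}"
                )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PROPERTY_NAMES}


@dataclass
class ScreenVerdict:
    """Per-property classes plus the derived overall pass and percent-excellent."""

    id: str
    classes: dict[str, str]
    overall_pass: bool
    pct_excellent: float


def classify_properties(profile: PropertyProfile, ranges: RangeTable | None = None) -> ScreenVerdict:
    """Classify each property as excellent/medium/fail and derive the verdict.

    Overall pass requires at least medium on all ten properties;
    pct_excellent is 100 × (#excellent) / 10.
    """
    if ranges is None:
        ranges = RangeTable()
    classes = {name: ranges.classify(name, getattr(profile, name)) for name in PROPERTY_NAMES}
    n_exc = sum(c == "excellent" for c in classes.values())
    return ScreenVerdict(
        id=profile.id,
        classes=classes,
        overall_pass=all(c != "fail" for c in classes.values()),
        pct_excellent=100.0 * n_exc / len(PROPERTY_NAMES),
    )


def affinity_filter(panel: pd.DataFrame) -> pd.Series:
    """Boolean per molecule: tight on DAT/NET/SERT, weak on hERG (all strict).

    ``panel`` must have kcal/mol columns DAT, NET, SERT, hERG (one row per
    molecule, as produced by ``predict_panel``).
    """
    required = list(TRANSPORTER_TARGETS) + ["hERG"]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise DataError(f"affinity panel lacks column(s) {missing}")
    ok = pd.Series(True, index=panel.index)
    for t in TRANSPORTER_TARGETS:
        ok &= panel[t] < TRANSPORTER_MAX_DELTA_G
    ok &= panel["hERG"] > HERG_MIN_DELTA_G
    return ok


def lipinski_filter(m: MoleculeRecord) -> tuple[bool, dict[str, bool]]:
    """Lipinski's rule of five on a molecule's descriptors.

    Returns (overall pass, per-criterion flags). All four inequalities are
    inclusive: MW ≤ 500 Da, logP ≤ 5, nHD ≤ 5, nHA ≤ 10.
    """
    missing = [k for k in LIPINSKI_BOUNDS if k not in m.descriptors]
    if missing:
        raise DataError(f"molecule {m.id!r} lacks descriptor(s) {missing}")
    flags = {k: m.descriptors[k] <= bound for k, bound in LIPINSKI_BOUNDS.items()}
    return all(flags.values()), flags


def novelty_filter(
    candidates: Sequence[tuple[MoleculeRecord, np.ndarray]],
    reference_vectors: Sequence[np.ndarray],
    max_sim: float = 0.5,
) -> list[bool]:
    """Per candidate: True iff cosine similarity to every reference is < max_sim."""
    from sgnc.similarity import cosine_similarity  # local import avoids a module cycle

    out = []
    for _, z in candidates:
        out.append(all(cosine_similarity(z, r) < max_sim for r in reference_vectors))
    return out


def rank_leads(verdicts: Sequence[ScreenVerdict]) -> list[ScreenVerdict]:
    """Overall-passing verdicts sorted by pct_excellent descending, ties by id."""
    if len(verdicts) == 0:
        raise DataError("cannot rank an empty verdict list")
    passing = [v for v in verdicts if v.overall_pass]
    return sorted(passing, key=lambda v: (-v.pct_excellent, v.id))
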