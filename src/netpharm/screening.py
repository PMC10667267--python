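"""Drug-likeness (QED) and oral-bioavailability (Veber) screening.

The expected active compounds (EAC) of a phytochemical library are selected
by two orthogonal filters:

* **QED** — the quantitative estimate of drug-likeness: each of eight
  physicochemical descriptors (MW, ALOGP, HBA, HBD, TPSA, ROTB, aromatic
  rings, structural alerts) is mapped through a normalized asymmetric
  double-sigmoid desirability function d_i(x) in (0, 1], and the score is the
  weighted geometric mean ``QED = exp(sum w_i ln d_i / sum w_i)``.
* **Veber's rule** — oral bioavailability: rotatable bonds <= 10 and
  topological polar surface area <= 140 A^2.

A compound is an EAC when QED >= 0.3 (inclusive) and the Veber verdict is
TRUE. Descriptor values are taken from the input table; when a structure
column is present and RDKit is installed they can instead be computed from
SMILES, but table-supplied values always win.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .mass_spec import ElementalFormula

__all__ = [
    "DescriptorSet",
    "DesirabilityParams",
    "CompoundRecord",
    "DESCRIPTOR_NAMES",
    "load_qed_params",
    "load_qed_weights",
    "desirability",
    "weighted_geometric_mean",
    "qed_score",
    "veber_pass",
    "screen_compounds",
    "select_eac",
]

DESCRIPTOR_NAMES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

QED_CUTOFF_DEFAULT = 0.3
VEBER_ROTB_MAX = 10
VEBER_TPSA_MAX = 140.0


@dataclass(frozen=True)
class DesirabilityParams:
    """Coefficients of one asymmetric double-sigmoid desirability function.

    raw(x) = a + b / (1 + exp(-(x - c + d/2)/e)) * (1 - 1/(1 + exp(-(x - c - d/2)/f)))

    and the returned desirability is raw(x)/dmax, where dmax is the maximum
    of raw over the descriptor range (supplied with published tables, or
    found numerically if omitted).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    dmax: Optional[float] = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.e == 0 or self.f == 0:
            raise ValueError("degenerate sigmoid: slope parameters e and f must be non-zero")
        if self.weight < 0:
            raise ValueError("desirability weight must be non-negative")

    def raw(self, x: float) -> float:
        exp1 = 1.0 + math.exp(-(x - self.c + self.d / 2.0) / self.e)
        exp2 = 1.0 + math.exp(-(x - self.c - self.d / 2.0) / self.f)
        return self.a + self.b / exp1 * (1.0 - 1.0 / exp2)

    def _dmax(self) -> float:
        if self.dmax is not None:
            return self.dmax
        # the raw ADS is unimodal; scan then refine around the best point
        import numpy as np
        from scipy.optimize import minimize_scalar

        span = max(abs(self.c), 1.0)
        grid = np.linspace(self.c - 20 * span, self.c + 20 * span, 4001)
        best = grid[int(np.argmax([self.raw(g) for g in grid]))]
        step = grid[1] - grid[0]
        res = minimize_scalar(
            lambda x: -self.raw(x), bracket=None, bounds=(best - step, best + step), method="bounded"
        )
        return -res.fun


def desirability(x: float, p: DesirabilityParams) -> float:
    """Normalized desirability of descriptor value ``x`` under ``p``, in (0, 1]."""
    return p.raw(x) / p._dmax()


@dataclass(frozen=True)
class DescriptorSet:
    """The eight physicochemical descriptors scored by QED.

    mw in Da, tpsa in A^2, alogp unitless; hba/hbd/rotb/arom/alerts counts.
    """

    mw: float
    alogp: float
    hba: int
    hbd: int
    tpsa: float
    rotb: int
    arom: int
    alerts: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.tpsa < 0:
            raise ValueError("tpsa must be non-negative")
        for name in ("hba", "hbd", "rotb", "arom", "alerts"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def as_ordered(self) -> tuple:
        """Values in canonical order (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS)."""
        return (self.mw, self.alogp, self.hba, self.hbd, self.tpsa, self.rotb, self.arom, self.alerts)


@dataclass
class CompoundRecord:
    """One isolate: identifiers, descriptors, and (once screened) verdicts."""

    compound_id: str
    name: str
    descriptors: DescriptorSet
    formula: Optional[ElementalFormula] = None
    qed: Optional[float] = None
    ob_pass: Optional[bool] = None
    is_eac: Optional[bool] = None


@lru_cache(maxsize=1)
def _load_tables() -> dict:
    with resources.files("netpharm.data").joinpath("qed_coefficients.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def load_qed_params() -> Dict[str, DesirabilityParams]:
    """The published per-descriptor desirability coefficient table."""
    raw = _load_tables()["ads"]
    return {
        name: DesirabilityParams(p["a"], p["b"], p["c"], p["d"], p["e"], p["f"], p["dmax"])
        for name, p in raw.items()
    }


def load_qed_weights(mode: str = "mean") -> Dict[str, float]:
    """Published weighting scheme: ``unweighted``, ``mean`` (default) or ``max``."""
    weights = _load_tables()["weights"]
    if mode == "weighted":  # CLI-friendly alias for the mean-weights default
        mode = "mean"
    if mode not in weights:
        raise ValueError(f"unknown QED weight mode {mode!r}; choose from {sorted(weights)}")
    return weights[mode]


def weighted_geometric_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """exp(sum w_i ln v_i / sum w_i); zero-weight entries are skipped.

    Invariant to rescaling all weights by a positive constant; equals every
    value when they are all identical.
    """
    num = 0.0
    den = 0.0
    for v, w in zip(values, weights):
        if w < 0:
            raise ValueError("weights must be non-negative")
        if w == 0.0:
            continue
        if v <= 0.0:
            raise ValueError(f"geometric mean requires positive values, got {v}")
        num += w * math.log(v)
        den += w
    if den <= 0.0:
        raise ValueError("at least one weight must be positive")
    return math.exp(num / den)


def qed_score(
    d: DescriptorSet,
    params: Optional[Mapping[str, DesirabilityParams]] = None,
    mode: str = "mean",
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Weighted geometric mean of the eight desirabilities, in (0, 1].

    ``mode`` selects the published weighting scheme; ``unweighted`` is the
    plain geometric mean; an explicit ``weights`` mapping overrides the mode.
    The score is invariant to rescaling all weights.
    """
    params = params or load_qed_params()
    weights = dict(weights) if weights is not None else load_qed_weights(mode)
    values = [desirability(x, params[name]) for name, x in zip(DESCRIPTOR_NAMES, d.as_ordered())]
    return weighted_geometric_mean(values, [weights[name] for name in DESCRIPTOR_NAMES])


def veber_pass(d: DescriptorSet) -> bool:
    """Oral-bioavailability verdict: ROTB <= 10 and TPSA <= 140 A^2 (inclusive)."""
    if d.rotb is None or d.tpsa is None:  # defensive: dataclass enforces presence
        missing = "rotb" if d.rotb is None else "tpsa"
        raise ValueError(f"missing descriptor {missing!r} required by Veber's rule")
    return d.rotb <= VEBER_ROTB_MAX and d.tpsa <= VEBER_TPSA_MAX


def screen_compounds(
    compounds: Iterable[CompoundRecord],
    qed_cutoff: float = QED_CUTOFF_DEFAULT,
    qed_mode: str = "mean",
) -> List[CompoundRecord]:
    """Compute QED, the Veber verdict, and the EAC flag for every record.

    Returns new records in input order; ``is_eac = (qed >= qed_cutoff) and ob_pass``.
    """
    params = load_qed_params()
    out = []
    for rec in compounds:
        q = qed_score(rec.descriptors, params, mode=qed_mode)
        ob = veber_pass(rec.descriptors)
        out.append(replace(rec, qed=q, ob_pass=ob, is_eac=(q >= qed_cutoff) and ob))
    return out


def select_eac(
    compounds: Sequence[CompoundRecord],
    qed_cutoff: float = QED_CUTOFF_DEFAULT,
) -> List[CompoundRecord]:
    """Re-flag and return the expected active compounds, preserving input order.

    Requires ``qed`` and ``ob_pass`` to be present (see :func:`screen_compounds`).
    Inclusive cutoff: a compound at exactly the QED cutoff is selected.
    """
    selected = []
    for rec in compounds:
        if rec.qed is None or rec.ob_pass is None:
            raise ValueError(f"compound {rec.compound_id!r} has not been screened")
        rec.is_eac = (rec.qed >= qed_cutoff) and rec.ob_pass
        if rec.is_eac:
            selected.append(rec)
    return selected
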