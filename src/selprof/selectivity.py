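"""Selectivity arithmetic: SI, ligand classes, SR and cluster S_scores.

The selectivity index of a ligand measured against an on-target and an
off-target isoform is the ratio of inhibition constants

    SI = Ki(off) / Ki(on)

so SI = 10 means ten-fold preference for the on-target. Ligands are
classified as on-target selective (``L_on``, SI > 5), off-target
selective (``L_off``, SI < 0.2) or non-selective (``L_ns``); boundary
values fall in ``L_ns`` because both inequalities are strict. A
cluster's selectivity score aggregates the class counts:

    S_score = 100 * (n_on - n_off) / (n_on + n_off + n_ns)

ranging from +100 (purely on-selective) to -100 (purely off-selective).
In double-selectivity mode two S_scores are computed against two
on-targets sharing one off-target and summed into a double S_score in
[-200, +200].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "LigandClass",
    "SelectivityConfig",
    "LigandSelectivity",
    "selectivity_index",
    "classify",
    "selectivity_ratio",
    "s_score",
    "double_s_score",
    "compute_selectivities",
]


class LigandClass(enum.Enum):
    L_ON = "L_on"
    L_OFF = "L_off"
    L_NS = "L_ns"


@dataclass(frozen=True)
class SelectivityConfig:
    """Targets and thresholds of one selectivity analysis."""

    on_target: str
    off_target: str
    si_on_threshold: float = 5.0
    si_off_threshold: float = 0.2
    s_score_cutoff: float = 70.0
    secondary_on_target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.on_target == self.off_target:
            raise ValueError("on_target and off_target must differ")
        if not self.si_off_threshold < self.si_on_threshold:
            raise ValueError("si_off_threshold must be below si_on_threshold")

    @property
    def double_mode(self) -> bool:
        return self.secondary_on_target is not None


@dataclass(frozen=True)
class LigandSelectivity:
    """Per-ligand SI and class for one on/off target pair."""

    cid: str
    si: float
    klass: LigandClass


def selectivity_index(ki_off: float, ki_on: float) -> float:
    """SI = Ki(off-target) / Ki(on-target), both in nM."""
    if not (ki_off > 0 and ki_on > 0):
        raise ValueError(f"Ki values must be positive, got {ki_off}, {ki_on}")
    return ki_off / ki_on


def classify(si: float, config: SelectivityConfig) -> LigandClass:
    """Assign a ligand class from its SI; thresholds are strict."""
    if not si > 0:
        raise ValueError(f"SI must be positive, got {si}")
    if si > config.si_on_threshold:
        return LigandClass.L_ON
    if si < config.si_off_threshold:
        return LigandClass.L_OFF
    return LigandClass.L_NS


def selectivity_ratio(si_a: float, si_b: float) -> float:
    """SR = log10(SI_a) - log10(SI_b); 0 means identical selectivity."""
    if not (si_a > 0 and si_b > 0):
        raise ValueError("SI values must be positive")
    return math.log10(si_a) - math.log10(si_b)


def s_score(n_on: int, n_off: int, n_ns: int) -> float:
    """Cluster selectivity score, 100 * (n_on - n_off) / cluster size."""
    for n in (n_on, n_off, n_ns):
        if n < 0 or int(n) != n:
            raise ValueError("class counts must be non-negative integers")
    total = n_on + n_off + n_ns
    if total == 0:
        raise ValueError("cannot score an empty cluster")
    return 100.0 * (n_on - n_off) / total


def double_s_score(s1: float, s2: float) -> float:
    """Sum of the two per-on-target S_scores, in [-200, +200]."""
    for s in (s1, s2):
        if not -100.0 <= s <= 100.0:
            raise ValueError(f"S_score {s} outside [-100, 100]")
    return s1 + s2


def compute_selectivities(
    entries: Sequence,
    config: SelectivityConfig,
    *,
    secondary: bool = False,
) -> dict[str, LigandSelectivity]:
    """SI and class for every ligand, keyed by CID.

    With ``secondary=True`` the SI is computed against
    ``config.secondary_on_target`` instead of ``config.on_target`` (the
    off-target is shared). Ligands lacking a Ki for either isoform are
    silently omitted; subset selection is the caller's concern.
    """
    on = config.secondary_on_target if secondary else config.on_target
    if on is None:
        raise ValueError("secondary selectivity requested without a "
                         "secondary_on_target")
    out: dict[str, LigandSelectivity] = {}
    for e in entries:
        ki_on = e.ki_by_target.get(on)
        ki_off = e.ki_by_target.get(config.off_target)
        if ki_on is None or ki_off is None:
            continue
        si = selectivity_index(ki_off, ki_on)
        out[e.cid] = LigandSelectivity(cid=e.cid, si=si,
                                       klass=classify(si, config))
    return out
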