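"""Curation of raw bioactivity records into a per-compound Ki table.

The pipeline follows the order metric filter -> provenance filter ->
per-(compound, isoform) replicate aggregation -> merge per compound ->
zinc-binding-group substructure filter, and emits an audit of the
record/ligand counts surviving each stage.

Replicate aggregation averages raw nM values after removing outliers by
a modified z-score on log10(Ki) (median/MAD based, default threshold
3.5); Ki error is multiplicative, so the outlier test runs on the log
scale while the reported mean stays on the nM scale. Both choices are
configurable (``outlier_rule``, ``mean``).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .datamodel import BioactivityRecord, LigandEntry, Metric

__all__ = [
    "SULFONAMIDE_SMARTS",
    "CurationConfig",
    "CurationAudit",
    "filter_by_metric",
    "filter_by_provenance",
    "aggregate_ki",
    "substructure_filter",
    "curate",
]

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")  # unparsable decoys are reported, not printed

#: Sulfonamide-type zinc-binding group; deliberately loose so that
#: sulfamates (O-linked) and sulfamides (N-linked) also match.
SULFONAMIDE_SMARTS = "[#16](=[OX1])(=[OX1])[NX3]"


@dataclass
class CurationConfig:
    """Knobs of the curation pipeline."""

    metric_keep: frozenset[Metric] = frozenset({Metric.KI})
    pmid_whitelist: Optional[frozenset[str]] = None
    outlier_zmax: float = 3.5
    outlier_rule: str = "modified-z"  # none | modified-z | trim-fraction
    trim_fraction: float = 0.1
    mean: str = "arithmetic"  # arithmetic | geometric
    substructure_smarts: str = SULFONAMIDE_SMARTS
    min_value_nM: Optional[float] = None
    max_value_nM: Optional[float] = None

    def __post_init__(self) -> None:
        if isinstance(self.metric_keep, (set, list, tuple)):
            self.metric_keep = frozenset(self.metric_keep)
        if self.pmid_whitelist is not None and not isinstance(
            self.pmid_whitelist, frozenset
        ):
            self.pmid_whitelist = frozenset(self.pmid_whitelist)
        if not self.outlier_zmax > 0:
            raise ValueError("outlier_zmax must be positive")
        if self.outlier_rule not in ("none", "modified-z", "trim-fraction"):
            raise ValueError(f"unknown outlier rule {self.outlier_rule!r}")
        if self.mean not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown mean {self.mean!r}")
        if Chem.MolFromSmarts(self.substructure_smarts) is None:
            raise ValueError(
                f"invalid substructure SMARTS: {self.substructure_smarts!r}")

    @property
    def substructure_query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.substructure_smarts)


@dataclass
class CurationAudit:
    """Per-stage survivor counts; input = survivors + removals at each stage."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append((stage, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, i, o, i - o) for s, i, o in self.stages],
            columns=["stage", "in", "out", "removed"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_by_metric(
    records: Sequence[BioactivityRecord], config: CurationConfig
) -> list[BioactivityRecord]:
    """Keep only records whose assay metric is in ``metric_keep``."""
    kept = [r for r in records if r.metric in config.metric_keep]
    removed = Counter(r.metric.value for r in records
                      if r.metric not in config.metric_keep)
    for metric, n in sorted(removed.items()):
        logger.info("metric filter: removed %d %s record(s)", n, metric)
    if not kept:
        logger.warning("metric filter: no records left")
    return kept


def filter_by_provenance(
    records: Sequence[BioactivityRecord], config: CurationConfig
) -> list[BioactivityRecord]:
    """Keep records whose PMID is whitelisted; pass-through when no list."""
    if config.pmid_whitelist is None:
        return list(records)
    kept = [r for r in records if r.pmid in config.pmid_whitelist]
    logger.info("provenance filter: %d -> %d records", len(records), len(kept))
    if not kept:
        logger.warning("provenance filter: no records left")
    return kept


def _modified_z(values_log: np.ndarray) -> np.ndarray:
    """Modified z-scores (Iglewicz-Hoaglin) of log10 activity values.

    Uses 0.6745 * (x - median)/MAD; with a degenerate MAD of zero it
    falls back to the mean absolute deviation (scaled by 1.253314), and
    reports all-zero scores when that is zero too (all values equal).
    """
    med = np.median(values_log)
    dev = values_log - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return 0.6745 * dev / mad
    mean_ad = np.mean(np.abs(dev))
    if mean_ad > 0:
        return dev / (1.253314 * mean_ad)
    return np.zeros_like(dev)


def aggregate_ki(
    values_nM: Sequence[float], config: Optional[CurationConfig] = None
) -> float:
    """Mean Ki (nM) of replicate measurements after outlier removal.

    Outliers are flagged on log10(Ki) by the configured rule; the mean
    of the surviving raw nM values is returned (geometric mean when
    configured). If the outlier rule would discard everything, the
    median of the original values is kept instead.
    """
    if config is None:
        config = CurationConfig()
    values = np.asarray(list(values_nM), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty replicate set")
    if np.any(values <= 0):
        raise ValueError("Ki values must be positive")

    logs = np.log10(values)
    if config.outlier_rule == "none" or values.size == 1:
        keep = np.ones(values.size, dtype=bool)
    elif config.outlier_rule == "modified-z":
        keep = np.abs(_modified_z(logs)) <= config.outlier_zmax
    else:  # trim-fraction: symmetric trim on the log scale
        k = int(np.floor(config.trim_fraction * values.size))
        order = np.argsort(logs, kind="stable")
        keep = np.ones(values.size, dtype=bool)
        if k > 0:
            keep[order[:k]] = False
            keep[order[-k:]] = False
    if not keep.any():
        return float(np.median(values))
    survivors = values[keep]
    if config.mean == "geometric":
        return float(10 ** np.mean(np.log10(survivors)))
    return float(np.mean(survivors))


def substructure_filter(
    entries: Sequence[LigandEntry],
    config: CurationConfig,
    diagnostics: Optional[list[str]] = None,
) -> list[LigandEntry]:
    """Keep ligands whose structure matches the zinc-binding-group SMARTS.

    Unparsable SMILES are removed with a diagnostic rather than raising:
    raw tables routinely carry a few broken strings.
    """
    query = config.substructure_query
    kept = []
    for e in entries:
        mol = Chem.MolFromSmiles(e.smiles)
        if mol is None:
            if diagnostics is not None:
                diagnostics.append(
                    f"substructure: unparsable SMILES for CID {e.cid}: {e.smiles!r}")
            continue
        if mol.HasSubstructMatch(query):
            kept.append(e)
    return kept


def curate(
    records: Sequence[BioactivityRecord], config: Optional[CurationConfig] = None
) -> tuple[list[LigandEntry], CurationAudit]:
    """Full curation pipeline from raw records to a ligand table.

    Returns the curated entries (one per CID, sorted by CID) and a
    :class:`CurationAudit` with counts surviving every stage. The first
    three stages count records; from aggregation onwards counts are
    ligands (unique CIDs).
    """
    if config is None:
        config = CurationConfig()
    audit = CurationAudit()

    stage1 = filter_by_metric(records, config)
    audit.add("metric", len(records), len(stage1))

    stage2 = filter_by_provenance(stage1, config)
    audit.add("provenance", len(stage1), len(stage2))

    lo, hi = config.min_value_nM, config.max_value_nM
    stage3 = [
        r for r in stage2
        if (lo is None or r.value_nM >= lo) and (hi is None or r.value_nM <= hi)
    ]
    audit.add("value_bounds", len(stage2), len(stage3))

    # replicate aggregation per (cid, target), then merge per cid
    grouped: dict[tuple[str, str], list[BioactivityRecord]] = defaultdict(list)
    for r in stage3:
        grouped[(r.cid, r.target)].append(r)
    per_cid: dict[str, dict[str, float]] = defaultdict(dict)
    smiles_by_cid: dict[str, str] = {}
    for (cid, target), group in grouped.items():
        per_cid[cid][target] = aggregate_ki([r.value_nM for r in group], config)
        canon = _canonical_or_raw(group[0].smiles)
        prev = smiles_by_cid.get(cid)
        if prev is None:
            smiles_by_cid[cid] = canon
        elif prev != canon:
            audit.diagnostics.append(
                f"merge: CID {cid} carries conflicting SMILES; kept {prev!r}")
    entries = [
        LigandEntry(cid=cid, smiles=smiles_by_cid[cid], ki_by_target=dict(ki))
        for cid, ki in sorted(per_cid.items())
    ]
    audit.add("aggregate_merge", len(stage3), len(entries))

    final = substructure_filter(entries, config, audit.diagnostics)
    audit.add("substructure", len(entries), len(final))
    return final, audit


def _canonical_or_raw(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return smiles if mol is None else Chem.MolToSmiles(mol)
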