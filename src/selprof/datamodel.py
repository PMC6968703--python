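"""Domain types and table I/O for bioactivity data and profiling reports.

The central objects mirror the stages of a selectivity-profiling run:
raw assay measurements (:class:`BioactivityRecord`), curated per-compound
Ki tables (:class:`LigandEntry`), fingerprint bit vectors
(:class:`Fingerprint`), pairwise Tanimoto matrices
(:class:`PairwiseMatrix`) and scored clusters (:class:`ClusterReport`).

All tables are plain CSV/TSV with a header row; activity values are
nanomolar throughout.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = [
    "Metric",
    "BioactivityRecord",
    "LigandEntry",
    "Fingerprint",
    "PairwiseMatrix",
    "ClusterReport",
    "RowDiagnostic",
    "SchemaError",
    "read_bioactivity_table",
    "write_ligand_table",
    "read_ligand_table",
    "write_cluster_report",
    "write_ligand_sdf",
]

#: Canonical column names of a bioactivity table. PubChem-style exports
#: with different headers are accommodated through ``column_map``.
REQUIRED_COLUMNS = ("cid", "smiles", "target", "metric", "value_nM")
OPTIONAL_COLUMNS = ("aid", "pmid", "units")

_KI_COL = re.compile(r"^Ki \[(?P<target>.+)\]$")

#: Unit label -> factor converting to nM.
_UNIT_FACTORS = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,  # micro sign
    "μm": 1e3,  # greek mu
    "mm": 1e6,
    "m": 1e9,
}


class Metric(enum.Enum):
    """Assay readout type attached to an activity value."""

    KI = "Ki"
    IC50 = "IC50"
    KD = "Kd"
    KM = "Km"
    EC50 = "EC50"

    @classmethod
    def parse(cls, text: str) -> "Metric":
        t = str(text).strip().lower()
        for m in cls:
            if m.value.lower() == t:
                return m
        raise ValueError(f"unknown assay metric {text!r}")


class SchemaError(ValueError):
    """A table is missing required columns or is structurally unusable."""


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected input row: 0-based data-row index plus the reason."""

    row: int
    reason: str


@dataclass(frozen=True)
class BioactivityRecord:
    """One raw assay measurement for one compound against one isoform."""

    cid: str
    smiles: str
    target: str
    metric: Metric
    value_nM: float
    aid: str = ""
    pmid: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not self.value_nM > 0:
            raise ValueError(f"value_nM must be positive, got {self.value_nM}")
        if not isinstance(self.metric, Metric):
            raise TypeError("metric must be a Metric")


@dataclass
class LigandEntry:
    """A curated ligand: one row per CID with mean Ki (nM) per isoform."""

    cid: str
    smiles: str
    ki_by_target: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ki_by_target:
            raise ValueError(f"ligand {self.cid}: ki_by_target must be non-empty")
        for target, ki in self.ki_by_target.items():
            if not ki > 0:
                raise ValueError(f"ligand {self.cid}: Ki for {target} must be > 0")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit vector; ``bits`` holds the set-bit indices."""

    scheme: str  # "path" | "keys"
    nbits: int
    bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.scheme not in ("path", "keys"):
            raise ValueError(f"unknown fingerprint scheme {self.scheme!r}")
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit index out of range")

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=np.uint8)
        if self.bits:
            arr[sorted(self.bits)] = 1
        return arr


@dataclass
class PairwiseMatrix:
    """Symmetric N x N Tanimoto similarity (Ti) or distance (Td) matrix."""

    kind: str  # "similarity" | "distance"
    values: np.ndarray
    ligand_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ligand_order)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ligand_order")
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("matrix values must lie in [0, 1]")
        expected_diag = 1.0 if self.kind == "similarity" else 0.0
        if n and not np.allclose(np.diag(self.values), expected_diag):
            raise ValueError(f"{self.kind} matrix diagonal must be {expected_diag}")

    @property
    def n(self) -> int:
        return len(self.ligand_order)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy's condensed ordering."""
        return squareform(self.values, checks=False)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.ligand_order, columns=self.ligand_order
        ).to_csv(path, index_label="cid")

    def to_condensed_csv(self, path: str | Path, *, scheme: str = "",
                         hash_version: str = "") -> None:
        """Condensed vector plus a JSON sidecar with the ligand order."""
        path = Path(path)
        np.savetxt(path, self.condensed(), fmt="%.10g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "ligand_order": self.ligand_order,
            "kind": self.kind,
            "scheme": scheme,
            "hash_version": hash_version,
        }, indent=1))


@dataclass
class ClusterReport:
    """A scored cluster: member CIDs, class counts and S_score(s)."""

    cluster_id: int
    members: list[str]
    counts: tuple[int, int, int]  # (n_on, n_off, n_ns)
    s_score: float
    s_score_secondary: Optional[float] = None
    double_s_score: Optional[float] = None

    def __post_init__(self) -> None:
        if sum(self.counts) != len(self.members):
            raise ValueError(
                f"cluster {self.cluster_id}: class counts {self.counts} do not "
                f"sum to member count {len(self.members)}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _to_nM(value: float, units: Optional[str]) -> float:
    if units is None or (isinstance(units, float) and np.isnan(units)) or units == "":
        return value
    factor = _UNIT_FACTORS.get(str(units).strip().lower())
    if factor is None:
        raise ValueError(f"unknown unit {units!r}")
    return value * factor


def read_bioactivity_table(
    path: str | Path,
    fmt: Optional[str] = None,
    *,
    column_map: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> tuple[list[BioactivityRecord], list[RowDiagnostic]]:
    """Read a raw bioactivity table.

    Parameters
    ----------
    path
        CSV or TSV file with a header row naming at least the columns
        ``cid, smiles, target, metric, value_nM``.
    fmt
        ``"csv"`` or ``"tsv"``; inferred from the file suffix when omitted.
    column_map
        Maps canonical column names to the actual header names, for
        exports using different labels.
    strict
        If True, the first malformed row raises instead of being
        collected as a diagnostic.

    Returns
    -------
    (records, diagnostics)
        Every data row lands in exactly one of the two lists, so
        ``len(records) + len(diagnostics)`` equals the data-row count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bioactivity table not found: {path}")
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    colmap = {name: name for name in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [c for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) "
            + ", ".join(colmap[c] for c in missing)
        )
    has_units = colmap["units"] in df.columns

    records: list[BioactivityRecord] = []
    diagnostics: list[RowDiagnostic] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            cid = row[colmap["cid"]].strip()
            smiles = row[colmap["smiles"]].strip()
            target = row[colmap["target"]].strip()
            if not cid or not smiles or not target:
                raise ValueError("missing CID, SMILES or target")
            raw_value = row[colmap["value_nM"]].strip()
            if not raw_value:
                raise ValueError("missing activity value")
            value = float(raw_value)
            if has_units:
                value = _to_nM(value, row[colmap["units"]])
            records.append(BioactivityRecord(
                cid=cid,
                smiles=smiles,
                target=target,
                metric=Metric.parse(row[colmap["metric"]]),
                value_nM=value,
                aid=row.get(colmap["aid"], "").strip(),
                pmid=(row.get(colmap["pmid"], "").strip() or None),
            ))
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"{path} row {i}: {exc}") from exc
            diagnostics.append(RowDiagnostic(row=i, reason=str(exc)))
    return records, diagnostics


def _ki_column(target: str) -> str:
    return f"Ki [{target}]"


def write_ligand_table(
    entries: Sequence[LigandEntry],
    path: str | Path,
    *,
    isoforms: Optional[Sequence[str]] = None,
) -> None:
    """Write a curated ligand table in wide format.

    One row per CID with columns ``cid, smiles`` and one ``Ki [<isoform>]``
    column per isoform (blank where a ligand was not measured). The
    isoform column set defaults to the union observed across entries;
    pass ``isoforms`` to force a fixed set of columns.
    """
    if not entries:
        raise ValueError("entries must be non-empty")
    cids = [e.cid for e in entries]
    if len(set(cids)) != len(cids):
        dupes = sorted({c for c in cids if cids.count(c) > 1})
        raise ValueError(f"duplicate CID(s) in ligand table: {', '.join(dupes)}")
    if isoforms is None:
        seen: dict[str, None] = {}
        for e in entries:
            for t in e.ki_by_target:
                seen.setdefault(t, None)
        isoforms = sorted(seen)
    rows = []
    for e in entries:
        row: dict[str, object] = {"cid": e.cid, "smiles": e.smiles}
        for t in isoforms:
            row[_ki_column(t)] = e.ki_by_target.get(t, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ligand_table(path: str | Path) -> list[LigandEntry]:
    """Read back a wide-format curated ligand table."""
    df = pd.read_csv(path, dtype={"cid": str}, keep_default_na=False)
    targets = {}
    for col in df.columns:
        m = _KI_COL.match(col)
        if m:
            targets[col] = m.group("target")
    entries = []
    for _, row in df.iterrows():
        ki = {
            t: float(row[col]) for col, t in targets.items()
            if str(row[col]).strip() != ""
        }
        entries.append(LigandEntry(cid=str(row["cid"]), smiles=row["smiles"],
                                   ki_by_target=ki))
    return entries


def write_cluster_report(
    reports: Sequence[ClusterReport],
    entries: Sequence[LigandEntry],
    path: str | Path,
    *,
    on_target: str,
    off_target: str,
    secondary_on_target: Optional[str] = None,
) -> pd.DataFrame:
    """Write the long-format selective-cluster report.

    One row per cluster member with its Ki values, SI, selectivity class
    and the cluster's score(s); rows sorted by descending cluster score
    (double score in double-selectivity mode), then cluster id. Output
    format is CSV, or a spreadsheet when ``path`` ends in ``.xlsx``.
    Returns the report as a DataFrame.
    """
    by_cid = {e.cid: e for e in entries}
    double = secondary_on_target is not None
    rows = []
    for rep in reports:
        for cid in rep.members:
            entry = by_cid.get(cid)
            if entry is None:
                raise KeyError(f"cluster {rep.cluster_id}: CID {cid!r} not found "
                               "in the ligand table")
            ki_on = entry.ki_by_target[on_target]
            ki_off = entry.ki_by_target[off_target]
            si = ki_off / ki_on
            row: dict[str, object] = {
                "cluster_id": rep.cluster_id,
                "cid": cid,
                "smiles": entry.smiles,
                f"Ki [{on_target}]": ki_on,
                f"Ki [{off_target}]": ki_off,
                "SI": si,
                "class": _klass_label(si),
                "S_score": rep.s_score,
            }
            if double:
                ki_on2 = entry.ki_by_target[secondary_on_target]
                row[f"Ki [{secondary_on_target}]"] = ki_on2
                row["SI_secondary"] = ki_off / ki_on2
                row["S_score_secondary"] = rep.s_score_secondary
                row["double_S_score"] = rep.double_s_score
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        sort_col = "double_S_score" if double else "S_score"
        df = df.sort_values([sort_col, "cluster_id"],
                            ascending=[False, True], kind="stable")
        df = df.reset_index(drop=True)
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return df


def _klass_label(si: float) -> str:
    # mirror of selectivity.classify at default thresholds; kept local so
    # the report writer needs no config object
    from .selectivity import SelectivityConfig, classify

    return classify(si, SelectivityConfig(on_target="_on", off_target="_off")).value


def write_ligand_sdf(entries: Sequence[LigandEntry], path: str | Path) -> None:
    """Export curated ligands as SDF with one Ki property field per isoform."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    try:
        for e in entries:
            mol = Chem.MolFromSmiles(e.smiles)
            if mol is None:
                raise ValueError(f"unparsable SMILES for CID {e.cid}: {e.smiles!r}")
            mol.SetProp("_Name", e.cid)
            mol.SetProp("CID", e.cid)
            for target, ki in e.ki_by_target.items():
                mol.SetProp(f"Ki [{target}] (nM)", repr(ki))
            writer.write(mol)
    finally:
        writer.close()
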