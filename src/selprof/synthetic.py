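"""Synthetic bioactivity tables with planted structure-selectivity signal.

The generator emulates the shape of a PubChem-derived inhibition table
for the human carbonic anhydrase (hCA) isoforms: a handful of
sulfonamide-bearing scaffold families with R-group variation, replicate
Ki measurements with log-normal noise and occasional gross outliers,
and a fraction of decoy records (wrong assay metric, or compounds
without the sulfonamide zinc-binding group).

Selectivity is planted at the scaffold level: each family carries a
log10 SI offset against the off-target (default +1.5 for an
on-selective family, -1.5 for off-selective, 0 for promiscuous), and
every ligand in the family inherits it exactly. Per-ligand potency
jitter shifts both isoforms together, so in the noise-free limit the
true SI of every ligand equals 10^offset; realized SI varies only
through replicate noise and surviving outliers.

Every draw flows from a single integer seed, so a scenario is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .datamodel import BioactivityRecord, Metric

__all__ = [
    "SimScenario",
    "ScaffoldSeries",
    "SUBSTITUENTS",
    "SCAFFOLD_TEMPLATES",
    "generate_scaffold_series",
    "assign_ki",
    "simulate",
    "write_fixture",
]

#: All 13 hCA isoform labels commonly reported with Ki data, for
#: interface realism; the generator only populates the scenario's
#: targets.
ISOFORM_LABELS = (
    "hCA I", "hCA II", "hCA III", "hCA IV", "hCA Va", "hCA Vb", "hCA VI",
    "hCA VII", "hCA IX", "hCA XI", "hCA XII", "hCA XIII", "hCA XIV",
)

#: R-group vocabulary (kept small so brute-force fingerprint oracles
#: stay fast); each is substituted for ``{R}`` in a template.
SUBSTITUENTS = (
    "F", "Cl", "Br", "C", "CC", "CCC", "OC", "OCC", "N", "O", "C(F)(F)F", "C#N",
)

#: Scaffold templates: sulfonamide-type zinc binders with one aromatic
#: attachment point. The first three echo chemotypes seen among hCA
#: inhibitors: an aryl-sulfamate ureide, a benzamido-thiadiazole
#: sulfonamide, and a benzenesulfonamide with a Boc-protected tail.
SCAFFOLD_TEMPLATES = (
    "NS(=O)(=O)Oc1ccc(NC(=O)Nc2ccc({R})cc2)cc1",
    "O=C(Nc1nnc(S(N)(=O)=O)s1)c1ccc({R})cc1",
    "NS(=O)(=O)c1ccc(CNC(=O)OC(C)(C)C)c({R})c1",
    "NS(=O)(=O)c1ccc(S(=O)(=O)Nc2ccc({R})cc2)cc1",
    "NS(=O)(=O)c1ccc2cc({R})ccc2c1",
)

#: Ki-measured decoys without a sulfonamide zinc-binding group.
NON_SULFONAMIDE_DECOYS = (
    "Oc1ccccc1C(=O)O",
    "CC(=O)Oc1ccccc1C(=O)O",
    "Oc1ccc2ccccc2c1",
    "CCN(CC)C(=O)c1ccccc1",
)

_CLASS_OFFSETS = {"on_selective": 1.5, "off_selective": -1.5, "promiscuous": 0.0}


@dataclass(frozen=True)
class SimScenario:
    """Study conditions of one synthetic dataset."""

    n_scaffolds: int = 3
    ligands_per_scaffold: int = 8
    scaffold_classes: tuple[str, ...] = (
        "on_selective", "off_selective", "promiscuous")
    class_offsets: dict[str, float] = field(
        default_factory=lambda: dict(_CLASS_OFFSETS))
    on_target: str = "hCA IX"
    off_target: str = "hCA II"
    secondary_on_target: Optional[str] = None
    noise_sd: float = 0.15           # replicate noise, log10 Ki units
    ligand_jitter_sd: float = 0.3    # per-ligand potency shift, log10 units
    base_log_ki_range: tuple[float, float] = (1.0, 2.5)  # off-target, log10 nM
    replicate_range: tuple[int, int] = (3, 6)  # inclusive uniform
    outlier_rate: float = 0.05       # per replicate, x100 in value
    decoy_rate: float = 0.1          # decoy records per clean record
    pmid_pool: tuple[str, ...] = ("25000001", "25000002", "25000003")
    foreign_pmid_pool: tuple[str, ...] = ("19999901", "19999902")
    foreign_pmid_rate: float = 0.0   # fraction of records from foreign labs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "decoy_rate", "foreign_pmid_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if self.ligands_per_scaffold > len(SUBSTITUENTS):
            raise ValueError(
                f"at most {len(SUBSTITUENTS)} ligands per scaffold "
                "(one per R-group)")
        if self.n_scaffolds > len(SCAFFOLD_TEMPLATES):
            raise ValueError(f"at most {len(SCAFFOLD_TEMPLATES)} scaffolds")


@dataclass(frozen=True)
class ScaffoldSeries:
    """One scaffold family: planted class plus its enumerated ligands."""

    name: str
    template: str
    klass: str
    smiles: tuple[str, ...]
    cids: tuple[str, ...]


def _instantiate(template: str, r_group: str) -> str:
    if "{R}" not in template:
        raise ValueError(f"template lacks an {{R}} attachment point: {template!r}")
    smi = template.replace("{R}", r_group)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ValueError(f"template + R-group does not parse: {smi!r}")
    return Chem.MolToSmiles(mol)


def generate_scaffold_series(scenario: SimScenario) -> list[ScaffoldSeries]:
    """Enumerate the scaffold families of a scenario.

    Deterministic: R-groups are taken in vocabulary order, so the same
    scenario always yields the same SMILES. Classes cycle through
    ``scaffold_classes`` across scaffolds.
    """
    series = []
    cid_counter = 1000
    for s in range(scenario.n_scaffolds):
        template = SCAFFOLD_TEMPLATES[s]
        klass = scenario.scaffold_classes[s % len(scenario.scaffold_classes)]
        smiles = tuple(
            _instantiate(template, SUBSTITUENTS[i])
            for i in range(scenario.ligands_per_scaffold)
        )
        cids = tuple(f"CID{cid_counter + i}" for i in range(len(smiles)))
        cid_counter += 100
        series.append(ScaffoldSeries(
            name=f"scaffold_{s + 1}", template=template, klass=klass,
            smiles=smiles, cids=cids))
    return series


def assign_ki(
    series: Sequence[ScaffoldSeries],
    scenario: SimScenario,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[BioactivityRecord], pd.DataFrame]:
    """Draw replicate Ki records for every ligand plus decoys.

    Returns the records and a ground-truth table with one row per
    ligand or decoy compound: cid, scaffold, planted class, planted
    log10 SI offset, true Ki per populated isoform, and an ``is_decoy``
    flag.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    on_targets = [scenario.on_target]
    if scenario.secondary_on_target is not None:
        on_targets.append(scenario.secondary_on_target)

    records: list[BioactivityRecord] = []
    truth_rows: list[dict] = []
    aid_counter = 500000

    def draw_pmid() -> str:
        if scenario.foreign_pmid_rate > 0 and rng.random() < scenario.foreign_pmid_rate:
            return str(rng.choice(scenario.foreign_pmid_pool))
        return str(rng.choice(scenario.pmid_pool))

    for fam in series:
        offset = scenario.class_offsets[fam.klass]
        lo, hi = scenario.base_log_ki_range
        base_log_off = rng.uniform(lo, hi)
        for cid, smi in zip(fam.cids, fam.smiles):
            jitter = rng.normal(0.0, scenario.ligand_jitter_sd)
            true_log = {scenario.off_target: base_log_off + jitter}
            for tgt in on_targets:
                true_log[tgt] = base_log_off + jitter - offset
            truth_rows.append({
                "cid": cid, "scaffold": fam.name, "class": fam.klass,
                "log10_si_offset": offset, "is_decoy": False,
                **{f"true_Ki [{t}]": 10 ** v for t, v in true_log.items()},
            })
            for tgt, mu in true_log.items():
                n_rep = int(rng.integers(scenario.replicate_range[0],
                                         scenario.replicate_range[1] + 1))
                for _ in range(n_rep):
                    aid_counter += 1
                    value = 10 ** (mu + rng.normal(0.0, scenario.noise_sd))
                    if rng.random() < scenario.outlier_rate:
                        value *= 100.0
                    records.append(BioactivityRecord(
                        cid=cid, smiles=smi, target=tgt, metric=Metric.KI,
                        value_nM=float(value), aid=f"AID{aid_counter}",
                        pmid=draw_pmid()))

    n_clean = len(records)
    n_decoy = int(round(scenario.decoy_rate * n_clean))
    decoy_cid = 9000
    for d in range(n_decoy):
        aid_counter += 1
        if d % 2 == 0 and records:
            # wrong-metric decoy: an IC50 measurement of a real ligand
            src = records[int(rng.integers(0, n_clean))]
            records.append(BioactivityRecord(
                cid=src.cid, smiles=src.smiles, target=src.target,
                metric=Metric.IC50,
                value_nM=float(10 ** rng.uniform(1.0, 3.0)),
                aid=f"AID{aid_counter}", pmid=draw_pmid()))
        else:
            # non-sulfonamide decoy: a Ki record without the zinc binder
            smi = NON_SULFONAMIDE_DECOYS[d % len(NON_SULFONAMIDE_DECOYS)]
            cid = f"CID{decoy_cid}"
            decoy_cid += 1
            records.append(BioactivityRecord(
                cid=cid, smiles=smi,
                target=str(rng.choice([scenario.on_target, scenario.off_target])),
                metric=Metric.KI,
                value_nM=float(10 ** rng.uniform(1.0, 3.0)),
                aid=f"AID{aid_counter}", pmid=draw_pmid()))
            truth_rows.append({
                "cid": cid, "scaffold": "decoy", "class": "decoy",
                "log10_si_offset": np.nan, "is_decoy": True,
            })
    truth = pd.DataFrame(truth_rows)
    return records, truth


def simulate(
    scenario: Optional[SimScenario] = None, *, seed: Optional[int] = None
) -> tuple[list[BioactivityRecord], pd.DataFrame]:
    """Generate a full synthetic table: series + Ki assignment."""
    if scenario is None:
        scenario = SimScenario()
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    series = generate_scaffold_series(scenario)
    return assign_ki(series, scenario)


def write_fixture(
    records: Sequence[BioactivityRecord],
    path: str | Path,
    truth: Optional[pd.DataFrame] = None,
) -> None:
    """Write records as a bioactivity CSV plus a ground-truth sidecar.

    The sidecar lands next to ``path`` with a ``.truth.csv`` suffix.
    """
    path = Path(path)
    rows = [{
        "cid": r.cid, "smiles": r.smiles, "target": r.target,
        "metric": r.metric.value, "value_nM": repr(r.value_nM),
        "aid": r.aid, "pmid": r.pmid or "",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
    if truth is not None:
        truth.to_csv(path.with_suffix(path.suffix + ".truth.csv"), index=False)
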