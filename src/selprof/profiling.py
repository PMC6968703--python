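"""End-to-end selectivity profiling pipeline.

Given a curated ligand table and a target pair (on-target vs
off-target, optionally a second on-target for double-selectivity
analysis), the pipeline selects the dually measured subset, builds
fingerprint similarity matrices, clusters ligands by structure, scores
every retained cluster with the S_score, and reports the clusters
selective for the on-target(s). In single-pair mode it also produces
the pairwise Ti-vs-SR table used to assess how tightly structural
similarity constrains selectivity similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clustering, fingerprints
from .curation import CurationAudit, CurationConfig, curate
from .datamodel import (ClusterReport, LigandEntry, PairwiseMatrix,
                        read_bioactivity_table, write_cluster_report,
                        write_ligand_table)
from .selectivity import (LigandClass, LigandSelectivity, SelectivityConfig,
                          compute_selectivities, double_s_score, s_score,
                          selectivity_ratio)

__all__ = [
    "ProfileResult",
    "select_pair_subset",
    "ti_sr_table",
    "sr_envelope",
    "score_clusters",
    "select_selective_clusters",
    "run_profile",
]

logger = logging.getLogger(__name__)

#: Ti bin edges of the similarity-vs-selectivity envelope summary.
DEFAULT_TI_BINS = (0.0, 0.4, 0.8, 1.0)


def select_pair_subset(
    entries: Sequence[LigandEntry], config: SelectivityConfig
) -> list[LigandEntry]:
    """Ligands measured against every isoform of the analysis.

    Requires Ki for the on-target and the off-target, plus the
    secondary on-target in double mode.
    """
    needed = [config.on_target, config.off_target]
    if config.double_mode:
        needed.append(config.secondary_on_target)
    subset = [e for e in entries
              if all(t in e.ki_by_target for t in needed)]
    logger.info("pair subset %s: %d of %d ligands", "/".join(needed),
                len(subset), len(entries))
    if len(subset) < 2:
        raise ValueError(
            f"only {len(subset)} ligand(s) carry Ki for all of "
            f"{', '.join(needed)}; nothing to cluster")
    return subset


def ti_sr_table(
    entries: Sequence[LigandEntry],
    similarity: PairwiseMatrix,
    config: SelectivityConfig,
) -> pd.DataFrame:
    """Per-pair Ti and SR over all n(n-1)/2 unordered ligand pairs."""
    order = similarity.ligand_order
    if [e.cid for e in entries] != order:
        raise ValueError("matrix ligand order does not match entries")
    sel = compute_selectivities(entries, config)
    rows = []
    for i, j in combinations(range(len(order)), 2):
        a, b = order[i], order[j]
        rows.append({
            "cid_a": a, "cid_b": b,
            "ti": similarity.values[i, j],
            "sr": selectivity_ratio(sel[a].si, sel[b].si),
        })
    return pd.DataFrame(rows, columns=["cid_a", "cid_b", "ti", "sr"])


def sr_envelope(
    pair_table: pd.DataFrame,
    bins: Sequence[float] = DEFAULT_TI_BINS,
) -> pd.DataFrame:
    """Per-Ti-bin spread of SR (bins closed on the right).

    Summarizes the similarity-selectivity funnel: structurally similar
    pairs should show SR near zero while dissimilar pairs may differ by
    several log units. Empty bins keep count 0 with NaN summaries.
    """
    if pair_table.empty:
        raise ValueError("pair table is empty")
    rows = []
    for lo, hi in zip(bins, bins[1:]):
        mask = (pair_table["ti"] > lo) & (pair_table["ti"] <= hi)
        if lo == bins[0]:  # first bin includes its left edge
            mask |= pair_table["ti"] == lo
        sub = pair_table.loc[mask, "sr"]
        if len(sub):
            rows.append({
                "ti_lo": lo, "ti_hi": hi, "count": len(sub),
                "max_abs_sr": float(sub.abs().max()),
                "sr_q2.5": float(sub.quantile(0.025)),
                "sr_q97.5": float(sub.quantile(0.975)),
            })
        else:
            rows.append({"ti_lo": lo, "ti_hi": hi, "count": 0,
                         "max_abs_sr": np.nan, "sr_q2.5": np.nan,
                         "sr_q97.5": np.nan})
    return pd.DataFrame(rows)


def score_clusters(
    clusters: Sequence[list[str]],
    ligand_selectivities: dict[str, LigandSelectivity],
    secondary_selectivities: Optional[dict[str, LigandSelectivity]] = None,
) -> list[ClusterReport]:
    """S_score every cluster; double mode adds the secondary and summed scores.

    Cluster ids are assigned 1..k in the given order (descending size
    as produced by the dendrogram cut).
    """
    reports = []
    for idx, members in enumerate(clusters, start=1):
        counts = _class_counts(members, ligand_selectivities, idx)
        primary = s_score(*counts)
        secondary = double_total = None
        if secondary_selectivities is not None:
            counts2 = _class_counts(members, secondary_selectivities, idx)
            secondary = s_score(*counts2)
            double_total = double_s_score(primary, secondary)
        reports.append(ClusterReport(
            cluster_id=idx, members=list(members), counts=counts,
            s_score=primary, s_score_secondary=secondary,
            double_s_score=double_total))
    return reports


def _class_counts(members, selectivities, cluster_id) -> tuple[int, int, int]:
    n = {LigandClass.L_ON: 0, LigandClass.L_OFF: 0, LigandClass.L_NS: 0}
    for cid in members:
        sel = selectivities.get(cid)
        if sel is None:
            raise KeyError(
                f"cluster {cluster_id}: no selectivity index for CID {cid!r}")
        n[sel.klass] += 1
    return (n[LigandClass.L_ON], n[LigandClass.L_OFF], n[LigandClass.L_NS])


def select_selective_clusters(
    reports: Sequence[ClusterReport], config: SelectivityConfig
) -> list[ClusterReport]:
    """Clusters selective for the on-target(s), sorted by descending score.

    Single mode keeps clusters with S_score strictly above the cutoff
    (default 70); double mode requires the double S_score strictly
    above twice the cutoff.
    """
    if config.double_mode:
        kept = [r for r in reports
                if r.double_s_score is not None
                and r.double_s_score > 2 * config.s_score_cutoff]
        kept.sort(key=lambda r: (-r.double_s_score, r.cluster_id))
    else:
        kept = [r for r in reports if r.s_score > config.s_score_cutoff]
        kept.sort(key=lambda r: (-r.s_score, r.cluster_id))
    return kept


@dataclass
class ProfileResult:
    """Everything one profiling run produced."""

    entries: list[LigandEntry]          # curated, full table
    subset: list[LigandEntry]           # dually measured analysis subset
    similarity: PairwiseMatrix
    distance: PairwiseMatrix
    clusters: list[list[str]]           # after the min-size filter
    reports: list[ClusterReport]        # all scored clusters
    selective: list[ClusterReport]      # above the S_score cutoff
    pair_table: Optional[pd.DataFrame]  # Ti/SR pairs (single mode only)
    audit: CurationAudit

    def summary(self) -> pd.DataFrame:
        rows = [{
            "cluster_id": r.cluster_id, "size": len(r.members),
            "n_on": r.counts[0], "n_off": r.counts[1], "n_ns": r.counts[2],
            "S_score": r.s_score,
            "S_score_secondary": r.s_score_secondary,
            "double_S_score": r.double_s_score,
        } for r in self.reports]
        return pd.DataFrame(rows)


def run_profile(
    bioactivity_path: str | Path,
    curation_config: Optional[CurationConfig] = None,
    selectivity_config: Optional[SelectivityConfig] = None,
    cut_config: Optional[clustering.CutConfig] = None,
    scheme: str = "keys",
    outdir: Optional[str | Path] = None,
) -> ProfileResult:
    """Full pipeline from a raw bioactivity table to selective clusters.

    Stages: curate -> subset on the target pair -> fingerprints ->
    Ti/Td matrices -> single-linkage clustering with a balanced cut ->
    S_score -> selective-cluster report. Deterministic for fixed inputs
    and configuration. When ``outdir`` is given, the curated table,
    audit, cluster report, membership and (single mode) pair table are
    written there as CSV.
    """
    if curation_config is None:
        curation_config = CurationConfig()
    if selectivity_config is None:
        selectivity_config = SelectivityConfig(on_target="hCA IX",
                                               off_target="hCA II")
    if cut_config is None:
        cut_config = clustering.CutConfig()

    records, diags = read_bioactivity_table(bioactivity_path)
    if diags:
        logger.warning("ingestion: %d malformed row(s) rejected", len(diags))
    entries, audit = curate(records, curation_config)
    if not entries:
        raise ValueError("curation removed every record; nothing to profile")

    subset = select_pair_subset(entries, selectivity_config)
    similarity, distance = fingerprints.build_matrices(subset, scheme)
    dendrogram = clustering.single_linkage(distance)
    clusters = clustering.filter_clusters(
        clustering.cut_at_height_ratio(dendrogram, cut_config), cut_config)

    primary_sel = compute_selectivities(subset, selectivity_config)
    secondary_sel = None
    if selectivity_config.double_mode:
        secondary_sel = compute_selectivities(subset, selectivity_config,
                                              secondary=True)
    reports = score_clusters(clusters, primary_sel, secondary_sel)
    selective = select_selective_clusters(reports, selectivity_config)

    pair_table = None
    if not selectivity_config.double_mode:
        pair_table = ti_sr_table(subset, similarity, selectivity_config)

    result = ProfileResult(
        entries=entries, subset=subset, similarity=similarity,
        distance=distance, clusters=clusters, reports=reports,
        selective=selective, pair_table=pair_table, audit=audit)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ligand_table(entries, outdir / "curated_ligands.csv")
        audit.to_csv(outdir / "curation_audit.csv")
        clustering.write_membership(clusters, outdir / "cluster_membership.csv")
        write_cluster_report(
            selective, subset, outdir / "selective_clusters.csv",
            on_target=selectivity_config.on_target,
            off_target=selectivity_config.off_target,
            secondary_on_target=selectivity_config.secondary_on_target)
        if pair_table is not None:
            pair_table.to_csv(outdir / "ti_sr_pairs.csv", index=False)
    return result
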