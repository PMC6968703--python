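# Methods

## Scope and model

`selprof` quantifies isoform selectivity at the level of chemical
series rather than single compounds. The underlying assumption is the
similarity principle applied to selectivity: ligands sharing a scaffold
tend to share a selectivity profile, so a cluster of structurally
similar ligands that is uniformly selective for an on-target isoform
identifies a chemotype causally linked to that selectivity. The
pipeline is ligand-only — it consumes compound structures (SMILES) and
inhibition constants (Ki, nM) and never touches protein structure.

Stages: curation → subset selection on a target pair → fingerprinting →
Tanimoto matrices → single-linkage clustering → balanced dendrogram cut
→ per-cluster selectivity scoring → selective-cluster report.

## Curation

Raw assay records (CID, SMILES, isoform, metric, value, AID, PMID) are
reduced to one mean Ki per (compound, isoform):

1. **Metric filter.** Only Ki records are comparable across assays;
   IC50/Kd/Km/EC50 records are dropped (configurable via
   `metric_keep`).
2. **Provenance filter.** An optional PMID whitelist restricts the data
   to publications from one laboratory, limiting inter-assay bias. No
   whitelist means pass-through.
3. **Replicate aggregation.** Replicates for one (compound, isoform)
   are averaged after outlier removal. Ki error is multiplicative, so
   outliers are flagged on log10(Ki) with the modified z-score
   0.6745·(x − median)/MAD at threshold `outlier_zmax = 3.5`; when the
   MAD degenerates to zero the mean absolute deviation (×1.253314)
   substitutes, and if removal would empty the set the median is kept.
   The reported mean is arithmetic on the raw nM values ("averaged"
   taken literally); a geometric mean and a trimmed rule are config
   options. The rule provably catches the generator's ×100 outliers at
   ≥ 3 replicates, where the MAD stays anchored by the clean majority.
4. **Merge per compound.** Per-isoform means are merged into one row
   per CID. Conflicting SMILES under one CID are flagged as a
   diagnostic and the first canonical form is kept — the right
   resolution is not inferable from the table itself.
5. **Substructure filter.** Only compounds bearing a sulfonamide-type
   zinc-binding group survive, SMARTS `[#16](=[OX1])(=[OX1])[NX3]`,
   deliberately loose so O-linked sulfamates and N-linked sulfamides
   also match. Unparsable SMILES are removed with a diagnostic.

Stage order is fixed and audited (counts in/out per stage); running the
substructure filter before aggregation would change audit counts but
not the final table. Ligands lacking Ki for either isoform of an
analysis are excluded at profiling time, not during curation, so one
curated table serves every target pair.

## Fingerprints

**Path scheme (1024 bits).** All simple linear paths of 1–7 heavy
atoms are enumerated; each path is rendered over (element symbol,
aromaticity via lowercase, bond order symbol) and canonicalized to the
lexicographically smaller reading direction; the canonical string is
hashed with 64-bit FNV-1a, XOR-folded to 10 bits. The hash is fixed and
versioned (`fnv1a64-xorfold10-v1`, reported by `selprof --version` and
in matrix sidecars) so fingerprints are bit-identical across platforms.
Single-atom paths are indexed for every element — a documented
divergence from the original FP2 design, harmless because all
downstream quantities are recomputed, never compared bit-for-bit
against other toolkits.

**Key scheme (166 bits).** The public 166 structural-key definitions
(the open MACCS set, taken at import time from RDKit's published
table). The matching loop is this package's own: plain keys fire on any
substructure match, counted keys require strictly more matches than
their threshold, key 125 fires on molecules with more than one aromatic
ring and key 166 on disconnected structures. The test suite pins the
result to exact bit equality with RDKit's independent C++ implementation
over a 50-molecule panel.

**Tanimoto.** Ti = |A∩B|/|A∪B| on set bits; Td = 1 − Ti. A pair of
all-zero fingerprints is defined as Ti = 0 (keeps matrices total); the
matrix diagonal is pinned to Ti = 1. Matrices are built over the
curated subset with both schemes sharing one ligand order, and persist
as square CSV or condensed vector + JSON sidecar.

Scheme choice: `keys` is the clustering default (tighter, more
interpretable series), `path` the default for the Ti–SR correlation,
where its wider dynamic range populates the low-similarity bins; with
structural keys, sulfonamide-rich collections rarely drop below
Ti ≈ 0.4 and the funnel's left edge is empty. FP3/FP4-style schemes are
deliberately not implemented (uninformative for this task).

## Clustering

Single linkage on the Td matrix, computed via
`scipy.cluster.hierarchy.linkage`; merge order on exact ties follows
scipy's deterministic ordering. The cut is implemented independently of
the merge order: threshold t = `height_ratio` × root merge height
(default 0.30), and clusters are the connected components of the graph
joining pairs with merge height strictly below t (union-find over the
linkage rows). Strictness matters only when merges sit exactly at the
threshold, in which case they stay split. An absolute-Td threshold mode
(`mode="absolute"`) covers the alternative reading of a fixed-distance
cut-off. Clusters are ordered (and numbered) by descending size, then
lowest member index, making cluster IDs reproducible; clusters with
fewer than `min_cluster_size = 5` members are dropped before scoring.

## Selectivity scoring

SI = Ki(off)/Ki(on). Classes: `L_on` SI > 5, `L_off` SI < 0.2, `L_ns`
otherwise — both inequalities strict, so boundary values land in
`L_ns`. S_score = 100(L_on − L_off)/size; selective clusters are those
with S_score strictly above the cutoff (default 70). SR uses base-10
logarithms, matching selectivity spreads quoted in log units. In double
mode each cluster gets one S_score per on-target against the shared
off-target; the report filter uses double S_score > 2 × cutoff — an
extension of the single-mode rule by this package, since only a
single-mode cutoff is established. SR is computed only in single-pair
mode, where one SI per ligand makes it well-defined.

## Synthetic data

The generator emulates a PubChem-style multi-isoform Ki table:

- **Structures.** Up to five sulfonamide scaffold templates with one
  aromatic attachment point, instantiated with ≤ 12 small R-groups
  (halogens, alkyl, alkoxy, amino, CF3, nitrile) in fixed vocabulary
  order. Defaults: 3 scaffolds × 8 ligands. Intra-family structural-key
  Ti (mean ≈ 0.89) comfortably exceeds inter-family Ti (≈ 0.53) — a
  tested property of the templates, not an assumption.
- **Activities.** log10 Ki(off) = scaffold base level (uniform in
  [1.0, 2.5], i.e. 10–300 nM, the range typical of potent sulfonamide
  inhibitors) + per-ligand jitter (sd 0.3) shared across isoforms;
  planted class offsets of +1.5 / −1.5 / 0 log units are subtracted on
  the on-target(s), so the true SI is exactly 10^offset in the
  noise-free limit. Replicates (uniform 3–6 per compound-isoform) add
  N(0, 0.15) log-noise; with probability 0.05 a replicate is multiplied
  ×100 (a gross outlier); a 0.1 decoy fraction mixes IC50 records and
  Ki records for non-sulfonamide compounds. A ground-truth sidecar maps
  every compound to its scaffold, class and true Ki.
- **Determinism.** One integer seed drives every draw.

What the generator does *not* emulate: real SAR landscapes (activity
cliffs within a series), inter-laboratory bias structure, correlated
replicate errors, tautomer/salt ambiguity, or the heavy-tailed
compound-series sizes of literature data. Passing the planted-recovery
tests therefore demonstrates that the machinery isolates
scaffold-linked selectivity under realistic noise, not that any
particular literature-scale result would be reproduced.

## Numerical and design notes

- Problem sizes in the test suite (24-ligand scenarios, 10–30-point
  oracle matrices, 50-molecule fingerprint panels, 20-seed Monte
  Carlo) were chosen so every brute-force oracle remains exact and the
  full suite runs in seconds.
- All-equal replicate sets have zero MAD and zero mean deviation; they
  are declared outlier-free.
- The report writer sorts by descending (double) S_score, then cluster
  id, with a stable sort, so output files are byte-reproducible.
- Unit handling: tables are nM throughout; an optional `units` column
  (nM/µM/mM/M) converts at ingestion.
- Ingestion never silently drops rows: every data row becomes either a
  record or a row-indexed diagnostic.

## Limitations

Selectivity is treated as a point estimate — no error propagation from
replicate scatter into SI or S_score. Cluster chemotypes are reported
as member lists; maximum-common-substructure extraction and any 2D
rendering are out of scope. Live database retrieval is out of scope:
the tool consumes a pre-assembled table in the documented schema.
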