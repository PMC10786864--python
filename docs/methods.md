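# Methods

`ppirep` implements a target-centric drug-repurposing workflow built on a
single premise: protein–protein interfaces from unrelated proteins can share
the same architecture, so a drug observed bound at one interface is a
candidate binder for structurally similar interfaces. The package covers the
full chain from structure files to a ranked candidate table, with a
synthetic-data layer that makes every stage testable offline.

## Structure model and contacts

Structures are read from PDB-format text (gemmi underneath, with a
pre-validation pass so malformed coordinate fields fail with a line number).
Polymer residues come from ATOM records and ligands from HETATM records;
waters are discarded, only the first model of multi-model files is used, and
for alternate locations the highest-occupancy conformer is kept (ties prefer
altloc A). Residues are identified by author number plus insertion code
throughout, because mutation mapping and interface reports are expressed in
author numbering.

Two atoms on different chains are *contacting* when their distance is
strictly less than the sum of their van der Waals radii plus a 0.5 Å
tolerance. The default radius set is C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80 Å with 1.70 Å for unknown elements; the table is overridable through
the `vdw_table` config key. Hydrogens participate when present — the rule is
atom-generic, and most deposited files lack them. A chain pair forms an
*interface* when at least five residues on each side participate in contacts.
Contact search uses a KD-tree pruned at the largest possible contact
distance with the exact per-pair criterion applied afterwards, so results
are identical to the all-pairs scan (this equivalence is asserted against a
brute-force oracle in the tests and the acceptance script).

Protein chains with fewer than 30 polymer residues are eliminated before
conformer analysis; ligand-only chains are exempt (they are not proteins and
carry the bound small molecules).

## Conformer grouping

Structure databases are redundant. Chains of one accession are grouped when
global sequence identity ≥ 0.95 **and** Cα RMSD over aligned identical
positions ≤ 2 Å. Identity is computed from a global alignment (match +1,
mismatch 0, gap open −10, extend −0.5) with alignment length — gaps
included — as denominator, which keeps partial-coverage chains from merging
with full-length ones. RMSD uses least-squares rigid superposition (Kabsch,
via an SVD-based rotation fit) and requires at least 20 aligned identical
positions; with fewer, chains are not linked, avoiding spurious links
between structures covering disjoint parts of a protein. Groups are
connected components of the link graph (single linkage): deterministic and
order-independent. The representative is the member with the most resolved
residues, ties broken by smallest (entry, chain) — the selection criterion
is a documented package choice, as is the Cα-only RMSD.

## Interface similarity and clustering

Similarity between two interfaces is an IS-score-style quantity in [0, 1].
The two interfaces are superposed (per-side index correspondence up to the
shorter side), residues are matched one-to-one by spatial proximity within
2·d0, and the score is

    S = (1/N_min) Σ_matched f_i / (1 + (d_i/d0)²),
    d0 = max(0.5, 1.24·(N_min − 15)^⅓ − 1.8),

where N_min is the smaller interface's residue count and
f_i = (1 + shared)/(1 + max(deg_i, deg_j)) rewards conservation of
cross-interface contacts between matched residues (1 when the contact
neighbourhoods correspond perfectly, never 0). Because an interface is an
unordered pair of sides, both side pairings are scored and the maximum
taken; the score is symmetric, bounded by 1, exactly 1 for self-comparison
and invariant under rigid transforms. Unrelated random 20-residue-per-side
interfaces score below the clustering threshold in ≥ 95% of seeded draws
(measured, not assumed — see the acceptance script).

Clusters come from average-linkage agglomerative clustering on distance
1 − S, cut at similarity 0.311 (configurable). Cutting one linkage tree at
a higher threshold always refines the partition at a lower one. Cluster
tables are plain TSV (cluster_id, interface_id) and reading enforces the
partition invariant.

## Repurposing strategies

The pathway's interaction network is built from a STRING-style edge list at
confidence ≥ 0.900 (0–1000 integer scores are normalized). Each node carries
a conformer count; a hetero edge expands to n_u × n_v theoretical conformer
pairs and a self edge to n(n+1)/2 unordered pairs with repetition. Coverage
is reported as an integer percentage of edges with at least one realized
structure.

Candidates are generated per cluster: **Repurposing To** proposes a drug
seen bound at any member interface for the cluster's pathway interfaces;
**Repurposing From** proposes a drug bound at a pathway interface for the
cluster's non-pathway members. Candidate identity is (drug, target); all
supporting source interfaces are kept as provenance. A source equal to the
target is never emitted, no pair crosses clusters, and output order is
independent of input order. A region filter drops pairs whose source and
target sit on opposite sides of the membrane (intracellular vs
extracellular annotations supplied as input); transmembrane or unannotated
interfaces pass with a warning.

## Docking-box scoring and selection

The docking box is the axis-aligned bounding box of all interface-residue
atoms plus 4 Å padding per face (configurable); every interface atom is
asserted to lie inside. Scoring is pluggable. The `external` engine adapter
shells out to an AutoDock-Vina-compatible executable (exhaustiveness 8
default) and parses the best-pose energy; a missing engine is an explicit
error, never a silent fallback. The `surrogate` scorer is a deterministic
distance-binned pair potential over receptor–ligand heavy atoms: −0.18 per
pair in the 3–5 Å well, +1.5 per Å of overlap below 2.5 Å, zero when no
receptor atom is within 8 Å. It depends only on pairwise distances (hence
rigid-invariant) and exists so the pipeline runs end to end without an
engine; its numbers are not comparable to Vina energies and only orderings
are meaningful.

Selection keeps scored pairs at or below −7.3 kcal/mol (configurable; the
literature quotes an average favorable binding energy of −7.75 ± 0.06
kcal/mol, and the observed score distribution breaks around −7.33, so the
operative default is "≈ −7.3 or better"), applies the region filter, and
sorts best-first. The control draws 35 approved drugs uniformly without
replacement (seed-reproducible), scores each against the candidate
interfaces, and summarizes mean/median/SD of the pooled energies.

## Mutation and sensitivity evidence

Cancer mutations (missense/nonsense records with canonical-sequence
positions, frequencies as fractions, optional SIFT scores) are mapped
through a SIFTS-style table to author-numbered chain residues. A
residue-name disagreement flags the record "mismatch"; positions outside
the table are "unmapped"; nothing is dropped — the three statuses partition
the input. Mapped records are intersected with interface residue sets
(annotated by side) and further with ligand-contacting residues (< 5 Å
from any ligand atom). Deleteriousness uses the conventional SIFT cutoff
0.05 (configurable); missing scores are "unknown" and excluded from
deleterious counts.

Viability screens are summarized per drug after complete-case filtering:
any cell line missing a value for any requested drug is omitted first, so
every drug is averaged over the same lines. Reported per drug: mean, sample
SD, and a t-based 95% CI (undefined and flagged below two lines). The
t-interval width is cross-checked against a 10⁴-resample bootstrap in the
tests.

## Synthetic data: what it emulates, and what it does not

Generators produce every input with the answer planted: complexes with an
exact number of contacting residue pairs (all other pairs ≥ 2 Å beyond
threshold), one-atom ligands at exact distances on or off the interface
(including bridging poses), conformer families (noisy rigid copies vs
hinge-displaced or mutated chains), descriptor families with known cluster
labels, and mutation/mapping/sensitivity/edge tables with planted
positives, thresholds straddled, and one incomplete cell line. Every
structural generator re-derives its truth with the brute-force contact scan
before returning, and identical seeds give byte-identical output.

Toy chains are poly-alanine Cα traces with idealized geometry; the contact,
similarity and selection rules are purely geometric/arithmetic, so passing
tests demonstrate the *rules*, not performance on real structures. The
fixtures do not emulate side-chain packing, crystallographic noise, missing
density, sequence-dependent contact propensities, or realistic docking
energetics; conclusions about real PDB-scale behaviour (interface counts,
candidate yields) are outside what these tests can show.

## Numerical choices and problem sizes

Strict inequalities at the contact (< r_a + r_b + 0.5 Å) and ligand
(< 5 Å) thresholds match the rules' "less than" formulation. Superposition
tolerances are 1e-6; degenerate (collinear) point sets are flagged.
Clustering ties are broken by smallest interface id, making every table
byte-reproducible. The bundled scenario uses three 2×30-residue complexes,
20-seed recovery sweeps, 100-draw null estimates and 50 random 200-atom
chain pairs for the contact-oracle check — sizes chosen so the whole suite
and the acceptance script each run in seconds while still exercising every
rule at its boundary.

## Known limitations

iAlign's exact IS-score is not reproduced (the surrogate shares its
semantics, not its numbers); PRISM predictions, SIFT, COSMIC, STRING and
DepMap are consumed as input tables, never queried; mmCIF, biological
assemblies and covalent ligands are unsupported; the surrogate scorer is
not a docking method and the −7.3 kcal/mol cutoff is only meaningful on the
external engine's scale.
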