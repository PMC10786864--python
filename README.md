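# ppirep

Drug repurposing via structural similarity of protein–protein interfaces,
for the Ras/Raf/MEK/ERK signalling pathway.

Proteins without classical binding pockets (the RAS family being the
canonical case) are hard to drug, but they act through protein–protein
interfaces — and unrelated proteins can form interfaces with the same
architecture. `ppirep` operationalizes that observation for structural
bioinformaticians: if an approved drug is observed bound at one interface,
every structurally similar interface is a candidate new target.

The pipeline:

1. **Structure model** — PDB I/O with author residue numbering; protein
   chains under 30 residues are eliminated.
2. **Conformer grouping** — chains of one protein are grouped at ≥ 95%
   global sequence identity and ≤ 2 Å Cα RMSD (Kabsch superposition over
   aligned identical positions); one representative per group.
3. **Interface extraction** — atoms on different chains closer than the sum
   of their van der Waals radii + 0.5 Å are contacting; ≥ 5 contacting
   residues on each side make an interface. Ligands within 5 Å of interface
   residues are mapped to it; glycerol (GOL) and isopropyl alcohol (IPA)
   are excluded from the approved-drug set as crystallography artefacts.
4. **Similarity clustering** — an interface-similarity score
   S = (1/N_min) Σ f_i /(1+(d_i/d0)²) over superposed, proximity-matched
   residues with contact-conservation weights f_i; average-linkage
   clustering cut at S = 0.311.
5. **Repurposing To / From** — per cluster, drugs bound at member
   interfaces are proposed for pathway interfaces (To) or, when bound at a
   pathway interface, for non-pathway members (From).
6. **Docking evaluation** — an interface-covering box (4 Å padding),
   a pluggable scorer (AutoDock-Vina-compatible adapter, exhaustiveness 8,
   or a deterministic surrogate pair potential for engine-free runs),
   selection at ΔG ≤ −7.3 kcal/mol, and a 35-drug random control.
7. **Evidence** — COSMIC-style mutations mapped through SIFTS-style tables
   onto interface and ligand-contact residues (SIFT < 0.05 = deleterious),
   and DepMap-style viability summaries with complete-case cell-line
   handling (mean, SD, t-based 95% CI).

A synthetic-data module generates every input with planted ground truth, so
the full pipeline runs and is tested entirely offline.

## Worked example

```python
from ppirep.pipeline import run_toy_pipeline

result = run_toy_pipeline(seed=1)
print(result.tables["candidates.tsv"])
```

prints

```
drug	target_interface	direction	cluster_id	source_interfaces
GNT	DRUG1_A_B	from	0	PATH1_A_B
TPV	PATH1_A_B	to	0	DRUG1_A_B
```

The generated scenario has three two-chain complexes: `PATH1` (a pathway
complex with the drug GNT at its interface), `DRUG1` (a structurally
similar non-pathway complex carrying TPV plus a glycerol artefact that the
FDA filter removes), and an unrelated `FAR1`. Clustering at 0.311 puts
`PATH1_A_B` and `DRUG1_A_B` in one cluster and isolates `FAR1_A_B`:

```
cluster_id	interface_id
0	DRUG1_A_B
0	PATH1_A_B
1	FAR1_A_B
```

so TPV (bound outside the pathway) is proposed *to* the pathway interface,
and GNT (bound inside) is proposed *from* it to the similar outside
interface. Each candidate is then pose-transferred onto its target by
interface superposition and scored with the surrogate potential
(`result.tables["scores.tsv"]`; surrogate numbers order poses but are not
docking energies), and the random control reports pooled mean/median/SD
over 35 drugs (`result.control`).

The same run is available from the shell:

```sh
ppirep synth --seed 1 --out scenario/   # structures/, tables/, truth.json
ppirep run   --seed 1 --out out/        # interface/cluster/candidate/score tables
```

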