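"""Mutation mapping onto interfaces and drug-sensitivity summaries.

Somatic cancer mutations (COSMIC-style records, canonical-sequence
positions) are mapped through a SIFTS-style residue table to author
residue numbers on specific chains, compared against interface residue
sets, and intersected with ligand-contacting residues.  Records are
never silently dropped: every input record ends up mapped,
mismatch-flagged, or unmapped.

Cell-viability screens (DepMap PRISM-assay style) are summarized per
drug with complete-case handling: any cell line missing a value for any
of the requested drugs is omitted before computing means, standard
deviations and t-based 95% confidence intervals, so every drug is
evaluated over the same cell lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutationRecord",
    "MappedMutation",
    "ResidueMapping",
    "map_mutation_to_chain",
    "interface_mutations",
    "classify_deleterious",
    "ligand_contact_mutations",
    "sensitivity_summary",
    "read_mutation_table",
    "read_mapping_table",
]

SIFT_DELETERIOUS_CUTOFF = 0.05


@dataclass(frozen=True)
class MutationRecord:
    accession: str
    seq_position: int  # 1-based canonical-sequence position
    ref_aa: str
    alt_aa: str
    mutation_type: str  # "missense" | "nonsense"
    frequency: float  # fraction of samples
    tissues: tuple[str, ...] = ()
    sift_score: float | None = None

    def __post_init__(self) -> None:
        if self.seq_position < 1:
            raise ValueError("sequence position must be >= 1")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be a fraction in [0, 1]")


@dataclass(frozen=True)
class MappedMutation:
    record: MutationRecord
    status: str  # "mapped" | "mismatch" | "unmapped"
    entry_id: str | None = None
    chain_id: str | None = None
    auth_number: int | None = None
    icode: str = ""
    side: str | None = None  # filled by interface_mutations
    deleterious: str | None = None  # "deleterious" | "tolerated" | "unknown"

    @property
    def residue_key(self) -> tuple[int, str] | None:
        if self.auth_number is None:
            return None
        return (self.auth_number, self.icode)


class ResidueMapping:
    """Canonical-position <-> author-residue lookup (SIFTS role).

    Rows: accession, seq_position, entry, chain, auth_number, icode,
    residue one-letter code at that position in the structure.
    """

    def __init__(self, rows: pd.DataFrame):
        required = {"accession", "seq_position", "entry", "chain",
                    "auth_number", "aa"}
        missing = required - set(rows.columns)
        if missing:
            raise ValueError(f"mapping table missing columns: {sorted(missing)}")
        if "icode" not in rows.columns:
            rows = rows.assign(icode="")
        rows = rows.fillna({"icode": ""})
        dup = rows.duplicated(subset=["accession", "entry", "chain",
                                      "auth_number", "icode"])
        if dup.any():
            raise ValueError("mapping not injective per chain")
        self._rows = rows
        self._index = {
            (r.accession, int(r.seq_position)): r
            for r in rows.itertuples(index=False)
        }

    def lookup(self, accession: str, seq_position: int):
        return self._index.get((accession, seq_position))


def map_mutation_to_chain(record: MutationRecord,
                          mapping: ResidueMapping) -> MappedMutation:
    """Map a canonical-position mutation to an author-numbered residue.

    A residue-name disagreement between the structure and the record's
    reference amino acid yields status "mismatch" (the record is kept
    and flagged, never dropped)."""
    row = mapping.lookup(record.accession, record.seq_position)
    if row is None:
        return MappedMutation(record=record, status="unmapped")
    status = "mapped" if row.aa == record.ref_aa else "mismatch"
    return MappedMutation(
        record=record, status=status, entry_id=row.entry, chain_id=row.chain,
        auth_number=int(row.auth_number), icode=str(row.icode or ""),
    )


def interface_mutations(mapped: Sequence[MappedMutation],
                        interface) -> list[MappedMutation]:
    """Subset of mapped mutations located at the interface, annotated
    with the side (chain_a / chain_b) they fall on."""
    located = []
    for m in mapped:
        if m.status == "unmapped" or m.chain_id is None:
            continue
        if m.entry_id is not None and m.entry_id != interface.entry_id:
            continue
        side = interface.side_of(m.chain_id, m.residue_key)
        if side is not None:
            located.append(replace(m, side=side))
    return located


def classify_deleterious(mapped: Sequence[MappedMutation],
                         sift_cutoff: float = SIFT_DELETERIOUS_CUTOFF
                         ) -> list[MappedMutation]:
    """Flag each record by its SIFT score: deleterious below the cutoff,
    tolerated otherwise, unknown when no score is available."""
    out = []
    for m in mapped:
        score = m.record.sift_score
        if score is None:
            flag = "unknown"
        elif score < sift_cutoff:
            flag = "deleterious"
        else:
            flag = "tolerated"
        out.append(replace(m, deleterious=flag))
    return out


def ligand_contact_mutations(interface_records: Sequence[MappedMutation],
                             binding) -> list[MappedMutation]:
    """Records whose residue is also a ligand-contacting residue
    (< 5 A from the bound ligand) of the given binding."""
    contact_keys = {(side, key) for side, key in binding.contact_residues}
    return [m for m in interface_records
            if m.side is not None and (m.side, m.residue_key) in contact_keys]


def sensitivity_summary(table: pd.DataFrame | str,
                        drugs: Sequence[str]) -> pd.DataFrame:
    """Per-drug viability summary with complete-case cell-line handling.

    ``table`` is long-format (cell_line, drug, value); negative values
    mean treated cells grew less than controls.  Cell lines lacking a
    value for any requested drug are omitted first, so the per-drug n is
    identical.  Returns a frame indexed by drug with columns
    mean, sd, ci_low, ci_high, n; with fewer than two surviving lines the
    CI is undefined (NaN) and flagged via the ``ci_defined`` column.
    """
    if isinstance(table, str):
        table = pd.read_csv(io.StringIO(table))
    missing = set(drugs) - set(table["drug"].unique())
    if missing:
        raise ValueError(f"drugs absent from table: {sorted(missing)}")
    wide = (table[table["drug"].isin(drugs)]
            .pivot_table(index="cell_line", columns="drug", values="value",
                         aggfunc="first")
            .reindex(columns=list(drugs)))
    complete = wide.dropna(axis=0, how="any")
    n = len(complete)
    rows = []
    for drug in drugs:
        values = complete[drug].to_numpy(dtype=float)
        mean = float(np.mean(values)) if n else np.nan
        sd = float(np.std(values, ddof=1)) if n >= 2 else np.nan
        if n >= 2 and sd > 0:
            half = float(stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n))
            ci = (mean - half, mean + half)
            defined = True
        elif n >= 2:
            ci = (mean, mean)
            defined = True
        else:
            ci = (np.nan, np.nan)
            defined = False
        rows.append({"drug": drug, "mean": mean, "sd": sd,
                     "ci_low": ci[0], "ci_high": ci[1], "n": n,
                     "ci_defined": defined})
    return pd.DataFrame(rows).set_index("drug")


def read_mutation_table(text: str) -> list[MutationRecord]:
    """Parse a COSMIC-style TSV into mutation records."""
    df = pd.read_csv(io.StringIO(text), sep="\t")
    records = []
    for row in df.itertuples(index=False):
        sift = getattr(row, "sift_score", None)
        if sift is not None and (isinstance(sift, float) and np.isnan(sift)):
            sift = None
        tissues = getattr(row, "tissues", "")
        records.append(MutationRecord(
            accession=row.accession,
            seq_position=int(row.seq_position),
            ref_aa=row.ref_aa,
            alt_aa=row.alt_aa,
            mutation_type=row.mutation_type,
            frequency=float(row.frequency),
            tissues=tuple(str(tissues).split(";")) if tissues else (),
            sift_score=None if sift is None else float(sift),
        ))
    return records


def read_mapping_table(text: str) -> ResidueMapping:
    return ResidueMapping(pd.read_csv(io.StringIO(text), sep="\t"))
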