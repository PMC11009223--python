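"""Pre-analysis ASV removal: negative-control contaminants and organelle/Archaea reads.

Two filters run before any composition analysis.  The contaminant filter
drops every ASV detected (count >= 1) in a sequenced blank, separately per
nucleic-acid type: DNA blanks clean DNA libraries and RNA blanks clean RNA
libraries, since the two library preparations have distinct contamination
profiles.  The organelle filter drops Archaea, chloroplast and
mitochondrial sequences, which carry 16S rRNA genes but are not part of
the bacterial community of interest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .iotab import FeatureTable, SampleMetadata, TaxonomyMap, normalize_taxon

__all__ = ["FilterReport", "remove_control_asvs", "remove_organelle_taxa"]


@dataclasses.dataclass
class FilterReport:
    """Which ASVs a filter removed, and why.

    ``removed`` maps a reason (``control_dna``, ``control_rna``,
    ``organelle``) to the set of ASV ids removed for that reason;
    ``samples_dropped`` lists control samples dropped from the table.
    """

    removed: dict[str, set[str]] = dataclasses.field(default_factory=dict)
    samples_dropped: list[str] = dataclasses.field(default_factory=list)

    @property
    def counts_removed(self) -> dict[str, int]:
        return {reason: len(ids) for reason, ids in self.removed.items()}

    def all_removed(self) -> set[str]:
        out: set[str] = set()
        for ids in self.removed.values():
            out |= ids
        return out

    def write_tsv(self, path: str | Path) -> None:
        lines = ["asv_id\treason"]
        for reason in sorted(self.removed):
            for asv in sorted(self.removed[reason]):
                lines.append(f"{asv}\t{reason}")
        summary = ", ".join(
            f"{reason}={n}" for reason, n in sorted(self.counts_removed.items())
        )
        lines.append(f"# summary: {summary or 'nothing removed'}; "
                     f"samples_dropped={len(self.samples_dropped)}")
        Path(path).write_text("\n".join(lines) + "\n")


def remove_control_asvs(
    table: FeatureTable, meta: SampleMetadata
) -> tuple[FeatureTable, FilterReport]:
    """Remove ASVs detected in negative controls, per molecule.

    For each molecule m, every ASV with a nonzero count in any control
    sample of molecule m is flagged and its counts are zeroed in all
    samples of molecule m; the control samples themselves are dropped.
    A flagged ASV's column is removed from the table outright when it is
    flagged for every molecule present among the surviving samples (the
    usual case: single-molecule tables lose the column entirely).

    With no control samples the table is returned unchanged.
    """
    table_samples = set(table.sample_ids)
    meta_ids = set(meta.sample_ids)
    unknown = [s for s in table.sample_ids if s not in meta_ids]
    if unknown:
        raise ValueError(f"table samples missing from metadata: {unknown[:5]}")

    report = FilterReport()
    df = table.to_dataframe()
    molecule_of = {s: meta.row(s)["molecule"] for s in table.sample_ids}
    table_molecules = set(molecule_of.values())
    # a control is relevant if its molecule has samples in this table;
    # a relevant control missing from the table is a hard error
    relevant = [
        s for s in meta.control_ids()
        if meta.row(s)["molecule"] in table_molecules
    ]
    missing_controls = [s for s in relevant if s not in table_samples]
    if missing_controls:
        raise ValueError(
            f"control sample(s) absent from the feature table: {missing_controls}"
        )
    controls = [s for s in relevant if s in table_samples]
    if not controls:
        return table, report
    flagged: dict[str, set[str]] = {}
    for molecule in ("DNA", "RNA"):
        ctrl_m = [s for s in controls if molecule_of[s] == molecule]
        if not ctrl_m:
            continue
        present = df.loc[ctrl_m].sum(axis=0) > 0
        flagged[molecule] = set(present.index[present])
        report.removed[f"control_{molecule.lower()}"] = set(flagged[molecule])

    report.samples_dropped = list(controls)
    keep_samples = [s for s in table.sample_ids if s not in set(controls)]
    if not keep_samples:
        raise ValueError("all samples are controls; nothing left to analyze")
    out = df.loc[keep_samples]

    for molecule, asvs in flagged.items():
        rows = [s for s in keep_samples if molecule_of[s] == molecule]
        cols = [a for a in out.columns if a in asvs]
        if rows and cols:
            out.loc[rows, cols] = 0

    molecules_present = {molecule_of[s] for s in keep_samples}
    drop_fully = [
        a for a in out.columns
        if all(a in flagged.get(m, set()) for m in molecules_present)
    ]
    out = out.drop(columns=drop_fully)
    if out.shape[1] == 0:
        raise ValueError("control filtering removed every ASV")
    filtered = FeatureTable(
        list(out.index), list(out.columns), out.to_numpy()
    )
    return filtered, report


ORGANELLE_RULES = (
    ("kingdom", "archaea"),
    ("class", "chloroplast"),
    ("family", "mitochondria"),
)


def remove_organelle_taxa(
    table: FeatureTable, tax: TaxonomyMap
) -> tuple[FeatureTable, FilterReport]:
    """Discard Archaea, chloroplast and mitochondrial ASVs.

    Matches the Greengenes tokens case-insensitively, ignoring contested-
    name brackets for this test only: kingdom Archaea, class Chloroplast,
    family mitochondria.  Every table ASV must have a lineage.
    """
    tax.require(table.asv_ids)
    removed: set[str] = set()
    for asv in table.asv_ids:
        lin = tax[asv]
        for rank, token in ORGANELLE_RULES:
            if normalize_taxon(lin.name_at(rank)) == token:
                removed.add(asv)
                break
    report = FilterReport(removed={"organelle": removed})
    if len(removed) == table.n_asvs:
        raise ValueError("organelle filtering removed every ASV")
    filtered = table.drop_asvs(removed) if removed else table
    return filtered, report
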