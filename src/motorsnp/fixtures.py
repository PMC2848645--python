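"""Access to the packaged curated data files.

The package ships, as plain-text data locked by SHA-256 checksums:

* ``table1_snps.tsv``   — the curated catalog of 89 myosin heavy chain
  missense SNP positions in the motor domain, with reference-frame
  substitutions, sub-domain labels, heterozygosity summaries, homozygote
  flags, screened counts, and disease flags;
* ``table2_myh11.tsv``  — a raw cluster-table example for smooth-muscle
  myosin (MYH11), exercising the dialect's duplicate rows, alternative
  alleles, and the two loop-1 splice numbering frames 7 residues apart;
* ``domain_model.json`` — the sub-domain model of S1;
* ``residue_properties.tsv`` — per-residue physico-chemical scales.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .domain_model import DomainModel
from .population_stats import PopulationObservation
from .reference_mapping import MappedPosition, fixture_mapped_position
from .variant_ingest import VariantRecord, parse_substitution


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("motorsnp") / "data" / name) as p:
        return Path(p)


def verify_checksums() -> None:
    """Raise if any packaged data file deviates from its recorded SHA-256."""
    sums = data_path("SHA256SUMS").read_text().strip().splitlines()
    for line in sums:
        digest, name = line.split()
        actual = hashlib.sha256(data_path(name).read_bytes()).hexdigest()
        if actual != digest:
            raise RuntimeError(f"packaged data file {name} fails its checksum")


def load_domain_model() -> DomainModel:
    return DomainModel.from_json(data_path("domain_model.json"))


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog row: the consolidated record plus its printed annotations."""

    record: VariantRecord
    section: str
    position_label: str
    reference_residue: Optional[str]  # printed reference residue when it differs
    reference_anomaly: bool

    def mapped(self) -> MappedPosition:
        """Catalog-mode mapping: the printed reference-frame position."""
        return fixture_mapped_position(self.record, self.reference_residue)


def load_snp_catalog() -> list[CatalogEntry]:
    """The packaged 89-record catalog as consolidated variant records."""
    text = data_path("table1_snps.tsv").read_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    entries: list[CatalogEntry] = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        flags = set() if row["flags"] == "-" else set(row["flags"].split(","))
        native, substituted, notation, positions, bound, rng = parse_substitution(
            row["substitution"]
        )
        het = None if row["ahp"] == "-" else float(row["ahp"])
        homo = {"Y": True, "N": False}.get(row["homozygote"])
        count = None if row["count"] == "-" else int(row["count"])
        obs = PopulationObservation(
            subpopulation="pooled",
            heterozygous_percent=het,
            homozygous_substituted_observed=homo,
            screened_count=count,
            discordant="discordant" in flags,
        )
        record = VariantRecord(
            rs_id=int(row["rs_id"]),
            gene=row["gene"],
            isoform=row["isoform"],
            native_residue=native,
            substituted_residues=substituted,
            isoform_positions=positions,
            notation=notation,
            upstream_bound=bound,
            ambiguous_range=rng,
            population=(obs,),
            disease_flag=row["disease"] == "1",
            flags=tuple(sorted(flags)),
        )
        ref_res = None if row["ref_if_different"] == "-" else row["ref_if_different"]
        if ref_res is not None:
            ref_res = ref_res[0]  # "E108" -> "E"
        entries.append(
            CatalogEntry(
                record=record,
                section=row["section"],
                position_label=row["position_label"],
                reference_residue=ref_res,
                reference_anomaly="homozygous_all" in flags,
            )
        )
    return entries


def load_myh11_cluster_text() -> str:
    return data_path("table2_myh11.tsv").read_text()
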