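"""Synthetic isoform families and planted variant tables with known truth.

Every downstream stage — dialect parsing, consolidation, alignment mapping,
domain assignment, burden counting — is testable offline against ground truth
generated here.  The generator emulates the real data's structure:

* an isoform family derived from one reference sequence by residue
  substitution (uniform random exchange away from the native residue, the
  simplest model adequate for coordinate-mapping tests) and by planted
  insertions/deletions, the analogue of the smooth-muscle loop-1 splice
  insert that shifts downstream numbering by 7;
* variants planted per sub-domain as a Poisson process with a stated
  per-residue rate, carrying disease flags, heterozygosity draws (a mixture
  of missing, zero, and a positive exponential component), and homozygote
  flags;
* a writer for the raw cluster-table dialect (duplicate rows per alternative
  numbering frame, one row per alternative allele, blank continuation ids),
  closing the emit → parse → consolidate round trip.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain_model import DomainModel, assign_domain
from .population_stats import PopulationObservation
from .variant_ingest import VariantRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion, in reference coordinates.

    ``isoforms`` restricts the event to the named isoforms (None = all).
    An insertion of length L places L new residues immediately before
    ``position``; a deletion removes residues position..position+length-1.
    """

    position: int
    length: int
    kind: str  # "insert" | "delete"
    isoforms: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("insert", "delete"):
            raise ValueError(f"indel kind must be insert or delete, got {self.kind!r}")
        if self.position < 1 or self.length < 1:
            raise ValueError("indel position and length must be >= 1")


@dataclass(frozen=True)
class SyntheticFamilySpec:
    reference_length: int
    n_isoforms: int
    target_identity: float
    indel_events: tuple[IndelEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length < 50:
            raise ValueError("reference_length must be >= 50")
        if self.n_isoforms < 1:
            raise ValueError("need at least one isoform")
        if not (0.0 < self.target_identity <= 1.0):
            raise ValueError("target_identity must be in (0, 1]")
        for ev in self.indel_events:
            end = ev.position + (ev.length - 1 if ev.kind == "delete" else 0)
            if end > self.reference_length:
                raise ValueError(
                    f"indel at {ev.position} (length {ev.length}) exceeds "
                    f"sequence length {self.reference_length}"
                )


@dataclass
class IsoformFamily:
    reference_name: str
    reference_seq: str
    isoforms: dict[str, str]
    # per isoform: isoform position (1-based) -> reference position, or None
    # for inserted residues with no reference counterpart
    truth_maps: dict[str, dict[int, Optional[int]]]
    realized_identity: dict[str, float]

    def inverse_map(self, isoform: str) -> dict[int, int]:
        """reference position -> isoform position (deleted positions absent)."""
        return {
            ref: iso
            for iso, ref in self.truth_maps[isoform].items()
            if ref is not None
        }

    def to_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(self.reference_seq), id=self.reference_name, description="")]
        records += [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.isoforms.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def indel_disturbed(self, isoform: str, halo: int = 10) -> set[int]:
        """Reference positions within ``halo`` residues of an indel edge."""
        tm = self.truth_maps[isoform]
        mapped_refs = sorted(r for r in tm.values() if r is not None)
        disturbed: set[int] = set()
        # deletions: gaps in the mapped reference positions
        for a, b in zip(mapped_refs, mapped_refs[1:]):
            if b > a + 1:
                disturbed.update(range(a - halo + 1, b + halo))
        # insertions: reference neighbourhood of inserted isoform residues
        iso_positions = sorted(tm)
        for p in iso_positions:
            if tm[p] is None:
                for q in (p - 1, p + 1):
                    r = tm.get(q)
                    if r is not None:
                        disturbed.update(range(r - halo, r + halo + 1))
        # terminal overhangs
        if mapped_refs:
            disturbed.update(range(1, mapped_refs[0] + 1))
            disturbed.update(range(mapped_refs[-1], len(self.reference_seq) + 1))
        return disturbed


def generate_isoform_family(spec: SyntheticFamilySpec) -> IsoformFamily:
    """Reference plus ``n_isoforms`` derived sequences with exact truth maps."""
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(AA20))
    ref = "".join(rng.choice(alphabet, size=spec.reference_length))

    isoforms: dict[str, str] = {}
    truth: dict[str, dict[int, Optional[int]]] = {}
    realized: dict[str, float] = {}
    p_sub = 1.0 - spec.target_identity
    for k in range(1, spec.n_isoforms + 1):
        name = f"iso{k}"
        residues = list(ref)
        if p_sub > 0:
            hits = np.flatnonzero(rng.random(spec.reference_length) < p_sub)
            for i in hits:
                choices = [c for c in AA20 if c != residues[i]]
                residues[i] = choices[rng.integers(len(choices))]
        refpos: list[Optional[int]] = list(range(1, spec.reference_length + 1))
        events = [
            ev
            for ev in spec.indel_events
            if ev.isoforms is None or name in ev.isoforms
        ]
        for ev in sorted(events, key=lambda e: e.position, reverse=True):
            at = ev.position - 1
            if ev.kind == "delete":
                del residues[at : at + ev.length]
                del refpos[at : at + ev.length]
            else:
                inserted = [str(c) for c in rng.choice(alphabet, size=ev.length)]
                residues[at:at] = inserted
                refpos[at:at] = [None] * ev.length
        seq = "".join(residues)
        tm = {i + 1: refpos[i] for i in range(len(seq))}
        matched = [
            (seq[i], ref[refpos[i] - 1]) for i in range(len(seq)) if refpos[i] is not None
        ]
        realized[name] = (
            sum(a == b for a, b in matched) / len(matched) if matched else 0.0
        )
        isoforms[name] = seq
        truth[name] = tm
    return IsoformFamily(
        reference_name="reference",
        reference_seq=ref,
        isoforms=isoforms,
        truth_maps=truth,
        realized_identity=realized,
    )


@dataclass(frozen=True)
class PlantSpec:
    """Statistical description of the planted variant table."""

    per_domain_rate: dict  # domain or coarse-region name -> variants per residue
    disease_fraction: float = 0.1
    ahp_missing_p: float = 0.35
    ahp_zero_p: float = 0.25
    ahp_mean: float = 5.0  # percent, exponential component
    homozygote_probability: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in self.per_domain_rate.items():
            if rate < 0:
                raise ValueError(f"negative rate for {name!r}")
        for frac in (
            self.disease_fraction,
            self.ahp_missing_p,
            self.ahp_zero_p,
            self.homozygote_probability,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.ahp_missing_p + self.ahp_zero_p > 1.0:
            raise ValueError("ahp point masses exceed 1")


@dataclass(frozen=True)
class PlantedVariant:
    rs_id: int
    isoform: str
    native_residue: str
    substituted_residues: tuple[str, ...]
    isoform_position: int
    reference_position: int
    true_label: str
    true_group: str
    true_category: str
    ahp: Optional[float]
    disease: bool
    homozygote: bool

    def to_record(self) -> VariantRecord:
        obs = PopulationObservation(
            subpopulation="pooled",
            heterozygous_percent=self.ahp,
            homozygous_substituted_observed=self.homozygote,
        )
        return VariantRecord(
            rs_id=self.rs_id,
            gene=self.isoform,
            isoform=self.isoform,
            native_residue=self.native_residue,
            substituted_residues=self.substituted_residues,
            isoform_positions=(self.isoform_position,),
            population=(obs,),
            disease_flag=self.disease,
        )


def _region_residues(model: DomainModel, name: str) -> list[int]:
    for dom in model.domains + model.coarse_regions:
        if dom.name == name:
            out: list[int] = []
            for a, b in dom.intervals:
                out.extend(range(a, b + 1))
            return out
    raise KeyError(f"no domain or coarse region named {name!r}")


def plant_variants(
    family: IsoformFamily, model: DomainModel, plant: PlantSpec
) -> tuple[list[PlantedVariant], pd.DataFrame]:
    """Plant variants per domain at the stated Poisson rates.

    Each planted variant carries its true reference position, domain label,
    group, category, disease flag, AHP draw, and homozygote flag; the second
    return value tabulates the truth for convenient comparison.
    """
    rng = np.random.default_rng(plant.seed)
    names = sorted(family.isoforms)
    inverse = {n: family.inverse_map(n) for n in names}
    variants: list[PlantedVariant] = []
    rs_counter = 9_000_000
    for region in sorted(plant.per_domain_rate):
        rate = plant.per_domain_rate[region]
        residues = [
            p for p in _region_residues(model, region) if p <= len(family.reference_seq)
        ]
        if not residues or rate == 0:
            continue
        n = rng.poisson(rate * len(residues))
        for _ in range(n):
            ref_pos = int(residues[rng.integers(len(residues))])
            carriers = [n_ for n_ in names if ref_pos in inverse[n_]]
            if not carriers:
                continue  # deleted in every isoform; cannot be reported
            isoform = carriers[rng.integers(len(carriers))]
            iso_pos = inverse[isoform][ref_pos]
            native = family.isoforms[isoform][iso_pos - 1]
            choices = [c for c in AA20 if c != native]
            substituted = (choices[rng.integers(len(choices))],)
            u = rng.random()
            if u < plant.ahp_missing_p:
                ahp = None
            elif u < plant.ahp_missing_p + plant.ahp_zero_p:
                ahp = 0.0
            else:
                ahp = float(min(rng.exponential(plant.ahp_mean), 50.0))
            disease = bool(rng.random() < plant.disease_fraction)
            homozygote = bool(rng.random() < plant.homozygote_probability)
            assignment = assign_domain(ref_pos, model)
            rs_counter += 1
            variants.append(
                PlantedVariant(
                    rs_id=rs_counter,
                    isoform=isoform,
                    native_residue=native,
                    substituted_residues=substituted,
                    isoform_position=iso_pos,
                    reference_position=ref_pos,
                    true_label=assignment.label,
                    true_group=assignment.group,
                    true_category=(
                        "disease_implicated"
                        if disease
                        else ("in_domain" if assignment.core_functional else "outside")
                    ),
                    ahp=ahp,
                    disease=disease,
                    homozygote=homozygote,
                )
            )
    truth = pd.DataFrame(
        [
            {
                "rs_id": v.rs_id,
                "isoform": v.isoform,
                "isoform_position": v.isoform_position,
                "reference_position": v.reference_position,
                "true_label": v.true_label,
                "true_group": v.true_group,
                "true_category": v.true_category,
                "disease": v.disease,
                "ahp": v.ahp,
            }
            for v in variants
        ]
    )
    return variants, truth


@dataclass(frozen=True)
class DialectOptions:
    """Formatting knobs for the cluster-table writer."""

    header: tuple[str, ...] = (
        "ID of SNP Cluster",
        "Gene",
        "Function",
        "Base Change",
        "Amino Acid Change",
        "Peptide Sequence#",
    )
    arrow: str = "-->"
    rs_prefix: str = "rs"
    # isoform name -> numbering offset of its alternative splice frame;
    # every row is duplicated at position + offset, as the loop-1 insert does
    alt_frame_offset: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.header) != 6:
            raise ValueError("the dialect has exactly six columns")


_BASES = "ACGT"


def _base_change(rs_id: int, allele_index: int) -> tuple[str, str]:
    # consistent annotation only; no codon model is implied
    b1 = _BASES[rs_id % 4]
    b2 = _BASES[(rs_id + 1 + allele_index) % 4]
    if b2 == b1:
        b2 = _BASES[(rs_id + 2 + allele_index) % 4]
    return b1, b2


def emit_cluster_table(
    variants: Sequence[PlantedVariant], dialect: DialectOptions = DialectOptions()
) -> str:
    """Write planted variants in the raw cluster-table dialect.

    One row per (allele, numbering frame); the cluster id appears on the
    first row of each cluster and is blank on continuation rows.
    """
    lines = ["\t".join(dialect.header)]
    for v in variants:
        frames = [v.isoform_position]
        offset = dialect.alt_frame_offset.get(v.isoform)
        if offset:
            frames.append(v.isoform_position + offset)
        first = True
        for allele_index, sub in enumerate(v.substituted_residues):
            b1, b2 = _base_change(v.rs_id, allele_index)
            for pos in frames:
                rs_field = f"{dialect.rs_prefix}{v.rs_id}" if first else ""
                first = False
                lines.append(
                    "\t".join(
                        [
                            rs_field,
                            v.isoform,
                            "missense",
                            f"{b1} {dialect.arrow}{b2}",
                            f"{v.native_residue} {dialect.arrow}{sub}",
                            str(pos),
                        ]
                    )
                )
    return "\n".join(lines) + "\n"


def variants_to_tsv(variants: Sequence[PlantedVariant]) -> str:
    lines = [
        "rs_id\tisoform\tsubstitution\tisoform_position\treference_position\t"
        "true_label\ttrue_category\tahp\tdisease\thomozygote"
    ]
    for v in variants:
        lines.append(
            "\t".join(
                [
                    str(v.rs_id),
                    v.isoform,
                    f"{v.native_residue}{v.isoform_position}"
                    + "/".join(v.substituted_residues),
                    str(v.isoform_position),
                    str(v.reference_position),
                    v.true_label,
                    v.true_category,
                    "-" if v.ahp is None else f"{v.ahp:.3f}",
                    "1" if v.disease else "0",
                    "1" if v.homozygote else "0",
                ]
            )
        )
    return "\n".join(lines) + "\n"
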