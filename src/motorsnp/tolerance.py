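"""Variant categorization, per-domain burden, and domain tolerance labels.

Every consolidated variant, once mapped and domain-labeled, falls in exactly
one category with fixed precedence:

  disease_implicated > unmappable > in_domain > outside

Disease-implicated records are excluded from the sub-domain SNP burdens,
which count only the benign catalog.  Burdens drive the three-hypothesis
classification of sub-domains:

* too_robust     — a domain that tolerates several benign substitutions; its
                   sequence paradigm is robust to intrusion.
* too_sensitive  — a domain nearly devoid of benign substitutions but
                   carrying disease-implicated ones; almost any change breaks
                   its function.
* function-neutral is a per-variant notion: substitutions with appreciable
  heterozygous prevalence (AHP >= 0.5% by default) present in healthy
  carriers, the candidates for inserting spectroscopic probes.

Physico-chemical assessment of a substitution (charge, polarity class,
side-chain surface area, helix propensity, Gly/Pro/Cys/aromatic special
cases) comes from packaged per-residue property tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .domain_model import DomainAssignment, DomainModel, assign_domain
from .population_stats import compute_ahp, homozygote_flag
from .reference_mapping import MappedPosition
from .variant_ingest import VariantRecord

CATEGORIES = ("disease_implicated", "unmappable", "in_domain", "outside")


@dataclass(frozen=True)
class AnnotatedVariant:
    record: VariantRecord
    mapped: MappedPosition
    assignment: Optional[DomainAssignment]
    ahp: Optional[float]
    homozygote: str
    category: str
    reference_anomaly: bool = False


def categorize_variant(
    record: VariantRecord,
    mapped: MappedPosition,
    assignment: Optional[DomainAssignment],
) -> str:
    """Category with precedence disease > unmappable > in_domain > outside."""
    if record.disease_flag:
        return "disease_implicated"
    if mapped.status != "mapped":
        return "unmappable"
    if assignment is not None and assignment.core_functional:
        return "in_domain"
    return "outside"


def annotate_variant(
    record: VariantRecord,
    mapped: MappedPosition,
    model: DomainModel,
    reference_anomaly: bool = False,
) -> AnnotatedVariant:
    assignment = None
    if mapped.status == "mapped":
        assignment = assign_domain(mapped.reference_position, model)
    return AnnotatedVariant(
        record=record,
        mapped=mapped,
        assignment=assignment,
        ahp=compute_ahp(record.population),
        homozygote=homozygote_flag(record.population),
        category=categorize_variant(record, mapped, assignment),
        reference_anomaly=reference_anomaly,
    )


@dataclass(frozen=True)
class DomainBurden:
    group: str
    n_snp_non_disease: int
    n_disease: int
    residue_extent: int


def domain_burden(annotated: Sequence[AnnotatedVariant], model: DomainModel) -> list[DomainBurden]:
    """Per-group benign and disease SNP counts over the core-functional groups.

    Each record counts once (multi-allele clusters are one position).  Benign
    counts cover category in_domain; disease-implicated records falling in a
    group are tallied separately and never mixed into the benign burden.
    """
    groups = [g for g in dict.fromkeys(d.group for d in model.domains)]
    benign = {g: 0 for g in groups}
    disease = {g: 0 for g in groups}
    for av in annotated:
        if av.assignment is None or not av.assignment.core_functional:
            continue
        g = av.assignment.group
        if av.category == "disease_implicated":
            disease[g] += 1
        elif av.category == "in_domain":
            benign[g] += 1
    return [
        DomainBurden(g, benign[g], disease[g], model.group_extent(g)) for g in groups
    ]


def per_domain_burden(
    annotated: Sequence[AnnotatedVariant], model: DomainModel
) -> dict[str, DomainBurden]:
    """Burdens at named-domain resolution (curated vicinity counts toward the
    domain it is near)."""
    out: dict[str, list[int]] = {d.name: [0, 0] for d in model.domains}
    for av in annotated:
        a = av.assignment
        if a is None or a.domain is None or not a.core_functional:
            continue
        if av.category == "disease_implicated":
            out[a.domain][1] += 1
        elif av.category == "in_domain":
            out[a.domain][0] += 1
    return {
        name: DomainBurden(model.domain(name).group, b, d, model.domain(name).extent)
        for name, (b, d) in out.items()
    }


@dataclass(frozen=True)
class ClassificationThresholds:
    # too_sensitive: at most this many benign SNPs alongside >=1 disease mutation
    max_benign_for_sensitive: int = 1
    # too_robust: at least this many benign SNPs
    min_benign_for_robust: int = 2


def classify_domain(
    burden: DomainBurden,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    coarse: bool = False,
) -> str:
    if coarse or burden.group == "none":
        return "unclassified"
    if (
        burden.n_snp_non_disease <= thresholds.max_benign_for_sensitive
        and burden.n_disease >= 1
    ):
        return "too_sensitive"
    if burden.n_snp_non_disease >= thresholds.min_benign_for_robust:
        return "too_robust"
    return "unclassified"


# -- substitution chemistry --------------------------------------------------

_PROPS: Optional[pd.DataFrame] = None


def residue_properties() -> pd.DataFrame:
    """Packaged per-residue property table, indexed by one-letter code."""
    global _PROPS
    if _PROPS is None:
        with resources.as_file(
            resources.files("motorsnp") / "data" / "residue_properties.tsv"
        ) as path:
            _PROPS = pd.read_csv(path, sep="\t", index_col="aa")
    return _PROPS


@dataclass(frozen=True)
class SubstitutionAssessment:
    native: str
    substituted: str
    charge_change: int
    polarity_change: str  # e.g. "charged->polar"
    size_change: float  # Å^2, substituted minus native surface area
    helix_propensity_change: str  # stabilizing | destabilizing | neutral
    special_flags: tuple[str, ...]


def assess_substitution(native: str, substituted: str) -> SubstitutionAssessment:
    """Deterministic physico-chemical report for one residue exchange."""
    props = residue_properties()
    for aa in (native, substituted):
        if aa not in props.index:
            raise ValueError(f"{aa!r} is not a standard amino acid")
    if native == substituted:
        raise ValueError("identical residue pair is not a substitution")
    n, s = props.loc[native], props.loc[substituted]
    d_helix = float(s["helix_penalty"] - n["helix_penalty"])  # penalty up = worse helix
    if abs(d_helix) < 0.05:
        helix = "neutral"
    else:
        helix = "destabilizing" if d_helix > 0 else "stabilizing"
    flags = []
    if substituted == "P":
        flags.append("proline_introduced")
    if native == "G":
        flags.append("glycine_lost")
    if substituted == "C":
        flags.append("cysteine_introduced")
    if substituted in "FWY" and native not in "FWY":
        flags.append("aromatic_introduced")
    return SubstitutionAssessment(
        native=native,
        substituted=substituted,
        charge_change=int(s["charge"] - n["charge"]),
        polarity_change=f"{n['polarity']}->{s['polarity']}",
        size_change=float(s["max_asa"] - n["max_asa"]),
        helix_propensity_change=helix,
        special_flags=tuple(flags),
    )


# -- probe candidates and the study summary ----------------------------------


@dataclass(frozen=True)
class ProbeCandidate:
    rs_id: int
    substitution: str
    reference_position: Optional[int]
    ahp: Optional[float]
    category: str
    domain_label: Optional[str]
    reference_anomaly: bool = False


def select_probe_candidates(
    annotated: Sequence[AnnotatedVariant], ahp_threshold: float = 0.5
) -> tuple[list[ProbeCandidate], list[ProbeCandidate]]:
    """Candidates for function-neutral probe insertion, plus anomalies.

    A candidate has AHP >= threshold (percent): healthy heterozygous carriers
    exist, so the substitution is tolerated in vivo.  Records whose
    substituted allele was homozygous in every tested subpopulation are
    returned separately flagged reference_anomaly — they indicate the
    reference sequence itself is likely wrong, not a tolerated substitution.
    """

    def as_candidate(av: AnnotatedVariant) -> ProbeCandidate:
        return ProbeCandidate(
            rs_id=av.record.rs_id,
            substitution=av.record.substitution_label(),
            reference_position=av.mapped.reference_position,
            ahp=av.ahp,
            category=av.category,
            domain_label=av.assignment.label if av.assignment else None,
            reference_anomaly=av.reference_anomaly,
        )

    candidates = [
        as_candidate(av)
        for av in annotated
        if av.ahp is not None and av.ahp >= ahp_threshold
    ]
    anomalies = [as_candidate(av) for av in annotated if av.reference_anomaly]
    return candidates, anomalies


@dataclass
class StudySummary:
    totals: dict[str, int]
    group_burdens: list[DomainBurden]
    domain_burdens: dict[str, DomainBurden]
    classifications: dict[str, str]
    domain_classifications: dict[str, str]
    candidates: list[ProbeCandidate]
    anomalies: list[ProbeCandidate]

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "group_burdens": [
                {
                    "group": b.group,
                    "n_snp_non_disease": b.n_snp_non_disease,
                    "n_disease": b.n_disease,
                    "residue_extent": b.residue_extent,
                }
                for b in self.group_burdens
            ],
            "domain_burdens": {
                name: {
                    "group": b.group,
                    "n_snp_non_disease": b.n_snp_non_disease,
                    "n_disease": b.n_disease,
                    "residue_extent": b.residue_extent,
                }
                for name, b in self.domain_burdens.items()
            },
            "classifications": self.classifications,
            "domain_classifications": self.domain_classifications,
            "candidates": [c.__dict__ for c in self.candidates],
            "anomalies": [c.__dict__ for c in self.anomalies],
        }


def summarize_study(
    annotated: Sequence[AnnotatedVariant],
    model: DomainModel,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    ahp_threshold: float = 0.5,
) -> StudySummary:
    """Headline counts, burdens, tolerance labels, and probe candidates.

    Conservation holds by construction: all = disease + unmappable +
    in_domain + outside, and in_domain equals the sum of group benign counts.
    """
    counts = {c: 0 for c in CATEGORIES}
    for av in annotated:
        counts[av.category] += 1
    totals = {
        "all": len(annotated),
        "disease_implicated": counts["disease_implicated"],
        "unmappable": counts["unmappable"],
        "remaining": counts["in_domain"] + counts["outside"],
        "in_domain": counts["in_domain"],
        "outside": counts["outside"],
    }
    burdens = domain_burden(annotated, model)
    dom_burdens = per_domain_burden(annotated, model)
    candidates, anomalies = select_probe_candidates(annotated, ahp_threshold)
    return StudySummary(
        totals=totals,
        group_burdens=burdens,
        domain_burdens=dom_burdens,
        classifications={b.group: classify_domain(b, thresholds) for b in burdens},
        domain_classifications={
            name: classify_domain(b, thresholds) for name, b in dom_burdens.items()
        },
        candidates=candidates,
        anomalies=anomalies,
    )
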