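"""Functional sub-domain geography of the myosin motor domain (S1).

The motor head's energy-transduction machinery is organized in conserved
sub-domains: the 7-stranded beta-sheet between the active and actin-binding
sites, Switch 1/Switch 2 (whose R246/E469 salt bridge is the phosphate-release
"back door"), the Switch 2 (relay) helix, the SH2/SH1 hinge with its G701
swivel, the converter, the lever-arm, the SH3 beta-barrel, and the
actin-binding loops (C-loop, Myopathy loop, Loops 2/3, the primary
hydrophobic contacts).  The model is shipped as an editable JSON data file
holding, in the skeletal 2x reference frame:

* core-functional intervals (1-based, inclusive on both ends);
* curated vicinity residues — positions assigned "near <domain>" by
  structural inspection rather than by interval membership;
* coarse regions (N-terminal, upper-50k, lower-50k and the residual
  C-terminal S1 segment) that tile the whole frame as a fallback.

Label precedence at a position: curated vicinity entry, then core-functional
interval, then coarse region.  The per-residue curated entries outrank the
intervals so that, e.g., residue 469 is labeled Switch 2 (beta-sheet group)
rather than merely the first residue of the Switch 2 helix interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

GROUPS = (
    "beta_sheet_region",
    "switch2_helix",
    "hinge",
    "converter",
    "lever_arm",
    "sh3",
    "actin_binding",
    "none",
)


@dataclass(frozen=True)
class DomainDefinition:
    name: str
    intervals: tuple[tuple[int, int], ...]
    category: str  # core_functional | coarse_region | annotation
    group: str = "none"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        spans = sorted(self.intervals)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError(f"{self.name}: overlapping intervals")
        for a, b in spans:
            if a < 1 or b < a:
                raise ValueError(f"{self.name}: bad interval [{a}, {b}]")

    def contains(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.intervals)

    @property
    def extent(self) -> int:
        return sum(b - a + 1 for a, b in self.intervals)


@dataclass(frozen=True)
class VicinityResidue:
    position: int
    label: str
    domain: str
    group: str


@dataclass(frozen=True)
class DomainAssignment:
    position: int
    label: str
    domain: Optional[str]
    group: str
    source: str  # interval | curated_vicinity | spatial | coarse
    tags: tuple[str, ...] = ()

    @property
    def core_functional(self) -> bool:
        return self.source in ("interval", "curated_vicinity", "spatial")


class DomainModel:
    """The packaged sub-domain model plus the position → label rule."""

    def __init__(
        self,
        domains: Sequence[DomainDefinition],
        curated_vicinity: Sequence[VicinityResidue],
        coarse_regions: Sequence[DomainDefinition],
        annotations: Sequence[DomainDefinition] = (),
        reference_length: int = 813,
        reference_name: str = "reference",
        special_tags: Optional[dict[int, tuple[str, ...]]] = None,
    ) -> None:
        self.domains = list(domains)
        self.curated = {v.position: v for v in curated_vicinity}
        self.coarse_regions = list(coarse_regions)
        self.annotations = list(annotations)
        self.reference_length = reference_length
        self.reference_name = reference_name
        self.special_tags = dict(special_tags or {})
        self._by_name = {d.name: d for d in self.domains}
        covered = set()
        for region in self.coarse_regions:
            for a, b in region.intervals:
                covered.update(range(a, b + 1))
        missing = set(range(1, reference_length + 1)) - covered
        if missing:
            raise ValueError(
                f"coarse regions do not tile 1..{reference_length}; "
                f"first uncovered position {min(missing)}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, payload: dict) -> "DomainModel":
        domains = [
            DomainDefinition(
                name=d["name"],
                intervals=tuple(tuple(iv) for iv in d["intervals"]),
                category=d.get("category", "core_functional"),
                group=d.get("group", "none"),
            )
            for d in payload["domains"]
        ]
        vicinity = [
            VicinityResidue(v["position"], v["label"], v["domain"], v["group"])
            for v in payload.get("curated_vicinity", [])
        ]
        coarse = [
            DomainDefinition(
                name=r["name"],
                intervals=tuple(tuple(iv) for iv in r["intervals"]),
                category="coarse_region",
            )
            for r in payload["coarse_regions"]
        ]
        annotations = [
            DomainDefinition(
                name=r["name"],
                intervals=tuple(tuple(iv) for iv in r["intervals"]),
                category="annotation",
            )
            for r in payload.get("annotations", [])
        ]
        tags = {
            int(pos): tuple(ts) for pos, ts in payload.get("special_tags", {}).items()
        }
        return cls(
            domains,
            vicinity,
            coarse,
            annotations,
            reference_length=payload.get("reference_length", 813),
            reference_name=payload.get("reference_name", "reference"),
            special_tags=tags,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def domain(self, name: str) -> DomainDefinition:
        return self._by_name[name]

    def group_extent(self, group: str) -> int:
        return sum(d.extent for d in self.domains if d.group == group)


def assign_domain(position: int, model: DomainModel) -> DomainAssignment:
    """Assign one reference position its unique sub-domain label.

    Precedence: curated vicinity residue, then core-functional interval, then
    enclosing coarse region.  Raises for positions outside the reference
    frame.  Positions carrying special tags (the G701 swivel) get them
    attached whatever the source.
    """
    if not (1 <= position <= model.reference_length):
        raise ValueError(
            f"position {position} outside reference frame 1..{model.reference_length}"
        )
    tags = model.special_tags.get(position, ())
    cur = model.curated.get(position)
    if cur is not None:
        return DomainAssignment(
            position, cur.label, cur.domain, cur.group, "curated_vicinity", tags
        )
    for dom in model.domains:
        if dom.contains(position):
            return DomainAssignment(position, dom.name, dom.name, dom.group, "interval", tags)
    for region in model.coarse_regions:
        if region.contains(position):
            return DomainAssignment(position, region.name, None, "none", "coarse", tags)
    raise AssertionError("coarse regions tile the frame; unreachable")


# -- structural proximity --------------------------------------------------


def _residue_heavy_atoms(structure, position: int):
    import gemmi

    coords = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.seqid.num == position:
                    for atom in residue:
                        if atom.element != gemmi.Element("H"):
                            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
        break  # first model only
    return coords


def spatial_vicinity(
    structure,
    position: int,
    domain: DomainDefinition | str,
    model: Optional[DomainModel] = None,
    cutoff: float = 8.0,
):
    """Classify a residue near/far from a sub-domain by atomic distance.

    ``structure`` is a ``gemmi.Structure`` (or a PDB path).  The residue at
    ``position`` is near the domain iff the minimum heavy-atom distance to
    any residue of the domain is <= ``cutoff`` (Å, default 8.0 — bracketing
    the most distant curated vicinity residue at ~7.5 Å).  Returns
    ``(verdict, min_distance)`` with verdict "near" or "far".
    """
    import gemmi

    if isinstance(structure, (str, Path)):
        structure = gemmi.read_structure(str(structure))
    if isinstance(domain, str):
        if model is None:
            raise ValueError("a DomainModel is required to look a domain up by name")
        domain = model.domain(domain)

    query = _residue_heavy_atoms(structure, position)
    if not query:
        raise ValueError(f"residue {position} absent from coordinates")
    if domain.contains(position):
        return "near", 0.0

    target = []
    for a, b in domain.intervals:
        for pos in range(a, b + 1):
            target.extend(_residue_heavy_atoms(structure, pos))
    if not target:
        raise ValueError(f"no residues of domain {domain.name!r} in coordinates")

    import numpy as np

    q = np.asarray(query)
    t = np.asarray(target)
    d2 = ((q[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    dmin = float(np.sqrt(d2.min()))
    return ("near" if dmin <= cutoff else "far"), dmin
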