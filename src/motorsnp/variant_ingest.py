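"""Parsing and consolidation of missense SNP cluster tables.

The raw input dialect is the flat tabular report produced when dbSNP cluster
records are reduced to one line per reported allele/position: columns are the
rs cluster id, gene symbol, function class, base change, amino-acid change,
and peptide position in the reporting isoform's own numbering.  A cluster may
span several physical rows: up to three alternative bases, alternative
splice-frame positions (e.g. the smooth-muscle loop-1 insert shifts every
position by 7), continuation rows with a blank cluster id, and verbatim
repeats.  ``parse_cluster_table`` reads the dialect row by row;
``consolidate_clusters`` folds the rows into one ``VariantRecord`` per rs id.

Position notation for catalog-style substitution strings:

* ``D108E``       exact — residue 108, D substituted by E
* ``R24P/L``      exact, two alternative substituted residues
* ``P(<82)L``     upstream bound — P→L somewhere before position 82; no
                  homology anchor exists, so the record is never mappable
* ``Y(389-390)H`` ambiguous range — likewise unmappable
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .population_stats import PopulationObservation

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ARROW = r"(?:-->|->|→)"


class PositionNotation(str, Enum):
    EXACT = "exact"
    UPSTREAM_BOUND = "upstream_bound"
    AMBIGUOUS_RANGE = "ambiguous_range"


@dataclass(frozen=True)
class RawClusterRow:
    """One physical row of the cluster-table dialect."""

    rs_id: int
    gene: str
    function_class: str
    base_change: tuple[str, str]
    aa_change: tuple[str, str]
    peptide_position: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for aa in self.aa_change:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{aa!r} is not a standard amino acid")
        if self.peptide_position < 1:
            raise ValueError("peptide position must be >= 1")


@dataclass(frozen=True)
class ParseError:
    line_number: int
    line: str
    reason: str


@dataclass(frozen=True)
class VariantRecord:
    """One consolidated rs cluster: a single substituted position in one gene."""

    rs_id: int
    gene: str
    isoform: str
    native_residue: str
    substituted_residues: tuple[str, ...]
    isoform_positions: tuple[int, ...]
    notation: PositionNotation = PositionNotation.EXACT
    upstream_bound: Optional[int] = None
    ambiguous_range: Optional[tuple[int, int]] = None
    population: tuple[PopulationObservation, ...] = ()
    disease_flag: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.substituted_residues:
            raise ValueError("a variant needs at least one substituted residue")
        for s in self.substituted_residues:
            if s == self.native_residue:
                raise ValueError(
                    f"rs{self.rs_id}: substituted residue equals native {s!r}"
                )

    def substitution_label(self) -> str:
        subs = "/".join(self.substituted_residues)
        if self.notation is PositionNotation.UPSTREAM_BOUND:
            return f"{self.native_residue}(<{self.upstream_bound}){subs}"
        if self.notation is PositionNotation.AMBIGUOUS_RANGE:
            a, b = self.ambiguous_range
            return f"{self.native_residue}({a}-{b}){subs}"
        return f"{self.native_residue}{self.isoform_positions[0]}{subs}"


_SUBST_RE = re.compile(
    r"^([A-Z])"
    r"(?:(\d+)|\(<(\d+)\)|\((\d+)-(\d+)\))"
    r"([A-Z](?:/[A-Z])*)$"
)


def parse_substitution(text: str):
    """Parse a catalog substitution string into its components.

    Returns ``(native, substituted_tuple, notation, positions, bound, rng)``.
    """
    m = _SUBST_RE.match(text.strip())
    if not m:
        raise ValueError(f"unparsable substitution {text!r}")
    native, exact, bound, lo, hi, subs = m.groups()
    substituted = tuple(subs.split("/"))
    for aa in (native, *substituted):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"{aa!r} in {text!r} is not a standard amino acid")
    if exact is not None:
        return native, substituted, PositionNotation.EXACT, (int(exact),), None, None
    if bound is not None:
        return native, substituted, PositionNotation.UPSTREAM_BOUND, (), int(bound), None
    return (
        native,
        substituted,
        PositionNotation.AMBIGUOUS_RANGE,
        (),
        None,
        (int(lo), int(hi)),
    )


_CHANGE_RE = re.compile(rf"^([A-Z])\s*{_ARROW}\s*([A-Z])$")

KNOWN_FUNCTION_CLASSES = frozenset(
    {"missense", "synonymous", "nonsense", "frameshift", "intron", "utr"}
)


def _split_fields(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    # whitespace dialect: the two change columns each hold "X -->Y"
    m = re.match(
        rf"^\s*(rs?\d+)?\s*(\S+)\s+(\S+)\s+([A-Z]\s*{_ARROW}\s*[A-Z])"
        rf"\s+([A-Z]\s*{_ARROW}\s*[A-Z])\s+(\d+)\s*$",
        line,
    )
    if not m:
        return []
    return [g or "" for g in m.groups()]


def _looks_like_header(fields: Sequence[str]) -> bool:
    joined = " ".join(fields).lower()
    return "cluster" in joined or "amino acid" in joined or "peptide" in joined


def parse_cluster_table(text: str) -> tuple[list[RawClusterRow], list[ParseError]]:
    """Parse cluster-table text into rows plus an error report.

    Malformed rows are collected in the error report with their line number,
    never silently dropped.  A blank cluster-id field continues the previous
    cluster.  Rows with an unrecognized function class are kept but flagged.
    """
    rows: list[RawClusterRow] = []
    errors: list[ParseError] = []
    current_rs: Optional[int] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = _split_fields(line)
        if len(fields) < 6:
            errors.append(ParseError(lineno, line, "wrong field count"))
            continue
        if _looks_like_header(fields):
            continue
        rs_field, gene, function, base_field, aa_field, pos_field = fields[:6]
        rs_field = rs_field.strip()
        if rs_field:
            m = re.fullmatch(r"(?:rs)?(\d+)", rs_field)
            if not m:
                errors.append(ParseError(lineno, line, f"bad cluster id {rs_field!r}"))
                continue
            current_rs = int(m.group(1))
        if current_rs is None:
            errors.append(ParseError(lineno, line, "continuation row before any cluster id"))
            continue
        bm = _CHANGE_RE.match(base_field.strip())
        am = _CHANGE_RE.match(aa_field.strip())
        if am is None:
            errors.append(ParseError(lineno, line, f"non-parsable amino acid change {aa_field!r}"))
            continue
        if bm is None:
            errors.append(ParseError(lineno, line, f"non-parsable base change {base_field!r}"))
            continue
        try:
            position = int(pos_field)
        except ValueError:
            errors.append(ParseError(lineno, line, f"non-integer position {pos_field!r}"))
            continue
        flags: tuple[str, ...] = ()
        if function.lower() not in KNOWN_FUNCTION_CLASSES:
            flags = ("unknown_function_class",)
        try:
            rows.append(
                RawClusterRow(
                    rs_id=current_rs,
                    gene=gene,
                    function_class=function.lower(),
                    base_change=(bm.group(1), bm.group(2)),
                    aa_change=(am.group(1), am.group(2)),
                    peptide_position=position,
                    flags=flags,
                )
            )
        except ValueError as exc:
            errors.append(ParseError(lineno, line, str(exc)))
    return rows, errors


def consolidate_clusters(
    rows: Iterable[RawClusterRow] | Iterable[VariantRecord],
    function_class: str = "missense",
) -> list[VariantRecord]:
    """Fold raw rows into one record per rs cluster.

    Alternative substituted residues collapse into ``substituted_residues``,
    alternative splice-frame positions into ``isoform_positions``.  Verbatim
    duplicate rows are deduplicated silently (the dialect demonstrably
    repeats them).  Only rows whose function class matches the filter are
    retained.  Conflicting native residues within a cluster flag the record
    ``inconsistent_native`` rather than raising.

    Passing already-consolidated records is a no-op (idempotence): records
    are merged by rs id, which leaves a consolidated set unchanged.
    """
    items = list(rows)
    if items and isinstance(items[0], VariantRecord):
        merged: dict[int, VariantRecord] = {}
        for rec in items:  # type: ignore[assignment]
            prev = merged.get(rec.rs_id)
            if prev is None:
                merged[rec.rs_id] = rec
            else:
                merged[rec.rs_id] = replace(
                    prev,
                    substituted_residues=tuple(
                        sorted(set(prev.substituted_residues) | set(rec.substituted_residues))
                    ),
                    isoform_positions=tuple(
                        sorted(set(prev.isoform_positions) | set(rec.isoform_positions))
                    ),
                )
        return sorted(merged.values(), key=lambda r: r.rs_id)

    kept = [r for r in items if r.function_class == function_class.lower()]
    seen: set = set()
    unique: list[RawClusterRow] = []
    for r in kept:
        key = (r.rs_id, r.gene, r.base_change, r.aa_change, r.peptide_position)
        if key not in seen:
            seen.add(key)
            unique.append(r)

    by_rs: dict[int, list[RawClusterRow]] = {}
    for r in unique:
        by_rs.setdefault(r.rs_id, []).append(r)

    records: list[VariantRecord] = []
    for rs_id in sorted(by_rs):
        group = by_rs[rs_id]
        natives = sorted({r.aa_change[0] for r in group})
        flags: tuple[str, ...] = ()
        if len(natives) > 1:
            flags = ("inconsistent_native",)
        genes = sorted({r.gene for r in group})
        if len(genes) > 1:
            flags = flags + ("inconsistent_gene",)
        records.append(
            VariantRecord(
                rs_id=rs_id,
                gene=genes[0],
                isoform=genes[0],
                native_residue=natives[0],
                substituted_residues=tuple(
                    sorted({r.aa_change[1] for r in group if r.aa_change[0] == natives[0]})
                ),
                isoform_positions=tuple(sorted({r.peptide_position for r in group})),
                flags=flags,
            )
        )
    return records


def records_to_tsv(records: Sequence[VariantRecord]) -> str:
    header = "rs_id\tgene\tisoform\tsubstitution\tpositions\tdisease\tflags"
    lines = [header]
    for r in records:
        lines.append(
            "\t".join(
                [
                    str(r.rs_id),
                    r.gene,
                    r.isoform,
                    r.substitution_label(),
                    ",".join(map(str, r.isoform_positions)) or "-",
                    "1" if r.disease_flag else "0",
                    ",".join(r.flags) or "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def records_to_json(records: Sequence[VariantRecord]) -> str:
    out = []
    for r in records:
        out.append(
            {
                "rs_id": r.rs_id,
                "gene": r.gene,
                "isoform": r.isoform,
                "native_residue": r.native_residue,
                "substituted_residues": list(r.substituted_residues),
                "isoform_positions": list(r.isoform_positions),
                "notation": r.notation.value,
                "upstream_bound": r.upstream_bound,
                "ambiguous_range": list(r.ambiguous_range) if r.ambiguous_range else None,
                "disease_flag": r.disease_flag,
                "flags": list(r.flags),
            }
        )
    return json.dumps(out, indent=1)
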