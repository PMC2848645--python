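"""Cross-isoform residue coordinate mapping into the skeletal 2x frame.

Every variant is reported in its own isoform's residue numbering.  To place
variants from 22 genes on one structural coordinate system they are mapped
into the fast skeletal 2x (MYH1) frame by deterministic global pairwise
alignment (Gotoh affine-gap dynamic programming, BLOSUM62, end gaps
penalized).  Positions falling in alignment gaps, or inside windows whose
local identity drops below a configurable floor, are classed unmappable —
isoforms lacking homology with the skeletal reference cannot be anchored.

Coordinates are 1-based throughout; alignment maps are strictly monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .variant_ingest import AMINO_ACIDS, PositionNotation, VariantRecord

NEG_INF = -1e9


@dataclass(frozen=True)
class AlignmentParams:
    """Global alignment parameters.

    gap_open is the score of the first residue of a gap, gap_extend of each
    additional residue (a gap of length L scores gap_open + (L-1)*gap_extend),
    matching the BLAST protein defaults 11/1.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    low_homology_floor: float = 50.0  # global %identity below which the map is flagged


@dataclass(frozen=True)
class HomologyGate:
    """Local-identity gate deciding mappability of a single position."""

    window: int = 21  # residues, centred on the query position
    min_local_identity: float = 50.0  # percent


@dataclass
class AlignmentMap:
    """Result of aligning one isoform against the reference.

    ``columns`` holds one (isoform_pos, reference_pos) pair per alignment
    column, with None marking a gap; ``pairs`` is the monotone subset where
    both positions are present.
    """

    isoform_name: str
    reference_name: str
    isoform_seq: str
    reference_seq: str
    columns: list[tuple[Optional[int], Optional[int]]]
    score: float
    percent_identity: float
    low_homology: bool = False
    _pairs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pairs = {i: j for i, j in self.columns if i is not None and j is not None}

    @property
    def pairs(self) -> dict[int, int]:
        return self._pairs

    def local_identity(self, isoform_pos: int, window: int = 21) -> float:
        """Percent identical columns in a window of alignment columns centred
        on the column holding ``isoform_pos``."""
        centre = None
        for k, (i, _) in enumerate(self.columns):
            if i == isoform_pos:
                centre = k
                break
        if centre is None:
            raise ValueError(f"isoform position {isoform_pos} not in alignment")
        half = window // 2
        lo, hi = max(0, centre - half), min(len(self.columns), centre + half + 1)
        n = hi - lo
        matches = 0
        for i, j in self.columns[lo:hi]:
            if i is not None and j is not None:
                if self.isoform_seq[i - 1] == self.reference_seq[j - 1]:
                    matches += 1
        return 100.0 * matches / n if n else 0.0


def _validate_sequence(seq: str, which: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{which} sequence contains non-standard residues {sorted(bad)}")
    return seq


def align_to_reference(
    isoform_seq: str,
    reference_seq: str,
    params: AlignmentParams = AlignmentParams(),
    isoform_name: str = "isoform",
    reference_name: str = "reference",
) -> AlignmentMap:
    """Global (end-to-end) affine-gap alignment of isoform vs reference.

    Deterministic: ties in the dynamic program are broken in a fixed order
    (diagonal, then gap in the reference, then gap in the isoform), so the
    same inputs always give byte-identical maps.
    """
    a = _validate_sequence(isoform_seq, "isoform")
    b = _validate_sequence(reference_seq, "reference")
    matrix = substitution_matrices.load(params.matrix)
    alphabet = matrix.alphabet
    ai = np.array([alphabet.index(c) for c in a], dtype=np.intp)
    bi = np.array([alphabet.index(c) for c in b], dtype=np.intp)
    sub = np.asarray(matrix, dtype=np.float64)
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend

    # Three-state Gotoh: M diagonal, X = gap in reference (isoform residue
    # unmatched), Y = gap in isoform.  Row-vectorized; the Y recurrence is a
    # running max handled with the cumulative-max transform.
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    js = np.arange(1, m + 1)
    Y[0, 1:] = go + (js - 1) * ge
    ext = ge * js
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
        srow = sub[ai[i - 1], bi]
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = best_prev + srow
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + go, X[i - 1, 1:] + ge), Y[i - 1, 1:] + go
        )
        base = np.maximum(M[i, :-1], X[i, :-1]) + go
        # Y[i,j] = max_{k<=j} (base_k + (j-k)*ge) via cumulative max,
        # where base_k scores a gap opened at column k
        Y[i, 1:] = np.maximum.accumulate(base - ext) + ext

    # traceback, fixed preference M > X > Y
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    score = float(finals[state])
    cols: list[tuple[Optional[int], Optional[int]]] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            cols.append((i, j))
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:  # X: a[i-1] vs gap
            cols.append((i, None))
            if j == 0:
                i -= 1
                continue
            cands = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            state = int(np.argmax(np.isclose(cands, X[i, j], atol=1e-6) * 1.0))
            # argmax over booleans picks the first True -> M > X > Y preference
            i -= 1
        else:  # Y: gap vs b[j-1]
            cols.append((None, j))
            if i == 0:
                j -= 1
                continue
            cands = (M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
            state = int(np.argmax(np.isclose(cands, Y[i, j], atol=1e-6) * 1.0))
            j -= 1
    cols.reverse()

    matches = sum(
        1
        for ci, cj in cols
        if ci is not None and cj is not None and a[ci - 1] == b[cj - 1]
    )
    identity = 100.0 * matches / len(cols) if cols else 0.0
    return AlignmentMap(
        isoform_name=isoform_name,
        reference_name=reference_name,
        isoform_seq=a,
        reference_seq=b,
        columns=cols,
        score=score,
        percent_identity=identity,
        low_homology=identity < params.low_homology_floor,
    )


@dataclass(frozen=True)
class MappedPosition:
    reference_position: Optional[int]
    reference_native_residue: Optional[str]
    status: str  # "mapped" | "unmappable"
    native_differs: bool = False

    def __post_init__(self) -> None:
        if (self.status == "mapped") != (self.reference_position is not None):
            raise ValueError("status must be 'mapped' iff a reference position is set")


UNMAPPABLE = MappedPosition(None, None, "unmappable")


def map_position(
    amap: AlignmentMap,
    record: VariantRecord,
    gate: HomologyGate = HomologyGate(),
) -> MappedPosition:
    """Translate a variant's isoform position into the reference frame.

    Upstream-bound and ambiguous-range notations have no exact position and
    return unmappable, as do positions in alignment gaps or in windows below
    the local-identity floor.  When a record carries alternative splice-frame
    positions, the frame whose isoform residue matches the record's native
    residue is used.
    """
    if record.notation is not PositionNotation.EXACT:
        return UNMAPPABLE
    candidates = [
        p for p in record.isoform_positions
        if p <= len(amap.isoform_seq) and amap.isoform_seq[p - 1] == record.native_residue
    ]
    if not candidates:
        if all(p > len(amap.isoform_seq) for p in record.isoform_positions):
            raise ValueError(
                f"rs{record.rs_id}: position(s) {record.isoform_positions} beyond "
                f"isoform length {len(amap.isoform_seq)}"
            )
        return UNMAPPABLE
    for pos in candidates:
        ref_pos = amap.pairs.get(pos)
        if ref_pos is None:
            continue
        if amap.local_identity(pos, gate.window) < gate.min_local_identity:
            continue
        ref_native = amap.reference_seq[ref_pos - 1]
        return MappedPosition(
            reference_position=ref_pos,
            reference_native_residue=ref_native,
            status="mapped",
            native_differs=ref_native != record.native_residue,
        )
    return UNMAPPABLE


def fixture_mapped_position(record: VariantRecord, reference_residue: Optional[str]) -> MappedPosition:
    """Mapping when only the printed catalog (no sequences) is available.

    The catalog's reference-frame column is accepted directly: exact
    positions are already in the skeletal 2x frame, bound/range notations are
    unmappable.  ``reference_residue`` is the printed reference residue when
    it differs from the isoform's native residue, else None.
    """
    if record.notation is not PositionNotation.EXACT:
        return UNMAPPABLE
    pos = record.isoform_positions[0]
    ref_native = reference_residue or record.native_residue
    return MappedPosition(
        reference_position=pos,
        reference_native_residue=ref_native,
        status="mapped",
        native_differs=reference_residue is not None,
    )


def map_to_tsv(amap: AlignmentMap, gate: HomologyGate = HomologyGate()) -> str:
    lines = ["isoform_pos\treference_pos\tlocal_identity"]
    for iso, ref in amap.columns:
        if iso is None:
            continue
        lines.append(
            f"{iso}\t{ref if ref is not None else '-'}\t"
            f"{amap.local_identity(iso, gate.window):.1f}"
        )
    return "\n".join(lines) + "\n"
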