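"""Manually-designed-motif (MDM) matching and catalytic-triad verification.

Nitrilases of the carbon-nitrogen hydrolase superfamily carry a Glu/Lys/Cys
catalytic triad. The screen uses two sets of four hand-designed, class-specific
sequence patterns (aliphatic vs aromatic substrate preference) written in a
PROSITE-like dash syntax: ``[FL]-[ILV]-...-X-...`` where a bracketed group
lists alternative residues and ``X`` matches any residue. The first three
patterns of each class each house one triad residue.

Matching is deterministic: :func:`match_strict` requires every element to
accept its residue; :func:`match_fuzzy` aligns a protein window against any
contiguous block of pattern elements and reports it when the mismatch fraction
is small enough, which is how divergent-but-recognisable motif regions in real
nitrilase homologs register.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from typing import Iterable, Literal, Optional

from .seqio import AA_ALPHABET, ProteinSequence

DEFAULT_MIN_ELEMENTS = 8
DEFAULT_MAX_MISMATCH_FRACTION = 0.3


class MotifParseError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MotifElement:
    """One pattern position: a fixed residue, an alternative set, or X."""

    kind: Literal["fixed", "alternatives", "wildcard"]
    residues: str = ""  # ordered; empty for wildcard
    catalytic: Optional[str] = None  # "E", "K" or "C"

    def matches(self, residue: str) -> bool:
        return self.kind == "wildcard" or residue in self.residues


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    id: str
    class_label: Literal["aliphatic", "aromatic"]
    elements: tuple[MotifElement, ...]

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def catalytic_positions(self) -> dict[str, int]:
        """Triad residue -> 0-based element index."""
        return {e.catalytic: i for i, e in enumerate(self.elements) if e.catalytic}

    def to_string(self) -> str:
        toks = []
        for e in self.elements:
            if e.kind == "wildcard":
                toks.append("X")
            elif e.kind == "fixed":
                toks.append(e.residues)
            else:
                toks.append(f"[{e.residues}]")
        return "-".join(toks)


@dataclasses.dataclass(frozen=True)
class MotifMatch:
    pattern_id: str
    protein_id: str
    start: int  # 0-based position in the protein
    matched_span: str
    elements_covered: int
    mismatches: int
    strict: bool
    element_start: int = 0  # 0-based index of first pattern element covered

    @property
    def mismatch_fraction(self) -> float:
        return self.mismatches / self.elements_covered

    @property
    def end(self) -> int:
        return self.start + len(self.matched_span)


def parse_motif(text: str, id: str, class_label: str,
                catalytic: dict[str, int] | None = None) -> MotifPattern:
    """Parse a dash-delimited pattern string.

    ``catalytic`` maps a triad residue letter to its 1-based element index.
    Emphasis markers (``*``) and stray whitespace in the source are stripped.
    A bracketed group containing X is a wildcard (X means "any" everywhere).
    """
    cleaned = text.replace("*", "").replace(" ", "")
    tokens = [t for t in cleaned.split("-") if t]  # tolerate trailing dashes
    elements: list[MotifElement] = []
    for idx, tok in enumerate(tokens):
        if tok.startswith("[") and tok.endswith("]"):
            group = tok[1:-1]
            bad = set(group) - AA_ALPHABET - {"X"}
            if bad:
                raise MotifParseError(
                    f"{id}: illegal letter(s) {sorted(bad)} in token {idx}: {tok!r}")
            if len(group) < 2:
                raise MotifParseError(
                    f"{id}: singleton bracket group in token {idx}: {tok!r}")
            if "X" in group:
                elements.append(MotifElement("wildcard"))
            else:
                elements.append(MotifElement("alternatives", group))
        elif tok == "X":
            elements.append(MotifElement("wildcard"))
        elif len(tok) == 1 and tok in AA_ALPHABET:
            elements.append(MotifElement("fixed", tok))
        else:
            raise MotifParseError(f"{id}: malformed token {idx}: {tok!r}")
    if catalytic:
        for residue, pos_1b in catalytic.items():
            i = pos_1b - 1
            if not 0 <= i < len(elements):
                raise MotifParseError(f"{id}: catalytic index {pos_1b} out of range")
            e = elements[i]
            elements[i] = MotifElement(e.kind, e.residues, residue)
    return MotifPattern(id, class_label, tuple(elements))


def load_motifs() -> list[MotifPattern]:
    """The packaged MDM set: four aliphatic + four aromatic patterns."""
    raw = json.loads(
        resources.files("nitriminer.data").joinpath("motifs.json").read_text())
    return [
        parse_motif(p["pattern"], p["id"], p["class_label"], p.get("catalytic"))
        for p in raw["patterns"]
    ]


def load_observed_matches() -> dict[str, dict[str, str]]:
    """Packaged observed motif-region snippets (positive controls)."""
    raw = json.loads(
        resources.files("nitriminer.data")
        .joinpath("observed_matches.json").read_text())
    return raw["snippets"]


def match_strict(pattern: MotifPattern, protein: ProteinSequence) -> list[MotifMatch]:
    """All windows where every residue is accepted by its pattern element."""
    k = len(pattern)
    seq = protein.seq
    out = []
    for p in range(len(seq) - k + 1):
        if all(e.matches(seq[p + i]) for i, e in enumerate(pattern.elements)):
            out.append(MotifMatch(pattern.id, protein.id, p, seq[p:p + k],
                                  k, 0, True))
    return out


def _fuzzy_candidates(pattern: MotifPattern, seq: str, min_elements: int,
                      max_fraction: float):
    n = len(pattern)
    for k in range(min_elements, n + 1):
        # tolerant floor so mismatches/k == max_fraction is accepted exactly
        max_mm = int(max_fraction * k + 1e-9)
        for es in range(0, n - k + 1):
            block = pattern.elements[es:es + k]
            for p in range(len(seq) - k + 1):
                mm = sum(1 for i, e in enumerate(block) if not e.matches(seq[p + i]))
                if mm <= max_mm:
                    yield p, k, es, mm


def match_fuzzy(pattern: MotifPattern, protein: ProteinSequence,
                min_elements: int = DEFAULT_MIN_ELEMENTS,
                max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
                ) -> list[MotifMatch]:
    """Best contiguous alignments of protein windows to pattern-element blocks.

    Every window/block pair with ``mismatches / elements_covered`` at or below
    the threshold and at least ``min_elements`` elements covered is a
    candidate; overlapping candidates are deduplicated keeping the lowest
    mismatch fraction (ties: widest coverage, then leftmost). Full-coverage
    zero-mismatch matches are never suppressed by one another, so every strict
    match is also reported here.
    """
    if min_elements > len(pattern):
        raise ValueError("min_elements exceeds pattern length")
    seq = protein.seq
    cands = [
        MotifMatch(pattern.id, protein.id, p, seq[p:p + k], k, mm,
                   mm == 0 and k == len(pattern), es)
        for p, k, es, mm in _fuzzy_candidates(
            pattern, seq, min_elements, max_mismatch_fraction)
    ]
    cands.sort(key=lambda m: (m.mismatch_fraction, -m.elements_covered, m.start,
                              m.element_start))
    kept: list[MotifMatch] = []
    for m in cands:
        overlaps = any(m.start < o.end and o.start < m.end for o in kept)
        if not overlaps or m.strict:
            kept.append(m)
    kept.sort(key=lambda m: (m.start, m.element_start))
    return kept


def best_match(pattern: MotifPattern, protein: ProteinSequence,
               min_elements: int = DEFAULT_MIN_ELEMENTS,
               max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
               ) -> Optional[MotifMatch]:
    """Best single match, strict preferred over fuzzy."""
    strict = match_strict(pattern, protein)
    if strict:
        return strict[0]
    fuzzy = match_fuzzy(pattern, protein, min_elements, max_mismatch_fraction)
    if not fuzzy:
        return None
    return min(fuzzy, key=lambda m: (m.mismatch_fraction, -m.elements_covered,
                                     m.start))


def locate_triad(protein: ProteinSequence,
                 class_patterns: Iterable[MotifPattern]) -> dict:
    """Locate the E/K/C catalytic triad via the class's tagged patterns.

    For each triad residue, the position is the protein index aligned to the
    tagged element in the best match of the pattern carrying that tag; the
    residue found there must actually be E/K/C respectively. ``complete`` is
    true when all three are located and verified.
    """
    report: dict = {"E": None, "K": None, "C": None}
    for pattern in class_patterns:
        for residue, elem_idx in pattern.catalytic_positions.items():
            m = best_match(pattern, protein)
            if m is None:
                continue
            if not (m.element_start <= elem_idx < m.element_start + m.elements_covered):
                continue  # fuzzy block does not cover the tagged element
            pos = m.start + (elem_idx - m.element_start)
            if protein.seq[pos] == residue:
                report[residue] = pos
    report["complete"] = all(report[r] is not None for r in "EKC")
    return report


def match_table(matches: Iterable[MotifMatch],
                class_of: dict[str, str]) -> list[dict]:
    """Match report rows (1-based starts) for TSV output."""
    return [
        {
            "protein_id": m.protein_id,
            "pattern_id": m.pattern_id,
            "class": class_of.get(m.pattern_id, ""),
            "start_1based": m.start + 1,
            "span": m.matched_span,
            "covered": m.elements_covered,
            "mismatches": m.mismatches,
            "strict": m.strict,
        }
        for m in matches
    ]
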