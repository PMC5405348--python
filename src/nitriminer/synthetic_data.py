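"""Seeded synthetic genomes with implanted nitrilase-like genes.

The generator emulates the inputs of the genome screen with known truth:
bacterial contigs carrying (a) implanted nitrilase-like ORFs that strictly
match all four manually designed motifs of one class, contain the E/K/C
triad, and sit at a controlled percent identity to a reference protein;
(b) unrelated background ORFs that survive the length filter but not the
homology window; and (c) sub-100-codon decoys that the length filter must
discard. Proteins are back-translated with uniform synonymous codon choice
under genetic code table 11, given an ATG start and TAA stop, and placed on a
random strand at random non-overlapping loci. Implants are insulated by a
short all-frame stop cassette so neighbouring sequence cannot read through.

All randomness flows from a single numpy Generator per call; identical
(config, seed) pairs produce byte-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .motif_engine import MotifPattern, load_motifs
from .seqio import NucleotideContig, ProteinSequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: stops translation in all six frames; palindromic under reverse complement
STOP_CASSETTE = "TTAATTAATTAA"

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    contig_id: str
    start: int  # CDS span incl. stop codon, forward-strand 0-based half-open
    end: int
    strand: str
    class_label: str  # aliphatic | aromatic | background | decoy_short
    designed_identity_to_ref: Optional[float] = None


@dataclasses.dataclass(frozen=True)
class GenomeConfig:
    n_aliphatic: int = 3
    n_aromatic: int = 2
    n_background: int = 3
    n_decoy: int = 5
    contig_length: int = 40_000
    n_contigs: int = 1
    nitrilase_length_range: tuple[int, int] = (260, 342)
    background_length_range: tuple[int, int] = (120, 200)
    decoy_length_range: tuple[int, int] = (30, 60)
    target_identity: float = 50.0
    reference: Optional[ProteinSequence] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        ref = d.pop("reference")
        d["reference_id"] = ref["id"] if ref else None
        return d


def _random_protein(rng: np.random.Generator, length: int,
                    name: str) -> ProteinSequence:
    aa = "M" + "".join(rng.choice(list(AA20), size=length - 1))
    return ProteinSequence(name, aa)


def generate_nitrilase_protein(class_label: str, length: int, seed=None,
                               rng: Optional[np.random.Generator] = None,
                               backbone: Optional[str] = None,
                               name: str = "synthetic",
                               patterns: Optional[list[MotifPattern]] = None,
                               ) -> tuple[ProteinSequence, dict[str, tuple[int, int]]]:
    """A protein strictly matching all four motifs of one class, in order.

    Motifs are separated by random (or backbone-derived) spacers; element
    residues are drawn from each element's allowed set, so the catalytic
    E/K/C land on their tagged elements. Returns the protein and the map of
    pattern id -> (start, end) span.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if patterns is None:
        patterns = load_motifs()
    pats = [p for p in patterns if p.class_label == class_label]
    total = sum(len(p) for p in pats)
    n_inner_gaps = len(pats)  # one before each motif (after the leading M)
    if length < 1 + total + n_inner_gaps:
        raise ValueError(
            f"length {length} infeasible: need >= {1 + total + n_inner_gaps}")

    budget = length - 1 - total  # residues available for spacers
    cuts = np.sort(rng.integers(0, budget - n_inner_gaps + 1, size=len(pats)))
    gaps = np.diff(np.concatenate([[0], cuts, [budget - n_inner_gaps]])) + 1
    gaps[-1] -= 1  # tail spacer may be empty

    def filler(pos: int, k: int) -> str:
        if backbone:
            return "".join(backbone[(pos + i) % len(backbone)] for i in range(k))
        return "".join(rng.choice(list(AA20), size=k))

    seq = "M"
    placements: dict[str, tuple[int, int]] = {}
    for pat, gap in zip(pats, gaps[:len(pats)]):
        seq += filler(len(seq), int(gap))
        start = len(seq)
        for e in pat.elements:
            pool = e.residues if e.kind != "wildcard" else AA20
            seq += pool[rng.integers(0, len(pool))]
        placements[pat.id] = (start, len(seq))
    seq += filler(len(seq), int(gaps[-1]))
    assert len(seq) == length
    return ProteinSequence(name, seq), placements


def mutate_to_identity(p: ProteinSequence, target: float, seed=None,
                       rng: Optional[np.random.Generator] = None,
                       frozen_positions: tuple[tuple[int, int], ...] = (),
                       name: Optional[str] = None) -> ProteinSequence:
    """Point-mutate outside frozen spans to a target percent identity.

    The realised (position-wise) identity is the nearest achievable to
    ``target`` given the sequence length; an infeasible target (too many
    frozen positions) raises with the minimum achievable identity.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    L = len(p)
    frozen = set()
    for s, e in frozen_positions:
        frozen.update(range(s, e))
    mutable = [i for i in range(L) if i not in frozen]
    n_mut = int(round((1.0 - target / 100.0) * L))
    if n_mut > len(mutable):
        min_achievable = 100.0 * (L - len(mutable)) / L
        raise ValueError(
            f"target {target}% infeasible with frozen spans; "
            f"minimum achievable identity is {min_achievable:.1f}%")
    sites = rng.choice(mutable, size=n_mut, replace=False)
    seq = list(p.seq)
    for i in sites:
        alternatives = AA20.replace(seq[i], "")
        seq[i] = alternatives[rng.integers(0, len(alternatives))]
    return ProteinSequence(name or f"{p.id}|mut{target:g}", "".join(seq))


def back_translate(protein: ProteinSequence,
                   rng: np.random.Generator) -> str:
    """CDS with ATG start, uniform synonymous codons, and a TAA stop."""
    codons = ["ATG"]
    for aa in protein.seq[1:]:
        pool = _CODONS_FOR[aa]
        codons.append(pool[rng.integers(0, len(pool))])
    codons.append("TAA")
    return "".join(codons)


def generate_genome(config: GenomeConfig, seed: int,
                    ) -> tuple[list[NucleotideContig], list[TruthRecord],
                               dict[str, ProteinSequence]]:
    """Synthetic contigs plus a truth table and the implanted proteins.

    Genes are assigned to contigs round-robin in a shuffled order; each
    contig lays its genes left to right with random background gaps. Raises
    if the genes do not fit in their contig.
    """
    rng = np.random.default_rng(seed)
    patterns = load_motifs()

    specs: list[tuple[str, str]] = []  # (gene_id, class_label)
    specs += [(f"ali_{i}", "aliphatic") for i in range(config.n_aliphatic)]
    specs += [(f"aro_{i}", "aromatic") for i in range(config.n_aromatic)]
    specs += [(f"bg_{i}", "background") for i in range(config.n_background)]
    specs += [(f"decoy_{i}", "decoy_short") for i in range(config.n_decoy)]

    proteins: dict[str, ProteinSequence] = {}
    identities: dict[str, Optional[float]] = {}
    for gene_id, label in specs:
        if label in ("aliphatic", "aromatic"):
            lo, hi = config.nitrilase_length_range
            length = int(rng.integers(lo, hi + 1))
            backbone = config.reference.seq if config.reference else None
            prot, placements = generate_nitrilase_protein(
                label, length, rng=rng, backbone=backbone, name=gene_id,
                patterns=patterns)
            if config.reference is not None:
                prot = mutate_to_identity(
                    prot, config.target_identity, rng=rng,
                    frozen_positions=tuple(placements.values()), name=gene_id)
                identities[gene_id] = config.target_identity
            else:
                identities[gene_id] = None
        else:
            lo, hi = (config.background_length_range if label == "background"
                      else config.decoy_length_range)
            length = int(rng.integers(lo, hi + 1))
            prot = _random_protein(rng, length, gene_id)
            identities[gene_id] = None
        proteins[gene_id] = prot

    order = [specs[i] for i in rng.permutation(len(specs))]
    per_contig: list[list[tuple[str, str]]] = [[] for _ in range(config.n_contigs)]
    for k, item in enumerate(order):
        per_contig[k % config.n_contigs].append(item)

    contigs: list[NucleotideContig] = []
    truth: list[TruthRecord] = []
    for ci, genes in enumerate(per_contig):
        contig_id = f"contig_{ci}"
        inserts = []
        for gene_id, label in genes:
            cds = back_translate(proteins[gene_id], rng)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            inserts.append((gene_id, label, cds, strand))
        used = sum(len(c) + 2 * len(STOP_CASSETTE) for _, _, c, _ in inserts)
        if used > config.contig_length:
            raise ValueError(
                f"{contig_id}: genes need {used} nt > contig length "
                f"{config.contig_length}")
        budget = config.contig_length - used
        cuts = np.sort(rng.integers(0, budget + 1, size=len(inserts)))
        gaps = np.diff(np.concatenate([[0], cuts, [budget]]))

        seq_parts: list[str] = []
        pos = 0
        for (gene_id, label, cds, strand), gap in zip(inserts, gaps[:-1]):
            filler = "".join(rng.choice(list("ACGT"), size=int(gap)))
            seq_parts.append(filler)
            pos += int(gap)
            oriented = cds if strand == "+" else _revcomp(cds)
            seq_parts.append(STOP_CASSETTE)
            pos += len(STOP_CASSETTE)
            start = pos
            seq_parts.append(oriented)
            pos += len(cds)
            truth.append(TruthRecord(
                gene_id, contig_id, start, pos, strand, label,
                identities[gene_id]))
            seq_parts.append(STOP_CASSETTE)
            pos += len(STOP_CASSETTE)
        tail = "".join(rng.choice(list("ACGT"), size=int(gaps[-1])))
        seq_parts.append(tail)
        contigs.append(NucleotideContig(contig_id, "".join(seq_parts)))
    return contigs, truth, proteins


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def truth_table(records) -> list[dict]:
    return [
        {
            "gene_id": t.gene_id,
            "contig_id": t.contig_id,
            "start_1based": t.start + 1,
            "end_1based": t.end,
            "strand": t.strand,
            "class_label": t.class_label,
            "designed_identity_to_ref": t.designed_identity_to_ref,
        }
        for t in records
    ]
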