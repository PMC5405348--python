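"""End-to-end screen: contigs -> ORFs -> homology window -> motifs ->
physicochemical profiles -> class labels -> tree placement.

Stages run strictly in order and every per-candidate decision is logged, so
the report exposes the filter funnel: a candidate absent at one stage is
absent at all later ones. The run is deterministic for a fixed configuration;
the report carries a hash of the configuration for exact reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

from . import __version__
from .classifier import classification_table, classify_combined
from .homology import IdentityWindow, identity_filter
from .motif_engine import load_motifs
from .physchem import profile_table, property_profile
from .phylo import cluster_concordance, nj_tree, pdistance_matrix
from .seqio import (NucleotideContig, ProteinSequence, find_orfs, orf_table,
                    read_fasta)

logger = logging.getLogger("nitriminer")


@dataclasses.dataclass
class PipelineConfig:
    genomes: list[str] = dataclasses.field(default_factory=list)
    reference: Optional[str] = None  # FASTA with one reference protein
    candidates: Optional[str] = None  # optional pre-made protein FASTA
    reference_set: Optional[str] = None  # labelled proteins for the tree
    min_aa: int = 100
    identity_low: float = 30.0
    identity_high: float = 80.0
    motif_min_required: int = 3

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclasses.dataclass
class ScreenReport:
    metadata: dict
    orfs: list[dict]
    homology: list[dict]
    candidates: list[dict]  # one row per candidate surviving the length filter
    motifs: list[dict]
    properties: list[dict]
    classification: list[dict]
    tree_newick: Optional[str]
    concordance: Optional[list[dict]]
    concordance_fraction: Optional[float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenReport":
        return cls(**d)


def _label_from_id(name: str) -> Optional[str]:
    low = name.lower()
    if "aliphatic" in low:
        return "aliphatic"
    if "aromatic" in low:
        return "aromatic"
    return None


def run_pipeline(config: PipelineConfig,
                 contigs: Optional[list[NucleotideContig]] = None,
                 reference: Optional[ProteinSequence] = None,
                 candidate_proteins: Optional[list[ProteinSequence]] = None,
                 reference_set: Optional[list[ProteinSequence]] = None,
                 ) -> ScreenReport:
    """Run the full screen.

    Inputs may come from the FASTA paths in ``config`` or be passed directly
    as in-memory objects (the latter win). Raises before any stage runs if
    required inputs are missing.
    """
    if contigs is None:
        contigs = []
        for path in config.genomes:
            if not Path(path).exists():
                raise FileNotFoundError(f"genome FASTA not found: {path}")
            contigs.extend(read_fasta(path, "nucleotide"))
    if reference is None:
        if config.reference is None:
            raise ValueError("a reference protein is required")
        reference = read_fasta(config.reference, "protein")[0]
    if candidate_proteins is None and config.candidates:
        candidate_proteins = read_fasta(config.candidates, "protein")
    if reference_set is None and config.reference_set:
        reference_set = read_fasta(config.reference_set, "protein")

    patterns = load_motifs()
    window = IdentityWindow(config.identity_low, config.identity_high)

    # stage 1: ORF extraction with the length-based false-positive filter
    all_orfs = []
    for contig in contigs:
        found = find_orfs(contig, min_aa=config.min_aa)
        logger.info("contig %s: %d ORFs >= %d aa", contig.id, len(found),
                    config.min_aa)
        all_orfs.extend(found)
    if not contigs:
        logger.warning("no contigs supplied")
    proteins = [o.protein for o in all_orfs]
    if candidate_proteins:
        proteins = proteins + list(candidate_proteins)

    # stage 2: identity window against the reference
    retained, homology_log = identity_filter(proteins, reference, window)
    for row in homology_log:
        logger.info("homology %(candidate_id)s: %(identity_pct)s%% "
                    "-> %(verdict)s", row)

    # stage 3: motif screen + classification (motifs, then properties)
    motif_rows: list[dict] = []
    survivors = []
    results = []
    profiles = []
    for prot in retained:
        result = classify_combined(prot, patterns,
                                   profile=None,
                                   min_required=config.motif_min_required)
        best_class_hits = max(result.motif_evidence.total_hits.values())
        if best_class_hits < config.motif_min_required:
            logger.info("motifs %s: best class hits %d < %d -> discarded",
                        prot.id, best_class_hits, config.motif_min_required)
            motif_rows.append({"protein_id": prot.id,
                               "ali_hits": result.motif_evidence.total_hits["aliphatic"],
                               "aro_hits": result.motif_evidence.total_hits["aromatic"],
                               "verdict": "discarded"})
            continue
        motif_rows.append({"protein_id": prot.id,
                           "ali_hits": result.motif_evidence.total_hits["aliphatic"],
                           "aro_hits": result.motif_evidence.total_hits["aromatic"],
                           "verdict": "retained"})
        # stage 4: physicochemical profile feeds the final classification
        profile = property_profile(prot)
        profiles.append(profile)
        result = classify_combined(prot, patterns, profile=profile,
                                   min_required=config.motif_min_required)
        survivors.append(prot)
        results.append(result)

    # stage 5: tree placement among labelled references
    tree_newick = None
    concordance_rows = None
    concordance_fraction = None
    if reference_set and survivors:
        labelled = {r.id: _label_from_id(r.id) for r in reference_set}
        labelled = {k: v for k, v in labelled.items() if v}
        if len(labelled) >= 2 and len(reference_set) + len(survivors) >= 3:
            seqs = list(reference_set) + survivors
            tree = nj_tree(pdistance_matrix(seqs))
            tree_newick = tree.newick()
            query_labels = {r.protein_id: r.label for r in results}
            concordance_fraction, concordance_rows = cluster_concordance(
                tree, query_labels, labelled)

    retained_ids = {p.id for p in retained}
    survivor_ids = {p.id for p in survivors}
    class_by_id = {r.protein_id: r for r in results}
    candidate_rows = []
    for o, prot in zip(all_orfs, [o.protein for o in all_orfs]):
        row = {
            "protein_id": prot.id,
            "contig_id": o.contig_id,
            "start_1based": o.start + 1,
            "end_1based": o.end,
            "strand": o.strand,
            "aa_length": len(prot),
            "passed_homology": prot.id in retained_ids,
            "passed_motifs": prot.id in survivor_ids,
            "label": (class_by_id[prot.id].label
                      if prot.id in survivor_ids else None),
            "triad_complete": (class_by_id[prot.id].triad_complete
                               if prot.id in survivor_ids else None),
        }
        candidate_rows.append(row)

    metadata = {
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "version": __version__,
        "n_contigs": len(contigs),
        "n_orfs": len(all_orfs),
        "n_after_homology": len(retained),
        "n_after_motifs": len(survivors),
    }
    return ScreenReport(
        metadata=metadata,
        orfs=orf_table(all_orfs),
        homology=homology_log,
        candidates=candidate_rows,
        motifs=motif_rows,
        properties=profile_table(profiles),
        classification=classification_table(results),
        tree_newick=tree_newick,
        concordance=concordance_rows,
        concordance_fraction=concordance_fraction,
    )


def _write_tsv(rows: list[dict], path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def write_report(report: ScreenReport, out_dir: str | Path,
                 formats: tuple[str, ...] = ("tsv", "json")) -> list[Path]:
    """Write per-stage TSV tables, a JSON bundle, and the newick tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "tsv" in formats:
        for name in ("orfs", "homology", "candidates", "motifs",
                     "properties", "classification"):
            path = out / f"{name}.tsv"
            _write_tsv(getattr(report, name), path)
            written.append(path)
        if report.concordance is not None:
            path = out / "concordance.tsv"
            _write_tsv(report.concordance, path)
            written.append(path)
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=1))
        written.append(path)
    if report.tree_newick:
        path = out / "tree.nwk"
        path.write_text(report.tree_newick + "\n")
        written.append(path)
    return written


def load_report(path: str | Path) -> ScreenReport:
    return ScreenReport.from_dict(json.loads(Path(path).read_text()))
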