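# nitriminer

In-silico genome mining for **nitrilases** — enzymes of the carbon–nitrogen
hydrolase superfamily that hydrolyse nitriles (R–C≡N) directly to the
carboxylic acid and ammonia. Sequenced bacterial genomes are full of
unannotated ("hypothetical"/"putative") proteins, and nitrilases are valuable
biocatalysts, so a screen that pulls convincing nitrilase candidates out of
raw contigs — and predicts whether they prefer aliphatic (chain) or aromatic
(ring) nitriles — is a practical discovery tool for enzyme hunters.

`nitriminer` implements that screen as a tested, reusable pipeline:

1. **ORF extraction** (`seqio`) — exhaustive six-frame scan (starts
   ATG/GTG/TTG, genetic code table 11); predicted proteins `< 100` aa are
   discarded as false positives.
2. **Homology window** (`homology`) — Smith–Waterman local alignment
   (BLOSUM62, affine gaps 11/1) against a reference nitrilase such as the
   biochemically characterised *Rhodococcus rhodochrous* J1 enzyme;
   candidates are kept only at 30–80 % identity (too distant is noise, too
   close is not novel).
3. **Motif screen** (`motif_engine`) — four manually designed, class-specific
   motifs (MDMs) per substrate class, written in PROSITE-like syntax, e.g.
   `[FL]-[ILV]-[AV]-F-P-E-[VT]-[FW]-[IL]-P-[GY]-Y-P-[WY]`. The first three
   motifs of each class house the catalytic **Glu/Lys/Cys triad**, which is
   located and verified residue-by-residue. A deterministic strict/fuzzy
   matcher replaces MAST-style scanning.
4. **Physicochemical profile** (`physchem`) — the nine classical ProtParam
   descriptors (residue count, molecular weight, theoretical pI, charged
   residue counts, 280 nm extinction coefficients, Guruprasad instability
   index, Ikai aliphatic index, Kyte–Doolittle GRAVY), reimplemented from
   the published constant tables.
5. **Classification** (`classifier`) — aliphatic vs aromatic by motif
   evidence first (the motifs are class-specific by design), falling back on
   a z-scaled distance to published per-class consensus property vectors.
6. **Tree placement** (`phylo`) — pairwise global-alignment p-distances and
   a from-scratch Saitou–Nei Neighbor-Joining tree placing candidates among
   labelled reference nitrilases; each query is scored by whether its
   nearest reference shares its class.

A seeded synthetic-genome generator (`synthetic_data`) produces contigs with
implanted motif-compliant nitrilase genes at controlled identity to the
reference, background ORFs and short decoys, so the whole pipeline is
testable end-to-end with known truth and no downloads.

## Worked example

Generate a synthetic genome whose implants sit at ~50 % identity to a
reference, then screen it:

```bash
nitriminer simulate --seed 7 --reference reference.fasta --out sim
nitriminer run --genomes sim/contigs.fasta --reference reference.fasta --out screen
```

From `screen/report.json` (metadata): 23 ORFs survive the 100-aa filter, 17
fall inside the 30–80 % identity window, and exactly the 5 implanted
nitrilase genes survive the motif screen:

```
{'n_contigs': 1, 'n_orfs': 23, 'n_after_homology': 17, 'n_after_motifs': 5}

protein_id              aa  identity%  label      triad
contig_0|2951-3907|+   318      38.11  aromatic   True
contig_0|6676-7698|+   340      37.08  aromatic   True
contig_0|17275-18126|- 283      34.74  aliphatic  True
contig_0|23328-24344|- 338      39.46  aliphatic  True
contig_0|28055-29044|- 329      38.22  aliphatic  True
```

Every candidate is reported with forward-strand 1-based coordinates, its
measured identity to the reference (all within the 30–50 % band typical of
novel homologs), the class called from its strict motif hits, and a verified
complete E/K/C catalytic triad. `screen/properties.tsv` carries the nine
descriptors per candidate, e.g. the first aromatic candidate: 318 aa,
37 505.0 Da, pI 8.86, instability index 56.68, aliphatic index 56.42,
GRAVY −0.636. Against the truth table written by `simulate`, recall of the
implants is 5/5, no sub-100-aa decoy is recovered, and all labels match.

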