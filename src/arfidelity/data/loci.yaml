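# AR ligand-binding-domain hotspot loci.
# Positions are 1-based coordinates into the packaged synthetic contig
# (true genomic coordinates are not asserted by this package).
loci:
  - gene: AR
    locus_id: L702H
    chrom: AR_LBD_synthetic
    position: 302
    ref_base: T
    alt_bases: [A]
    codon_notation: "CtC>CaC"
    orientation: "+"
  - gene: AR
    locus_id: W742C
    chrom: AR_LBD_synthetic
    position: 703
    ref_base: G
    alt_bases: [T, C]
    codon_notation: "TGg>TGt/c"
    orientation: "+"
  - gene: AR
    locus_id: H875Y
    chrom: AR_LBD_synthetic
    position: 1294
    ref_base: C
    alt_bases: [T]
    codon_notation: "cAT>tAT"
    orientation: "+"
  - gene: AR
    locus_id: F877L
    chrom: AR_LBD_synthetic
    position: 1300
    ref_base: T
    alt_bases: [C]
    codon_notation: "tTC>cTC"
    orientation: "+"
  - gene: AR
    locus_id: T878A
    chrom: AR_LBD_synthetic
    position: 1303
    ref_base: A
    alt_bases: [G]
    codon_notation: "aCT>gCT"
    orientation: "+"
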