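"""Curated example data from a staged sheep hair-follicle transcriptome.

These small tables are the package's worked example: category-wise gene
lists of predicted lncRNA targets and differentially expressed mRNAs for
hair-follicle/skin development processes and signalling pathways, the
six-way genomic-context census of an identified lncRNA catalogue, and the
sequencing-yield totals used by the QC arithmetic example.

Gene symbols are stored uppercased with hyphens preserved (e.g.
``TNF-ALPHA``, ``ICAM-1``); matching throughout the package is
case-insensitive.  Source lists repeat a few symbols (e.g. ``LHX2``,
``KRT71``); the sets here are deduplicated, so set sizes may be smaller
than the raw list lengths.

A note on the hair-follicle category: the source tabulation marks 13
overlapping genes, but the strict intersection of the two printed lists
contains 12 (the target list carries FOXE1 where the mRNA list carries
FOXN1).  The strict set semantics are implemented; the discrepancy is
documented in the methods note.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Tuple


def _genes(*symbols: str) -> FrozenSet[str]:
    return frozenset(s.upper() for s in symbols)


#: category -> (lncRNA target gene set, DE mRNA gene set)
HF_GENE_SETS: Dict[str, Tuple[FrozenSet[str], FrozenSet[str]]] = {
    "hair_follicle_development": (
        _genes(
            "DKK1", "KRT25", "HOXC13", "FOXE1", "SOS1", "DSG4", "LHX2", "CDH3",
            "MYSM1", "ERCC2", "CD109", "FZD3", "ALX4", "LGR5", "RELA", "CELSR1",
            "WNT10A", "LDB1", "LRP4", "FGF10", "FST",
        ),
        _genes(
            "DKK1", "KRT25", "HOXC13", "FOXN1", "LGR4", "ACVR1B", "SOX9",
            "SOSTDC1", "DSG4", "TP63", "LAMA5", "NOTCH1", "TGFB2", "LHX2",
            "INHBA", "ZDHHC21", "DNASE1L2", "KRT71", "TMEM79", "FZD3", "FZD6",
            "ALX4", "LGR5", "TNF-ALPHA", "CELSR1", "MSX2", "EGFR", "KRT17",
            "WNT10A", "KRT27", "SMO", "APCDD1", "LRP4", "SNAI1", "FGF10",
        ),
    ),
    "epidermis_development": (
        _genes("WNT16", "DKK1", "KRT25", "DSG4", "SOS1", "FOXE1", "HOXC13", "OVOL1"),
        _genes(
            "FOXN1", "INHBA", "TGFB2", "LRP4", "NOTCH1", "KDF1", "WNT10A",
            "LAMA5", "DKK1", "EDAR", "CELSR1", "LGR5", "TP63", "ALX4", "KRT25",
            "DLL1", "SOSTDC1", "SOX9", "DSG4", "LHX2", "ACVR1B", "LGR4", "VDR",
            "TMEM79", "ALOX15B", "SFN", "MSX2", "CYP27B1", "H2AFY2", "FOXE1",
            "KRT36", "MAFF", "KRT84", "HES5", "DNASE1L2", "KRT27", "CST6",
            "HOXC13",
        ),
    ),
    "skin_development": (
        _genes(
            "WNT16", "CLDN1", "COL5A1", "DKK1", "DHCR24", "KRT25", "ALOXE3",
            "DSG4", "COL5A2", "SOS1", "PSEN1", "JUP", "OVOL1", "FOXE1", "HOXC13",
        ),
        _genes(
            "FOXN1", "TGFB2", "INHBA", "KDF1", "WNT16", "COL1A1", "ALOX12B",
            "TFAP2B", "EDAR", "CLDN1", "VDR", "LAMA5", "COL5A1", "DLL1", "LGR5",
            "DKK1", "DHCR24", "GRHL2", "KRT25", "ALX4", "SOX9", "SOSTDC1",
            "FA2H", "PTCH2", "ACVR1B", "LHX2", "ASPRV1", "CSTA", "ALOXE3",
            "COL1A2", "ITGA3", "CYP26B1", "LRP4", "NOTCH1", "WNT10A", "TGM3",
            "ACER1", "CELSR1", "ITGB4", "ABCA12", "TP63", "ATP8A2", "WNT5A",
            "LGR4", "KRT1", "FRAS1", "TCF15", "KRT27", "DSG4", "COL5A2", "JUP",
            "FOXE1", "DNASE1L2", "SFN", "HOXC13", "KRT71",
        ),
    ),
    "cell_differentiation": (
        _genes(
            "SFRP1", "PPP1R16B", "CDH5", "IL1B", "ENG", "ALMS1", "PSMB8",
            "SFRP2", "WNT5B", "DKKL1", "TRAF6", "PSEN1", "TMEM176A", "IRF4",
            "LHX8", "FGB", "PM20D1", "WNT16", "PAX8", "PTTG1IP", "NLE1",
            "AURKB", "DPEP1", "CIB1", "TAF9B", "TEX11", "FGG", "CDK1", "PDK4",
            "TDGF1", "IDO1", "MAEL", "CLEC5A", "HSP90B1", "RBM10", "PTK2B",
            "IGF1", "AIFM2",
        ),
        _genes(
            "NOTCH1", "MYCN", "SFRP1", "WNT5B", "DLL1", "WNT16", "HES5",
            "PDZD7", "MFSD2A", "ITGA8", "TRIM62", "TH", "FOXB1", "TGFB2",
            "LGI1", "DPEP1", "MYRF", "PLA2G3", "PTCH2", "LAMA5", "FZD1",
            "EDN1", "TDGF1", "CLEC5A", "LTBP3", "TGM3", "PRDM1", "CTGF",
            "UNC5C", "KLF5", "GRIP1", "ISG15", "BMPER", "BMP2", "TNR",
            "PTK2B", "TFAP2", "PTCH1",
        ),
    ),
    "wnt_signaling": (
        _genes(
            "WNT16", "SFRP1", "FZD4", "SFRP2", "DKK1", "FBXW11", "PSEN1",
            "HOXC13", "CSNK1A1", "DAAM1",
        ),
        _genes(
            "WIF1", "WNT16", "SFRP1", "MMP7", "WNT10A", "FZD1", "SFRP4",
            "WNT3", "WNT5A", "SFRP5", "SERPINF1", "CAMK2A", "BAMBI", "FZD4",
            "FZD5", "CSNK1E", "SFRP2", "NOTUM", "PLCB4", "WNT2", "WNT2B",
            "FZD3", "VANGL1", "DKK1", "NFATC4", "DAAM2", "FZD6", "PRICKLE1",
            "WNT8B", "PPARD", "HOXC13", "PRKACB", "FRAT2", "FOSL1", "DAAM1",
        ),
    ),
    "tnf_signaling": (
        _genes("IL1B", "IL18R1", "DNM1L", "JUNB"),
        _genes(
            "PIK3R5", "CREB3L4", "SELE", "MAP2K6", "EDN1", "NOD2", "ICAM-1",
            "PIK3CB", "IL15", "FOS", "CXCL10", "PIK3R3", "JUNB", "MLKL",
            "MAP3K5", "MMP14", "MMP9", "MMP3", "TNF-ALPHA",
        ),
    ),
    "mapk_signaling": (
        _genes(
            "IL1B", "MAPKAPK5", "TRAF6", "NTRK2", "PDGFRA", "PLA2G4D", "SOS1",
        ),
        _genes(
            "IL1R1", "MAP2K6", "DUSP4", "IL1A", "TGFB2", "CACNA2D3", "PLA2G4F",
            "CACNA1D", "FGF19", "CACNB1", "GADD45B", "FOS", "BDNF", "DUSP2",
            "PDGFRA", "HSPA1B", "RASGRP2", "IL1R2", "PTPRR", "DUSP1", "CACNG6",
            "MAP3K6", "HSPA2", "MAPKAPK3", "HSPA6", "MAP3K5", "PLA2G4D",
            "PLA2G4E", "MRAS", "FLNC", "FGF9", "TGFB3", "MEF2C", "FGFR4",
        ),
    ),
    "hedgehog_signaling": (
        _genes("FBXW11", "CSNK1A1", "CDON"),
        _genes(
            "HHIP", "GLI1", "GLI2", "CSNK1E", "LRP2", "CDON", "GPR161",
            "ARRB1", "SMO", "PRKACB", "CUL3",
        ),
    ),
}


def hf_target_sets() -> Dict[str, FrozenSet[str]]:
    return {k: v[0] for k, v in HF_GENE_SETS.items()}


def hf_de_mrna_sets() -> Dict[str, FrozenSet[str]]:
    return {k: v[1] for k, v in HF_GENE_SETS.items()}


#: six-way genomic-context census of the identified lncRNA catalogue
CONTEXT_CENSUS: Dict[str, int] = {
    "exonic_sense": 95,
    "intronic_sense": 1213,
    "exonic_antisense": 1467,
    "intronic_antisense": 988,
    "bidirectional": 557,
    "intergenic": 5873,
}

#: total identified lncRNAs (known + novel) in the same catalogue
TOTAL_LNCRNAS = 10_193

#: sequencing yield of the 18-library study (fragments)
RAW_READS = 1_847_973_012
CLEAN_READS = 1_726_188_919
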