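"""Frozen expected command outputs for the bundled demonstration database.

Row contents were frozen from the public archive records the demo fixture
mirrors (ribosome-profiling studies DRP003075/ERP013565, the PC3 study
SRP010679, and the GEO series GSE24355/GSE25842/GSE100007/GSE41637).  Where
the published listings were truncated by ``head``, the truncated suffix is
marked so tests compare only the printed prefix.
"""

# search '"ribosome profiling"'
SEARCH_RIBOSOME_PROFILING = [
    ("DRP003075", "DRX019536", "DRS026974", "DRR021383"),
    ("DRP003075", "DRX019537", "DRS026982", "DRR021384"),
    ("DRP003075", "DRX019538", "DRS026979", "DRR021385"),
    ("DRP003075", "DRX019540", "DRS026984", "DRR021387"),
    ("DRP003075", "DRX019541", "DRS026978", "DRR021388"),
    ("DRP003075", "DRX019543", "DRS026980", "DRR021390"),
    ("DRP003075", "DRX019544", "DRS026981", "DRR021391"),
    ("ERP013565", "ERX1264364", "ERS1016056", "ERR1190989"),
]

# metadata SRP010679
METADATA_SRP010679 = [
    ("SRP010679", f"SRX{118285 + i}", f"SRS{290854 + i}", f"SRR{403882 + i}")
    for i in range(12)
]

# metadata SRP010679 --desc   (first four rows of the printed listing)
_PC3 = "source_name: PC3 human prostate cancer cells || cell line: PC3"
METADATA_SRP010679_DESC_HEAD = [
    METADATA_SRP010679[0] + (f"{_PC3} || sample type: polyA RNA || treatment: vehicle",),
    METADATA_SRP010679[1]
    + (f"{_PC3} || sample type: ribosome protected RNA || treatment: vehicle",),
    METADATA_SRP010679[2] + (f"{_PC3} || sample type: polyA RNA || treatment: rapamycin",),
    METADATA_SRP010679[3]
    + (f"{_PC3} || sample type: ribosome protected RNA || treatment: rapamycin",),
]

# metadata SRP010679 --desc --expand: trailing columns of the printed
# listing (run_accession, cell_line, sample_type, source_name, treatment)
_SRC = "pc3 human prostate cancer cells"
METADATA_SRP010679_EXPANDED_TAIL = [
    ("SRR403882", "pc3", "polya rna", _SRC, "vehicle"),
    ("SRR403883", "pc3", "ribosome protected rna", _SRC, "vehicle"),
    ("SRR403884", "pc3", "polya rna", _SRC, "rapamycin"),
    ("SRR403885", "pc3", "ribosome protected rna", _SRC, "rapamycin"),
    ("SRR403886", "pc3", "polya rna", _SRC, "pp242"),
    ("SRR403887", "pc3", "ribosome protected rna", _SRC, "pp242"),
    ("SRR403888", "pc3", "polya rna", _SRC, "vehicle"),
    ("SRR403889", "pc3", "ribosome protected rna", _SRC, "vehicle"),
    ("SRR403890", "pc3", "polya rna", _SRC, "rapamycin"),
    ("SRR403891", "pc3", "ribosome protected rna", _SRC, "rapamycin"),
    ("SRR403892", "pc3", "polya rna", _SRC, "pp242"),
    ("SRR403893", "pc3", "ribosome protected rna", _SRC, "pp242"),
]

# gse-to-srp GSE24355 GSE25842
GSE_TO_SRP = [
    ("GSE24355", "SRP003870"),
    ("GSE25842", "SRP005378"),
]

# gse-to-srp --detailed --expand GSE100007
GSE100007_DETAILED = [
    ("GSE100007", "SRP109126", "SRX2916198", "SRS2282390", "GSM2667747", "GSM2667747"),
    ("GSE100007", "SRP109126", "SRX2916199", "SRS2282391", "GSM2667748", "GSM2667748"),
    ("GSE100007", "SRP109126", "SRX2916200", "SRS2282392", "GSM2667749", "GSM2667749"),
    ("GSE100007", "SRP109126", "SRX2916201", "SRS2282393", "GSM2667750", "GSM2667750"),
    ("GSE100007", "SRP109126", "SRX2916202", "SRS2282394", "GSM2667751", "GSM2667751"),
    ("GSE100007", "SRP109126", "SRX2916203", "SRS2282395", "GSM2667752", "GSM2667752"),
    ("GSE100007", "SRP109126", "SRX2916204", "SRS2282396", "GSM2667753", "GSM2667753"),
    ("GSE100007", "SRP109126", "SRX2916205", "SRS2282397", "GSM2667754", "GSM2667754"),
    ("GSE100007", "SRP109126", "SRX2916206", "SRS2282400", "GSM2667755", "GSM2667755"),
]

# gse-to-gsm GSE41637
GSE41637_GSMS = [("GSE41637", f"GSM{1020640 + i}_1") for i in range(9)]

# gse-to-gsm --desc GSE41637
_TISSUES = [
    ("mouse_brain", "brain"),
    ("mouse_colon", "colon"),
    ("mouse_heart", "heart"),
    ("mouse_kidney", "kidney"),
    ("mouse_liver", "liver"),
    ("mouse_lung", "lung"),
    ("mouse_skm", "skeletal muscle"),
    ("mouse_spleen", "spleen"),
    ("mouse_testes", "testes"),
]
GSE41637_DESC = [
    ("GSE41637", f"GSM{1020640 + i}_1",
     f"source_name: {src} || strain: DBA/2J || tissue: {tis}")
    for i, (src, tis) in enumerate(_TISSUES)
]

# gse-to-gsm --desc --expand GSE41637  (published listing truncated to 7 rows)
GSE41637_EXPANDED = [
    ("GSE41637", f"GSM{1020640 + i}_1", src, "dba/2j", tis)
    for i, (src, tis) in enumerate(_TISSUES)
]
GSE41637_EXPANDED_PRINTED_ROWS = 7

# gsm-to-srr GSM1020640 GSM1020646
GSM_TO_SRR = [
    ("GSM1020640_1", "SRR594393"),
    ("GSM1020646_1", "SRR594399"),
]
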