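# Residue positions reported in laboratory-based mutational-profiling studies to confer
# lapatinib resistance in ErbB-family kinases (numbering includes the 24-residue signal
# sequence). Editable benchmark list for hotspots.benchmark_overlap; one record per line:
#   <kinase> <residue_index>
EGFR 718
EGFR 726
EGFR 733
EGFR 790
EGFR 854
ErbB2 726
ErbB2 734
ErbB2 798
ErbB2 862
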