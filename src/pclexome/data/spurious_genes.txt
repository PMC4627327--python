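# Genes frequently found mutated in cancer sequencing surveys for reasons
# unrelated to tumor biology (very long coding sequence, late replication,
# low expression).  Edit freely: recurrence keeps these genes but pathway
# enrichment excludes them.  One symbol per line.
TTN
MUC16
MUC4
MUC5B
OBSCN
RYR1
RYR2
RYR3
PCLO
CSMD1
CSMD3
LRP1B
FLG
USH2A
DNAH5
DNAH9
DNAH11
SYNE1
SYNE2
NEB
GPR98
AHNAK2
DST
HYDIN
FAT4
PKHD1
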