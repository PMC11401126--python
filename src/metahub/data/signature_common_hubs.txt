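LCK; STAT1; IFNG; BIRC5; FN1; CD44; CTNNB1; TP53; CCND1; EGFR; ESR1; STAT3; KDR; JUN; MYC; AR; IL6; MMP1; MMP9; FOS; KRAS; UBC; IGF1R; AKT1; NFKB1; ITGB1; MAPK14; SPP1; MMP2; VCAN; RELA
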