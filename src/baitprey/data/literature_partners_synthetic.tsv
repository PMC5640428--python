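# SYNTHETIC stand-in for the curated list of 31 previously established KCC2
# physical/functional partners that were not recovered in the multi-epitope
# AP-MS screen. The first 14 symbols are partners named in the primary
# literature (NETO2, GluK2, 4.1N, beta-PIX, PAM, RCC1, PKC, WNK/SPAK/OSR1
# kinases, GABA-B receptor, mGluR1/5, RAB11); the remaining 17 entries are
# placeholders that pad the list to its published size. Use for exercising the
# literature-merge contract only, not for biological interpretation.
NETO2
GRIK2
EPB41L1
ARHGEF7
MYCBP2
RCC1
PRKCB
WNK1
STK39
OXSR1
GABBR1
GRM1
GRM5
RAB11A
LITSYN15
LITSYN16
LITSYN17
LITSYN18
LITSYN19
LITSYN20
LITSYN21
LITSYN22
LITSYN23
LITSYN24
LITSYN25
LITSYN26
LITSYN27
LITSYN28
LITSYN29
LITSYN30
LITSYN31
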