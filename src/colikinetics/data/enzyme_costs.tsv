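# Enzyme concentration and protein length table for the reduced reference
# model (synthetic values chosen at physiological magnitudes; lengths are
# approximate subunit-complex totals in amino acids).  Reactions missing a
# conc_uM entry in analyses fall back to the 18 uM average; reactions
# without an enzyme (feed, washout, leak, growth) are omitted.
reaction	conc_uM	aa_count
XCH_GLC	20.0	362
XCH_ACE	12.0	362
XCH_P	8.0	362
PTS	42.0	1530
PGI	36.0	549
PFK	15.0	320
FBA	60.0	359
GDH	90.0	920
PYK	28.0	470
PPS	6.0	792
ZWF	12.0	491
NONOX	25.0	1650
PPC	9.0	883
PDH	14.0	2870
GLT	18.0	427
GS	4.0	967
ICD	55.0	416
KGDH	10.0	2750
SDH	11.0	1180
MDH	40.0	312
ACK	23.0	1090
G6P_SPILL	2.0	199
P5P_SPILL	2.0	199
MGS	5.0	152
FBP_SPILL	2.0	199
PEP_SPILL	2.0	199
PYR_OUT	3.0	420
CIT_OUT	3.0	487
KG_OUT	3.0	432
SUC_OUT	3.0	445
PPK	7.0	688
NDHI	16.0	4020
NDH2	30.0	434
SQR	11.0	690
CYTBO	24.0	1340
ATP_SYN	38.0	3480
ATP_NGAM	18.0	500
ADK	40.0	214
CYA	2.0	848
DOS	3.0	799
PNT	12.0	1510
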