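pathway	transcription_factor	gene	direction	probe_id
AR	AR	AR_T01	1	AR_T01_at
AR	AR	AR_T01	1	AR_T01_x_at
AR	AR	AR_T02	1	AR_T02_at
AR	AR	AR_T02	1	AR_T02_x_at
AR	AR	AR_T03	1	AR_T03_at
AR	AR	AR_T04	1	AR_T04_at
AR	AR	AR_T05	1	AR_T05_at
AR	AR	AR_T06	-1	AR_T06_at
AR	AR	AR_T07	1	AR_T07_at
AR	AR	AR_T08	1	AR_T08_at
AR	AR	AR_T09	1	AR_T09_at
AR	AR	AR_T10	1	AR_T10_at
AR	AR	AR_T11	-1	AR_T11_at
AR	AR	AR_T12	-1	AR_T12_at
AR	AR	AR_T12	-1	AR_T12_x_at
AR	AR	AR_T13	1	AR_T13_at
AR	AR	AR_T13	1	AR_T13_x_at
AR	AR	AR_T14	1	AR_T14_at
AR	AR	AR_T15	1	AR_T15_at
AR	AR	AR_T16	1	AR_T16_at
AR	AR	AR_T16	1	AR_T16_x_at
AR	AR	AR_T17	1	AR_T17_at
AR	AR	AR_T18	-1	AR_T18_at
AR	AR	AR_T19	-1	AR_T19_at
AR	AR	AR_T20	1	AR_T20_at
AR	AR	AR_T21	1	AR_T21_at
AR	AR	AR_T21	1	AR_T21_x_at
AR	AR	AR_T22	1	AR_T22_at
AR	AR	AR_T22	1	AR_T22_x_at
AR	AR	AR_T23	1	AR_T23_at
AR	AR	AR_T23	1	AR_T23_x_at
AR	AR	AR_T24	1	AR_T24_at
AR	AR	AR_T25	1	AR_T25_at
AR	AR	AR_T25	1	AR_T25_x_at
AR	AR	AR_T26	1	AR_T26_at
TGFB	SMAD2/3-SMAD4	TGFB_T01	1	TGFB_T01_at
TGFB	SMAD2/3-SMAD4	TGFB_T01	1	TGFB_T01_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T02	1	TGFB_T02_at
TGFB	SMAD2/3-SMAD4	TGFB_T02	1	TGFB_T02_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T03	1	TGFB_T03_at
TGFB	SMAD2/3-SMAD4	TGFB_T04	1	TGFB_T04_at
TGFB	SMAD2/3-SMAD4	TGFB_T05	1	TGFB_T05_at
TGFB	SMAD2/3-SMAD4	TGFB_T05	1	TGFB_T05_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T06	1	TGFB_T06_at
TGFB	SMAD2/3-SMAD4	TGFB_T06	1	TGFB_T06_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T07	1	TGFB_T07_at
TGFB	SMAD2/3-SMAD4	TGFB_T08	1	TGFB_T08_at
TGFB	SMAD2/3-SMAD4	TGFB_T08	1	TGFB_T08_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T09	1	TGFB_T09_at
TGFB	SMAD2/3-SMAD4	TGFB_T10	1	TGFB_T10_at
TGFB	SMAD2/3-SMAD4	TGFB_T10	1	TGFB_T10_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T11	1	TGFB_T11_at
TGFB	SMAD2/3-SMAD4	TGFB_T12	1	TGFB_T12_at
TGFB	SMAD2/3-SMAD4	TGFB_T13	1	TGFB_T13_at
TGFB	SMAD2/3-SMAD4	TGFB_T14	1	TGFB_T14_at
TGFB	SMAD2/3-SMAD4	TGFB_T15	1	TGFB_T15_at
TGFB	SMAD2/3-SMAD4	TGFB_T15	1	TGFB_T15_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T16	1	TGFB_T16_at
TGFB	SMAD2/3-SMAD4	TGFB_T17	-1	TGFB_T17_at
TGFB	SMAD2/3-SMAD4	TGFB_T18	-1	TGFB_T18_at
TGFB	SMAD2/3-SMAD4	TGFB_T18	-1	TGFB_T18_x_at
TGFB	SMAD2/3-SMAD4	TGFB_T19	-1	TGFB_T19_at
TGFB	SMAD2/3-SMAD4	TGFB_T20	1	TGFB_T20_at
TGFB	SMAD2/3-SMAD4	TGFB_T21	1	TGFB_T21_at
TGFB	SMAD2/3-SMAD4	TGFB_T22	1	TGFB_T22_at
TGFB	SMAD2/3-SMAD4	TGFB_T22	1	TGFB_T22_x_at
NFKB	NFKB1-RELA	NFKB_T01	1	NFKB_T01_at
NFKB	NFKB1-RELA	NFKB_T01	1	NFKB_T01_x_at
NFKB	NFKB1-RELA	NFKB_T02	1	NFKB_T02_at
NFKB	NFKB1-RELA	NFKB_T02	1	NFKB_T02_x_at
NFKB	NFKB1-RELA	NFKB_T03	1	NFKB_T03_at
NFKB	NFKB1-RELA	NFKB_T03	1	NFKB_T03_x_at
NFKB	NFKB1-RELA	NFKB_T04	1	NFKB_T04_at
NFKB	NFKB1-RELA	NFKB_T04	1	NFKB_T04_x_at
NFKB	NFKB1-RELA	NFKB_T05	1	NFKB_T05_at
NFKB	NFKB1-RELA	NFKB_T06	1	NFKB_T06_at
NFKB	NFKB1-RELA	NFKB_T07	1	NFKB_T07_at
NFKB	NFKB1-RELA	NFKB_T08	1	NFKB_T08_at
NFKB	NFKB1-RELA	NFKB_T08	1	NFKB_T08_x_at
NFKB	NFKB1-RELA	NFKB_T09	1	NFKB_T09_at
NFKB	NFKB1-RELA	NFKB_T10	1	NFKB_T10_at
NFKB	NFKB1-RELA	NFKB_T11	1	NFKB_T11_at
NFKB	NFKB1-RELA	NFKB_T12	1	NFKB_T12_at
NFKB	NFKB1-RELA	NFKB_T13	1	NFKB_T13_at
NFKB	NFKB1-RELA	NFKB_T14	-1	NFKB_T14_at
NFKB	NFKB1-RELA	NFKB_T14	-1	NFKB_T14_x_at
NFKB	NFKB1-RELA	NFKB_T15	1	NFKB_T15_at
NFKB	NFKB1-RELA	NFKB_T16	1	NFKB_T16_at
NFKB	NFKB1-RELA	NFKB_T17	1	NFKB_T17_at
NFKB	NFKB1-RELA	NFKB_T18	1	NFKB_T18_at
NFKB	NFKB1-RELA	NFKB_T19	1	NFKB_T19_at
NFKB	NFKB1-RELA	NFKB_T19	1	NFKB_T19_x_at
NFKB	NFKB1-RELA	NFKB_T20	1	NFKB_T20_at
NFKB	NFKB1-RELA	NFKB_T21	1	NFKB_T21_at
NFKB	NFKB1-RELA	NFKB_T22	-1	NFKB_T22_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T01	1	JAKSTAT12_T01_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T01	1	JAKSTAT12_T01_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T02	1	JAKSTAT12_T02_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T02	1	JAKSTAT12_T02_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T03	-1	JAKSTAT12_T03_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T04	1	JAKSTAT12_T04_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T05	1	JAKSTAT12_T05_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T05	1	JAKSTAT12_T05_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T06	-1	JAKSTAT12_T06_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T07	1	JAKSTAT12_T07_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T07	1	JAKSTAT12_T07_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T08	1	JAKSTAT12_T08_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T08	1	JAKSTAT12_T08_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T09	1	JAKSTAT12_T09_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T10	-1	JAKSTAT12_T10_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T11	1	JAKSTAT12_T11_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T12	-1	JAKSTAT12_T12_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T12	-1	JAKSTAT12_T12_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T13	1	JAKSTAT12_T13_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T13	1	JAKSTAT12_T13_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T14	-1	JAKSTAT12_T14_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T15	1	JAKSTAT12_T15_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T16	1	JAKSTAT12_T16_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T16	1	JAKSTAT12_T16_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T17	-1	JAKSTAT12_T17_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T17	-1	JAKSTAT12_T17_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T18	1	JAKSTAT12_T18_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T19	1	JAKSTAT12_T19_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T20	-1	JAKSTAT12_T20_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T21	1	JAKSTAT12_T21_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T22	1	JAKSTAT12_T22_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T23	1	JAKSTAT12_T23_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T23	1	JAKSTAT12_T23_x_at
JAK-STAT1/2	STAT1/2	JAKSTAT12_T24	1	JAKSTAT12_T24_at
JAK-STAT3	STAT3	JAKSTAT3_T01	1	JAKSTAT3_T01_at
JAK-STAT3	STAT3	JAKSTAT3_T01	1	JAKSTAT3_T01_x_at
JAK-STAT3	STAT3	JAKSTAT3_T02	1	JAKSTAT3_T02_at
JAK-STAT3	STAT3	JAKSTAT3_T03	-1	JAKSTAT3_T03_at
JAK-STAT3	STAT3	JAKSTAT3_T04	-1	JAKSTAT3_T04_at
JAK-STAT3	STAT3	JAKSTAT3_T04	-1	JAKSTAT3_T04_x_at
JAK-STAT3	STAT3	JAKSTAT3_T05	-1	JAKSTAT3_T05_at
JAK-STAT3	STAT3	JAKSTAT3_T06	1	JAKSTAT3_T06_at
JAK-STAT3	STAT3	JAKSTAT3_T07	1	JAKSTAT3_T07_at
JAK-STAT3	STAT3	JAKSTAT3_T08	1	JAKSTAT3_T08_at
JAK-STAT3	STAT3	JAKSTAT3_T09	1	JAKSTAT3_T09_at
JAK-STAT3	STAT3	JAKSTAT3_T10	1	JAKSTAT3_T10_at
JAK-STAT3	STAT3	JAKSTAT3_T11	1	JAKSTAT3_T11_at
JAK-STAT3	STAT3	JAKSTAT3_T12	1	JAKSTAT3_T12_at
JAK-STAT3	STAT3	JAKSTAT3_T13	1	JAKSTAT3_T13_at
JAK-STAT3	STAT3	JAKSTAT3_T14	1	JAKSTAT3_T14_at
JAK-STAT3	STAT3	JAKSTAT3_T15	1	JAKSTAT3_T15_at
JAK-STAT3	STAT3	JAKSTAT3_T16	-1	JAKSTAT3_T16_at
JAK-STAT3	STAT3	JAKSTAT3_T16	-1	JAKSTAT3_T16_x_at
JAK-STAT3	STAT3	JAKSTAT3_T17	1	JAKSTAT3_T17_at
JAK-STAT3	STAT3	JAKSTAT3_T18	1	JAKSTAT3_T18_at
JAK-STAT3	STAT3	JAKSTAT3_T18	1	JAKSTAT3_T18_x_at
JAK-STAT3	STAT3	JAKSTAT3_T19	1	JAKSTAT3_T19_at
JAK-STAT3	STAT3	JAKSTAT3_T20	1	JAKSTAT3_T20_at
JAK-STAT3	STAT3	JAKSTAT3_T21	1	JAKSTAT3_T21_at
JAK-STAT3	STAT3	JAKSTAT3_T22	-1	JAKSTAT3_T22_at
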