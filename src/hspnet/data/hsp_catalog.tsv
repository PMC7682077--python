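gene	family	subfamily
HSPE1	HSP10
HSPB1	HSP20
HSPB2	HSP20
HSPB3	HSP20
CRYAA	HSP20
CRYAB	HSP20
HSPB6	HSP20
HSPB7	HSP20
HSPB8	HSP20
HSPB9	HSP20
ODF1	HSP20
HSPB11	HSP20
DNAJA1	HSP40	DNAJA
DNAJA2	HSP40	DNAJA
DNAJA3	HSP40	DNAJA
DNAJA4	HSP40	DNAJA
DNAJB1	HSP40	DNAJB
DNAJB2	HSP40	DNAJB
DNAJB3	HSP40	DNAJB
DNAJB4	HSP40	DNAJB
DNAJB5	HSP40	DNAJB
DNAJB6	HSP40	DNAJB
DNAJB7	HSP40	DNAJB
DNAJB8	HSP40	DNAJB
DNAJB9	HSP40	DNAJB
DNAJB11	HSP40	DNAJB
DNAJB12	HSP40	DNAJB
DNAJB13	HSP40	DNAJB
DNAJB14	HSP40	DNAJB
DNAJC1	HSP40	DNAJC
DNAJC2	HSP40	DNAJC
DNAJC3	HSP40	DNAJC
DNAJC4	HSP40	DNAJC
DNAJC5	HSP40	DNAJC
DNAJC5B	HSP40	DNAJC
DNAJC6	HSP40	DNAJC
DNAJC7	HSP40	DNAJC
DNAJC8	HSP40	DNAJC
DNAJC9	HSP40	DNAJC
DNAJC10	HSP40	DNAJC
DNAJC11	HSP40	DNAJC
DNAJC12	HSP40	DNAJC
DNAJC13	HSP40	DNAJC
DNAJC14	HSP40	DNAJC
DNAJC15	HSP40	DNAJC
DNAJC16	HSP40	DNAJC
DNAJC17	HSP40	DNAJC
DNAJC18	HSP40	DNAJC
DNAJC19	HSP40	DNAJC
HSCB	HSP40	DNAJC
DNAJC21	HSP40	DNAJC
DNAJC22	HSP40	DNAJC
SEC63	HSP40	DNAJC
DNAJC24	HSP40	DNAJC
DNAJC25	HSP40	DNAJC
GAK	HSP40	DNAJC
DNAJC27	HSP40	DNAJC
DNAJC28	HSP40	DNAJC
SACS	HSP40	DNAJC
DNAJC30	HSP40	DNAJC
HSPD1	HSP60
HSPA1A	HSP70
HSPA1B	HSP70
HSPA1L	HSP70
HSPA2	HSP70
HSPA4	HSP70
HSPA4L	HSP70
HSPA5	HSP70
HSPA6	HSP70
HSPA7	HSP70
HSPA8	HSP70
HSPA9	HSP70
HSPA12A	HSP70
HSPA12B	HSP70
HSPA13	HSP70
HSPA14	HSP70
HSP90AA1	HSP90
HSP90AB1	HSP90
HSP90B1	HSP90
TRAP1	HSP90
HSPH1	large HSP
HYOU1	large HSP
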