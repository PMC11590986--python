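protein_id,primary_name,synonyms
P19429,"Troponin I, cardiac muscle",TNNI3|cardiac troponin I
P45379,"Troponin T, cardiac muscle",TNNT2|cardiac troponin T
P63316,"Troponin C, slow skeletal and cardiac muscles",TNNC1
Q92736,Ryanodine receptor 2,RyR2
P16615,Sarcoplasmic/endoplasmic reticulum calcium ATPase 2,ATP2A2|SERCA2
P26678,Cardiac phospholamban,PLN
Q13936,Voltage-dependent L-type calcium channel subunit alpha-1C,CACNA1C
P32418,Sodium/calcium exchanger 1,SLC8A1|NCX1
P29474,"Nitric oxide synthase, endothelial",NOS3|eNOS
P14780,Matrix metalloproteinase-9,MMP9
P17302,Gap junction alpha-1 protein,GJA1|connexin 43|Cx43
O14958,Calsequestrin-2,CASQ2
P0DP23,Calmodulin-1,CALM1
Q8NE86,"Calcium uniporter protein, mitochondrial",MCU
Q9BPX6,"Calcium uptake protein 1, mitochondrial",MICU1
Q8IYU8,"Calcium uptake protein 2, mitochondrial",MICU2
Q6J4K2,Mitochondrial sodium/calcium exchanger protein,SLC8B1|NCLX
Q14643,"Inositol 1,4,5-trisphosphate receptor type 1",ITPR1
Q14571,"Inositol 1,4,5-trisphosphate receptor type 2",ITPR2
Q14573,"Inositol 1,4,5-trisphosphate receptor type 3",ITPR3
Q13557,Calcium/calmodulin-dependent protein kinase type II subunit delta,CAMK2D
Q13586,Stromal interaction molecule 1,STIM1
Q96D31,Calcium release-activated calcium channel protein 1,ORAI1
P48995,Short transient receptor potential channel 1,TRPC1
Q13507,Short transient receptor potential channel 3,TRPC3
Q9Y210,Short transient receptor potential channel 6,TRPC6
Q01668,Voltage-dependent L-type calcium channel subunit alpha-1D,CACNA1D
O43497,Voltage-dependent T-type calcium channel subunit alpha-1G,CACNA1G
Q08289,Voltage-dependent L-type calcium channel subunit beta-2,CACNB2
P63098,Calcineurin subunit B type 1,PPP3R1
P23327,Sarcoplasmic reticulum histidine-rich calcium-binding protein,HRC
P05976,"Myosin light chain 1/3, skeletal muscle isoform",MYL1
Q9C100,Calcium regulatory protein 1,CARP1
Q9C101,Calcium regulatory protein 2,CARP2
Q9C102,Calcium regulatory protein 3,CARP3
Q9C103,Calcium regulatory protein 4,CARP4
Q9C104,Calcium regulatory protein 5,CARP5
Q9C105,Calcium regulatory protein 6,CARP6
Q9C106,Calcium regulatory protein 7,CARP7
Q9C107,Calcium regulatory protein 8,CARP8
Q9C108,Calcium regulatory protein 9,CARP9
Q9C109,Calcium regulatory protein 10,CARP10
Q9C110,Calcium regulatory protein 11,CARP11
Q9C111,Calcium regulatory protein 12,CARP12
Q9C112,Calcium regulatory protein 13,CARP13
Q9C113,Calcium regulatory protein 14,CARP14
Q9C114,Calcium regulatory protein 15,CARP15
Q9C115,Calcium regulatory protein 16,CARP16
Q9C116,Calcium regulatory protein 17,CARP17
Q9C117,Calcium regulatory protein 18,CARP18
Q9C118,Calcium regulatory protein 19,CARP19
Q9C119,Calcium regulatory protein 20,CARP20
Q9C120,Calcium regulatory protein 21,CARP21
Q9C121,Calcium regulatory protein 22,CARP22
Q9C122,Calcium regulatory protein 23,CARP23
Q9C123,Calcium regulatory protein 24,CARP24
Q9C124,Calcium regulatory protein 25,CARP25
Q9C125,Calcium regulatory protein 26,CARP26
Q9C126,Calcium regulatory protein 27,CARP27
Q9C127,Calcium regulatory protein 28,CARP28
Q9C128,Calcium regulatory protein 29,CARP29
Q9C129,Calcium regulatory protein 30,CARP30
Q9C130,Calcium regulatory protein 31,CARP31
Q9C131,Calcium regulatory protein 32,CARP32
Q9C132,Calcium regulatory protein 33,CARP33
Q9C133,Calcium regulatory protein 34,CARP34
Q9C134,Calcium regulatory protein 35,CARP35
Q9C135,Calcium regulatory protein 36,CARP36
Q9C136,Calcium regulatory protein 37,CARP37
Q9C137,Calcium regulatory protein 38,CARP38
Q9C138,Calcium regulatory protein 39,CARP39
Q9C139,Calcium regulatory protein 40,CARP40
Q9C140,Calcium regulatory protein 41,CARP41
Q9C141,Calcium regulatory protein 42,CARP42
Q9C142,Calcium regulatory protein 43,CARP43
Q9C143,Calcium regulatory protein 44,CARP44
Q9C144,Calcium regulatory protein 45,CARP45
Q9C145,Calcium regulatory protein 46,CARP46
Q9C146,Calcium regulatory protein 47,CARP47
Q9C147,Calcium regulatory protein 48,CARP48
Q9C148,Calcium regulatory protein 49,CARP49
Q9C149,Calcium regulatory protein 50,CARP50
Q9C150,Calcium regulatory protein 51,CARP51
Q9C151,Calcium regulatory protein 52,CARP52
Q9C152,Calcium regulatory protein 53,CARP53
Q9C153,Calcium regulatory protein 54,CARP54
Q9C154,Calcium regulatory protein 55,CARP55
Q9C155,Calcium regulatory protein 56,CARP56
Q9C156,Calcium regulatory protein 57,CARP57
Q9C157,Calcium regulatory protein 58,CARP58
Q9C158,Calcium regulatory protein 59,CARP59
Q9C159,Calcium regulatory protein 60,CARP60
Q9C160,Calcium regulatory protein 61,CARP61
Q9C161,Calcium regulatory protein 62,CARP62
Q9C162,Calcium regulatory protein 63,CARP63
Q9C163,Calcium regulatory protein 64,CARP64
Q9C164,Calcium regulatory protein 65,CARP65
Q9C165,Calcium regulatory protein 66,CARP66
Q9C166,Calcium regulatory protein 67,CARP67
Q9C167,Calcium regulatory protein 68,CARP68
Q9C168,Calcium regulatory protein 69,CARP69
Q9C169,Calcium regulatory protein 70,CARP70
Q9C170,Calcium regulatory protein 71,CARP71
Q9C171,Calcium regulatory protein 72,CARP72
Q9C172,Calcium regulatory protein 73,CARP73
Q9C173,Calcium regulatory protein 74,CARP74
Q9C174,Calcium regulatory protein 75,CARP75
Q9C175,Calcium regulatory protein 76,CARP76
Q9C176,Calcium regulatory protein 77,CARP77
Q9C177,Calcium regulatory protein 78,CARP78
Q9C178,Calcium regulatory protein 79,CARP79
Q9C179,Calcium regulatory protein 80,CARP80
Q9C180,Calcium regulatory protein 81,CARP81
Q9C181,Calcium regulatory protein 82,CARP82
Q9C182,Calcium regulatory protein 83,CARP83
Q9C183,Calcium regulatory protein 84,CARP84
Q9C184,Calcium regulatory protein 85,CARP85
Q9C185,Calcium regulatory protein 86,CARP86
Q9C186,Calcium regulatory protein 87,CARP87
Q9C187,Calcium regulatory protein 88,CARP88
Q9C188,Calcium regulatory protein 89,CARP89
Q9C189,Calcium regulatory protein 90,CARP90
Q9C190,Calcium regulatory protein 91,CARP91
Q9C191,Calcium regulatory protein 92,CARP92
Q9C192,Calcium regulatory protein 93,CARP93
Q9C193,Calcium regulatory protein 94,CARP94
Q9C194,Calcium regulatory protein 95,CARP95
Q9C195,Calcium regulatory protein 96,CARP96
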