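# SYNTHETIC toy S-value matrix, mGy/(MBq.h): target rows x source columns.
# Diagonal-dominant stand-in for phantom S-values, for tests and worked
# examples only (not a published phantom).
,brain,liver,lung,kidneys,spleen,pancreas,heart_wall,stomach,small_intestine,gall_bladder,bladder,red_marrow,thyroid,rest_of_body
brain,0.02,0.0001929,0.0002119,0.0003099,0.0003492,0.0001784,0.0001657,0.0001862,0.0002219,0.0001839,0.0002678,0.0002734,0.0001711,0.0002631
liver,0.0001509,0.016,0.0003451,0.0003099,0.0002694,0.0002151,0.0001913,0.0002385,0.0002056,0.000325,0.0001926,0.0002048,0.0003114,0.0002037
lung,0.0002036,0.0001642,0.024,0.0002028,0.0003278,0.0002073,0.0003048,0.0002474,0.0002436,0.000343,0.0003296,0.0001658,0.000199,0.000187
kidneys,0.0003311,0.0002608,0.0002243,0.06,0.0002198,0.0002863,0.0001957,0.0001548,0.0002892,0.0002174,0.0002184,0.0002052,0.0002003,0.000264
spleen,0.0002168,0.0002351,0.0001904,0.000251,0.09,0.0002341,0.0002307,0.0003388,0.0001596,0.0002152,0.0002538,0.0002697,0.0001585,0.0001983
pancreas,0.0001609,0.0001515,0.0002144,0.0002314,0.0003218,0.13,0.0002932,0.0002414,0.0002678,0.0001793,0.0003104,0.0002259,0.000232,0.0002632
heart_wall,0.0002021,0.0002373,0.000177,0.0002906,0.0001701,0.0002059,0.06,0.0001763,0.0002598,0.0001894,0.0003002,0.000206,0.0003436,0.000263
stomach,0.0001676,0.000274,0.0001918,0.0002255,0.0001915,0.0002068,0.0002726,0.1,0.0001539,0.0003333,0.0001994,0.0002472,0.0001757,0.0002267
small_intestine,0.0003065,0.0001978,0.0003189,0.0002728,0.0002768,0.000331,0.0002519,0.0001778,0.035,0.0002769,0.00031,0.0001753,0.0001936,0.0003365
gall_bladder,0.0002626,0.0001908,0.0002348,0.0002283,0.0001761,0.0002684,0.0001604,0.000162,0.0002018,0.2,0.0002626,0.0003313,0.0001961,0.0001799
bladder,0.0001768,0.0001647,0.000181,0.000194,0.0003396,0.0003247,0.0001782,0.000306,0.0001513,0.0002828,0.08,0.0002216,0.0001951,0.0002624
red_marrow,0.0003361,0.0003158,0.0003131,0.0002522,0.0003448,0.0003179,0.0002754,0.0003278,0.0001675,0.0001935,0.0003315,0.02,0.0001667,0.000228
thyroid,0.0002935,0.0002691,0.0002565,0.0002985,0.0003167,0.0001542,0.0003294,0.0002704,0.0003253,0.000248,0.0002166,0.0001767,0.5,0.000174
rest_of_body,0.0003168,0.0001856,0.0001641,0.0002849,0.0002532,0.0001862,0.0001577,0.0002068,0.0003232,0.0002249,0.0003042,0.0003475,0.0003125,0.0015
testes,0.0002472,0.0003403,0.0001891,0.0001882,0.0002889,0.0003433,0.0002784,0.0002645,0.0003229,0.000205,0.0009,0.0001619,0.0001929,0.0003124
uli_wall,0.0002619,0.0003174,0.0002261,0.0001568,0.0002664,0.0002796,0.0001742,0.0002725,0.002,0.0003425,0.0008,0.0002652,0.00028,0.0002287
lli_wall,0.0002583,0.0002388,0.0002607,0.0002787,0.0002809,0.000319,0.0001836,0.0001953,0.0015,0.0003368,0.0012,0.0001754,0.0002118,0.0002903
breast,0.0001901,0.0003,0.0008,0.0003359,0.0002477,0.0002183,0.0001855,0.0001791,0.0001622,0.0003151,0.0002179,0.0001995,0.0003257,0.0001777
thymus,0.0001772,0.0002025,0.001,0.0001746,0.0001902,0.0003353,0.000325,0.0002886,0.0001782,0.0002925,0.0003488,0.0002881,0.000258,0.0002951
skin,0.0003297,0.0002339,0.0002912,0.000274,0.0002718,0.0002439,0.0002259,0.0001516,0.0003129,0.0002541,0.0002761,0.0002047,0.0002559,0.0003
bone_surface,0.0002469,0.0002546,0.0002086,0.0002044,0.0002741,0.00017,0.0001751,0.0001873,0.0002187,0.0003438,0.0003203,0.004,0.000288,0.0002318
adrenals,0.0003052,0.0002898,0.0001522,0.003,0.0002019,0.0003347,0.0002745,0.0003304,0.0003128,0.0002329,0.000329,0.0003467,0.000196,0.0002358
muscle,0.0001665,0.0002498,0.0002405,0.0002469,0.0001771,0.0002521,0.0002251,0.0002354,0.0003034,0.0002507,0.0001544,0.0002304,0.0003288,0.0004
uterus,0.000181,0.0001518,0.0002639,0.0001933,0.0002161,0.0003061,0.0003279,0.0001968,0.0001884,0.0002079,0.0011,0.0001521,0.0002982,0.0003391
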