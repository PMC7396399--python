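# Published per-region test-retest variability (TRV, %) and one-way ICC of
# the total distribution volume by estimator, brain BACE1 radioligand
# test-retest study (12 gray-matter regions).  Empty cells were illegible in
# the source table.
region,trv_mean_1tcm,trv_sd_1tcm,trv_mean_2tcm,trv_sd_2tcm,trv_mean_ga,trv_sd_ga,icc_1tcm,icc_2tcm,icc_ga
CERCX,11.7,11.3,12.4,11.0,11.5,10.5,0.646,0.644,0.667
CAU,19.2,10.4,20.5,9.8,19.6,12.9,0.261,0.291,0.193
PUT,14.7,9.1,16.1,7.7,15.8,9.3,0.577,0.487,0.509
THA,15.8,9.2,16.6,9.0,16.5,10.6,0.484,0.504,0.425
LFC,15.8,9.4,17.4,8.1,16.2,10.0,0.505,0.492,0.486
LTC,14.3,8.0,14.7,8.3,14.2,8.2,0.535,0.542,0.507
HIP,15.5,8.7,,7.1,16.4,8.8,0.535,0.548,0.508
LOC,15.0,8.7,15.5,8.9,15.2,8.7,0.568,0.565,0.561
LPC,16.7,9.9,17.6,9.0,17.0,10.8,0.579,0.599,0.573
ACC,15.4,7.3,15.1,8.8,15.6,7.3,0.487,0.418,0.465
PCC,15.5,9.6,15.8,8.4,15.3,7.9,0.401,0.443,0.412
AMG,18.5,8.5,19.6,9.3,19.3,9.2,0.454,0.417,0.390
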