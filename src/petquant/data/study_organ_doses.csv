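# Published per-organ absorbed dose estimates (adult male model) for the
# first-in-human dosimetry study of the 18F BACE1 radioligand, uSv/MBq.
organ,mean,sd
adrenals,16.8,1.0
brain,15.6,0.9
breasts,7.66,0.3
gallbladder_wall,57.7,40.9
lli_wall,21.7,3.4
small_intestine,45.5,9.8
stomach_wall,13.1,0.9
uli_wall,51,11.1
heart_wall,35.7,6.5
kidneys,29.4,4.7
liver,70.5,5.9
lungs,37.1,2.4
muscle,9.28,0.2
ovaries,15.2,1.4
pancreas,92.9,52.2
red_marrow,18.6,1.2
osteogenic_cells,40,3.5
skin,6.37,0.2
spleen,28.8,10.0
testes,7.26,0.4
thymus,9.28,0.5
thyroid,14.9,4.7
urinary_bladder_wall,57.5,21.2
uterus,15.2,1.2
total_body,13.4,0.2
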