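crop,economic_coefficient,water_content,uptake_rate
rice,0.45,0.12,0.414
wheat,0.40,0.12,0.485
corn,0.40,0.13,0.471
beans,0.34,0.13,0.450
canola,0.25,0.10,0.450
peanut,0.43,0.10,0.450
sunflower,0.30,0.10,0.450
cotton,0.10,0.08,0.450
potato,0.70,0.70,0.423
sugar_cane,0.50,0.50,0.450
sugar_beets,0.70,0.75,0.407
vegetables,0.60,0.90,0.450
melon,0.70,0.90,0.450
tobacco,0.55,0.85,0.450
other_crops,0.40,0.12,0.450
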