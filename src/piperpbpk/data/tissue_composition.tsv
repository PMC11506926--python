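# Human tissue-composition table for mechanistic (method 2) tissue:plasma
# partitioning.  Fractional extracellular/intracellular water, neutral
# lipid and neutral phospholipid, and acidic phospholipid concentration
# (mg/g) are the published Rodgers-Rowland composition dataset (the same
# rat-derived values the method's authors applied to human predictions);
# volume_frac is the fractional tissue volume of a 70-kg adult (L per kg
# body weight, ICRP-style reference values).  blood_cells volume_frac
# corresponds to whole blood (0.0771 L/kg) at hematocrit 0.45; the plasma
# row carries the complementary plasma volume and no composition.
tissue	f_ew	f_iw	f_nl	f_np	ap	volume_frac
adipose	0.135	0.017	0.853	0.0016	0.40	0.1427
bone	0.100	0.346	0.017	0.0017	0.67	0.0856
brain	0.162	0.620	0.039	0.0015	0.40	0.0200
gut	0.282	0.475	0.038	0.0125	2.41	0.0171
heart	0.320	0.456	0.014	0.0111	2.25	0.0047
kidney	0.273	0.483	0.012	0.0242	5.03	0.0044
liver	0.161	0.573	0.014	0.0245	4.56	0.0257
lung	0.336	0.446	0.022	0.0128	3.91	0.0076
muscle	0.118	0.630	0.010	0.0072	1.53	0.4000
skin	0.382	0.291	0.060	0.0044	1.32	0.0371
spleen	0.207	0.579	0.0077	0.0113	3.18	0.0026
blood_cells	0.0	0.603	0.0017	0.0029	0.50	0.0347
plasma	0.0	0.0	0.0	0.0	0.0	0.0424
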