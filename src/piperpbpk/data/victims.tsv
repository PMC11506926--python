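# Ten CYP3A4 victim-drug parameter sets for interaction simulation.
# SYNTHETIC stand-in fixture: the simulation platform's built-in victim
# compound files are unpublished, so each record was assembled once from
# open literature: doses are the studied single doses; fu_plasma, B/P and
# Vss from standard clinical-pharmacology compilations (Goodman & Gilman
# appendix-style tables); hepatic unbound intrinsic clearance
# (clint_u_liver, whole liver, L/h) back-calculated from reported systemic
# clearance via the well-stirred model at Qh 90 L/h; fm_cyp3a4 from
# published fraction-metabolized analyses of CYP3A DDI victims;
# gut CLint (clint_gut, uL/min, unbound, fu_gut = 1 convention) chosen to
# reproduce reported intestinal availability Fg through the Qgut model
# (Fg values per Gertz/Galetin-style first-pass compilations: midazolam
# 0.57, simvastatin 0.66, triazolam 0.75, alfentanil 0.76, nifedipine
# 0.78, cyclosporine 0.44, ritonavir 0.82, clarithromycin 0.92,
# itraconazole 0.90, carbamazepine 0.97). ka in 1/h; renal_cl L/h.
name	mw	dose_mg	fu_plasma	bp_ratio	vss	ka	clint_u_liver	fm_cyp3a4	fu_gut	qgut	clint_gut	renal_cl	source_note
carbamazepine	236.27	400	0.26	1.07	1.0	0.5	15.9	0.36	1.0	15.7	8083	0.0	low-clearance anticonvulsant; CYP3A4 ~36% of hepatic CL (rest 2C8/UGT); negligible gut extraction
clarithromycin	747.95	250	0.30	0.90	2.5	0.6	82.1	0.70	1.0	12.0	17391	10.0	macrolide; ~30-40% renal; hepatic metabolism predominantly CYP3A4
midazolam	325.77	5	0.03	0.66	1.0	2.0	849	0.94	1.0	15.7	197400	0.0	reference CYP3A probe; Eh ~0.3, Fg ~0.57
itraconazole	705.63	200	0.004	0.58	4.0	0.4	3965	0.85	1.0	10.0	18519	0.0	fed-capsule dosing; very high binding, large Vss
ritonavir	720.94	100	0.015	0.60	0.41	0.8	375	0.90	1.0	13.0	47561	0.0	CYP3A4 substrate (also 2D6); low Vss
nifedipine	346.34	20	0.04	0.68	0.8	1.5	974	0.88	1.0	16.0	75214	0.0	intermediate-extraction dihydropyridine; Fg ~0.78
cyclosporine	1202.6	200	0.036	1.36	3.5	0.7	1167	0.75	1.0	8.0	169697	0.0	large cyclic peptide; low permeability, Fg ~0.44
triazolam	343.21	0.25	0.10	0.62	0.8	2.5	170	0.92	1.0	15.7	87222	0.0	short-acting benzodiazepine; near-complete CYP3A4 metabolism
alfentanil	416.52	0.043	0.08	0.63	0.6	2.0	142	0.92	1.0	15.7	82632	0.0	low-extraction opioid CYP3A probe (minidose)
simvastatin	418.57	40	0.05	0.60	1.2	1.0	2520	0.99	1.0	11.0	94444	0.0	lactone prodrug; essentially complete CYP3A4 dependence, strong hepatic + gut first pass
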