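# Intrinsic amide hydrogen-exchange rate parameters (dipeptide calibration).
# Source: poly-DL-alanine reference rates and side-chain perturbation factors
# from the NMR dipeptide calibration of Bai, Milne, Mayne & Englander (1993),
# with ionizable side-chain variants after Connelly et al. (1993), as
# distributed in the Englander-laboratory exchange-rate spreadsheets
# (hx2.med.upenn.edu). Validated in this package against five printed
# literature anchors (see tests/test_acceptance.py).
#
# Scalar constants block. Reference rate constants are log10 values at the
# reference temperature: acid and base rates in M^-1 min^-1, the
# water-catalyzed rate in min^-1. "HD" = NH -> ND exchange in D2O,
# "DH" = ND -> NH back exchange in H2O. pK_solvent is the solvent
# autoionization constant used to convert acidity into catalyst
# concentrations ([D+]/[OD-] or [H+]/[OH-]). Activation energies in cal/mol.
#!reference_temperature_K	293.0
#!log_kA_HD	1.62
#!log_kB_HD	10.18
#!log_kW_HD	-1.50
#!pK_solvent_HD	15.05
#!log_kA_DH	1.40
#!log_kB_DH	10.00
#!log_kW_DH	-1.79
#!pK_solvent_DH	14.17
#!Ea_acid_cal_mol	14000.0
#!Ea_base_cal_mol	17000.0
#!Ea_water_cal_mol	19000.0
#
# Per-residue log10 perturbation factors. "own" = effect of the side chain on
# the backbone amide of its own residue; "next" = effect on the amide of the
# following residue. The water pathway is scaled by the base factors.
# Ionizable groups carry protonated/deprotonated variants mixed by the pK
# columns (model-compound values in each solvent). Pro has no backbone NH
# (exchanges = 0); only its "next" factors are meaningful (trans conformer).
# Nterm/Cterm are pseudo-rows for the free termini created by digestion:
# Nterm (alpha-ammonium) contributes "next" factors to residue 2's amide,
# Cterm (alpha-carboxyl) contributes "own" factors to the final amide.
residue	variant	exchanges	acid_own	acid_next	base_own	base_next	pK_H2O	pK_D2O
A	-	1	0.00	0.00	0.00	0.00	.	.
R	-	1	-0.59	-0.32	0.08	0.22	.	.
N	-	1	-0.58	-0.13	0.49	0.32	.	.
D	prot	1	-0.90	-0.12	0.69	0.60	3.87	4.48
D	deprot	1	0.90	0.58	0.10	-0.18	3.87	4.48
C	-	1	-0.54	-0.46	0.62	0.55	.	.
E	prot	1	-0.60	-0.27	0.24	0.39	4.33	4.93
E	deprot	1	-0.90	0.31	-0.11	-0.15	4.33	4.93
Q	-	1	-0.47	-0.27	0.06	0.20	.	.
G	-	1	-0.22	0.22	0.27	0.17	.	.
H	prot	1	-0.80	-0.51	0.80	0.83	7.00	7.42
H	deprot	1	0.00	0.00	-0.10	0.14	7.00	7.42
I	-	1	-0.91	-0.59	-0.73	-0.23	.	.
L	-	1	-0.57	-0.13	-0.58	-0.21	.	.
K	-	1	-0.56	-0.29	-0.04	0.12	.	.
M	-	1	-0.64	-0.28	-0.01	0.11	.	.
F	-	1	-0.52	-0.43	-0.24	0.06	.	.
P	-	0	0.00	-0.19	0.00	-0.24	.	.
S	-	1	-0.44	-0.39	0.37	0.30	.	.
T	-	1	-0.79	-0.47	-0.07	0.20	.	.
W	-	1	-0.40	-0.44	-0.41	-0.11	.	.
Y	-	1	-0.41	-0.37	-0.27	0.05	.	.
V	-	1	-0.74	-0.30	-0.70	-0.14	.	.
Nterm	prot	0	0.00	-1.32	0.00	1.62	.	.
Cterm	prot	0	0.05	0.00	0.00	0.00	3.66	4.06
Cterm	deprot	0	0.96	0.00	-1.80	0.00	3.66	4.06
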