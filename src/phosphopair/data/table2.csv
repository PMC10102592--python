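protein_label,prot_fc_idc,prot_fc_ilc,phos_fc_idc,phos_fc_ilc
H1X_HUMAN,1.78,0.56,ND,ND
CO4B_HUMAN,0.25,3.14,ND,ND
CRKL_HUMAN,0.63,3.26,ND,ND
CALD1_HUMAN,1.58,4.26,0.43,1.34
SC22B_HUMAN,3.99,4.11,1.80,2.44
CAVN1_HUMAN,0.63,0.74,0.18,0.23
ROA1_HUMAN,2.17,2.60,1.77,0.47
DREB_HUMAN,3.04,13.27,1.06,1.61
KTN1_HUMAN,3.78,4.90,3.36,0.41
SEPT2_HUMAN,1.83,2.43,3.82,0.67
UTRO_HUMAN,1.16,6.55,0.27,1.61
SEPT9_HUMAN,2.54,4.38,2.80,0.65
MAP1B_HUMAN,2.80,1.17,0.20,1.80
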