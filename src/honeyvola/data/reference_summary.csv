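compound,compound_class,rt_min,ri,f_value,sig_code,mean_Egypt,sd_Egypt,mean_Morocco,sd_Morocco,mean_Greece,sd_Greece,mean_Spain,sd_Spain,mean_Nectar,sd_Nectar
1-Octanol,alcohol,18.92,1069,4.21,**,0,0,0,0,0,0,0,0,0.003,0.005
1-Nonanol,alcohol,21.04,1170,24.27,***,0,0,0,0,0,0,0,0,0.01,0.01
2-Methylbutanal,aldehyde,6.79,<800,5.11,**,0.07,0.09,0,0,0,0,0,0,0,0
Furfural,aldehyde,13.25,837,3.22,*,0.13,0.17,0.14,0.22,0.01,0.01,0.004,0.01,0.02,0.02
Benzaldehyde,aldehyde,16.75,978,3.65,*,0,0,0.04,0.05,0.04,0.02,0.004,0.01,0.07,0.09
Octanal,aldehyde,17.45,1005,1.58,ns,0,0,0.01,0.02,0.02,0.03,0,0,0.01,0.01
Benzeneacetaldehyde,aldehyde,18.58,1059,5.88,**,0,0,0.10,0.09,0.10,0.11,0.003,0.01,0.46,0.50
Nonanal,aldehyde,19.64,1107,7.58,***,0,0,0.09,0.05,0.15,0.11,0.03,0.06,0,0
"Lilac aldehyde (isomer I, A)",aldehyde,20.57,1147,0.89,ns,0.13,0.23,0.06,0.09,0.05,0.14,0.10,0.09,0,0
"Lilac aldehyde (isomer II, B)",aldehyde,20.63,1149,3.89,**,0.06,0.08,0.06,0.11,0.24,0.22,0.06,0.06,0.04,0.06
"Lilac aldehyde (isomer III, C)",aldehyde,20.76,1156,2.75,*,0.14,0.07,0.27,0.09,0.31,0.35,0.09,0.08,0,0
"Lilac aldehyde (isomer IV, D)",aldehyde,21.17,1176,49.19,***,0,0,0,0,0,0,0.06,0.02,0,0
Decanal,aldehyde,21.77,1209,3.48,*,0,0,0,0,0.09,0.13,0,0,0.03,0.02
"α,4-Dimethyl-3-cyclohexene-1-acetaldehyde",aldehyde,22.31,1234,6.41,***,0.05,0.07,0.07,0.04,0.003,0.01,0.06,0.04,0.003,0.005
Heptane,hydrocarbon,9.49,<800,7.92,***,0.09,0.05,0.05,0.06,0,0,0.04,0.06,0,0
Octane,hydrocarbon,12.26,800,3.18,*,0.01,0.02,0.01,0.02,0.03,0.02,0.01,0.01,0.04,0.02
Nonane,hydrocarbon,14.94,900,1.56,ns,0,0,0,0,0.02,0.03,0,0,0.001,0.01
Delta-3-carene,hydrocarbon,17.94,1024,16.84,***,0,0,0,0,0,0,0,0,0.007,0.005
Undecane,hydrocarbon,19.59,1099,16.84,***,0,0,0,0,0,0,0,0,0.007,0.005
Dill ether,ether,21.72,1203,22.42,***,0.11,0.08,0.13,0.05,0,0,0.07,0.03,0.003,0.005
Ethyl hexanoate,ester,17.25,993,4.21,**,0,0,0,0,0,0,0,0,0.003,0.005
Ethyl malonate,ester,18.67,1044,4.21,**,0,0,0,0,0,0,0,0,0.003,0.005
Ethyl heptanoate,ester,19.44,1092,16.84,***,0,0,0,0,0,0,0,0,0.007,0.005
Ethyl octanoate,ester,21.36,1191,7.94,***,0,0,0.01,0.01,0.03,0.02,0.003,0.009,0.03,0.02
Ethyl nonanoate,ester,23.26,1290,2.89,*,0.03,0.05,0.01,0.02,0.04,0.03,0.02,0.02,0.07,0.05
Methyl anthranilate,ester,24.74,1366,2.06,ns,0.03,0.05,0,0,0.02,0.03,0,0,0,0
Ethyl decanoate,ester,25.05,1389,1.02,ns,0.04,0.09,0,0,0.02,0.02,0.09,0.02,0.04,0.01
Ethyl dodecanoate,ester,28.42,1588,12.42,***,0,0,0,0,0.003,0.004,0,0,0.01,0.00
Ethyl hexadecanoate,ester,34.94,1990,1.29,ns,0,0,0,0,0.002,0.004,0,0,0,0
6-Methyl-5-hepten-2-one,ketone,17.06,986,2.85,*,0,0,0,0,0.001,0.002,0,0,0,0
β-Damascenone,ketone,25.37,1401,1.75,ns,0,0,0,0,0.003,0.06,0,0,0.003,0.005
Benzeneethanol,phenolic,20.20,1129,7.16,***,0,0,0,0,0,0,0,0,0.07,0.09
Benzeneacetonitrile,phenolic,20.71,1154,7.35,***,0,0,0,0,0,0,0,0,0.04,0.05
"3,4,5-Trimethylphenol",phenolic,24.10,1330,1.16,ns,0,0,0,0,0.003,0.005,0,0,0.002,0.004
α-Pinene,terpene,16.18,949,3.38,*,0,0,0,0,0.01,0.09,0,0,0.01,0.004
Herboxide isomer II,terpene,17.55,1007,4.92,**,0.05,0.05,0.10,0.13,0.01,0.01,0.08,0.06,0.003,0.01
Para-cymene,terpene,18.13,1038,2.24,ns,0,0,0.03,0.05,0.03,0.03,0.03,0.05,0,0
dL-Limonene,terpene,18.25,1044,0.86,ns,0.01,0.02,0.01,0.01,0.002,0.003,0,0,0,0
cis-Linalool oxide,terpene,19.11,1077,9.02,***,0.08,0.08,0.11,0.04,0.02,0.01,0.04,0.02,0.003,0.01
Linalool,terpene,19.54,1103,4.29,**,0.04,0.05,0.02,0.02,0.07,0.03,0.06,0.02,0.02,0.03
Hotrienol,terpene,19.63,1104,1.47,ns,0,0,0.01,0.02,0,0,0.02,0.03,0.03,0.08
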