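# Synthetic stand-in candidate panel: 41 cohort gene ids mirroring the
# size of a GWAS type-1-diabetes candidate list. Edit freely; one id per line.
G00007
G00012
G00021
G00030
G00032
G00042
G00043
G00057
G00060
G00062
G00063
G00078
G00081
G00089
G00090
G00097
G00106
G00107
G00112
G00113
G00117
G00126
G00127
G00133
G00135
G00139
G00144
G00146
G00151
G00153
G00154
G00158
G00168
G00177
G00178
G00180
G00182
G00187
G00195
G00198
G00200
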